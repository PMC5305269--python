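"""Forward predictions and least-squares estimation of the two-mechanism
mutation model."""

import numpy as np
import pytest

import varscape as vs
from varscape.mutation_model import (MutationModelParams, expected_counts,
                                     expected_proportion, fit_composition,
                                     fit_distribution, fit_F_given_R,
                                     fold_difference, morgan_fraction,
                                     scan_R_range, summarize_fits)


def toy_params(R=10.0, M_d=205.0, fm_snp=0.67, fs_snp=0.72):
    F_M = {"SNP_Ts": fm_snp / 2, "SNP_Tv": fm_snp / 2, "i1": 1 - fm_snp}
    F_S = {"SNP_Ts": fs_snp / 2, "SNP_Tv": fs_snp / 2, "i1": 1 - fs_snp}
    return MutationModelParams(R=R, M_d=M_d, F_M=F_M, F_S=F_S)


class TestForward:
    def test_expected_count_example(self):
        assert expected_counts(2.0, 1.0, toy_params()) == pytest.approx(2460)

    def test_zero_everything(self):
        p = toy_params(R=0.0, M_d=0.0)
        assert expected_counts(0.0, 1.0, p) == 0.0

    def test_density_linear_in_r(self):
        p = toy_params()
        r = np.array([0.0, 1.0, 5.0])
        dens = expected_counts(r, 1.0, p)
        slope, intercept = np.polyfit(r, dens, 1)
        assert slope == pytest.approx(p.M_d)
        assert intercept / slope == pytest.approx(p.R)

    def test_proportion_limits(self):
        p = toy_params()
        assert expected_proportion(0.0, p, "SNP") == pytest.approx(0.72)
        assert expected_proportion(1e9, p, "SNP") == pytest.approx(0.67,
                                                                   abs=1e-6)

    def test_equal_f_constant(self):
        p = toy_params(fm_snp=0.7, fs_snp=0.7)
        r = np.linspace(0, 50, 11)
        assert expected_proportion(r, p, "SNP") == pytest.approx(0.7)

    def test_proportion_worked_value(self):
        # (3*0.67 + 10*0.72) / 13
        assert expected_proportion(3.0, toy_params(), "SNP") == pytest.approx(
            0.7085, abs=1e-4)

    def test_monotone_and_bounded_across_landscapes(self, rng):
        for _ in range(50):
            fm, fs = rng.uniform(0.05, 0.95, 2)
            R = rng.uniform(0.1, 50)
            p = toy_params(R=R, fm_snp=fm, fs_snp=fs)
            r = np.sort(rng.uniform(0, 12, 30))
            f = expected_proportion(r, p, "SNP")
            assert np.all(f >= min(fm, fs) - 1e-12)
            assert np.all(f <= max(fm, fs) + 1e-12)
            diffs = np.diff(f)
            assert np.all(diffs * np.sign(fm - fs) >= -1e-12)
            if abs(fm - fs) > 0.01:
                coef = np.corrcoef(r, f)[0, 1]
                assert np.sign(coef) == np.sign(fm - fs)

    def test_renormalized_denominator_matches_count_ratio(self):
        p = toy_params()
        r = 4.0
        ts = expected_proportion(r, p, "SNP_Ts", "SNP")
        num = r * p.F_M["SNP_Ts"] + p.R * p.F_S["SNP_Ts"]
        den = (r * (p.F_M["SNP_Ts"] + p.F_M["SNP_Tv"])
               + p.R * (p.F_S["SNP_Ts"] + p.F_S["SNP_Tv"]))
        assert ts == pytest.approx(num / den)


class TestFoldDifferenceAndFraction:
    def test_fold_examples(self):
        assert fold_difference(10, 0, 10) == pytest.approx(2.0)
        assert fold_difference(10, 0, 3.5) == pytest.approx(13.5 / 3.5)

    def test_fold_limit_large_R(self):
        assert fold_difference(10, 0, 1e9) == pytest.approx(1.0, abs=1e-6)

    def test_morgan_fraction_values(self):
        assert morgan_fraction(300.0, 0.0, n_total_Mb=100.0) == 1.0
        assert morgan_fraction(300.0, 10.0, n_total_Mb=100.0) == pytest.approx(
            0.230769, abs=1e-6)

    def test_morgan_fraction_from_intervals(self, arm_center_genome):
        ivs = vs.build_intervals(arm_center_genome.maps, "pf")
        G = sum(m.genetic_length for m in arm_center_genome.maps)
        N = sum(m.length for m in arm_center_genome.maps) / 1e6
        assert morgan_fraction(ivs, 10.0) == pytest.approx(G / (G + 10 * N))


class TestFitComposition:
    R_GRID = np.array([0.0, 2.0, 5.0, 10.0])

    def test_noiseless_exact_recovery(self):
        f = (self.R_GRID * 0.67 + 10 * 0.72) / (self.R_GRID + 10)
        fr = fit_composition(self.R_GRID, f)
        assert fr["R"] == pytest.approx(10.0, abs=1e-6)
        assert fr["F_M"] == pytest.approx(0.67, abs=1e-6)
        assert fr["F_S"] == pytest.approx(0.72, abs=1e-6)

    def test_flat_data_unidentifiable_R(self):
        f = np.full(6, 0.7)
        fr = fit_composition(np.array([0, 1, 2, 4, 6, 8.0]), f)
        assert fr["F_M"] == pytest.approx(fr["F_S"], abs=1e-4)
        assert abs(fr.t["R"]) < 1e-3 or fr.se["R"] > 1e3

    def test_too_few_rates_rejected(self):
        with pytest.raises(ValueError):
            fit_composition(np.array([1, 1, 2, 2.0]), np.full(4, 0.5))

    def test_out_of_range_F_reported_unclamped(self):
        r = np.linspace(0.4, 10, 20)
        f = (r * 0.0002 + 10 * 0.02) / (r + 10)
        fr = fit_F_given_R(r, f, R=9900.0)
        assert fr["F_M"] < 0  # reported, not clamped


class TestFitDistribution:
    def test_noiseless_matches_ols_oracle(self, rng):
        r = np.sort(rng.uniform(0, 10, 25))
        n = rng.uniform(0.5, 1.2, 25)
        y = (r + 3.5) * n * 1500
        fr = fit_distribution(r, n, y)
        assert fr["R"] == pytest.approx(3.5, abs=1e-6)
        assert fr["M_d"] == pytest.approx(1500, abs=1e-3)
        # independent closed form: OLS of density on r
        slope, intercept = np.polyfit(r, y / n, 1)
        assert fr["M_d"] == pytest.approx(slope)
        assert fr["R"] == pytest.approx(intercept / slope)

    def test_no_r_dependence_flagged(self):
        r = np.array([0, 2, 5, 8.0])
        fr = fit_distribution(r, np.ones(4), np.full(4, 100.0))
        assert not fr.converged
        assert fr["R"] == np.inf


class TestFitFGivenR:
    def test_true_R_recovers_F(self):
        r = np.linspace(0, 10, 12)
        f = (r * 0.67 + 10 * 0.72) / (r + 10)
        fr = fit_F_given_R(r, f, R=10.0)
        assert fr["F_M"] == pytest.approx(0.67, abs=1e-9)
        assert fr["F_S"] == pytest.approx(0.72, abs=1e-9)

    def test_extreme_presumed_R_exits_unit_interval(self):
        r = np.linspace(0.4, 10, 20)
        f = (r * 0.01 + 10 * 0.99) / (r + 10)
        fr = fit_F_given_R(r, f, R=0.01)
        assert not (0 <= fr["F_M"] <= 1 and 0 <= fr["F_S"] <= 1)

    def test_self_consistency_with_full_fit(self, rng):
        r = np.sort(rng.uniform(0, 10, 30))
        f = (r * 0.6 + 8 * 0.8) / (r + 8) + rng.normal(0, 1e-3, 30)
        full = fit_composition(r, f)
        fixed = fit_F_given_R(r, f, R=full["R"])
        assert fixed["F_M"] == pytest.approx(full["F_M"], abs=1e-6)
        assert fixed["F_S"] == pytest.approx(full["F_S"], abs=1e-6)


class TestScanR:
    def test_truth_acceptable_single_definition(self):
        r = np.linspace(0, 10, 15)
        f = (r * 0.67 + 10 * 0.72) / (r + 10)
        res = scan_R_range({"SNP/variants": (r, f)},
                           grid=np.array([0.1, 1.0, 10.0, 100.0]))
        assert res["acceptable"][2]

    def test_two_sided_range_contains_truth(self):
        r = np.linspace(0.4, 10, 30)
        low_fs = (r * 0.022 + 10 * 0.0002) / (r + 10)   # near-0 F_S type
        low_fm = (r * 0.0002 + 10 * 0.02) / (r + 10)    # near-0 F_M type
        grid = np.unique(np.concatenate([np.geomspace(0.01, 9900, 200), [10.0]]))
        res = scan_R_range({"lo": (r, low_fs), "hi": (r, low_fm)}, grid)
        assert res["R_lo"] is not None
        assert res["R_lo"] > 0.011 and res["R_hi"] < 9000
        assert res["R_lo"] <= 10.0 <= res["R_hi"]

    def test_acceptance_contiguous_on_noiseless_data(self):
        r = np.linspace(0.4, 10, 30)
        f = (r * 0.022 + 10 * 0.0002) / (r + 10)
        res = scan_R_range({"lo": (r, f)})
        mask = res["acceptable"]
        assert (mask[:-1] != mask[1:]).sum() <= 2


class TestSummarize:
    def _fit(self, R, t, p):
        return vs.FitResult(estimates={"R": R}, se={"R": 1.0}, t={"R": t},
                            p={"R": p}, df=10, converged=True, sse=1.0,
                            pseudo_r2=0.5, n_obs=13)

    def test_bh_step_up(self):
        """Step-up over p = (0.01, 0.02, 0.2): at FDR 0.05 the thresholds are
        (0.017, 0.033, 0.05) so only the first two are rejected; at FDR 0.25
        the largest p (0.2) sits below its own threshold 0.25 and the step-up
        rejects all three."""
        fits = [self._fit(1, 5, 0.01), self._fit(2, 4, 0.02),
                self._fit(3, 1.5, 0.2)]
        out = summarize_fits(fits, fdr=0.05)
        assert list(out["bh_significant"]) == [True, True, False]
        out = summarize_fits(fits, fdr=0.25)
        assert list(out["bh_significant"]) == [True, True, True]

    def test_t_cutoff(self):
        fits = [self._fit(1, 0.5, 0.6), self._fit(2, 1.0, 0.3),
                self._fit(3, 2.0, 0.05)]
        out = summarize_fits(fits, t_cutoff=1.0)
        assert out["n_kept"] == 1 and out["median"] == 3

    def test_median_of_survivors(self):
        fits = [self._fit(0.7, 2, 0.04), self._fit(9.6, 3, 0.01),
                self._fit(55.3, 2.5, 0.02)]
        out = summarize_fits(fits, t_cutoff=1.0)
        assert out["median"] == pytest.approx(9.6)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            summarize_fits([])
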