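"""Generator contracts: map construction, model-faithful variant draws,
selection thinning, artifact injection, and file round trips."""

import numpy as np
import pytest
from scipy import stats

import varscape as vs
from varscape.mutation_model import MutationModelParams
from varscape.selection_model import SelectionParams
from varscape.synthetic_data import (SimulationParams, SyntheticGenomeSpec,
                                     apply_selection, inject_artifacts,
                                     make_genome, simulate_variants)


def single_chrom_spec(length=1_000_000, rate=2.0, seed=5, **kw):
    return SyntheticGenomeSpec(chromosomes=[("c", length)],
                               rate_domains={"c": [(length, rate)]},
                               seed=seed, **kw)


class TestMakeGenome:
    def test_constant_rate_map(self):
        g = make_genome(single_chrom_spec(10_000_000, 5.0))
        assert g.maps[0].genetic_length == pytest.approx(50.0)

    def test_three_domain_map(self):
        spec = SyntheticGenomeSpec(
            chromosomes=[("c", 10_000_000)],
            rate_domains={"c": [(3_000_000, 8.0), (4_000_000, 0.5),
                                (3_000_000, 8.0)]}, seed=1)
        g = make_genome(spec)
        assert g.maps[0].genetic_length == pytest.approx(50.0)  # 24 + 2 + 24

    def test_deterministic_given_seed(self, tmp_path):
        spec = single_chrom_spec(300_000)
        a, b = make_genome(spec), make_genome(spec)
        assert a.sequences == b.sequences
        assert np.array_equal(a.chromatin["c"], b.chromatin["c"])
        assert a.features["exon"] == b.features["exon"]
        va = simulate_variants(a, SimulationParams(seed=9))
        vb = simulate_variants(b, SimulationParams(seed=9))
        pa, pb = tmp_path / "a.gff3", tmp_path / "b.gff3"
        vs.write_polymorphism_gff3(pa, va)
        vs.write_polymorphism_gff3(pb, vb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_bad_partition_rejected(self):
        with pytest.raises(ValueError):
            SyntheticGenomeSpec(chromosomes=[("c", 1000)],
                                rate_domains={"c": [(400, 1.0), (500, 1.0)]})

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError):
            SyntheticGenomeSpec(chromosomes=[("c", 0)],
                                rate_domains={"c": []})

    def test_features_within_bounds(self, arm_center_genome):
        for kind, per_chrom in arm_center_genome.features.items():
            for chrom, spans in per_chrom.items():
                L = dict(arm_center_genome.spec.chromosomes)[chrom]
                assert all(0 <= s < e <= L for s, e in spans), kind


class TestSimulateVariants:
    def test_expected_total_count(self):
        g = make_genome(single_chrom_spec())
        p = MutationModelParams(R=10.0, M_d=205.0)
        v = simulate_variants(g, SimulationParams(params=p, seed=6))
        # (r + R) * n * M*d = (2 + 10) * 1 * 205
        assert abs(len(v) - 2460) < 4 * np.sqrt(2460)

    def test_R_zero_tracks_recombination(self):
        spec = SyntheticGenomeSpec(
            chromosomes=[("c", 2_000_000)],
            rate_domains={"c": [(1_000_000, 5.0), (1_000_000, 0.0)]}, seed=2)
        g = make_genome(spec)
        p = MutationModelParams(R=0.0, M_d=300.0)
        v = simulate_variants(g, SimulationParams(params=p, seed=3))
        assert all(x.source == "morgan" for x in v)
        assert all(x.start < 1_000_000 for x in v)  # none in the r=0 domain

    def test_identical_F_gives_uniform_type_mix(self):
        g = make_genome(single_chrom_spec(2_000_000, 4.0))
        F = {"SNP_Ts": 0.35, "SNP_Tv": 0.35, "i1": 0.30}
        p = MutationModelParams(R=10.0, M_d=500.0, F_M=dict(F), F_S=dict(F))
        v = simulate_variants(g, SimulationParams(params=p, seed=7))
        snp = sum(1 for x in v if x.classify().is_snp)
        prop = snp / len(v)
        assert abs(prop - 0.7) < 4 * np.sqrt(0.7 * 0.3 / len(v))

    def test_per_interval_counts_match_model(self):
        """Chi-square goodness of fit of per-window counts against
        (r + R) * n * M*d over 50 one-Mb windows of varying rate."""
        rng = np.random.default_rng(11)
        rates = rng.choice([0.5, 2.0, 7.0], size=50)
        spec = SyntheticGenomeSpec(
            chromosomes=[("c", 50_000_000)],
            rate_domains={"c": [(1_000_000, float(x)) for x in rates]},
            seed=12)
        g = make_genome(spec)
        p = MutationModelParams(R=10.0, M_d=300.0)
        v = simulate_variants(g, SimulationParams(params=p, seed=13))
        ivs = vs.build_intervals(g.maps, "pf")
        recs, w = vs.select_population(v, mode="unique")
        t = vs.count_by_interval(recs, w, ivs)
        obs = t.counts["all"].to_numpy()
        info = t.interval_info
        exp = (info["r"] + p.R) * info["n_Mb"] * p.M_d
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        assert stats.chi2.sf(chi2, len(obs)) > 0.01

    def test_per_interval_proportions_match_model(self, arm_center_genome,
                                                  arm_center_variants):
        ivs = vs.build_intervals(arm_center_genome.maps, "pf")
        recs, w = vs.select_population(arm_center_variants, mode="unique")
        t = vs.count_by_interval(recs, w, ivs)
        p = MutationModelParams(R=10.0, M_d=400.0)
        from varscape.mutation_model import expected_proportion
        for i in range(len(ivs)):
            n_all = t.counts["all"].iloc[i]
            if n_all < 500:
                continue
            f_exp = expected_proportion(t.interval_info["r"].iloc[i], p, "SNP")
            f_obs = t.counts["SNP"].iloc[i] / n_all
            assert abs(f_obs - f_exp) < 5 * np.sqrt(f_exp * (1 - f_exp) / n_all)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            MutationModelParams(R=-1.0)
        with pytest.raises(ValueError):
            MutationModelParams(F_M={"SNP_Ts": 0.5, "i1": 0.2},
                                F_S={"SNP_Ts": 0.5, "i1": 0.5})


class TestApplySelection:
    def test_background_U_zero_is_uniform(self, arm_center_genome,
                                          arm_center_variants):
        sel = SelectionParams(U=0.0, s_d=0.2, c=0.017)
        out = apply_selection(arm_center_variants, "background", sel=sel,
                              seed=1, maps=arm_center_genome.maps)
        # retention probability is 1 everywhere after normalization
        assert len(out) == len(arm_center_variants)

    def test_background_thins_low_recombination_harder(self, arm_center_genome,
                                                       arm_center_variants):
        sel = SelectionParams(U=0.48, s_d=0.05, c=0.017)
        out = apply_selection(arm_center_variants, "background", sel=sel,
                              seed=1, maps=arm_center_genome.maps)
        cmap = arm_center_genome.maps[0]

        def center_fraction(vset):
            mine = [v for v in vset if v.chrom == "c1"]
            return (sum(1 for v in mine if 1.5e6 <= v.start < 4.5e6)
                    / len(mine))

        assert center_fraction(out) < center_fraction(arm_center_variants)

    def test_direct_removal_expectation(self):
        snps = [vs.VariantRecord("c", 10 * i, 10 * i + 1, "A", "G",
                                 frozenset(["iso01"])) for i in range(1000)]
        dels = [vs.VariantRecord("c", 100_000 + 10 * i, 100_000 + 10 * i + 2,
                                 "NN", "", frozenset(["iso01"]))
                for i in range(1000)]
        out = apply_selection(snps + dels, "direct",
                              sel={"non-SNP": 0.5, "SNP": 0.0}, seed=3)
        survivors = len(out)
        assert abs(survivors - 1500) < 4 * np.sqrt(1000 * 0.25)
        assert sum(1 for v in out if v.classify().is_snp) == 1000

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            apply_selection([], "sweeps", sel=None)


class TestArtifacts:
    def test_split_rate_one(self):
        v = vs.VariantRecord("c", 100, 103, "ACG", "GTA",
                             frozenset(["iso01", "iso02"]), id="v1")
        sim = SimulationParams(artifact_rates={"split": 1.0}, seed=0)
        out, ledger = inject_artifacts([v], sim)
        assert len(out) == 3
        assert all(o.classify().is_snp for o in out)
        assert all(o.isolates == v.isolates for o in out)
        assert [o.start for o in out] == [100, 101, 102]
        assert ledger[0]["kind"] == "split"

    def test_zero_rates_identity(self, arm_center_variants):
        sim = SimulationParams(seed=0)
        out, ledger = inject_artifacts(arm_center_variants, sim)
        assert out == arm_center_variants and ledger == []

    def test_corrupt_then_clean_round_trip(self, arm_center_genome):
        """Splitting and overshadow injection are fully undone by adjacent
        combining plus conflict resolution: per-type counts are restored and
        every overshadowed injection is censored."""
        p = MutationModelParams(R=10.0, M_d=60.0)
        clean = simulate_variants(arm_center_genome,
                                  SimulationParams(params=p, seed=21))
        sim = SimulationParams(
            params=p, seed=21,
            artifact_rates={"split": 0.7, "overshadow": 0.5})
        dirty, ledger = inject_artifacts(clean, sim)
        assert len(dirty) > len(clean)

        def type_counts(vset):
            out = {}
            for v in vset:
                for lab in v.classify().type_labels:
                    out[lab] = out.get(lab, 0) + 1
            return out

        recovered = vs.resolve_conflicts(vs.combine_adjacent(dirty))
        baseline = vs.resolve_conflicts(vs.combine_adjacent(clean))
        assert type_counts(recovered) == type_counts(baseline)
        ghost_ids = {i for entry in ledger if entry["kind"] == "overshadow"
                     for i in entry["injected"]}
        assert ghost_ids
        assert not ghost_ids & {v.id for v in recovered}


class TestWriters:
    def test_dataset_round_trip(self, tmp_path):
        from varscape.variant_io import (read_expression_gff3, read_fasta,
                                         read_features_gff3, read_wig_fixed)

        spec = single_chrom_spec(200_000, 3.0)
        g = make_genome(spec)
        v = simulate_variants(g, SimulationParams(seed=4))
        vs.write_dataset(tmp_path, g, v)
        seqs = read_fasta(tmp_path / "genome.fa")
        assert seqs == g.sequences
        feats = read_features_gff3(tmp_path / "features.gff3")
        assert feats["exon"]["c"] == g.features["exon"]["c"]
        expr = read_expression_gff3(tmp_path / "expression.gff3")
        assert [(s, e) for s, e, _ in expr["c"]] == [
            (s, e) for s, e, _ in g.expression["c"]]
        wig = read_wig_fixed(tmp_path / "chromatin.wig")
        assert np.allclose(wig["c"], g.chromatin["c"], atol=1e-4)
        back = vs.parse_polymorphism_gff3(tmp_path / "variants.gff3")
        assert len(back) == len(v)
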