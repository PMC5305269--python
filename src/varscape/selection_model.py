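"""Background-selection coupling of the mutation model.

Background selection removes linked neutral variants around deleterious
mutations, more strongly where recombination is low.  Coupling the classical
reduction factor to the two-mechanism mutation model gives the expected
post-selection count of an interval at recombination rate r:

    v_b = (r + R) * n * M*d * exp(-U / (s_d + r*(1 - F))) / (1 + F)

with U the deleterious mutation rate per generation, s_d the average
selection coefficient against heterozygous deleterious mutations, and F the
inbreeding coefficient, F = (1 - c)/(1 + c) for outcrossing rate c in a
selfing species.  The factor is type-independent, so background selection
reshapes the variant *distribution* but leaves the *composition* untouched.

Direct selection, by contrast, removes types at different rates and distorts
the composition; the closed-form distortion of the fitted coefficients is
implemented in :func:`distortion_apparent_R`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .mutation_model import (FitResult, MutationModelParams, _finish_fit,
                             expected_counts)

__all__ = [
    "SelectionParams",
    "inbreeding_coefficient",
    "bgs_factor",
    "expected_counts_with_bgs",
    "fit_sd",
    "pseudo_r2",
    "distortion_apparent_R",
]


def inbreeding_coefficient(c: float) -> float:
    """F = (1 - c)/(1 + c): full selfing (c=0) gives F=1, full outcrossing
    (c=1) gives F=0."""
    if not 0.0 <= c <= 1.0:
        raise ValueError("outcrossing rate must be in [0, 1]")
    return (1.0 - c) / (1.0 + c)


@dataclass
class SelectionParams:
    """Background-selection parameters.  Defaults follow the accepted
    literature values for C. elegans: U = 0.48 deleterious mutations per
    generation and an outcrossing rate of 1.7%."""

    U: float = 0.48
    s_d: float = 0.2
    c: float = 0.017
    #: scale applied to r inside the exponent (unit knob; the model applies
    #: the cM/Mb value directly by default)
    r_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.U < 0:
            raise ValueError("U must be non-negative")
        if not 0.0 < self.s_d <= 1.0:
            raise ValueError("s_d must be in (0, 1]")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError("outcrossing rate must be in [0, 1]")

    @property
    def F(self) -> float:
        return inbreeding_coefficient(self.c)


def bgs_factor(r, sel: SelectionParams, s_d: float | None = None):
    """Multiplicative diversity reduction exp(-U/(s_d + r(1-F))) / (1+F).

    Lies in (0, 1/(1+F)], increases with r and s_d, decreases with U.
    """
    r = np.asarray(r, dtype=float) * sel.r_scale
    sd = sel.s_d if s_d is None else s_d
    F = sel.F
    denom = sd + r * (1.0 - F)
    if np.any(denom <= 0) and sel.U > 0:
        raise ZeroDivisionError("s_d + r(1-F) must be positive when U > 0")
    out = np.exp(-sel.U / denom) / (1.0 + F)
    return float(out) if out.ndim == 0 else out


def expected_counts_with_bgs(r, n_Mb, params: MutationModelParams,
                             sel: SelectionParams):
    """Expected post-selection count v_b = v_o * bgs_factor.  The factor is
    type-independent: per-type proportions are unchanged."""
    return expected_counts(r, n_Mb, params) * bgs_factor(r, sel)


def pseudo_r2(predicted, observed) -> float:
    """1 - SS_res/SS_tot on the count scale; negative for worse-than-mean
    predictions."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    sst = float(np.sum((observed - observed.mean()) ** 2))
    if sst == 0:
        raise ValueError("zero total variance")
    ssr = float(np.sum((observed - predicted) ** 2))
    return 1.0 - ssr / sst


def fit_sd(r, n_Mb, counts, R_presumed: float, md_grid,
           U: float = 0.48, c: float = 0.017, r_scale: float = 1.0):
    """One-parameter estimation of s_d for each presumed M*d on a grid.

    For each grid value the combined model v_b(r) is fitted to the observed
    per-interval counts by least squares over s_d alone (R, M*d, U, c held
    fixed), reproducing the grid procedure: s_d and M*d are poorly identified
    jointly, so the grid is scanned and the row with the smallest p reported
    as best.  Estimates outside (0, 1] are flagged, not clamped.

    Returns (rows, best_row); each row is a dict with M_d, s_d, se, t, p,
    pseudo_r2, in_range, converged.
    """
    md_grid = np.asarray(md_grid, dtype=float)
    if md_grid.size == 0:
        raise ValueError("empty M*d grid")
    r = np.asarray(r, dtype=float)
    n = np.asarray(n_Mb, dtype=float)
    y = np.asarray(counts, dtype=float)
    F = inbreeding_coefficient(c)

    rows = []
    for md in md_grid:
        base = (r + R_presumed) * n * md / (1.0 + F)

        def resid(theta):
            sd = theta[0]
            denom = sd + r * r_scale * (1.0 - F)
            bad = denom <= 0
            pred = np.where(bad, 1e9,
                            base * np.exp(-U / np.where(bad, 1.0, denom)))
            return pred - y

        best = None
        for sd0 in (0.05, 0.2, 0.5):
            try:
                sol = optimize.least_squares(resid, np.array([sd0]),
                                             method="lm", xtol=1e-12,
                                             ftol=1e-12, max_nfev=2000)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            rows.append({"M_d": float(md), "s_d": np.nan, "se": np.inf,
                         "t": 0.0, "p": 1.0, "pseudo_r2": np.nan,
                         "in_range": False, "converged": False})
            continue
        sd_hat = float(best.x[0])
        res = best.fun
        df = max(len(y) - 1, 1)
        sse = float(res @ res)
        jtj = float((best.jac.T @ best.jac).item())
        se = np.sqrt(sse / df / jtj) if jtj > 0 else np.inf
        t = sd_hat / se if se > 0 else np.inf
        p = float(2 * stats.t.sf(abs(t), df))
        rows.append({
            "M_d": float(md), "s_d": sd_hat, "se": float(se), "t": float(t),
            "p": p, "pseudo_r2": pseudo_r2(y - res, y),
            "in_range": 0.0 < sd_hat <= 1.0, "converged": bool(best.success),
        })
    finite = [row for row in rows if row["converged"]]
    best_row = min(finite, key=lambda row: row["p"]) if finite else None
    return rows, best_row


def distortion_apparent_R(params: MutationModelParams, q: float,
                          numerator: str = "SNP", refit: bool = True,
                          r_grid=None):
    """Apparent coefficients after direct selection removes a fraction q of
    the complement of the numerator class (e.g. q of the indels, none of the
    SNPs).

    With F the numerator-class probability of each mechanism, the surviving
    proportion curve is exactly the model curve with

        R'   = R * (1 - q*(1 - F_S)) / (1 - q*(1 - F_M))
        F_M' = F_M / (1 - q*(1 - F_M))
        F_S' = F_S / (1 - q*(1 - F_S))

    so type-biased removal masquerades as a shifted R.  When ``refit`` is
    true the closed form is verified by regenerating noiseless proportions on
    an r grid and re-estimating with the LM composition fit.
    """
    sets_fm = sum(v for k, v in params.F_M.items()
                  if k.startswith("SNP")) if numerator == "SNP" else params.F_M[numerator]
    sets_fs = sum(v for k, v in params.F_S.items()
                  if k.startswith("SNP")) if numerator == "SNP" else params.F_S[numerator]
    fm, fs = float(sets_fm), float(sets_fs)
    a = 1.0 - q * (1.0 - fm)
    b = 1.0 - q * (1.0 - fs)
    if a <= 0 or b <= 0:
        raise ZeroDivisionError("q = 1 with F = 0: all variants removed")
    R_prime = params.R * b / a
    fm_prime = fm / a
    fs_prime = fs / b
    out = {"R_prime": R_prime, "F_M_prime": fm_prime, "F_S_prime": fs_prime}
    if refit:
        from .mutation_model import fit_composition

        r = np.linspace(0.0, 12.0, 25) if r_grid is None else np.asarray(r_grid)
        f = (r * fm_prime + R_prime * fs_prime) / (r + R_prime)
        fr = fit_composition(r, f)
        out["refit"] = fr
        out["refit_max_abs_diff"] = max(
            abs(fr["R"] - R_prime),
            abs(fr["F_M"] - fm_prime),
            abs(fr["F_S"] - fs_prime),
        )
    return out
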