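"""The two-mechanism (Morgan/Sanger) mutation model and its estimation.

The model splits mutation processes into a class whose output scales with
genetic distance g in cM (Morgan mechanism, coefficient M — anchored to
programmed meiotic double-strand breaks) and a class whose output scales with
physical distance n in Mb (Sanger mechanism, coefficient S — e.g. replication
errors).  With R = S/M (cM/Mb) and d generations of divergence, an interval
with recombination rate r = g/n accumulates

    v_o = (r + R) * n * M * d                      (expected variant count)

variants, and the expected proportion of a variant type with per-mechanism
generation probabilities F_M and F_S is

    f_o = (r * F_M + R * F_S) / (r + R).

Only the product M*d is identifiable from a single dataset.  Estimation is
unconstrained Levenberg-Marquardt least squares over intervals, with standard
errors from the Jacobian at the optimum; out-of-range F estimates are
reported, not clamped — an F outside [0, 1] is the model's own signal that a
presumed R is unacceptable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "MutationModelParams",
    "FitResult",
    "DEFAULT_F_M",
    "DEFAULT_F_S",
    "expected_counts",
    "expected_proportion",
    "fit_composition",
    "fit_distribution",
    "fit_F_given_R",
    "scan_R_range",
    "morgan_fraction",
    "fold_difference",
    "summarize_fits",
]

# Per-type generation probabilities for the two mechanisms.  SNP totals and
# i40-699 entries follow the published point estimates (F_M(SNP) = 0.67,
# F_S(SNP) = 0.72; F_M(i40-699) = 0.022, F_S(i40-699) = 0.005); the SNP mass
# is split Ts/Tv and the remaining mass spread over the small-indel classes
# in decreasing order of size.  Each table sums to 1.
DEFAULT_F_M = {
    "SNP_Ts": 0.67 * 0.55,
    "SNP_Tv": 0.67 * 0.45,
    "i0": 0.010,
    "i1": 0.110,
    "i2": 0.055,
    "i3": 0.034,
    "i4": 0.022,
    "i5-9": 0.030,
    "i10-19": 0.017,
    "i20-39": 0.010,
    "i40-699": 0.022,
    "i700-4999": 0.020,
}
DEFAULT_F_S = {
    "SNP_Ts": 0.72 * 0.60,
    "SNP_Tv": 0.72 * 0.40,
    "i0": 0.008,
    "i1": 0.130,
    "i2": 0.060,
    "i3": 0.030,
    "i4": 0.018,
    "i5-9": 0.018,
    "i10-19": 0.006,
    "i20-39": 0.004,
    "i40-699": 0.005,
    "i700-4999": 0.001,
}


@dataclass
class MutationModelParams:
    """Full parameterization: R (cM/Mb), the product M*d (variants per cM),
    and the per-type generation probability tables."""

    R: float = 10.0
    M_d: float = 205.0
    F_M: dict = field(default_factory=lambda: dict(DEFAULT_F_M))
    F_S: dict = field(default_factory=lambda: dict(DEFAULT_F_S))

    def __post_init__(self) -> None:
        if self.R < 0 or self.M_d < 0:
            raise ValueError("R and M*d must be non-negative")
        for name, table in (("F_M", self.F_M), ("F_S", self.F_S)):
            if any(p < 0 or p > 1 for p in table.values()):
                raise ValueError(f"{name} entries must be in [0, 1]")
            if not math.isclose(sum(table.values()), 1.0, abs_tol=1e-6):
                raise ValueError(f"{name} must sum to 1")
        if set(self.F_M) != set(self.F_S):
            raise ValueError("F_M and F_S must share the same type labels")

    def type_labels(self) -> tuple[str, ...]:
        return tuple(self.F_M)


@dataclass
class FitResult:
    estimates: dict
    se: dict
    t: dict
    p: dict
    df: int
    converged: bool
    sse: float
    pseudo_r2: float
    n_obs: int
    aggregated: bool = False  # pooled multi-scheme rows: p values carry a caveat

    def __getitem__(self, name: str) -> float:
        return self.estimates[name]


# ---------------------------------------------------------------------------
# Forward predictions


def expected_counts(r, n_Mb, params: MutationModelParams):
    """Expected variant count of an interval: (r + R) * n * M*d."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n_Mb, dtype=float)
    if np.any(r < 0) or np.any(n < 0):
        raise ValueError("negative recombination rate or length")
    out = (r + params.R) * n * params.M_d
    return float(out) if out.ndim == 0 else out


def _denominator_sets(labels):
    snp = {l for l in labels if l.startswith("SNP")}
    return {"all": set(labels), "SNP": snp, "non-SNP": set(labels) - snp}


def expected_proportion(r, params: MutationModelParams, type_label: str,
                        denominator: str = "all"):
    """Expected proportion of one type: (r*F_M + R*F_S) / (r + R).

    For denominators other than all variants the F tables are renormalized
    over the denominator set and R is rescaled to the effective
    R * F_S(D) / F_M(D) — algebraically identical to the exact count ratio.
    """
    r = np.asarray(r, dtype=float)
    sets = _denominator_sets(params.type_labels())
    if denominator not in sets:
        raise ValueError(f"unknown denominator {denominator!r}")
    den = sets[denominator]
    if type_label in sets:  # composite numerator (SNP / non-SNP / all)
        num = sets[type_label]
    elif type_label in params.F_M:
        num = {type_label}
    else:
        raise ValueError(f"unknown type label {type_label!r}")
    if not num <= den:
        raise ValueError(f"{type_label!r} is not part of denominator {denominator!r}")
    fm_den = sum(params.F_M[l] for l in den)
    fs_den = sum(params.F_S[l] for l in den)
    fm = sum(params.F_M[l] for l in num) / fm_den
    fs = sum(params.F_S[l] for l in num) / fs_den
    R_eff = params.R * fs_den / fm_den
    if np.any(r + R_eff == 0):
        raise ZeroDivisionError("r + R = 0: proportion undefined")
    out = (r * fm + R_eff * fs) / (r + R_eff)
    return float(out) if out.ndim == 0 else out


def fold_difference(r_hi: float, r_lo: float, R: float) -> float:
    """Predicted ratio of variant density between two recombination rates:
    (r_hi + R) / (r_lo + R).  Large R makes mutation position-independent
    (ratio -> 1); small R concentrates variants in high-recombination DNA."""
    if r_lo + R == 0:
        raise ZeroDivisionError("r_lo + R = 0")
    if R < 0:
        raise ValueError("R must be non-negative")
    return (r_hi + R) / (r_lo + R)


def morgan_fraction(intervals_or_g, R: float, n_total_Mb: float | None = None) -> float:
    """Fraction of all variants of Morgan (genetic-distance) origin:
    sum(g_i) / (sum(g_i) + R * sum(n_i)).

    Accepts either a collection of intervals or explicit totals
    (g_total_cM, R, n_total_Mb).
    """
    if R < 0:
        raise ValueError("R must be non-negative")
    if n_total_Mb is None:
        G = sum(iv.g for iv in intervals_or_g)
        N = sum(iv.n for iv in intervals_or_g)
    else:
        G, N = float(intervals_or_g), float(n_total_Mb)
    return G / (G + R * N)


# ---------------------------------------------------------------------------
# Least-squares machinery


def _finish_fit(names, theta, jac, resid, n_obs, y, aggregated=False,
                converged=True):
    p = len(names)
    df = max(n_obs - p, 1)
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    try:
        cov = np.linalg.inv(jac.T @ jac) * (sse / df)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, theta / se, np.inf)
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    return FitResult(
        estimates=dict(zip(names, map(float, theta))),
        se=dict(zip(names, map(float, se))),
        t=dict(zip(names, map(float, tvals))),
        p=dict(zip(names, map(float, pvals))),
        df=df,
        converged=converged,
        sse=sse,
        pseudo_r2=1.0 - sse / sst if sst > 0 else np.nan,
        n_obs=n_obs,
        aggregated=aggregated,
    )


def _clean_xy(*arrays):
    arrays = [np.asarray(a, dtype=float) for a in arrays]
    keep = np.logical_and.reduce([np.isfinite(a) for a in arrays])
    return [a[keep] for a in arrays]


def fit_composition(r, f, weights=None, starts=(0.1, 1.0, 10.0, 100.0),
                    aggregated: bool = False) -> FitResult:
    """Levenberg-Marquardt fit of the 3-parameter proportion curve
    f(r) = (r*F_M + R*F_S) / (r + R) to per-interval proportions.

    Multi-start over the R grid; the best SSE solution is kept.  F estimates
    outside [0, 1] are reported as-is.
    """
    if weights is None:
        r, f = _clean_xy(r, f)
        w = np.ones_like(r)
    else:
        r, f, w = _clean_xy(r, f, weights)
        w = np.sqrt(w)
    if len(r) < 4:
        raise ValueError("need at least 4 intervals")
    if len(np.unique(r)) < 3:
        raise ValueError("need at least 3 distinct recombination rates")

    def resid(theta):
        R, fm, fs = theta
        denom = r + R
        bad = denom <= 0
        out = np.where(bad, 1e6, (r * fm + R * fs) / np.where(bad, 1.0, denom) - f)
        return out * w

    best = None
    for R0 in starts:
        lin = _solve_F_linear(r, f, R0, w)
        x0 = np.array([R0, lin[0], lin[1]])
        try:
            sol = optimize.least_squares(resid, x0, method="lm", xtol=1e-12,
                                         ftol=1e-12, max_nfev=5000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return FitResult({}, {}, {}, {}, df=max(len(r) - 3, 1), converged=False,
                         sse=np.inf, pseudo_r2=np.nan, n_obs=len(r),
                         aggregated=aggregated)
    return _finish_fit(("R", "F_M", "F_S"), best.x, best.jac, best.fun,
                       len(r), f * w, aggregated=aggregated,
                       converged=bool(best.success))


def fit_distribution(r, n_Mb, counts, starts=None,
                     aggregated: bool = False) -> FitResult:
    """Fit count = (r + R) * n * M*d over intervals.

    The model is linear in r on the density scale, so the fit is seeded by
    OLS of count/n on r (slope = M*d, intercept = M*d * R) and polished by
    Levenberg-Marquardt for the same SE/t/p machinery as the composition fit.
    A fit with no r dependence (slope <= 0) is flagged unidentifiable.
    """
    r, n, y = _clean_xy(r, n_Mb, counts)
    if len(r) < 4:
        raise ValueError("need at least 4 intervals")
    if len(np.unique(r)) < 3:
        raise ValueError("need at least 3 distinct recombination rates")
    dens = y / n
    ols = np.polyfit(r, dens, 1)
    slope, intercept = float(ols[0]), float(ols[1])
    # no usable r dependence: slope at or below zero, or an implied R far
    # beyond any biologically meaningful value
    if slope <= 0 or not np.isfinite(intercept / slope) or intercept / slope > 1e6:
        return FitResult(
            estimates={"R": np.inf, "M_d": max(dens.mean(), 0.0)},
            se={"R": np.inf, "M_d": np.inf},
            t={"R": 0.0, "M_d": 0.0}, p={"R": 1.0, "M_d": 1.0},
            df=max(len(r) - 2, 1), converged=False, sse=np.nan,
            pseudo_r2=np.nan, n_obs=len(r), aggregated=aggregated,
        )

    def resid(theta):
        R, md = theta
        return (r + R) * n * md - y

    x0 = np.array([max(intercept / slope, 1e-6), slope])
    sol = optimize.least_squares(resid, x0, method="lm", xtol=1e-12,
                                 ftol=1e-12, max_nfev=5000)
    return _finish_fit(("R", "M_d"), sol.x, sol.jac, sol.fun, len(r), y,
                       aggregated=aggregated, converged=bool(sol.success))


def _solve_F_linear(r, f, R, w=None):
    """Closed-form weighted LS for (F_M, F_S) at fixed R: the model is linear
    in the F coefficients, f = F_M * r/(r+R) + F_S * R/(r+R)."""
    X = np.column_stack([r / (r + R), R / (r + R)])
    if w is not None:
        X = X * w[:, None]
        f = f * w
    beta, *_ = np.linalg.lstsq(X, f, rcond=None)
    return beta


def fit_F_given_R(r, f, R: float, aggregated: bool = False) -> FitResult:
    """Two-parameter fit of (F_M, F_S) with R presumed and held fixed."""
    r, f = _clean_xy(r, f)
    if len(r) < 3:
        raise ValueError("need at least 3 intervals")
    X = np.column_stack([r / (r + R), R / (r + R)])
    beta, *_ = np.linalg.lstsq(X, f, rcond=None)
    resid = X @ beta - f
    return _finish_fit(("F_M", "F_S"), beta, X, resid, len(r), f,
                       aggregated=aggregated)


def scan_R_range(proportion_sets, grid=None):
    """Acceptable-R scan: a presumed R is acceptable iff, for every supplied
    proportion definition, the fitted F_M and F_S both land inside [0, 1].

    ``proportion_sets`` maps a definition label to its (r, f) arrays.  The
    default grid is log-spaced over [0.01, 9900].  Returns a dict with the
    grid, the acceptance mask, and the extreme acceptable values (None if the
    acceptable set is empty).
    """
    if grid is None:
        grid = np.geomspace(0.01, 9900.0, 200)
    grid = np.asarray(grid, dtype=float)
    mask = np.ones(len(grid), dtype=bool)
    for label, (r, f) in proportion_sets.items():
        r, f = _clean_xy(r, f)
        for i, R in enumerate(grid):
            if not mask[i]:
                continue
            fm, fs = _solve_F_linear(r, f, R)
            if not (0.0 <= fm <= 1.0 and 0.0 <= fs <= 1.0):
                mask[i] = False
    if not mask.any():
        return {"grid": grid, "acceptable": mask, "R_lo": None, "R_hi": None}
    acc = grid[mask]
    return {"grid": grid, "acceptable": mask,
            "R_lo": float(acc.min()), "R_hi": float(acc.max())}


def summarize_fits(fits, t_cutoff=None, p_cutoff=None, fdr=None,
                   param: str = "R"):
    """Filter a collection of fits and summarize the surviving estimates.

    Applies |t| > t_cutoff and/or p < p_cutoff filters on the chosen
    parameter, optionally a Benjamini-Hochberg significance call at the given
    FDR, and reports the median and quartiles of the surviving estimates.
    """
    from statsmodels.stats.multitest import multipletests

    fits = list(fits)
    if not fits:
        raise ValueError("empty fit collection")
    keep = []
    for fr in fits:
        if not fr.converged or param not in fr.estimates:
            continue
        if t_cutoff is not None and not abs(fr.t[param]) > t_cutoff:
            continue
        if p_cutoff is not None and not fr.p[param] < p_cutoff:
            continue
        keep.append(fr)
    values = np.array([fr.estimates[param] for fr in keep])
    out = {
        "n_total": len(fits),
        "n_kept": len(keep),
        "kept": keep,
        "median": float(np.median(values)) if len(values) else np.nan,
        "q1": float(np.percentile(values, 25)) if len(values) else np.nan,
        "q3": float(np.percentile(values, 75)) if len(values) else np.nan,
        "aggregated_caveat": any(fr.aggregated for fr in keep),
    }
    if fdr is not None:
        pvals = np.array([fr.p[param] for fr in fits
                          if fr.converged and param in fr.p])
        rej, _, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
        out["bh_significant"] = rej
        out["bh_fdr"] = fdr
    return out
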