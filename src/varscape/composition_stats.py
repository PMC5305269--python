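"""Per-interval variant counting, the variant-proportion metric, and the
correlation / regression / t-test screens.

A *proportion* is the fraction of one variant type within a broader set
(all variants, all non-SNPs, or all SNPs) inside one genomic interval, e.g.
an interval with 70 SNPs and 30 indels of which one is an i40-699 has an
i40-699/all-variants proportion of 1%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .variant_io import DEFAULT_SIZE_SCHEME, SizeClassScheme

__all__ = [
    "CompositionTable",
    "ProportionDefinition",
    "count_by_interval",
    "proportions",
    "correlate",
    "linear_fit",
    "group_difference_test",
]

#: Valid denominator labels for a proportion definition.
DENOMINATORS = ("all", "non-SNP", "SNP")


@dataclass
class ProportionDefinition:
    numerator: str
    denominator: str = "all"
    min_count: int = 300

    def __post_init__(self) -> None:
        if self.denominator not in DENOMINATORS:
            raise ValueError(f"denominator must be one of {DENOMINATORS}")
        if self.denominator == "SNP" and self.numerator not in ("SNP_Ts", "SNP_Tv"):
            raise ValueError("SNP denominator takes Ts/Tv numerators only")

    @property
    def label(self) -> str:
        short = {"SNP_Ts": "Ts", "SNP_Tv": "Tv"}.get(self.numerator, self.numerator)
        den = {"all": "variants", "non-SNP": "non-SNPs", "SNP": "SNPs"}[self.denominator]
        return f"{short}/{den}"


@dataclass
class CompositionTable:
    """Per-interval counts by variant-type label.

    ``counts`` has one row per interval and one column per label (the three
    denominators plus SNP_Ts/SNP_Tv and every size-class label; overlapping
    size classes are counted independently).  ``interval_info`` carries the
    matching (scheme, chrom, bounds, n, g, r) rows.
    """

    counts: pd.DataFrame
    interval_info: pd.DataFrame
    mode: str = "unique"
    meta: dict = field(default_factory=dict)


def count_by_interval(
    records,
    weights,
    intervals,
    scheme: SizeClassScheme = DEFAULT_SIZE_SCHEME,
) -> CompositionTable:
    """Count a weighted working set into interval rows.

    A variant is counted in an interval only if both of its endpoints lie
    within the interval; boundary-straddling variants are counted nowhere.
    When the interval list pools several boundary schemes, a variant is
    counted once per scheme (the schemes tile the chromosome independently).
    """
    import bisect

    labels = ["all", "SNP", "non-SNP", "SNP_Ts", "SNP_Tv", *scheme.labels]
    chroms = {iv.chrom for iv in intervals}
    lookup: dict[tuple, tuple[list, list]] = {}
    for idx, iv in enumerate(intervals):
        starts, items = lookup.setdefault((iv.chrom, iv.scheme), ([], []))
        starts.append(iv.phys_start)
        items.append((idx, iv))
    for starts, items in lookup.values():
        order = np.argsort(starts)
        starts[:] = [starts[i] for i in order]
        items[:] = [items[i] for i in order]

    counts = np.zeros((len(intervals), len(labels)))
    col = {lab: j for j, lab in enumerate(labels)}
    for rec, w in zip(records, weights):
        if rec.chrom not in chroms:
            raise KeyError(f"variant on unknown chromosome {rec.chrom!r}")
        vc = rec.classify(scheme)
        for (chrom, _), (starts, items) in lookup.items():
            if chrom != rec.chrom:
                continue
            k = bisect.bisect_right(starts, rec.start) - 1
            if k < 0:
                continue
            idx, iv = items[k]
            if iv.contains(rec.start, rec.end):
                for lab in vc.type_labels:
                    counts[idx, col[lab]] += w

    info = pd.DataFrame(
        {
            "scheme": [iv.scheme for iv in intervals],
            "chrom": [iv.chrom for iv in intervals],
            "phys_start": [iv.phys_start for iv in intervals],
            "phys_end": [iv.phys_end for iv in intervals],
            "n_Mb": [iv.n for iv in intervals],
            "g_cM": [iv.g for iv in intervals],
            "r": [iv.r for iv in intervals],
        }
    )
    return CompositionTable(
        counts=pd.DataFrame(counts, columns=labels),
        interval_info=info,
    )


def proportions(table: CompositionTable, defs) -> pd.DataFrame:
    """Per-interval proportion matrix, one column per definition.

    Intervals whose denominator count falls below the definition's
    ``min_count`` are dropped (NaN) for that definition.
    """
    out = {}
    for d in defs:
        num = table.counts[d.numerator].to_numpy(dtype=float)
        den = table.counts[d.denominator].to_numpy(dtype=float)
        ok = den >= max(d.min_count, 1)
        if np.any(den == 0):
            warnings.warn(f"{int((den == 0).sum())} interval(s) with zero "
                          f"{d.denominator} count dropped for {d.label}")
        vals = np.full(len(den), np.nan)
        vals[ok] = num[ok] / den[ok]
        out[d.label] = vals
    return pd.DataFrame(out, index=table.counts.index)


def correlate(x, y, method: str = "pearson", group_by=None):
    """Correlation coefficient and two-sided p value.

    ``method`` is pearson, spearman, or kendall (tau-b, tie-corrected).
    ``group_by`` optionally stratifies into per-group results (e.g. one row
    per chromosome), returning a DataFrame.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if group_by is not None:
        groups = np.asarray(group_by)[keep]
        rows = []
        for g in pd.unique(groups):
            sel = groups == g
            coef, p = correlate(x[sel], y[sel], method)
            rows.append({"group": g, "coef": coef, "p": p, "n": int(sel.sum())})
        return pd.DataFrame(rows)
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    elif method == "kendall":
        res = stats.kendalltau(x, y)  # tau-b
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def linear_fit(x, y):
    """Ordinary least squares of y on x.

    Returns a dict with slope, intercept, the t statistic of the slope
    (slope / SE), its two-sided p from the t distribution with n - 2 degrees
    of freedom, and R^2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    res = stats.linregress(x, y)
    t = res.slope / res.stderr if res.stderr > 0 else np.inf
    return {
        "slope": res.slope,
        "intercept": res.intercept,
        "se_slope": res.stderr,
        "t": t,
        "p": res.pvalue,
        "r2": res.rvalue ** 2,
        "df": len(x) - 2,
    }


def group_difference_test(a, b):
    """Welch two-sample t test (two-sided) between two proportion groups."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
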