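"""Interval boundary schemes and per-interval genomic summaries.

Four tiling schemes are supported: 1-Mb windows laid from the left (``pf``)
or right (``pr``) telomere, and 5-cM windows laid from the left (``gf``) or
right (``gr``) telomere on the genetic map.  A terminal fragment shorter than
0.2 Mb of physical length is merged into its neighbouring interval.  Genetic
positions of arbitrary base pairs come from linear interpolation between the
map anchors (a Marey-map view of the chromosome).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChromosomeMap",
    "GenomicInterval",
    "IntervalScheme",
    "SCHEMES",
    "WS256_CHROMOSOME_LENGTHS",
    "build_intervals",
    "merge_spans",
    "feature_density",
    "track_summary",
    "adjust_lengths",
    "read_genetic_map_tsv",
    "intervals_to_frame",
]

#: Reference chromosome lengths (bp) of the C. elegans WS256/ce11 assembly;
#: public reference constants used by the structural window-count check.
WS256_CHROMOSOME_LENGTHS = {
    "I": 15072434,
    "II": 15279421,
    "III": 13783801,
    "IV": 17493829,
    "V": 20924180,
    "X": 17718942,
}


@dataclass
class ChromosomeMap:
    """Piecewise-linear genetic map of one chromosome.

    ``anchors`` are ordered (bp, cM) pairs, monotone non-decreasing in both
    coordinates, starting at bp 0.
    """

    name: str
    length: int
    anchors: list[tuple[float, float]]
    _bp: np.ndarray = field(init=False, repr=False)
    _cm: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: non-positive length")
        a = np.asarray(self.anchors, dtype=float)
        if a.ndim != 2 or a.shape[1] != 2 or a.shape[0] < 2:
            raise ValueError("anchors must be >= 2 (bp, cM) pairs")
        if a[0, 0] != 0:
            raise ValueError("first anchor must be at bp 0")
        if np.any(np.diff(a[:, 0]) <= 0) or np.any(np.diff(a[:, 1]) < 0):
            raise ValueError(f"chromosome {self.name}: non-monotone map")
        self._bp, self._cm = a[:, 0], a[:, 1]

    @property
    def genetic_length(self) -> float:
        return float(self._cm[-1] - self._cm[0])

    def bp_to_cm(self, bp) -> np.ndarray | float:
        """Genetic position of a physical position, clamped beyond the
        terminal anchors."""
        return np.interp(bp, self._bp, self._cm)

    def cm_to_bp(self, cm) -> np.ndarray | float:
        """Leftmost physical position reaching a genetic position (the
        inverse is set-valued across zero-recombination stretches)."""
        cm = np.asarray(cm, dtype=float)
        idx = np.searchsorted(self._cm, cm, side="left")
        idx = np.clip(idx, 1, len(self._cm) - 1)
        c0, c1 = self._cm[idx - 1], self._cm[idx]
        b0, b1 = self._bp[idx - 1], self._bp[idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(c1 > c0, (cm - c0) / np.where(c1 > c0, c1 - c0, 1.0), 0.0)
        out = b0 + np.clip(frac, 0.0, 1.0) * (b1 - b0)
        out = np.clip(out, self._bp[0], self._bp[-1])
        return float(out) if out.ndim == 0 else out

    def rate_at(self, bp) -> np.ndarray | float:
        """Local recombination rate (cM/Mb): slope of the map segment."""
        bp = np.asarray(bp, dtype=float)
        idx = np.searchsorted(self._bp, bp, side="right")
        idx = np.clip(idx, 1, len(self._bp) - 1)
        dg = self._cm[idx] - self._cm[idx - 1]
        dn = (self._bp[idx] - self._bp[idx - 1]) / 1e6
        out = dg / dn
        return float(out) if out.ndim == 0 else out


@dataclass
class IntervalScheme:
    id: str  # pf | pr | gf | gr
    step: float = 0.0  # 1e6 bp for pf/pr, 5 cM for gf/gr (0 -> default)
    merge_threshold_bp: float = 0.2e6

    def __post_init__(self) -> None:
        if self.id not in ("pf", "pr", "gf", "gr"):
            raise ValueError(f"unknown scheme {self.id!r}")
        if self.step == 0.0:
            self.step = 1e6 if self.physical else 5.0
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def physical(self) -> bool:
        return self.id.startswith("p")

    @property
    def forward(self) -> bool:
        return self.id.endswith("f")


SCHEMES = {sid: IntervalScheme(sid) for sid in ("pf", "pr", "gf", "gr")}


@dataclass
class GenomicInterval:
    chrom: str
    phys_start: int
    phys_end: int
    g_start: float
    g_end: float
    scheme: str
    densities: dict = field(default_factory=dict)
    tracks: dict = field(default_factory=dict)
    n_override: float | None = None  # set by adjust_lengths

    @property
    def n(self) -> float:
        """Physical length in Mb (possibly exon/CDS-adjusted)."""
        if self.n_override is not None:
            return self.n_override
        return (self.phys_end - self.phys_start) / 1e6

    @property
    def g(self) -> float:
        """Genetic length in cM (follows the adjusted n at constant r)."""
        raw_g = self.g_end - self.g_start
        if self.n_override is None:
            return raw_g
        raw_n = (self.phys_end - self.phys_start) / 1e6
        return raw_g * self.n_override / raw_n

    @property
    def r(self) -> float:
        """Recombination rate, cM/Mb."""
        raw_n = (self.phys_end - self.phys_start) / 1e6
        return (self.g_end - self.g_start) / raw_n

    def contains(self, start: int, end: int) -> bool:
        """Both-ends rule: a variant belongs to the interval only if its whole
        span does (boundary-straddling variants belong to no interval)."""
        if start == end:  # insertion point
            return self.phys_start < start < self.phys_end
        return self.phys_start <= start and end <= self.phys_end


def _boundaries(cmap: ChromosomeMap, scheme: IntervalScheme) -> np.ndarray:
    """Physical breakpoints of the tiling, including both telomeres."""
    if scheme.physical:
        total = float(cmap.length)
        cuts = np.arange(scheme.step, total, scheme.step)
        if scheme.forward:
            bps = np.concatenate([[0.0], cuts, [total]])
        else:
            bps = np.concatenate([[0.0], np.sort(total - cuts), [total]])
    else:
        total = cmap.genetic_length
        cuts = np.arange(scheme.step, total, scheme.step)
        if not scheme.forward:
            cuts = np.sort(total - cuts)
        bps = np.concatenate([[0.0], cmap.cm_to_bp(cuts), [float(cmap.length)]])
    bps = np.unique(bps)
    # merge terminal fragments shorter than the physical threshold; interior
    # fragments can only arise for genetic schemes over zero-recombination
    # stretches and are merged the same way
    keep = [bps[0]]
    for b in bps[1:-1]:
        if b - keep[-1] >= scheme.merge_threshold_bp:
            keep.append(b)
    last = bps[-1]
    if last - keep[-1] < scheme.merge_threshold_bp and len(keep) > 1:
        keep.pop()
    keep.append(last)
    if len(keep) == 2 and cmap.length < scheme.merge_threshold_bp:
        warnings.warn(
            f"chromosome {cmap.name} shorter than the merge threshold: "
            "single interval"
        )
    return np.asarray(keep)


def build_intervals(maps, scheme: IntervalScheme | str):
    """Tile each chromosome with the given boundary scheme.

    Intervals are disjoint and exhaustive; per chromosome the physical lengths
    sum to the chromosome length and the genetic lengths sum to the map
    length.
    """
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    out: list[GenomicInterval] = []
    for cmap in maps:
        bps = _boundaries(cmap, scheme)
        cms = cmap.bp_to_cm(bps)
        for i in range(len(bps) - 1):
            out.append(
                GenomicInterval(
                    chrom=cmap.name,
                    phys_start=int(round(bps[i])),
                    phys_end=int(round(bps[i + 1])),
                    g_start=float(cms[i]),
                    g_end=float(cms[i + 1]),
                    scheme=scheme.id,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Feature densities and track summaries


def merge_spans(spans):
    """Union-merge (start, end) spans: duplicates, contained spans, and
    overlaps all collapse; order-independent."""
    spans = sorted((int(s), int(e)) for s, e in spans if e > s)
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _overlap_bp(spans, start, end) -> int:
    return sum(max(0, min(e, end) - max(s, start)) for s, e in spans)


def feature_density(interval: GenomicInterval, features, kind: str) -> float:
    """Fraction of the interval occupied by the (merged) spans of one feature
    kind.  Intron space is counted net of any exon space inside introns."""
    if kind not in features:
        raise KeyError(f"unknown feature kind {kind!r}")
    per_chrom = features[kind]
    spans = merge_spans(per_chrom.get(interval.chrom, []))
    occupied = _overlap_bp(spans, interval.phys_start, interval.phys_end)
    if kind == "intron":
        exon_like = []
        for k in ("exon", "CDS"):
            if k in features:
                exon_like = merge_spans(features[k].get(interval.chrom, []))
                break
        # subtract exon space lying inside intron space
        inter = []
        for s, e in spans:
            for xs, xe in exon_like:
                lo, hi = max(s, xs), min(e, xe)
                if lo < hi:
                    inter.append((lo, hi))
        occupied -= _overlap_bp(merge_spans(inter), interval.phys_start,
                                interval.phys_end)
    length = interval.phys_end - interval.phys_start
    d = occupied / length
    interval.densities[kind] = d
    return d


def track_summary(interval: GenomicInterval, track, kind: str,
                  read_length: int = 100, wig_step: int = 10) -> float:
    """Per-interval summary of a sequence or signal track.

    ``gc``: (G+C) fraction of the interval sequence (*track* is the chromosome
    sequence string).  ``expression``: sum over coverage segments of
    depth x read length, apportioned by overlap fraction, divided by the
    interval length (*track* is a list of (start, end, depth) segments).
    ``chromatin``: mean of the fixed-step values whose step starts inside the
    interval (*track* is the per-chromosome value array).
    """
    s, e = interval.phys_start, interval.phys_end
    if kind == "gc":
        seq = track[s:e]
        if not seq:
            raise ValueError("missing sequence for interval")
        gc = sum(1 for b in seq.upper() if b in "GC")
        value = gc / len(seq)
    elif kind == "expression":
        total = 0.0
        for seg_s, seg_e, depth in track:
            ov = max(0, min(seg_e, e) - max(seg_s, s))
            if ov and seg_e > seg_s:
                total += depth * read_length * (ov / (seg_e - seg_s))
        value = total / (e - s)
    elif kind == "chromatin":
        i0 = (s + wig_step - 1) // wig_step
        i1 = e // wig_step
        vals = np.asarray(track[i0:i1], dtype=float)
        if vals.size == 0:
            raise ValueError("no chromatin steps inside interval")
        value = float(vals.mean())
    else:
        raise ValueError(f"unknown track kind {kind!r}")
    interval.tracks[kind] = value
    return value


def adjust_lengths(interval: GenomicInterval, excluded_feature_bp: int) -> GenomicInterval:
    """Shrink the interval's physical length by the space of an excluded
    feature class (exons or CDS), assuming the feature is evenly spread so
    genetic and physical distance shrink proportionately: r is unchanged and
    g' = r * n'."""
    raw_n = (interval.phys_end - interval.phys_start) / 1e6
    n_prime = raw_n - excluded_feature_bp / 1e6
    if n_prime <= 0:
        raise ValueError("excluded feature occupies the entire interval")
    interval.n_override = n_prime
    return interval


# ---------------------------------------------------------------------------
# I/O helpers


def read_genetic_map_tsv(path):
    """Read a (chrom, bp, cM) anchor table into ChromosomeMap objects.
    Chromosome length is taken as the last anchor's bp."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["chrom", "bp", "cM"], header=0)
    maps = []
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("bp")
        maps.append(ChromosomeMap(
            name=str(chrom),
            length=int(grp["bp"].iloc[-1]),
            anchors=list(zip(grp["bp"], grp["cM"])),
        ))
    return maps


def intervals_to_frame(intervals):
    """Flatten intervals into a DataFrame (one row per interval)."""
    import pandas as pd

    rows = []
    for iv in intervals:
        row = {
            "scheme": iv.scheme, "chrom": iv.chrom,
            "phys_start": iv.phys_start, "phys_end": iv.phys_end,
            "g_start": iv.g_start, "g_end": iv.g_end,
            "n_Mb": iv.n, "g_cM": iv.g, "r": iv.r,
        }
        row.update({f"density_{k}": v for k, v in iv.densities.items()})
        row.update({f"track_{k}": v for k, v in iv.tracks.items()})
        rows.append(row)
    return pd.DataFrame(rows)
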