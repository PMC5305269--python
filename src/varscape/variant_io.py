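"""Polymorphism-record parsing, classification, curation, and annotation.

Records are held in the coordinate convention used throughout the package:
0-based, half-open ``[start, end)``.  Insertions are zero-length spans with
``start == end`` at the insertion point.  At the GFF3 boundary coordinates are
1-based inclusive; an insertion is written with ``start == end`` at the base
preceding the insertion point, mirroring the WormBase Polymorphisms-track
dialect (``substitution=REF/ALT``, ``insertion=SEQ``, ``deletion=SEQ``,
``strains=`` carrier list).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import gffutils.iterators

__all__ = [
    "VariantRecord",
    "VariantClass",
    "SizeClassScheme",
    "DEFAULT_SIZE_SCHEME",
    "EXON_FEATURE_KINDS",
    "classify_variant",
    "parse_polymorphism_gff3",
    "write_polymorphism_gff3",
    "combine_adjacent",
    "resolve_conflicts",
    "annotate_variants",
    "select_population",
    "read_features_gff3",
    "read_expression_gff3",
    "read_fasta",
    "read_wig_fixed",
]

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}

#: Feature kinds whose union defines "affects exons": a variant affects an exon
#: if it changes at least one base of any coding or structured-RNA feature.
EXON_FEATURE_KINDS = ("CDS", "five_prime_UTR", "three_prime_UTR", "pseudogene", "ncRNA")


class VariantParseError(ValueError):
    pass


@dataclass
class SizeClassScheme:
    """Ordered size classes for non-SNP variants, keyed by absolute net
    base-pair change.  Entries may overlap (each label is counted
    independently), e.g. i40-699 and i100-4999 overlap between 100 and 699.
    """

    entries: tuple[tuple[str, int, float], ...]

    def __post_init__(self) -> None:
        for label, lo, hi in self.entries:
            if lo < 0 or hi < lo:
                raise ValueError(f"bad size range for {label!r}: [{lo}, {hi}]")

    def labels_for(self, net_change: int) -> frozenset[str]:
        size = abs(net_change)
        return frozenset(
            label for label, lo, hi in self.entries if lo <= size <= hi
        )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _, _ in self.entries)


#: Default size-class labels.  Only some labels are fixed by convention
#: (i0, i1, i40-699, i100-4999); the rest follow the same naming pattern and
#: are fully configurable.  i40-699 and i100-4999 deliberately overlap.
DEFAULT_SIZE_SCHEME = SizeClassScheme(
    entries=(
        ("i0", 0, 0),
        ("i1", 1, 1),
        ("i2", 2, 2),
        ("i3", 3, 3),
        ("i4", 4, 4),
        ("i5-9", 5, 9),
        ("i10-19", 10, 19),
        ("i20-39", 20, 39),
        ("i40-699", 40, 699),
        ("i100-4999", 100, 4999),
        ("i700+", 700, math.inf),
    )
)


@dataclass(frozen=True)
class VariantClass:
    category: str  # "SNP_Ts" | "SNP_Tv" | "non-SNP"
    net_change: int
    size_labels: frozenset[str]

    @property
    def is_snp(self) -> bool:
        return self.category.startswith("SNP")

    @property
    def type_labels(self) -> frozenset[str]:
        """All counting labels this variant contributes to."""
        base = {"all"}
        if self.is_snp:
            base |= {"SNP", self.category}
        else:
            base |= {"non-SNP"} | self.size_labels
        return frozenset(base)


def classify_variant(
    ref: str, alt: str, scheme: SizeClassScheme = DEFAULT_SIZE_SCHEME
) -> VariantClass:
    """Classify an allele pair.

    SNPs are single-base substitutions, split into transitions (A<->G, C<->T)
    and transversions.  Everything else is a non-SNP labelled with every
    scheme entry whose range contains \\|len(alt) - len(ref)\\|; an equal-length
    multi-base substitution therefore lands in i0.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError(f"ref and alt are identical ({ref!r}): not a variant")
    if len(ref) == 1 and len(alt) == 1:
        pair = {ref, alt}
        if pair <= PURINES or pair <= PYRIMIDINES:
            return VariantClass("SNP_Ts", 0, frozenset())
        return VariantClass("SNP_Tv", 0, frozenset())
    net = len(alt) - len(ref)
    return VariantClass("non-SNP", net, scheme.labels_for(net))


@dataclass
class VariantRecord:
    """One polymorphism record.

    ``start``/``end`` are 0-based half-open; ``start == end`` marks an
    insertion point.  ``isolates`` is the carrier set.  ``flags`` holds
    feature-relation booleans filled in by :func:`annotate_variants`.
    """

    chrom: str
    start: int
    end: int
    ref: str
    alt: str
    isolates: frozenset[str]
    source: str = "simulated"
    id: str | None = None
    flags: dict = field(default_factory=dict)
    _vclass: VariantClass | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end < start in {self.id or self!r}")
        if not self.ref and not self.alt:
            raise ValueError("both ref and alt empty")
        if not self.isolates:
            raise ValueError("isolates set is empty")
        self.isolates = frozenset(self.isolates)

    def classify(self, scheme: SizeClassScheme = DEFAULT_SIZE_SCHEME) -> VariantClass:
        if self._vclass is None or scheme is not DEFAULT_SIZE_SCHEME:
            vc = classify_variant(self.ref, self.alt, scheme)
            if scheme is DEFAULT_SIZE_SCHEME:
                self._vclass = vc
            return vc
        return self._vclass

    @property
    def is_insertion(self) -> bool:
        return self.start == self.end

    @property
    def is_deletion(self) -> bool:
        return self.end > self.start and len(self.alt) < len(self.ref)


# ---------------------------------------------------------------------------
# GFF3 I/O


def _record_to_gff3(v: VariantRecord) -> str:
    if v.is_insertion:
        gff_start = gff_end = v.start  # base before the insertion point
        kind = "insertion"
        detail = f"insertion={v.alt}"
    else:
        gff_start, gff_end = v.start + 1, v.end
        if len(v.ref) == 1 and len(v.alt) == 1:
            kind = "SNP"
            detail = f"substitution={v.ref}/{v.alt}"
        elif not v.alt:
            kind = "deletion"
            detail = f"deletion={v.ref}"
        else:
            kind = "complex_substitution"
            detail = f"substitution={v.ref}/{v.alt}"
    attrs = []
    if v.id:
        attrs.append(f"ID={v.id}")
    attrs.append(detail)
    attrs.append("strains=" + ",".join(sorted(v.isolates)))
    return "\t".join(
        [v.chrom, v.source, kind, str(gff_start), str(gff_end), ".", "+", ".",
         ";".join(attrs)]
    )


def write_polymorphism_gff3(path, variants) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for v in variants:
            fh.write(_record_to_gff3(v) + "\n")


def parse_polymorphism_gff3(path, scheme: SizeClassScheme = DEFAULT_SIZE_SCHEME):
    """Read polymorphism records written in the Polymorphisms-track dialect.

    Malformed lines raise :class:`VariantParseError` with the line number;
    records with end < start are rejected with a warning and counted.
    """
    records: list[VariantRecord] = []
    rejected = 0
    for lineno, feat in enumerate(gffutils.iterators.DataIterator(str(path)), 1):
        try:
            attrs = feat.attributes
            strains = attrs.get("strains", [])  # comma-split by the parser
            isolates = frozenset(
                s.strip() for item in strains for s in item.split(",")
                if s.strip())
            vid = attrs.get("ID", [None])[0]
            if feat.featuretype == "insertion":
                alt = attrs.get("insertion", [""])[0]
                start = end = int(feat.start)
                ref = ""
            elif feat.featuretype == "deletion":
                ref = attrs.get("deletion", [""])[0]
                start, end = int(feat.start) - 1, int(feat.end)
                if not ref:
                    ref = "N" * (end - start)
                alt = ""
            else:
                sub = attrs.get("substitution", [None])[0]
                if sub is None or "/" not in sub:
                    raise VariantParseError(
                        f"line {lineno}: missing substitution= attribute"
                    )
                ref, alt = sub.split("/", 1)
                start, end = int(feat.start) - 1, int(feat.end)
            if end < start:
                rejected += 1
                continue
            rec = VariantRecord(
                chrom=feat.seqid, start=start, end=end, ref=ref, alt=alt,
                isolates=isolates, source=feat.source, id=vid,
            )
            rec.classify(scheme)
            records.append(rec)
        except VariantParseError:
            raise
        except Exception as exc:  # malformed line content
            raise VariantParseError(f"line {lineno}: {exc}") from exc
    if rejected:
        warnings.warn(f"{rejected} record(s) with end < start rejected")
    return records


# ---------------------------------------------------------------------------
# Curation


def combine_adjacent(variants):
    """Merge maximal runs of immediately adjacent records carried by identical
    isolate sets into a single record (alleles concatenated in genomic order).

    Input need not be sorted; output is sorted by (chrom, start, end).
    Idempotent, and never increases the record count.
    """
    out: list[VariantRecord] = []

    def flush(run) -> None:
        if len(run) == 1:
            out.append(run[0])
        else:
            out.append(VariantRecord(
                chrom=run[0].chrom,
                start=run[0].start,
                end=run[-1].end,
                ref="".join(v.ref for v in run),
                alt="".join(v.alt for v in run),
                isolates=run[0].isolates,
                source=run[0].source,
                id=run[0].id,
            ))

    # runs are keyed by carrier set so that records of other isolates
    # interleaved in coordinate order cannot break a run
    pending: dict[frozenset, list[VariantRecord]] = {}
    current_chrom = None
    for v in sorted(variants, key=lambda x: (x.chrom, x.start, x.end)):
        if v.chrom != current_chrom:
            for run in pending.values():
                flush(run)
            pending = {}
            current_chrom = v.chrom
        run = pending.get(v.isolates)
        if run is not None and run[-1].end == v.start:
            run.append(v)
        else:
            if run is not None:
                flush(run)
            pending[v.isolates] = [v]
    for run in pending.values():
        flush(run)
    out.sort(key=lambda v: (v.chrom, v.start, v.end))
    return out


def _synthesize_merged(chrom, members, isolate):
    """Build the single record replacing a cluster of overlapping records.

    The true joint allele is unknowable from conflicting calls, so a curation
    convention applies: the merged record spans the union; if every member
    removes bases (deletion-like) the result is a deletion, otherwise a
    complex substitution whose alt length carries the summed net change of
    the members.  Placeholder IUPAC alleles (N for ref, M for alt) mark the
    synthesized sequence.
    """
    start = min(v.start for v in members)
    end = max(v.end for v in members)
    span = end - start
    if all(v.is_deletion for v in members):
        ref, alt = "N" * span, ""
    else:
        net = sum(len(v.alt) - len(v.ref) for v in members)
        ref, alt = "N" * span, "M" * max(span + net, 0)
    return VariantRecord(
        chrom=chrom, start=start, end=end, ref=ref, alt=alt,
        isolates=frozenset([isolate]), source="curated",
        id=None,
    )


def resolve_conflicts(variants, per_isolate: bool = True):
    """Censor overshadowed records and merge overlapping ones, one isolate at
    a time.

    A record whose span lies strictly inside a deletion of the same isolate is
    censored.  Remaining records that overlap are merged into one record
    spanning their union.  Records identical across isolates are regrouped
    afterwards.  Idempotent.
    """
    if not per_isolate:
        raise NotImplementedError("conflict resolution is defined per isolate")
    per_iso: dict[tuple[str, str], list[VariantRecord]] = {}
    for v in variants:
        for iso in v.isolates:
            per_iso.setdefault((v.chrom, iso), []).append(v)

    resolved: dict[tuple, dict] = {}

    def _add(rec: VariantRecord, iso: str) -> None:
        key = (rec.chrom, rec.start, rec.end, rec.ref, rec.alt, rec.source)
        slot = resolved.setdefault(key, {"rec": rec, "isolates": set()})
        slot["isolates"].add(iso)

    for (chrom, iso), recs in per_iso.items():
        recs = sorted(recs, key=lambda v: (v.start, v.end))
        deletions = [v for v in recs if v.is_deletion]
        kept = []
        for v in recs:
            shadowed = any(
                d is not v
                and d.start <= v.start
                and v.end <= d.end
                and (v.start, v.end) != (d.start, d.end)
                for d in deletions
            )
            if not shadowed:
                kept.append(v)
        # merge overlapping spans into union clusters
        out = []
        cluster: list[VariantRecord] = []
        cluster_end = -1
        for v in kept:
            if cluster and v.start < cluster_end:
                cluster.append(v)
                cluster_end = max(cluster_end, v.end)
            else:
                if cluster:
                    out.append(cluster)
                cluster = [v]
                cluster_end = v.end
        if cluster:
            out.append(cluster)
        for members in out:
            if len(members) == 1:
                _add(members[0], iso)
            else:
                _add(_synthesize_merged(chrom, members, iso), iso)

    final = []
    for slot in resolved.values():
        rec = slot["rec"]
        final.append(replace(rec, isolates=frozenset(slot["isolates"]),
                             flags=dict(rec.flags)))
    final.sort(key=lambda v: (v.chrom, v.start, v.end, v.ref, v.alt))
    return final


# ---------------------------------------------------------------------------
# Annotation


def _overlaps(v: VariantRecord, fs: int, fe: int) -> bool:
    if v.is_insertion:
        # an insertion changes a feature only if it falls strictly inside it
        return fs < v.start < fe
    return v.start < fe and fs < v.end


def _inside(v: VariantRecord, fs: int, fe: int) -> bool:
    if v.is_insertion:
        return fs < v.start < fe
    return fs <= v.start and v.end <= fe


def annotate_variants(variants, features, exon_kinds=EXON_FEATURE_KINDS):
    """Set per-feature-kind ``affects_X`` / ``inside_X`` flags on each record.

    ``features`` maps a kind name to merged spans per chromosome:
    ``{kind: {chrom: [(start, end), ...]}}`` in 0-based half-open coordinates.
    ``affects_X`` means at least one base of the feature is changed;
    ``inside_X`` means no DNA outside the feature is affected.  The composite
    ``affects_exon`` flag is the union over *exon_kinds* that are present
    (unless an explicit ``exon`` kind is supplied).
    """
    import bisect

    indexed = {}
    for kind, per_chrom in features.items():
        indexed[kind] = {
            chrom: (sorted(spans), [s for s, _ in sorted(spans)])
            for chrom, spans in per_chrom.items()
        }

    for v in variants:
        for kind, per_chrom in indexed.items():
            affects = inside = False
            if v.chrom in per_chrom:
                spans, starts = per_chrom[v.chrom]
                lo = bisect.bisect_right(starts, v.start) - 1
                hi = bisect.bisect_right(starts, v.end)
                for fs, fe in spans[max(lo, 0):hi + 1]:
                    if _overlaps(v, fs, fe):
                        affects = True
                        if _inside(v, fs, fe):
                            inside = True
                        break
            v.flags[f"affects_{kind}"] = affects
            v.flags[f"inside_{kind}"] = inside
        if "exon" not in indexed:
            present = [k for k in exon_kinds if k in indexed]
            v.flags["affects_exon"] = any(v.flags[f"affects_{k}"] for k in present)
    return variants


# ---------------------------------------------------------------------------
# Population selection


def select_population(
    variants,
    filterspec=None,
    mode: str = "unique",
    exclude_isolates=(),
):
    """Build a weighted working set.

    ``filterspec`` is a predicate over records (flag combinators are ordinary
    lambdas, e.g. ``lambda v: not v.flags["affects_exon"]``).  In ``unique``
    mode each variant counts once; in ``aggregate`` mode it counts once per
    retained carrier isolate.  Variants private to excluded isolates drop out.
    """
    if mode not in ("unique", "aggregate"):
        raise ValueError(f"unknown mode {mode!r}")
    excluded = frozenset(exclude_isolates)
    out_records, out_weights = [], []
    for v in variants:
        retained = v.isolates - excluded
        if not retained:
            continue
        if filterspec is not None and not filterspec(v):
            continue
        out_records.append(v)
        out_weights.append(len(retained) if mode == "aggregate" else 1)
    if not out_records:
        warnings.warn("population selection produced an empty set")
    return out_records, out_weights


# ---------------------------------------------------------------------------
# Readers for the companion annotation and track formats


def read_features_gff3(path):
    """Read feature annotations into {kind: {chrom: [(start, end), ...]}}
    (0-based half-open)."""
    features: dict[str, dict[str, list]] = {}
    for feat in gffutils.iterators.DataIterator(str(path)):
        spans = features.setdefault(feat.featuretype, {}).setdefault(feat.seqid, [])
        spans.append((int(feat.start) - 1, int(feat.end)))
    return features


def read_expression_gff3(path):
    """Read coverage segments into {chrom: [(start, end, depth), ...]}."""
    expression: dict[str, list] = {}
    for feat in gffutils.iterators.DataIterator(str(path)):
        depth = float(feat.score) if feat.score not in (".", None) else 0.0
        expression.setdefault(feat.seqid, []).append(
            (int(feat.start) - 1, int(feat.end), depth)
        )
    return expression


def read_fasta(path):
    """Read chromosome sequences into {name: sequence string}."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_wig_fixed(path):
    """Read a fixed-step WIG file into {chrom: numpy value array}.

    Only the fixedStep dialect written by the synthetic-data module is
    supported (no installed library reads text WIG)."""
    import numpy as np

    tracks: dict[str, list] = {}
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                current = tracks.setdefault(fields["chrom"], [])
            else:
                if current is None:
                    raise VariantParseError("WIG value before fixedStep header")
                current.append(float(line))
    return {chrom: np.asarray(vals) for chrom, vals in tracks.items()}
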