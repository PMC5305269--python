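"""Synthetic genomes, maps, annotation tracks, and variant sets.

Everything downstream (curation, interval statistics, model fitting) is
exercised on data generated here, with the statistical structure the analysis
assumes: chromosomes with arm-high / center-low recombination landscapes, a
piecewise-linear genetic map, gene/repeat annotations, expression and
chromatin tracks, and variants drawn from the two-mechanism mutation model —
Morgan-origin variants placed with density proportional to the local
recombination rate, Sanger-origin variants uniform in physical distance, and
per-origin type probabilities F_M / F_S.  Optional thinning emulates
background or direct selection, and an artifact injector reproduces the
curation defects seen in real polymorphism tracks (split adjacent records,
duplicated overlapping records, records overshadowed by deletions).

No coalescent genealogy or linkage structure among variants is modelled; the
isolate-sharing model (geometric, mean 3 carriers) is a stand-in needed only
to exercise aggregation and adjacency rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome_intervals import ChromosomeMap
from .mutation_model import MutationModelParams
from .selection_model import SelectionParams, bgs_factor
from .variant_io import VariantRecord

__all__ = [
    "SyntheticGenomeSpec",
    "SimulationParams",
    "GenomeBundle",
    "default_genome_spec",
    "make_genome",
    "simulate_variants",
    "apply_selection",
    "inject_artifacts",
    "write_fasta",
    "write_genetic_map_tsv",
    "write_features_gff3",
    "write_expression_gff3",
    "write_wig_fixed",
    "write_dataset",
]

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class FeatureConfig:
    """Knobs for annotation generation (lengths in bp)."""

    intergenic_mean: float = 3000.0
    exon_mean: float = 250.0
    intron_mean: float = 320.0
    exons_per_gene: float = 4.0
    ncrna_fraction: float = 0.10
    essential_fraction: float = 0.05
    repeat_gap_mean: float = 8000.0
    repeat_len_mean: float = 300.0


@dataclass
class SyntheticGenomeSpec:
    """Genome blueprint: chromosome sizes, recombination-rate domains
    (ordered (span_bp, rate cM/Mb) partitions of each chromosome), feature
    densities, and the isolate panel size."""

    chromosomes: list
    rate_domains: dict
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    n_isolates: int = 40
    gc_content: float = 0.36
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_isolates < 1:
            raise ValueError("need at least one isolate")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name}: non-positive length")
            domains = self.rate_domains.get(name)
            if not domains:
                raise ValueError(f"chromosome {name}: no rate domains")
            if any(rate < 0 or span <= 0 for span, rate in domains):
                raise ValueError(f"chromosome {name}: bad rate domain")
            if sum(span for span, _ in domains) != length:
                raise ValueError(
                    f"chromosome {name}: rate domains must partition the "
                    "chromosome exactly"
                )

    @property
    def isolates(self) -> list:
        return [f"iso{i:02d}" for i in range(1, self.n_isolates + 1)]


def default_genome_spec(seed: int = 0, scale: float = 1.0) -> SyntheticGenomeSpec:
    """Six chromosomes of 14-21 Mb with the arm/center recombination pattern
    typical of holocentric nematode chromosomes: high-rate arms (~25% of the
    chromosome each) flanking a low-rate center.  ``scale`` shrinks every
    chromosome for fast test genomes."""
    sizes = [15, 15, 14, 17, 21, 18]
    names = ["I", "II", "III", "IV", "V", "X"]
    arm_rates = [7.0, 6.5, 7.5, 7.0, 6.0, 4.0]
    center_rates = [0.5, 0.6, 0.4, 0.5, 0.7, 1.2]
    chromosomes, rate_domains = [], {}
    for name, mb, hi, lo in zip(names, sizes, arm_rates, center_rates):
        L = int(mb * 1e6 * scale)
        arm = int(0.25 * L)
        center = L - 2 * arm
        chromosomes.append((name, L))
        rate_domains[name] = [(arm, hi), (center, lo), (arm, hi)]
    return SyntheticGenomeSpec(chromosomes=chromosomes,
                               rate_domains=rate_domains, seed=seed)


@dataclass
class SimulationParams:
    params: MutationModelParams = field(default_factory=MutationModelParams)
    selection: SelectionParams | None = None
    direct_selection: dict | None = None
    artifact_rates: dict = field(default_factory=lambda: {
        "split": 0.0, "duplicate": 0.0, "overshadow": 0.0})
    sharing_mean: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for key, p in self.artifact_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"artifact rate {key} outside [0, 1]")
        if self.direct_selection:
            if any(not 0.0 <= p <= 1.0 for p in self.direct_selection.values()):
                raise ValueError("removal probabilities must be in [0, 1]")


@dataclass
class GenomeBundle:
    spec: SyntheticGenomeSpec
    sequences: dict
    maps: list
    features: dict       # kind -> {chrom: [(start, end), ...]}
    expression: dict     # chrom -> [(start, end, depth), ...]
    chromatin: dict      # chrom -> np.ndarray of 10-bp step values
    isolates: list

    def map_for(self, chrom: str) -> ChromosomeMap:
        for m in self.maps:
            if m.name == chrom:
                return m
        raise KeyError(chrom)


# ---------------------------------------------------------------------------
# Genome construction


def _random_sequence(rng, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return BASES[idx].tobytes().decode()


def _make_map(name: str, domains) -> ChromosomeMap:
    anchors = [(0.0, 0.0)]
    bp = cm = 0.0
    for span, rate in domains:
        bp += span
        cm += span / 1e6 * rate
        anchors.append((bp, cm))
    return ChromosomeMap(name=name, length=int(bp), anchors=anchors)


def _make_features(rng, name: str, length: int, cfg: FeatureConfig):
    feats = {k: [] for k in ("exon", "CDS", "intron", "ncRNA", "repeat",
                             "essential_gene", "essential_exon")}
    expression = []
    pos = 0
    while True:
        pos += int(rng.exponential(cfg.intergenic_mean)) + 1
        gene_start = pos
        n_exons = 1 + rng.poisson(cfg.exons_per_gene - 1)
        exons = []
        for i in range(n_exons):
            elen = int(np.clip(rng.lognormal(np.log(cfg.exon_mean), 0.5), 30, 3000))
            exons.append((pos, pos + elen))
            pos += elen
            if i < n_exons - 1:
                ilen = int(np.clip(rng.lognormal(np.log(cfg.intron_mean), 0.6),
                                   40, 5000))
                feats["intron"].append((pos, pos + ilen))
                pos += ilen
        if pos >= length:
            # drop the gene running off the end; introns may linger but are
            # clipped below
            break
        is_ncrna = rng.random() < cfg.ncrna_fraction
        if is_ncrna:
            feats["ncRNA"].extend(exons)
        else:
            feats["exon"].extend(exons)
            feats["CDS"].extend(exons)
            depth = float(rng.lognormal(1.2, 0.8))
            expression.append((gene_start, pos, depth))
            if rng.random() < cfg.essential_fraction:
                feats["essential_gene"].append((gene_start, pos))
                feats["essential_exon"].extend(exons)
    pos = 0
    while True:
        pos += int(rng.exponential(cfg.repeat_gap_mean)) + 1
        rlen = int(rng.exponential(cfg.repeat_len_mean)) + 20
        if pos + rlen >= length:
            break
        feats["repeat"].append((pos, pos + rlen))
        pos += rlen
    for kind in feats:
        feats[kind] = [(s, min(e, length)) for s, e in feats[kind] if s < length]
    return feats, expression


def make_genome(spec: SyntheticGenomeSpec) -> GenomeBundle:
    """Build the full genome bundle.  Deterministic for a given spec seed."""
    rng = np.random.default_rng(spec.seed)
    sequences, maps = {}, []
    features = {}
    expression, chromatin = {}, {}
    for name, length in spec.chromosomes:
        sequences[name] = _random_sequence(rng, length, spec.gc_content)
        cmap = _make_map(name, spec.rate_domains[name])
        maps.append(cmap)
        feats, expr = _make_features(rng, name, length, spec.feature_config)
        for kind, spans in feats.items():
            features.setdefault(kind, {})[name] = spans
        expression[name] = expr
        n_steps = length // 10
        step_mid = np.arange(n_steps) * 10.0 + 5.0
        rate_term = 0.1 * cmap.rate_at(step_mid)
        chromatin[name] = 1.0 + rate_term + rng.normal(0.0, 0.15, n_steps)
    return GenomeBundle(spec=spec, sequences=sequences, maps=maps,
                        features=features, expression=expression,
                        chromatin=chromatin, isolates=spec.isolates)


# ---------------------------------------------------------------------------
# Variant simulation

#: Size ranges used when materializing each generated type label.
_SIZE_RANGES = {
    "i0": (2, 6), "i1": (1, 1), "i2": (2, 2), "i3": (3, 3), "i4": (4, 4),
    "i5-9": (5, 9), "i10-19": (10, 19), "i20-39": (20, 39),
    "i40-699": (40, 699), "i700-4999": (700, 4999), "i100-4999": (100, 4999),
}
_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV_PARTNERS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def _sample_size(rng, lo: int, hi: int) -> int:
    if lo == hi:
        return lo
    # log-uniform over the range: small indels dominate wide classes
    return int(np.exp(rng.uniform(np.log(lo), np.log(hi + 1))))


def _sample_isolates(rng, isolates, mean: float) -> frozenset:
    k = min(int(rng.geometric(1.0 / mean)), len(isolates))
    chosen = rng.choice(len(isolates), size=max(k, 1), replace=False)
    return frozenset(isolates[i] for i in chosen)


def _synthesize(rng, seq: str, pos: int, label: str, L: int):
    """Build (start, end, ref, alt) for one variant of the given type at a
    physical position, reading alleles off the reference sequence."""
    if label in ("SNP_Ts", "SNP_Tv"):
        pos = min(pos, L - 1)
        ref = seq[pos]
        alt = (_TS_PARTNER[ref] if label == "SNP_Ts"
               else _TV_PARTNERS[ref][rng.integers(2)])
        return pos, pos + 1, ref, alt
    lo, hi = _SIZE_RANGES[label]
    size = _sample_size(rng, lo, hi)
    if label == "i0":
        pos = min(pos, L - size - 1)
        ref = seq[pos:pos + size]
        alt = "".join(_TS_PARTNER[b] for b in ref)  # every base differs
        return pos, pos + size, ref, alt
    if rng.random() < 0.5 and size < L - 2:  # deletion
        pos = int(np.clip(pos, 1, L - size - 1))
        ref = seq[pos:pos + size]
        return pos, pos + size, ref, ""
    pos = int(np.clip(pos, 1, L - 1))  # insertion before base at pos
    alt = BASES[rng.integers(0, 4, size)].tobytes().decode()
    return pos, pos, "", alt


def simulate_variants(genome: GenomeBundle, sim: SimulationParams):
    """Draw variants from the two-mechanism model.

    Per chromosome, the Morgan-origin count is Poisson(M*d x map length) with
    positions placed by inverse transform on the genetic map (density
    proportional to the local recombination rate); the Sanger-origin count is
    Poisson(M*d x R x physical Mb) with uniform positions.  Types are drawn
    from F_M or F_S according to origin, and each variant is carried by a
    random isolate subset (geometric sharing).  Deterministic given the seed.
    """
    rng = np.random.default_rng(sim.seed)
    p = sim.params
    labels = list(p.type_labels())
    fm = np.array([p.F_M[l] for l in labels])
    fs = np.array([p.F_S[l] for l in labels])
    out = []
    counter = 0
    for cmap in genome.maps:
        name, L = cmap.name, cmap.length
        seq = genome.sequences[name]
        G = cmap.genetic_length
        n_morgan = rng.poisson(p.M_d * G)
        n_sanger = rng.poisson(p.M_d * p.R * L / 1e6)
        morgan_pos = cmap.cm_to_bp(rng.uniform(0.0, G, n_morgan))
        sanger_pos = rng.uniform(0.0, L, n_sanger)
        morgan_types = rng.choice(len(labels), size=n_morgan, p=fm)
        sanger_types = rng.choice(len(labels), size=n_sanger, p=fs)
        positions = np.concatenate([morgan_pos, sanger_pos]).astype(int)
        types = np.concatenate([morgan_types, sanger_types])
        origins = np.concatenate([np.zeros(n_morgan, dtype=int),
                                  np.ones(n_sanger, dtype=int)])
        order = np.argsort(positions, kind="stable")
        for idx in order:
            label = labels[types[idx]]
            start, end, ref, alt = _synthesize(rng, seq, int(positions[idx]),
                                               label, L)
            counter += 1
            out.append(VariantRecord(
                chrom=name, start=start, end=end, ref=ref, alt=alt,
                isolates=_sample_isolates(rng, genome.isolates,
                                          sim.sharing_mean),
                source="morgan" if origins[idx] == 0 else "sanger",
                id=f"var{counter:07d}",
            ))
    return out


# ---------------------------------------------------------------------------
# Selection thinning


def apply_selection(variants, mode: str, sel=None, seed: int = 0,
                    maps=None, restrict_flag: str | None = None):
    """Thin a variant set.

    ``background`` mode retains each variant independently with a
    type-independent probability proportional to the background-selection
    factor at its local recombination rate, normalized so the maximum
    retention probability is 1 (``sel`` is a SelectionParams; ``maps`` supply
    the rates).  ``direct`` mode removes each variant with its type's removal
    probability (``sel`` is a {type label: probability} table, optionally
    restricted to variants whose ``restrict_flag`` annotation is set).
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    if mode == "background":
        if maps is None:
            raise ValueError("background mode needs genetic maps for rates")
        by_name = {m.name: m for m in maps}
        rates = np.array([by_name[v.chrom].rate_at(min(v.start,
                                                       by_name[v.chrom].length - 1))
                          for v in variants])
        factors = bgs_factor(rates, sel)
        retention = factors / factors.max()
        keep = rng.random(len(variants)) < retention
        return [v for v, k in zip(variants, keep) if k]
    if mode == "direct":
        table = dict(sel)
        out = []
        for v in variants:
            if restrict_flag is not None and not v.flags.get(restrict_flag):
                out.append(v)
                continue
            labels = v.classify().type_labels
            prob = max((p for k, p in table.items() if k in labels), default=0.0)
            if rng.random() >= prob:
                out.append(v)
        return out
    raise ValueError(f"unknown selection mode {mode!r}")


# ---------------------------------------------------------------------------
# Curation-artifact injection


def inject_artifacts(variants, sim: SimulationParams):
    """Corrupt a clean variant set the way real polymorphism tracks are
    corrupted, returning (corrupted records, ground-truth ledger).

    split: a multi-base equal-length substitution becomes per-base SNP
    records with the identical isolate set.  duplicate: a span record gains a
    partially overlapping copy.  overshadow: a SNP is planted strictly inside
    an existing deletion of one of its carriers.  At zero rates the input is
    returned unchanged.
    """
    rng = np.random.default_rng(sim.seed + 1)
    rates = sim.artifact_rates
    out, ledger = [], []
    extra_id = 0
    for v in variants:
        vc = v.classify()
        did_split = False
        if (rates.get("split", 0) > 0 and not vc.is_snp
                and len(v.ref) == len(v.alt) >= 2
                and all(a != b for a, b in zip(v.ref, v.alt))
                and rng.random() < rates["split"]):
            pieces = []
            for i, (a, b) in enumerate(zip(v.ref, v.alt)):
                extra_id += 1
                pieces.append(VariantRecord(
                    chrom=v.chrom, start=v.start + i, end=v.start + i + 1,
                    ref=a, alt=b, isolates=v.isolates, source=v.source,
                    id=f"art{extra_id:07d}"))
            out.extend(pieces)
            ledger.append({"kind": "split", "original": v.id,
                           "injected": [p.id for p in pieces]})
            did_split = True
        if not did_split:
            out.append(v)
        if (rates.get("duplicate", 0) > 0 and v.end - v.start >= 2
                and rng.random() < rates["duplicate"]):
            extra_id += 1
            dup = replace(v, start=v.start + 1, end=v.end + 1,
                          ref=("N" * len(v.ref) if v.ref else ""),
                          id=f"art{extra_id:07d}", flags=dict(v.flags))
            out.append(dup)
            ledger.append({"kind": "duplicate", "original": v.id,
                           "injected": [dup.id]})
        if (rates.get("overshadow", 0) > 0 and v.is_deletion
                and v.end - v.start >= 3
                and rng.random() < rates["overshadow"]):
            extra_id += 1
            iso = sorted(v.isolates)[0]
            ghost = VariantRecord(
                chrom=v.chrom, start=v.start + 1, end=v.start + 2,
                ref="A", alt="G", isolates=frozenset([iso]),
                source="artifact", id=f"art{extra_id:07d}")
            out.append(ghost)
            ledger.append({"kind": "overshadow", "original": v.id,
                           "injected": [ghost.id]})
    return out, ledger


# ---------------------------------------------------------------------------
# Writers (plain-text formats only)


def write_fasta(path, sequences) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_genetic_map_tsv(path, maps) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tbp\tcM\n")
        for m in maps:
            for bp, cm in m.anchors:
                fh.write(f"{m.name}\t{int(bp)}\t{cm:.6f}\n")


def write_features_gff3(path, features) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for kind, per_chrom in features.items():
            for chrom, spans in per_chrom.items():
                for i, (s, e) in enumerate(spans, 1):
                    fh.write(f"{chrom}\tsynthetic\t{kind}\t{s + 1}\t{e}\t.\t+\t."
                             f"\tID={kind}_{chrom}_{i}\n")


def write_expression_gff3(path, expression) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, segs in expression.items():
            for i, (s, e, depth) in enumerate(segs, 1):
                fh.write(f"{chrom}\tsynthetic\tcoverage\t{s + 1}\t{e}\t"
                         f"{depth:.3f}\t+\t.\tID=cov_{chrom}_{i}\n")


def write_wig_fixed(path, chromatin, step: int = 10) -> None:
    with open(path, "w") as fh:
        for chrom, values in chromatin.items():
            fh.write(f"fixedStep chrom={chrom} start=1 step={step} span={step}\n")
            for v in values:
                fh.write(f"{v:.4f}\n")


def write_dataset(outdir, genome: GenomeBundle, variants) -> None:
    """Emit a complete miniature dataset (FASTA, map TSV, feature and
    expression GFF3, fixed-step WIG, polymorphism GFF3)."""
    import os

    from .variant_io import write_polymorphism_gff3

    os.makedirs(outdir, exist_ok=True)
    join = lambda n: os.path.join(outdir, n)
    write_fasta(join("genome.fa"), genome.sequences)
    write_genetic_map_tsv(join("genetic_map.tsv"), genome.maps)
    write_features_gff3(join("features.gff3"), genome.features)
    write_expression_gff3(join("expression.gff3"), genome.expression)
    write_wig_fixed(join("chromatin.wig"), genome.chromatin)
    write_polymorphism_gff3(join("variants.gff3"), variants)
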