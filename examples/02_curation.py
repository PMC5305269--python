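"""Curation round trip: inject the defects seen in real polymorphism tracks,
then repair them.

Multi-base substitutions are split into adjacent per-base SNP records and
ghost records are planted inside deletions; merging adjacent same-carrier
records and censoring overshadowed records restores the original per-type
counts.
"""

import collections

import varscape as vs

chroms = [("c1", 6_000_000)]
domains = {"c1": [(1_500_000, 8.0), (3_000_000, 0.5), (1_500_000, 8.0)]}
genome = vs.make_genome(vs.SyntheticGenomeSpec(chromosomes=chroms,
                                               rate_domains=domains, seed=3))
params = vs.MutationModelParams(R=10.0, M_d=80.0)
clean = vs.simulate_variants(genome, vs.SimulationParams(params=params,
                                                         seed=4))

sim = vs.SimulationParams(params=params, seed=4,
                          artifact_rates={"split": 0.8, "overshadow": 0.5})
dirty, ledger = vs.inject_artifacts(clean, sim)
kinds = collections.Counter(entry["kind"] for entry in ledger)
print(f"clean records: {len(clean)};  corrupted records: {len(dirty)}")
print(f"injected artifacts: {dict(kinds)}")

repaired = vs.resolve_conflicts(vs.combine_adjacent(dirty))
baseline = vs.resolve_conflicts(vs.combine_adjacent(clean))


def type_counts(records):
    out = collections.Counter()
    for v in records:
        out[v.classify().category] += 1
    return out


print(f"after repair: {len(repaired)} records "
      f"(baseline pipeline on clean data: {len(baseline)})")
print(f"per-category counts match baseline: "
      f"{type_counts(repaired) == type_counts(baseline)}")
print()
print("Split-adjacency artifacts are exactly undone by adjacent-record")
print("merging, and every planted overshadowed record is censored by the")
print("per-isolate conflict resolution.")
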