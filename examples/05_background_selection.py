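"""The combined mutation + background-selection model.

Background selection removes linked neutral variants preferentially where
recombination is low, steepening the variant-density landscape without
touching composition.  This script thins a synthetic variant set with the
background-selection factor, re-fits the distribution (the apparent R drops),
estimates s_d on an M*d grid, and shows the closed-form distortion that
type-biased direct selection inflicts on the apparent R.
"""

import numpy as np

import varscape as vs
from varscape.selection_model import distortion_apparent_R, fit_sd

chroms = [("c1", 6_000_000), ("c2", 6_000_000), ("c3", 6_000_000)]
domains = {name: [(1_500_000, 8.0), (3_000_000, 0.5), (1_500_000, 8.0)]
           for name, _ in chroms}
genome = vs.make_genome(vs.SyntheticGenomeSpec(chromosomes=chroms,
                                               rate_domains=domains, seed=9))
truth = vs.MutationModelParams(R=10.0, M_d=1500.0)
variants = vs.simulate_variants(genome, vs.SimulationParams(params=truth,
                                                            seed=10))

sel = vs.SelectionParams(U=0.48, s_d=0.2, c=0.017)  # literature values
thinned = vs.apply_selection(variants, "background", sel=sel, seed=11,
                             maps=genome.maps)
print(f"variants: {len(variants)} before, {len(thinned)} after background "
      f"selection (F = {sel.F:.4f})")

intervals = vs.build_intervals(genome.maps, "pf")
records, weights = vs.select_population(thinned, mode="unique")
table = vs.count_by_interval(records, weights, intervals)
r = table.interval_info["r"].to_numpy()
n = table.interval_info["n_Mb"].to_numpy()
counts = table.counts["all"].to_numpy()

naive = vs.fit_distribution(r, n, counts)
print(f"mutation-model-only fit after thinning: apparent R = "
      f"{naive['R']:.1f} (mutation truth was 10) — selection masquerades as "
      f"a smaller R")

# thinning keeps the most-retained interval intact (retention normalized to
# max 1), which rescales the recoverable M*d upward relative to the
# pre-selection 1500; the grid spans that effective scale
rows, best = fit_sd(r, n, counts, R_presumed=10.0,
                    md_grid=np.linspace(4000, 12000, 9), U=0.48, c=0.017)
print("combined-model s_d estimates on the M*d grid (presumed R = 10):")
for row in rows:
    star = " <- best p" if best and row["M_d"] == best["M_d"] else ""
    flag = "" if row["in_range"] else "  (outside (0,1])"
    print(f"  M*d = {row['M_d']:6.0f}  s_d = {row['s_d']:8.3f} "
          f"+/- {row['se']:.3f}  p = {row['p']:.2g}{star}{flag}")

out = distortion_apparent_R(
    vs.MutationModelParams(
        R=10.0, M_d=1500.0,
        F_M={"SNP_Ts": 0.4, "SNP_Tv": 0.4, "i1": 0.2},
        F_S={"SNP_Ts": 0.35, "SNP_Tv": 0.35, "i1": 0.3}), q=0.5)
print(f"direct selection removing 50% of non-SNPs: apparent R = "
      f"{out['R_prime']:.3f} (true 10), refit agreement "
      f"{out['refit_max_abs_diff']:.1e}")
print()
print("Background selection changes the distribution but not composition;")
print("type-biased direct selection shifts the apparent R by the exact")
print("closed form R' = R(1-q(1-F_S))/(1-q(1-F_M)).")
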