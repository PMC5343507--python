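"""Correlate fitness landscapes of orthologues over the four position sets.

The trio generator builds three 80-position landscapes whose per-position
amino-acid profiles share a common signal with mixing weight rho = 0.6.
Profiles are Pearson-correlated over (a) identical-WT pairs, (b) aligned
pairs, (c) aligned pairs with differing WT, (d) four-fold symmetric pairs,
and each distribution is contrasted with the all-pairs null by a
two-sample KS test.
"""

import timscan as ts

cfg = ts.LandscapeTrioConfig(n_positions=80, rho=0.6, wt_policy="sampled", seed=4)
landscapes, maps = ts.simulate_landscape_trio(cfg)
a, b = landscapes["orthoA"], landscapes["orthoB"]
amap = maps[("orthoA", "orthoB")]

null = ts.correlation_distribution(
    a, b, ts.build_position_set(a, b, "null_all_pairs"), "null_all_pairs"
)
print(f"{'set':24s} {'n':>5s} {'mean R':>7s} {'mode':>6s} {'KS p vs null':>12s}")
for label in ("identical_wt", "aligned", "aligned_nonidentical", "fourfold"):
    pairs = ts.build_position_set(a, b, label, alignment=amap)
    dist = ts.correlation_distribution(a, b, pairs, label)
    _, p = ts.compare_distributions_ks(dist, null)
    print(
        f"{label:24s} {len(dist.r_values):5d} {dist.r_values.mean():7.3f} "
        f"{dist.mode:6.2f} {p:12.2e}"
    )
print(f"{'null_all_pairs':24s} {len(null.r_values):5d} {null.r_values.mean():7.3f} "
      f"{null.mode:6.2f}")
# Aligned and four-fold sets inherit the shared signal (mean R near rho);
# the all-pairs null centers on zero, and the KS test separates them.
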