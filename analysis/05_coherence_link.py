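"""HC-EC synchronization and representation strength.

First tests the cross-trial correlation between HC context and EC object
strengths (sign-flip cluster test), then correlates each trial's z-scored
imaginary coherence (per band) with the strengths averaged over the
0.65-0.80 s window, and tests the Fisher-z correlations at the group level
with BH-FDR over bands.  (The generator's shared gain is sustained over the
whole movement period, so the cross-trial coupling has no genuine temporal
localization to derive a window from; the configured window is used.)
"""

import json

import numpy as np

from _cohort import RESULTS, get_cohort
from navrsa.connectivity import group_band_correlation
from navrsa.stats import cluster_perm_signflip

study = get_cohort()
X = study.cross_trial_matrix()
ct = cluster_perm_signflip(np.nan_to_num(X), rng=3)
print(f"cross-trial HC-EC strength correlation: mean z "
      f"{np.nanmean(X):+.3f}, cluster p = {ct.min_p:.3f}")
widx = study.run_cfg.scheme.window_interval(*study.run_cfg.strength_window)
centers = study.run_cfg.scheme.centers_s
print(f"strength window: {centers[widx[0]]:.2f}-{centers[widx[-1]]:.2f} s")

out = dict(cross_trial_mean_z=float(np.nanmean(X)),
           cross_trial_cluster_p=ct.min_p,
           window_s=[float(centers[widx[0]]), float(centers[widx[-1]])])
for kind in ("object", "context"):
    Z = study.coherence_strength_z(kind, widx)
    g = group_band_correlation(Z)
    print(f"\ncoherence vs {kind} representation strength "
          f"(n = {len(Z)} subjects):")
    print(g.round(4).to_string())
    g.to_csv(RESULTS / f"coherence_{kind}_correlation.tsv", sep="\t")
    out[kind] = {b: dict(mean_z=float(g.loc[b, "mean_z"]),
                         p=float(g.loc[b, "p"]),
                         p_fdr=float(g.loc[b, "p_fdr"]))
                 for b in g.index}
(RESULTS / "coherence_link.json").write_text(json.dumps(out, indent=2))
print(f"\nwrote {RESULTS / 'coherence_link.json'}")
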