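"""Cross-phase predictability: does responding during acquisition predict
fear recall, extinction, and reinstatement-test responding?

Runs HC3 robust regressions over the default specification grid (11
predictor -> criterion pairs x stimulus x transform x ranking) and pools
standardized betas across specifications.
"""

import condrel as cr
from condrel.crossphase import PredictionSpec

scr, ratings = cr.simulate_cohort(cr.CohortConfig(n_participants=60, seed=4))
table = cr.apply_trial_exclusions(scr)

# build measures for every transform x ranking combination
frames = []
for tr in ("RAW", "LOG", "LOG_RC"):
    for rk in (False, True):
        m = cr.phase_measures(cr.apply_transform(table, tr))
        if rk:
            m = cr.rank_phase_measures(m)
        m["transform"], m["ranked"] = tr, rk
        frames.append(m)
import pandas as pd

measures = pd.concat(frames, ignore_index=True)

specs = [PredictionSpec(p, c, stim, tr, rk)
         for p, c in cr.default_prediction_pairs()
         for stim in ("CSP", "CSM", "DISC")
         for tr in ("RAW", "LOG", "LOG_RC")
         for rk in (False, True)]
grid = cr.predict_grid(measures, specs)
print(f"grid of {len(grid)} regressions; "
      f"{grid.significant.sum()} significant at two-sided alpha = 0.05")

top = grid.dropna(subset=["beta_std"]).nlargest(3, "beta_std")
for _, row in top.iterrows():
    print(f"  {row['predictor']} -> {row['criterion']} ({row['stimulus']}, "
          f"{row['transform']}, ranked={row['ranked']}): "
          f"beta = {row['beta_std']:.3f} ({row['strength']}), p = {row['p']:.4f}")

# pooled contrast: CS discrimination betas vs CS+ betas across the grid
res = cr.pooled_beta_comparison(grid, "stimulus", "DISC", "CSP")
print(f"pooled DISC vs CS+ betas: {res.method} t = {res.statistic:.2f}, "
      f"df = {res.df:.0f}, p = {res.p:.4g}, d = {res.cohens_d:.2f}")
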