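"""Simulate a two-timepoint fear-conditioning cohort with known ground truth.

Generates trial-level skin-conductance amplitudes and fear ratings for the
2-day protocol (habituation + acquisition on day 1; extinction,
reinstatement, reinstatement-test on day 2), run twice six months apart.
"""

import condrel as cr

cfg = cr.CohortConfig(n_participants=40, seed=1, nonresponder_fraction=0.05)
scr, ratings = cr.simulate_cohort(cfg)

print(scr.head(8).to_string(index=False))
print(f"\n{len(scr)} SCR trials, {len(ratings)} ratings, "
      f"{scr.participant.nunique()} participants")
print(f"zero-response fraction: {(scr.value == 0).mean():.3f}")

# closed-form reliability implied by the CS+ variance components: the ICC of
# the 13-trial acquisition average that the estimators should recover
comp = cfg.components["CSP"]
print(f"true ICC of a 13-trial average (CS+ components): {cr.true_icc(comp, 13):.3f}")

flags = cr.flag_nonresponders(scr)
n_flagged = flags[flags.nonresponder].participant.nunique()
print(f"participants flagged as US non-responders: {n_flagged}")
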