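"""Combine a significant original study with its replication.

A hypothetical two-group experiment: the original reports t(78) = 2.211
(n = 40 per group, two-tailed p = .03), the replication — twice as large
— reports t(158) = 1.040 (p = .30). How big is the effect, once we
account for the original having been selected for significance?
"""

import hybridmeta as hm

original = hm.g_from_t(2.211, 40, 40)       # Hedges' g = 0.490
replication = hm.g_from_t(1.040, 80, 80)    # Hedges' g = 0.164
pair = hm.StudyPair(original=original, replication=replication)

print(f"original     g = {original.y:.3f}  (weight {1 / original.variance:.3f})")
print(f"replication  g = {replication.y:.3f}  (weight {1 / replication.variance:.3f})")
print()

for name, res in hm.analyze_pair(pair).items():
    print(f"{name:13s} {res.estimate: .3f}  "
          f"95% CI ({res.ci_low: .3f}, {res.ci_high: .3f})  "
          f"p = {res.p_two_tailed:.3f}")

advice = hm.advise_method(80, 160, "uncertain")
print(f"\nguideline {advice.guideline_id}: interpret the "
      f"{advice.recommended.value} result")
print(f"observed power of the original at d = {replication.y:.3f}: "
      f"{hm.observed_power(replication.y, 40, 40, 0.05):.2f}")

# Fixed-effect pooling says 0.270 and significant; the selection-corrected
# hybrid says 0.103 and far from significant -- the original's "medium"
# effect carries little evidence once its significance filter is undone.
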