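"""Correlations as the effect measure.

Effects are Fisher-transformed internally (variance 1/(n-3), normal
sampling backend) and reported back as correlations.
"""

import hybridmeta as hm

pair = hm.StudyPair(
    original=hm.z_from_r(0.45, 55),      # significant at two-tailed .05
    replication=hm.z_from_r(0.10, 96),
    rule=hm.SignificanceRule(alpha=0.05, direction="positive"),
)

for name, res in hm.analyze_pair(pair).items():
    rep = res.report()  # back-transformed to the r scale
    print(f"{name:13s} r = {rep['estimate']: .3f}  "
          f"95% CI ({rep['ci_low']: .3f}, {rep['ci_high']: .3f})  "
          f"p = {rep['p_two_tailed']:.3f}")

advice = hm.advise_method(55, 96, "uncertain")
print(f"\nguideline {advice.guideline_id}: interpret the "
      f"{advice.recommended.value} result")

# The replication is larger than the original, so under uncertainty about
# the true effect the guidelines say to trust the replication alone.
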