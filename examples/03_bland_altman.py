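"""Bland-Altman agreement before and after calibration.

The absolute mean difference E|a-b| (with its SD) is the headline "bias"
statistic: unlike the signed mean difference it cannot be driven to zero by
symmetric scatter, so it reflects how far a single reading can actually be
from the truth.  The a-priori validity rule asks every pair to agree within
10 mmHg systolic / 5 mmHg diastolic.
"""
import numpy as np

from wristbp import (
    ProtocolConfig,
    assemble_day2_pairs,
    bland_altman,
    calibrate_pairs,
    improvement_metrics,
    pairs_to_arrays,
    simulate_cohort,
    simulate_study,
    validity_check,
)
from wristbp.core import Channel

cohort = simulate_cohort(20, seed=5)
dataset = simulate_study(cohort, ProtocolConfig(independent_measurements=0), seed=6)
pairs = []
for p in cohort:
    radial, _ = assemble_day2_pairs(dataset.day2_session(p.patient_id))
    pairs += radial

jackknife = calibrate_pairs(pairs)
for channel in Channel:
    dev, ref = pairs_to_arrays(pairs, channel)
    pre = bland_altman(dev, ref, channel)
    jk = jackknife[channel]
    post = bland_altman(jk.calibrated, jk.reference, channel)
    imp = improvement_metrics(pre, post)
    print(f"{channel.value} vs intra-radial (n={pre.n}):")
    print(f"  pre-calibration : AMD {pre.absolute_mean_difference:5.1f} "
          f"(SD {pre.sd_absolute:4.1f}) mmHg, signed {pre.signed_mean_difference:+5.1f}, "
          f"LoA [{pre.limits_of_agreement[0]:.1f}, {pre.limits_of_agreement[1]:.1f}]")
    print(f"  post-calibration: AMD {post.absolute_mean_difference:5.1f} "
          f"(SD {post.sd_absolute:4.1f}) mmHg, paired p {post.paired_p:.2f}")
    print(f"  accuracy improvement {imp.accuracy_improvement_rounded}%, "
          f"validity rule pre/post: {validity_check(pre)}/{validity_check(post)}\n")
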