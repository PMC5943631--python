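"""Jackknife leave-one-out calibration of the wrist cuff against the aorta.

Simulates the Day-2 schedule for 20 patients with the default miscalibrated
device, pools the wrist/intra-aortic simultaneous pairs, and calibrates each
channel: every pair is held out once, the remaining pairs fit an affine
(intercept + slope) map from device output to reference pressure, and the
fit is applied to the held-out device value.  The deployed model (fit on all
pairs) is what a manufacturer would ship; the held-out values are what the
agreement analysis consumes, because they were never used to fit the model
that produced them.
"""
import numpy as np

from wristbp import (
    ProtocolConfig,
    assemble_day2_pairs,
    calibrate_pairs,
    simulate_cohort,
    simulate_study,
)
from wristbp.core import Channel

cohort = simulate_cohort(20, seed=3)
dataset = simulate_study(cohort, ProtocolConfig(independent_measurements=0), seed=4)

aortic_pairs = []
for p in cohort:
    _, aortic = assemble_day2_pairs(dataset.day2_session(p.patient_id))
    aortic_pairs += aortic
print(f"pooled {len(aortic_pairs)} wrist/intra-aortic simultaneous pairs")

results = calibrate_pairs(aortic_pairs)
for channel in Channel:
    jk = results[channel]
    resid = jk.held_out_residuals
    print(f"\n{channel.value}:")
    print(f"  deployed model: calibrated = {jk.deployed.intercept:+.2f} "
          f"+ {jk.deployed.slope:.3f} x device   (n={jk.deployed.n_training})")
    print(f"  held-out |error|: mean {np.mean(np.abs(resid)):.2f} mmHg "
          f"(device raw: {np.mean(np.abs(jk.device - jk.reference)):.2f} mmHg)")
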