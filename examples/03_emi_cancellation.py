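"""Full EMI-cancellation workflow: simulate, train, cancel, evaluate.

Runs the complete pipeline on a 64x64 single-slice FSE scan contaminated by
broadband plus 50 Hz-harmonic EMI at ~20x the receiver-noise power.  By
default the linear least-squares baseline is used (seconds); pass --cnn to
train the five-layer CNN exactly at the published hyper-parameters instead
(a few minutes on one CPU core).  Prints the background-noise std of the
contaminated, cancelled and shielded reconstructions and the shielded-
equivalence verdict (the 5% criterion).
"""

import sys

from ulfmri.pipeline import RunConfig, run_pipeline

use_cnn = "--cnn" in sys.argv
cfg = RunConfig(seed=1, canceller="cnn" if use_cnn else "linear")
print(f"canceller: {cfg.canceller} "
      f"({'~4 min' if use_cnn else 'seconds; pass --cnn for the CNN'})")

res = run_pipeline(cfg)
rep = res.report
for arm in ("contaminated", "cancelled", "shielded"):
    print(f"background noise std, {arm:13s}: {rep.sigma_bg[arm]:.5f}")
print(f"shielded deviation: {100 * rep.shielded_deviation:.2f}% "
      f"-> {'PASS' if rep.pass_5pct else 'FAIL'} (criterion: within 5%)")
print(f"EMI-band suppression: {rep.suppression_db:.1f} dB")
print("\nThe deviation compares the cancelled image's background noise with")
print("the EMI-free shielded twin that shares the same MRI signal and")
print("receiver-noise realization — the ground truth a shielding cage gives.")
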