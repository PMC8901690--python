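"""Direct estimation vs block-matching speckle tracking across image quality.

Runs the direct spectral method (LTC) and the two conventional baselines
(DCC: normalized spatial block matching; FTC: spectral block matching)
on the same LV phantom at high and low contrast-to-noise ratio.  The
block matchers track a myocardial boundary through displacement fields
and read strain from its arc length; their accuracy depends on image
quality, while the spectral estimate degrades far less.
"""

import logging

import numpy as np

from ltcstrain import pipeline
from ltcstrain.registration import Landmarks
from ltcstrain.synthetic_phantom import lv_phantom

logging.disable(logging.WARNING)

for cnr in (8.0, 2.0):
    seq, truth = lv_phantom(peak_strain=-15.0, n_frames=20, cnr=cnr, seed=3)
    peak = np.abs(truth.gls_truth).max()
    print(f"\nCNR {cnr:.0f} dB (truth peak GLS {peak:.1f} %):")
    res = pipeline.analyze_ltc(seq, Landmarks.from_array(truth.landmarks[0]))
    nmae = np.abs(res.gls.gls - truth.gls_truth).mean() / peak
    print(f"  LTC: peak {res.metrics.gls_p:5.1f} %   normalized MAE {nmae:.3f}")
    for kernel in ("ftc", "dcc"):
        r = pipeline.analyze_ste(seq, truth.boundary[0], kernel=kernel)
        nmae = np.abs(r.gls.gls - truth.gls_truth).mean() / peak
        print(f"  {kernel.upper()}: peak {r.metrics.gls_p:5.1f} %   "
              f"normalized MAE {nmae:.3f}")

print("\nLower normalized MAE is better; the baselines lose accuracy at "
      "low CNR while the direct estimate barely moves.")
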