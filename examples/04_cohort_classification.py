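"""Separate impaired from normal ventricles by peak strain.

Builds two small phantom cohorts — normal function (peak GLS -18%) and
impaired function (peak GLS -9%), at mixed image quality — measures each
subject's peak absolute GLS with the direct estimator, and evaluates the
classifier with a bootstrap ROC analysis (lower |GLS| indicates disease).
Scaled-down version of a clinical reader study.
"""

import logging

import numpy as np

from ltcstrain import pipeline
from ltcstrain.evaluation import roc_analysis
from ltcstrain.registration import Landmarks
from ltcstrain.synthetic_phantom import lv_phantom

logging.disable(logging.WARNING)
CNRS = (2.0, 4.0, 8.0)


def cohort(peak_strain, seed0, n=4):
    vals = []
    for i in range(n):
        seq, truth = lv_phantom(peak_strain=peak_strain, n_frames=20,
                                cnr=CNRS[i % 3], seed=seed0 + i)
        res = pipeline.analyze_ltc(seq, Landmarks.from_array(truth.landmarks[0]))
        vals.append(res.metrics.gls_p)
    return vals


impaired = cohort(-9.0, 100)
normal = cohort(-18.0, 200)
print("impaired GLS_P (%):", np.round(impaired, 1))
print("normal   GLS_P (%):", np.round(normal, 1))

roc = roc_analysis(impaired, normal, n_resamples=500, seed=0)
print(f"\nAUC = {roc.auc:.2f}  (95% bootstrap CI {roc.auc_ci[0]:.2f}-{roc.auc_ci[1]:.2f})")
print(f"Youden index = {roc.yi:.2f}, distance to corner = {roc.corner_distance:.2f}")
print("AUC near 1 means peak GLS cleanly separates the two function states.")
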