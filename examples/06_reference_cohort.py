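"""Worked example on the published reference cohort tables.

Recomputes the derived OFR columns (OFR = mean_up - mean_dw, combined SD,
SEM) from each subject's printed per-direction moments and applies the 0.05
classification threshold to the printed comparison p-values.
"""

import numpy as np

from ofrlab.datasets import reference_cohort, reference_comparison_pvalues
from ofrlab.stats import classify_cohort

ref = reference_cohort()
ref["ofr"] = ref.mean_up - ref.mean_dw
ref["ofr_sd"] = np.hypot(ref.sd_up, ref.sd_dw)
ref["ofr_sem"] = np.sqrt(ref.sd_up**2 / ref.n_up + ref.sd_dw**2 / ref.n_dw)

print("recomputed vs printed derived columns (correlated condition):")
view = ref[ref.condition == "correlated"][
    ["subject", "ofr", "ofr_printed", "ofr_sd", "ofr_sd_printed", "ofr_sem", "ofr_sem_printed"]
]
print(view.round(3).to_string(index=False))

pvals = reference_comparison_pvalues()
for group in ("control", "patient"):
    res = classify_cohort(pvals.loc[pvals.group == group, "p_comparison"], alpha=0.05)
    print(f"\n{group}s: {res['n_sensitive']} of {res['n_subjects']} "
          "flagged sensitive to interocular correlation")
# Expected: 5 of 6 stereo-normal controls flagged, 0 of 6 stereo-deficient
# patients — the separation that motivates the OFR-based screening idea.
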