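"""Two-arm synthetic study: wild-type-like vs mutant-like embryos.

Runs both end-to-end pipelines on six simulated embryos per arm.  The
mutant arm is programmed with slower (0.8 vs 1.2 µm/min), less coordinated
(rho 0.2 vs 0.8) migration and a broadened basal marker peak (FWHM 2.0 vs
1.3 µm) — the directions of change seen when basal-lamina cues fail.  The
group comparison should report significantly lower velocity and
coordination and a significantly larger FWHM in the mutant arm.
"""

import tempfile
import warnings

from metquant.pipeline import run_profile_pipeline, run_tracking_pipeline
from metquant.studies import profile_contrast_config, tracking_contrast_config

with tempfile.TemporaryDirectory() as scratch:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tracking = run_tracking_pipeline(tracking_contrast_config(seed=1), scratch)
        profile = run_profile_pipeline(profile_contrast_config(seed=1), scratch)

print("tracking: mutant vs wild type (unpaired two-tailed t test on embryo means)")
pairwise = tracking["group"].pairwise
print(
    pairwise[["cell_type", "metric", "t", "p", "stars"]].to_string(index=False)
)
print(
    "\nnegative t = mutant below wild type; stars: * p≤0.05 ** p≤0.01 *** p≤0.001"
)

print("\nbasal peak metrics: mutant vs wild type")
print(
    profile["peak_stats"][
        ["metric", "mean", "control_mean", "t", "p", "stars"]
    ].to_string(index=False)
)
print(
    "\nThe FWHM row shows the programmed broadening (≈2.0 vs ≈1.3 µm) recovered"
    "\nby the pipeline with high confidence; amplitude differs only within noise."
)
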