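"""Quantify nuclear marker levels across two developmental states.

Builds synthetic fixed images for two groups of six embryos in which the
nuclei carry either high (pre-transition) or low (post-migration) levels
of a nuclear marker, measures the mean gray value of 30 elliptical nucleus
ROIs per embryo, and compares the embryo means with an unpaired two-tailed
t test — the scheme used to show a transcription factor being switched off
after migration.
"""

import numpy as np
from scipy import stats

from metquant.profiler import nuclear_mean_gray

rng = np.random.default_rng(7)


def embryo_value(level: float) -> float:
    """One embryo: 30 nuclei of the given mean intensity over background."""
    image = rng.normal(5.0, 1.0, (150, 150))
    centers = rng.uniform(12, 138, (30, 2))
    yy, xx = np.indices(image.shape)
    for cy, cx in centers:
        mask = ((yy - cy) / 4) ** 2 + ((xx - cx) / 4) ** 2 <= 1.0
        image[mask] = rng.normal(level, 2.0)
    rois = [(cy, cx, 4, 4) for cy, cx in centers]
    return nuclear_mean_gray(image, rois)


pre = [embryo_value(110.0) for _ in range(6)]
post = [embryo_value(45.0) for _ in range(6)]
t, p = stats.ttest_ind(pre, post)

print("nuclear mean gray per embryo (n = 30 nuclei each):")
print("  pre-transition :", np.round(pre, 1))
print("  post-migration :", np.round(post, 1))
print(f"\nunpaired two-tailed t test: t = {t:.2f}, p = {p:.2e}")
print(
    "The drop in nuclear mean gray quantifies down-regulation of the marker"
    "\nafter migration; p < 0.001 at this programmed effect size."
)
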