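"""Measure apicobasal marker peaks on a synthetic columnar epithelium.

Renders a cross-section with a sharp apical peak (amplitude 120, FWHM
1.0 µm at 2 µm along the line) and a broader basal peak (amplitude 100,
FWHM 1.3 µm at 17 µm), runs the preprocessing chain (paraboloid background
subtraction + 3% stack-histogram threshold), extracts 60-px-wide line
profiles for each of 10 cells, averages them into an embryo profile, and
reports windowed peak amplitude and FWHM.
"""

import warnings

import numpy as np

from metquant.pipeline import ConditionSpec, ProfileConfig, process_profile_image
from metquant.profiler import LineROI
from metquant.peaks import measure_peak
from metquant.synthio import EpitheliumSimParams, PeakSpec, simulate_epithelium

params = EpitheliumSimParams(
    peaks=(PeakSpec(2.0, 120.0, 1.0), PeakSpec(17.0, 100.0, 1.3)),
    margin_rows_px=900,
    background_level=6.0,
    background_gradient=4.0,
    seed=1,
)
image, truth = simulate_epithelium(params)
print(f"epithelium image: {image.shape} px at {params.pixel_size_um} µm/px")

cfg = ProfileConfig(conditions={"demo": ConditionSpec(simulate={})})
px = params.pixel_size_um
rois = [
    LineROI(
        (row.y_start_um, row.x_center_px * px),
        (row.y_end_um, row.x_center_px * px),
        width_px=60,
    )
    for row in truth.lines.itertuples()
]
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    embryo_profile = process_profile_image(image, rois, px, cfg)

print(
    f"embryo profile: {len(embryo_profile.distances_um)} samples over "
    f"{embryo_profile.length_um:.1f} µm (apical→basal), n = {embryo_profile.n} cells"
)
for label, window, programmed in (
    ("apical", (0.0, 10.0), (120.0, 1.0)),
    ("basal", (10.0, 20.0), (100.0, 1.3)),
):
    pm = measure_peak(embryo_profile, window, "demo", "marker", label)
    print(
        f"{label:>6}: amplitude {pm.amplitude:6.1f} (programmed {programmed[0]:.0f}), "
        f"position {pm.peak_position_um:5.2f} µm, "
        f"FWHM {pm.fwhm_um:.2f} µm (programmed {programmed[1]:.1f})"
    )
print(
    "\nAmplitudes report relative protein levels; FWHM reports how tightly"
    "\nthe marker is localized — broadening signals loss of polarity."
)
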