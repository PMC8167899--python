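"""Canonical synthetic study designs.

These bundle the generator and pipeline settings used to validate the
package end to end: a wild-type-like arm at the canonical migration
parameters, a "mutant-like" arm with programmed deficits in speed,
coordination, and basal-peak spread, and a set of epithelium conditions
spanning the peak-width regimes the profile pipeline must resolve.  Problem
sizes are kept compact (smaller fields, fewer nuclei per embryo) so a full
multi-seed study runs on a laptop in minutes; the programmed biology —
speeds, coordination levels, peak geometry, six embryos per arm — follows
the study design the package emulates.
"""

from __future__ import annotations

from .pipeline import PipelineConfig

__all__ = [
    "tracking_contrast_config",
    "profile_contrast_config",
    "fwhm_recovery_conditions",
    "CONTRAST_MOVIE_SHAPE",
]

# Compact movie geometry for multi-embryo contrast studies: 12 frames
# (22 min), 12 z-slices, 80x80 µm field, 6+6 nuclei per embryo.
CONTRAST_MOVIE_SHAPE = (12, 12, 160, 160)

_CONTRAST_MOVIE_BASE = {
    "image_shape_voxels": CONTRAST_MOVIE_SHAPE,
    "n_pmec": 6,
    "n_icp": 6,
    "min_separation_um": 6.0,
}


def tracking_contrast_config(seed: int, n_embryos: int = 6) -> PipelineConfig:
    """Two-arm tracking study: wild-type-like vs slow/uncoordinated mutant.

    The mutant arm migrates at 2/3 the wild-type speed with most of the
    step coordination removed, mirroring the direction (not the magnitude)
    of laminin-mutant migration defects.
    """
    return PipelineConfig(
        seed=seed,
        tracking={
            "control": "wild_type",
            "min_tracks_warn": 5,
            "conditions": {
                "wild_type": {
                    "n_embryos": n_embryos,
                    "simulate": {
                        **_CONTRAST_MOVIE_BASE,
                        "speed_um_per_min": 1.2,
                        "coordination_rho": 0.8,
                    },
                },
                "mutant": {
                    "n_embryos": n_embryos,
                    "simulate": {
                        **_CONTRAST_MOVIE_BASE,
                        "speed_um_per_min": 0.8,
                        "coordination_rho": 0.2,
                    },
                },
            },
        },
    )


# Compact epithelium geometry for multi-embryo profile studies.
_CONTRAST_EPI_BASE = {
    "n_cells": 10,
    "cell_width_px": 40,
    "margin_rows_px": 800,
    "background_level": 4.0,
    "background_gradient": 3.0,
}


def profile_contrast_config(seed: int, n_embryos: int = 6) -> PipelineConfig:
    """Two-arm profile study: narrow vs broadened basal marker peak.

    The wild-type-like arm carries a basal peak of 1.3 µm FWHM; the mutant
    arm the ~2 µm spread seen when basal polarity fails.  Amplitudes are
    equal so the contrast is purely in peak width.
    """
    return PipelineConfig(
        seed=seed,
        profile={
            "control": "wild_type",
            "marker": "basal_marker",
            "line_width_px": 30,
            "windows": {"basal": (10.0, 20.0)},
            "conditions": {
                "wild_type": {
                    "n_embryos": n_embryos,
                    "simulate": {
                        **_CONTRAST_EPI_BASE,
                        "peaks": [[14.0, 100.0, 1.3]],
                    },
                },
                "mutant": {
                    "n_embryos": n_embryos,
                    "simulate": {
                        **_CONTRAST_EPI_BASE,
                        "peaks": [[14.0, 100.0, 2.0]],
                    },
                },
            },
        },
    )


def fwhm_recovery_conditions() -> dict[str, dict]:
    """Epithelium conditions spanning the peak-width regimes of interest.

    Three conditions carry apical/basal Gaussian peaks whose programmed
    FWHMs cover {0.8, 1.0, 1.3, 1.8, 2.0, 2.4} µm — the narrow wild-type
    and broadened mutant spreads the peak metrics must distinguish.
    """
    base = {
        "n_cells": 10,
        "margin_rows_px": 1700,
        "background_level": 4.0,
        "background_gradient": 3.0,
    }
    return {
        "narrow": {**base, "peaks": [[2.0, 120.0, 0.8], [17.0, 100.0, 1.0]]},
        "mid": {**base, "peaks": [[2.0, 120.0, 1.3], [17.0, 100.0, 1.8]]},
        "broad": {**base, "peaks": [[2.0, 120.0, 2.0], [17.0, 100.0, 2.4]]},
    }
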