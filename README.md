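# metquant

Quantitative image analysis for studies of epithelial transitions in the
*Drosophila* embryonic midgut (and similar collectively migrating,
repolarizing tissues).  The package implements two measurement pipelines
plus the synthetic ground-truthed data needed to validate them without
access to raw embryo movies:

1. **4D nucleus tracking** — drift estimation and compensation on
   time-lapse z-stacks, anisotropy-adjusted 3D Laplacian-of-Gaussian blob
   detection with strongest-minima pruning, frame-to-frame constrained
   linear-assignment linking, curation to full-span tracks, nuclear-
   diameter cell-type classification (PMEC < 3.5 µm, ICP > 5.5 µm), and
   migration statistics: velocity (mean instantaneous 3D speed, µm/min),
   directional persistence (net displacement / path length), and
   coordination (velocity correlation with the nearest neighbouring
   track).
2. **Apicobasal fluorescence profiling** — the ImageJ-style preprocessing
   chain (8-bit, invert, sliding-paraboloid background subtraction, 3%
   stack-histogram threshold), 60-px-wide line profiles from 1 µm above
   the apical membrane to 1 µm below the basal mesoderm surface, cell →
   embryo → condition averaging, windowed peak amplitude and full width at
   half maximum (apical 0–10 µm, basal 10–20 µm), nuclear mean-gray
   levels, and mutant-vs-control statistics (unpaired two-tailed t tests,
   one-way ANOVA, mean ± SEM/SD plots).

Both pipelines are driven from Python (see `examples/`) or from a thin CLI
(`metquant simulate-movie | simulate-epithelium | track | profile |
explain-defaults`).

## The statistics at the core

For a track with positions x₀ … x_T (µm, one per frame, Δt = 2 min):

* instantaneous speed  vₜ = ‖xₜ₊₁ − xₜ‖ / Δt
* velocity  v̄ = mean(vₜ)
* directional persistence  P = ‖x_T − x₀‖ / Σₜ ‖xₜ₊₁ − xₜ‖  ∈ [0, 1]
* coordination  C = corr(u, w), where u and w stack the (z, y, x)
  components of the track's and its nearest neighbour's instantaneous
  velocity series.

For an embryo-level intensity profile I(s) along the apical→basal axis,
peak amplitude is max I(s) within a window and FWHM is the distance
between the half-maximum crossings on either flank of that peak
(for a Gaussian peak, FWHM = 2√(2 ln 2)·σ ≈ 2.355 σ).

## Worked example

```python
from metquant import MovieSimParams, simulate_movie
from metquant.pipeline import TrackingConfig, ConditionSpec, process_movie
from metquant.validate import match_tracks_to_ground_truth

movie, truth = simulate_movie(MovieSimParams(seed=3))   # 15+15 nuclei, 31 frames
cfg = TrackingConfig(conditions={"wt": ConditionSpec(simulate={})})
result = process_movie(movie, cfg, embryo_id="demo")
print(result["embryo_summary"][["cell_type", "n_tracks",
                                "velocity_um_per_min",
                                "directional_persistence", "coordination"]])
matches = match_tracks_to_ground_truth(result["tracks"], truth)
print("recovered:", matches["classified_correctly"].mean())
```

prints (seed 3):

```
  cell_type  n_tracks  velocity_um_per_min  directional_persistence  coordination
0       ICP        15             1.376969                 0.995132      0.973665
1      PMEC        15             1.362613                 0.993735      0.972637
recovered: 1.0
```

All 30 ground-truth nuclei come back as full-length, correctly classified
tracks.  The measured velocity (~1.37 µm/min) matches the programmed
acquisition-frame motion — the 1.2 µm/min directed step plus the constant
global drift gives ‖v·Δt·û + d‖/Δt = 1.359 µm/min — within ~1%, and
persistence ≈ 0.99 reflects nearly straight directed migration.  The
`examples/` scripts walk through the profile pipeline and the two-arm
group comparison the same way, printing the numbers they compute and what
they mean.

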