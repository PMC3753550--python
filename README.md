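# apicoquant

Quantitative image analysis of apical plasma-membrane remodelling in
fluorescence time-lapse microscopy, built for the cellularizing
*Drosophila* embryo and similar epithelial systems: during
cellularization the apical surface flattens — villous membrane
protrusions retract over ~40 min — while apical early endosomes
(Rab5-positive puncta) proliferate and endocytic cargo is trafficked
basally past the advancing cellularization furrow.

The package provides five measurement pipelines over calibrated TIFF
stacks, plus a seeded synthetic-scene generator that supplies ground
truth for every stage:

| pipeline | readout |
|---|---|
| `coverage_timeseries` | fractional apical coverage by protrusions per frame: bleach correction → oriented Mexican-hat filter bank (Ricker × Gaussian, σx=7, σy=1 px, 18 orientations over [0, π)) → orientation maximum-intensity projection → Otsu segmentation → skeleton-pixel density; conditions compared with an exact small-sample Kolmogorov–Smirnov test |
| `puncta_timeseries` | puncta count and integrated intensity per frame (robust-background threshold: trimmed mean + 2 SD; 8-connected components, 2–200 px), normalized as a ratio to the mean of the first 20 frames |
| `count_subapical_structures` | structures per 25×25 μm² region, counted independently in five z sections 0.2 μm apart |
| `link_detections` → `filter_tracks` → `classify_tracks` → `displacement_profile` | gated, globally optimal frame-to-frame linking; keep tracks ≥ 6 frames originating within 5 μm of the apical membrane; classify as apically persistent vs basally descending (max depth > 5 μm); profile maximal depth per stage window against furrow position |
| `object_colocalization` | percentage of reference-channel objects overlapping the partner channel's segmentation (≥ 30% pixel overlap, configurable; per-object fractions emitted) |

The model and parameter choices, the synthetic-data regimes and the
numerical edge cases are documented in [`docs/methods.md`](docs/methods.md).

## Worked example

Generate a wild-type-like movie (protrusion count decaying to 10% over
60 frames) and an arrest-phenotype movie (constant count), then measure
coverage:

```python
import numpy as np
from scipy import stats
from apicoquant import (ProtrusionMovieConfig, gen_protrusion_movie,
                        coverage_timeseries)

for profile, seed in [("wildtype", 11), ("persistent", 14)]:
    cfg = ProtrusionMovieConfig(seed=seed, profile=profile)
    stack, truth = gen_protrusion_movie(cfg)
    series = coverage_timeseries(stack)
    rho = stats.spearmanr(series.time_s, series.coverage).statistic
    print(f"{profile:10s} coverage {series.coverage[0]:.4f} -> "
          f"{series.coverage[-1]:.4f}  Spearman(time, coverage) = {rho:+.3f}")
```

prints

```
wildtype   coverage 0.0427 -> 0.0000  Spearman(time, coverage) = -0.998
persistent coverage 0.0444 -> 0.0448  Spearman(time, coverage) = +0.004
```

i.e. the measured protrusion coverage of the wild-type movie decays
essentially monotonically to zero as the surface flattens, while the
arrest phenotype holds its initial coverage — the separation that the
exact KS test then quantifies (with three movies per condition, full
separation of the final coverages gives D = 1 at the exact-test floor
p = 0.1).

The same workflows are available from a shell via the `apicoquant` CLI
(`simulate`, `flatten`, `puncta`, `count-subapical`, `track`, `coloc`),
each taking a TOML config with strict key checking; see
`apicoquant --help`.

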