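# gastromotil

Quantification of regional gastric motility from free-breathing dynamic
image series (2-D cine MRI of the stomach).

Peristaltic contractions — ring-like indentations that originate in the
upper corpus and travel toward the pylorus at a few mm/s, roughly three
times per minute — can be seen directly in dynamic MRI, but turning them
into numbers is mostly manual work. This package implements a
semi-automatic measurement chain for researchers analysing such series:

1. **Motion correction** — landmark-based rigid alignment of every frame
   to frame 1, minimising `Σᵢ ‖T(P_{t,i}) − P_{1,i}‖²` over (Δx, Δy, θ)
   with a Nelder–Mead simplex (Procrustes-seeded restart), scored by the
   DVARS instability metric
   `1/(T−1) Σ_t √(1/n Σ_p (I_{p,t} − I_{p,t−1})²)` along a probe line.
2. **Centerline estimation** — each segmented curvature (lesser and
   greater) is spline-resampled to 200 equal-arc-length wall-points; paired
   midpoints are validated by a 90 %-diameter inscribed circle, and a
   single 5th-order polynomial through all valid midpoints of all frames
   becomes the fixed reference axis.
3. **Contraction maps** — per wall-point radial distance `Dc(n, t)` to the
   axis, reference radius `ref(n) = mean_t Dc(n, t)`, contraction size
   `ref(n) − Dc(n, t)` and percentage occlusion `100·size/ref`, displayed
   as (time × normalized length) greyscale maps.
4. **Regional metrics** — waves marked on the map (manually, or by the
   built-in ridge follower) give per-region propagation speed
   `region_width/(t₂ − t₁)`, contraction frequency from inter-wave gaps,
   regional size/occlusion, and the gastric motility index
   `GMI = mean speed × mean size` for proximal/distal region groups.
5. **Statistics** — Shapiro–Wilk screening, Kruskal–Wallis + Dunn,
   Welch's t, ANOVA + Tukey, and distal-to-proximal trend fits with
   Spearman correlation, formatted into a report.

Because no scanner data ships with the package, a **synthetic phantom**
generates dynamic series with analytic ground truth — a curved tubular
stomach with travelling Gaussian indentations, cyclic rigid breathing
motion, co-moving landmarks, and seeded noise — so the whole chain is
testable end to end. See `docs/methods.md` for models, parameter defaults
and known measurement biases.

## Worked example

```python
import numpy as np
from gastromotil import PhantomConfig, render_series, extract_maps, analyze_maps
from gastromotil.registration import correct_series, dvars, probe_line

cfg = PhantomConfig(seed=1)          # 100 frames, 3 cpm waves at 3 mm/s, 5 mm deep
phantom = render_series(cfg)

corrected, transforms = correct_series(phantom.images, phantom.landmarks)
line = probe_line(phantom.images, phantom.contours[0].greater.vertices)
print(f"DVARS raw / corrected: {dvars(phantom.images, line).value:.2f} / "
      f"{dvars(corrected, line).value:.2f}")

result = extract_maps(phantom.contours_still, cfg.frame_interval_s)
print(f"wall lengths: lesser {result.wall_lengths['lesser']:.0f} mm, "
      f"greater {result.wall_lengths['greater']:.0f} mm; "
      f"centerline {result.centerline.length_mm:.0f} mm")

region_df, gmi_df, tracks = analyze_maps(result)
med = region_df.groupby("curvature")[["speed_mm_s", "frequency_cpm", "size_mm"]].median()
print(med.round(2))
print(gmi_df.round(2).to_string(index=False))
```

prints

```
DVARS raw / corrected: 14.85 / 3.57
wall lengths: lesser 208 mm, greater 292 mm; centerline 243 mm
           speed_mm_s  frequency_cpm  size_mm
curvature
greater          3.03            3.0     3.76
lesser           3.11            3.0     3.70
           group  mean_speed_mm_s  mean_size_mm  gmi_mm2_s
  greater_distal             3.06          3.72      11.38
greater_proximal             3.06          3.73      11.40
   lesser_distal             3.11          3.68      11.46
 lesser_proximal             3.11          3.66      11.40
         overall             3.08          3.70      11.41
```

Reading the numbers: motion correction cuts the DVARS instability score by
~4× (what remains is contraction signal plus noise, which correction should
not remove). The recovered wave speed (3.03–3.11 mm/s) and frequency
(3.0 cycles/min) match the phantom's configured 3 mm/s and 3 cycles/min;
the regional contraction size of ~3.7 mm is the configured 5 mm depth minus
the known mean-reference bias of the size definition (the bias-free
peak-to-trough estimate, `metrics.peak_contraction_size(map,
"peak_to_trough")`, returns ≈ 5 mm). The GMI of ~11 mm²/s is speed × size.

## Command line

Each stage is also a `gastromotil` subcommand operating on files
(multi-page TIFF / optional NIfTI for images; CSV for landmarks, contours,
maps, tracks and metrics):

```bash
gastromotil phantom   --config cfg.yaml --out phantom/
gastromotil register  --images phantom/images.tif --landmarks phantom/landmarks.csv \
                      --contours phantom/contours_true.csv --out reg/
gastromotil centerline --contours reg/contours_corrected.csv --out centerline/
gastromotil maps      --contours reg/contours_corrected.csv --frame-interval 0.65 --out maps/
gastromotil metrics   --map maps/map_greater_size.csv --curvature-length 286 --out metrics/
gastromotil report    --metrics metrics/region_metrics.csv --gmi metrics/gmi.csv --out report/
```

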