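# pavactin

Quantitative analysis of plant epidermal cells from fluorescence microscopy:
**pavement-cell shape morphometrics**, **cortical actin dynamics** via
frame-correlation decay, and **actin architecture metrics** (occupancy,
anisotropy, skewness, CV) — together with a synthetic-microscopy generator
that produces ground-truth inputs for every stage, so each analysis step has
a recovery test.

The package is aimed at plant cell biologists quantifying how actin
regulators (e.g. the Arp2/3 complex or ROP-GTPase effectors such as RIC4)
change pavement-cell lobing and cortical cytoskeleton behaviour in
time-lapse Lifeact-GFP movies and boundary-stained cell mosaics.

## The quantities computed

**Cell shape** — per labelled cell in a segmentation mask:

- area *A* (µm²),
- circularity 4π·A / P² (1 for a circle, lower for lobed cells), with the
  perimeter *P* from the 4-direction Crofton estimator,
- solidity A / A_hull (area over convex-hull area; decreases as lobes
  deepen).

An exact polygon oracle (shoelace area, segment-sum perimeter, convex hull)
computes the same descriptors analytically from ground-truth boundary
vertices.

**Actin dynamics** — for each square ROI sampled on a randomly positioned
grid overlay (20 µm default pitch), the Pearson correlation *r* between all
frame pairs; the mean of each superdiagonal of the T×T correlation matrix
gives the decay trace r(Δt). Traces are Fisher z-transformed
(z = atanh r) and normalized by z at the smallest lag, so curves from ROIs
with different baseline correlation are comparable: faster decay = more
dynamic actin. Groups are compared per lag with two-tailed Welch t tests
and Benjamini–Hochberg correction across the lag family.

**Actin architecture** — per ROI and frame, then averaged over time:
multiscale Hessian ridge enhancement → Otsu segmentation → thinning, then

- occupancy: actin-positive pixel fraction,
- anisotropy: structure-tensor coherence (λ₁−λ₂)/(λ₁+λ₂+ε) per skeleton
  branch, averaged with branch-length weights (1 = aligned, 0 = isotropic),
- skewness and coefficient of variation of masked intensities (both rise
  with filament bundling).

**Synthetic generator** — Lifeact-GFP-like movies (persistent-random-walk
filaments, exponential turnover with rebirth, bundling multiplier, PSF,
photobleaching, camera noise; 149 frames at 400 ms by default) and
propidium-iodide-like mosaics of lobed cells r(θ) = R(1 + a·sin(mθ+φ)),
both with exact ground truth.

## Worked example

```python
import numpy as np
import pavactin as pv

# two genotype-like conditions: slow vs fast actin turnover
groups = {}
for name, rate in [("stable", 0.01), ("dynamic", 0.1)]:
    traces = []
    for seed in range(4):                      # four recordings per group
        params = pv.FilamentSimParams(
            width_px=192, height_px=192, n_filaments=80,
            turnover_rate_per_s=rate, seed=seed)
        stack, truth = pv.simulate_filament_movie(params)
        rois = pv.make_roi_grid(stack, spacing_um=6.4, side_um=6.4, seed=0)
        pv.flag_low_signal_rois(stack, rois)   # drop background-only ROIs
        traces += pv.stack_traces(stack, rois, name)[:5]
    groups[name] = traces

comp = pv.compare_groups(groups["stable"], groups["dynamic"])
lag2s = comp["lag_s"] == 2.0
print("z_norm gap at 2 s lag: %.3f" % comp.loc[lag2s, "mean_diff"].iloc[0])
print("BH-significant lags:   %d / %d" % (comp["sig_05"].sum(), len(comp)))
```

prints (seeds as above):

```
z_norm gap at 2 s lag: 0.237
BH-significant lags:   147 / 148
```

i.e. the slowly remodelling condition keeps a ~0.23 higher normalized
correlation at a 2-second lag, and the per-lag Welch/BH comparison flags
essentially every lag (lag 1 is identically 1 by construction and is never
significant). The same movies feed the architecture metrics
(`pv.summarize_structure`) and the mosaic generator feeds the shape
morphometrics (`pv.measure_cells`, `pv.compare_shape_groups`).

A command-line interface mirrors the library:

```sh
pavactin simulate movie movie.tif --n-frames 149 --seed 1
pavactin preprocess movie.tif pre.tif rois.csv --radius 50 --spacing-um 20
pavactin dynamics pre.tif traces.csv --rois rois.csv --group wt
pavactin structure pre.tif metrics.csv --rois rois.csv
pavactin simulate cells mosaic.tif --lobe-amplitude 0.35
pavactin shape measure mosaic.tif cells.csv --pixel-size 0.5
```

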