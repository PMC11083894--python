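# mitoquant

Quantification of the full 3D mitochondrial network in living cells from
dye-stained confocal z-stacks, and analysis of dye photostability under
repetitive 3D imaging.

Mitochondrial morphology, quantity and membrane potential (ΔΨm) change with
differentiation, interventions and disease. Cationic dyes such as TMRM,
CMXRos and JC-1 accumulate in polarized mitochondria, so their fluorescence
is a ΔΨm proxy; combined with a nuclear stain (Hoechst) and a whole-cell
stain (Calcein-AM), a confocal z-stack lets you measure, per cell, every
connected mitochondrial structure ("object"), its volume and intensity, and
the nuclear/cytoplasmic volumes that normalize them. This package implements
that pipeline for anyone quantifying mitochondrial networks in 3D —
myogenic progenitors (mesoangioblasts) and multi-nucleated myotubes are the
motivating example — plus the statistics used to decide which dye/microscope
combination tolerates repetitive imaging.

## What it computes

**Segmentation** (`mitoquant.segmentation`): 3D median filter → white
top-hat with an anisotropy-corrected ellipsoidal element (removes diffuse
dye background) → constant-value threshold → 26-connected component
labeling → per-object voxel count, volume (µm³), mean/total intensity, and
size class (<2 µm³ fragmented, 2–10 µm³ medium, >10 µm³ network).
Intensities are measured on the unfiltered input so the ΔΨm readout is not
distorted by morphology filters.

**Per-cell morphometry** (`mitoquant.morphometry`): nucleus and whole-cell
channels are thresholded (the cell mask hole-filled, so vacuoles count as
cell volume); cytoplasm = cell − nucleus; summaries include object count,
total mitochondrial volume and intensity, % mitochondrial volume per
cytoplasm volume, and the size-class profile; groups are reported as
mean ± SD.

**Photostability** (`mitoquant.photostability`): for 10 consecutive
acquisitions of one field, each ROI's mean intensity over the maximum
intensity projection is normalized to its first acquisition. The relative
signal y at normalized time t ∈ [0, 1] is modeled as

    y ~ N(μ(t), σ(t)²),   μ(t) = α + βt (or α),   log σ(t) = γ + δt (or γ)

fitted by maximum likelihood; candidate models are compared through the
minimized minus log-likelihood penalized by the number of estimated
parameters (an AIC form, smaller is better). β is the relative-intensity
change over the whole series: β = −0.14 means a 14% signal loss by the
tenth acquisition.

**Synthetic data** (`mitoquant.simulate`): ground-truthed three-channel
stacks — random-walk tubules and globular mitochondria with
ΔΨm-proportional intensities inside an ellipsoidal cell, diffuse
background, PSF blur, Poisson + Gaussian noise — and repetitive-imaging
series with a planted decay slope and optional rod→globule fragmentation.
Every analysis above is validated against these known truths.

## Worked example

```python
from mitoquant import AnalysisConfig, SimCellParams, quantify_cell, simulate_cell

channels, truth = simulate_cell(SimCellParams(seed=0))   # mito+nucleus+cell stacks
cfg = AnalysisConfig(threshold_value=60.0, threshold_nucleus=250.0, threshold_cell=150.0)
q = quantify_cell(channels, cfg, cell_id="demo")

print(f"objects recovered / planted : {q.n_objects} / {truth.n_objects}")
print(f"total mt volume             : {q.total_mt_volume_um3:.1f} um3 "
      f"(planted {truth.total_mito_volume_um3:.1f})")
print(f"cytoplasm volume            : {q.cytoplasm_volume_um3:.0f} um3")
print(f"% mt volume per cytoplasm   : {q.pct_mt_per_cytoplasm:.2f} %")
print(f"size classes (<2, 2-10, >10): " + ", ".join(f"{p:.1f}%" for p in q.size_class_pct))
```

prints:

```
objects recovered / planted : 30 / 30
total mt volume             : 154.5 um3 (planted 154.7)
cytoplasm volume            : 4071 um3
% mt volume per cytoplasm   : 3.80 %
size classes (<2, 2-10, >10): 20.0%, 76.7%, 3.3%
```

All 30 planted mitochondrial objects are found, the recovered total volume
agrees with the planted 154.7 µm³, and the size-class profile says most
objects are medium-sized with one network-scale structure.

The same operations are exposed as a CLI (`mitoquant simulate | segment |
quantify | photostab | report`), and `analysis/01…04` run the full
narrative: simulate two populations, quantify them into the standard group
table, fit the photobleaching trends per dye × microscope, and recompute
the reference worked examples. Outputs land in `results/`.

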