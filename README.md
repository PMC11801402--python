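# imflow

Flow-cytometry-like single-cell analysis of fluorescence microscopy
images — for cell biologists who want population-level intensity readouts
(glucose uptake, mitochondrial membrane potential, any single-channel
probe) from a standard fluorescence microscope, with the same analytics a
flow cytometrist would use, and a ground-truth synthetic generator to
validate every stage.

## What it computes

Given grayscale frames with a known pixel pitch, `imflow`:

1. segments cells by **global minimum cross-entropy (Li) thresholding**
   — the threshold *t\** minimizes
   −Σ_{g<t} g·h(g)·ln μ_low(t) − Σ_{g≥t} g·h(g)·ln μ_high(t)
   over histogram bins g — with distance-transform watershed declumping
   and an inclusive equivalent-diameter gate d = 2√(A/π)·pitch ∈ [18, 38] µm;
2. measures each cell's **whole-cell mean intensity** (no background
   subtraction, no nuclear masking) and maps it to the continuous 8-bit
   scale (×255);
3. builds flow-style **KDE frequency plots** (Gaussian kernel, Silverman
   bandwidth h = 1.06·s·n^(−1/5)) and extracts four histogram
   characteristics — peak location, FWHM, mean, median — plus their
   relative changes, 100·(group − control)/control;
4. tests group differences with **Student's t** (two groups) or **one-way
   ANOVA** (three+) at α = 0.05 on per-image means, and joins the
   imaging and flow-cytometry results into a **concordance report**
   (sign agreement and magnitude ratio per metric).

A synthetic generator produces matched microscopy frames (calibrated
signal-to-background ratios ≈ 20 and ≈ 80 for the glucose-like and
MMP-like channels) and flow event samples (SBR ≈ 10 and ≈ 1000) from one
known per-cell distribution, so recovery of counts, intensities and fold
changes is testable end to end. See `docs/methods.md` for the full model.

## Worked example

The core loop — simulate a known experiment, segment it back — in a few
lines (`examples/01_simulate_and_segment.py` is the complete script):

```python
from imflow import GeneratorParams, SegmentationParams, measure_sbr, segment_image
from imflow.synthetic import generate_experiment

params = GeneratorParams(n_images=2, groups={"control": 1.0})
experiment = generate_experiment(params, seed=1)
image = experiment.images["control"][0]
mask = experiment.label_masks["control"][0]
cells, _, counts = segment_image(image, SegmentationParams())
```

Running the script prints

```
frame (900, 1200), pitch 0.370 um/px
true cells: 65
measured SBR (truth mask): 20.4
segmentation counts: {'objects_initial': 65, 'removed_border': 0, 'removed_gate': 0, 'cells_measured': 65}
recovered mean cell intensity: 0.2530 (truth 0.2549)
```

— all 65
simulated cells are identified, none are lost to the border or diameter
gate, the in-cell/background intensity ratio sits at the glucose-channel
target of ~20, and the recovered mean per-cell intensity agrees with the
ground truth to under 1%.

Running the full two-group pipeline (`examples/03_concordance_report.py`,
treated group = 1.3× control mean) prints a concordance table whose
mean-intensity row reads

```
metric   group  rel_change_imaging_pct  rel_change_flow_pct  sign_agree
  mean treated               28.4                 27.3             True
```

— both modalities recover the configured +30% shift (flow is attenuated
slightly by its additive baseline), and the per-image / per-tube t-tests
report p ≪ 0.05.

Each script in `examples/` is a short narrative of one capability:
simulation + segmentation, histogram characteristics, the end-to-end
concordance report, and CSV/FCS flow-file reading. The same stages are
available from the shell:

```bash
imflow run-all --outdir run0 --seed 7          # simulate → segment → histogram → compare
imflow simulate --outdir run1 --seed 3         # or stage by stage
imflow segment --outdir run1 --seed 3
```

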