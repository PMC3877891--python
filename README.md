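# raftperm

Quantitative analysis toolkit for membrane-permeabilization studies built
around fluctuation microscopy and dose–response pharmacology:

- **`raftperm.nb_brightness`** — Number & Brightness analysis of confocal
  image stacks: integer-shift registration, per-pixel temporal moments,
  apparent brightness `B = σ²/⟨k⟩`, molecular brightness `ε = B − 1`, and
  stack quality control (mean-decay and variance-convergence rules).
- **`raftperm.image_quant`** — 2-D image quantification: manually-seeded
  watershed membrane masking, background-corrected membrane intensity, a
  fixed-order bright-spot counter (Gauss → max-normalize → white top-hat →
  extended maxima → fill holes → shrink to points), Pearson colocalization,
  and dye-positivity fractions.
- **`raftperm.dose_response`** — four-parameter Hill fitting (multi-start,
  log-scale optimization), binding-vs-killing cooperativity comparison, and
  dual-wavelength viability → IC50 extraction.
- **`raftperm.oligomer_model`** — mechanistic model in which non-cooperative
  Langmuir binding feeds mass-action membrane oligomerization and a
  log-normal per-cell kill threshold, producing a steep (Hill n ≈ 3–4)
  killing curve from Hill n = 1 binding; includes threshold calibration,
  IC50-vs-site-density analysis and a Monte-Carlo cross-check.
- **`raftperm.uptake_kinetics`** — two-compartment binding/internalization
  model with closed-form solution and the initial-slope estimator of
  membrane binding (slope ∝ binding sites).
- **`raftperm.membrane_probes`** — l-format fluorescence anisotropy and
  generalized polarization calculators with per-condition summaries.
- **`raftperm.stats_utils`** — Pearson/Spearman correlation with Fisher
  z-transform confidence intervals.
- **`raftperm.synthetic_data`** — generators for every input the pipeline
  consumes (fluctuation stacks, spot/cell images, dose–response tables,
  uptake traces, cell-line panels), each returning known ground truth; all
  bit-reproducible for a fixed seed.

## Command line

```sh
# generate synthetic inputs (ground truth written as a .truth.json sidecar)
raftperm simulate nb    --config nb.json   --out stack.tif --seed 1
raftperm simulate spots --out spots.tif --seed 1
raftperm simulate dose  --config dose.json --out dose.csv --seed 1

# analyses
raftperm nb --stack stack.tif --region center:128 --out report.json
raftperm spots --image spots.tif --sigma 1.5 --tophat 6 --h 0.1
raftperm membrane --image cell.tif --seeds seeds.json --bg-roi roi.json
raftperm coloc --ch1 a.tif --ch2 b.tif --mask m.tif
raftperm hill --data dose.csv --kind killing --constrain bottom=0,top=1
raftperm oligomer hill                 # shipped demo regime
raftperm oligomer ic50-sweep --out sweep.csv
raftperm uptake-slope --trace trace.csv --window 30
raftperm probes gp --data probes.csv
raftperm corr --data panel.csv --x marker_level --y ic50 --log-y
```

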