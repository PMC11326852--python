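# phaseformer

Electron-density prediction from Patterson maps with a hybrid 3D-CNN /
transformer and one-way partial-structure attention.

## The problem

X-ray crystallography measures the *amplitudes* |F(h,k,l)| of a crystal's
structure factors but not their *phases* φ(h,k,l) — the crystallographic
phase problem. The electron density

ρ(x, y, z) = (1/V) · Σ_{h,k,l} |F(h,k,l)| · exp(−2πi(hx + ky + lz − φ(h,k,l)))

is therefore not directly recoverable from a diffraction experiment. What
*is* directly computable from measured intensities is the Patterson map,

p(u, v, w) = (1/V) · Σ_{h,k,l} |F(h,k,l)|² · exp(−2πi(hu + kv + lw)),

the autocorrelation of the density. This package provides a toolkit for a
learning-based attack on a simplified form of the problem: short peptide
fragments (2–15 residues) in orthorhombic P1 cells, where a neural network
g(θ, p, u₁..u_J) is trained to regress the density map e from the Patterson
map p, optionally conditioned on per-residue "partial structures" u_j —
standardized standalone density maps of each amino acid present, in an
idealized conformation.

It is aimed at structural-bioinformatics researchers who want a
self-contained, CPU-sized testbed for Patterson-to-density learning:
crystallographic math core, synthetic dataset generator, model, training,
and phasing-quality evaluation, with no external data dependencies.

## What's inside

- `phaseformer.xtal` — structure factors by direct summation (point or
  Cromer–Mann Gaussian scatterers), FFT density/Patterson synthesis, map
  normalization to [−1, 1], phase-error statistics in resolution shells.
- `phaseformer.fragments` / `phaseformer.dataset` — random peptide-like
  fragments with idealized backbone geometry, and the dataset rules: cell
  expansion to a ≥ 2.75 Å intermolecular contact (or a fixed cell),
  axis reindexing (longest first), center-of-mass centering, per-residue
  partial-structure maps, grid-size binning.
- `phaseformer.nn` — the model (patch tokenization after a conv stem,
  L layers of one-way attention in which Patterson tokens attend partial
  tokens but never the reverse, tanh decoder) on a compact numpy
  reverse-mode autodiff engine.
- `phaseformer.training` — MSE + negative-Pearson loss (weights
  0.9999 / 10⁻⁴), Adam, recycling (retraining with a previous model's
  predictions as a second input channel), evaluation reports.
- `phaseformer.estimator.PhaseFormerRegressor` — a scikit-learn style
  fit/predict wrapper.
- `phaseformer` CLI — `gen-fragments`, `build-maps`, `gen-dataset`,
  `train`, `predict` (CCP4 map export), `evaluate`, `run`.

## Worked example

Train the desk-scale model on 8 synthetic dipeptides (fixed 15.5 Å cells,
d_min 2.0 Å, 16³ grids) and evaluate on the training set:

```python
import phaseformer as pf
from phaseformer.presets import (toy_dipeptide_dataset, toy_model_config,
                                 toy_train_config)

dataset = toy_dipeptide_dataset(n=8, seed=11)
params, history = pf.train(toy_model_config(seed=0), dataset.examples,
                           toy_train_config(steps=500, seed=0))
print(f"final train loss {history[-1]['loss']:.6f} "
      f"mean PC {history[-1]['mean_pc']:.3f}")

report = pf.evaluate(params, dataset.examples, n_shells=5)
print(f"mean PC {report.mean_pc:.3f}, "
      f"mean phase error {report.overall_mean_phase_error_deg:.1f} deg")
```

Output from this exact run:

```
final train loss 0.000067 mean PC 0.977
mean PC 0.977, mean phase error 6.0 deg
```

A train-set Pearson correlation of 0.98 means the toy model memorizes the
8 maps nearly perfectly, and the 6° mean phase error says the memorized
maps are essentially phased to the resolution limit — every resolution
shell sits far below the 60° threshold for a usefully phased set. (These
are *training-set* numbers: the experiment demonstrates model capacity,
not generalization.) The same flow through the CLI:

```bash
phaseformer run --config examples/toy.yaml --out runs/toy
```

writes `dataset/`, `model.npz`, `report.json` and a machine-parsable
`pipeline.log`.

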