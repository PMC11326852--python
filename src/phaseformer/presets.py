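"""Canonical desk-scale study conditions.

One place defines the toy dipeptide setting used by the examples, tests
and the reproduction script, so they all exercise identical conditions:

* dipeptides from a GLY/ALA/SER alphabet with uniform backbone dihedrals;
* fixed 15.5 x 15.5 x 15.5 A cells — large enough that dipeptides nearly
  always satisfy the 2.75 A intermolecular contact threshold, and sized so
  the map grid works out to exactly 16^3 (no padding, and the resolution
  sphere stays strictly inside the Nyquist limit of the grid);
* maps to d_min 2.0 A with oversampling 2.0 (1.0 A voxels);
* the default 2-layer / 4-head / 16^3-grid model.

The full-scale setting this emulates (0.5 A voxels at d_min 1.5 A, and
41 x 30 x 24 A cells for 15-mers) is available through BuilderConfig
defaults; the toy numbers here are chosen for single-CPU tractability.
"""

from __future__ import annotations

from .dataset import BuilderConfig
from .fragments import DatasetResult, GeneratorConfig, generate_dataset
from .nn.model import ModelConfig
from .training import TrainConfig

__all__ = [
    "TOY_CELL", "TOY_D_MIN", "TOY_OVERSAMPLING", "TOY_ALPHABET",
    "toy_generator_config", "toy_builder_config", "toy_model_config",
    "toy_train_config", "toy_dipeptide_dataset",
]

TOY_CELL = (15.5, 15.5, 15.5)
TOY_D_MIN = 2.0
TOY_OVERSAMPLING = 2.0
TOY_ALPHABET = ("GLY", "ALA", "SER")


def toy_generator_config(seed: int = 11, n_residues: int = 2) -> GeneratorConfig:
    return GeneratorConfig(n_residues=n_residues, residue_alphabet=TOY_ALPHABET,
                           seed=seed)


def toy_builder_config(**overrides) -> BuilderConfig:
    kwargs = dict(d_min=TOY_D_MIN, oversampling=TOY_OVERSAMPLING,
                  mode="fixed_cell", fixed_cell=TOY_CELL)
    kwargs.update(overrides)
    return BuilderConfig(**kwargs)


def toy_model_config(seed: int = 0, **overrides) -> ModelConfig:
    return ModelConfig(seed=seed, **overrides)


def toy_train_config(steps: int = 500, seed: int = 0, **overrides) -> TrainConfig:
    """Full-batch training on the 8-example toy set: one batch per epoch."""
    kwargs = dict(epochs=steps, batch_size=8, learning_rate=1e-3, seed=seed)
    kwargs.update(overrides)
    return TrainConfig(**kwargs)


def toy_dipeptide_dataset(n: int = 8, seed: int = 11) -> DatasetResult:
    """Generate the toy dipeptide example set (16^3 grids, J=2 partials)."""
    return generate_dataset(n, toy_generator_config(seed), toy_builder_config())
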