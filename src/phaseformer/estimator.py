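"""scikit-learn style estimator wrapping model construction and training.

`PhaseFormerRegressor` turns the Patterson-to-density network into a
fit/predict object that composes with sklearn tooling (get_params /
set_params / clone work through BaseEstimator introspection). X is an
array of Patterson maps with shape (n_samples, N1, N2, N3) — or
(n_samples, C, N1, N2, N3) when a recycling channel is supplied — and y
the matching density maps (n_samples, N1, N2, N3). Per-sample
partial-structure maps are passed as ``partials`` with shape
(n_samples, J, N1, N2, N3).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .dataset import ExampleRecord, PartialStructureSet
from .nn.model import ModelConfig
from .training import LossConfig, TrainConfig, pearson, predict_examples, train
from .xtal import UnitCell, VolumeGrid

__all__ = ["PhaseFormerRegressor"]


class PhaseFormerRegressor(BaseEstimator, RegressorMixin):
    """Volumetric regressor from Patterson maps to electron-density maps.

    Parameters mirror the model and training configs; fitted state lives in
    ``params_`` (trained weights), ``config_`` and ``history_``.

    ``score`` returns the mean Pearson correlation between predicted and
    true maps — the field's standard map-agreement statistic — rather than
    R^2.
    """

    def __init__(self, patch=(4, 4, 4), channels=8, d_t=64, heads=4,
                 d_head=16, layers=2, ff_width=128, epochs=100, batch_size=8,
                 learning_rate=1e-3, optimizer="adam", w_mse=0.9999,
                 w_pc=1e-4, epsilon=1e-8, seed=0):
        self.patch = patch
        self.channels = channels
        self.d_t = d_t
        self.heads = heads
        self.d_head = d_head
        self.layers = layers
        self.ff_width = ff_width
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.w_mse = w_mse
        self.w_pc = w_pc
        self.epsilon = epsilon
        self.seed = seed

    # -- helpers --------------------------------------------------------------
    @staticmethod
    def _check_X(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 4:
            X = X[:, None]
        if X.ndim != 5:
            raise ValueError(
                "X must have shape (n, N1, N2, N3) or (n, C, N1, N2, N3)")
        return X

    def _to_examples(self, X, y, partials) -> list[ExampleRecord]:
        grid = X.shape[2:]
        cell = UnitCell(*[float(n) for n in grid])  # nominal 1 A/voxel cell
        spacing = (1.0, 1.0, 1.0)
        records = []
        for i in range(X.shape[0]):
            dens = VolumeGrid(y[i], cell, spacing, "density", True)
            patt = VolumeGrid(X[i, 0], cell, spacing, "patterson", True)
            pset = PartialStructureSet(
                [] if partials is None else
                [VolumeGrid(partials[i, j], cell, spacing, "partial", True)
                 for j in range(partials.shape[1])])
            records.append(ExampleRecord(
                id=f"sample-{i:06d}", patterson=patt, density=dens,
                partials=pset, cell=cell, n_residues=len(pset)))
        return records

    # -- sklearn API ----------------------------------------------------------
    def fit(self, X, y, partials=None):
        X = self._check_X(X)
        y = np.asarray(y, dtype=float)
        if y.shape != (X.shape[0],) + X.shape[2:]:
            raise ValueError("y must match X's sample count and grid dims")
        if partials is not None:
            partials = np.asarray(partials, dtype=float)
        grid = tuple(int(n) for n in X.shape[2:])
        config = ModelConfig(
            grid=grid, patch=tuple(self.patch), in_channels=X.shape[1],
            channels=self.channels, d_t=self.d_t, heads=self.heads,
            d_head=self.d_head, layers=self.layers, ff_width=self.ff_width,
            seed=self.seed)
        examples = self._to_examples(X, y, partials)
        base = None
        if X.shape[1] == 2:
            base = {ex.id: X[i, 1] for i, ex in enumerate(examples)}
        params, history = train(
            config, examples,
            TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                        learning_rate=self.learning_rate,
                        optimizer=self.optimizer, seed=self.seed),
            LossConfig(self.w_mse, self.w_pc, self.epsilon),
            base_predictions=base)
        self.config_ = config
        self.params_ = params
        self.history_ = history
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict(self, X, partials=None):
        if not hasattr(self, "params_"):
            raise AttributeError("PhaseFormerRegressor is not fitted yet")
        X = self._check_X(X)
        if partials is not None:
            partials = np.asarray(partials, dtype=float)
        examples = self._to_examples(
            X, np.zeros((X.shape[0],) + X.shape[2:]), partials)
        base = None
        if X.shape[1] == 2:
            base = {ex.id: X[i, 1] for i, ex in enumerate(examples)}
        preds = predict_examples(self.params_, examples, base)
        return np.stack([preds[ex.id] for ex in examples])

    def score(self, X, y, partials=None):
        """Mean voxel-wise Pearson correlation between prediction and truth."""
        pred = self.predict(X, partials=partials)
        y = np.asarray(y, dtype=float)
        return float(np.mean([pearson(yi, pi, self.epsilon)
                              for yi, pi in zip(y, pred)]))
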