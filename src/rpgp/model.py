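"""Model/Results front end for the RP + GP classifier.

:class:`RPGPClassifier` is constructed from data (an expression matrix or
plain arrays plus binary labels) and a configuration; :meth:`fit` runs the
optional random projection and the evolutionary search and returns an
:class:`RPGPResults` carrying the fitted program, its training fitness,
the per-generation fitness trace and prediction/summary methods.

Example
-------
>>> from rpgp import simulate, RPGPClassifier
>>> from rpgp.gp import DESK_PROFILE
>>> m, y, _ = simulate.generate(simulate.SyntheticSpec(
...     n_samples=60, n_features=500, n_informative=20,
...     effect_size=1.5, seed=3))
>>> model = RPGPClassifier(m, y, n_components=25, gp_config=DESK_PROFILE)
>>> res = model.fit(seed=0)
>>> res.predict(m).shape
(60,)
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .gp import GPConfig, classify, evolve, to_sexpr
from .io import ExpressionMatrix, LabelVector
from .metrics import confusion, mcc, training_accuracy
from .projection import ProjectionMatrix, build_projection, project

__all__ = ["RPGPClassifier", "RPGPResults"]


def _as_matrix(X) -> ExpressionMatrix:
    if isinstance(X, ExpressionMatrix):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    # plain arrays are taken samples x features, the sklearn convention
    n, d = X.shape
    return ExpressionMatrix(
        X.T,
        [f"feature_{i + 1}" for i in range(d)],
        [f"sample_{j + 1}" for j in range(n)],
    )


def _as_labels(y, matrix: ExpressionMatrix) -> LabelVector:
    if isinstance(y, LabelVector):
        y.check_aligned(matrix)
        return y
    arr = np.asarray(y, dtype=int)
    return LabelVector(arr, "positive", list(matrix.sample_ids), "negative")


class RPGPClassifier:
    """Random-projection + genetic-programming binary classifier.

    Parameters
    ----------
    X
        :class:`ExpressionMatrix` (features x samples) or array
        (samples x features).
    y
        :class:`LabelVector` aligned with ``X``, or a 0/1 array.
    n_components
        Target dimension ``k`` of the random projection; ``None`` evolves
        directly on the raw features.
    scheme
        Projection scheme (see :mod:`rpgp.projection`).
    gp_config
        :class:`~rpgp.gp.GPConfig`; defaults to the full-budget profile.
    """

    def __init__(
        self,
        X,
        y,
        *,
        n_components: int | None = None,
        scheme: str = "gaussian_unit_columns",
        gp_config: GPConfig | None = None,
    ):
        self.matrix = _as_matrix(X)
        self.labels = _as_labels(y, self.matrix)
        self.n_components = n_components
        self.scheme = scheme
        self.gp_config = gp_config if gp_config is not None else GPConfig()

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, labels, positive_class: str, **kwargs
    ) -> "RPGPClassifier":
        """Build from a samples-x-features DataFrame and a label sequence.

        ``labels`` may be a Series/array of class names; ``positive_class``
        names the class mapped to 1.
        """
        matrix = ExpressionMatrix(
            data.to_numpy(dtype=float).T,
            [str(c) for c in data.columns],
            [str(i) for i in data.index],
        )
        raw = pd.Series(list(labels)).astype(str)
        classes = sorted(raw.unique())
        if len(classes) != 2:
            raise ValueError(f"expected exactly two classes, found {classes}")
        if positive_class not in classes:
            raise ValueError(
                f"positive class {positive_class!r} not among {classes}"
            )
        negative = [c for c in classes if c != positive_class][0]
        y = LabelVector(
            (raw == positive_class).astype(int).to_numpy(),
            positive_class,
            list(matrix.sample_ids),
            negative,
        )
        return cls(matrix, y, **kwargs)

    def _design(self, matrix: ExpressionMatrix, projection) -> np.ndarray:
        if projection is not None:
            matrix = project(matrix, projection)
        return matrix.values.T  # samples x features

    def fit(self, seed: int = 0) -> "RPGPResults":
        """Run projection (if configured) and the evolutionary search."""
        projection = None
        if self.n_components is not None:
            projection = build_projection(
                self.matrix.n_features, self.n_components, seed, self.scheme
            )
        X = self._design(self.matrix, projection)
        result = evolve(X, self.labels.labels, replace(self.gp_config, seed=seed))
        return RPGPResults(self, result, projection, seed)


class RPGPResults:
    """Fitted program with its provenance, diagnostics and predictions."""

    def __init__(self, model: RPGPClassifier, evolution, projection, seed: int):
        self.model = model
        self.evolution = evolution
        self.projection: ProjectionMatrix | None = projection
        self.seed = seed
        self.tree = evolution.best_tree
        self.fitness = evolution.best_fitness
        self.trace = list(evolution.trace)
        preds = self.predict(model.matrix)
        self.train_confusion = confusion(preds, model.labels.labels)
        self.train_mcc = mcc(self.train_confusion)

    @property
    def program(self) -> str:
        """The fitted classifier as an S-expression over feature slots."""
        return to_sexpr(self.tree)

    def predict(self, X) -> np.ndarray:
        """0/1 predictions for new data (same feature space as training)."""
        matrix = _as_matrix(X)
        if matrix.n_features != self.model.matrix.n_features:
            raise ValueError(
                f"expected {self.model.matrix.n_features} features, got "
                f"{matrix.n_features}"
            )
        design = self.model._design(matrix, self.projection)
        return np.asarray(classify(self.tree, design), dtype=int)

    def summary(self) -> str:
        """Human-readable fit report."""
        m = self.model
        c = self.train_confusion
        lines = [
            "RP-GP binary classifier results",
            "=" * 47,
            f"samples:              {m.matrix.n_samples}",
            f"features:             {m.matrix.n_features}",
            f"projected dimension:  "
            f"{self.projection.k if self.projection else 'none (raw features)'}",
            f"projection scheme:    "
            f"{self.projection.scheme if self.projection else '-'}",
            f"positive class:       {m.labels.positive_class_name}",
            f"seed:                 {self.seed}",
            f"generations:          {self.evolution.generations}",
            f"population size:      {m.gp_config.population_size}",
            "-" * 47,
            f"best training fitness ((1+MCC)/2): {self.fitness:.4f}",
            f"training MCC:                      {self.train_mcc:.4f}",
            f"training accuracy (MCC x 100):     "
            f"{training_accuracy(c):.2f}",
            f"confusion (tp, tn, fp, fn):        "
            f"({c.n_tp}, {c.n_tn}, {c.n_fp}, {c.n_fn})",
            "-" * 47,
            "best program:",
            f"  {self.program}",
        ]
        return "\n".join(lines)

    def plot_fitness_trace(self, ax=None):
        """Plot the best-fitness trace (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(range(len(self.trace)), self.trace, drawstyle="steps-post")
        ax.set_xlabel("generation")
        ax.set_ylabel("best standardized fitness")
        ax.set_ylim(0, 1.02)
        return ax
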