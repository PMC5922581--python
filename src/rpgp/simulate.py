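"""Synthetic microarray-like data with planted class signal.

Real expression studies in this regime pair very few samples (N ~ 50-150)
with very many features (d ~ 10,000-55,000), binary and possibly
imbalanced classes, a subset of informative features, and heavy noise.
This generator emulates those shapes so the whole pipeline can be
exercised without downloading anything.

Two planting rules are available:

``linear_shift``
    Background features are independent Gaussians ``N(0, noise_sd^2)``
    (optionally correlated in blocks); each informative feature's mean is
    shifted by ``effect_size * noise_sd`` in the positive class. With
    ``effect_size = 0`` the labels are independent of the data — the null
    model used for calibration checks.
``nonlinear_ratio``
    Labels are derived from three informative features through
    ``class = [x_a / x_b - x_c >= 0]`` (with the same protected-division
    convention as the GP evaluator), so the division primitive is
    genuinely required to express the rule, not just linear recovery.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .gp import DIV_EPS
from .io import ExpressionMatrix, LabelVector

__all__ = ["SyntheticSpec", "generate"]

RULES = ("linear_shift", "nonlinear_ratio")

#: Within-block correlation used when ``correlation_block_size > 0``.
BLOCK_RHO = 0.5


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Defaults emulate a typical two-class expression study: 100 samples,
    10,000 features of which 1% are informative with a one-noise-SD mean
    shift, balanced classes, independent unit-variance background noise.
    """

    n_samples: int = 100
    n_features: int = 10_000
    n_informative: int = 100
    effect_size: float = 1.0
    class_balance: float = 0.5
    noise_sd: float = 1.0
    correlation_block_size: int = 0
    rule: str = "linear_shift"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValidationError("need at least 4 samples (2 per class)")
        if self.n_features < 1:
            raise ValidationError("need at least one feature")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValidationError(
                "n_informative must lie in [0, n_features]"
            )
        if not 0.0 < self.class_balance < 1.0:
            raise ValidationError("class_balance must lie in (0, 1)")
        n_pos = int(round(self.class_balance * self.n_samples))
        if self.rule == "linear_shift" and not 0 < n_pos < self.n_samples:
            raise ValidationError(
                "class_balance leaves one class empty at this sample size"
            )
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.correlation_block_size < 0:
            raise ValidationError("correlation_block_size must be >= 0")
        if self.rule not in RULES:
            raise ValidationError(f"rule must be one of {RULES}")
        if self.rule == "nonlinear_ratio" and self.n_informative < 3:
            raise ValidationError(
                "nonlinear_ratio needs at least 3 informative features"
            )


def _background(spec: SyntheticSpec, rng) -> np.ndarray:
    """d x N Gaussian background, optionally with correlated blocks."""
    d, n = spec.n_features, spec.n_samples
    eps = rng.standard_normal((d, n))
    if spec.correlation_block_size <= 1:
        return spec.noise_sd * eps
    b = spec.correlation_block_size
    n_blocks = -(-d // b)  # ceil
    z = rng.standard_normal((n_blocks, n))
    shared = np.repeat(z, b, axis=0)[:d]
    x = np.sqrt(BLOCK_RHO) * shared + np.sqrt(1.0 - BLOCK_RHO) * eps
    return spec.noise_sd * x  # marginal variance stays noise_sd^2


def generate(spec: SyntheticSpec):
    """Generate one dataset.

    Returns
    -------
    (ExpressionMatrix, LabelVector, ndarray)
        The ``d x N`` matrix, the aligned 0/1 labels (positive class name
        ``"case"``), and the sorted indices of the informative features —
        the planted ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    d, n = spec.n_features, spec.n_samples

    values = _background(spec, rng)
    informative = np.sort(
        rng.choice(d, size=spec.n_informative, replace=False)
    )

    if spec.rule == "linear_shift":
        n_pos = int(round(spec.class_balance * n))
        labels = np.zeros(n, dtype=int)
        labels[rng.permutation(n)[:n_pos]] = 1
        shift = spec.effect_size * spec.noise_sd
        values[np.ix_(informative, labels == 1)] += shift
    else:  # nonlinear_ratio
        a, b, c = informative[:3]
        xb = values[b]
        ratio = np.where(np.abs(xb) < DIV_EPS, 1.0, values[a] / np.where(
            np.abs(xb) < DIV_EPS, 1.0, xb))
        labels = (ratio - values[c] >= 0.0).astype(int)
        if labels.min() == labels.max():  # pragma: no cover - p ~ 0.5^n
            raise ValidationError(
                "nonlinear_ratio produced a single class; change the seed"
            )

    feature_ids = [f"gene_{i + 1}" for i in range(d)]
    sample_ids = [f"sample_{j + 1}" for j in range(n)]
    matrix = ExpressionMatrix(values, feature_ids, sample_ids)
    y = LabelVector(labels, "case", sample_ids, "control")
    return matrix, y, informative
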