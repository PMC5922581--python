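"""Random projection of expression data to a low-dimensional latent space.

An expression matrix ``X`` (``d x N``) is mapped through the origin to a
``k``-dimensional subspace (``k << d``) with a random ``k x d`` matrix
``R``::

    X_rp = R @ X            # k x N

Two schemes are provided:

``gaussian_unit_columns``
    Standard-normal entries with every column of ``R`` rescaled to unit
    Euclidean length. This is the default and the scheme whose column-norm
    invariant is enforced.
``sparse_achlioptas``
    Achlioptas' database-friendly matrix: entries ``sqrt(3) * {+1, 0, -1}``
    with probabilities ``{1/6, 2/3, 1/6}``.

``R`` is generated from a seed and never sees the data, so the same ``R``
can legitimately be applied to training and test samples: no information
leaks through it. No ``sqrt(d/k)`` rescaling is applied by :func:`project`;
distance-preservation checks apply it externally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DimensionError, FormatError
from .io import ExpressionMatrix

__all__ = [
    "SCHEMES",
    "ProjectionMatrix",
    "build_projection",
    "project",
    "write_projection",
    "read_projection",
]

SCHEMES = ("gaussian_unit_columns", "sparse_achlioptas")


@dataclass(frozen=True)
class ProjectionMatrix:
    """A seeded ``k x d`` random projection matrix."""

    R: np.ndarray
    k: int
    d: int
    seed: int
    scheme: str

    def __post_init__(self) -> None:
        if self.R.shape != (self.k, self.d):
            raise DimensionError(
                f"R has shape {self.R.shape}, expected ({self.k}, {self.d})"
            )


def build_projection(
    d: int,
    k: int,
    seed: int,
    scheme: str = "gaussian_unit_columns",
) -> ProjectionMatrix:
    """Construct the random ``k x d`` projection matrix for ``(k, d, seed, scheme)``.

    Deterministic: identical arguments produce an identical matrix.
    """
    if k <= 0:
        raise ValueError(f"target dimension k must be positive, got {k}")
    if k >= d:
        raise DimensionError(
            f"target dimension k={k} must be smaller than source dimension d={d}"
        )
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    rng = np.random.default_rng(seed)
    if scheme == "gaussian_unit_columns":
        R = rng.standard_normal((k, d))
        norms = np.linalg.norm(R, axis=0)
        # A zero column has probability 0; regenerate defensively if it occurs.
        while np.any(norms == 0.0):
            zero = norms == 0.0
            R[:, zero] = rng.standard_normal((k, int(zero.sum())))
            norms = np.linalg.norm(R, axis=0)
        R = R / norms
    else:  # sparse_achlioptas
        R = np.sqrt(3.0) * rng.choice(
            np.array([1.0, 0.0, -1.0]),
            size=(k, d),
            p=[1.0 / 6.0, 2.0 / 3.0, 1.0 / 6.0],
        )
    return ProjectionMatrix(R=R, k=k, d=d, seed=int(seed), scheme=scheme)


def project(m: ExpressionMatrix, p: ProjectionMatrix) -> ExpressionMatrix:
    """Map ``m`` (``d x N``) to the latent space: returns a ``k x N`` matrix.

    Constructed features are named ``RP_1 .. RP_k``. The map is linear and
    acts column-wise, so projecting a concatenation of sample sets equals
    concatenating their projections.
    """
    if p.d != m.n_features:
        raise DimensionError(
            f"projection expects d={p.d} features but matrix has "
            f"{m.n_features} (matrix {m.values.shape}, R {p.R.shape})"
        )
    values = p.R @ m.values
    feature_ids = [f"RP_{i + 1}" for i in range(p.k)]
    return ExpressionMatrix(values, feature_ids, list(m.sample_ids))


def write_projection(p: ProjectionMatrix, path, delimiter: str = "\t") -> None:
    """Serialize ``R`` as TSV with a one-line header recording (k, d, seed, scheme)."""
    header = f"k={p.k}{delimiter}d={p.d}{delimiter}seed={p.seed}{delimiter}scheme={p.scheme}"
    np.savetxt(
        path, p.R, fmt="%.17g", delimiter=delimiter, header=header, comments="# "
    )


def read_projection(path, delimiter: str = "\t") -> ProjectionMatrix:
    """Inverse of :func:`write_projection`."""
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("# "):
        raise FormatError(f"{path}: missing projection header line")
    meta = {}
    for token in first[2:].strip().split(delimiter):
        key, _, value = token.partition("=")
        meta[key] = value
    try:
        k, d, seed = int(meta["k"]), int(meta["d"]), int(meta["seed"])
        scheme = meta["scheme"]
    except KeyError as exc:
        raise FormatError(f"{path}: incomplete projection header: {first!r}") from exc
    R = np.loadtxt(path, delimiter=delimiter, comments="#", ndmin=2)
    return ProjectionMatrix(R=R, k=k, d=d, seed=seed, scheme=scheme)
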