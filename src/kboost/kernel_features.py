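"""Per-TF RBF kernels and kernel principal components.

Each transcription factor (TF) contributes one regression block: its
expression vector across the n samples is lifted into the implicit feature
space of the radial-basis-function kernel

    K[i, u] = exp(-(v_i - v_u)^2 / gamma),

the kernel is double-centered so the implicit features have zero mean, and
the leading kernel principal components (KPCs) are extracted by
eigendecomposition.  KPC columns are normalized to unit Euclidean norm, so a
single-TF regression reduces to an orthonormal projection — the property the
boosting stage relies on to avoid any matrix inversion.

Only the KPCs and eigenvalues are retained per TF; the n x n kernels are
scratch space, so peak additional memory is O(n^2) regardless of the number
of TFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .exceptions import (
    DegenerateTFError,
    InvalidInputError,
    InvalidParameterError,
    ShapeError,
)

__all__ = [
    "ExpressionMatrix",
    "TFIndex",
    "KPCBlock",
    "KernelFeatureSet",
    "rbf_kernel",
    "center_kernel",
    "kernel_pca",
    "build_feature_library",
]

#: eigenvalues in [-_PSD_CLIP, 0) are treated as exact zeros (floating-point
#: noise from the symmetric eigensolver)
_PSD_CLIP = 1e-10


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples matrix of real-valued expression.

    Parameters
    ----------
    values
        Real matrix of shape (G, n); no missing or non-finite entries.
    gene_ids
        G unique gene identifiers (row labels).
    sample_ids
        n unique sample identifiers (column labels).
    constant_genes
        Row indices whose expression had zero sample variance; populated by
        :func:`kboost.grn_inference.standardize_expression`, empty on raw
        input.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    constant_genes: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "constant_genes", frozenset(self.constant_genes))
        if values.ndim != 2:
            raise ShapeError(f"expression values must be 2-D, got ndim={values.ndim}")
        G, n = values.shape
        if G < 2:
            raise ShapeError(f"need at least 2 genes, got G={G}")
        if n < 3:
            raise ShapeError(f"need at least 3 samples, got n={n}")
        if len(self.gene_ids) != G:
            raise ShapeError(f"{len(self.gene_ids)} gene ids for {G} rows")
        if len(self.sample_ids) != n:
            raise ShapeError(f"{len(self.sample_ids)} sample ids for {n} columns")
        if len(set(self.gene_ids)) != G:
            raise InvalidInputError("duplicate gene ids")
        if len(set(self.sample_ids)) != n:
            raise InvalidInputError("duplicate sample ids")
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None


@dataclass(frozen=True)
class TFIndex:
    """Ordered row indices of the transcription factors.

    The order is the column order of every TF-indexed structure downstream
    (prior matrix, posterior matrix).
    """

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        object.__setattr__(self, "indices", idx)
        if len(idx) < 1:
            raise InvalidParameterError("TFIndex needs at least one TF")
        if len(set(idx)) != len(idx):
            raise InvalidParameterError("TF indices must be unique")
        if any(i < 0 for i in idx):
            raise InvalidParameterError("TF indices must be nonnegative")

    def __len__(self) -> int:
        return len(self.indices)

    def validate_against(self, n_genes: int) -> None:
        bad = [i for i in self.indices if i >= n_genes]
        if bad:
            raise InvalidParameterError(
                f"TF indices {bad} out of range for G={n_genes}"
            )

    @classmethod
    def from_ids(cls, gene_ids: tuple[str, ...], tf_ids: list[str]) -> "TFIndex":
        lookup = {g: i for i, g in enumerate(gene_ids)}
        missing = [t for t in tf_ids if t not in lookup]
        if missing:
            raise InvalidParameterError(f"TF ids not in expression matrix: {missing}")
        return cls(tuple(lookup[t] for t in tf_ids))


class KPCBlock(NamedTuple):
    """Kernel principal components of one TF: n x z orthonormal columns and
    the z retained eigenvalues (descending)."""

    kpcs: np.ndarray
    eigenvalues: np.ndarray


@dataclass(frozen=True)
class KernelFeatureSet:
    """Per-TF KPC blocks keyed by TF column position.

    ``tf_rows[p]`` is the gene-row index of TF column p; ``excluded`` holds
    column positions of TFs whose kernel was degenerate (these receive zero
    posterior everywhere downstream).
    """

    gamma: float
    tf_rows: tuple[int, ...]
    blocks: dict[int, KPCBlock]
    excluded: frozenset[int]

    @property
    def n_tfs(self) -> int:
        return len(self.tf_rows)


def rbf_kernel(v: np.ndarray, gamma: float) -> np.ndarray:
    """RBF kernel matrix of a 1-D sample vector.

    ``K[i, u] = exp(-(v[i] - v[u])^2 / gamma)`` — symmetric, unit diagonal,
    entries in (0, 1].
    """
    if gamma <= 0:
        raise InvalidParameterError(f"gamma must be positive, got {gamma}")
    v = np.asarray(v, dtype=float).ravel()
    if v.size < 2:
        raise ShapeError(f"need at least 2 samples, got {v.size}")
    if not np.all(np.isfinite(v)):
        raise InvalidInputError("rbf_kernel input contains non-finite values")
    d = v[:, None] - v[None, :]
    K = np.exp(-(d * d) / gamma)
    np.fill_diagonal(K, 1.0)
    return K


def center_kernel(K: np.ndarray) -> np.ndarray:
    """Double-center a kernel matrix: ``K - 1K - K1 + 1K1`` with ``1`` the
    n x n matrix of 1/n.

    Equivalent to centering the implicit feature vectors at their mean; every
    row and column of the result sums to zero.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ShapeError(f"kernel must be square, got shape {K.shape}")
    row_means = K.mean(axis=1, keepdims=True)
    col_means = K.mean(axis=0, keepdims=True)
    total = K.mean()
    Kc = K - row_means - col_means + total
    return (Kc + Kc.T) / 2.0


def kernel_pca(
    K_centered: np.ndarray, eig_threshold: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Extract unit-norm kernel principal components from a centered kernel.

    Eigenvalues are sorted descending; component i is the projection
    ``K_centered @ alpha_i`` rescaled to unit norm (for an exact eigenpair
    this equals the unit eigenvector, since K_centered alpha = lambda alpha).
    Retention is relative: keep positive eigenvalues with
    ``lambda_i >= eig_threshold * lambda_1``.  Signs are fixed so the
    largest-magnitude entry of each column is positive.

    Raises
    ------
    DegenerateTFError
        If no eigenvalue survives (e.g. the zero matrix from a constant TF).
    """
    if eig_threshold < 0:
        raise InvalidParameterError(f"eig_threshold must be >= 0, got {eig_threshold}")
    K_centered = np.asarray(K_centered, dtype=float)
    if K_centered.ndim != 2 or K_centered.shape[0] != K_centered.shape[1]:
        raise ShapeError(f"centered kernel must be square, got {K_centered.shape}")
    evals, evecs = np.linalg.eigh(K_centered)
    evals = evals[::-1].copy()
    evecs = evecs[:, ::-1]
    evals[(evals < 0) & (evals >= -_PSD_CLIP)] = 0.0
    lam1 = evals[0]
    if lam1 <= 0:
        raise DegenerateTFError("no positive eigenvalue: kernel has no variance")
    keep = (evals > 0) & (evals >= eig_threshold * lam1)
    evals = evals[keep]
    proj = K_centered @ evecs[:, keep]
    norms = np.linalg.norm(proj, axis=0)
    kpcs = proj / norms
    # deterministic sign: largest-magnitude entry of each column positive
    flip = kpcs[np.argmax(np.abs(kpcs), axis=0), np.arange(kpcs.shape[1])] < 0
    kpcs[:, flip] *= -1.0
    return kpcs, evals


def build_feature_library(
    X: ExpressionMatrix,
    tfs: TFIndex,
    gamma: float = 60.0,
    eig_threshold: float = 1e-6,
) -> KernelFeatureSet:
    """Compute one KPC block per TF from a standardized expression matrix.

    Kernels are computed one TF at a time and discarded after decomposition,
    so additional working memory stays O(n^2).  TFs whose kernel is
    degenerate (constant expression) are recorded in ``excluded`` rather than
    raising.
    """
    if gamma <= 0:
        raise InvalidParameterError(f"gamma must be positive, got {gamma}")
    tfs.validate_against(X.n_genes)
    blocks: dict[int, KPCBlock] = {}
    excluded: set[int] = set()
    for col, row in enumerate(tfs.indices):
        try:
            K = rbf_kernel(X.values[row], gamma)
            kpcs, evals = kernel_pca(center_kernel(K), eig_threshold)
        except DegenerateTFError:
            excluded.add(col)
            continue
        blocks[col] = KPCBlock(kpcs, evals)
    return KernelFeatureSet(
        gamma=gamma,
        tf_rows=tuple(tfs.indices),
        blocks=blocks,
        excluded=frozenset(excluded),
    )
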