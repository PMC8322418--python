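"""Core inference: greedy kernel-PCA-regression boosting with Bayesian model
averaging.

For each target gene j the algorithm greedily explores small subsets of TFs.
At every boosting iteration it fits, on the current residuals, a shrunken
kernel-PCA regression for every candidate TF, scores each resulting model by
its unnormalized log posterior

    log P(A) + log pi(A)
      = -((n - 1) / 2) * ln(RSS_A)                      (Jeffreys-marginalized
                                                         Gaussian likelihood)
      + sum_p [ 1(p in A) ln w_p + 1(p not in A) ln(1 - w_p) ]   (binomial prior)

and keeps the best one for the next iteration.  The posterior probability
that TF p regulates gene j is the Bayesian-model-averaged share of explored
models containing p.  A final heuristic multiplies each TF column of the
posterior matrix by its sample variance, which preserves the sparse
out-degree distribution of biological networks.

Everything is deterministic: ties in the greedy selection go to the lowest
TF column index, and all posterior arithmetic is done in log space via
log-sum-exp.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp

from .exceptions import InvalidParameterError, ShapeError
from .kernel_features import (
    ExpressionMatrix,
    KernelFeatureSet,
    TFIndex,
    build_feature_library,
)

__all__ = [
    "PriorMatrix",
    "ModelRecord",
    "GRNPosterior",
    "KBoostConfig",
    "standardize_expression",
    "default_shrinkage",
    "log_marginal_likelihood",
    "log_model_prior",
    "fit_component",
    "boost_gene",
    "bma_posterior",
    "variance_scaling",
    "kboost",
]

#: RSS is clamped below at _RSS_FLOOR * n before taking logs; a numerically
#: perfect fit would otherwise send the log marginal likelihood to +inf.
_RSS_FLOOR = 1e-12


@dataclass(frozen=True)
class PriorMatrix:
    """G x P matrix of per-edge prior probabilities, entries strictly in (0, 1).

    Row j, column p is the prior probability that TF p (in TFIndex order)
    regulates gene j.  The noninformative default is 0.5 everywhere, under
    which all model priors of equal size cancel in the model average.
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2:
            raise ShapeError(f"prior matrix must be 2-D, got ndim={w.ndim}")
        if not np.all((w > 0.0) & (w < 1.0)):
            raise InvalidParameterError("prior weights must lie strictly in (0, 1)")

    @classmethod
    def uniform(cls, n_genes: int, n_tfs: int, value: float = 0.5) -> "PriorMatrix":
        return cls(np.full((n_genes, n_tfs), float(value)))


@dataclass(frozen=True)
class ModelRecord:
    """One explored TF subset for one gene.

    ``members`` is ordered with possible repeats (the same TF may be selected
    at several boosting iterations); the prior and the membership indicator
    of the model average use the distinct set.
    """

    gene: int
    members: tuple[int, ...]
    rss: float
    log_ml: float
    log_prior: float

    @property
    def distinct(self) -> frozenset[int]:
        return frozenset(self.members)


@dataclass(frozen=True)
class KBoostConfig:
    """Tunable parameters of the inference.

    gamma
        RBF kernel width; default 60 on standardized expression.
    nu
        Shrinkage multiplier in (0, 1] applied to every regression
        coefficient.  ``None`` (the default) resolves to the sample-size
        rule: 10/n when n > 10, else 0.5.
    iterations
        Boosting iterations; also the maximum number of TFs per gene.
    eig_threshold
        Relative eigenvalue retention threshold of the kernel PCA.
    seed
        Carried along for stochastic downstream consumers; the core
        inference itself is deterministic.
    """

    gamma: float = 60.0
    nu: float | None = None
    iterations: int = 3
    eig_threshold: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise InvalidParameterError(f"gamma must be positive, got {self.gamma}")
        if self.nu is not None and not (0.0 < self.nu <= 1.0):
            raise InvalidParameterError(f"nu must be in (0, 1], got {self.nu}")
        if self.iterations < 1:
            raise InvalidParameterError(
                f"iterations must be >= 1, got {self.iterations}"
            )
        if self.eig_threshold < 0:
            raise InvalidParameterError(
                f"eig_threshold must be >= 0, got {self.eig_threshold}"
            )


@dataclass(frozen=True)
class GRNPosterior:
    """Posterior edge-probability matrices of an inferred network.

    ``raw[j, p]`` is the Bayesian-model-averaged probability that TF column p
    regulates gene j; ``scaled`` is raw after per-column variance scaling.
    Self-loops and excluded (degenerate) TF columns are exactly zero.
    """

    raw: np.ndarray
    scaled: np.ndarray
    gene_ids: tuple[str, ...]
    tf_rows: tuple[int, ...]
    excluded_tfs: frozenset[int]

    @property
    def tf_ids(self) -> tuple[str, ...]:
        return tuple(self.gene_ids[r] for r in self.tf_rows)

    def edge_scores(
        self, use_scaled: bool = False, by_id: bool = False
    ) -> dict[tuple, float]:
        """Flatten to a {(TF, target): score} mapping, excluding self-loops.

        Keys are gene-row index pairs, or identifier pairs with ``by_id``.
        """
        mat = self.scaled if use_scaled else self.raw
        scores: dict[tuple, float] = {}
        for p, tf_row in enumerate(self.tf_rows):
            for j in range(mat.shape[0]):
                if j == tf_row:
                    continue
                key = (
                    (self.gene_ids[tf_row], self.gene_ids[j]) if by_id else (tf_row, j)
                )
                scores[key] = float(mat[j, p])
        return scores


def standardize_expression(X: ExpressionMatrix) -> ExpressionMatrix:
    """Scale every gene to sample mean 0 and sample variance 1 (n-1 denominator).

    Constant genes cannot be standardized; their rows are set to zero and
    their indices recorded in ``constant_genes``.
    """
    values = X.values
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, ddof=1, keepdims=True)
    constant = np.nonzero(sds.ravel() == 0.0)[0]
    safe = np.where(sds == 0.0, 1.0, sds)
    out = (values - means) / safe
    out[constant, :] = 0.0
    return ExpressionMatrix(
        values=out,
        gene_ids=X.gene_ids,
        sample_ids=X.sample_ids,
        constant_genes=frozenset(int(i) for i in constant) | X.constant_genes,
    )


def default_shrinkage(n: int) -> float:
    """Sample-size rule for the shrinkage parameter: 10/n if n > 10, else 0.5.

    Shrinkage damps per-step fits so that residual sums of squares — and
    hence posteriors, whose log scales with (n-1)/2 — do not become
    overconfident as n grows.
    """
    if n < 2:
        raise InvalidParameterError(f"need n >= 2 samples, got {n}")
    return 10.0 / n if n > 10 else 0.5


def log_marginal_likelihood(rss: float, n: int) -> float:
    """Log marginal likelihood of a model with residual sum of squares ``rss``:
    ``-((n - 1) / 2) * ln(rss)``.

    Obtained by integrating the Gaussian noise variance out under a Jeffreys
    prior with the fitted component held fixed.  ``rss`` is clamped below at
    ``1e-12 * n`` so a numerically perfect fit stays finite.
    """
    rss = max(float(rss), _RSS_FLOOR * n)
    return -0.5 * (n - 1) * np.log(rss)


def log_model_prior(members: Iterable[int], w_row: np.ndarray) -> float:
    """Log binomial prior of a TF subset under per-edge weights ``w_row``.

    Each of the P TFs contributes ln(w_p) if it is in the (distinct) member
    set and ln(1 - w_p) otherwise; repeats in ``members`` count once.
    """
    w = np.asarray(w_row, dtype=float)
    if not np.all((w > 0.0) & (w < 1.0)):
        raise InvalidParameterError("prior weights must lie strictly in (0, 1)")
    member_set = set(int(m) for m in members)
    inside = np.zeros(w.shape[0], dtype=bool)
    inside[list(member_set)] = True
    return float(np.sum(np.where(inside, np.log(w), np.log1p(-w))))


def fit_component(
    kpcs_p: np.ndarray, residual: np.ndarray, nu: float
) -> tuple[np.ndarray, np.ndarray]:
    """Shrunken least-squares fit of one TF's KPC block to a residual vector.

    With orthonormal columns g the exact least-squares coefficients are
    g^T residual; shrinkage multiplies them by nu.  Returns (beta, prediction).
    """
    kpcs_p = np.asarray(kpcs_p, dtype=float)
    residual = np.asarray(residual, dtype=float).ravel()
    if kpcs_p.ndim != 2 or kpcs_p.shape[0] != residual.shape[0]:
        raise ShapeError(
            f"kpcs shape {kpcs_p.shape} incompatible with residual length "
            f"{residual.shape[0]}"
        )
    if not (0.0 < nu <= 1.0):
        raise InvalidParameterError(f"nu must be in (0, 1], got {nu}")
    beta = nu * (kpcs_p.T @ residual)
    return beta, kpcs_p @ beta


def boost_gene(
    j: int,
    lib: KernelFeatureSet,
    x_j: np.ndarray,
    w_row: np.ndarray,
    cfg: KBoostConfig,
) -> list[ModelRecord]:
    """Greedy boosting exploration of TF subsets for one gene.

    Iteration 1 evaluates every candidate TF as a singleton model; each later
    iteration evaluates, for every candidate, the model extending the
    selected prefix by that TF, fit on the current residuals.  Every
    evaluated model is recorded (the explored set the model average runs
    over), the best extends the prefix, and the cumulative prediction is
    updated with the selected shrunken component.  The same TF may be
    selected repeatedly.  Candidates never include the gene itself or
    excluded TFs; with no candidates the record list is empty.
    """
    x_j = np.asarray(x_j, dtype=float).ravel()
    n = x_j.shape[0]
    nu = cfg.nu if cfg.nu is not None else default_shrinkage(n)
    candidates = [
        p
        for p in range(lib.n_tfs)
        if p not in lib.excluded and lib.tf_rows[p] != j
    ]
    if not candidates:
        return []

    # log-prior bookkeeping: start from the empty set, add ln(w/(1-w)) per
    # newly included TF
    w = np.asarray(w_row, dtype=float)
    if w.shape[0] != lib.n_tfs:
        raise ShapeError(f"prior row length {w.shape[0]} != P={lib.n_tfs}")
    log_odds = np.log(w) - np.log1p(-w)
    empty_log_prior = log_model_prior((), w)

    records: list[ModelRecord] = []
    prefix: tuple[int, ...] = ()
    prefix_set: set[int] = set()
    prefix_log_prior = empty_log_prior
    residual = x_j.copy()
    rss_cur = float(residual @ residual)

    for _ in range(cfg.iterations):
        best_p = -1
        best_score = -np.inf
        best_rss = np.nan
        for p in candidates:
            kpcs = lib.blocks[p].kpcs
            c = kpcs.T @ residual
            # closed form for the RSS after subtracting nu * g (g^T r):
            # ||r||^2 - nu (2 - nu) ||g^T r||^2
            rss_p = rss_cur - nu * (2.0 - nu) * float(c @ c)
            log_ml = log_marginal_likelihood(rss_p, n)
            log_prior = prefix_log_prior + (0.0 if p in prefix_set else log_odds[p])
            records.append(
                ModelRecord(
                    gene=j,
                    members=prefix + (p,),
                    rss=max(rss_p, _RSS_FLOOR * n),
                    log_ml=log_ml,
                    log_prior=log_prior,
                )
            )
            score = log_ml + log_prior
            if score > best_score:
                best_score = score
                best_p = p
                best_rss = rss_p
        # commit the winner: update ensemble prediction and residuals
        kpcs = lib.blocks[best_p].kpcs
        beta, pred = fit_component(kpcs, residual, nu)
        residual = residual - pred
        rss_cur = float(residual @ residual)
        if best_p not in prefix_set:
            prefix_log_prior += log_odds[best_p]
            prefix_set.add(best_p)
        prefix = prefix + (best_p,)
        del best_rss
    return records


def bma_posterior(records: Sequence[ModelRecord], P: int) -> np.ndarray:
    """Bayesian model average over explored models for one gene.

    Model weights are the normalized exp(log_ml + log_prior) over all
    records (log-sum-exp); the posterior for TF p is the summed weight of
    models whose distinct member set contains p.  Empty input yields zeros.
    """
    out = np.zeros(P)
    if not records:
        return out
    log_post = np.array([r.log_ml + r.log_prior for r in records])
    log_weights = log_post - logsumexp(log_post)
    weights = np.exp(log_weights)
    for r, wt in zip(records, weights):
        for p in r.distinct:
            out[p] += wt
    return np.clip(out, 0.0, 1.0)


def variance_scaling(raw: np.ndarray) -> np.ndarray:
    """Multiply each TF column by its sample variance (n-1 denominator).

    A heuristic that suppresses promiscuous TF columns and preserves the
    sparse out-degree distribution typical of biological networks; the
    within-column ranking is unchanged.
    """
    raw = np.asarray(raw, dtype=float)
    col_var = raw.var(axis=0, ddof=1)
    return raw * col_var[None, :]


def kboost(
    X: ExpressionMatrix,
    tfs: TFIndex,
    W: PriorMatrix | None = None,
    cfg: KBoostConfig | None = None,
) -> GRNPosterior:
    """Infer a gene regulatory network from expression data.

    Standardizes the expression matrix, builds the per-TF kernel-PCA feature
    library once, runs the greedy boosting exploration and Bayesian model
    average for every gene, and applies the column-variance scaling
    heuristic.  Deterministic given its inputs.

    Parameters
    ----------
    X
        Expression matrix, G genes x n samples (raw scale; standardized
        internally).
    tfs
        Row indices of the candidate regulators; their order is the column
        order of ``W`` and of the returned matrices.
    W
        Optional G x P prior-probability matrix; ``None`` means the
        noninformative all-0.5 prior.
    cfg
        Algorithm parameters; ``None`` means all defaults.
    """
    cfg = cfg or KBoostConfig()
    tfs.validate_against(X.n_genes)
    G, n = X.n_genes, X.n_samples
    P = len(tfs)
    if W is None:
        W = PriorMatrix.uniform(G, P)
    if W.weights.shape != (G, P):
        raise ShapeError(
            f"prior matrix shape {W.weights.shape} != (G={G}, P={P})"
        )
    Xs = standardize_expression(X)
    nu = cfg.nu if cfg.nu is not None else default_shrinkage(n)
    run_cfg = replace(cfg, nu=nu)
    lib = build_feature_library(Xs, tfs, cfg.gamma, cfg.eig_threshold)
    raw = np.zeros((G, P))
    for j in range(G):
        if j in Xs.constant_genes:
            continue
        records = boost_gene(j, lib, Xs.values[j], W.weights[j], run_cfg)
        raw[j, :] = bma_posterior(records, P)
    # enforce structural zeros (already zero by construction)
    for p, row in enumerate(lib.tf_rows):
        raw[row, p] = 0.0
    if lib.excluded:
        raw[:, sorted(lib.excluded)] = 0.0
    return GRNPosterior(
        raw=raw,
        scaled=variance_scaling(raw),
        gene_ids=Xs.gene_ids,
        tf_rows=lib.tf_rows,
        excluded_tfs=lib.excluded,
    )
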