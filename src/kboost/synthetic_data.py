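"""Synthetic benchmark generation: gold-standard networks, steady-state
expression, and noisy prior matrices.

The generator emulates steady-state multifactorial expression data: a sparse
directed acyclic TF -> gene network is sampled with a heavy-ish tailed
out-degree distribution, root genes are perturbed independently per sample
(i.i.d. standard normal), and each regulated gene is a sum of per-edge
signed-coefficient link functions of its regulators plus Gaussian noise,
evaluated in topological order.  ``perturb_prior`` reproduces the
noisy-informative-prior experiment design: a fraction of (TF, target) pair
statuses is flipped (balanced between edge deletions and additions where
possible) and present/absent pairs receive weights 0.6/0.4 by default.

All randomness flows from the integer seed of the spec through named
generators; no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .evaluation import GoldStandard
from .exceptions import CycleError, InvalidParameterError
from .grn_inference import PriorMatrix
from .kernel_features import ExpressionMatrix

__all__ = [
    "SimulationSpec",
    "simulate_network",
    "simulate_expression",
    "perturb_prior",
]

LINK_FUNCTIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "linear": lambda x: x,
    "tanh-saturating": np.tanh,
    "quadratic": lambda x: x * x,
}


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic benchmark instance.

    n_genes, n_tfs
        Network size; the first ``n_tfs`` gene rows are the TFs and the gene
        order is the topological order of the sampled DAG.
    avg_outdegree
        Expected number of targets per TF (heavy-ish tail across TFs).
    n_samples
        Steady-state observations (multifactorial-style: every root gene is
        re-perturbed in every sample).
    noise_sd
        Standard deviation of the additive Gaussian noise on regulated genes.
    link_function
        Shape of each regulator's effect: linear, tanh-saturating, or
        quadratic.
    """

    n_genes: int = 50
    n_tfs: int = 10
    avg_outdegree: float = 3.0
    n_samples: int = 100
    noise_sd: float = 0.25
    link_function: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tfs < 1 or self.n_tfs > self.n_genes:
            raise InvalidParameterError(
                f"need 1 <= n_tfs <= n_genes, got P={self.n_tfs}, G={self.n_genes}"
            )
        if self.avg_outdegree < 0 or self.avg_outdegree >= self.n_genes:
            raise InvalidParameterError(
                f"avg_outdegree must be in [0, G), got {self.avg_outdegree}"
            )
        if self.n_samples < 3:
            raise InvalidParameterError(f"need n_samples >= 3, got {self.n_samples}")
        if self.noise_sd < 0:
            raise InvalidParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.link_function not in LINK_FUNCTIONS:
            raise InvalidParameterError(
                f"unknown link function {self.link_function!r}; "
                f"choose from {sorted(LINK_FUNCTIONS)}"
            )

    @property
    def tf_rows(self) -> tuple[int, ...]:
        return tuple(range(self.n_tfs))

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(f"G{i + 1}" for i in range(self.n_genes))

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(f"S{i + 1}" for i in range(self.n_samples))


def simulate_network(spec: SimulationSpec) -> GoldStandard:
    """Sample a directed acyclic TF -> gene gold-standard network.

    TF p may regulate any gene with a larger row index (the row order is the
    topological order), so the graph is acyclic by construction and has no
    self-loops.  Per-TF target rates are log-normal around ``avg_outdegree``,
    giving a few hub TFs.  The returned gold standard labels the complete
    TF x gene universe.
    """
    rng = np.random.default_rng([spec.seed, 0])
    G, P = spec.n_genes, spec.n_tfs
    propensity = rng.lognormal(mean=0.0, sigma=1.0, size=P)
    target_rate = spec.avg_outdegree * propensity / propensity.mean()
    edges: set[tuple[int, int]] = set()
    for p in range(P):
        allowed = np.arange(p + 1, G)
        if allowed.size == 0:
            continue
        prob = min(1.0, target_rate[p] / allowed.size)
        hit = allowed[rng.random(allowed.size) < prob]
        edges.update((p, int(j)) for j in hit)
    return GoldStandard.from_positive_edges(
        edges, tf_keys=list(range(P)), target_keys=list(range(G))
    )


def _topological_order(n_genes: int, regulators: dict[int, list[int]]) -> list[int]:
    order: list[int] = []
    state = {}  # 0 = unvisited, 1 = on stack, 2 = done
    def visit(j: int) -> None:
        if state.get(j) == 2:
            return
        if state.get(j) == 1:
            raise CycleError("regulatory network contains a directed cycle")
        state[j] = 1
        for p in regulators.get(j, ()):
            visit(p)
        state[j] = 2
        order.append(j)
    for j in range(n_genes):
        visit(j)
    return order


def simulate_expression(gold: GoldStandard, spec: SimulationSpec) -> ExpressionMatrix:
    """Generate a steady-state expression matrix consistent with a gold network.

    Genes without regulators are i.i.d. standard normal per sample; each
    regulated gene is the sum over its regulators of
    ``coefficient * link(regulator expression)`` plus N(0, noise_sd^2)
    noise, with coefficients drawn once as sign * Uniform(0.5, 1.5).
    Raises :class:`CycleError` on cyclic input.
    """
    rng = np.random.default_rng([spec.seed, 1])
    G, n = spec.n_genes, spec.n_samples
    link = LINK_FUNCTIONS[spec.link_function]
    regulators: dict[int, list[int]] = {}
    for (p, j), lab in sorted(gold.labels.items()):
        if lab == 1:
            regulators.setdefault(j, []).append(p)
    for regs in regulators.values():
        regs.sort()
    order = _topological_order(G, regulators)
    values = np.zeros((G, n))
    for j in order:
        regs = regulators.get(j, [])
        if not regs:
            values[j] = rng.standard_normal(n)
            continue
        x = np.zeros(n)
        for p in regs:
            coef = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.5)
            x += coef * link(values[p])
        if spec.noise_sd > 0:
            x += spec.noise_sd * rng.standard_normal(n)
        values[j] = x
    return ExpressionMatrix(
        values=values, gene_ids=spec.gene_ids, sample_ids=spec.sample_ids
    )


def perturb_prior(
    gold: GoldStandard,
    flip_fraction: float,
    w_in: float = 0.6,
    w_out: float = 0.4,
    seed: int = 0,
    n_genes: int | None = None,
    tf_rows: tuple[int, ...] | None = None,
) -> PriorMatrix:
    """Build a noisy informative prior matrix from a gold standard.

    Flips the presence/absence status of ``floor(flip_fraction * n_pairs)``
    labeled pairs, balanced between deletions of true edges and additions of
    false ones as far as the pool sizes allow, then assigns ``w_in`` to
    present and ``w_out`` to absent pairs.  ``flip_fraction = 0`` encodes the
    gold standard exactly; ``flip_fraction = 1`` encodes its complement.

    The gold standard must use integer (TF row, gene row) keys.  ``n_genes``
    and ``tf_rows`` default to the extent of the gold universe.
    """
    if not (0.0 <= flip_fraction <= 1.0):
        raise InvalidParameterError(
            f"flip_fraction must be in [0, 1], got {flip_fraction}"
        )
    if not (0.0 < w_out < w_in < 1.0):
        raise InvalidParameterError(
            f"need 0 < w_out < w_in < 1, got w_in={w_in}, w_out={w_out}"
        )
    pairs = sorted(gold.labels)
    if tf_rows is None:
        tf_rows = tuple(sorted({p for p, _ in pairs}))
    if n_genes is None:
        n_genes = 1 + max(max(j for _, j in pairs), max(tf_rows))
    col_of = {row: col for col, row in enumerate(tf_rows)}

    rng = np.random.default_rng([seed, 2])
    present = [pair for pair in pairs if gold.labels[pair] == 1]
    absent = [pair for pair in pairs if gold.labels[pair] == 0]
    n_flip = int(np.floor(flip_fraction * len(pairs)))
    n_del = min(len(present), n_flip // 2)
    n_add = min(len(absent), n_flip - n_del)
    n_del = min(len(present), n_flip - n_add)  # top up if additions ran out
    flipped: set[tuple[int, int]] = set()
    if n_del:
        chosen = rng.choice(len(present), size=n_del, replace=False)
        flipped.update(present[i] for i in chosen)
    if n_add:
        chosen = rng.choice(len(absent), size=n_add, replace=False)
        flipped.update(absent[i] for i in chosen)

    weights = np.full((n_genes, len(tf_rows)), w_out)
    for pair in pairs:
        status = gold.labels[pair] == 1
        if pair in flipped:
            status = not status
        p, j = pair
        weights[j, col_of[p]] = w_in if status else w_out
    return PriorMatrix(weights)
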