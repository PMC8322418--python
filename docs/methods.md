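# Methods

## Model and inference procedure

The package treats GRN inference as unsupervised classification of the
G × P binary adjacency matrix C (gene j is regulated by TF p). Expression
of each gene is assumed to be a steady-state linear combination of
(possibly nonlinear) functions of its regulators' expression plus i.i.d.
Gaussian noise. The posterior P(C_{j,p}=1 | x) is approximated by Bayesian
model averaging over the TF subsets explored by a greedy boosting search:

1. **Standardization.** Every gene row is scaled to sample mean 0 and
   sample variance 1 (n−1 denominator). Zero-variance genes cannot be
   standardized; their rows are zeroed and they are skipped as targets.
2. **Feature construction.** Per TF: RBF kernel with width γ on the
   standardized expression vector, double centering (so the implicit
   features have zero mean), eigendecomposition, retention of leading
   eigenvalues, projection, and normalization of each kernel principal
   component (KPC) to unit norm. For an exact eigenpair the normalized
   projection equals the unit eigenvector, so the KPC block is orthonormal
   and a one-block regression needs no inversion. Kernels are scratch
   space: peak extra memory is O(n²) independent of P.
3. **Greedy boosting.** For each gene, iteration 1 fits every candidate TF
   (all non-degenerate TFs except the gene itself) as a singleton; each
   later iteration refits every candidate on the current residuals as an
   extension of the selected prefix. Coefficients are shrunken exact
   projections β = ν gᵀ r; the residual update uses the shrunken
   prediction, so with ν < 1 the same TF can be selected repeatedly.
   Every evaluated model is recorded; the maximum number of distinct TFs
   per gene equals the iteration count.
4. **Scoring.** A model's log marginal likelihood is −((n−1)/2)·ln RSS —
   the closed form obtained by giving the noise variance a Jeffreys prior
   and holding the fitted component fixed. Its log prior is binomial with
   per-edge weights w_{j,p} ∈ (0,1); membership uses the distinct TF set.
5. **Averaging.** Model weights are softmax(log ML + log prior) over all
   recorded models (log-sum-exp throughout; raw likelihoods would
   underflow for n ≳ 50). The posterior for an edge is the summed weight
   of models containing that TF.
6. **Variance scaling.** Each TF column of the posterior matrix is
   multiplied by its sample variance (n−1 denominator over the G entries).
   This suppresses columns that are uniformly mediocre and preserves a
   sparse out-degree distribution; within-column rankings are unchanged.
   Both matrices are returned; the raw one carries probability semantics
   and is the default for ranked output and thresholding.

The core is fully deterministic: greedy ties resolve to the lowest TF
column index, and eigenvector signs are fixed by making each column's
largest-magnitude entry positive (regression fits are sign-invariant, so
this affects only reproducibility of the stored components).

## Parameters

| parameter | default | meaning |
|---|---|---|
| γ (`gamma`) | 60 | RBF kernel width on standardized expression (squared-distance divisor; dimensionless after standardization). Larger γ makes the kernel flatter and the fit closer to linear. |
| ν (`nu`) | 10/n if n > 10 else 0.5 | shrinkage on regression coefficients; damps RSS differences between models so posteriors do not saturate as n grows. |
| `iterations` | 3 | boosting steps = maximum distinct TFs per gene. |
| `eig_threshold` | 1e-6 | relative eigenvalue retention: keep λᵢ ≥ threshold·λ₁ (and λᵢ > 0). |
| `tau` | 0.2 | strict posterior threshold used when discretizing the network. |

The γ, iteration and ν defaults are the package's standard operating
point for benchmark-style data; the eigenvalue threshold is a design
choice of this implementation (a relative rule is scale-free and robust
to n — no fixed cap on the number of components is imposed).

## Design choices where the design was open

- **Self-regulation** is excluded: a TF never appears in its own candidate
  set and its self-edge posterior is exactly 0. A TF's expression
  trivially predicts itself, and benchmark gold standards exclude
  self-loops.
- **Repeated selections** are allowed during boosting, but the prior and
  the membership indicator of the model average use the distinct set.
- **The explored model set** for the average is every model evaluated at
  any iteration (all singletons at step 1, all prefix∪{p} extensions
  later), not only the selected ones — the Occam's-window style of model
  averaging.
- **RSS floor**: RSS is clamped at 1e-12·n before logs, so numerically
  perfect fits stay finite without changing rankings among imperfect fits.
- **Eigendecomposition guard**: eigenvalues in [−1e-10, 0) are treated as
  zeros (symmetric-solver noise); a TF whose kernel retains nothing (e.g.
  constant expression) is excluded and its posterior column is zero.
- **Metrics**: AUROC uses trapezoidal tie handling (the Mann–Whitney
  statistic); AUPR uses step-sum integration over distinct thresholds
  (interpolated PR is optimistically biased). Partial gold standards are
  scored over labeled pairs only. F1 threshold selection uses the
  keep-if-strictly-greater rule with ties going to the lowest threshold.
- **Closeness**: the thresholded network is essentially always
  disconnected, where classical closeness is ill-defined, so TF influence
  is reported as unnormalized outgoing *harmonic* closeness
  (Σ 1/d(v,u) over reachable u): the distance-discounted count of genes a
  TF regulates directly or indirectly. Thresholding defaults to the raw
  matrix; a flag switches to the variance-scaled one.

## Synthetic benchmarks

`synthetic_data` generates the fixture layer every stage is verified on:

- **Topology**: a directed acyclic TF→gene network over a fixed
  topological order (TFs first), with per-TF target rates drawn log-normal
  around `avg_outdegree`, giving a few hub TFs. Real benchmark networks
  contain cycles; a DAG is generated instead because it has exact steady
  states without fixed-point solving.
- **Expression**: genes without regulators are i.i.d. standard normal per
  sample (a multifactorial-style perturbation of every root in every
  sample); regulated genes are Σ coefficient·link(regulator) + N(0,
  noise_sd²) evaluated in topological order, with per-edge coefficients
  ±Uniform(0.5, 1.5) and linear, tanh-saturating or quadratic links.
- **Noisy priors**: `perturb_prior` flips the presence status of a given
  fraction of all labeled pairs (balanced between deletions and additions
  where pool sizes allow) and assigns weights 0.6/0.4 to present/absent
  pairs.

Default study conditions are G=50 genes, P=10 TFs, average out-degree 3,
n=100 samples, noise SD 0.25, linear links — small enough for a laptop
test run, large enough that recovery is far from chance. What passing
tests on these fixtures shows: the inference recovers planted structure
well above a permuted-gold control and benefits from a mildly corrupted
informative prior. What they do not show: performance on cyclic or
feedback-heavy networks, non-Gaussian measurement noise, hidden
confounders, or realistic microarray/RNA-seq noise models — the simulator
makes no attempt at kinetic (ODE-level) realism.

## Numerical notes

- All posterior arithmetic is in log space with log-sum-exp.
- Candidate RSS during boosting uses the orthonormal-projection identity
  RSS_new = ‖r‖² − ν(2−ν)‖gᵀr‖², which is exact; equivalence with an
  explicit-residual reference implementation is asserted to 1e-8.
- Sample variance uses the n−1 denominator throughout (standardization
  and column scaling).
- Raw posteriors lie in [0,1]; variance-scaled values therefore lie in
  [0, 0.25] (a [0,1] variable's variance is at most 1/4).

## Known limitations

- Edges are directed TF→target by construction but the method cannot
  distinguish direction between two TFs that regulate each other; cycles
  in the true system violate the steady-state generative assumption.
- The marginal likelihood treats the fitted component as fixed (no
  integration over β), a deliberate simplification for speed.
- γ is not estimated from data; the kernel family is RBF only.
- Single-threaded by contract; vectorized internally but no parallel or
  out-of-core execution.
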