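"""Deliberately naive reference implementation of the inference core.

Written straight from the model equations with explicit Python loops and no
shared code with the package: kernels are recomputed from scratch for every
gene, residual sums of squares are summed element by element, candidate
models are refit explicitly, and the model average exponentiates shifted log
posteriors directly.  It exists solely as the independent oracle for
equivalence tests on small instances; it is O(G^2 * iterations * n^3) and
unusable beyond toy sizes.

It must share only the *conventions* of the package (relative eigenvalue
threshold, unit-norm sign-fixed components, RSS floor, lowest-index
tie-break, n-1 variance denominator), not its code paths.
"""

import math

import numpy as np


def _standardize(values):
    G, n = values.shape
    out = np.zeros_like(values, dtype=float)
    constant = set()
    for g in range(G):
        row = values[g]
        mean = sum(row) / n
        var = sum((x - mean) ** 2 for x in row) / (n - 1)
        if var == 0.0:
            constant.add(g)
            continue
        sd = math.sqrt(var)
        for i in range(n):
            out[g, i] = (row[i] - mean) / sd
    return out, constant


def _kpcs_of_vector(v, gamma, eig_threshold):
    """RBF kernel -> double centering -> eigendecomposition -> unit-norm
    sign-fixed components. Returns None when degenerate."""
    n = len(v)
    K = np.zeros((n, n))
    for i in range(n):
        for u in range(n):
            K[i, u] = math.exp(-((v[i] - v[u]) ** 2) / gamma)
    ones = np.full((n, n), 1.0 / n)
    Kc = K - ones @ K - K @ ones + ones @ K @ ones
    Kc = (Kc + Kc.T) / 2.0
    evals, evecs = np.linalg.eigh(Kc)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    evals = np.where((evals < 0) & (evals >= -1e-10), 0.0, evals)
    if evals[0] <= 0:
        return None
    keep = [i for i in range(n) if evals[i] > 0 and evals[i] >= eig_threshold * evals[0]]
    cols = []
    for i in keep:
        proj = Kc @ evecs[:, i]
        proj = proj / math.sqrt(sum(x * x for x in proj))
        jmax = int(np.argmax(np.abs(proj)))
        if proj[jmax] < 0:
            proj = -proj
        cols.append(proj)
    return np.column_stack(cols)


def _log_prior(member_set, w_row):
    total = 0.0
    for p, w in enumerate(w_row):
        total += math.log(w) if p in member_set else math.log(1.0 - w)
    return total


def _log_ml(rss, n):
    rss = max(rss, 1e-12 * n)
    return -0.5 * (n - 1) * math.log(rss)


def naive_kboost(values, tf_rows, W, gamma=60.0, nu=None, iterations=3,
                 eig_threshold=1e-6):
    """Posterior edge-probability matrices computed the slow, literal way.

    Returns (raw, scaled) G x P arrays.
    """
    values = np.asarray(values, dtype=float)
    G, n = values.shape
    P = len(tf_rows)
    if nu is None:
        nu = 10.0 / n if n > 10 else 0.5
    Xs, constant = _standardize(values)

    raw = np.zeros((G, P))
    for j in range(G):
        if j in constant:
            continue
        candidates = [
            p for p in range(P)
            if tf_rows[p] != j and tf_rows[p] not in constant
        ]
        if not candidates:
            continue
        explored = []  # (member_set, rss)
        prefix_pred = np.zeros(n)
        prefix_members = []
        for _ in range(iterations):
            best = None
            for p in candidates:
                kpcs = _kpcs_of_vector(Xs[tf_rows[p]], gamma, eig_threshold)
                residual = Xs[j] - prefix_pred
                beta = nu * (kpcs.T @ residual)
                pred = kpcs @ beta
                new_resid = residual - pred
                rss = sum(e * e for e in new_resid)
                member_set = frozenset(prefix_members + [p])
                explored.append((member_set, rss))
                score = _log_ml(rss, n) + _log_prior(member_set, W[j])
                if best is None or score > best[0]:
                    best = (score, p, pred)
            prefix_pred = prefix_pred + best[2]
            prefix_members.append(best[1])
        # Bayesian model average over every explored model
        log_posts = [
            _log_ml(rss, n) + _log_prior(ms, W[j]) for ms, rss in explored
        ]
        shift = max(log_posts)
        weights = [math.exp(lp - shift) for lp in log_posts]
        total = sum(weights)
        for (member_set, _), wt in zip(explored, weights):
            for p in member_set:
                raw[j, p] += wt / total

    scaled = np.zeros_like(raw)
    for p in range(P):
        col = raw[:, p]
        mean = sum(col) / G
        var = sum((x - mean) ** 2 for x in col) / (G - 1)
        scaled[:, p] = col * var
    return raw, scaled
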