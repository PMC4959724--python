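"""Population structure: IBS distance, UPGMA, admixture MCMC, Evanno delta-K.

The admixture model assumes each individual's genome is a mixture of K
ancestral populations: sample i has membership proportions Q[i] (a point
on the K-simplex) and population k has allele frequencies P[k, l] at
locus l.  Each observed allele copy carries a latent population of
origin z; a Gibbs sampler alternates

  z | Q, P   (categorical, proportional to Q[i,k] * P[k,l,allele]),
  P | z      (Dirichlet posterior under a uniform prior),
  Q | z      (Dirichlet(alpha + per-sample origin counts)),

with allele frequencies independent across populations (no correlated-
frequencies variant).  Model choice across K uses the log evidence
estimate LnP(D) = mean(trace) - var(trace)/2 over the post-burn-in
log-likelihood trace, and the Evanno statistic
delta-K = |L''(K)| / sd(L(K)), whose maximum over interior K suggests
the number of subpopulations.  Replicate runs at one K are combined
after undoing label switching by permutation alignment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from skbio import DistanceMatrix, TreeNode

from .diversity import GenotypeMatrix

__all__ = [
    "StructureRun",
    "ibs_distance",
    "upgma",
    "ladderize_with_outgroup",
    "gibbs_admixture",
    "lnpd",
    "delta_k",
    "best_k",
    "align_runs",
]


def ibs_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Identity-by-state distance: 1 - mean fraction of shared alleles.

    For one locus the two unordered diploid calls share 0, 1 or 2
    alleles (multiset intersection); the per-locus similarity is that
    count over 2, averaged across loci where both samples are called.
    """
    n = matrix.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared_sum = 0.0
            n_shared_loci = 0
            for a, b in zip(matrix.calls[i], matrix.calls[j]):
                if a is None or b is None:
                    continue
                n_shared_loci += 1
                rem = list(b)
                hits = 0
                for allele in a:
                    if allele in rem:
                        rem.remove(allele)
                        hits += 1
                shared_sum += hits / 2.0
            if n_shared_loci == 0:
                raise ValueError(
                    f"samples {matrix.sample_ids[i]!r} and "
                    f"{matrix.sample_ids[j]!r} share no called locus")
            d[i, j] = d[j, i] = 1.0 - shared_sum / n_shared_loci
    return DistanceMatrix(d, ids=matrix.sample_ids)


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage agglomeration producing a rooted ultrametric tree.

    Nodes merge at height = half the cluster distance; ties are broken
    toward the pair whose (sorted) smallest member ids are
    lexicographically least, which makes the output deterministic.
    """
    ids = list(dm.ids)
    if len(ids) < 2:
        raise ValueError("UPGMA needs at least 2 taxa")
    data = np.asarray(dm.data, dtype=float)
    if np.isnan(data).any():
        raise ValueError("distance matrix contains NaN")

    # active clusters: key -> (TreeNode, size, height, min sample id)
    nodes: dict[int, tuple[TreeNode, int, float, str]] = {
        i: (TreeNode(name=ids[i]), 1, 0.0, ids[i]) for i in range(len(ids))
    }
    dist: dict[frozenset[int], float] = {
        frozenset((i, j)): data[i, j]
        for i in range(len(ids)) for j in range(i + 1, len(ids))
    }
    next_key = len(ids)
    while len(nodes) > 1:
        best_pair, best_d = None, np.inf
        for pair, dv in dist.items():
            i, j = sorted(pair, key=lambda k: nodes[k][3])
            tag = (nodes[i][3], nodes[j][3])
            if dv < best_d - 1e-12 or (abs(dv - best_d) <= 1e-12
                                       and best_pair is not None
                                       and tag < best_tag):
                best_pair, best_d, best_tag = (i, j), dv, tag
            elif best_pair is None:
                best_pair, best_d, best_tag = (i, j), dv, tag
        i, j = best_pair
        node_i, size_i, h_i, min_i = nodes[i]
        node_j, size_j, h_j, min_j = nodes[j]
        height = best_d / 2.0
        node_i.length = height - h_i
        node_j.length = height - h_j
        parent = TreeNode(children=[node_i, node_j])
        # average linkage to every other active cluster
        for k in list(nodes):
            if k in (i, j):
                continue
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            dist[frozenset((next_key, k))] = (
                (size_i * dik + size_j * djk) / (size_i + size_j))
        dist.pop(frozenset((i, j)))
        del nodes[i], nodes[j]
        nodes[next_key] = (parent, size_i + size_j, height, min(min_i, min_j))
        next_key += 1
    (root, _, _, _), = nodes.values()
    root.length = None
    return root


def ladderize_with_outgroup(tree: TreeNode, outgroup: str) -> TreeNode:
    """Reorder children so the clade containing the outgroup draws first.

    UPGMA trees are already rooted; the outgroup only affects display
    order, not topology or branch lengths.
    """
    tips = {t.name for t in tree.tips()}
    if outgroup not in tips:
        raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")
    for node in tree.postorder(include_self=True):
        if node.children:
            node.children.sort(
                key=lambda c: (outgroup not in {t.name for t in c.tips()}
                               if c.children else c.name != outgroup))
    return tree


@dataclass
class StructureRun:
    """Posterior summary of one admixture MCMC run.

    ``loglik_trace`` holds the data log-likelihood at each retained
    (post-burn-in) sweep; Q and P are posterior means over those sweeps.
    """

    K: int
    Q: np.ndarray             # (n_samples, K), rows sum to 1
    P: np.ndarray             # (K, n_loci, max alleles), sums to 1 per locus
    alpha: float
    loglik_trace: np.ndarray  # (reps,)
    seed: int
    burnin: int
    reps: int
    sample_ids: list[str] = field(default_factory=list)


def _encode_alleles(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Integer-code calls as X (n, L, 2) with -1 for missing, plus allele counts."""
    n, L = matrix.n_samples, matrix.n_loci
    X = np.full((n, L, 2), -1, dtype=np.int64)
    n_alleles = np.zeros(L, dtype=np.int64)
    for j in range(L):
        col = matrix.locus_calls(j)
        alleles = sorted({a for c in col if c is not None for a in c})
        code = {a: idx for idx, a in enumerate(alleles)}
        n_alleles[j] = max(len(alleles), 1)
        for i, c in enumerate(col):
            if c is not None:
                X[i, j, 0] = code[c[0]]
                X[i, j, 1] = code[c[1]]
    return X, n_alleles


def gibbs_admixture(matrix: GenotypeMatrix, K: int, burnin: int = 1000,
                    reps: int = 5000, alpha: float = 1.0,
                    seed: int = 0) -> StructureRun:
    """Gibbs sampler for the independent-frequencies admixture model.

    Returns posterior-mean Q and P and the post-burn-in log-likelihood
    trace.  Missing calls contribute no origin counts and are skipped in
    the likelihood.  Deterministic for a fixed seed.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > matrix.n_samples:
        raise ValueError("K must not exceed the number of samples")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    X, n_alleles = _encode_alleles(matrix)
    n, L, _ = X.shape
    Jmax = int(n_alleles.max())
    allele_mask = np.arange(Jmax)[None, :] < n_alleles[:, None]  # (L, Jmax)
    observed = X >= 0                                            # (n, L, 2)
    Xsafe = np.where(observed, X, 0)
    lgrid = np.broadcast_to(np.arange(L)[None, :], (n, L))

    # initialise from the priors
    Q = rng.dirichlet(np.full(K, alpha), size=n)                 # (n, K)
    P = rng.gamma(1.0, size=(K, L, Jmax)) * allele_mask[None]
    P /= P.sum(axis=2, keepdims=True)

    Q_sum = np.zeros_like(Q)
    P_sum = np.zeros_like(P)
    trace = np.zeros(reps)
    igrid = np.broadcast_to(np.arange(n)[:, None], (n, L))

    for sweep in range(burnin + reps):
        countsP = np.zeros((K, L, Jmax))
        countsQ = np.zeros((n, K))
        loglik = 0.0
        for c in (0, 1):
            Xc = Xsafe[:, :, c]                                  # (n, L)
            obs = observed[:, :, c]
            # w[k, i, l] = Q[i, k] * P[k, l, Xc[i, l]]
            w = Q.T[:, :, None] * P[:, np.arange(L)[None, :], Xc]
            tot = w.sum(axis=0)
            loglik += float(np.log(tot[obs]).sum())
            u = rng.random((n, L)) * tot
            z = (np.cumsum(w, axis=0) < u[None]).sum(axis=0)
            z = np.minimum(z, K - 1)
            np.add.at(countsP, (z[obs], lgrid[obs], Xc[obs]), 1.0)
            np.add.at(countsQ, (igrid[obs], z[obs]), 1.0)
        # conjugate updates (Dirichlet via normalized gammas)
        G = rng.gamma(1.0 + countsP) * allele_mask[None]
        P = G / G.sum(axis=2, keepdims=True)
        Gq = rng.gamma(alpha + countsQ)
        Q = Gq / Gq.sum(axis=1, keepdims=True)
        if sweep >= burnin:
            Q_sum += Q
            P_sum += P
            trace[sweep - burnin] = loglik

    return StructureRun(K=K, Q=Q_sum / reps, P=P_sum / reps, alpha=alpha,
                        loglik_trace=trace, seed=seed, burnin=burnin,
                        reps=reps, sample_ids=list(matrix.sample_ids))


def lnpd(run: StructureRun | np.ndarray) -> float:
    """Model evidence estimate: mean of the trace minus half its variance."""
    trace = np.asarray(run.loglik_trace if isinstance(run, StructureRun) else run,
                       dtype=float)
    if trace.size < 1:
        raise ValueError("empty log-likelihood trace")
    var = float(np.var(trace, ddof=1)) if trace.size > 1 else 0.0
    return float(trace.mean()) - var / 2.0


def delta_k(lnpd_by_k: dict[int, list[float]]) -> pd.DataFrame:
    """Evanno table: mean/sd of LnP(D), first and second differences, delta-K.

    delta-K(K) = |L'(K+1) - L'(K)| / sd(L(K)) is defined only at interior
    K with at least two runs and non-zero sd (NaN elsewhere).
    """
    ks = sorted(lnpd_by_k)
    if len(ks) < 3:
        raise ValueError("delta-K needs at least 3 consecutive K values")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("K values must be consecutive")
    mean = {k: float(np.mean(lnpd_by_k[k])) for k in ks}
    sd = {k: float(np.std(lnpd_by_k[k], ddof=1)) if len(lnpd_by_k[k]) > 1
          else np.nan for k in ks}
    rows = []
    for k in ks:
        lp = mean[k] - mean[k - 1] if k - 1 in mean else np.nan
        lpp = (abs((mean[k + 1] - mean[k]) - (mean[k] - mean[k - 1]))
               if (k - 1 in mean and k + 1 in mean) else np.nan)
        dk = lpp / sd[k] if (not np.isnan(lpp) and sd[k] and sd[k] > 0) else np.nan
        rows.append({"K": k, "mean_lnpd": mean[k], "sd_lnpd": sd[k],
                     "lprime": lp, "abs_lpp": lpp, "delta_k": dk})
    return pd.DataFrame(rows).set_index("K")


def best_k(table: pd.DataFrame) -> int:
    """K with the largest defined delta-K."""
    col = table["delta_k"].dropna()
    if col.empty:
        raise ValueError("delta-K undefined at every K")
    return int(col.idxmax())


def _permutation_cost(Q_ref: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """cost[k1, k2] = sum_i (Q_ref[i,k1] - Q[i,k2])^2 (decomposes over columns)."""
    diff = Q_ref[:, :, None] - Q[:, None, :]
    return np.square(diff).sum(axis=0)


def _best_permutation(Q_ref: np.ndarray, Q: np.ndarray,
                      exhaustive: bool) -> tuple[int, ...]:
    cost = _permutation_cost(Q_ref, Q)
    K = cost.shape[0]
    if exhaustive:
        return min(itertools.permutations(range(K)),
                   key=lambda perm: sum(cost[k, perm[k]] for k in range(K)))
    _, cols = linear_sum_assignment(cost)
    return tuple(int(c) for c in cols)


def align_runs(runs: list[StructureRun], exhaustive: bool | None = None,
               ) -> np.ndarray:
    """Undo label switching across replicate runs and average their Q.

    Each run's cluster labels are permuted to best match the first run
    (minimum summed squared difference of Q columns); the permutation
    search is exhaustive for K <= 8 and an optimal assignment solve
    above.  Returns the aligned average Q, rows summing to 1.
    """
    if not runs:
        raise ValueError("no runs to align")
    K = runs[0].K
    if any(r.K != K for r in runs):
        raise ValueError("all runs must share the same K")
    if any(r.Q.shape != runs[0].Q.shape for r in runs):
        raise ValueError("all runs must share the same sample set")
    if exhaustive is None:
        exhaustive = K <= 8
    ref = runs[0].Q
    acc = np.array(ref, dtype=float, copy=True)
    for run in runs[1:]:
        perm = _best_permutation(ref, run.Q, exhaustive)
        acc += run.Q[:, perm]
    avg = acc / len(runs)
    return avg / avg.sum(axis=1, keepdims=True)
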