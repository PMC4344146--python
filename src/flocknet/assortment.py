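"""Weighted discrete assortativity by node type, with uncertainty.

The assortativity coefficient generalises Newman's discrete coefficient
to weighted networks: with e_ij the fraction of total edge weight joining
type-i to type-j ends and a_i = sum_j e_ij,

    r = (sum_i e_ii - sum_i a_i^2) / (1 - sum_i a_i^2).

Perfectly segregated networks score 1; a single represented type leaves r
undefined (returned as NaN). The standard error comes from an
edge-jackknife (each nonzero dyad removed in turn) and significance from
a node-permutation null that shuffles the type labels across nodes,
preserving the association structure, each node's gregariousness and the
type counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from flocknet.networks import AssociationNetwork


@dataclass
class MixingMatrix:
    """Type-by-type edge-weight fractions e and their marginals a."""

    types: list[str]
    e: np.ndarray
    a: np.ndarray


@dataclass
class AssortmentResult:
    """Observed assortativity with jackknife SE and permutation-null summary."""

    r: float
    se_jackknife: float
    null_lo: float
    null_hi: float
    p_perm: float
    n_perm: int
    n_nodes: int

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "se": self.se_jackknife,
            "null_lo": self.null_lo,
            "null_hi": self.null_hi,
            "p": self.p_perm,
            "n_perm": self.n_perm,
            "n_nodes": self.n_nodes,
        }


def _as_w_and_types(net, types):
    if isinstance(net, AssociationNetwork):
        W = net.W
        if types is None:
            types = net.attr_vector("parity")
    else:
        W = np.asarray(net, dtype=float)
    if types is None:
        raise ValueError("types required when net is a bare matrix")
    types = np.asarray(types)
    if types.shape[0] != W.shape[0]:
        raise ValueError("types length must match network size")
    return W, types


def mixing_matrix(net, types=None) -> MixingMatrix:
    """Fraction of total edge weight joining each ordered pair of types.

    Each undirected dyad of weight w contributes w/2 to e[type_a][type_b]
    and w/2 to e[type_b][type_a]; e is normalised to sum to 1.
    """
    W, types = _as_w_and_types(net, types)
    total = W.sum()  # == 2 * total dyad weight, both ordered ends counted
    if total <= 0:
        raise ValueError("zero-weight network has no mixing matrix")
    labels = sorted(set(types.tolist()))
    t_index = np.array([labels.index(t) for t in types])
    T = len(labels)
    e = np.zeros((T, T))
    for i in range(T):
        for j in range(T):
            e[i, j] = W[np.ix_(t_index == i, t_index == j)].sum()
    e /= total
    return MixingMatrix(types=labels, e=e, a=e.sum(axis=1))


def assortativity_weighted(net, types=None) -> float:
    """Weighted discrete assortativity r; NaN if a single type carries all weight."""
    mm = mixing_matrix(net, types)
    trace = np.trace(mm.e)
    a2 = float(np.sum(mm.a**2))
    if np.isclose(a2, 1.0):
        return float("nan")
    # r is bounded by 1 mathematically; clip rounding from the division
    return float(np.clip((trace - a2) / (1.0 - a2), -1.0, 1.0))


def _sums_for_r(W: np.ndarray, same_type: np.ndarray, type_onehot: np.ndarray):
    """Sufficient statistics of r: total weight, same-type weight, per-type strengths."""
    total = W.sum()
    within = (W * same_type).sum()
    strengths = type_onehot.T @ W.sum(axis=1)
    return total, within, strengths


def _r_from_sums(total, within, strengths):
    if total <= 0:
        return float("nan")
    trace = within / total
    a = strengths / total
    a2 = float(np.sum(a**2))
    if np.isclose(a2, 1.0):
        return float("nan")
    return float(np.clip((trace - a2) / (1.0 - a2), -1.0, 1.0))


def jackknife_se(net, types=None) -> float:
    """Edge-jackknife standard error of r.

    Every nonzero dyad m is zeroed in turn, giving r_(-m); then
    se^2 = sum_m (r_(-m) - r)^2.
    """
    W, types = _as_w_and_types(net, types)
    iu, ju = np.triu_indices_from(W, k=1)
    w = W[iu, ju]
    nz = w > 0
    if nz.sum() < 2:
        raise ValueError("jackknife requires >= 2 nonzero dyads")
    labels = sorted(set(types.tolist()))
    t_index = np.array([labels.index(t) for t in types])
    onehot = np.eye(len(labels))[t_index]
    same = (t_index[:, None] == t_index[None, :]).astype(float)
    total, within, strengths = _sums_for_r(W, same, onehot)
    r = _r_from_sums(total, within, strengths)

    dev_sq = 0.0
    for i, j, wij in zip(iu[nz], ju[nz], w[nz]):
        tot_m = total - 2 * wij
        within_m = within - (2 * wij if t_index[i] == t_index[j] else 0.0)
        strengths_m = strengths.copy()
        strengths_m[t_index[i]] -= wij
        strengths_m[t_index[j]] -= wij
        r_m = _r_from_sums(tot_m, within_m, strengths_m)
        if np.isnan(r_m):
            continue
        dev_sq += (r_m - r) ** 2
    return float(np.sqrt(dev_sq))


def node_permutation_null(
    net,
    types=None,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    alternative: str = "two-sided",
) -> AssortmentResult:
    """Assortativity against a node-permutation null.

    Type labels are permuted across nodes (equivalent to jointly shuffling
    the matrix rows and columns), which preserves the association
    patterns, each node's weighted degree and the type counts. Returns the
    observed r, the empirical 2.5/97.5 null percentiles and the add-one
    Monte-Carlo p-value (two-tailed by default; ``alternative='greater'``
    gives the one-tailed version).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    W, types = _as_w_and_types(net, types)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = sorted(set(types.tolist()))
    t_index = np.array([labels.index(t) for t in types])
    onehot = np.eye(len(labels))
    r_obs = assortativity_weighted(W, types)

    strengths_node = W.sum(axis=1)
    total = W.sum()
    r_null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(t_index)
        same = perm[:, None] == perm[None, :]
        within = (W * same).sum()
        strengths = onehot[perm].T @ strengths_node
        r_null[b] = _r_from_sums(total, within, strengths)

    finite = r_null[np.isfinite(r_null)]
    if finite.size == 0:
        null_lo = null_hi = float("nan")
        p = 1.0
    else:
        null_lo, null_hi = np.percentile(finite, [2.5, 97.5])
        if alternative == "greater":
            exceed = np.sum(finite >= r_obs)
        else:
            exceed = np.sum(np.abs(finite) >= abs(r_obs))
        p = float((1 + exceed) / (1 + finite.size))
    try:
        se = jackknife_se(W, types) if np.isfinite(r_obs) else float("nan")
    except ValueError:  # fewer than 2 nonzero dyads
        se = float("nan")
    return AssortmentResult(
        r=float(r_obs),
        se_jackknife=se,
        null_lo=float(null_lo),
        null_hi=float(null_hi),
        p_perm=p,
        n_perm=n_perm,
        n_nodes=W.shape[0],
    )
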