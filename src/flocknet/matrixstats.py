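"""Dyadic matrix comparison: Mantel tests and MRQAP with double semi-partialing.

Both procedures operate on the strictly-lower-triangle vectors of aligned
symmetric matrices (diagonal always excluded). Significance comes from
joint row/column permutations, which respect the node-level
non-independence of dyadic data. The Mantel confidence interval is an
individual-level bootstrap: nodes are resampled with replacement, both
matrices are re-indexed accordingly and r recomputed (percentile limits).

MRQAP-DSP regresses one dependent matrix on several predictor matrices by
OLS on the triangle vectors; each predictor's null distribution is built
by permuting the residual of that predictor on the remaining predictors
(double semi-partialing), which isolates its unique contribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm


@dataclass
class MantelResult:
    r: float
    p_perm: float
    ci_lo: float
    ci_hi: float
    n_perm: int
    n_boot: int
    n_nodes: int
    ci_contains_r: bool = True

    def to_dict(self) -> dict:
        return {
            "r": self.r, "p": self.p_perm, "ci_lo": self.ci_lo,
            "ci_hi": self.ci_hi, "n_perm": self.n_perm,
            "n_boot": self.n_boot, "n_nodes": self.n_nodes,
        }


@dataclass
class MRQAPResult:
    predictors: list[str]
    coefficients: dict[str, float]
    p_dsp: dict[str, float]
    intercept: float
    F_full: float
    r2_full: float
    n_perm: int
    n_nodes: int

    def to_dict(self) -> dict:
        out = {"F": self.F_full, "r2": self.r2_full, "n_perm": self.n_perm,
               "n_nodes": self.n_nodes, "intercept": self.intercept}
        for name in self.predictors:
            out[f"coeff_{name}"] = self.coefficients[name]
            out[f"p_{name}"] = self.p_dsp[name]
        return out


def _check_square_symmetric(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(M, M.T):
        raise ValueError(f"{name} must be symmetric")
    return M


def _tri(M: np.ndarray) -> np.ndarray:
    iu, ju = np.tril_indices_from(M, k=-1)
    return M[iu, ju]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def mantel(
    m1,
    m2,
    n_perm: int = 10_000,
    n_boot: int = 1_000,
    seed: int | np.random.Generator = 0,
) -> MantelResult:
    """Mantel correlation between two aligned symmetric matrices.

    r is the Pearson correlation of the strictly-lower-triangle vectors;
    the p-value comes from jointly permuting the rows and columns of m2
    (add-one, two-tailed); the 95% CI from bootstrap resampling of
    individuals (percentile method, self-pairs of duplicated individuals
    masked). Zero variance in either triangle yields r = NaN.
    """
    M1 = _check_square_symmetric(getattr(m1, "W", getattr(m1, "B", m1)), "m1")
    M2 = _check_square_symmetric(getattr(m2, "W", getattr(m2, "B", m2)), "m2")
    if M1.shape != M2.shape:
        raise ValueError("matrices must be aligned to the same roster")
    n = M1.shape[0]
    if n < 3:
        raise ValueError("need at least 3 individuals")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    v1 = _tri(M1)
    r_obs = _pearson(v1, _tri(M2))
    if np.isnan(r_obs):
        return MantelResult(r=float("nan"), p_perm=1.0, ci_lo=float("nan"),
                            ci_hi=float("nan"), n_perm=n_perm, n_boot=n_boot,
                            n_nodes=n)

    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = _pearson(v1, _tri(M2[np.ix_(perm, perm)]))
        if np.isfinite(r_p) and abs(r_p) >= abs(r_obs) - 1e-15:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)

    iu, ju = np.tril_indices(n, k=-1)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(n, size=n)
        keep = idx[iu] != idx[ju]  # duplicated individuals give degenerate self-pairs
        if keep.sum() < 3:
            continue
        b1 = M1[np.ix_(idx, idx)][iu, ju][keep]
        b2 = M2[np.ix_(idx, idx)][iu, ju][keep]
        r_b = _pearson(b1, b2)
        if np.isfinite(r_b):
            boots.append(r_b)
    if boots:
        ci_lo, ci_hi = np.percentile(boots, [2.5, 97.5])
    else:
        ci_lo = ci_hi = float("nan")
    return MantelResult(
        r=r_obs, p_perm=float(p), ci_lo=float(ci_lo), ci_hi=float(ci_hi),
        n_perm=n_perm, n_boot=len(boots), n_nodes=n,
        ci_contains_r=bool(np.isnan(ci_lo) or ci_lo <= r_obs <= ci_hi),
    )


def _unvec(v: np.ndarray, n: int) -> np.ndarray:
    M = np.zeros((n, n))
    iu, ju = np.tril_indices(n, k=-1)
    M[iu, ju] = v
    M[ju, iu] = v
    return M


def mrqap_dsp(
    dep,
    predictors: dict[str, np.ndarray] | list[np.ndarray],
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> MRQAPResult:
    """Multiple regression QAP with double semi-partialing.

    OLS (with intercept) of the dependent matrix's lower triangle on the
    predictors' triangles gives the coefficients, F and R^2. For each
    predictor X_j, its residual on the remaining predictors is permuted as
    a matrix (joint row/column shuffles) and substituted back; the add-one
    two-tailed proportion of permuted |beta_j| exceeding the observed
    gives p_dsp.
    """
    if isinstance(predictors, dict):
        names = list(predictors)
        mats = [predictors[k] for k in names]
    else:
        names = [f"x{j + 1}" for j in range(len(predictors))]
        mats = list(predictors)
    if not mats:
        raise ValueError("need at least one predictor")

    D = _check_square_symmetric(getattr(dep, "W", getattr(dep, "B", dep)), "dep")
    n = D.shape[0]
    if n < 4:
        raise ValueError("need at least 4 individuals")
    Xm = [
        _check_square_symmetric(getattr(m, "W", getattr(m, "B", m)), name)
        for m, name in zip(mats, names)
    ]
    for name, M in zip(names, Xm):
        if M.shape != D.shape:
            raise ValueError(f"predictor {name} not aligned with dep")

    y = _tri(D)
    X = np.column_stack([_tri(M) for M in Xm])

    # collinearity check on the triangle vectors, naming the offender
    for j, name in enumerate(names):
        others = np.column_stack(
            [np.ones(len(y))] + [X[:, k] for k in range(X.shape[1]) if k != j]
        )
        resid = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
        if np.sum(resid**2) <= 1e-12 * max(np.sum(X[:, j] ** 2), 1e-300):
            raise ValueError(
                f"predictor {name!r} is collinear with the remaining predictors"
            )

    design = sm.add_constant(X)
    fit = sm.OLS(y, design).fit()
    coeffs = {name: float(fit.params[j + 1]) for j, name in enumerate(names)}
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    p_dsp = {}
    for j, name in enumerate(names):
        others = np.column_stack(
            [np.ones(len(y))] + [X[:, k] for k in range(X.shape[1]) if k != j]
        )
        beta_o = np.linalg.lstsq(others, X[:, j], rcond=None)[0]
        resid_mat = _unvec(X[:, j] - others @ beta_o, n)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Xp = X.copy()
            Xp[:, j] = _tri(resid_mat[np.ix_(perm, perm)])
            beta = np.linalg.lstsq(sm.add_constant(Xp), y, rcond=None)[0]
            if abs(beta[j + 1]) >= abs(fit.params[j + 1]) - 1e-15:
                exceed += 1
        p_dsp[name] = float((1 + exceed) / (1 + n_perm))

    return MRQAPResult(
        predictors=names,
        coefficients=coeffs,
        p_dsp=p_dsp,
        intercept=float(fit.params[0]),
        F_full=float(fit.fvalue),
        r2_full=float(fit.rsquared),
        n_perm=n_perm,
        n_nodes=n,
    )
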