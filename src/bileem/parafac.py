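"""Non-negativity-constrained PARAFAC (CANDECOMP) for EEM tensor stacks.

The model represents a stack of EEMs as a sum of F trilinear components,

    X[i, j, k] = sum_f A[i, f] * B[j, f] * C[k, f] + E[i, j, k],

where A holds per-sample scores (concentration proxies in the thin limit)
and B, C are emission / excitation loading spectra.  Fitting is alternating
least squares with exact non-negative least-squares sub-solves per mode,
multi-start with best-RSS selection, and the usual diagnostics: residual sum
of squares and core consistency (CORCONDIA).  Non-negativity is on for all
three modes by default: negative scores or loadings are physically
meaningless, and the constraint keeps the model from chasing the small
negatives left by blank subtraction and scatter excision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment, nnls as _scipy_nnls

from .eem_core import EEMTensor
from .errors import AlignmentError, DegenerateModelError

__all__ = [
    "FitOptions",
    "ParafacModel",
    "fit_parafac",
    "rss",
    "core_consistency",
    "model_sweep",
    "match_factors",
    "peak_location",
    "tucker_congruence",
]


@dataclass
class FitOptions:
    """ALS fitting controls.

    ``tol`` is the relative RSS change between successive iterations below
    which the fit is declared converged; defaults follow the standard
    N-way-style convention (1e-6, at most 2500 iterations).
    """

    nonneg: tuple[bool, bool, bool] = (True, True, True)
    tol: float = 1e-6
    max_iter: int = 2500
    n_starts: int = 10
    init: str = "random_nonneg"   # random_nonneg | svd_based
    seed: int = 0

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1 or self.n_starts < 1:
            raise ValueError("max_iter and n_starts must be >= 1")
        if self.init not in ("random_nonneg", "svd_based"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclass
class ParafacModel:
    """Fitted trilinear model: scores A [I x F], loadings B [J x F], C [K x F].

    B and C columns are scaled to unit maximum with the magnitude absorbed
    into A, so scores are comparable across samples; reconstruction is
    invariant to this convention.
    """

    F: int
    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    emission_grid: np.ndarray
    excitation_grid: np.ndarray
    rss: float
    n_iter: int
    converged: bool
    seed: int
    rss_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    scaling: str = "unit_max_BC"

    def reconstruct(self) -> np.ndarray:
        return np.einsum("if,jf,kf->ijk", self.A, self.B, self.C)


# ---------------------------------------------------------------------------
# Non-negative least squares with a shared Gram matrix
# ---------------------------------------------------------------------------
# Every row of a mode update solves  min_{x>=0} x'Gx - 2 x'v  with the SAME
# F x F Gram matrix G (Hadamard product of the other modes' Grams).  For the
# small F used here (<= ~7) the exact solution is found by enumerating
# candidate active sets and checking the KKT conditions, batched over rows.

def _nnls_shared_gram(G: np.ndarray, V: np.ndarray) -> np.ndarray:
    F = G.shape[0]
    n = V.shape[0]
    scale = max(np.trace(G), np.abs(V).max(), 1.0)
    eps = 1e-10 * scale
    Greg = G + (1e-13 * max(np.trace(G), 1.0) / F) * np.eye(F)
    X = np.zeros((n, F))
    assigned = np.all(V <= eps, axis=1)  # x = 0 is KKT-optimal
    idx_all = np.arange(F)
    for size in range(F, 0, -1):
        if np.all(assigned):
            break
        for S in combinations(range(F), size):
            if np.all(assigned):
                break
            S = np.array(S)
            try:
                XS = np.linalg.solve(Greg[np.ix_(S, S)], V[:, S].T).T
            except np.linalg.LinAlgError:
                continue
            ok = np.all(XS >= -eps, axis=1)
            comp = np.setdiff1d(idx_all, S, assume_unique=True)
            if comp.size:
                # dual feasibility on the inactive set: grad = Gx - v >= 0
                grad = XS @ G[np.ix_(S, comp)] - V[:, comp]
                ok &= np.all(grad >= -eps, axis=1)
            take = ok & ~assigned
            if np.any(take):
                X[np.ix_(take, S)] = np.maximum(XS[take], 0.0)
                assigned |= take
    if not np.all(assigned):
        # rare numerical fallback: row-wise NNLS on the Cholesky factor
        L = np.linalg.cholesky(Greg)
        for i in np.nonzero(~assigned)[0]:
            rhs = np.linalg.solve(L, V[i])
            X[i], _ = _scipy_nnls(L.T, rhs)
    return X


def _ls_shared_gram(G: np.ndarray, V: np.ndarray) -> np.ndarray:
    Greg = G + (1e-13 * max(np.trace(G), 1.0) / G.shape[0]) * np.eye(G.shape[0])
    return np.linalg.solve(Greg, V.T).T


# ---------------------------------------------------------------------------
# ALS core
# ---------------------------------------------------------------------------

def _init_factors(X, F, how, rng):
    I, J, K = X.shape
    if how == "random_nonneg":
        scale = max(np.abs(X).max(), 1.0) ** (1.0 / 3.0)
        return [rng.uniform(0.1, 1.0, size=(d, F)) * scale for d in (I, J, K)]
    # svd_based: leading singular vectors of each unfolding, made non-negative
    mats = []
    for mode, d in zip(range(3), (I, J, K)):
        unf = np.moveaxis(X, mode, 0).reshape(d, -1)
        u, s, _ = np.linalg.svd(unf, full_matrices=False)
        r = min(F, u.shape[1])
        M = np.abs(u[:, :r] * np.sqrt(s[:r]))
        if r < F:
            M = np.hstack([M, rng.uniform(0.1, 1.0, size=(d, F - r))])
        mats.append(M + 1e-9)
    return mats


def _als_single(X, F, opts: FitOptions, rng) -> tuple[list, float, int, bool, np.ndarray]:
    A, B, C = _init_factors(X, F, opts.init, rng)
    norm_x2 = float(np.sum(X * X))
    solve = [
        _nnls_shared_gram if nn else _ls_shared_gram for nn in opts.nonneg
    ]
    trace = []
    prev = np.inf
    converged = False
    n_iter = 0
    for it in range(opts.max_iter):
        n_iter = it + 1
        G = (B.T @ B) * (C.T @ C)
        V = np.einsum("ijk,jf,kf->if", X, B, C, optimize=True)
        A = solve[0](G, V)
        G = (A.T @ A) * (C.T @ C)
        V = np.einsum("ijk,if,kf->jf", X, A, C, optimize=True)
        B = solve[1](G, V)
        G = (A.T @ A) * (B.T @ B)
        V = np.einsum("ijk,if,jf->kf", X, A, B, optimize=True)
        C = solve[2](G, V)
        # rss from the just-solved mode-C normal equations (exact, cheap)
        cur = norm_x2 - 2.0 * float(np.sum(C * V)) + float(np.sum(G * (C.T @ C)))
        cur = max(cur, 0.0)
        trace.append(cur)
        if prev < np.inf:
            denom = max(prev, 1e-300)
            if abs(prev - cur) / denom < opts.tol or cur == 0.0:
                converged = True
                break
        elif cur == 0.0:
            converged = True
            break
        prev = cur
    return [A, B, C], trace[-1], n_iter, converged, np.array(trace)


def fit_parafac(tensor: EEMTensor | np.ndarray, F: int,
                opts: FitOptions | None = None) -> ParafacModel:
    """Fit an F-component non-negative PARAFAC model by multi-start ALS.

    Runs ``opts.n_starts`` independent initializations (seeds derived from
    ``opts.seed``) and keeps the lowest-RSS solution.  Factors are ordered
    by descending total score; B and C columns are normalized to unit
    maximum.  Masked cells must have been interpolated upstream - no missing
    data enters the fit.
    """
    if opts is None:
        opts = FitOptions()
    if isinstance(tensor, EEMTensor):
        X = tensor.values
        em_grid, ex_grid = tensor.emission_grid, tensor.excitation_grid
    else:
        X = np.asarray(tensor, dtype=float)
        em_grid = np.arange(X.shape[1], dtype=float)
        ex_grid = np.arange(X.shape[2], dtype=float)
    if X.ndim != 3 or X.size == 0:
        raise ValueError("tensor must be a non-empty 3-way array")
    if np.any(~np.isfinite(X)):
        raise ValueError("tensor contains non-finite values; interpolate gaps first")
    if F < 1:
        raise ValueError("F must be >= 1")
    if F > min(X.shape):
        warnings.warn(
            f"F={F} exceeds min tensor dimension {min(X.shape)}; "
            "rank-deficient fit likely", stacklevel=2)
    seeds = np.random.SeedSequence(opts.seed).spawn(opts.n_starts)
    best = None
    for ss in seeds:
        rng = np.random.default_rng(ss)
        factors, final_rss, n_iter, conv, trace = _als_single(X, F, opts, rng)
        if best is None or final_rss < best[1]:
            best = (factors, final_rss, n_iter, conv, trace)
    (A, B, C), final_rss, n_iter, conv, trace = best

    # normalize B, C to unit-max columns; absorb magnitude into A
    for f in range(F):
        for M in (B, C):
            m = M[:, f].max()
            if m > 0:
                M[:, f] /= m
                A[:, f] *= m
    # order by descending total score; ties by ascending excitation peak
    keys = [(-A[:, f].sum(), float(ex_grid[int(np.argmax(C[:, f]))]), f)
            for f in range(F)]
    order = [f for *_, f in sorted(keys)]
    A, B, C = A[:, order], B[:, order], C[:, order]

    return ParafacModel(
        F=F, A=A, B=B, C=C,
        emission_grid=np.asarray(em_grid, dtype=float),
        excitation_grid=np.asarray(ex_grid, dtype=float),
        rss=float(final_rss), n_iter=n_iter, converged=bool(conv),
        seed=opts.seed, rss_trace=trace,
    )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def rss(model: ParafacModel, tensor: EEMTensor | np.ndarray) -> float:
    """Residual sum of squares between the tensor and its reconstruction."""
    X = tensor.values if isinstance(tensor, EEMTensor) else np.asarray(tensor)
    if X.shape != (model.A.shape[0], model.B.shape[0], model.C.shape[0]):
        raise AlignmentError("tensor shape does not match model dimensions")
    resid = X - model.reconstruct()
    return float(np.sum(resid * resid))


def core_consistency(model: ParafacModel, tensor: EEMTensor | np.ndarray) -> float:
    """CORCONDIA, in percent (unclipped; may be negative).

    Solves least squares for the F x F x F Tucker core G given the fitted
    loadings and compares it to the superidentity T (ones on the
    superdiagonal): ``100 * (1 - sum((G - T)^2) / sum(T^2))``.  Near 100
    indicates valid trilinear structure; it collapses when the model is
    over-factored.
    """
    X = tensor.values if isinstance(tensor, EEMTensor) else np.asarray(tensor)
    F = model.F
    for name, M in (("A", model.A), ("B", model.B), ("C", model.C)):
        if np.linalg.matrix_rank(M) < F:
            raise DegenerateModelError(
                f"loading matrix {name} is rank-deficient; core is undefined")
    # pinv(C (x) B (x) A) = pinv(C) (x) pinv(B) (x) pinv(A): the LS core is a
    # mode-wise product with the pseudo-inverses
    Ap, Bp, Cp = (np.linalg.pinv(M) for M in (model.A, model.B, model.C))
    core = np.einsum("fi,gj,hk,ijk->fgh", Ap, Bp, Cp, X, optimize=True)
    target = np.zeros((F, F, F))
    target[np.arange(F), np.arange(F), np.arange(F)] = 1.0
    return float(100.0 * (1.0 - np.sum((core - target) ** 2) / F))


def model_sweep(tensor: EEMTensor | np.ndarray,
                F_range=range(1, 8),
                opts: FitOptions | None = None) -> pd.DataFrame:
    """Fit the tensor at each factor count; tabulate diagnostics.

    Columns: F, core_consistency, rss, converged, n_iter.  RSS should be
    non-increasing in F for best-of-starts fits; violations signal local
    optima and are reported as warnings, not errors.
    """
    if opts is None:
        opts = FitOptions()
    rows = []
    models = []
    prev_rss = np.inf
    for F in F_range:
        model = fit_parafac(tensor, F, opts)
        try:
            cc = core_consistency(model, tensor)
        except DegenerateModelError:
            cc = np.nan
        if model.rss > prev_rss * (1 + 1e-9):
            warnings.warn(
                f"RSS increased from F={F - 1} to F={F}; likely local optimum",
                stacklevel=2)
        prev_rss = model.rss
        rows.append((F, cc, model.rss, model.converged, model.n_iter))
        models.append(model)
    table = pd.DataFrame(
        rows, columns=["F", "core_consistency", "rss", "converged", "n_iter"])
    table.attrs["models"] = models
    return table


def tucker_congruence(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine (Tucker congruence) between two profile vectors."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def match_factors(model_a: ParafacModel, model_b: ParafacModel):
    """Optimal factor pairing between two models on the same grids.

    Maximizes summed Tucker congruence of the concatenated (B, C) spectral
    profiles via linear assignment.  Returns ``(permutation, congruences)``
    where ``permutation[f]`` is the factor of ``model_b`` matched to factor
    ``f`` of ``model_a``.
    """
    if (not np.array_equal(model_a.emission_grid, model_b.emission_grid)
            or not np.array_equal(model_a.excitation_grid, model_b.excitation_grid)):
        raise AlignmentError("models are on different wavelength grids")
    Fa, Fb = model_a.F, model_b.F
    M = np.zeros((Fa, Fb))
    for f in range(Fa):
        pa = np.concatenate([model_a.B[:, f], model_a.C[:, f]])
        for g in range(Fb):
            pb = np.concatenate([model_b.B[:, g], model_b.C[:, g]])
            M[f, g] = tucker_congruence(pa, pb)
    row, col = linear_sum_assignment(-M)
    perm = np.full(Fa, -1, dtype=int)
    scores = np.zeros(Fa)
    for r, c in zip(row, col):
        perm[r] = c
        scores[r] = M[r, c]
    return perm, scores


def peak_location(model: ParafacModel, f: int) -> tuple[float, float]:
    """(excitation nm, emission nm) of factor ``f``'s loading maxima.

    ``f`` is 1-based; ties resolve to the lowest wavelength.
    """
    if not (1 <= f <= model.F):
        raise ValueError(f"factor index {f} outside 1..{model.F}")
    k = int(np.argmax(model.C[:, f - 1]))
    j = int(np.argmax(model.B[:, f - 1]))
    return float(model.excitation_grid[k]), float(model.emission_grid[j])
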