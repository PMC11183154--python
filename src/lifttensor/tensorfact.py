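"""Non-negative canonical polyadic (NCP) decomposition of multiway motor data.

A non-negative tensor ``X`` of shape ``M x T x J x P x K`` (space x time x
object x participant x trial) is approximated by a sum of ``R`` rank-one
outer products,

    X[m,t,j,p,k]  ~=  sum_r  A[m,r] B[t,r] C[j,r] D[p,r] E[k,r],

with every factor entry constrained to be non-negative, so each component
reads directly as a muscle/force grouping with a temporal activation profile
and per-object / per-participant / per-trial recruitment levels.  The solver
is block-coordinate HALS (hierarchical alternating least squares): each
factor column is updated in closed form under the non-negativity constraint,
which makes the squared-error objective monotonically non-increasing.

Model fit is summarised by the variance accounted for,

    VAF = 1 - MSE / var(vec(X)),

with MSE the per-entry squared reconstruction error and ``var`` the
population variance of the vectorised tensor.  The rank is chosen as the
smallest ``R`` whose mean VAF over several random restarts reaches a
threshold (0.6 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "FactorModel",
    "FitReport",
    "RankSweep",
    "DegenerateInputError",
    "RankSelectionError",
    "reconstruct",
    "ncp_decompose",
    "ncp_best_of",
    "fix_scale",
    "vaf",
    "select_rank",
    "match_factors",
]

_MODE_NAMES = ("spatial", "temporal", "object", "participant", "trial")


class DegenerateInputError(ValueError):
    """Raised for inputs that make the requested operation meaningless."""


class RankSelectionError(RuntimeError):
    """No candidate rank reached the VAF threshold; carries the sweep."""

    def __init__(self, message: str, sweep: "RankSweep"):
        super().__init__(message)
        self.sweep = sweep


@dataclass
class FactorModel:
    """A CP model as a tuple of non-negative factor matrices, one per mode.

    For the 5-way motor tensor the factors are, in order, the spatial (A),
    temporal (B), object (C), participant (D) and trial (E) matrices, each
    with ``R`` columns.  The class itself is agnostic to the number of modes.
    """

    factors: tuple[np.ndarray, ...]

    def __post_init__(self):
        self.factors = tuple(np.asarray(f, dtype=float) for f in self.factors)
        ranks = {f.shape[1] for f in self.factors}
        if len(ranks) != 1:
            raise ValueError(f"factor matrices disagree on rank: {sorted(ranks)}")
        for i, f in enumerate(self.factors):
            if f.ndim != 2:
                raise ValueError(f"factor {i} is not a matrix")
            if np.any(f < 0):
                raise ValueError(f"factor {i} has negative entries")

    @property
    def rank(self) -> int:
        return self.factors[0].shape[1]

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(f.shape[0] for f in self.factors)

    @property
    def n_modes(self) -> int:
        return len(self.factors)

    # Named accessors for the canonical 5-way layout.
    @property
    def A(self) -> np.ndarray:  # noqa: N802 - conventional factor names
        return self.factors[0]

    @property
    def B(self) -> np.ndarray:  # noqa: N802
        return self.factors[1]

    @property
    def C(self) -> np.ndarray:  # noqa: N802
        return self.factors[2]

    @property
    def D(self) -> np.ndarray:  # noqa: N802
        return self.factors[3]

    @property
    def E(self) -> np.ndarray:  # noqa: N802
        return self.factors[4]

    def copy(self) -> "FactorModel":
        return FactorModel(tuple(f.copy() for f in self.factors))


@dataclass
class FitReport:
    """Diagnostics of one NCP fit."""

    objective: float
    mse: float
    vaf: float
    n_iter: int
    seed: int
    converged: bool
    objective_history: list[float] = field(default_factory=list, repr=False)


@dataclass
class RankSweep:
    """Mean VAF per candidate rank and the selected rank."""

    candidate_ranks: np.ndarray
    mean_vaf: np.ndarray
    sd_vaf: np.ndarray
    selected_rank: int
    threshold: float


# ---------------------------------------------------------------------------
# Reconstruction and fit metrics
# ---------------------------------------------------------------------------

def reconstruct(model: FactorModel) -> np.ndarray:
    """Evaluate the CP model as a dense array (sum of rank-one outer products)."""
    n = model.n_modes
    letters = "mtjpkabcdefgh"[:n]
    operands = []
    subscript_parts = []
    for letter, f in zip(letters, model.factors):
        operands.append(f)
        subscript_parts.append(f"{letter}r")
    expr = ",".join(subscript_parts) + "->" + letters
    return np.einsum(expr, *operands, optimize=True)


def vaf(X: np.ndarray, model_or_xhat) -> float:
    """Variance accounted for: ``1 - MSE / var(vec(X))`` (population variance)."""
    X = np.asarray(X, dtype=float)
    xhat = (
        reconstruct(model_or_xhat)
        if isinstance(model_or_xhat, FactorModel)
        else np.asarray(model_or_xhat, dtype=float)
    )
    if xhat.shape != X.shape:
        raise ValueError(f"shape mismatch: {xhat.shape} vs {X.shape}")
    var = float(np.var(X))
    if var == 0.0:
        raise DegenerateInputError("tensor is constant; VAF is undefined")
    mse = float(np.mean((xhat - X) ** 2))
    return 1.0 - mse / var


def fix_scale(model: FactorModel) -> FactorModel:
    """Resolve the CP scaling ambiguity.

    The spatial, temporal, participant and trial factors are rescaled to unit
    Frobenius norm and the object factor absorbs the product of the removed
    norms, so the reconstruction is unchanged.  With the 5-way layout this is
    ||A||_F = ||B||_F = ||D||_F = ||E||_F = 1, C <- ||A|| ||B|| ||D|| ||E|| C.
    """
    if model.n_modes != 5:
        raise ValueError("fix_scale expects the 5-way spatial/temporal/object/"
                         "participant/trial layout")
    norms = [float(np.linalg.norm(f)) for f in model.factors]
    for i, nrm in enumerate(norms):
        if nrm == 0.0:
            raise DegenerateInputError(
                f"{_MODE_NAMES[i]} factor matrix is all-zero; scale is undefined")
    A, B, C, D, E = model.factors
    scale = norms[0] * norms[1] * norms[3] * norms[4]
    return FactorModel((
        A / norms[0], B / norms[1], C * scale, D / norms[3], E / norms[4],
    ))


# ---------------------------------------------------------------------------
# HALS solver
# ---------------------------------------------------------------------------

def _mttkrp(Xperm: np.ndarray, factors, mode: int) -> np.ndarray:
    """Matricized-tensor times Khatri-Rao product for one mode.

    ``Xperm`` is the tensor with axis ``mode`` moved to the front (and made
    contiguous once, outside the iteration loop).  The remaining axes are
    contracted one factor at a time, which keeps everything in BLAS-friendly
    matrix products.
    """
    n = len(factors)
    order = [i for i in range(n) if i != mode]
    Z = Xperm @ factors[order[-1]]  # contracts the trailing axis -> (..., R)
    for ax in reversed(order[:-1]):
        Z = np.einsum("...ir,ir->...r", Z, factors[ax], optimize=True)
    return Z


def ncp_decompose(
    X: np.ndarray,
    R: int,
    init_seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[FactorModel, FitReport]:
    """Fit a rank-``R`` non-negative CP model by HALS.

    Parameters
    ----------
    X : non-negative array (any number of modes >= 2).
    R : number of rank-one components.
    init_seed : seed of the |N(0,1)| factor initialization.
    tol : relative objective-change stopping criterion.
    max_iter : cap on full HALS sweeps.

    Returns the factor model (not yet scale-fixed) and a fit report whose
    ``objective`` is the squared reconstruction error summed over entries.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("tensor contains non-finite entries")
    if np.any(X < 0):
        raise ValueError("tensor has negative entries; NCP requires X >= 0")
    if R < 1:
        raise ValueError(f"rank must be >= 1, got {R}")
    norm_x2 = float(np.sum(X**2))
    if norm_x2 == 0.0:
        raise DegenerateInputError("all-zero tensor cannot be decomposed")

    n = X.ndim
    rng = np.random.default_rng(init_seed)
    factors = [np.abs(rng.standard_normal((d, R))) for d in X.shape]
    grams = [f.T @ f for f in factors]

    # One contiguous permuted copy of X per mode, reused every sweep.
    perms = [
        np.ascontiguousarray(np.moveaxis(X, mode, 0)) for mode in range(n)
    ]

    eps = 1e-30
    floor = 1e-12  # keep columns alive: exact zeros can never re-grow
    history: list[float] = []
    prev_obj = np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for mode in range(n):
            M = _mttkrp(perms[mode], factors, mode)
            G = np.ones((R, R))
            for i, gr in enumerate(grams):
                if i != mode:
                    G *= gr
            F = factors[mode]
            for r in range(R):
                g_rr = G[r, r]
                if g_rr <= eps:
                    F[:, r] = floor
                    continue
                col = F[:, r] + (M[:, r] - F @ G[:, r]) / g_rr
                np.maximum(col, floor, out=col)
                F[:, r] = col
            grams[mode] = F.T @ F
        # objective from the last mode's cached quantities:
        # ||X - Xhat||^2 = ||X||^2 - 2<X,Xhat> + ||Xhat||^2
        inner = float(np.sum(factors[n - 1] * M))
        G_all = G * grams[n - 1]
        obj = norm_x2 - 2.0 * inner + float(np.sum(G_all))
        obj = max(obj, 0.0)
        history.append(obj)
        if prev_obj - obj <= tol * max(prev_obj, eps) and n_iter > 1:
            converged = True
            break
        prev_obj = obj

    model = FactorModel(tuple(factors))
    mse = history[-1] / X.size
    var = float(np.var(X))
    fit_vaf = 1.0 - mse / var if var > 0 else np.nan
    report = FitReport(
        objective=history[-1],
        mse=mse,
        vaf=fit_vaf,
        n_iter=n_iter,
        seed=init_seed,
        converged=converged,
        objective_history=history,
    )
    return model, report


def ncp_best_of(
    X: np.ndarray,
    R: int,
    n_restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[FactorModel, FitReport]:
    """Best (lowest final objective) of ``n_restarts`` seeded HALS runs."""
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    seeds = _spawn_seeds(seed, n_restarts)
    best: tuple[FactorModel, FitReport] | None = None
    for s in seeds:
        model, report = ncp_decompose(X, R, init_seed=s, tol=tol, max_iter=max_iter)
        if best is None or report.objective < best[1].objective:
            best = (model, report)
    assert best is not None
    return best


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent integer seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def select_rank(
    X: np.ndarray,
    R_max: int = 10,
    n_realizations: int = 10,
    threshold: float = 0.6,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> RankSweep:
    """VAF-based rank selection.

    For every candidate rank 1..``R_max`` the mean VAF over
    ``n_realizations`` randomly initialized fits is recorded; the selected
    rank is the smallest one whose mean VAF reaches ``threshold``
    (ties at the threshold accepted).  Raises :class:`RankSelectionError`
    (carrying the full curve) if no rank qualifies.
    """
    ranks = np.arange(1, R_max + 1)
    mean_vaf = np.empty(R_max)
    sd_vaf = np.empty(R_max)
    master = np.random.SeedSequence(seed)
    for i, R in enumerate(ranks):
        child = np.random.SeedSequence(entropy=master.entropy, spawn_key=(int(R),))
        seeds = child.generate_state(n_realizations) % (2**31)
        vals = []
        for s in seeds:
            _, report = ncp_decompose(
                X, int(R), init_seed=int(s), tol=tol, max_iter=max_iter
            )
            vals.append(report.vaf)
        mean_vaf[i] = float(np.mean(vals))
        sd_vaf[i] = float(np.std(vals))
    qualifying = ranks[mean_vaf >= threshold]
    if qualifying.size == 0:
        sweep = RankSweep(ranks, mean_vaf, sd_vaf, selected_rank=-1,
                          threshold=threshold)
        raise RankSelectionError(
            f"no rank in 1..{R_max} reached mean VAF {threshold}", sweep)
    return RankSweep(ranks, mean_vaf, sd_vaf,
                     selected_rank=int(qualifying[0]), threshold=threshold)


# ---------------------------------------------------------------------------
# Factor matching (CP is identifiable only up to permutation and scale)
# ---------------------------------------------------------------------------

def match_factors(
    estimated: FactorModel, planted: FactorModel
) -> tuple[np.ndarray, np.ndarray]:
    """Match estimated components to planted ones by cosine congruence.

    Components are assigned with the Hungarian algorithm so that the summed
    product-over-modes cosine similarity is maximal.  Returns
    ``(perm, congruences)`` where ``perm[r]`` is the planted column matched
    to estimated column ``r`` and ``congruences[mode, r]`` is the cosine
    similarity of estimated column ``r`` with its match in that mode
    (scale-invariant, in [0, 1] for non-negative factors).
    """
    if estimated.rank != planted.rank:
        raise ValueError(
            f"rank mismatch: {estimated.rank} vs {planted.rank}")
    if estimated.shape != planted.shape:
        raise ValueError(
            f"dimension mismatch: {estimated.shape} vs {planted.shape}")
    R = estimated.rank
    sim = np.ones((R, R))
    per_mode = []
    for Fe, Fp in zip(estimated.factors, planted.factors):
        ne = np.linalg.norm(Fe, axis=0)
        np_ = np.linalg.norm(Fp, axis=0)
        ne[ne == 0] = 1.0
        np_[np_ == 0] = 1.0
        cos = (Fe / ne).T @ (Fp / np_)
        per_mode.append(cos)
        sim *= cos
    row, col = linear_sum_assignment(-sim)
    perm = np.empty(R, dtype=int)
    perm[row] = col
    congruences = np.array([
        [per_mode[m][r, perm[r]] for r in range(R)]
        for m in range(len(per_mode))
    ])
    return perm, congruences
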