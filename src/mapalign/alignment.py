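"""Map alignment: comparing the macro-scale geometry of two diffusion maps.

Given diffusion bases built from two different metrics on the same agents,
the *map alignment statistic* (MAS) ``Z_k`` measures how much of the first
metric's macro-scale organization is captured by the second's leading
diffusion coordinates:

    Z_k(f1, f2) = sum_{j<=k} u-hat_j * P_k^{(2)}(phi_j^{(1)})

where ``P_k`` standardizes the squared norm of the projection of
``phi_j^{(1)}`` onto ``span(phi_1^{(2)}, ..., phi_k^{(2)})`` against an
analytic null: if the two geometries are unrelated, that squared norm is
distributed as the squared projection of a uniform random unit vector in
R^n onto a fixed k-dimensional coordinate subspace — a Beta random variable
with mean ``k/n`` and variance ``2(n-k)k / (n^3 + 2n^2)``.  Each summand is
then centered with unit variance under the null, and the eigenvalue weights
``u-hat`` (unit 2-norm) emphasize the modes that carry the most diffusion
energy.  The statistic is not symmetric in its arguments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .diffusion import DiffusionBasis

__all__ = [
    "NullModel",
    "AlignmentResult",
    "SubspaceSuggestion",
    "project_norm",
    "standardized_projection",
    "null_model",
    "map_alignment_statistic",
    "suggest_k",
]

#: below this total eigenvalue energy the weight vector u-hat is undefined
_UNWEIGHTABLE_NORM = 1e-12


def _check_nk(n: int, k: int) -> None:
    if not 0 < k < n:
        raise ValueError(f"need 0 < k < n, got k = {k}, n = {n}")


@dataclass(frozen=True)
class NullModel:
    """Null distribution of a squared projection norm for unrelated geometries.

    The squared norm of a uniform random unit vector in R^n projected onto a
    fixed k-dimensional subspace is Beta distributed with mean ``k/n`` and
    variance ``2(n-k)k/(n^3+2n^2)``.  These moments pin the shape pair down
    to ``(k/2, (n-k)/2)``; the reversed order sometimes quoted for this law
    would give mean ``(n-k)/n`` and is inconsistent with the stated moments
    (see ``note``).
    """

    n: int
    k: int
    mean: float = field(init=False)
    variance: float = field(init=False)
    shape: tuple[float, float] = field(init=False)
    note: str = field(init=False, repr=False)

    def __post_init__(self):
        _check_nk(self.n, self.k)
        n, k = self.n, self.k
        object.__setattr__(self, "mean", k / n)
        object.__setattr__(self, "variance", 2.0 * (n - k) * k / (n**3 + 2 * n**2))
        object.__setattr__(self, "shape", (k / 2.0, (n - k) / 2.0))
        object.__setattr__(
            self,
            "note",
            "shape order (k/2, (n-k)/2) chosen for consistency with the "
            "mean k/n and variance 2(n-k)k/(n^3+2n^2); the reversed order "
            "((n-k)/2, k/2) would imply mean (n-k)/n",
        )

    @property
    def frozen(self):
        """The scipy frozen Beta distribution for density/cdf diagnostics."""
        a, b = self.shape
        return stats.beta(a, b)

    def pdf(self, x) -> np.ndarray:
        return self.frozen.pdf(x)

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        a, b = self.shape
        return rng.beta(a, b, size=size)


@dataclass(frozen=True)
class AlignmentResult:
    """All intermediates of one MAS evaluation.

    ``sq_projections[j]`` is the squared norm of the projection of mode
    ``j+1`` of the first basis onto the leading-k subspace of the second;
    ``standardized`` are the corresponding ``P_k`` values; ``weights`` is the
    unit-norm eigenvalue weight vector u-hat (zeros when ``unweightable``).
    """

    n: int
    k: int
    sq_projections: np.ndarray
    standardized: np.ndarray
    weights: np.ndarray
    z: float
    unweightable: bool = False

    def __post_init__(self):
        if not self.unweightable:
            if abs(np.linalg.norm(self.weights) - 1.0) > 1e-10:
                raise ValueError("weights must have unit 2-norm")
        if np.min(self.sq_projections) < -1e-10 or np.max(self.sq_projections) > 1 + 1e-10:
            raise ValueError("squared projections must lie in [0, 1]")
        if not math.isfinite(self.z):
            raise ValueError("Z_k must be finite")


def project_norm(phi: np.ndarray, B2: DiffusionBasis, k: int) -> float:
    """Norm of the projection of a unit vector onto B2's leading-k mode span.

    With orthonormal columns this is ``sqrt(sum_j <phi, phi_j^{(2)}>^2)``
    over ``j = 1 .. k``.
    """
    phi = np.asarray(phi, dtype=float)
    nrm = np.linalg.norm(phi)
    if abs(nrm - 1.0) > 1e-8:
        raise ValueError(f"phi must be a unit vector (|phi| = {nrm:.3e})")
    if not 1 <= k <= B2.size:
        raise ValueError(f"k must satisfy 1 <= k <= {B2.size}, got {k}")
    if phi.shape[0] != B2.n:
        raise ValueError("phi dimension does not match the basis")
    c = B2.eigenvectors[:, :k].T @ phi
    return float(np.sqrt(np.sum(c**2)))


def standardized_projection(sq_norm: float, n: int, k: int) -> float:
    """Center and scale a squared projection norm by its null moments.

    ``P = (sq_norm - k/n) * sqrt((n^3 + 2n^2) / (2 (n-k) k))`` — zero mean
    and unit variance when the two geometries are unrelated.
    """
    _check_nk(n, k)
    if not -1e-10 <= sq_norm <= 1 + 1e-10:
        raise ValueError(f"squared norm must lie in [0, 1], got {sq_norm}")
    return float((sq_norm - k / n) * math.sqrt((n**3 + 2 * n**2) / (2.0 * (n - k) * k)))


def null_model(n: int, k: int) -> NullModel:
    """Analytic null for squared projections of unrelated diffusion modes."""
    return NullModel(n=n, k=k)


def map_alignment_statistic(B1: DiffusionBasis, B2: DiffusionBasis, k: int) -> AlignmentResult:
    """Map alignment statistic ``Z_k(f1, f2)`` between two diffusion bases.

    Projects each of the first ``k`` modes of ``B1`` onto the span of the
    first ``k`` modes of ``B2``, standardizes the squared norms against the
    analytic null, and sums them weighted by ``B1``'s normalized eigenvalue
    vector.  Large positive values indicate that the two metrics organize
    the agents along related macro-scale lines; the statistic is not
    symmetric, so ``Z_k(f2, f1)`` is computed by swapping arguments.

    Degenerate case: if all of ``B1``'s leading eigenvalues are ~0 the
    weight vector is undefined; ``Z_k = 0`` is returned with
    ``unweightable=True``.
    """
    if B1.n != B2.n:
        raise ValueError(f"bases have different agent counts: {B1.n} vs {B2.n}")
    if B1.agent_ids != B2.agent_ids:
        diff = set(B1.agent_ids) ^ set(B2.agent_ids)
        raise ValueError(
            "bases are not over the same ordered agent set; "
            f"symmetric difference: {sorted(diff) if diff else 'same set, different order'}"
        )
    n = B1.n
    if not 1 <= k <= min(B1.size, B2.size):
        raise ValueError(f"k must satisfy 1 <= k <= {min(B1.size, B2.size)}, got {k}")
    _check_nk(n, k)

    C = B2.eigenvectors[:, :k].T @ B1.eigenvectors[:, :k]  # (k modes of B2) x (k modes of B1)
    sq = np.clip(np.sum(C**2, axis=0), 0.0, 1.0)
    scale = math.sqrt((n**3 + 2 * n**2) / (2.0 * (n - k) * k))
    P = (sq - k / n) * scale

    lam = B1.eigenvalues[:k]
    nrm = float(np.linalg.norm(lam))
    if nrm < _UNWEIGHTABLE_NORM:
        return AlignmentResult(
            n=n, k=k, sq_projections=sq, standardized=P,
            weights=np.zeros(k), z=0.0, unweightable=True,
        )
    u_hat = lam / nrm
    z = float(u_hat @ P)
    return AlignmentResult(
        n=n, k=k, sq_projections=sq, standardized=P, weights=u_hat, z=z,
    )


@dataclass(frozen=True)
class SubspaceSuggestion:
    """Outcome of the spectral-tail heuristic for choosing the subspace size k.

    ``k`` is the smallest cut after which the eigenvalue tail is consistent
    with a power law ``C j^(-beta)``; ``tail_errors[c]`` maps each candidate
    cut to the maximum relative deviation of its tail from the fitted law.
    When several spectra (frames) are supplied, ``stable_fraction_modes``
    flags modes whose variance-explained fraction is stable across frames —
    tail-like behavior.
    """

    k: int
    converged: bool
    coefficient: float
    exponent: float
    tail_errors: dict[int, float]
    stable_fraction_modes: np.ndarray | None = None


def _power_law_tail_error(lam: np.ndarray, cut: int) -> tuple[float, float, float]:
    """Fit ``lam_j ~ C j^(-beta)`` for j > cut; return (max rel. error, C, beta)."""
    j = np.arange(cut + 1, lam.shape[0] + 1, dtype=float)
    tail = lam[cut:]
    keep = tail > 0
    if keep.sum() < 2:
        return np.inf, np.nan, np.nan
    lj, ll = np.log(j[keep]), np.log(tail[keep])
    beta_neg, logc = np.polyfit(lj, ll, 1)
    fit = np.exp(logc + beta_neg * lj)
    err = float(np.max(np.abs(tail[keep] - fit) / tail[keep]))
    return err, float(np.exp(logc)), float(-beta_neg)


def suggest_k(
    spectra,
    *,
    rel_tol: float = 0.2,
    min_tail: int = 5,
    stability_cv: float = 0.1,
) -> SubspaceSuggestion:
    """Suggest the subspace size k from the decay of diffusion spectra.

    The head of a diffusion spectrum tracks macro-scale organization while
    the bulk decays like a power law ``C j^(-beta)`` (noise and small-scale
    structure).  For each candidate cut the tail is fit by least squares on
    log-log axes; the smallest cut whose tail deviates from its fit by less
    than ``rel_tol`` relative error everywhere is returned.  If no cut
    qualifies, the cut with the smallest maximum deviation is returned with
    ``converged=False``.

    Non-positive tail entries are excluded from fits; a spectrum whose tail
    is entirely non-positive raises.  With several spectra the mean spectrum
    drives the cut and a cross-frame stability diagnostic is attached: modes
    whose variance-explained fraction ``lambda_j / sum(lambda)`` has a
    coefficient of variation below ``stability_cv`` across frames behave
    like tail modes.
    """
    arrs = [np.asarray(s, dtype=float) for s in spectra]
    if not arrs:
        raise ValueError("need at least one spectrum")
    if any(a.shape[0] < 10 for a in arrs):
        raise ValueError("each spectrum must have at least 10 eigenvalues")
    m = min(a.shape[0] for a in arrs)
    stacked = np.stack([a[:m] for a in arrs])
    lam = stacked.mean(axis=0)
    if not np.any(lam > 0):
        raise ValueError("all eigenvalues non-positive; cannot fit a power-law tail")

    errors: dict[int, float] = {}
    best_c, best_err = 1, np.inf
    coeff = expo = np.nan
    chosen = None
    for c in range(1, m - min_tail + 1):
        err, C, beta = _power_law_tail_error(lam, c)
        errors[c] = err
        if err < best_err:
            best_c, best_err = c, err
        if chosen is None and err < rel_tol:
            chosen = c
            coeff, expo = C, beta
    if not errors:
        raise ValueError("spectrum too short for any candidate cut")
    converged = chosen is not None
    if not converged:
        chosen = best_c
        _, coeff, expo = _power_law_tail_error(lam, chosen)

    stability = None
    if len(arrs) > 1:
        fracs = stacked / np.clip(np.abs(stacked).sum(axis=1, keepdims=True), 1e-300, None)
        mean_f = fracs.mean(axis=0)
        sd_f = fracs.std(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(np.abs(mean_f) > 0, sd_f / np.abs(mean_f), np.inf)
        stability = cv < stability_cv

    return SubspaceSuggestion(
        k=int(chosen),
        converged=converged,
        coefficient=float(coeff),
        exponent=float(expo),
        tail_errors=errors,
        stable_fraction_modes=stability,
    )
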