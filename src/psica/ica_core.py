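"""Maximum-likelihood ICA with P-spline source densities.

The observed (reduced, demeaned) data ``X`` (Q x V) is modelled as ``X = A S``
with independent unit-variance source rows ``S``.  Writing ``B = A^{-1}``,
the joint log-likelihood over samples is

    L(B, f) = sum_v sum_q log f_q(B(q,.) X(.,v)) + V log|det B|,

where each source density ``f_q`` is estimated nonparametrically by P-spline
histogram smoothing (:mod:`psica.pspline_density`).  Optimization alternates
density refreshes with safeguarded Newton-Raphson updates of ``B``; the
closed-form gradient and Hessian use the analytic score ``(log f_q)'`` and
its derivative.  Convergence is declared on the Amari metric between
successive unmixing matrices, which is invariant to the permutation and
scaling indeterminacies of ICA.

When a parcellation is supplied, each sample is scored under the density of
its own region (``f_{iq}`` fitted to the component's values inside region
``i``), relaxing the identically-distributed assumption across regions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import pspline_density as psd
from .parcellation import ParcellationMap, fit_region_densities, merge_small_regions

logger = logging.getLogger(__name__)

__all__ = [
    "ICAConfig",
    "UnmixingState",
    "MixedData",
    "SingularMatrixError",
    "StepFailureError",
    "DegenerateComponentError",
    "log_likelihood",
    "likelihood_gradient",
    "likelihood_hessian",
    "newton_step",
    "standardize_sources",
    "amari_index",
    "amari_distance",
    "run_ica",
]


class SingularMatrixError(np.linalg.LinAlgError):
    """An unmixing matrix (or Amari argument) is numerically singular."""


class StepFailureError(RuntimeError):
    """No admissible Newton or fallback gradient step could be found."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateComponentError(ValueError):
    """A source row has (numerically) zero variance."""


@dataclass
class ICAConfig:
    """Settings for :func:`run_ica`.

    tol
        Amari-metric convergence threshold between successive unmixing
        matrices (the step metric, not a distance to any truth).
    max_iter
        Outer-iteration cap; hitting it sets ``converged=False`` on the
        returned state instead of raising.
    n_bins / n_knots / degree / epsilon_factor
        Histogram and B-spline settings forwarded to the density fits.
        ``n_bins=None`` uses the sample-size rule in
        :func:`psica.pspline_density.default_bins` (per region).
    delta_grid
        Candidate smoothing penalties; AIC-selected once per component and
        region at the first iteration, then held fixed.
    diff_order
        Order of the coefficient difference penalty.
    min_region_size
        Regions smaller than this are merged into the nearest-id region
        before any density fitting.
    """

    tol: float = 1e-6
    max_iter: int = 200
    n_bins: int | None = None
    n_knots: int = 25
    degree: int = 3
    delta_grid: tuple = tuple(np.logspace(-3.0, 3.0, 7))
    diff_order: int = 3
    epsilon_factor: float = 0.1
    min_region_size: int = 50
    hessian_ridge: float = 1e-8
    max_halvings: int = 20
    seed: int | None = None

    def __post_init__(self):
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class MixedData:
    """Demeaned mixed-signal matrix (rows = reduced dimensions, cols = samples)."""

    values: np.ndarray
    demeaned: bool = True

    @classmethod
    def from_array(cls, X) -> "MixedData":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (components x samples)")
        Xc = X - X.mean(axis=1, keepdims=True)
        return cls(values=Xc, demeaned=True)

    @property
    def n_components(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class UnmixingState:
    """Result of an ICA run: unmixing matrix, sources, densities, traces."""

    B: np.ndarray
    S: np.ndarray
    densities: list  # per component: list of SplineDensityModel, one per region
    parcellation: ParcellationMap
    iteration: int
    amari_trace: np.ndarray
    loglik_trace: np.ndarray
    converged: bool
    config: ICAConfig

    @property
    def mixing(self) -> np.ndarray:
        return np.linalg.inv(self.B)


# ---------------------------------------------------------------------------
# likelihood and derivatives
# ---------------------------------------------------------------------------

def _as_region_models(dens_q):
    """Normalize a per-component density spec to a list of per-region models."""
    if hasattr(dens_q, "log_density"):
        return [dens_q]
    return list(dens_q)


def _per_sample(models, s_row, labels, attr):
    """Evaluate ``attr`` of each sample's own region density."""
    if len(models) == 1:
        return getattr(models[0], attr)(s_row)
    out = np.empty_like(s_row)
    for i, m in enumerate(models):
        sel = labels == i
        if np.any(sel):
            out[sel] = getattr(m, attr)(s_row[sel])
    return out


def _check_labels(densities, labels, V):
    n_regions = max(len(_as_region_models(d)) for d in densities)
    if n_regions > 1:
        if labels is None:
            raise ValueError("region labels required for region-specific densities")
        labels = np.asarray(labels)
        if labels.size != V:
            raise ValueError("labels length does not match number of samples")
    return labels


def _logabsdet(B) -> float:
    sign, logdet = np.linalg.slogdet(B)
    if sign == 0 or not np.isfinite(logdet):
        raise SingularMatrixError("unmixing matrix is singular")
    return float(logdet)


def log_likelihood(B, X, densities, labels=None) -> float:
    """Joint ICA log-likelihood sum_{v,q} log f_q(S(q,v)) + V log|det B|."""
    B = np.asarray(B, dtype=float)
    X = np.asarray(X, dtype=float)
    Q, V = X.shape
    logdet = _logabsdet(B)
    labels = _check_labels(densities, labels, V)
    S = B @ X
    total = V * logdet
    for q in range(Q):
        models = _as_region_models(densities[q])
        total += float(np.sum(_per_sample(models, S[q], labels, "log_density")))
    return total


def _score_matrix(S, densities, labels, attr):
    Q, V = S.shape
    out = np.empty_like(S)
    for q in range(Q):
        models = _as_region_models(densities[q])
        out[q] = _per_sample(models, S[q], labels, attr)
    return out


def likelihood_gradient(B, X, densities, labels=None) -> np.ndarray:
    """dL/dB(q,j) = sum_v score_q(S(q,v)) X(j,v) + V (B^{-T})(q,j)."""
    B = np.asarray(B, dtype=float)
    X = np.asarray(X, dtype=float)
    Q, V = X.shape
    labels = _check_labels(densities, labels, V)
    try:
        Binv = np.linalg.inv(B)
    except np.linalg.LinAlgError as exc:
        raise SingularMatrixError(str(exc)) from exc
    S = B @ X
    psi = _score_matrix(S, densities, labels, "score")
    return psi @ X.T + V * Binv.T


def likelihood_hessian(B, X, densities, labels=None) -> np.ndarray:
    """Q^2 x Q^2 Hessian of L in row-major vec ordering of B.

    Block (q, q') has entries
    ``delta_{qq'} sum_v score'_q(S(q,v)) X(j,v) X(j',v) - V B^{-1}(j,q') B^{-1}(j',q)``.
    """
    B = np.asarray(B, dtype=float)
    X = np.asarray(X, dtype=float)
    Q, V = X.shape
    labels = _check_labels(densities, labels, V)
    try:
        Binv = np.linalg.inv(B)
    except np.linalg.LinAlgError as exc:
        raise SingularMatrixError(str(exc)) from exc
    S = B @ X
    psi_p = _score_matrix(S, densities, labels, "score_prime")
    H = np.zeros((Q * Q, Q * Q))
    for q in range(Q):
        block = (X * psi_p[q]) @ X.T
        H[q * Q:(q + 1) * Q, q * Q:(q + 1) * Q] += block
    # det-term curvature: element [(q,j),(q',k)] = -V * Binv[j,q'] * Binv[k,q]
    det_part = -V * np.einsum("jb,ka->ajbk", Binv, Binv)
    H += det_part.reshape(Q * Q, Q * Q)
    return H


# ---------------------------------------------------------------------------
# Newton update with safeguards
# ---------------------------------------------------------------------------

def newton_step(B, gradient, hessian, loglik_fn, ll_current=None,
                max_halvings: int = 20, ridge: float = 1e-8):
    """One safeguarded Newton-Raphson update ``B - H^{-1} g``.

    The candidate step is halved (up to ``max_halvings`` times) whenever the
    log-likelihood would decrease or det(B) would change sign; if no Newton
    fraction is admissible a backtracking gradient-ascent step is tried.
    Returns ``(B_new, ll_new)`` with ``ll_new >= ll_current`` (within 1e-10)
    and det(B_new) of the same sign as det(B).
    """
    B = np.asarray(B, dtype=float)
    Q = B.shape[0]
    g = np.asarray(gradient, dtype=float).reshape(Q * Q)
    H = np.asarray(hessian, dtype=float)
    if ll_current is None:
        ll_current = float(loglik_fn(B))
    sign0 = np.sign(np.linalg.det(B))

    scale = abs(np.trace(H)) / (Q * Q) + 1e-12
    Hr = H - ridge * scale * np.eye(Q * Q)  # shift curvature away from singularity
    try:
        step = np.linalg.solve(Hr, g).reshape(Q, Q)
    except np.linalg.LinAlgError:
        step = None

    def admissible(cand):
        d = np.linalg.det(cand)
        if not np.isfinite(d) or np.sign(d) != sign0 or d == 0:
            return None
        ll = loglik_fn(cand)
        if np.isfinite(ll) and ll >= ll_current - 1e-10:
            return ll
        return None

    if step is not None and np.all(np.isfinite(step)):
        t = 1.0
        for _ in range(max_halvings + 1):
            cand = B - t * step
            ll = admissible(cand)
            if ll is not None:
                return cand, ll
            t *= 0.5

    # fallback: scaled gradient ascent with backtracking
    gnorm = np.linalg.norm(g)
    if gnorm < 1e-12:
        return B.copy(), ll_current
    direction = g.reshape(Q, Q) / gnorm
    t = 1.0
    for _ in range(40):
        cand = B + t * direction
        ll = admissible(cand)
        if ll is not None:
            return cand, ll
        t *= 0.5
    raise StepFailureError(
        "no admissible Newton or gradient step",
        diagnostics={"grad_norm": gnorm, "ll": ll_current, "det_sign": sign0},
    )


def standardize_sources(B, X):
    """Rescale rows of ``B`` so that each row of ``S = B X`` has unit variance.

    Returns ``(B, S, factors)`` where ``factors`` are the per-row standard
    deviations divided out; the model fit is invariant up to the known scale
    indeterminacy.
    """
    B = np.asarray(B, dtype=float)
    X = np.asarray(X, dtype=float)
    S = B @ X
    sd = S.std(axis=1)
    if np.any(sd < 1e-12) or not np.all(np.isfinite(sd)):
        bad = np.where(~(sd >= 1e-12))[0]
        raise DegenerateComponentError(f"source rows {bad.tolist()} have ~zero variance")
    return B / sd[:, None], S / sd[:, None], sd


# ---------------------------------------------------------------------------
# Amari metric
# ---------------------------------------------------------------------------

def amari_index(P) -> float:
    """Amari index of a square matrix; 0 iff P is a scaled permutation."""
    P = np.abs(np.asarray(P, dtype=float))
    Q = P.shape[0]
    if not np.all(np.isfinite(P)):
        raise SingularMatrixError("non-finite entries in Amari argument")
    row = (P.sum(axis=1) / P.max(axis=1) - 1.0).sum()
    col = (P.sum(axis=0) / P.max(axis=0) - 1.0).sum()
    return float((row + col) / (2.0 * Q))


def amari_distance(B1, B2) -> float:
    """Amari metric d(B1, B2) via P = B1 B2^{-1}; permutation/scale blind."""
    B1 = np.asarray(B1, dtype=float)
    B2 = np.asarray(B2, dtype=float)
    try:
        P = B1 @ np.linalg.inv(B2)
    except np.linalg.LinAlgError as exc:
        raise SingularMatrixError(str(exc)) from exc
    return amari_index(P)


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

def _fit_densities(S, pmap, config, deltas):
    """Fit per-component, per-region density models; selects deltas once."""
    densities = []
    for q in range(S.shape[0]):
        if deltas[q] is None:
            deltas[q] = [None] * pmap.n_regions
        models = fit_region_densities(
            S[q], pmap,
            n_bins=config.n_bins,
            n_knots=config.n_knots,
            degree=config.degree,
            diff_order=config.diff_order,
            epsilon_factor=config.epsilon_factor,
            delta_grid=config.delta_grid,
            deltas=deltas[q],
        )
        densities.append(models)
    return densities


def run_ica(X, config: ICAConfig | None = None, parcellation: ParcellationMap | None = None,
            B0=None) -> UnmixingState:
    """Alternate density estimation and Newton updates until the Amari step
    between successive unmixing matrices falls below ``config.tol``.

    Each outer iteration: standardize source rows to unit variance,
    re-fit the P-spline densities from the current sources (kept only if
    they do not lower the joint likelihood), then take one safeguarded
    Newton-Raphson step on ``B``.  Deterministic given the inputs.
    """
    config = config or ICAConfig()
    if isinstance(X, MixedData):
        Xc = X.values
    else:
        Xc = MixedData.from_array(X).values
    Q, V = Xc.shape
    if V <= Q:
        raise ValueError(f"need more samples than components (Q={Q}, V={V})")

    if parcellation is None:
        pmap = ParcellationMap.single(V)
    else:
        pmap = merge_small_regions(parcellation, config.min_region_size)
    labels = pmap.labels if pmap.n_regions > 1 else None

    B = np.eye(Q) if B0 is None else np.array(B0, dtype=float)
    if abs(np.linalg.det(B)) == 0:
        raise SingularMatrixError("initial unmixing matrix is singular")

    deltas = [None] * Q
    densities = None
    ll_cur = None
    amari_trace: list[float] = []
    loglik_trace: list[float] = []
    converged = False
    it = 0

    for it in range(1, config.max_iter + 1):
        B, S, sd = standardize_sources(B, Xc)
        if densities is not None:
            # keep the likelihood comparable: rescaling row q of B by 1/sd
            # maps exactly to rescaling its densities by the same factor
            densities = [[m.rescale(1.0 / sd[q]) for m in _as_region_models(densities[q])]
                         for q in range(Q)]
        try:
            new_densities = _fit_densities(S, pmap, config, deltas)
            ll_new = log_likelihood(B, Xc, new_densities, labels)
            refit_ok = np.isfinite(ll_new)
        except psd.FitConvergenceError as exc:
            logger.debug("density refresh failed at iteration %d: %s", it, exc)
            refit_ok = False
            ll_new = -np.inf
        if densities is None:
            if not refit_ok:
                raise psd.FitConvergenceError("initial density fit failed")
            densities, ll_cur = new_densities, ll_new
        elif refit_ok and ll_new >= ll_cur - 1e-9:
            densities, ll_cur = new_densities, ll_new
        else:
            ll_cur = log_likelihood(B, Xc, densities, labels)

        grad = likelihood_gradient(B, Xc, densities, labels)
        hess = likelihood_hessian(B, Xc, densities, labels)
        B_new, ll_post = newton_step(
            B, grad, hess,
            loglik_fn=lambda M: log_likelihood(M, Xc, densities, labels),
            ll_current=ll_cur,
            max_halvings=config.max_halvings,
            ridge=config.hessian_ridge,
        )
        step = amari_distance(B, B_new)
        amari_trace.append(step)
        loglik_trace.append(ll_post)
        logger.info("iter %d: loglik=%.6f amari_step=%.3e", it, ll_post, step)
        B, ll_cur = B_new, ll_post
        if step < config.tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"ICA did not converge in {config.max_iter} iterations "
            f"(last Amari step {amari_trace[-1]:.3e})",
            RuntimeWarning,
        )

    B, S, sd = standardize_sources(B, Xc)
    densities = [[m.rescale(1.0 / sd[q]) for m in _as_region_models(densities[q])]
                 for q in range(Q)]
    B, S, densities = _order_components(B, S, densities)
    return UnmixingState(
        B=B, S=S, densities=densities, parcellation=pmap, iteration=it,
        amari_trace=np.asarray(amari_trace), loglik_trace=np.asarray(loglik_trace),
        converged=converged, config=config,
    )


def _order_components(B, S, densities):
    """Reporting convention: order components by decreasing explained variance
    of A(.,q) S(q,.); flip signs so each source row has positive skewness
    (ties broken by a positive max-abs value)."""
    A = np.linalg.inv(B)
    ev = np.sum(A ** 2, axis=0)  # rows of S have unit variance
    order = np.argsort(-ev, kind="stable")
    B, S = B[order], S[order]
    densities = [densities[q] for q in order]
    for q in range(S.shape[0]):
        skew = np.mean(S[q] ** 3)
        flip = skew < 0 or (skew == 0 and S[q][np.argmax(np.abs(S[q]))] < 0)
        if flip:
            S[q] = -S[q]
            B[q] = -B[q]
            densities[q] = [m.mirror() for m in densities[q]]
    return B, S, densities
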