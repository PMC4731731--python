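"""Density estimation by P-spline histogram smoothing.

A sample is summarized by an equidistant-bin histogram whose counts are
modelled as Poisson with a log-linear B-spline mean,

    n_j ~ Poisson(lambda_j),    log lambda_j = sum_l D(m_j, l) beta_l,

where ``D`` is a B-spline design matrix evaluated at the bin midpoints
``m_j``.  A difference penalty ``delta * sum_l (Diff^m beta)_l^2 / 2`` on
adjacent coefficients keeps the fit smooth even with a generous number of
basis functions (the Eilers-Marx P-spline construction).  The fitted spline,
exponentiated and renormalized, is a proper, strictly positive, continuous
density.  The score function d/ds log f(s) and its derivative are available
analytically from the B-spline basis derivatives, which is what makes this
density estimator attractive inside a likelihood-based ICA loop.

The default penalty differences are third order: their null space is the
quadratic log-densities, so shrinkage pulls the fit toward a Gaussian shape
and — because quadratics are reproduced exactly by the cubic basis and cost
no penalty — the fitted density conserves the histogram's mean and variance
essentially exactly at every smoothing level.  Second-order differences
(null space: exponential tilts) are available via ``diff_order=2``; they
conserve only the mean exactly, with the variance drifting as ``delta``
grows.  Two-moment conservation is what keeps unit-variance standardized
sources consistent with their fitted densities inside the ICA loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "DENSITY_FLOOR",
    "Histogram",
    "SplineDensityModel",
    "DegenerateSampleError",
    "FitConvergenceError",
    "default_bins",
    "build_histogram",
    "build_bspline_basis",
    "fit_penalized_poisson",
    "select_penalty",
    "density_eval",
    "score_eval",
    "score_prime_eval",
]

# Lower bound applied to every evaluated density so that log-likelihoods
# stay finite even for samples far outside the fitted domain.
DENSITY_FLOOR = 1e-12
_LOG_FLOOR = math.log(DENSITY_FLOOR)

# Number of intervals of the trapezoid grid used to normalize densities.
_NORM_GRID = 2048


class DegenerateSampleError(ValueError):
    """Raised when a sample (or region) is constant and cannot be binned."""


class FitConvergenceError(RuntimeError):
    """Penalized IRLS failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_beta: np.ndarray | None = None):
        super().__init__(message)
        self.last_beta = last_beta


def default_bins(n_samples: int) -> int:
    """Histogram bin count rule: 100 bins for large samples, sqrt rule below."""
    if n_samples >= 10_000:
        return 100
    return max(20, math.ceil(math.sqrt(n_samples)))


@dataclass(frozen=True)
class Histogram:
    """Equidistant histogram with half-open bins ``(c[j-1], c[j]]``."""

    cutpoints: np.ndarray
    counts: np.ndarray
    midpoints: np.ndarray
    epsilon: float
    bin_width: float

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.cutpoints[0]), float(self.cutpoints[-1])


def build_histogram(sample, n_bins: int | None = None, epsilon: float | None = None) -> Histogram:
    """Bin a sample into ``n_bins`` equidistant half-open intervals.

    The binning range is padded by ``epsilon`` on both sides (default
    ``0.1 * std(sample)``) to avoid boundary effects; a value falling exactly
    on an interior cutpoint is assigned to the left bin.
    """
    s = np.asarray(sample, dtype=float).ravel()
    if s.size < 2:
        raise ValueError("need at least two samples to build a histogram")
    if not np.all(np.isfinite(s)):
        raise ValueError("sample contains non-finite values")
    lo, hi = float(s.min()), float(s.max())
    if lo == hi:
        raise DegenerateSampleError("sample is constant; histogram is degenerate")
    if n_bins is None:
        n_bins = default_bins(s.size)
    if n_bins < 4:
        raise ValueError(f"n_bins must be >= 4, got {n_bins}")
    if epsilon is None:
        epsilon = 0.1 * float(s.std())
    if not epsilon > 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")

    cutpoints = np.linspace(lo - epsilon, hi + epsilon, n_bins + 1)
    # searchsorted(side="left") maps v in (c[j-1], c[j]] to index j
    idx = np.searchsorted(cutpoints, s, side="left") - 1
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    midpoints = 0.5 * (cutpoints[:-1] + cutpoints[1:])
    bin_width = float(cutpoints[1] - cutpoints[0])
    return Histogram(cutpoints=cutpoints, counts=counts, midpoints=midpoints,
                     epsilon=float(epsilon), bin_width=bin_width)


def _knot_vector(domain: tuple[float, float], n_knots: int, degree: int) -> np.ndarray:
    a, b = float(domain[0]), float(domain[1])
    n_seg = n_knots - degree
    if n_seg < 2:
        raise ValueError(f"n_knots={n_knots} too small for degree {degree} (need >= degree + 2)")
    h = (b - a) / n_seg
    interior = np.linspace(a, b, n_seg + 1)  # exact endpoints
    left = a - h * np.arange(degree, 0, -1)
    right = b + h * np.arange(1, degree + 1)
    return np.concatenate([left, interior, right])


def build_bspline_basis(eval_points, domain, n_knots: int, degree: int, deriv: int = 0) -> np.ndarray:
    """B-spline design matrix on equally spaced knots spanning ``domain``.

    Points outside the domain are clamped to its boundary before evaluation.
    Rows of the (deriv=0) matrix sum to one on the domain interior.
    """
    x = np.asarray(eval_points, dtype=float).ravel()
    a, b = float(domain[0]), float(domain[1])
    t = _knot_vector((a, b), n_knots, degree)
    # clip to the actual spline support taken from the knot vector (not the
    # nominal domain, which can differ by a rounding ulp) and stay just
    # inside the right edge: the basis support is half-open there
    lo, hi = t[degree], t[-degree - 1]
    xc = np.clip(x, lo, np.nextafter(hi, lo))
    spl = BSpline(t, np.eye(n_knots), degree, extrapolate=False)
    if deriv:
        spl = spl.derivative(deriv)
    D = spl(xc)
    # the right endpoint can fall on the last knot boundary; scipy handles it,
    # but guard against stray NaN from float fuzz at the very edge
    if not np.all(np.isfinite(D)):
        D = np.nan_to_num(D, nan=0.0)
    return D


def _diff_penalty(n_knots: int, order: int) -> np.ndarray:
    if not 1 <= order < n_knots:
        raise ValueError(f"penalty difference order {order} invalid for {n_knots} knots")
    d = np.diff(np.eye(n_knots), n=order, axis=0)  # (L-order, L)
    return d.T @ d


@dataclass
class SplineDensityModel:
    """A fitted P-spline density: ``f(s) = exp(spline(s)) / norm_const``."""

    degree: int
    n_knots: int
    coefficients: np.ndarray
    penalty: float
    domain: tuple[float, float]
    norm_const: float
    n_samples: int
    bin_width: float
    diff_order: int = 3
    edf: float = float("nan")
    deviance: float = float("nan")
    converged: bool = True
    fitted_means: np.ndarray | None = field(default=None, repr=False)

    # -- evaluation ---------------------------------------------------------
    def _basis(self, s, deriv: int = 0) -> np.ndarray:
        return build_bspline_basis(s, self.domain, self.n_knots, self.degree, deriv=deriv)

    def log_density(self, s) -> np.ndarray:
        """log f(s); clamped to the boundary value outside the domain.

        Always finite (the spline has finite coefficients), and exactly
        compatible with :meth:`rescale`, which the ICA loop relies on.
        """
        return self._basis(s) @ self.coefficients - math.log(self.norm_const)

    def density(self, s) -> np.ndarray:
        """f(s), floored at ``DENSITY_FLOOR`` so returned values are positive."""
        return np.maximum(np.exp(self.log_density(s)), DENSITY_FLOOR)

    def score(self, s) -> np.ndarray:
        """d/ds log f(s); zero outside the fitted domain (clamped tails)."""
        s = np.asarray(s, dtype=float)
        out = self._basis(s, deriv=1) @ self.coefficients
        a, b = self.domain
        outside = (s < a) | (s > b)
        if np.any(outside):
            out = np.where(outside, 0.0, out)
        return out

    def score_prime(self, s) -> np.ndarray:
        """d^2/ds^2 log f(s); zero outside the fitted domain."""
        s = np.asarray(s, dtype=float)
        out = self._basis(s, deriv=2) @ self.coefficients
        a, b = self.domain
        outside = (s < a) | (s > b)
        if np.any(outside):
            out = np.where(outside, 0.0, out)
        return out

    def mirror(self) -> "SplineDensityModel":
        """Density of ``-S`` when this model describes ``S``.

        On the equally spaced knot grid the mirrored spline is the original
        with reversed coefficients on the negated, reversed domain.
        """
        a, b = self.domain
        return SplineDensityModel(
            degree=self.degree,
            n_knots=self.n_knots,
            coefficients=self.coefficients[::-1].copy(),
            penalty=self.penalty,
            domain=(-b, -a),
            norm_const=self.norm_const,
            n_samples=self.n_samples,
            bin_width=self.bin_width,
            diff_order=self.diff_order,
            edf=self.edf,
            deviance=self.deviance,
            converged=self.converged,
            fitted_means=self.fitted_means,
        )

    def rescale(self, factor: float) -> "SplineDensityModel":
        """Density of ``factor * S`` when this model describes ``S``.

        Scaling the knots and domain by ``factor`` and the normalizer by the
        same factor gives exactly f_new(s) = f_old(s / factor) / factor, so a
        joint ICA log-likelihood is invariant under simultaneous row rescaling
        of the unmixing matrix and this transformation of its densities.
        """
        if not factor > 0:
            raise ValueError("rescale factor must be positive")
        a, b = self.domain
        return SplineDensityModel(
            degree=self.degree,
            n_knots=self.n_knots,
            coefficients=self.coefficients.copy(),
            penalty=self.penalty,
            domain=(a * factor, b * factor),
            norm_const=self.norm_const * factor,
            n_samples=self.n_samples,
            bin_width=self.bin_width * factor,
            diff_order=self.diff_order,
            edf=self.edf,
            deviance=self.deviance,
            converged=self.converged,
            fitted_means=self.fitted_means,
        )


def _poisson_deviance(n: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(n > 0, n * np.log(n / mu), 0.0)
    return float(2.0 * np.sum(term - (n - mu)))


def fit_penalized_poisson(
    hist: Histogram,
    n_knots: int = 25,
    degree: int = 3,
    penalty: float = 0.0,
    diff_order: int = 3,
    max_iter: int = 100,
    gtol: float = 1e-8,
    ridge: float = 1e-10,
) -> SplineDensityModel:
    """Fit the penalized Poisson log-linear model to histogram counts.

    Maximizes ``sum_j n_j log mu_j - sum_j mu_j - delta/2 * ||Diff^m beta||^2``
    by iteratively reweighted least squares with step halving; ``mu_j =
    exp(D(m_j, .) beta)``.  Convergence requires the gradient max-norm to
    fall below ``gtol`` scaled by the total count (the gradient of a Poisson
    fit cannot be resolved below the rounding floor of ``sum(n)``).  The
    returned model's density is the continuous interpolant ``exp(spline)``
    renormalized to integrate to one over the histogram's padded domain.
    """
    if penalty < 0:
        raise ValueError("penalty must be nonnegative")
    n = hist.counts.astype(float)
    if n.sum() == 0:
        raise DegenerateSampleError("histogram has no counts")
    domain = hist.domain
    D = build_bspline_basis(hist.midpoints, domain, n_knots, degree)
    P = _diff_penalty(n_knots, diff_order)
    gtol_abs = gtol * max(1.0, float(n.sum()))

    # a tiny coefficient ridge keeps the objective strictly concave and the
    # optimum finite even when entire bin runs are empty
    coef_ridge = 1e-8

    def pen_ll(beta: np.ndarray) -> float:
        eta = np.clip(D @ beta, -300.0, 300.0)
        return float(n @ eta - np.exp(eta).sum() - 0.5 * penalty * beta @ P @ beta
                     - 0.5 * coef_ridge * beta @ beta)

    # start from a least-squares projection of the log counts
    y0 = np.log(n + 0.5)
    beta = np.linalg.lstsq(D, y0, rcond=None)[0]
    ll = pen_ll(beta)
    converged = False
    stalls = 0
    A = None
    for _ in range(max_iter):
        eta = np.clip(D @ beta, -300.0, 300.0)
        mu = np.exp(eta)
        g = D.T @ (n - mu) - penalty * (P @ beta) - coef_ridge * beta
        if np.max(np.abs(g)) < gtol_abs:
            converged = True
            break
        A = D.T @ (D * mu[:, None]) + penalty * P + (coef_ridge + ridge) * np.eye(n_knots)
        try:
            step = np.linalg.solve(A, g)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - ridge guards this
            raise FitConvergenceError(f"IRLS normal equations singular: {exc}", beta) from exc
        # step halving keeps the penalized likelihood ascending
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            ll_cand = pen_ll(cand)
            if np.isfinite(ll_cand) and ll_cand >= ll - 1e-12:
                improved = ll_cand - ll > 1e-10 * (1.0 + abs(ll))
                beta, ll = cand, ll_cand
                break
            t *= 0.5
        else:
            raise FitConvergenceError("IRLS step halving failed to improve the fit", beta)
        # near-empty tail runs make the gradient crawl: once the objective
        # stops moving at float resolution the iterate is the numerical optimum
        stalls = 0 if improved else stalls + 1
        if stalls >= 3:
            converged = True
            break
    else:
        raise FitConvergenceError(
            f"IRLS did not reach gradient norm {gtol_abs:g} in {max_iter} iterations", beta
        )

    eta = np.clip(D @ beta, -300.0, 300.0)
    mu = np.exp(eta)
    W = mu
    Ainfo = D.T @ (D * W[:, None])
    Apen = Ainfo + penalty * P + ridge * np.eye(n_knots)
    edf = float(np.trace(np.linalg.solve(Apen, Ainfo)))
    deviance = _poisson_deviance(n, mu)

    # normalize exp(spline) to a unit-integral density over the domain
    grid = np.linspace(domain[0], domain[1], _NORM_GRID + 1)
    spline_vals = build_bspline_basis(grid, domain, n_knots, degree) @ beta
    norm_const = float(np.trapezoid(np.exp(spline_vals), grid))
    if not (np.isfinite(norm_const) and norm_const > 0):
        raise FitConvergenceError("density normalization failed (non-finite integral)", beta)

    return SplineDensityModel(
        degree=degree,
        n_knots=n_knots,
        coefficients=beta,
        penalty=float(penalty),
        domain=domain,
        norm_const=norm_const,
        n_samples=hist.n_samples,
        bin_width=hist.bin_width,
        diff_order=diff_order,
        edf=edf,
        deviance=deviance,
        converged=converged,
        fitted_means=mu,
    )


def select_penalty(hist: Histogram, candidate_deltas, n_knots: int = 25, degree: int = 3,
                   **fit_kwargs) -> float:
    """Choose the smoothing penalty minimizing AIC = deviance + 2 * edf.

    Ties (within 1e-12) break toward the larger, smoother penalty.
    """
    deltas = [float(d) for d in np.atleast_1d(candidate_deltas)]
    if not deltas:
        raise ValueError("need at least one candidate penalty")
    best_delta, best_aic = None, np.inf
    for d in sorted(deltas):
        model = fit_penalized_poisson(hist, n_knots=n_knots, degree=degree, penalty=d, **fit_kwargs)
        aic = model.deviance + 2.0 * model.edf
        if best_delta is None or aic <= best_aic + 1e-12:
            best_delta, best_aic = d, min(aic, best_aic)
    return best_delta


# functional aliases matching the operation-style surface
def density_eval(model: SplineDensityModel, s) -> np.ndarray:
    return model.density(s)


def score_eval(model: SplineDensityModel, s) -> np.ndarray:
    return model.score(s)


def score_prime_eval(model: SplineDensityModel, s) -> np.ndarray:
    return model.score_prime(s)
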