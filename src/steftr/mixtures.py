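"""1-D Gaussian mixture fitting, model selection and histogram scoring.

A feature histogram is modeled as a mixture of N univariate Gaussians

    p(f | M_N) = sum_n pi_n Normal(f; mu_n, sigma_n),

fitted by expectation-maximization. The cluster number is grown from 1 and
stops at the first N whose 10-fold cross-validated held-out log-likelihood no
longer improves; the previous N is kept. Histogram quality is scored by the
separation index

    s(H) = (1 - Ov(M_N)) + min(N, Mx(H)) / N,

where Ov is the overlapping area of adjacent components and Mx counts visible
density peaks (kernel density estimate, ignoring maxima below 0.1% of the
peak density).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats


def _logsumexp_rows(logd: np.ndarray) -> np.ndarray:
    """Stable log-sum-exp over the last axis (scipy's version is much slower)."""
    m = logd.max(axis=-1, keepdims=True)
    return (m + np.log(np.exp(logd - m).sum(axis=-1, keepdims=True)))[..., 0]

SIGMA_FLOOR_FRACTION = 1e-6  # of the data range
EM_TOL = 1e-6
EM_MAX_ITER = 500
N_RESTARTS = 10
CV_RESTARTS = 3
CV_FOLDS = 10
CV_SUBSAMPLE = 5000  # selection only; final fits and labeling see more data
CV_EM_TOL = 1e-5
CV_EM_MAX_ITER = 300
OVERLAP_GRID = 4096
KDE_GRID = 1024
PEAK_FRACTION = 1e-3  # local maxima below this fraction of the peak density are noise


class MixtureFitError(ValueError):
    """Raised when a mixture cannot be fitted (too few or degenerate values)."""


@dataclass
class MixtureModel:
    """A fitted 1-D Gaussian mixture, components sorted by mean ascending."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    ll_path: np.ndarray = field(default_factory=lambda: np.array([]))
    cv_log_likelihood: float | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        order = np.argsort(self.means, kind="mergesort")
        self.weights = self.weights[order]
        self.means = self.means[order]
        self.sds = self.sds[order]
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise MixtureFitError("mixture weights must sum to 1")
        if np.any(self.sds <= 0):
            raise MixtureFitError("component standard deviations must be positive")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def component_log_densities(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.log(self.weights) + stats.norm.logpdf(x[..., None], self.means, self.sds)

    def logpdf(self, x) -> np.ndarray:
        return _logsumexp_rows(self.component_log_densities(x))

    def pdf(self, x) -> np.ndarray:
        return np.exp(self.logpdf(x))

    def responsibilities(self, x) -> np.ndarray:
        """Posterior component probabilities for each value; rows sum to 1."""
        logd = self.component_log_densities(x)
        return np.exp(logd - _logsumexp_rows(logd)[..., None])

    def assign(self, x) -> np.ndarray:
        """Maximum-posterior component index (components sorted by mean)."""
        return np.argmax(self.component_log_densities(x), axis=-1)

    def mean_loglik(self, x) -> float:
        return float(np.mean(self.logpdf(x)))


_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _em_once(
    values: np.ndarray,
    n_components: int,
    mu: np.ndarray,
    sigma_floor: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, list[float]]:
    n = len(values)
    x = values[:, None]
    sigma = np.full(n_components, max(values.std(), sigma_floor))
    pi = np.full(n_components, 1.0 / n_components)
    ll_path: list[float] = []
    ll_old = -np.inf
    for _ in range(max_iter):
        logd = (
            np.log(pi)
            - np.log(sigma)
            - _LOG_SQRT_2PI
            - 0.5 * ((x - mu) / sigma) ** 2
        )
        norm = _logsumexp_rows(logd)
        ll = float(norm.sum())
        ll_path.append(ll)
        resp = np.exp(logd - norm[:, None])
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        pi = nk / n
        mu = (resp * x).sum(axis=0) / nk
        var = (resp * (x - mu) ** 2).sum(axis=0) / nk
        sigma = np.maximum(np.sqrt(var), sigma_floor)
        if np.isfinite(ll_old) and abs(ll - ll_old) <= tol * abs(ll_old):
            break
        ll_old = ll
    return pi, mu, sigma, ll, ll_path


def fit_gmm_em(
    values,
    n_components: int,
    seed: int = 1,
    n_restarts: int = N_RESTARTS,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> MixtureModel:
    """Fit an N-component 1-D Gaussian mixture by EM, best of seeded restarts.

    Iterates to a relative log-likelihood change below 1e-6 (or 500
    iterations); sigma is floored at 1e-6 of the data range. Requires at
    least 5 values per component.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if n_components < 1:
        raise MixtureFitError("n_components must be >= 1")
    if len(values) < 5 * n_components:
        raise MixtureFitError(f"need at least {5 * n_components} values for N={n_components}")
    span = float(np.ptp(values))
    if span == 0.0:
        raise MixtureFitError("all values identical")
    sigma_floor = SIGMA_FLOOR_FRACTION * span

    if n_components == 1:
        mu = float(values.mean())
        sd = max(float(values.std()), sigma_floor)
        ll = float(stats.norm.logpdf(values, mu, sd).sum())
        return MixtureModel(np.array([1.0]), np.array([mu]), np.array([sd]), ll, np.array([ll]))

    rng = np.random.default_rng(seed)
    best: tuple[float, tuple] | None = None
    for r in range(n_restarts):
        if r == 0:  # deterministic quantile spread; usually already near the optimum
            mu0 = np.quantile(values, (np.arange(n_components) + 0.5) / n_components)
        else:
            mu0 = rng.choice(values, size=n_components, replace=False)
        pi, mu, sigma, ll, path = _em_once(
            values, n_components, np.asarray(mu0, dtype=float), sigma_floor, tol, max_iter
        )
        if best is None or ll > best[0]:
            best = (ll, (pi, mu, sigma, path))
    ll, (pi, mu, sigma, path) = best
    return MixtureModel(pi, mu, sigma, ll, np.asarray(path))


def refine_fit(values, model: MixtureModel, tol: float = EM_TOL, max_iter: int = EM_MAX_ITER) -> MixtureModel:
    """Continue EM on (possibly different) values from an already-fitted model."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    sigma_floor = SIGMA_FLOOR_FRACTION * float(np.ptp(values))
    pi, mu, sigma, ll, path = _em_once(
        values, model.n_components, model.means.copy(), sigma_floor, tol, max_iter
    )
    return MixtureModel(pi, mu, sigma, ll, np.asarray(path))


def select_cluster_number(
    values,
    max_n: int,
    seed: int = 1,
    n_folds: int = CV_FOLDS,
    cv_subsample: int | None = CV_SUBSAMPLE,
) -> int:
    """Grow the cluster number from 1; keep the last N that improved.

    N grows one at a time; growth stops at the first candidate whose k-fold
    cross-validated mean held-out log-likelihood does not exceed the previous
    candidate's, and the previous N is returned (capped at ``max_n``). Very
    large value pools are subsampled (seeded) for this selection step only.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if max_n < 1:
        raise MixtureFitError("max_n must be >= 1")
    if cv_subsample is not None and len(values) > cv_subsample:
        rng = np.random.default_rng(seed)
        values = rng.choice(values, size=cv_subsample, replace=False)
    prev_scores = _cv_fold_scores(values, 1, seed, n_folds)
    best_n = 1
    for n in range(2, max_n + 1):
        if len(values) < 5 * n:
            break
        scores = _cv_fold_scores(values, n, seed, n_folds)
        if scores is None:
            break
        # Paired one-sided t-test on per-fold differences: a candidate must
        # improve the held-out likelihood significantly (5% level), otherwise
        # chance-level CV gains would grow N indefinitely.
        diff = scores - prev_scores
        if len(diff) > 1:
            se = float(diff.std(ddof=1) / np.sqrt(len(diff)))
            t_crit = float(stats.t.ppf(0.95, len(diff) - 1))
        else:
            se, t_crit = 0.0, 0.0
        if float(diff.mean()) <= t_crit * se:
            break
        prev_scores = scores
        best_n = n
    return best_n


def _cv_fold_scores(
    values: np.ndarray, n_components: int, seed: int, n_folds: int
) -> np.ndarray | None:
    """Held-out mean log-likelihood per fold; folds fixed across candidate N."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(values))
    folds = np.array_split(perm, n_folds)
    scores = []
    for i, test_idx in enumerate(folds):
        if len(test_idx) == 0:
            continue
        mask = np.ones(len(values), dtype=bool)
        mask[test_idx] = False
        train = values[mask]
        if len(train) < 5 * n_components:
            return None
        try:
            model = fit_gmm_em(
                train,
                n_components,
                seed=seed + i,
                n_restarts=CV_RESTARTS,
                tol=CV_EM_TOL,
                max_iter=CV_EM_MAX_ITER,
            )
        except MixtureFitError:
            return None
        scores.append(model.mean_loglik(values[test_idx]))
    return np.asarray(scores)


def overlap_proportion(model: MixtureModel, grid_size: int = OVERLAP_GRID) -> float:
    """Overlapping area of adjacent (mean-sorted) weighted components.

    For each adjacent pair, min(pi_a phi_a, pi_b phi_b) is integrated
    numerically over [mu_1 - 4 sigma_max, mu_N + 4 sigma_max]; the pairwise
    overlaps are summed and clipped to [0, 1]. A single component has zero
    overlap by definition.
    """
    if model.n_components == 1:
        return 0.0
    sigma_max = float(model.sds.max())
    lo = float(model.means[0] - 4 * sigma_max)
    hi = float(model.means[-1] + 4 * sigma_max)
    grid = np.linspace(lo, hi, grid_size)
    dens = model.weights * stats.norm.pdf(grid[:, None], model.means, model.sds)
    total = 0.0
    for a in range(model.n_components - 1):
        total += float(np.trapezoid(np.minimum(dens[:, a], dens[:, a + 1]), grid))
    return float(np.clip(total, 0.0, 1.0))


def count_local_maxima(
    values,
    grid_size: int = KDE_GRID,
    peak_fraction: float = PEAK_FRACTION,
    max_values: int | None = None,
    seed: int = 1,
) -> int:
    """Count visible peaks of a kernel density estimate of the values.

    A Gaussian KDE with Silverman bandwidth is evaluated on a regular grid;
    maxima are (+ -> -) sign changes of the finite-difference derivative, and
    maxima whose density falls below ``peak_fraction`` of the peak density
    are ignored as noise.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 30:
        raise ValueError("need at least 30 values for peak counting")
    if np.ptp(values) == 0.0:
        raise ValueError("degenerate (constant) data")
    if max_values is not None and len(values) > max_values:
        rng = np.random.default_rng(seed)
        values = rng.choice(values, size=max_values, replace=False)
    kde = stats.gaussian_kde(values, bw_method="silverman")
    bw = float(kde.factor * values.std(ddof=1))
    grid = np.linspace(values.min() - 3 * bw, values.max() + 3 * bw, grid_size)
    dens = kde(grid)
    # Noise maxima are "small" in both senses: low density and low rise.
    # Requiring height and prominence above the threshold keeps genuine modes
    # while discarding ripples riding on a broad component.
    threshold = peak_fraction * dens.max()
    peaks, _ = signal.find_peaks(dens, height=threshold, prominence=threshold)
    return int(len(peaks))


@dataclass(frozen=True)
class HistogramScore:
    """Separation-index score card for one feature histogram."""

    feature_kind: str
    n_components: int
    overlap: float
    n_maxima: int
    separation: float

    @staticmethod
    def compute(feature_kind: str, model: MixtureModel, n_maxima: int) -> "HistogramScore":
        ov = overlap_proportion(model)
        n = model.n_components
        s = (1.0 - ov) + min(n, n_maxima) / n
        return HistogramScore(feature_kind, n, ov, n_maxima, s)


def separation_index(values, model: MixtureModel, feature_kind: str = "", **kde_kwargs) -> HistogramScore:
    """Score a histogram's values under its fitted mixture model."""
    mx = count_local_maxima(values, **kde_kwargs)
    return HistogramScore.compute(feature_kind, model, mx)
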