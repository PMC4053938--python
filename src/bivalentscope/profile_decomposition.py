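"""Correlation-distance k-means over binding profiles and the six-parameter
two-Gaussian decomposition of an aggregate TSS profile.

The clustering distance is d(a, b) = 1 - PearsonR(a, b), making cluster
membership invariant to per-row scale and offset.  Stability across random
restarts is quantified with the adjusted Rand index, which is invariant to
the arbitrary labelling of k-means clusters.

The bimodal model of an aggregate profile is a superposition of two
non-normalized Gaussians,

    f(x) = A * ( w * exp(-(x - mu1)^2 / (2 sigma1^2))
               + (1 - w) * exp(-(x - mu2)^2 / (2 sigma2^2)) ),

six free parameters (two means, two widths, one relative weight, one overall
amplitude), fitted by least squares from multiple starts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.metrics import adjusted_rand_score

from .profile_engine import MetaProfile, ProfileMatrix

log = logging.getLogger(__name__)


# --------------------------------------------------------------- clustering


@dataclass
class ClusterResult:
    k: int
    assignment: dict[str, int]
    centroids: np.ndarray  # k x n_bins, per-bin mean of raw member profiles
    within_cluster_mean_corr: float
    seed: int
    excluded: list[str] = field(default_factory=list)  # zero-variance rows
    objective_history: list[float] = field(default_factory=list)
    n_iter: int = 0

    def labels(self, gene_ids: list[str]) -> np.ndarray:
        return np.array([self.assignment[g] for g in gene_ids])


@dataclass
class StabilityReport:
    n_realizations: int
    ari_matrix: np.ndarray

    @property
    def mean_ari(self) -> float:
        n = self.n_realizations
        iu = np.triu_indices(n, k=1)
        return float(self.ari_matrix[iu].mean())


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    return (x - mu) / sd


def cluster_profiles(
    matrix: ProfileMatrix, k: int, seed: int = 0, max_iter: int = 300
) -> ClusterResult:
    """Lloyd k-means under Pearson correlation distance d = 1 - r.

    Rows with zero variance have undefined correlation and are excluded up
    front (logged).  Assignment is against the mean of the standardized
    member profiles (which maximizes summed correlation, so the objective is
    non-increasing); reported centroids are per-bin raw means of members.
    An emptied cluster is re-seeded from the point farthest from its
    centroid.  Deterministic given the seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    raw = matrix.values
    sds = raw.std(axis=1)
    # rows constant up to float rounding have no usable correlation structure
    keep = sds > 1e-10 * (np.abs(raw).max(axis=1) + 1e-30)
    excluded = [g for g, ok in zip(matrix.gene_ids, keep) if not ok]
    if excluded:
        log.warning("excluding %d zero-variance profile(s) from clustering", len(excluded))
    ids = [g for g, ok in zip(matrix.gene_ids, keep) if ok]
    x = raw[keep]
    n = x.shape[0]
    if n < k:
        raise ValueError(f"only {n} rows with nonzero variance for k={k}")
    z = _standardize_rows(x)  # each row: zero mean, norm sqrt(n_bins)
    nb = x.shape[1]
    rng = np.random.default_rng(seed)
    centers = z[rng.choice(n, size=k, replace=False)].copy()

    def correlations(c: np.ndarray) -> np.ndarray:
        """n x k Pearson r between each row and each center."""
        cz = _standardize_rows(c)
        return z @ cz.T / nb

    labels = np.full(n, -1, dtype=int)
    history: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        r = correlations(centers)
        new_labels = np.argmax(r, axis=1)
        # re-seed empty clusters from the globally worst-fit point
        for c in range(k):
            if not np.any(new_labels == c):
                worst = int(np.argmin(r[np.arange(n), new_labels]))
                new_labels[worst] = c
        objective = float((1.0 - r[np.arange(n), new_labels]).sum())
        history.append(objective)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        centers = np.vstack([z[labels == c].mean(axis=0) for c in range(k)])
    raw_centroids = np.vstack([x[labels == c].mean(axis=0) for c in range(k)])
    r = correlations(centers)
    within = float(r[np.arange(n), labels].mean())
    return ClusterResult(
        k=k,
        assignment=dict(zip(ids, labels.tolist())),
        centroids=raw_centroids,
        within_cluster_mean_corr=within,
        seed=seed,
        excluded=excluded,
        objective_history=history,
        n_iter=it,
    )


def cluster_stability(
    matrix: ProfileMatrix,
    k: int,
    n_realizations: int = 100,
    base_seed: int = 0,
) -> StabilityReport:
    """Pairwise adjusted Rand index across restarts with consecutive seeds."""
    if n_realizations < 2:
        raise ValueError("need >= 2 realizations")
    runs = [
        cluster_profiles(matrix, k, seed=base_seed + i) for i in range(n_realizations)
    ]
    ids = sorted(runs[0].assignment)
    label_mat = np.array([[run.assignment[g] for g in ids] for run in runs])
    ari = np.eye(n_realizations)
    for i in range(n_realizations):
        for j in range(i + 1, n_realizations):
            ari[i, j] = ari[j, i] = adjusted_rand_score(label_mat[i], label_mat[j])
    return StabilityReport(n_realizations=n_realizations, ari_matrix=ari)


# --------------------------------------------------------------- bimodal fit


@dataclass
class BimodalFit:
    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    w: float
    amplitude: float
    rss: float
    converged: bool

    def __post_init__(self) -> None:
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("sigmas must be > 0")
        if not (0 < self.w < 1):
            raise ValueError("w must be in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "mu1_bp": self.mu1,
            "sigma1_bp": self.sigma1,
            "mu2_bp": self.mu2,
            "sigma2_bp": self.sigma2,
            "weight_first": self.w,
            "amplitude": self.amplitude,
            "rss": self.rss,
            "converged": self.converged,
        }


def evaluate_bimodal(fit: BimodalFit, x: np.ndarray | float) -> np.ndarray | float:
    """Model value at x for a fitted (or constructed) parameter set."""
    return _model(
        np.asarray(x, dtype=float),
        fit.mu1,
        fit.sigma1,
        fit.mu2,
        fit.sigma2,
        fit.w,
        fit.amplitude,
    )


def _model(x, mu1, s1, mu2, s2, w, a):
    return a * (
        w * np.exp(-((x - mu1) ** 2) / (2 * s1**2))
        + (1 - w) * np.exp(-((x - mu2) ** 2) / (2 * s2**2))
    )


def _initial_means(x: np.ndarray, y: np.ndarray) -> list[tuple[float, float]]:
    """Candidate (mu1, mu2) pairs: the two strongest local maxima of a lightly
    smoothed profile, and the axis quartiles."""
    kernel = np.ones(3) / 3.0
    ys = np.convolve(y, kernel, mode="same")
    interior = np.arange(1, len(x) - 1)
    is_max = (ys[interior] >= ys[interior - 1]) & (ys[interior] >= ys[interior + 1])
    peaks = interior[is_max]
    peaks = peaks[np.argsort(ys[peaks])[::-1]]
    pairs = []
    if len(peaks) >= 2:
        m = sorted((float(x[peaks[0]]), float(x[peaks[1]])))
        pairs.append((m[0], m[1]))
    elif len(peaks) == 1:
        pairs.append((float(x[peaks[0]]), float(x[peaks[0]]) + 0.1 * np.ptp(x)))
    q1, q3 = np.quantile(x, [0.25, 0.75])
    pairs.append((float(q1), float(q3)))
    return pairs[:2]


def fit_two_gaussians(
    profile: MetaProfile,
    bin_width: float | None = None,
    max_nfev: int = 2000,
) -> BimodalFit:
    """Least-squares fit of the six-parameter two-Gaussian model.

    Multi-start initialization: means at the two strongest local maxima and
    at the axis quartiles; sigma at 0.02x, 0.1x and 0.3x the axis span
    (the narrow scale is needed when one component spans only a few bins);
    w in {0.3, 0.5}.  The best residual sum of squares wins.  Widths are bounded
    below at bin_width / 2 to prevent collapse onto a single bin.  Components
    are reordered afterwards so mu1 <= mu2 (the model is symmetric under the
    swap (mu1, s1) <-> (mu2, s2), w <-> 1 - w).
    """
    x = np.asarray(profile.axis, dtype=float)
    y = np.asarray(profile.values, dtype=float)
    if len(x) < 12:
        raise ValueError("need >= 12 bins (twice the parameter count)")
    if np.any(y < 0):
        raise ValueError("profile must be non-negative")
    if np.all(y == 0):
        raise ValueError("profile is identically zero")
    span = float(np.ptp(x))
    if bin_width is None:
        bin_width = float(np.median(np.diff(x)))
    sigma_floor = bin_width / 2.0
    amp0 = float(y.max())
    lo = [x.min(), sigma_floor, x.min(), sigma_floor, 1e-4, 1e-12]
    hi = [x.max(), 2 * span, x.max(), 2 * span, 1 - 1e-4, np.inf]

    def residuals(theta):
        return _model(x, *theta) - y

    def jacobian(theta):
        mu1, s1, mu2, s2, w, a = theta
        g1 = np.exp(-((x - mu1) ** 2) / (2 * s1**2))
        g2 = np.exp(-((x - mu2) ** 2) / (2 * s2**2))
        return np.column_stack(
            [
                a * w * g1 * (x - mu1) / s1**2,
                a * w * g1 * (x - mu1) ** 2 / s1**3,
                a * (1 - w) * g2 * (x - mu2) / s2**2,
                a * (1 - w) * g2 * (x - mu2) ** 2 / s2**3,
                a * (g1 - g2),
                w * g1 + (1 - w) * g2,
            ]
        )

    best = None
    any_converged = False
    for mu1, mu2 in _initial_means(x, y):
        for sig_frac in (0.02, 0.1, 0.3):
            for w0 in (0.3, 0.5):
                theta0 = np.clip(
                    [mu1, sig_frac * span, mu2, sig_frac * span, w0, amp0 / 0.5],
                    lo,
                    hi,
                )
                try:
                    sol = least_squares(
                        residuals,
                        theta0,
                        jac=jacobian,
                        bounds=(lo, hi),
                        max_nfev=max_nfev,
                        xtol=5e-16,
                        ftol=5e-16,
                        gtol=5e-16,
                    )
                except Exception:  # pragma: no cover - defensive
                    continue
                rss = float(2 * sol.cost)
                if sol.status > 0:
                    any_converged = True
                if best is None or rss < best[0]:
                    best = (rss, sol.x, sol.status > 0)
    if best is None:  # pragma: no cover - all starts failed
        raise RuntimeError("all fit initializations failed")
    rss, theta, converged = best
    mu1, s1, mu2, s2, w, a = (float(v) for v in theta)
    if mu1 > mu2:
        mu1, s1, mu2, s2, w = mu2, s2, mu1, s1, 1 - w
    w = float(np.clip(w, 1e-6, 1 - 1e-6))
    return BimodalFit(
        mu1=mu1,
        sigma1=s1,
        mu2=mu2,
        sigma2=s2,
        w=w,
        amplitude=a,
        rss=rss,
        converged=converged and any_converged,
    )
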