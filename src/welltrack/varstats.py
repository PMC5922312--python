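"""Behavioral-variability statistics.

The population of individuals lives in the two-dimensional behavioral
space (activity, radial index). This module provides:

* a Gaussian kernel density map of that space,
  ``P(x, y) = (1 / (N 2 pi sx sy)) sum_i exp(-[(x-xi)^2/sx^2 +
  (y-yi)^2/sy^2] / 2)``, with per-axis bandwidths ``s = N^(-1/6) * alpha``
  (``alpha`` = sample SD of that axis) — the standard normal-reference
  rule in two dimensions;
* the generalized variance ``|Sigma|`` (determinant of the covariance
  matrix), which in 2-D reduces to ``sx^2 sy^2 (1 - rho^2)`` — a single
  scalar measuring dispersion on the plane;
* per-individual covariance ellipses (semiaxes = sqrt of the covariance
  eigenvalues, reducing to per-axis SDs when uncorrelated);
* intra- vs inter-individual variability distributions over 30-s
  fragments (coefficient of variation, or SD for the signed tortuosity
  parameters) and the fragment-shuffling permutation test comparing them;
* the group permutation test on the generalized-variance (or centroid)
  difference between two populations;
* polar coordinates (r, theta) of individuals around the population's
  mean behavior;
* the Pearson-correlation t-test.

Both permutation tests report the plain proportion of permuted statistics
at or above the observed one (1000 shuffles by default) and are fully
determined by their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_N_PERM = 1000

#: Parameters whose dispersion is measured with the SD instead of the CV
#: (they take both signs, making the CV meaningless).
SD_PARAMETERS = ("tortuosity", "instant_tortuosity")


def _as_points(sample) -> np.ndarray:
    pts = np.asarray(sample, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("sample must be an (N, 2) array of points")
    if not np.isfinite(pts).all():
        raise ValueError("sample contains non-finite values")
    return pts


# ---------------------------------------------------------------------------
# Density maps

@dataclass
class DensityMap:
    """Kernel density on a regular grid; integrates to 1."""

    x: np.ndarray           # (nx,) grid coordinates
    y: np.ndarray           # (ny,)
    values: np.ndarray      # (ny, nx), values[iy, ix] = P(x[ix], y[iy])
    bandwidths: tuple[float, float]

    def integral(self) -> float:
        """Sum of cell values times cell area (should be ~1)."""
        dx = self.x[1] - self.x[0]
        dy = self.y[1] - self.y[0]
        return float(self.values.sum() * dx * dy)

    def to_dataframe(self):
        import pandas as pd

        xx, yy = np.meshgrid(self.x, self.y)
        return pd.DataFrame({"x": xx.ravel(), "y": yy.ravel(),
                             "density": self.values.ravel()})


def kde_bandwidths(points: np.ndarray) -> tuple[float, float]:
    """Per-axis bandwidth ``N^(-1/6) * sample SD`` (normal-reference rule
    for a 2-D density)."""
    pts = _as_points(points)
    n = len(pts)
    alpha = pts.std(axis=0, ddof=1)
    if (alpha == 0).any():
        raise ValueError("degenerate axis: zero sample SD")
    return tuple(n ** (-1.0 / 6.0) * alpha)


def kernel_density_map(sample, grid_size: int = 200,
                       padding_bandwidths: float = 3.0) -> DensityMap:
    """Gaussian-kernel probability density of the behavioral plane.

    Gaussians of per-axis SD ``sigma = N^(-1/6) * alpha`` are summed at
    the data points and evaluated on a ``grid_size x grid_size`` lattice
    covering the data range padded by ``padding_bandwidths`` bandwidths,
    which keeps the numerical integral within 0.01 of 1.
    """
    pts = _as_points(sample)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    sx, sy = kde_bandwidths(pts)
    x = np.linspace(pts[:, 0].min() - padding_bandwidths * max(sx, sy),
                    pts[:, 0].max() + padding_bandwidths * max(sx, sy),
                    grid_size)
    y = np.linspace(pts[:, 1].min() - padding_bandwidths * max(sx, sy),
                    pts[:, 1].max() + padding_bandwidths * max(sx, sy),
                    grid_size)
    # separable kernels: values = Gy @ Gx.T up to the common prefactor
    gx = np.exp(-0.5 * ((x[:, None] - pts[None, :, 0]) / sx) ** 2)
    gy = np.exp(-0.5 * ((y[:, None] - pts[None, :, 1]) / sy) ** 2)
    values = gy @ gx.T / (len(pts) * 2.0 * np.pi * sx * sy)
    return DensityMap(x=x, y=y, values=values, bandwidths=(sx, sy))


# ---------------------------------------------------------------------------
# Generalized variance and ellipses

def generalized_variance(sample) -> float:
    """Determinant of the 2x2 sample covariance matrix (n-1 normalized).

    Equals ``sx^2 sy^2 (1 - rho^2)``: maximal at fixed marginal variances
    when the two axes are uncorrelated, shrinking to 0 as the points
    collapse onto a line.
    """
    pts = _as_points(sample)
    if len(pts) < 3:
        raise ValueError("generalized variance needs at least 3 points")
    det = float(np.linalg.det(np.cov(pts.T)))
    return max(det, 0.0)   # guard against negative round-off


@dataclass(frozen=True)
class Ellipse:
    """Covariance isocontour of one individual's fragment cloud."""

    center: tuple[float, float]
    semiaxes: tuple[float, float]      # sqrt of eigenvalues, major first
    orientation: float                 # major-axis angle, radians

    def axes_vectors(self) -> np.ndarray:
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        return np.array([[c, s], [-s, c]])


def individual_ellipse(points) -> Ellipse:
    """Covariance ellipse of a fragment cloud.

    Principal axes are the covariance eigenvectors; each semiaxis is the
    square root of its eigenvalue, so with no correlation the semiaxes
    reduce to the per-axis standard deviations.
    """
    pts = _as_points(points)
    if len(pts) < 3:
        raise ValueError("ellipse needs at least 3 fragments")
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    semi = np.sqrt(np.clip(evals, 0.0, None))
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return Ellipse(center=tuple(pts.mean(axis=0)),
                   semiaxes=(float(semi[0]), float(semi[1])),
                   orientation=angle)


# ---------------------------------------------------------------------------
# Intra- vs inter-individual variability

@dataclass
class VariabilityDistributions:
    """Dispersion across time within individuals vs across individuals.

    ``intra``: one dispersion value per individual (across its fragments).
    ``inter``: one dispersion value per fragment time-window (across
    individuals).
    """

    intra: np.ndarray
    inter: np.ndarray
    measure: str            # "cv" or "sd"


def _dispersion(values: np.ndarray, axis: int, measure: str) -> np.ndarray:
    sd = np.nanstd(values, axis=axis, ddof=1)
    if measure == "sd":
        return sd
    mean = np.abs(np.nanmean(values, axis=axis))
    if (mean == 0).any():
        warnings.warn("zero mean under CV; falling back to SD",
                      RuntimeWarning, stacklevel=3)
        return sd
    return sd / mean


def _fragment_matrix(all_fragments, parameter_name: str) -> np.ndarray:
    """(n_individuals, n_windows) parameter matrix from FragmentSeries."""
    series = [np.asarray(s.parameter(parameter_name), dtype=float)
              if hasattr(s, "parameter") else np.asarray(s, dtype=float)
              for s in all_fragments]
    counts = {len(s) for s in series}
    if len(series) < 2:
        raise ValueError("need at least 2 individuals")
    if len(counts) != 1:
        raise ValueError(f"fragment counts differ across individuals: "
                         f"{sorted(counts)}")
    mat = np.vstack(series)
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 fragments per individual")
    return mat


def variability_distributions(all_fragments, parameter_name: str
                              ) -> VariabilityDistributions:
    """Intra- and inter-individual dispersion of one behavioral parameter.

    ``all_fragments`` is a list of per-individual
    :class:`~welltrack.behavior.FragmentSeries` (or plain per-individual
    value arrays) with aligned fragment counts. Dispersion is the CV, or
    the SD for the signed tortuosity parameters.
    """
    mat = _fragment_matrix(all_fragments, parameter_name)
    measure = "sd" if parameter_name in SD_PARAMETERS else "cv"
    intra = _dispersion(mat, axis=1, measure=measure)
    inter = _dispersion(mat, axis=0, measure=measure)
    return VariabilityDistributions(intra=intra, inter=inter,
                                    measure=measure)


# ---------------------------------------------------------------------------
# Permutation tests

@dataclass
class PermutationResult:
    """Outcome of a permutation test (p = proportion of permuted
    statistics >= observed; identical groups give p = 1)."""

    observed: float
    permuted: np.ndarray
    p_value: float
    n_perm: int
    seed: int | None
    statistic: str = ""

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "observed": self.observed,
                "p_value": self.p_value, "n_perm": self.n_perm,
                "seed": self.seed}


def _perm_pvalue(observed: float, permuted: np.ndarray,
                 add_one: bool) -> float:
    b = int((permuted >= observed).sum())
    if add_one:
        return (b + 1) / (len(permuted) + 1)
    return b / len(permuted)


def _intra_inter_stat(mat: np.ndarray, measure: str) -> float:
    intra = _dispersion(mat, axis=1, measure=measure)
    inter = _dispersion(mat, axis=0, measure=measure)
    return float(np.nanmedian(inter) - np.nanmedian(intra))


def permutation_test_intra_inter(all_fragments, parameter_name: str,
                                 n_perm: int = DEFAULT_N_PERM,
                                 seed: int | None = None,
                                 add_one: bool = False) -> PermutationResult:
    """Is inter-individual variability larger than intra-individual?

    Observed statistic: median(inter) - median(intra) dispersion. Each
    permutation shuffles the pooled 30-s fragments across individuals
    (per-individual fragment counts preserved) and recomputes the
    statistic; the p-value is the proportion of shuffles at or above the
    observed difference.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    mat = _fragment_matrix(all_fragments, parameter_name)
    measure = "sd" if parameter_name in SD_PARAMETERS else "cv"
    observed = _intra_inter_stat(mat, measure)
    rng = np.random.default_rng(seed)
    flat = mat.ravel()
    permuted = np.empty(n_perm)
    for k in range(n_perm):
        shuffled = rng.permutation(flat).reshape(mat.shape)
        permuted[k] = _intra_inter_stat(shuffled, measure)
    return PermutationResult(
        observed=observed, permuted=permuted,
        p_value=_perm_pvalue(observed, permuted, add_one),
        n_perm=n_perm, seed=seed,
        statistic=f"median_inter_minus_intra[{parameter_name}]")


def _group_stat(a: np.ndarray, b: np.ndarray, statistic: str) -> float:
    if statistic == "generalized_variance_diff":
        return abs(generalized_variance(a) - generalized_variance(b))
    if statistic == "mean_diff":
        return float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))
    raise ValueError(f"unknown statistic {statistic!r}")


def permutation_test_groups(group_a, group_b,
                            statistic: str = "generalized_variance_diff",
                            n_perm: int = DEFAULT_N_PERM,
                            seed: int | None = None,
                            add_one: bool = False) -> PermutationResult:
    """Compare the dispersion (or centroid) of two populations.

    Observed statistic: |stat(A) - stat(B)| with stat the generalized
    variance, or the Euclidean distance between group centroids for
    ``mean_diff``. Individuals are shuffled between the groups (sizes
    preserved) to build the null distribution.
    """
    a, b = _as_points(group_a), _as_points(group_b)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("both groups need at least 3 individuals")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = _group_stat(a, b, statistic)
    pooled = np.vstack([a, b])
    na = len(a)
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_perm)
    for k in range(n_perm):
        idx = rng.permutation(len(pooled))
        permuted[k] = _group_stat(pooled[idx[:na]], pooled[idx[na:]],
                                  statistic)
    return PermutationResult(
        observed=observed, permuted=permuted,
        p_value=_perm_pvalue(observed, permuted, add_one),
        n_perm=n_perm, seed=seed, statistic=statistic)


# ---------------------------------------------------------------------------
# Polar view of the behavioral space

def polar_coordinates(sample, pools: list[list[int]] | None = None,
                      center: np.ndarray | None = None):
    """(r, theta) of each individual around the population's mean behavior.

    ``r`` is the Euclidean distance in raw (activity, radial index) units;
    ``theta`` is the angle to the activity axis in (-pi, pi]. With
    ``pools``, each pool is summarized by the mean of its members'
    ``r`` and ``theta`` values.
    """
    pts = _as_points(sample)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    if center is None:
        center = pts.mean(axis=0)
    delta = pts - center
    r = np.hypot(delta[:, 0], delta[:, 1])
    theta = np.arctan2(delta[:, 1], delta[:, 0])
    if pools is None:
        return r, theta
    r_pool, t_pool = [], []
    for pool in pools:
        if len(pool) == 0:
            raise ValueError("empty pool")
        r_pool.append(float(r[list(pool)].mean()))
        t_pool.append(float(theta[list(pool)].mean()))
    return np.asarray(r_pool), np.asarray(t_pool)


# ---------------------------------------------------------------------------
# Correlation test

def correlation_r_test(x, y) -> tuple[float, float]:
    """Pearson R with the two-sided t-test of the null R = 0.

    ``t = R * sqrt(n - 2) / sqrt(1 - R^2)`` against Student's t with
    ``n - 2`` degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p)
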