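"""Temporal analysis of 9-point insulin time courses.

Profiles are log2(insulin/basal) SILAC ratios measured at 0, 15 s, 30 s,
1, 2, 5, 10, 20 and 60 min.  The module scales profiles to [0, 1],
derives kinetic features (area under the curve, order-2 polynomial fit),
clusters profiles by fuzzy c-means, and labels cluster centroids with
kinetic archetypes (sustained increase, transient, decreased).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

#: The fixed stimulation time axis, in minutes.
TIMEPOINTS_MIN = np.array([0.0, 0.25, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 60.0])

N_TIMEPOINTS = len(TIMEPOINTS_MIN)


@dataclass
class TimeCourseProfile:
    """Replicate-level log2 ratios on the fixed 9-point time axis.

    ``replicate_log2`` has shape (9, n_replicates) with NaN marking a
    value not quantified in that replicate.  ``log2_ratios`` is the
    per-timepoint median over quantified replicates (NaN where no
    replicate was quantified).
    """

    replicate_log2: np.ndarray
    timepoints_min: np.ndarray = field(
        default_factory=lambda: TIMEPOINTS_MIN.copy()
    )

    def __post_init__(self) -> None:
        self.replicate_log2 = np.asarray(self.replicate_log2, dtype=float)
        if self.replicate_log2.ndim == 1:
            self.replicate_log2 = self.replicate_log2[:, None]
        if self.replicate_log2.shape[0] != len(self.timepoints_min):
            raise ValueError(
                "replicate_log2 must have one row per timepoint "
                f"({len(self.timepoints_min)}), got shape "
                f"{self.replicate_log2.shape}"
            )

    @property
    def log2_ratios(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmedian(self.replicate_log2, axis=1)

    @property
    def n_missing_timepoints(self) -> int:
        return int(np.isnan(self.log2_ratios).sum())


def interpolate_missing(
    log2_ratios: np.ndarray, timepoints_min: np.ndarray | None = None
) -> np.ndarray:
    """Fill missing (NaN) timepoints by linear interpolation in real time.

    Values outside the quantified range are clamped to the nearest
    quantified value.  Requires at least 2 quantified points.
    """
    y = np.asarray(log2_ratios, dtype=float)
    t = TIMEPOINTS_MIN if timepoints_min is None else np.asarray(timepoints_min)
    ok = np.isfinite(y)
    if ok.sum() < 2:
        raise ValueError("need at least 2 quantified timepoints to interpolate")
    if ok.all():
        return y.copy()
    return np.interp(t, t[ok], y[ok])


def scale_profile(
    log2_ratios: np.ndarray, timepoints_min: np.ndarray | None = None
) -> tuple[np.ndarray, bool]:
    """Min-max scale a profile to [0, 1] after interpolating missing points.

    Returns ``(scaled, degenerate)``.  A constant profile carries no
    kinetic information; it is mapped to all-0.5 and flagged degenerate.
    """
    y = interpolate_missing(log2_ratios, timepoints_min)
    lo, hi = y.min(), y.max()
    if hi - lo < 1e-12:
        return np.full_like(y, 0.5), True
    return (y - lo) / (hi - lo), False


def compute_auc(
    scaled: np.ndarray, timepoints_min: np.ndarray | None = None
) -> float:
    """Trapezoidal area under a scaled profile over normalized time.

    Time is normalized by the final timepoint (60 min -> 1.0), so an
    all-ones profile has AUC exactly 1 and any scaled profile falls in
    [0, 1].  The real (strongly non-uniform) time axis is used, so early
    timepoints contribute little area.
    """
    t = TIMEPOINTS_MIN if timepoints_min is None else np.asarray(timepoints_min)
    t_norm = t / t.max()
    return float(np.trapezoid(np.asarray(scaled, dtype=float), t_norm))


def fit_poly2(
    scaled: np.ndarray, timepoints_min: np.ndarray | None = None
) -> np.ndarray:
    """Least-squares quadratic fit to a scaled profile.

    Time is normalized to [0, 1].  Coefficients are returned
    highest-degree first, ``(a2, a1, a0)``; a constant profile at 0.5
    yields (0, 0, 0.5).
    """
    t = TIMEPOINTS_MIN if timepoints_min is None else np.asarray(timepoints_min)
    t_norm = t / t.max()
    return np.polyfit(t_norm, np.asarray(scaled, dtype=float), 2)


@dataclass
class ClusterModel:
    """Fitted fuzzy c-means model.

    memberships rows sum to 1; ``objective_history`` records the fuzzy
    objective sum(u^m d^2) once per iteration and is non-increasing.
    """

    n_clusters: int
    fuzzifier: float
    centroids: np.ndarray
    memberships: np.ndarray
    objective_history: list[float]
    n_iter: int
    converged: bool
    seed: int | None = None

    @property
    def hard_labels(self) -> np.ndarray:
        return np.argmax(self.memberships, axis=1)


def _fcm_memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Bezdek membership update u_ik = 1 / sum_j (d_ik/d_jk)^(2/(m-1))."""
    zero_rows = (d2 <= 1e-300).any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-1.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
    if zero_rows.any():
        # coincident point/centroid: full membership split over the
        # zero-distance centroids (standard singularity rule)
        for i in np.where(zero_rows)[0]:
            z = d2[i] <= 1e-300
            u[i] = z / z.sum()
    return u


def fuzzy_cmeans(
    profiles: np.ndarray,
    n_clusters: int = 18,
    fuzzifier: float = 2.0,
    tolerance: float = 1e-6,
    max_iter: int = 300,
    seed: int | None = None,
) -> ClusterModel:
    """Fuzzy c-means clustering of scaled temporal profiles.

    Standard alternating Bezdek updates under squared Euclidean
    distance: memberships from centroid distances, then weighted
    centroids, until the largest centroid coordinate change falls below
    ``tolerance``.  Initial centroids are drawn uniformly inside the
    per-dimension bounding box of the data, which makes the result
    deterministic for a fixed seed and exactly invariant (up to noise in
    the data itself) to the ordering of the input rows.
    """
    x = np.asarray(profiles, dtype=float)
    if x.ndim != 2:
        raise ValueError("profiles must be a 2-D array")
    n, d = x.shape
    if n < n_clusters:
        raise ValueError(f"need at least {n_clusters} profiles, got {n}")
    if fuzzifier <= 1.0:
        raise ValueError("fuzzifier must be > 1")
    rng = np.random.default_rng(seed)
    lo, hi = x.min(axis=0), x.max(axis=0)
    centroids = lo + rng.random((n_clusters, d)) * (hi - lo)

    history: list[float] = []
    converged = False
    u = None
    it = 0
    for it in range(1, max_iter + 1):
        d2 = cdist(x, centroids, "sqeuclidean")
        u = _fcm_memberships(d2, fuzzifier)
        history.append(float((u**fuzzifier * d2).sum()))
        w = u**fuzzifier
        new_centroids = (w.T @ x) / w.sum(axis=0)[:, None]
        shift = np.abs(new_centroids - centroids).max()
        centroids = new_centroids
        if shift < tolerance:
            converged = True
            break
    return ClusterModel(
        n_clusters=n_clusters,
        fuzzifier=fuzzifier,
        centroids=centroids,
        memberships=u,
        objective_history=history,
        n_iter=it,
        converged=converged,
        seed=seed,
    )


SHAPE_SUSTAINED = "sustained_increase"
SHAPE_TRANSIENT = "transient"
SHAPE_DECREASED = "decreased"
SHAPE_OTHER = "other"


def label_cluster_shape(
    centroid: np.ndarray, timepoints_min: np.ndarray | None = None
) -> str:
    """Assign a kinetic archetype to one centroid on the scaled [0,1] axis.

    sustained increase: the final value holds >= 60% of the maximum and
    the post-1-min maximum rises >= 0.3 above the initial value;
    decreased: the final value drops > 0.3 below the initial value;
    transient: the peak occurs after t=0 but before 5 min and the final
    value has fallen to <= 40% of the peak.  Decreased is tested before
    transient because a monotone decay also peaks "before 5 min" (at
    t=0); requiring the transient peak to be interior disambiguates the
    two, and anything else (e.g. flat) is "other".
    """
    c = np.asarray(centroid, dtype=float)
    t = TIMEPOINTS_MIN if timepoints_min is None else np.asarray(timepoints_min)
    initial, final = c[0], c[-1]
    cmax = c.max()
    t_peak = t[int(np.argmax(c))]
    late_max = c[t >= 1.0].max()
    if final >= 0.6 * cmax and late_max - initial >= 0.3:
        return SHAPE_SUSTAINED
    if final < initial - 0.3:
        return SHAPE_DECREASED
    if 0.0 < t_peak < 5.0 and final <= 0.4 * cmax:
        return SHAPE_TRANSIENT
    return SHAPE_OTHER


def label_cluster_shapes(
    centroids: np.ndarray, timepoints_min: np.ndarray | None = None
) -> list[str]:
    """Shape label for every centroid row."""
    return [label_cluster_shape(c, timepoints_min) for c in centroids]


def cluster_profiles(
    scaled_profiles: np.ndarray,
    n_clusters: int = 18,
    fuzzifier: float = 2.0,
    tolerance: float = 1e-6,
    max_iter: int = 300,
    seed: int | None = None,
) -> tuple[ClusterModel, np.ndarray, list[str]]:
    """Cluster scaled profiles; return (model, hard labels, shape per site).

    The per-site shape is the shape label of its maximum-membership
    cluster's centroid.
    """
    model = fuzzy_cmeans(
        scaled_profiles,
        n_clusters=n_clusters,
        fuzzifier=fuzzifier,
        tolerance=tolerance,
        max_iter=max_iter,
        seed=seed,
    )
    shapes = label_cluster_shapes(model.centroids)
    hard = model.hard_labels
    return model, hard, [shapes[k] for k in hard]
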