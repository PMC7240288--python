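"""SD_BOLD computation: from a minimally preprocessed 4-D series to a
gray-matter map of temporal BOLD variability.

The fixed pipeline order is::

    bandpass -> polynomial detrend -> noise-component removal
             -> grand-mean scaling -> gray-matter mask -> voxelwise SD

Temporal SD is translation-invariant, so the mean-deviation step changes
nothing numerically; it is kept explicit because the map is defined on
deviation series.  Grand-mean scaling (one scalar per subject) makes maps
comparable across subjects without disturbing their temporal SD structure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from scipy.linalg import qr as scipy_qr

logger = logging.getLogger("boldvar")


class VariabilityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# containers


@dataclass
class BoldSeries:
    """One subject's 4-D voxel time series (x, y, z, t)."""

    data: np.ndarray
    tr_seconds: float
    subject_id: str = ""
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise VariabilityError("BOLD series must be 4-D (x, y, z, t)")
        if self.data.shape[3] < 2:
            raise VariabilityError("need at least 2 timepoints")
        if self.tr_seconds <= 0:
            raise VariabilityError("tr_seconds must be positive")
        if not np.all(np.isfinite(self.data)):
            raise VariabilityError("series contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        return BoldSeries(data, self.tr_seconds, self.subject_id, self.affine)


@dataclass
class BrainMask:
    data: np.ndarray  # boolean 3-D
    source: str = "whole_brain"  # {gm_threshold, region_label, whole_brain}

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise VariabilityError("mask must be 3-D")
        if not self.data.any():
            raise VariabilityError("mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class ComponentSet:
    """ICA decomposition of a run: spatial maps and time courses.

    Component estimation itself is pluggable machinery (any matrix
    factorization with this layout works); only classification and removal
    are part of the pipeline proper.
    """

    spatial_maps: np.ndarray  # (n_components, n_voxels_in_mask)
    time_courses: np.ndarray  # (n_components, t)
    labels: list[set] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.spatial_maps = np.asarray(self.spatial_maps, dtype=float)
        self.time_courses = np.asarray(self.time_courses, dtype=float)
        if self.spatial_maps.shape[0] != self.time_courses.shape[0]:
            raise VariabilityError("spatial maps and time courses disagree on count")
        if not self.labels:
            self.labels = [set() for _ in range(self.spatial_maps.shape[0])]


@dataclass
class SDBoldMap:
    """Per-voxel temporal SD, defined inside the mask, NaN outside."""

    data: np.ndarray
    mask: BrainMask
    subject_id: str = ""

    def __post_init__(self) -> None:
        inside = self.data[self.mask.data]
        if np.any(inside < 0):
            raise VariabilityError("negative SD inside mask")

    def values(self) -> np.ndarray:
        """In-mask SD values as a flat vector (C order of the mask)."""
        return self.data[self.mask.data]


@dataclass
class MotionSummary:
    mean_absolute_mm: float
    mean_relative_mm: float
    max_absolute_mm: float
    max_relative_mm: float
    passed: bool


@dataclass
class ComponentThresholds:
    """Quantitative artifact-classification thresholds.

    spike: any time-course point >= ``spike_sd`` SDs from the mean.
    high_frequency: >= ``hf_power_fraction`` of (DC-excluded) periodogram
    power above ``hf_cutoff_hz``.
    spotty: above-threshold support (|z| >= ``spatial_z``) covering
    >= ``spotty_fraction`` of in-mask voxels with no 26-connected cluster of
    >= ``min_cluster_voxels``.
    """

    spike_sd: float = 6.0
    hf_cutoff_hz: float = 0.13
    hf_power_fraction: float = 0.75
    spatial_z: float = 2.0
    spotty_fraction: float = 0.25
    min_cluster_voxels: int = 10


# ---------------------------------------------------------------------------
# temporal filtering


def bandpass(series: BoldSeries, low_hz: float = 0.01, high_hz: float = 0.1) -> BoldSeries:
    """Zero-phase 4th-order Butterworth band-pass along the time axis."""
    nyq = 1.0 / (2.0 * series.tr_seconds)
    if not (0.0 < low_hz < high_hz):
        raise VariabilityError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise VariabilityError(f"high_hz={high_hz} must be below Nyquist ({nyq})")
    sos = signal.butter(4, [low_hz, high_hz], btype="bandpass",
                        fs=1.0 / series.tr_seconds, output="sos")
    out = signal.sosfiltfilt(sos, series.data, axis=3)
    return series.with_data(out)


def detrend_poly(series: BoldSeries, order: int = 2) -> BoldSeries:
    """Remove the per-voxel least-squares polynomial (in time) of given order.

    The residual is orthogonal to the polynomial basis, so the operation is
    idempotent and absorbs any added polynomial trend of the same order.
    """
    if order not in (1, 2):
        raise VariabilityError("detrend order must be 1 or 2")
    t = series.n_timepoints
    if t <= order + 1:
        raise VariabilityError(f"need more than {order + 1} timepoints for order {order}")
    x = np.linspace(-1.0, 1.0, t)
    B = np.vander(x, order + 1, increasing=True)  # well-conditioned on [-1, 1]
    flat = series.data.reshape(-1, t).T  # (t, v)
    coef, *_ = np.linalg.lstsq(B, flat, rcond=None)
    resid = (flat - B @ coef).T.reshape(series.data.shape)
    return series.with_data(resid)


# ---------------------------------------------------------------------------
# ICA component classification and removal


def _power_fraction_high(tc: np.ndarray, tr: float, cutoff_hz: float) -> float:
    f, p = signal.periodogram(tc, fs=1.0 / tr)
    keep = f > 0  # exclude DC
    total = p[keep].sum()
    if total <= 0:
        return 0.0
    return float(p[keep & (f > cutoff_hz)].sum() / total)


def classify_component(time_course: np.ndarray,
                       spatial_map: np.ndarray | None = None,
                       mask: BrainMask | None = None,
                       tr_seconds: float = 2.0,
                       thresholds: ComponentThresholds | None = None) -> set:
    """Flag one ICA component with quantitative artifact criteria.

    Returns a subset of {"spike", "high_frequency", "spotty"}.  The spatial
    criterion needs both a spatial map (values over in-mask voxels) and the
    mask volume for connectivity; without them it is skipped.  Criteria that
    require human visual judgment (motion ringing, susceptibility, white
    matter/ventricle patterns, drift) are out of scope here.
    """
    th = thresholds or ComponentThresholds()
    tc = np.asarray(time_course, dtype=float)
    if tc.size < 8:
        raise VariabilityError("component time course needs >= 8 timepoints")
    flags: set = set()

    sd = tc.std(ddof=1)
    if sd > 0 and np.any(np.abs(tc - tc.mean()) >= th.spike_sd * sd):
        flags.add("spike")

    if _power_fraction_high(tc, tr_seconds, th.hf_cutoff_hz) >= th.hf_power_fraction:
        flags.add("high_frequency")

    if spatial_map is not None and mask is not None and spatial_map.size:
        # spatial maps follow the MELODIC convention of already being
        # z-statistic images; they are thresholded directly.  (A
        # self-standardized binary map could never put >= 25% of its mass
        # beyond 2 SD, so re-scoring here would make the criterion void.)
        z = np.asarray(spatial_map, dtype=float)
        if z.std() > 0:
            support = np.abs(z) >= th.spatial_z
            frac = support.mean()
            if frac >= th.spotty_fraction:
                vol = np.zeros(mask.data.shape, dtype=bool)
                vol[mask.data] = support
                labeled, n = ndimage.label(vol, structure=np.ones((3, 3, 3)))
                if n == 0 or np.bincount(labeled.ravel())[1:].max() < th.min_cluster_voxels:
                    flags.add("spotty")
    return flags


def classify_components(comps: ComponentSet, mask: BrainMask | None,
                        tr_seconds: float,
                        thresholds: ComponentThresholds | None = None) -> ComponentSet:
    """Classify every component; stores and returns the flag sets."""
    comps.labels = [
        classify_component(comps.time_courses[i], comps.spatial_maps[i],
                           mask, tr_seconds, thresholds)
        for i in range(comps.time_courses.shape[0])
    ]
    return comps


def regress_out(series: BoldSeries, noise_time_courses: np.ndarray) -> BoldSeries:
    """Remove the OLS projection onto noise time courses (plus intercept).

    A rank-deficient noise design drops the dependent columns with a
    warning rather than failing.
    """
    tcs = np.atleast_2d(np.asarray(noise_time_courses, dtype=float))
    t = series.n_timepoints
    if tcs.shape[1] != t:
        raise VariabilityError("noise time courses must match series length")
    D = np.column_stack([np.ones(t), tcs.T])
    # drop linearly dependent columns via pivoted QR
    _, R, piv = scipy_qr(D, pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > diag[0] * 1e-10).sum())
    if rank < D.shape[1]:
        warnings.warn(f"noise design rank-deficient; dropping "
                      f"{D.shape[1] - rank} dependent column(s)", stacklevel=2)
        D = D[:, np.sort(piv[:rank])]
    flat = series.data.reshape(-1, t).T
    coef, *_ = np.linalg.lstsq(D, flat, rcond=None)
    resid = (flat - D @ coef).T.reshape(series.data.shape)
    return series.with_data(resid)


def remove_flagged_components(series: BoldSeries, comps: ComponentSet) -> BoldSeries:
    """Regress out only components carrying at least one artifact flag.

    Classification is conservative: a component with no flag is kept, no
    matter how ambiguous it looks.
    """
    bad = [i for i, f in enumerate(comps.labels) if f]
    if not bad:
        return series
    return regress_out(series, comps.time_courses[bad])


# ---------------------------------------------------------------------------
# masking, scaling, SD


def gm_threshold_mask(prob_map: np.ndarray, threshold: float = 0.43) -> BrainMask:
    """Mask of voxels whose gray-matter probability strictly exceeds threshold."""
    p = np.asarray(prob_map, dtype=float)
    if p.min() < 0 or p.max() > 1:
        raise VariabilityError("probability map values must lie in [0, 1]")
    m = p > threshold
    if not m.any():
        raise VariabilityError(f"no gray matter above probability {threshold}")
    return BrainMask(m, source="gm_threshold")


def grand_mean_scale(series: BoldSeries, mask: BrainMask) -> BoldSeries:
    """Scale the whole 4-D array so the in-mask grand mean equals 100.

    One scalar per subject (over all in-mask voxels and timepoints), so the
    temporal SD structure is preserved up to a common factor and the result
    is invariant to positive rescaling of the input.
    """
    if mask.data.shape != series.spatial_shape:
        raise VariabilityError("mask shape does not match series")
    gm = float(series.data[mask.data].mean())
    if gm <= 0:
        raise VariabilityError(f"in-mask grand mean must be positive, got {gm}")
    return series.with_data(series.data * (100.0 / gm))


def compute_sdbold(series: BoldSeries, mask: BrainMask) -> SDBoldMap:
    """Voxelwise temporal SD of the mean-deviation series, inside the mask.

    Each in-mask voxel's temporal mean is subtracted and the sample SD
    (denominator T-1) of the deviations computed.  Outside the mask the map
    is NaN.
    """
    if mask.data.shape != series.spatial_shape:
        raise VariabilityError("mask shape does not match series")
    if series.n_timepoints < 2:
        raise VariabilityError("SD undefined for fewer than 2 timepoints")
    vox = series.data[mask.data]  # (v, t)
    dev = vox - vox.mean(axis=1, keepdims=True)
    sd = dev.std(axis=1, ddof=1)
    out = np.full(series.spatial_shape, np.nan)
    out[mask.data] = sd
    return SDBoldMap(out, mask, series.subject_id)


def motion_qc(abs_mm: np.ndarray, rel_mm: np.ndarray,
              abs_threshold: float = 2.0, rel_threshold: float = 2.5) -> MotionSummary:
    """Summarize a motion trace and apply single-timepoint exclusion rules."""
    a = np.asarray(abs_mm, dtype=float)
    r = np.asarray(rel_mm, dtype=float)
    if a.size == 0 or r.size == 0:
        raise VariabilityError("motion trace is empty")
    if np.any(a < 0) or np.any(r < 0):
        raise VariabilityError("displacements must be non-negative")
    ma, mr = float(a.max()), float(r.max())
    return MotionSummary(float(a.mean()), float(r.mean()), ma, mr,
                         passed=(ma <= abs_threshold and mr <= rel_threshold))


# ---------------------------------------------------------------------------
# ICA adapter and full pipeline


def estimate_components(series: BoldSeries, mask: BrainMask, n_components: int,
                        seed: int | None = 0) -> ComponentSet:
    """Whitened-PCA + fixed-point spatial ICA adapter for testing.

    A thin wrapper around scikit-learn's FastICA producing the
    (spatial maps, time courses) layout the classifier consumes.  Any other
    factorization with the same layout can be plugged in instead.
    """
    from sklearn.decomposition import FastICA

    X = series.data[mask.data]  # (v, t)
    ica = FastICA(n_components=n_components, random_state=seed, max_iter=500)
    maps = ica.fit_transform(X)  # (v, c)
    tcs = ica.mixing_  # (t, c)
    return ComponentSet(spatial_maps=maps.T, time_courses=tcs.T)


def sdbold_pipeline(series: BoldSeries, gm_prob: np.ndarray,
                    gm_threshold: float = 0.43,
                    low_hz: float = 0.01, high_hz: float = 0.1,
                    detrend_order: int = 2,
                    components: ComponentSet | None = None,
                    thresholds: ComponentThresholds | None = None) -> SDBoldMap:
    """Full SD_BOLD chain in the fixed, logged order.

    Band-pass filtering and detrending strip each voxel's temporal mean, so
    the raw mean volume is restored before grand-mean scaling (the scaling
    is defined on signal level, the SD on fluctuations; temporal SD is
    unaffected by the restored constant).
    """
    if series.n_timepoints < 8:
        raise VariabilityError("pipeline needs at least 8 timepoints")
    mean_vol = series.data.mean(axis=3)
    logger.info("sdbold[%s]: bandpass %.3f-%.3f Hz", series.subject_id, low_hz, high_hz)
    s = bandpass(series, low_hz, high_hz)
    logger.info("sdbold[%s]: detrend order %d", series.subject_id, detrend_order)
    s = detrend_poly(s, detrend_order)
    mask = gm_threshold_mask(gm_prob, gm_threshold)
    if components is not None:
        comps = classify_components(components, mask, series.tr_seconds, thresholds)
        n_bad = sum(bool(f) for f in comps.labels)
        logger.info("sdbold[%s]: removing %d flagged component(s)", series.subject_id, n_bad)
        s = remove_flagged_components(s, comps)
    logger.info("sdbold[%s]: grand-mean scaling to 100", series.subject_id)
    s = s.with_data(s.data + mean_vol[..., None])
    s = grand_mean_scale(s, mask)
    logger.info("sdbold[%s]: SD over %d gray-matter voxels", series.subject_id, mask.n_voxels)
    return compute_sdbold(s, mask)
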