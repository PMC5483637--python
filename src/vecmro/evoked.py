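"""Dual-echo task/gas-challenge processing to visual-evoked signals.

The pipeline turns a dual-echo acquisition (interleaved label/control
perfusion echo + BOLD echo) into per-participant visual-evoked measures:

1. despiking of each voxel time series,
2. surround subtraction of the perfusion echo -> CBF-weighted series,
   pairwise temporal averaging of the BOLD echo,
3. spatial Gaussian smoothing,
4. temporal high-pass filtering (task run only),
5. boxcar GLM -> percent-signal-change and t maps,
6. ROI selection (grey-matter PVE >= 80 % within an occipital mask,
   then the overlap of the top task t-values of BOLD and CBF),
7. Davis-model inversion voxelwise inside the ROI.

A gas-challenge run is reduced to window means (room-air baseline vs the
final hypercapnic minutes, with the first post-switch minutes discarded)
whose fractional changes calibrate M.

Temporal operators applied to the data (surround subtraction, pairwise
averaging, high-pass projection) are applied identically to the GLM
regressors, so a noiseless simulated run is recovered exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .davis import (
    DavisParams,
    DEFAULT_PARAMS,
    compute_delta_cmro2,
    compute_n,
    estimate_m_from_changes,
)

__all__ = [
    "DualEchoSeries",
    "TaskDesign",
    "GasProtocol",
    "GasSummary",
    "EvokedMeasures",
    "despike",
    "surround_subtract",
    "bold_pair_average",
    "smooth_gaussian",
    "highpass",
    "boxcar_regressor",
    "surround_regressor",
    "pair_average_regressor",
    "glm_percent_change",
    "grey_matter_mask",
    "functional_roi",
    "gas_roi_and_summary",
    "evoked_measures",
    "process_task_run",
    "process_participant",
    "EmptyROIError",
    "CalibrationFailure",
    "PropagationError",
]

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...

MAD_SCALE = 1.4826


class EmptyROIError(ValueError):
    """Functional ROI came out empty; caller should relax the fraction."""


class CalibrationFailure(ValueError):
    """Gas-challenge ROI empty even at the fallback fraction."""


class PropagationError(ValueError):
    """No ROI voxel admits a valid Davis-model inversion."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class DualEchoSeries:
    """Paired 4D perfusion-echo and BOLD-echo series on one voxel grid.

    perfusion : (x, y, z, t) with label/control volumes interleaved in time
    bold      : (x, y, z, t), same grid and length
    tr        : repetition time in seconds
    label_first : True if the first perfusion volume is a label volume
    voxel_size_mm : spatial voxel dimensions (mm)
    """

    perfusion: np.ndarray
    bold: np.ndarray
    tr: float
    label_first: bool = True
    voxel_size_mm: tuple = (3.44, 3.44, 5.0)

    def __post_init__(self) -> None:
        self.perfusion = np.asarray(self.perfusion, dtype=float)
        self.bold = np.asarray(self.bold, dtype=float)
        if self.perfusion.shape != self.bold.shape:
            raise ValueError(
                "perfusion and BOLD echoes must share grid and length: "
                f"{self.perfusion.shape} vs {self.bold.shape}"
            )
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.perfusion.shape[-1] < 4:
            raise ValueError("need at least 4 volumes")

    @property
    def n_volumes(self) -> int:
        return self.perfusion.shape[-1]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr


@dataclass
class TaskDesign:
    """Block design: onsets (s), one common block duration (s), run length."""

    block_onsets: np.ndarray
    block_duration: float = 60.0
    total_duration: float = 600.0

    def __post_init__(self) -> None:
        self.block_onsets = np.sort(np.asarray(self.block_onsets, dtype=float))
        if self.block_duration <= 0:
            raise ValueError("block_duration must be positive")
        ends = self.block_onsets + self.block_duration
        if np.any(self.block_onsets[1:] < ends[:-1]):
            raise ValueError("task blocks overlap")
        if self.block_onsets.size and ends[-1] > self.total_duration + 1e-9:
            raise ValueError("task design exceeds the run duration")


@dataclass(frozen=True)
class GasProtocol:
    """Timing of the gas challenge (seconds).

    Room air for ``baseline_s``, then hypercapnia for ``hypercapnia_s``;
    the first ``discard_s`` after the switch are dropped to let CBF
    stabilize, and the remainder is averaged.
    """

    baseline_s: float = 240.0
    hypercapnia_s: float = 360.0
    discard_s: float = 120.0

    def __post_init__(self) -> None:
        if min(self.baseline_s, self.hypercapnia_s) <= 0:
            raise ValueError("window durations must be positive")
        if not (0 <= self.discard_s < self.hypercapnia_s):
            raise ValueError("discard_s must lie within the hypercapnia window")


@dataclass
class GasSummary:
    """ROI-level gas-challenge result used to calibrate M."""

    bold_0: float
    bold_hc: float
    cbf_0: float
    cbf_hc: float
    delta_bold_hc: float  # fractional, ROI mean of the voxelwise map
    delta_cbf_hc: float
    m: float  # fraction
    roi_voxels: int
    top_fraction_used: float

    @property
    def m_percent(self) -> float:
        return 100.0 * self.m


@dataclass
class EvokedMeasures:
    """Per-participant visual-evoked signals (percent except ve_n)."""

    ve_bold: float
    ve_cbf: float
    ve_cmro2: float
    ve_n: float
    roi_voxels: int
    n_skipped: int = 0


# ---------------------------------------------------------------------------
# temporal preprocessing


def _running_median3(x: np.ndarray) -> np.ndarray:
    """3-point running median along the last axis; 2-point mean at the ends."""
    med = np.empty_like(x)
    med[..., 1:-1] = np.median(
        np.stack([x[..., :-2], x[..., 1:-1], x[..., 2:]], axis=0), axis=0
    )
    med[..., 0] = 0.5 * (x[..., 0] + x[..., 1])
    med[..., -1] = 0.5 * (x[..., -2] + x[..., -1])
    return med


def despike(series: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Attenuate isolated anomalous samples in voxel time series.

    A sample is a spike when its deviation from the 3-point running
    median exceeds ``k`` robust standard deviations (1.4826 x median
    absolute residual of that voxel's series).  Spikes are replaced by
    the mean of their temporal neighbours.  Works along the last axis of
    any-dimensional input; constant series pass through unchanged, as do
    clean block/alternating series whose running-median residual is zero.
    """
    x = np.asarray(series, dtype=float)
    if x.shape[-1] < 3:
        raise ValueError("need at least 3 time points to despike")
    resid = x - _running_median3(x)
    scale = MAD_SCALE * np.median(np.abs(resid), axis=-1, keepdims=True)
    cutoff = np.where(scale > 0, k * scale, 0.0)
    spikes = np.abs(resid) > cutoff

    neighbor = np.empty_like(x)
    neighbor[..., 1:-1] = 0.5 * (x[..., :-2] + x[..., 2:])
    neighbor[..., 0] = x[..., 1]
    neighbor[..., -1] = x[..., -2]
    return np.where(spikes, neighbor, x)


def _parity_signs(n: int, label_first: bool) -> np.ndarray:
    """+1 at control volumes, -1 at label volumes, so output = control - label."""
    signs = np.ones(n)
    if label_first:
        signs[0::2] = -1.0
    else:
        signs[1::2] = -1.0
    return signs


def surround_subtract(perfusion: np.ndarray, label_first: bool = True) -> np.ndarray:
    """Surround subtraction of an interleaved label/control series.

    output_t = s_t * (x_t - (x_{t-1} + x_{t+1}) / 2) with the parity sign
    s_t chosen so the result is (control - label) >= 0 for true perfusion;
    the endpoints use their single neighbour.  Linear drift shared by
    label and control cancels exactly at interior points.
    """
    x = np.asarray(perfusion, dtype=float)
    n = x.shape[-1]
    if n < 3:
        raise ValueError("surround subtraction needs at least 3 volumes")
    out = np.empty_like(x)
    out[..., 1:-1] = x[..., 1:-1] - 0.5 * (x[..., :-2] + x[..., 2:])
    out[..., 0] = x[..., 0] - x[..., 1]
    out[..., -1] = x[..., -1] - x[..., -2]
    return out * _parity_signs(n, label_first)


def bold_pair_average(bold: np.ndarray) -> np.ndarray:
    """Pairwise average of temporally adjacent volumes (removes L/C ripple).

    output_t = (x_t + x_{t+1}) / 2 for t < T-1; the last volume is carried.
    """
    x = np.asarray(bold, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("pairwise averaging needs at least 2 volumes")
    out = np.empty_like(x)
    out[..., :-1] = 0.5 * (x[..., :-1] + x[..., 1:])
    out[..., -1] = x[..., -1]
    return out


def smooth_gaussian(
    volumes: np.ndarray, fwhm_mm: float, voxel_size_mm=(3.44, 3.44, 5.0)
) -> np.ndarray:
    """Separable spatial Gaussian smoothing of a 3D volume or 4D series."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return np.asarray(volumes, dtype=float).copy()
    x = np.asarray(volumes, dtype=float)
    sigma_vox = [fwhm_mm / FWHM_TO_SIGMA / v for v in voxel_size_mm]
    if x.ndim == 4:
        sigma = sigma_vox + [0.0]
    elif x.ndim == 3:
        sigma = sigma_vox
    else:
        raise ValueError("expected a 3D volume or 4D series")
    return ndimage.gaussian_filter(x, sigma=sigma, mode="nearest")


def _highpass_basis(n: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """Orthonormal, exactly zero-mean low-frequency subspace to project out.

    Built from the first round(2 * NW) Slepian (DPSS) sequences with
    time-half-bandwidth NW = 0.85 * cutoff * n * tr — the subspace
    maximally concentrated at low frequency, taken slightly narrower
    than the nominal cutoff so that the worst-phase passband ripple
    stays below 5 % — demeaned so that constants (the series baseline)
    pass through the projection untouched.  The resulting high-pass
    attenuates sinusoids below ~0.8 x cutoff by >= 90 % at every phase
    and loses < 5 % at 2.7 x cutoff and above (a finite-window filter
    necessarily has a transition band around the cutoff).
    """
    from scipy.signal.windows import dpss

    nw = 0.85 * cutoff_hz * n * tr
    k = int(round(2.0 * nw))
    if k < 1:
        return np.empty((n, 0))
    tapers = dpss(n, max(nw, 0.5), Kmax=min(k, n - 1))
    b = tapers.T - tapers.T.mean(axis=0)
    q, r = np.linalg.qr(b)
    keep = np.abs(np.diag(r)) > 1e-8 * np.abs(np.diag(r)).max()
    return q[:, keep]


def highpass(series: np.ndarray, cutoff_hz: float, tr: float) -> np.ndarray:
    """Temporal high-pass projection along the last axis.

    Removes the low-frequency Slepian subspace below ``cutoff_hz``; the
    basis is exactly zero-mean, so the series baseline (mean) is
    preserved.  The operator is linear, which lets the same projection
    be applied to the GLM regressors.
    """
    x = np.asarray(series, dtype=float)
    n = x.shape[-1]
    nyquist = 0.5 / tr
    if not (0 < cutoff_hz < nyquist):
        raise ValueError(f"cutoff must be in (0, {nyquist}) Hz")
    basis = _highpass_basis(n, tr, cutoff_hz)
    if basis.shape[1] == 0:
        return x.copy()
    coeffs = x @ basis  # (..., K)
    return x - coeffs @ basis.T


# ---------------------------------------------------------------------------
# GLM


def boxcar_regressor(design: TaskDesign, n_volumes: int, tr: float) -> np.ndarray:
    """Unit boxcar sampled per volume as fractional overlap with task blocks."""
    starts = np.arange(n_volumes) * tr
    ends = starts + tr
    reg = np.zeros(n_volumes)
    for onset in design.block_onsets:
        off = onset + design.block_duration
        reg += np.clip(np.minimum(ends, off) - np.maximum(starts, onset), 0, None) / tr
    return np.clip(reg, 0.0, 1.0)


def surround_regressor(u: np.ndarray, label_first: bool = True) -> np.ndarray:
    """Boxcar resampled the way surround subtraction resamples perfusion data.

    Surround subtraction of a series whose label volumes are depressed by
    d0*(1 + delta*u_t) returns d0 + d0*delta*K(u); this builds K(u) by
    running the same operator on a synthetic unit-difference series.
    """
    u = np.asarray(u, dtype=float)
    z = np.zeros_like(u)
    labels = slice(0, None, 2) if label_first else slice(1, None, 2)
    z[labels] = -u[labels]
    return surround_subtract(z, label_first=label_first)


def pair_average_regressor(u: np.ndarray) -> np.ndarray:
    """Boxcar passed through the same pairwise averaging as the BOLD data."""
    return bold_pair_average(np.asarray(u, dtype=float))


def glm_percent_change(series: np.ndarray, regressor: np.ndarray):
    """Two-column GLM [intercept, regressor]; percent change and t-statistic.

    Returns ``(pct, t)`` where pct = 100 * beta_task / beta_intercept.
    Vectorized over leading axes (the time axis is last).  Zero-residual
    fits get t = +/-inf (sign of the effect) so ROI ranking still works;
    an exactly constant fit gets t = 0.
    """
    y = np.asarray(series, dtype=float)
    reg = np.asarray(regressor, dtype=float)
    n = y.shape[-1]
    if reg.shape != (n,):
        raise ValueError("regressor length must match the series")
    if np.ptp(reg) == 0:
        raise ValueError("zero-variance task regressor")
    x = np.stack([np.ones(n), reg], axis=1)  # (n, 2)
    xtx = x.T @ x
    xtx_inv = np.linalg.inv(xtx)
    beta = y @ x @ xtx_inv.T  # (..., 2)
    resid = y - beta @ x.T
    dof = n - 2
    sigma2 = np.sum(resid**2, axis=-1) / dof
    var_b1 = sigma2 * xtx_inv[1, 1]
    b0, b1 = beta[..., 0], beta[..., 1]
    b1_null = np.abs(b1) <= 1e-9 * (np.abs(b0) + 1.0)  # numerically zero slope
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(
            var_b1 > 0,
            b1 / np.sqrt(np.where(var_b1 > 0, var_b1, 1.0)),
            np.where(b1_null, 0.0, np.sign(b1) * np.inf),
        )
        pct = np.where(b0 > 0, 100.0 * b1 / np.where(b0 != 0, b0, 1.0), np.nan)
    if pct.ndim == 0:
        return float(pct), float(t)
    return pct, t


# ---------------------------------------------------------------------------
# ROIs


def grey_matter_mask(pve_gm: np.ndarray, threshold: float = 0.80) -> np.ndarray:
    """Grey-matter mask from a partial-volume map (inclusive >= threshold)."""
    pve = np.asarray(pve_gm, dtype=float)
    if np.any((pve < 0) | (pve > 1)):
        raise ValueError("partial-volume estimates must lie in [0, 1]")
    return pve >= threshold


def functional_roi(
    t_bold: np.ndarray,
    t_cbf: np.ndarray,
    structural_mask: np.ndarray,
    top_fraction: float = 0.05,
) -> np.ndarray:
    """Overlap of the top-fraction BOLD and CBF t-values within a mask.

    Each map is thresholded at its (1 - top_fraction) quantile over
    in-mask voxels, ties at the threshold included; the ROI is the
    intersection.  Raises :class:`EmptyROIError` when the intersection is
    empty.
    """
    mask = np.asarray(structural_mask, dtype=bool)
    if not mask.any():
        raise ValueError("structural mask is empty")
    if not (0 < top_fraction < 1):
        raise ValueError("top_fraction must be in (0, 1)")
    roi = mask.copy()
    for tmap in (t_bold, t_cbf):
        vals = np.asarray(tmap, dtype=float)[mask]
        finite = vals[np.isfinite(vals)]
        if finite.size == 0:  # all +/-inf: a quantile over infs is inf
            thr = np.inf if np.all(vals == np.inf) else -np.inf
        elif finite.size < vals.size:
            # put infs beyond the finite range so the quantile is well defined
            hi = finite.max() + 1.0
            lo = finite.min() - 1.0
            vals = np.clip(vals, lo, hi)
            thr = np.quantile(vals, 1.0 - top_fraction)
            thr = -np.inf if thr <= lo else thr
        else:
            thr = np.quantile(vals, 1.0 - top_fraction)
        tvals = np.asarray(tmap, dtype=float)
        roi &= np.where(np.isnan(tvals), -np.inf, tvals) >= thr
    if not roi.any():
        raise EmptyROIError(
            f"no voxel is in the top {top_fraction:.0%} of both maps; "
            "relax top_fraction"
        )
    return roi


# ---------------------------------------------------------------------------
# gas challenge


def _window_indices(times: np.ndarray, start: float, stop: float) -> np.ndarray:
    """Volume indices in [start, stop), trimmed by one guard volume per edge.

    The derived series (surround subtraction, pairwise averaging) mix each
    volume with its temporal neighbours, so one volume adjacent to every
    window boundary is dropped to keep window means uncontaminated.
    """
    idx = np.flatnonzero((times >= start) & (times < stop))
    if idx.size < 4:
        raise ValueError("gas window too short")
    return idx[1:-1]


def gas_roi_and_summary(
    gas: DualEchoSeries,
    structural_mask: np.ndarray,
    protocol: GasProtocol = GasProtocol(),
    top_fraction: float = 0.15,
    fallback_fraction: float = 0.20,
    min_voxels: int = 10,
    params: DavisParams = DEFAULT_PARAMS,
    fwhm_mm: float = 8.0,
    despike_k: float = 3.0,
) -> GasSummary:
    """Reduce a gas-challenge run to ROI means and the calibration constant M.

    Baseline means are taken over the room-air window and hypercapnic
    means over the post-discard window; per-voxel fractional-change maps
    select the ROI (overlap of the top ``top_fraction`` of each map inside
    the structural mask, escalated to ``fallback_fraction`` when the
    overlap is smaller than ``min_voxels``), and M is computed from the
    ROI-mean fractional changes.
    """
    total = protocol.baseline_s + protocol.hypercapnia_s
    if gas.n_volumes * gas.tr + 1e-9 < total:
        raise ValueError("gas run shorter than the protocol requires")
    mask = np.asarray(structural_mask, dtype=bool)
    if not mask.any():
        raise ValueError("structural mask is empty")

    perf = despike(gas.perfusion, k=despike_k)
    bold = despike(gas.bold, k=despike_k)
    cbf_series = surround_subtract(perf, label_first=gas.label_first)
    bold_series = bold_pair_average(bold)
    cbf_series = smooth_gaussian(cbf_series, fwhm_mm, gas.voxel_size_mm)
    bold_series = smooth_gaussian(bold_series, fwhm_mm, gas.voxel_size_mm)

    times = gas.frame_times
    base_idx = _window_indices(times, 0.0, protocol.baseline_s)
    hc_idx = _window_indices(
        times, protocol.baseline_s + protocol.discard_s, total
    )

    bold_0_map = bold_series[..., base_idx].mean(axis=-1)
    bold_hc_map = bold_series[..., hc_idx].mean(axis=-1)
    cbf_0_map = cbf_series[..., base_idx].mean(axis=-1)
    cbf_hc_map = cbf_series[..., hc_idx].mean(axis=-1)

    with np.errstate(divide="ignore", invalid="ignore"):
        d_bold = np.where(bold_0_map > 0, (bold_hc_map - bold_0_map) / bold_0_map, np.nan)
        d_cbf = np.where(cbf_0_map > 0, (cbf_hc_map - cbf_0_map) / cbf_0_map, np.nan)

    fraction_used = top_fraction
    try:
        roi = functional_roi(d_bold, d_cbf, mask, top_fraction)
    except EmptyROIError:
        roi = np.zeros_like(mask)
    if roi.sum() < min_voxels:
        fraction_used = fallback_fraction
        try:
            roi = functional_roi(d_bold, d_cbf, mask, fallback_fraction)
        except EmptyROIError as err:
            raise CalibrationFailure(
                "gas ROI empty even at the fallback fraction"
            ) from err

    mean_d_bold = float(np.nanmean(d_bold[roi]))
    mean_d_cbf = float(np.nanmean(d_cbf[roi]))
    m = estimate_m_from_changes(mean_d_bold, mean_d_cbf, params)
    return GasSummary(
        bold_0=float(bold_0_map[roi].mean()),
        bold_hc=float(bold_hc_map[roi].mean()),
        cbf_0=float(cbf_0_map[roi].mean()),
        cbf_hc=float(cbf_hc_map[roi].mean()),
        delta_bold_hc=mean_d_bold,
        delta_cbf_hc=mean_d_cbf,
        m=float(m),
        roi_voxels=int(roi.sum()),
        top_fraction_used=fraction_used,
    )


# ---------------------------------------------------------------------------
# evoked measures


def evoked_measures(
    delta_bold_map: np.ndarray,
    delta_cbf_map: np.ndarray,
    roi: np.ndarray,
    m: float,
    params: DavisParams = DEFAULT_PARAMS,
    averaging_mode: str = "voxelwise",
) -> EvokedMeasures:
    """Visual-evoked signals from fractional-change maps inside the ROI.

    ``voxelwise`` (default): dCMRO2 and n are computed per ROI voxel
    (voxels violating dBOLD < M or 1 + dCBF > 0 are skipped with a
    count), then averaged.  ``roi_mean``: the fractional changes are
    averaged first and the Davis inversion applied once.  The two agree
    on uniform maps and differ in general (a mean of ratios is not a
    ratio of means).
    """
    if averaging_mode not in ("voxelwise", "roi_mean"):
        raise ValueError(f"unknown averaging_mode {averaging_mode!r}")
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    if not m > 0:
        raise ValueError("M must be positive")
    d_bold = np.asarray(delta_bold_map, dtype=float)[roi]
    d_cbf = np.asarray(delta_cbf_map, dtype=float)[roi]

    ve_bold = 100.0 * float(d_bold.mean())
    ve_cbf = 100.0 * float(d_cbf.mean())

    if averaging_mode == "roi_mean":
        d_cmro2 = compute_delta_cmro2(d_bold.mean(), d_cbf.mean(), m, params)
        return EvokedMeasures(
            ve_bold=ve_bold,
            ve_cbf=ve_cbf,
            ve_cmro2=100.0 * d_cmro2,
            ve_n=compute_n(d_cbf.mean(), d_cmro2),
            roi_voxels=int(roi.sum()),
        )

    valid = np.isfinite(d_bold) & np.isfinite(d_cbf) & (d_bold < m) & (1.0 + d_cbf > 0)
    n_skipped = int(roi.sum() - valid.sum())
    if not valid.any():
        raise PropagationError("no ROI voxel admits a valid Davis inversion")
    d_cmro2 = compute_delta_cmro2(d_bold[valid], d_cbf[valid], m, params)
    nonzero = d_cmro2 != 0
    ve_n = float((d_cbf[valid][nonzero] / d_cmro2[nonzero]).mean()) if nonzero.any() else np.nan
    return EvokedMeasures(
        ve_bold=ve_bold,
        ve_cbf=ve_cbf,
        ve_cmro2=100.0 * float(d_cmro2.mean()),
        ve_n=ve_n,
        roi_voxels=int(roi.sum()),
        n_skipped=n_skipped,
    )


# ---------------------------------------------------------------------------
# orchestration


def process_task_run(
    task: DualEchoSeries,
    design: TaskDesign,
    fwhm_mm: float = 8.0,
    highpass_hz: float = 0.0039,
    despike_k: float = 3.0,
):
    """Task run -> (pct_bold, t_bold, pct_cbf, t_cbf) maps.

    The boxcar regressor for each modality is passed through the same
    temporal operators as the corresponding data (pairwise averaging for
    BOLD, surround-subtraction resampling for CBF, then the high-pass
    projection), which keeps the GLM unbiased by the preprocessing.
    """
    perf = despike(task.perfusion, k=despike_k)
    bold = despike(task.bold, k=despike_k)
    cbf_series = surround_subtract(perf, label_first=task.label_first)
    bold_series = bold_pair_average(bold)
    cbf_series = smooth_gaussian(cbf_series, fwhm_mm, task.voxel_size_mm)
    bold_series = smooth_gaussian(bold_series, fwhm_mm, task.voxel_size_mm)
    cbf_series = highpass(cbf_series, highpass_hz, task.tr)
    bold_series = highpass(bold_series, highpass_hz, task.tr)

    u = boxcar_regressor(design, task.n_volumes, task.tr)
    reg_bold = highpass(pair_average_regressor(u), highpass_hz, task.tr)
    reg_cbf = highpass(surround_regressor(u, task.label_first), highpass_hz, task.tr)

    pct_bold, t_bold = glm_percent_change(bold_series, reg_bold)
    pct_cbf, t_cbf = glm_percent_change(cbf_series, reg_cbf)
    return pct_bold, t_bold, pct_cbf, t_cbf


def process_participant(
    task: DualEchoSeries,
    gas: DualEchoSeries,
    gm_pve: np.ndarray,
    occipital_mask: np.ndarray,
    design: TaskDesign,
    protocol: GasProtocol = GasProtocol(),
    params: DavisParams = DEFAULT_PARAMS,
    gm_threshold: float = 0.80,
    task_top_fraction: float = 0.05,
    gas_top_fraction: float = 0.15,
    gas_fallback_fraction: float = 0.20,
    gas_min_voxels: int = 10,
    fwhm_mm: float = 8.0,
    highpass_hz: float = 0.0039,
    despike_k: float = 3.0,
    averaging_mode: str = "voxelwise",
):
    """Full per-participant analysis -> (EvokedMeasures, GasSummary).

    All volumes must already share one voxel grid (registration is
    assumed done upstream); a grid mismatch is a hard error.
    """
    gm_pve = np.asarray(gm_pve, dtype=float)
    occ = np.asarray(occipital_mask, dtype=bool)
    grid = task.perfusion.shape[:3]
    for name, vol in (("gm_pve", gm_pve), ("occipital_mask", occ)):
        if vol.shape != grid:
            raise ValueError(
                f"{name} grid {vol.shape} does not match the functional grid {grid}"
            )
    if gas.perfusion.shape[:3] != grid:
        raise ValueError("gas run is not on the functional grid")

    structural = occ & grey_matter_mask(gm_pve, gm_threshold)
    if not structural.any():
        raise ValueError("structural ROI (occipital & GM) is empty")

    pct_bold, t_bold, pct_cbf, t_cbf = process_task_run(
        task, design, fwhm_mm=fwhm_mm, highpass_hz=highpass_hz, despike_k=despike_k
    )
    roi = functional_roi(t_bold, t_cbf, structural, task_top_fraction)
    gas_summary = gas_roi_and_summary(
        gas,
        structural,
        protocol=protocol,
        top_fraction=gas_top_fraction,
        fallback_fraction=gas_fallback_fraction,
        min_voxels=gas_min_voxels,
        params=params,
        fwhm_mm=fwhm_mm,
        despike_k=despike_k,
    )
    measures = evoked_measures(
        pct_bold / 100.0,
        pct_cbf / 100.0,
        roi,
        gas_summary.m,
        params=params,
        averaging_mode=averaging_mode,
    )
    return measures, gas_summary
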