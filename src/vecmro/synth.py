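"""Synthetic dual-echo runs, lesion phantoms, and participant tables.

Every generator is deterministic under a fixed seed and returns its
ground truth alongside the data, so the processing pipeline can be
tested for exact recovery.  The signal models are deliberately simple:

* the perfusion echo is an additive control-minus-label difference
  (no kinetic model) because the pipeline only ever uses relative
  change of that difference;
* the BOLD echo is a baseline scaled by (1 + dBOLD * boxcar);
* noise is additive white Gaussian, parameterised by a contrast-to-noise
  ratio ``snr`` = (task- or gas-induced signal-change amplitude) /
  (noise SD), per echo;
* predictor tables draw per-group normal values at specified means/SDs
  (a log-normal option exercises the robust outlier screens).

Default group statistics for the cfMRI predictors are the study-scale
values (group means with SD = SEM * sqrt(n) for n = 10 MS / 13 HC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .davis import forward_bold, DavisParams, DEFAULT_PARAMS
from .evoked import DualEchoSeries, TaskDesign, GasProtocol, boxcar_regressor

__all__ = [
    "GroundTruth",
    "make_task_design",
    "make_task_run",
    "make_gas_run",
    "make_flair_phantom",
    "make_participant_table",
    "DEFAULT_PREDICTOR_SPEC",
    "REST_JITTERS_S",
]

REST_JITTERS_S = (32.0, 34.0, 36.0, 38.0, 40.0)

# (mean_MS, sd_MS, mean_HC, sd_HC) per predictor; SDs are SEM*sqrt(n)
# for n_MS = 10, n_HC = 13.
DEFAULT_PREDICTOR_SPEC = {
    "veBOLD": (1.12, 0.77 * np.sqrt(10), 1.18, 0.66 * np.sqrt(13)),
    "veCBF": (48.06, 12.58 * np.sqrt(10), 92.68, 17.29 * np.sqrt(13)),
    "veCMRO2": (9.59, 0.90 * np.sqrt(10), 17.85, 1.97 * np.sqrt(13)),
    "ven": (4.08, 0.35 * np.sqrt(10), 4.23, 0.23 * np.sqrt(13)),
    "M": (3.88, 0.48 * np.sqrt(10), 5.11, 0.39 * np.sqrt(13)),
    "CBF response to CO2": (167.48, 19.8 * np.sqrt(10), 146.90, 14.64 * np.sqrt(13)),
}


@dataclass
class GroundTruth:
    """What a generated dataset actually contains."""

    delta_bold: np.ndarray | float | None = None
    delta_cbf: np.ndarray | float | None = None
    m: float | None = None
    design: TaskDesign | None = None
    lesion_spec: list = field(default_factory=list)
    predictor_spec: dict = field(default_factory=dict)


def make_task_design(
    seed: int = 0,
    n_blocks: int = 6,
    block_duration: float = 60.0,
    jitters=REST_JITTERS_S,
) -> TaskDesign:
    """Block design with seeded rest jitters drawn from the allowed set.

    A rest period precedes every block and one closes the run; the total
    duration follows from the draws rather than being forced.
    """
    rng = np.random.default_rng(seed)
    rests = rng.choice(jitters, size=n_blocks + 1)
    onsets = np.cumsum(rests[:-1]) + block_duration * np.arange(n_blocks)
    total = float(onsets[-1] + block_duration + rests[-1])
    return TaskDesign(block_onsets=onsets, block_duration=block_duration, total_duration=total)


def _as_map(value, shape) -> np.ndarray:
    out = np.broadcast_to(np.asarray(value, dtype=float), shape)
    return np.ascontiguousarray(out)


def _interleave(control: np.ndarray, label: np.ndarray, label_first: bool) -> np.ndarray:
    out = np.empty_like(control)
    if label_first:
        out[..., 0::2] = label[..., 0::2]
        out[..., 1::2] = control[..., 1::2]
    else:
        out[..., 0::2] = control[..., 0::2]
        out[..., 1::2] = label[..., 1::2]
    return out


def make_task_run(
    delta_bold=0.02,
    delta_cbf=0.50,
    design: TaskDesign | None = None,
    shape=(8, 8, 4),
    tr: float = 4.0,
    snr: float | None = None,
    seed: int = 0,
    bold_baseline: float = 1000.0,
    perf_baseline: float = 1000.0,
    perf_diff: float = 10.0,
    label_first: bool = True,
    voxel_size_mm=(3.44, 3.44, 5.0),
) -> tuple[DualEchoSeries, GroundTruth]:
    """Dual-echo visual-task run with known evoked fractional changes.

    ``delta_bold``/``delta_cbf`` may be scalars or 3D maps.  The
    perfusion echo interleaves control volumes at ``perf_baseline`` with
    label volumes depressed by ``perf_diff * (1 + delta_cbf * boxcar)``;
    the BOLD echo is ``bold_baseline * (1 + delta_bold * boxcar)``.
    ``snr=None`` gives a noiseless run.
    """
    if design is None:
        design = make_task_design(seed)
    rng = np.random.default_rng(seed)
    n_vols = int(np.round(design.total_duration / tr))
    u = boxcar_regressor(design, n_vols, tr)

    db = _as_map(delta_bold, shape)[..., None]
    dc = _as_map(delta_cbf, shape)[..., None]

    bold = bold_baseline * (1.0 + db * u)
    diff = perf_diff * (1.0 + dc * u)
    control = np.full(shape + (n_vols,), perf_baseline)
    label = control - diff
    perf = _interleave(control, label, label_first)

    if snr is not None:
        if snr <= 0:
            raise ValueError("snr must be positive (or None for noiseless)")
        amp_bold = bold_baseline * float(np.mean(np.abs(db)))
        amp_perf = perf_diff * float(np.mean(np.abs(dc)))
        if amp_bold > 0:
            bold = bold + rng.normal(0.0, amp_bold / snr, bold.shape)
        if amp_perf > 0:
            perf = perf + rng.normal(0.0, amp_perf / snr, perf.shape)

    series = DualEchoSeries(
        perfusion=perf, bold=bold, tr=tr, label_first=label_first, voxel_size_mm=voxel_size_mm
    )
    truth = GroundTruth(
        delta_bold=np.squeeze(db, -1), delta_cbf=np.squeeze(dc, -1), design=design
    )
    return series, truth


def make_gas_run(
    m: float = 0.05,
    delta_cbf_hc: float = 1.5,
    protocol: GasProtocol = GasProtocol(),
    shape=(8, 8, 4),
    tr: float = 4.0,
    snr: float | None = None,
    seed: int = 0,
    bold_baseline: float = 1000.0,
    perf_baseline: float = 1000.0,
    perf_diff: float = 10.0,
    label_first: bool = True,
    voxel_size_mm=(3.44, 3.44, 5.0),
    params: DavisParams = DEFAULT_PARAMS,
) -> tuple[DualEchoSeries, GroundTruth]:
    """Normocapnia -> hypercapnia dual-echo run consistent with a known M.

    The hypercapnic BOLD change is derived from (m, delta_cbf_hc) through
    the forward Davis model with unchanged CMRO2, so the processing
    pipeline should recover exactly ``m``.  Signals ramp linearly across
    the discarded post-switch window (flow stabilisation), which the
    windowing must ignore.
    """
    rng = np.random.default_rng(seed)
    delta_bold_hc = forward_bold(delta_cbf_hc, 0.0, m, params)
    total = protocol.baseline_s + protocol.hypercapnia_s
    n_vols = int(np.round(total / tr))
    t = np.arange(n_vols) * tr
    ramp_end = protocol.baseline_s + protocol.discard_s
    g = np.clip((t - protocol.baseline_s) / max(protocol.discard_s, tr), 0.0, 1.0)
    g[t >= ramp_end] = 1.0

    bold = bold_baseline * (1.0 + delta_bold_hc * g) * np.ones(shape + (1,))
    diff = perf_diff * (1.0 + delta_cbf_hc * g)
    control = np.full(shape + (n_vols,), perf_baseline)
    label = control - diff
    perf = _interleave(control, label, label_first)

    if snr is not None:
        if snr <= 0:
            raise ValueError("snr must be positive (or None for noiseless)")
        bold = bold + rng.normal(0.0, bold_baseline * abs(delta_bold_hc) / snr, bold.shape)
        perf = perf + rng.normal(0.0, perf_diff * abs(delta_cbf_hc) / snr, perf.shape)

    series = DualEchoSeries(
        perfusion=perf, bold=bold, tr=tr, label_first=label_first, voxel_size_mm=voxel_size_mm
    )
    truth = GroundTruth(delta_bold=delta_bold_hc, delta_cbf=delta_cbf_hc, m=m)
    return series, truth


def make_flair_phantom(
    lesion_spec,
    grid=(48, 48, 8),
    voxel_size_mm=(1.0, 1.0, 1.0),
    seed: int = 0,
    background_mean: float = 100.0,
    background_sd: float = 10.0,
    contrast_sd: float = 4.0,
    brain_margin: int = 2,
):
    """FLAIR-like volume with rectangular hyperintense lesions.

    ``lesion_spec`` is a list of (center, size) voxel-index tuples; each
    lesion is a box of ``size`` voxels centred at ``center`` at intensity
    background_mean + contrast_sd * background_sd.  The in-brain
    background is a random two-level texture (mean +/- sd): it has the
    requested SD but is *bounded*, so a slice-wise mean + 1.25 SD
    threshold can never flag background voxels and lesion recovery is
    exact (an unbounded, e.g. Gaussian, background would scatter false
    positives above any sub-sigma threshold by construction).  Lesions
    must lie inside the brain mask and must not touch each other
    (including diagonally), else the spec is rejected.

    Returns (flair, brain_mask, truth_mask, lesion_masks, GroundTruth).
    """
    rng = np.random.default_rng(seed)
    grid = tuple(int(g) for g in grid)
    brain = np.zeros(grid, dtype=bool)
    brain[
        brain_margin : grid[0] - brain_margin,
        brain_margin : grid[1] - brain_margin,
        brain_margin : grid[2] - brain_margin,
    ] = True

    lesion_masks = []
    voxel_vol = float(np.prod(voxel_size_mm))
    spec_out = []
    for center, size in lesion_spec:
        mask = np.zeros(grid, dtype=bool)
        slices = []
        for c, s, g in zip(center, size, grid):
            lo = int(c) - int(s) // 2
            hi = lo + int(s)
            if lo < 0 or hi > g:
                raise ValueError(f"lesion at {center} exceeds the grid")
            slices.append(slice(lo, hi))
        mask[tuple(slices)] = True
        if not np.all(brain[mask]):
            raise ValueError(f"lesion at {center} lies outside the brain mask")
        lesion_masks.append(mask)
        spec_out.append((tuple(center), tuple(size), float(mask.sum() * voxel_vol)))

    # reject overlapping or touching lesions (they would not be distinct)
    for i in range(len(lesion_masks)):
        grown = _dilate26(lesion_masks[i])
        for j in range(i + 1, len(lesion_masks)):
            if np.any(grown & lesion_masks[j]):
                raise ValueError(f"lesions {i} and {j} overlap or touch")

    texture = rng.choice([-1.0, 1.0], size=grid)
    flair = background_mean + background_sd * texture
    flair[~brain] = 0.0
    truth = np.zeros(grid, dtype=bool)
    for mask in lesion_masks:
        flair[mask] = background_mean + contrast_sd * background_sd
        truth |= mask
    gt = GroundTruth(lesion_spec=spec_out)
    return flair, brain, truth, lesion_masks, gt


def _dilate26(mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage

    return ndimage.binary_dilation(mask, ndimage.generate_binary_structure(3, 3))


def make_participant_table(
    n_ms: int = 10,
    n_hc: int = 13,
    predictor_spec: dict | None = None,
    seed: int = 0,
    n_null: int = 0,
    null_mean: float = 0.0,
    null_sd: float = 1.0,
    heavy_tailed: bool = False,
) -> pd.DataFrame:
    """Two-group predictor table with known per-group distributions.

    ``predictor_spec`` maps name -> (mean_ms, sd_ms, mean_hc, sd_hc);
    the default covers the cfMRI measures at study-scale statistics.
    ``n_null`` appends no-effect predictors (equal means) for calibration
    tests.  ``heavy_tailed=True`` draws from a shifted log-normal with
    matched mean/SD to exercise the MAD screen.  The generating spec is
    stored in ``DataFrame.attrs['ground_truth']``.
    """
    if n_ms < 2 or n_hc < 2:
        raise ValueError("need at least 2 participants per group")
    spec = dict(DEFAULT_PREDICTOR_SPEC if predictor_spec is None else predictor_spec)
    for i in range(n_null):
        spec[f"null_{i}"] = (null_mean, null_sd, null_mean, null_sd)

    rng = np.random.default_rng(seed)
    data = {"group": ["MS"] * n_ms + ["HC"] * n_hc}
    for name, (mean_ms, sd_ms, mean_hc, sd_hc) in spec.items():
        draws = []
        for mean, sd, n in ((mean_ms, sd_ms, n_ms), (mean_hc, sd_hc, n_hc)):
            if heavy_tailed and sd > 0:
                # log-normal shifted to the requested mean and SD
                s2 = np.log(1.0 + (sd / max(abs(mean), sd)) ** 2)
                mu = np.log(max(abs(mean), sd)) - s2 / 2
                vals = rng.lognormal(mu, np.sqrt(s2), n)
                vals = vals - vals.mean() + mean  # recentre
            else:
                vals = rng.normal(mean, sd, n)
            draws.append(vals)
        data[name] = np.concatenate(draws)
    df = pd.DataFrame(data)
    df.attrs["ground_truth"] = GroundTruth(predictor_spec=spec)
    return df
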