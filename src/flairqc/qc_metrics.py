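"""No-reference technical QC parameters of a 3D-FLAIR head volume.

Given a volume plus tissue masks, this module derives the parameter set a
multi-scanner QC programme tracks per study: bias-corrected tissue
statistics, WM/GM (Michelson) contrast, brain noise, CNR, a background
quality index penalizing structured artefact (ghosting) in the air region,
and directional MTF50/MTF10 from cortical-edge profiles (see
:mod:`flairqc.mtf`).

Segmentation is consumed, not performed: masks come from the phantom's
ground truth (or an external segmentation of the same contract).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import QCResult, TissueMasks, Volume
from .mtf import (  # noqa: F401  (re-exported: this module is the QC surface)
    EdgeProfileSet,
    EdgeSamplingError,
    MTFConfig,
    MTFCurve,
    estimate_mtf,
    extract_edge_profiles,
    mtf_threshold_frequency,
)

#: robust SD of the (voxel - 3x3x3 local median) residual on unit Gaussian
#: noise; calibrated once by simulation and fixed.  The raw residual MAD
#: underestimates the voxel SD by this factor.
MEDIAN_RESIDUAL_FACTOR = 0.9536


@dataclass(frozen=True)
class QCConfig:
    """Constants of the QC pipeline."""

    bias_fwhm_mm: float = 60.0       # low-pass scale of the bias-field estimate (>= 40)
    erosion_vox: int = 1             # mask erosion before tissue statistics
    min_mask_vox: int = 100
    qi_k: float = 4.0                # robust threshold: median + k * (1.4826 MAD)
    qi_min_component: int = 5        # voxels; smaller bright clusters are ignored
    qi_head_dilation: int = 3
    qi_frame: int = 2                # border frame excluded from the background
    qi_min_background: int = 10000
    mtf: MTFConfig = field(default_factory=MTFConfig)


def estimate_bias_field(
    volume: Volume, masks: TissueMasks, config: QCConfig = QCConfig()
) -> np.ndarray:
    """Smooth multiplicative intensity field, mean 1 over the brain.

    The volume is first flattened tissue-wise (divided by each class's
    median within WM/GM/CSF), leaving approximately the bias field on brain
    voxels; a heavy normalized Gaussian convolution then smooths it and
    extrapolates it over the rest of the head.  Far from the brain the
    field is 1 (no correction).
    """
    if not masks.head.any():
        raise ValueError("empty head mask: cannot estimate a bias field")
    brain = masks.wm | masks.gm | masks.csf
    if not brain.any():
        raise ValueError("empty brain (WM|GM|CSF) mask: cannot estimate a bias field")
    flat = np.zeros(volume.shape)
    for m in (masks.wm, masks.gm, masks.csf):
        if m.any():
            med = np.median(volume.data[m])
            if med > 0:
                flat[m] = volume.data[m] / med
    sigma_vox = tuple(
        config.bias_fwhm_mm * 0.42466 / sp for sp in volume.spacing_mm
    )
    w = brain.astype(np.float64)
    num = ndimage.gaussian_filter(flat * w, sigma_vox, mode="constant", cval=0.0)
    den = ndimage.gaussian_filter(w, sigma_vox, mode="constant", cval=0.0)
    field = np.ones(volume.shape)
    support = den > 1e-3
    field[support] = num[support] / den[support]
    field /= field[brain].mean()
    np.clip(field, 0.2, 5.0, out=field)
    return field


def correct_bias(
    volume: Volume, masks: TissueMasks, config: QCConfig = QCConfig()
) -> Volume:
    """Divide out the estimated bias field.

    Guarantees that the WM coefficient of variation does not increase: if
    the division would worsen it (e.g. a bias-free volume where the field
    estimate is pure error), the input volume is returned unchanged.
    """
    field = estimate_bias_field(volume, masks, config)
    corrected = Volume(volume.data / field, volume.spacing_mm)
    wm = _eroded(masks.wm, config.erosion_vox)
    if wm.sum() >= config.min_mask_vox:
        def cov(v):
            x = v.data[wm]
            return np.std(x) / max(np.mean(x), 1e-12)
        if cov(corrected) > cov(volume):
            return Volume(volume.data.copy(), volume.spacing_mm)
    return corrected


def _eroded(mask: np.ndarray, n: int) -> np.ndarray:
    return ndimage.binary_erosion(mask, iterations=n) if n > 0 else mask


def tissue_stats(
    volume: Volume, masks: TissueMasks, config: QCConfig = QCConfig()
) -> tuple[float, float, float]:
    """Median WM, GM and CSF signal over 1-voxel-eroded masks."""
    out = []
    for name in ("wm", "gm", "csf"):
        m = _eroded(getattr(masks, name), config.erosion_vox)
        if m.sum() < config.min_mask_vox:
            raise ValueError(
                f"{name.upper()} mask too small after erosion "
                f"({int(m.sum())} < {config.min_mask_vox} voxels)"
            )
        out.append(float(np.median(volume.data[m])))
    return out[0], out[1], out[2]


def compute_contrast(mu_gm: float, mu_wm: float) -> float:
    """Michelson WM/GM contrast (mu_GM - mu_WM)/(mu_GM + mu_WM).

    Negative when the FLAIR ordering inverts; callers treat that as a flag,
    not an error.
    """
    if mu_gm + mu_wm <= 0:
        raise ValueError("tissue means sum to zero; contrast undefined")
    return (mu_gm - mu_wm) / (mu_gm + mu_wm)


def estimate_noise(
    volume: Volume, masks: TissueMasks, config: QCConfig = QCConfig()
) -> float:
    """Robust brain-noise SD from the local-median residual in eroded WM.

    The residual (voxel minus its 3x3x3 median) is insensitive to slow
    signal variation such as leftover bias; its MAD-based SD is rescaled by
    the calibrated :data:`MEDIAN_RESIDUAL_FACTOR`.
    """
    wm = _eroded(masks.wm, config.erosion_vox)
    if wm.sum() < config.min_mask_vox:
        raise ValueError(
            f"WM mask too small after erosion ({int(wm.sum())} < {config.min_mask_vox})"
        )
    resid = volume.data - ndimage.median_filter(volume.data, size=3)
    r = resid[wm]
    mad = np.median(np.abs(r - np.median(r)))
    return float(1.4826 * mad / MEDIAN_RESIDUAL_FACTOR)


def compute_cnr(mu_gm: float, mu_wm: float, noise_sd: float) -> float:
    """Contrast-to-noise ratio (mu_GM - mu_WM)/noise_sd; sign preserved."""
    if noise_sd <= 0:
        raise ValueError(
            "noise_sd must be positive; for noise-free volumes CNR is "
            "undefined (flag the study instead)"
        )
    return (mu_gm - mu_wm) / noise_sd


def background_mask(
    volume: Volume, masks: TissueMasks, config: QCConfig = QCConfig()
) -> np.ndarray:
    """Air region for the QI: outside the dilated head, inside the frame."""
    bg = ~ndimage.binary_dilation(masks.head, iterations=config.qi_head_dilation)
    f = config.qi_frame
    if f > 0:
        frame = np.zeros(volume.shape, dtype=bool)
        frame[f:-f, f:-f, f:-f] = True
        bg &= frame
    return bg


def compute_qi(
    volume: Volume, masks: TissueMasks, config: QCConfig = QCConfig()
) -> float:
    """Background quality index in [0, 1]; 1 = artefact-free air.

    qi = 1 - N_artefact/N_background, where artefact voxels exceed a robust
    threshold (median + k * 1.4826 MAD of the background) and belong to a
    connected component of at least ``qi_min_component`` voxels, so that
    isolated noise-tail voxels do not count but ghosting does.
    """
    bg = background_mask(volume, masks, config)
    n_bg = int(bg.sum())
    if n_bg < config.qi_min_background:
        raise ValueError(f"background too small ({n_bg} < {config.qi_min_background} voxels)")
    vals = volume.data[bg]
    med = np.median(vals)
    mad = np.median(np.abs(vals - med))
    thr = med + config.qi_k * 1.4826 * mad
    art = bg & (volume.data > thr)
    lab, n_comp = ndimage.label(art)
    if n_comp:
        sizes = np.bincount(lab.ravel())[1:]
        keep = np.flatnonzero(sizes >= config.qi_min_component) + 1
        n_art = int(sizes[keep - 1].sum()) if keep.size else 0
    else:
        n_art = 0
    return 1.0 - n_art / n_bg


def compute_qc(
    volume: Volume, masks: TissueMasks, config: QCConfig = QCConfig()
) -> QCResult:
    """Full per-study QC: bias correction, tissue stats, contrast/noise/CNR,
    QI, and per-axis MTF50/MTF10.

    Stage failures are recorded per-parameter in ``result.flags`` rather
    than aborting the study; the result may therefore be partial.
    """
    result = QCResult()
    try:
        corrected = correct_bias(volume, masks, config)
    except ValueError as e:
        result.flags["bias"] = str(e)
        corrected = volume

    mu = None
    try:
        mu = tissue_stats(corrected, masks, config)
        result.contrast = compute_contrast(mu[1], mu[0])
        if result.contrast < 0:
            result.flags["contrast"] = "inverted GM/WM ordering"
    except ValueError as e:
        result.flags["contrast"] = str(e)

    try:
        result.noise_sd = estimate_noise(corrected, masks, config)
    except ValueError as e:
        result.flags["noise_sd"] = str(e)

    if mu is not None and result.noise_sd is not None:
        try:
            result.cnr = compute_cnr(mu[1], mu[0], result.noise_sd)
        except ValueError as e:
            result.flags["cnr"] = str(e)

    try:
        # raw volume: the air region must not be touched by brain-driven correction
        result.qi = compute_qi(volume, masks, config)
    except ValueError as e:
        result.flags["qi"] = str(e)

    for axis in ("FH", "AP", "RL"):
        key = axis.lower()
        try:
            profiles = extract_edge_profiles(corrected, masks, axis, config.mtf)
            curve = estimate_mtf(profiles, config.mtf)
            result.n_edges_used[axis] = profiles.n_accepted
            result.mtf_curves[axis] = {
                "freq_cyc_per_mm": curve.freq_cyc_per_mm.tolist(),
                "modulation": curve.modulation.tolist(),
            }
            result.mtf50[axis] = mtf_threshold_frequency(curve, 0.5)
            result.mtf10[axis] = mtf_threshold_frequency(curve, 0.1)
            if not np.isfinite(result.mtf50[axis]) or not np.isfinite(result.mtf10[axis]):
                result.flags[f"mtf_{key}"] = "threshold beyond measurable band"
        except (EdgeSamplingError, RuntimeError) as e:
            result.flags[f"mtf_{key}"] = str(e)
    result.validate()
    return result


def qc_row(study_id: str, device_id: str, result: QCResult) -> dict:
    """Flatten a QCResult into one cohort-CSV row."""
    row = {
        "study_id": study_id,
        "device_id": device_id,
        "contrast": result.contrast,
        "noise_sd": result.noise_sd,
        "cnr": result.cnr,
        "qi": result.qi,
    }
    for axis in ("FH", "AP", "RL"):
        a = axis.lower()
        row[f"mtf50_{a}"] = result.mtf50.get(axis, np.nan)
        row[f"mtf10_{a}"] = result.mtf10.get(axis, np.nan)
        row[f"n_edges_{a}"] = result.n_edges_used.get(axis, 0)
    row["flags"] = ";".join(f"{k}:{v}" for k, v in result.flags.items())
    return row
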