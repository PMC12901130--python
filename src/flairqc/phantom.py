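"""Synthetic 3D-FLAIR-like head phantoms and multi-scanner cohorts.

The phantom is a nested-ellipsoid head: a WM core wrapped in a bright GM
cortical ribbon, a dark CSF shell (FLAIR suppresses CSF), two ventricle
ellipsoids, and air background.  Degradations are applied in a fixed order:
tissue means -> multiplicative bias field -> anisotropic Gaussian blur ->
AP ghost -> Rician noise.  Everything is generated on a supersampled grid
and block-averaged down, so tissue interfaces carry continuously
distributed sub-voxel phases; the edge-based MTF estimator depends on that.

A cohort couples a latent per-device quality to the degradation strengths
(contrast separation, SNR, blur, ghosting) while each device also gets an
arbitrary global intensity gain, as real scanners do.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import nibabel as nib
import numpy as np
from scipy import ndimage

from .core import AXES, BG, CSF, GM, WM, TissueMasks, Volume

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 0.42466

DEFAULT_TISSUE_MEANS = {"WM": 200.0, "GM": 300.0, "CSF": 50.0, "background": 0.0}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic head volume.

    ``blur_fwhm_mm`` is per anatomical axis (FH, AP, RL); ``noise_sd`` is the
    Gaussian sd of each quadrature channel (magnitude images get Rician
    noise, Rayleigh in air); ``bias_amplitude`` is the peak fractional
    modulation of the multiplicative bias field; ``ghost_amplitude`` scales a
    copy of the head signal shifted along AP by ``ghost_shift_fraction`` of
    the field of view.  ``supersample`` is the integer grid refinement used
    during rasterization; ``gm_thickness_vox``/``csf_thickness_vox`` set the
    cortical ribbon and CSF shell thickness in (final-grid) voxels.
    """

    matrix_size: tuple[int, int, int] = (128, 128, 128)
    voxel_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tissue_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_MEANS)
    )
    blur_fwhm_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: float = 0.0
    bias_amplitude: float = 0.0
    ghost_amplitude: float = 0.0
    ghost_shift_fraction: float = 0.25
    supersample: int = 2
    gm_thickness_vox: float = 7.0
    csf_thickness_vox: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.matrix_size) != 3 or any(
            int(n) != n or n <= 0 for n in self.matrix_size
        ):
            raise ValueError(f"matrix_size must be 3 positive integers, got {self.matrix_size}")
        if len(self.voxel_spacing_mm) != 3 or any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError(f"voxel_spacing_mm must be 3 positive reals, got {self.voxel_spacing_mm}")
        m = self.tissue_means
        for k in ("WM", "GM", "CSF", "background"):
            if k not in m or m[k] < 0:
                raise ValueError(f"tissue_means must define nonnegative {k!r}")
        if not (m["GM"] > m["WM"] > m["CSF"] > m["background"]):
            raise ValueError(
                "FLAIR-like ordering violated: need GM > WM > CSF > background, "
                f"got {m}"
            )
        fov = [n * s for n, s in zip(self.matrix_size, self.voxel_spacing_mm)]
        for f, fv in zip(self.blur_fwhm_mm, fov):
            if f < 0:
                raise ValueError("blur FWHM must be nonnegative")
            if f > fv / 2:
                raise ValueError(f"blur FWHM {f} mm exceeds half the field of view ({fv / 2} mm)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.bias_amplitude < 0:
            raise ValueError("bias_amplitude must be nonnegative")
        if not (0.0 <= self.ghost_amplitude < 1.0):
            raise ValueError("ghost_amplitude must lie in [0, 1)")
        if not (0.0 < self.ghost_shift_fraction < 1.0):
            raise ValueError("ghost_shift_fraction must lie in (0, 1)")
        if int(self.supersample) != self.supersample or self.supersample < 1:
            raise ValueError("supersample must be a positive integer")


@dataclass
class GroundTruth:
    """Known generative parameters of a phantom, the oracle for recovery tests."""

    masks: TissueMasks
    latent_quality: float
    true_blur_sigma_mm: tuple[float, float, float]
    true_noise_sd: float
    true_contrast: float
    tissue_means: dict[str, float] = field(default_factory=dict)
    bias_field: np.ndarray | None = None


def _ellipsoid_mask(
    coords: tuple[np.ndarray, np.ndarray, np.ndarray],
    center_mm: tuple[float, float, float],
    semiaxes_mm: tuple[float, float, float],
) -> np.ndarray:
    q = np.zeros((coords[0].size, coords[1].size, coords[2].size), dtype=np.float32)
    for ax, (x, c, a) in enumerate(zip(coords, center_mm, semiaxes_mm)):
        u = ((x - c) / a).astype(np.float32) ** 2
        q += u.reshape([-1 if i == ax else 1 for i in range(3)])
    return q <= 1.0


def _head_geometry(spec: PhantomSpec):
    """Semi-axes (mm) of the nested surfaces, scaled to the field of view."""
    fov = np.array(spec.matrix_size, dtype=float) * np.array(spec.voxel_spacing_mm)
    head = np.array([0.36, 0.40, 0.33]) * fov  # FH, AP, RL
    sp = np.array(spec.voxel_spacing_mm)
    t_csf = spec.csf_thickness_vox * sp
    t_gm = spec.gm_thickness_vox * sp
    gm_outer = head - t_csf
    wm_outer = gm_outer - t_gm
    if np.any(wm_outer <= 0.05 * fov):
        raise ValueError("matrix too small for the nested head geometry")
    vent_semi = wm_outer * np.array([0.40, 0.50, 0.22])
    vent_off = 0.35 * wm_outer[2]
    return head, gm_outer, wm_outer, vent_semi, vent_off


def _label_map_supersampled(spec: PhantomSpec) -> np.ndarray:
    s = int(spec.supersample)
    head, gm_outer, wm_outer, vent_semi, vent_off = _head_geometry(spec)
    coords = []
    for n, sp in zip(spec.matrix_size, spec.voxel_spacing_mm):
        pitch = sp / s
        x = (np.arange(n * s, dtype=np.float64) + 0.5) * pitch - n * sp / 2.0
        coords.append(x)
    coords = tuple(coords)
    lab = np.zeros(tuple(n * s for n in spec.matrix_size), dtype=np.uint8)
    lab[_ellipsoid_mask(coords, (0, 0, 0), tuple(head))] = CSF
    lab[_ellipsoid_mask(coords, (0, 0, 0), tuple(gm_outer))] = GM
    lab[_ellipsoid_mask(coords, (0, 0, 0), tuple(wm_outer))] = WM
    for sign in (+1.0, -1.0):
        lab[_ellipsoid_mask(coords, (0, 0, sign * vent_off), tuple(vent_semi))] = CSF
    return lab


def _block_mean(a: np.ndarray, s: int) -> np.ndarray:
    if s == 1:
        return np.asarray(a, dtype=np.float64)
    n0, n1, n2 = (d // s for d in a.shape)
    return a.reshape(n0, s, n1, s, n2, s).mean(axis=(1, 3, 5), dtype=np.float64)


def _bias_field(
    spec: PhantomSpec, rng: np.random.Generator, oversample: int = 1
) -> np.ndarray:
    """Separable low-order polynomial field, peak modulation = bias_amplitude."""
    factors = []
    for n in spec.matrix_size:
        u = np.linspace(-1.0, 1.0, n * oversample, dtype=np.float32)
        c1, c2 = rng.uniform(-1.0, 1.0, size=2)
        factors.append(1.0 + c1 * u + c2 * (u**2 - 1.0 / 3.0))
    f = factors[0][:, None, None] * factors[1][None, :, None] * factors[2][None, None, :]
    f = f / f.mean(dtype=np.float64)
    m = f - 1.0
    peak = np.abs(m).max()
    if peak < 1e-12:
        return np.ones_like(f)
    return 1.0 + np.float32(spec.bias_amplitude) * m / peak


def generate_phantom(
    spec: PhantomSpec, latent_quality: float = 0.0
) -> tuple[Volume, GroundTruth]:
    """Rasterize one phantom volume with its ground-truth masks.

    Deterministic for a fixed spec (the seed drives the bias-field
    polynomial and the noise).  Degradations are applied in the documented
    order; with all degradations at zero, pure-WM voxels carry exactly the
    WM tissue mean.
    """
    s = int(spec.supersample)
    lab_ss = _label_map_supersampled(spec)

    masks = TissueMasks(
        wm=_block_mean(lab_ss == WM, s) >= 1.0 - 1e-12,
        gm=_block_mean(lab_ss == GM, s) >= 1.0 - 1e-12,
        csf=_block_mean(lab_ss == CSF, s) >= 1.0 - 1e-12,
        head=_block_mean(lab_ss != BG, s) > 0.5,
        background=_block_mean(lab_ss == BG, s) >= 1.0 - 1e-12,
    )

    means = np.zeros(4, dtype=np.float32)
    means[BG] = spec.tissue_means["background"]
    means[CSF] = spec.tissue_means["CSF"]
    means[GM] = spec.tissue_means["GM"]
    means[WM] = spec.tissue_means["WM"]
    img_ss = means[lab_ss]
    del lab_ss

    # bias and blur act on the supersampled scene: the scanner PSF degrades
    # the continuous object, not the sampled image, and the super-resolution
    # MTF estimator downstream can tell the difference
    rng = np.random.default_rng(spec.seed)
    bias = None
    if spec.bias_amplitude > 0:
        bias_ss = _bias_field(spec, rng, oversample=s)
        img_ss = img_ss * bias_ss
        bias = _block_mean(bias_ss, s)
        del bias_ss
    else:
        # keep the rng stream aligned whether or not bias is applied
        rng.uniform(-1.0, 1.0, size=6)

    sub_pitch = tuple(sp / s for sp in spec.voxel_spacing_mm)
    sigma_sub = tuple(
        f * FWHM_TO_SIGMA / p for f, p in zip(spec.blur_fwhm_mm, sub_pitch)
    )
    if any(sv > 0 for sv in sigma_sub):
        img_ss = ndimage.gaussian_filter(img_ss, sigma=sigma_sub, mode="constant", cval=0.0)
    img = _block_mean(img_ss, s)
    del img_ss

    if spec.ghost_amplitude > 0:
        shift = int(round(spec.ghost_shift_fraction * spec.matrix_size[1]))
        img = img + spec.ghost_amplitude * np.roll(img, shift, axis=1)

    if spec.noise_sd > 0:
        g1 = rng.normal(0.0, spec.noise_sd, size=img.shape)
        g2 = rng.normal(0.0, spec.noise_sd, size=img.shape)
        img = np.hypot(img + g1, g2)

    m = spec.tissue_means
    truth = GroundTruth(
        masks=masks,
        latent_quality=latent_quality,
        true_blur_sigma_mm=tuple(f * FWHM_TO_SIGMA for f in spec.blur_fwhm_mm),
        true_noise_sd=spec.noise_sd,
        true_contrast=(m["GM"] - m["WM"]) / (m["GM"] + m["WM"]),
        tissue_means=dict(m),
        bias_field=bias,
    )
    return Volume(img, spec.voxel_spacing_mm), truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class DeviceProfile:
    """Per-device distributions over phantom parameters.

    ``latent_quality`` is the device's true quality on the observer's scale;
    per-study parameters are drawn from truncated normals with the means and
    sds below.  ``gain`` is the device's arbitrary global intensity scale.
    """

    device_id: str
    latent_quality: float
    gain: float = 1.0
    contrast_mean: float = 0.20
    contrast_sd: float = 0.015
    snr_mean: float = 14.0
    snr_sd: float = 1.4
    blur_fwhm_mean_mm: tuple[float, float, float] = (2.6, 3.0, 2.6)
    blur_fwhm_sd_mm: float = 0.25
    bias_amplitude_mean: float = 0.15
    bias_amplitude_sd: float = 0.05
    ghost_amplitude_mean: float = 0.05
    ghost_amplitude_sd: float = 0.015
    latent_sd: float = 0.25


@dataclass(frozen=True)
class CohortSpec:
    """A multi-device cohort: devices x studies_per_device phantom studies."""

    devices: tuple[DeviceProfile, ...]
    studies_per_device: int = 10
    seed: int = 0
    matrix_size: tuple[int, int, int] = (128, 128, 128)
    voxel_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    supersample: int = 2

    def __post_init__(self) -> None:
        ids = [d.device_id for d in self.devices]
        if len(set(ids)) != len(ids):
            raise ValueError("device_ids must be unique")
        if self.studies_per_device < 1:
            raise ValueError("studies_per_device must be >= 1")


def default_cohort_spec(
    n_devices: int = 15,
    studies_per_device: int = 10,
    seed: int = 0,
    matrix_size: tuple[int, int, int] = (128, 128, 128),
    voxel_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
    supersample: int = 2,
) -> CohortSpec:
    """Cohort emulating a 15-scanner 3D-FLAIR fleet with known latent quality.

    Latent quality q is spread evenly over [-1.5, 1.5] across devices and
    drives contrast separation, WM SNR, blur and ghosting; a random
    per-device intensity gain decouples absolute signal units from q.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0))).spawn(1)[0]
    qs = np.linspace(-1.5, 1.5, n_devices) if n_devices > 1 else np.array([0.0])
    devices = []
    for i, q in enumerate(qs):
        gain = float(np.exp(rng.normal(0.0, 0.6)))
        base_fwhm = 2.8 - 0.4 * q
        snr = 25.0 * float(np.exp(0.30 * q))
        devices.append(
            DeviceProfile(
                device_id=f"D{i + 1:02d}",
                latent_quality=float(q),
                gain=gain,
                contrast_mean=0.20 + 0.04 * q,
                snr_mean=snr,
                snr_sd=0.1 * snr,
                blur_fwhm_mean_mm=(base_fwhm, 1.15 * base_fwhm, base_fwhm),
                blur_fwhm_sd_mm=0.35,
                ghost_amplitude_mean=max(0.0, 0.12 - 0.05 * q),
                ghost_amplitude_sd=0.03,
            )
        )
    return CohortSpec(
        devices=tuple(devices),
        studies_per_device=studies_per_device,
        seed=seed,
        matrix_size=matrix_size,
        voxel_spacing_mm=voxel_spacing_mm,
        supersample=supersample,
    )


def study_seed(cohort_seed: int, device_id: str, study_index: int) -> np.random.SeedSequence:
    """Stable per-study seed from (cohort seed, device_id, study index)."""
    return np.random.SeedSequence(
        (int(cohort_seed), zlib.crc32(device_id.encode()), int(study_index))
    )


def draw_study_spec(
    cohort: CohortSpec, device: DeviceProfile, study_index: int
) -> tuple[PhantomSpec, float]:
    """Draw one study's phantom parameters from its device's distributions."""
    rng = np.random.default_rng(study_seed(cohort.seed, device.device_id, study_index))
    m = float(np.clip(rng.normal(device.contrast_mean, device.contrast_sd), 0.02, 0.60))
    snr = float(np.clip(rng.normal(device.snr_mean, device.snr_sd), 3.0, None))
    fwhm = tuple(
        float(np.clip(rng.normal(f, device.blur_fwhm_sd_mm), 0.0, None))
        for f in device.blur_fwhm_mean_mm
    )
    bias = float(np.clip(rng.normal(device.bias_amplitude_mean, device.bias_amplitude_sd), 0.0, 0.5))
    ghost = float(np.clip(rng.normal(device.ghost_amplitude_mean, device.ghost_amplitude_sd), 0.0, 0.8))
    latent = float(device.latent_quality + rng.normal(0.0, device.latent_sd))
    wm = 200.0 * device.gain
    csf = 50.0 * device.gain
    gm = wm * (1.0 + m) / (1.0 - m)
    spec = PhantomSpec(
        matrix_size=cohort.matrix_size,
        voxel_spacing_mm=cohort.voxel_spacing_mm,
        tissue_means={"WM": wm, "GM": gm, "CSF": csf, "background": 0.0},
        blur_fwhm_mm=fwhm,
        noise_sd=wm / snr,
        bias_amplitude=bias,
        ghost_amplitude=ghost,
        supersample=cohort.supersample,
        seed=int(rng.integers(2**31)),
    )
    return spec, latent


@dataclass
class StudyRecord:
    study_id: str
    device_id: str
    volume: Volume
    truth: GroundTruth


def iter_cohort(spec: CohortSpec) -> Iterator[StudyRecord]:
    """Generate the cohort's studies one at a time (memory-friendly)."""
    for device in spec.devices:
        for j in range(spec.studies_per_device):
            pspec, latent = draw_study_spec(spec, device, j)
            vol, truth = generate_phantom(pspec, latent_quality=latent)
            yield StudyRecord(f"{device.device_id}-S{j:02d}", device.device_id, vol, truth)


def generate_cohort(spec: CohortSpec) -> list[StudyRecord]:
    """All studies of the cohort as a list; see :func:`iter_cohort`."""
    return list(iter_cohort(spec))


# ---------------------------------------------------------------------------
# on-disk study format: NIfTI volume + NIfTI masks + JSON sidecar

_MASK_NAMES = ("wm", "gm", "csf", "head", "background")


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def write_study(
    volume: Volume,
    truth: GroundTruth,
    outdir: str | Path,
    study_id: str,
    device_id: str = "NA",
) -> Path:
    """Serialize a study as NIfTI volume + masks with a JSON metadata sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = _affine(volume.spacing_mm)
    nib.save(nib.Nifti1Image(volume.data, aff), outdir / f"{study_id}.nii.gz")
    for name in _MASK_NAMES:
        arr = getattr(truth.masks, name).astype(np.uint8)
        nib.save(nib.Nifti1Image(arr, aff), outdir / f"{study_id}_mask_{name}.nii.gz")
    meta = {
        "study_id": study_id,
        "device_id": device_id,
        "axes": list(AXES),
        "voxel_spacing_mm": list(volume.spacing_mm),
        "latent_quality": truth.latent_quality,
        "true_blur_sigma_mm": list(truth.true_blur_sigma_mm),
        "true_noise_sd": truth.true_noise_sd,
        "true_contrast": truth.true_contrast,
        "tissue_means": truth.tissue_means,
    }
    sidecar = outdir / f"{study_id}.json"
    sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return outdir / f"{study_id}.nii.gz"


def read_study(path: str | Path) -> tuple[Volume, TissueMasks, dict]:
    """Load a study written by :func:`write_study`.

    ``path`` is the volume NIfTI (or its path without extension).  Raises if
    the JSON sidecar is missing or its spacing disagrees with the NIfTI
    header.
    """
    path = Path(path)
    stem = path.name
    for ext in (".nii.gz", ".nii"):
        if stem.endswith(ext):
            stem = stem[: -len(ext)]
    base = path.parent / stem
    sidecar = base.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing metadata sidecar {sidecar} for study volume {path}"
        )
    meta = json.loads(sidecar.read_text())
    img = nib.load(str(base) + ".nii.gz")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    side_spacing = tuple(float(s) for s in meta["voxel_spacing_mm"])
    if not np.allclose(spacing, side_spacing, rtol=0, atol=1e-4):
        raise ValueError(
            f"voxel spacing mismatch: NIfTI header {spacing} vs sidecar {side_spacing}"
        )
    if list(meta.get("axes", AXES)) != list(AXES):
        raise ValueError(f"unexpected axis order {meta.get('axes')}; expected {list(AXES)}")
    vol = Volume(np.asarray(img.dataobj, dtype=np.float64), spacing)
    masks = TissueMasks(
        **{
            name: np.asarray(
                nib.load(f"{base}_mask_{name}.nii.gz").dataobj
            ).astype(bool)
            for name in _MASK_NAMES
        }
    )
    return vol, masks, meta
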