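"""Shared containers for volumes and tissue masks.

Array axis convention throughout the package: axis 0 = FH (feet--head,
frequency encoding), axis 1 = AP (anterior--posterior, phase encoding),
axis 2 = RL (right--left, slice encoding).  Spacing is in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: canonical anatomical axis labels, in array-axis order
AXES: tuple[str, str, str] = ("FH", "AP", "RL")

#: tissue label codes used by the phantom label map
BG, CSF, GM, WM = 0, 1, 2, 3


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing in mm.

    ``data`` is indexed [FH, AP, RL]; ``spacing_mm`` gives the voxel pitch
    along each of those axes.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    axes: tuple[str, str, str] = AXES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")
        if tuple(self.axes) != AXES:
            raise ValueError(f"axes must be {AXES}, got {tuple(self.axes)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def fov_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing_mm))


@dataclass
class TissueMasks:
    """Boolean masks for the tissue classes of a head volume.

    ``wm``/``gm``/``csf`` mark *pure* voxels of each tissue (no partial
    volume), ``head`` marks everything inside the outer head surface and
    ``background`` marks pure air.  Masks are pairwise disjoint.
    """

    wm: np.ndarray
    gm: np.ndarray
    csf: np.ndarray
    head: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.wm, self.gm, self.csf, self.head, self.background)}
        if len(shapes) != 1:
            raise ValueError("all masks must share one shape")
        for name in ("wm", "gm", "csf", "head", "background"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        if np.any(self.wm & self.gm) or np.any(self.gm & self.csf) or np.any(self.wm & self.csf):
            raise ValueError("tissue masks must be pairwise disjoint")
        if np.any(self.background & self.head):
            raise ValueError("background and head masks must be disjoint")

    def label_map(self) -> np.ndarray:
        """Label volume with BG/CSF/GM/WM codes; mixed voxels stay BG."""
        lab = np.zeros(self.wm.shape, dtype=np.uint8)
        lab[self.csf] = CSF
        lab[self.gm] = GM
        lab[self.wm] = WM
        return lab


@dataclass
class QCResult:
    """Technical quality parameters of one study.

    MTF threshold frequencies are in cycles/mm, keyed by anatomical axis.
    ``flags`` records per-parameter failures (the value is then None/NaN).
    """

    contrast: float | None = None
    noise_sd: float | None = None
    cnr: float | None = None
    qi: float | None = None
    mtf50: dict[str, float] = field(default_factory=dict)
    mtf10: dict[str, float] = field(default_factory=dict)
    n_edges_used: dict[str, int] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)
    mtf_curves: dict[str, dict] = field(default_factory=dict)

    def validate(self) -> None:
        if self.qi is not None and not (0.0 <= self.qi <= 1.0):
            raise ValueError(f"qi out of [0, 1]: {self.qi}")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for ax in self.mtf50:
            if ax in self.mtf10 and np.isfinite(self.mtf10[ax]) and np.isfinite(self.mtf50[ax]):
                if self.mtf10[ax] < self.mtf50[ax]:
                    raise ValueError(f"mtf10 < mtf50 on axis {ax}")
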