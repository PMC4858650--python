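"""Voxelised digital-mouse phantom.

A deliberately simple labelled geometry: an ellipsoidal body containing an
ellipsoidal liver (scaled to a requested volume), a spherical heart blood
pool, a tubular intestine segment and a spherical bladder.  The label map
plays the role of the CT-side organ segmentation: it defines the ROIs used
for quantification and, in voxel mode, the support over which simulated
counts are distributed.

No anatomical realism beyond labelled shapes is attempted; tomographic
effects (attenuation, scatter, partial volume) are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["LABEL_LEGEND", "GeometryConfig", "LabelVolume", "make_phantom"]

#: Canonical organ legend shared by the phantom and the renderers.
LABEL_LEGEND = {
    0: "background",
    1: "body",
    2: "liver",
    3: "heart_blood",
    4: "intestine",
    5: "bladder",
}

#: Organ labels that carry activity, in legend order.
ORGAN_LABELS = ("body", "liver", "heart_blood", "intestine", "bladder")


@dataclass(frozen=True)
class GeometryConfig:
    """Phantom geometry.  Positions are fractions of the grid extent.

    The liver is an ellipsoid with fixed axis ratios rescaled so that its
    analytic volume equals ``liver_volume_mL``; after voxelisation the
    rendered volume matches the request to within the boundary-voxel bound.
    """

    shape: tuple = (48, 48, 80)
    voxel_size_mm: tuple = (0.5, 0.5, 0.5)
    liver_volume_mL: float = 1.0
    body_semiaxes_frac: tuple = (0.42, 0.42, 0.47)
    liver_center_frac: tuple = (0.5, 0.5, 0.62)
    liver_axis_ratios: tuple = (1.3, 1.0, 0.7)
    heart_center_frac: tuple = (0.5, 0.5, 0.82)
    heart_radius_mm: float = 1.6
    intestine_center_frac: tuple = (0.5, 0.5, 0.30)
    intestine_radius_mm: float = 1.3
    intestine_length_frac: float = 0.55
    bladder_center_frac: tuple = (0.5, 0.5, 0.12)
    bladder_radius_mm: float = 1.4

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"shape must be three positive integers, got {self.shape}")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be three positive reals")
        if not self.liver_volume_mL > 0:
            raise ValueError("liver_volume_mL must be positive")


@dataclass
class LabelVolume:
    """3-D integer organ-label grid with physical voxel size.

    ``legend`` maps label values to organ names; every voxel value present
    in ``labels`` must appear in the legend, and liver and heart must be
    non-empty and disjoint (disjointness is guaranteed by construction —
    each voxel holds a single label).
    """

    labels: np.ndarray
    voxel_size_mm: tuple
    legend: dict = field(default_factory=lambda: dict(LABEL_LEGEND))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D grid")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel dimensions must be positive")
        present = set(np.unique(self.labels).tolist())
        unknown = present - set(self.legend)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} missing from legend")
        for organ in ("liver", "heart_blood"):
            if self.label_value(organ) not in present:
                raise ValueError(f"{organ} region is empty")

    def label_value(self, organ: str) -> int:
        for value, name in self.legend.items():
            if name == organ:
                return value
        raise KeyError(f"organ {organ!r} not in legend")

    def mask(self, organ) -> np.ndarray:
        """Boolean mask for an organ given by name or label value."""
        value = organ if isinstance(organ, (int, np.integer)) else self.label_value(organ)
        if value not in self.legend:
            raise KeyError(f"label {organ!r} not in legend")
        return self.labels == value

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def volume_mL(self, organ) -> float:
        """Organ volume in mL (voxel count times voxel volume)."""
        return float(self.mask(organ).sum()) * self.voxel_volume_mm3 / 1000.0


def _grids_mm(cfg: GeometryConfig):
    """Voxel-centre coordinates (mm) along each axis, as broadcast grids."""
    axes = [
        (np.arange(n) + 0.5) * v
        for n, v in zip(cfg.shape, cfg.voxel_size_mm)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(grids, center_mm, semiaxes_mm):
    x, y, z = grids
    cx, cy, cz = center_mm
    a, b, c = semiaxes_mm
    return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0


def make_phantom(cfg: GeometryConfig = GeometryConfig()) -> LabelVolume:
    """Voxelise the configured geometry into a :class:`LabelVolume`.

    Deterministic: the same config always yields the identical grid.
    Raises ``ValueError`` if two organs overlap (naming the colliding
    labels) or if the body is empty.
    """
    extent = tuple(n * v for n, v in zip(cfg.shape, cfg.voxel_size_mm))
    grids = _grids_mm(cfg)

    def at(frac):
        return tuple(f * e for f, e in zip(frac, extent))

    body = _ellipsoid(grids, at((0.5, 0.5, 0.5)),
                      tuple(f * e for f, e in zip(cfg.body_semiaxes_frac, extent)))
    if not body.any():
        raise ValueError("empty geometry: body ellipsoid contains no voxels")

    # Liver semi-axes: fixed ratios rescaled to the requested volume.
    rx, ry, rz = cfg.liver_axis_ratios
    target_mm3 = cfg.liver_volume_mL * 1000.0
    s = (target_mm3 * 3.0 / (4.0 * math.pi * rx * ry * rz)) ** (1.0 / 3.0)
    liver = _ellipsoid(grids, at(cfg.liver_center_frac), (rx * s, ry * s, rz * s))

    heart = _ellipsoid(grids, at(cfg.heart_center_frac), (cfg.heart_radius_mm,) * 3)
    bladder = _ellipsoid(grids, at(cfg.bladder_center_frac), (cfg.bladder_radius_mm,) * 3)

    x, y, z = grids
    icx, icy, icz = at(cfg.intestine_center_frac)
    half_len = 0.5 * cfg.intestine_length_frac * extent[0]
    intestine = (
        ((y - icy) ** 2 + (z - icz) ** 2 <= cfg.intestine_radius_mm**2)
        & (np.abs(x - icx) <= half_len)
    )

    organs = {
        "liver": liver,
        "heart_blood": heart,
        "intestine": intestine,
        "bladder": bladder,
    }
    for name, mask in organs.items():
        if not mask.any():
            raise ValueError(f"empty geometry: organ {name!r} contains no voxels")
        if not (mask <= body).all():
            raise ValueError(f"organ {name!r} extends outside the body ellipsoid")
    names = list(organs)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if (organs[a] & organs[b]).any():
                raise ValueError(f"overlapping organ definitions: {a!r} and {b!r}")

    labels = np.zeros(cfg.shape, dtype=np.int16)
    labels[body] = 1
    value_of = {name: v for v, name in LABEL_LEGEND.items()}
    for name, mask in organs.items():
        labels[mask] = value_of[name]
    return LabelVolume(labels=labels, voxel_size_mm=tuple(cfg.voxel_size_mm))
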