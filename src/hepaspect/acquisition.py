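"""Framed SPECT-like count acquisition from the kinetic model.

The renderer works at the activity-map level: for each frame the expected
organ counts are

    E[counts] = calibration * 60 * injected_MBq
                * ∫ frac_organ(t) * 2^(-t / T_half) dt   (t in minutes),

evaluated in closed form (every organ fraction is a finite exponential
mixture, and the Tc-99m decay factor just shifts each rate).  Optional
Poisson noise is applied per organ (ROI mode) or per voxel (voxel mode,
with the organ expectation spread uniformly over the organ's voxels).

No tomographic projection, reconstruction, attenuation or scatter is
modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import AnimalRecord
from .kinetics import DECAY_RATE_PER_MIN, frame_integral, organ_fraction_mixtures
from .phantom import ORGAN_LABELS, LabelVolume

__all__ = [
    "dynamic_schedule",
    "static_schedule",
    "DynamicAcquisition",
    "render_acquisition",
]


def dynamic_schedule(n_frames: int = 30, frame_s: float = 30.0, start_s: float = 0.0):
    """The dynamic protocol: contiguous 30 s frames spanning 0-15 min.

    Returns an ``(n_frames, 2)`` array of frame ``(start, end)`` times in
    seconds post-injection.
    """
    edges = start_s + frame_s * np.arange(n_frames + 1)
    return np.column_stack([edges[:-1], edges[1:]])


def static_schedule(center_min: float = 40.0, duration_s: float = 30.0):
    """A single static frame centred on ``center_min`` minutes (default 40)."""
    c = center_min * 60.0
    return np.array([[c - duration_s / 2.0, c + duration_s / 2.0]])


def _validate_frames(frames):
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 2 or frames.shape[1] != 2:
        raise ValueError("frames must be an (n, 2) array of (start, end) seconds")
    if np.any(frames[:, 1] <= frames[:, 0]):
        raise ValueError("every frame must have positive duration")
    if np.any(frames[1:, 0] < frames[:-1, 1] - 1e-9):
        raise ValueError("frames must be non-overlapping and increasing")
    if np.any(frames[:, 0] < 0):
        raise ValueError("frames must start at or after injection (t = 0)")
    return frames


@dataclass
class DynamicAcquisition:
    """A framed count acquisition, in ROI or voxel mode.

    In ROI mode ``counts`` has shape ``(n_frames, n_organs)`` with columns
    ordered as ``organ_labels``; in voxel mode it has shape
    ``(n_frames, *grid_shape)``.  ``calibration`` is the detector
    sensitivity in counts per MBq per second.  Poisson-mode counts are
    integer; with noise disabled the stored values are the (real-valued)
    expectations.
    """

    frames: np.ndarray
    counts: np.ndarray
    injected_MBq: float
    calibration: float
    mode: str = "roi"
    organ_labels: tuple = ORGAN_LABELS

    def __post_init__(self):
        self.frames = _validate_frames(self.frames)
        self.counts = np.asarray(self.counts)
        if self.injected_MBq <= 0:
            raise ValueError("injected_MBq must be positive")
        if self.calibration <= 0:
            raise ValueError("calibration must be positive")
        if self.mode not in ("roi", "voxel"):
            raise ValueError(f"mode must be 'roi' or 'voxel', got {self.mode!r}")
        if self.counts.shape[0] != self.frames.shape[0]:
            raise ValueError("counts first axis must match the number of frames")
        if self.mode == "roi" and self.counts.shape != (
            self.frames.shape[0],
            len(self.organ_labels),
        ):
            raise ValueError("ROI-mode counts must be (n_frames, n_organs)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def frame_midpoints_min(self) -> np.ndarray:
        return self.frames.mean(axis=1) / 60.0

    def frame_durations_s(self) -> np.ndarray:
        return self.frames[:, 1] - self.frames[:, 0]

    def organ_counts(self, organ: str) -> np.ndarray:
        """Per-frame total counts for one organ (either mode)."""
        if self.mode == "roi":
            try:
                j = self.organ_labels.index(organ)
            except ValueError:
                raise KeyError(f"unknown organ {organ!r}") from None
            return self.counts[:, j]
        raise ValueError("voxel-mode acquisitions need a phantom; use roi_activity")


def expected_organ_counts(
    animal: AnimalRecord,
    frames,
    calibration: float,
    heart_blood_share: float = 0.1,
) -> np.ndarray:
    """Noise-free expected counts, shape ``(n_frames, n_organs)``."""
    frames = _validate_frames(frames)
    mixes = organ_fraction_mixtures(animal.kinetics, heart_blood_share)
    out = np.empty((frames.shape[0], len(ORGAN_LABELS)))
    for i, (t0, t1) in enumerate(frames):
        for j, organ in enumerate(ORGAN_LABELS):
            integral = frame_integral(
                mixes[organ], t0 / 60.0, t1 / 60.0, extra_rate=DECAY_RATE_PER_MIN
            )
            out[i, j] = calibration * 60.0 * animal.injected_MBq * integral
    return out


def render_acquisition(
    phantom: LabelVolume | None,
    animal: AnimalRecord,
    schedule,
    seed: int | None = None,
    *,
    mode: str = "roi",
    poisson: bool = True,
    calibration: float = 50.0,
    heart_blood_share: float = 0.1,
    horizon_min: float = 180.0,
) -> DynamicAcquisition:
    """Render a framed acquisition for one animal.

    Parameters
    ----------
    phantom
        Label volume; required in voxel mode, may be ``None`` in ROI mode.
    schedule
        ``(n, 2)`` frame start/end times in seconds.
    seed
        Seeds the Poisson noise; ignored when ``poisson`` is False.
    mode
        ``'roi'`` (per-organ frame totals, the fast default) or
        ``'voxel'`` (full grids aligned to the phantom).
    """
    frames = _validate_frames(schedule)
    if frames[-1, 1] > horizon_min * 60.0 + 1e-9:
        raise ValueError(
            f"schedule extends to {frames[-1, 1] / 60.0:.1f} min, beyond the "
            f"simulated horizon of {horizon_min:.1f} min"
        )
    expected = expected_organ_counts(animal, frames, calibration, heart_blood_share)
    rng = np.random.default_rng(seed)

    if mode == "roi":
        counts = rng.poisson(expected).astype(np.int64) if poisson else expected
        return DynamicAcquisition(
            frames=frames, counts=counts, injected_MBq=animal.injected_MBq,
            calibration=calibration, mode="roi",
        )
    if mode != "voxel":
        raise ValueError(f"mode must be 'roi' or 'voxel', got {mode!r}")
    if phantom is None:
        raise ValueError("voxel mode requires a phantom")

    masks = {organ: phantom.mask(organ) for organ in ORGAN_LABELS}
    shape = phantom.labels.shape
    vox = np.zeros((frames.shape[0],) + shape)
    for j, organ in enumerate(ORGAN_LABELS):
        m = masks[organ]
        nvox = int(m.sum())
        if nvox == 0:
            if np.any(expected[:, j] > 0):
                raise ValueError(f"organ {organ!r} has activity but no voxels")
            continue
        per_voxel = expected[:, j] / nvox
        vox[:, m] = per_voxel[:, None]
    counts = rng.poisson(vox).astype(np.int64) if poisson else vox
    return DynamicAcquisition(
        frames=frames, counts=counts, injected_MBq=animal.injected_MBq,
        calibration=calibration, mode="voxel",
    )
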