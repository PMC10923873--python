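"""Geometric and intensity standardization of a case.

Three steps, mirroring a standard prostate mpMRI pipeline:

1. **center-axis alignment** — an in-plane rotation about the volume center
   so that the line joining the whole-gland centroid and the TZ centroid is
   vertical (aligned with the height axis).  This puts the gland into the
   canonical left–right symmetric orientation that the mirrored-input
   network assumes.
2. **center crop** — in-plane crop about the image center (the gland sits
   centrally in clinical acquisitions); depth is untouched.
3. **normalization** — T2 and high-b channels are min–max scaled to [0, 1]
   per patient; ADC is quantitative across patients, so it is clipped at a
   patient-independent value and divided by it.

Bias-field correction and inter-sequence registration are upstream
responsibilities; phantoms are generated pre-aligned.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .phantom import MpMRICase

__all__ = ["PreprocessConfig", "align_center_axis", "center_crop",
           "normalize_case", "preprocess_case"]


@dataclass(frozen=True)
class PreprocessConfig:
    crop_size: tuple[int, int] = (128, 128)
    # ADC clip in 1e-6 mm^2/s units on raw maps; phantoms are already on a
    # [0, 1] scale, so pipelines on phantoms pass adc_clip_value=1.0.
    adc_clip_value: float = 3000.0
    rotate: bool = True

    def __post_init__(self):
        if self.adc_clip_value <= 0:
            raise ValueError("adc_clip_value must be > 0")


def _inplane_centroid(mask: np.ndarray) -> np.ndarray:
    """(height, width) centroid of a binary volume, projected in-plane."""
    if mask.sum() == 0:
        raise ValueError("empty mask has no centroid")
    zz, yy, xx = np.nonzero(mask)
    return np.array([yy.mean(), xx.mean()])


def rotation_angle_deg(prostate_mask: np.ndarray, tz_mask: np.ndarray) -> float:
    """In-plane angle (degrees) that verticalizes the gland→TZ centroid line."""
    c_pro = _inplane_centroid(prostate_mask)
    c_tz = _inplane_centroid(tz_mask)
    dh, dw = c_tz - c_pro
    if abs(dh) < 1e-9 and abs(dw) < 1e-9:
        return 0.0
    return float(np.degrees(np.arctan2(dw, dh)))


def _rotate_volume(vol: np.ndarray, angle_deg: float, order: int) -> np.ndarray:
    """Rotate every slice about the in-plane center; shape preserved."""
    if angle_deg == 0.0:
        return vol.copy()
    return ndimage.rotate(vol, angle_deg, axes=(1, 2), reshape=False,
                          order=order, mode="constant", cval=float(vol.min()))


def align_center_axis(case: MpMRICase, prostate_mask: np.ndarray | None = None
                      ) -> tuple[MpMRICase, float]:
    """Rotate all channels/masks so the gland→TZ centroid line is vertical.

    Images are interpolated linearly, masks with nearest neighbour.
    Returns the rotated case and the applied angle in degrees.
    """
    if prostate_mask is None:
        prostate_mask = case.prostate_mask
    if prostate_mask.sum() == 0 or case.tz_mask.sum() == 0:
        raise ValueError("alignment needs non-empty prostate and TZ masks")
    angle = rotation_angle_deg(prostate_mask, case.tz_mask)
    rotated = replace(
        case,
        t2w=_rotate_volume(case.t2w, angle, order=1),
        adc=_rotate_volume(case.adc, angle, order=1),
        highb=_rotate_volume(case.highb, angle, order=1),
        tz_mask=_rotate_volume(case.tz_mask, angle, order=0).astype(np.uint8),
        pz_mask=_rotate_volume(case.pz_mask, angle, order=0).astype(np.uint8),
        lesion_mask=_rotate_volume(case.lesion_mask, angle, order=0).astype(np.uint8),
    )
    # nearest-neighbour rotation can create single-voxel zone overlaps;
    # zone identity is ill-defined there, TZ (the inner gland) wins
    overlap = rotated.tz_mask & rotated.pz_mask
    rotated.pz_mask = (rotated.pz_mask & ~overlap).astype(np.uint8)
    rotated.lesion_mask = (rotated.lesion_mask & rotated.prostate_mask).astype(np.uint8)
    return rotated, angle


def crop_slices(in_plane_shape: tuple[int, int], crop_size: tuple[int, int]
                ) -> tuple[slice, slice]:
    """Index ranges of the centered in-plane crop."""
    out = []
    for size, want in zip(in_plane_shape, crop_size):
        if want > size:
            raise ValueError(f"crop {want} exceeds axis size {size}")
        lo = (size - want) // 2
        out.append(slice(lo, lo + want))
    return tuple(out)


def center_crop(volumes: dict[str, np.ndarray] | MpMRICase,
                crop_size: tuple[int, int]):
    """Crop all channels/masks identically about the in-plane center."""
    if isinstance(volumes, MpMRICase):
        sl = crop_slices(volumes.t2w.shape[1:], crop_size)
        index = (slice(None),) + sl
        return replace(
            volumes,
            **{name: getattr(volumes, name)[index].copy()
               for name in ("t2w", "adc", "highb", "tz_mask", "pz_mask", "lesion_mask")},
        )
    first = next(iter(volumes.values()))
    sl = crop_slices(first.shape[1:], crop_size)
    index = (slice(None),) + sl
    return {name: vol[index].copy() for name, vol in volumes.items()}


def _minmax(vol: np.ndarray) -> np.ndarray:
    lo, hi = float(vol.min()), float(vol.max())
    if hi - lo < 1e-12:
        raise ValueError("constant volume: min-max normalization undefined")
    return ((vol - lo) / (hi - lo)).astype(np.float32)


def normalize_case(case: MpMRICase, cfg: PreprocessConfig = PreprocessConfig()
                   ) -> MpMRICase:
    """Min–max scale T2/high-b per patient; clip-and-scale ADC; masks untouched."""
    adc = np.clip(case.adc, 0.0, cfg.adc_clip_value) / cfg.adc_clip_value
    return replace(case, t2w=_minmax(case.t2w), highb=_minmax(case.highb),
                   adc=adc.astype(np.float32))


def preprocess_case(case: MpMRICase, cfg: PreprocessConfig = PreprocessConfig(),
                    sidecar_path=None) -> MpMRICase:
    """Full pipeline: optional rotation, center crop, normalization.

    When `sidecar_path` is given, provenance (angle, crop indices, clip
    value) is written there as JSON.
    """
    angle = 0.0
    if cfg.rotate:
        case, angle = align_center_axis(case)
    sl = crop_slices(case.t2w.shape[1:], cfg.crop_size)
    case = center_crop(case, cfg.crop_size)
    case = normalize_case(case, cfg)
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(
                {
                    "case_id": case.case_id,
                    "rotation_deg": angle,
                    "crop": [[s.start, s.stop] for s in sl],
                    "adc_clip_value": cfg.adc_clip_value,
                    "config": dataclasses.asdict(cfg),
                },
                fh, indent=2,
            )
    return case
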