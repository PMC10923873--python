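"""Ground-truth label encodings for zone-aware lesion detection.

Two encodings of a binary lesion mask are supported:

* **binary** — one channel, 1 at lesion voxels, 0 elsewhere; the label space
  of a conventional voxelwise cross-entropy.
* **hierarchical** — two channels ``m = [m0, m1]``.  ``m0`` carries the
  diffusion-common "lesion anywhere" evidence required of every clinically
  significant lesion; ``m1`` adds the T2-weighted evidence that PI-RADS
  requires for transition-zone (TZ) lesions on top of it:

  ==========================  =========
  voxel                       m
  ==========================  =========
  lesion ∩ TZ                 [1, 1]
  lesion ∩ PZ                 [1, 0]
  anything else               [0, 0]
  ==========================  =========

  The pattern [0, 1] (T2 evidence without diffusion evidence) is undefined
  and never emitted: ``m1 <= m0`` holds at every voxel.

Lesion voxels that fall outside both zonal masks (zonal masks are produced
by an upstream segmentation model and can be imperfect) are labeled [1, 0]:
the diffusion-common channel applies to every lesion, while T2 evidence is
the TZ-specific addition.  Such voxels are counted and reported via a
warning so mask problems are visible.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["encode_binary", "encode_hierarchical"]


def _check_binary(mask: np.ndarray, name: str) -> np.ndarray:
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError(f"{name} must be binary (values 0/1)")
    return mask.astype(np.uint8)


def encode_binary(lesion_mask: np.ndarray) -> np.ndarray:
    """One-channel label volume of shape (1, D, H, W): 1 iff lesion voxel."""
    lesion = _check_binary(lesion_mask, "lesion_mask")
    return lesion[None]


def encode_hierarchical(lesion_mask: np.ndarray, tz_mask: np.ndarray,
                        pz_mask: np.ndarray) -> np.ndarray:
    """Two-channel hierarchical label volume of shape (2, D, H, W).

    Raises on shape mismatch and on overlapping zonal masks.
    """
    lesion = _check_binary(lesion_mask, "lesion_mask")
    tz = _check_binary(tz_mask, "tz_mask")
    pz = _check_binary(pz_mask, "pz_mask")
    if not (lesion.shape == tz.shape == pz.shape):
        raise ValueError(
            f"mask shapes differ: lesion {lesion.shape}, tz {tz.shape}, pz {pz.shape}"
        )
    if np.any(tz & pz):
        raise ValueError("tz_mask and pz_mask overlap; zones must be disjoint")
    m0 = lesion
    m1 = lesion & tz
    orphans = int((lesion & ~(tz | pz)).sum())
    if orphans:
        warnings.warn(
            f"{orphans} lesion voxel(s) outside TZ∪PZ; labeled [1,0]",
            stacklevel=2,
        )
    return np.stack([m0, m1]).astype(np.uint8)
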