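"""Synthetic multi-parametric MRI phantoms of the prostate.

Each phantom is a co-registered stack of three channels (T2-weighted, ADC,
high-b diffusion) over a centered prostate ellipsoid that is split into an
inner transition-zone (TZ) ellipsoid and the surrounding peripheral-zone
(PZ) shell.  Three kinds of focal structure can be placed:

* **TZ lesions** — asymmetric blobs that darken T2 and ADC and brighten
  the high-b channel (the appearance of clinically significant cancer in
  the transition zone);
* **PZ lesions** — blobs with strong ADC/high-b contrast but weak T2
  contrast, as in the peripheral zone;
* **symmetric mimic pairs** — lesion-like blobs placed at exact mirror
  positions about the mid-width axis, emulating benign hyperplastic
  nodules and central-zone wings.  They look like cancer channel-wise but
  are left–right symmetric and are *excluded* from the lesion mask, so a
  symmetry-blind detector is drawn into false positives on them.

All intensities are additive offsets on zone-wise base levels plus i.i.d.
Gaussian noise.  Deterministic structure is built from arithmetic that is
exactly mirror-symmetric about the mid-width axis (blob + flipped blob),
so a noiseless mimic-only phantom equals its own width-flip bit-for-bit.
A single RNG stream derived from ``PhantomSpec.seed`` drives every random
choice, making generation reproducible.

On-disk format: one NIfTI (.nii.gz) file per channel and mask, a CSV
lesion table, and a YAML sidecar with case id and voxel spacing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

try:
    import nibabel as nib
except ImportError:  # pragma: no cover
    nib = None

__all__ = ["PhantomSpec", "MpMRICase", "generate_phantom", "write_case", "read_case"]

CHANNELS = ("t2w", "adc", "highb")
MASKS = ("tz_mask", "pz_mask", "lesion_mask")

# zone base levels per channel, on the normalized [0, 1] intensity scale
_BASE = {
    "t2w": {"bg": 0.15, "tz": 0.45, "pz": 0.75},
    "adc": {"bg": 0.35, "tz": 0.70, "pz": 0.72},
    "highb": {"bg": 0.20, "tz": 0.25, "pz": 0.28},
}


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for one synthetic case.

    Contrasts are per-channel signed offsets (t2w, adc, highb) added inside
    a blob.  Defaults follow the channel contrast relations of prostate
    mpMRI: lesions and their benign mimics are dark on ADC and T2 and
    bright on high-b diffusion, with TZ lesions showing stronger T2
    contrast and PZ lesions stronger diffusion contrast.
    """

    volume_shape: tuple[int, int, int] = (16, 128, 128)
    spacing_mm: tuple[float, float, float] = (3.0, 0.625, 0.625)
    n_lesions_tz: int = 1
    n_lesions_pz: int = 1
    n_symmetric_mimic_pairs: int = 1
    lesion_radius_mm: tuple[float, float] = (4.0, 8.0)
    lesion_contrast_tz: tuple[float, float, float] = (-0.25, -0.30, 0.30)
    lesion_contrast_pz: tuple[float, float, float] = (-0.08, -0.35, 0.35)
    mimic_contrast: tuple[float, float, float] = (-0.22, -0.30, 0.30)
    noise_sigma: float = 0.02
    mimic_jitter_voxels: int = 0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_lesions_tz, self.n_lesions_pz, self.n_symmetric_mimic_pairs) < 0:
            raise ValueError("object counts must be >= 0")
        lo, hi = self.lesion_radius_mm
        if not (0 < lo <= hi):
            raise ValueError("lesion_radius_mm must be a positive (lo, hi) range")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if min(self.spacing_mm) <= 0:
            raise ValueError("spacing must be strictly positive")
        if min(self.volume_shape) < 4:
            raise ValueError("volume_shape too small")


@dataclass
class MpMRICase:
    """A patient's aligned channel stack, zonal masks and lesion annotation."""

    t2w: np.ndarray
    adc: np.ndarray
    highb: np.ndarray
    tz_mask: np.ndarray
    pz_mask: np.ndarray
    lesion_mask: np.ndarray
    lesion_table: pd.DataFrame
    spacing_mm: tuple[float, float, float]
    case_id: str = "case-0000"

    def validate(self) -> None:
        shapes = {v.shape for v in (self.t2w, self.adc, self.highb,
                                    self.tz_mask, self.pz_mask, self.lesion_mask)}
        if len(shapes) != 1:
            raise ValueError(f"volume shapes differ: {shapes}")
        if np.any(self.tz_mask & self.pz_mask):
            raise ValueError("tz_mask and pz_mask overlap")
        if np.any(self.lesion_mask & ~(self.tz_mask | self.pz_mask)):
            raise ValueError("lesion voxels outside TZ∪PZ")

    @property
    def prostate_mask(self) -> np.ndarray:
        return (self.tz_mask | self.pz_mask).astype(np.uint8)

    def channel_stack(self) -> np.ndarray:
        """Five-channel float32 model input: T2, ADC, high-b, TZ, PZ."""
        return np.stack([
            self.t2w, self.adc, self.highb,
            self.tz_mask.astype(np.float32), self.pz_mask.astype(np.float32),
        ]).astype(np.float32)


def _ellipsoid(shape, center, semi_axes_vox) -> np.ndarray:
    """Binary mask of voxel centers inside an axis-aligned ellipsoid."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes_vox))
    return (q <= 1.0).astype(np.uint8)


def _zone_masks(shape, spacing):
    center = tuple((s - 1) / 2.0 for s in shape)
    prostate_ax = tuple(f * s for f, s in zip((0.38, 0.32, 0.32), shape))
    tz_ax = tuple(0.58 * a for a in prostate_ax)
    prostate = _ellipsoid(shape, center, prostate_ax)
    tz = _ellipsoid(shape, center, tz_ax)
    pz = (prostate & ~tz).astype(np.uint8)
    return tz, pz


def _blob(shape, center, radius_mm, spacing, rng) -> tuple[np.ndarray, float]:
    """Random mildly anisotropic ellipsoid; returns (mask, equivalent radius mm)."""
    aniso = rng.uniform(0.8, 1.2, size=3)
    semi_mm = radius_mm * aniso
    semi_vox = [max(r / s, 0.6) for r, s in zip(semi_mm, spacing)]
    eq_radius = float(np.prod(semi_mm) ** (1.0 / 3.0))
    return _ellipsoid(shape, center, semi_vox), eq_radius


def _touches(blob, occupied) -> bool:
    """True when `blob` intersects or is face/edge/corner adjacent to
    `occupied`; a one-voxel gap keeps placed objects as separate connected
    components."""
    grown = ndimage.binary_dilation(np.asarray(blob, dtype=bool),
                                    structure=np.ones((3, 3, 3), dtype=bool))
    return bool((grown & occupied).any())


def _sample_center(rng, zone_mask, min_midline_offset_vox, shape):
    """Draw a voxel inside `zone_mask` at least the given offset off-midline."""
    coords = np.argwhere(zone_mask)
    cx = (shape[2] - 1) / 2.0
    for _ in range(500):
        z, y, x = coords[rng.integers(len(coords))]
        if abs(x - cx) >= min_midline_offset_vox:
            return (int(z), int(y), int(x))
    raise ValueError("could not sample an off-midline center; zone too narrow")


def generate_phantom(spec: PhantomSpec) -> MpMRICase:
    """Generate one synthetic case.  Raises if the requested objects cannot
    be placed without overlap within a bounded number of attempts."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape, spacing = tuple(spec.volume_shape), tuple(spec.spacing_mm)
    tz, pz = _zone_masks(shape, spacing)
    prostate = (tz | pz).astype(bool)

    channels = {}
    for name in CHANNELS:
        base = _BASE[name]
        vol = np.full(shape, base["bg"], dtype=np.float64)
        vol[tz.astype(bool)] = base["tz"]
        vol[pz.astype(bool)] = base["pz"]
        channels[name] = vol

    # mild radial T2 shading inside the gland; exactly mirror-symmetric
    center = tuple((s - 1) / 2.0 for s in shape)
    gy, gx = np.ogrid[0:shape[1], 0:shape[2]]
    r2 = (((gy - center[1]) / shape[1]) ** 2 + ((gx - center[2]) / shape[2]) ** 2)
    channels["t2w"] += prostate * (0.08 * (1.0 - 4.0 * r2))[None, :, :]

    occupied = np.zeros(shape, dtype=bool)
    lesion_mask = np.zeros(shape, dtype=np.uint8)
    records = []

    def place(zone_name, zone_mask, contrast, lesion_id):
        nonlocal lesion_mask, occupied
        for _ in range(200):
            radius = rng.uniform(*spec.lesion_radius_mm)
            ctr = _sample_center(rng, zone_mask, 2.0, shape)
            blob, eq_r = _blob(shape, ctr, radius, spacing, rng)
            full = int(blob.sum())
            blob &= prostate  # lesions live inside the gland
            # a lesion mostly amputated by the gland boundary is re-drawn, so
            # discretized volumes stay close to the analytic ellipsoid volume
            if full == 0 or blob.sum() < 0.9 * full or _touches(blob, occupied):
                continue
            in_tz = int((blob & tz).sum())
            in_pz = int((blob & pz).sum())
            zone = "TZ" if in_tz >= in_pz else "PZ"
            if zone != zone_name:
                continue
            occupied |= blob.astype(bool)
            lesion_mask |= blob
            for name, off in zip(CHANNELS, contrast):
                channels[name] += off * blob
            zz, yy, xx = np.nonzero(blob)
            records.append(dict(lesion_id=lesion_id, zone=zone,
                                cz=float(zz.mean()), cy=float(yy.mean()),
                                cx=float(xx.mean()), radius_mm=eq_r))
            return
        raise ValueError(
            f"could not place a {zone_name} lesion after 200 attempts; "
            "spec is over-crowded"
        )

    def place_mimic_pair():
        nonlocal occupied
        w = shape[2]
        for _ in range(200):
            radius = rng.uniform(*spec.lesion_radius_mm)
            r_vox_x = radius / spacing[2]
            ctr = _sample_center(rng, prostate.astype(np.uint8),
                                 2.0 + r_vox_x, shape)
            blob, _ = _blob(shape, ctr, radius, spacing, rng)
            blob &= prostate
            partner = np.flip(blob, axis=2)
            if spec.mimic_jitter_voxels:
                shift = int(rng.integers(-spec.mimic_jitter_voxels,
                                         spec.mimic_jitter_voxels + 1))
                partner = np.roll(partner, shift, axis=2)
                partner &= prostate
            pair = (blob | partner).astype(bool)
            # mimics are background tissue, not label components: plain
            # non-overlap with already-placed structure suffices
            if blob.sum() == 0 or not partner.any() or (pair & occupied).any():
                continue
            occupied |= pair
            contrib = blob.astype(np.float64) + partner.astype(np.float64)
            for name, off in zip(CHANNELS, spec.mimic_contrast):
                channels[name] += off * contrib
            return
        raise ValueError(
            "could not place a mimic pair after 200 attempts; spec is over-crowded"
        )

    lesion_id = 0
    for _ in range(spec.n_lesions_tz):
        place("TZ", tz, spec.lesion_contrast_tz, lesion_id)
        lesion_id += 1
    for _ in range(spec.n_lesions_pz):
        place("PZ", pz, spec.lesion_contrast_pz, lesion_id)
        lesion_id += 1
    for _ in range(spec.n_symmetric_mimic_pairs):
        place_mimic_pair()

    if spec.noise_sigma > 0:
        for name in CHANNELS:
            channels[name] += rng.normal(0.0, spec.noise_sigma, size=shape)

    case_id = f"phantom-{spec.seed:06d}"
    table = pd.DataFrame.from_records(
        records, columns=["lesion_id", "zone", "cz", "cy", "cx", "radius_mm"]
    )
    table.insert(0, "case_id", case_id)
    case = MpMRICase(
        t2w=channels["t2w"].astype(np.float32),
        adc=channels["adc"].astype(np.float32),
        highb=channels["highb"].astype(np.float32),
        tz_mask=tz, pz_mask=pz, lesion_mask=lesion_mask,
        lesion_table=table, spacing_mm=spacing, case_id=case_id,
    )
    case.validate()
    return case


def mirror_symmetry_score(volume: np.ndarray) -> float:
    """Pearson correlation between a channel and its width-flip."""
    a = np.asarray(volume, dtype=np.float64).ravel()
    b = np.flip(volume, axis=-1).astype(np.float64).ravel()
    return float(np.corrcoef(a, b)[0, 1])


# -- on-disk round trip -------------------------------------------------------


def _affine(spacing) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def write_case(case: MpMRICase, directory) -> dict[str, Path]:
    """Write NIfTI channels/masks, a CSV lesion table and a YAML sidecar."""
    case.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    aff = _affine(case.spacing_mm)
    for name in CHANNELS:
        p = directory / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(getattr(case, name).astype(np.float32), aff), p)
        paths[name] = p
    for name in MASKS:
        p = directory / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(getattr(case, name).astype(np.uint8), aff), p)
        paths[name] = p
    paths["lesion_table"] = directory / "lesion_table.csv"
    case.lesion_table.to_csv(paths["lesion_table"], index=False)
    paths["meta"] = directory / "meta.yaml"
    with open(paths["meta"], "w") as fh:
        yaml.safe_dump(
            {"case_id": case.case_id, "spacing_mm": [float(s) for s in case.spacing_mm]},
            fh,
        )
    return paths


def read_case(directory) -> MpMRICase:
    """Inverse of :func:`write_case`; raises naming any missing file."""
    directory = Path(directory)
    volumes = {}
    for name in CHANNELS + MASKS:
        p = directory / f"{name}.nii.gz"
        if not p.exists():
            raise FileNotFoundError(f"missing volume file: {p}")
        data = np.asanyarray(nib.load(p).dataobj)
        volumes[name] = data.astype(np.uint8 if name in MASKS else np.float32)
    table_path = directory / "lesion_table.csv"
    if not table_path.exists():
        raise FileNotFoundError(f"missing lesion table: {table_path}")
    table = pd.read_csv(table_path)
    if table.empty:
        table = pd.DataFrame(
            columns=["case_id", "lesion_id", "zone", "cz", "cy", "cx", "radius_mm"]
        )
    meta_path = directory / "meta.yaml"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing sidecar: {meta_path}")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    case = MpMRICase(
        **volumes,
        lesion_table=table,
        spacing_mm=tuple(meta["spacing_mm"]),
        case_id=str(meta["case_id"]),
    )
    case.validate()
    return case


def spec_to_yaml(spec: PhantomSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(spec), fh)


def spec_from_yaml(path) -> PhantomSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    fields = {f.name for f in dataclasses.fields(PhantomSpec)}
    kwargs = {k: tuple(v) if isinstance(v, list) else v
              for k, v in raw.items() if k in fields}
    return PhantomSpec(**kwargs)
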