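"""Lesion detection scoring and FROC / patient-level ROC evaluation.

Detections are the strict local maxima (26-neighbourhood) of the model's
lesion-probability channel, greedily non-maximum-suppressed in world
(millimetre) space.  A detection is a true positive when it falls within
``radius_mm`` (default 5 mm) of any ground-truth lesion voxel, measured
to the nearest lesion voxel centre — a shape-aware reading that tolerates
small registration mismatch between imaging and histopathology.  A lesion
counts as detected when at least one true-positive point maps to it;
extra true positives on an already-detected lesion never become false
positives.

The FROC curve sweeps a threshold over all detection scores and reports
lesion sensitivity against the mean number of false positives per
patient; operating-point sensitivities use the right-continuous step
convention (the sensitivity at the largest achieved FP rate not exceeding
the operating point).  Patient-level classification uses the maximum of
the probability map as the patient score and a rank-based (Mann–Whitney)
AUC; confidence intervals come from bootstrap resampling of patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "DetectionPoint", "DetectionSet", "FROCResult",
    "extract_detections", "adjudicate", "froc", "sensitivity_at",
    "fp_at_sensitivity", "patient_score", "roc_auc", "bootstrap_ci",
    "make_cv_splits", "OPERATING_POINTS",
]

OPERATING_POINTS = (0.5, 1.0, 1.5, 2.0, 2.5)


@dataclass(frozen=True)
class DetectionPoint:
    voxel: tuple[int, int, int]
    score: float
    world_mm: tuple[float, float, float]


@dataclass
class DetectionSet:
    """Adjudicated detections of one case."""

    case_id: str
    points: list[DetectionPoint]
    is_tp: np.ndarray          # bool per point
    lesion_id: np.ndarray      # component id per point (-1 for FP)
    n_lesions: int

    @property
    def scores(self) -> np.ndarray:
        return np.array([p.score for p in self.points], dtype=float)

    def lesion_detection_scores(self) -> np.ndarray:
        """Best TP score per lesion (-inf when a lesion was never hit)."""
        best = np.full(self.n_lesions, -np.inf)
        for score, tp, lid in zip(self.scores, self.is_tp, self.lesion_id):
            if tp:
                best[lid] = max(best[lid], score)
        return best

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(case_id=self.case_id, z=p.voxel[0], y=p.voxel[1], x=p.voxel[2],
                 score=p.score, adjudication="TP" if tp else "FP")
            for p, tp in zip(self.points, self.is_tp)
        ]
        return pd.DataFrame(rows, columns=["case_id", "z", "y", "x", "score",
                                           "adjudication"])


@dataclass
class FROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    fp_per_patient: np.ndarray
    operating_sensitivity: dict[float, float]
    ci: dict[float, tuple[float, float]] = field(default_factory=dict)


def _score_channel(prob_map: np.ndarray, channel: str) -> np.ndarray:
    prob_map = np.asarray(prob_map)
    if prob_map.ndim == 3:
        return prob_map
    if prob_map.ndim != 4:
        raise ValueError("probability map must be (C, D, H, W) or (D, H, W)")
    if channel == "p0":
        return prob_map[0]
    if channel == "p1":
        return prob_map[1]
    if channel == "max":
        return prob_map.max(axis=0)
    raise ValueError(f"unknown detection channel {channel!r}")


def extract_detections(prob_map: np.ndarray, min_score: float = 0.1,
                       min_separation_mm: float = 5.0,
                       spacing: tuple[float, float, float] = (3.0, 0.625, 0.625),
                       channel: str = "p0") -> list[DetectionPoint]:
    """Strict 26-neighbourhood local maxima with greedy world-space NMS,
    sorted by descending score."""
    vol = _score_channel(prob_map, channel)
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    neighbour_max = ndimage.maximum_filter(vol, footprint=footprint,
                                           mode="constant", cval=-np.inf)
    # candidates: at least as high as every neighbour.  A saturated model
    # output forms constant plateaus (e.g. sigmoid == 1.0 in float32), so a
    # connected plateau strictly above its surroundings counts as ONE
    # detection at the voxel nearest its centroid; a component whose border
    # touches an equal-valued non-candidate voxel is a shoulder, not a
    # maximum, and a plateau spanning the whole volume (constant map) has no
    # surroundings to dominate and yields nothing.
    cand = (vol >= neighbour_max) & (vol >= min_score)
    labels, n_comp = ndimage.label(cand, structure=np.ones((3, 3, 3)))
    peaks, scores = [], []
    for comp, sl in zip(range(1, n_comp + 1), ndimage.find_objects(labels)):
        grown = tuple(slice(max(s.start - 1, 0), min(s.stop + 1, dim))
                      for s, dim in zip(sl, vol.shape))
        mask = labels[grown] == comp
        if mask.size == vol.size and mask.all():
            continue
        local = vol[grown]
        value = local[mask].flat[0]
        border = ndimage.binary_dilation(mask, structure=np.ones((3, 3, 3))) & ~mask
        if np.any(local[border] >= value):
            continue
        coords = np.argwhere(mask) + [g.start for g in grown]
        rep = coords[np.argmin(((coords - coords.mean(axis=0)) ** 2).sum(axis=1))]
        peaks.append(rep)
        scores.append(value)
    if not peaks:
        return []
    peaks = np.array(peaks)
    scores = np.array(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    peaks, scores = peaks[order], scores[order]
    world = peaks * np.asarray(spacing)

    kept: list[int] = []
    for i in range(len(peaks)):
        if all(np.linalg.norm(world[i] - world[j]) >= min_separation_mm
               for j in kept):
            kept.append(i)
    return [
        DetectionPoint(tuple(int(v) for v in peaks[i]), float(scores[i]),
                       tuple(float(w) for w in world[i]))
        for i in kept
    ]


def adjudicate(points: list[DetectionPoint], lesion_mask: np.ndarray,
               spacing: tuple[float, float, float], radius_mm: float = 5.0,
               case_id: str = "case") -> DetectionSet:
    """TP iff the world-space distance to the nearest lesion voxel centre is
    <= radius_mm; the point is assigned to that voxel's connected component."""
    if spacing is None:
        raise ValueError("voxel spacing is required for millimetre adjudication")
    labels, n_lesions = ndimage.label(np.asarray(lesion_mask) > 0)
    is_tp = np.zeros(len(points), dtype=bool)
    lesion_id = np.full(len(points), -1, dtype=int)
    if n_lesions and points:
        lesion_vox = np.argwhere(labels > 0)
        tree = cKDTree(lesion_vox * np.asarray(spacing))
        query = np.array([p.world_mm for p in points])
        dist, idx = tree.query(query)
        hit = dist <= radius_mm
        is_tp[hit] = True
        lesion_id[hit] = labels[tuple(lesion_vox[idx[hit]].T)] - 1
    return DetectionSet(case_id, list(points), is_tp, lesion_id, int(n_lesions))


def froc(detection_sets: list[DetectionSet],
         operating_points=OPERATING_POINTS) -> FROCResult:
    """Threshold sweep over the union of detection scores."""
    if not detection_sets:
        raise ValueError("need at least one case")
    n_cases = len(detection_sets)
    total_lesions = sum(ds.n_lesions for ds in detection_sets)
    if total_lesions == 0:
        raise ValueError("sensitivity undefined: no lesions in the cohort")

    lesion_scores = np.concatenate(
        [ds.lesion_detection_scores() for ds in detection_sets]
        or [np.empty(0)]
    )
    fp_scores = np.concatenate(
        [ds.scores[~ds.is_tp] for ds in detection_sets] or [np.empty(0)]
    )
    all_scores = np.concatenate([ds.scores for ds in detection_sets])
    thresholds = np.unique(all_scores)[::-1]
    if thresholds.size == 0:
        thresholds = np.array([np.inf])

    lesion_sorted = np.sort(lesion_scores)
    fp_sorted = np.sort(fp_scores)
    sens = np.empty(thresholds.size)
    fp_rate = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        sens[i] = (lesion_sorted.size - np.searchsorted(lesion_sorted, t,
                                                        side="left")) / total_lesions
        fp_rate[i] = (fp_sorted.size - np.searchsorted(fp_sorted, t,
                                                       side="left")) / n_cases

    operating = {
        float(fp): sensitivity_at(fp_rate, sens, fp) for fp in operating_points
    }
    return FROCResult(thresholds, sens, fp_rate, operating)


def sensitivity_at(fp_rate: np.ndarray, sens: np.ndarray, fp_level: float) -> float:
    """Right-continuous step convention: sensitivity of the largest achieved
    FP rate not exceeding `fp_level` (0 when no threshold achieves it)."""
    ok = np.asarray(fp_rate) <= fp_level
    return float(np.asarray(sens)[ok].max()) if ok.any() else 0.0


def fp_at_sensitivity(result: FROCResult, target: float = 0.8) -> float:
    """Smallest mean FP/patient at which sensitivity >= target (inf if never)."""
    reached = result.sensitivity >= target
    return float(result.fp_per_patient[reached].min()) if reached.any() else np.inf


def patient_score(prob_map: np.ndarray, channel: str = "p0") -> float:
    """Patient-level probability of disease: maximum of the lesion channel."""
    return float(_score_channel(prob_map, channel).max())


def roc_auc(scores, labels) -> float:
    """Rank-based AUC (the normalized Mann–Whitney U statistic)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def bootstrap_ci(metric_fn, cases: list, n_boot: int = 1000, level: float = 0.95,
                 seed: int = 0) -> tuple[float, float]:
    """Percentile CI of `metric_fn(list_of_cases)` under patient resampling.

    Resamples that leave the metric undefined (e.g. a single-class draw)
    are skipped.
    """
    rng = np.random.default_rng(seed)
    n = len(cases)
    stats = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            stats.append(metric_fn([cases[i] for i in idx]))
        except ValueError:
            continue
    if not stats:
        raise ValueError("metric undefined on every bootstrap resample")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def make_cv_splits(case_ids: list, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Random k-fold partition; fold sizes differ by at most one."""
    case_ids = np.asarray(case_ids)
    if k > case_ids.size:
        raise ValueError(f"k={k} exceeds the number of cases ({case_ids.size})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(case_ids.size)
    return [case_ids[np.sort(chunk)] for chunk in np.array_split(perm, k)]
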