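"""Training loop and ablation driver.

The optimization protocol: Adam, a fixed epoch budget with early stopping
when the training loss has not improved for a set number of consecutive
epochs, focal loss on binary labels as the baseline objective and the
zonal loss as the anatomy-aware alternative.  The ablation grid crosses
{symmetric dual-path, single-path} x {zonal, focal-binary}; the
single-path arm feeds the original stack to both encoder inputs, which
removes the mirrored view while keeping the parameter count identical.

Everything is seeded: weight initialization through ``ModelConfig.seed``
and data order through ``TrainConfig.seed``, so a rerun with the same
seeds reproduces the loss history exactly.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import nn
from .labels import encode_binary, encode_hierarchical
from .phantom import MpMRICase
from .sym_net import ModelConfig, SymNet, build_model
from .zonal_loss import LossConfig, focal_loss_binary_t, zonal_loss_t
from . import detect_eval as de

__all__ = ["TrainConfig", "prepare_case", "train", "evaluate_model", "run_ablation"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 60
    early_stop_patience: int = 30
    lr: float = 1e-3
    batch_size: int = 2
    loss: str = "zonal"           # "zonal" | "focal_binary"
    loss_cfg: LossConfig = LossConfig()
    symmetric: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.early_stop_patience > self.epochs:
            raise ValueError("patience must not exceed the epoch budget")
        if self.lr <= 0:
            raise ValueError("learning rate must be > 0")
        if self.loss not in ("zonal", "focal_binary"):
            raise ValueError("loss must be 'zonal' or 'focal_binary'")


def prepare_case(case: MpMRICase, loss: str) -> tuple[np.ndarray, np.ndarray]:
    """(input stack, label volume) for one case under the given objective."""
    stack = case.channel_stack()
    if loss == "zonal":
        label = encode_hierarchical(case.lesion_mask, case.tz_mask, case.pz_mask)
    else:
        label = encode_binary(case.lesion_mask)
    return stack, label.astype(np.float32)


def train(model: SymNet, cases: list[tuple[np.ndarray, np.ndarray]],
          cfg: TrainConfig) -> tuple[SymNet, list[float]]:
    """Fit `model` on (stack, label) pairs; returns it holding the
    best-loss weights, plus the per-epoch mean loss history."""
    if not cases:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.lr)
    loss_fn = zonal_loss_t if cfg.loss == "zonal" else focal_loss_binary_t

    history: list[float] = []
    best_loss = np.inf
    best_state = model.state_dict()
    stale = 0
    n = len(cases)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            stacks = np.stack([cases[i][0] for i in idx])
            labels = np.stack([cases[i][1] for i in idx])
            x = nn.Tensor(stacks)
            mirrored = None if cfg.symmetric else x
            probs = model.forward(x, mirrored)
            loss = loss_fn(probs, labels, cfg.loss_cfg)
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss ({value}) at step {start}; "
                    "lower the learning rate or check the inputs"
                )
            epoch_loss += value * len(idx)
            opt.zero_grad()
            loss.backward()
            opt.step()
        epoch_loss /= n
        history.append(epoch_loss)
        if epoch_loss < best_loss - 1e-12:
            best_loss = epoch_loss
            best_state = copy.deepcopy(model.state_dict())
            stale = 0
        else:
            stale += 1
            if stale > cfg.early_stop_patience:
                break
    model.load_state_dict(best_state)
    return model, history


def evaluate_model(model: SymNet, cases: list[MpMRICase], symmetric: bool = True,
                   min_score: float = 0.1, min_separation_mm: float = 5.0,
                   radius_mm: float = 5.0) -> dict:
    """FROC + patient-level metrics of a trained model on held-out cases."""
    detection_sets = []
    scores, labels = [], []
    for case in cases:
        prob = model.predict(case.channel_stack(), single_path=not symmetric)
        points = de.extract_detections(prob, min_score=min_score,
                                       min_separation_mm=min_separation_mm,
                                       spacing=case.spacing_mm)
        detection_sets.append(
            de.adjudicate(points, case.lesion_mask, case.spacing_mm,
                          radius_mm=radius_mm, case_id=case.case_id)
        )
        scores.append(de.patient_score(prob))
        labels.append(int(case.lesion_mask.any()))
    result = de.froc(detection_sets)
    metrics = {
        "froc": result,
        "detection_sets": detection_sets,
        "fp_at_sens80": de.fp_at_sensitivity(result, 0.8),
        "patient_scores": np.array(scores),
        "patient_labels": np.array(labels),
    }
    for fp, s in result.operating_sensitivity.items():
        metrics[f"sens_at_{fp:g}_fp"] = s
    try:
        metrics["patient_auc"] = de.roc_auc(scores, labels)
    except ValueError:
        metrics["patient_auc"] = np.nan
    return metrics


ABLATION_GRID = (
    {"symmetric": False, "loss": "focal_binary"},
    {"symmetric": False, "loss": "zonal"},
    {"symmetric": True, "loss": "focal_binary"},
    {"symmetric": True, "loss": "zonal"},
)


def run_ablation(train_cases: list[MpMRICase], test_cases: list[MpMRICase],
                 model_cfg: ModelConfig, train_cfg: TrainConfig,
                 grid=ABLATION_GRID, n_boot: int = 0) -> pd.DataFrame:
    """Train every arm of the grid on identical cases and seeds.

    Returns one row per arm with the FROC operating-point sensitivities,
    the patient AUC, and the mean FP/patient needed for 0.8 sensitivity.
    With ``n_boot > 0``, bootstrap CIs over test patients are added for the
    operating-point sensitivities.
    """
    rows = []
    for arm in grid:
        out_channels = 2 if arm["loss"] == "zonal" else 1
        cfg_m = replace(model_cfg, out_channels=out_channels)
        cfg_t = replace(train_cfg, symmetric=arm["symmetric"], loss=arm["loss"])
        model = build_model(cfg_m)
        prepared = [prepare_case(c, arm["loss"]) for c in train_cases]
        model, history = train(model, prepared, cfg_t)
        metrics = evaluate_model(model, test_cases, symmetric=arm["symmetric"])
        row = {
            "symmetric": arm["symmetric"],
            "loss": arm["loss"],
            "patient_auc": metrics["patient_auc"],
            "fp_at_sens80": metrics["fp_at_sens80"],
            "final_train_loss": history[-1],
        }
        for fp in de.OPERATING_POINTS:
            row[f"sens_at_{fp:g}_fp"] = metrics[f"sens_at_{fp:g}_fp"]
        if n_boot > 0:
            sets = metrics["detection_sets"]
            for fp in de.OPERATING_POINTS:
                lo, hi = de.bootstrap_ci(
                    lambda subset, fp=fp: de.froc(subset).operating_sensitivity[fp],
                    sets, n_boot=n_boot, seed=cfg_t.seed,
                )
                row[f"sens_at_{fp:g}_fp_ci"] = (lo, hi)
        rows.append(row)
    return pd.DataFrame(rows)
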