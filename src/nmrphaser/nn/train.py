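"""Training loop, Adam optimizer, inference helpers and checkpoints.

Training follows the published recipe: Adam (learning rate 1e-4, weight
decay 1e-5), mini-batch size 4, categorical cross-entropy, and a two-stage
curriculum — pretraining on a coarse-error dataset (easier to
discriminate), then fine-tuning on the fine-error dataset.  "Episodes" are
interpreted as epochs.  All randomness flows from ``TrainConfig.seed``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict, field
from typing import List, Optional, Sequence

import numpy as np

from ..spectrum import Spectrum1D
from .model import CLASS_ORDER, NetConfig, PhaseClassifier, preprocess_input
from .layers import softmax, softmax_cross_entropy

__all__ = [
    "TrainConfig",
    "ClassifierOutput",
    "Adam",
    "train",
    "predict",
    "predict_batch",
    "save_checkpoint",
    "load_checkpoint",
]

logger = logging.getLogger(__name__)

LABEL_TO_INDEX = {name: i for i, name in enumerate(CLASS_ORDER)}


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (published defaults)."""

    epochs: int = 400
    batch_size: int = 4
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    seed: int = 0
    curriculum: str = "both"  # pretrain | finetune | both
    #: exact-symmetry augmentation: reverse the spectrum and conjugate it,
    #: giving the mirror-image sample with identical PH1 error and negated
    #: PH0 (a label swap for the ph0 task); mirrored ph1 samples are
    #: re-rotated so the PH0 companion keeps the equal-magnitude design.
    #: None = auto (enabled).
    mirror_augment: "bool | None" = None
    #: fraction of ph1-task samples whose PH0 companion is rotated to an
    #: arbitrary value (uniform up to the coarse range) instead of the
    #: matched +-|PH1| pairing: the iterative corrector queries the ph1
    #: model at states with already-corrected PH0, which the matched-only
    #: design never shows
    companion_randomize: float = 0.35
    #: label smoothing applied to the cross-entropy targets
    label_smoothing: float = 0.0
    #: average the weights of the last third of fine-tuning epochs (SWA) and
    #: keep whichever of {best-validation epoch, averaged weights} validates
    #: better
    weight_averaging: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.label_smoothing < 1.0:
            raise ValueError("label_smoothing must be in [0, 1)")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("invalid optimizer rates")
        if self.curriculum not in ("pretrain", "finetune", "both"):
            raise ValueError("curriculum must be pretrain | finetune | both")


@dataclass
class ClassifierOutput:
    """Probabilities and logits over (negative, zero, positive)."""

    probs: np.ndarray
    logits: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.logits = np.asarray(self.logits, dtype=float)
        if self.probs.shape != (3,) or self.logits.shape != (3,):
            raise ValueError("probs and logits must be 3-vectors")
        if np.any(self.probs < 0) or abs(self.probs.sum() - 1.0) > 1e-6:
            raise ValueError("probs must be a distribution summing to 1")

    @property
    def argmax_label(self) -> str:
        return CLASS_ORDER[int(np.argmax(self.probs))]

    @property
    def zero_prob(self) -> float:
        return float(self.probs[LABEL_TO_INDEX["zero"]])


class Adam:
    """Adam with decoupled weight decay over a model's parameter list."""

    def __init__(self, model: PhaseClassifier, lr: float, weight_decay: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.model = model
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(layer.params[k])
                  for name, layer, k in model.parameters()}
        self.v = {name: np.zeros_like(layer.params[k])
                  for name, layer, k in model.parameters()}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for name, layer, k in self.model.parameters():
            g = layer.grads[k]
            m = self.m[name]
            v = self.v[name]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if self.wd:
                update = update + self.wd * layer.params[k]
            layer.params[k] = layer.params[k] - self.lr * update


def _dataset_arrays(samples: Sequence, cfg: NetConfig, with_phase: bool = False):
    """Stack a list of TrainingSample into (X, y[, true phases]) arrays."""
    if not samples:
        raise ValueError("dataset is empty")
    lengths = {len(s.spectrum) for s in samples}
    if len(lengths) > 1:
        raise ValueError(
            "samples of mixed lengths must be batched per length; "
            f"got lengths {sorted(lengths)}"
        )
    X = np.stack([preprocess_input(s.spectrum, cfg) for s in samples])
    y = np.array([LABEL_TO_INDEX[s.label] for s in samples], dtype=np.intp)
    if with_phase:
        P = np.array(
            [(s.true_phase.ph0, s.true_phase.ph1) for s in samples], dtype=float
        )
        return X, y, P
    return X, y


def _rotate_inputs(xb: np.ndarray, idx: np.ndarray, delta_deg: np.ndarray) -> None:
    """Rotate selected samples by a constant phase (degrees), in place.

    A constant rotation of the complex spectrum is exact and renormalizes
    the channels the same way the preprocessor would.
    """
    delta = np.deg2rad(delta_deg)
    cos_d = np.cos(delta)[:, None].astype(xb.dtype)
    sin_d = np.sin(delta)[:, None].astype(xb.dtype)
    re, im = xb[idx, 0], xb[idx, 1]
    re2 = re * cos_d - im * sin_d
    im2 = re * sin_d + im * cos_d
    scale = np.max(np.abs(re2), axis=1, keepdims=True)
    xb[idx, 0] = re2 / scale
    xb[idx, 1] = im2 / scale


def _mirror_batch(xb: np.ndarray, yb: np.ndarray, pb: np.ndarray, task: str,
                  mask: np.ndarray, rng: np.random.Generator,
                  companion_max: float = 10.0,
                  randomize_frac: float = 0.35):
    """Exact-symmetry batch augmentation.

    Mirror (reverse + conjugate): maps a spectrum with phase error
    (PH0, PH1) onto the mirror-image spectrum with error (-PH0 - PH1, PH1)
    — the first-order label is preserved, the pure zeroth-order label
    changes sign.  In channel terms: real reversed, imaginary reversed and
    negated.  Applied to the masked samples of the batch.

    For the ph1 task the mirrored companion error ``-PH0 - PH1`` falls
    outside the equal-magnitude training design, so mirrored samples are
    additionally rotated by the known constant phase that restores a
    companion of ``+-|PH1|`` with a fresh random sign, keeping them exactly
    in-distribution.  (``companion_max`` is kept for experimentation with
    uniformly randomized companions; the matched-companion form is the
    default recipe.)
    """
    xb = xb.copy()
    yb = yb.copy()
    xb[mask, 0] = xb[mask, 0, ::-1]
    xb[mask, 1] = -xb[mask, 1, ::-1]
    if task == "ph0":
        yb[mask] = 2 - yb[mask]  # negative <-> positive, zero fixed
    else:
        n = len(yb)
        ph0_now = np.where(mask, -(pb[:, 0] + pb[:, 1]), pb[:, 0])
        matched = rng.choice([-1.0, 1.0], size=n) * np.abs(pb[:, 1])
        randomized = rng.uniform(-companion_max, companion_max, size=n)
        target = np.where(rng.random(n) < randomize_frac, randomized, matched)
        delta = target - ph0_now
        idx = np.where(np.abs(delta) > 1e-12)[0]
        if idx.size:
            _rotate_inputs(xb, idx, delta[idx])
    return xb, yb


def _run_epochs(model, X, y, P, Xv, yv, tcfg: TrainConfig, epochs: int,
                rng: np.random.Generator, history: List[dict], stage: str,
                opt: Adam) -> None:
    n = X.shape[0]
    task = getattr(model, "task", "ph0")
    best = {"val_accuracy": -1.0, "state": None}
    swa_from = epochs - max(1, epochs // 3)
    swa_sum: dict = {}
    swa_count = 0
    for epoch in range(epochs):
        # cosine decay of the learning rate over the stage
        opt.lr = tcfg.learning_rate * 0.5 * (
            1.0 + math.cos(math.pi * epoch / max(epochs, 1))
        )
        model.set_training(True)
        order = rng.permutation(n)
        losses = []
        correct = 0
        for start in range(0, n, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            xb, yb = X[idx], y[idx]
            use_mirror = (
                tcfg.mirror_augment if tcfg.mirror_augment is not None else True
            )
            if use_mirror:
                mask = rng.random(len(idx)) < 0.5
                if mask.any() or task == "ph1":
                    xb, yb = _mirror_batch(
                        xb, yb, P[idx], task, mask, rng,
                        companion_max=20.0 if stage == "pretrain" else 10.0,
                        randomize_frac=tcfg.companion_randomize,
                    )
            logits = model.forward(xb)
            loss, g = softmax_cross_entropy(logits, yb, tcfg.label_smoothing)
            if not math.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (loss={loss}) at {stage} epoch {epoch}"
                )
            model.zero_grad()
            model.backward(g.astype(logits.dtype))
            opt.step()
            losses.append(loss)
            correct += int(np.sum(np.argmax(logits, axis=1) == yb))
        rec = {
            "stage": stage,
            "epoch": epoch,
            "loss": float(np.mean(losses)),
            "accuracy": correct / n,
        }
        if Xv is not None:
            va, vl = evaluate(model, Xv, yv)
            rec["val_accuracy"] = va
            rec["val_loss"] = vl
            if stage == "finetune" and va > best["val_accuracy"]:
                best = {"val_accuracy": va, "state": model.state_dict()}
        if (tcfg.weight_averaging and stage == "finetune"
                and epoch >= swa_from):
            state = model.state_dict()
            for key, val in state.items():
                if key in swa_sum:
                    swa_sum[key] += val
                else:
                    swa_sum[key] = val.astype(np.float64)
            swa_count += 1
        history.append(rec)
        logger.info(
            "%s epoch %d: loss=%.4f acc=%.3f%s",
            stage,
            epoch,
            rec["loss"],
            rec["accuracy"],
            f" val_acc={rec.get('val_accuracy', float('nan')):.3f}"
            if Xv is not None
            else "",
        )
    # candidate final weights: averaged tail-of-training (SWA) vs the best
    # single validation epoch; keep whichever validates better
    if swa_count and Xv is not None:
        swa_state = {k: (v / swa_count) for k, v in swa_sum.items()}
        current = model.state_dict()
        model.load_state_dict(swa_state)
        swa_acc, _ = evaluate(model, Xv, yv)
        if swa_acc > best["val_accuracy"]:
            best = {"val_accuracy": swa_acc, "state": swa_state}
            history.append({"stage": stage, "epoch": "swa", "val_accuracy": swa_acc})
        else:
            model.load_state_dict(current)
    # keep the best-validation weights of the fine-tuning stage
    if best["state"] is not None:
        model.load_state_dict(best["state"])
        history.append(
            {"stage": stage, "epoch": "best", "val_accuracy": best["val_accuracy"]}
        )


def _mirror_inputs(X: np.ndarray) -> np.ndarray:
    """Reverse-and-conjugate a batch of preprocessed inputs."""
    Xm = X[:, :, ::-1].copy()
    if Xm.shape[1] > 1:
        Xm[:, 1] *= -1
    return Xm


def _batch_probs(model: PhaseClassifier, X: np.ndarray, tta):
    """(probs, logits) for a batch, optionally mirror-ensembled.

    For the ph0 task the mirror transform is an exact, in-distribution
    symmetry (it negates PH0 and swaps the outer classes), so averaging the
    permuted class probabilities of the original and mirrored inputs is a
    free two-view ensemble.  For ph1 the transform moves the accompanying
    PH0 error outside the training design (equal-magnitude companion), so
    the ensemble is disabled there; ``tta=None`` selects this per-task
    default automatically.
    """
    logits = model.forward(X)
    probs = softmax(logits.astype(float), axis=-1)
    if tta is None:
        tta = getattr(model, "task", "ph0") == "ph0"
    if tta and getattr(model, "task", "ph0") == "ph0":
        pm = softmax(model.forward(_mirror_inputs(X)).astype(float), axis=-1)
        probs = 0.5 * (probs + pm[:, ::-1])  # negative <-> positive under mirror
    return probs, logits


def evaluate(model: PhaseClassifier, X: np.ndarray, y: np.ndarray,
             batch: int = 16, tta=None):
    """(accuracy, mean loss) of a model on stacked arrays."""
    model.set_training(False)
    losses = []
    correct = 0
    eps = 1e-12
    for start in range(0, X.shape[0], batch):
        yb = y[start : start + batch]
        probs, _ = _batch_probs(model, X[start : start + batch], tta)
        losses.append(float(-np.sum(np.log(probs[np.arange(len(yb)), yb] + eps))))
        correct += int(np.sum(np.argmax(probs, axis=1) == yb))
    return correct / X.shape[0], float(np.sum(losses) / X.shape[0])


def train(
    model: PhaseClassifier,
    train_set: Sequence,
    val_set: Optional[Sequence],
    tcfg: TrainConfig,
    pretrain_set: Optional[Sequence] = None,
    pretrain_epochs: Optional[int] = None,
):
    """Train a classifier, optionally with the two-stage curriculum.

    With ``curriculum='both'`` the model first runs ``pretrain_epochs``
    epochs on ``pretrain_set`` (coarse 5–10° / 5–20° errors), then
    ``tcfg.epochs`` on ``train_set`` (fine errors).  Returns
    ``(model, history)`` where history holds one record per epoch with
    loss/accuracy (and validation metrics when a validation set is given).
    Fully deterministic for a fixed ``tcfg.seed``.
    """
    if not train_set and tcfg.curriculum != "pretrain":
        raise ValueError("empty training set")
    rng = np.random.default_rng(tcfg.seed)
    history: List[dict] = []
    opt = Adam(model, tcfg.learning_rate, tcfg.weight_decay)

    Xv = yv = None
    if val_set:
        Xv, yv = _dataset_arrays(val_set, model.cfg)

    if tcfg.curriculum in ("pretrain", "both"):
        if not pretrain_set:
            raise ValueError("curriculum includes pretraining but no pretrain_set given")
        Xp, yp, Pp = _dataset_arrays(pretrain_set, model.cfg, with_phase=True)
        n_pre = pretrain_epochs if pretrain_epochs is not None else tcfg.epochs
        _run_epochs(model, Xp, yp, Pp, Xv, yv, tcfg, n_pre, rng, history, "pretrain", opt)

    if tcfg.curriculum in ("finetune", "both"):
        X, y, P = _dataset_arrays(train_set, model.cfg, with_phase=True)
        _run_epochs(model, X, y, P, Xv, yv, tcfg, tcfg.epochs, rng, history, "finetune", opt)

    return model, history


def predict(model: PhaseClassifier, spec: Spectrum1D,
            tta=None) -> ClassifierOutput:
    """Deterministic inference on one spectrum (mirror-ensembled by default)."""
    model.set_training(False)
    x = preprocess_input(spec, model.cfg)
    probs, logits = _batch_probs(model, x[None], tta)
    return ClassifierOutput(probs=probs[0], logits=logits[0].astype(float))


def predict_batch(model: PhaseClassifier, specs: Sequence[Spectrum1D],
                  batch: int = 16, tta=None) -> List[ClassifierOutput]:
    """Inference on a list of equal-length spectra (batched for speed)."""
    model.set_training(False)
    X = np.stack([preprocess_input(s, model.cfg) for s in specs])
    outs: List[ClassifierOutput] = []
    for start in range(0, X.shape[0], batch):
        probs, logits = _batch_probs(model, X[start : start + batch], tta)
        for p, l in zip(probs, logits):
            outs.append(ClassifierOutput(probs=p, logits=l.astype(float)))
    return outs


# ---------------------------------------------------------------------------
# checkpoints: one .npz holding every weight plus a JSON config manifest
# ---------------------------------------------------------------------------


def save_checkpoint(path, model: PhaseClassifier, task: str,
                    synth_config_hash: str = "", extra: Optional[dict] = None) -> None:
    """Write weights + embedded JSON manifest to a single ``.npz`` file."""
    manifest = {
        "format": "nmrphaser-checkpoint-v1",
        "task": task,
        "net_config": asdict(model.cfg),
        "synth_config_hash": synth_config_hash,
        "class_order": list(CLASS_ORDER),
    }
    if extra:
        manifest.update(extra)
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    arrays["manifest_json"] = np.frombuffer(
        json.dumps(manifest, sort_keys=True).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path, expect_task: Optional[str] = None) -> PhaseClassifier:
    """Rebuild a classifier from a checkpoint, validating compatibility."""
    with np.load(path) as data:
        try:
            manifest = json.loads(bytes(data["manifest_json"]).decode())
        except KeyError as exc:
            raise ValueError(f"{path}: not an nmrphaser checkpoint") from exc
        if manifest.get("format") != "nmrphaser-checkpoint-v1":
            raise ValueError(f"{path}: unknown checkpoint format")
        if expect_task and manifest["task"] != expect_task:
            raise ValueError(
                f"{path}: checkpoint is for task {manifest['task']!r}, "
                f"expected {expect_task!r}"
            )
        ncfg = manifest["net_config"]
        for key in ("conv_channels", "conv_kernels", "conv_strides"):
            ncfg[key] = tuple(ncfg[key])
        cfg = NetConfig(**ncfg)
        model = PhaseClassifier(cfg, seed=0)
        state = {
            k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")
        }
        model.load_state_dict(state)
    model.task = manifest["task"]
    model.synth_config_hash = manifest.get("synth_config_hash", "")
    return model
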