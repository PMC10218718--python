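"""3-class patch classification with three transfer-learning setups.

The classifier assigns each 224x224 stain-normalized patch to *tumor*,
*stroma* or *other* through a softmax output of dimension 3. Three
pre-training sequences are supported, differing only in how the model is
initialized and whether a domain-specific source dataset is used before
fine-tuning on the target training set:

* **SETUP-1** — start from shared pretrained weights, pre-train on the
  domain dataset, then fine-tune on the target set;
* **SETUP-2** — start from shared pretrained weights and fine-tune on the
  target set directly;
* **SETUP-3** — start from random weights, pre-train on the domain dataset,
  then fine-tune on the target set.

For the default numpy backbone the "shared pretrained weights" are a fixed,
documented initialization (the same parameter draw for every run), which
preserves what the setups compare — the pre-training *sequence* — at desk
scale; adapters for published large architectures can supply real pretrained
weights through the same interface.

Fine-tuning follows the standard protocol: hyperparameters by 5-fold
cross-validation on the training set, the epoch budget by early stopping on
a held-out third of the training patches, and a final retraining on the full
training set for that many epochs. Every stage executed is recorded in the
model's provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from tsr_slide.datatypes import CLASS_NAMES, PatchSet
from tsr_slide.nn import SmallCNN, TrainHistory
from tsr_slide.util import derive_seed, downsample_patches

logger = logging.getLogger(__name__)

#: Fixed parameter draw shared by every "pretrained" initialization.
SURROGATE_INIT_SEED = 76_301

SETUPS = ("SETUP1", "SETUP2", "SETUP3")

DEFAULT_GRID = [{"lr": 0.005, "optimizer": "adam", "batch_size": 32}]


@dataclass
class TrainConfig:
    """Configuration of one classifier training run."""

    setup: str = "SETUP2"
    backbone: str = "small-cnn"
    grid: list[dict] = field(default_factory=lambda: [dict(g) for g in DEFAULT_GRID])
    k_folds: int = 5
    val_fraction: float = 1.0 / 3.0
    max_epochs: int = 12
    patience: int = 5
    cv_epochs: int = 6
    pretrain_epochs: int = 5
    early_stopping: bool = True
    input_hw: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.setup not in SETUPS:
            raise ValueError(f"setup must be one of {SETUPS}, got {self.setup!r}")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if not self.grid:
            raise ValueError("hyperparameter grid must be nonempty")


@dataclass
class ClassifierModel:
    """A trained patch classifier plus its training provenance."""

    net: SmallCNN
    class_order: tuple[str, str, str] = CLASS_NAMES
    patch_size: int = 224
    provenance: list[dict] = field(default_factory=list)

    def predict(self, patches: PatchSet | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-patch probability 3-vectors and argmax class indices.

        Probabilities sum to 1 per patch; argmax ties resolve to the lower
        class index, i.e. the fixed order tumor > stroma > other.
        """
        arr = patches.patches if isinstance(patches, PatchSet) else np.asarray(patches)
        if arr.ndim != 4 or arr.shape[1] != self.patch_size or arr.shape[2] != self.patch_size:
            raise ValueError(
                f"expected (N, {self.patch_size}, {self.patch_size}, 3) patches, "
                f"got {arr.shape}"
            )
        x = downsample_patches(arr, self.net.input_hw)
        probs = self.net.predict_proba(x)
        return probs, probs.argmax(axis=1)

    def accuracy(self, patches: PatchSet) -> float:
        if patches.labels is None:
            raise ValueError("patch set has no labels")
        _, pred = self.predict(patches)
        return float((pred == patches.labels).mean())

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.net.params)
        sidecar = {
            "class_order": list(self.class_order),
            "patch_size": self.patch_size,
            "input_hw": self.net.input_hw,
            "channels": list(self.net.channels),
            "provenance": self.provenance,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        net = SmallCNN(
            input_hw=sidecar["input_hw"], channels=tuple(sidecar["channels"])
        )
        with np.load(path.with_suffix(".npz")) as data:
            net.params = {k: data[k] for k in data.files}
        return cls(
            net=net,
            class_order=tuple(sidecar["class_order"]),
            patch_size=sidecar["patch_size"],
            provenance=sidecar["provenance"],
        )


def _make_backbone(config: TrainConfig) -> SmallCNN:
    if config.backbone != "small-cnn":
        raise ValueError(
            f"unknown backbone {config.backbone!r}; register an adapter or use 'small-cnn'"
        )
    return SmallCNN(input_hw=config.input_hw, seed=0)


def _xy(patches: PatchSet, input_hw: int) -> tuple[np.ndarray, np.ndarray]:
    if patches.labels is None:
        raise ValueError("labeled patch set required")
    return downsample_patches(patches.patches, input_hw), np.asarray(patches.labels)


# --------------------------------------------------------------------------
# model selection


def make_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Shuffled partition of range(n) into k folds (sizes differ by <= 1)."""
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    rng = np.random.default_rng(seed)
    return [np.sort(f) for f in np.array_split(rng.permutation(n), k)]


def cross_validate(
    train: PatchSet,
    grid: list[dict],
    k: int = 5,
    seed: int = 0,
    epochs: int = 6,
    base_net: Optional[SmallCNN] = None,
    input_hw: int = 32,
) -> tuple[dict, list[list[float]]]:
    """k-fold CV over a hyperparameter grid; returns (best, per-fold scores).

    Each candidate is scored by its mean held-out-fold accuracy; every fold
    training restarts from ``base_net`` (or a fresh fixed-seed network), so
    candidates differ only in their hyperparameters. Ties keep the earlier
    grid entry.
    """
    if not grid:
        raise ValueError("hyperparameter grid must be nonempty")
    x, y = _xy(train, base_net.input_hw if base_net is not None else input_hw)
    folds = make_folds(len(x), k, derive_seed(seed, "cv-folds"))
    all_idx = np.arange(len(x))

    scores: list[list[float]] = []
    for ci, hp in enumerate(grid):
        fold_scores = []
        for fi, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(all_idx, test_idx)
            net = base_net.clone() if base_net is not None else SmallCNN(input_hw=input_hw, seed=SURROGATE_INIT_SEED)
            net.fit(
                x[train_idx],
                y[train_idx],
                epochs=epochs,
                lr=hp.get("lr", 0.005),
                optimizer=hp.get("optimizer", "adam"),
                batch_size=hp.get("batch_size", 32),
                seed=derive_seed(seed, f"cv-{ci}-{fi}"),
            )
            fold_scores.append(net.accuracy(x[test_idx], y[test_idx]))
        scores.append(fold_scores)
        logger.info("CV candidate %s: mean accuracy %.4f", hp, np.mean(fold_scores))

    means = [float(np.mean(s)) for s in scores]
    best = int(np.argmax(means))  # first maximum -> first in grid order
    return dict(grid[best]), scores


def best_epoch_from_curve(val_accuracies: list[float], patience: int) -> int:
    """Earliest epoch (1-based) achieving the best validation accuracy.

    Mirrors the stopping rule used during training: the best epoch is the
    first one attaining the maximum seen before patience ran out.
    """
    if not val_accuracies:
        raise ValueError("empty validation curve")
    best_acc, best_epoch, since = -np.inf, 0, 0
    for epoch, acc in enumerate(val_accuracies, start=1):
        if acc > best_acc:
            best_acc, best_epoch, since = acc, epoch, 0
        else:
            since += 1
            if since >= patience:
                break
    return best_epoch


def select_epochs_early_stopping(
    train: PatchSet,
    val_fraction: float = 1.0 / 3.0,
    patience: int = 5,
    seed: int = 0,
    max_epochs: int = 12,
    hp: Optional[dict] = None,
    base_net: Optional[SmallCNN] = None,
) -> tuple[int, TrainHistory]:
    """Pick the epoch budget by early stopping on a held-out validation split.

    About ``val_fraction`` of the training patches are held out; training
    stops once validation accuracy has not improved for ``patience`` epochs,
    and the epoch of the (earliest) best validation accuracy is returned
    together with the training history.
    """
    if patience < 1:
        raise ValueError("patience must be >= 1")
    hp = hp or dict(DEFAULT_GRID[0])
    x, y = _xy(train, base_net.input_hw if base_net is not None else 32)
    n = len(x)
    n_val = int(round(n * val_fraction))
    if n_val == 0 or n_val == n:
        raise ValueError(f"validation split of {n_val} samples from {n} is empty")
    rng = np.random.default_rng(derive_seed(seed, "early-stop-split"))
    order = rng.permutation(n)
    val_idx, train_idx = order[:n_val], order[n_val:]

    net = base_net.clone() if base_net is not None else SmallCNN(input_hw=32, seed=SURROGATE_INIT_SEED)

    def stop(_epoch: int, history: TrainHistory) -> bool:
        curve = history.val_accuracy
        best = int(np.argmax(curve))  # first maximum
        return len(curve) - 1 - best >= patience

    history = net.fit(
        x[train_idx],
        y[train_idx],
        epochs=max_epochs,
        lr=hp.get("lr", 0.005),
        optimizer=hp.get("optimizer", "adam"),
        batch_size=hp.get("batch_size", 32),
        seed=derive_seed(seed, "early-stop-train"),
        val=(x[val_idx], y[val_idx]),
        stop_callback=stop,
    )
    best_epoch = best_epoch_from_curve(history.val_accuracy, patience)
    return best_epoch, history


# --------------------------------------------------------------------------
# setups


def run_setup(
    setup: str,
    domain_set: Optional[PatchSet],
    target_train: PatchSet,
    config: Optional[TrainConfig] = None,
) -> ClassifierModel:
    """Train a classifier under one of the three pre-training setups.

    ``domain_set`` (the domain-specific source dataset) is required for
    SETUP1 and SETUP3 and must be absent for SETUP2. The returned model's
    ``provenance`` lists every stage executed, in order.
    """
    config = config or TrainConfig(setup=setup)
    if setup not in SETUPS:
        raise ValueError(f"setup must be one of {SETUPS}, got {setup!r}")
    needs_domain = setup in ("SETUP1", "SETUP3")
    if needs_domain and domain_set is None:
        raise ValueError(f"{setup} requires a domain pre-training set")
    if not needs_domain and domain_set is not None:
        raise ValueError("SETUP2 takes no domain set (direct fine-tuning)")

    net = _make_backbone(config)
    provenance: list[dict] = []
    if setup in ("SETUP1", "SETUP2"):
        net.reinit(SURROGATE_INIT_SEED)
        provenance.append({"stage": "init", "initializer": "pretrained-surrogate"})
    else:
        net.reinit(derive_seed(config.seed, "random-init"))
        provenance.append({"stage": "init", "initializer": "random"})

    hp0 = dict(config.grid[0])
    if needs_domain:
        xd, yd = _xy(domain_set, net.input_hw)
        net.fit(
            xd,
            yd,
            epochs=config.pretrain_epochs,
            lr=hp0.get("lr", 0.005),
            optimizer=hp0.get("optimizer", "adam"),
            batch_size=hp0.get("batch_size", 32),
            seed=derive_seed(config.seed, "pretrain"),
        )
        provenance.append(
            {"stage": "pretrain", "dataset": "domain", "n": len(domain_set),
             "epochs": config.pretrain_epochs}
        )

    snapshot = net.clone()  # fine-tuning stages all start from here

    if len(config.grid) > 1:
        hp, cv_scores = cross_validate(
            target_train,
            config.grid,
            k=config.k_folds,
            seed=config.seed,
            epochs=config.cv_epochs,
            base_net=snapshot,
        )
        provenance.append(
            {"stage": "cross-validation", "k": config.k_folds, "chosen": hp,
             "mean_scores": [float(np.mean(s)) for s in cv_scores]}
        )
    else:
        hp = hp0

    if config.early_stopping:
        epochs, history = select_epochs_early_stopping(
            target_train,
            val_fraction=config.val_fraction,
            patience=config.patience,
            seed=config.seed,
            max_epochs=config.max_epochs,
            hp=hp,
            base_net=snapshot,
        )
        provenance.append(
            {"stage": "early-stopping", "best_epoch": epochs,
             "val_curve": [round(a, 4) for a in history.val_accuracy]}
        )
    else:
        epochs = config.max_epochs

    net = snapshot  # retrain on the full target set from the pre-fine-tune state
    xt, yt = _xy(target_train, net.input_hw)
    net.fit(
        xt,
        yt,
        epochs=epochs,
        lr=hp.get("lr", 0.005),
        optimizer=hp.get("optimizer", "adam"),
        batch_size=hp.get("batch_size", 32),
        seed=derive_seed(config.seed, "finetune"),
    )
    provenance.append(
        {"stage": "finetune", "dataset": "target", "n": len(target_train),
         "epochs": epochs, "hyperparameters": hp}
    )
    return ClassifierModel(
        net=net,
        patch_size=target_train.patches.shape[1],
        provenance=provenance,
    )


def compare_setups(
    domain_set: PatchSet,
    target_train: PatchSet,
    test_set: PatchSet,
    config: Optional[TrainConfig] = None,
):
    """Run all three setups from one config and tabulate test accuracies.

    Returns a one-row-per-backbone DataFrame with a column per setup
    (the shape of a setup-comparison accuracy table) and the per-setup
    trained models.
    """
    import pandas as pd

    config = config or TrainConfig()
    accs, models = {}, {}
    for setup in SETUPS:
        cfg_kwargs = {**config.__dict__, "setup": setup}
        cfg = TrainConfig(**cfg_kwargs)
        model = run_setup(
            setup,
            domain_set if setup in ("SETUP1", "SETUP3") else None,
            target_train,
            cfg,
        )
        models[setup] = model
        accs[f"{setup} accuracy"] = 100.0 * model.accuracy(test_set)
    report = pd.DataFrame(accs, index=[config.backbone])
    return report, models
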