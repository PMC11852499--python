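"""Task-incremental training protocol: Model / Results objects.

`TaskIncrementalModel` is built from an ordered sequence of class-disjoint
task chunks.  ``fit()`` runs the two-phase protocol:

* **Initial phase** (first chunk, at least two classes): the backbone,
  the unified classifier and the per-task self-supervised heads train
  jointly on augmented epochs with the composite loss
  ``L_CE + lambda2 * L_SS``; class prototypes are computed and the
  prototype-conditioned diffusion replayer is trained on the extracted
  features.
* **Incremental phases** (one per further chunk): the backbone is frozen
  except for the convolutional encoder; the classifier grows new output
  rows; features of *all* old classes are replayed by the diffusion
  model and mixed with the new chunk's real features; fresh
  self-supervised heads are trained for the new task; prototypes and the
  replayer are updated.

``fit`` returns an :class:`ILResults` carrying the accuracy matrix,
per-phase Cohen's kappa, the forgetting/transfer metrics and a
``summary()`` table.  ``fit_joint`` trains a joint (non-incremental)
reference model used for the forward-transfer rate.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from . import nn
from .augmentation import AugmentConfig, augment_epochs
from .epochs import EEGEpochs
from .metrics import (AccuracyMatrix, average_accuracy, backward_forgetting_rate,
                      cohen_kappa, confusion_matrix, forward_transfer_rate)
from .mtsfe import BACKBONE_BLOCKS, MTSFE, MTSFEConfig, block_digest
from .pggr import (DiffusionSchedule, DiffusionTrainer, LUNet, LUNetConfig,
                   PrototypeSet, compute_prototypes, sample_replay_features)
from .sstg import (HeadPair, LossConfig, cross_entropy_from_logits, ss_fg_loss,
                   total_training_loss)

__all__ = ["TaskChunk", "TrainConfig", "TaskIncrementalModel", "ILResults",
           "UnifiedClassifier", "derive_seed", "make_task_sequence"]


def derive_seed(master: int, tag: str) -> int:
    """Deterministic per-module seed fan-out from a master seed."""
    return int((int(master) * 1_000_003 + zlib.crc32(tag.encode())) % (2 ** 31))


@dataclass
class TaskChunk:
    """One task's data: train/test epochs with globally disjoint class ids."""

    task_id: int
    train: EEGEpochs
    test: EEGEpochs
    classes: tuple[int, ...]

    def __post_init__(self):
        self.classes = tuple(sorted(int(c) for c in self.classes))
        for ep in (self.train, self.test):
            present = set(np.unique(ep.labels).tolist())
            if not present <= set(self.classes):
                raise ValueError(f"chunk {self.task_id} labels {present} outside classes {self.classes}")


def make_task_sequence(train: EEGEpochs, test: EEGEpochs,
                       class_groups: list[tuple[int, ...]]) -> list[TaskChunk]:
    """Split epochs into task chunks by class group (first group >= 2 classes)."""
    seen: set[int] = set()
    chunks = []
    for i, grp in enumerate(class_groups):
        grp = tuple(int(c) for c in grp)
        if seen & set(grp):
            raise ValueError("class groups must be disjoint")
        if i == 0 and len(grp) < 2:
            raise ValueError("the initial task needs at least two classes")
        seen |= set(grp)
        tr = train.select(np.isin(train.labels, grp))
        te = test.select(np.isin(test.labels, grp))
        chunks.append(TaskChunk(i, tr, te, grp))
    return chunks


@dataclass
class TrainConfig:
    """Optimization and replay settings for both phases.

    Defaults follow the reference protocol (Adam, lr 0.01, batch 64, cap
    of 2000 epochs with early stopping on a 10% validation split); tests
    and desk-scale runs pass smaller ``max_epochs``.
    """

    lr: float = 0.01
    batch_size: int = 64
    max_epochs: int = 2000
    patience: int = 50
    val_fraction: float = 0.1
    loss: LossConfig = field(default_factory=LossConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    semantic_dim: int = 64
    head_hidden: int = 128
    # replay / diffusion
    replay: bool = True
    replay_injection: str = "encoder_output"  # or "encoder_input"
    pggr_retrain: bool = False
    diffusion_steps: int = 100
    diffusion_lr: float = 3e-3
    diffusion_train_steps: int = 800
    diffusion_batch: int = 64
    lunet_widths: tuple[int, ...] = (16, 32)
    lunet_cond_dim: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.replay_injection not in ("encoder_output", "encoder_input"):
            raise ValueError("replay_injection must be encoder_output or encoder_input")


class UnifiedClassifier(nn.Module):
    """Growing linear classifier G_W over TSFs."""

    def __init__(self, d_in: int, n_classes: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / np.sqrt(d_in)
        self.w = self.register(nn.Parameter(rng.uniform(-bound, bound, (d_in, n_classes)),
                                            name="gw.w", block="classifier"))
        self.b = self.register(nn.Parameter(np.zeros(n_classes), name="gw.b", block="classifier"))

    @property
    def n_classes(self) -> int:
        return self.w.shape[1]

    def __call__(self, f: nn.Tensor) -> nn.Tensor:
        return f @ self.w + self.b

    def expand(self, n_new: int, rng: np.random.Generator) -> None:
        """Grow the output by n_new classes; old weight columns are kept verbatim."""
        if n_new < 0:
            raise ValueError("n_new must be >= 0")
        if n_new == 0:
            return
        d = self.w.shape[0]
        bound = 1.0 / np.sqrt(d)
        self.w.data = np.concatenate([self.w.data, rng.uniform(-bound, bound, (d, n_new))], axis=1)
        self.b.data = np.concatenate([self.b.data, np.zeros(n_new)])


class ILResults:
    """Fitted state and diagnostics of one incremental-learning run."""

    def __init__(self, model: "TaskIncrementalModel", acc_matrix: AccuracyMatrix,
                 kappas: list[float], loss_log: list[dict]):
        self.model = model
        self.accuracy_matrix = acc_matrix
        self.kappas = list(kappas)
        self.loss_log = loss_log

    # -- metrics -----------------------------------------------------------
    def average_accuracy(self, phase: int | None = None) -> float:
        return average_accuracy(self.accuracy_matrix, phase)

    def bfr(self) -> float:
        return backward_forgetting_rate(self.accuracy_matrix)

    def ftr(self, joint_reference: np.ndarray) -> float:
        return forward_transfer_rate(self.accuracy_matrix, joint_reference)

    def predict(self, epochs: EEGEpochs) -> np.ndarray:
        return self.model._predict(epochs)

    def summary(self) -> str:
        m = self.accuracy_matrix
        lines = ["Task-incremental learning results",
                 "=" * 46,
                 f"{'phase':>5} {'classes':>8} {'Acc. (%)':>10} {'Kappa':>8}"]
        n_cum = 0
        for p in range(m.n_phases):
            n_cum += len(self.model.chunks[p].classes)
            lines.append(f"{p + 1:>5} {n_cum:>8} {self.average_accuracy(p):>10.2f} "
                         f"{self.kappas[p]:>8.4f}")
        if m.n_phases > 1:
            lines.append("-" * 46)
            lines.append(f"BFR (backward forgetting rate): {self.bfr():.2f}%")
        return "\n".join(lines)

    def plot_accuracy(self, ax=None):
        """Per-task accuracy across phases (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.accuracy_matrix.acc
        for task in range(m.shape[1]):
            ys = m[:, task]
            ax.plot(np.arange(1, m.shape[0] + 1), ys, marker="o", label=f"task {task + 1}")
        ax.set_xlabel("phase")
        ax.set_ylabel("accuracy (%)")
        ax.legend()
        return ax


class TaskIncrementalModel:
    """Continual decoder over an ordered sequence of task chunks."""

    def __init__(self, chunks: list[TaskChunk], mtsfe_config: MTSFEConfig,
                 train_config: TrainConfig | None = None):
        if not chunks:
            raise ValueError("need at least one task chunk")
        if len(chunks[0].classes) < 2:
            raise ValueError("the initial task must contain at least two classes")
        all_classes = [c for ch in chunks for c in ch.classes]
        if len(set(all_classes)) != len(all_classes):
            raise ValueError("task chunks must have disjoint class ids")
        if sorted(all_classes) != list(range(len(all_classes))):
            raise ValueError("class ids must be contiguous from 0")
        self.chunks = list(chunks)
        self.mtsfe_config = mtsfe_config
        self.train_config = train_config or TrainConfig()
        # fitted state (populated by fit)
        self.backbone: MTSFE | None = None
        self.classifier: UnifiedClassifier | None = None
        self.prototypes: PrototypeSet | None = None
        self.denoiser: LUNet | None = None
        self.schedule: DiffusionSchedule | None = None
        self.frozen_digests: list[str] = []

    @classmethod
    def from_epochs(cls, train: EEGEpochs, test: EEGEpochs,
                    class_groups: list[tuple[int, ...]], mtsfe_config: MTSFEConfig,
                    train_config: TrainConfig | None = None) -> "TaskIncrementalModel":
        return cls(make_task_sequence(train, test, class_groups), mtsfe_config, train_config)

    # -- feature plumbing ----------------------------------------------------
    def _replay_dim(self) -> int:
        v = self.chunks[0].train.n_samples
        cfg = self.mtsfe_config
        if self.train_config.replay_injection == "encoder_output":
            return cfg.feature_dim(v)
        return 2 * cfg.d_model * cfg.n_tokens(v)

    def _replay_features(self, epochs: EEGEpochs) -> np.ndarray:
        """Features at the level PGGR models (post- or pre-encoder)."""
        assert self.backbone is not None
        was = self.backbone.training
        self.backbone.eval()
        if self.train_config.replay_injection == "encoder_output":
            out = self.backbone(epochs.data).data.copy()
        else:
            pre = self.backbone.pre_encoder(epochs.data)
            out = pre.data.reshape(pre.shape[0], -1).copy()
        self.backbone.train(was)
        return out

    def _replay_logits(self, feats: np.ndarray) -> nn.Tensor:
        """Classifier logits for replayed features under the injection mode."""
        t = nn.Tensor(feats)
        if self.train_config.replay_injection == "encoder_input":
            cfg = self.mtsfe_config
            tp = cfg.n_tokens(self.chunks[0].train.n_samples)
            pre = t.reshape(feats.shape[0], 2 * cfg.d_model, 1, tp)
            t = self.backbone.encode(pre)
        return self.classifier(t)

    def _predict(self, epochs: EEGEpochs) -> np.ndarray:
        if self.backbone is None:
            raise RuntimeError("model is not fitted")
        f = self.backbone.extract(epochs)
        logits = self.classifier(nn.Tensor(f)).data
        return np.argmax(logits, axis=1)

    # -- phases ---------------------------------------------------------------
    def fit(self, seed: int | None = None) -> ILResults:
        cfg = self.train_config
        master = cfg.seed if seed is None else int(seed)
        n_phases = len(self.chunks)
        acc = AccuracyMatrix(n_phases)
        kappas: list[float] = []
        loss_log: list[dict] = []
        self.frozen_digests = []

        mcfg = replace(self.mtsfe_config, seed=derive_seed(master, "mtsfe"))
        self.backbone = MTSFE(mcfg)
        rng = np.random.default_rng(derive_seed(master, "classifier"))
        v = self.chunks[0].train.n_samples
        self.classifier = UnifiedClassifier(mcfg.feature_dim(v), len(self.chunks[0].classes), rng)
        self.prototypes = None
        self.schedule = DiffusionSchedule.linear(cfg.diffusion_steps)
        self.denoiser = LUNet(self._replay_dim(), sum(len(c.classes) for c in self.chunks),
                              LUNetConfig(widths=cfg.lunet_widths, cond_dim=cfg.lunet_cond_dim,
                                          seed=derive_seed(master, "lunet")))

        for phase, chunk in enumerate(self.chunks):
            if phase == 0:
                log = self._train_phase(chunk, master, phase, initial=True)
            else:
                self.backbone.freeze_for_increment()
                self.classifier.expand(len(chunk.classes),
                                       np.random.default_rng(derive_seed(master, f"expand{phase}")))
                log = self._train_phase(chunk, master, phase, initial=False)
                self.frozen_digests.append(block_digest(self.backbone, BACKBONE_BLOCKS))
            loss_log.extend(log)
            # prototypes + replayer update on this chunk's real features
            feats = self._replay_features(chunk.train)
            self.prototypes = compute_prototypes(feats, chunk.train.labels, base=self.prototypes)
            if cfg.replay:
                self._update_pggr(feats, chunk.train.labels, master, phase)
            # evaluate all seen tasks
            preds_all, true_all = [], []
            for seen in self.chunks[: phase + 1]:
                pred = self._predict(seen.test)
                acc.set(phase, seen.task_id, 100.0 * float(np.mean(pred == seen.test.labels)))
                preds_all.append(pred)
                true_all.append(seen.test.labels)
            cm = confusion_matrix(np.concatenate(true_all), np.concatenate(preds_all),
                                  n_classes=self.classifier.n_classes)
            kappas.append(cohen_kappa(cm))
        return ILResults(self, acc, kappas, loss_log)

    def evaluate_all_seen(self, phase: int | None = None) -> dict[int, float]:
        """Per-task percent accuracy on held-out data for every seen task."""
        if self.backbone is None:
            raise RuntimeError("model is not fitted")
        upto = len(self.chunks) if phase is None else phase + 1
        out = {}
        for chunk in self.chunks[:upto]:
            pred = self._predict(chunk.test)
            out[chunk.task_id] = 100.0 * float(np.mean(pred == chunk.test.labels))
        return out

    def _train_phase(self, chunk: TaskChunk, master: int, phase: int, initial: bool) -> list[dict]:
        cfg = self.train_config
        lcfg = cfg.loss
        backbone, gw = self.backbone, self.classifier
        rng = np.random.default_rng(derive_seed(master, f"phase{phase}"))
        heads = HeadPair(gw.w.shape[0], len(chunk.classes),
                         np.random.default_rng(derive_seed(master, f"heads{phase}")),
                         semantic_dim=cfg.semantic_dim, hidden=cfg.head_hidden,
                         task_id=chunk.task_id)
        local = {c: i for i, c in enumerate(chunk.classes)}
        local_labels_base = np.array([local[c] for c in chunk.train.labels])

        # train/validation split (stratified)
        val_mask = np.zeros(chunk.train.n_trials, dtype=bool)
        if cfg.val_fraction > 0 and chunk.train.n_trials >= 10:
            for c in np.unique(chunk.train.labels):
                idx = np.flatnonzero(chunk.train.labels == c)
                n_val = max(1, int(round(cfg.val_fraction * len(idx))))
                val_mask[rng.choice(idx, size=n_val, replace=False)] = True
        fit_ep = chunk.train.select(~val_mask)
        val_ep = chunk.train.select(val_mask) if val_mask.any() else None

        opt = nn.Adam(backbone.parameters() + gw.parameters() + heads.parameters(), lr=cfg.lr)

        # replayed features for old classes (incremental phases only)
        replay_feats = replay_labels = None
        if not initial and cfg.replay:
            old_classes = [c for ch in self.chunks[:phase] for c in ch.classes]
            per_class = chunk.train.n_trials // max(len(chunk.classes), 1)
            replay_feats, replay_labels = sample_replay_features(
                old_classes, per_class, self.prototypes, self.schedule, self.denoiser,
                seed=derive_seed(master, f"replay{phase}"))

        log: list[dict] = []
        best_val, best_state, since_best = -np.inf, None, 0
        n_fit = fit_ep.n_trials
        local_fit = np.array([local[c] for c in fit_ep.labels])
        for epoch in range(cfg.max_epochs):
            aug_cfg = AugmentConfig(cfg.augment.n_segments, cfg.augment.n_copies,
                                    seed=derive_seed(master, f"aug{phase}.{epoch}"))
            aug = augment_epochs(fit_ep, aug_cfg)
            backbone.train()
            # stop-gradient branch: original views, no graph
            f_orig = backbone.extract(fit_ep)
            z_orig = heads.project(nn.Tensor(f_orig)).data
            order = rng.permutation(aug.n_trials)
            bs = min(cfg.batch_size, aug.n_trials)
            ep_loss = []
            for start in range(0, aug.n_trials, bs):
                sel = order[start:start + bs]
                xb = aug.data[sel]
                yb_global = aug.labels[sel]
                yb_local = np.array([local[c] for c in yb_global])
                pair = sel % n_fit  # copy m of trial t pairs with trial t
                if initial:
                    feats = backbone(xb)
                else:
                    pre = backbone.pre_encoder(xb).detach()  # frozen backbone
                    feats = backbone.encode(pre)
                logits = gw(feats)
                if replay_feats is not None:
                    r_logits = self._replay_logits(replay_feats)
                    all_logits = nn.concatenate([logits, r_logits], axis=0)
                    all_labels = np.concatenate([yb_global, replay_labels])
                else:
                    all_logits, all_labels = logits, yb_global
                ce_main = cross_entropy_from_logits(all_logits, all_labels)
                aux_logits = heads.classify_logits(feats)
                ss_ce = cross_entropy_from_logits(aux_logits, yb_local)
                z_aug = heads.project(feats)
                fg = ss_fg_loss(z_aug, z_orig[pair])
                ss = ss_ce + lcfg.lambda1 * fg
                loss = total_training_loss(ce_main, ss, lcfg, ss_ce=ss_ce)
                opt.zero_grad()
                loss.backward()
                opt.step()
                ep_loss.append(float(loss.data))
            log.append({"phase": phase, "epoch": epoch, "loss": float(np.mean(ep_loss))})
            # early stopping on the validation split; with replay active the
            # replayed old-class features join the criterion so a new-task-only
            # validation set cannot reward a degenerate always-new predictor
            if val_ep is not None:
                if initial:
                    backbone.recalibrate_bn(fit_ep.data)
                pred = self._predict(val_ep)
                val_acc = float(np.mean(pred == val_ep.labels))
                if replay_feats is not None:
                    r_pred = np.argmax(self._replay_logits(replay_feats).data, axis=1)
                    val_acc = 0.5 * (val_acc + float(np.mean(r_pred == replay_labels)))
                if val_acc > best_val + 1e-12:
                    best_val, since_best = val_acc, 0
                    best_state = (backbone.state_dict(), gw.state_dict(),
                                  _bn_stats(backbone))
                else:
                    since_best += 1
                    if since_best >= cfg.patience:
                        break
        if best_state is not None:
            backbone.load_state_dict(best_state[0])
            gw.load_state_dict(best_state[1])
            _set_bn_stats(backbone, best_state[2])
        elif initial:
            backbone.recalibrate_bn(fit_ep.data)
        return log

    def _update_pggr(self, feats: np.ndarray, labels: np.ndarray,
                     master: int, phase: int) -> None:
        cfg = self.train_config
        if cfg.pggr_retrain or phase == 0:
            self.denoiser = LUNet(self._replay_dim(),
                                  sum(len(c.classes) for c in self.chunks),
                                  LUNetConfig(widths=cfg.lunet_widths,
                                              cond_dim=cfg.lunet_cond_dim,
                                              seed=derive_seed(master, "lunet")))
        train_feats, train_labels = feats, np.asarray(labels, dtype=int)
        if phase > 0 and cfg.replay:
            old_classes = [c for ch in self.chunks[:phase] for c in ch.classes]
            per_class = max(1, feats.shape[0] // max(len(np.unique(labels)), 1))
            gen, glab = sample_replay_features(
                old_classes, per_class, self.prototypes, self.schedule, self.denoiser,
                seed=derive_seed(master, f"pggr_replay{phase}"))
            train_feats = np.vstack([gen, feats])
            train_labels = np.concatenate([glab, train_labels])
        trainer = DiffusionTrainer(self.denoiser, self.schedule, lr=cfg.diffusion_lr,
                                   seed=derive_seed(master, f"pggr{phase}"))
        trainer.fit(train_feats, train_labels, self.prototypes,
                    n_steps=cfg.diffusion_train_steps, batch_size=cfg.diffusion_batch)

    # -- joint reference -------------------------------------------------------
    def fit_joint(self, seed: int | None = None) -> np.ndarray:
        """Jointly train a fresh model on all chunks at once; returns the
        per-task percent accuracies (the acc** references for FTR)."""
        cfg = self.train_config
        master = derive_seed(cfg.seed if seed is None else int(seed), "joint")
        all_classes = tuple(c for ch in self.chunks for c in ch.classes)
        train = _concat_epochs([ch.train for ch in self.chunks])
        test = _concat_epochs([ch.test for ch in self.chunks])
        joint_chunk = TaskChunk(0, train, test, all_classes)
        clone = TaskIncrementalModel([joint_chunk], self.mtsfe_config, cfg)
        res = clone.fit(seed=master)
        accs = []
        for ch in self.chunks:
            pred = res.predict(ch.test)
            accs.append(100.0 * float(np.mean(pred == ch.test.labels)))
        return np.asarray(accs)

    # -- persistence -------------------------------------------------------------
    def save_state(self, path: str) -> None:
        """Serialize the fitted state (backbone, classifier, replayer,
        prototypes) into a single NPZ archive."""
        if self.backbone is None:
            raise RuntimeError("nothing to save; call fit() first")
        arrays: dict[str, np.ndarray] = {}
        for prefix, mod in (("bb", self.backbone), ("gw", self.classifier),
                            ("dn", self.denoiser)):
            for k, v in mod.state_dict().items():
                arrays[f"{prefix}/{k}"] = v
        for i, bn in enumerate(self.backbone.t_bns + [self.backbone.s_bn]):
            arrays[f"bnstat/{i}/mean"] = bn.running_mean
            arrays[f"bnstat/{i}/var"] = bn.running_var
        for c, v in self.prototypes.prototypes.items():
            arrays[f"proto/{c}"] = v
        arrays["sched/betas"] = self.schedule.betas
        meta = {"mtsfe": asdict(self.mtsfe_config),
                "n_classes": self.classifier.n_classes,
                "frozen": self.backbone.backbone_frozen}
        np.savez(path, __meta=json.dumps(meta), **arrays)

    def load_state(self, path: str) -> None:
        """Restore a fitted state saved by :meth:`save_state`."""
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["__meta"]))
            arrays = {k: f[k] for k in f.files if k != "__meta"}
        if meta["mtsfe"] != asdict(self.mtsfe_config):
            raise ValueError("state was saved under a different backbone configuration")
        cfg = self.train_config
        master = cfg.seed
        self.backbone = MTSFE(replace(self.mtsfe_config))
        v = self.chunks[0].train.n_samples
        self.classifier = UnifiedClassifier(self.mtsfe_config.feature_dim(v), 2,
                                            np.random.default_rng(0))
        n_cls = int(meta["n_classes"])
        self.classifier.w.data = np.zeros((self.classifier.w.shape[0], n_cls))
        self.classifier.b.data = np.zeros(n_cls)
        self.schedule = DiffusionSchedule(arrays["sched/betas"])
        self.denoiser = LUNet(self._replay_dim(), sum(len(c.classes) for c in self.chunks),
                              LUNetConfig(widths=cfg.lunet_widths,
                                          cond_dim=cfg.lunet_cond_dim,
                                          seed=derive_seed(master, "lunet")))
        for prefix, mod in (("bb", self.backbone), ("gw", self.classifier),
                            ("dn", self.denoiser)):
            state = {k.split("/", 1)[1]: v for k, v in arrays.items()
                     if k.startswith(prefix + "/")}
            mod.load_state_dict(state)
        for i, bn in enumerate(self.backbone.t_bns + [self.backbone.s_bn]):
            bn.running_mean = arrays[f"bnstat/{i}/mean"].copy()
            bn.running_var = arrays[f"bnstat/{i}/var"].copy()
        protos = {int(k.split("/")[1]): v for k, v in arrays.items() if k.startswith("proto/")}
        self.prototypes = PrototypeSet(protos)
        if meta["frozen"]:
            self.backbone.freeze_for_increment()


def _bn_stats(backbone: MTSFE) -> list[tuple[np.ndarray, np.ndarray]]:
    return [(bn.running_mean.copy(), bn.running_var.copy())
            for bn in backbone.t_bns + [backbone.s_bn]]


def _set_bn_stats(backbone: MTSFE, stats) -> None:
    for bn, (mu, var) in zip(backbone.t_bns + [backbone.s_bn], stats):
        bn.running_mean = mu.copy()
        bn.running_var = var.copy()


def _concat_epochs(parts: list[EEGEpochs]) -> EEGEpochs:
    data = np.concatenate([p.data for p in parts], axis=0)
    labels = np.concatenate([p.labels for p in parts])
    return EEGEpochs(data, labels, parts[0].fs)
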