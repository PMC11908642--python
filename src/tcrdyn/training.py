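"""MLM pretraining with per-epoch checkpointing, checkpoint finetuning, and
checkpoint-sweep evaluation.

``pretrain`` runs one optimization pass per epoch over the corpus pairing for
that epoch (re-drawn in the per-epoch re-pairing regime) with corruption
re-drawn every epoch, saving a checkpoint every ``checkpoint_every`` epochs.
``finetune`` transfers a checkpoint's encoder under a fresh classification
head (optionally preceded by a task-adaptive MLM pass over the finetuning
sequences) and reports held-out AUROC/AUPRC for one stratified split.
``sweep`` repeats finetuning for every stride-th checkpoint over all
(dataset, split) combinations, emitting a run manifest before execution.
"""

from __future__ import annotations

import csv
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import _autograd as ag
from ._optim import AdamW
from .encoding import EncodedExample, Vocabulary, build_vocabulary, encode_pair
from .masking import MaskedBatch, MaskingPolicy, corrupt
from .metrics import ScoredLabels, auprc, auroc
from .model import Checkpoint, EncoderState, TransformerModel, transfer_encoder
from .synthetic import CorpusMode, LabeledPair, PretrainCorpus

logger = logging.getLogger("tcrdyn.training")


class TrainingError(RuntimeError):
    pass


class StratificationError(ValueError):
    """A cross-validation fold would contain a single class."""


@dataclass(frozen=True)
class PretrainSchedule:
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 1e-3
    weight_decay: float = 0.01
    checkpoint_every: int = 1
    eval_fraction: float = 0.1
    masking: MaskingPolicy = field(default_factory=MaskingPolicy)
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise TrainingError(f"epochs must be >= 1, got {self.epochs}")
        if not 0.0 <= self.eval_fraction < 1.0:
            raise TrainingError(f"eval_fraction must be in [0, 1), got {self.eval_fraction}")
        if self.checkpoint_every < 1:
            raise TrainingError("checkpoint_every must be >= 1")


@dataclass(frozen=True)
class FinetunePlan:
    n_splits: int = 5
    epochs: int = 6
    batch_size: int = 16
    learning_rate: float = 1e-3
    weight_decay: float = 0.01
    test_fraction: float = 0.2
    tapt: bool = False
    tapt_epochs: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_splits < 2:
            raise TrainingError(f"n_splits must be >= 2, got {self.n_splits}")


@dataclass
class LossCurve:
    """Per-epoch pretraining losses (mean masked cross-entropy, nats)."""

    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    eval_loss: list[Optional[float]] = field(default_factory=list)

    def append(self, epoch: int, train: float, eval_: Optional[float]):
        if self.epochs and epoch <= self.epochs[-1]:
            raise TrainingError("epochs must be strictly increasing")
        if train < 0 or (eval_ is not None and eval_ < 0):
            raise TrainingError("losses must be nonnegative")
        self.epochs.append(epoch)
        self.train_loss.append(train)
        self.eval_loss.append(eval_)

    def series(self, which: str) -> list[float]:
        if which == "train":
            return list(self.train_loss)
        if which == "eval":
            if any(v is None for v in self.eval_loss):
                raise TrainingError("eval loss was not recorded for every epoch")
            return [float(v) for v in self.eval_loss]
        raise TrainingError(f"unknown loss series {which!r}")

    def to_csv(self, path: str | Path):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "train_loss", "eval_loss"])
            for e, t, v in zip(self.epochs, self.train_loss, self.eval_loss):
                w.writerow([e, f"{t:.6f}", "" if v is None else f"{v:.6f}"])

    @classmethod
    def from_csv(cls, path: str | Path) -> "LossCurve":
        curve = cls()
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            for row in reader:
                curve.append(
                    int(row["epoch"]),
                    float(row["train_loss"]),
                    float(row["eval_loss"]) if row["eval_loss"] else None,
                )
        return curve


@dataclass
class CheckpointSeries:
    checkpoints: list[Checkpoint] = field(default_factory=list)

    def __len__(self):
        return len(self.checkpoints)

    def __iter__(self):
        return iter(self.checkpoints)

    def __getitem__(self, i):
        return self.checkpoints[i]

    def epochs(self) -> list[int]:
        return [c.epoch for c in self.checkpoints]


@dataclass
class SweepResult:
    """Per-checkpoint downstream metrics aggregated across (dataset, split) runs."""

    epochs: list[int]
    records: list[dict]          # epoch, dataset, split, auroc, auprc
    mean_auroc: dict[int, float]
    sd_auroc: dict[int, float]
    mean_auprc: dict[int, float]
    sd_auprc: dict[int, float]
    per_dataset_mean_auroc: dict[int, dict[str, float]]
    manifest: list[dict]

    def to_csv(self, path: str | Path):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "dataset", "split", "auroc", "auprc"])
            for r in self.records:
                w.writerow([r["epoch"], r["dataset"], r["split"],
                            f"{r['auroc']:.6f}", f"{r['auprc']:.6f}"])

    def summary_rows(self) -> list[dict]:
        return [
            {
                "epoch": e,
                "mean_auroc": self.mean_auroc[e],
                "sd_auroc": self.sd_auroc[e],
                "mean_auprc": self.mean_auprc[e],
                "sd_auprc": self.sd_auprc[e],
            }
            for e in self.epochs
        ]

    def summary_to_csv(self, path: str | Path):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "mean_auroc", "sd_auroc", "mean_auprc", "sd_auprc"])
            for row in self.summary_rows():
                w.writerow([row["epoch"], f"{row['mean_auroc']:.6f}", f"{row['sd_auroc']:.6f}",
                            f"{row['mean_auprc']:.6f}", f"{row['sd_auprc']:.6f}"])


def _derive_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % 2**31)


def _encode_samples(
    pairs: Sequence[tuple], vocab: Vocabulary, max_len: int
) -> list[EncodedExample]:
    return [
        encode_pair(a.residues if a is not None else None, c.residues, vocab, max_len)
        for a, c in pairs
    ]


def _batched(indices: np.ndarray, batch_size: int):
    for i in range(0, len(indices), batch_size):
        yield indices[i : i + batch_size]


def _slice_batch(batch: MaskedBatch, idx: np.ndarray) -> MaskedBatch:
    return MaskedBatch(
        corrupted_ids=batch.corrupted_ids[idx],
        targets=batch.targets[idx],
        selection_mask=batch.selection_mask[idx],
        segment_ids=batch.segment_ids[idx],
        position_ids=batch.position_ids[idx],
        attention_mask=batch.attention_mask[idx],
    )


def _run_mlm_epochs(
    model: TransformerModel,
    corpus_pairs_fn,
    n_epochs: int,
    batch_size: int,
    learning_rate: float,
    weight_decay: float,
    masking: MaskingPolicy,
    vocab: Vocabulary,
    seed: int,
    optimizer: Optional[AdamW] = None,
    start_epoch: int = 1,
    epoch_callback=None,
) -> AdamW:
    """Shared MLM loop used by pretraining and the task-adaptive variant.

    ``corpus_pairs_fn(e)`` returns that epoch's (antigen-or-None, cdr3) list.
    """
    max_len = model.config.max_len
    n_samples = len(corpus_pairs_fn(start_epoch))
    steps_per_epoch = int(np.ceil(n_samples / batch_size))
    if optimizer is None:
        optimizer = AdamW(
            model.trainable(), lr=learning_rate, weight_decay=weight_decay,
            total_steps=n_epochs * steps_per_epoch,
        )
    for e in range(start_epoch, start_epoch + n_epochs):
        t0 = time.monotonic()
        pairs = corpus_pairs_fn(e)
        examples = _encode_samples(pairs, vocab, max_len)
        batch_all = corrupt(examples, masking, seed=_derive_seed(seed, 101, e), vocab=vocab)
        order = np.random.default_rng(_derive_seed(seed, 102, e)).permutation(len(examples))
        drop_rng = np.random.default_rng(_derive_seed(seed, 103, e))
        loss_sum, sel_sum = 0.0, 0
        for idx in _batched(order, batch_size):
            sub = _slice_batch(batch_all, idx)
            if sub.n_selected == 0:
                continue
            loss = model.mlm_loss(sub, rng=drop_rng)
            if not np.isfinite(loss.data):
                raise TrainingError(f"non-finite MLM loss at epoch {e}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            loss_sum += float(loss.data) * sub.n_selected
            sel_sum += sub.n_selected
        train_loss = loss_sum / max(sel_sum, 1)
        if epoch_callback is not None:
            epoch_callback(e, train_loss, time.monotonic() - t0)
    return optimizer


def pretrain(
    state: EncoderState,
    corpus: PretrainCorpus,
    schedule: PretrainSchedule,
    checkpoint_dir: Optional[str | Path] = None,
    save_initial: bool = False,
) -> tuple[CheckpointSeries, LossCurve]:
    """MLM-pretrain ``state`` on ``corpus``; returns checkpoints and the loss curve.

    The evaluation loss is computed on a held-out ``eval_fraction`` of the
    CDR3 pool with a fixed pairing and a fixed corruption seed, so eval losses
    are comparable across epochs.  Fully deterministic given the schedule seed.
    """
    if len(corpus) == 0:
        raise TrainingError("pretraining corpus is empty")
    vocab = build_vocabulary()
    rng = np.random.default_rng(_derive_seed(schedule.seed, 100))
    n_eval = int(round(schedule.eval_fraction * len(corpus)))
    perm = rng.permutation(len(corpus))
    eval_idx, train_idx = perm[:n_eval], perm[n_eval:]
    if len(train_idx) == 0:
        raise TrainingError("eval_fraction leaves no training sequences")

    train_corpus = PretrainCorpus(
        mode=corpus.mode, antigens=corpus.antigens,
        cdr3s=tuple(corpus.cdr3s[i] for i in train_idx), seed=corpus.seed,
    )
    eval_batch: Optional[MaskedBatch] = None
    if n_eval:
        eval_corpus = PretrainCorpus(
            mode=(CorpusMode.CDR3_ONLY if corpus.mode == CorpusMode.CDR3_ONLY
                  else CorpusMode.STATIC_PAIRED),
            antigens=corpus.antigens,
            cdr3s=tuple(corpus.cdr3s[i] for i in eval_idx),
            seed=_derive_seed(schedule.seed, 104),
        )
        eval_examples = _encode_samples(eval_corpus.pairs_for_epoch(0), vocab, state.config.max_len)
        eval_batch = corrupt(eval_examples, schedule.masking,
                             seed=_derive_seed(schedule.seed, 105), vocab=vocab)

    model = TransformerModel(state)
    series = CheckpointSeries()
    curve = LossCurve()

    def eval_loss_now() -> Optional[float]:
        if eval_batch is None:
            return None
        eval_model = TransformerModel(model.to_state())
        return float(eval_model.mlm_loss(eval_batch, rng=None).data)

    if save_initial:
        # epoch-0 baseline: the untrained initialization, before any pass
        series.checkpoints.append(
            Checkpoint(epoch=0, encoder=model.to_state(state.init_seed),
                       train_loss=0.0, eval_loss=eval_loss_now())
        )

    def on_epoch(e: int, train_loss: float, elapsed: float):
        ev = eval_loss_now()
        curve.append(e, train_loss, ev)
        logger.info("pretrain epoch %d: train_loss=%.4f eval_loss=%s (%.2fs)",
                    e, train_loss, "NA" if ev is None else f"{ev:.4f}", elapsed)
        if e % schedule.checkpoint_every == 0:
            ck = Checkpoint(epoch=e, encoder=model.to_state(state.init_seed),
                            train_loss=train_loss, eval_loss=ev)
            series.checkpoints.append(ck)
            if checkpoint_dir is not None:
                from .model import save_checkpoint

                save_checkpoint(ck, checkpoint_dir)

    _run_mlm_epochs(
        model, train_corpus.pairs_for_epoch, schedule.epochs, schedule.batch_size,
        schedule.learning_rate, schedule.weight_decay, schedule.masking, vocab,
        schedule.seed, epoch_callback=on_epoch,
    )
    return series, curve


def stratified_split(
    labels: np.ndarray, test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """One stratified shuffled train/test split; both folds keep both classes."""
    labels = np.asarray(labels)
    train_parts, test_parts = [], []
    rng = np.random.default_rng(seed)
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        if len(idx) == 0:
            raise StratificationError(f"dataset contains no examples of class {cls}")
        idx = rng.permutation(idx)
        n_test = max(1, int(round(test_fraction * len(idx))))
        if n_test >= len(idx):
            raise StratificationError(f"class {cls} too small for test_fraction={test_fraction}")
        test_parts.append(idx[:n_test])
        train_parts.append(idx[n_test:])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts))


def finetune(
    checkpoint: Checkpoint,
    dataset: list[LabeledPair],
    plan: FinetunePlan,
    split_index: int,
) -> tuple[float, float, np.ndarray]:
    """Finetune one checkpoint on one stratified split; return held-out metrics.

    The encoder is transferred unfrozen under a freshly initialized head.
    With ``plan.tapt`` a task-adaptive MLM pass over the training-fold
    sequences precedes classification training.
    """
    labels = np.array([p.label for p in dataset])
    split_seed = _derive_seed(plan.seed, 200, split_index)
    train_idx, test_idx = stratified_split(labels, plan.test_fraction, split_seed)

    model = transfer_encoder(checkpoint, head_seed=_derive_seed(plan.seed, 201, split_index))
    vocab = build_vocabulary()
    max_len = model.config.max_len

    if plan.tapt:
        tapt_pairs = [(dataset[i].antigen, dataset[i].cdr3) for i in train_idx]
        _run_mlm_epochs(
            model, lambda e: tapt_pairs, plan.tapt_epochs, plan.batch_size,
            plan.learning_rate, plan.weight_decay, MaskingPolicy(), vocab,
            _derive_seed(plan.seed, 202, split_index),
        )

    def encode_subset(idx):
        exs = [
            encode_pair(dataset[i].antigen.residues, dataset[i].cdr3.residues, vocab, max_len,
                        label=dataset[i].label)
            for i in idx
        ]
        return (
            np.stack([e.token_ids for e in exs]),
            np.stack([e.segment_ids for e in exs]),
            np.stack([e.position_ids for e in exs]),
            np.stack([e.attention_mask for e in exs]),
            np.array([e.label for e in exs]),
        )

    tok, seg, pos, att, y = encode_subset(train_idx)
    steps_per_epoch = int(np.ceil(len(train_idx) / plan.batch_size))
    optimizer = AdamW(model.trainable(), lr=plan.learning_rate,
                      weight_decay=plan.weight_decay,
                      total_steps=plan.epochs * steps_per_epoch)
    for e in range(plan.epochs):
        order = np.random.default_rng(_derive_seed(plan.seed, 203, split_index, e)).permutation(len(y))
        drop_rng = np.random.default_rng(_derive_seed(plan.seed, 204, split_index, e))
        for idx in _batched(order, plan.batch_size):
            logits = model.cls_logits(tok[idx], seg[idx], pos[idx], att[idx], rng=drop_rng)
            loss = ag.binary_cross_entropy_with_logits(logits, y[idx][:, None])
            if not np.isfinite(loss.data):
                raise TrainingError(f"non-finite finetuning loss (split {split_index}, epoch {e})")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()

    tok, seg, pos, att, y_test = encode_subset(test_idx)
    eval_model = TransformerModel(model.to_state())
    scores = ag.sigmoid(eval_model.cls_logits(tok, seg, pos, att, rng=None).data[:, 0])
    sl = ScoredLabels(scores=scores, labels=y_test)
    return auroc(sl), auprc(sl), scores


def build_manifest(
    checkpoints: CheckpointSeries,
    datasets: dict[str, list[LabeledPair]],
    plan: FinetunePlan,
    checkpoint_stride: int = 1,
) -> list[dict]:
    """Enumerate every (checkpoint, dataset, split) finetuning run of a sweep."""
    if len(checkpoints) == 0:
        raise TrainingError("checkpoint series is empty")
    if checkpoint_stride < 1 or checkpoint_stride > len(checkpoints):
        raise TrainingError(
            f"checkpoint_stride {checkpoint_stride} invalid for {len(checkpoints)} checkpoints"
        )
    swept = checkpoints.checkpoints[::checkpoint_stride]
    return [
        {"epoch": ck.epoch, "dataset": name, "split": s}
        for ck in swept
        for name in datasets
        for s in range(plan.n_splits)
    ]


def sweep(
    checkpoints: CheckpointSeries,
    datasets: dict[str, list[LabeledPair]],
    plan: FinetunePlan,
    checkpoint_stride: int = 1,
    manifest_path: Optional[str | Path] = None,
) -> SweepResult:
    """Finetune every stride-th checkpoint over all (dataset, split) runs."""
    manifest = build_manifest(checkpoints, datasets, plan, checkpoint_stride)
    if manifest_path is not None:
        with open(manifest_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "dataset", "split"])
            for row in manifest:
                w.writerow([row["epoch"], row["dataset"], row["split"]])

    swept = checkpoints.checkpoints[::checkpoint_stride]
    by_epoch = {ck.epoch: ck for ck in swept}
    records = []
    for row in manifest:
        t0 = time.monotonic()
        roc, prc, _ = finetune(by_epoch[row["epoch"]], datasets[row["dataset"]], plan, row["split"])
        records.append({**row, "auroc": roc, "auprc": prc})
        logger.info("sweep epoch=%d dataset=%s split=%d auroc=%.4f auprc=%.4f (%.2fs)",
                    row["epoch"], row["dataset"], row["split"], roc, prc,
                    time.monotonic() - t0)

    epochs = [ck.epoch for ck in swept]
    mean_auroc, sd_auroc, mean_auprc, sd_auprc, per_ds = {}, {}, {}, {}, {}
    for e in epochs:
        rocs = np.array([r["auroc"] for r in records if r["epoch"] == e])
        prcs = np.array([r["auprc"] for r in records if r["epoch"] == e])
        mean_auroc[e] = float(rocs.mean())
        sd_auroc[e] = float(rocs.std(ddof=1)) if len(rocs) > 1 else 0.0
        mean_auprc[e] = float(prcs.mean())
        sd_auprc[e] = float(prcs.std(ddof=1)) if len(prcs) > 1 else 0.0
        per_ds[e] = {
            name: float(np.mean([r["auroc"] for r in records
                                 if r["epoch"] == e and r["dataset"] == name]))
            for name in datasets
        }
    return SweepResult(
        epochs=epochs, records=records,
        mean_auroc=mean_auroc, sd_auroc=sd_auroc,
        mean_auprc=mean_auprc, sd_auprc=sd_auprc,
        per_dataset_mean_auroc=per_ds, manifest=manifest,
    )
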