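"""Pretraining-dynamics statistics and dataset-similarity analysis.

``threshold_report`` formalizes the loss-threshold heuristic: once the
pretraining loss drops below a fixed value (default 1.0 nats), downstream
performance stops improving on average and merely oscillates.  The report
records the first crossing epoch, the mean and sample standard deviation of
downstream AUROC over post-threshold swept checkpoints, the best swept epoch
overall, and how many SDs that best value sits above the post-threshold mean
(values above 2 SD are flagged as exceptional).

``needleman_wunsch`` / ``similarity_report`` quantify how close a pretraining
repertoire is to a finetuning dataset by global alignment of randomly sampled
same-role sequence pairs (mean alignment score and mean percent identity).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .synthetic import Role, SequenceRecord
from .training import LossCurve, SweepResult


class AnalysisError(ValueError):
    pass


@dataclass
class ThresholdReport:
    threshold: float
    loss_series_used: str
    crossed: bool
    first_crossing_epoch: Optional[int]
    post_threshold_epochs: list[int]
    post_mean_auroc: Optional[float]
    post_sd_auroc: Optional[float]
    sd_defined: bool
    best_epoch: Optional[int]
    best_auroc: Optional[float]
    best_deviation_in_sd: Optional[float]
    exceeds_2sd: Optional[bool]

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def to_json(self, path: str | Path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    def to_text(self) -> str:
        lines = [
            f"loss threshold          : {self.threshold} nats ({self.loss_series_used} series)",
            f"first crossing epoch    : {self.first_crossing_epoch if self.crossed else 'never crossed'}",
        ]
        if self.crossed:
            lines.append(f"post-threshold epochs   : {self.post_threshold_epochs}")
            if self.post_mean_auroc is not None:
                lines.append(f"post-threshold mean AUROC: {self.post_mean_auroc:.4f}")
            lines.append(
                "post-threshold SD AUROC : "
                + (f"{self.post_sd_auroc:.4f}" if self.sd_defined
                   else "undefined (<2 checkpoints or zero variance)")
            )
        lines += [
            f"best swept epoch        : {self.best_epoch} (AUROC {self.best_auroc:.4f})"
            if self.best_epoch is not None else "best swept epoch        : n/a",
        ]
        if self.best_deviation_in_sd is not None:
            flag = " (exceeds 2 SD)" if self.exceeds_2sd else ""
            lines.append(f"best deviation          : {self.best_deviation_in_sd:+.2f} SD{flag}")
        else:
            lines.append("best deviation          : undefined")
        return "\n".join(lines)


def threshold_report(
    loss_curve: LossCurve,
    sweep_result: SweepResult,
    threshold: float = 1.0,
    series: str = "train",
) -> ThresholdReport:
    """Loss-threshold analysis of a pretraining run against its sweep.

    The sweep may cover a stride-subset of the loss curve's epochs.  The
    post-threshold statistics use the swept checkpoints whose loss is strictly
    below ``threshold``; the best epoch is taken over ALL swept checkpoints
    (earliest epoch wins ties).  Standard deviation is the sample SD (n-1).
    """
    losses = loss_curve.series(series)
    loss_by_epoch = dict(zip(loss_curve.epochs, losses))
    swept_epochs = sweep_result.epochs
    if not swept_epochs:
        raise AnalysisError("sweep result contains no checkpoints")

    crossing = next((e for e, l in zip(loss_curve.epochs, losses) if l < threshold), None)

    best_epoch, best_auroc = None, -np.inf
    for e in swept_epochs:
        v = sweep_result.mean_auroc[e]
        if v > best_auroc:  # strict: earliest epoch wins ties
            best_epoch, best_auroc = e, v

    if crossing is None:
        return ThresholdReport(
            threshold=threshold, loss_series_used=series, crossed=False,
            first_crossing_epoch=None, post_threshold_epochs=[],
            post_mean_auroc=None, post_sd_auroc=None, sd_defined=False,
            best_epoch=best_epoch, best_auroc=float(best_auroc),
            best_deviation_in_sd=None, exceeds_2sd=None,
        )

    post_epochs = [e for e in swept_epochs if e in loss_by_epoch and loss_by_epoch[e] < threshold]
    post = np.array([sweep_result.mean_auroc[e] for e in post_epochs])
    post_mean = float(post.mean()) if len(post) else None
    sd_defined = len(post) >= 2
    post_sd = float(post.std(ddof=1)) if sd_defined else None

    # deviation-in-SD is defined only when the sample SD exists and is nonzero
    deviation, exceeds = None, None
    if sd_defined and post_sd is not None and post_sd > 1e-12:
        deviation = float((best_auroc - post_mean) / post_sd)
        exceeds = deviation > 2.0

    return ThresholdReport(
        threshold=threshold, loss_series_used=series, crossed=True,
        first_crossing_epoch=crossing, post_threshold_epochs=post_epochs,
        post_mean_auroc=post_mean, post_sd_auroc=post_sd, sd_defined=sd_defined,
        best_epoch=best_epoch, best_auroc=float(best_auroc),
        best_deviation_in_sd=deviation, exceeds_2sd=exceeds,
    )


# ---------------------------------------------------------------------------
# Global alignment similarity


@dataclass(frozen=True)
class AlignmentParams:
    """Global-alignment settings; defaults are the common protein choices
    (BLOSUM62, gap open -10, gap extend -0.5).  'identity' selects a +1/-1
    match/mismatch matrix instead of a substitution matrix."""

    matrix: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -0.5
    n_sampled_pairs: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.n_sampled_pairs < 1:
            raise AnalysisError("n_sampled_pairs must be >= 1")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise AnalysisError("gap penalties must be <= 0 (penalty convention)")

    def to_dict(self) -> dict:
        return {
            "matrix": self.matrix, "gap_open": self.gap_open,
            "gap_extend": self.gap_extend, "n_sampled_pairs": self.n_sampled_pairs,
            "seed": self.seed,
        }


def _build_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if params.matrix == "identity":
        aligner.match_score = 1.0
        aligner.mismatch_score = -1.0
    else:
        aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def needleman_wunsch(
    a: str, b: str, params: AlignmentParams | None = None
) -> tuple[float, float]:
    """Global (Needleman–Wunsch) alignment score and percent identity.

    Percent identity is 100 x identical aligned columns / alignment length,
    computed on one optimal alignment.  An empty sequence yields the defined
    all-gap alignment with identity 0.
    """
    if params is None:
        params = AlignmentParams()
    aligner = _build_aligner(params)
    if not a or not b:
        n = max(len(a), len(b))
        score = 0.0 if n == 0 else params.gap_open + params.gap_extend * (n - 1)
        return float(score), 0.0
    alignment = aligner.align(a, b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    identical = sum(x == y and x != "-" for x, y in zip(row_a, row_b))
    identity = 100.0 * identical / len(row_a)
    return float(alignment.score), identity


@dataclass
class SimilarityReport:
    params: AlignmentParams
    mean_score: dict[str, float] = field(default_factory=dict)
    mean_percent_identity: dict[str, float] = field(default_factory=dict)
    skipped_roles: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "mean_score": self.mean_score,
            "mean_percent_identity": self.mean_percent_identity,
            "skipped_roles": self.skipped_roles,
        }

    def to_json(self, path: str | Path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    def to_text(self) -> str:
        lines = ["role      mean_score  mean_percent_identity"]
        for role in sorted(self.mean_score):
            lines.append(
                f"{role:<9} {self.mean_score[role]:>10.2f}  {self.mean_percent_identity[role]:>8.1f}%"
            )
        for role in self.skipped_roles:
            lines.append(f"{role:<9} {'--':>10}  {'--':>9} (role absent)")
        return "\n".join(lines)


def similarity_report(
    pretrain_records: list[SequenceRecord],
    finetune_records: list[SequenceRecord],
    params: AlignmentParams | None = None,
) -> SimilarityReport:
    """Mean alignment score/identity between random cross-dataset pairs, per role.

    Samples ``n_sampled_pairs`` (pretrain, finetune) pairs for each role
    present in both sets; a role absent from either set is skipped (recorded
    in ``skipped_roles``), mirroring single-sequence corpora that carry no
    antigens.
    """
    if params is None:
        params = AlignmentParams()
    report = SimilarityReport(params=params)
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 7]))
    for role in (Role.ANTIGEN, Role.CDR3):
        pre = [r for r in pretrain_records if r.role == role]
        fin = [r for r in finetune_records if r.role == role]
        if not pre or not fin:
            report.skipped_roles.append(role.value)
            continue
        scores, identities = [], []
        pre_idx = rng.integers(0, len(pre), size=params.n_sampled_pairs)
        fin_idx = rng.integers(0, len(fin), size=params.n_sampled_pairs)
        for i, j in zip(pre_idx, fin_idx):
            s, pid = needleman_wunsch(pre[i].residues, fin[j].residues, params)
            scores.append(s)
            identities.append(pid)
        report.mean_score[role.value] = float(np.mean(scores))
        report.mean_percent_identity[role.value] = float(np.mean(identities))
    return report


# ---------------------------------------------------------------------------
# Figure-style exports


def plot_loss_curve(
    curve: LossCurve, path: str | Path, best_epoch: Optional[int] = None,
    threshold: Optional[float] = None,
):
    """Loss-vs-epoch plot with the best downstream epoch highlighted."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.epochs, curve.train_loss, label="train loss")
    if any(v is not None for v in curve.eval_loss):
        ax.plot(curve.epochs, [v if v is not None else np.nan for v in curve.eval_loss],
                label="eval loss")
    if threshold is not None:
        ax.axhline(threshold, color="gray", ls=":", label=f"threshold {threshold}")
    if best_epoch is not None and best_epoch in curve.epochs:
        i = curve.epochs.index(best_epoch)
        ax.plot([best_epoch], [curve.train_loss[i]], "ro", label=f"best downstream (epoch {best_epoch})")
    ax.set_xlabel("pretraining epoch")
    ax.set_ylabel("masked cross-entropy (nats)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_sweep(sweep_result: SweepResult, path: str | Path, best_epoch: Optional[int] = None):
    """Downstream AUROC/AUPRC (mean +- SD) versus pretraining epoch."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    epochs = sweep_result.epochs
    mroc = [sweep_result.mean_auroc[e] for e in epochs]
    sroc = [sweep_result.sd_auroc[e] for e in epochs]
    mprc = [sweep_result.mean_auprc[e] for e in epochs]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(epochs, mroc, yerr=sroc, marker="o", capsize=3, label="AUROC")
    ax.plot(epochs, mprc, marker="s", ls="--", label="AUPRC")
    if best_epoch is not None and best_epoch in epochs:
        ax.plot([best_epoch], [sweep_result.mean_auroc[best_epoch]], "r*", markersize=14,
                label=f"best (epoch {best_epoch})")
    ax.set_xlabel("pretraining epoch")
    ax.set_ylabel("held-out downstream metric")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
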