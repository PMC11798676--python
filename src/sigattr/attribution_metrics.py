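"""Evaluation measures for attributions against ground truth.

Presence on either side means activity > 0.  The Combined Score is
(1 - scaled Manhattan distance) + precision + recall, with a maximum of 3.
KL divergence uses activity proportions, base-2 logs, an epsilon-smoothed
denominator, and the standard 0*log(.) = 0 convention on the truth side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from sigattr.catalogs_spectra import Attribution

__all__ = [
    "ConfusionCounts",
    "SampleEvaluation",
    "MetricsConfig",
    "confusion_counts",
    "evaluate_sample",
    "summarize",
]

_MEASURES = (
    "precision",
    "recall",
    "specificity",
    "f1",
    "scaled_manhattan",
    "scaled_l2",
    "kl_divergence",
    "combined_score",
)


@dataclass(frozen=True)
class MetricsConfig:
    epsilon: float = 0.001  # KL smoothing constant

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def universe_size(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class SampleEvaluation:
    sample_id: str
    precision: float
    recall: float
    specificity: float
    f1: float
    scaled_manhattan: float
    scaled_l2: float
    kl_divergence: float
    combined_score: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in _MEASURES}


def confusion_counts(
    truth: Attribution, inferred: Attribution, universe: Sequence[str]
) -> ConfusionCounts:
    """Signature-presence confusion counts over the offered universe."""
    uni = set(universe)
    if len(uni) != len(list(universe)):
        raise ValueError("universe contains duplicates")
    t, i = truth.signatures, inferred.signatures
    outside = (t | i) - uni
    if outside:
        raise ValueError(f"signatures outside universe: {sorted(outside)!r}")
    tp = len(t & i)
    fp = len(i - t)
    fn = len(t - i)
    tn = len(uni) - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def evaluate_sample(
    truth: Attribution,
    inferred: Attribution,
    universe: Sequence[str],
    spectrum_total: float,
    config: MetricsConfig | None = None,
) -> SampleEvaluation:
    """All per-sample measures for one (truth, inferred) pair.

    spectrum_total is M, the sample's total mutation count, used to scale
    the Manhattan and L2 activity distances.  An empty inferred attribution
    has precision 1 (nothing was called, so nothing was called wrongly) and
    recall 0.
    """
    config = config or MetricsConfig()
    if spectrum_total <= 0:
        raise ValueError("spectrum_total must be positive")
    cc = confusion_counts(truth, inferred, universe)
    names = list(universe)
    x = truth.as_vector(names)
    y = inferred.as_vector(names)

    precision = cc.tp / (cc.tp + cc.fp) if (cc.tp + cc.fp) > 0 else 1.0
    recall = cc.tp / cc.p if cc.p > 0 else 1.0
    specificity = cc.tn / (cc.tn + cc.fp) if (cc.tn + cc.fp) > 0 else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    scaled_manhattan = float(np.abs(x - y).sum() / spectrum_total)
    scaled_l2 = float(np.linalg.norm(x - y) / spectrum_total)

    xp = x / x.sum() if x.sum() > 0 else x
    yp = y / y.sum() if y.sum() > 0 else y
    support = xp > 0
    kl = float(
        np.sum(
            xp[support]
            * np.log2(xp[support] / (yp[support] + config.epsilon))
        )
    )
    combined = (1.0 - scaled_manhattan) + precision + recall
    return SampleEvaluation(
        sample_id=truth.sample_id,
        precision=precision,
        recall=recall,
        specificity=specificity,
        f1=f1,
        scaled_manhattan=scaled_manhattan,
        scaled_l2=scaled_l2,
        kl_divergence=kl,
        combined_score=combined,
    )


def evaluations_frame(
    evaluations: Sequence[SampleEvaluation],
    approach: str | Sequence[str],
    cancer_type: str | Sequence[str] = "all",
) -> pd.DataFrame:
    """Tidy per-sample table: one row per (sample, approach)."""
    n = len(evaluations)
    approaches = [approach] * n if isinstance(approach, str) else list(approach)
    types = (
        [cancer_type] * n if isinstance(cancer_type, str) else list(cancer_type)
    )
    rows = []
    for ev, app, ct in zip(evaluations, approaches, types, strict=True):
        row = {"sample_id": ev.sample_id, "approach": app, "cancer_type": ct}
        row.update(ev.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(evaluations: pd.DataFrame) -> pd.DataFrame:
    """Mean/median/SD of every measure per (approach, cancer_type) and
    overall, plus dense ranks by mean combined_score (ties share a rank).
    """
    if evaluations.empty:
        raise ValueError("no evaluations to summarize")
    frames = []
    grouped = evaluations.groupby(["approach", "cancer_type"], sort=True)
    for (app, ct), grp in grouped:
        frames.append(_summary_row(grp, app, ct))
    for app, grp in evaluations.groupby("approach", sort=True):
        frames.append(_summary_row(grp, app, "overall"))
    out = pd.DataFrame(frames)
    out["rank"] = (
        out.groupby("cancer_type")["mean_combined_score"]
        .rank(method="dense", ascending=False)
        .astype(int)
    )
    return out


def _summary_row(grp: pd.DataFrame, approach: str, cancer_type: str) -> dict:
    row: dict = {
        "approach": approach,
        "cancer_type": cancer_type,
        "n_samples": len(grp),
    }
    for m in _MEASURES:
        row[f"mean_{m}"] = float(grp[m].mean())
        row[f"median_{m}"] = float(grp[m].median())
        row[f"sd_{m}"] = float(grp[m].std(ddof=1)) if len(grp) > 1 else 0.0
    return row
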