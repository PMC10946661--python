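"""Accuracy evaluation: the pooled ACC metric, error matrices, and the
hulled-vs-hulless comparison.

Each image prediction consists of two binary decisions (anthocyanin
present?, melanin present?).  ACC pools both decisions of every image into
one contingency: ACC = (TP + TN) / (P + N), where P and N are the true
positive/negative decision counts (P + N = 2 x images).  Per-pigment
accuracies and the 4-class error matrix are always reported alongside, so
the per-pigment-averaged reading of the metric is also available.

The hull comparison is a two-sided Mann-Whitney rank-sum test on per-image
correctness indicators split by hull status — exact permutation enumeration
for small samples (correctness indicators are heavily tied, so the exact
null is enumerated directly), tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import mannwhitneyu, rankdata

from .labels import CLASS_CODES, PigmentLabel

__all__ = [
    "EvalReport",
    "compute_acc",
    "confusion_4class",
    "compare_groups",
    "EXACT_ENUMERATION_LIMIT",
]

EXACT_ENUMERATION_LIMIT = 20  # total sample size up to which the exact null is enumerated


@dataclass
class EvalReport:
    """Pooled and per-pigment accuracy plus the 4-class error matrix."""

    tp: int
    tn: int
    p: int
    n: int
    acc: float
    per_pigment: dict
    confusion_4class: list  # 4x4 nested list, rows = truth NP/A/M/AM
    group_comparison: dict | None = None

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "EvalReport":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            data = json.loads(source)
        else:
            with open(source) as fh:
                data = json.load(fh)
        return cls(**data)


def _as_labels(labels) -> list[PigmentLabel]:
    return [
        lab if isinstance(lab, PigmentLabel) else PigmentLabel.from_code(str(lab))
        for lab in labels
    ]


def confusion_4class(predictions, truths) -> np.ndarray:
    """4x4 count table; rows = truth, columns = prediction (NP/A/M/AM)."""
    preds = _as_labels(predictions)
    truth = _as_labels(truths)
    if len(preds) != len(truth):
        raise ValueError("predictions and truths differ in length")
    table = np.zeros((4, 4), dtype=int)
    for p, t in zip(preds, truth):
        table[CLASS_CODES.index(t.code), CLASS_CODES.index(p.code)] += 1
    return table


def _binary_tally(preds, truth, pigment: str) -> dict:
    pv = np.array([getattr(p, pigment) for p in preds], dtype=bool)
    tv = np.array([getattr(t, pigment) for t in truth], dtype=bool)
    tp = int((pv & tv).sum())
    tn = int((~pv & ~tv).sum())
    fp = int((pv & ~tv).sum())
    fn = int((~pv & tv).sum())
    return {"tp": tp, "tn": tn, "fp": fp, "fn": fn, "acc": (tp + tn) / len(pv)}


def compute_acc(predictions, truths, hulled=None) -> EvalReport:
    """Evaluate predicted against true pigment labels.

    ``hulled`` (optional, one flag per image) adds the hulled-vs-hulless
    rank-sum comparison of per-image correctness for each pigment.
    """
    preds = _as_labels(predictions)
    truth = _as_labels(truths)
    if len(preds) == 0:
        raise ValueError("empty prediction set")
    if len(preds) != len(truth):
        raise ValueError(
            f"length mismatch: {len(preds)} predictions vs {len(truth)} truths"
        )
    per = {pig: _binary_tally(preds, truth, pig) for pig in ("anthocyanin", "melanin")}
    tp = per["anthocyanin"]["tp"] + per["melanin"]["tp"]
    tn = per["anthocyanin"]["tn"] + per["melanin"]["tn"]
    p_tot = sum(per[pig]["tp"] + per[pig]["fn"] for pig in per)
    n_tot = sum(per[pig]["tn"] + per[pig]["fp"] for pig in per)

    group = None
    if hulled is not None:
        flags = np.asarray(list(hulled), dtype=bool)
        if flags.size != len(preds):
            raise ValueError("hulled flags length mismatch")
        group = {}
        for pig in ("anthocyanin", "melanin"):
            correct = np.array(
                [getattr(p, pig) == getattr(t, pig) for p, t in zip(preds, truth)],
                dtype=float,
            )
            stat, pval = compare_groups(correct[flags], correct[~flags])
            group[pig] = {
                "hulled_mean_correct": float(correct[flags].mean()) if flags.any() else None,
                "hulless_mean_correct": float(correct[~flags].mean()) if (~flags).any() else None,
                "statistic": stat,
                "p_value": pval,
            }

    return EvalReport(
        tp=tp,
        tn=tn,
        p=p_tot,
        n=n_tot,
        acc=(tp + tn) / (p_tot + n_tot),
        per_pigment=per,
        confusion_4class=confusion_4class(preds, truth).tolist(),
        group_comparison=group,
    )


def compare_groups(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test on two groups of indicators.

    Returns ``(U statistic of group_a, p-value)``.  For total sample sizes
    up to ``EXACT_ENUMERATION_LIMIT`` the permutation null is enumerated
    exactly (correct under arbitrary ties); larger samples use the
    tie-corrected normal approximation.
    """
    a = np.asarray(list(group_a), dtype=np.float64)
    b = np.asarray(list(group_b), dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # average ranks for ties
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0

    if n1 + n2 <= EXACT_ENUMERATION_LIMIT:
        center = n1 * n2 / 2.0
        dev_obs = abs(u_obs - center)
        hits = 0
        for idx in combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
            if abs(u - center) >= dev_obs - 1e-12:
                hits += 1
        pval = hits / comb(n1 + n2, n1)
        return float(u_obs), float(pval)

    res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
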