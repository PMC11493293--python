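"""Late fusion of the three stream classifiers and ablation evaluation.

Each stream emits a normalized score triple per item. The fused decision is
a majority vote over the streams' argmax labels; when all three disagree
(a three-way tie) the class with the largest summed score wins, with the
fixed class order (none, weak, strong) breaking exact score ties. Pure
score-sum fusion is available as an alternative rule. Frame decisions are
aggregated to clip decisions by plurality with ties broken toward the
stronger class.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np

from .dataio import LABELS
from .metrics import MetricsReport, compute_metrics, confusion_matrix
from .nn.train import StreamPrediction

__all__ = [
    "FusionError",
    "FusionResult",
    "fuse",
    "fuse_scores",
    "aggregate_clip",
    "run_ablation",
    "STREAM_NAMES",
]

STREAM_NAMES = ("temporal", "spatial", "glcm")


class FusionError(ValueError):
    """Raised for malformed prediction sets or empty clips."""


@dataclass
class FusionResult:
    """Outcome of fusing three stream predictions for one item."""

    label: str
    votes: tuple[str, str, str]
    score_sums: np.ndarray
    tie_broken: bool


def fuse(preds: Sequence[StreamPrediction], method: str = "vote") -> FusionResult:
    """Fuse exactly three stream predictions into one decision.

    ``method='vote'`` (default): majority over argmax labels; a three-way
    tie falls back to the largest summed score. ``method='score_sum'``:
    argmax of the summed score triples directly. Exact score ties resolve
    to the earliest class in (none, weak, strong) order; ``tie_broken``
    flags any decision that was not a strict majority vote.
    """
    if len(preds) != 3:
        raise FusionError(f"fusion requires exactly 3 stream predictions, got {len(preds)}")
    classes = preds[0].classes
    if any(p.classes != classes for p in preds):
        raise FusionError("stream predictions must share one class order")
    if method not in ("vote", "score_sum"):
        raise FusionError(f"unknown fusion method {method!r}")

    votes = tuple(p.argmax_label for p in preds)
    score_sums = np.sum([p.scores for p in preds], axis=0)

    if method == "score_sum":
        label = classes[int(np.argmax(score_sums))]
        return FusionResult(label=label, votes=votes, score_sums=score_sums,
                            tie_broken=votes.count(label) < 2)

    counts = {lab: votes.count(lab) for lab in classes}
    best = max(counts.values())
    if best >= 2:
        label = next(lab for lab in classes if counts[lab] == best)
        return FusionResult(label=label, votes=votes, score_sums=score_sums, tie_broken=False)
    # three-way disagreement: largest summed score, class order on exact ties
    label = classes[int(np.argmax(score_sums))]
    return FusionResult(label=label, votes=votes, score_sums=score_sums, tie_broken=True)


def fuse_scores(score_rows: Sequence[np.ndarray], method: str = "vote") -> FusionResult:
    """Convenience wrapper: fuse three raw score triples."""
    return fuse([StreamPrediction(scores=np.asarray(s)) for s in score_rows], method=method)


_STRENGTH = {lab: i for i, lab in enumerate(LABELS)}  # none < weak < strong


def aggregate_clip(frame_labels: Sequence[str]) -> str:
    """Plurality label over a clip's frame decisions.

    Ties are broken toward the stronger class (strong > weak > none) — a
    conservative policy for feeding control that prefers not to under-read
    feeding demand.
    """
    if len(frame_labels) == 0:
        raise FusionError("cannot aggregate an empty clip")
    bad = [l for l in frame_labels if l not in _STRENGTH]
    if bad:
        raise FusionError(f"unknown labels {bad[:5]}")
    counts = {lab: 0 for lab in LABELS}
    for lab in frame_labels:
        counts[lab] += 1
    best = max(counts.values())
    return max((lab for lab in LABELS if counts[lab] == best), key=lambda l: _STRENGTH[l])


def run_ablation(
    stream_scores: dict[str, np.ndarray],
    true_labels: Sequence[str],
    streams: Optional[Iterable[str]] = None,
    method: str = "vote",
) -> dict[tuple[str, ...], MetricsReport]:
    """Evaluate every non-empty subset of the selected streams.

    ``stream_scores`` maps stream name → (N, 3) score array over the same N
    items. Single streams use their own argmax; two-stream combinations use
    summed-score argmax; the three-stream combination uses :func:`fuse`.

    Returns a dict keyed by the stream-name tuple of each combination.
    """
    names = tuple(streams) if streams is not None else STREAM_NAMES
    if not names:
        raise FusionError("at least one stream must be selected")
    missing = [n for n in names if n not in stream_scores]
    if missing:
        raise FusionError(f"no scores available for stream(s): {missing}")
    n_items = len(true_labels)
    for n in names:
        if stream_scores[n].shape != (n_items, len(LABELS)):
            raise FusionError(
                f"stream {n!r} scores have shape {stream_scores[n].shape}, "
                f"expected {(n_items, len(LABELS))}"
            )

    reports: dict[tuple[str, ...], MetricsReport] = {}
    for size in range(1, len(names) + 1):
        for combo in combinations(names, size):
            if size == 1:
                pred_idx = stream_scores[combo[0]].argmax(axis=1)
                predicted = [LABELS[i] for i in pred_idx]
            elif size == 2:
                summed = stream_scores[combo[0]] + stream_scores[combo[1]]
                predicted = [LABELS[i] for i in summed.argmax(axis=1)]
            else:
                predicted = [
                    fuse_scores([stream_scores[n][i] for n in combo], method=method).label
                    for i in range(n_items)
                ]
            conf = confusion_matrix(true_labels, predicted)
            reports[combo] = compute_metrics(conf)
    return reports
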