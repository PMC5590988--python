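"""Evaluation statistics: normalized edit-distance score and filter metrics.

The quality of a genotyped insertion is the edit distance between the
called and the true insertion sequence divided by the length of the true
sequence,

    Score(output, correct) = ed(output, correct) / |correct|.

A score of 0 is a perfect reconstruction; an insertion that was not
genotyped is scored with an empty output, which gives exactly 1.  The
score is not symmetric (the denominator is always the truth length), and
it can exceed 1 when the output is longer than the truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import edlib
import pandas as pd

from insfill.readfilter import (
    AlignmentIndex,
    InsertSizeModel,
    ReadAlignmentRecord,
    insert_size_bounds,
)

__all__ = [
    "ScoreReport",
    "edit_distance",
    "score",
    "summarize_by_length",
    "gapfiller_baseline_filter",
]


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (unit-cost substitutions, insertions, deletions)."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return int(edlib.align(a, b, mode="NW", task="distance")["editDistance"])


@dataclass(frozen=True)
class ScoreReport:
    """Normalized edit distance of a call against its truth."""

    edit_distance: int
    score: float
    truth_length: int


def score(output: Optional[str], correct: str) -> ScoreReport:
    """Score a called insertion; ``output=None`` means not genotyped.

    An ungenotyped insertion is scored as an empty output, so its edit
    distance is exactly the truth length and the score is exactly 1.
    """
    if not correct:
        raise ValueError("true insertion sequence must be non-empty")
    out = output or ""
    ed = edit_distance(out, correct)
    return ScoreReport(edit_distance=ed, score=ed / len(correct), truth_length=len(correct))


def summarize_by_length(
    calls: Iterable[Tuple[str, Optional[str]]],
    bins: Sequence[int],
) -> pd.DataFrame:
    """Mean score and genotyped counts per truth-length bin.

    ``calls`` yields ``(truth_sequence, output_or_None)`` pairs; ``bins``
    are ascending edges, bin ``i`` covering lengths ``[bins[i], bins[i+1])``.
    Ungenotyped calls contribute a score of 1.
    """
    edges = list(bins)
    if len(edges) < 2 or any(a >= b for a, b in zip(edges, edges[1:])):
        raise ValueError("bins must be ascending edges with at least two values")
    rows = []
    for truth, output in calls:
        rep = score(output, truth)
        rows.append((rep.truth_length, rep.score, output is not None and output != ""))
    df = pd.DataFrame(rows, columns=["length", "score", "genotyped"])
    df["bin"] = pd.cut(df["length"], edges, right=False)
    out = (
        df.groupby("bin", observed=False)
        .agg(n=("score", "size"), n_genotyped=("genotyped", "sum"), mean_score=("score", "mean"))
        .reset_index()
    )
    out["bin_lo"] = [iv.left for iv in out["bin"]]
    out["bin_hi"] = [iv.right for iv in out["bin"]]
    return out[["bin_lo", "bin_hi", "n", "n_genotyped", "mean_score"]]


def gapfiller_baseline_filter(
    alignments: Union[AlignmentIndex, Iterable[ReadAlignmentRecord]],
    gap: Tuple[int, int],
    max_distance: Optional[int] = None,
    model: Optional[InsertSizeModel] = None,
) -> set:
    """Baseline filter: unmapped reads whose mate maps near the gap.

    This mirrors the scheme used by distance-based gap fillers: every
    unaligned read from a pair whose aligned read starts within
    ``max_distance`` of the gap is selected.  The default distance is the
    model's maximum insert size (mu + z*sigma).
    """
    index = (
        alignments
        if isinstance(alignments, AlignmentIndex)
        else AlignmentIndex(alignments)
    )
    if max_distance is None:
        if model is None:
            raise ValueError("give max_distance or a model to derive it from")
        max_distance = insert_size_bounds(model)[1]
    s, e = gap
    return index.rescueable_in(max(0, s - max_distance), e + max_distance)
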