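"""The distance-from-diagonal (DfD) statistic and classical fluency metrics.

DfD quantifies how scrambled the shared items of two recall sequences are:

    DfD = sum over matrix cells of  m_ij * |i - j|

where m is the unique-mode recurrence matrix (repetitions removed before
matching). Identical sequences put every match on the diagonal, giving 0;
the score grows as shared items drift apart in rank. Fully disjoint lists
also score 0 (no matching cells) — a documented degeneracy: DfD measures
order similarity *of the overlap*, not overlap itself.

Classical metrics computed alongside: correct-word list length (unique,
in-category tokens), its pair average and signed difference, per-list
repetition proportion, and the pair's intrusion count.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .recurrence import AnnotatedPair, build_recurrence_matrix, reduce_unique

RepDenominator = Literal["total", "unique"]


def compute_dfd(
    pair_or_x: AnnotatedPair | Sequence[str],
    y: Sequence[str] | None = None,
    exclude_intrusions: bool = False,
) -> int:
    """Distance-from-diagonal of a pair of unique-reduced sequences.

    Accepts either an :class:`AnnotatedPair` or two token sequences
    (unique-reduced internally if needed). Intrusions are matchable by
    default; ``exclude_intrusions`` (AnnotatedPair input only) removes
    out-of-category tokens from both sequences before matching.

    Returns a non-negative integer; 0 for a perfect match and for fully
    disjoint lists.
    """
    if isinstance(pair_or_x, AnnotatedPair):
        ux, uy = pair_or_x.unique_a, pair_or_x.unique_b
        if exclude_intrusions:
            bad = pair_or_x.intrusion_tokens()
            ux = [t for t in ux if t not in bad]
            uy = [t for t in uy if t not in bad]
    else:
        if y is None:
            raise TypeError("compute_dfd needs an AnnotatedPair or two sequences")
        ux, _ = reduce_unique(list(pair_or_x))
        uy, _ = reduce_unique(list(y))
    if not ux or not uy:
        return 0
    m = build_recurrence_matrix(ux, uy, mode="unique").m
    ii, jj = np.nonzero(m)
    return int(np.abs(ii - jj).sum())


def repetition_proportion(
    tokens: Sequence[str], denominator: RepDenominator = "total"
) -> float:
    """Share of a list's production that is perseveration.

    ``total`` (default) divides the repeat count by the full token count,
    repeats included; ``unique`` divides by the unique-item count. An empty
    list scores 0.
    """
    if not tokens:
        return 0.0
    unique, reps = reduce_unique(list(tokens))
    denom = len(tokens) if denominator == "total" else len(unique)
    return len(reps) / denom


@dataclass
class PairMetrics:
    """All per-pair quantities used in the group comparisons."""

    participant_id: str
    visit_a: int
    visit_b: int
    group_a: str
    group_b: str
    dfd: int
    length_a: int          # unique, in-category ("correct") words, list a
    length_b: int
    average_length: float
    length_difference: int  # length_b - length_a (signed)
    repetition_proportion_a: float
    repetition_proportion_b: float
    repetition_proportion_avg: float
    intrusion_count_a: int
    intrusion_count_b: int
    intrusion_count_pair: int

    def as_dict(self) -> dict:
        return asdict(self)


def pair_metrics(
    pair: AnnotatedPair,
    rep_denominator: RepDenominator = "total",
    dfd_exclude_intrusions: bool = False,
) -> PairMetrics:
    """Compute :class:`PairMetrics` from an annotated pair.

    Length counts unique AND in-category tokens (intrusions are not
    "correct" words); the DfD keeps intrusions matchable unless told
    otherwise; the intrusion count is over occurrences in both raw lists.
    """
    intr_tokens = pair.intrusion_tokens()
    len_a = sum(1 for t in pair.unique_a if t not in intr_tokens)
    len_b = sum(1 for t in pair.unique_b if t not in intr_tokens)
    rp_a = repetition_proportion(pair.tokens_a, rep_denominator)
    rp_b = repetition_proportion(pair.tokens_b, rep_denominator)
    return PairMetrics(
        participant_id=pair.list_a.participant_id,
        visit_a=pair.list_a.visit_index,
        visit_b=pair.list_b.visit_index,
        group_a=pair.list_a.group,
        group_b=pair.list_b.group,
        dfd=compute_dfd(pair, exclude_intrusions=dfd_exclude_intrusions),
        length_a=len_a,
        length_b=len_b,
        average_length=(len_a + len_b) / 2,
        length_difference=len_b - len_a,
        repetition_proportion_a=rp_a,
        repetition_proportion_b=rp_b,
        repetition_proportion_avg=(rp_a + rp_b) / 2,
        intrusion_count_a=len(pair.intrusions_a),
        intrusion_count_b=len(pair.intrusions_b),
        intrusion_count_pair=len(pair.intrusions_a) + len(pair.intrusions_b),
    )


def metrics_table(metrics: Sequence[PairMetrics]) -> pd.DataFrame:
    """One row per pair, ready for CSV export or the stats module."""
    return pd.DataFrame([m.as_dict() for m in metrics])
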