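"""Recurrence (similarity) matrices between two recall sequences.

The core object is a binary match matrix: cell (i, j) is 1 exactly when
token i of the first (chronologically earlier) list equals token j of the
second list after normalization. Identical lists light up the diagonal;
order changes scatter points away from it; repeats put several points in
one row or column.

Two modes exist because visualization and quantification differ: ``raw``
keeps repeats (so perseverations are visible as extra points), ``unique``
works on unique-reduced lists (each token's first occurrence only), which
is the form the distance-from-diagonal statistic is defined on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .io_model import FluencyList, Vocabulary, normalize_token

Mode = Literal["raw", "unique"]


@dataclass(frozen=True)
class RepetitionRecord:
    """A perseveration: the token at ``position`` already occurred at
    ``first_position`` (both 0-based, raw order)."""

    position: int
    first_position: int
    token: str


def reduce_unique(tokens: Sequence[str]) -> tuple[list[str], list[RepetitionRecord]]:
    """Remove repeats, keeping each token's first occurrence in order.

    Returns the unique-reduced sequence and one :class:`RepetitionRecord`
    per removed occurrence. ``len(unique) + len(repetitions) == len(tokens)``.
    """
    unique: list[str] = []
    first_pos: dict[str, int] = {}
    repetitions: list[RepetitionRecord] = []
    for pos, tok in enumerate(tokens):
        if tok in first_pos:
            repetitions.append(RepetitionRecord(pos, first_pos[tok], tok))
        else:
            first_pos[tok] = pos
            unique.append(tok)
    return unique, repetitions


def detect_intrusions(
    tokens: Sequence[str],
    vocab: Vocabulary | None = None,
    flags: Sequence[bool] | None = None,
) -> list[int]:
    """Positions (0-based) of out-of-category tokens.

    Source-curated ``flags`` take precedence over vocabulary lookup; with
    neither available intrusion detection is impossible and a ValueError is
    raised. Each out-of-category *occurrence* counts (a repeated intrusion
    contributes one position per occurrence).
    """
    if flags is not None:
        if len(flags) != len(tokens):
            raise ValueError("intrusion flags length mismatch")
        return [i for i, f in enumerate(flags) if f]
    if vocab is None or len(vocab) == 0:
        raise ValueError(
            "intrusion detection unavailable: no vocabulary and no source flags"
        )
    return [i for i, t in enumerate(tokens) if t not in vocab]


@dataclass
class RecurrenceMatrix:
    """Binary match matrix between two token sequences.

    ``m[i, j] == 1`` iff ``x_tokens[i] == y_tokens[j]`` (tokens are expected
    pre-normalized). The x axis carries the chronologically first list.
    """

    m: np.ndarray
    x_tokens: list[str]
    y_tokens: list[str]
    mode: Mode

    @property
    def shape(self) -> tuple[int, int]:
        return self.m.shape

    def match_indices(self) -> np.ndarray:
        """(k, 2) array of (i, j) coordinates of the 1-cells."""
        return np.argwhere(self.m)

    def to_text(self, path: str | Path, delimiter: str = "\t") -> None:
        """Export as a 0/1 grid with header rows listing the axis tokens."""
        lines = [
            "# x_tokens: " + delimiter.join(self.x_tokens),
            "# y_tokens: " + delimiter.join(self.y_tokens),
            f"# mode: {self.mode}",
        ]
        for row in self.m:
            lines.append(delimiter.join(str(int(v)) for v in row))
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def build_recurrence_matrix(
    x: Sequence[str], y: Sequence[str], mode: Mode = "raw"
) -> RecurrenceMatrix:
    """Build the |x| × |y| binary match matrix.

    In ``unique`` mode the inputs must be duplicate-free (use
    :func:`reduce_unique` first); each row and column then holds at most
    one 1. Empty sequences yield a 0-sized dimension.
    """
    if mode not in ("raw", "unique"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "unique":
        for name, seq in (("x", x), ("y", y)):
            if len(set(seq)) != len(seq):
                raise ValueError(f"unique mode requires duplicate-free {name} sequence")
    xa = np.asarray(list(x), dtype=object)
    ya = np.asarray(list(y), dtype=object)
    m = (xa[:, None] == ya[None, :]).astype(np.int8) if len(xa) and len(ya) else np.zeros(
        (len(xa), len(ya)), dtype=np.int8
    )
    return RecurrenceMatrix(m=m, x_tokens=list(x), y_tokens=list(y), mode=mode)


@dataclass
class AnnotatedPair:
    """Two lists from one participant, with everything the pair plot and the
    pair metrics need: normalized and unique-reduced sequences, repetition
    records, intrusion positions, and the items missing from either list."""

    list_a: FluencyList
    list_b: FluencyList
    tokens_a: list[str] = field(default_factory=list)  # normalized, raw order
    tokens_b: list[str] = field(default_factory=list)
    unique_a: list[str] = field(default_factory=list)
    unique_b: list[str] = field(default_factory=list)
    repetitions_a: list[RepetitionRecord] = field(default_factory=list)
    repetitions_b: list[RepetitionRecord] = field(default_factory=list)
    intrusions_a: list[int] = field(default_factory=list)  # raw positions
    intrusions_b: list[int] = field(default_factory=list)
    missing_from_b: list[str] = field(default_factory=list)  # in unique_a only
    missing_from_a: list[str] = field(default_factory=list)  # in unique_b only

    def matrix(self, mode: Mode = "raw") -> RecurrenceMatrix:
        """Recurrence matrix of the pair; x axis = first list."""
        if mode == "unique":
            return build_recurrence_matrix(self.unique_a, self.unique_b, "unique")
        return build_recurrence_matrix(self.tokens_a, self.tokens_b, "raw")

    def intrusion_tokens(self) -> set[str]:
        return {self.tokens_a[i] for i in self.intrusions_a} | {
            self.tokens_b[i] for i in self.intrusions_b
        }


def annotate_pair(
    a: FluencyList,
    b: FluencyList,
    vocab: Vocabulary | None = None,
    allow_cross_participant: bool = False,
) -> AnnotatedPair:
    """Normalize, unique-reduce and annotate a chronological pair of lists.

    ``a`` must precede ``b`` chronologically and both must belong to the
    same participant (override with ``allow_cross_participant`` to compare
    across people deliberately). Intrusions come from source flags when the
    lists carry them, else from ``vocab``; if neither is available the
    intrusion fields are left empty (pair metrics then count 0 intrusions,
    and :func:`detect_intrusions` is the strict entry point).
    """
    if a.participant_id != b.participant_id and not allow_cross_participant:
        raise ValueError(
            f"lists belong to different participants ({a.participant_id!r} vs "
            f"{b.participant_id!r}); pass allow_cross_participant=True to override"
        )
    if a.participant_id == b.participant_id and a.visit_index > b.visit_index:
        raise ValueError(
            f"list a (visit {a.visit_index}) must precede list b (visit {b.visit_index})"
        )

    def _canon(fl: FluencyList) -> list[str]:
        toks = fl.normalized_tokens()
        if vocab is not None:
            toks = [vocab.canonical(t) if t else t for t in toks]
        return toks

    tokens_a, tokens_b = _canon(a), _canon(b)
    unique_a, reps_a = reduce_unique(tokens_a)
    unique_b, reps_b = reduce_unique(tokens_b)

    def _intrusions(fl: FluencyList, toks: list[str]) -> list[int]:
        flags = (fl.annotations or {}).get("intrusion")
        if flags is not None and len(flags) == len(toks):
            return detect_intrusions(toks, flags=flags)
        if vocab is not None and len(vocab):
            return detect_intrusions(toks, vocab=vocab)
        return []

    set_a, set_b = set(unique_a), set(unique_b)
    return AnnotatedPair(
        list_a=a,
        list_b=b,
        tokens_a=tokens_a,
        tokens_b=tokens_b,
        unique_a=unique_a,
        unique_b=unique_b,
        repetitions_a=reps_a,
        repetitions_b=reps_b,
        intrusions_a=_intrusions(a, tokens_a),
        intrusions_b=_intrusions(b, tokens_b),
        missing_from_b=[t for t in unique_a if t not in set_b],
        missing_from_a=[t for t in unique_b if t not in set_a],
    )
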