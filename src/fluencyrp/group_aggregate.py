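"""Group-level cumulative scaled heatmaps and between-group difference maps.

Every chronologically adjacent within-participant pair whose two visits both
carry a group's diagnosis contributes one binary recurrence matrix. The
matrices are zero-padded to the group's maximum dimensions (origin — the
first-recalled × first-recalled cell — anchored at (0, 0)), summed
elementwise, and divided by the number of pairs. Each cell is then the
proportion of the group's pairs that match at that coordinate, so the grid
lives in [0, 1]. Subtracting one group's grid from another's (after
co-padding) shows where one group's recall patterns are denser.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .io_model import Cohort, Vocabulary
from .recurrence import AnnotatedPair, Mode, annotate_pair

PairRule = Literal["both-visits", "first-visit"]


def collect_group_pairs(
    cohort: Cohort,
    group: str,
    vocab: Vocabulary | None = None,
    pair_rule: PairRule = "both-visits",
) -> list[AnnotatedPair]:
    """All consecutive within-participant pairs belonging to ``group``.

    ``both-visits`` (default, conservative) requires the diagnosis label at
    BOTH visits to equal ``group``; ``first-visit`` assigns a pair by the
    label at its first visit only. A participant whose diagnosis changes
    mid-series contributes no pair spanning the transition under the
    default rule.
    """
    pairs = []
    for a, b in cohort.consecutive_pairs():
        if pair_rule == "both-visits":
            keep = a.group == group and b.group == group
        elif pair_rule == "first-visit":
            keep = a.group == group
        else:
            raise ValueError(f"unknown pair_rule {pair_rule!r}")
        if keep:
            pairs.append(annotate_pair(a, b, vocab=vocab))
    return pairs


def _padded_sum(pairs: Sequence[AnnotatedPair], mode: Mode) -> tuple[np.ndarray, int]:
    mats = [p.matrix(mode).m for p in pairs]
    max_x = max(m.shape[0] for m in mats)
    max_y = max(m.shape[1] for m in mats)
    total = np.zeros((max_x, max_y), dtype=float)
    for m in mats:
        total[: m.shape[0], : m.shape[1]] += m
    return total, len(mats)


@dataclass
class GroupHeatmap:
    """Cumulative scaled recurrence grid for one diagnostic group."""

    grid: np.ndarray  # values in [0, 1]
    n_pairs: int
    group: str
    mode: Mode

    def export(self, prefix: str | Path, delimiter: str = "\t") -> None:
        """Numeric grid + JSON sidecar with group, n_pairs and mode."""
        prefix = Path(prefix)
        np.savetxt(prefix.with_suffix(".tsv"), self.grid, delimiter=delimiter, fmt="%.6g")
        prefix.with_suffix(".json").write_text(
            json.dumps(
                {"group": self.group, "n_pairs": self.n_pairs, "mode": self.mode,
                 "shape": list(self.grid.shape)},
                indent=2,
            )
        )


@dataclass
class DifferenceMap:
    """Elementwise difference of two co-padded group heatmaps (A − B)."""

    grid: np.ndarray  # values in [-1, 1]
    label_a: str
    label_b: str
    mode: Mode

    def export(self, prefix: str | Path, delimiter: str = "\t") -> None:
        prefix = Path(prefix)
        np.savetxt(prefix.with_suffix(".tsv"), self.grid, delimiter=delimiter, fmt="%.6g")
        prefix.with_suffix(".json").write_text(
            json.dumps(
                {"label_a": self.label_a, "label_b": self.label_b, "mode": self.mode,
                 "shape": list(self.grid.shape)},
                indent=2,
            )
        )


def accumulate_heatmap(
    pairs: Sequence[AnnotatedPair], mode: Mode = "raw", group: str = ""
) -> GroupHeatmap:
    """Zero-pad, sum and scale a group's recurrence matrices.

    Raw mode is the default: the drawn plots include repeats as plotted
    points, and the aggregate view mirrors them. Raises on an empty pair
    list (a heatmap of nothing is undefined).
    """
    if not pairs:
        raise ValueError("accumulate_heatmap needs at least one pair")
    total, n = _padded_sum(pairs, mode)
    return GroupHeatmap(grid=total / n, n_pairs=n, group=group, mode=mode)


def difference_map(a: GroupHeatmap, b: GroupHeatmap) -> DifferenceMap:
    """a.grid − b.grid after co-padding to the elementwise max dimensions."""
    if a.mode != b.mode:
        raise ValueError(f"mode mismatch: {a.mode!r} vs {b.mode!r}")
    nx = max(a.grid.shape[0], b.grid.shape[0])
    ny = max(a.grid.shape[1], b.grid.shape[1])
    ga = np.zeros((nx, ny))
    gb = np.zeros((nx, ny))
    ga[: a.grid.shape[0], : a.grid.shape[1]] = a.grid
    gb[: b.grid.shape[0], : b.grid.shape[1]] = b.grid
    return DifferenceMap(grid=ga - gb, label_a=a.group, label_b=b.group, mode=a.mode)
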