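"""Data model and I/O for verbal-fluency tables and category vocabularies.

A fluency "list" is one participant-visit recall sequence: the animals (or
other category members) a participant named in 60 s, in production order.
Longitudinal datasets hold many such lists per participant, one per clinic
visit, each carrying a per-visit diagnosis label (e.g. healthy control vs.
probable Alzheimer's disease).

Tables are long-format delimited text: one row per produced token, keyed by
participant, visit and within-list position. Column names, not positions,
identify fields, so differently laid-out deposits can be read by renaming.
"""

from __future__ import annotations

import logging
import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("fluencyrp")

#: Columns every fluency table must carry (after applying ``column_map``).
REQUIRED_COLUMNS = ("participant_id", "group", "visit_index", "position", "token")
#: Optional per-token annotation columns (curated transcripts may carry them).
FLAG_COLUMNS = ("intrusion_flag", "repetition_flag")

_WS_RUN = re.compile(r"\s+")
_PUNCT = string.punctuation + "‘’“”"


def normalize_token(raw: str) -> str:
    """Canonicalize one transcribed token for exact-match comparison.

    Lowercases, strips surrounding whitespace and punctuation, and collapses
    internal whitespace runs to a single space. Multi-word items ("polar
    bear") stay one token. Returns the empty string if nothing survives;
    callers drop such tokens with a warning.
    """
    s = _WS_RUN.sub(" ", str(raw).strip().lower())
    return s.strip(_PUNCT + " ")


@dataclass
class FluencyList:
    """One participant-visit recall sequence, in raw production order.

    Tokens are stored exactly as read — no de-duplication, no normalization —
    so downstream annotation can point back at raw positions. ``annotations``
    optionally carries source-curated per-token flags keyed ``"intrusion"``
    and ``"repetition"`` (each a sequence of bools aligned with ``tokens``).
    """

    participant_id: str
    visit_index: int
    group: str
    tokens: list[str]
    category: str = "animals"
    visit_label: str | None = None
    annotations: dict[str, list[bool]] | None = None

    def __post_init__(self) -> None:
        if self.visit_index < 1:
            raise ValueError(
                f"visit_index must be >= 1, got {self.visit_index} "
                f"for participant {self.participant_id!r}"
            )
        if self.annotations:
            for key, flags in self.annotations.items():
                if len(flags) != len(self.tokens):
                    raise ValueError(
                        f"{key} flags length {len(flags)} != {len(self.tokens)} tokens"
                    )

    def normalized_tokens(self) -> list[str]:
        """Tokens after :func:`normalize_token`; empty results are dropped."""
        out = []
        for t in self.tokens:
            n = normalize_token(t)
            if n:
                out.append(n)
            else:
                logger.warning(
                    "dropping token %r (empty after normalization) for %s visit %d",
                    t, self.participant_id, self.visit_index,
                )
        return out

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class Vocabulary:
    """The set of valid category members, used for intrusion detection.

    ``alias_map`` sends normalized surface forms to canonical members
    (e.g. "dogs" -> "dog"); membership is tested after normalization and
    aliasing.
    """

    category: str
    members: set[str]
    alias_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {c for c in self.alias_map.values() if c not in self.members}
        if bad:
            raise ValueError(
                f"alias canonical form(s) not in vocabulary: {sorted(bad)}"
            )

    def canonical(self, token: str) -> str:
        """Normalized token after alias resolution."""
        n = normalize_token(token)
        return self.alias_map.get(n, n)

    def __contains__(self, token: str) -> bool:
        return self.canonical(token) in self.members

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class Cohort:
    """All fluency lists of a dataset, grouped by participant.

    Within a participant, lists are kept sorted by ``visit_index`` and no two
    lists share a visit index.
    """

    lists: dict[str, list[FluencyList]]
    provenance: str = "<memory>"

    def __post_init__(self) -> None:
        for pid, pls in self.lists.items():
            pls.sort(key=lambda fl: fl.visit_index)
            seen = [fl.visit_index for fl in pls]
            if len(set(seen)) != len(seen):
                raise ValueError(f"duplicate visit_index for participant {pid!r}: {seen}")

    def participants(self) -> list[str]:
        return sorted(self.lists)

    def n_lists(self) -> int:
        return sum(len(v) for v in self.lists.values())

    def iter_lists(self) -> Iterator[FluencyList]:
        for pid in self.participants():
            yield from self.lists[pid]

    def consecutive_pairs(self) -> Iterator[tuple[FluencyList, FluencyList]]:
        """Every chronologically adjacent within-participant pair (a, b)."""
        for pid in self.participants():
            pls = self.lists[pid]
            for a, b in zip(pls, pls[1:]):
                yield a, b


def _assign_visit_indices(df: pd.DataFrame) -> pd.DataFrame:
    """Derive ``visit_index`` from a sortable ``visit_label`` per participant.

    Ascending label order (dates sort lexically in ISO form); ties broken by
    first appearance in the file, with a warning.
    """
    df = df.copy()
    idx = []
    for pid, sub in df.groupby("participant_id", sort=False):
        labels = list(dict.fromkeys(sub["visit_label"]))
        ordered = sorted(labels)
        if len(set(ordered)) != len(ordered):
            logger.warning("tied visit labels for participant %r; file order used", pid)
        rank = {lab: i + 1 for i, lab in enumerate(ordered)}
        idx.append(sub["visit_label"].map(rank))
    df["visit_index"] = pd.concat(idx).sort_index()
    return df


def read_fluency_table(
    path: str | Path,
    delimiter: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> Cohort:
    """Read a long-format fluency table into a :class:`Cohort`.

    Parameters
    ----------
    path
        Delimited UTF-8 text with a header row. Required columns (possibly
        via ``column_map``): participant_id, group, visit_index (or a
        sortable visit_label), position, token. Optional: intrusion_flag,
        repetition_flag, visit_label, category.
    delimiter
        Field separator; ``None`` auto-detects (csv.Sniffer).
    column_map
        Source-column -> canonical-column renames, for deposits whose
        headers differ.

    Raises
    ------
    ValueError
        If a required column is missing (named in the message) or a
        (participant, visit, position) triple is duplicated.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=delimiter,
        engine="python" if delimiter is None else "c",
        dtype=str,
        keep_default_na=False,
        na_values=[""],
    )
    if column_map:
        df = df.rename(columns=dict(column_map))

    if "visit_index" not in df.columns and "visit_label" in df.columns:
        missing_core = [c for c in ("participant_id", "group", "position", "token")
                        if c not in df.columns]
        if missing_core:
            raise ValueError(f"missing required column(s): {missing_core}")
        df = _assign_visit_indices(df)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")

    n0 = len(df)
    df = df.dropna(subset=["participant_id", "visit_index", "token"])
    rejected = n0 - len(df)
    if rejected:
        logger.warning("rejected %d row(s) with missing participant/visit/token", rejected)

    df["visit_index"] = df["visit_index"].astype(int)
    df["position"] = df["position"].astype(int)

    dup = df.duplicated(subset=["participant_id", "visit_index", "position"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            "duplicate (participant, visit, position): "
            f"({first['participant_id']}, {first['visit_index']}, {first['position']})"
        )

    lists: dict[str, list[FluencyList]] = {}
    for (pid, visit), sub in df.groupby(["participant_id", "visit_index"], sort=True):
        sub = sub.sort_values("position")
        annotations = None
        present_flags = [c for c in FLAG_COLUMNS if c in sub.columns]
        if present_flags:
            annotations = {}
            for col in present_flags:
                key = col.removesuffix("_flag")
                annotations[key] = [
                    str(v).strip().lower() in ("1", "true", "yes", "t") for v in sub[col]
                ]
        lists.setdefault(str(pid), []).append(
            FluencyList(
                participant_id=str(pid),
                visit_index=int(visit),
                group=str(sub["group"].iloc[0]),
                tokens=list(sub["token"]),
                category=str(sub["category"].iloc[0]) if "category" in sub.columns else "animals",
                visit_label=str(sub["visit_label"].iloc[0]) if "visit_label" in sub.columns else None,
                annotations=annotations,
            )
        )
    return Cohort(lists=lists, provenance=str(path))


def write_fluency_table(cohort: Cohort, path: str | Path, delimiter: str = ",") -> None:
    """Write a cohort back to the long table format (round-trips with
    :func:`read_fluency_table`)."""
    rows = []
    for fl in cohort.iter_lists():
        for pos, tok in enumerate(fl.tokens, start=1):
            row = {
                "participant_id": fl.participant_id,
                "group": fl.group,
                "visit_index": fl.visit_index,
                "position": pos,
                "token": tok,
                "category": fl.category,
            }
            if fl.visit_label is not None:
                row["visit_label"] = fl.visit_label
            if fl.annotations:
                for key, flags in fl.annotations.items():
                    row[f"{key}_flag"] = int(flags[pos - 1])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


def load_vocabulary(path: str | Path, category: str = "animals") -> Vocabulary:
    """Load a plain-text vocabulary: one member per line, ``#`` comments
    ignored, optional ``alias<TAB>canonical`` lines."""
    members: set[str] = set()
    aliases: dict[str, str] = {}
    for raw_line in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw_line.strip()
        if not line or line.startswith("#"):
            continue
        if "\t" in line:
            alias, canonical = line.split("\t", 1)
            aliases[normalize_token(alias)] = normalize_token(canonical)
        else:
            n = normalize_token(line)
            if n:
                members.add(n)
    return Vocabulary(category=category, members=members, alias_map=aliases)


def write_vocabulary(vocab: Vocabulary, path: str | Path) -> None:
    lines = sorted(vocab.members)
    lines += [f"{a}\t{c}" for a, c in sorted(vocab.alias_map.items())]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def cohort_from_lists(lists: Iterable[FluencyList], provenance: str = "<memory>") -> Cohort:
    """Group loose FluencyLists into a Cohort."""
    by_pid: dict[str, list[FluencyList]] = {}
    for fl in lists:
        by_pid.setdefault(fl.participant_id, []).append(fl)
    return Cohort(lists=by_pid, provenance=provenance)
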