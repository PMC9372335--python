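"""Reproduction of the published UCSD ADRC animal-fluency analysis from a
local copy of the deposited dataset (https://osf.io/j6qea/).

The deposit is not redistributed with this package; download it manually
and point :func:`reproduce_osf_analysis` at the fluency table. The exact
column layout of the deposit is not fixed here — pass ``column_map`` to
rename its headers onto the canonical ones (participant_id, group,
visit_index or visit_label, position, token).

The function runs the complete pipeline — ingest, cohort filters, pair
metrics, Welch comparisons, the logistic model ladder, and the group
heatmap pair counts — and reports every disambiguation choice it used
(repetition-proportion denominator, heatmap pair-inclusion rule, intrusion
source), since the published numbers depend on them.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

from .group_aggregate import PairRule, collect_group_pairs
from .io_model import Vocabulary, load_vocabulary, read_fluency_table
from .metrics import RepDenominator
from .stats import GROUP_HC, GROUP_PROBAD, apply_cohort_filters, group_descriptives, run_model_ladder

#: Where the acceptance pipeline expects a manual download to live.
DEFAULT_DATA_PATH = Path("data/osf_adrc/fluency.csv")


def reproduce_osf_analysis(
    data_path: str | Path = DEFAULT_DATA_PATH,
    vocab_path: str | Path | None = None,
    column_map: Mapping[str, str] | None = None,
    rep_denominator: RepDenominator = "total",
    pair_rule: PairRule = "both-visits",
    out_path: str | Path | None = None,
) -> dict:
    """Run the full published analysis on a local copy of the deposit.

    Returns (and optionally writes as JSON) group means/SDs and Welch tests
    for DfD, list length, repetition proportion and intrusions; the filtered
    sample sizes; the heatmap pair counts per group; the model ladder; and
    the analysis choices used.

    Raises FileNotFoundError with download instructions if the deposit is
    not present locally.
    """
    data_path = Path(data_path)
    if not data_path.exists():
        raise FileNotFoundError(
            f"deposited dataset not found at {data_path}; download the UCSD "
            "ADRC semantic-fluency deposit from https://osf.io/j6qea/ and "
            "save its fluency table there (adapt columns via column_map)"
        )
    cohort = read_fluency_table(data_path, column_map=column_map)
    vocab: Vocabulary | None = load_vocabulary(vocab_path) if vocab_path else None

    sample = apply_cohort_filters(cohort, vocab=vocab, rep_denominator=rep_denominator)
    desc = group_descriptives(sample)
    ladder = run_model_ladder(sample)
    pair_counts = {
        g: len(collect_group_pairs(cohort, g, vocab=vocab, pair_rule=pair_rule))
        for g in (GROUP_HC, GROUP_PROBAD)
    }
    result = {
        "choices": {
            "rep_denominator": rep_denominator,
            "pair_rule": pair_rule,
            "intrusion_source": "source flags if present, else vocabulary"
            if vocab else "source flags only",
            "dfd_intrusions": "matchable (retained in unique lists)",
        },
        "n_by_group": sample.n_by_group(),
        "filter_counts": sample.filter_counts,
        "descriptives": desc.to_dict(orient="records"),
        "heatmap_pair_counts": pair_counts,
        "model_ladder": ladder,
    }
    if out_path is not None:
        Path(out_path).write_text(json.dumps(result, indent=2))
    return result
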