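#!/usr/bin/env python
"""Reproduce the published group analysis on a local copy of the UCSD ADRC
semantic-fluency deposit (https://osf.io/j6qea/).

The deposit is not redistributed. Download it, save the fluency table as
data/osf_adrc/fluency.csv (or pass --data), mapping its headers onto
participant_id, group, visit_index (or visit_label), position, token — see
--column-map. The script prints group descriptives (DfD, list length,
repetition proportion, intrusions), Welch tests, the filtered sample sizes,
the per-group heatmap pair counts, the full model ladder, and every
analysis choice it used.

Example:
    python scripts/reproduce_osf.py --data data/osf_adrc/fluency.csv \\
        --column-map subject=participant_id --column-map word=token \\
        --out results/osf_reproduction.json
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from fluencyrp.osf import DEFAULT_DATA_PATH, reproduce_osf_analysis


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__,
                                 formatter_class=argparse.RawDescriptionHelpFormatter)
    ap.add_argument("--data", type=Path, default=DEFAULT_DATA_PATH)
    ap.add_argument("--vocab", type=Path, default=None,
                    help="Category vocabulary for intrusion detection; omit "
                         "if the deposit carries curated intrusion flags.")
    ap.add_argument("--column-map", action="append", default=[],
                    metavar="SRC=DST", help="Rename a source column (repeatable).")
    ap.add_argument("--rep-denominator", choices=["total", "unique"], default="total")
    ap.add_argument("--pair-rule", choices=["both-visits", "first-visit"],
                    default="both-visits")
    ap.add_argument("--out", type=Path, default=None)
    args = ap.parse_args()

    column_map = dict(item.split("=", 1) for item in args.column_map)
    result = reproduce_osf_analysis(
        data_path=args.data,
        vocab_path=args.vocab,
        column_map=column_map or None,
        rep_denominator=args.rep_denominator,
        pair_rule=args.pair_rule,
        out_path=args.out,
    )
    print(json.dumps(result, indent=2))


if __name__ == "__main__":
    main()
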