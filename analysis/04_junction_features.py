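#!/usr/bin/env python
"""Rejoined-site features and the Fisher contrasts between size classes.

Builds the junction feature table (insertion / MH / neither, plus the
2-vs-3 bp MH-length split) for the published site inventories and tests the
published contrasts: insertion frequency in rearrangements vs small
deletions, and MH frequency in medium vs small deletions.
"""

import json
from pathlib import Path

from sectormut.contrast_stats import fisher_exact_two_sided
from sectormut.datasets import (
    synthetic_rearrangement_sites,
    synthetic_small_medium_del_sites,
)
from sectormut.junction_analysis import summarize_junction_features

ROOT = Path(__file__).resolve().parent.parent / "results"

CONTRASTS = [
    ("insertions: rearrangement vs small_del", "rearrangement", "small_del", "ins"),
    ("insertions: rearrangement vs medium_del", "rearrangement", "medium_del", "ins"),
    ("MH: medium_del vs small_del", "medium_del", "small_del", "mh"),
    ("MH: medium_del vs rearrangement", "medium_del", "rearrangement", "mh"),
    ("neither: small_del vs rearrangement", "small_del", "rearrangement", "none"),
    ("MH >=3 bp: medium_del vs small_del", "medium_del", "small_del", "mh_ge3"),
]


def main() -> None:
    out = ROOT / "junctions"
    out.mkdir(parents=True, exist_ok=True)
    sites = synthetic_rearrangement_sites() + synthetic_small_medium_del_sites()
    table = summarize_junction_features(sites)
    (out / "junction_features.json").write_text(
        json.dumps(table.as_dict(), indent=1, sort_keys=True)
    )
    rows = ["label\ta\tb\tc\td\todds_ratio\tp_two_sided"]
    for label, ca, cb, feature in CONTRASTS:
        res = fisher_exact_two_sided(table.contingency(ca, cb, feature), label=label)
        (a, b), (c, d) = res.table
        rows.append(f"{label}\t{a}\t{b}\t{c}\t{d}\t{res.odds_ratio:.3g}\t{res.p_two_sided:.3g}")
        print(f"{label}: p = {res.p_two_sided:.4g}")
    (out / "contrasts.tsv").write_text("\n".join(rows) + "\n")


if __name__ == "__main__":
    main()
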