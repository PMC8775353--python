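#!/usr/bin/env python
"""Generate the synthetic sector suite used by the downstream analyses.

Seven chimeric sectors at 85x coverage, each a dominant single-cell lineage
(f = 0.7) plus a minor one, on a shared random reference. Writes FASTA,
mutation tables (TSV + VCF), SV breakends, per-sector depth tracks, and the
ground-truth JSON under results/fixtures/.
"""

import json
from pathlib import Path

from sectormut.synthetic_data import SimConfig, emit_fixture_suite

OUT = Path(__file__).resolve().parent.parent / "results" / "fixtures"


def main() -> None:
    cfg = SimConfig(seed=1, n_sectors=7)
    paths = emit_fixture_suite(cfg, OUT)
    truth = json.loads((OUT / "truth.json").read_text())
    n_mut = sum(len(t["mutations"]) for t in truth.values())
    n_del = sum(len(t["deleted_regions"]) for t in truth.values())
    print(f"wrote {len(paths)} files to {OUT}")
    print(f"{len(truth)} sectors, {n_mut} implanted mutations, "
          f"{n_del} heterozygous large deletions")


if __name__ == "__main__":
    main()
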