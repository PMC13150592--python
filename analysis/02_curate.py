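#!/usr/bin/env python
"""Curate raw activity records into one pIC50 entry per compound.

Reads results/synthetic_activity.csv, applies the assay filter, unit
standardization, replicate averaging and the 3-fold consistency rule,
and writes results/curated.csv.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
import bcrpqsar as bq  # noqa: E402
from bcrpqsar import io  # noqa: E402

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    records, skipped = io.read_activity_table(
        RESULTS / "synthetic_activity.csv")
    entries = bq.curate(
        records,
        allowed=lambda tags: "assay_type:cell_based_transport" in tags)
    io.write_curated_csv(entries, RESULTS / "curated.csv")
    n_inc = sum(not e.consistent for e in entries)
    print(f"read {len(records)} records ({len(skipped)} skipped), "
          f"curated to {len(entries)} unique compounds")
    print(f"  {n_inc} flagged for >3-fold replicate disagreement "
          "(retained, not dropped)")


if __name__ == "__main__":
    main()
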