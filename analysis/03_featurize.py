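#!/usr/bin/env python
"""Compute substructure-dictionary fingerprints for the curated set.

Reads results/curated.csv, builds the model matrix from every shipped
dictionary (MACCS keys, count sections, curated functional groups, and
the systematic ring x substituent enumeration), and writes
results/features.csv plus the target vector results/target.csv.
"""
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
import bcrpqsar as bq  # noqa: E402
from bcrpqsar import io  # noqa: E402

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    entries = io.read_curated_csv(RESULTS / "curated.csv")
    smiles = [e.smiles_std for e in entries]
    specs = bq.default_specs()
    table = bq.build_feature_table(smiles, specs, compound_ids=smiles)
    io.write_feature_table_csv(table, RESULTS / "features.csv")
    pd.DataFrame({"smiles_std": smiles,
                  "pic50": [e.pic50 for e in entries]}).to_csv(
        RESULTS / "target.csv", index=False)
    density = table.matrix.mean()
    print(f"featurized {table.n} compounds x {table.p} bits "
          f"({', '.join(f'{s.name}:{len(s)}' for s in specs)})")
    print(f"  overall bit density {density:.3f}")


if __name__ == "__main__":
    main()
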