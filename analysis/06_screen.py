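#!/usr/bin/env python
"""Screen the external set through the applicability domain.

Loads the finalized model and the cross-split similarity calibration,
computes each external compound's max Tanimoto to the training set,
classifies it into the high/low-similarity group (strict cutoff), and
flags in-domain predicted inhibitors as screening candidates.  Also
profiles descriptor ranges of the two groups.  Writes
results/screening.csv and results/descriptor_ranges.json.
"""
import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
import bcrpqsar as bq  # noqa: E402
from bcrpqsar import io  # noqa: E402

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    target = pd.read_csv(RESULTS / "target.csv")
    train_smiles = list(target["smiles_std"])
    model = bq.load_model(RESULTS / "final_model.joblib")
    cal_raw = io.read_report(RESULTS / "ad_calibration.json")
    cal = bq.ADCalibration(
        per_split=cal_raw["per_split"],
        final_cutoff=cal_raw["final_cutoff"],
        mean_fpr=cal_raw["mean_fpr"],
        morgan_params=cal_raw["morgan_params"],
        fpr_target=cal_raw["fpr_target"],
        activity_threshold=cal_raw["activity_threshold"])
    external = io.read_smiles_list(RESULTS / "external_screen.smi")
    train_fps = [bq.morgan_fingerprint(s, **cal.morgan_params)
                 for s in train_smiles]
    specs = bq.default_specs()

    def featurizer(smiles):
        return bq.build_feature_table(smiles, specs)

    verdicts, excluded = bq.screen_external(
        external, model, train_fps, cal, featurizer,
        training_smiles=train_smiles)
    pd.DataFrame([v.__dict__ for v in verdicts]).to_csv(
        RESULTS / "screening.csv", index=False)

    high = [v.smiles for v in verdicts if v.in_domain]
    low = [v.smiles for v in verdicts if not v.in_domain]
    profiles = {}
    for name, group in (("high_similarity", high),
                        ("low_similarity", low)):
        if group:
            profiles[name] = bq.descriptor_range_profile(group)
    (RESULTS / "descriptor_ranges.json").write_text(
        json.dumps(profiles, indent=1))

    n_cand = sum(v.candidate for v in verdicts)
    print(f"screened {len(verdicts)} external compounds "
          f"({len(excluded)} excluded as overlaps/parse failures)")
    print(f"  cutoff {cal.final_cutoff:.3f}: {len(high)} in-domain, "
          f"{len(low)} out-of-domain")
    print(f"  {n_cand} in-domain candidates with predicted pIC50 >= "
          f"{cal.activity_threshold}")
    for v in [v for v in verdicts if v.candidate][:10]:
        print(f"    {v.compound_id:8s} maxTan {v.max_tanimoto:.3f} "
              f"predicted {v.predicted_pic50:.2f}")


if __name__ == "__main__":
    main()
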