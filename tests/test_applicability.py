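"""Applicability-domain calibration: TP/FP partition, cutoff sweep
(with brute-force oracle), cross-split averaging, external screening,
and descriptor range profiling."""
import numpy as np
import pytest

import bcrpqsar as bq
from bcrpqsar.applicability import cutoff_sweep, tp_fp_partition
from bcrpqsar.records import ValidationError


class TestPartition:
    @pytest.mark.parametrize("obs,pred,label", [
        (5.5, 5.5, "TP"),
        (4.5, 5.5, "FP"),
        (5.5, 4.5, "other"),   # FN: predicted negative, excluded
        (4.5, 4.5, "other"),   # TN
    ])
    def test_cases(self, obs, pred, label):
        assert tp_fp_partition([obs], [pred], 5.0) == [label]


def _brute_force_sweep(mt, labels, lo=0.4, hi=0.8, step=0.01,
                       target=0.3):
    grid = np.round(np.arange(lo, hi + step / 2, step), 10)
    fpr = None
    for c in grid:
        keep = mt > c
        tp = sum(1 for m, l in zip(keep, labels) if m and l == "TP")
        fp = sum(1 for m, l in zip(keep, labels) if m and l == "FP")
        fpr = 0.0 if tp + fp == 0 else fp / (tp + fp)
        if fpr < target:
            return float(c), fpr, True
    return float(grid[-1]), fpr, False


class TestCutoffSweep:
    def test_fp_free_region_attains_target_at_grid_start(self):
        # the single FP sits below every TP, so FPR crosses the target
        # immediately once it is excluded
        c, f, a = cutoff_sweep([0.5, 0.6, 0.7, 0.45],
                               ["TP", "TP", "TP", "FP"],
                               fpr_target=0.3)
        assert a and f < 0.3

    def test_constructed_separation_matches_oracle(self):
        """FPs concentrated at low similarity: the first crossing is in
        the gap, and equals an independent brute-force scan."""
        rng = np.random.default_rng(0)
        mt = np.concatenate([rng.uniform(0.40, 0.50, 40),   # FPs
                             rng.uniform(0.60, 0.95, 30)])  # TPs
        labels = ["FP"] * 40 + ["TP"] * 30
        got = cutoff_sweep(mt, labels)
        expect = _brute_force_sweep(mt, labels)
        assert got == expect
        # initial FPR 40/70 > 0.3; with FPs below 0.50 the crossing
        # happens once enough of them are excluded, never after the gap
        assert 0.40 <= got[0] <= 0.61 and got[1] < 0.3

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(1)
        for trial in range(20):
            n = int(rng.integers(5, 40))
            mt = rng.random(n) * 0.6 + 0.3
            labels = ["TP" if rng.random() > 0.4 else "FP"
                      for _ in range(n)]
            if "TP" not in labels or "FP" not in labels:
                continue
            assert cutoff_sweep(mt, labels) == \
                _brute_force_sweep(mt, labels)

    def test_vacuous_target_returns_grid_start(self):
        c, f, a = cutoff_sweep([0.5, 0.6], ["TP", "FP"], fpr_target=1.0)
        assert c == 0.4 and a

    def test_unattainable_target_flags_and_returns_grid_end(self):
        # FPs at high similarity: FPR stays high until retention dies
        c, f, a = cutoff_sweep([0.9, 0.95], ["TP", "FP"],
                               fpr_target=0.0)
        assert c == 0.8 and not a

    def test_missing_class_is_an_error(self):
        with pytest.raises(ValidationError):
            cutoff_sweep([0.5], ["TP"])

    def test_fpr_nonincreasing_on_separated_fixture(self):
        mt = np.concatenate([np.linspace(0.4, 0.55, 10),
                             np.linspace(0.6, 0.9, 15)])
        labels = ["FP"] * 10 + ["TP"] * 15
        grid = np.round(np.arange(0.4, 0.801, 0.01), 10)
        last = 1.1
        for c in grid:
            keep = mt > c
            tp = int(keep[10:].sum())
            fp = int(keep[:10].sum())
            fpr = 0.0 if tp + fp == 0 else fp / (tp + fp)
            assert fpr <= last + 1e-12
            last = fpr


class TestCalibrate:
    def _split(self, sid, cutpoint=0.55):
        rng = np.random.default_rng(sid)
        mt = np.concatenate([rng.uniform(0.4, cutpoint, 10),
                             rng.uniform(0.65, 0.9, 20)])
        obs = np.concatenate([np.full(10, 4.5), np.full(20, 5.5)])
        pred = np.full(30, 5.5)       # everything called positive
        return {"split_id": sid, "observed": obs, "predicted": pred,
                "max_tanimoto": mt}

    def test_identical_splits_average_to_single_cutoff(self):
        sp = self._split(0)
        cal = bq.calibrate([sp, sp, sp])
        assert cal.final_cutoff == cal.per_split[0]["cutoff"]

    def test_mean_of_two_cutoffs(self):
        cal = bq.calibrate([self._split(1, 0.5), self._split(2, 0.6)])
        cuts = [d["cutoff"] for d in cal.per_split]
        assert cal.final_cutoff == pytest.approx(np.mean(cuts))

    def test_split_without_both_classes_is_skipped(self):
        good = self._split(3)
        bad = {"split_id": 9, "observed": np.full(5, 5.5),
               "predicted": np.full(5, 5.5),
               "max_tanimoto": np.full(5, 0.7)}
        cal = bq.calibrate([good, bad])
        assert len(cal.per_split) == 1

    def test_zero_usable_splits_is_an_error(self):
        bad = {"split_id": 0, "observed": np.full(5, 5.5),
               "predicted": np.full(5, 5.5),
               "max_tanimoto": np.full(5, 0.7)}
        with pytest.raises(ValidationError):
            bq.calibrate([bad])


class TestScreening:
    @pytest.fixture(scope="class")
    def setup(self, tiny_synth=None):
        import bcrpqsar as bq
        ds = bq.generate_dataset(bq.SyntheticSpec(n=80, seed=21))
        specs = [bq.counts_spec(), bq.funcgroups_spec()]
        table = bq.build_feature_table(ds.compounds, specs)
        kept, _ = bq.variance_filter(table)
        model = bq.fit("RF", {"n_estimators": 40, "max_depth": 5},
                       kept, ds.pic50, seed=0)
        train_fps = [bq.morgan_fingerprint(s) for s in ds.compounds]
        cal = bq.ADCalibration(per_split=[], final_cutoff=0.5,
                               mean_fpr=0.2)

        def featurizer(smiles):
            return bq.build_feature_table(smiles, specs)

        return ds, model, train_fps, cal, featurizer

    def test_training_overlap_excluded(self, setup):
        ds, model, fps, cal, feat = setup
        ext = [(ds.compounds[0], "dup"), ("CCOC(=O)c1ccncc1", "new")]
        verdicts, excluded = bq.screen_external(ext, model, fps, cal,
                                                feat,
                                                training_smiles=ds.compounds)
        assert any("dup" in e for e in excluded)
        assert [v.compound_id for v in verdicts] == ["new"]

    def test_boundary_similarity_is_low_group(self, setup):
        ds, model, fps, cal, feat = setup
        ext = [(ds.compounds[0], "same")]   # identical: max tan 1.0
        verdicts, _ = bq.screen_external(ext, model, fps, cal, feat)
        assert verdicts[0].max_tanimoto == 1.0 and verdicts[0].in_domain
        cal_eq = bq.ADCalibration(per_split=[], final_cutoff=1.0,
                                  mean_fpr=0.0)
        verdicts, _ = bq.screen_external(ext, model, fps, cal_eq, feat)
        assert not verdicts[0].in_domain     # strict inequality

    def test_empty_external_list(self, setup):
        _, model, fps, cal, feat = setup
        verdicts, excluded = bq.screen_external([], model, fps, cal,
                                                feat)
        assert verdicts == [] and excluded == []

    def test_order_invariance(self, setup):
        ds, model, fps, cal, feat = setup
        ext = [("CCOC(=O)c1ccncc1", "a"), ("Clc1ccc(Cl)cc1", "b"),
               ("O=[N+]([O-])c1ccccc1C", "c")]
        v1, _ = bq.screen_external(ext, model, fps, cal, feat)
        v2, _ = bq.screen_external(ext[::-1], model, fps, cal, feat)
        assert v1 == v2

    def test_candidate_flag_logic(self, setup):
        ds, model, fps, cal, feat = setup
        ext = [(s, f"e{i}") for i, s in enumerate(ds.compounds[1:6])]
        verdicts, _ = bq.screen_external(ext, model, fps, cal, feat)
        for v in verdicts:
            assert v.candidate == (v.in_domain and
                                   v.predicted_pic50 >= 5.0)
        # sorted by predicted pIC50 descending
        preds = [v.predicted_pic50 for v in verdicts]
        assert preds == sorted(preds, reverse=True)


class TestDescriptorProfile:
    def test_single_compound_min_equals_max(self):
        prof = bq.descriptor_range_profile(["CCO"])
        for stats in prof.values():
            assert stats["min"] == stats["max"]

    def test_alkane_group_has_zero_tpsa_range(self):
        prof = bq.descriptor_range_profile(["CCC", "CCCC", "CCCCC"])
        assert prof["tpsa"]["min"] == prof["tpsa"]["max"] == 0.0

    def test_ranges_widen_monotonically_with_supersets(self):
        group = ["CCO", "c1ccccc1", "O=[N+]([O-])c1ccccc1",
                 "C1COCCN1c1ccncc1"]
        prev = bq.descriptor_range_profile(group[:1])
        for k in range(2, len(group) + 1):
            cur = bq.descriptor_range_profile(group[:k])
            for name in cur:
                assert cur[name]["min"] <= prev[name]["min"] + 1e-12
                assert cur[name]["max"] >= prev[name]["max"] - 1e-12
            prev = cur


class TestFprModes:
    def test_textbook_denominator_is_selectable_and_reported(self):
        rng = np.random.default_rng(7)
        mt = rng.random(60) * 0.5 + 0.4
        obs = np.where(rng.random(60) > 0.3, 5.5, 4.5)
        pred = np.where(rng.random(60) > 0.4, 5.5, 4.5)
        sp = {"split_id": 0, "observed": obs, "predicted": pred,
              "max_tanimoto": mt}
        cal = bq.calibrate([sp])
        rec = cal.per_split[0]
        assert {"fpr_positives_at_cutoff",
                "fpr_textbook_at_cutoff"} <= set(rec)
        # the sweep criterion follows the selected mode
        cal_tb = bq.calibrate([sp], fpr_mode="textbook")
        rec_tb = cal_tb.per_split[0]
        assert rec_tb["fpr_at_cutoff"] == pytest.approx(
            rec_tb["fpr_textbook_at_cutoff"])
        assert rec["fpr_at_cutoff"] == pytest.approx(
            rec["fpr_positives_at_cutoff"])
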