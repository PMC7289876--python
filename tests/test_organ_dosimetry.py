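"""Organ dose aggregation: weighting factors, means, contributions."""

import numpy as np
import pandas as pd
import pytest

from voxdose import organ_dosimetry as od


class TestWeightingTables:
    def test_icrp103_values(self):
        w = od.WeightingTables.icrp103()
        assert w.w_r == 1.0
        for organ in ("red_bone_marrow", "colon", "lung", "stomach", "breast"):
            assert w.w_t[organ] == 0.12
        assert w.w_t["gonads"] == 0.08
        for organ in ("bladder", "liver", "esophagus", "thyroid"):
            assert w.w_t[organ] == 0.04
        for organ in ("skin", "bone_surface", "salivary_glands", "brain"):
            assert w.w_t[organ] == 0.01
        remainders = [o for o, v in w.w_t.items() if v == 0.0092]
        assert len(remainders) == 13 and "thymus" not in w.w_t

    def test_sex_conditional_vocabulary(self):
        female = od.WeightingTables.icrp103("female")
        male = od.WeightingTables.icrp103("male")
        assert "prostate" not in female.w_t and "breast" in female.w_t
        assert "uterus" not in male.w_t and "breast" not in male.w_t
        assert len(female.w_t) == 26 and len(male.w_t) == 25

    def test_photon_w_r_fixed(self):
        with pytest.raises(ValueError):
            od.WeightingTables(w_r=2.0)


def _toy_grid():
    rng = np.random.default_rng(0)
    dose = rng.uniform(0.0, 20.0, size=(4, 4, 4))
    labels = np.zeros((4, 4, 4), dtype=np.uint8)
    mask = np.zeros(64, dtype=bool)
    mask[rng.choice(64, size=7, replace=False)] = True
    labels.ravel()[mask] = 3
    return dose, labels


class TestOrganMean:
    def test_matches_brute_force_sum_over_count(self):
        dose, labels = _toy_grid()
        expected = 0.0
        n = 0
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    if labels[i, j, k] == 3:
                        expected += dose[i, j, k]
                        n += 1
        assert od.organ_mean_dose(dose, labels, 3) == pytest.approx(expected / n)

    def test_uniform_dose_returns_that_dose(self):
        _, labels = _toy_grid()
        dose = np.full((4, 4, 4), 7.25)
        assert od.organ_mean_dose(dose, labels, 3) == pytest.approx(7.25)

    def test_absent_organ_is_an_error_not_zero(self):
        dose, labels = _toy_grid()
        with pytest.raises(od.OrganMissingError):
            od.organ_mean_dose(dose, labels, 9)
        with pytest.raises(od.OrganMissingError):
            od.organ_mean_dose(dose, labels, "spleen", label_map={"liver": 3})

    def test_shape_mismatch_rejected(self):
        dose, labels = _toy_grid()
        with pytest.raises(ValueError):
            od.organ_mean_dose(dose[:2], labels, 3)

    def test_naive_loop_equivalence_on_random_grid(self):
        rng = np.random.default_rng(1)
        dose = rng.exponential(5.0, size=(16, 16, 16))
        labels = rng.integers(0, 6, size=(16, 16, 16)).astype(np.uint8)
        for lab in range(1, 6):
            naive = dose[labels == lab].sum() / (labels == lab).sum()
            assert od.organ_mean_dose(dose, labels, lab) == naive


class TestDoseChain:
    def test_equivalent_dose_identity_for_photons(self):
        assert od.equivalent_dose(13.4) == 13.4
        assert od.equivalent_dose(0.0) == 0.0
        with pytest.raises(ValueError):
            od.equivalent_dose(-1.0)

    def test_effective_dose_examples(self):
        w = od.WeightingTables.icrp103()
        # thyroid: W_T = 0.04, 21.2 mSv equivalent
        assert od.effective_organ_dose(21.2, "thyroid", w) == pytest.approx(0.848)
        # lung: W_T = 0.12
        assert od.effective_organ_dose(13.4, "lung", w) == pytest.approx(1.608)
        assert od.effective_organ_dose(0.0, "brain", w) == 0.0
        with pytest.raises(KeyError):
            od.effective_organ_dose(5.0, "thymus", w)


def _random_table(seed=0, sex="female"):
    rng = np.random.default_rng(seed)
    w = od.WeightingTables.icrp103(sex)
    organs = list(w.w_t)
    absorbed = rng.uniform(5.0, 25.0, len(organs))
    df = pd.DataFrame(
        {
            "absorbed_mGy": absorbed,
            "equivalent_mSv": absorbed,
            "effective_mSv": [a * w.w_t[o] for a, o in zip(absorbed, organs)],
        },
        index=organs,
    )
    table = od.OrganDoseTable(data=df, ed_mc=float(df["effective_mSv"].sum()))
    df["contribution"] = od.organ_contribution(table)
    return table


class TestTotalsAndContributions:
    def test_total_is_exact_sum_and_order_invariant(self):
        t = _random_table()
        assert od.total_effective_dose(t) == pytest.approx(
            sum(t.data["effective_mSv"]), abs=1e-12
        )
        shuffled = od.OrganDoseTable(
            data=t.data.sample(frac=1.0, random_state=3), ed_mc=t.ed_mc
        )
        assert od.total_effective_dose(shuffled) == pytest.approx(
            od.total_effective_dose(t), abs=1e-12
        )

    def test_single_organ_total_and_contribution(self):
        df = pd.DataFrame(
            {"absorbed_mGy": [10.0], "equivalent_mSv": [10.0], "effective_mSv": [1.2]},
            index=["lung"],
        )
        t = od.OrganDoseTable(data=df, ed_mc=1.2)
        assert od.total_effective_dose(t) == 1.2
        assert od.organ_contribution(t).iloc[0] == pytest.approx(1.0)

    def test_contributions_match_elementwise_division(self):
        t = _random_table(seed=5)
        c = od.organ_contribution(t)
        ed = od.total_effective_dose(t)
        for organ in t.organs:
            assert c[organ] == pytest.approx(t.data.loc[organ, "effective_mSv"] / ed)
        assert c.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_total_is_an_error(self):
        df = pd.DataFrame(
            {"absorbed_mGy": [0.0], "equivalent_mSv": [0.0], "effective_mSv": [0.0]},
            index=["lung"],
        )
        with pytest.raises(ValueError):
            od.organ_contribution(od.OrganDoseTable(data=df, ed_mc=0.0))

    def test_empty_table_rejected(self):
        t = od.OrganDoseTable(data=pd.DataFrame(columns=["effective_mSv"]), ed_mc=0.0)
        with pytest.raises(ValueError):
            od.total_effective_dose(t)


class TestBuildTable:
    def _label_grid(self, sex):
        w = od.WeightingTables.icrp103(sex)
        organs = list(w.w_t)
        label_map = {o: i + 1 for i, o in enumerate(organs)}
        n = len(organs)
        labels = np.zeros((n, 2, 2), dtype=np.uint8)
        for i, o in enumerate(organs):
            labels[i] = label_map[o]
        return labels, label_map

    def test_build_and_linearity(self):
        labels, label_map = self._label_grid("male")
        rng = np.random.default_rng(2)
        dose = rng.uniform(1.0, 10.0, labels.shape)
        t1 = od.build_organ_dose_table(dose, labels, label_map, "male")
        t3 = od.build_organ_dose_table(3.0 * dose, labels, label_map, "male")
        assert t3.ed_mc == pytest.approx(3.0 * t1.ed_mc)
        assert np.allclose(t3.data["contribution"], t1.data["contribution"])
        assert t1.data["contribution"].sum() == pytest.approx(1.0, abs=1e-9)
        # equivalent = absorbed for photons, effective = equivalent * w_t
        w = od.WeightingTables.icrp103("male")
        for organ in t1.organs:
            row = t1.data.loc[organ]
            assert row["equivalent_mSv"] == row["absorbed_mGy"]
            assert row["effective_mSv"] == pytest.approx(row["equivalent_mSv"] * w.w_t[organ])

    def test_missing_organs_flagged_not_imputed(self):
        labels, label_map = self._label_grid("male")
        labels[labels == label_map["spleen"]] = 0
        dose = np.ones(labels.shape)
        t = od.build_organ_dose_table(dose, labels, label_map, "male")
        assert t.missing == ("spleen",)
        assert "spleen" not in t.organs
        full = od.build_organ_dose_table(np.ones(labels.shape),
                                         *(self._label_grid("male"))[:2], "male")
        # removing an organ lowers the whole-body sum (nothing is imputed)
        assert t.ed_mc < full.ed_mc

    def test_sex_restriction(self):
        labels_f, map_f = self._label_grid("female")
        t = od.build_organ_dose_table(np.ones(labels_f.shape), labels_f, map_f, "female")
        assert "prostate" not in t.organs and "breast" in t.organs
        labels_m, map_m = self._label_grid("male")
        t = od.build_organ_dose_table(np.ones(labels_m.shape), labels_m, map_m, "male")
        assert "uterus" not in t.organs and "breast" not in t.organs


class TestReportIO:
    def test_csv_and_json_output(self, tmp_path):
        t = _random_table(seed=7, sex="male")
        csv = tmp_path / "organs.csv"
        od.write_table_csv(t, csv)
        back = pd.read_csv(csv, index_col="organ")
        assert set(back.columns) == {
            "absorbed_mGy", "equivalent_mSv", "effective_mSv", "contribution",
        }
        # report rounding: 1 dp doses, 3 dp contributions
        assert np.allclose(back["absorbed_mGy"] * 10, np.round(back["absorbed_mGy"] * 10))
        js = tmp_path / "organs.json"
        od.write_table_json(t, js)
        import json

        payload = json.loads(js.read_text())
        assert payload["ed_mc_mSv"] == pytest.approx(t.ed_mc)
        assert payload["organs"]["lung"]["effective_mSv"] == pytest.approx(
            t.data.loc["lung", "effective_mSv"]
        )
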