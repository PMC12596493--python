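import json

import numpy as np
import pytest
from hypothesis import given, strategies as st

from multimorbnet.ingest import read_records, stratify
from multimorbnet.netbuild import pair_contingency
from multimorbnet.simulate import (
    GroundTruth,
    PlantedPair,
    SyntheticConfig,
    decomposition_config,
    generate_records,
    joint_from_or,
    make_catalog,
    recovery_config,
    study_config,
    write_fixture,
)


class TestJointFromOr:
    def test_independence(self):
        assert joint_from_or(0.5, 0.5, 1.0) == pytest.approx((0.25, 0.25, 0.25, 0.25))

    def test_large_psi_approaches_perfect_coupling(self):
        p11, p10, p01, _ = joint_from_or(0.3, 0.3, 1e9)
        assert p11 == pytest.approx(0.3, abs=1e-4)
        assert p10 == pytest.approx(0.0, abs=1e-4)

    def test_cells_reproduce_the_target_odds_ratio(self):
        p11, p10, p01, p00 = joint_from_or(0.1, 0.1, 4.0)
        assert (p11 * p00) / (p10 * p01) == pytest.approx(4.0, abs=1e-10)
        assert p11 + p10 + p01 + p00 == pytest.approx(1.0, abs=1e-12)

    @given(
        st.floats(0.01, 0.9),
        st.floats(0.01, 0.9),
        st.floats(0.05, 50.0),
    )
    def test_marginals_and_or_always_recovered(self, p_x, p_y, psi):
        p11, p10, p01, p00 = joint_from_or(p_x, p_y, psi)
        assert p11 + p10 == pytest.approx(p_x, abs=1e-9)
        assert p11 + p01 == pytest.approx(p_y, abs=1e-9)
        if min(p11, p10, p01, p00) > 1e-9:
            assert (p11 * p00) / (p10 * p01) == pytest.approx(psi, rel=1e-6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            joint_from_or(0.0, 0.5, 2.0)
        with pytest.raises(ValueError):
            joint_from_or(0.5, 0.5, -1.0)


class TestConfigValidation:
    def test_overlapping_planted_pairs_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            SyntheticConfig(
                seed=1,
                strata=(("male", (40, 59), 100),),
                catalog={"A00": 0.1, "B00": 0.1, "C00": 0.1},
                planted_pairs=(
                    PlantedPair("A00", "B00", 2.0),
                    PlantedPair("B00", "C00", 2.0),
                ),
            )

    def test_planted_disease_missing_from_catalog_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            SyntheticConfig(
                seed=1,
                strata=(("male", (40, 59), 100),),
                catalog={"A00": 0.1},
                planted_pairs=(PlantedPair("A00", "B00", 2.0),),
            )

    def test_marginals_must_be_probabilities(self):
        with pytest.raises(ValueError):
            SyntheticConfig(seed=1, strata=(), catalog={"A00": 1.5})


def test_catalog_spans_chapters_1_to_14():
    from multimorbnet.icd10 import chapter_of

    cat = make_catalog(100, seed=0)
    chapters = {chapter_of(c) for c in cat}
    assert chapters == set(range(1, 15))
    assert all(0 < m < 1 for m in cat.values())


class TestGenerateRecords:
    def test_same_seed_reproduces_cohort_exactly(self):
        cfg = study_config(seed=5, scale=0.01)
        r1, t1 = generate_records(cfg)
        r2, t2 = generate_records(cfg)
        assert r1 == r2
        assert t1.to_json() == t2.to_json()

    def test_no_empty_records_and_ages_in_band(self):
        cfg = study_config(seed=5, scale=0.01)
        records, _ = generate_records(cfg)
        assert all(r.codes for r in records)
        for r in records:
            assert 40 <= r.age_years <= 59

    def test_sex_scoped_pairs_planted_only_in_their_sex(self):
        cfg = decomposition_config(seed=3, n_per_sex=500)
        _, truth = generate_records(cfg)
        male = truth.planted["male_40-59"]
        female = truth.planted["female_40-59"]
        male_only = {k for k, v in male.items() if v["scope"] == "male_only"}
        assert male_only and not (male_only & set(female))
        shared = {k for k, v in male.items() if v["scope"] == "both_sexes"}
        assert shared <= set(female)

    def test_null_pairs_have_empirical_or_near_one(self):
        """psi = 1 everywhere: the empirical OR stays within binomial
        sampling error of 1 at n = 20 000."""
        # enough background diseases that empty-row redraws are rare and the
        # non-empty conditioning cannot distort pair odds
        catalog = {"A00": 0.10, "B00": 0.10, "C00": 0.08, "D50": 0.08}
        catalog.update({f"I{j:02d}": 0.08 for j in range(20)})
        cfg = SyntheticConfig(
            seed=11,
            strata=(("male", (40, 59), 20_000),),
            catalog=catalog,
            planted_pairs=(
                PlantedPair("A00", "B00", 1.0),
                PlantedPair("C00", "D50", 1.0),
            ),
        )
        records, _ = generate_records(cfg)
        stratum = stratify(records, "all")["all_40-59"]
        for x, y in (("A00", "B00"), ("C00", "D50")):
            t = pair_contingency(stratum, x, y)
            oddsr = (t.a * t.d) / (t.b * t.c)
            assert 0.8 <= oddsr <= 1.25

    def test_planted_or_moves_the_cooccurrence(self):
        catalog = {"A00": 0.10, "B00": 0.10}
        catalog.update({f"I{j:02d}": 0.08 for j in range(20)})
        cfg = SyntheticConfig(
            seed=11,
            strata=(("male", (40, 59), 20_000),),
            catalog=catalog,
            planted_pairs=(PlantedPair("A00", "B00", 6.0),),
        )
        records, truth = generate_records(cfg)
        stratum = stratify(records, "all")["all_40-59"]
        t = pair_contingency(stratum, "A00", "B00")
        oddsr = (t.a * t.d) / (t.b * t.c)
        assert 4.5 <= oddsr <= 8.0
        key = GroundTruth.pair_key("A00", "B00")
        assert truth.planted["male_40-59"][key]["target_or"] == 6.0


class TestWriteFixture:
    def test_round_trip_reproduces_cohort(self, tmp_path):
        cfg = study_config(seed=7, scale=0.005)
        records, truth = generate_records(cfg)
        cohort_path, truth_path = write_fixture(records, truth, tmp_path)
        back, report = read_records(cohort_path)
        assert back == records and not report.row_errors
        manifest = json.loads(truth_path.read_text())
        n_pairs = sum(len(v) for v in manifest["planted"].values())
        assert n_pairs > 0

    def test_manifest_lists_every_planted_pair_once_per_stratum(self, tmp_path):
        cfg = recovery_config(seed=2, n_records=300)
        records, truth = generate_records(cfg)
        _, truth_path = write_fixture(records, truth, tmp_path)
        manifest = json.loads(truth_path.read_text())
        planted = manifest["planted"]["male_40-59"]
        assert len(planted) == len(cfg.planted_pairs)

    def test_empty_strata_yield_valid_empty_files(self, tmp_path):
        cfg = SyntheticConfig(seed=1, strata=(), catalog={"A00": 0.1})
        records, truth = generate_records(cfg)
        cohort_path, _ = write_fixture(records, truth, tmp_path)
        back, _ = read_records(cohort_path)
        assert back == []
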