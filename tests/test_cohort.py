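"""Cohort schema, I/O, inclusion filtering and compound-score tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cogtypology.cohort import (COMPOUND_SCORE_NAMES, TIME_BASED_SCORES, CohortError,
                                CohortTable, SchemaError, ZeroVarianceError,
                                apply_inclusion, compound_scores, read_cohort,
                                standardize_and_orient, write_cohort)
from cogtypology.simulate import default_spec, generate

from conftest import make_cohort, make_participant


class TestReadWrite:
    def test_csv_round_trip_is_identity(self, tmp_path):
        table = make_cohort([make_participant(f"p{i}", mmse=27 + i % 4) for i in range(5)])
        path = tmp_path / "cohort.csv"
        write_cohort(table, path)
        assert read_cohort(path).equals(table)

    def test_tsv_dialect_round_trip(self, tmp_path):
        table = make_cohort([make_participant("a"), make_participant("b")])
        path = tmp_path / "cohort.tsv"
        write_cohort(table, path)
        assert read_cohort(path).equals(table)

    def test_synthetic_cohort_round_trip(self, tmp_path, default_cohort):
        table, _ = default_cohort
        path = tmp_path / "synthetic.csv"
        write_cohort(table, path)
        assert read_cohort(path).equals(table)

    def test_three_row_file_reads_three_participants(self, tmp_path):
        table = make_cohort([make_participant(f"p{i}") for i in range(3)])
        path = tmp_path / "three.csv"
        write_cohort(table, path)
        assert len(read_cohort(path)) == 3

    def test_duplicate_id_rejected_by_name(self):
        rows = [make_participant("dup"), make_participant("dup")]
        with pytest.raises(CohortError, match="dup"):
            make_cohort(rows)

    def test_unknown_column_is_schema_error(self, tmp_path):
        table = make_cohort([make_participant("a")])
        df = table.data.copy()
        df["extraneous"] = 1
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="extraneous"):
            read_cohort(path)

    def test_missing_cells_stay_missing(self, tmp_path):
        table = make_cohort([make_participant("a")])
        df = table.data.copy()
        df.loc[0, "delayed_recall"] = np.nan
        path = tmp_path / "gap.csv"
        df.to_csv(path, index=False)
        read_back = read_cohort(path)
        assert np.isnan(read_back.data.loc[0, "delayed_recall"])


class TestInclusion:
    def test_mmse_boundary_26_excluded(self):
        table = make_cohort([make_participant("ok"), make_participant("border", mmse=26)])
        included, log = apply_inclusion(table)
        assert included.ids == ["ok"]
        assert log[0]["id"] == "border" and "mmse" in log[0]["reason"]

    def test_mmse_27_hads_15_retained(self):
        table = make_cohort([
            make_participant("edge", mmse=27, hads_anxiety=15, hads_depression=15),
            make_participant("other"),
        ])
        included, _ = apply_inclusion(table)
        assert "edge" in included.ids

    def test_hads_16_excluded(self):
        table = make_cohort([make_participant("ok"), make_participant("anx", hads_anxiety=16)])
        included, log = apply_inclusion(table)
        assert included.ids == ["ok"]
        assert "HADS" in log[0]["reason"]

    def test_inclusive_flags_relax_boundaries(self):
        table = make_cohort([make_participant("b", mmse=26, hads_anxiety=16, hads_depression=16)])
        included, log = apply_inclusion(table, mmse_inclusive=True, hads_inclusive=True)
        assert included.ids == ["b"] and log == []

    def test_incomplete_battery_dropped_and_logged(self):
        rows = [make_participant("full"), make_participant("partial")]
        table = make_cohort(rows)
        table.data.loc[1, "recall_block_3"] = np.nan
        included, log = apply_inclusion(table)
        assert included.ids == ["full"]
        assert "did not complete" in log[0]["reason"]

    def test_cohort_of_158_with_three_failures_retains_155(self):
        """A 158-row cohort built to fail 3 screens leaves the canonical 155."""
        table, _ = generate(default_spec(seed=3))
        extra = [
            make_participant("x-mmse", mmse=26),
            make_participant("x-hads", hads_depression=16),
            make_participant("x-incomplete"),
        ]
        df = pd.concat([table.data, pd.DataFrame(extra)], ignore_index=True)
        df.loc[df["id"] == "x-incomplete", "tmt_b_seconds"] = np.nan
        big = CohortTable(df)
        assert len(big) == 158
        included, log = apply_inclusion(big)
        assert len(included) == 155
        assert len(log) == 3

    def test_idempotent(self, default_cohort):
        table, _ = default_cohort
        once, _ = apply_inclusion(table)
        twice, log = apply_inclusion(once)
        assert twice.equals(once) and log == []

    def test_empty_result_is_error(self):
        table = make_cohort([make_participant("a", mmse=20)])
        with pytest.raises(CohortError, match="excluded every participant"):
            apply_inclusion(table)


class TestCompoundScores:
    def test_definitional_values(self):
        row = make_participant(
            "p", fluency_s=20, fluency_f=16, fluency_professions=18, fluency_animals=26,
            digit_span_forward=8, digit_span_backward=4, tmt_a_seconds=30.0,
            tmt_b_seconds=60.0, recall_block_1=5, recall_block_2=7, recall_block_3=8,
            recall_block_4=9, recall_block_5=10, delayed_recall=9, rt_median_ms=310.0)
        mat = compound_scores(make_cohort([row]))
        expected = {
            "phonemic_fluency": 18.0,
            "semantic_fluency": 22.0,
            "working_memory_span": 6.0,
            "tmt_a": 30.0,
            "tmt_b_over_a": 2.0,
            "immediate_recall": 39.0,
            "delayed_recall": 9.0,
            "response_speed": 310.0,
        }
        for name, value in expected.items():
            assert mat.loc["p", name] == pytest.approx(value)

    def test_recognition_never_enters(self):
        a = make_cohort([make_participant("p", recognition=15)])
        b = make_cohort([make_participant("p", recognition=0)])
        pd.testing.assert_frame_equal(compound_scores(a), compound_scores(b))

    def test_zero_tmt_a_is_error(self):
        table = make_cohort([make_participant("p", tmt_a_seconds=0.0)])
        with pytest.raises(CohortError, match="ratio undefined"):
            compound_scores(table)

    def test_permutation_equivariance(self, default_cohort):
        table, _ = default_cohort
        mat = compound_scores(table)
        perm = np.random.default_rng(1).permutation(len(table))
        shuffled = CohortTable(table.data.iloc[perm].reset_index(drop=True))
        pd.testing.assert_frame_equal(compound_scores(shuffled), mat.iloc[perm])


class TestStandardizeAndOrient:
    def test_arithmetic_sequence_z_scores(self):
        rows = []
        for i, scale in enumerate((1, 2, 3)):
            rows.append(make_participant(
                f"p{i}", fluency_s=10 * scale, fluency_f=10 * scale,
                fluency_professions=10 * scale, fluency_animals=10 * scale,
                digit_span_forward=2 * scale, digit_span_backward=2 * scale,
                tmt_a_seconds=10.0 * scale, tmt_b_seconds=30.0 * scale * scale,
                recall_block_1=scale, recall_block_2=scale, recall_block_3=scale,
                recall_block_4=scale, recall_block_5=scale, delayed_recall=scale,
                rt_median_ms=100.0 * scale))
        cm = standardize_and_orient(compound_scores(make_cohort(rows)))
        col = cm.to_frame()["phonemic_fluency"].to_numpy()
        np.testing.assert_allclose(col, [-1.0, 0.0, 1.0], atol=1e-12)

    def test_columns_standardized_before_orientation(self, default_cohort):
        table, _ = default_cohort
        raw = compound_scores(table)
        cm = standardize_and_orient(raw, orient=False)
        assert np.all(np.abs(cm.scores.mean(axis=0)) < 1e-9)
        assert np.all(np.abs(cm.scores.std(axis=0, ddof=1) - 1) < 1e-9)

    def test_orientation_flips_only_time_scores(self, default_cohort):
        table, _ = default_cohort
        raw = compound_scores(table)
        plain = standardize_and_orient(raw, orient=False).to_frame()
        oriented = standardize_and_orient(raw, orient=True).to_frame()
        for name in COMPOUND_SCORE_NAMES:
            sign = -1.0 if name in TIME_BASED_SCORES else 1.0
            np.testing.assert_allclose(oriented[name], sign * plain[name], atol=1e-12)

    def test_orientation_preserves_magnitudes(self, default_cohort):
        table, _ = default_cohort
        raw = compound_scores(table)
        plain = standardize_and_orient(raw, orient=False)
        oriented = standardize_and_orient(raw, orient=True)
        np.testing.assert_allclose(np.abs(plain.scores), np.abs(oriented.scores), atol=1e-12)

    def test_constant_column_raises_naming_score(self):
        rows = [make_participant(f"p{i}", mmse=28 + i) for i in range(3)]
        table = make_cohort(rows)
        raw = compound_scores(table)  # every participant identical
        with pytest.raises(ZeroVarianceError, match="phonemic_fluency"):
            standardize_and_orient(raw)

    @given(st.integers(0, 2**31 - 1))
    def test_z_columns_always_centered_unit_sd(self, seed):
        rng = np.random.default_rng(seed)
        raw = pd.DataFrame(rng.normal(50, 10, size=(6, 8)),
                           columns=list(COMPOUND_SCORE_NAMES),
                           index=[f"p{i}" for i in range(6)])
        cm = standardize_and_orient(raw)
        assert np.all(np.abs(cm.scores.mean(axis=0)) < 1e-9)
        assert np.all(np.abs(cm.scores.std(axis=0, ddof=1) - 1) < 1e-9)
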