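import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import callusopt as co
from callusopt.design import (
    RAW_COLUMNS,
    SchemaError,
    decode_features,
    encode_condition,
    full_grid,
    load_raw_table,
    save_raw_table,
    summarize_conditions,
)


class TestTreatments:
    def test_table_has_eight_validated_treatments(self):
        assert sorted(co.TREATMENTS) == list(range(1, 9))
        assert co.TREATMENTS[8].concentrations() == (0, 0, 0, 0)

    def test_concentration_multiset_matches_published_combinations(self):
        expected = {
            1: (0.0, 0.3, 0.0, 2.0),
            2: (0.2, 0.0, 0.0, 0.0),
            3: (1.0, 0.0, 0.0, 0.0),
            4: (0.2, 0.2, 0.0, 0.0),
            5: (0.2, 0.0, 0.2, 0.0),
            6: (0.5, 0.5, 0.0, 0.0),
            7: (1.0, 0.0, 1.0, 0.0),
            8: (0.0, 0.0, 0.0, 0.0),
        }
        assert {k: t.concentrations() for k, t in co.TREATMENTS.items()} == expected


class TestEncoding:
    @pytest.mark.parametrize(
        "condition, expected",
        [
            ((6, "shoot", 1, 8), (0.5, 0.5, 0, 0, 1, 8, 0, 0, 0, 1)),
            ((8, "leaf", 8, 25), (0, 0, 0, 0, 8, 25, 1, 0, 0, 0)),
            ((1, "root", 4, 25), (0, 0.3, 0, 2, 4, 25, 0, 0, 1, 0)),
        ],
    )
    def test_known_conditions_encode_to_expected_vectors(self, condition, expected):
        x = encode_condition(co.CultureCondition(*condition))
        assert x.tolist() == pytest.approx(list(expected))

    def test_encode_decode_is_a_bijection_on_the_grid(self):
        grid = full_grid()
        assert len(grid) == 192
        assert len(set(grid)) == 192
        for c in grid:
            assert decode_features(encode_condition(c)) == c

    def test_invalid_condition_fields_raise_schema_errors(self):
        with pytest.raises(SchemaError):
            co.CultureCondition(9, "leaf", 1, 8)
        with pytest.raises(SchemaError):
            co.CultureCondition(1, "stem", 1, 8)
        with pytest.raises(SchemaError):
            co.CultureCondition(1, "leaf", 2, 8)
        with pytest.raises(SchemaError):
            decode_features(np.zeros(9))


class TestSpeed:
    @pytest.mark.parametrize(
        "day, diam, mode, expected",
        [
            (8, 4.0, "as_written", 2.0),
            (25, 0.0, "as_written", 0.0),
            (8, 4.0, "inverted", 0.5),
            (25, 0.0, "inverted", 0.0),
        ],
    )
    def test_speed_formula(self, day, diam, mode, expected):
        assert co.compute_speed(day, diam, mode) == expected

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            co.compute_speed(0, 1.0)
        with pytest.raises(ValueError):
            co.compute_speed(8, -1.0)
        with pytest.raises(ValueError):
            co.compute_speed(8, 1.0, mode="sideways")


class TestRawTable:
    def _tiny_csv(self):
        return io.StringIO(
            "treatment_id,explant,ms_level,sampling_day,subset_id,replicate_id,callus,diameter_mm\n"
            "6,shoot,1,8,1,1,1,3.0\n"
            "6,shoot,1,8,1,2,1,3.0\n"
        )

    def test_well_formed_file_round_trips(self):
        df = load_raw_table(self._tiny_csv())
        assert len(df) == 2
        assert df["callus"].tolist() == [1, 1]

    def test_unknown_explant_names_row_and_column(self):
        bad = self._tiny_csv().getvalue().replace("shoot", "stem")
        with pytest.raises(SchemaError, match="explant"):
            load_raw_table(io.StringIO(bad))

    def test_no_callus_with_positive_diameter_rejected(self):
        bad = self._tiny_csv().getvalue().replace("1,2,1,3.0", "1,2,0,3.0")
        with pytest.raises(SchemaError, match="diameter"):
            load_raw_table(io.StringIO(bad))

    def test_full_synthetic_export_round_trips(self, default_raw, tmp_path):
        path = tmp_path / "raw.csv"
        save_raw_table(default_raw, path)
        back = load_raw_table(path)
        pd.testing.assert_frame_equal(back, default_raw[RAW_COLUMNS])

    def test_column_mapping_adapter(self):
        csv = io.StringIO("trt,explant,ms_level,sampling_day,subset_id,replicate_id,callus,diameter_mm\n6,shoot,1,8,1,1,1,3.0\n")
        df = load_raw_table(csv, schema={"treatment_id": "trt"})
        assert df["treatment_id"].tolist() == [6]


def _records(n, n_callus, treatment=6, explant="shoot", ms=1, day=8, diam=3.0):
    return pd.DataFrame(
        {
            "treatment_id": treatment,
            "explant": explant,
            "ms_level": ms,
            "sampling_day": day,
            "subset_id": [1 + i % 3 for i in range(n)],
            "replicate_id": range(1, n + 1),
            "callus": [1] * n_callus + [0] * (n - n_callus),
            "diameter_mm": [diam] * n_callus + [0.0] * (n - n_callus),
        }
    )


class TestSummaries:
    @pytest.mark.parametrize(
        "n_callus, expected_pct", [(24, 100.0), (0, 0.0), (6, 25.0)]
    )
    def test_induction_percentage(self, n_callus, expected_pct):
        s = summarize_conditions(_records(24, n_callus))
        assert len(s) == 1
        assert s["induction_pct"].iloc[0] == expected_pct
        if n_callus == 0:
            assert s["speed"].iloc[0] == 0.0
            assert s["mean_diameter_mm"].iloc[0] == 0.0

    def test_mean_diameter_averages_callused_pieces_only(self):
        s = summarize_conditions(_records(24, 6, diam=4.0))
        assert s["mean_diameter_mm"].iloc[0] == 4.0
        assert s["speed"].iloc[0] == 2.0  # day 8 / 4 mm

    def test_empty_input_yields_empty_output(self):
        s = summarize_conditions(pd.DataFrame(columns=RAW_COLUMNS))
        assert len(s) == 0

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_permutation_invariance(self, seed):
        df = _records(24, 6).sample(frac=1.0, random_state=seed).reset_index(drop=True)
        s = summarize_conditions(df)
        assert s["induction_pct"].iloc[0] == 25.0

    def test_additive_over_disjoint_condition_sets(self, default_raw):
        half_a = default_raw[default_raw["ms_level"] == 1]
        half_b = default_raw[default_raw["ms_level"] != 1]
        merged = pd.concat(
            [summarize_conditions(half_a), summarize_conditions(half_b)],
            ignore_index=True,
        ).sort_values(
            ["treatment_id", "explant", "ms_level", "sampling_day"]
        ).reset_index(drop=True)
        full = summarize_conditions(default_raw).sort_values(
            ["treatment_id", "explant", "ms_level", "sampling_day"]
        ).reset_index(drop=True)
        pd.testing.assert_frame_equal(merged, full)
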