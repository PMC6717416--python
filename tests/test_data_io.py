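"""Concentration table I/O, unit normalization, censoring policy and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dermrisk import reference
from dermrisk.data_io import (
    SchemaError, ValidationError, apply_lod_policy, from_mg_per_kg,
    read_concentration_table, read_rfd_table, summarize_concentrations,
    to_mg_per_kg, write_concentration_csv,
)
from tests.conftest import make_table


def _write_csv(path, rows):
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


CSV_ROW = {"sample_id": "s1", "brand": "b1", "country": "IR", "color": "black",
           "metal": "Pb", "value": 185.34, "unit": "ppb", "below_lod": False, "lod": 10.0}


class TestReadConcentrationTable:
    def test_ppb_converted_to_canonical(self, tmp_path):
        t = read_concentration_table(_write_csv(tmp_path / "c.csv", [CSV_ROW]))
        assert t.values("Pb")[0] == pytest.approx(0.18534)

    def test_ppm_is_canonical(self, tmp_path):
        row = dict(CSV_ROW, metal="Al", value=0.54, unit="ppm")
        t = read_concentration_table(_write_csv(tmp_path / "c.csv", [row]))
        assert t.values("Al")[0] == pytest.approx(0.54)

    def test_empty_file_with_header_gives_empty_table(self, tmp_path):
        path = tmp_path / "c.csv"
        pd.DataFrame(columns=list(CSV_ROW)).to_csv(path, index=False)
        t = read_concentration_table(path)
        assert len(t) == 0 and t.measurements == []

    def test_row_count_preserved(self, tmp_path):
        rows = [dict(CSV_ROW, sample_id=f"s{i}", value=1.0 + i) for i in range(32)]
        t = read_concentration_table(_write_csv(tmp_path / "c.csv", rows))
        assert len(t) == 32

    def test_missing_column_names_the_column(self, tmp_path):
        rows = [{k: v for k, v in CSV_ROW.items() if k != "metal"}]
        with pytest.raises(SchemaError, match="metal"):
            read_concentration_table(_write_csv(tmp_path / "c.csv", rows))

    def test_nonpositive_value_names_the_row(self, tmp_path):
        rows = [CSV_ROW, dict(CSV_ROW, sample_id="s2", value=-1.0)]
        with pytest.raises(ValidationError, match="1"):
            read_concentration_table(_write_csv(tmp_path / "c.csv", rows))

    def test_unit_map_fallback(self, tmp_path):
        rows = [{k: v for k, v in CSV_ROW.items() if k != "unit"}]
        t = read_concentration_table(_write_csv(tmp_path / "c.csv", rows), {"Pb": "ppb"})
        assert t.values("Pb")[0] == pytest.approx(0.18534)

    def test_censored_rows_carry_lod(self, tmp_path):
        rows = [dict(CSV_ROW, below_lod=True, value="")]
        t = read_concentration_table(_write_csv(tmp_path / "c.csv", rows))
        m = t.measurements[0]
        assert m.below_lod and m.lod == pytest.approx(0.01) and m.concentration is None

    def test_write_read_round_trip(self, tmp_path):
        table = make_table({"Pb": [0.1, 0.2, None], "Al": [0.5, 0.6, 0.7]})
        write_concentration_csv(table, tmp_path / "out.csv")
        back = read_concentration_table(tmp_path / "out.csv")
        np.testing.assert_allclose(sorted(back.values("Pb")), [0.1, 0.2])
        assert back.censored_fraction("Pb") == pytest.approx(1 / 3)


@settings(max_examples=50, deadline=None)
@given(st.floats(min_value=1e-6, max_value=1e6, allow_nan=False))
def test_unit_round_trip(value):
    assert from_mg_per_kg(to_mg_per_kg(value, "ppb"), "ppb") == pytest.approx(value, rel=1e-12)


class TestLodPolicy:
    def test_exclusion_at_study_fraction(self):
        # 7 of 32 censored = 21.9% >= 20% threshold -> metal excluded
        t = make_table({"Cr": [1.0 + i for i in range(25)] + [None] * 7})
        out, dec = apply_lod_policy(t, "Cr", exclusion_fraction=0.20)
        assert dec.excluded and dec.censored_fraction == pytest.approx(7 / 32)
        assert "Cr" not in out.metals

    def test_exactly_at_threshold_excludes(self):
        t = make_table({"Cd": [1.0] * 8 + [None] * 2})
        out, dec = apply_lod_policy(t, "Cd", exclusion_fraction=0.20)
        assert dec.excluded and dec.censored_fraction == pytest.approx(0.2)

    def test_just_below_threshold_substitutes(self):
        t = make_table({"Cd": [1.0] * 9 + [None] * 2})
        out, dec = apply_lod_policy(t, "Cd", exclusion_fraction=0.20)
        assert not dec.excluded and dec.n_imputed == 2

    def test_no_censoring_leaves_table_unchanged(self):
        t = make_table({"Pb": [0.1, 0.2, 0.3]})
        out, dec = apply_lod_policy(t, "Pb")
        pd.testing.assert_frame_equal(out.df, t.df)
        assert not dec.excluded and dec.n_imputed == 0

    def test_half_lod_substitution_values(self):
        t = make_table({"Cd": [1.0] * 29 + [None] * 3}, lods={"Cd": 0.05})
        out, dec = apply_lod_policy(t, "Cd", substitution="half-lod")
        imputed = out.df.loc[out.df["imputed"], "concentration"]
        assert len(imputed) == 3 and np.allclose(imputed, 0.025)

    def test_full_lod_and_zero_rules(self):
        t = make_table({"Cd": [1.0] * 29 + [None] * 3}, lods={"Cd": 0.05})
        out, _ = apply_lod_policy(t, "Cd", substitution="full-lod")
        assert np.allclose(out.df.loc[out.df["imputed"], "concentration"], 0.05)
        out, _ = apply_lod_policy(t, "Cd", substitution="zero")
        assert len(out) == 29  # zero rule drops censored rows

    def test_non_censored_count_never_changes(self):
        t = make_table({"Cd": [1.0] * 20 + [None] * 3})
        before = int(t.df["concentration"].notna().sum())
        out, _ = apply_lod_policy(t, "Cd")
        assert int((~out.df["below_lod"]).sum()) == before

    def test_unknown_metal_raises(self, tiny_table):
        with pytest.raises(KeyError):
            apply_lod_policy(tiny_table, "Hg")


class TestSummaries:
    def test_identical_values_degenerate(self):
        t = make_table({"Al": [0.4, 0.4, 0.4]})
        row = summarize_concentrations(t).iloc[0]
        assert row["mean"] == pytest.approx(0.4)
        assert row["sd"] == pytest.approx(0.0, abs=1e-12)
        assert row["median"] == pytest.approx(0.4)
        assert row["min"] == row["max"] == 0.4

    def test_p90_matches_interpolation_oracle(self):
        values = list(range(1, 11))
        t = make_table({"Al": values})
        row = summarize_concentrations(t).iloc[0]
        # sort-and-interpolate: position 0.9*(n-1) between order statistics
        pos = 0.9 * (len(values) - 1)
        lo, frac = int(pos), pos - int(pos)
        expected = sorted(values)[lo] * (1 - frac) + sorted(values)[lo + 1] * frac
        assert row["p90"] == pytest.approx(expected)

    def test_stats_match_brute_force_on_subtable(self):
        rng = np.random.default_rng(8)
        t = make_table({"Pb": rng.lognormal(0, 1, 16).tolist(),
                        "Al": rng.lognormal(0, 1, 16).tolist()})
        sub = t.by_metal("Pb")
        row = summarize_concentrations(sub).iloc[0]
        v = np.sort(sub.values("Pb"))
        assert row["mean"] == pytest.approx(v.mean())
        assert row["sd"] == pytest.approx(v.std(ddof=1))
        assert row["median"] == pytest.approx(np.median(v))

    def test_empty_group_absent_not_zero(self):
        t = make_table({"Pb": [None, None, None]})
        out = summarize_concentrations(t)
        assert out.empty

    def test_equal_n_pooling_property(self):
        # pooled mean equals the unweighted mean of stratum means at equal n
        rng = np.random.default_rng(9)
        from dermrisk.data_io import ConcentrationTable

        frames = [make_table({"Pb": rng.lognormal(0, 1, 4).tolist()}, brand=f"b{i}").df
                  for i in range(8)]
        t = ConcentrationTable(pd.concat(frames, ignore_index=True))
        per_brand = summarize_concentrations(t, "brand")
        pooled = summarize_concentrations(t)
        assert pooled.iloc[0]["mean"] == pytest.approx(per_brand["mean"].mean())


class TestReferenceTables:
    def test_dermal_rfd_never_exceeds_ingestion(self, rfds):
        for e in rfds.values():
            assert e.rfd_derm <= e.rfd_ing

    def test_detection_limits_canonical_units(self):
        lods = reference.detection_limits()
        assert lods["Ba"] == pytest.approx(0.05e-3)   # reported in ppb
        assert lods["Fe"] == pytest.approx(0.1)       # reported in ppm

    def test_pooled_mean_unrecoverable_for_censored_cells(self):
        for metal in ("Ba", "Cd"):
            with pytest.raises(ValueError):
                reference.pooled_brand_mean(metal)

    def test_rfd_csv_reader(self, tmp_path):
        path = tmp_path / "rfd.csv"
        pd.DataFrame([{"metal": "Pb", "rfd_ing": 0.0035, "rfd_derm": 0.00052}]).to_csv(path, index=False)
        table = read_rfd_table(path)
        assert table["Pb"].basis("dermal") == pytest.approx(0.00052)
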