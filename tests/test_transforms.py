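"""Hellinger transform, indicator standardization, padding, gauge-derived
hydroperiod indicators."""

import datetime as dt
import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from concord import (
    GaugeSeries,
    HydroperiodMatrix,
    derive_hydro_indicators,
    hellinger,
    hydro_matrix_from_gauges,
    pad_to_common_dimension,
    procrustes_fit,
    read_gauge_csv,
    standardize_env,
)

from conftest import make_community


def make_hydro(values, sites=None) -> HydroperiodMatrix:
    values = np.asarray(values, dtype=float)
    sites = sites or [f"S{i}" for i in range(values.shape[0])]
    return HydroperiodMatrix(
        pd.DataFrame(
            values, index=sites,
            columns=["days_ponded", "max_depth", "amplitude_ratio", "evap_index"],
        )
    )


class TestHellinger:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ([1, 1, 2], [0.5, 0.5, 0.7071067811865476]),
            ([4, 0, 0], [1.0, 0.0, 0.0]),
        ],
    )
    def test_known_rows(self, row, expected):
        m = make_community([row, [1, 1, 1], [2, 3, 4]])
        out = hellinger(m)
        np.testing.assert_allclose(out.values[0], expected, atol=1e-12)
        assert out.kind == "hellinger"

    def test_empty_site_becomes_zero_row_with_warning(self, caplog):
        m = make_community([[0, 0, 0], [1, 1, 1], [2, 3, 4]])
        with caplog.at_level(logging.WARNING):
            out = hellinger(m)
        np.testing.assert_array_equal(out.values[0], [0, 0, 0])
        assert "empty site" in caplog.text

    @given(
        arrays(
            float,
            (6, 4),
            elements=st.floats(0, 1e6, allow_nan=False, width=32),
        ).filter(lambda a: (a.sum(axis=1) > 0).all())
    )
    def test_rows_have_unit_norm(self, values):
        out = hellinger(make_community(values))
        np.testing.assert_allclose(
            np.linalg.norm(out.values, axis=1), 1.0, atol=1e-12
        )

    @given(
        arrays(float, (5, 3), elements=st.floats(0.015625, 1e3, width=32)),
        st.floats(0.001, 1e4),
    )
    def test_row_scale_invariance(self, values, c):
        """Hellinger depends only on relative abundances within a site."""
        scaled = values.copy()
        scaled[2] *= c
        a = hellinger(make_community(values)).values
        b = hellinger(make_community(scaled)).values
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestStandardizeEnv:
    def test_arithmetic_sequence_zscores(self):
        h = make_hydro(np.column_stack([[100, 200, 300]] * 4))
        out = standardize_env(h)
        np.testing.assert_allclose(
            out.values[:, 0], [-1.224744871, 0.0, 1.224744871], atol=1e-9
        )
        assert out.kind == "zscore"

    def test_constant_column_zeroed_with_warning(self, caplog):
        vals = np.array([[5, 1, 0.1, 0.2], [5, 2, 0.5, 0.4], [5, 3, 0.9, 0.6]])
        with caplog.at_level(logging.WARNING):
            out = standardize_env(make_hydro(vals))
        np.testing.assert_array_equal(out.values[:, 0], 0.0)
        assert "zero-variance" in caplog.text

    def test_idempotent_on_standardized_input(self, rng):
        h = make_hydro(rng.normal(size=(8, 4)))
        once = standardize_env(h)
        twice = standardize_env(HydroperiodMatrix(once.data))
        np.testing.assert_allclose(once.values, twice.values, atol=1e-10)

    def test_columns_centered_and_unit_sd(self, rng):
        out = standardize_env(make_hydro(rng.uniform(0, 100, (20, 4))))
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.values.std(axis=0), 1.0, atol=1e-10)


class TestPadding:
    def test_narrow_matrix_padded_wide_untouched(self, rng):
        x = hellinger(make_community(rng.uniform(1, 5, (10, 4))))
        y = hellinger(make_community(rng.uniform(1, 5, (10, 7))))
        x2, y2 = pad_to_common_dimension(x, y)
        assert x2.values.shape == (10, 7)
        assert y2 is y
        np.testing.assert_array_equal(x2.values[:, :4], x.values)
        np.testing.assert_array_equal(x2.values[:, 4:], 0.0)
        assert x2.kind == "padded"

    def test_equal_widths_pass_through(self, rng):
        x = hellinger(make_community(rng.uniform(1, 5, (6, 3))))
        y = hellinger(make_community(rng.uniform(1, 5, (6, 3))))
        assert pad_to_common_dimension(x, y) == (x, y)

    def test_padding_leaves_procrustes_r_unchanged(self, rng):
        """Zero columns added to both matrices must not move the statistic."""
        x = hellinger(make_community(rng.uniform(0, 5, (12, 5))))
        y = hellinger(make_community(rng.uniform(0, 5, (12, 5))))
        r_plain = procrustes_fit(x, y).r
        wide = hellinger(make_community(rng.uniform(1, 2, (12, 8))))
        x_pad, _ = pad_to_common_dimension(x, wide)
        y_pad, _ = pad_to_common_dimension(y, wide)
        assert procrustes_fit(x_pad, y_pad).r == pytest.approx(r_plain, abs=1e-12)

    def test_row_mismatch_error(self, rng):
        x = hellinger(make_community(rng.uniform(1, 5, (6, 3))))
        y = hellinger(make_community(rng.uniform(1, 5, (5, 3))))
        with pytest.raises(ValueError, match="site order"):
            pad_to_common_dimension(x, y)


class TestGaugeIndicators:
    def test_flooded_through_september(self):
        g = GaugeSeries(
            site_id="W1",
            dates=[dt.date(2014, 5, 10), dt.date(2014, 6, 15), dt.date(2014, 7, 20)],
            depths_cm=[50, 40, 30],
            flooded_through_september=True,
            evap_index=0.25,
        )
        row = derive_hydro_indicators(g)
        assert row["days_ponded"] == 365
        assert row["max_depth"] == 50
        assert row["amplitude_ratio"] == pytest.approx(0.4)
        assert row["evap_index"] == 0.25

    def test_constant_depth_zero_amplitude(self):
        g = GaugeSeries(
            "W2", [dt.date(2014, 5, 1), dt.date(2014, 6, 1)], [20, 20], True, 0.5
        )
        assert derive_hydro_indicators(g)["amplitude_ratio"] == 0.0

    def test_dry_wetland_guard(self):
        g = GaugeSeries(
            "W3",
            [dt.date(2014, 5, 1), dt.date(2014, 6, 1)],
            [0, 0],
            False,
            0.9,
            dry_date=dt.date(2014, 6, 10),
        )
        row = derive_hydro_indicators(g)
        assert row["max_depth"] == 0.0
        assert row["amplitude_ratio"] == 0.0
        assert row["days_ponded"] == 40

    def test_undetermined_hydroperiod_error(self):
        g = GaugeSeries(
            "W4", [dt.date(2014, 5, 1), dt.date(2014, 6, 1)], [10, 5], False, 0.9
        )
        with pytest.raises(ValueError, match="undetermined"):
            derive_hydro_indicators(g)

    def test_csv_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {
                "site_id": ["A", "A", "B", "B"],
                "date": ["2014-05-01", "2014-07-01", "2014-05-02", "2014-08-01"],
                "depth_cm": [30.0, 10.0, 80.0, 60.0],
                "dry_date": ["2014-08-15", "2014-08-15", None, None],
                "flooded_through_september": [False, False, True, True],
                "evap_index": [0.7, 0.7, 0.2, 0.2],
            }
        )
        p = tmp_path / "gauges.csv"
        df.to_csv(p, index=False)
        hydro = hydro_matrix_from_gauges(read_gauge_csv(p))
        assert hydro.data.loc["A", "days_ponded"] == 106
        assert hydro.data.loc["B", "days_ponded"] == 365
        assert hydro.data.loc["B", "amplitude_ratio"] == pytest.approx(0.25)
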