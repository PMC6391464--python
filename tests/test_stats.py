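"""Fold changes, Welch t, the significance filter, zero-replacement/log10."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mzsift.stats import (apply_filters, signed_fold_change,
                          transform_abundances, welch_t)
from mzsift.table import FeatureTable


def welch_oracle(x, y):
    """Literal transcription of the Welch formulas."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    from scipy.stats import t as tdist
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


def make_table(abund: dict[str, list[float]], rts=None, groups=None):
    """abund: feature -> abundances over samples [B1..B3, L1..L3, H1..H3]."""
    n = len(next(iter(abund.values())))
    if groups is None:
        per = n // 3
        groups = ["Blank"] * per + ["Low"] * per + ["High"] * per
    ids = [f"{g}_{i}" for i, g in enumerate(groups)]
    ab = pd.DataFrame(abund, index=ids).T
    feats = pd.DataFrame({"mz": 200.0, "rt": rts if rts is not None
                          else [200.0] * len(abund)}, index=ab.index)
    samples = pd.DataFrame({"group": groups, "sample_type": "incubation",
                            "injection_index": range(n)}, index=ids)
    return FeatureTable(ab, feats, samples)


class TestSignedFoldChange:
    @pytest.mark.parametrize("a,b,expected", [
        (100.0, 200.0, 2.0), (200.0, 100.0, -2.0), (5.0, 5.0, 1.0),
    ])
    def test_examples(self, a, b, expected):
        assert signed_fold_change(a, b) == pytest.approx(expected)

    def test_degenerate_cases(self):
        assert math.isnan(signed_fold_change(0.0, 0.0))
        assert signed_fold_change(0.0, 5.0) == math.inf
        assert signed_fold_change(5.0, 0.0) == -math.inf

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            signed_fold_change(-1.0, 2.0)


class TestWelchT:
    def test_identical_samples_give_t0_p1(self):
        t, _, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_textbook_example(self):
        t, df, p = welch_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == pytest.approx(4.0, abs=1e-9)
        assert p == pytest.approx(0.0214, abs=1e-3)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1, 2, 3])

    def test_matches_formula_oracle_on_random_inputs(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            nx, ny = rng.integers(2, 12, 2)
            x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 3), nx)
            y = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 3), ny)
            t, df, p = welch_t(x, y)
            to, dfo, po = welch_oracle(x, y)
            assert abs(t - to) < 1e-10
            assert abs(df - dfo) < 1e-10
            assert abs(p - po) < 1e-10


class TestApplyFilters:
    def brute_force(self, table, fc=1.5, pthr=0.001, window=(60.0, 600.0)):
        """Direct enumeration of the filter predicate."""
        keep = []
        for f in table.feature_names:
            rt_ok = window[0] <= table.features.loc[f, "rt"] <= window[1]
            any_pair = False
            for a, b in (("Blank", "Low"), ("Blank", "High"), ("Low", "High")):
                xa = table.abundance.loc[f, table.group_columns(a)].to_numpy()
                xb = table.abundance.loc[f, table.group_columns(b)].to_numpy()
                fc_v = signed_fold_change(xa.mean(), xb.mean())
                _, _, p = welch_t(xa, xb)
                if not math.isnan(fc_v) and (abs(fc_v) > fc) and p < pthr:
                    any_pair = True
            if any_pair and rt_ok:
                keep.append(f)
        return keep

    def test_toy_table_matches_brute_force(self):
        table = make_table({
            "up": [1, 1.1, 0.9, 5, 5.1, 4.9, 10, 10.1, 9.9],
            "flat": [5, 5.1, 4.9, 5.0, 5.2, 4.8, 5.1, 5.0, 4.9],
            "noisy": [1, 9, 2, 8, 1, 9, 2, 8, 1],
            "down": [10, 10.1, 9.9, 5, 5.1, 4.9, 1, 1.1, 0.9],
            "small_fc": [5, 5.01, 4.99, 6, 6.01, 5.99, 7, 7.01, 6.99],
            "zeroblank": [0, 0, 0, 50, 51, 49, 100, 101, 99],
        })
        filtered, verdicts, _ = apply_filters(table)
        assert set(filtered.feature_names) == set(self.brute_force(table))

    def test_rt_window_edges(self):
        table = make_table(
            {"at59": [0, 0, 0, 50, 51, 49, 100, 101, 99],
             "at60": [0, 0, 0, 50, 51, 49, 100, 101, 99],
             "at600": [0, 0, 0, 50, 51, 49, 100, 101, 99],
             "at601": [0, 0, 0, 50, 51, 49, 100, 101, 99]},
            rts=[59.0, 60.0, 600.0, 601.0])
        filtered, _, _ = apply_filters(table)
        assert set(filtered.feature_names) == {"at60", "at600"}

    def test_missing_group_named_in_error(self):
        table = make_table({"f": [1, 2, 3, 4, 5, 6]},
                           groups=["Low"] * 3 + ["High"] * 3)
        with pytest.raises(ValueError, match="Blank"):
            apply_filters(table)

    def test_filter_is_monotone_in_thresholds(self):
        rng = np.random.default_rng(1)
        table = make_table({f"f{i}": rng.lognormal(3, 1, 9).tolist()
                            for i in range(30)})
        base, _, _ = apply_filters(table, fc_thresh=1.5, p_thresh=0.001)
        looser, _, _ = apply_filters(table, fc_thresh=1.2, p_thresh=0.01)
        assert set(base.feature_names) <= set(looser.feature_names)


class TestTransformAbundances:
    def test_zero_replacement_with_global_min(self):
        table = make_table({"f": [0, 5, 10, 2, 5, 10, 2, 5, 10]})
        out = transform_abundances(table)
        expected = np.log10([2, 5, 10, 2, 5, 10, 2, 5, 10])
        np.testing.assert_allclose(out.abundance.loc["f"], expected)

    def test_no_zeros_is_pure_log10(self):
        table = make_table({"f": [1, 2, 4, 8, 16, 32, 64, 128, 256]})
        out = transform_abundances(table)
        np.testing.assert_allclose(
            out.abundance.loc["f"],
            np.log10(table.abundance.loc["f"].astype(float)))

    def test_min_is_global_across_features(self):
        table = make_table({
            "a": [0, 100, 100, 100, 100, 100, 100, 100, 100],
            "b": [7, 50, 50, 50, 50, 50, 50, 50, 50]})
        out = transform_abundances(table)
        # the zero in feature a is replaced by 7, the minimum from feature b
        assert out.abundance.loc["a"].iloc[0] == pytest.approx(np.log10(7))

    def test_all_zero_table_rejected(self):
        table = make_table({"f": [0.0] * 9})
        with pytest.raises(ValueError):
            transform_abundances(table)

    def test_double_transform_rejected(self):
        table = make_table({"f": [1.0] * 9})
        with pytest.raises(ValueError):
            transform_abundances(transform_abundances(table))
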