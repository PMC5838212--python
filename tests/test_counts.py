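"""Normalization, enrichment calling, detection, clustering, and ddCt."""

import numpy as np
import pandas as pd
import pytest

from evcargo.counts import (
    CtTable,
    call_enriched,
    cluster_heatmap,
    ddct_relative_expression,
    detect_mirnas,
    fold_change,
    quantile_normalize,
    spikein_normalize,
)

from conftest import toy_matrix


def _two_sample(endog_a, endog_b, pos_a=(100.0,), pos_b=(200.0,)):
    n = len(endog_a)
    values = {
        "s1": list(endog_a) + list(pos_a),
        "s2": list(endog_b) + list(pos_b),
    }
    ids = [f"m{i}" for i in range(n)] + [f"POS_{i}" for i in range(len(pos_a))]
    classes = {i: "endogenous" for i in ids[:n]} | {i: "positive" for i in ids[n:]}
    df = pd.DataFrame(values)
    df.index = ids
    return toy_matrix(
        {s: pd.Series(df[s].to_numpy(), index=ids) for s in df.columns},
        classes,
        {"s1": "CR", "s2": "ATP"},
    )


class TestSpikeinNormalize:
    def test_geometric_mean_scaling_hand_example(self):
        # positive-control sums 100 and 200 -> factors sqrt(2) and sqrt(2)/2,
        # both post-normalization sums = sqrt(100*200)
        m = _two_sample([10.0, 20.0], [10.0, 20.0])
        out = spikein_normalize(m)
        pos = out.values.loc[out.probes_of("positive")]
        target = np.sqrt(100.0 * 200.0)
        assert pos["s1"].sum() == pytest.approx(target)
        assert pos["s2"].sum() == pytest.approx(target)
        assert out.values.loc["m0", "s1"] == pytest.approx(10.0 * np.sqrt(2))
        assert out.values.loc["m0", "s2"] == pytest.approx(10.0 * np.sqrt(2) / 2)
        assert out.state == "spikein_normalized"

    def test_equal_control_sums_is_identity(self):
        m = _two_sample([5.0, 7.0], [1.0, 2.0], pos_a=(50.0, 50.0), pos_b=(60.0, 40.0))
        out = spikein_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_zero_positive_controls_error_names_sample(self):
        m = _two_sample([5.0], [5.0], pos_a=(0.0,), pos_b=(10.0,))
        with pytest.raises(ValueError, match="s1"):
            spikein_normalize(m)

    def test_requires_raw_state(self):
        m = _two_sample([5.0], [5.0])
        out = spikein_normalize(m)
        with pytest.raises(ValueError, match="raw"):
            spikein_normalize(out)


def _qn_oracle(x):
    """Brute-force quantile normalization: per-rank cross-sample means, ties
    averaged over the tied ranks' reference values."""
    n, s = x.shape
    ref = np.mean(np.sort(x, axis=0), axis=1)
    out = np.zeros_like(x, dtype=float)
    for j in range(s):
        col = list(x[:, j])
        order = sorted(range(n), key=lambda i: col[i])
        rank_of = {}
        for r, i in enumerate(order):
            rank_of[i] = r
        for i in range(n):
            tied = [rank_of[i2] for i2 in range(n) if col[i2] == col[i]]
            out[i, j] = np.mean([ref[r] for r in tied])
    return out


class TestQuantileNormalize:
    def _matrix(self, cols):
        n = len(next(iter(cols.values())))
        ids = [f"m{i}" for i in range(n)]
        values = {s: pd.Series(v, index=ids, dtype=float) for s, v in cols.items()}
        classes = {i: "endogenous" for i in ids}
        conds = {s: "CR" for s in cols}
        return toy_matrix(values, classes, conds, state="spikein_normalized")

    def test_two_by_two_worked_example(self):
        m = self._matrix({"a": [1.0, 3.0], "b": [2.0, 4.0]})
        out = quantile_normalize(m)
        np.testing.assert_allclose(
            out.values.to_numpy(), [[1.5, 1.5], [3.5, 3.5]]
        )

    def test_identical_columns_fixed_point(self):
        m = self._matrix({"a": [4.0, 1.0, 9.0], "b": [4.0, 1.0, 9.0]})
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_rank_order_preserved_within_column(self):
        m = self._matrix({"a": [1.0, 3.0, 2.0], "b": [9.0, 4.0, 6.0]})
        out = quantile_normalize(m)
        for s in ("a", "b"):
            assert list(np.argsort(out.values[s].to_numpy())) == list(
                np.argsort(m.values[s].to_numpy())
            )

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = (rng.integers(2, 11), rng.integers(2, 6))
        x = rng.integers(0, 6, size=shape).astype(float)  # many ties
        m = self._matrix({f"s{j}": x[:, j] for j in range(shape[1])})
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(), _qn_oracle(x), atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_sorted_columns_identical(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.gamma(2.0, 50.0, size=(40, 4))
        m = self._matrix({f"s{j}": x[:, j] for j in range(4)})
        out = quantile_normalize(m).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 4):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)

    def test_single_sample_rejected(self):
        m = self._matrix({"a": [1.0, 2.0]})
        with pytest.raises(ValueError, match="2 samples"):
            quantile_normalize(m)

    def test_controls_pass_through_unchanged(self):
        ids = ["m0", "m1", "NEG_A"]
        m = toy_matrix(
            {
                "a": pd.Series([1.0, 3.0, 7.0], index=ids),
                "b": pd.Series([2.0, 4.0, 9.0], index=ids),
            },
            {"m0": "endogenous", "m1": "endogenous", "NEG_A": "negative"},
            {"a": "CR", "b": "ATP"},
            state="spikein_normalized",
        )
        out = quantile_normalize(m)
        assert out.values.loc["NEG_A", "a"] == 7.0
        assert out.values.loc["NEG_A", "b"] == 9.0


def _quantile_matrix(cols, conds):
    n = len(next(iter(cols.values())))
    ids = [f"m{i}" for i in range(n)]
    return toy_matrix(
        {s: pd.Series(v, index=ids, dtype=float) for s, v in cols.items()},
        {i: "endogenous" for i in ids},
        conds,
        state="quantile_normalized",
    )


class TestFoldChangeAndEnrichment:
    def test_mean_ratio(self):
        m = _quantile_matrix(
            {"c1": [10.0], "c2": [10.0], "t1": [14.0], "t2": [16.0]},
            {"c1": "CR", "c2": "CR", "t1": "ATP", "t2": "ATP"},
        )
        fc = fold_change(m, "CR")
        assert fc.iloc[0]["fold_change"] == pytest.approx(1.5)

    def test_baseline_vs_itself_is_unity(self):
        rngv = np.random.default_rng(3).gamma(2, 30, size=6)
        m = _quantile_matrix(
            {"a": rngv, "b": rngv},
            {"a": "CR", "b": "ATP"},
        )
        fc = fold_change(m, "ATP")
        # identical values in both conditions -> FC identically 1
        assert np.allclose(fc["fold_change"], 1.0)

    def test_zero_baseline_uses_pseudocount(self):
        m = _quantile_matrix(
            {"c": [0.0], "t": [5.0]}, {"c": "CR", "t": "ATP"}
        )
        fc = fold_change(m, "CR")
        assert fc.iloc[0]["fold_change"] == pytest.approx(11.0)  # 5.5 / 0.5

    def test_unknown_baseline_errors(self):
        m = _quantile_matrix({"c": [1.0], "t": [2.0]}, {"c": "CR", "t": "ATP"})
        with pytest.raises(ValueError, match="baseline"):
            fold_change(m, "nope")

    def test_threshold_boundary_inclusive(self):
        fc = pd.DataFrame(
            {
                "mirna": ["a", "b"],
                "condition": ["ATP", "ATP"],
                "fold_change": [1.5, 1.49],
            }
        )
        res = call_enriched(fc, 1.5)
        assert res[0].mirnas() == {"a"}

    def test_no_change_gives_empty_results(self):
        fc = pd.DataFrame(
            {"mirna": ["a"], "condition": ["ATP"], "fold_change": [1.0]}
        )
        assert call_enriched(fc)[0].entries == []

    @pytest.mark.parametrize("seed", range(5))
    def test_antitone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        fc = pd.DataFrame(
            {
                "mirna": [f"m{i}" for i in range(30)],
                "condition": ["ATP"] * 30,
                "fold_change": rng.uniform(0.2, 4.0, 30),
            }
        )
        t1, t2 = sorted(rng.uniform(0.5, 3.0, 2))
        low = call_enriched(fc, t1)[0].mirnas()
        high = call_enriched(fc, t2)[0].mirnas()
        assert high <= low


class TestDetection:
    def _matrix(self, endo, neg, conds=None):
        ids = [f"m{i}" for i in range(len(next(iter(endo.values()))))]
        nids = [f"NEG_{i}" for i in range(len(next(iter(neg.values()))))]
        values = {
            s: pd.Series(list(endo[s]) + list(neg[s]), index=ids + nids)
            for s in endo
        }
        classes = {i: "endogenous" for i in ids} | {i: "negative" for i in nids}
        return toy_matrix(
            values, classes, conds or {s: "CR" for s in endo}, state="quantile_normalized"
        )

    def test_all_zero_counts_detect_nothing(self):
        m = self._matrix({"a": [0.0, 0.0]}, {"a": [1.0, 2.0, 3.0]})
        assert detect_mirnas(m) == set()

    def test_clearly_expressed_mirna_detected(self):
        # negatives 1/2/3 -> mean 2, sd 1 -> threshold 4; m0 at 20 detected
        m = self._matrix({"a": [20.0, 3.0]}, {"a": [1.0, 2.0, 3.0]})
        assert detect_mirnas(m) == {"m0"}

    def test_lower_multiplier_never_shrinks_set(self):
        rng = np.random.default_rng(5)
        m = self._matrix(
            {"a": rng.gamma(2, 10, 20)}, {"a": rng.uniform(1, 10, 6)}
        )
        strict = detect_mirnas(m, multiplier=3.0)
        loose = detect_mirnas(m, multiplier=1.0)
        assert strict <= loose

    def test_no_negatives_requires_floor(self):
        ids = ["m0"]
        m = toy_matrix(
            {"a": pd.Series([5.0], index=ids)},
            {"m0": "endogenous"},
            {"a": "CR"},
            state="quantile_normalized",
        )
        with pytest.raises(ValueError, match="floor"):
            detect_mirnas(m)
        assert detect_mirnas(m, floor=4.0) == {"m0"}


class TestClusterHeatmap:
    def _matrix(self, rows):
        ids = list(rows)
        samples = {"a": "CR", "b": "ATP"}
        values = {
            s: pd.Series([rows[i][j] for i in ids], index=ids)
            for j, s in enumerate(samples)
        }
        return toy_matrix(
            values, {i: "endogenous" for i in ids}, samples, state="quantile_normalized"
        )

    def test_identical_rows_merge_at_zero_distance(self):
        m = self._matrix({"x": [4.0, 8.0], "y": [4.0, 8.0], "z": [100.0, 1.0]})
        res = cluster_heatmap(m)
        first_merge = res.row_linkage[0]
        assert first_merge[2] == pytest.approx(0.0)

    def test_block_structure_splits_at_top_level(self):
        m = self._matrix(
            {
                "a1": [10.0, 11.0],
                "a2": [10.5, 11.5],
                "b1": [1000.0, 1100.0],
                "b2": [1010.0, 1090.0],
            }
        )
        res = cluster_heatmap(m)
        order = res.row_order
        # the two abundance blocks stay contiguous in leaf order
        pos = {name: order.index(name) for name in ("a1", "a2", "b1", "b2")}
        assert {abs(pos["a1"] - pos["a2"]), abs(pos["b1"] - pos["b2"])} == {1}

    def test_leaf_order_is_permutation(self):
        m = self._matrix({f"m{i}": [float(i), float(i * 2)] for i in range(6)})
        res = cluster_heatmap(m)
        assert sorted(res.row_order) == sorted(f"m{i}" for i in range(6))

    def test_single_row_degenerate(self):
        m = self._matrix({"only": [3.0, 4.0]})
        res = cluster_heatmap(m)
        assert res.row_linkage is None
        assert res.row_order == ["only"]


def _ct_table(dcts: dict[str, float], hk_ct=20.0):
    """Build a Ct table with given per-group dCt for one target."""
    rows = []
    for group, dct in dcts.items():
        for r in (1, 2):
            s = f"{group}{r}"
            rows.append({"sample": s, "group": group, "target": "miR-x", "ct": hk_ct + dct})
            rows.append({"sample": s, "group": group, "target": "hk", "ct": hk_ct})
    return CtTable(data=pd.DataFrame(rows), housekeeping="hk")


class TestDdct:
    @pytest.mark.parametrize(
        "ddct_value,expected", [(0.0, 1.0), (1.0, 0.5), (-2.0, 4.0)]
    )
    def test_closed_form(self, ddct_value, expected):
        t = _ct_table({"calibrator": 5.0, "treated": 5.0 + ddct_value})
        assert ddct_relative_expression(t, "miR-x") == pytest.approx(expected)

    def test_missing_group_errors(self):
        rows = [
            {"sample": "a", "group": "calibrator", "target": "miR-x", "ct": 25.0},
            {"sample": "a", "group": "calibrator", "target": "hk", "ct": 20.0},
        ]
        t = CtTable(data=pd.DataFrame(rows), housekeeping="hk")
        with pytest.raises(ValueError, match="treated"):
            ddct_relative_expression(t, "miR-x")

    def test_nonpositive_ct_rejected(self):
        rows = [
            {"sample": "a", "group": "calibrator", "target": "hk", "ct": -1.0},
        ]
        with pytest.raises(ValueError, match="finite"):
            CtTable(data=pd.DataFrame(rows), housekeeping="hk")

    def test_housekeeping_required_per_sample(self):
        rows = [
            {"sample": "a", "group": "calibrator", "target": "miR-x", "ct": 25.0},
        ]
        with pytest.raises(ValueError, match="housekeeping"):
            CtTable(data=pd.DataFrame(rows), housekeeping="hk")
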