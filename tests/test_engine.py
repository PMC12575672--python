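"""Split-resample engine: splits, P_replicability, curves."""

import numpy as np
import pytest

from repliconn.engine import (
    PReplicability,
    ReplicationCurve,
    ShuffleRecord,
    draw_split,
    estimate_p_replicability,
    min_replicable_n,
    run_curve,
    summarize_effects,
    union_replicability,
)


def _record(n, p_dis, p_rep, shuffle=0, r_dis=0.2, r_rep=0.2):
    empty = np.array([], dtype=int)
    return ShuffleRecord(shuffle, n, empty, empty, r_dis, p_dis, r_rep, p_rep)


def _curve(values_by_n, metric="sc"):
    """Curve with prescribed p_replicability values (no records needed)."""
    curve = ReplicationCurve("p", metric, tuple(sorted(values_by_n)), 0.05, [])
    for n, v in values_by_n.items():
        curve.p_replicability[n] = PReplicability(v, 100, 100, False)
    return curve


class TestDrawSplit:
    def test_sizes_and_disjointness(self, rng):
        dis, rep = draw_split(900, 425, rng)
        assert len(dis) == len(rep) == 425
        assert len(np.intersect1d(dis, rep)) == 0
        assert len(np.union1d(dis, rep)) == 850

    def test_exact_halving_uses_everyone(self, rng):
        dis, rep = draw_split(50, 25, rng)
        assert len(np.union1d(dis, rep)) == 50

    def test_deterministic_given_seed(self):
        a = draw_split(100, 40, np.random.default_rng(5))
        b = draw_split(100, 40, np.random.default_rng(5))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_oversized_request_rejected(self, rng):
        with pytest.raises(ValueError):
            draw_split(100, 51, rng)


class TestPReplicability:
    def test_all_significant_gives_one(self):
        records = [_record(100, 0.01, 0.01, s) for s in range(100)]
        assert estimate_p_replicability(records).value == 1.0

    def test_partial_replication_fraction(self):
        # 80 discovery-significant, 60 of them replicate -> 0.75
        records = [_record(100, 0.01, 0.01, s) for s in range(60)]
        records += [_record(100, 0.01, 0.50, s) for s in range(60, 80)]
        records += [_record(100, 0.50, 0.01, s) for s in range(80, 100)]
        est = estimate_p_replicability(records)
        assert est.value == 0.75
        assert est.n_discovery_significant == 80
        assert not est.low_confidence

    def test_no_discoveries_is_undefined_not_zero(self):
        records = [_record(100, 0.5, 0.01, s) for s in range(10)]
        est = estimate_p_replicability(records)
        assert est.value is None

    def test_small_denominator_flagged(self):
        records = [_record(100, 0.01, 0.01, 0)] + [
            _record(100, 0.5, 0.5, s) for s in range(1, 20)
        ]
        assert estimate_p_replicability(records).low_confidence

    def test_mixed_sizes_rejected(self):
        with pytest.raises(ValueError):
            estimate_p_replicability([_record(50, 0.1, 0.1), _record(100, 0.1, 0.1)])

    def test_invariant_to_record_order_and_relabeling(self, rng):
        records = [
            _record(100, p, q, s)
            for s, (p, q) in enumerate(rng.uniform(0, 0.2, size=(30, 2)))
        ]
        shuffled = [records[i] for i in rng.permutation(30)]
        for rec in shuffled:
            rec.discovery_ids = rng.permutation(100)[:50]  # relabel subjects
        assert (
            estimate_p_replicability(records).value
            == estimate_p_replicability(shuffled).value
        )


class TestMinReplicableN:
    def test_first_crossing(self):
        assert min_replicable_n(_curve({25: 0.3, 50: 0.85, 75: 0.9})) == 50

    def test_all_below_threshold_is_sentinel(self):
        assert min_replicable_n(_curve({25: 0.5, 50: 0.8})) is None  # strict >

    def test_immediate_crossing(self):
        assert min_replicable_n(_curve({25: 0.95, 50: 0.2})) == 25

    def test_undefined_entries_fail(self):
        assert min_replicable_n(_curve({25: None, 50: 0.9})) == 50


class TestUnionRule:
    def test_single_contributing_metric(self):
        curves = [_curve({25: 0.1}, m) for m in ("fa", "rd")] + [
            _curve({25: 0.1, 150: 0.9}, "sc")
        ]
        u = union_replicability(curves)
        assert u.replicable and u.contributing == {"sc": 150} and u.min_n == 150

    def test_nothing_replicates(self):
        u = union_replicability([_curve({25: 0.1}, "sc")])
        assert not u.replicable and u.min_n is None

    def test_two_metrics_both_reported(self):
        u = union_replicability(
            [_curve({25: 0.9}, "sc"), _curve({25: 0.2, 50: 0.95}, "fa")]
        )
        assert set(u.contributing) == {"sc", "fa"} and u.min_n == 25


class TestRunCurve:
    def test_noiseless_signal_saturates(self, rng):
        X = rng.standard_normal((120, 10))
        y = X @ rng.standard_normal(10)
        curve = run_curve(X, y, grid=(25, 50), n_shuffles=4, seed=0)
        assert curve.p_replicability[25].value == 1.0
        assert curve.p_replicability[50].value == 1.0

    def test_grid_truncated_to_dataset(self, rng, caplog):
        X = rng.standard_normal((60, 5))
        y = X @ rng.standard_normal(5)
        curve = run_curve(X, y, grid=(25, 100), n_shuffles=2, seed=0)
        assert curve.grid == (25,)

    def test_phenotypes_get_independent_splits(self, rng):
        """Two phenotypes analyzed under one master seed must not share
        fold/split assignments (seeds are keyed by the phenotype tag)."""
        X = rng.standard_normal((60, 6))
        y = rng.standard_normal(60)
        a = run_curve(X, y, phenotype="iq", grid=(25,), n_shuffles=2, seed=3)
        b = run_curve(X, y, phenotype="mood", grid=(25,), n_shuffles=2, seed=3)
        assert not np.array_equal(a.records[0].discovery_ids, b.records[0].discovery_ids)

    def test_shuffle_count_stability(self, rng):
        """Doubling the shuffle count moves P_replicability by no more than
        the binomial Monte-Carlo scale."""
        X = rng.standard_normal((120, 10))
        y = X @ rng.standard_normal(10) + 2.0 * rng.standard_normal(120)
        p10 = run_curve(X, y, grid=(50,), n_shuffles=10, seed=0).p_replicability[50]
        p20 = run_curve(X, y, grid=(50,), n_shuffles=20, seed=0).p_replicability[50]
        assert abs(p10.value - p20.value) < 2 * np.sqrt(0.25 / 10)

    def test_deterministic_and_resumable(self, tmp_path, rng):
        X = rng.standard_normal((60, 8))
        y = X @ rng.standard_normal(8) + rng.standard_normal(60)
        path = tmp_path / "records.tsv"
        a = run_curve(X, y, grid=(25,), n_shuffles=3, seed=7, records_path=path)
        n_rows = len(path.read_text().splitlines())
        b = run_curve(X, y, grid=(25,), n_shuffles=3, seed=7, records_path=path)
        assert len(path.read_text().splitlines()) == n_rows  # nothing recomputed
        assert a.p_replicability[25].value == b.p_replicability[25].value
        c = run_curve(X, y, grid=(25,), n_shuffles=3, seed=7)
        assert [r.r_dis for r in a.records] == pytest.approx(
            [r.r_dis for r in c.records]
        )


class TestSummarizeEffects:
    def test_identical_effects_give_zero_delta(self):
        records = [_record(50, 0.01, 0.01, s, r_dis=0.3, r_rep=0.3) for s in range(5)]
        records += [_record(100, 0.01, 0.01, s, r_dis=0.4, r_rep=0.4) for s in range(5)]
        curve = ReplicationCurve("p", "sc", (50, 100), 0.05, records)
        table, cross = summarize_effects(curve)
        assert table["delta_r"].abs().max() == 0.0
        assert cross == pytest.approx(1.0)

    def test_two_point_curve_correlation_bounded(self):
        records = [_record(50, 0.01, 0.01, 0, r_dis=0.1, r_rep=0.3)]
        records += [_record(100, 0.01, 0.01, 0, r_dis=0.2, r_rep=0.25)]
        curve = ReplicationCurve("p", "sc", (50, 100), 0.05, records)
        _, cross = summarize_effects(curve)
        assert -1.0 <= cross <= 1.0

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            summarize_effects(ReplicationCurve("p", "sc", (), 0.05, []))
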