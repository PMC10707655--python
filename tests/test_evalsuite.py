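"""Event matching, delta statistics, KDE, and Multiple Correspondence Analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bleedwatch.evalsuite import (
    EventLog,
    delta_stats,
    kde_density,
    match_events,
    mca,
    read_event_log,
    write_event_log,
)


class TestMatching:
    def test_identical_logs_all_tp(self):
        s = EventLog("system", [5.0, 20.0, 60.0])
        h = EventLog("human", [5.0, 20.0, 60.0])
        m = match_events(s, h)
        assert (m.tp, m.fp, m.fn) == (3, 0, 0)
        assert np.all(m.deltas == 0)

    def test_empty_system_all_fn(self):
        m = match_events(EventLog("system", []), EventLog("human", [1.0, 2.0, 3.0]))
        assert (m.tp, m.fp, m.fn) == (0, 0, 3)

    def test_two_by_two_case(self):
        """Exhaustively checkable 2x2 matching with one pair in tolerance."""
        m = match_events(
            EventLog("system", [10.0, 30.0]),
            EventLog("human", [12.5, 50.0]),
            tolerance_s=5,
        )
        assert (m.tp, m.fp, m.fn) == (1, 1, 1)
        assert m.pairs == [(10.0, 12.5, -2.5)]
        outcomes = dict((t, o) for t, o in m.outcome_per_event)
        assert outcomes == {10.0: "TP", 30.0: "FP", 50.0: "FN"}

    def test_nearest_first_greedy(self):
        # one human event, two system candidates: closer one wins
        m = match_events(
            EventLog("system", [9.0, 11.0]), EventLog("human", [10.5]), tolerance_s=5
        )
        assert m.pairs[0][0] == 11.0
        assert m.fp == 1

    def test_video_mismatch_rejected(self):
        with pytest.raises(ValueError):
            match_events(
                EventLog("system", [], video_id="a"),
                EventLog("human", [], video_id="b"),
            )

    def test_bad_source_rejected(self):
        with pytest.raises(ValueError):
            EventLog("robot", [1.0])


class TestDeltaStats:
    def test_constant_deltas(self):
        assert delta_stats([-3, -3, -3]) == (-3.0, 0.0)

    def test_five_point_case(self):
        med, iqr = delta_stats([-1, -2, -3, -4, -5])
        assert (med, iqr) == (-3.0, 2.0)

    def test_single_delta(self):
        assert delta_stats([-2.0]) == (-2.0, 0.0)

    def test_zero_pairs_rejected(self):
        with pytest.raises(ValueError):
            delta_stats([])

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_matches_sort_based_oracle(self, deltas):
        """Median/IQR equal a naive interpolated-order-statistic oracle."""

        def quantile_type7(xs, q):
            xs = sorted(xs)
            h = (len(xs) - 1) * q
            lo = int(np.floor(h))
            hi = min(lo + 1, len(xs) - 1)
            return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

        med, iqr = delta_stats(deltas)
        assert med == pytest.approx(quantile_type7(deltas, 0.5), abs=1e-9)
        expected_iqr = quantile_type7(deltas, 0.75) - quantile_type7(deltas, 0.25)
        assert iqr == pytest.approx(expected_iqr, abs=1e-9)


class TestKDE:
    def test_integrates_to_one(self, rng):
        grid, dens = kde_density(rng.normal(0, 2, 50))
        assert abs(np.trapezoid(dens, grid) - 1) < 1e-3

    def test_degenerate_data_symmetric_peak_at_zero(self):
        grid, dens = kde_density([0.0, 0.0, 0.0], bandwidth=1.0)
        assert abs(grid[np.argmax(dens)]) < 0.02
        mid = len(grid) // 2
        np.testing.assert_allclose(dens[:mid], dens[-mid:][::-1], atol=1e-9)

    def test_two_point_closed_form(self):
        """Density of {-5, 5} with h=1 equals the two-Gaussian mixture."""
        grid, dens = kde_density([-5.0, 5.0], bandwidth=1.0)
        phi = lambda z: np.exp(-0.5 * z**2) / np.sqrt(2 * np.pi)
        expected = 0.5 * (phi(grid + 5) + phi(grid - 5))
        np.testing.assert_allclose(dens, expected, atol=1e-12)
        i_neg = np.argmin(abs(grid + 5))
        i_pos = np.argmin(abs(grid - 5))
        assert dens[i_neg] == pytest.approx(dens[i_pos], rel=1e-6)

    def test_zero_variance_auto_bandwidth_falls_back(self):
        with pytest.warns(UserWarning, match="zero-spread"):
            grid, dens = kde_density([2.0, 2.0, 2.0])
        assert abs(np.trapezoid(dens, grid) - 1) < 1e-3


def _ca_oracle(contingency: np.ndarray) -> np.ndarray:
    """Brute-force classical CA singular values of a contingency table."""
    p = contingency / contingency.sum()
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    return np.linalg.svd(s, compute_uv=False)


class TestMCA:
    def test_identical_binary_pair(self):
        """Perfect association concentrates all inertia on one axis."""
        t = pd.DataFrame({"a": ["x", "y"] * 10, "b": ["u", "v"] * 10})
        res = mca(t)
        # oracle: (J - Q)/Q = 1 total, fully on dim 1
        assert res.principal_inertias[0] == pytest.approx(1.0, abs=1e-10)
        assert res.total_inertia == pytest.approx(1.0, abs=1e-10)
        if len(res.principal_inertias) > 1:
            assert res.principal_inertias[1] == pytest.approx(0.0, abs=1e-10)
        assert np.all(res.variable_sq_correlations.to_numpy() <= 1 + 1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_total_inertia_identity(self, seed):
        """Sum of principal inertias is (J - Q)/Q for any categorical table."""
        r = np.random.default_rng(seed)
        n = int(r.integers(20, 60))
        t = pd.DataFrame(
            {
                "a": r.choice(list("xy"), n),
                "b": r.choice(list("uvw"), n),
                "c": r.choice(list("pq"), n),
            }
        )
        if any(t[c].nunique() < 2 for c in t.columns):
            return
        res = mca(t)
        j = sum(t[c].nunique() for c in t.columns)
        q = t.shape[1]
        assert res.total_inertia == pytest.approx((j - q) / q, abs=1e-10)
        assert np.all(np.diff(res.principal_inertias) <= 1e-10)

    def test_two_variable_mca_matches_ca_oracle(self):
        """For Q=2 the indicator-MCA inertias are (1 ± σ_CA)/2 scaled —
        verified against a brute-force CA of the contingency table."""
        r = np.random.default_rng(7)
        a = r.choice(list("xyz"), 120)
        b = np.where(r.uniform(size=120) < 0.6, a, r.choice(list("xyz"), 120))
        t = pd.DataFrame({"a": a, "b": pd.Series(b).map({"x": "u", "y": "v", "z": "w"})})
        res = mca(t)
        cont = pd.crosstab(t["a"], t["b"]).to_numpy().astype(float)
        sigma_ca = _ca_oracle(cont)
        sigma_ca = sigma_ca[sigma_ca > 1e-10]
        # indicator MCA of two variables has inertias (1 ± σ_CA)/2; the
        # leading ones are (1 + σ)/2 since (1 − σ1)/2 ≤ 1/2 ≤ (1 + σk)/2
        expected = np.sort(
            np.concatenate([(1 + sigma_ca) / 2, (1 - sigma_ca) / 2])
        )[::-1]
        got = np.sort(res.principal_inertias)[::-1]
        np.testing.assert_allclose(got[: len(sigma_ca)], expected[: len(sigma_ca)], atol=1e-8)

    def test_row_permutation_invariance(self):
        r = np.random.default_rng(3)
        t = pd.DataFrame({"a": r.choice(list("xy"), 40), "b": r.choice(list("uv"), 40)})
        res1 = mca(t)
        perm = r.permutation(40)
        res2 = mca(t.iloc[perm].reset_index(drop=True))
        np.testing.assert_allclose(
            res1.principal_inertias, res2.principal_inertias, atol=1e-10
        )
        np.testing.assert_allclose(
            np.abs(res1.individual_coordinates[perm]),
            np.abs(res2.individual_coordinates),
            atol=1e-8,
        )

    def test_constant_variable_dropped_with_warning(self):
        t = pd.DataFrame(
            {"a": ["x", "y"] * 6, "b": ["u", "v"] * 6, "const": ["TP"] * 12}
        )
        with pytest.warns(UserWarning, match="constant"):
            res = mca(t)
        assert res.dropped_variables == ["const"]
        assert "const" not in res.variable_sq_correlations.index

    def test_single_variable_rejected(self):
        with pytest.raises(ValueError):
            mca(pd.DataFrame({"a": ["x", "y"] * 5}))


class TestScenarioReproduction:
    def test_system_early_by_three_seconds(self, rng):
        """System events 3 s ± noise ahead of human review: the delta
        distribution concentrates near −3 and lead is reported positive."""
        all_deltas = []
        for vid in range(10):
            human_times = np.sort(rng.uniform(30, 600, 5))
            system_times = human_times - 3.0 + rng.normal(0, 0.5, 5)
            m = match_events(
                EventLog("system", list(system_times), video_id=f"v{vid}"),
                EventLog("human", list(human_times), video_id=f"v{vid}"),
            )
            assert m.tp == 5
            all_deltas.extend(m.deltas)
        med, iqr = delta_stats(all_deltas)
        assert med == pytest.approx(-3.0, abs=0.5)
        grid, dens = kde_density(all_deltas)
        assert grid[np.argmax(dens)] == pytest.approx(-3.0, abs=1.0)

    def test_concordant_detection_gives_constant_outcome(self):
        """When system and human flag the same events, the outcome variable
        carries no discrimination and MCA drops it as constant."""
        rows = []
        for vid in range(4):
            times = [10.0 + 40 * k for k in range(3)]
            m = match_events(
                EventLog("system", times, video_id=f"v{vid}"),
                EventLog("human", times, video_id=f"v{vid}"),
            )
            rows += [
                {"outcome": o, "video": f"v{vid}", "band": "early" if t < 50 else "late"}
                for t, o in m.outcome_per_event
            ]
        table = pd.DataFrame(rows)
        with pytest.warns(UserWarning, match="constant"):
            res = mca(table)
        assert res.dropped_variables == ["outcome"]


class TestEventLogIO:
    def test_round_trip(self, tmp_path):
        logs = [
            EventLog("system", [4.0, 9.5], video_id="v1"),
            EventLog("human", [5.0], video_id="v1"),
            EventLog("human", [7.0, 8.0], video_id="v2"),
        ]
        write_event_log(logs, tmp_path / "events.csv")
        back = read_event_log(tmp_path / "events.csv")
        by_key = {(lg.video_id, lg.source): lg.events for lg in back}
        assert by_key[("v1", "system")] == [4.0, 9.5]
        assert by_key[("v1", "human")] == [5.0]
        assert by_key[("v2", "human")] == [7.0, 8.0]
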