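"""Aggregation and group statistics against printed-table and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest

from gcdyn.aggregate import (
    angle_histogram,
    compare_groups,
    grand_mean,
    group_summary,
    holm_sidak_adjust,
    per_animal_summary,
    round_half_away,
)


def _table(rows):
    return pd.DataFrame(rows, columns=["genotype", "age_months", "animal_id", "gc_id", "metric_name", "value"])


def test_per_animal_summary_worked_examples():
    t = _table(
        [("c", 2, "a1", i, "len", v) for i, v in enumerate([1.0, 2.0, 3.0])]
        + [("c", 2, "a2", 0, "len", 5.0)]
    )
    s = per_animal_summary(t).set_index("animal_id")
    assert s.loc["a1", "mean"] == pytest.approx(2.0)
    assert s.loc["a1", "sem"] == pytest.approx(1.0 / np.sqrt(3))
    assert s.loc["a1", "n"] == 3
    assert s.loc["a2", "mean"] == 5.0
    assert np.isnan(s.loc["a2", "sem"])


def test_per_animal_summary_matches_brute_force_on_random_table():
    rng = np.random.default_rng(0)
    rows = []
    for a in range(4):
        for g in range(rng.integers(2, 8)):
            for metric in ("len", "vel"):
                rows.append(("c", 2, f"a{a}", g, metric, float(rng.normal())))
    t = _table(rows)
    s = per_animal_summary(t)
    for _, row in s.iterrows():
        vals = [
            v for (_, _, aid, gid, m, v) in t.itertuples(index=False)
            if aid == row["animal_id"] and m == row["metric_name"]
        ]
        assert row["mean"] == pytest.approx(np.mean(vals))
        assert row["sem"] == pytest.approx(np.std(vals, ddof=1) / np.sqrt(len(vals)))


def test_duplicate_and_nonfinite_rows_rejected():
    dup = _table([("c", 2, "a1", 0, "len", 1.0), ("c", 2, "a1", 0, "len", 2.0)])
    with pytest.raises(ValueError, match="duplicate"):
        per_animal_summary(dup)
    bad = _table([("c", 2, "a1", 0, "len", np.inf)])
    with pytest.raises(ValueError, match="finite"):
        per_animal_summary(bad)


def test_grand_mean_unweighted_reproduces_printed_totals():
    # per-animal track lengths and turning angles exactly as printed
    assert grand_mean([29.26, 31.04, 38.31, 33.17, 30.18], decimals=2) == 32.39
    assert grand_mean([-38.34, -44.53, -43.73], decimals=2) == -42.20
    assert grand_mean([7.0]) == 7.0
    with pytest.raises(ValueError):
        grand_mean([])


def test_rounding_is_half_away_from_zero():
    assert round_half_away(0.125, 2) == 0.13
    assert round_half_away(-0.125, 2) == -0.13
    assert round_half_away(2.675, 2) == 2.68


def test_group_summary_totals():
    rows = []
    animal_means = {"a1": 10.0, "a2": 20.0, "a3": 36.0}
    for aid, m in animal_means.items():
        for g in range(3):
            rows.append(("c", 2, aid, g, "len", m + (g - 1) * 2.0))
    s = group_summary(_table(rows)).iloc[0]
    assert s["grand_mean"] == pytest.approx(22.0)  # unweighted over animals
    assert s["n_animals"] == 3
    assert s["n_gcs"] == 9


def test_mann_whitney_exact_enumeration_and_invariances():
    a = [1.0, 2.0, 3.0, 4.0, 5.0]
    b = [10.0, 11.0, 12.0, 13.0, 14.0]
    p = compare_groups(a, b)
    assert p == pytest.approx(2 / 252)  # exhaustive rank enumeration, n=5 vs 5
    assert compare_groups(b, a) == pytest.approx(p)  # label swap
    # invariance under a monotone transform
    assert compare_groups(np.exp(a), np.exp(b)) == pytest.approx(p)
    assert compare_groups([3.0, 3.0, 3.0], [3.0, 3.0]) == 1.0


def test_holm_sidak_closed_form():
    adj = holm_sidak_adjust([0.01, 0.04, 0.2])
    assert adj[0] == pytest.approx(1 - (1 - 0.01) ** 3, abs=1e-10)
    assert adj[0] == pytest.approx(0.0297, abs=1e-4)
    # step-down: later p's adjusted over the remaining family
    assert adj[1] == pytest.approx(max(adj[0], 1 - (1 - 0.04) ** 2), abs=1e-10)


def test_holm_sidak_t_family():
    rng = np.random.default_rng(1)
    a = {"len": rng.normal(10, 1, 20), "vel": rng.normal(1, 0.1, 20)}
    b = {"len": rng.normal(13, 1, 20), "vel": rng.normal(1, 0.1, 20)}
    res = compare_groups(a, b, method="holm_sidak_t")
    assert set(res) == {"len", "vel"}
    assert res["len"] < 0.001
    assert res["vel"] > 0.05
    with pytest.raises(ValueError, match="famil"):
        compare_groups(a, {"len": b["len"]}, method="holm_sidak_t")


def test_angle_histogram_worked_examples():
    h = angle_histogram([-90.0, 90.0, -90.0]).set_index("turning_class")["fraction"]
    assert h["vertical"] == 1.0
    h2 = angle_histogram([0.0, -45.0, 90.0, 180.0]).set_index("turning_class")["fraction"]
    assert h2["horizontal"] == 0.5
    assert h2["diagonal"] == 0.25
    assert h2["vertical"] == 0.25
    assert h2.sum() == pytest.approx(1.0)


def test_horizontally_biased_batch_has_horizontal_modal_class():
    """50 simulated tracks with heading preference 0 deg (kappa=4): the
    modal turning class of the per-track mean angles is horizontal."""
    from gcdyn.synthgc import MotilityParams, simulate_track
    from gcdyn.track import resample_track, track_summary

    angles = []
    for s in range(50):
        p = MotilityParams(
            mean_speed=0.008, heading_pref=0.0, heading_concentration=4.0, seed=700 + s
        )
        t = resample_track(simulate_track(p), 300.0)
        angles.append(track_summary(t).mean_angle)
    h = angle_histogram(angles).set_index("turning_class")["fraction"]
    assert h.idxmax() == "horizontal"
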