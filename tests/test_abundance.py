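import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from uprseq.abundance import (
    build_trajectory,
    build_trajectories,
    call_de,
    compute_q_values,
    mean_relative_abundance,
    overlap_counts,
    replicate_relative_abundance,
)
from uprseq.matrix import Strain, Treatment

from conftest import flat_controls, make_matrix, matrix_from_levels


def test_mean_relative_abundance_arithmetic():
    m = make_matrix({"g": {("none", 0): [9, 10, 11], ("DTT", 15): [18, 20, 22]}})
    rel = mean_relative_abundance(m, Strain.WT, Treatment.DTT, 15, pseudocount=0.01)
    assert rel["g"] == pytest.approx(20.01 / 10.01)


def test_mean_relative_abundance_identity():
    m = make_matrix({"g": {("none", 0): [5, 6, 7], ("DTT", 15): [7, 5, 6]}})
    rel = mean_relative_abundance(m, Strain.WT, Treatment.DTT, 15, pseudocount=0.01)
    assert rel["g"] == pytest.approx(1.0)


def test_pseudocount_rescues_silent_control():
    # control all zero, treated mean 5: (5 + 0.01) / 0.01 = 501
    m = make_matrix({"g": {("none", 0): [0, 0, 0], ("DTT", 15): [5, 5, 5]}})
    rel = mean_relative_abundance(m, Strain.WT, Treatment.DTT, 15, pseudocount=0.01)
    assert rel["g"] == pytest.approx(501.0)
    with pytest.raises(ZeroDivisionError):
        mean_relative_abundance(m, Strain.WT, Treatment.DTT, 15, pseudocount=0.0)


def test_replicate_relative_abundance_powers_of_two():
    m = make_matrix(
        {
            "flat": {("none", 0): [10, 10, 10], ("DTT", 15): [10, 10, 10]},
            "doubling": {("none", 0): [10, 10, 10], ("DTT", 15): [20, 20, 20]},
            "mixed": {("none", 0): [10, 10, 10], ("DTT", 15): [5, 10, 20]},
        }
    )
    log2rel = replicate_relative_abundance(m, Strain.WT, Treatment.DTT, 15, pseudocount=0.0)
    assert np.allclose(log2rel.loc["flat"], [0, 0, 0])
    assert np.allclose(log2rel.loc["doubling"], [1, 1, 1])
    assert np.allclose(log2rel.loc["mixed"], [-1, 0, 1])


@pytest.mark.parametrize(
    "levels, expected_x",
    [
        ((1.0, 2.0, 3.0), (1.0, 1.0, 1.0)),
        ((0.0, 0.0, 0.0), (0.0, 0.0, 0.0)),
        ((2.0, 1.0, 1.0), (2.0, -1.0, 0.0)),
    ],
)
def test_trajectory_adjacent_differences(levels, expected_x):
    m = matrix_from_levels({"g": {"DTT": levels}})
    traj = build_trajectory(m, "g", Strain.WT, Treatment.DTT, pseudocount=0.0)
    assert traj.x == pytest.approx(expected_x)
    assert traj.log2rel == pytest.approx(levels)


def test_trajectory_telescoping_sum():
    rng = np.random.default_rng(3)
    levels = {
        f"g{i}": {"DTT": tuple(rng.normal(0, 2, 3))} for i in range(20)
    }
    m = matrix_from_levels(levels)
    df = build_trajectories(m, Strain.WT, Treatment.DTT)
    total = df[["x1", "x2", "x3"]].sum(axis=1)
    assert np.allclose(total, df["log2rel_60"], atol=1e-9)


def test_relative_abundance_scale_invariance():
    m = make_matrix({"g": {("none", 0): [4, 5, 6], ("DTT", 15): [9, 10, 11]}})
    scaled = make_matrix(
        {"g": {("none", 0): [40, 50, 60], ("DTT", 15): [90, 100, 110]}}
    )
    r1 = mean_relative_abundance(m, Strain.WT, Treatment.DTT, 15, pseudocount=0.0)
    r2 = mean_relative_abundance(scaled, Strain.WT, Treatment.DTT, 15, pseudocount=0.0)
    assert r1["g"] == pytest.approx(r2["g"])


def test_q_value_identical_groups_is_one():
    m = make_matrix(
        {
            "null": {("none", 0): [5, 6, 7], ("DTT", 15): [5, 6, 7]},
            "same": {("none", 0): [3, 3, 3], ("DTT", 15): [3, 3, 3]},
        }
    )
    q = compute_q_values(m, Treatment.DTT, 15)
    assert q["same"] == pytest.approx(1.0)


def test_q_values_control_fdr_under_global_null():
    rng = np.random.default_rng(1)
    n = 2000
    values = {
        f"g{i}": {
            ("none", 0): rng.lognormal(3, 0.2, 3).tolist(),
            ("DTT", 15): rng.lognormal(3, 0.2, 3).tolist(),
        }
        for i in range(n)
    }
    q = compute_q_values(make_matrix(values), Treatment.DTT, 15)
    assert (q < 0.1).mean() <= 0.12


def test_q_values_monotone_in_raw_p():
    rng = np.random.default_rng(2)
    values = {
        f"g{i}": {
            ("none", 0): rng.lognormal(3, 0.2, 3).tolist(),
            ("DTT", 15): rng.lognormal(3 + (i % 5) * 0.3, 0.2, 3).tolist(),
        }
        for i in range(100)
    }
    m = make_matrix(values)
    from uprseq.abundance import welch_ttest

    treated = np.log2(m.condition_values(Strain.WT, Treatment.DTT, 15).to_numpy() + 0.01)
    control = np.log2(m.condition_values(Strain.WT, Treatment.NONE, 0).to_numpy() + 0.01)
    _, p = welch_ttest(treated, control, axis=1)
    q = compute_q_values(m, Treatment.DTT, 15).to_numpy()
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)


@pytest.mark.parametrize(
    "fc, q, expected",
    [(5.0, 0.01, "UP"), (3.0, 0.2, "NS"), (0.4, 0.05, "DOWN"), (1.5, 0.01, "NS"), (0.6, 0.01, "NS")],
)
def test_de_rule(fc, q, expected):
    m = make_matrix({"g": {("none", 0): [1, 1, 1], ("DTT", 15): [fc] * 3}})
    provided = pd.Series({"g": q})
    calls = call_de(m, Treatment.DTT, 15, q_source="provided", provided_q=provided, pseudocount=0.0)
    assert calls.loc[0, "status"] == expected


def test_de_requires_q_when_provided_source():
    m = make_matrix({"g": {("none", 0): [1, 1, 1], ("DTT", 15): [2, 2, 2]}})
    with pytest.raises(ValueError, match="provided"):
        call_de(m, Treatment.DTT, 15, q_source="provided")


def test_overlap_counts_examples():
    out = overlap_counts({"A": {"g1", "g2"}, "B": {"g2", "g3"}})
    counts = dict(zip(out["members"], out["count"]))
    assert counts == {"A": 1, "B": 1, "A|B": 1}
    disjoint = overlap_counts({"A": {"g1"}, "B": {"g2"}})
    assert dict(zip(disjoint["members"], disjoint["count"]))["A|B"] == 0
    same = overlap_counts({"A": {"g1", "g2"}, "B": {"g1", "g2"}})
    assert dict(zip(same["members"], same["count"])) == {"A": 0, "B": 0, "A|B": 2}


@settings(max_examples=50, derandomize=True)
@given(
    st.lists(
        st.sets(st.sampled_from([f"g{i}" for i in range(12)])),
        min_size=2,
        max_size=4,
    )
)
def test_overlap_regions_partition_the_union(sets):
    named = {chr(65 + i): s for i, s in enumerate(sets)}
    out = overlap_counts(named)
    union = set().union(*named.values())
    assert out["count"].sum() == len(union)
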