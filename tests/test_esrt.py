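import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from uprseq.esrt import (
    ReferenceGroup,
    ReferenceGroupSpec,
    candidate_set,
    chi_square_pvalue,
    chi_square_statistic,
    classify_all,
    fit_reference_group,
)
from uprseq.matrix import Strain, Treatment

from conftest import matrix_from_levels


def _x_to_levels(x):
    return tuple(np.cumsum(x))


def _de_frame(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "treatment", "timepoint_min", "status"]
    ).assign(strain="WT", fold_change=np.nan, q_value=np.nan)


def test_fit_reference_group_hand_case():
    # refs with x = (1,1,1) and (3,3,3): mu = (2,2,2), nu = (2,2,2) at n-1 = 1
    m = matrix_from_levels(
        {"r1": {"DTT": _x_to_levels([1, 1, 1])}, "r2": {"DTT": _x_to_levels([3, 3, 3])}}
    )
    spec = ReferenceGroupSpec("B", Treatment.DTT, ("r1", "r2"), 0.1)
    group = fit_reference_group(m, spec, pseudocount=0.0)
    assert group.mu == pytest.approx((2, 2, 2))
    assert group.nu == pytest.approx((2, 2, 2))


def test_fit_rejects_degenerate_reference_variance():
    # x-vectors (1,0,0), (2,0,0), (3,0,0): nu_2 = nu_3 = 0
    m = matrix_from_levels(
        {
            "r1": {"DTT": _x_to_levels([1, 0, 0])},
            "r2": {"DTT": _x_to_levels([2, 0, 0])},
            "r3": {"DTT": _x_to_levels([3, 0, 0])},
        }
    )
    spec = ReferenceGroupSpec("A", Treatment.DTT, ("r1", "r2", "r3"), 0.1)
    with pytest.raises(ValueError, match="nu_2"):
        fit_reference_group(m, spec, pseudocount=0.0)


def test_fit_requires_two_references():
    with pytest.raises(ValueError, match=">=2 reference genes"):
        ReferenceGroupSpec("A", Treatment.DTT, ("only",), 0.1)


def test_fit_missing_reference_is_named():
    m = matrix_from_levels({"r1": {"DTT": (1, 2, 3)}})
    spec = ReferenceGroupSpec("A", Treatment.DTT, ("r1", "ghost"), 0.1)
    with pytest.raises(KeyError, match="ghost"):
        fit_reference_group(m, spec, pseudocount=0.0)


def test_fit_is_invariant_to_reference_order():
    m = matrix_from_levels(
        {
            "r1": {"DTT": (0.5, 1.0, 1.5)},
            "r2": {"DTT": (1.0, 2.0, 3.0)},
            "r3": {"DTT": (1.5, 2.5, 4.0)},
        }
    )
    a = fit_reference_group(
        m, ReferenceGroupSpec("A", Treatment.DTT, ("r1", "r2", "r3"), 0.1), pseudocount=0.0
    )
    b = fit_reference_group(
        m, ReferenceGroupSpec("A", Treatment.DTT, ("r3", "r1", "r2"), 0.1), pseudocount=0.0
    )
    assert a.mu == pytest.approx(b.mu)
    assert a.nu == pytest.approx(b.nu)


def test_chi_square_statistic_cases():
    assert chi_square_statistic([2, 2, 2], [2, 2, 2], [1, 1, 1]) == 0.0
    assert chi_square_statistic([3, 2, 2], [2, 2, 2], [2, 2, 2]) == pytest.approx(0.5)
    assert chi_square_statistic([0, 0, 0], [1, 1, 1], [1, 1, 1]) == pytest.approx(3.0)
    with pytest.raises(ValueError):
        chi_square_statistic([1, 1, 1], [0, 0, 0], [1, 0, 1])


def test_chi_square_statistic_matches_literal_loop():
    rng = np.random.default_rng(5)
    for _ in range(1000):
        x, mu = rng.normal(size=3), rng.normal(size=3)
        nu = rng.uniform(0.1, 5, size=3)
        expected = sum((x[i] - mu[i]) ** 2 / nu[i] for i in range(3))
        got = chi_square_statistic(x, mu, nu)
        assert got == pytest.approx(expected, rel=1e-12)


def test_chi_square_pvalue_against_density_integral():
    # density of chi-square with 3 df: sqrt(x) exp(-x/2) / sqrt(2 pi)
    def density(x):
        return np.sqrt(x) * np.exp(-x / 2) / np.sqrt(2 * np.pi)

    for stat in (0.5, 2.0, 6.2514, 11.34):
        expected, _ = integrate.quad(density, stat, np.inf)
        assert chi_square_pvalue(stat) == pytest.approx(expected, abs=1e-8)
    assert chi_square_pvalue(6.2514) == pytest.approx(0.100, abs=5e-4)
    assert chi_square_pvalue(0.0) == 1.0
    assert chi_square_pvalue(1e6) < 1e-12
    with pytest.raises(ValueError):
        chi_square_pvalue(-1.0)


def test_large_p_selects_reference_like_trajectories():
    stats = np.linspace(0, 20, 50)
    p = chi_square_pvalue(stats)
    assert np.all(np.diff(p) < 0)


def test_moving_x1_away_from_mu_never_raises_p():
    mu, nu = np.array([1.0, 0.5, 0.2]), np.array([0.3, 0.3, 0.3])
    deltas = np.linspace(0, 4, 30)
    p = [
        chi_square_pvalue(chi_square_statistic([mu[0] + d, 0.7, 0.1], mu, nu))
        for d in deltas
    ]
    assert np.all(np.diff(p) <= 1e-15)


def test_candidate_set_rules():
    de = _de_frame(
        [
            ("up30dtt", "DTT", 30, "UP"),
            ("up30dtt", "TM", 30, "NS"),
            ("uptm", "TM", 60, "UP"),
            ("never", "DTT", 15, "NS"),
            ("never", "TM", 15, "NS"),
        ]
    )
    assert candidate_set(de, Treatment.DTT) == {"up30dtt"}
    assert candidate_set(de, Treatment.TM) == {"uptm"}


def test_classify_identity_and_fold_change_gate():
    # gene1's trajectory equals group mu exactly -> chi2 = 0, P = 1;
    # gene2 matches a low-induction archetype whose 15-min fold change (2^1.2)
    # fails the >4 gate.
    mu_hi = (2.5, -1.0, -0.5)
    mu_lo = (1.2, -0.5, -0.2)
    m = matrix_from_levels(
        {
            "gene1": {"DTT": _x_to_levels(mu_hi)},
            "gene2": {"DTT": _x_to_levels(mu_lo)},
            "r1": {"DTT": _x_to_levels(np.add(mu_hi, 0.3))},
            "r2": {"DTT": _x_to_levels(np.subtract(mu_hi, 0.3))},
        }
    )
    de = _de_frame(
        [(g, "DTT", 15, "UP") for g in ("gene1", "gene2", "r1", "r2")]
    )
    spec = ReferenceGroupSpec("A", Treatment.DTT, ("r1", "r2"), 0.1, min_fc15=4.0, ttest_timepoint=15)
    hi = ReferenceGroup(spec, mu_hi, (0.2, 0.2, 0.2))
    lo = ReferenceGroup(spec, mu_lo, (0.2, 0.2, 0.2))

    calls = classify_all(m, {"A": hi}, de, pseudocount=0.0)
    row = calls.set_index("gene_id").loc["gene1"]
    assert row["p_A"] == pytest.approx(1.0)
    assert bool(row["member_A"])

    calls_lo = classify_all(m, {"A": lo}, de, pseudocount=0.0)
    row2 = calls_lo.set_index("gene_id").loc["gene2"]
    assert row2["p_A"] == pytest.approx(1.0)
    assert not bool(row2["member_A"])  # perfect fit but fold change 2^1.2 < 4


def test_reference_genes_are_flagged_members_of_their_group():
    mu = (1.0, 1.0, 1.0)
    m = matrix_from_levels(
        {
            "r1": {"DTT": _x_to_levels(np.add(mu, 0.3))},
            "r2": {"DTT": _x_to_levels(np.subtract(mu, 0.3))},
            "bg": {"DTT": (0.0, 0.0, 0.0)},
        }
    )
    de = _de_frame([("bg", "DTT", 15, "NS"), ("r1", "DTT", 15, "NS"), ("r2", "DTT", 15, "NS")])
    spec = ReferenceGroupSpec("B", Treatment.DTT, ("r1", "r2"), 0.1)
    group = ReferenceGroup(spec, mu, (0.2, 0.2, 0.2))
    calls = classify_all(m, {"B": group}, de, pseudocount=0.0).set_index("gene_id")
    # references stay members (flagged) even when not DE candidates
    assert bool(calls.loc["r1", "member_B"]) and bool(calls.loc["r1", "reference_B"])
    assert not bool(calls.loc["bg", "member_B"])


def test_null_calibration_of_trajectory_test():
    """x ~ N(mu, nu) at known parameters gives uniform upper-tail P."""
    rng = np.random.default_rng(4)
    mu, nu = np.array([1.0, 0.5, 0.2]), np.array([0.4, 0.3, 0.5])
    x = rng.normal(mu, np.sqrt(nu), size=(10000, 3))
    p = chi_square_pvalue(chi_square_statistic(x, mu, nu))
    assert (p > 0.1).mean() == pytest.approx(0.90, abs=0.01)
    assert (p > 0.05).mean() == pytest.approx(0.95, abs=0.008)
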