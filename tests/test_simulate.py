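import numpy as np
import pandas as pd
import pytest

from uprseq.abundance import build_trajectories
from uprseq.esrt import classify_all
from uprseq.matrix import Strain, Treatment
from uprseq.simulate import (
    ARCHETYPE_FLOORS,
    GeneratorConfig,
    REFERENCE_ARCHETYPE,
    generate_activities,
    generate_expression,
    generate_promoters,
    simulate_upr_replicates,
    truth_reference_groups,
)
from uprseq.motifs import scan_promoter, UPRE1, UPRE2


def test_expression_generator_is_deterministic():
    gc = GeneratorConfig(n_genes=100)
    wt1, h1, t1 = generate_expression(gc, 42)
    wt2, h2, t2 = generate_expression(GeneratorConfig(n_genes=100), 42)
    assert wt1.values.equals(wt2.values)
    assert h1.values.equals(h2.values)
    assert t1.equals(t2)
    wt3, _, _ = generate_expression(GeneratorConfig(n_genes=100), 43)
    assert not wt1.values.equals(wt3.values)


def test_design_matches_the_study_layout():
    gc = GeneratorConfig(n_genes=50)
    wt, hac1, _ = generate_expression(gc, 0)
    wt_conditions = {(s.treatment.value, s.timepoint) for s in wt.samples}
    assert wt_conditions == {
        ("none", 0),
        ("DTT", 15), ("DTT", 30), ("DTT", 60),
        ("TM", 15), ("TM", 30), ("TM", 60),
    }
    # the deletion strain was sampled at 15 and 60 min only
    hac1_conditions = {(s.treatment.value, s.timepoint) for s in hac1.samples}
    assert hac1_conditions == {
        ("none", 0), ("DTT", 15), ("DTT", 60), ("TM", 15), ("TM", 60),
    }
    assert all(
        sum(1 for s in wt.samples if s.condition == c) == 3 for c in wt.conditions()
    )


def test_truth_covers_every_gene_and_plants_references():
    gc = GeneratorConfig(n_genes=200)
    wt, _, truth = generate_expression(gc, 5)
    assert list(truth["gene_id"]) == wt.gene_ids
    refs = truth[truth["is_reference"]]
    assert set(refs["gene_id"]) == set(REFERENCE_ARCHETYPE)
    assert not truth["archetype"].isna().any()
    # UBC7 is deliberately Hac1-independent; all other references dependent
    by_gene = truth.set_index("gene_id")
    assert not by_gene.loc["UBC7", "hac1_dependent"]
    assert by_gene.loc["DER1", "hac1_dependent"]


def test_noise_free_limit_reproduces_planted_trajectories():
    gc = GeneratorConfig(n_genes=60, replicate_cv=1e-9, group_sigma2=1e-8)
    wt, _, truth = generate_expression(gc, 3)
    traj = build_trajectories(wt, Strain.WT, Treatment.DTT, pseudocount=0.0)
    planted = truth.set_index("gene_id")
    for gene in wt.gene_ids[:20]:
        for tp in (15, 30, 60):
            assert traj.loc[gene, f"log2rel_{tp}"] == pytest.approx(
                planted.loc[gene, f"log2rel_DTT_{tp}"], abs=1e-5
            )


def test_zero_replicate_noise_members_are_calibrated():
    """With no replicate noise, planted members drawn from N(mu, nu) and
    scored against the true mu/nu have uniform P — the generator and the
    classifier agree on the generative model."""
    gc = GeneratorConfig(
        n_genes=262, replicate_cv=1e-9,
        archetype_fractions={"groupB": 0.6, "flat": 0.4},
    )
    wt, _, truth = generate_expression(gc, 2)
    groups = {"B": truth_reference_groups(gc)["B"]}
    planted = truth[(truth["archetype"] == "groupB") & (~truth["is_reference"])]
    de = pd.DataFrame(
        {
            "gene_id": planted["gene_id"],
            "treatment": "DTT",
            "timepoint_min": 60,
            "status": "UP",
        }
    )
    calls = classify_all(wt, groups, de, pseudocount=0.0).set_index("gene_id")
    p = calls.loc[planted["gene_id"], "p_A" if "p_A" in calls else "p_B"]
    n = len(p)
    assert n == 150
    # group members are drawn conditional on an induction floor, which only
    # trims the far left of the level distribution; P stays near-uniform
    assert (p > 0.1).mean() == pytest.approx(0.9, abs=5 * np.sqrt(0.09 / n))
    assert abs(p.mean() - 0.5) < 0.15


def test_reference_fit_recovers_configured_parameters():
    """Deterministic reference planting: fitted mu within replicate-noise
    error of the archetype means, nu of the right magnitude."""
    from uprseq.esrt import fit_canonical_groups

    gc = GeneratorConfig(n_genes=300)
    wt, _, _ = generate_expression(gc, 9)
    fitted = fit_canonical_groups(wt)
    expected = truth_reference_groups(gc)
    for gid in "ABCD":
        assert np.allclose(fitted[gid].mu, expected[gid].mu, atol=0.8)
        assert np.all(np.asarray(fitted[gid].nu) > 0.1)
        assert np.all(np.asarray(fitted[gid].nu) < 2.5)


def test_archetype_induction_floors_hold():
    gc = GeneratorConfig(n_genes=400)
    _, _, truth = generate_expression(gc, 13)
    for arch, (kind, floor) in ARCHETYPE_FLOORS.items():
        drug = "DTT" if arch in ("groupA", "groupB") else "TM"
        sub = truth[(truth["archetype"] == arch) & (~truth["is_reference"])]
        if kind == "x1":
            vals = sub[f"log2rel_{drug}_15"]
        else:
            vals = sub[f"log2rel_{drug}_60"]
        assert (vals >= floor - 1e-9).all()


def test_hac1_attenuation_applies_to_dependent_genes_only():
    from uprseq.abundance import mean_relative_abundance

    gc = GeneratorConfig(n_genes=120, replicate_cv=1e-9)
    wt, hac1, truth = generate_expression(gc, 8)
    wt_rel = np.log2(mean_relative_abundance(wt, Strain.WT, Treatment.DTT, 60, 0.0))
    mu_rel = np.log2(
        mean_relative_abundance(hac1, Strain.HAC1_DEL, Treatment.DTT, 60, 0.0)
    )
    t = truth.set_index("gene_id")
    dep = t[t["hac1_dependent"] & (t["archetype"] == "groupB")].index
    indep = t[~t["hac1_dependent"] & (t["archetype"] == "groupB")].index
    assert len(dep) > 0
    gap = wt_rel.loc[dep] - mu_rel.loc[dep]
    assert np.allclose(gap, 2.0, atol=1e-5)  # attenuation 4 = 2 log2 units
    if len(indep):
        gap = wt_rel.loc[indep] - mu_rel.loc[indep]
        assert np.allclose(gap, 0.0, atol=1e-5)


def test_baseline_distribution_matches_configuration():
    gc = GeneratorConfig(
        n_genes=5000, archetype_fractions={"flat": 1.0}, plant_references=False
    )
    wt, _, _ = generate_expression(gc, 17)
    t0 = wt.condition_values(Strain.WT, Treatment.NONE, 0).to_numpy()
    log_fpkm = np.log(t0[:, 0])
    n = len(log_fpkm)
    se_mean = gc.base_log_sd / np.sqrt(n)
    assert abs(log_fpkm.mean() - gc.base_log_mean) < 3 * se_mean * 1.1
    se_sd = gc.base_log_sd / np.sqrt(2 * (n - 1))
    assert abs(log_fpkm.std(ddof=1) - gc.base_log_sd) < 3 * se_sd * 1.2


def test_promoter_generator_determinism_and_truth():
    gc = GeneratorConfig(promoter_length=300)
    p1, t1 = generate_promoters(gc, 21, n_promoters=30)
    p2, t2 = generate_promoters(GeneratorConfig(promoter_length=300), 21, n_promoters=30)
    assert p1 == p2 and t1.equals(t2)
    zero = GeneratorConfig(upre1_plant_prob=0.0, upre2_plant_prob=0.0, promoter_length=300)
    _, t0 = generate_promoters(zero, 4, n_promoters=20)
    assert t0.empty


def test_planted_motifs_are_recovered_by_the_scanner():
    gc = GeneratorConfig(promoter_length=400, upre1_plant_prob=1.0, upre2_plant_prob=1.0)
    promoters, truth = generate_promoters(gc, 6, n_promoters=25)
    for row in truth.itertuples(index=False):
        hits = scan_promoter(row.gene_id, promoters[row.gene_id])
        assert any(
            h.motif_id == row.motif_id
            and h.position == row.position
            and h.strand == row.strand
            for h in hits
        ), f"planted {row} not recovered"


def test_activity_generator_zero_noise_and_determinism():
    gc = GeneratorConfig(activity_cv=1e-9, activity_effects=(("a", "b", 0.1, 0.2, 0.0),))
    acts, truth = generate_activities(gc, 1)
    acts2, _ = generate_activities(gc, 1)
    assert acts.equals(acts2)
    from uprseq.interactions import analyze_interactions

    out = analyze_interactions(acts)
    assert out.loc[0, "I"] == pytest.approx(0.0, abs=1e-6)


def test_upr_observation_simulator_null_is_symmetric():
    wt, mut = simulate_upr_replicates(1000, attenuation=1.0, seed=5)
    assert wt.shape == mut.shape == (1000, 3)
    assert abs(wt.mean() - mut.mean()) < 0.05
    wt4, mut4 = simulate_upr_replicates(1000, attenuation=4.0, seed=5)
    assert wt4.mean() - mut4.mean() == pytest.approx(2.0, abs=0.05)


def test_invalid_configurations_rejected():
    with pytest.raises(ValueError, match="sum to 1"):
        GeneratorConfig(archetype_fractions={"flat": 0.5}).validate()
    with pytest.raises(ValueError, match="attenuation"):
        GeneratorConfig(hac1_attenuation=0.5).validate()
    with pytest.raises(ValueError, match="CV"):
        GeneratorConfig(replicate_cv=0.0).validate()
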