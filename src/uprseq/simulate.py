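"""Seeded generators for every input the pipeline consumes, with ground truth.

The expression generator emulates the FPKM matrices of a DTT/TM time-course
experiment downstream of alignment: wild type sampled at 0/15/30/60 min
under each drug, the hac1-del mutant at 0/15/60 min, three biological
replicates per condition, multiplicative log-normal replicate noise, and
planted induction archetypes:

* ``groupA`` — rapid DTT induction peaking at 15 min, then decaying;
* ``groupB`` — gradual DTT induction;
* ``groupC`` — gradual TM induction;
* ``groupD`` — flat until 30 min, induced late at 60 min of TM;
* ``flat`` / ``down`` / ``noisy_up`` — background behaviours.

Reference genes are planted deterministically so that their sample mean and
(n-1) variance of trajectory differences equal the configured mu/nu exactly
(before replicate noise); ordinary group members draw their differences
x_i ~ Normal(mu_i, nu_i) — precisely the model the chi-square classifier
assumes, so its null calibration carries over to planted data.  Genes
flagged Hac1-dependent have their induction divided by the attenuation
factor in the hac1-del matrix.  Generators are pure functions of
(config, seed): same inputs, byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .esrt import CANONICAL_GROUP_SPECS
from .matrix import ExpressionMatrix, SampleDesign, Strain, Treatment
from .motifs import BUILTIN_MOTIFS, Motif, reverse_complement

__all__ = [
    "GeneratorConfig",
    "ARCHETYPES",
    "generate_expression",
    "generate_promoters",
    "generate_activities",
    "write_expression_tsv",
    "write_design_tsv",
]

ARCHETYPES = ("groupA", "groupB", "groupC", "groupD", "flat", "down", "noisy_up")

#: planted log2 relative abundance at 15/30/60 min, per archetype and drug.
#: Group shapes follow the four verbal induction patterns; magnitudes are
#: set so planted genes clear the DE and group-A fold-change gates by a
#: comfortable margin at the default noise (see docs/methods.md).
DEFAULT_TRAJECTORIES: dict[str, dict[str, tuple[float, float, float]]] = {
    "groupA": {"DTT": (3.0, 1.8, 1.2), "TM": (0.0, 0.0, 0.0)},
    "groupB": {"DTT": (0.8, 1.8, 2.8), "TM": (0.0, 0.0, 0.0)},
    "groupC": {"DTT": (0.0, 0.0, 0.0), "TM": (0.8, 1.6, 2.4)},
    "groupD": {"DTT": (0.0, 0.0, 0.0), "TM": (0.0, 0.2, 1.8)},
    "flat": {"DTT": (0.0, 0.0, 0.0), "TM": (0.0, 0.0, 0.0)},
    "down": {"DTT": (-1.2, -1.8, -2.2), "TM": (-1.2, -1.8, -2.2)},
    "noisy_up": {"DTT": (1.4, 1.4, 1.4), "TM": (1.4, 1.4, 1.4)},
}

#: induction floor per group archetype: a draw failing its floor is not a
#: credible instance of the archetype (group genes are, by definition,
#: upregulated genes) and is redrawn.  groupA floors x1 (the 15-min log2
#: induction feeding the fold-change>4 gate); the others floor the 60-min
#: log2 level.
ARCHETYPE_FLOORS: dict[str, tuple[str, float]] = {
    "groupA": ("x1", 2.6),
    "groupB": ("level60", 1.6),
    "groupC": ("level60", 1.6),
    "groupD": ("level60", 1.6),
}

#: group of each canonical reference gene (UBC7 is planted Hac1-INdependent
#: to exercise the curated override path)
REFERENCE_ARCHETYPE = {
    "DER1": "groupA", "HRD1": "groupA", "UBC7": "groupA",
    "KAR2": "groupB", "LHS1": "groupB", "ERO1": "groupB",
    "MPD1": "groupB", "PDI1": "groupB",
    "SEC12": "groupD", "SEC24": "groupD", "SFB3": "groupD", "HRD3": "groupD",
}
# KAR2/ERO1/PDI1 double as group C references: give them the C trajectory under TM
GROUP_C_REFS = ("KAR2", "ERO1", "PDI1")


@dataclass
class GeneratorConfig:
    """Study-design knobs of the synthetic experiment."""

    n_genes: int = 1000
    archetype_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "groupA": 0.05, "groupB": 0.05, "groupC": 0.05, "groupD": 0.05,
            "down": 0.05, "noisy_up": 0.05, "flat": 0.70,
        }
    )
    #: natural-log location/scale of baseline FPKM
    base_log_mean: float = 3.9
    base_log_sd: float = 1.5
    #: multiplicative replicate noise (coefficient of variation)
    replicate_cv: float = 0.20
    n_replicates: int = 3
    trajectories: dict[str, dict[str, tuple[float, float, float]]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_TRAJECTORIES.items()
        }
    )
    #: per-component variance nu_i of planted group trajectories (log2^2).
    #: SD ~0.7 log2 (~1.6-fold) spread among co-regulated reference genes;
    #: must dominate the replicate-noise variance of a measured x-component
    #: (~0.056 at CV 20%, n=3) for trajectory distances to be meaningful.
    group_sigma2: float = 0.5
    #: fold by which Hac1-dependent induction shrinks in hac1-del cells
    hac1_attenuation: float = 4.0
    #: fraction of group genes whose induction is Hac1-dependent
    hac1_dependent_fraction: float = 0.85
    plant_references: bool = True
    # promoter generation
    promoter_length: int = 1000
    base_frequencies: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    upre1_plant_prob: float = 0.3
    upre2_plant_prob: float = 0.3
    # enzyme activities: (gene_a, gene_b, T_A, T_B, true I), deviation units
    activity_effects: tuple[tuple[str, str, float, float, float], ...] = (
        ("usa1", "yet3", 0.30, 0.20, -0.15),
        ("esr1", "usa1", 0.40, 0.30, -0.35),
        ("esr1", "yet3", 0.40, 0.20, 0.00),
    )
    activity_cv: float = 0.05
    activity_replicates: int = 3

    def validate(self) -> None:
        if abs(sum(self.archetype_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("archetype fractions must sum to 1")
        unknown = set(self.archetype_fractions) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")
        if self.replicate_cv <= 0 or self.activity_cv <= 0:
            raise ValueError("CV must be > 0")
        if self.hac1_attenuation < 1:
            raise ValueError("attenuation factor must be >= 1")
        if not np.isclose(sum(self.base_frequencies), 1.0):
            raise ValueError("base frequencies must sum to 1")


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative noise with the requested linear-scale CV."""
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def _centered_offsets(n: int) -> np.ndarray:
    """n values with mean 0 and (n-1)-denominator sample variance exactly 1."""
    c = np.arange(n, dtype=float) - (n - 1) / 2
    return c / c.std(ddof=1)


def _planted_levels(config, rng, archetypes, hac1_dep, gene_ids):
    """log2 relative abundance at 15/30/60 per gene per drug, plus truth x."""
    n = len(gene_ids)
    levels = {t: np.zeros((n, 3)) for t in ("DTT", "TM")}
    sd = np.sqrt(config.group_sigma2)
    ref_members: dict[str, list[int]] = {}
    for i, g in enumerate(gene_ids):
        if g in REFERENCE_ARCHETYPE:
            ref_members.setdefault(REFERENCE_ARCHETYPE[g], []).append(i)
    # deterministic reference planting: sample mean/variance match mu/nu exactly
    for arch, idx in ref_members.items():
        drug = "DTT" if arch in ("groupA", "groupB") else "TM"
        mu_x = np.diff(np.concatenate([[0.0], config.trajectories[arch][drug]]))
        offsets = _centered_offsets(len(idx))
        for j, i in enumerate(idx):
            x = mu_x + sd * offsets[j]
            levels[drug][i] = np.cumsum(x)
    for j, g in enumerate(GROUP_C_REFS):
        if g not in gene_ids:
            continue
        i = gene_ids.index(g)
        mu_x = np.diff(np.concatenate([[0.0], config.trajectories["groupC"]["TM"]]))
        x = mu_x + sd * _centered_offsets(len(GROUP_C_REFS))[j]
        levels["TM"][i] = np.cumsum(x)
    for i, g in enumerate(gene_ids):
        if g in REFERENCE_ARCHETYPE:
            continue
        arch = archetypes[i]
        for drug in ("DTT", "TM"):
            mean_levels = np.asarray(config.trajectories[arch][drug], dtype=float)
            if arch.startswith("group") and np.any(mean_levels != 0):
                mu_x = np.diff(np.concatenate([[0.0], mean_levels]))
                kind, floor = ARCHETYPE_FLOORS[arch]
                for _ in range(1000):
                    x = rng.normal(mu_x, sd)
                    value = x[0] if kind == "x1" else x.sum()
                    if value >= floor:
                        break
                else:  # pragma: no cover - unreachable at sane configs
                    raise RuntimeError(f"cannot satisfy induction floor for {arch}")
                levels[drug][i] = np.cumsum(x)
            else:
                levels[drug][i] = mean_levels
    return levels


def generate_expression(
    config: GeneratorConfig, seed: int
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame]:
    """Synthesize (WT matrix, hac1-del matrix, truth table).

    Replicate FPKM = baseline x 2^(planted log2 trajectory) x log-normal
    noise.  The truth table records each gene's archetype, Hac1 dependence,
    reference status and planted trajectory levels.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    ref_genes = list(REFERENCE_ARCHETYPE) if config.plant_references else []
    n_bg = config.n_genes - len(ref_genes)
    if n_bg < 0:
        raise ValueError("n_genes smaller than the reference gene set")
    counts = {
        a: int(round(f * n_bg)) for a, f in config.archetype_fractions.items()
    }
    # absorb rounding drift into the most abundant archetype
    bulk = max(counts, key=counts.get)
    counts[bulk] += n_bg - sum(counts.values())
    archetypes = ref_genes and [REFERENCE_ARCHETYPE[g] for g in ref_genes] or []
    gene_ids = list(ref_genes)
    k = 0
    for arch in ARCHETYPES:
        for _ in range(counts.get(arch, 0)):
            gene_ids.append(f"G{k:05d}")
            archetypes.append(arch)
            k += 1
    n = len(gene_ids)
    is_ref = np.array([g in REFERENCE_ARCHETYPE for g in gene_ids])
    group_like = np.array([a.startswith("group") for a in archetypes])
    hac1_dep = rng.random(n) < config.hac1_dependent_fraction
    hac1_dep &= group_like | np.array([a == "noisy_up" for a in archetypes])
    # canonical references are Hac1-dependent by construction — except UBC7,
    # planted independent so the curated override path is exercised
    hac1_dep[is_ref] = True
    if "UBC7" in gene_ids:
        hac1_dep[gene_ids.index("UBC7")] = False

    levels = _planted_levels(config, rng, archetypes, hac1_dep, gene_ids)
    base = rng.lognormal(config.base_log_mean, config.base_log_sd, size=n)

    def make_matrix(strain: Strain, timepoints: Sequence[int]) -> ExpressionMatrix:
        samples, cols = [], {}
        atten = np.where(hac1_dep, np.log2(config.hac1_attenuation), 0.0)
        for r in range(1, config.n_replicates + 1):
            sid = f"{strain.value}_t0_r{r}"
            samples.append(SampleDesign(sid, strain, Treatment.NONE, 0, r))
            cols[sid] = base * _lognormal_noise(rng, config.replicate_cv, n)
        for drug, treatment in (("DTT", Treatment.DTT), ("TM", Treatment.TM)):
            for ti, t in enumerate((15, 30, 60)):
                if t not in timepoints:
                    continue
                log2rel = levels[drug][:, ti].copy()
                if strain is Strain.HAC1_DEL:
                    log2rel = log2rel - atten
                for r in range(1, config.n_replicates + 1):
                    sid = f"{strain.value}_{drug}_t{t}_r{r}"
                    samples.append(SampleDesign(sid, strain, treatment, t, r))
                    cols[sid] = (
                        base
                        * np.exp2(log2rel)
                        * _lognormal_noise(rng, config.replicate_cv, n)
                    )
        values = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
        return ExpressionMatrix(values, samples)

    wt = make_matrix(Strain.WT, (15, 30, 60))
    hac1 = make_matrix(Strain.HAC1_DEL, (15, 60))
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "archetype": archetypes,
            "hac1_dependent": hac1_dep,
            "is_reference": is_ref,
        }
    )
    for drug in ("DTT", "TM"):
        for ti, t in enumerate((15, 30, 60)):
            truth[f"log2rel_{drug}_{t}"] = levels[drug][:, ti]
    return wt, hac1, truth


def truth_reference_groups(config: GeneratorConfig):
    """The four induction groups built from the generator's own parameters.

    mu is the adjacent-timepoint difference of the archetype's planted
    trajectory and nu the configured planted spread — the exact parameters
    under which planted members' x-vectors were drawn, so classification
    against these groups inherits the chi-square test's uniform-P
    calibration (recall ~ 1 - p_threshold).  Fitting from the planted
    reference genes instead re-estimates mu/nu from 3-5 noisy trajectories
    and is substantially more variable (see docs/methods.md).
    """
    from .esrt import ReferenceGroup

    groups = {}
    arch_of = {"A": "groupA", "B": "groupB", "C": "groupC", "D": "groupD"}
    for spec in CANONICAL_GROUP_SPECS:
        levels = np.asarray(config.trajectories[arch_of[spec.group_id]][spec.treatment.value])
        mu = np.diff(np.concatenate([[0.0], levels]))
        nu = np.full(3, config.group_sigma2)
        groups[spec.group_id] = ReferenceGroup(spec, tuple(mu), tuple(nu))
    return groups


def simulate_upr_replicates(
    n_genes: int,
    attenuation: float,
    cv: float = 0.20,
    n_replicates: int = 3,
    seed: int = 0,
    wt_level: float = 2.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Replicate-level log2 relative abundances for a WT vs hac1-del comparison.

    Each gene's WT replicates scatter around a planted log2 induction
    ``wt_level`` with multiplicative log-normal noise of the given CV; the
    hac1-del replicates scatter around ``wt_level - log2(attenuation)``.
    ``attenuation=1`` is the null: both strains draw i.i.d. from the same
    distribution.  Returns (wt, hac1) arrays of shape (n_genes, n_replicates).
    """
    rng = np.random.default_rng(seed)
    wt = wt_level + np.log2(_lognormal_noise(rng, cv, (n_genes, n_replicates)))
    mut = (wt_level - np.log2(attenuation)) + np.log2(
        _lognormal_noise(rng, cv, (n_genes, n_replicates))
    )
    return wt, mut


def _sample_concrete(motif: Motif, rng: np.random.Generator) -> str:
    return "".join(rng.choice(sorted(s)) for s in motif.sets)


def generate_promoters(
    config: GeneratorConfig,
    seed: int,
    gene_ids: Sequence[str] | None = None,
    n_promoters: int = 100,
) -> tuple[dict[str, str], pd.DataFrame]:
    """I.i.d.-background promoters with optionally planted UPRE motifs.

    Planted sites are concrete 7-mers drawn uniformly per position from the
    consensus match sets, written at non-overlapping uniform positions on a
    uniform random strand; the truth table records gene, motif, position
    (start-codon-relative) and strand.  Background matches arise by chance
    on top of the plants and are *not* listed in the truth.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"P{k:04d}" for k in range(n_promoters)]
    L = config.promoter_length
    bases = np.array(list("ACGT"))
    plant_probs = {"UPRE1": config.upre1_plant_prob, "UPRE2": config.upre2_plant_prob}
    motifs = {m.motif_id: m for m in BUILTIN_MOTIFS}
    promoters: dict[str, str] = {}
    truth_rows = []
    for gid in gene_ids:
        seq = rng.choice(bases, size=L, p=list(config.base_frequencies))
        occupied: list[tuple[int, int]] = []
        for mid, prob in plant_probs.items():
            if rng.random() >= prob:
                continue
            motif = motifs[mid]
            w = len(motif)
            for _ in range(200):
                start = int(rng.integers(0, L - w + 1))
                if all(start + w <= s or start >= e for s, e in occupied):
                    break
            else:
                raise RuntimeError("motif planting density too high to avoid overlap")
            occupied.append((start, start + w))
            concrete = _sample_concrete(motif, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            insert = concrete if strand == "+" else reverse_complement(concrete)
            seq[start : start + w] = list(insert)
            truth_rows.append(
                {
                    "gene_id": gid,
                    "motif_id": mid,
                    "position": start - L,
                    "strand": strand,
                    "planted_seq": concrete,
                }
            )
        promoters[gid] = "".join(seq)
    truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "motif_id", "position", "strand", "planted_seq"]
    )
    return promoters, truth


def generate_activities(
    config: GeneratorConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate enzyme activities for WT, singles and doubles, plus truth.

    WT mean is 1; single means 1+T; double means 1+T_A+T_B+I (deviation
    convention); replicates carry multiplicative log-normal noise.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    for gene_a, gene_b, t_a, t_b, i_true in config.activity_effects:
        enzyme = f"enzyme_{gene_a}_{gene_b}"
        means = {
            "WT": 1.0,
            gene_a: 1.0 + t_a,
            gene_b: 1.0 + t_b,
            ";".join(sorted((gene_a, gene_b))): 1.0 + t_a + t_b + i_true,
        }
        for genotype, mean in means.items():
            noise = _lognormal_noise(rng, config.activity_cv, config.activity_replicates)
            for r, value in enumerate(mean * noise, start=1):
                rows.append(
                    {
                        "genotype": genotype,
                        "enzyme": enzyme,
                        "replicate": r,
                        "activity": float(value),
                    }
                )
        truth_rows.append(
            {
                "gene_a": min(gene_a, gene_b),
                "gene_b": max(gene_a, gene_b),
                "enzyme": enzyme,
                "T_A": t_a if gene_a < gene_b else t_b,
                "T_B": t_b if gene_a < gene_b else t_a,
                "true_I": i_true,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values.copy()
    df.insert(0, "gene_id", df.index)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_design_tsv(matrix: ExpressionMatrix, path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in matrix.samples],
            "strain": [s.strain.value for s in matrix.samples],
            "treatment": [s.treatment.value for s in matrix.samples],
            "timepoint_min": [s.timepoint for s in matrix.samples],
            "replicate": [s.replicate for s in matrix.samples],
        }
    ).to_csv(path, sep="\t", index=False)
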