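"""Classify induced genes into ER-stress induction groups A-D.

Four induction archetypes are anchored by curated reference genes (classic
UPR targets):

* **A** — rapid induction under DTT, peak at 15 min (refs DER1, HRD1, UBC7);
* **B** — gradual induction under DTT (refs KAR2, LHS1, ERO1, MPD1, PDI1);
* **C** — gradual induction under TM (refs KAR2, ERO1, PDI1);
* **D** — late induction under TM, flat until 60 min (refs SEC12, SEC24,
  SFB3, HRD3).

For each group, the mean mu_i and variance nu_i of the reference genes'
adjacent-timepoint log2 differences x_i are fitted; a candidate gene's fit
to the archetype is scored as

    chi2 = sum_i (x_i - mu_i)^2 / nu_i ,

referred to a central chi-square distribution with 3 degrees of freedom
under the normality assumption on x_i.  Selection is *inverted* relative to
ordinary hypothesis testing: a LARGE upper-tail P (small chi2, i.e. a
trajectory close to the reference pattern) selects the gene.  Groups A and B
use P > 0.1, groups C and D use P > 0.05; group A additionally requires a
linear fold change > 4 at 15 min of DTT.  Candidates are restricted to genes
significantly upregulated at >=1 timepoint of the group's drug.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import DEFAULT_PSEUDOCOUNT, DEStatus, build_trajectories, mean_relative_abundance
from .matrix import ExpressionMatrix, Strain, Treatment

__all__ = [
    "GROUP_IDS",
    "CANONICAL_GROUP_SPECS",
    "ReferenceGroupSpec",
    "ReferenceGroup",
    "fit_reference_group",
    "fit_canonical_groups",
    "chi_square_statistic",
    "chi_square_pvalue",
    "candidate_set",
    "classify_all",
]

GROUP_IDS = ("A", "B", "C", "D")

#: reject reference sets whose spread collapses below this variance
NU_FLOOR = 1e-8

DF = 3  # three adjacent-timepoint differences


@dataclass(frozen=True)
class ReferenceGroupSpec:
    """Configuration of one induction group before fitting."""

    group_id: str
    treatment: Treatment
    reference_genes: tuple[str, ...]
    p_threshold: float
    #: group A only: minimum linear fold change at 15 min of DTT
    min_fc15: float | None = None
    ttest_timepoint: int = 60

    def __post_init__(self) -> None:
        if len(self.reference_genes) < 2:
            raise ValueError(
                f"group {self.group_id}: >=2 reference genes required for a variance"
            )


CANONICAL_GROUP_SPECS: tuple[ReferenceGroupSpec, ...] = (
    ReferenceGroupSpec("A", Treatment.DTT, ("DER1", "HRD1", "UBC7"), 0.1, 4.0, 15),
    ReferenceGroupSpec("B", Treatment.DTT, ("KAR2", "LHS1", "ERO1", "MPD1", "PDI1"), 0.1, None, 60),
    ReferenceGroupSpec("C", Treatment.TM, ("KAR2", "ERO1", "PDI1"), 0.05, None, 60),
    ReferenceGroupSpec("D", Treatment.TM, ("SEC12", "SEC24", "SFB3", "HRD3"), 0.05, None, 60),
)


@dataclass(frozen=True)
class ReferenceGroup:
    """A fitted induction group: spec plus mu/nu of reference trajectories."""

    spec: ReferenceGroupSpec
    mu: tuple[float, float, float]
    nu: tuple[float, float, float]

    @property
    def group_id(self) -> str:
        return self.spec.group_id

    @property
    def treatment(self) -> Treatment:
        return self.spec.treatment


def fit_reference_group(
    matrix: ExpressionMatrix,
    spec: ReferenceGroupSpec,
    strain: Strain = Strain.WT,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ddof: int = 1,
    nu_floor: float = NU_FLOOR,
) -> ReferenceGroup:
    """Fit mu_i / nu_i from the reference genes' x-vectors.

    ``nu`` uses the unbiased (n-1) sample variance by default; with as few
    as three references the denominator choice is material, so it is exposed
    via ``ddof``.  Numerically degenerate references (nu_i <= nu_floor) are
    a configuration error, not an infinite statistic.
    """
    traj = build_trajectories(matrix, strain, spec.treatment, pseudocount)
    missing = [g for g in spec.reference_genes if g not in traj.index]
    if missing:
        raise KeyError(f"group {spec.group_id}: reference gene(s) absent: {missing}")
    x = traj.loc[list(spec.reference_genes), ["x1", "x2", "x3"]].to_numpy()
    mu = x.mean(axis=0)
    nu = x.var(axis=0, ddof=ddof)
    for i, v in enumerate(nu, start=1):
        if v <= nu_floor:
            raise ValueError(
                f"group {spec.group_id}: degenerate reference variance nu_{i}={v:.3g}"
            )
    return ReferenceGroup(spec=spec, mu=tuple(mu), nu=tuple(nu))


def fit_canonical_groups(
    matrix: ExpressionMatrix,
    strain: Strain = Strain.WT,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ddof: int = 1,
    specs: Sequence[ReferenceGroupSpec] = CANONICAL_GROUP_SPECS,
) -> dict[str, ReferenceGroup]:
    return {
        spec.group_id: fit_reference_group(matrix, spec, strain, pseudocount, ddof)
        for spec in specs
    }


def chi_square_statistic(x, mu, nu) -> np.ndarray | float:
    """sum_i (x_i - mu_i)^2 / nu_i over the three trajectory differences.

    Vectorized over leading axes of ``x``; zero iff x == mu.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    nu = np.asarray(nu, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("all nu_i must be positive")
    out = (((x - mu) ** 2) / nu).sum(axis=-1)
    return float(out) if out.ndim == 0 else out


def chi_square_pvalue(stat) -> np.ndarray | float:
    """Upper-tail probability Pr(chi2_3 >= stat).

    P(0) = 1 and P decreases in the statistic, so reference-like
    trajectories (small chi2) receive large P — large P *selects* genes.
    """
    stat = np.asarray(stat, dtype=float)
    if np.any(stat < 0):
        raise ValueError("chi-square statistic must be >= 0")
    out = stats.chi2.sf(stat, DF)
    return float(out) if out.ndim == 0 else out


def candidate_set(
    de_calls: pd.DataFrame,
    treatment: Treatment,
    mode: str = "any",
    timepoints: Iterable[int] = (15, 30, 60),
) -> set[str]:
    """Genes significantly upregulated under the group's drug.

    ``mode='any'`` (default): UP at >=1 of the timepoints; ``'all'``: UP at
    every timepoint present.
    """
    sub = de_calls[
        (de_calls["treatment"] == treatment.value)
        & (de_calls["timepoint_min"].isin(list(timepoints)))
    ]
    if sub.empty:
        raise ValueError(f"no DE calls for treatment {treatment.value}")
    up = sub[sub["status"] == DEStatus.UP.value]
    if mode == "any":
        return set(up["gene_id"])
    if mode == "all":
        need = sub["timepoint_min"].nunique()
        counts = up.groupby("gene_id")["timepoint_min"].nunique()
        return set(counts[counts == need].index)
    raise ValueError(f"unknown candidate mode {mode!r}")


def classify_all(
    matrix: ExpressionMatrix,
    groups: Mapping[str, ReferenceGroup],
    de_calls: pd.DataFrame,
    strain: Strain = Strain.WT,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    candidate_mode: str = "any",
) -> pd.DataFrame:
    """Score and classify every gene against every fitted group.

    Returns one row per gene with, per group g: ``chi2_g``, ``p_g``,
    ``candidate_g``, ``reference_g`` and ``member_g``; plus ``is_esrt``
    (member of >=1 group) and a ``groups`` label.  Reference genes are
    scored against their own full-group mu/nu (no leave-one-out), are always
    reported as members of their group and are flagged so the forced
    membership is auditable.  A BH-adjusted column per group is emitted for
    information only; selection thresholds apply to raw P, as large-P
    selection has no standard multiplicity correction.
    """
    from statsmodels.stats.multitest import multipletests

    genes = matrix.gene_ids
    out = pd.DataFrame({"gene_id": genes})
    trajectories = {
        t: build_trajectories(matrix, strain, t, pseudocount)
        for t in {g.treatment for g in groups.values()}
    }
    fc15_dtt = None
    member_any = np.zeros(len(genes), dtype=bool)
    labels = [[] for _ in genes]
    for gid in sorted(groups):
        group = groups[gid]
        traj = trajectories[group.treatment]
        x = traj.loc[genes, ["x1", "x2", "x3"]].to_numpy()
        chi2 = chi_square_statistic(x, group.mu, group.nu)
        p = chi_square_pvalue(chi2)
        cand_ids = candidate_set(de_calls, group.treatment, candidate_mode)
        candidate = np.array([g in cand_ids for g in genes])
        member = candidate & (p > group.spec.p_threshold)
        if group.spec.min_fc15 is not None:
            if fc15_dtt is None:
                fc15_dtt = mean_relative_abundance(
                    matrix, strain, Treatment.DTT, 15, pseudocount
                )
            member &= fc15_dtt.loc[genes].to_numpy() > group.spec.min_fc15
        reference = np.array([g in group.spec.reference_genes for g in genes])
        member |= reference
        out[f"chi2_{gid}"] = chi2
        out[f"p_{gid}"] = p
        # informational only; membership thresholds raw P
        out[f"p_adj_{gid}"] = multipletests(p, method="fdr_bh")[1]
        out[f"candidate_{gid}"] = candidate
        out[f"reference_{gid}"] = reference
        out[f"member_{gid}"] = member
        member_any |= member
        for i, m in enumerate(member):
            if m:
                labels[i].append(gid)
    out["is_esrt"] = member_any
    out["groups"] = ["|".join(l) for l in labels]
    return out
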