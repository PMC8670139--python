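"""Relative transcript abundance, log2 trajectories, DE calling and Venn counts.

Relative transcript abundance of a gene is its (replicate-averaged) FPKM in
drug-treated cells divided by its FPKM in untreated cells of the same
strain; the 0-min sample is the shared control for both DTT and TM series.
A small pseudocount keeps ratios finite for silent genes.  Trajectories are
summarized by the three adjacent-timepoint differences of log2 relative
abundance, x1 = log2rel(15) - 0, x2 = log2rel(30) - log2rel(15),
x3 = log2rel(60) - log2rel(30), which telescope to log2rel(60).
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix, MatrixValidationError, Strain, Treatment

__all__ = [
    "DEFAULT_PSEUDOCOUNT",
    "Trajectory",
    "DEStatus",
    "mean_relative_abundance",
    "replicate_relative_abundance",
    "build_trajectory",
    "build_trajectories",
    "compute_q_values",
    "call_de",
    "overlap_counts",
]

#: additive FPKM constant applied to numerator and denominator of every ratio
DEFAULT_PSEUDOCOUNT = 0.01

TREATED_TIMEPOINTS = (15, 30, 60)


class DEStatus(str, enum.Enum):
    UP = "UP"
    DOWN = "DOWN"
    NS = "NS"


@dataclass(frozen=True)
class Trajectory:
    """Per-gene induction trajectory under one drug.

    ``rel`` holds linear relative abundances at 15/30/60 min, ``log2rel``
    their log2, and ``x`` the three adjacent-timepoint differences (the
    implicit value at t=0 is log2rel = 0: each gene is scaled to its own
    untreated level).
    """

    gene_id: str
    strain: Strain
    treatment: Treatment
    rel: tuple[float, float, float]
    log2rel: tuple[float, float, float]
    x: tuple[float, float, float]


def _mean_control(matrix: ExpressionMatrix, strain: Strain) -> pd.Series:
    return matrix.condition_values(strain, Treatment.NONE, 0).mean(axis=1)


def mean_relative_abundance(
    matrix: ExpressionMatrix,
    strain: Strain,
    treatment: Treatment,
    timepoint: int,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.Series:
    """Linear induction ratio per gene: (mean treated FPKM + eps) / (mean t0 FPKM + eps)."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    treated = matrix.condition_values(strain, treatment, timepoint).mean(axis=1)
    control = _mean_control(matrix, strain)
    denom = control + pseudocount
    if pseudocount == 0 and (denom == 0).any():
        gene = denom.index[(denom == 0).to_numpy()][0]
        raise ZeroDivisionError(
            f"gene {gene!r} has zero control FPKM and pseudocount=0"
        )
    out = (treated + pseudocount) / denom
    out.name = f"rel_{treatment.value}_{timepoint}"
    return out


def replicate_relative_abundance(
    matrix: ExpressionMatrix,
    strain: Strain,
    treatment: Treatment,
    timepoint: int,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-replicate log2 induction: log2((FPKM_r + eps) / (mean t0 FPKM + eps)).

    Replicates are unpaired biological cultures, so each treated replicate is
    divided by the *mean* of the untreated replicates rather than paired.
    This gives the strain-comparison t-test its per-replicate observations;
    the mean of 2**value approximates mean_relative_abundance (exact when
    replicates are equal).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    treated = matrix.condition_values(strain, treatment, timepoint)
    denom = _mean_control(matrix, strain) + pseudocount
    if (denom == 0).any():
        gene = denom.index[(denom == 0).to_numpy()][0]
        raise ZeroDivisionError(
            f"gene {gene!r} has zero control FPKM and pseudocount=0"
        )
    return np.log2(treated.add(pseudocount).div(denom, axis=0))


def build_trajectories(
    matrix: ExpressionMatrix,
    strain: Strain,
    treatment: Treatment,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """All genes' trajectories under one drug as a frame.

    Columns: rel_15/30/60, log2rel_15/30/60, x1, x2, x3.  x-columns are the
    adjacent-timepoint differences fed to the chi-square classifier.
    """
    rel = {
        t: mean_relative_abundance(matrix, strain, treatment, t, pseudocount)
        for t in TREATED_TIMEPOINTS
    }
    df = pd.DataFrame(
        {f"rel_{t}": rel[t] for t in TREATED_TIMEPOINTS}
        | {f"log2rel_{t}": np.log2(rel[t]) for t in TREATED_TIMEPOINTS}
    )
    df["x1"] = df["log2rel_15"]
    df["x2"] = df["log2rel_30"] - df["log2rel_15"]
    df["x3"] = df["log2rel_60"] - df["log2rel_30"]
    return df


def build_trajectory(
    matrix: ExpressionMatrix,
    gene_id: str,
    strain: Strain,
    treatment: Treatment,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> Trajectory:
    if gene_id not in matrix.values.index:
        raise KeyError(gene_id)
    df = build_trajectories(matrix, strain, treatment, pseudocount)
    row = df.loc[gene_id]
    return Trajectory(
        gene_id=gene_id,
        strain=strain,
        treatment=treatment,
        rel=tuple(row[[f"rel_{t}" for t in TREATED_TIMEPOINTS]]),
        log2rel=tuple(row[[f"log2rel_{t}" for t in TREATED_TIMEPOINTS]]),
        x=tuple(row[["x1", "x2", "x3"]]),
    )


def welch_ttest(a: np.ndarray, b: np.ndarray, axis: int = -1) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Welch t-test along an axis; degenerate 0/0 cases get p = 1."""
    res = stats.ttest_ind(a, b, axis=axis, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(t)
    t = np.where(bad, 0.0, t)
    p = np.where(bad, 1.0, p)
    return t, p


def compute_q_values(
    matrix: ExpressionMatrix,
    treatment: Treatment,
    timepoint: int,
    strain: Strain = Strain.WT,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.Series:
    """Per-gene BH q-values for treated-vs-untreated differential expression.

    Welch's two-sided t on log2(FPKM + eps), treated replicates against the
    0-min replicates, Benjamini-Hochberg adjusted across all genes.  This is
    a deliberately simple internal engine; externally computed q-values can
    be supplied to :func:`call_de` instead.
    """
    treated = matrix.condition_values(strain, treatment, timepoint)
    control = matrix.condition_values(strain, Treatment.NONE, 0)
    if treated.shape[1] < 2 or control.shape[1] < 2:
        raise MatrixValidationError("q-value computation needs >=2 replicates per condition")
    a = np.log2(treated.to_numpy() + pseudocount)
    b = np.log2(control.to_numpy() + pseudocount)
    _, p = welch_ttest(a, b, axis=1)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.Series(q, index=matrix.values.index, name="q")


def call_de(
    matrix: ExpressionMatrix,
    treatment: Treatment,
    timepoint: int,
    strain: Strain = Strain.WT,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    q_max: float = 0.1,
    q_source: str = "internal",
    provided_q: pd.Series | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Call UP / DOWN / NS per gene at one condition.

    UP requires linear fold change > ``fc_up`` and q < ``q_max``; DOWN
    requires fold change < ``fc_down`` and q < ``q_max`` (defaults 2 / 0.5 /
    0.1).  Fold change is the replicate-averaged linear relative abundance.
    """
    fc = mean_relative_abundance(matrix, strain, treatment, timepoint, pseudocount)
    if q_source == "internal":
        q = compute_q_values(matrix, treatment, timepoint, strain, pseudocount)
    elif q_source == "provided":
        if provided_q is None:
            raise ValueError("q_source='provided' but no q values supplied")
        q = provided_q.reindex(fc.index)
        if q.isna().any():
            gene = q.index[q.isna()][0]
            raise MatrixValidationError(f"no provided q-value for gene {gene!r}")
    else:
        raise ValueError(f"unknown q_source {q_source!r}")
    status = np.where(
        (fc > fc_up) & (q < q_max),
        DEStatus.UP.value,
        np.where((fc < fc_down) & (q < q_max), DEStatus.DOWN.value, DEStatus.NS.value),
    )
    return pd.DataFrame(
        {
            "gene_id": fc.index,
            "strain": strain.value,
            "treatment": treatment.value,
            "timepoint_min": timepoint,
            "fold_change": fc.to_numpy(),
            "q_value": q.to_numpy(),
            "status": status,
        }
    ).reset_index(drop=True)


def overlap_counts(sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Exact Venn-region cardinalities for >=2 named gene-ID sets.

    One row per non-empty membership pattern; ``members`` is a
    ``|``-joined sorted list of the set names defining the region.  Region
    counts sum to the size of the union.
    """
    named = {k: set(v) for k, v in sets.items()}
    if len(named) < 2:
        raise ValueError("need at least two sets")
    names = sorted(named)
    rows = []
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(named[n] for n in combo))
            outside = set.union(set(), *(named[n] for n in names if n not in combo))
            rows.append({"members": "|".join(combo), "count": len(inside - outside)})
    return pd.DataFrame(rows)
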