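"""Genetic-interaction (epistasis) scores from enzyme-activity replicates.

A mutant's trait value T is its mean extracellular enzyme activity relative
to wild type; the interaction of two deletions is I = T_AB - T_A - T_B.
Two trait conventions are supported:

* ``relative`` — T = mean(mutant)/mean(WT), the formula read literally;
* ``deviation`` (default) — T = mean(mutant)/mean(WT) - 1.

Only the deviation convention makes "near zero = additive" internally
consistent for modest effects: two no-effect single mutants with a
no-effect double give I = 0 under deviation but I = -1 under raw relative.
Values within a tolerance tau of zero are additive; below -tau negative;
above +tau positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ActivityRecord",
    "InteractionResult",
    "DEFAULT_TAU",
    "trait_value",
    "interaction_value",
    "classify_interaction",
    "bootstrap_interaction",
    "analyze_interactions",
    "read_activity_table",
]

DEFAULT_TAU = 0.1
CONVENTIONS = ("relative", "deviation")


@dataclass(frozen=True)
class ActivityRecord:
    """Replicate activities (U/mL or WT-normalized units) of one genotype."""

    genotype: frozenset[str]  # deleted genes; empty set = wild type
    enzyme: str
    activities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.activities) < 2:
            raise ValueError(f"genotype {set(self.genotype) or 'WT'}: >=2 replicates required")
        if any(a <= 0 for a in self.activities):
            raise ValueError(f"genotype {set(self.genotype) or 'WT'}: activities must be > 0")

    @property
    def mean(self) -> float:
        return float(np.mean(self.activities))


@dataclass(frozen=True)
class InteractionResult:
    gene_a: str
    gene_b: str
    enzyme: str
    T_A: float
    T_B: float
    T_AB: float
    I: float
    label: str
    convention: str
    ci_low: float | None = None
    ci_high: float | None = None


def trait_value(
    mutant: ActivityRecord, wildtype: ActivityRecord, convention: str = "deviation"
) -> float:
    """Relative activity of a mutant, optionally centred at zero (deviation)."""
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    if wildtype.mean <= 0:
        raise ValueError("wild-type mean activity must be > 0")
    ratio = mutant.mean / wildtype.mean
    return ratio - 1.0 if convention == "deviation" else ratio


def interaction_value(t_a: float, t_b: float, t_ab: float) -> float:
    """I = T_AB - T_A - T_B; grouped as T_AB - (T_A + T_B) so the value is
    bitwise symmetric in (A, B)."""
    return t_ab - (t_a + t_b)


def classify_interaction(i: float, tau: float = DEFAULT_TAU) -> str:
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if abs(i) <= tau:
        return "additive"
    return "negative" if i < 0 else "positive"


def bootstrap_interaction(
    wildtype: ActivityRecord,
    single_a: ActivityRecord,
    single_b: ActivityRecord,
    double_ab: ActivityRecord,
    convention: str = "deviation",
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap interval on I, resampling replicates with replacement."""
    rng = np.random.default_rng(seed)
    samples = np.empty(n_boot)
    arrs = [np.asarray(r.activities) for r in (wildtype, single_a, single_b, double_ab)]
    for k in range(n_boot):
        w, a, b, ab = (arr[rng.integers(0, len(arr), len(arr))].mean() for arr in arrs)
        if convention == "deviation":
            ta, tb, tab = a / w - 1, b / w - 1, ab / w - 1
        else:
            ta, tb, tab = a / w, b / w, ab / w
        samples[k] = tab - ta - tb
    lo, hi = np.quantile(samples, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def read_activity_table(path) -> pd.DataFrame:
    """Tidy activities TSV: genotype (``;``-joined deletions or ``WT``), enzyme, replicate, activity."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"genotype", "enzyme", "replicate", "activity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"activity table missing columns: {sorted(missing)}")
    return df


def _records_from_frame(df: pd.DataFrame, enzyme: str) -> dict[frozenset[str], ActivityRecord]:
    out = {}
    for genotype, sub in df[df["enzyme"] == enzyme].groupby("genotype"):
        genes = frozenset() if genotype == "WT" else frozenset(str(genotype).split(";"))
        out[genes] = ActivityRecord(genes, enzyme, tuple(sub["activity"].astype(float)))
    return out


def analyze_interactions(
    activities: pd.DataFrame,
    convention: str = "deviation",
    tau: float = DEFAULT_TAU,
    bootstrap: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every double mutant present against its singles and wild type.

    The table must contain, per enzyme, a WT genotype, both singles and the
    double for every pair scored.  With ``bootstrap > 0`` a percentile CI on
    I is added.
    """
    rows = []
    for enzyme in sorted(activities["enzyme"].unique()):
        records = _records_from_frame(activities, enzyme)
        wt = records.get(frozenset())
        if wt is None:
            raise ValueError(f"enzyme {enzyme!r}: wild-type genotype missing")
        doubles = sorted(
            (g for g in records if len(g) == 2), key=lambda g: tuple(sorted(g))
        )
        for pair in doubles:
            a, b = sorted(pair)
            for single in (a, b):
                if frozenset({single}) not in records:
                    raise ValueError(f"enzyme {enzyme!r}: single mutant {single!r} missing")
            t_a = trait_value(records[frozenset({a})], wt, convention)
            t_b = trait_value(records[frozenset({b})], wt, convention)
            t_ab = trait_value(records[pair], wt, convention)
            i = interaction_value(t_a, t_b, t_ab)
            row = {
                "gene_a": a,
                "gene_b": b,
                "enzyme": enzyme,
                "T_A": t_a,
                "T_B": t_b,
                "T_AB": t_ab,
                "I": i,
                "label": classify_interaction(i, tau),
                "convention": convention,
            }
            if bootstrap:
                lo, hi = bootstrap_interaction(
                    wt, records[frozenset({a})], records[frozenset({b})], records[pair],
                    convention, bootstrap, seed,
                )
                row["ci_low"], row["ci_high"] = lo, hi
            rows.append(row)
    return pd.DataFrame(rows)
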