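import numpy as np
import pandas as pd
import pytest

from uprseq.matrix import ExpressionMatrix, SampleDesign, Strain, Treatment


def make_matrix(values, strain=Strain.WT):
    """Build an ExpressionMatrix from {gene: {(treatment, timepoint): [reps...]}}.

    Every gene must define the same conditions with the same replicate count.
    """
    genes = list(values)
    conds = sorted(values[genes[0]], key=lambda c: (c[0], c[1]))
    samples, cols = [], {}
    for tr, tp in conds:
        n_reps = len(values[genes[0]][(tr, tp)])
        for r in range(1, n_reps + 1):
            sid = f"{strain.value}_{tr}_{tp}_r{r}"
            samples.append(SampleDesign(sid, strain, Treatment(tr), tp, r))
            cols[sid] = [float(values[g][(tr, tp)][r - 1]) for g in genes]
    df = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    return ExpressionMatrix(df, samples)


def flat_controls(n_reps=3, value=1.0):
    return {("none", 0): [value] * n_reps}


def matrix_from_levels(levels, n_reps=3, base=1.0, strain=Strain.WT):
    """Noise-free matrix from per-gene log2 relative levels at 15/30/60.

    ``levels`` maps gene -> {treatment: (l15, l30, l60)}; every replicate of
    a condition takes the exact deterministic value base * 2**level.
    """
    values = {}
    for gene, per_drug in levels.items():
        conds = dict(flat_controls(n_reps, base))
        for drug, (l15, l30, l60) in per_drug.items():
            for tp, lev in zip((15, 30, 60), (l15, l30, l60)):
                conds[(drug, tp)] = [base * 2.0**lev] * n_reps
        values[gene] = conds
    return make_matrix(values, strain)


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic experiment shared by pipeline-level tests."""
    from uprseq.simulate import GeneratorConfig, generate_expression

    n_bg = 300
    config = GeneratorConfig(
        n_genes=312,
        archetype_fractions={
            "groupA": 25 / n_bg, "groupB": 25 / n_bg, "groupC": 25 / n_bg,
            "groupD": 25 / n_bg, "flat": 200 / n_bg,
        },
    )
    wt, hac1, truth = generate_expression(config, seed=11)
    return config, wt, hac1, truth
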