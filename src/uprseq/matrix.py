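"""Expression matrices, sample designs and provenance-stamped result tables.

The pipeline consumes gene x sample FPKM tables (plain TSV, first column
``gene_id``) together with a five-column sample design TSV
(``sample_id  strain  treatment  timepoint_min  replicate``).  Values are
relative transcript abundances *upstream* of this package (FPKM); anything
downstream of alignment/quantification is in scope, the quantification
itself is not.
"""

from __future__ import annotations

import enum
import hashlib
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Strain",
    "Treatment",
    "SampleDesign",
    "ExpressionMatrix",
    "ResultTable",
    "read_expression_table",
    "read_design_table",
    "write_result_table",
    "read_result_table",
    "MatrixValidationError",
]

#: timepoints (minutes after drug addition) of the canonical design
TIMEPOINTS = (0, 15, 30, 60)


class MatrixValidationError(ValueError):
    """Raised when an abundance table or design violates its contract."""


class Strain(str, enum.Enum):
    WT = "WT"
    HAC1_DEL = "hac1"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Treatment(str, enum.Enum):
    NONE = "none"
    DTT = "DTT"
    TM = "TM"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class SampleDesign:
    """One sequencing sample: strain, drug, minutes after addition, replicate."""

    sample_id: str
    strain: Strain
    treatment: Treatment
    timepoint: int
    replicate: int

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise MatrixValidationError(
                f"sample {self.sample_id!r}: timepoint {self.timepoint} not in {TIMEPOINTS}"
            )
        if self.timepoint == 0 and self.treatment is not Treatment.NONE:
            raise MatrixValidationError(
                f"sample {self.sample_id!r}: timepoint 0 is the untreated control "
                f"and must have treatment 'none', got {self.treatment.value!r}"
            )
        if self.timepoint != 0 and self.treatment is Treatment.NONE:
            raise MatrixValidationError(
                f"sample {self.sample_id!r}: treated timepoints require a treatment"
            )
        if self.replicate < 1:
            raise MatrixValidationError(
                f"sample {self.sample_id!r}: replicate must be a positive integer"
            )

    @property
    def condition(self) -> tuple[Strain, Treatment, int]:
        return (self.strain, self.treatment, self.timepoint)


class ExpressionMatrix:
    """Gene x sample abundance matrix bound to a validated sample design.

    Columns of ``values`` are ordered like ``samples``.  All abundances are
    finite and non-negative; missing cells are a load-time error rather than
    something to impute (the procedure has no imputation step).
    """

    def __init__(self, values: pd.DataFrame, samples: Sequence[SampleDesign]):
        samples = list(samples)
        if list(values.columns) != [s.sample_id for s in samples]:
            raise MatrixValidationError("matrix columns must match design sample order")
        if values.index.duplicated().any():
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise MatrixValidationError(f"duplicate gene IDs: {dupes[:5]}")
        arr = values.to_numpy(dtype=float, copy=False)
        if np.isnan(arr).any():
            gene = values.index[np.isnan(arr).any(axis=1)][0]
            raise MatrixValidationError(f"missing abundance for gene {gene!r}")
        if (arr < 0).any():
            gene = values.index[(arr < 0).any(axis=1)][0]
            raise MatrixValidationError(f"negative abundance for gene {gene!r}")
        keys = [(s.strain, s.treatment, s.timepoint, s.replicate) for s in samples]
        if len(set(keys)) != len(keys):
            raise MatrixValidationError("duplicate (strain, treatment, timepoint, replicate)")
        counts: dict[tuple, int] = {}
        for s in samples:
            counts[s.condition] = counts.get(s.condition, 0) + 1
        for cond, n in counts.items():
            if n < 2:
                raise MatrixValidationError(
                    f"condition {tuple(str(c) for c in cond)} has {n} replicate(s); >=2 required"
                )
        self.values = values.astype(float)
        self.samples = samples
        self._by_condition: dict[tuple, list[str]] = {}
        for s in samples:
            self._by_condition.setdefault(s.condition, []).append(s.sample_id)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def conditions(self) -> list[tuple[Strain, Treatment, int]]:
        return list(self._by_condition)

    def has_condition(self, strain: Strain, treatment: Treatment, timepoint: int) -> bool:
        return (strain, treatment, timepoint) in self._by_condition

    def condition_values(
        self, strain: Strain, treatment: Treatment, timepoint: int
    ) -> pd.DataFrame:
        """Replicate columns (genes x replicates) for one condition."""
        key = (strain, treatment, timepoint)
        if key not in self._by_condition:
            raise MatrixValidationError(
                f"condition ({strain.value}, {treatment.value}, {timepoint}) absent from design"
            )
        return self.values[self._by_condition[key]]

    def equivalent(self, other: "ExpressionMatrix", rtol: float = 0.0) -> bool:
        """Equality up to column/row ordering (loading is order-insensitive)."""
        if sorted(self.gene_ids) != sorted(other.gene_ids):
            return False
        mine = {s.sample_id: s for s in self.samples}
        theirs = {s.sample_id: s for s in other.samples}
        if mine != theirs:
            return False
        a = self.values.sort_index().sort_index(axis=1)
        b = other.values.sort_index().sort_index(axis=1)
        return np.allclose(a.to_numpy(), b.to_numpy(), rtol=rtol, atol=0.0)


def read_design_table(design_path: str | Path) -> list[SampleDesign]:
    design_path = Path(design_path)
    if not design_path.exists():
        raise FileNotFoundError(design_path)
    df = pd.read_csv(design_path, sep="\t", comment="#", dtype=str)
    required = ["sample_id", "strain", "treatment", "timepoint_min", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MatrixValidationError(f"design table missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        try:
            strain = Strain(row.strain)
        except ValueError as exc:
            raise MatrixValidationError(
                f"sample {row.sample_id!r}: unknown strain {row.strain!r}"
            ) from exc
        try:
            treatment = Treatment(row.treatment)
        except ValueError as exc:
            raise MatrixValidationError(
                f"sample {row.sample_id!r}: unknown treatment {row.treatment!r}"
            ) from exc
        out.append(
            SampleDesign(
                sample_id=str(row.sample_id),
                strain=strain,
                treatment=treatment,
                timepoint=int(row.timepoint_min),
                replicate=int(row.replicate),
            )
        )
    return out


def read_expression_table(
    matrix_path: str | Path, design_path: str | Path
) -> ExpressionMatrix:
    """Load a gene x sample FPKM TSV plus its design TSV into a validated matrix.

    Every matrix column must be described by exactly one design row and vice
    versa; mismatches fail loudly with the offending sample name instead of
    silently dropping columns.
    """
    matrix_path = Path(matrix_path)
    if not matrix_path.exists():
        raise FileNotFoundError(matrix_path)
    designs = read_design_table(design_path)
    df = pd.read_csv(matrix_path, sep="\t", comment="#", index_col="gene_id")
    design_ids = [s.sample_id for s in designs]
    undesigned = [c for c in df.columns if c not in design_ids]
    if undesigned:
        raise MatrixValidationError(
            f"matrix column(s) without a design row: {undesigned}"
        )
    orphans = [sid for sid in design_ids if sid not in df.columns]
    if orphans:
        raise MatrixValidationError(f"design row(s) without a matrix column: {orphans}")
    # reorder columns to the design order; permuting input columns is harmless
    return ExpressionMatrix(df[design_ids], designs)


@dataclass
class ResultTable:
    """A gene-keyed (or otherwise keyed) table with a provenance header.

    Provenance (pipeline version, config hash, seed) rides along as
    ``#``-prefixed ``key=value`` lines so every written artifact records how
    it was produced.
    """

    data: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)
    #: set to None for long-format tables keyed by more than one column
    key_column: str | None = "gene_id"

    def __post_init__(self) -> None:
        if self.key_column is not None and self.key_column in self.data.columns:
            if self.data[self.key_column].duplicated().any():
                raise MatrixValidationError(f"duplicate {self.key_column} in result table")


def _format_cell(v) -> str:
    if isinstance(v, enum.Enum):
        return str(v.value)
    if isinstance(v, (bool, np.bool_)):
        return "true" if v else "false"
    if isinstance(v, (float, np.floating)):
        return f"{v:.6g}"
    return str(v)


def write_result_table(table: ResultTable, path: str | Path) -> None:
    """Serialize as TSV with 6-significant-digit numerics and ``#`` provenance."""
    path = Path(path)
    lines = [f"# {k}={v}" for k, v in sorted(table.provenance.items())]
    buf = io.StringIO()
    df = table.data
    buf.write("\t".join(map(str, df.columns)) + "\n")
    for row in df.itertuples(index=False):
        buf.write("\t".join(_format_cell(v) for v in row) + "\n")
    path.write_text("\n".join(lines) + ("\n" if lines else "") + buf.getvalue())


def read_result_table(path: str | Path, key_column: str = "gene_id") -> ResultTable:
    path = Path(path)
    provenance = {}
    with path.open() as fh:
        text_lines = fh.readlines()
    body = []
    for line in text_lines:
        if line.startswith("#"):
            k, _, v = line[1:].strip().partition("=")
            provenance[k.strip()] = v
        else:
            body.append(line)
    df = pd.read_csv(io.StringIO("".join(body)), sep="\t")
    return ResultTable(data=df, provenance=provenance, key_column=key_column)


def config_hash(config: Mapping) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
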