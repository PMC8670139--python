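"""Degenerate UPR-element (UPRE) consensus scanning in promoters.

Two 7-bp IUPAC consensuses of Hac1-type binding sites are built in:
UPRE-1 ``CASNGKD`` and UPRE-2 ``ACGTGKY``.  Promoters are the bases
immediately 5' of a gene's start codon, reported in start-codon-relative
coordinates (position -1 is the base just before the A of ATG; a hit's
position is the coding-strand coordinate of its leftmost base).  Scanning
covers both strands by default — bZIP binding is orientation-tolerant — and
reports every overlapping occurrence.  Genes are labelled UPRE1_only /
UPRE2_only / both / none from their hit counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IUPAC",
    "Motif",
    "MotifHit",
    "UPRE1",
    "UPRE2",
    "BUILTIN_MOTIFS",
    "parse_iupac",
    "reverse_complement",
    "scan_promoter",
    "scan_promoters",
    "classify_upre",
    "extract_promoters",
    "write_promoter_fasta",
    "read_promoter_fasta",
]

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class Motif:
    """A degenerate consensus with its compiled overlapping-match pattern."""

    motif_id: str
    consensus: str
    sets: tuple[frozenset[str], ...]
    pattern: "re.Pattern[str]"

    def __len__(self) -> int:
        return len(self.consensus)

    def matches(self, kmer: str) -> bool:
        """Per-position set membership (the definition, used by the scanner's oracle)."""
        if len(kmer) != len(self.sets):
            return False
        return all(base in s for base, s in zip(kmer, self.sets))


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence with start-codon-relative coordinates.

    ``position`` is the coding-strand coordinate of the hit's leftmost base
    (negative upstream); ``matched_seq`` is the 7-mer as read on the
    reported strand, i.e. it matches the consensus there.
    """

    gene_id: str
    motif_id: str
    position: int
    strand: str
    matched_seq: str


def parse_iupac(consensus: str, motif_id: str | None = None) -> Motif:
    """Compile an IUPAC consensus into a Motif matcher."""
    if not consensus:
        raise ValueError("empty consensus")
    consensus = consensus.upper()
    sets = []
    for i, code in enumerate(consensus):
        if code not in IUPAC:
            raise ValueError(f"invalid IUPAC code {code!r} at position {i}")
        sets.append(IUPAC[code])
    # lookahead regex reports overlapping occurrences
    body = "".join(s if len((s := "".join(sorted(cs)))) == 1 else f"[{s}]" for cs in sets)
    pattern = re.compile(f"(?=({body}))")
    return Motif(motif_id or consensus, consensus, tuple(sets), pattern)


UPRE1 = parse_iupac("CASNGKD", "UPRE1")
UPRE2 = parse_iupac("ACGTGKY", "UPRE2")
BUILTIN_MOTIFS = (UPRE1, UPRE2)


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def scan_promoter(
    gene_id: str,
    seq: str,
    motifs: Sequence[Motif] = BUILTIN_MOTIFS,
    strands: str = "both",
) -> list[MotifHit]:
    """All motif occurrences in one promoter sequence.

    The promoter is given 5'->3' on the coding strand with its last base
    adjacent to the start codon, so a hit starting at 0-based offset ``i``
    of an ``L``-base promoter sits at position ``i - L``.  With
    ``strands='both'`` the reverse complement is scanned too; minus-strand
    hits keep the coding-strand coordinate of their leftmost base and report
    the matched 7-mer as read on the minus strand.  Ambiguous bases in the
    promoter never match.
    """
    if strands not in ("coding", "both"):
        raise ValueError(f"strands must be 'coding' or 'both', got {strands!r}")
    seq = seq.upper()
    L = len(seq)
    hits: list[MotifHit] = []
    for motif in motifs:
        for m in motif.pattern.finditer(seq):
            hits.append(MotifHit(gene_id, motif.motif_id, m.start() - L, "+", m.group(1)))
        if strands == "both":
            rc = reverse_complement(seq)
            w = len(motif)
            for m in motif.pattern.finditer(rc):
                # offset j on the reverse strand <-> leftmost coding base L - j - w
                pos = (L - m.start() - w) - L
                hits.append(MotifHit(gene_id, motif.motif_id, pos, "-", m.group(1)))
    hits.sort(key=lambda h: (h.motif_id, h.position, h.strand))
    return hits


def scan_promoters(
    promoters: Mapping[str, str],
    motifs: Sequence[Motif] = BUILTIN_MOTIFS,
    strands: str = "both",
) -> pd.DataFrame:
    """Scan many promoters; one row per hit (gene_id, motif_id, position, strand, matched_seq)."""
    rows = []
    for gene_id in promoters:
        for h in scan_promoter(gene_id, promoters[gene_id], motifs, strands):
            rows.append(h.__dict__)
    return pd.DataFrame(
        rows, columns=["gene_id", "motif_id", "position", "strand", "matched_seq"]
    )


def classify_upre(
    hits: pd.DataFrame, gene_ids: Iterable[str]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Label every gene UPRE1_only / UPRE2_only / both / none from hit counts.

    "Only" is read as "at least one of this motif and none of the other";
    raw counts are emitted so an exactly-one reading can be applied
    downstream.  Returns the per-gene table and the four summary counts.
    """
    gene_ids = list(gene_ids)
    counts = (
        hits.groupby(["gene_id", "motif_id"]).size().unstack(fill_value=0)
        if len(hits)
        else pd.DataFrame()
    )
    rows = []
    for g in gene_ids:
        n1 = int(counts.loc[g, "UPRE1"]) if g in counts.index and "UPRE1" in counts else 0
        n2 = int(counts.loc[g, "UPRE2"]) if g in counts.index and "UPRE2" in counts else 0
        if n1 and n2:
            label = "both"
        elif n1:
            label = "UPRE1_only"
        elif n2:
            label = "UPRE2_only"
        else:
            label = "none"
        rows.append({"gene_id": g, "n_upre1": n1, "n_upre2": n2, "label": label})
    table = pd.DataFrame(rows, columns=["gene_id", "n_upre1", "n_upre2", "label"])
    summary = {
        lab: int((table["label"] == lab).sum())
        for lab in ("UPRE1_only", "UPRE2_only", "both", "none")
    }
    return table, summary


def extract_promoters(
    genome_fasta: str | Path,
    annotation_gff3: str | Path,
    length: int = 1000,
    gene_ids: Iterable[str] | None = None,
    feature_types: Sequence[str] = ("gene",),
) -> tuple[dict[str, str], pd.DataFrame]:
    """Cut promoter sequences (coding-strand 5'->3') out of a genome.

    For a + strand gene the promoter is the ``length`` bases immediately 5'
    of the annotated start (0-based half-open genomic slice
    ``[start-length, start)``); for a - strand gene, the reverse complement
    of the slice immediately 3' of the feature's end coordinate.  Promoters
    truncated by a contig edge are clipped and flagged.  Returns the
    promoter dict and a metadata frame (contig, genomic span, strand,
    clipped).
    """
    import gffutils
    from pyfaidx import Fasta

    genome = Fasta(str(genome_fasta), as_raw=True, sequence_always_upper=True)
    db = gffutils.create_db(
        str(annotation_gff3), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    wanted = set(gene_ids) if gene_ids is not None else None
    promoters: dict[str, str] = {}
    meta_rows = []
    for ftype in feature_types:
        for feat in db.features_of_type(ftype):
            gid = feat.attributes.get("ID", [feat.id])[0]
            if wanted is not None and gid not in wanted:
                continue
            if feat.seqid not in genome:
                raise KeyError(f"contig {feat.seqid!r} absent from genome FASTA")
            contig = genome[feat.seqid]
            clen = len(contig)
            if feat.strand == "+":
                end0 = feat.start - 1  # GFF3 1-based start -> 0-based CDS start
                begin0 = max(0, end0 - length)
                seq = str(contig[begin0:end0])
            elif feat.strand == "-":
                begin0 = feat.end  # 1-based inclusive end == 0-based exclusive end
                end0 = min(clen, begin0 + length)
                seq = reverse_complement(str(contig[begin0:end0]))
            else:
                raise ValueError(f"gene {gid!r} has no strand in the annotation")
            promoters[gid] = seq
            meta_rows.append(
                {
                    "gene_id": gid,
                    "contig": feat.seqid,
                    "span_start": begin0,
                    "span_end": end0,
                    "strand": feat.strand,
                    "clipped": len(seq) < length,
                }
            )
    if wanted is not None:
        missing = wanted - set(promoters)
        if missing:
            raise KeyError(f"gene(s) absent from annotation: {sorted(missing)[:5]}")
    meta = pd.DataFrame(
        meta_rows,
        columns=["gene_id", "contig", "span_start", "span_end", "strand", "clipped"],
    )
    return promoters, meta


def write_promoter_fasta(promoters: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gid, description="promoter")
        for gid, seq in promoters.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_promoter_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
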