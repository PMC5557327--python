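"""Input/output for the standard formats the pipeline touches.

Reads GFF3 annotations into ranked gene models, homolog-pair tables
(BLAST-tabular or minimal four-column TSV), peptide/CDS FASTA, and
RPKM expression matrices; writes the TSV reports downstream stages emit.
Coordinates are GFF3 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDES = set("ACGT")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class GenomeIOError(ValueError):
    """Malformed input: bad line, duplicate id, invariant violation."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), as used for all report percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GeneModel:
    """A gene's chromosome placement.

    ``rank`` is the 1-based ordinal of the gene among all genes of the same
    chromosome sorted by ascending start (ties: ascending end, then gene id).
    Ranks always reflect the full annotation, never a family subset, because
    tandem/proximal typing depends on genome-wide adjacency.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "unknown"
    rank: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GenomeIOError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-", "unknown"}:
            raise GenomeIOError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class PeptideRecord:
    """A peptide with externally supplied signal-peptide flag and subfamily label."""

    peptide_id: str
    sequence: str
    has_signal_peptide: bool = False
    subfamily: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeIOError(f"peptide {self.peptide_id}: empty sequence")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise GenomeIOError(
                f"peptide {self.peptide_id}: invalid residues {sorted(bad)}"
            )


@dataclass(frozen=True)
class CodingPair:
    """A pre-aligned, gap-free pair of coding sequences (unit of Ka/Ks)."""

    id_a: str
    id_b: str
    cds_a: str
    cds_b: str

    def __post_init__(self) -> None:
        for gid, seq in ((self.id_a, self.cds_a), (self.id_b, self.cds_b)):
            validate_cds(seq, name=gid)
        if len(self.cds_a) != len(self.cds_b):
            raise GenomeIOError(
                f"pair ({self.id_a},{self.id_b}): unequal CDS lengths "
                f"{len(self.cds_a)} vs {len(self.cds_b)}"
            )

    @property
    def n_codons(self) -> int:
        return len(self.cds_a) // 3


def validate_cds(seq: str, name: str = "<cds>") -> None:
    """Check CDS invariants: ACGT alphabet, length % 3 == 0, no internal stop."""
    if not seq:
        raise GenomeIOError(f"{name}: empty CDS")
    bad = set(seq) - NUCLEOTIDES
    if bad:
        raise GenomeIOError(f"{name}: invalid nucleotides {sorted(bad)}")
    if len(seq) % 3:
        raise GenomeIOError(f"{name}: length {len(seq)} not divisible by 3")
    for i in range(0, len(seq) - 3, 3):
        if seq[i : i + 3] in STOP_CODONS:
            raise GenomeIOError(f"{name}: internal stop codon at position {i + 1}")
    if seq[-3:] in STOP_CODONS and len(seq) == 3:
        raise GenomeIOError(f"{name}: sequence is a lone stop codon")


@dataclass
class ExpressionMatrix:
    """Genes x developmental stages of RPKM; rectangular, finite, non-negative."""

    gene_ids: list[str]
    stage_ids: list[str]
    values: pd.DataFrame = field(repr=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        arr = df.to_numpy(dtype=float)
        if arr.size:
            if not np.isfinite(arr).all():
                raise GenomeIOError("expression values must be finite")
            if (arr < 0).any():
                raise GenomeIOError("expression values must be >= 0")
        return cls(list(df.index), list(df.columns), df.astype(float))

    def profile(self, gene_id: str):
        return self.values.loc[gene_id].to_numpy(dtype=float)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.values.index


# ---------------------------------------------------------------------------
# GFF3


def _assign_ranks(genes: list[GeneModel]) -> list[GeneModel]:
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    out: list[GeneModel] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.gene_id))
        for i, g in enumerate(ordered, start=1):
            out.append(
                GeneModel(g.gene_id, g.chromosome, g.start, g.end, g.strand, rank=i)
            )
    return out


def read_gff(path: str | Path, feature_type: str = "gene") -> list[GeneModel]:
    """Read GFF3 features of ``feature_type`` into rank-annotated gene models.

    Ranks are assigned per chromosome by ascending start; ties broken by
    ascending end, then lexical gene id. Raises :class:`GenomeIOError` with a
    line number for malformed lines and on duplicate gene ids.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        ncols = len(line.split("\t"))
        if ncols != 9:
            raise GenomeIOError(
                f"{path.name}:{lineno}: malformed GFF3 line "
                f"({ncols} columns, expected 9)"
            )
    if not text.strip() or all(
        l.startswith("#") or not l.strip() for l in text.splitlines()
    ):
        return []
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="error",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in db.features_of_type(feature_type):
        gid = feat.attributes.get("ID", [feat.id])[0]
        if gid in seen:
            raise GenomeIOError(f"duplicate gene_id {gid!r}")
        seen.add(gid)
        strand = feat.strand if feat.strand in {"+", "-"} else "unknown"
        genes.append(GeneModel(gid, feat.seqid, feat.start, feat.end, strand))
    return _assign_ranks(genes)


def write_gff(genes: list[GeneModel], path: str | Path, feature_type: str = "gene") -> None:
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.chromosome, g.start, g.end, g.gene_id)):
        strand = g.strand if g.strand in {"+", "-"} else "."
        lines.append(
            "\t".join(
                [
                    g.chromosome,
                    "crpevol",
                    feature_type,
                    str(g.start),
                    str(g.end),
                    ".",
                    strand,
                    ".",
                    f"ID={g.gene_id}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Homolog-pair tables


def read_pairs_table(
    path: str | Path, max_evalue: float = 0.01
) -> list[tuple[str, str, float, float]]:
    """Read a homolog-pair table, keeping rows with E-value < ``max_evalue``.

    Accepts the minimal four-column TSV (gene_a, gene_b, score, evalue) or
    12-column BLAST tabular (evalue in column 11, bit score in column 12).
    Self-pairs are dropped; unordered duplicates collapse to the best
    (smallest) E-value. Returns (gene_a, gene_b, score, evalue) tuples with
    ids in canonical (sorted) order.
    """
    best: dict[tuple[str, str], tuple[float, float]] = {}
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) >= 12:
            a, b, escol, sccol = fields[0], fields[1], fields[10], fields[11]
        elif len(fields) >= 4:
            a, b, sccol, escol = fields[0], fields[1], fields[2], fields[3]
        else:
            raise GenomeIOError(
                f"{path.name}:{lineno}: expected >=4 tab-separated columns"
            )
        try:
            evalue = float(escol)
            score = float(sccol)
        except ValueError as exc:
            raise GenomeIOError(
                f"{path.name}:{lineno}: non-numeric score/E-value"
            ) from exc
        if a == b:
            continue
        if evalue >= max_evalue:
            continue
        key = (min(a, b), max(a, b))
        prev = best.get(key)
        if prev is None or evalue < prev[1]:
            best[key] = (score, evalue)
    return [(a, b, sc, ev) for (a, b), (sc, ev) in sorted(best.items())]


def write_pairs_table(
    pairs: list[tuple[str, str, float, float]], path: str | Path
) -> None:
    lines = [f"{a}\t{b}\t{sc:g}\t{ev:g}" for a, b, sc, ev in pairs]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# FASTA


def read_peptide_fasta(
    path: str | Path,
    subfamilies: dict[str, str] | None = None,
    signal_flags: dict[str, bool] | None = None,
) -> list[PeptideRecord]:
    """Read peptides; lowercase is upper-cased, subfamily/signal flags attached."""
    subfamilies = subfamilies or {}
    signal_flags = signal_flags or {}
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            PeptideRecord(
                rec.id,
                str(rec.seq).upper(),
                has_signal_peptide=signal_flags.get(rec.id, False),
                subfamily=subfamilies.get(rec.id, ""),
            )
        )
    return records


def read_cds_fasta(path: str | Path) -> dict[str, str]:
    """Read CDS sequences keyed by id; upper-cased, alphabet validated lazily."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise GenomeIOError(f"duplicate sequence id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def read_subfamily_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV: gene/peptide id -> subfamily label."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise GenomeIOError("subfamily table rows need 2 columns")
        out[fields[0]] = fields[1]
    return out


# ---------------------------------------------------------------------------
# Cysteine signatures


def cys_signature(peptide: PeptideRecord | str) -> tuple[str, int]:
    """Spacing pattern of cysteines, e.g. ``"C-X4-C-X2-C"``, plus the C count.

    The spacer count k in ``Xk`` is the number of residues between consecutive
    cysteines. Returns ("", 0) for a cysteine-free sequence and ("C", 1) for a
    single cysteine.
    """
    seq = peptide.sequence if isinstance(peptide, PeptideRecord) else peptide
    positions = [i for i, aa in enumerate(seq) if aa == "C"]
    if not positions:
        return "", 0
    parts = ["C"]
    for prev, nxt in zip(positions, positions[1:]):
        parts.append(f"X{nxt - prev - 1}")
        parts.append("C")
    return "-".join(parts), len(positions)


# ---------------------------------------------------------------------------
# Expression tables and TSV reports


def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read a TSV with a stage-id header row and gene ids in the first column."""
    path = Path(path)
    lines = [l for l in path.read_text().splitlines() if l.strip()]
    if not lines:
        raise GenomeIOError(f"{path.name}: empty expression table")
    header = lines[0].split("\t")
    stage_ids = header[1:]
    if not stage_ids:
        raise GenomeIOError(f"{path.name}: missing stage header")
    for s in stage_ids:
        try:
            float(s)
        except ValueError:
            continue
        raise GenomeIOError(f"{path.name}: header row looks numeric; missing header?")
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise GenomeIOError(
                f"{path.name}:{lineno}: ragged row "
                f"({len(fields)} columns, expected {len(header)})"
            )
        gene_ids.append(fields[0])
        try:
            vals = [float(v) for v in fields[1:]]
        except ValueError as exc:
            raise GenomeIOError(f"{path.name}:{lineno}: non-numeric value") from exc
        if any(v < 0 for v in vals):
            raise GenomeIOError(f"{path.name}:{lineno}: negative RPKM value")
        rows.append(vals)
    df = pd.DataFrame(rows, index=gene_ids, columns=stage_ids)
    return ExpressionMatrix.from_dataframe(df)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    lines = ["gene_id\t" + "\t".join(matrix.stage_ids)]
    for gid in matrix.gene_ids:
        vals = matrix.values.loc[gid]
        lines.append(gid + "\t" + "\t".join(f"{v:g}" for v in vals))
    Path(path).write_text("\n".join(lines) + "\n")


def write_tsv(rows: list[dict], path: str | Path, columns: list[str] | None = None) -> None:
    """Write report rows as a TSV with a fixed, stable column order."""
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    lines = ["\t".join(columns)]
    for row in rows:
        lines.append("\t".join(str(row.get(c, "")) for c in columns))
    Path(path).write_text("\n".join(lines) + "\n")


def read_tsv(path: str | Path) -> list[dict]:
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    if not lines:
        return []
    header = lines[0].split("\t")
    return [dict(zip(header, l.split("\t"))) for l in lines[1:]]
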