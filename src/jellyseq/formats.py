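"""Domain types and file I/O for the royal-jelly RNA pipeline.

All coordinates are 0-based half-open internally.  GFF3 is 1-based closed
at the file boundary, BED and bedGraph are 0-based half-open; the
conversion happens here and nowhere else.  Every downstream module speaks
only in the types defined in this file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

Strand = Literal["+", "-"]

#: Closed biotype vocabulary.  Anything outside it is coerced to "other".
BIOTYPES = ("protein_coding", "tRNA", "pre_miRNA", "other")

#: Constant Phred quality used for simulated FASTQ (Q37).
FASTQ_QUALITY_CHAR = "F"


class JellyseqError(Exception):
    """Base class for all package errors."""


class FormatError(JellyseqError):
    """A file could not be parsed in the declared dialect."""


class ValidationError(JellyseqError):
    """A domain object violates one of its invariants."""


def _other_strand(strand: str) -> Strand:
    return "-" if strand == "+" else "+"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneFeature:
    """A gene-level annotation interval with biotype and transcript lengths."""

    gene_id: str
    reference: str
    start: int
    end: int
    strand: Strand
    biotype: str = "other"
    transcript_lengths: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise ValidationError(f"gene {self.gene_id}: unknown biotype {self.biotype!r}")
        if not self.transcript_lengths:
            object.__setattr__(self, "transcript_lengths", (self.end - self.start,))
        if min(self.transcript_lengths) <= 0:
            raise ValidationError(f"gene {self.gene_id}: non-positive transcript length")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def mean_transcript_length(self) -> float:
        return float(np.mean(self.transcript_lengths))

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class AnnotatedReference:
    """Reference sequences plus strand-aware gene features and species labels."""

    sequences: dict[str, str]
    features: list[GeneFeature] = field(default_factory=list)
    species_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for feat in self.features:
            if feat.reference not in self.sequences:
                raise ValidationError(
                    f"gene {feat.gene_id}: unknown reference {feat.reference!r}"
                )
            if feat.end > len(self.sequences[feat.reference]):
                raise ValidationError(
                    f"gene {feat.gene_id}: interval [{feat.start}, {feat.end}) "
                    f"exceeds reference length {len(self.sequences[feat.reference])}"
                )
        unknown = set(self.species_of) - set(self.sequences)
        if unknown:
            raise ValidationError(f"species_of names unknown references: {sorted(unknown)}")

    def length(self, reference: str) -> int:
        return len(self.sequences[reference])

    def features_on(self, reference: str) -> list[GeneFeature]:
        return [f for f in self.features if f.reference == reference]

    def feature_by_id(self, gene_id: str) -> GeneFeature:
        for f in self.features:
            if f.gene_id == gene_id:
                return f
        raise KeyError(gene_id)

    def references_of_species(self, species: str) -> list[str]:
        return [r for r, s in self.species_of.items() if s == species]


@dataclass(frozen=True)
class AlignedRead:
    """One mapped read interval with strand, mate index and fragment identity."""

    read_id: str
    fragment_id: str
    mate: int
    reference: str
    start: int
    end: int
    strand: Strand
    sample: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"read {self.read_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.mate not in (1, 2):
            raise ValidationError(f"read {self.read_id}: mate must be 1 or 2")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"read {self.read_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Fragment:
    """A mate-merged sequenced molecule: union interval plus sense strand."""

    fragment_id: str
    reference: str
    start: int
    end: int
    strand: Strand
    sample: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


class CountMatrix:
    """Per-gene (or per-group) counts across samples with optional size factors.

    Thin wrapper around a pandas DataFrame (rows = gene/group ids, columns =
    sample ids) carrying the per-sample size factors once computed.
    """

    def __init__(self, counts: pd.DataFrame, size_factors: pd.Series | None = None):
        if (counts.to_numpy() < 0).any():
            raise ValidationError("counts must be nonnegative")
        if size_factors is not None:
            size_factors = size_factors.reindex(counts.columns)
            if (size_factors <= 0).any() or size_factors.isna().any():
                raise ValidationError("size factors must be positive for every sample")
        self.counts = counts
        self.size_factors = size_factors

    @property
    def row_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def normalized(self) -> pd.DataFrame:
        if self.size_factors is None:
            raise ValidationError("size factors not computed yet")
        return self.counts / self.size_factors

    def __repr__(self) -> str:  # pragma: no cover
        return f"CountMatrix({len(self.row_ids)} rows x {len(self.sample_ids)} samples)"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an order-preserving name -> uppercase sequence map.

    The record name is the first whitespace-delimited header token.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FormatError(f"{path}:{lineno}: expected FASTA header line")
            break
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"{path}: duplicate record name {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    """Write sequences as FASTA wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(
    path: str | Path,
    reference: AnnotatedReference | Mapping[str, str] | None = None,
) -> list[GeneFeature]:
    """Read gene rows from a GFF3 file into GeneFeature objects.

    Coordinates are converted from 1-based closed to 0-based half-open.  A
    missing ``biotype`` attribute defaults to "other".  When a reference is
    supplied, features beyond its sequence bounds raise ValidationError.
    """
    path = Path(path)
    features: list[GeneFeature] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                row = feature_from_line(line)
            except Exception as exc:
                raise FormatError(f"{path}:{lineno}: malformed GFF3 row: {exc}") from exc
            if row.featuretype != "gene":
                continue
            gene_id = (row.attributes.get("ID") or [None])[0]
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: gene row without ID attribute")
            biotype = (row.attributes.get("biotype") or ["other"])[0]
            if biotype not in BIOTYPES:
                biotype = "other"
            tlen_attr = row.attributes.get("transcript_lengths")
            # GFF3 attribute values are comma-separated lists
            tlens = tuple(
                int(x) for item in (tlen_attr or []) for x in str(item).split(",")
            )
            features.append(
                GeneFeature(
                    gene_id=gene_id,
                    reference=row.seqid,
                    start=row.start - 1,
                    end=row.end,
                    strand=row.strand,
                    biotype=biotype,
                    transcript_lengths=tlens,
                )
            )
    features.sort(key=lambda f: (f.reference, f.start))
    if reference is not None:
        lengths = (
            {n: len(s) for n, s in reference.sequences.items()}
            if isinstance(reference, AnnotatedReference)
            else {n: len(s) for n, s in reference.items()}
        )
        for feat in features:
            if feat.reference not in lengths:
                raise ValidationError(f"gene {feat.gene_id}: unknown reference")
            if feat.end > lengths[feat.reference]:
                raise ValidationError(
                    f"gene {feat.gene_id}: beyond end of {feat.reference}"
                )
    return features


def write_gff3(features: Sequence[GeneFeature], path: str | Path) -> None:
    """Write GeneFeatures as GFF3 gene rows (1-based closed coordinates)."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for feat in sorted(features, key=lambda f: (f.reference, f.start)):
            attrs = (
                f"ID={feat.gene_id};biotype={feat.biotype};"
                f"transcript_lengths={','.join(str(x) for x in feat.transcript_lengths)}"
            )
            handle.write(
                "\t".join(
                    [
                        feat.reference,
                        "jellyseq",
                        "gene",
                        str(feat.start + 1),
                        str(feat.end),
                        ".",
                        feat.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Alignments (minimal SAM and fragment BED dialects)
# ---------------------------------------------------------------------------

def read_alignments(
    path: str | Path,
    dialect: Literal["sam", "bed"] = "sam",
    sample: str = "",
) -> list[AlignedRead]:
    """Read mapped reads from a minimal SAM or a fragment-BED file.

    The SAM dialect supports @SQ headers, the FLAG bits for strand / mate /
    paired, POS and CIGAR strings containing only M operations.  Unmapped
    records are skipped with a logged count; any other CIGAR operation is an
    unsupported-dialect error.
    """
    if dialect == "sam":
        return _read_sam(Path(path), sample)
    if dialect == "bed":
        return _read_fragment_bed(Path(path), sample)
    raise FormatError(f"unknown alignment dialect {dialect!r}")


def _read_sam(path: Path, sample: str) -> list[AlignedRead]:
    reads: list[AlignedRead] = []
    n_unmapped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                n_unmapped += 1
                continue
            if rec.cigartuples is None or any(op != 0 for op, _ in rec.cigartuples):
                raise FormatError(
                    f"{path}: read {rec.query_name}: only M CIGAR operations are "
                    "supported by the minimal SAM dialect"
                )
            mate = 2 if rec.is_read2 else 1
            reads.append(
                AlignedRead(
                    read_id=f"{rec.query_name}/{mate}",
                    fragment_id=rec.query_name,
                    mate=mate,
                    reference=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    sample=sample,
                )
            )
    if n_unmapped:
        logger.info("%s: skipped %d unmapped records", path, n_unmapped)
    return reads


def _read_fragment_bed(path: Path, sample: str) -> list[AlignedRead]:
    reads: list[AlignedRead] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: fragment BED needs 6 columns")
            ref, start, end, name, _score, strand = parts[:6]
            if "/" in name:
                frag_id, mate_str = name.rsplit("/", 1)
                mate = int(mate_str)
            else:
                frag_id, mate = name, 1
            reads.append(
                AlignedRead(
                    read_id=name,
                    fragment_id=frag_id,
                    mate=mate,
                    reference=ref,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    sample=sample,
                )
            )
    return reads


def _sam_header(reference_lengths: Mapping[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": name, "LN": length} for name, length in reference_lengths.items()],
        }
    )


def write_sam(
    reads: Sequence[AlignedRead],
    reference_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write reads as minimal SAM (all-M CIGAR, mates paired by fragment_id)."""
    header = _sam_header(reference_lengths)
    by_fragment: dict[str, list[AlignedRead]] = {}
    for read in reads:
        by_fragment.setdefault(read.fragment_id, []).append(read)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in reads:
            mates = by_fragment[read.fragment_id]
            paired = len(mates) == 2
            rec = pysam.AlignedSegment(header)
            rec.query_name = read.fragment_id
            rec.reference_name = read.reference
            rec.reference_start = read.start
            rec.cigarstring = f"{read.length}M"
            rec.mapping_quality = 60
            flag = 0
            if read.strand == "-":
                flag |= 0x10
            if paired:
                other = next(m for m in mates if m is not read)
                flag |= 0x1 | 0x2
                flag |= 0x40 if read.mate == 1 else 0x80
                if other.strand == "-":
                    flag |= 0x20
                rec.next_reference_name = other.reference
                rec.next_reference_start = other.start
                tlen = max(m.end for m in mates) - min(m.start for m in mates)
                rec.template_length = tlen if read.start <= other.start else -tlen
            rec.flag = flag
            out.write(rec)


def write_fastq(
    reads: Sequence[AlignedRead],
    sequences: Mapping[str, str],
    path: str | Path,
) -> None:
    """Write read sequences as FASTQ with constant Q37 qualities.

    Reads on the minus strand are reverse-complemented back to read
    orientation.
    """
    with open(path, "w") as handle:
        for read in reads:
            seq = sequences[read.reference][read.start : read.end]
            if read.strand == "-":
                seq = str(Seq(seq).reverse_complement())
            handle.write(
                f"@{read.read_id}\n{seq}\n+\n{FASTQ_QUALITY_CHAR * len(seq)}\n"
            )


# ---------------------------------------------------------------------------
# BED / bedGraph / TSV
# ---------------------------------------------------------------------------

def write_bed(items: Sequence, path: str | Path) -> None:
    """Write intervals as BED6 (0-based half-open), sorted by (reference, start).

    Duplex candidates are written over their full union interval with the
    overlap length in the score column; reads and fragments get score 0.
    """
    rows = []
    for item in items:
        if hasattr(item, "overlap_len"):  # DuplexCandidate
            name = f"{item.fwd_read}|{item.rev_read}"
            rows.append(
                (item.reference, item.union_start, item.union_end, name,
                 item.overlap_len, "+")
            )
        else:
            name = getattr(item, "read_id", None) or getattr(item, "fragment_id", ".")
            rows.append((item.reference, item.start, item.end, name, 0, item.strand))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as handle:
        for row in rows:
            handle.write("\t".join(str(x) for x in row) + "\n")


def write_bedgraph(
    values: np.ndarray, reference: str, path: str | Path, append: bool = False
) -> None:
    """Write a per-base track as run-length-compressed bedGraph."""
    values = np.asarray(values)
    mode = "a" if append else "w"
    with open(path, mode) as handle:
        if len(values) == 0:
            return
        boundaries = np.flatnonzero(np.diff(values)) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [len(values)]])
        for s, e in zip(starts, ends):
            v = values[s]
            if v != 0:
                handle.write(f"{reference}\t{s}\t{e}\t{v:g}\n")


def read_counts_tsv(path: str | Path) -> CountMatrix:
    """Read a row_ids x samples count table (TSV with header row)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(df)


def write_counts_tsv(matrix: CountMatrix, path: str | Path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="id")


def read_gene2go_tsv(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column gene -> GO term TSV into term -> gene-set mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: gene2go table needs gene and term columns")
    gene_col, term_col = df.columns[:2]
    mapping: dict[str, set[str]] = {}
    for gene, term in zip(df[gene_col], df[term_col]):
        mapping.setdefault(term, set()).add(gene)
    return mapping


def write_gene2go_tsv(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("gene_id\tterm_id\n")
        for gene, term in pairs:
            handle.write(f"{gene}\t{term}\n")


def read_species_tsv(path: str | Path) -> dict[str, str]:
    """Read a reference -> species label map (two-column TSV)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_species_tsv(species_of: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("reference\tspecies\n")
        for ref, sp in species_of.items():
            handle.write(f"{ref}\t{sp}\n")


def read_titration_csv(path: str | Path) -> pd.DataFrame:
    """Read a titration CSV with concentration, signal and replicate columns."""
    df = pd.read_csv(path)
    required = {"concentration", "signal"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: titration CSV needs columns {sorted(required)}")
    if "replicate" not in df.columns:
        df["replicate"] = 1
    return df


def write_titration_csv(
    protein_concs: np.ndarray, signal: np.ndarray, path: str | Path
) -> None:
    """Write a (n_conc x n_replicates) signal matrix as long-form CSV."""
    signal = np.atleast_2d(np.asarray(signal))
    if signal.shape[0] != len(protein_concs):
        signal = signal.T
    rows = []
    for i, conc in enumerate(protein_concs):
        for j in range(signal.shape[1]):
            rows.append((conc, signal[i, j], j + 1))
    pd.DataFrame(rows, columns=["concentration", "signal", "replicate"]).to_csv(
        path, index=False
    )
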