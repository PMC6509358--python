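"""Species/biotype composition, library-size normalization, enrichment tests,
and strand-specific coverage.

Fragments (mate-merged read pairs) are assigned to genes strand-specifically
under the dUTP chemistry of stranded TruSeq libraries, where the sense
strand of a fragment is the alignment strand of mate 2.  Counts are
normalized with mean-ratio size factors (each sample's total divided by the
mean total) and species enrichment is tested with a two-sided Welch
two-sample t test on normalized counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as student_t

from .formats import (
    AlignedRead,
    AnnotatedReference,
    CountMatrix,
    Fragment,
    JellyseqError,
    Strand,
)

UNANNOTATED = "Other"

StrandedProtocol = Literal["dutp", "fr"]


class CompositionError(JellyseqError):
    pass


# ---------------------------------------------------------------------------
# Mate merging and strand correction
# ---------------------------------------------------------------------------

def fragment_sense_strand(
    mates: Sequence[AlignedRead], protocol: StrandedProtocol = "dutp"
) -> Strand:
    """Sense strand of a fragment from its mates' alignment strands.

    dUTP chemistry: the sense strand is the strand of mate 2 (equivalently
    the opposite of mate 1).  "fr" libraries: the strand of mate 1.
    """
    if protocol not in ("dutp", "fr"):
        raise CompositionError(f"unknown stranded protocol {protocol!r}")
    anchor_mate = 2 if protocol == "dutp" else 1
    for read in mates:
        if read.mate == anchor_mate:
            return read.strand
    # only the other mate present: infer by flipping
    strand = mates[0].strand
    return "-" if strand == "+" else "+"


def merge_fragments(
    reads: Sequence[AlignedRead], protocol: StrandedProtocol = "dutp"
) -> list[Fragment]:
    """Merge mates into fragments: union interval plus protocol sense strand."""
    by_fragment: dict[tuple[str, str], list[AlignedRead]] = {}
    for read in reads:
        by_fragment.setdefault((read.sample, read.fragment_id), []).append(read)
    fragments = []
    for (sample, frag_id), mates in by_fragment.items():
        refs = {m.reference for m in mates}
        if len(refs) != 1:
            raise CompositionError(f"fragment {frag_id}: mates on different references")
        fragments.append(
            Fragment(
                fragment_id=frag_id,
                reference=mates[0].reference,
                start=min(m.start for m in mates),
                end=max(m.end for m in mates),
                strand=fragment_sense_strand(mates, protocol),
                sample=sample,
            )
        )
    fragments.sort(key=lambda f: (f.sample, f.reference, f.start))
    return fragments


def sense_corrected_reads(
    reads: Sequence[AlignedRead], protocol: StrandedProtocol = "dutp"
) -> list[AlignedRead]:
    """Replace each read's alignment strand by its fragment's sense strand.

    Used ahead of the duplex screen so that read strand means molecule
    strand rather than sequencing chemistry.
    """
    by_fragment: dict[tuple[str, str], list[AlignedRead]] = {}
    for read in reads:
        by_fragment.setdefault((read.sample, read.fragment_id), []).append(read)
    corrected = []
    for mates in by_fragment.values():
        sense = fragment_sense_strand(mates, protocol)
        for read in mates:
            corrected.append(
                AlignedRead(
                    read_id=read.read_id,
                    fragment_id=read.fragment_id,
                    mate=read.mate,
                    reference=read.reference,
                    start=read.start,
                    end=read.end,
                    strand=sense,
                    sample=read.sample,
                )
            )
    corrected.sort(key=lambda r: (r.sample, r.reference, r.start, r.read_id))
    return corrected


# ---------------------------------------------------------------------------
# Gene assignment and counting
# ---------------------------------------------------------------------------

@dataclass
class AssignmentResult:
    """Per-gene fragment counts plus unassigned tallies."""

    gene_counts: CountMatrix
    unannotated: pd.Series  # fragments overlapping no gene, per sample
    ambiguous: pd.Series  # fragments overlapping >= 2 eligible genes, per sample


def assign_reads_to_genes(
    fragments: Sequence[Fragment],
    annotation: AnnotatedReference,
) -> AssignmentResult:
    """Assign fragments to genes: positional overlap plus strand agreement.

    A fragment is counted for a gene iff its interval overlaps the gene
    span and its sense strand equals the gene strand.  Fragments eligible
    for two or more genes are ambiguous and dropped (tallied); fragments
    overlapping no gene are tallied as unannotated ("Other").
    """
    feats_by_ref: dict[str, list] = {}
    for feat in annotation.features:
        feats_by_ref.setdefault(feat.reference, []).append(feat)
    for feats in feats_by_ref.values():
        feats.sort(key=lambda f: f.start)

    samples = sorted({f.sample for f in fragments})
    gene_counts: dict[str, dict[str, int]] = {}
    unann = dict.fromkeys(samples, 0)
    ambig = dict.fromkeys(samples, 0)
    starts_by_ref = {
        ref: np.array([f.start for f in feats])
        for ref, feats in feats_by_ref.items()
    }
    for frag in fragments:
        feats = feats_by_ref.get(frag.reference, [])
        if feats:
            starts = starts_by_ref[frag.reference]
            i = int(np.searchsorted(starts, frag.end))
            eligible = [
                f for f in feats[:i]
                if f.end > frag.start and f.strand == frag.strand
            ]
        else:
            eligible = []
        if len(eligible) == 1:
            row = gene_counts.setdefault(
                eligible[0].gene_id, dict.fromkeys(samples, 0)
            )
            row[frag.sample] += 1
        elif len(eligible) == 0:
            unann[frag.sample] += 1
        else:
            ambig[frag.sample] += 1

    df = pd.DataFrame.from_dict(gene_counts, orient="index", columns=samples)
    df = df.fillna(0).astype(int).sort_index()
    return AssignmentResult(
        gene_counts=CountMatrix(df),
        unannotated=pd.Series(unann, dtype=int),
        ambiguous=pd.Series(ambig, dtype=int),
    )


def size_factors_mean_ratio(matrix: CountMatrix) -> pd.Series:
    """Size factor of a sample = its total count / mean total across samples."""
    totals = matrix.counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        raise CompositionError("every sample needs a positive total count")
    factors = totals / totals.mean()
    matrix.size_factors = factors
    return factors


# ---------------------------------------------------------------------------
# Composition summaries
# ---------------------------------------------------------------------------

@dataclass
class CompositionTable:
    """Normalized (species, biotype) composition across samples.

    ``counts`` holds raw fragment counts per (species, biotype) group,
    ``normalized`` the mean-ratio-normalized counts, ``fractions`` the
    per-sample fractions (summing to 1 before filtering), and ``report``
    the filtered view where groups below ``min_fraction`` in every sample
    are collapsed out.  Viral groups carry biotype "NA"; bee fragments
    overlapping no gene appear as biotype "Other".
    """

    counts: pd.DataFrame
    normalized: pd.DataFrame
    fractions: pd.DataFrame
    report: pd.DataFrame
    group_of_sample: dict[str, str]
    size_factors: pd.Series
    min_fraction: float


def summarize_composition(
    fragments: Sequence[Fragment],
    annotation: AnnotatedReference,
    group_of_sample: Mapping[str, str],
    min_fraction: float = 0.01,
) -> CompositionTable:
    """Summarize fragment counts by species and, within the bee, biotype.

    Every mapped fragment counts toward its reference's species.  Bee
    fragments are split by biotype via strand-aware gene assignment
    (ambiguous fragments dropped, unassigned as "Other"); viral species are
    single NA-biotype groups covering all their fragments regardless of
    strand.  Counts are normalized with mean-ratio size factors.
    """
    samples = sorted({f.sample for f in fragments})
    bee_refs = set(annotation.references_of_species("apis"))
    bee_frags = [f for f in fragments if f.reference in bee_refs]
    viral_frags = [f for f in fragments if f.reference not in bee_refs]

    assignment = assign_reads_to_genes(bee_frags, annotation)
    biotype_of = {f.gene_id: f.biotype for f in annotation.features}

    rows: dict[tuple[str, str], dict[str, float]] = {}
    gene_df = assignment.gene_counts.counts
    for gene_id, row in gene_df.iterrows():
        key = ("apis", biotype_of[gene_id])
        acc = rows.setdefault(key, dict.fromkeys(samples, 0.0))
        for sample in samples:
            acc[sample] += float(row.get(sample, 0))
    if assignment.unannotated.sum() > 0:
        rows[("apis", UNANNOTATED)] = {
            s: float(assignment.unannotated.get(s, 0)) for s in samples
        }
    # ambiguous fragments get no gene but still belong to the species total
    if assignment.ambiguous.sum() > 0:
        rows[("apis", "ambiguous")] = {
            s: float(assignment.ambiguous.get(s, 0)) for s in samples
        }
    for frag in viral_frags:
        species = annotation.species_of.get(frag.reference, frag.reference)
        acc = rows.setdefault((species, "NA"), dict.fromkeys(samples, 0.0))
        acc[frag.sample] += 1.0

    counts = pd.DataFrame.from_dict(rows, orient="index", columns=samples).fillna(0.0)
    counts.index = pd.MultiIndex.from_tuples(counts.index, names=["species", "biotype"])
    counts = counts.sort_index()

    matrix = CountMatrix(counts)
    factors = size_factors_mean_ratio(matrix)
    normalized = matrix.normalized()
    fractions = counts.div(counts.sum(axis=0), axis=1)
    keep = (fractions >= min_fraction).any(axis=1)
    report = normalized.loc[keep].copy()
    return CompositionTable(
        counts=counts,
        normalized=normalized,
        fractions=fractions,
        report=report,
        group_of_sample=dict(group_of_sample),
        size_factors=factors,
        min_fraction=min_fraction,
    )


# ---------------------------------------------------------------------------
# Welch test and enrichment report
# ---------------------------------------------------------------------------

def welch_t_test(x_values, y_values) -> tuple[float, float, float]:
    """Two-sided Welch two-sample t test.

    t = (mean_x - mean_y) / sqrt(s2_x/n_x + s2_y/n_y) with
    Welch-Satterthwaite degrees of freedom; p from the Student-t survival
    function.  Requires two values per group; both variances zero is
    degenerate and raises.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise CompositionError("Welch test needs at least two values per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    if vx == 0 and vy == 0:
        if np.isclose(x.mean(), y.mean()):
            return 0.0, float(nx + ny - 2), 1.0
        raise CompositionError("both group variances are zero (degenerate test)")
    se2 = vx / nx + vy / ny
    t_stat = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * student_t.sf(abs(t_stat), df)
    return float(t_stat), float(df), float(min(p, 1.0))


def enrichment_report(
    table: CompositionTable,
    species_a: str = "apis",
    species_b: str = "vdv1",
    alpha: float = 0.05,
    use: Literal["normalized", "fractions"] = "normalized",
) -> pd.DataFrame:
    """Welch-test species_a vs species_b totals within each fraction group.

    Returns one row per sample group with t, df, two-sided p and the
    significance flag at the chosen alpha.  Groups with fewer than two
    replicates are skipped with a warning.
    """
    values = table.normalized if use == "normalized" else table.fractions

    def species_totals(species: str) -> pd.Series:
        if species in values.index.get_level_values("species"):
            return values.loc[species].sum(axis=0)
        return pd.Series(0.0, index=values.columns)

    totals_a = species_totals(species_a)
    totals_b = species_totals(species_b)
    rows = []
    groups = sorted(set(table.group_of_sample.values()))
    for group in groups:
        members = [s for s, g in table.group_of_sample.items() if g == group]
        if len(members) < 2:
            warnings.warn(f"group {group!r} has < 2 replicates; test skipped")
            continue
        t_stat, df, p = welch_t_test(totals_a[members], totals_b[members])
        rows.append(
            {
                "group": group,
                "species_a": species_a,
                "species_b": species_b,
                "n_replicates": len(members),
                "t": t_stat,
                "df": df,
                "p": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Strand-specific coverage
# ---------------------------------------------------------------------------

@dataclass
class CoverageTrack:
    """Per-base coverage of one reference strand."""

    reference: str
    strand: Strand
    values: np.ndarray
    transform: Literal["raw", "log10p1"] = "raw"


def strand_coverage(
    items: Sequence[Fragment] | Sequence[AlignedRead],
    reference: str,
    reference_length: int,
    transform: Literal["raw", "log10p1"] = "raw",
) -> tuple[CoverageTrack, CoverageTrack]:
    """Per-base depth on each strand of one reference.

    With transform="log10p1" the counts x are reported as log10(x + 1), the
    conventional log scale for viral coverage plots.
    """
    tracks = {}
    for strand in ("+", "-"):
        depth = np.zeros(reference_length)
        starts = np.array(
            [it.start for it in items if it.reference == reference and it.strand == strand],
            dtype=int,
        )
        ends = np.array(
            [it.end for it in items if it.reference == reference and it.strand == strand],
            dtype=int,
        )
        np.add.at(depth, starts, 1.0)
        dec = ends[ends < reference_length]
        np.add.at(depth, dec, -1.0)
        depth = np.cumsum(depth)
        if transform == "log10p1":
            depth = np.log10(depth + 1.0)
        tracks[strand] = CoverageTrack(reference, strand, depth, transform)
    return tracks["+"], tracks["-"]
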