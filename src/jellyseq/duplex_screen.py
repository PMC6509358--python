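"""Opposite-strand read-overlap screen for putative dsRNA.

A duplex candidate is a pair of a forward- and a reverse-strand read from
two distinct molecules on the same reference whose positional overlap is at
least ``min_overlap`` (default 25 nt) and whose overhang on either side is
at most ``max_overhang`` (default 100 nt).  Candidates are deduplicated by
their overlap coordinates (the duplexed region), classified against the
gene annotation, quantified per gene, and normalized with median-of-ratios
(DESeq-style) size factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .formats import (
    AlignedRead,
    AnnotatedReference,
    CountMatrix,
    Fragment,
    JellyseqError,
    ValidationError,
)

#: Precedence when a duplex overlaps genes of several biotypes.
_BIOTYPE_PRIORITY = ("tRNA", "pre_miRNA", "protein_coding", "other")


class ScreenError(JellyseqError):
    pass


@dataclass
class ScreenParams:
    """Overlap/overhang rule of the screen."""

    min_overlap: int = 25
    max_overhang: int = 100
    exclude_mates: bool = True
    unit: Literal["read", "fragment"] = "read"
    dedupe_key: Literal["overlap", "union"] = "overlap"

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ScreenError("min_overlap must be >= 1")
        if self.max_overhang < 0:
            raise ScreenError("max_overhang must be >= 0")


@dataclass(frozen=True)
class DuplexCandidate:
    """One opposite-strand read pair passing the overlap/overhang rule."""

    reference: str
    fwd_read: str
    rev_read: str
    fwd_fragment: str
    rev_fragment: str
    overlap_start: int
    overlap_end: int
    union_start: int
    union_end: int
    overlap_len: int
    left_overhang: int
    right_overhang: int
    sample: str = ""


@dataclass
class UniqueDuplex:
    """A deduplicated duplex locus with gene assignment and support."""

    reference: str
    key_start: int
    key_end: int
    length: int
    assigned_genes: tuple[str, ...]
    biotype_class: str
    support: int
    support_by_sample: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Candidate calling
# ---------------------------------------------------------------------------

def _pair_candidate(
    fwd: AlignedRead | Fragment,
    rev: AlignedRead | Fragment,
    params: ScreenParams,
) -> DuplexCandidate | None:
    overlap_start = max(fwd.start, rev.start)
    overlap_end = min(fwd.end, rev.end)
    overlap = overlap_end - overlap_start
    left = max(fwd.start, rev.start) - min(fwd.start, rev.start)
    right = max(fwd.end, rev.end) - min(fwd.end, rev.end)
    if overlap < params.min_overlap or left > params.max_overhang or right > params.max_overhang:
        return None
    fwd_id = getattr(fwd, "read_id", None) or fwd.fragment_id
    rev_id = getattr(rev, "read_id", None) or rev.fragment_id
    if params.exclude_mates and fwd.fragment_id == rev.fragment_id:
        return None
    return DuplexCandidate(
        reference=fwd.reference,
        fwd_read=fwd_id,
        rev_read=rev_id,
        fwd_fragment=fwd.fragment_id,
        rev_fragment=rev.fragment_id,
        overlap_start=overlap_start,
        overlap_end=overlap_end,
        union_start=min(fwd.start, rev.start),
        union_end=max(fwd.end, rev.end),
        overlap_len=overlap,
        left_overhang=left,
        right_overhang=right,
        sample=fwd.sample,
    )


def _validate_candidate(cand: DuplexCandidate, params: ScreenParams) -> None:
    ok = (
        cand.overlap_len == cand.overlap_end - cand.overlap_start
        and cand.overlap_len >= params.min_overlap
        and cand.left_overhang <= params.max_overhang
        and cand.right_overhang <= params.max_overhang
        and (not params.exclude_mates or cand.fwd_fragment != cand.rev_fragment)
    )
    if not ok:
        raise ValidationError(f"candidate violates screen invariants: {cand}")


def call_duplexes(
    reads: Sequence[AlignedRead] | Sequence[Fragment],
    params: ScreenParams | None = None,
) -> list[DuplexCandidate]:
    """Call all opposite-strand pairs passing the overlap/overhang rule.

    Reads are processed per (sample, reference).  Both strand lists are
    sorted by start and joined with a sliding window bounded by the
    max-overhang constraint (|start difference| <= max_overhang is a
    necessary condition for a call), so the all-pairs rule is applied only
    within the window.  With unit="fragment" the inputs must already be
    mate-merged fragments.  Every emitted candidate is re-checked against
    its own invariants.
    """
    params = params or ScreenParams()
    if params.unit == "fragment":
        if any(isinstance(r, AlignedRead) for r in reads):
            raise ScreenError(
                "unit='fragment' requires mate-merged fragments; "
                "merge mates first (composition.merge_fragments)"
            )
    groups: dict[tuple[str, str], tuple[list, list]] = {}
    for read in reads:
        key = (read.sample, read.reference)
        fw, rv = groups.setdefault(key, ([], []))
        (fw if read.strand == "+" else rv).append(read)

    candidates: list[DuplexCandidate] = []
    for (_, _), (fwd_reads, rev_reads) in groups.items():
        fwd_reads.sort(key=lambda r: r.start)
        rev_reads.sort(key=lambda r: r.start)
        rev_starts = [r.start for r in rev_reads]
        j_lo = 0
        for fwd in fwd_reads:
            lo = fwd.start - params.max_overhang
            hi = fwd.start + params.max_overhang
            while j_lo < len(rev_reads) and rev_starts[j_lo] < lo:
                j_lo += 1
            j = j_lo
            while j < len(rev_reads) and rev_starts[j] <= hi:
                cand = _pair_candidate(fwd, rev_reads[j], params)
                if cand is not None:
                    _validate_candidate(cand, params)
                    candidates.append(cand)
                j += 1
    candidates.sort(key=lambda c: (c.reference, c.overlap_start, c.overlap_end, c.sample))
    return candidates


# ---------------------------------------------------------------------------
# Dedup, classification, quantification
# ---------------------------------------------------------------------------

def dedupe_and_classify(
    candidates: Iterable[DuplexCandidate],
    annotation: AnnotatedReference,
    params: ScreenParams | None = None,
) -> list[UniqueDuplex]:
    """Group candidates by their duplicate key and classify each locus.

    The duplicate key is the overlap interval (default) or the union
    interval.  A unique duplex is assigned to every gene whose span
    intersects the *overlap* interval, strand-agnostically (a duplex has
    both strands); with no intersecting gene the class is "unannotated",
    otherwise the highest-priority biotype among assigned genes
    (tRNA > pre_miRNA > protein_coding > other).
    """
    params = params or ScreenParams()
    grouped: dict[tuple[str, int, int], list[DuplexCandidate]] = {}
    for cand in candidates:
        if params.dedupe_key == "union":
            key = (cand.reference, cand.union_start, cand.union_end)
        else:
            key = (cand.reference, cand.overlap_start, cand.overlap_end)
        grouped.setdefault(key, []).append(cand)

    feats_by_ref: dict[str, list] = {}
    for feat in annotation.features:
        feats_by_ref.setdefault(feat.reference, []).append(feat)

    uniques: list[UniqueDuplex] = []
    for (ref, key_start, key_end), group in grouped.items():
        ov_start = min(c.overlap_start for c in group)
        ov_end = max(c.overlap_end for c in group)
        genes = tuple(
            f.gene_id
            for f in feats_by_ref.get(ref, [])
            if f.overlaps(ov_start, ov_end)
        )
        if genes:
            biotypes = {annotation.feature_by_id(g).biotype for g in genes}
            biotype_class = next(b for b in _BIOTYPE_PRIORITY if b in biotypes)
        else:
            biotype_class = "unannotated"
        support_by_sample: dict[str, int] = {}
        for cand in group:
            support_by_sample[cand.sample] = support_by_sample.get(cand.sample, 0) + 1
        uniques.append(
            UniqueDuplex(
                reference=ref,
                key_start=key_start,
                key_end=key_end,
                length=key_end - key_start if params.dedupe_key == "overlap"
                else ov_end - ov_start,
                assigned_genes=genes,
                biotype_class=biotype_class,
                support=len(group),
                support_by_sample=support_by_sample,
            )
        )
    uniques.sort(key=lambda u: (u.reference, u.key_start, u.key_end))
    return uniques


def length_distribution(
    unique_duplexes: Sequence[UniqueDuplex], bin_width: int = 25
) -> pd.DataFrame:
    """Histogram of duplex (overlap) lengths in fixed-width bins."""
    if bin_width < 1:
        raise ScreenError("bin_width must be >= 1")
    if not unique_duplexes:
        return pd.DataFrame(columns=["bin_start", "bin_end", "count"]).astype(int)
    lengths = np.array([u.length for u in unique_duplexes])
    n_bins = int(lengths.max() // bin_width) + 1
    counts = np.bincount(lengths // bin_width, minlength=n_bins)
    nonzero = np.flatnonzero(counts)
    return pd.DataFrame(
        {
            "bin_start": nonzero * bin_width,
            "bin_end": (nonzero + 1) * bin_width,
            "count": counts[nonzero],
        }
    )


def count_duplexes_per_gene(
    unique_duplexes: Sequence[UniqueDuplex],
    samples: Sequence[str],
) -> CountMatrix:
    """Per-gene unique-duplex counts across samples.

    A duplex intersecting k genes increments each of the k gene rows by one
    in every sample where it has candidate support.  Only genes with at
    least one duplex in at least one sample appear.
    """
    counts: dict[str, dict[str, int]] = {}
    for dup in unique_duplexes:
        for gene in dup.assigned_genes:
            row = counts.setdefault(gene, dict.fromkeys(samples, 0))
            for sample, n in dup.support_by_sample.items():
                if n > 0 and sample in row:
                    row[sample] += 1
    df = pd.DataFrame.from_dict(counts, orient="index", columns=list(samples))
    df = df.fillna(0).astype(int).sort_index()
    return CountMatrix(df)


def size_factors_median_ratio(matrix: CountMatrix) -> pd.Series:
    """DESeq-style median-of-ratios size factors.

    For each gene with a positive geometric mean across samples, form the
    ratio of its count in a sample to that geometric mean; the sample's
    factor is the median ratio.
    """
    counts = matrix.counts
    if counts.shape[1] < 2:
        raise ScreenError("median-of-ratios needs at least two samples")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ScreenError(
            "no gene has positive counts in every sample; "
            "consider the mean-ratio size factors instead"
        )
    ref = counts.loc[positive]
    geomeans = pd.Series(gmean(ref, axis=1), index=ref.index)
    factors = ref.div(geomeans, axis=0).median(axis=0)
    matrix.size_factors = factors
    return factors
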