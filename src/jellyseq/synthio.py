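"""Synthetic inputs with the statistical structure the pipeline assumes.

Generates a toy bee chromosome with biotyped genes and unannotated gaps,
viral references, stranded 100 bp paired-end fragments under dUTP chemistry
(including planted opposite-strand duplex pairs with a ground-truth
sidecar), noisy multiphasic MST titrations, and a gene->GO universe with
controllable gene-length bias.  Every generator is a pure function of its
config and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .binding_mst import hill_signal, isotherm
from .formats import (
    AlignedRead,
    AnnotatedReference,
    GeneFeature,
    JellyseqError,
    Strand,
)

logger = logging.getLogger(__name__)

TOTAL_RJ = "total_rj"
MRJP3_BOUND = "mrjp3_bound"

#: Library design of the study being emulated: three total royal-jelly RNA
#: libraries and two MRJP-3 pull-down libraries.
DEFAULT_SAMPLES: tuple[tuple[str, str], ...] = (
    ("RJ_1", TOTAL_RJ),
    ("RJ_2", TOTAL_RJ),
    ("RJ_3", TOTAL_RJ),
    ("MRJP3_1", MRJP3_BOUND),
    ("MRJP3_2", MRJP3_BOUND),
)


class ConfigError(JellyseqError):
    """A simulation config is inconsistent or infeasible."""


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------

@dataclass
class ReferenceConfig:
    """Layout of the toy combined bee + virus reference."""

    bee_length: int = 100_000
    viral_species: tuple[str, ...] = ("vdv1", "dwv")
    viral_length: int = 10_000
    #: biotype proportions for bee genes
    biotype_props: dict[str, float] = field(
        default_factory=lambda: {
            "protein_coding": 0.55,
            "tRNA": 0.25,
            "pre_miRNA": 0.10,
            "other": 0.10,
        }
    )
    gap_range: tuple[int, int] = (100, 600)

    #: gene length ranges per biotype (tRNA / pre-miRNA genes are short)
    length_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "protein_coding": (500, 2500),
            "tRNA": (70, 90),
            "pre_miRNA": (70, 120),
            "other": (200, 1000),
        }
    )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def make_reference(config: ReferenceConfig, seed: int) -> AnnotatedReference:
    """Build a small annotated bee chromosome plus viral references.

    Genes tile the bee chromosome separated by unannotated gaps; each gene
    gets a biotype, a strand, and 1-3 transcript lengths.  Each viral
    reference carries a single genome-spanning gene.  Deterministic given
    the seed.
    """
    rng = np.random.default_rng(seed)
    props = config.biotype_props
    total = sum(props.values())
    if not np.isclose(total, 1.0):
        raise ConfigError(f"biotype proportions sum to {total}, expected 1")
    biotypes = list(props)
    p = np.array([props[b] for b in biotypes])

    sequences = {"bee_chr1": _random_seq(rng, config.bee_length)}
    species_of = {"bee_chr1": "apis"}
    features: list[GeneFeature] = []

    pos = int(rng.integers(*config.gap_range))
    idx = 0
    while True:
        biotype = str(rng.choice(biotypes, p=p))
        lo, hi = config.length_ranges[biotype]
        glen = int(rng.integers(lo, hi + 1))
        if pos + glen > config.bee_length - config.gap_range[0]:
            break
        idx += 1
        n_tx = int(rng.integers(1, 4))
        tlens = tuple(
            int(max(30, round(glen * rng.uniform(0.5, 1.0)))) for _ in range(n_tx)
        )
        features.append(
            GeneFeature(
                gene_id=f"bee_g{idx:04d}",
                reference="bee_chr1",
                start=pos,
                end=pos + glen,
                strand="+" if rng.random() < 0.5 else "-",
                biotype=biotype,
                transcript_lengths=tlens,
            )
        )
        pos += glen + int(rng.integers(*config.gap_range))
    if not features:
        raise ConfigError("requested gene space exceeds chromosome length")

    for virus in config.viral_species:
        sequences[virus] = _random_seq(rng, config.viral_length)
        species_of[virus] = virus
        features.append(
            GeneFeature(
                gene_id=f"{virus}_genome",
                reference=virus,
                start=0,
                end=config.viral_length,
                strand="+",
                biotype="protein_coding",
                transcript_lengths=(config.viral_length,),
            )
        )
    return AnnotatedReference(sequences, features, species_of)


def annotation_gaps(
    reference: AnnotatedReference, ref_name: str
) -> list[tuple[int, int]]:
    """Unannotated intervals of one reference (complement of gene spans)."""
    length = reference.length(ref_name)
    feats = sorted(reference.features_on(ref_name), key=lambda f: f.start)
    gaps = []
    pos = 0
    for f in feats:
        if f.start > pos:
            gaps.append((pos, f.start))
        pos = max(pos, f.end)
    if pos < length:
        gaps.append((pos, length))
    return gaps


# ---------------------------------------------------------------------------
# Stranded paired-end fragments
# ---------------------------------------------------------------------------

@dataclass
class DuplexLocus:
    """A locus where opposite-strand duplex fragment pairs are planted."""

    locus: str | tuple[str, int, int]  # gene_id or (reference, start, end)
    n_pairs: int = 10
    max_offset: int | None = None  # None: read_length - min_overlap


@dataclass
class SimConfig:
    """Stranded paired-end fragment simulation under dUTP chemistry."""

    seed: int
    read_length: int = 100
    n_fragments: int = 4000
    #: default species mix shared by all samples
    species_mix: dict[str, float] = field(
        default_factory=lambda: {"apis": 0.495, "vdv1": 0.495, "dwv": 0.010}
    )
    #: per-group overrides; the MRJP-3 pull-down is VDV-1-enriched
    species_mix_by_group: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            MRJP3_BOUND: {"apis": 0.250, "vdv1": 0.745, "dwv": 0.005},
        }
    )
    #: within-bee biotype mix; "unannotated" draws fragments from gaps
    biotype_mix: dict[str, float] = field(
        default_factory=lambda: {
            "protein_coding": 0.45,
            "tRNA": 0.20,
            "pre_miRNA": 0.05,
            "other": 0.05,
            "unannotated": 0.25,
        }
    )
    duplex_loci: list[DuplexLocus] = field(default_factory=list)
    fragment_length_mean: float = 250.0
    fragment_length_sd: float = 40.0
    fragment_length_max: int = 600
    #: replicate-to-replicate jitter of mixing proportions (logit scale)
    mix_jitter_sd: float = 0.10
    viral_sense_fraction: float = 0.75  # 3:1 sense:antisense
    min_overlap: int = 25
    max_overhang: int = 100
    samples: tuple[tuple[str, str], ...] = DEFAULT_SAMPLES

    def __post_init__(self) -> None:
        for name, mix in [("species_mix", self.species_mix), ("biotype_mix", self.biotype_mix)]:
            if not np.isclose(sum(mix.values()), 1.0):
                raise ConfigError(f"{name} proportions must sum to 1")
        for mix in self.species_mix_by_group.values():
            if not np.isclose(sum(mix.values()), 1.0):
                raise ConfigError("per-group species_mix proportions must sum to 1")


@dataclass
class SimulatedReads:
    """Simulator output: raw-alignment-strand reads plus planted truth.

    ``fragment_senses`` records the true molecule sense strand of every
    simulated fragment — the ground truth that strand correction from SAM
    flags must recover.
    """

    reads: list[AlignedRead]
    truth_duplexes: pd.DataFrame
    group_of_sample: dict[str, str]
    fragment_senses: dict[str, Strand] = field(default_factory=dict)
    n_resampled: int = 0


def _jitter_mix(
    mix: Mapping[str, float], rng: np.random.Generator, sd: float
) -> dict[str, float]:
    keys = list(mix)
    logits = np.log(np.clip([mix[k] for k in keys], 1e-12, None))
    logits = logits + rng.normal(0.0, sd, size=len(keys))
    w = np.exp(logits - logits.max())
    w /= w.sum()
    return dict(zip(keys, w))


def _mate_pair(
    fragment_id: str,
    reference: str,
    fstart: int,
    fend: int,
    sense: Strand,
    read_length: int,
    sample: str,
) -> list[AlignedRead]:
    """Two mates of a fragment under dUTP: mate 2 aligns on the sense strand."""
    mlen = min(read_length, fend - fstart)
    if sense == "+":
        m2 = (fstart, fstart + mlen, "+")
        m1 = (fend - mlen, fend, "-")
    else:
        m2 = (fend - mlen, fend, "-")
        m1 = (fstart, fstart + mlen, "+")
    return [
        AlignedRead(f"{fragment_id}/1", fragment_id, 1, reference, m1[0], m1[1], m1[2], sample),
        AlignedRead(f"{fragment_id}/2", fragment_id, 2, reference, m2[0], m2[1], m2[2], sample),
    ]


def simulate_fragments(
    reference: AnnotatedReference, config: SimConfig
) -> SimulatedReads:
    """Simulate stranded paired-end fragments plus planted duplex pairs.

    Ordinary bee fragments are drawn from gene spans on the gene's sense
    strand (or from unannotated gaps, on the plus strand); viral fragments
    come from both strands at the configured sense:antisense ratio.  Planted
    duplex pairs are two distinct fragments of exactly one read length on
    opposite strands whose overlap and overhangs satisfy the screen rule by
    construction; the ground-truth table is validated before being returned.
    """
    rng = np.random.default_rng(config.seed)
    reads: list[AlignedRead] = []
    truth_rows: list[dict] = []
    n_resampled = 0
    group_of_sample = dict(config.samples)

    genes_by_biotype: dict[str, list[GeneFeature]] = {}
    for feat in reference.features:
        if reference.species_of.get(feat.reference) == "apis":
            genes_by_biotype.setdefault(feat.biotype, []).append(feat)
    gaps = {
        ref: annotation_gaps(reference, ref)
        for ref in reference.references_of_species("apis")
    }

    for sample, group in config.samples:
        base_mix = config.species_mix_by_group.get(group, config.species_mix)
        mix = _jitter_mix(base_mix, rng, config.mix_jitter_sd)
        species_names = list(mix)
        counts = rng.multinomial(config.n_fragments, [mix[s] for s in species_names])
        frag_idx = 0
        for species, n_sp in zip(species_names, counts):
            for _ in range(n_sp):
                frag_idx += 1
                fragment_id = f"{sample}_f{frag_idx:06d}"
                if species == "apis":
                    read_set, resampled = _bee_fragment(
                        fragment_id, sample, reference, config,
                        genes_by_biotype, gaps, rng,
                    )
                else:
                    read_set, resampled = _viral_fragment(
                        fragment_id, sample, reference, species, config, rng
                    )
                n_resampled += resampled
                reads.extend(read_set)

        for li, locus in enumerate(config.duplex_loci):
            ref_name, lo, hi = _resolve_locus(reference, locus.locus)
            max_off = locus.max_offset
            if max_off is None:
                max_off = config.read_length - config.min_overlap
            max_off = min(max_off, config.max_overhang,
                          hi - lo - config.read_length)
            if max_off < 0:
                raise ConfigError(f"duplex locus {locus.locus} shorter than a read")
            for pi in range(locus.n_pairs):
                off = int(rng.integers(0, max_off + 1))
                a = int(rng.integers(lo, hi - config.read_length - off + 1))
                fwd_iv = (a, a + config.read_length)
                rev_iv = (a + off, a + off + config.read_length)
                if rng.random() < 0.5:
                    fwd_iv, rev_iv = rev_iv, fwd_iv
                fwd_id = f"{sample}_dupx{li}_{pi:04d}F"
                rev_id = f"{sample}_dupx{li}_{pi:04d}R"
                reads.extend(
                    _mate_pair(fwd_id, ref_name, *fwd_iv, "+", config.read_length, sample)
                )
                reads.extend(
                    _mate_pair(rev_id, ref_name, *rev_iv, "-", config.read_length, sample)
                )
                ov_start = max(fwd_iv[0], rev_iv[0])
                ov_end = min(fwd_iv[1], rev_iv[1])
                truth_rows.append(
                    {
                        "sample": sample,
                        "reference": ref_name,
                        "fwd_fragment": fwd_id,
                        "rev_fragment": rev_id,
                        "fwd_start": fwd_iv[0],
                        "fwd_end": fwd_iv[1],
                        "rev_start": rev_iv[0],
                        "rev_end": rev_iv[1],
                        "overlap_start": ov_start,
                        "overlap_end": ov_end,
                        "overlap_len": ov_end - ov_start,
                    }
                )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "sample", "reference", "fwd_fragment", "rev_fragment",
            "fwd_start", "fwd_end", "rev_start", "rev_end",
            "overlap_start", "overlap_end", "overlap_len",
        ],
    )
    # planted-truth sidecar must verify against its own constraints
    if len(truth):
        overhang_l = (truth[["fwd_start", "rev_start"]].max(axis=1)
                      - truth[["fwd_start", "rev_start"]].min(axis=1))
        overhang_r = (truth[["fwd_end", "rev_end"]].max(axis=1)
                      - truth[["fwd_end", "rev_end"]].min(axis=1))
        assert (truth["overlap_len"] >= config.min_overlap).all()
        assert (overhang_l <= config.max_overhang).all()
        assert (overhang_r <= config.max_overhang).all()
    if n_resampled:
        logger.info("resampled %d fragments longer than their feature", n_resampled)
    # mate 2 carries the sense strand under dUTP chemistry by construction
    senses: dict[str, Strand] = {
        r.fragment_id: r.strand for r in reads if r.mate == 2
    }
    return SimulatedReads(reads, truth, group_of_sample, senses, n_resampled)


def _resolve_locus(
    reference: AnnotatedReference, locus: str | tuple[str, int, int]
) -> tuple[str, int, int]:
    if isinstance(locus, str):
        feat = reference.feature_by_id(locus)
        return feat.reference, feat.start, feat.end
    return locus


def _fragment_length(config: SimConfig, rng: np.random.Generator) -> int:
    length = int(round(rng.normal(config.fragment_length_mean, config.fragment_length_sd)))
    return int(np.clip(length, config.read_length, config.fragment_length_max))


def _bee_fragment(
    fragment_id: str,
    sample: str,
    reference: AnnotatedReference,
    config: SimConfig,
    genes_by_biotype: dict[str, list[GeneFeature]],
    gaps: dict[str, list[tuple[int, int]]],
    rng: np.random.Generator,
) -> tuple[list[AlignedRead], int]:
    biotypes = list(config.biotype_mix)
    probs = np.array([config.biotype_mix[b] for b in biotypes])
    biotype = str(rng.choice(biotypes, p=probs))
    if biotype == "unannotated":
        ref_name = str(rng.choice(list(gaps)))
        lens = np.array([g[1] - g[0] for g in gaps[ref_name]], dtype=float)
        usable = lens >= config.read_length
        gs, ge = gaps[ref_name][
            int(rng.choice(np.flatnonzero(usable), p=lens[usable] / lens[usable].sum()))
        ]
        flen = min(_fragment_length(config, rng), ge - gs)
        start = int(rng.integers(gs, ge - flen + 1))
        # gap fragments are emitted on the plus strand (no annotation to
        # define sense); keeps noise-free instances free of spurious duplexes
        return _mate_pair(fragment_id, ref_name, start, start + flen,
                          "+", config.read_length, sample), 0
    pool = genes_by_biotype.get(biotype)
    if not pool:
        raise ConfigError(f"no genes of biotype {biotype!r} in the reference")
    resampled = 0
    gene = pool[int(rng.integers(len(pool)))]
    flen = _fragment_length(config, rng)
    if flen > gene.length:
        resampled = 1
        flen = gene.length
    start = gene.start + int(rng.integers(0, gene.length - flen + 1))
    return _mate_pair(fragment_id, gene.reference, start, start + flen,
                      gene.strand, config.read_length, sample), resampled


def _viral_fragment(
    fragment_id: str,
    sample: str,
    reference: AnnotatedReference,
    species: str,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[AlignedRead], int]:
    refs = reference.references_of_species(species)
    if not refs:
        raise ConfigError(f"species {species!r} absent from the reference")
    ref_name = refs[int(rng.integers(len(refs)))]
    length = reference.length(ref_name)
    flen = min(_fragment_length(config, rng), length)
    start = int(rng.integers(0, length - flen + 1))
    sense: Strand = "+" if rng.random() < config.viral_sense_fraction else "-"
    return _mate_pair(fragment_id, ref_name, start, start + flen,
                      sense, config.read_length, sample), 0


# ---------------------------------------------------------------------------
# MST titrations
# ---------------------------------------------------------------------------

@dataclass
class TitrationSimConfig:
    """Noisy multiphasic MST titration, 16-step 1:1-mixed dilution series.

    ``protein_concs`` and ``labeled_conc`` are the *prepared* concentrations;
    mixing the dilution series 1:1 with the labeled species halves both, and
    the returned curve carries the in-capillary values.
    """

    seed: int
    phases: tuple[tuple[float, float], ...] = ((4e-9, 1.0), (3e-7, 1.0), (2.5e-5, 1.0))
    labeled_conc: float = 5e-9
    protein_concs: np.ndarray = field(
        default_factory=lambda: np.geomspace(1e-9, 2e-4, 16)
    )
    baseline: float = 100.0
    noise_sd: float = 0.01  # relative to the dynamic range
    replicates: int = 3

    def __post_init__(self) -> None:
        self.protein_concs = np.asarray(self.protein_concs, dtype=float)
        if len(self.protein_concs) != 16:
            raise ConfigError("a titration is a 16-step dilution series")
        if not np.all(np.diff(self.protein_concs) > 0):
            raise ConfigError("protein concentrations must be strictly increasing")
        if any(kd <= 0 for kd, _ in self.phases):
            raise ConfigError("dissociation constants must be positive")


@dataclass
class TitrationCurve:
    """MST-style signal vs in-capillary protein concentration."""

    protein_concs: np.ndarray  # molar, in-capillary
    signal: np.ndarray  # (n_conc, n_replicates)
    labeled_conc: float  # molar, in-capillary
    kind: str = "binding"  # "binding" | "self_association"

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """All (concentration, signal) points, replicates flattened."""
        n_rep = self.signal.shape[1]
        return np.repeat(self.protein_concs, n_rep), self.signal.ravel()


def simulate_titration(config: TitrationSimConfig) -> TitrationCurve:
    """Simulate a multiphasic ligand-depletion titration with Gaussian noise."""
    rng = np.random.default_rng(config.seed)
    p_eff = config.protein_concs / 2.0
    l_eff = config.labeled_conc / 2.0
    ideal = config.baseline + sum(
        amp * isotherm(p_eff, kd, l_eff) for kd, amp in config.phases
    )
    dynamic_range = sum(abs(amp) for _, amp in config.phases) or 1.0
    noise = rng.normal(0.0, config.noise_sd * dynamic_range,
                       size=(len(p_eff), config.replicates))
    signal = ideal[:, None] + noise
    return TitrationCurve(p_eff, signal, l_eff, kind="binding")


@dataclass
class SelfAssocSimConfig:
    """Self-association titration: labeled monomer vs unlabeled protein."""

    seed: int
    kd_app: float = 3.5e-6
    hill: float = 1.0
    s0: float = 50.0
    delta_s: float = 1.0
    # saturates by ~40 uM added protein, as in the assay being emulated
    concs: np.ndarray = field(default_factory=lambda: np.geomspace(5e-8, 4e-5, 16))
    noise_sd: float = 0.02
    replicates: int = 3

    def __post_init__(self) -> None:
        self.concs = np.asarray(self.concs, dtype=float)
        if self.kd_app <= 0:
            raise ConfigError("kd_app must be positive")


def simulate_self_association(config: SelfAssocSimConfig) -> TitrationCurve:
    """Simulate a Hill-type self-association curve with Gaussian noise."""
    rng = np.random.default_rng(config.seed)
    ideal = hill_signal(config.concs, config.kd_app, config.hill,
                        config.s0, config.delta_s)
    noise = rng.normal(0.0, config.noise_sd * abs(config.delta_s),
                       size=(len(config.concs), config.replicates))
    return TitrationCurve(config.concs, ideal[:, None] + noise,
                          labeled_conc=0.0, kind="self_association")


# ---------------------------------------------------------------------------
# GO universe
# ---------------------------------------------------------------------------

@dataclass
class GoTruth:
    """Ground truth for a simulated gene->GO universe."""

    planted_term: str | None
    interest_genes: set[str]


def make_go_universe(
    reference: AnnotatedReference,
    n_terms: int,
    seed: int,
    *,
    length_bias: bool = False,
    bias_exponent: float = 1.0,
    term_size_range: tuple[int, int] = (5, 40),
    interest_size: int = 100,
    planted_term_size: int = 25,
    planted_enrichment: float = 0.8,
) -> tuple[pd.DataFrame, GoTruth]:
    """Assign GO terms to bee genes, optionally with gene-length bias.

    With bias enabled, the probability that a gene is annotated to a term
    grows with its mean transcript length (weight ~ length**bias_exponent).
    One extra term is planted as truly enriched in a designated interest
    set: ``planted_enrichment`` of its genes are drawn from that set.
    """
    genes = [
        f for f in reference.features
        if reference.species_of.get(f.reference) == "apis"
    ]
    if len(genes) < 50:
        raise ConfigError("reference must carry at least 50 bee genes")
    rng = np.random.default_rng(seed)
    gene_ids = np.array([g.gene_id for g in genes])
    lengths = np.array([g.mean_transcript_length for g in genes])
    weights = lengths ** bias_exponent if length_bias else np.ones(len(genes))
    weights = weights / weights.sum()

    pairs: list[tuple[str, str]] = []
    for t in range(n_terms):
        size = int(rng.integers(*term_size_range))
        members = rng.choice(gene_ids, size=min(size, len(gene_ids)),
                             replace=False, p=weights)
        pairs.extend((g, f"GO:{t:07d}") for g in members)

    # cap the interest set at a third of the universe so the planted term's
    # enrichment stands out against the base rate
    interest = set(rng.choice(gene_ids, size=min(interest_size, len(gene_ids) // 3),
                              replace=False))
    planted = None
    if n_terms > 0:
        planted = "GO:planted"
        n_from_interest = int(round(planted_term_size * planted_enrichment))
        inside = rng.choice(sorted(interest), size=n_from_interest, replace=False)
        outside_pool = sorted(set(gene_ids) - interest)
        outside = rng.choice(outside_pool, size=planted_term_size - n_from_interest,
                             replace=False)
        pairs.extend((g, planted) for g in np.concatenate([inside, outside]))

    mapping = pd.DataFrame(pairs, columns=["gene_id", "term_id"])
    return mapping, GoTruth(planted_term=planted, interest_genes=interest)
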