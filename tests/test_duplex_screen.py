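"""The overlap/overhang screen against a brute-force oracle, plus
deduplication, classification, quantification and normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_read
from jellyseq import composition, duplex_screen
from jellyseq.duplex_screen import (
    DuplexCandidate,
    ScreenError,
    ScreenParams,
    UniqueDuplex,
    call_duplexes,
    count_duplexes_per_gene,
    dedupe_and_classify,
    length_distribution,
    size_factors_median_ratio,
)
from jellyseq.formats import AnnotatedReference, CountMatrix, GeneFeature


def brute_force_pairs(reads, params: ScreenParams):
    """All-pairs oracle: every (forward, reverse) pair passing the rule."""
    called = set()
    for f in reads:
        if f.strand != "+":
            continue
        for r in reads:
            if r.strand != "-" or r.sample != f.sample or r.reference != f.reference:
                continue
            overlap = min(f.end, r.end) - max(f.start, r.start)
            left = abs(f.start - r.start)
            right = abs(f.end - r.end)
            if overlap < params.min_overlap or left > params.max_overhang \
                    or right > params.max_overhang:
                continue
            if params.exclude_mates and f.fragment_id == r.fragment_id:
                continue
            called.add((f.read_id, r.read_id))
    return called


class TestCallDuplexes:
    def test_basic_overlap_geometry(self):
        cands = call_duplexes(
            [make_read(0, 100, "+", "f1"), make_read(60, 160, "-", "f2")]
        )
        (c,) = cands
        assert (c.overlap_start, c.overlap_end, c.overlap_len) == (60, 100, 40)
        assert (c.left_overhang, c.right_overhang) == (60, 60)
        assert (c.union_start, c.union_end) == (0, 160)

    def test_excess_overhang_rejected(self):
        cands = call_duplexes(
            [make_read(0, 200, "+", "f1"), make_read(150, 400, "-", "f2")]
        )
        assert cands == []  # left overhang 150 > 100

    def test_short_overlap_rejected(self):
        cands = call_duplexes(
            [make_read(0, 100, "+", "f1"), make_read(80, 180, "-", "f2")]
        )
        assert cands == []  # overlap 20 < 25

    def test_mate_pair_excluded_by_default(self):
        reads = [make_read(0, 100, "+", "f1", 1), make_read(50, 150, "-", "f1", 2)]
        assert call_duplexes(reads) == []
        params = ScreenParams(exclude_mates=False)
        assert len(call_duplexes(reads, params)) == 1

    def test_samples_screened_independently(self):
        reads = [
            make_read(0, 100, "+", "f1", sample="s1"),
            make_read(50, 150, "-", "f2", sample="s2"),
        ]
        assert call_duplexes(reads) == []

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_sweep_equals_brute_force_oracle(self, seed):
        """Sliding-window join is exactly the all-pairs rule on 200 reads."""
        rng = np.random.default_rng(seed)
        reads = []
        for i in range(200):
            start = int(rng.integers(0, 2000))
            length = int(rng.integers(30, 150))
            reads.append(
                make_read(
                    start, start + length,
                    "+" if rng.random() < 0.5 else "-",
                    f"f{i // 2}", mate=i % 2 + 1,
                    reference=str(rng.choice(["chrA", "chrB"])),
                )
            )
        params = ScreenParams()
        got = {(c.fwd_read, c.rev_read) for c in call_duplexes(reads, params)}
        assert got == brute_force_pairs(reads, params)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_mirror_symmetry(self, seed):
        """Mirroring coordinates (x -> L-x, strands swapped) mirrors the calls."""
        L = 3000
        rng = np.random.default_rng(seed)
        reads, mirrored = [], []
        for i in range(80):
            start = int(rng.integers(0, 2500))
            length = int(rng.integers(30, 150))
            strand = "+" if rng.random() < 0.5 else "-"
            reads.append(make_read(start, start + length, strand, f"f{i}"))
            mirrored.append(
                make_read(
                    L - (start + length), L - start,
                    "-" if strand == "+" else "+", f"f{i}",
                )
            )
        direct = {
            (c.overlap_start, c.overlap_end) for c in call_duplexes(reads)
        }
        image = {
            (L - e, L - s) for s, e in (
                (c.overlap_start, c.overlap_end) for c in call_duplexes(mirrored)
            )
        }
        assert direct == image

    def test_candidates_sorted_and_self_valid(self, default_sim):
        reads = composition.sense_corrected_reads(default_sim.reads)
        bee = [r for r in reads if r.reference == "bee_chr1"]
        cands = call_duplexes(bee)
        keys = [(c.reference, c.overlap_start, c.overlap_end) for c in cands]
        assert keys == sorted(keys)
        for c in cands:
            assert c.overlap_len >= 25
            assert max(c.left_overhang, c.right_overhang) <= 100

    def test_fragment_unit_requires_merged_input(self):
        with pytest.raises(ScreenError, match="mate"):
            call_duplexes(
                [make_read(0, 100, "+", "f1")], ScreenParams(unit="fragment")
            )


class TestDedupeAndClassify:
    @pytest.fixture
    def annotation(self, toy_reference):
        return toy_reference

    def test_identical_overlaps_merge_with_support(self, annotation):
        reads = [
            make_read(100, 200, "+", "a", reference="bee_chr1"),
            make_read(150, 250, "-", "b", reference="bee_chr1"),
            make_read(100, 200, "+", "c", reference="bee_chr1"),
        ]
        uniq = dedupe_and_classify(call_duplexes(reads), annotation)
        (u,) = uniq
        assert u.support == 2
        assert (u.key_start, u.key_end, u.length) == (150, 200, 50)
        assert u.assigned_genes == ("geneA",)
        assert u.biotype_class == "protein_coding"

    def test_trna_classification(self, annotation):
        reads = [
            make_read(500, 580, "+", "a", reference="bee_chr1"),
            make_read(510, 580, "-", "b", reference="bee_chr1"),
        ]
        (u,) = dedupe_and_classify(call_duplexes(reads), annotation)
        assert u.biotype_class == "tRNA"

    def test_gap_overlap_is_unannotated(self, annotation):
        reads = [
            make_read(600, 680, "+", "a", reference="bee_chr1"),
            make_read(610, 690, "-", "b", reference="bee_chr1"),
        ]
        (u,) = dedupe_and_classify(call_duplexes(reads), annotation)
        assert u.assigned_genes == ()
        assert u.biotype_class == "unannotated"

    def test_partial_gene_overlap_assigned_to_gene(self, annotation):
        # overlap [380, 440) crosses geneA's end into the gap
        reads = [
            make_read(380, 460, "+", "a", reference="bee_chr1"),
            make_read(360, 440, "-", "b", reference="bee_chr1"),
        ]
        (u,) = dedupe_and_classify(call_duplexes(reads), annotation)
        assert u.assigned_genes == ("geneA",)

    def test_union_keying_flag(self, annotation):
        reads = [
            make_read(100, 200, "+", "a", reference="bee_chr1"),
            make_read(150, 250, "-", "b", reference="bee_chr1"),
            make_read(120, 200, "+", "c", reference="bee_chr1"),
        ]
        params = ScreenParams(dedupe_key="union")
        uniq = dedupe_and_classify(call_duplexes(reads, params), annotation, params)
        assert len(uniq) == 2  # same overlap, different unions


class TestLengthDistribution:
    def test_empty_input(self):
        hist = length_distribution([], 50)
        assert hist.empty

    def test_binned_counts(self):
        dups = [
            UniqueDuplex("r", 0, n, n, (), "unannotated", 1) for n in (30, 30, 90)
        ]
        hist = length_distribution(dups, 50)
        assert dict(zip(hist["bin_start"], hist["count"])) == {0: 2, 50: 1}

    @pytest.mark.parametrize("bin_width", [1, 10, 25, 100])
    def test_total_invariant_under_bin_width(self, bin_width):
        rng = np.random.default_rng(0)
        dups = [
            UniqueDuplex("r", 0, n, n, (), "unannotated", 1)
            for n in rng.integers(25, 300, size=57)
        ]
        assert length_distribution(dups, bin_width)["count"].sum() == 57

    def test_rejects_bad_bin_width(self):
        with pytest.raises(ScreenError):
            length_distribution([], 0)


class TestCountAndNormalize:
    def test_single_duplex_counts_once(self):
        dup = UniqueDuplex("r", 0, 50, 50, ("g1",), "other", 1, {"s1": 1})
        cm = count_duplexes_per_gene([dup], ["s1", "s2"])
        assert cm.counts.loc["g1", "s1"] == 1
        assert cm.counts.loc["g1", "s2"] == 0

    def test_multi_gene_duplex_increments_each_gene(self):
        dup = UniqueDuplex("r", 0, 50, 50, ("g1", "g2"), "other", 2, {"s1": 2})
        cm = count_duplexes_per_gene([dup], ["s1"])
        assert cm.counts.loc["g1", "s1"] == 1
        assert cm.counts.loc["g2", "s1"] == 1
        # column sum exceeds the unique-duplex count when genes are shared
        assert cm.counts["s1"].sum() == 2 > 1

    def test_median_ratio_worked_example(self):
        """Counts [[10,20],[20,40]]: geometric means sqrt(200), sqrt(800)."""
        cm = CountMatrix(
            pd.DataFrame([[10, 20], [20, 40]], index=["g1", "g2"],
                         columns=["s1", "s2"])
        )
        factors = size_factors_median_ratio(cm)
        assert factors["s1"] == pytest.approx(1 / np.sqrt(2), abs=1e-4)
        assert factors["s2"] == pytest.approx(np.sqrt(2), abs=1e-4)
        normalized = cm.normalized()
        assert normalized.loc["g1", "s1"] == pytest.approx(normalized.loc["g1", "s2"])

    def test_identical_samples_unit_factors(self):
        cm = CountMatrix(
            pd.DataFrame([[5, 5], [9, 9]], index=["a", "b"], columns=["x", "y"])
        )
        assert (size_factors_median_ratio(cm) == 1).all()

    def test_scale_equivariance(self, rng):
        """Scaling one sample's counts by k scales its factor relative to
        the others by k (the geometric-mean reference rescales by k^(1/m),
        so the absolute factor moves by k^((m-1)/m))."""
        counts = pd.DataFrame(
            rng.integers(1, 500, size=(30, 4)),
            index=[f"g{i}" for i in range(30)],
            columns=list("abcd"),
        )
        base = size_factors_median_ratio(CountMatrix(counts))
        scaled_counts = counts.copy()
        scaled_counts["c"] = counts["c"] * 7
        scaled = size_factors_median_ratio(CountMatrix(scaled_counts))
        assert scaled["c"] / scaled["a"] == pytest.approx(7 * base["c"] / base["a"])
        assert scaled["c"] == pytest.approx(7 ** (3 / 4) * base["c"])
        # factors are invariant to scaling every sample alike
        all_scaled = size_factors_median_ratio(CountMatrix(counts * 7))
        assert np.allclose(all_scaled, base)

    def test_all_zero_gene_rows_error(self):
        cm = CountMatrix(
            pd.DataFrame([[0, 3], [4, 0]], index=["a", "b"], columns=["x", "y"])
        )
        with pytest.raises(ScreenError, match="mean-ratio"):
            size_factors_median_ratio(cm)


class TestOnSimulatedData:
    def test_all_planted_pairs_recovered(self, default_sim):
        """Every planted opposite-strand fragment pair is called."""
        reads = composition.sense_corrected_reads(default_sim.reads)
        bee = [r for r in reads if r.reference == "bee_chr1"]
        cands = call_duplexes(bee)
        called_pairs = {
            (c.sample, c.fwd_fragment, c.rev_fragment) for c in cands
        }
        truth = default_sim.truth_duplexes
        for row in truth.itertuples():
            assert (row.sample, row.fwd_fragment, row.rev_fragment) in called_pairs

    def test_no_mate_pairs_and_no_same_sense_calls(self, default_sim):
        """Precision on noise-free data: every call joins two distinct
        molecules of opposite true sense."""
        reads = composition.sense_corrected_reads(default_sim.reads)
        cands = call_duplexes(reads)
        senses = default_sim.fragment_senses
        for c in cands:
            assert c.fwd_fragment != c.rev_fragment
            assert senses[c.fwd_fragment] == "+"
            assert senses[c.rev_fragment] == "-"

    def test_raw_strand_mode_mate_exclusion(self, default_sim):
        """On raw alignment strands, short fragments' mates overlap on
        opposite strands; the fragment-id rule must screen all of them out."""
        cands = call_duplexes(default_sim.reads)  # raw strands
        assert all(c.fwd_fragment != c.rev_fragment for c in cands)
        relaxed = call_duplexes(
            default_sim.reads, ScreenParams(exclude_mates=False)
        )
        mate_calls = [c for c in relaxed if c.fwd_fragment == c.rev_fragment]
        assert len(mate_calls) > 0  # the rule is load-bearing here
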