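import numpy as np
import pytest

import rdna_chromatin as rc
from rdna_chromatin.genome_build import GenomeBuild, Insertion, build_augmented_genome
from rdna_chromatin.mappability import (
    KmerRecord,
    MappabilityParams,
    classify_and_summarize,
    extend_and_count,
    mappability_track,
    reverse_complement,
    tile_kmers,
    unique_hits,
)

from .oracles import brute_force_mappability, genome_occurrences


def _toy_build(seq, repeat_start=0, repeat_len=None):
    repeat_len = repeat_len if repeat_len is not None else len(seq)
    b = GenomeBuild(
        name="toy",
        sequences={"chr1": seq},
        insertion=Insertion("chr1", repeat_start, repeat_len),
    )
    b.validate()
    return b


class TestTileKmers:
    def test_enumeration(self):
        tiles = tile_kmers("ACGTA", 3)
        assert [(t.seq, t.start) for t in tiles] == [("ACG", 0), ("CGT", 1), ("GTA", 2)]

    def test_reverse_strand_tiles_are_reverse_complements(self):
        tiles = tile_kmers("ACGTA", 3, strand="-")
        assert [(t.seq, t.start) for t in tiles] == [("CGT", 0), ("ACG", 1), ("TAC", 2)]

    def test_count_is_length_minus_k_plus_one(self):
        assert len(tile_kmers("A" * 45_309, 36)) == 45_274

    def test_too_short_interval_rejected(self):
        with pytest.raises(ValueError):
            tile_kmers("AC", 3)


class TestUniqueHits:
    def test_single_occurrence_reported_plus_strand(self):
        build = _toy_build("AAAACGTAAAA")
        hits = unique_hits([KmerRecord("ACGT", 3, "+")], build)
        assert hits == [(3, "+")]

    def test_multi_mapper_discarded(self):
        build = _toy_build("ACGTTTTACGT")
        assert unique_hits([KmerRecord("ACGT", 0, "+")], build) == []

    def test_reverse_complement_occurrence_counts(self):
        # "CCCC" appears once forward; "GGGG" elsewhere matches it as revcomp
        build = _toy_build("CCCCAAAGGGGAAA")
        assert unique_hits([KmerRecord("CCCC", 0, "+")], build) == []

    def test_palindromic_kmer_counts_once_per_locus(self):
        # ACGT is its own reverse complement; one locus -> unique
        build = _toy_build("AAAACGTAAAA")
        fwd = KmerRecord("ACGT", 3, "+")
        rev = KmerRecord(reverse_complement("ACGT"), 3, "-")
        hits = unique_hits([fwd, rev], build)
        assert len(hits) == 1  # both-strand tiles collapse to one alignment

    def test_n_kmers_never_match(self):
        build = _toy_build("AANTTAANTT")
        assert unique_hits([KmerRecord("ANTT", 2, "+")], build) == []

    def test_agrees_with_string_scan_oracle(self):
        rng = np.random.default_rng(3)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
        build = _toy_build(seq)
        k = 8
        tiles = tile_kmers(seq, k, "+") + tile_kmers(seq, k, "-")
        hits = set(unique_hits(tiles, build))
        for t in tiles:
            expected_unique = genome_occurrences(build.sequences, t.seq) == 1
            strand = "+" if t.seq == reverse_complement(t.seq) else t.strand
            assert ((t.start, strand) in hits) == expected_unique


class TestExtendAndCount:
    def test_single_plus_hit(self):
        params = MappabilityParams(k=36, ext=200)
        track = extend_and_count([(0, "+")], params, 500)
        assert (track.counts[:200] == 1).all() and (track.counts[200:] == 0).all()

    def test_minus_hit_extends_upstream_with_clipping(self):
        params = MappabilityParams(k=36, ext=200)
        track = extend_and_count([(10, "-")], params, 500)
        # fragment [10+36-200, 46) clipped to [0, 46)
        assert (track.counts[:46] == 1).all() and (track.counts[46:] == 0).all()

    def test_no_hits_gives_zero_track(self):
        track = extend_and_count([], MappabilityParams(), 100)
        assert not track.counts.any()

    def test_interior_of_unique_sequence_reaches_400(self, clean_build):
        track = mappability_track(clean_build)
        L = clean_build.repeat_length
        assert track.max_possible == 400
        assert (track.counts[199 : L - 235] == 400).all()
        assert track.counts.max() == 400


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed,n_pseudo", [(0, 0), (1, 1), (2, 2), (3, 3)])
    def test_matches_brute_force_exactly(self, seed, n_pseudo):
        build, _ = rc.simulate_genome(
            rc.SyntheticGenomeSpec(
                host_length=6_000,
                repeat_length=1_500,
                n_pseudogenes=n_pseudo,
                pseudogene_fraction=0.15,
                seed=seed,
            )
        )
        params = MappabilityParams(k=36, ext=200)
        track = mappability_track(build, params)
        expected = brute_force_mappability(
            build.sequences, build.repeat_sequence(), k=36, ext=200
        )
        np.testing.assert_array_equal(track.counts, expected)

    def test_adding_pseudogene_never_increases_counts(self):
        spec0 = rc.SyntheticGenomeSpec(
            host_length=6_000, repeat_length=1_500, n_pseudogenes=0, seed=5
        )
        build0, _ = rc.simulate_genome(spec0)
        counts0 = mappability_track(build0).counts
        # paste a copy of repeat[200:500] into the host portion
        repeat = build0.repeat_sequence()
        chrom = build0.insertion.chrom
        seq = build0.sequences[chrom]
        mutated = seq[:3000] + repeat[200:500] + seq[3300:]
        build1 = GenomeBuild(
            name="b1", sequences={chrom: mutated}, insertion=build0.insertion
        )
        build1.validate()
        counts1 = mappability_track(build1).counts
        assert (counts1 <= counts0).all()
        assert (counts1 < counts0).any()

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(9)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1_200)])
        fwd = _toy_build(seq, 0, 400)
        counts_fwd = mappability_track(fwd, MappabilityParams(k=10, ext=40)).counts
        rc_seq = reverse_complement(seq)
        # the repeat interval [0, 400) maps to [len-400, len) on the revcomp
        rev = GenomeBuild(
            name="rev",
            sequences={"chr1": rc_seq},
            insertion=Insertion("chr1", len(seq) - 400, 400),
        )
        counts_rev = mappability_track(rev, MappabilityParams(k=10, ext=40)).counts
        np.testing.assert_array_equal(counts_rev, counts_fwd[::-1])


class TestClassifyAndSummarize:
    def test_all_zero_track_is_fully_unmappable(self):
        params = MappabilityParams()
        track = extend_and_count([], params, 100)
        (overall,) = classify_and_summarize(track)
        assert overall.bases_above_threshold == 0
        assert overall.fraction_above_threshold == 0.0

    def test_half_mappable_feature(self):
        from rdna_chromatin.genome_build import RepeatAnnotation
        from rdna_chromatin.mappability import MappabilityTrack

        params = MappabilityParams()
        counts = np.array([400] * 50 + [0] * 50)
        track = MappabilityTrack(counts=counts, params=params)
        ann = RepeatAnnotation(features=[("all", 0, 100)], repeat_length=100)
        overall, feat = classify_and_summarize(track, ann)
        assert feat.fraction_above_threshold == 0.5
        assert overall.fraction_above_threshold == 0.5

    def test_threshold_is_strict(self):
        from rdna_chromatin.mappability import MappabilityTrack

        params = MappabilityParams()  # cutoff = 0.25 * 400 = 100
        track = MappabilityTrack(counts=np.array([100, 101, 99]), params=params)
        (overall,) = classify_and_summarize(track)
        assert overall.bases_above_threshold == 1  # only the 101

    def test_length_mismatch_rejected(self):
        from rdna_chromatin.genome_build import RepeatAnnotation
        from rdna_chromatin.mappability import MappabilityTrack

        track = MappabilityTrack(counts=np.zeros(50, dtype=int), params=MappabilityParams())
        ann = RepeatAnnotation(features=[("f", 0, 10)], repeat_length=60)
        with pytest.raises(ValueError):
            classify_and_summarize(track, ann)

    def test_paper_scale_fractions_hand_computable(self):
        """Feature summaries on a constructed track with known fractions:
        coding 60% mappable, spacer 20%, overall weighted mix."""
        from rdna_chromatin.genome_build import RepeatAnnotation
        from rdna_chromatin.mappability import MappabilityTrack

        params = MappabilityParams()
        counts = np.concatenate(
            [
                np.full(600, 400),  # coding: 600 of 1000 mappable
                np.full(400, 0),
                np.full(100, 300),  # spacer: 100 of 500 mappable
                np.full(400, 50),
            ]
        )
        track = MappabilityTrack(counts=counts, params=params)
        ann = RepeatAnnotation(
            features=[("coding", 0, 1000), ("spacer", 1000, 1500)], repeat_length=1500
        )
        overall, coding, spacer = classify_and_summarize(track, ann)
        assert coding.fraction_above_threshold == pytest.approx(0.6)
        assert spacer.fraction_above_threshold == pytest.approx(0.2)
        assert overall.bases_above_threshold == 700
        assert overall.fraction_above_threshold == pytest.approx(700 / 1500)
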