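"""Adapter trimming, read placement, peak calling, summit windows."""

import numpy as np
import pytest

from gselexmine._seq import revcomp
from gselexmine.selex_sim import emit_reads, run_selection, AffinityModel
from gselexmine.synthetic_data import (
    DEFAULT_LINKER_5,
    build_library,
    generate_genome,
)
from gselexmine.tagproc import (
    AlignedTag,
    GenomeIndex,
    Peak,
    call_peaks,
    extract_windows,
    map_read_pairs,
    map_reads,
    trim_adapters,
)

L5 = DEFAULT_LINKER_5


class TestTrimAdapters:
    def test_full_5prime_adapter_removed(self):
        insert = "ACGTACGTACGTACGTACGTACGT"
        [(_, trimmed)] = trim_adapters([("r", L5 + insert)])
        assert trimmed == insert

    def test_read_without_adapter_unchanged(self):
        seq = "TATATATAGCGCGCGCATATTATA"
        assert trim_adapters([("r", seq)]) == [("r", seq)]

    def test_overlap_below_threshold_not_trimmed(self):
        insert = "ACGTACGTACGTACGTACGTACGT"
        seq = L5[-14:] + insert  # 14 < min_overlap of 15
        assert trim_adapters([("r", seq)]) == [("r", seq)]

    def test_partial_adapter_suffix_at_read_start_removed(self):
        insert = "ACGTACGTACGTACGTACGTACGT"
        seq = L5[-20:] + insert
        assert trim_adapters([("r", seq)]) == [("r", insert)]

    def test_3prime_adapter_removed_from_read_end(self):
        insert = "ACGTACGTACGTACGTACGTACGT"
        seq = insert + revcomp(L5)[:18]
        assert trim_adapters([("r", seq)]) == [("r", insert)]

    def test_short_reads_discarded_after_trimming(self):
        assert trim_adapters([("r", L5 + "ACGTACGT")]) == []


class TestMapping:
    def test_exact_read_maps_to_its_interval(self, small_genome):
        seq = small_genome.contigs["chr1"][1000:1050]
        [tag] = map_reads([("r", seq)], small_genome)
        assert (tag.contig, tag.start, tag.end, tag.strand) == ("chr1", 1000, 1050, "+")

    def test_reverse_complement_read_maps_minus_strand(self, small_genome):
        seq = revcomp(small_genome.contigs["chr1"][2000:2040])
        [tag] = map_reads([("r", seq)], small_genome)
        assert (tag.contig, tag.start, tag.end, tag.strand) == ("chr1", 2000, 2040, "-")

    def test_multi_locus_read_discarded(self):
        genome = generate_genome(1, 3000, seed=1)
        seq = genome.contigs["chr1"]
        dup = seq[:500] + seq[100:140] + seq[540:]  # second copy of [100,140)
        genome.contigs["chr1"] = dup
        assert map_reads([("r", seq[100:140])], genome) == []

    def test_one_mismatch_tolerated_when_allowed(self, small_genome):
        seq = list(small_genome.contigs["chr2"][500:550])
        seq[25] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[25]]
        read = "".join(seq)
        assert map_reads([("r", read)], small_genome, max_mismatches=0) == []
        [tag] = map_reads([("r", read)], small_genome, max_mismatches=1)
        assert (tag.contig, tag.start) == ("chr2", 500)

    def test_concordant_pair_merges_to_fragment_interval(self, small_genome):
        frag = small_genome.contigs["chr1"][3000:3100]
        r1 = frag[:40]
        r2 = revcomp(frag)[:40]
        [tag] = map_read_pairs([("p", r1)], [("p", r2)], small_genome)
        assert (tag.start, tag.end) == (3000, 3100)

    def test_trim_then_map_round_trip_recovers_fragments(self, small_genome):
        """With no sequencing errors every uniquely placed fragment is exact."""
        lib = build_library(small_genome, 300, seed=21)
        rounds = run_selection(lib, AffinityModel(), rounds=1, seed=0)
        r1, r2 = emit_reads(rounds[0], lib, read_len=75, n_read_pairs=300,
                            substitution_rate=0.0, seed=5)
        t1, t2 = trim_adapters(r1), trim_adapters(r2)
        index = GenomeIndex(small_genome)
        tags = map_read_pairs(t1, t2, small_genome, index=index)
        true_intervals = {(f.contig, f.start, f.end) for f in lib.fragments}
        recovered = sum((t.contig, t.start, t.end) in true_intervals for t in tags)
        assert recovered / len(tags) > 0.95  # repeats/ambiguity may drop a few


class TestCallPeaks:
    def test_identical_pools_give_zero_peaks(self, small_genome, small_library):
        tags = [AlignedTag(f.contig, f.start, f.end, f.strand)
                for f in small_library.fragments]
        assert call_peaks(tags, tags, small_genome) == []

    def test_empty_control_rejected(self, small_genome):
        tags = [AlignedTag("chr1", 0, 100, "+")]
        with pytest.raises(ValueError):
            call_peaks(tags, [], small_genome)

    def test_planted_enrichment_yields_one_peak_with_summit_inside(self, small_genome):
        rng = np.random.default_rng(17)
        clen = len(small_genome.contigs["chr1"])
        region = (5000, 5200)

        def uniform_tags(n):
            starts = rng.integers(0, clen - 100, size=n)
            return [AlignedTag("chr1", int(s), int(s) + 100, "+") for s in starts]

        ctrl = uniform_tags(20_000)
        extra = [AlignedTag("chr1", int(s), int(s) + 100, "+")
                 for s in rng.integers(region[0] - 60, region[1] - 40, size=1200)]
        sel = uniform_tags(20_000 - len(extra)) + extra
        peaks = call_peaks(sel, ctrl, small_genome)
        overlapping = [p for p in peaks if p.start < region[1] and p.end > region[0]]
        assert len(overlapping) == 1
        peak = overlapping[0]
        assert peak.start - 150 <= peak.summit <= peak.end + 150
        assert peak.start <= peak.summit < peak.end

    def test_fold_enrichment_tracks_planted_ratio(self, small_genome):
        rng = np.random.default_rng(23)
        clen = len(small_genome.contigs["chr1"])
        base = 20_000
        ctrl = [AlignedTag("chr1", int(s), int(s) + 100, "+")
                for s in rng.integers(0, clen - 100, size=base)]
        # 10x local enrichment over [8000, 8200)
        extra = [AlignedTag("chr1", int(s), int(s) + 100, "+")
                 for s in rng.integers(7900, 8100, size=1500)]
        sel = [AlignedTag("chr1", int(s), int(s) + 100, "+")
               for s in rng.integers(0, clen - 100, size=base - len(extra))] + extra
        peaks = [p for p in call_peaks(sel, ctrl, small_genome)
                 if p.start < 8200 and p.end > 8000]
        assert peaks
        cov_ctrl = base * 100 / clen  # expected per-base control coverage
        cov_uniform = (base - 1500) * 100 / clen
        cov_plateau = 1500 * 100 / 200  # extra fragments plateau over the 200-bp span
        planted_ratio = (cov_uniform + cov_plateau) / cov_ctrl
        assert abs(peaks[0].fold_enrichment - planted_ratio) / planted_ratio < 0.3

    def test_ranking_is_a_permutation_ordered_by_fe(self, small_genome):
        rng = np.random.default_rng(5)
        clen = len(small_genome.contigs["chr1"])
        ctrl = [AlignedTag("chr1", int(s), int(s) + 100, "+")
                for s in rng.integers(0, clen - 100, size=10_000)]
        sel = list(ctrl)
        for center, n in ((3000, 900), (9000, 500), (15000, 250)):
            sel += [AlignedTag("chr1", int(s), int(s) + 100, "+")
                    for s in rng.integers(center - 100, center + 100, size=n)]
        peaks = call_peaks(sel, ctrl, small_genome)
        assert sorted(p.rank for p in peaks) == list(range(1, len(peaks) + 1))
        fes = [p.fold_enrichment for p in sorted(peaks, key=lambda p: p.rank)]
        assert fes == sorted(fes, reverse=True)
        assert max(p.fold_enrichment for p in peaks) == fes[0]


class TestExtractWindows:
    def test_default_window_is_50bp_centered_on_summit(self, small_genome):
        peak = Peak("chr1", 80, 130, 100, 5.0, 1e-9, rank=1)
        [w] = extract_windows([peak], small_genome)
        assert (w.start, w.end) == (76, 126)
        assert len(w.sequence) == 50
        assert w.sequence == small_genome.contigs["chr1"][76:126]
        assert not w.truncated

    def test_window_near_contig_start_is_clipped_and_flagged(self, small_genome):
        peak = Peak("chr1", 0, 50, 10, 5.0, 1e-9, rank=1)
        [w] = extract_windows([peak], small_genome)
        assert w.start == 0 and w.truncated

    def test_zero_flanks_give_single_base_window(self, small_genome):
        peak = Peak("chr1", 90, 140, 100, 5.0, 1e-9, rank=1)
        [w] = extract_windows([peak], small_genome, flank_left=0, flank_right=0)
        assert len(w.sequence) == 1
        assert w.sequence == small_genome.contigs["chr1"][100]

    def test_49bp_variant_supported(self, small_genome):
        peak = Peak("chr1", 80, 130, 100, 5.0, 1e-9, rank=1)
        [w] = extract_windows([peak], small_genome, flank_left=24, flank_right=24)
        assert len(w.sequence) == 49


def test_null_label_permutation_rarely_yields_peaks(small_genome):
    """Exchangeable selected/control tags: 0 peaks in >=95% of 100 trials."""
    lib = build_library(small_genome, 8000, seed=0)
    tags = [AlignedTag(f.contig, f.start, f.end, f.strand) for f in lib.fragments]
    rng = np.random.default_rng(1234)
    zero = 0
    for _ in range(100):
        perm = rng.permutation(len(tags))
        sel = [tags[i] for i in perm[:4000]]
        ctrl = [tags[i] for i in perm[4000:]]
        zero += len(call_peaks(sel, ctrl, small_genome)) == 0
    assert zero >= 95
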