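"""m6A/m6Am classification: merging, extension, DRACH anchoring, 5'UTR rule."""

import numpy as np
import pytest

from clipmod import (
    ClassifyParams,
    GenomicInterval,
    classify_sites,
    load_annotation,
)
from clipmod.annotation import AnnotationIndex, TranscriptModel, reverse_complement
from clipmod.cits import CitsPeak
from clipmod.io import write_methyl_bed
from clipmod.modsite import (
    MergedInterval,
    call_m6a,
    call_m6am,
    extend_peaks,
    is_drach,
    merge_miclip_cits,
)

from conftest import site_key, truth_keys


def peak(chrom, pos, strand, k=3):
    return CitsPeak(GenomicInterval(chrom, pos, pos + 1, strand), k=k, n=k, L=100,
                    p_value=0.001, q_value=0.005)


def seq_index(seq: str, strand_seqs=None) -> AnnotationIndex:
    """Annotation-free index over a literal chr1 sequence (plus optional others)."""
    genome = {"chr1": seq.upper()}
    if strand_seqs:
        genome.update({k: v.upper() for k, v in strand_seqs.items()})
    return AnnotationIndex({}, genome)


class TestMergeMiclip:
    def test_gap1_spanning_interval(self):
        merged = merge_miclip_cits([peak("chr1", 100, "+")], [peak("chr1", 102, "+")], gap=1)
        assert len(merged) == 1
        iv = merged[0].interval
        assert (iv.start, iv.end) == (100, 103)

    def test_two_intervening_bases_stay_separate(self):
        merged = merge_miclip_cits([peak("chr1", 100, "+")], [peak("chr1", 103, "+")], gap=1)
        assert len(merged) == 2

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError, match="2 replicates"):
            merge_miclip_cits([peak("chr1", 100, "+")], gap=1)

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            gap = int(rng.integers(0, 3))
            a = [peak("chr1", int(p), "+") for p in np.unique(rng.integers(0, 200, 20))]
            b = [peak("chr1", int(p), "+") for p in np.unique(rng.integers(0, 200, 20))]
            merged = merge_miclip_cits(a, b, gap=gap)
            # oracle: exhaustive transitive closure over pooled positions
            pool = sorted({site_key(x)[2] for x in a + b})
            clusters, cur = [], [pool[0]]
            for p in pool[1:]:
                if p - cur[-1] <= gap + 1:
                    cur.append(p)
                else:
                    clusters.append(cur)
                    cur = [p]
            clusters.append(cur)
            assert [(m.interval.start, m.interval.end) for m in merged] == [
                (c[0], c[-1] + 1) for c in clusters
            ]


class TestExtendPeaks:
    @pytest.mark.parametrize(
        "start,end,expected",
        [((100, 101), None, (98, 103)), ((0, 1), None, (0, 3)), ((100, 103), None, (98, 105))],
    )
    def test_symmetric_extension(self, start, end, expected):
        iv = GenomicInterval("chr1", *start, "+")
        out = extend_peaks([iv], extend=2)
        assert (out[0].interval.start, out[0].interval.end) == expected

    def test_capped_at_chromosome_end(self):
        iv = GenomicInterval("chr1", 98, 100, "+")
        out = extend_peaks([iv], extend=5, chrom_sizes={"chr1": 101})
        assert (out[0].interval.start, out[0].interval.end) == (93, 101)


def brute_force_m6a(index: AnnotationIndex, intervals, flank=2):
    """Independent 5-mer enumeration over every genomic position."""
    sites = set()
    for m in intervals:
        iv = m.interval
        seq = index.genome[iv.chrom]
        for center in range(iv.start, iv.end):
            lo, hi = center - 2, center + 3
            if lo < 0 or hi > len(seq):
                continue
            if abs(center - iv.start) > len(iv) + flank or hi > iv.end + flank or lo < iv.start - flank:
                pass  # window may extend flank nt beyond the peak
            kmer = seq[lo:hi]
            if iv.strand == "-":
                kmer = reverse_complement(kmer)
            if is_drach(kmer):
                sites.add((iv.chrom, iv.strand, center))
    return sites


class TestCallM6a:
    def test_ggacu_center_a_called(self):
        #            0123456789
        index = seq_index("TTGGACTTTT")
        iv = MergedInterval(GenomicInterval("chr1", 4, 5, "+"), 3, (4,))
        sites = call_m6a([iv], index)
        assert [site_key(s) for s in sites] == [("chr1", "+", 4)]
        assert sites[0].motif == "GGACT"

    def test_no_central_a_no_site(self):
        index = seq_index("TTGGGCTTTT")
        iv = MergedInterval(GenomicInterval("chr1", 4, 5, "+"), 3, (4,))
        assert call_m6a([iv], index) == []

    def test_minus_strand_motif(self):
        # sense GGACT on minus = genomic AGTCC reverse-complemented
        index = seq_index(reverse_complement("TTGGACTTTT"))
        iv = MergedInterval(GenomicInterval("chr1", 5, 6, "-"), 3, (5,))
        sites = call_m6a([iv], index)
        assert [site_key(s) for s in sites] == [("chr1", "-", 5)]
        assert sites[0].motif == "GGACT"

    def test_central_a_must_lie_inside_peak(self):
        # DRACH at center 7 but peak covers only position 4
        index = seq_index("TTTTTGGACTTT")
        iv = MergedInterval(GenomicInterval("chr1", 4, 5, "+"), 3, (4,))
        assert call_m6a([iv], index) == []
        # widening the peak to include the A recovers it
        iv2 = MergedInterval(GenomicInterval("chr1", 4, 8, "+"), 3, (4,))
        assert [site_key(s) for s in call_m6a([iv2], index)] == [("chr1", "+", 7)]

    def test_n_in_window_never_matches(self):
        index = seq_index("TTGGNCTTTT")
        iv = MergedInterval(GenomicInterval("chr1", 4, 5, "+"), 3, (4,))
        assert call_m6a([iv], index) == []

    def test_matches_brute_force_enumeration(self, sim_index):
        rng = np.random.default_rng(8)
        chroms = sorted(sim_index.genome)
        intervals = []
        for _ in range(500):
            chrom = chroms[rng.integers(len(chroms))]
            start = int(rng.integers(10, sim_index.chrom_length(chrom) - 20))
            width = int(rng.integers(1, 8))
            strand = "+" if rng.integers(2) == 0 else "-"
            intervals.append(
                MergedInterval(GenomicInterval(chrom, start, start + width, strand), 1, (start,))
            )
        got = {site_key(s) for s in call_m6a(intervals, sim_index)}
        assert got == brute_force_m6a(sim_index, intervals)


class TestCallM6am:
    def _utr5_index(self):
        """Single + strand transcript, utr5 [0,200), on a controllable genome."""
        seq = list("C" * 400)
        tx = TranscriptModel(
            "t", "g", "+",
            exons=[GenomicInterval("chr1", 0, 400, "+")],
            cds_span=(200, 350),
        )
        return seq, tx

    def _index_with(self, seq, tx):
        return AnnotationIndex({tx.transcript_id: tx}, {"chr1": "".join(seq)})

    def test_candidate_in_first_quarter_kept(self):
        seq, tx = self._utr5_index()
        seq[30] = "A"
        index = self._index_with(seq, tx)
        iv = MergedInterval(GenomicInterval("chr1", 28, 33, "+"), 2, (30,))
        sites = call_m6am([iv], [], index)
        assert [site_key(s) for s in sites] == [("chr1", "+", 30)]

    def test_candidate_beyond_quarter_dropped(self):
        seq, tx = self._utr5_index()
        seq[80] = "A"  # offset 80 of a 200-nt utr5; quarter = 50
        index = self._index_with(seq, tx)
        iv = MergedInterval(GenomicInterval("chr1", 78, 83, "+"), 2, (80,))
        assert call_m6am([iv], [], index) == []

    def test_coinciding_m6a_site_excluded(self):
        seq, tx = self._utr5_index()
        seq[30] = "A"
        index = self._index_with(seq, tx)
        iv = MergedInterval(GenomicInterval("chr1", 28, 33, "+"), 2, (30,))
        m6a = call_m6a(
            [MergedInterval(GenomicInterval("chr1", 30, 31, "+"), 1, (30,))], index
        )  # no DRACH here, so fabricate the exclusion set directly
        from clipmod.modsite import MethylSite

        blocker = MethylSite(GenomicInterval("chr1", 30, 31, "+"), "m6A", "GGACT",
                             GenomicInterval("chr1", 28, 33, "+"), 1)
        assert call_m6am([iv], [blocker], index) == []

    def test_run_representative_is_five_prime_most(self):
        seq, tx = self._utr5_index()
        for p in (30, 31, 32):
            seq[p] = "A"
        index = self._index_with(seq, tx)
        iv = MergedInterval(GenomicInterval("chr1", 29, 34, "+"), 2, (31,))
        sites = call_m6am([iv], [], index)
        assert [site_key(s) for s in sites] == [("chr1", "+", 30)]
        assert sites[0].motif == "A3"

    def test_minus_strand_five_prime_most_is_genomic_right(self):
        seq = list("G" * 400)
        tx = TranscriptModel(
            "t", "g", "-",
            exons=[GenomicInterval("chr1", 0, 400, "-")],
            cds_span=(50, 200),  # utr5 = [200, 400) on minus
        )
        for p in (370, 371, 372):
            seq[p] = "T"  # sense A on minus strand
        index = AnnotationIndex({"t": tx}, {"chr1": "".join(seq)})
        iv = MergedInterval(GenomicInterval("chr1", 369, 374, "-"), 2, (371,))
        sites = call_m6am([iv], [], index)
        # transcript-sense 5'-most A of the run is the genomically rightmost T
        assert [site_key(s) for s in sites] == [("chr1", "-", 372)]


@pytest.fixture(scope="module")
def classified(sim_spec, sim_data, sim_index):
    from clipmod import CitsParams, call_cits, extract_truncations, simulate_clip_library

    truth = sim_data["truth"]
    reps = []
    for rep in (1, 2):
        df, _ = simulate_clip_library(sim_spec, truth, "wildtype", rep, assay="miclip")
        reps.append(call_cits(extract_truncations(df, f"rep{rep}"), sim_index, CitsParams()))
    return classify_sites(reps[0], reps[1], sim_index)


class TestClassifyPipeline:
    def test_planted_sites_recovered(self, classified, sim_data):
        m6a, m6am = classified
        truth = sim_data["truth"]
        got_a, got_am = {site_key(s) for s in m6a}, {site_key(s) for s in m6am}
        t_a, t_am = truth_keys(truth.m6a_sites), truth_keys(truth.m6am_sites)
        assert len(got_a & t_a) / len(t_a) >= 0.9
        assert len(got_a & t_a) / max(len(got_a), 1) >= 0.9
        assert len(got_am & t_am) / len(t_am) >= 0.9

    def test_output_sets_disjoint(self, classified):
        m6a, m6am = classified
        assert {site_key(s) for s in m6a}.isdisjoint({site_key(s) for s in m6am})

    def test_every_m6a_has_drach_centered_a(self, classified, sim_index):
        m6a, _ = classified
        for s in m6a:
            kmer = sim_index.sequence(s.site.chrom, s.site.start - 2, s.site.start + 3)
            if s.site.strand == "-":
                kmer = reverse_complement(kmer)
            assert is_drach(kmer) and kmer[2] == "A"

    def test_every_m6am_in_first_quarter_of_a_utr5(self, classified, sim_index):
        from clipmod.modsite import _in_first_utr5_fraction

        _, m6am = classified
        assert m6am, "no m6Am sites classified"
        for s in m6am:
            assert _in_first_utr5_fraction(sim_index, s.site.chrom, s.site.strand,
                                           s.site.start, 0.25)

    def test_byte_identical_bed_output(self, classified, tmp_path):
        m6a, _ = classified
        for i in (1, 2):
            write_methyl_bed(m6a, tmp_path / f"out{i}.bed")
        assert (tmp_path / "out1.bed").read_bytes() == (tmp_path / "out2.bed").read_bytes()
        assert (tmp_path / "out1.bed").read_bytes()  # non-empty
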