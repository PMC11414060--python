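"""m6A / m6Am site classification from anti-m6A miCLIP CITS peaks.

The procedure: CITS from two miCLIP replicates are merged at a maximum
gap of 1 bp, each merged peak is extended 2 nt on both sides, and

* m6A — extended peaks containing a DRACH 5-mer (D=[AGU], R=[AG], A, C,
  H=[ACU]; DNA alphabet T<->U) on the sense strand are kept, and the
  coordinate of the motif's central A becomes the m6A site;
* m6Am — extended peaks containing at least one sense-strand A are kept,
  consecutive As are merged into runs, the 5'-most A of each run (in
  transcript sense) becomes a candidate, candidates are restricted to the
  first quarter of an annotated 5'UTR, and any candidate coinciding with
  an m6A coordinate is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .annotation import (
    UTR5,
    AnnotationIndex,
    GenomicInterval,
    genomic_to_meta,
    reverse_complement,
)
from .cits import MergedSite, _chrom, _pos, _strand, _support, cluster_sites

# DNA-alphabet DRACH character classes, position 2 is the methylated A
DRACH_CLASSES = ("AGT", "AG", "A", "C", "ACT")


def is_drach(kmer: str) -> bool:
    return len(kmer) == 5 and all(b in cls for b, cls in zip(kmer, DRACH_CLASSES))


@dataclass
class ClassifyParams:
    merge_gap: int = 1        # max intervening bases when merging replicate CITS
    extend: int = 2           # nt added on both sides of a merged peak
    utr5_fraction: float = 0.25  # m6Am must fall in the first quarter of a 5'UTR
    motif_flank: int = 2      # DRACH bases may extend this far beyond the peak


@dataclass(frozen=True)
class MethylSite:
    """A classified site: the A coordinate, class label and evidence."""

    site: GenomicInterval      # length-1 interval of the A (sense strand)
    klass: str                 # "m6A" or "m6Am"
    motif: str                 # DRACH 5-mer (m6A) or A-run descriptor (m6Am)
    source_peak: GenomicInterval
    support: int

    def __post_init__(self):
        if self.klass not in ("m6A", "m6Am"):
            raise ValueError(f"unknown class {self.klass!r}")


@dataclass(frozen=True)
class MergedInterval:
    """Replicate-merged miCLIP peak: spanning interval + member evidence."""

    interval: GenomicInterval
    support: int
    member_positions: tuple[int, ...]


def merge_miclip_cits(*replicates: Sequence, gap: int = 1) -> list[MergedInterval]:
    """Merge miCLIP CITS across >=2 replicates into spanning intervals.

    Sites with at most ``gap`` intervening bases cluster together; each
    merged interval spans its member sites and records summed support.
    """
    if len(replicates) < 2:
        raise ValueError("miCLIP merging is defined on at least 2 replicates")
    pooled = [p for rep in replicates for p in rep]
    out = []
    for cluster in cluster_sites(pooled, gap):
        positions = tuple(sorted({_pos(r) for r in cluster}))
        out.append(
            MergedInterval(
                interval=GenomicInterval(
                    _chrom(cluster[0]), positions[0], positions[-1] + 1, _strand(cluster[0])
                ),
                support=sum(_support(r) for r in cluster),
                member_positions=positions,
            )
        )
    out.sort(key=lambda m: (m.interval.chrom, m.interval.start, m.interval.strand))
    return out


def extend_peaks(
    intervals: Sequence[MergedInterval | GenomicInterval],
    extend: int,
    chrom_sizes: Optional[dict[str, int]] = None,
) -> list[MergedInterval]:
    """Symmetric, strand-independent extension, clipped to [0, chrom length)."""
    out = []
    for item in intervals:
        iv = item.interval if isinstance(item, MergedInterval) else item
        start = max(0, iv.start - extend)
        end = iv.end + extend
        if chrom_sizes is not None and iv.chrom in chrom_sizes:
            end = min(end, chrom_sizes[iv.chrom])
        ext = GenomicInterval(iv.chrom, start, end, iv.strand)
        if isinstance(item, MergedInterval):
            out.append(MergedInterval(ext, item.support, item.member_positions))
        else:
            out.append(MergedInterval(ext, 1, (iv.start,)))
    return out


def _sense_window(index: AnnotationIndex, iv: GenomicInterval, pad: int) -> tuple[str, int]:
    """Sense-strand sequence of iv padded by ``pad`` nt each side.

    Returns (sequence, genomic start of the window).  Padding is clipped
    at chromosome boundaries; the genomic start reflects the clipping.
    """
    start = max(0, iv.start - pad)
    end = min(index.chrom_length(iv.chrom), iv.end + pad)
    seq = index.sequence(iv.chrom, start, end)
    if iv.strand == "-":
        seq = reverse_complement(seq)
    return seq, start


def _sense_index_to_genomic(i: int, window_start: int, window_len: int, strand: str) -> int:
    return window_start + i if strand == "+" else window_start + window_len - 1 - i


def call_m6a(
    extended: Sequence[MergedInterval], index: AnnotationIndex, params: ClassifyParams | None = None
) -> list[MethylSite]:
    """Select DRACH-containing peaks; the motif's central A is the m6A site.

    The central A must lie inside the extended peak; the outer motif bases
    may extend up to ``motif_flank`` nt beyond it.  A 5-mer containing N
    never matches.  Duplicate A coordinates are reported once (first
    source peak in coordinate order wins).
    """
    params = params or ClassifyParams()
    seen: dict[tuple[str, str, int], MethylSite] = {}
    for peak in extended:
        iv = peak.interval
        seq, win_start = _sense_window(index, iv, params.motif_flank)
        win_len = len(seq)
        for i in range(win_len - 4):
            kmer = seq[i : i + 5]
            if not is_drach(kmer):
                continue
            gpos = _sense_index_to_genomic(i + 2, win_start, win_len, iv.strand)
            if not iv.contains(gpos):
                continue
            key = (iv.chrom, iv.strand, gpos)
            if key not in seen:
                seen[key] = MethylSite(
                    site=GenomicInterval(iv.chrom, gpos, gpos + 1, iv.strand),
                    klass="m6A",
                    motif=kmer,
                    source_peak=iv,
                    support=peak.support,
                )
    sites = list(seen.values())
    sites.sort(key=lambda s: (s.site.chrom, s.site.start, s.site.strand))
    return sites


def call_m6am(
    extended: Sequence[MergedInterval],
    m6a_sites: Sequence[MethylSite],
    index: AnnotationIndex,
    params: ClassifyParams | None = None,
) -> list[MethylSite]:
    """m6Am candidates: 5'-most A of each sense A-run inside an extended
    peak, kept when the position falls within the first
    floor(utr5_fraction * utr5_length) nt of any annotated 5'UTR and does
    not coincide with an m6A coordinate."""
    params = params or ClassifyParams()
    m6a_coords = {(s.site.chrom, s.site.strand, s.site.start) for s in m6a_sites}
    seen: dict[tuple[str, str, int], MethylSite] = {}
    for peak in extended:
        iv = peak.interval
        seq, win_start = _sense_window(index, iv, 0)
        win_len = len(seq)
        i = 0
        while i < win_len:
            if seq[i] != "A":
                i += 1
                continue
            j = i
            while j < win_len and seq[j] == "A":
                j += 1
            run_len = j - i
            gpos = _sense_index_to_genomic(i, win_start, win_len, iv.strand)  # 5'-most A
            key = (iv.chrom, iv.strand, gpos)
            if (
                key not in seen
                and key not in m6a_coords
                and _in_first_utr5_fraction(index, iv.chrom, iv.strand, gpos, params.utr5_fraction)
            ):
                seen[key] = MethylSite(
                    site=GenomicInterval(iv.chrom, gpos, gpos + 1, iv.strand),
                    klass="m6Am",
                    motif=f"A{run_len}",
                    source_peak=iv,
                    support=peak.support,
                )
            i = j
    sites = list(seen.values())
    sites.sort(key=lambda s: (s.site.chrom, s.site.start, s.site.strand))
    return sites


def _in_first_utr5_fraction(
    index: AnnotationIndex, chrom: str, strand: str, pos: int, fraction: float
) -> bool:
    """True when the position lies in the first ``fraction`` of the 5'UTR of
    at least one transcript (permissive any-transcript rule)."""
    for tid in index.transcripts_at(chrom, strand, pos):
        meta = genomic_to_meta(index, tid, pos)
        if meta is None:
            continue
        region, offset, region_length = meta
        if region == UTR5 and offset < int(fraction * region_length):
            return True
    return False


def classify_sites(
    rep1: Sequence,
    rep2: Sequence,
    index: AnnotationIndex,
    params: ClassifyParams | None = None,
) -> tuple[list[MethylSite], list[MethylSite]]:
    """Full miCLIP classification: merge, extend, call m6A then m6Am."""
    params = params or ClassifyParams()
    merged = merge_miclip_cits(rep1, rep2, gap=params.merge_gap)
    sizes = {c: len(s) for c, s in index.genome.items()}
    extended = extend_peaks(merged, params.extend, chrom_sizes=sizes)
    m6a = call_m6a(extended, index, params)
    m6am = call_m6am(extended, m6a, index, params)
    return m6a, m6am
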