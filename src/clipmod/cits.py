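"""Per-nucleotide truncation tracks and CITS peak calling.

iCLIP cDNAs truncate at the crosslinked nucleotide, so the position one
base 5' of each read start (in read orientation) marks the putative
protein-RNA contact.  Candidate sites are scored against a uniform
within-transcript null: with n truncations over a pre-mRNA span of L nt,
a position carrying k events gets the binomial tail p = P(X >= k),
X ~ Bin(n, 1/L).  Benjamini-Hochberg correction is applied jointly across
all tested positions genome-wide and sites at q <= 0.01 are significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .annotation import AnnotationIndex, GenomicInterval

log = logging.getLogger(__name__)

TrackKey = tuple[str, str]  # (chrom, strand)


@dataclass
class TruncationTrack:
    """Sparse per-nucleotide truncation counts for one library.

    ``data`` maps (chrom, strand) -> (sorted position array, count array);
    ``library_size`` equals the sum of all counts.
    """

    sample_id: str
    data: dict[TrackKey, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    library_size: int = 0
    n_skipped: int = 0  # unusable records (unmapped / strandless / negative coordinate)

    @classmethod
    def from_arrays(cls, sample_id: str, per_key: dict[TrackKey, tuple[np.ndarray, np.ndarray]],
                    n_skipped: int = 0) -> "TruncationTrack":
        data = {}
        total = 0
        for key, (pos, cnt) in per_key.items():
            order = np.argsort(pos, kind="stable")
            pos, cnt = np.asarray(pos)[order], np.asarray(cnt)[order]
            data[key] = (pos.astype(np.int64), cnt.astype(np.int64))
            total += int(cnt.sum())
        return cls(sample_id=sample_id, data=data, library_size=total, n_skipped=n_skipped)

    def count_at(self, chrom: str, strand: str, position: int) -> int:
        arr = self.data.get((chrom, strand))
        if arr is None:
            return 0
        pos, cnt = arr
        i = np.searchsorted(pos, position)
        if i < len(pos) and pos[i] == position:
            return int(cnt[i])
        return 0

    def window_counts(self, chrom: str, strand: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Total counts in each half-open window [start, end)."""
        arr = self.data.get((chrom, strand))
        if arr is None:
            return np.zeros(len(starts), dtype=np.int64)
        pos, cnt = arr
        csum = np.concatenate([[0], np.cumsum(cnt)])
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        return csum[hi] - csum[lo]

    def cpm_scale(self) -> float:
        return 1e6 / self.library_size if self.library_size else 0.0


@dataclass(frozen=True)
class CitsPeak:
    """A single-nucleotide candidate crosslink site with its test context."""

    site: GenomicInterval
    k: int           # truncation count at the site
    n: int           # truncations in the background unit (transcript span)
    L: int           # background unit length (nt)
    p_value: float
    q_value: float
    sample_id: str = ""


@dataclass(frozen=True)
class MergedSite:
    """Representative single-nucleotide site of a replicate-merged cluster."""

    site: GenomicInterval
    support: int     # summed truncation count across cluster members
    n_members: int = 1


@dataclass
class CitsParams:
    fdr_threshold: float = 0.01
    min_count: int = 2
    merge_gap: int = 0

    def __post_init__(self):
        if not (0 < self.fdr_threshold < 1):
            raise ValueError(f"fdr_threshold must be in (0, 1), got {self.fdr_threshold}")


def extract_truncations(alignments, sample_id: str) -> TruncationTrack:
    """Convert read alignments to a truncation track.

    ``alignments`` is a BED6 DataFrame/path of read records or a BAM path.
    The truncation is placed one nt 5' of the read start in read
    orientation: plus-strand read [s, e) -> s-1; minus-strand read -> e.
    Events at negative coordinates and strandless/unmapped records are
    dropped and counted in ``n_skipped``.
    """
    if isinstance(alignments, (str, Path)) and str(alignments).endswith(".bam"):
        df = _reads_from_bam(alignments)
    elif isinstance(alignments, pd.DataFrame):
        df = alignments
    else:
        df = pd.read_csv(
            alignments, sep="\t", header=None, usecols=range(6),
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str, "strand": str},
        )
    if df.empty:
        return TruncationTrack(sample_id=sample_id)
    stranded = df["strand"].isin(["+", "-"])
    n_skipped = int((~stranded).sum())
    df = df[stranded]
    event = np.where(df["strand"] == "+", df["start"] - 1, df["end"]).astype(np.int64)
    valid = event >= 0
    n_skipped += int((~valid).sum())
    sub = pd.DataFrame({"chrom": df["chrom"].values, "strand": df["strand"].values, "pos": event})[valid]
    per_key = {}
    for (chrom, strand), grp in sub.groupby(["chrom", "strand"], sort=True):
        pos, cnt = np.unique(grp["pos"].values, return_counts=True)
        per_key[(chrom, strand)] = (pos, cnt)
    return TruncationTrack.from_arrays(sample_id, per_key, n_skipped=n_skipped)


def _reads_from_bam(path) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            rows.append(
                (rec.reference_name, rec.reference_start, rec.reference_end,
                 rec.query_name, 0, "-" if rec.is_reverse else "+")
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def call_cits(
    track: TruncationTrack, index: AnnotationIndex, params: CitsParams | None = None
) -> list[CitsPeak]:
    """Call significant crosslink-induced truncation sites.

    Each position is tested once, under the representative (longest-mRNA)
    transcript covering it; the background unit is that transcript's full
    genomic (pre-mRNA) span.  Positions outside any transcript are not
    tested (their count is logged).

    The BH family covers every nucleotide of every covered transcript, not
    just positions reaching ``min_count``: sub-threshold positions carry an
    implicit p = 1, so they can never be called but still count toward the
    correction.  Correcting only over data-selected positions would shrink
    the family and inflate the realized FDR well past the nominal level.
    """
    params = params or CitsParams()
    candidates: list[tuple[GenomicInterval, int, int, int, float]] = []
    n_untested = 0
    family_size = 0  # total testable positions (Sigma span lengths, n >= 1)
    for (chrom, strand), (pos, cnt) in sorted(track.data.items()):
        txs = [
            tx for tx in index.transcripts.values()
            if tx.chrom == chrom and tx.strand == strand
        ]
        # longest-mRNA-first claiming implements the representative rule
        txs.sort(key=lambda t: (-t.mrna_length, t.transcript_id))
        claimed = np.zeros(len(pos), dtype=bool)
        for tx in txs:
            s, e = tx.span
            lo, hi = np.searchsorted(pos, [s, e])
            if hi <= lo:
                continue
            n = int(cnt[lo:hi].sum())
            L = e - s
            family_size += L
            idx = np.arange(lo, hi)[~claimed[lo:hi]]
            claimed[lo:hi] = True
            testable = idx[cnt[idx] >= params.min_count]
            if len(testable) == 0:
                continue
            k = cnt[testable]
            p = binom.sf(k - 1, n, 1.0 / L)
            for j, pv in zip(testable, p):
                site = GenomicInterval(chrom, int(pos[j]), int(pos[j]) + 1, strand)
                candidates.append((site, int(cnt[j]), n, L, float(pv)))
        n_untested += int((~claimed).sum())
    if n_untested:
        log.info("call_cits: %d positions outside any transcript not tested", n_untested)
    if not candidates:
        return []
    pvals = np.array([c[4] for c in candidates])
    qvals = _bh_qvalues(pvals, family_size)
    peaks = [
        CitsPeak(site=c[0], k=c[1], n=c[2], L=c[3], p_value=c[4],
                 q_value=float(q), sample_id=track.sample_id)
        for c, q in zip(candidates, qvals)
        if q <= params.fdr_threshold
    ]
    peaks.sort(key=lambda p: (p.site.chrom, p.site.start, p.site.strand))
    return peaks


def _bh_qvalues(pvals: np.ndarray, family_size: int) -> np.ndarray:
    """Benjamini-Hochberg q-values over a family of ``family_size`` tests of
    which only the supplied p-values can be non-trivial (the rest are 1)."""
    m = max(family_size, len(pvals))
    order = np.argsort(pvals, kind="stable")
    ranked = pvals[order] * m / np.arange(1, len(pvals) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(ranked)
    q[order] = np.minimum(ranked, 1.0)
    return q


def filter_against_control(cits: Sequence[CitsPeak], control_cits: Sequence) -> list[CitsPeak]:
    """Drop peaks whose exact (chrom, strand, position) occurs in the control set."""
    control = {(_chrom(c), _strand(c), _pos(c)) for c in control_cits}
    return [p for p in cits if (_chrom(p), _strand(p), _pos(p)) not in control]


def _site_of(peak) -> GenomicInterval:
    return peak.site if hasattr(peak, "site") else peak


def _chrom(p) -> str:
    return _site_of(p).chrom


def _strand(p) -> str:
    return _site_of(p).strand


def _pos(p) -> int:
    return _site_of(p).start


def _support(p) -> int:
    if hasattr(p, "k"):
        return p.k
    if hasattr(p, "support"):
        return p.support
    return 1


def cluster_sites(
    records: Iterable, gap: int
) -> list[list]:
    """Group single-nucleotide records on the same chrom/strand into clusters
    with at most ``gap`` intervening bases between consecutive members
    (i.e. coordinate difference <= gap + 1)."""
    recs = sorted(records, key=lambda r: (_chrom(r), _strand(r), _pos(r)))
    clusters: list[list] = []
    for r in recs:
        if clusters:
            last = clusters[-1][-1]
            if (
                _chrom(r) == _chrom(last)
                and _strand(r) == _strand(last)
                and _pos(r) - _pos(last) <= gap + 1
            ):
                clusters[-1].append(r)
                continue
        clusters.append([r])
    return clusters


def merge_replicate_peaks(peak_lists: Sequence[Sequence], gap: int = 0) -> list[MergedSite]:
    """Union peak lists across replicates and collapse near-identical sites.

    Sites whose coordinates differ by <= gap + 1 on the same chrom/strand
    form one cluster, reported at the position with the highest summed
    support (ties: 5'-most in transcript sense).  gap=0 collapses only
    identical positions.
    """
    pooled = [p for lst in peak_lists for p in lst]
    merged = []
    for cluster in cluster_sites(pooled, gap):
        by_pos: dict[int, int] = {}
        for r in cluster:
            by_pos[_pos(r)] = by_pos.get(_pos(r), 0) + _support(r)
        strand = _strand(cluster[0])
        # max support; ties break to the 5'-most position in transcript sense
        best = max(by_pos, key=lambda p: (by_pos[p], -p if strand == "+" else p))
        merged.append(
            MergedSite(
                site=GenomicInterval(_chrom(cluster[0]), best, best + 1, strand),
                support=sum(by_pos.values()),
                n_members=len(cluster),
            )
        )
    merged.sort(key=lambda m: (m.site.chrom, m.site.start, m.site.strand))
    return merged


@dataclass
class RatioTrack:
    """Binned iCLIP/SMI CPM ratio, per (chrom, strand)."""

    bin_size: int
    data: dict[TrackKey, tuple[np.ndarray, np.ndarray]]  # (bin start, ratio)


def normalize_to_input(
    clip: TruncationTrack, smi: TruncationTrack, bin_size: int = 50, eps_cpm: float = 0.5
) -> RatioTrack:
    """Per-bin (clip CPM + eps) / (smi CPM + eps) over occupied bins."""
    if smi.library_size == 0:
        raise ValueError(
            "SMI library is empty; input normalization is undefined — use the "
            "un-normalized CPM density instead"
        )
    out: dict[TrackKey, tuple[np.ndarray, np.ndarray]] = {}
    keys = sorted(set(clip.data) | set(smi.data))
    for key in keys:
        bins = set()
        for track in (clip, smi):
            if key in track.data:
                bins.update((track.data[key][0] // bin_size).tolist())
        starts = np.array(sorted(b * bin_size for b in bins), dtype=np.int64)
        c = clip.window_counts(*key, starts, starts + bin_size) * clip.cpm_scale()
        s = smi.window_counts(*key, starts, starts + bin_size) * smi.cpm_scale()
        out[key] = (starts, (c + eps_cpm) / (s + eps_cpm))
    return RatioTrack(bin_size=bin_size, data=out)
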