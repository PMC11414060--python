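"""Anchored signal-density profiles, matched random-site nulls, and the
50-nt peak-overlap rule.

An anchor profile averages a truncation track (in events per million)
over strand-aware offsets around a set of single-nucleotide anchors;
"downstream" (positive offsets) is 5'->3' in transcript sense.  A matched
random-site null of equal size is drawn from transcribed positions,
stratified by region type and chromosome, and the per-site summed density
within +/-Q nt (default Q=100) is compared between real and random
anchors with a Wilcoxon (Mann-Whitney) rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .annotation import CDS, INTRON, UTR3, UTR5, AnnotationIndex, GenomicInterval, genomic_to_meta
from .cits import TruncationTrack, _chrom, _pos, _strand

log = logging.getLogger(__name__)


@dataclass
class AnchorProfile:
    offsets: np.ndarray          # -W .. +W
    mean: np.ndarray             # mean density (CPM) per offset over anchors
    sem: np.ndarray              # SEM over anchors
    null_mean: np.ndarray
    null_sem: np.ndarray
    site_sums: np.ndarray        # per-anchor summed density within +/-Q
    null_sums: np.ndarray
    u_statistic: float
    p_value: float
    n_anchors: int
    window: int                  # W
    quant_window: int            # Q
    n_truncated_windows: int = 0


def _anchor_matrix(
    track: TruncationTrack, anchors: Sequence, index: AnnotationIndex, W: int
) -> tuple[np.ndarray, int]:
    """Per-anchor CPM density over offsets -W..W; off-chromosome offsets
    contribute zero (window truncated, counted)."""
    scale = track.cpm_scale()
    mat = np.zeros((len(anchors), 2 * W + 1))
    n_trunc = 0
    for i, a in enumerate(anchors):
        chrom, strand, pos = _chrom(a), _strand(a), _pos(a)
        clen = index.chrom_length(chrom) if chrom in index.genome else None
        arr = track.data.get((chrom, strand))
        lo_g, hi_g = pos - W, pos + W + 1
        if lo_g < 0 or (clen is not None and hi_g > clen):
            n_trunc += 1
        if arr is None:
            continue
        tpos, tcnt = arr
        lo, hi = np.searchsorted(tpos, [lo_g, hi_g])
        if hi <= lo:
            continue
        sel_pos, sel_cnt = tpos[lo:hi], tcnt[lo:hi]
        off = sel_pos - pos if strand == "+" else pos - sel_pos
        mat[i, off + W] = sel_cnt * scale
    return mat, n_trunc


def anchor_profile(
    track: TruncationTrack,
    anchors: Sequence,
    index: AnnotationIndex,
    W: int = 500,
    Q: int = 100,
    random_anchors: Optional[Sequence] = None,
    match_regions: bool = True,
    seed: int = 0,
) -> AnchorProfile:
    """Signal density around anchors vs matched random sites.

    ``random_anchors`` may be supplied; otherwise they are drawn with
    :func:`sample_random_sites` under ``seed``.  The test compares
    per-site density sums within +/-Q nt (two-sided Wilcoxon rank-sum).
    """
    if not anchors:
        raise ValueError("empty anchor list")
    if track.library_size == 0:
        raise ValueError("empty track")
    if random_anchors is None:
        random_anchors = sample_random_sites(anchors, index, match_regions=match_regions, seed=seed)
    mat, n_trunc = _anchor_matrix(track, anchors, index, W)
    nmat, _ = _anchor_matrix(track, random_anchors, index, W)
    offsets = np.arange(-W, W + 1)
    qmask = np.abs(offsets) <= Q
    site_sums = mat[:, qmask].sum(axis=1)
    null_sums = nmat[:, qmask].sum(axis=1)
    u, p = mannwhitneyu(site_sums, null_sums, alternative="two-sided", method="asymptotic")

    def _sem(m):
        return m.std(axis=0, ddof=1) / np.sqrt(m.shape[0]) if m.shape[0] > 1 else np.zeros(m.shape[1])

    return AnchorProfile(
        offsets=offsets,
        mean=mat.mean(axis=0),
        sem=_sem(mat),
        null_mean=nmat.mean(axis=0),
        null_sem=_sem(nmat),
        site_sums=site_sums,
        null_sums=null_sums,
        u_statistic=float(u),
        p_value=float(p),
        n_anchors=len(anchors),
        window=W,
        quant_window=Q,
        n_truncated_windows=n_trunc,
    )


def _region_pools(index: AnnotationIndex) -> dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]:
    """(chrom, region) -> (positions, strand codes) over representative transcripts."""
    pools: dict[tuple[str, str], list[tuple[np.ndarray, str]]] = {}
    for tid in index.representative_transcripts():
        tx = index.transcripts[tid]
        for region in (UTR5, CDS, UTR3, INTRON):
            for iv in tx.features.get(region, []):
                pools.setdefault((tx.chrom, region), []).append(
                    (np.arange(iv.start, iv.end), tx.strand)
                )
        if not tx.is_coding:
            for e in tx.exons:
                pools.setdefault((tx.chrom, "noncoding"), []).append(
                    (np.arange(e.start, e.end), tx.strand)
                )
    out = {}
    for key, chunks in pools.items():
        pos = np.concatenate([c[0] for c in chunks])
        strands = np.concatenate([np.full(len(c[0]), 0 if c[1] == "+" else 1) for c in chunks])
        out[key] = (pos, strands)
    return out


def _anchor_region(index: AnnotationIndex, chrom: str, strand: str, pos: int) -> str:
    tid = index.representative_at(chrom, strand, pos)
    if tid is None:
        return "any"
    tx = index.transcripts[tid]
    meta = genomic_to_meta(index, tid, pos)
    if meta is not None:
        return meta[0]
    return "noncoding" if not tx.is_coding else "any"


def sample_random_sites(
    anchors: Sequence,
    index: AnnotationIndex,
    match_regions: bool = True,
    seed: int = 0,
) -> list[GenomicInterval]:
    """Random transcribed sites matching the anchors' region distribution
    and per-chromosome counts (one random site per anchor, seeded).

    With ``match_regions=False`` sites are drawn uniformly from all
    transcribed positions on the anchor's chromosome.  Empty strata fall
    back to the unstratified pool with a warning.
    """
    rng = np.random.default_rng(seed)
    pools = _region_pools(index)
    all_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for (chrom, _), (pos, strands) in sorted(pools.items()):
        if chrom in all_by_chrom:
            p0, s0 = all_by_chrom[chrom]
            all_by_chrom[chrom] = (np.concatenate([p0, pos]), np.concatenate([s0, strands]))
        else:
            all_by_chrom[chrom] = (pos, strands)

    out = []
    for a in anchors:
        chrom, strand, pos = _chrom(a), _strand(a), _pos(a)
        region = _anchor_region(index, chrom, strand, pos) if match_regions else "any"
        pool = pools.get((chrom, region)) if region != "any" else None
        if pool is None:
            if match_regions and region != "any":
                log.warning("no %s positions on %s; falling back to unstratified", region, chrom)
            pool = all_by_chrom.get(chrom)
        if pool is None:
            raise ValueError(f"no transcribed positions available on chromosome {chrom}")
        i = int(rng.integers(len(pool[0])))
        p = int(pool[0][i])
        s = "+" if pool[1][i] == 0 else "-"
        out.append(GenomicInterval(chrom, p, p + 1, s))
    return out


@dataclass
class OverlapResult:
    extended_nt: int
    n_a: int
    n_b: int
    n_overlapping_a: int

    @property
    def fraction(self) -> float:
        return self.n_overlapping_a / self.n_a if self.n_a else 0.0


def _as_interval(x) -> GenomicInterval:
    if isinstance(x, GenomicInterval):
        return x
    iv = getattr(x, "site", None) or getattr(x, "interval", None)
    if iv is None:
        raise TypeError(f"cannot interpret {x!r} as an interval")
    return iv


def overlap_peaks(
    a: Sequence, b: Sequence, extend_nt: int = 50, stranded: bool = True
) -> OverlapResult:
    """Fraction of A peaks that, after extending both sets by ``extend_nt``
    per side, share >= 1 nt with any extended B peak."""
    ivs_a = [_as_interval(x) for x in a]
    ivs_b = [_as_interval(x) for x in b]

    by_key: dict[tuple, list[tuple[int, int]]] = {}
    for iv in ivs_b:
        key = (iv.chrom, iv.strand) if stranded else (iv.chrom,)
        by_key.setdefault(key, []).append((max(0, iv.start - extend_nt), iv.end + extend_nt))
    # for each key sort by start and track the running max end for prefix queries
    prepared = {}
    for key, lst in by_key.items():
        lst = sorted(lst)
        starts = np.array([s for s, _ in lst])
        ends = np.array([e for _, e in lst])
        max_end = np.maximum.accumulate(ends)
        prepared[key] = (starts, max_end)

    n_hit = 0
    for iv in ivs_a:
        key = (iv.chrom, iv.strand) if stranded else (iv.chrom,)
        if key not in prepared:
            continue
        s, e = max(0, iv.start - extend_nt), iv.end + extend_nt
        starts, max_end = prepared[key]
        i = np.searchsorted(starts, e, side="left")  # B peaks starting before A ends
        if i > 0 and max_end[i - 1] > s:
            n_hit += 1
    return OverlapResult(extended_nt=extend_nt, n_a=len(ivs_a), n_b=len(ivs_b), n_overlapping_a=n_hit)


def profile_frame(profile: AnchorProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "offset": profile.offsets,
            "mean": profile.mean,
            "sem": profile.sem,
            "null_mean": profile.null_mean,
            "null_sem": profile.null_sem,
        }
    )
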