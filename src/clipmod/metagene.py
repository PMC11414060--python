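"""Length-standardized metagene profiles and peak feature distributions.

Each transcript's 5'UTR, CDS and 3'UTR are rescaled to a fixed number of
bins (defaults 50/100/70) so that profiles average over transcripts of
different lengths.  Densities are expressed as events (crosslinks) per
million library events, averaged per transcript.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import CDS, INTRON, UTR3, UTR5, AnnotationIndex, genomic_to_meta
from .cits import TruncationTrack, _chrom, _pos, _strand

log = logging.getLogger(__name__)

DEFAULT_BIN_COUNTS = {UTR5: 50, CDS: 100, UTR3: 70}
META_REGIONS = (UTR5, CDS, UTR3)


@dataclass
class MetageneProfile:
    bins: list[tuple[str, int]]        # (region, bin index) in transcript order
    density: np.ndarray                # mean events-per-million per bin over transcripts
    sem: np.ndarray
    n_transcripts: int
    bin_counts: dict[str, int]
    n_events_used: int = 0
    n_events_excluded: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": [r for r, _ in self.bins],
                "bin": [i for _, i in self.bins],
                "density": self.density,
                "sem": self.sem,
            }
        )


def _iter_events(events):
    """Yield (chrom, strand, pos, count) from a track or a site list."""
    if isinstance(events, TruncationTrack):
        for (chrom, strand), (pos, cnt) in sorted(events.data.items()):
            for p, c in zip(pos.tolist(), cnt.tolist()):
                yield chrom, strand, p, c
    else:
        for s in events:
            yield _chrom(s), _strand(s), _pos(s), 1


def metagene(
    events,
    index: AnnotationIndex,
    bin_counts: dict[str, int] | None = None,
    normalize: str = "cpm",
    smi=None,
) -> MetageneProfile:
    """Standardized metagene profile of a truncation track or site list.

    Events are assigned to their representative transcript and mapped to
    (region, offset); the bin is floor(offset / region_length * n_bins).
    Transcripts missing any of the three mRNA regions are excluded from
    averaging (their events are counted as excluded).  ``normalize`` is
    "cpm" or "input-ratio" (requires ``smi``).
    """
    bin_counts = dict(bin_counts or DEFAULT_BIN_COUNTS)
    if normalize not in ("cpm", "input-ratio"):
        raise ValueError(f"unknown normalize mode {normalize!r}")
    if normalize == "input-ratio" and smi is None:
        raise ValueError("input-ratio mode requires an SMI track")

    offsets = {}
    cursor = 0
    bins: list[tuple[str, int]] = []
    for region in META_REGIONS:
        offsets[region] = cursor
        bins.extend((region, i) for i in range(bin_counts[region]))
        cursor += bin_counts[region]
    total_bins = cursor

    ev = list(_iter_events(events))
    library_size = sum(c for _, _, _, c in ev)
    if library_size == 0:
        raise ValueError("empty event set")

    per_tx: dict[str, np.ndarray] = {}
    used = excluded = 0
    for chrom, strand, pos, count in ev:
        tid = index.representative_at(chrom, strand, pos)
        if tid is None:
            excluded += count
            continue
        tx = index.transcripts[tid]
        if not tx.is_coding or any(tx.region_length(r) == 0 for r in META_REGIONS):
            excluded += count
            continue
        meta = genomic_to_meta(index, tid, pos)
        if meta is None or meta[0] == INTRON:
            excluded += count
            continue
        region, off, region_len = meta
        b = min(int(off / region_len * bin_counts[region]), bin_counts[region] - 1)
        arr = per_tx.setdefault(tid, np.zeros(total_bins))
        arr[offsets[region] + b] += count
        used += count

    if not per_tx:
        density = np.zeros(total_bins)
        sem = np.zeros(total_bins)
        n_tx = 0
    else:
        mat = np.stack([per_tx[t] for t in sorted(per_tx)]) * (1e6 / library_size)
        density = mat.mean(axis=0)
        n_tx = mat.shape[0]
        sem = mat.std(axis=0, ddof=1) / np.sqrt(n_tx) if n_tx > 1 else np.zeros(total_bins)

    if normalize == "input-ratio":
        ref = metagene(smi, index, bin_counts=bin_counts, normalize="cpm")
        eps = 0.5
        density = (density + eps) / (ref.density + eps)
        sem = np.zeros_like(density)

    return MetageneProfile(
        bins=bins, density=density, sem=sem, n_transcripts=n_tx,
        bin_counts=bin_counts, n_events_used=used, n_events_excluded=excluded,
    )


@dataclass
class FeatureDistribution:
    counts: dict[str, int] = field(default_factory=dict)
    lengths_kb: dict[str, float] = field(default_factory=dict)
    peaks_per_kb: dict[str, float] = field(default_factory=dict)
    percent: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        regions = sorted(self.counts)
        return pd.DataFrame(
            {
                "region": regions,
                "count": [self.counts[r] for r in regions],
                "length_kb": [self.lengths_kb.get(r, float("nan")) for r in regions],
                "peaks_per_kb": [self.peaks_per_kb.get(r, float("nan")) for r in regions],
                "percent": [self.percent[r] for r in regions],
            }
        )


def feature_distribution(
    peaks, index: AnnotationIndex, length_normalized: bool = False
) -> FeatureDistribution:
    """Distribution of peaks over transcript regions.

    Raw mode reports the percentage of peaks per region over
    {utr5, cds, utr3, intron, noncoding, intergenic}; normalized mode also
    divides counts by the summed region length (Kb) over the assayed
    (one representative per gene) transcripts.  Intergenic peaks are
    excluded from per-Kb denominators.
    """
    counts: dict[str, int] = {}
    for p in peaks:
        chrom, strand, pos = _chrom(p), _strand(p), _pos(p)
        tid = index.representative_at(chrom, strand, pos)
        if tid is None:
            bucket = "intergenic"
        else:
            tx = index.transcripts[tid]
            if not tx.is_coding:
                meta = genomic_to_meta(index, tid, pos)
                bucket = INTRON if (meta is not None and meta[0] == INTRON) else "noncoding"
            else:
                meta = genomic_to_meta(index, tid, pos)
                bucket = meta[0] if meta is not None else "noncoding"
        counts[bucket] = counts.get(bucket, 0) + 1

    lengths_nt: dict[str, int] = {}
    for tid in index.representative_transcripts():
        tx = index.transcripts[tid]
        if tx.is_coding:
            for region in (UTR5, CDS, UTR3, INTRON):
                lengths_nt[region] = lengths_nt.get(region, 0) + tx.region_length(region)
        else:
            lengths_nt["noncoding"] = lengths_nt.get("noncoding", 0) + tx.mrna_length
            lengths_nt[INTRON] = lengths_nt.get(INTRON, 0) + tx.region_length(INTRON)

    total = sum(counts.values())
    percent = {r: 100.0 * c / total for r, c in counts.items()} if total else {}
    lengths_kb = {r: v / 1000.0 for r, v in lengths_nt.items()}
    peaks_per_kb = {}
    if length_normalized:
        for r, c in counts.items():
            if r != "intergenic" and lengths_kb.get(r, 0) > 0:
                peaks_per_kb[r] = c / lengths_kb[r]
    return FeatureDistribution(
        counts=counts, lengths_kb=lengths_kb, peaks_per_kb=peaks_per_kb, percent=percent
    )
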