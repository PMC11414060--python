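"""Readers and writers for the plain-text interchange formats.

BED6 is the native site/peak format (0-based half-open, native to the
package's internal coordinates); truncation tracks round-trip through
per-strand bedGraph; tabular outputs are TSV.  All writers are
deterministic: fixed sort orders and fixed float formatting, so repeated
runs produce byte-identical files.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import GenomicInterval
from .cits import CitsPeak, MergedSite, TruncationTrack
from .modsite import MethylSite

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=range(6), names=BED6_COLUMNS,
        dtype={"chrom": str, "name": str, "strand": str},
    )
    return df


def bed6_to_sites(df: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand)
        for r in df.itertuples(index=False)
    ]


def read_sites(path) -> list[GenomicInterval]:
    return bed6_to_sites(read_bed6(path))


def write_bed6(rows: Sequence[tuple], path) -> None:
    with open(path, "w") as out:
        for r in sorted(rows):
            out.write("\t".join(map(str, r)) + "\n")


def _bed_score(q_value: float) -> int:
    if q_value <= 0:
        return 1000
    return min(1000, round(-10.0 * math.log10(q_value)))


def write_cits_bed(peaks: Sequence[CitsPeak], path) -> None:
    """BED6: name=sample, score=round(-10*log10 q) capped at 1000."""
    rows = [
        (p.site.chrom, p.site.start, p.site.end, p.sample_id or "cits",
         _bed_score(p.q_value), p.site.strand)
        for p in peaks
    ]
    write_bed6(rows, path)


def write_cits_tsv(peaks: Sequence[CitsPeak], path) -> None:
    df = pd.DataFrame(
        [
            (p.site.chrom, p.site.start, p.site.end, p.site.strand, p.k, p.n, p.L,
             p.p_value, p.q_value, p.sample_id)
            for p in peaks
        ],
        columns=["chrom", "start", "end", "strand", "k", "n", "L", "p_value", "q_value", "sample_id"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_merged_bed(sites: Sequence[MergedSite], path, name: str = "merged") -> None:
    rows = [
        (m.site.chrom, m.site.start, m.site.end, name, min(1000, m.support), m.site.strand)
        for m in sites
    ]
    write_bed6(rows, path)


def write_methyl_bed(sites: Sequence[MethylSite], path) -> None:
    """BED6 for classified sites: name=class:motif, score=support (capped)."""
    rows = [
        (s.site.chrom, s.site.start, s.site.end, f"{s.klass}:{s.motif}",
         min(1000, s.support), s.site.strand)
        for s in sites
    ]
    write_bed6(rows, path)


def write_methyl_tsv(sites: Sequence[MethylSite], path) -> None:
    df = pd.DataFrame(
        [
            (s.site.chrom, s.site.start, s.site.strand, s.klass, s.motif, s.support,
             s.source_peak.start, s.source_peak.end)
            for s in sites
        ],
        columns=["chrom", "pos", "strand", "klass", "motif", "support", "peak_start", "peak_end"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_track_bedgraph(track: TruncationTrack, prefix) -> tuple[Path, Path]:
    """One bedGraph per strand: ``<prefix>.plus.bedgraph`` / ``.minus.bedgraph``."""
    prefix = Path(prefix)
    paths = {}
    for strand, tag in (("+", "plus"), ("-", "minus")):
        path = prefix.parent / f"{prefix.name}.{tag}.bedgraph"
        with open(path, "w") as out:
            for (chrom, st), (pos, cnt) in sorted(track.data.items()):
                if st != strand:
                    continue
                for p, c in zip(pos.tolist(), cnt.tolist()):
                    out.write(f"{chrom}\t{p}\t{p + 1}\t{c}\n")
        paths[tag] = path
    return paths["plus"], paths["minus"]


def read_track_bedgraph(plus_path, minus_path, sample_id: str) -> TruncationTrack:
    per_key: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "count"],
                         dtype={"chrom": str})
        for chrom, grp in df.groupby("chrom", sort=True):
            per_key[(chrom, strand)] = (grp["start"].to_numpy(), grp["count"].to_numpy())
    return TruncationTrack.from_arrays(sample_id, per_key)
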