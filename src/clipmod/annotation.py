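"""Strand-aware transcript models built from GTF + FASTA.

Every other stage of the pipeline asks this module two questions: "which
transcript(s) cover this genomic position?" and "where does this position
fall along the mRNA (5'UTR / CDS / 3'UTR / intron, and how far into that
region in transcript sense)?".  Coordinates are 0-based half-open
internally; GTF's 1-based inclusive convention is converted at the
boundary and BED I/O is native.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gffutils
import pyfaidx
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

UTR5 = "utr5"
CDS = "cds"
UTR3 = "utr3"
INTRON = "intron"
REGIONS = (UTR5, CDS, UTR3, INTRON)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GtfParseError(ValueError):
    """Raised for a structurally malformed GTF line; names the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open, 0-based, stranded genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class TranscriptModel:
    """One transcript: ordered exons plus derived region features.

    ``features`` maps region name -> list of genomic intervals sorted by
    genomic coordinate.  On the minus strand the 5'UTR occupies the
    genomically 3'-most blocks; all transcript-sense logic lives in
    :func:`genomic_to_meta`.
    """

    transcript_id: str
    gene_id: str
    strand: str
    exons: list[GenomicInterval]
    cds_span: Optional[tuple[int, int]] = None  # genomic (start, end), half-open
    features: dict[str, list[GenomicInterval]] = field(default_factory=dict)

    def __post_init__(self):
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if not self.features:
            self.features = _derive_features(self.exons, self.cds_span, self.strand)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0].start, self.exons[-1].end

    @property
    def mrna_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_span is not None

    def region_length(self, region: str) -> int:
        return sum(len(iv) for iv in self.features.get(region, []))

    @property
    def utr5_length(self) -> int:
        return self.region_length(UTR5)


def _derive_features(
    exons: list[GenomicInterval], cds_span: Optional[tuple[int, int]], strand: str
) -> dict[str, list[GenomicInterval]]:
    chrom = exons[0].chrom
    introns = [
        GenomicInterval(chrom, a.end, b.start, strand)
        for a, b in zip(exons, exons[1:])
        if b.start > a.end
    ]
    feats: dict[str, list[GenomicInterval]] = {INTRON: introns}
    if cds_span is None:
        return feats
    cs, ce = cds_span
    left, mid, right = [], [], []
    for e in exons:
        if e.end <= cs:
            left.append(e)
        elif e.start >= ce:
            right.append(e)
        else:
            if e.start < cs:
                left.append(GenomicInterval(chrom, e.start, cs, strand))
            mid.append(GenomicInterval(chrom, max(e.start, cs), min(e.end, ce), strand))
            if e.end > ce:
                right.append(GenomicInterval(chrom, ce, e.end, strand))
    feats[CDS] = mid
    if strand == "+":
        feats[UTR5], feats[UTR3] = left, right
    else:
        feats[UTR5], feats[UTR3] = right, left
    return feats


class AnnotationIndex:
    """Transcript models plus interval lookup and genome sequence access."""

    def __init__(self, transcripts: dict[str, TranscriptModel], genome: dict[str, str]):
        self.transcripts = transcripts
        self.genome = genome
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for tid, tx in transcripts.items():
            key = (tx.chrom, tx.strand)
            tree = self._trees.setdefault(key, IntervalTree())
            s, e = tx.span
            tree.addi(s, e, tid)

    def chrom_length(self, chrom: str) -> int:
        return len(self.genome[chrom])

    def sequence(self, chrom: str, start: int, end: int) -> str:
        return self.genome[chrom][max(start, 0) : end]

    def transcripts_at(self, chrom: str, strand: str, pos: int) -> list[str]:
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.at(pos))

    def representative_at(self, chrom: str, strand: str, pos: int) -> Optional[str]:
        """Transcript with the longest mRNA covering ``pos`` (ties: lexicographic id)."""
        tids = self.transcripts_at(chrom, strand, pos)
        if not tids:
            return None
        return min(tids, key=lambda t: (-self.transcripts[t].mrna_length, t))

    def representative_transcripts(self) -> list[str]:
        """One representative (longest-mRNA) transcript per gene."""
        by_gene: dict[str, list[str]] = {}
        for tid, tx in self.transcripts.items():
            by_gene.setdefault(tx.gene_id, []).append(tid)
        return sorted(
            min(tids, key=lambda t: (-self.transcripts[t].mrna_length, t))
            for tids in by_gene.values()
        )


def _validate_gtf_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GtfParseError(f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise GtfParseError(f"{path}:{lineno}: non-integer start/end") from None
            if start < 1 or end < start:
                raise GtfParseError(f"{path}:{lineno}: invalid coordinates {start}-{end}")
            if fields[6] not in ("+", "-", "."):
                raise GtfParseError(f"{path}:{lineno}: invalid strand {fields[6]!r}")


def load_annotation(gtf_path, fasta_path) -> AnnotationIndex:
    """Build an :class:`AnnotationIndex` from a GTF and a FASTA.

    Exon records grouped by ``transcript_id`` are required; CDS records are
    optional (non-coding transcripts carry exons + introns only).  A
    transcript whose CDS is not contained in its exons is skipped with a
    logged warning.  Malformed GTF lines raise :class:`GtfParseError`
    naming the offending line.
    """
    gtf_path, fasta_path = Path(gtf_path), Path(fasta_path)
    _validate_gtf_lines(gtf_path)
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    gene_of: dict[str, str] = {}
    for f in db.all_features():
        if f.featuretype not in ("exon", "CDS"):
            continue
        tid = f.attributes["transcript_id"][0]
        gene_of[tid] = f.attributes.get("gene_id", [tid])[0]
        # GTF 1-based inclusive -> 0-based half-open
        rec = (f.seqid, f.start - 1, f.end, f.strand)
        (exons if f.featuretype == "exon" else cds).setdefault(tid, []).append(rec)

    fa = pyfaidx.Fasta(str(fasta_path))
    genome = {name: str(fa[name][:]).upper() for name in fa.keys()}

    transcripts: dict[str, TranscriptModel] = {}
    for tid, recs in exons.items():
        ivs = [GenomicInterval(c, s, e, st) for c, s, e, st in sorted(recs, key=lambda r: r[1])]
        cds_span = None
        if tid in cds:
            # every CDS record must lie within one exon
            if not all(
                any(e.start <= s and ee <= e.end for e in ivs) for _, s, ee, _ in cds[tid]
            ):
                log.warning("transcript %s: CDS not contained in exons; skipped", tid)
                continue
            cds_span = (min(r[1] for r in cds[tid]), max(r[2] for r in cds[tid]))
        transcripts[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=gene_of[tid],
            strand=ivs[0].strand,
            exons=ivs,
            cds_span=cds_span,
        )
    return AnnotationIndex(transcripts, genome)


def transcript_sequence(index: AnnotationIndex, transcript_id: str) -> str:
    """Sense-strand (mature mRNA) sequence: spliced, reverse-complemented on minus."""
    try:
        tx = index.transcripts[transcript_id]
    except KeyError:
        raise KeyError(f"unknown transcript id: {transcript_id}") from None
    seq = "".join(index.sequence(tx.chrom, e.start, e.end) for e in tx.exons)
    return reverse_complement(seq) if tx.strand == "-" else seq


def genomic_to_meta(
    index: AnnotationIndex, transcript_id: str, position: int
) -> Optional[tuple[str, int, int]]:
    """Map a genomic position to (region, offset-in-region, region_length).

    The offset is measured 5'->3' in mRNA sense.  Returns ``None`` when the
    position is not inside the transcript span (an explicit "not in
    transcript" result rather than an exception).
    """
    tx = index.transcripts[transcript_id]
    s, e = tx.span
    if not (s <= position < e):
        return None
    for region in REGIONS:
        ivs = tx.features.get(region, [])
        hit = next((iv for iv in ivs if iv.contains(position)), None)
        if hit is None:
            continue
        region_length = sum(len(iv) for iv in ivs)
        if tx.strand == "+":
            offset = sum(len(iv) for iv in ivs if iv.end <= hit.start) + (position - hit.start)
        else:
            offset = sum(len(iv) for iv in ivs if iv.start >= hit.end) + (hit.end - 1 - position)
        return region, offset, region_length
    # coding transcript positions are fully partitioned; only reachable for
    # non-coding transcripts' exonic space
    return None


def write_gtf(transcripts: Iterable[TranscriptModel], path) -> None:
    """Emit exon + CDS records (1-based inclusive), deterministic order."""
    with open(path, "w") as out:
        for tx in sorted(transcripts, key=lambda t: (t.chrom, t.span[0], t.transcript_id)):
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
            for e in tx.exons:
                out.write(
                    f"{tx.chrom}\tclipmod\texon\t{e.start + 1}\t{e.end}\t.\t{tx.strand}\t.\t{attrs}\n"
                )
            for c in tx.features.get(CDS, []):
                out.write(
                    f"{tx.chrom}\tclipmod\tCDS\t{c.start + 1}\t{c.end}\t.\t{tx.strand}\t.\t{attrs}\n"
                )


def write_features_bed(index: AnnotationIndex, path) -> None:
    """BED6 of every region interval; name=``transcript:region``, score=0."""
    rows = []
    for tid, tx in index.transcripts.items():
        for region, ivs in tx.features.items():
            for iv in ivs:
                rows.append((iv.chrom, iv.start, iv.end, f"{tid}:{region}", 0, iv.strand))
    rows.sort()
    with open(path, "w") as out:
        for r in rows:
            out.write("\t".join(map(str, r)) + "\n")
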