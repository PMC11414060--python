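"""Synthetic genome, annotation and CLIP/miCLIP libraries with planted truth.

The generator emulates the data regimes of an iCLIP/miCLIP study on a
small random genome: multi-exon coding transcripts with 5'UTR/CDS/3'UTR
and CDS-internal introns; planted protein crosslink sites; planted m6A
sites whose DRACH context is written into the genome (in CDS/3'UTR,
where such sites concentrate in real data); planted m6Am adenosines
within the first quarter of 5'UTRs; and per-condition truncation
libraries — wildtype, size-matched input (SMI, no enrichment), GFP-only
control (its own small artifact-site set), and a knockdown condition
with attenuated enrichment.  Truncation events are Poisson per
transcribed nucleotide and each event is emitted as a read starting one
nt 3' of the event, so that truncation extraction inverts the simulation
exactly.  Everything is deterministic under the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import pyfaidx
import yaml

from .annotation import (
    CDS,
    INTRON,
    UTR3,
    UTR5,
    GenomicInterval,
    TranscriptModel,
    reverse_complement,
    write_gtf,
)

CONDITIONS = ("wildtype", "gfp", "smi", "knockdown")
_COND_CODE = {c: i for i, c in enumerate(CONDITIONS)}
_ASSAY_CODE = {"iclip": 0, "miclip": 1}


@dataclass
class SimulationSpec:
    """All knobs of the synthetic study, with the default study conditions."""

    seed: int = 0
    n_transcripts: int = 40
    n_chroms: int = 2
    utr5_range: tuple[int, int] = (120, 300)
    cds_range: tuple[int, int] = (400, 900)
    utr3_range: tuple[int, int] = (150, 400)
    introns_range: tuple[int, int] = (1, 3)
    intron_len_range: tuple[int, int] = (200, 600)
    intergenic_gap_range: tuple[int, int] = (300, 800)
    n_crosslink_sites: int = 60
    n_m6a_sites: int = 50
    n_m6am_sites: int = 30
    enrichment: float = 20.0          # fold increase of truncation rate at planted sites
    background_rate: float = 0.5      # expected truncation events per transcribed nt
    replicates: int = 2
    knockdown_attenuation: float = 0.3
    gfp_artifact_fraction: float = 0.05
    read_length: int = 35

    def __post_init__(self):
        if self.enrichment <= 1:
            raise ValueError("enrichment must exceed 1")
        for name in ("n_transcripts", "n_crosslink_sites", "n_m6a_sites", "n_m6am_sites"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key, val in raw.items():
            if isinstance(val, list):
                raw[key] = tuple(val)
        return cls(**raw)


@dataclass
class TruthTable:
    """Planted truth, consistent with the emitted FASTA/GTF."""

    features: pd.DataFrame         # transcript_id, gene_id, chrom, strand, region, start, end
    chrom_sizes: dict[str, int]
    crosslink_sites: pd.DataFrame  # chrom, strand, pos, transcript_id
    m6a_sites: pd.DataFrame        # + motif column
    m6am_sites: pd.DataFrame
    gfp_sites: pd.DataFrame

    def spans(self) -> pd.DataFrame:
        """Per-transcript genomic span (pre-mRNA, introns included)."""
        grp = self.features.groupby(["transcript_id", "chrom", "strand"], sort=True)
        return grp.agg(start=("start", "min"), end=("end", "max")).reset_index()


def _derived_seed(spec: SimulationSpec, assay: str, condition: str, replicate: int) -> int:
    return (spec.seed * 1000003 + _ASSAY_CODE[assay] * 7919 + _COND_CODE[condition] * 101 + replicate) % (2**31 - 1)


def _build_transcript(
    rng: np.random.Generator, spec: SimulationSpec, chrom: str, start: int, strand: str,
    tid: str, gene: str,
) -> TranscriptModel:
    u5 = int(rng.integers(*spec.utr5_range))
    cds_len = int(rng.integers(*spec.cds_range))
    u3 = int(rng.integers(*spec.utr3_range))
    n_introns = int(rng.integers(spec.introns_range[0], spec.introns_range[1] + 1))
    # genomic-order region lengths; on minus strand the 5'UTR sits 3'-most genomically
    left, right = (u5, u3) if strand == "+" else (u3, u5)
    mrna = left + cds_len + right
    # intron breakpoints strictly inside the CDS block (genomic mRNA coordinates)
    lo, hi = left + 20, left + cds_len - 20
    breaks = sorted(set(int(b) for b in rng.integers(lo, hi, size=n_introns)))
    intron_lens = [int(rng.integers(*spec.intron_len_range)) for _ in breaks]

    exons = []
    g = start
    prev = 0
    for b, ilen in zip(breaks, intron_lens):
        exons.append(GenomicInterval(chrom, g, g + (b - prev), strand))
        g += (b - prev) + ilen
        prev = b
    exons.append(GenomicInterval(chrom, g, g + (mrna - prev), strand))

    def to_genomic(x: int) -> int:
        """Map genomic-order mRNA coordinate to genomic coordinate."""
        shift = start
        prev_b = 0
        for b, ilen in zip(breaks, intron_lens):
            if x < b:
                break
            shift += ilen
            prev_b = b
        return shift + x

    cds_span = (to_genomic(left), to_genomic(left + cds_len - 1) + 1)
    return TranscriptModel(
        transcript_id=tid, gene_id=gene, strand=strand, exons=exons, cds_span=cds_span
    )


def _region_offset_to_genomic(tx: TranscriptModel, region: str, offset: int) -> int:
    """Genomic coordinate of a transcript-sense offset within a region."""
    ivs = tx.features[region]
    if tx.strand == "+":
        for iv in ivs:
            if offset < len(iv):
                return iv.start + offset
            offset -= len(iv)
    else:
        for iv in reversed(ivs):
            if offset < len(iv):
                return iv.end - 1 - offset
            offset -= len(iv)
    raise ValueError(f"offset beyond {region} of {tx.transcript_id}")


class _Occupancy:
    """Minimum-distance bookkeeping for planted positions, per chromosome."""

    def __init__(self, min_dist: int = 12):
        self.min_dist = min_dist
        self.by_chrom: dict[str, list[int]] = {}

    def ok(self, chrom: str, pos: int) -> bool:
        return all(abs(pos - q) >= self.min_dist for q in self.by_chrom.get(chrom, []))

    def add(self, chrom: str, pos: int) -> None:
        self.by_chrom.setdefault(chrom, []).append(pos)


def simulate_reference(
    spec: SimulationSpec, out_dir
) -> tuple[Path, Path, TruthTable]:
    """Write genome FASTA (+ .fai), GTF and truth tables; return their paths
    and the in-memory :class:`TruthTable`.

    Raises ``ValueError`` naming the violated constraint when the spec is
    infeasible (e.g. more m6Am sites than transcripts with a usable 5'UTR
    quarter).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    transcripts: list[TranscriptModel] = []
    chrom_cursor: dict[str, int] = {f"chr{i + 1}": 0 for i in range(spec.n_chroms)}
    chrom_names = list(chrom_cursor)
    for t in range(spec.n_transcripts):
        chrom = chrom_names[t % spec.n_chroms]
        gap = int(rng.integers(*spec.intergenic_gap_range))
        start = chrom_cursor[chrom] + gap
        strand = "+" if rng.integers(2) == 0 else "-"
        tid, gene = f"tx{t + 1:04d}", f"gene{t + 1:04d}"
        tx = _build_transcript(rng, spec, chrom, start, strand, tid, gene)
        transcripts.append(tx)
        chrom_cursor[chrom] = tx.span[1]
    chrom_sizes = {
        c: cur + int(rng.integers(*spec.intergenic_gap_range)) for c, cur in chrom_cursor.items()
    }

    genome = {
        c: rng.choice(np.array(list("ACGT")), size=n).tolist() for c, n in chrom_sizes.items()
    }

    occupied = _Occupancy()

    def _write_sense(chrom: str, center: int, strand: str, sense9: str) -> None:
        seq = sense9 if strand == "+" else reverse_complement(sense9)
        genome[chrom][center - 4 : center + 5] = list(seq)

    def _plant(n_sites: int, chooser, label: str) -> list[dict]:
        rows = []
        tries = 0
        while len(rows) < n_sites:
            tries += 1
            if tries > 200 * max(n_sites, 1):
                raise ValueError(
                    f"infeasible spec: could not place {n_sites} {label} sites "
                    f"(placed {len(rows)}); relax counts or enlarge regions"
                )
            row = chooser()
            if row is None or not occupied.ok(row["chrom"], row["pos"]):
                continue
            occupied.add(row["chrom"], row["pos"])
            rows.append(row)
        return rows

    coding = [tx for tx in transcripts if tx.is_coding]

    # ---- m6A: DRACH context written into CDS/3'UTR ----------------------
    def choose_m6a():
        tx = coding[int(rng.integers(len(coding)))]
        w_cds, w_utr3 = tx.region_length(CDS), tx.region_length(UTR3)
        region = CDS if rng.random() < w_cds / (w_cds + w_utr3) else UTR3
        ivs = tx.features[region]
        iv = ivs[int(rng.integers(len(ivs)))]
        if len(iv) < 12:
            return None
        g = int(rng.integers(iv.start + 4, iv.end - 5))
        motif = (
            "AGT"[int(rng.integers(3))] + "AG"[int(rng.integers(2))] + "AC" + "ACT"[int(rng.integers(3))]
        )
        return {"chrom": tx.chrom, "strand": tx.strand, "pos": g,
                "transcript_id": tx.transcript_id, "motif": motif}

    m6a_rows = _plant(spec.n_m6a_sites, choose_m6a, "m6A")
    for row in m6a_rows:
        # flanks chosen so exactly one DRACH center exists in the +/-2 window
        _write_sense(row["chrom"], row["pos"], row["strand"], "TC" + row["motif"] + "CC")

    # ---- m6Am: lone A in the first quarter of a 5'UTR -------------------
    feasible = [tx for tx in coding if tx.utr5_length // 4 >= 10]
    if spec.n_m6am_sites > len(feasible):
        raise ValueError(
            f"infeasible spec: n_m6am_sites={spec.n_m6am_sites} exceeds the "
            f"{len(feasible)} transcripts whose 5'UTR quarter can host a site"
        )
    m6am_hosts = rng.permutation(len(feasible))[: spec.n_m6am_sites]
    m6am_rows = []
    for i in m6am_hosts:
        tx = feasible[int(i)]
        quarter = int(0.25 * tx.utr5_length)
        off = int(rng.integers(4, quarter - 4))
        g = _region_offset_to_genomic(tx, UTR5, off)
        if not occupied.ok(tx.chrom, g):
            raise ValueError("infeasible spec: m6Am placement collided with another site")
        occupied.add(tx.chrom, g)
        _write_sense(tx.chrom, g, tx.strand, "CCCCACCCC")
        m6am_rows.append(
            {"chrom": tx.chrom, "strand": tx.strand, "pos": g,
             "transcript_id": tx.transcript_id, "utr5_offset": off}
        )

    # ---- protein crosslink sites: exonic, no sequence context -----------
    def choose_crosslink():
        tx = coding[int(rng.integers(len(coding)))]
        exon = tx.exons[int(rng.integers(len(tx.exons)))]
        if len(exon) < 12:
            return None
        g = int(rng.integers(exon.start + 4, exon.end - 5))
        return {"chrom": tx.chrom, "strand": tx.strand, "pos": g, "transcript_id": tx.transcript_id}

    crosslink_rows = _plant(spec.n_crosslink_sites, choose_crosslink, "crosslink")
    n_gfp = max(1, round(spec.gfp_artifact_fraction * spec.n_crosslink_sites))
    gfp_rows = _plant(n_gfp, choose_crosslink, "GFP artifact")

    # ---- write reference files ------------------------------------------
    fasta_path = out_dir / "genome.fa"
    with open(fasta_path, "w") as fh:
        for chrom in chrom_names:
            fh.write(f">{chrom}\n")
            seq = "".join(genome[chrom])
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    pyfaidx.Faidx(str(fasta_path))

    gtf_path = out_dir / "annotation.gtf"
    write_gtf(transcripts, gtf_path)

    feat_rows = []
    for tx in transcripts:
        for region in (UTR5, CDS, UTR3, INTRON):
            for iv in tx.features.get(region, []):
                feat_rows.append(
                    (tx.transcript_id, tx.gene_id, tx.chrom, tx.strand, region, iv.start, iv.end)
                )
    features = pd.DataFrame(
        feat_rows, columns=["transcript_id", "gene_id", "chrom", "strand", "region", "start", "end"]
    ).sort_values(["chrom", "start", "transcript_id", "region"], kind="stable").reset_index(drop=True)

    truth = TruthTable(
        features=features,
        chrom_sizes=chrom_sizes,
        crosslink_sites=pd.DataFrame(crosslink_rows),
        m6a_sites=pd.DataFrame(m6a_rows),
        m6am_sites=pd.DataFrame(m6am_rows),
        gfp_sites=pd.DataFrame(gfp_rows),
    )
    features.to_csv(out_dir / "truth_features.tsv", sep="\t", index=False)
    truth.crosslink_sites.to_csv(out_dir / "truth_crosslink_sites.tsv", sep="\t", index=False)
    truth.m6a_sites.to_csv(out_dir / "truth_m6a_sites.tsv", sep="\t", index=False)
    truth.m6am_sites.to_csv(out_dir / "truth_m6am_sites.tsv", sep="\t", index=False)
    truth.gfp_sites.to_csv(out_dir / "truth_gfp_sites.tsv", sep="\t", index=False)
    return fasta_path, gtf_path, truth


def _transcribed_positions(truth: TruthTable) -> dict[tuple[str, str], np.ndarray]:
    """All pre-mRNA positions per (chrom, strand), from transcript spans."""
    out: dict[tuple[str, str], list[np.ndarray]] = {}
    for _, row in truth.spans().iterrows():
        out.setdefault((row.chrom, row.strand), []).append(np.arange(row.start, row.end))
    return {k: np.unique(np.concatenate(v)) for k, v in sorted(out.items())}


def simulate_clip_library(
    spec: SimulationSpec,
    truth: TruthTable,
    condition: str,
    replicate: int = 1,
    assay: str = "iclip",
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, dict]:
    """Draw one truncation library and emit it as BED6 read records.

    Truncation counts are Poisson(background_rate) per transcribed nt,
    multiplied by ``enrichment`` at planted sites (crosslink sites for
    ``assay="iclip"``, m6A+m6Am for ``assay="miclip"``).  The knockdown
    condition attenuates enrichment by ``knockdown_attenuation``; SMI has
    no enrichment; the GFP control enriches only its own artifact sites.
    Each event at position p becomes a read starting one nt 3' of p, so
    truncation extraction recovers p exactly.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    if assay not in _ASSAY_CODE:
        raise ValueError(f"unknown assay {assay!r}")
    if seed is None:
        seed = _derived_seed(spec, assay, condition, replicate)
    rng = np.random.default_rng(seed)
    sample_id = f"{assay}_{condition}_rep{replicate}"

    if condition == "gfp":
        site_df = truth.gfp_sites
        fold = spec.enrichment
    elif condition == "smi":
        site_df = None
        fold = 1.0
    else:
        site_df = (
            truth.crosslink_sites
            if assay == "iclip"
            else pd.concat([truth.m6a_sites, truth.m6am_sites], ignore_index=True)
        )
        fold = spec.enrichment * (spec.knockdown_attenuation if condition == "knockdown" else 1.0)

    enriched: dict[tuple[str, str], set[int]] = {}
    if site_df is not None and not site_df.empty:
        for _, row in site_df.iterrows():
            enriched.setdefault((row.chrom, row.strand), set()).add(int(row.pos))

    reads = []
    expected = {}
    L = spec.read_length
    for (chrom, strand), positions in _transcribed_positions(truth).items():
        lam = np.full(len(positions), spec.background_rate)
        hot = enriched.get((chrom, strand), ())
        if hot:
            mask = np.isin(positions, sorted(hot))
            lam[mask] *= fold
            for p in sorted(hot):
                expected[(chrom, strand, p)] = spec.background_rate * fold
        counts = rng.poisson(lam)
        nz = counts > 0
        clen = truth.chrom_sizes[chrom]
        for p, c in zip(positions[nz].tolist(), counts[nz].tolist()):
            if strand == "+":
                s, e = p + 1, min(p + 1 + L, clen)
            else:
                s, e = max(p - L, 0), p
            if e <= s:
                continue
            reads.extend([(chrom, s, e, sample_id, 0, strand)] * c)
    df = pd.DataFrame(reads, columns=["chrom", "start", "end", "name", "score", "strand"])
    df = df.sort_values(["chrom", "start", "end", "strand"], kind="stable").reset_index(drop=True)
    rates = {"sample_id": sample_id, "fold": fold, "background_rate": spec.background_rate,
             "expected_site_rate": expected}
    return df, rates


def simulate_gene_foldchanges(
    spec: SimulationSpec,
    truth: Optional[TruthTable] = None,
    effect: float = 0.3,
    n_genes: int = 2000,
    target_fraction: float = 0.3,
    sigma: float = 0.5,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Per-gene log2 fold changes: N(0, sigma) for non-targets, shifted to
    N(-effect, sigma) for targets.  Gene ids reuse the reference's genes
    when a truth table is given (padded with extra synthetic genes)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if truth is not None:
        base = sorted(truth.features["gene_id"].unique().tolist())
    else:
        base = []
    genes = base + [f"gene_extra{i:05d}" for i in range(len(base), n_genes)]
    genes = genes[:n_genes] if len(genes) >= n_genes else genes
    n = len(genes)
    n_targets = int(round(target_fraction * n))
    is_target = np.zeros(n, dtype=bool)
    is_target[rng.permutation(n)[:n_targets]] = True
    log2fc = rng.normal(0.0, sigma, size=n)
    log2fc[is_target] -= effect
    return pd.DataFrame({"gene_id": genes, "log2fc": log2fc, "is_target": is_target})


def write_reads_bam(reads: pd.DataFrame, chrom_sizes: dict[str, int], path) -> Path:
    """Write BED6-style read records as an unsorted BAM (interface testing)."""
    import pysam

    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": c, "LN": n} for c, n in sorted(chrom_sizes.items())],
    }
    tid_of = {c: i for i, c in enumerate(sorted(chrom_sizes))}
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for i, r in enumerate(reads.itertuples(index=False)):
            a = pysam.AlignedSegment()
            a.query_name = f"{r.name}.{i}"
            length = int(r.end) - int(r.start)
            a.query_sequence = "N" * length
            a.reference_id = tid_of[r.chrom]
            a.reference_start = int(r.start)
            a.cigarstring = f"{length}M"
            a.mapping_quality = 60
            a.is_reverse = r.strand == "-"
            bam.write(a)
    return Path(path)


def simulate_dataset(spec: SimulationSpec, out_dir) -> dict:
    """Full dataset: reference + per-condition libraries + sample sheet.

    Writes BED6 reads per sample and a TSV sample sheet
    (sample_id, path, group) consumed by the counts module; returns a
    manifest of written paths.
    """
    out_dir = Path(out_dir)
    fasta, gtf, truth = simulate_reference(spec, out_dir)
    manifest = {"fasta": str(fasta), "gtf": str(gtf), "samples": []}
    plan = [("iclip", "wildtype"), ("iclip", "smi"), ("iclip", "gfp"),
            ("miclip", "wildtype"), ("miclip", "knockdown")]
    rows = []
    for assay, condition in plan:
        for rep in range(1, spec.replicates + 1):
            df, rates = simulate_clip_library(spec, truth, condition, rep, assay=assay)
            path = out_dir / f"{rates['sample_id']}.reads.bed"
            df.to_csv(path, sep="\t", header=False, index=False)
            rows.append((rates["sample_id"], str(path), f"{assay}_{condition}"))
            manifest["samples"].append(str(path))
    sheet = pd.DataFrame(rows, columns=["sample_id", "path", "group"])
    sheet.to_csv(out_dir / "samples.tsv", sep="\t", index=False)
    manifest["sample_sheet"] = str(out_dir / "samples.tsv")
    spec.to_yaml(out_dir / "sim_spec.yaml")
    return manifest
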