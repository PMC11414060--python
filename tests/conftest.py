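"""Shared fixtures: a tiny hand-built annotation and a seeded synthetic dataset."""

import numpy as np
import pytest

from clipmod import SimulationSpec, load_annotation, simulate_reference

TINY_GTF = """\
chr1\ttest\texon\t1\t100\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\ttest\texon\t201\t300\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\ttest\tCDS\t51\t100\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\ttest\tCDS\t201\t250\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr2\ttest\texon\t1\t100\t.\t-\t.\tgene_id "g2"; transcript_id "t2";
chr2\ttest\texon\t201\t300\t.\t-\t.\tgene_id "g2"; transcript_id "t2";
chr2\ttest\tCDS\t51\t100\t.\t-\t.\tgene_id "g2"; transcript_id "t2";
chr2\ttest\tCDS\t201\t250\t.\t-\t.\tgene_id "g2"; transcript_id "t2";
"""


def _random_fasta(names, length, seed):
    rng = np.random.default_rng(seed)
    records = []
    for name in names:
        seq = "".join(rng.choice(list("ACGT"), size=length))
        records.append(f">{name}\n" + "\n".join(seq[i : i + 60] for i in range(0, length, 60)))
    return "\n".join(records) + "\n"


@pytest.fixture(scope="session")
def tiny_paths(tmp_path_factory):
    d = tmp_path_factory.mktemp("tiny")
    gtf = d / "tiny.gtf"
    fasta = d / "tiny.fa"
    gtf.write_text(TINY_GTF)
    fasta.write_text(_random_fasta(["chr1", "chr2"], 400, seed=11))
    return gtf, fasta


@pytest.fixture(scope="session")
def tiny_index(tiny_paths):
    gtf, fasta = tiny_paths
    return load_annotation(gtf, fasta)


@pytest.fixture(scope="session")
def sim_spec():
    return SimulationSpec(
        seed=7,
        n_transcripts=16,
        n_crosslink_sites=20,
        n_m6a_sites=15,
        n_m6am_sites=8,
    )


@pytest.fixture(scope="session")
def sim_data(sim_spec, tmp_path_factory):
    d = tmp_path_factory.mktemp("sim")
    fasta, gtf, truth = simulate_reference(sim_spec, d)
    return {"dir": d, "fasta": fasta, "gtf": gtf, "truth": truth}


@pytest.fixture(scope="session")
def sim_index(sim_data):
    return load_annotation(sim_data["gtf"], sim_data["fasta"])


def site_key(obj):
    """Canonical (chrom, strand, pos) of a peak/site-like object."""
    site = getattr(obj, "site", obj)
    return site.chrom, site.strand, site.start


def truth_keys(df):
    return {(r.chrom, r.strand, int(r.pos)) for r in df.itertuples(index=False)}
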