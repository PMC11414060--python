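"""Per-site count matrices, normalization, and group comparisons.

Site-level counts (truncations within site +/- flank nt) are normalized
with median-of-ratios size factors and compared between sample groups
with rank tests: a two-sided Mann-Whitney U for two groups, one-way
ANOVA with Tukey HSD post-hoc contrasts for three or more.  A closed-form
ddCT helper implements qPCR relative quantification
(RQ = 2^-((CTt - CTr) - (CTt0 - CTr0))).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f_oneway, mannwhitneyu
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .cits import TruncationTrack, _chrom, _pos, _strand


@dataclass
class SiteCountMatrix:
    counts: pd.DataFrame          # rows: site ids, columns: sample ids, integer values
    size_factors: pd.Series       # per-sample normalization scalar (> 0)
    flank: int = 2

    def normalized(self) -> pd.DataFrame:
        return self.counts / self.size_factors


def median_of_ratios(
    counts: pd.DataFrame, min_rows: int = 10, fallback_libs: pd.Series | None = None
) -> pd.Series:
    """DESeq-style size factors: median over rows of count / row geometric
    mean, using rows positive in every sample.  Falls back to library-size
    ratios (``fallback_libs`` or the matrix column sums) when fewer than
    ``min_rows`` such rows exist."""
    positive = counts[(counts > 0).all(axis=1)]
    if len(positive) >= min_rows:
        log_geo = np.log(positive).mean(axis=1)
        ratios = np.log(positive).sub(log_geo, axis=0)
        factors = np.exp(ratios.median(axis=0))
    else:
        libs = (fallback_libs if fallback_libs is not None else counts.sum(axis=0)).astype(float)
        libs = libs.reindex(counts.columns)
        if (libs <= 0).any():
            raise ValueError("cannot derive size factors: a sample has zero total counts")
        factors = libs / np.exp(np.log(libs).mean())
    return factors


def count_sites(
    sites: Sequence, tracks: Mapping[str, TruncationTrack], flank: int = 2
) -> SiteCountMatrix:
    """Reads (truncation events) overlapping each site +/- flank, per sample."""
    ids, keys = [], []
    for s in sites:
        chrom, strand, pos = _chrom(s), _strand(s), _pos(s)
        ids.append(f"{chrom}:{strand}:{pos}")
        keys.append((chrom, strand, pos))
    data = {}
    for sample_id in sorted(tracks):
        track = tracks[sample_id]
        col = np.zeros(len(keys), dtype=np.int64)
        for i, (chrom, strand, pos) in enumerate(keys):
            starts = np.array([max(0, pos - flank)])
            ends = np.array([pos + flank + 1])
            col[i] = track.window_counts(chrom, strand, starts, ends)[0]
        data[sample_id] = col
    counts = pd.DataFrame(data, index=ids)
    libs = pd.Series({sid: tracks[sid].library_size for sid in counts.columns})
    return SiteCountMatrix(
        counts=counts, size_factors=median_of_ratios(counts, fallback_libs=libs), flank=flank
    )


@dataclass
class GroupComparison:
    labels: list[str]
    group_means: dict[str, float]
    test: str                     # "mann-whitney" or "anova-tukey"
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None = None   # Tukey HSD contrasts for >= 3 groups
    group_values: dict[str, np.ndarray] = field(default_factory=dict, repr=False)


def _group_values(matrix_or_values, groups) -> dict[str, np.ndarray]:
    """Pool per-row values per group label.

    ``matrix_or_values`` is a SiteCountMatrix (columns = samples; values
    normalized by size factors before pooling) or a mapping/Series of
    per-gene values with ``groups`` mapping ids to labels.
    """
    out: dict[str, list[float]] = {}
    if isinstance(matrix_or_values, SiteCountMatrix):
        norm = matrix_or_values.normalized()
        for sample, label in groups.items():
            out.setdefault(label, []).extend(norm[sample].tolist())
    else:
        values = pd.Series(matrix_or_values)
        for gid, label in groups.items():
            if gid in values.index:
                out.setdefault(label, []).append(float(values[gid]))
    return {k: np.asarray(v, dtype=float) for k, v in out.items()}


def compare_groups(matrix_or_values, groups: Mapping[str, str]) -> GroupComparison:
    """Rank-based comparison of >= 2 sample groups.

    Two groups: two-sided Mann-Whitney U on pooled per-row values.
    Three or more: one-way ANOVA F test plus Tukey HSD pairwise contrasts.
    """
    by_label = _group_values(matrix_or_values, groups)
    labels = sorted(by_label)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    for lab in labels:
        if len(by_label[lab]) == 0:
            raise ValueError(f"group {lab!r} is empty")
    means = {lab: float(np.mean(by_label[lab])) for lab in labels}
    if len(labels) == 2:
        u, p = mannwhitneyu(by_label[labels[0]], by_label[labels[1]], alternative="two-sided")
        return GroupComparison(
            labels=labels, group_means=means, test="mann-whitney",
            statistic=float(u), p_value=float(p), group_values=by_label,
        )
    f, p = f_oneway(*(by_label[lab] for lab in labels))
    values = np.concatenate([by_label[lab] for lab in labels])
    tags = np.concatenate([[lab] * len(by_label[lab]) for lab in labels])
    tk = pairwise_tukeyhsd(values, tags)
    pairwise = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    return GroupComparison(
        labels=labels, group_means=means, test="anova-tukey",
        statistic=float(f), p_value=float(p), pairwise=pairwise, group_values=by_label,
    )


def ddct(ct_target: float, ct_ref: float, ct_target_t0: float, ct_ref_t0: float) -> float:
    """qPCR relative quantity: 2^-ddCT with reference-gene and baseline
    normalization (ddCT = (CTt - CTr) - (CTt0 - CTr0))."""
    delta_delta = (ct_target - ct_ref) - (ct_target_t0 - ct_ref_t0)
    return float(2.0 ** (-delta_delta))


def target_vs_nontarget_foldchange(
    per_gene_log2fc: Mapping[str, float] | pd.Series,
    gene_set: set[str],
    labels: tuple[str, str] = ("target", "non-target"),
) -> GroupComparison:
    """Compare log2 fold changes of a gene set against its complement.

    ``gene_set`` is the target (or m6A-containing) gene list; all other
    genes in ``per_gene_log2fc`` form the comparison group.
    """
    values = pd.Series(per_gene_log2fc)
    in_set = values.index.isin(gene_set)
    if not in_set.any():
        raise ValueError("gene set does not intersect the fold-change table")
    if in_set.all():
        raise ValueError("gene set covers every gene; the complement is empty")
    groups = {gid: (labels[0] if hit else labels[1]) for gid, hit in zip(values.index, in_set)}
    return compare_groups(values, groups)
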