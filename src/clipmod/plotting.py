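"""Minimal matplotlib figures for metagene and anchor profiles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .enrichment import AnchorProfile
from .metagene import MetageneProfile


def plot_metagene(profile: MetageneProfile, path, title: str = "Metagene profile") -> None:
    fig, ax = plt.subplots(figsize=(7, 3))
    x = np.arange(len(profile.density))
    ax.plot(x, profile.density, lw=1.2, color="tab:blue")
    ax.fill_between(x, profile.density - profile.sem, profile.density + profile.sem,
                    alpha=0.3, color="tab:blue", linewidth=0)
    cursor = 0
    for region in ("utr5", "cds", "utr3"):
        n = profile.bin_counts[region]
        ax.axvline(cursor, color="grey", lw=0.5)
        ax.text(cursor + n / 2, ax.get_ylim()[1], region.upper(), ha="center", va="bottom")
        cursor += n
    ax.set_xlabel("standardized position")
    ax.set_ylabel("events per million")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_anchor(profile: AnchorProfile, path, title: str = "Anchored density") -> None:
    fig, ax = plt.subplots(figsize=(6, 3.5))
    for mean, sem, label, color in (
        (profile.mean, profile.sem, "anchors", "tab:red"),
        (profile.null_mean, profile.null_sem, "random sites", "tab:grey"),
    ):
        ax.plot(profile.offsets, mean, lw=1.2, label=label, color=color)
        ax.fill_between(profile.offsets, mean - sem, mean + sem, alpha=0.3,
                        color=color, linewidth=0)
    ax.axvline(0, color="black", lw=0.5, ls="--")
    ax.set_xlabel("offset from site (nt, transcript sense)")
    ax.set_ylabel("mean density (CPM)")
    ax.legend(frameon=False)
    ax.set_title(f"{title} (p = {profile.p_value:.2g})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
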