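"""Per-chromosome allele-frequency plots of candidate markers.

A local replacement for web-based SNP plotting: one panel per chromosome,
high-bulk donor-allele frequency against physical position (Mbp), passing
candidates highlighted and merged candidate regions shaded.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .clustering import CandidateRegion  # noqa: E402
from .genome import GenomeModel  # noqa: E402


def plot_allele_frequency(results, regions: list[CandidateRegion],
                          genome: GenomeModel, path: str | Path) -> Path:
    """Scatter HAB donor-allele frequency vs position, one panel per chromosome."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    chroms = genome.chromosome_names
    ncol = 3
    nrow = (len(chroms) + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 2.2 * nrow),
                             sharey=True, squeeze=False)
    by_chrom = dict(tuple(results.groupby("chrom"))) if len(results) else {}
    regions_by_chrom: dict[str, list[CandidateRegion]] = {}
    for r in regions:
        regions_by_chrom.setdefault(r.chrom, []).append(r)

    for i, chrom in enumerate(chroms):
        ax = axes[i // ncol][i % ncol]
        ax.set_title(chrom, fontsize=9)
        ax.set_xlim(0, genome.chromosome(chrom).length_bp / 1e6)
        ax.set_ylim(0, 1.05)
        for reg in regions_by_chrom.get(chrom, []):
            ax.axvspan(reg.start / 1e6, max(reg.end, reg.start + 1) / 1e6,
                       color="gold", alpha=0.4, lw=0)
        sub = by_chrom.get(chrom)
        if sub is not None and len(sub):
            ax.scatter(sub["pos"] / 1e6, sub["freq_hab"], s=12, c="grey",
                       label="evaluated")
            hits = sub[sub["passed"]]
            if len(hits):
                ax.scatter(hits["pos"] / 1e6, hits["freq_hab"], s=22, c="crimson",
                           zorder=3, label="candidate")
        if i % ncol == 0:
            ax.set_ylabel("HAB donor-allele freq")
        if i // ncol == nrow - 1:
            ax.set_xlabel("position (Mbp)")
    for j in range(len(chroms), nrow * ncol):
        axes[j // ncol][j % ncol].set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
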