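"""Genome model: chromosomes with physical/genetic scales and founder-diagnostic sites.

The two founders of the cross are called the *donor* (the introgressed,
high-amylose parent, an African rice) and the *recurrent* parent (the Asian
rice background the population was repeatedly backcrossed to).  A founder
site is a position at which the two parents carry different, fixed alleles,
so pooled reads at that site report the parental origin of the underlying
haplotypes.  Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: default genetic/physical rate (cM per Mbp); on chromosome 6 this makes a
#: 2.1 Mbp physical interval correspond to about 10 cM.
DEFAULT_CM_PER_MBP = 4.76

# IRGSP-1.0 chromosome sizes, rounded to 10 kb.
_RICE_CHROM_MBP = {
    "chr01": 43.27, "chr02": 35.94, "chr03": 36.41, "chr04": 35.50,
    "chr05": 29.96, "chr06": 31.25, "chr07": 29.70, "chr08": 28.44,
    "chr09": 23.01, "chr10": 23.21, "chr11": 29.02, "chr12": 27.53,
}

#: position of the granule-bound starch synthase I (waxy) locus on chr 6
GBSS1_CHROM = "chr06"
GBSS1_POS = 1_769_686

#: minor amylose loci: starch synthase IVa region on chr 1, NAC TF on chr 11
MINOR_QTL_CHR01 = ("chr01", 30_038_502)
MINOR_QTL_CHR11 = ("chr11", 18_288_616)

_NUCS = np.array(list("ACGT"))


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    length_cm: float

    def __post_init__(self):
        if self.length_bp <= 0:
            raise ValueError(f"{self.name}: chromosome length must be positive")
        if self.length_cm < 0:
            raise ValueError(f"{self.name}: genetic length must be >= 0")


@dataclass
class GenomeModel:
    """Chromosome table plus founder-diagnostic site map.

    Parameters
    ----------
    chromosomes
        Ordered list of :class:`Chromosome`.
    sites
        DataFrame with columns ``chrom, pos, donor, recurrent``: 1-based
        positions with the single-nucleotide allele fixed in each founder.
    """

    chromosomes: list[Chromosome]
    sites: pd.DataFrame
    _site_pos: dict[str, np.ndarray] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self):
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        required = {"chrom", "pos", "donor", "recurrent"}
        if not required.issubset(self.sites.columns):
            raise ValueError(f"sites table needs columns {sorted(required)}")
        self.sites = self.sites.reset_index(drop=True)
        by_name = {c.name: c for c in self.chromosomes}
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            if chrom not in by_name:
                raise ValueError(f"site on unknown chromosome {chrom!r}")
            pos = grp["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"{chrom}: site positions must be strictly increasing")
            if pos[0] < 1 or pos[-1] > by_name[chrom].length_bp:
                raise ValueError(f"{chrom}: site position outside chromosome")
            if (grp["donor"] == grp["recurrent"]).any():
                raise ValueError(f"{chrom}: founder alleles must differ at every site")
            self._site_pos[chrom] = pos

    @property
    def chromosome_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def site_positions(self, chrom: str) -> np.ndarray:
        return self._site_pos.get(chrom, np.empty(0, dtype=int))

    def site_index(self, chrom: str, pos: int) -> int:
        p = self.site_positions(chrom)
        i = int(np.searchsorted(p, pos))
        if i >= len(p) or p[i] != pos:
            raise KeyError(f"no founder site at {chrom}:{pos}")
        return i

    def n_sites(self) -> int:
        return len(self.sites)


def default_rice_genome(
    site_spacing: int = 50_000,
    cm_per_mbp: float = DEFAULT_CM_PER_MBP,
    extra_sites: list[tuple[str, int]] | None = None,
) -> GenomeModel:
    """Rice-like 12-chromosome genome with evenly spaced founder sites.

    Sites are laid down every ``site_spacing`` bp starting at
    ``site_spacing // 2``; the waxy locus (chr06:1,769,686) and the two minor
    amylose loci on chr01 and chr11 are always included so that the default
    QTL model refers to real sites.  Allele pairs cycle deterministically
    through the distinct ordered nucleotide pairs, so the map itself carries
    no randomness.
    """
    chroms = [
        Chromosome(name, int(round(mbp * 1e6)), mbp * cm_per_mbp)
        for name, mbp in _RICE_CHROM_MBP.items()
    ]
    anchors = {GBSS1_CHROM: [GBSS1_POS],
               MINOR_QTL_CHR01[0]: [MINOR_QTL_CHR01[1]],
               MINOR_QTL_CHR11[0]: [MINOR_QTL_CHR11[1]]}
    for chrom, pos in (extra_sites or []):
        anchors.setdefault(chrom, []).append(pos)

    rows = []
    pair_cycle = [(a, b) for a in "ACGT" for b in "ACGT" if a != b]
    k = 0
    for c in chroms:
        pos = list(range(site_spacing // 2, c.length_bp + 1, site_spacing))
        pos = sorted(set(pos) | set(anchors.get(c.name, [])))
        for p in pos:
            if c.name == GBSS1_CHROM and p == GBSS1_POS:
                donor, recurrent = "A", "G"  # Asn-encoding vs Asp-encoding
            else:
                donor, recurrent = pair_cycle[k % len(pair_cycle)]
                k += 1
            rows.append((c.name, p, donor, recurrent))
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "donor", "recurrent"])
    return GenomeModel(chroms, sites)
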