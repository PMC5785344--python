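"""Forward-in-time simulation of a BC2F8 RIL population and pooled sequencing.

Pedigree: F1 (donor x recurrent), two backcrosses to the recurrent parent,
then seven generations of selfing by single-seed descent (F1->F8 indexing,
i.e. "BC2F8" = the BC2F1 selfed seven times).  Meiosis follows the Haldane
model: per chromosome the crossover count is Poisson with mean equal to the
genetic length in Morgans, breakpoints uniform on the physical map, no
interference.  Phenotypes are purely additive over a small set of QTLs plus
Gaussian environmental noise.  Pooled sequencing of a bulk draws a Poisson
read depth per site from the bulk's allele pool (each member's two haplotypes
weighted equally) with a per-read uniform base-error model.

Haplotypes are run-length encoded as (segment ends, origins) arrays, with
origin 0 = recurrent, 1 = donor; a segment's start is the previous end + 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeModel

DONOR = 1
RECURRENT = 0

_NUCLEOTIDES = "ACGT"


@dataclass(frozen=True)
class Haplotype:
    """Mosaic of founder segments along one chromosome (RLE)."""

    ends: np.ndarray     # 1-based inclusive segment end positions, ascending
    origins: np.ndarray  # int8, same length; 0 recurrent / 1 donor

    def __post_init__(self):
        if len(self.ends) != len(self.origins) or len(self.ends) == 0:
            raise ValueError("ends and origins must be equal-length, non-empty")
        if not np.all(np.diff(self.ends) > 0):
            raise ValueError("segment ends must be strictly increasing")

    @property
    def length(self) -> int:
        return int(self.ends[-1])

    def segments(self) -> list[tuple[int, int, str]]:
        """Segments as (start, end, 'donor'|'recurrent'), 1-based inclusive."""
        out, start = [], 1
        for end, o in zip(self.ends, self.origins):
            out.append((start, int(end), "donor" if o == DONOR else "recurrent"))
            start = int(end) + 1
        return out

    def origin_at(self, positions: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.ends, positions)
        return self.origins[idx]

    def simplify(self) -> "Haplotype":
        keep = np.append(self.origins[1:] != self.origins[:-1], True)
        return Haplotype(self.ends[keep], self.origins[keep])


def uniform_haplotype(length: int, origin: int) -> Haplotype:
    return Haplotype(np.array([length]), np.array([origin], dtype=np.int8))


@dataclass
class Individual:
    """Diploid genome as two haplotypes per chromosome, plus the phenotype."""

    haplotypes: dict[str, tuple[Haplotype, Haplotype]]
    phenotype_ac: float | None = None  # amylose, % of total starch
    id: str | None = None

    def dosage(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Donor-allele dosage (0/1/2) at each position."""
        h1, h2 = self.haplotypes[chrom]
        return (h1.origin_at(positions).astype(np.int64)
                + h2.origin_at(positions).astype(np.int64))


def founder(genome: GenomeModel, origin: int, id: str | None = None) -> Individual:
    haps = {
        c.name: (uniform_haplotype(c.length_bp, origin),
                 uniform_haplotype(c.length_bp, origin))
        for c in genome.chromosomes
    }
    return Individual(haps, id=id)


@dataclass
class QtlModel:
    """Additive QTL model for amylose content.

    ``qtl_effects`` entries are (chrom, pos, effect): the phenotype shift, in
    percentage points of amylose, of a homozygous-donor genotype relative to
    homozygous-recurrent (heterozygotes get half).  Defaults are calibrated
    so the recurrent parent scores 23.2%, a line homozygous-donor at the waxy
    locus alone 25.7%, and progeny span roughly 19-27% with transgressive
    segregation skewed toward the low parent: a major +2.5 effect at the waxy
    locus, a small positive minor locus on chr 11 and a larger negative minor
    locus on chr 1.
    """

    baseline_ac: float = 23.2
    qtl_effects: list[tuple[str, int, float]] = field(default_factory=lambda: [
        ("chr06", 1_769_686, +2.5),
        ("chr11", 18_288_616, +0.75),
        ("chr01", 30_038_502, -2.25),
    ])
    env_sd: float = 0.8

    def __post_init__(self):
        if self.env_sd < 0:
            raise ValueError("env_sd must be >= 0")

    def validate_sites(self, genome: GenomeModel) -> None:
        for chrom, pos, _ in self.qtl_effects:
            genome.site_index(chrom, pos)  # KeyError if absent


# ---------------------------------------------------------------------------
# meiosis

def _gamete_chromosome(h1: Haplotype, h2: Haplotype, length_bp: int,
                       length_cm: float, rng: np.random.Generator) -> Haplotype:
    n_xo = rng.poisson(length_cm / 100.0) if length_cm > 0 else 0
    current = int(rng.integers(2))
    if n_xo == 0:
        return (h1, h2)[current]
    breaks = np.sort(rng.integers(1, length_bp, size=n_xo))
    # walk intervals [prev+1, b] alternating between the two parental haplotypes
    ends, origins = [], []
    parents = (h1, h2)
    prev = 0
    for b in list(breaks) + [length_bp]:
        if b <= prev:
            current ^= 1
            continue
        h = parents[current]
        i0 = int(np.searchsorted(h.ends, prev + 1))
        i1 = int(np.searchsorted(h.ends, b))
        seg_ends = h.ends[i0:i1 + 1].copy()
        seg_ends[-1] = b
        ends.append(seg_ends)
        origins.append(h.origins[i0:i1 + 1])
        prev = b
        current ^= 1
    hap = Haplotype(np.concatenate(ends), np.concatenate(origins).astype(np.int8))
    return hap.simplify()


def simulate_gamete(parent: Individual, genome: GenomeModel,
                    rng: np.random.Generator | int) -> dict[str, Haplotype]:
    """One recombinant gamete: a haplotype per chromosome (Haldane model)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = {}
    for c in genome.chromosomes:
        h1, h2 = parent.haplotypes[c.name]
        out[c.name] = _gamete_chromosome(h1, h2, c.length_bp, c.length_cm, rng)
    return out


def _cross(p1: Individual, p2: Individual, genome: GenomeModel,
           rng: np.random.Generator) -> Individual:
    g1 = simulate_gamete(p1, genome, rng)
    g2 = simulate_gamete(p2, genome, rng)
    return Individual({c: (g1[c], g2[c]) for c in g1})


def breed_bc2f8(genome: GenomeModel, n_progeny: int,
                rng_seed: int | np.random.SeedSequence,
                n_backcrosses: int = 2, n_selfings: int = 7) -> list[Individual]:
    """Independent BC2F8 lines: F1, two backcrosses, seven selfings (SSD)."""
    if n_progeny < 1:
        raise ValueError("n_progeny must be >= 1")
    ss = (rng_seed if isinstance(rng_seed, np.random.SeedSequence)
          else np.random.SeedSequence(rng_seed))
    donor = founder(genome, DONOR, id="donor")
    recurrent = founder(genome, RECURRENT, id="recurrent")
    f1 = _cross(donor, recurrent, genome, np.random.default_rng(ss.spawn(1)[0]))
    progeny = []
    for i, child_ss in enumerate(ss.spawn(n_progeny)):
        rng = np.random.default_rng(child_ss)
        ind = f1
        for _ in range(n_backcrosses):
            ind = _cross(ind, recurrent, genome, rng)
        for _ in range(n_selfings):
            ind = _cross(ind, ind, genome, rng)
        ind.id = f"RIL{i + 1:03d}"
        progeny.append(ind)
    return progeny


def assign_phenotypes(population: list[Individual], qtl: QtlModel,
                      rng_seed: int | np.random.Generator) -> list[Individual]:
    """Set ``phenotype_ac`` on each individual from the additive QTL model."""
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    for ind in population:
        ac = qtl.baseline_ac
        for chrom, pos, effect in qtl.qtl_effects:
            d = ind.dosage(chrom, np.array([pos]))[0]
            ac += effect * d / 2.0
        if qtl.env_sd > 0:
            ac += rng.normal(0.0, qtl.env_sd)
        ind.phenotype_ac = float(ac)
    return population


def phenotype_table(population: list[Individual]) -> pd.DataFrame:
    return pd.DataFrame({
        "sample": [ind.id for ind in population],
        "ac": [ind.phenotype_ac for ind in population],
    })


def genotype_table(population: list[Individual], genome: GenomeModel) -> pd.DataFrame:
    """Long table of donor-allele dosage (0/1/2) per individual per site."""
    frames = []
    for chrom in genome.chromosome_names:
        pos = genome.site_positions(chrom)
        if len(pos) == 0:
            continue
        cols = {"chrom": chrom, "pos": pos}
        cols.update({ind.id: ind.dosage(chrom, pos) for ind in population})
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# pooled sequencing

@dataclass
class SitePileup:
    """Per-site, per-cohort read counts by nucleotide with a site quality."""

    chrom: str
    pos: int
    sample: str
    counts: dict[str, int]
    phred: float

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass
class PhredModel:
    """Site-quality generator: constant ``value`` with an optional fraction of
    degraded sites at ``degraded_value`` (exercises the phred < 30 filter)."""

    value: float = 40.0
    degraded_fraction: float = 0.0
    degraded_value: float = 20.0

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        q = np.full(n, self.value)
        if self.degraded_fraction > 0:
            bad = rng.random(n) < self.degraded_fraction
            q[bad] = self.degraded_value
        return q


def pooled_donor_frequency(bulk: list[Individual], chrom: str,
                           positions: np.ndarray) -> np.ndarray:
    """True donor-allele frequency in the pool (equal DNA per member)."""
    if not bulk:
        raise ValueError("empty bulk")
    dos = np.zeros(len(positions), dtype=float)
    for ind in bulk:
        dos += ind.dosage(chrom, positions)
    return dos / (2 * len(bulk))


def _sample_reads(p_donor: np.ndarray, donor: np.ndarray, recurrent: np.ndarray,
                  mean_depth: float, error_rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Per-site ACGT count matrix for one cohort (vectorised over sites)."""
    n = len(p_donor)
    depth = rng.poisson(mean_depth, size=n)
    n_donor = rng.binomial(depth, p_donor)
    n_recur = depth - n_donor
    counts = np.zeros((n, 4), dtype=np.int64)
    nuc_idx = {b: i for i, b in enumerate(_NUCLEOTIDES)}
    d_idx = np.array([nuc_idx[b] for b in donor])
    r_idx = np.array([nuc_idx[b] for b in recurrent])
    if error_rate > 0:
        err_d = rng.binomial(n_donor, error_rate)
        err_r = rng.binomial(n_recur, error_rate)
        n_donor -= err_d
        n_recur -= err_r
        # each errored read becomes one of the three other nucleotides
        for true_idx, errs in ((d_idx, err_d), (r_idx, err_r)):
            dist = rng.multinomial(errs, [1 / 3] * 3)
            for k in range(3):
                tgt = (true_idx + 1 + k) % 4
                np.add.at(counts, (np.arange(n), tgt), dist[:, k])
    np.add.at(counts, (np.arange(n), d_idx), n_donor)
    np.add.at(counts, (np.arange(n), r_idx), n_recur)
    return counts


def simulate_bulk_pileup(bulk_members: list[Individual], site: tuple[str, int],
                         genome: GenomeModel, mean_depth: float, error_rate: float,
                         rng_seed: int | np.random.Generator,
                         phred_model: PhredModel | None = None,
                         sample: str = "bulk") -> SitePileup:
    """Pooled read counts for one bulk at one founder site."""
    df = simulate_cohort_pileup(bulk_members, genome, mean_depth, error_rate,
                                rng_seed, phred_model, sample=sample,
                                restrict=[site])
    row = df.iloc[0]
    return SitePileup(row["chrom"], int(row["pos"]), sample,
                      {b: int(row[b]) for b in _NUCLEOTIDES}, float(row["phred"]))


def simulate_cohort_pileup(members: list[Individual], genome: GenomeModel,
                           mean_depth: float, error_rate: float,
                           rng_seed: int | np.random.Generator,
                           phred_model: PhredModel | None = None,
                           sample: str = "bulk",
                           restrict: list[tuple[str, int]] | None = None,
                           ) -> pd.DataFrame:
    """Pileup table (chrom, pos, sample, A, C, G, T, phred) over founder sites."""
    if not members:
        raise ValueError("empty bulk")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if not (0 <= error_rate < 0.25):
        raise ValueError("error_rate must be in [0, 0.25)")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    phred_model = phred_model or PhredModel()
    wanted = None
    if restrict is not None:
        wanted = {}
        for chrom, pos in restrict:
            wanted.setdefault(chrom, set()).add(pos)
    frames = []
    for chrom in genome.chromosome_names:
        pos = genome.site_positions(chrom)
        if wanted is not None:
            pos = np.array(sorted(set(pos) & wanted.get(chrom, set())), dtype=int)
        if len(pos) == 0:
            continue
        sub = genome.sites[genome.sites["chrom"] == chrom].set_index("pos")
        donor = sub.loc[pos, "donor"].to_numpy()
        recur = sub.loc[pos, "recurrent"].to_numpy()
        p = pooled_donor_frequency(members, chrom, pos)
        counts = _sample_reads(p, donor, recur, mean_depth, error_rate, rng)
        block = pd.DataFrame({"chrom": chrom, "pos": pos, "sample": sample})
        for i, b in enumerate(_NUCLEOTIDES):
            block[b] = counts[:, i]
        block["phred"] = phred_model.draw(len(pos), rng)
        frames.append(block)
    return pd.concat(frames, ignore_index=True)
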