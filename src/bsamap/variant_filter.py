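"""Threshold-based SNP calling and the SNP filtering cascade.

A site is called in a cohort when an allele different from the reference
passes three inequalities simultaneously: total depth >= ``min_coverage``,
supporting reads >= ``min_count`` and supporting fraction >= ``min_freq``.
The published thresholds are 20/20/90% for the bulks, 5/5/100% for the
parents, and 20/8/30% for allele mining in diverse accessions.

The cascade then applies, in order: removal of SNPs shared between the two
bulks, removal of sites with quality (phred) below 30, and removal of
multi-allelic or non-parental sites.  Each step only ever removes calls, so
the cascade is monotone and idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import SitePileup

logger = logging.getLogger(__name__)

_NUCLEOTIDES = ("A", "C", "G", "T")

CALL_COLUMNS = ["chrom", "pos", "allele", "count", "depth", "freq", "phred", "sample"]


@dataclass(frozen=True)
class CallParams:
    """Caller thresholds: minimum depth, supporting reads, and allele fraction."""

    min_coverage: int
    min_count: int
    min_freq: float

    def __post_init__(self):
        if not (self.min_coverage >= self.min_count >= 0):
            raise ValueError("need min_coverage >= min_count >= 0")
        if not (0 < self.min_freq <= 1):
            raise ValueError("min_freq must be in (0, 1]")


#: published presets
BULK_PARAMS = CallParams(min_coverage=20, min_count=20, min_freq=0.90)
PARENT_PARAMS = CallParams(min_coverage=5, min_count=5, min_freq=1.00)
MINING_PARAMS = CallParams(min_coverage=20, min_count=8, min_freq=0.30)


@dataclass(frozen=True)
class VariantCall:
    chrom: str
    pos: int
    allele: str
    count: int
    depth: int
    freq: float
    phred: float
    sample: str


def call_site(pileup: SitePileup, params: CallParams,
              ref_allele: str) -> VariantCall | None:
    """Call the best non-reference allele at one site, or no-call (None)."""
    depth = pileup.depth
    if depth == 0 or depth < params.min_coverage:
        return None
    alts = {b: c for b, c in pileup.counts.items() if b != ref_allele and c > 0}
    if not alts:
        return None
    allele = max(sorted(alts), key=alts.get)
    count = alts[allele]
    if count < params.min_count or count / depth < params.min_freq:
        return None
    return VariantCall(pileup.chrom, pileup.pos, allele, count, depth,
                       count / depth, pileup.phred, pileup.sample)


def call_cohort(pileup: pd.DataFrame, params: CallParams,
                ref_alleles: pd.DataFrame) -> pd.DataFrame:
    """Vectorised `call_site` over a cohort pileup table.

    ``pileup`` has columns chrom, pos, sample, A, C, G, T, phred;
    ``ref_alleles`` maps (chrom, pos) -> ``ref`` column.  Returns a call
    table with :data:`CALL_COLUMNS`.
    """
    df = pileup.merge(ref_alleles[["chrom", "pos", "ref"]], on=["chrom", "pos"],
                      how="inner")
    counts = df[list(_NUCLEOTIDES)].to_numpy()
    depth = counts.sum(axis=1)
    # mask out the reference allele, take the best remaining one
    masked = counts.copy()
    for i, b in enumerate(_NUCLEOTIDES):
        masked[(df["ref"] == b).to_numpy(), i] = -1
    best = masked.argmax(axis=1)
    best_count = masked[range(len(df)), best]
    ok = ((depth >= params.min_coverage)
          & (best_count >= params.min_count)
          & (best_count >= params.min_freq * depth)
          & (best_count > 0))
    out = pd.DataFrame({
        "chrom": df["chrom"], "pos": df["pos"],
        "allele": [_NUCLEOTIDES[i] for i in best],
        "count": best_count, "depth": depth,
        "freq": best_count / depth.clip(min=1),
        "phred": df["phred"], "sample": df["sample"],
    }).loc[np.asarray(ok, dtype=bool)]
    return out.reset_index(drop=True)


def _key(calls: pd.DataFrame) -> pd.Index:
    return pd.MultiIndex.from_frame(calls[["chrom", "pos", "allele"]])


def filter_shared(hab_calls: pd.DataFrame, lab_calls: pd.DataFrame,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop SNPs present in both bulks; returns (hab_only, lab_only)."""
    hk, lk = _key(hab_calls), _key(lab_calls)
    hab_only = hab_calls[~hk.isin(lk)].reset_index(drop=True)
    lab_only = lab_calls[~lk.isin(hk)].reset_index(drop=True)
    logger.info("shared-SNP filter: HAB %d->%d, LAB %d->%d",
                len(hab_calls), len(hab_only), len(lab_calls), len(lab_only))
    return hab_only, lab_only


def filter_quality(calls: pd.DataFrame, min_phred: float = 30.0) -> pd.DataFrame:
    """Keep calls with phred >= min_phred (sites scoring < 30 are removed)."""
    phred = pd.to_numeric(calls["phred"], errors="coerce")
    missing = phred.isna()
    if missing.any():
        logger.warning("%d calls with missing phred treated as failing", missing.sum())
    kept = calls.loc[(phred >= min_phred).fillna(False).to_numpy(bool)] \
        .reset_index(drop=True)
    logger.info("quality filter (phred >= %s): %d->%d", min_phred, len(calls), len(kept))
    return kept


def parent_genotypes(parent_pileup: pd.DataFrame, params: CallParams = PARENT_PARAMS,
                     het_floor: int = 2) -> pd.DataFrame:
    """Genotype a parent cohort at every site.

    status per site: ``hom`` (a single allele passes the parent thresholds),
    ``het`` (no allele reaches min_freq but two alleles each have >=
    ``het_floor`` reads), or ``nocall``.  Under the 100%-frequency parent
    preset a parent can never be called heterozygous by the caller itself,
    so two-allele sites are recorded as het for step-2 classification
    instead of being discarded.
    """
    counts = parent_pileup[list(_NUCLEOTIDES)].to_numpy()
    n = len(parent_pileup)
    depth = counts.sum(axis=1)
    top = counts.argmax(axis=1)
    top_count = counts[np.arange(n), top]
    covered = depth >= params.min_coverage
    hom = (covered & (top_count >= params.min_count)
           & (top_count >= params.min_freq * depth) & (top_count > 0))
    ge_floor = counts >= het_floor
    het = covered & ~hom & (ge_floor.sum(axis=1) >= 2)
    nuc = np.array(_NUCLEOTIDES)
    status = np.where(hom, "hom", np.where(het, "het", "nocall"))
    allele = np.where(hom, nuc[top], None)
    alleles = np.where(hom, nuc[top], "").astype(object)
    for i in np.flatnonzero(het):
        alleles[i] = ",".join(nuc[ge_floor[i]])
    return pd.DataFrame({"chrom": parent_pileup["chrom"].to_numpy(),
                         "pos": parent_pileup["pos"].to_numpy(),
                         "status": status, "allele": allele, "alleles": alleles})


def filter_biallelic_parental(calls: pd.DataFrame,
                              cohort_pileups: list[pd.DataFrame],
                              parent1_geno: pd.DataFrame,
                              parent2_geno: pd.DataFrame,
                              noise_floor: int = 2) -> pd.DataFrame:
    """Exclude multi-allelic positions and positions with non-parental alleles.

    A position is multi-allelic when >= 3 alleles each have >= ``noise_floor``
    supporting reads summed across all cohorts.  A call is non-parental when
    its allele is absent from both parents' observed allele sets.  Positions
    where neither parent could be genotyped are dropped and logged (their
    parental provenance cannot be verified).
    """
    if calls.empty:
        return calls.copy()
    pooled = pd.concat(cohort_pileups, ignore_index=True)
    allele_counts = pooled.groupby(["chrom", "pos"])[list(_NUCLEOTIDES)].sum()
    n_alleles = (allele_counts >= noise_floor).sum(axis=1)
    multi = set(n_alleles[n_alleles >= 3].index)

    def _allele_map(geno: pd.DataFrame) -> dict:
        called = geno[geno["status"].isin(("hom", "het")) & (geno["alleles"] != "")]
        return {(t.chrom, t.pos): set(t.alleles.split(","))
                for t in called.itertuples(index=False)}

    p1, p2 = _allele_map(parent1_geno), _allele_map(parent2_geno)
    keep = []
    n_multi = n_nonpar = n_noparent = 0
    for _, r in calls.iterrows():
        key = (r["chrom"], r["pos"])
        if key in multi:
            n_multi += 1
            keep.append(False)
            continue
        parental = p1.get(key, set()) | p2.get(key, set())
        if not parental:
            n_noparent += 1
            keep.append(False)
            continue
        if r["allele"] not in parental:
            n_nonpar += 1
            keep.append(False)
            continue
        keep.append(True)
    out = calls.loc[np.array(keep, dtype=bool)].reset_index(drop=True)
    logger.info("biallelic/parental filter: %d->%d (multi-allelic %d, "
                "non-parental %d, parent no-call %d)",
                len(calls), len(out), n_multi, n_nonpar, n_noparent)
    return out


def run_cascade(hab_calls: pd.DataFrame, lab_calls: pd.DataFrame,
                cohort_pileups: list[pd.DataFrame],
                parent1_geno: pd.DataFrame, parent2_geno: pd.DataFrame,
                min_phred: float = 30.0, noise_floor: int = 2,
                ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full filter cascade in published order; returns (hab, lab, ledger).

    Order: two-way shared-SNP removal -> phred -> multi-allelic/non-parental.
    The ledger records counts in/out per stage per bulk.
    """
    ledger = []

    def note(stage, h, l):
        ledger.append((stage, len(h), len(l)))

    note("called", hab_calls, lab_calls)
    hab, lab = filter_shared(hab_calls, lab_calls)
    note("bulk_specific", hab, lab)
    hab, lab = filter_quality(hab, min_phred), filter_quality(lab, min_phred)
    note("phred_pass", hab, lab)
    hab = filter_biallelic_parental(hab, cohort_pileups, parent1_geno,
                                    parent2_geno, noise_floor)
    lab = filter_biallelic_parental(lab, cohort_pileups, parent1_geno,
                                    parent2_geno, noise_floor)
    note("biallelic_parental", hab, lab)
    ledger_df = pd.DataFrame(ledger, columns=["stage", "hab_n", "lab_n"])
    return hab, lab, ledger_df
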