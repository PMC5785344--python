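"""Two-step candidate-marker identification from pooled allele counts.

At a trait-neutral locus each parental genome should contribute about half
of the pooled reads, so donor vs recurrent read counts in a bulk are tested
against a 1:1 null with a df=1 chi-square goodness-of-fit statistic,
(a-b)^2/(a+b), without continuity correction.  An exact two-sided binomial
P-value is carried alongside as an oracle.  A site becomes a candidate when

* the parental configuration supports it: step 1, both parents homozygous
  for different alleles; step 2, a parent heterozygous but the two bulks
  fixed for different alleles;
* the donor allele reaches >= 90% of reads in the high bulk (HAB);
* the chi-square P-value is below alpha in *both* bulks, with the low bulk
  (LAB) skewed toward the recurrent allele.

No multiple-testing correction is applied by default (per-site alpha); an
optional Bonferroni switch is provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

RESULT_COLUMNS = [
    "chrom", "pos", "donor_allele", "recurrent_allele",
    "hab_donor", "hab_recurrent", "lab_donor", "lab_recurrent",
    "freq_hab", "freq_lab",
    "chi2_hab", "p_hab", "chi2_lab", "p_lab",
    "binom_p_hab", "binom_p_lab",
    "coverage_hab", "coverage_lab", "step", "passed",
]


def chisq_one_to_one(count_a: int, count_b: int) -> tuple[float, float]:
    """Chi-square test of a 1:1 segregation null on two read counts.

    Returns (statistic, P-value); ``(nan, nan)`` when both counts are zero
    (no test possible).  No Yates correction.
    """
    n = count_a + count_b
    if n == 0:
        return (math.nan, math.nan)
    stat = (count_a - count_b) ** 2 / n
    return (float(stat), float(stats.chi2.sf(stat, df=1)))


def exact_binomial_p(count_a: int, count_b: int) -> float:
    """Exact two-sided binomial P-value against p=1/2 (oracle statistic)."""
    n = count_a + count_b
    if n == 0:
        return math.nan
    return float(stats.binomtest(count_a, n, 0.5).pvalue)


@dataclass(frozen=True)
class SiteAlleles:
    donor: str
    recurrent: str


def _pileup_counts(pileup: pd.DataFrame) -> dict[tuple[str, int], dict[str, int]]:
    return {(t.chrom, int(t.pos)): {"A": int(t.A), "C": int(t.C),
                                    "G": int(t.G), "T": int(t.T)}
            for t in pileup.itertuples(index=False)}


def classify_candidates(hab_calls: pd.DataFrame, lab_calls: pd.DataFrame,
                        hab_pileup: pd.DataFrame, lab_pileup: pd.DataFrame,
                        donor_geno: pd.DataFrame, recurrent_geno: pd.DataFrame,
                        alpha: float = 0.05, hab_freq_cutoff: float = 0.90,
                        direction: bool = True,
                        bonferroni: bool = False) -> pd.DataFrame:
    """Evaluate every HAB bulk-specific call as a candidate marker.

    ``hab_calls``/``lab_calls`` are the outputs of the filter cascade;
    ``*_pileup`` provide raw per-allele counts (a no-call in one bulk is
    evaluated with that bulk's raw counts, not with zero reads);
    ``donor_geno``/``recurrent_geno`` are `parent_genotypes` tables for the
    donor and recurrent parents.  Returns one row per evaluated site,
    sorted by (chrom, pos), with ``passed`` marking candidates.
    """
    hab_counts = _pileup_counts(hab_pileup)
    lab_counts = _pileup_counts(lab_pileup)
    dg = donor_geno.set_index(["chrom", "pos"])
    rg = recurrent_geno.set_index(["chrom", "pos"])
    lab_allele = {(r["chrom"], int(r["pos"])): r["allele"]
                  for _, r in lab_calls.iterrows()}

    n_tests = max(len(hab_calls), 1)
    eff_alpha = alpha / n_tests if bonferroni else alpha

    rows = []
    for _, call in hab_calls.iterrows():
        key = (call["chrom"], int(call["pos"]))
        try:
            dstat = dg.loc[key]
            rstat = rg.loc[key]
        except KeyError:
            continue
        step = 0
        alleles = None
        if dstat["status"] == "hom" and rstat["status"] == "hom" \
                and dstat["allele"] != rstat["allele"]:
            step = 1
            alleles = SiteAlleles(dstat["allele"], rstat["allele"])
        elif "het" in (dstat["status"], rstat["status"]):
            other = lab_allele.get(key)
            if other is not None and other != call["allele"]:
                # bulks fixed for different alleles; HAB's allele plays the
                # donor role (the high bulk is enriched for donor genome)
                step = 2
                alleles = SiteAlleles(call["allele"], other)
        if step == 0:
            continue

        hc = hab_counts.get(key, {})
        lc = lab_counts.get(key, {})
        a_h, b_h = hc.get(alleles.donor, 0), hc.get(alleles.recurrent, 0)
        a_l, b_l = lc.get(alleles.donor, 0), lc.get(alleles.recurrent, 0)
        chi_h, p_h = chisq_one_to_one(a_h, b_h)
        chi_l, p_l = chisq_one_to_one(a_l, b_l)
        freq_h = a_h / (a_h + b_h) if a_h + b_h else math.nan
        freq_l = a_l / (a_l + b_l) if a_l + b_l else math.nan

        passed = (not math.isnan(freq_h) and freq_h >= hab_freq_cutoff
                  and not math.isnan(p_h) and p_h < eff_alpha
                  and not math.isnan(p_l) and p_l < eff_alpha)
        if direction and passed:
            passed = freq_l <= 0.5
        rows.append((key[0], key[1], alleles.donor, alleles.recurrent,
                     a_h, b_h, a_l, b_l, freq_h, freq_l,
                     chi_h, p_h, chi_l, p_l,
                     exact_binomial_p(a_h, b_h), exact_binomial_p(a_l, b_l),
                     a_h + b_h, a_l + b_l, step, passed))
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    out = out.astype({"pos": int, "step": int, "passed": bool})
    return out.sort_values(["chrom", "pos"]).reset_index(drop=True)


def coverage_report(results: pd.DataFrame, expected_min: int = 20) -> pd.DataFrame:
    """Annotate candidates with per-site coverage range across the bulks.

    Sites whose minimum bulk coverage falls below ``expected_min`` are
    flagged low-confidence: low coverage produces spurious deviations from
    the 50% segregation expectation.
    """
    out = results.copy()
    if out.empty:
        for c in ("coverage_min", "coverage_max"):
            out[c] = pd.Series(dtype=int)
        out["low_confidence"] = pd.Series(dtype=bool)
        return out
    cov = out[["coverage_hab", "coverage_lab"]].to_numpy()
    out["coverage_min"] = cov.min(axis=1)
    out["coverage_max"] = cov.max(axis=1)
    out["low_confidence"] = out["coverage_min"] < expected_min
    return out


def null_allele_fraction(n_sites: int = 1000, mean_depth: float = 50.0,
                         bulk_size: int = 10, allele_freq: float = 0.5,
                         rng_seed: int | np.random.Generator = 0,
                         ) -> tuple[float, float]:
    """Mean donor-read fraction at trait-neutral unlinked loci.

    Simulates, per site, the genotypes of an equal-contribution bulk of
    ``bulk_size`` diploids whose population donor-allele frequency is
    ``allele_freq`` (0.5 for an F2-derived RIL, 0.125 for a BC2 design),
    then Poisson read depths drawn from the pooled allele frequencies.
    Returns (mean fraction, Monte-Carlo SE of that mean).
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    dosage = rng.binomial(2, allele_freq, size=(n_sites, bulk_size))
    pool_p = dosage.sum(axis=1) / (2 * bulk_size)
    depth = rng.poisson(mean_depth, size=n_sites)
    depth = np.clip(depth, 1, None)
    frac = rng.binomial(depth, pool_p) / depth
    return float(frac.mean()), float(frac.std(ddof=1) / math.sqrt(n_sites))
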