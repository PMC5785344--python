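# Methods

## Population and meiosis model

The simulator produces BC₂F₈ recombinant inbred lines: an F1 between a
donor and a recurrent founder, two backcrosses to the recurrent parent,
then seven generations of selfing by single-seed descent (we index
generations F1→F8, so "BC₂F₈" means the BC₂F₁ selfed seven times; the
convention is stated because usage differs between groups). Each line is
bred independently; there is no selection during line development and no
shared ancestry beyond the F1.

Meiosis follows the Haldane model: the number of crossovers per chromosome
is Poisson with mean equal to the genetic length in Morgans, breakpoints
are uniform on the physical map, and there is no interference or sex
difference. This is the simplest standard model and is adequate for the
allele-frequency behaviour the pipeline consumes; chiasma interference
would slightly reduce the variance of introgression-block lengths but not
the expectations the tests check. Haplotypes are run-length encoded as
(segment end, parental origin) arrays, so a genome costs a few dozen
integers and populations of thousands are cheap.

Expected consequences used as test oracles: the donor-genome fraction
after one F1 plus two backcrosses is (1/2)³ = 12.5% at every locus
(selfing leaves allele frequency unchanged), and residual heterozygosity
is (1/4)·(1/2)⁷ ≈ 0.00195 (the BC₂F₁ is heterozygous at 1/4 of loci and
each selfing halves heterozygosity).

## Genome, markers and map

The default genome is the 12 rice chromosomes at IRGSP-like physical
lengths with a uniform genetic map of 4.76 cM/Mbp, chosen so that a
2.1 Mbp physical interval on chromosome 6 corresponds to ≈10 cM.
Founder-diagnostic sites (fixed differences between the parents) are laid
down every 50 kb; the waxy/*GBSS1* position chr06:1,769,686 and the two
minor-locus positions chr01:30,038,502 and chr11:18,288,616 are always
included. Real inter-specific rice crosses segregate for roughly one SNP
per 1–2 kb, so 50 kb is deliberately sparse — dense enough that several
markers fall inside any selected introgression block, sparse enough that
a full pipeline run takes ~2 s. Coordinates are 1-based inclusive
everywhere except BED exports (0-based half-open).

## Phenotype model

Amylose content is additive: AC = 23.2 + Σⱼ eⱼ·(dosageⱼ/2) + N(0, σ_env),
with dosage the donor-allele count (0/1/2) and eⱼ the homozygous-donor
shift in percentage points. Defaults: a major effect +2.5 at the waxy
locus (so a line homozygous-donor there alone scores 25.7%, matching the
donor parent), a minor +0.75 on chr 11 and a minor −2.25 on chr 1,
σ_env = 0.8. The asymmetric minors make the simulated progeny span
≈19.7–27.2% with transgressive segregation skewed toward the low side,
the pattern reported for this type of cross; symmetric minors of equal
magnitude produce too little downward transgression. No dominance or
epistasis is modelled — residual heterozygosity in an F8 is ~0.2%, so
dominance would be empirically invisible anyway.

## Pooled sequencing model

A bulk pools its members with equal weight (equal DNA per individual; each
member's two haplotypes weigh equally). Per site, read depth is
Poisson(mean depth; defaults 53× for the high bulk, 59× for the low bulk,
30× for parents), reads are drawn binomially from the pool's true allele
frequency, and each read is corrupted with probability `error_rate`
(default 0.005) to a uniformly chosen different nucleotide. Site quality
is a constant phred 40 by default; a configurable fraction of degraded
(phred 20) sites exists to exercise the quality filter. The model skips
read mapping, local realignment and indels entirely: what it emulates is
per-site allele-count data of the kind a mapper plus basic variant caller
would emit, and passing tests therefore say nothing about
mapping/realignment artefacts, reference bias, or indel-adjacent errors in
real data.

## Calling and the filter cascade

A cohort's site is called when a non-reference allele satisfies depth ≥
min_coverage, supporting reads ≥ min_count and frequency ≥ min_freq
simultaneously (bulks 20/20/90%, parents 5/5/100%, diverse-accession
mining 20/8/30%; the synthetic reference is the recurrent parent). The
cascade then removes, in order: SNPs called in both bulks, sites with
phred < 30 (strictly; 30.0 is kept), and multi-allelic or non-parental
sites. "Multi-allelic" is operationalised as ≥3 alleles each with ≥2
supporting reads across all cohorts (the count floor is configurable).
Positions where neither parent could be genotyped are dropped and logged,
since parental provenance cannot be verified. A parent showing two alleles
with ≥2 reads each but no allele at 100% is recorded as heterozygous
rather than discarded — such sites feed step 2 of the association test.
Each stage only removes calls, so the cascade is monotone and idempotent
(property-tested). The phred filter is applied to the site-level quality
score, the natural reading when working from pileups.

## Association

Donor vs recurrent read counts are tested per bulk against a 1:1 null with
χ² = (a−b)²/(a+b), df 1, no Yates correction; the exact two-sided binomial
P-value is computed alongside. For counts summing to ≤60 the two tests'
α=0.05 decisions differ only on an enumerated boundary set (54 ordered
pairs), frozen as a regression fixture. Candidates must satisfy the
parental step-1/step-2 configuration, a ≥90% donor-read frequency in the
high bulk, and P < 0.05 in both bulks; a direction requirement (high bulk
toward donor, low bulk toward recurrent, i.e. low-bulk donor frequency
≤ 0.5) is on by default and can be disabled. No multiple-testing
correction is applied by default, matching the per-site α recipe; a
Bonferroni switch exists. Sites missing a call in one bulk are still
evaluated on that bulk's raw read counts — a no-call is not zero reads.
Coverage per candidate is reported and anything under 20× is flagged
low-confidence, since low coverage produces spurious deviations from the
null.

The package computes two null read fractions for trait-neutral loci: 50%
for an equal-frequency pool (the classical BSA expectation) and 12.5% for
a BC₂-derived population. These are inconsistent expectations for the same
backcross design; both are implemented and reported, and the association
test itself does not depend on either (it conditions on the observed
counts).

## Region clustering and annotation

Passing candidates merge by single-linkage: same chromosome, gap ≤ 1 Mb
(any max_gap larger than the largest intra-cluster gap reproduces the same
region, so the rule is not sensitive near the default). Region spans are
end − start in bp, also reported in Mbp and as span × 4.76 cM/Mbp.

CDS substitutions are located by codon arithmetic on spliced CDS
coordinates counted from the translation start (A of ATG = 1): codon
⌊(p−1)/3⌋+1, offset (p−1) mod 3. When only the reference amino acid is
known (the usual case when re-annotating a published table), the set of
reference codons compatible with (amino acid, base, offset) is enumerated,
the substitution applied to each, and the resulting amino-acid set
reported; a singleton set is an unambiguous prediction. Conservative
changes are labelled by Dayhoff substitution groups ({AGPST}, {DENQ},
{HKR}, {ILMV}, {FWY}, {C}) — chosen over a strict acidic/amide split
because the field conventionally treats Asp→Asn as conservative, which
only the grouped table reproduces. The label is descriptive; no functional
score is claimed. One documented source inconsistency: the prose in the
underlying study places the exon-12 G/A substitution "on chromosome 12",
while its own tables and protein-position arithmetic place it in exon 12
of the chromosome-6 waxy gene; the package follows the tables.

## Co-expression screen

Candidate × guide Pearson correlations on a genes × samples matrix, pass
if ≥ 0.6 (inclusive). The "weighted" variant normalises per-sample weights
to sum to one and uses weighted means/covariances; with equal weights it
equals the ordinary coefficient, and it is an approximation to (not a
reimplementation of) the weighted statistic of public rice co-expression
databases. The synthetic generator plants a gene against a standard-normal
guide profile as α·guide + √(1−α²)·noise, so the expected sample
correlation is α. Sensitivity note: at n = 40 samples the probability that
a pair with true correlation exactly 0.7 shows r̂ ≥ 0.6 is the Fisher-z
tail ≈ 0.86; ≥95% detection holds for a population of planted pairs with
correlations spread over [0.7, 0.95], which is how the recovery property
is exercised.

## Pipeline, problem sizes and determinism

`run_pipeline` executes simulate → bulk → sequence → call/filter →
associate → cluster → (optional) annotate/co-express → report, persists
every stage's tables, and writes a manifest (package and dependency
versions, full configuration, per-stage counts) from which a run can be
reproduced byte-identically. All randomness flows from a single seed
through `numpy.random.SeedSequence` spawning, so runs are bit-reproducible
across processes. Default problem sizes — 100 progeny, 10+10 bulks,
~7,500 markers, depths 53×/59× — run in about two seconds; the 20-seed
power experiment in the test suite runs in well under a minute.

## Power of the default design (known limitation)

With 100 progeny at 12.5% donor frequency, the number of major-locus
carriers is Binomial(100, 0.125): in ~11% of populations fewer than 9
carriers exist, and phenotypic noise lets the upper tail of the ~88
non-carriers displace carriers from the top-10 bulk. Monte-Carlo over the
default phenotype model gives P(high-bulk donor frequency ≥ 0.9 at the
causal locus) ≈ 0.71 per experiment; with marker densities that place
several sites inside every shared introgression block, the end-to-end
detection rate of the major locus is ~75–85% per seeded run (17/20 on the
suite's fixed seeds). A 90% high-bulk frequency cutoff with 10-member
bulks is therefore a real power constraint of this design, not an
implementation artefact; larger bulks or a lower cutoff (both
configurable) raise power at the cost of more linkage-drag candidates.
False positives behave well: unlinked chromosomes contribute essentially
no passing sites under the defaults.

## Degenerate inputs and numerical choices

Zero-depth sites are no-calls, not errors; chi-square on (0, 0) returns a
no-test marker (NaN) rather than raising; empty candidate sets cluster to
an empty region list; zero-variance expression vectors raise an explicit
undefined-correlation error; tie-breaks (bulk membership, called allele)
are deterministic by id/alphabet so all outputs are order-invariant.
P-values use scipy's survival functions directly; no tolerance tuning is
involved anywhere in the pipeline itself.
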