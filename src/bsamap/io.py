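"""File formats: minimal VCF v4.2 (DP/AD per cohort) and TSV tables.

The reference-allele convention is recurrent-parent-as-reference: REF is the
recurrent allele and the donor allele is always the first ALT.  Any other
nucleotide observed in a cohort (sequencing error) is appended as an extra
ALT so that AD round-trips the full pileup.  Site quality is stored per
cohort in the custom FORMAT field SQ and summarised in QUAL as the minimum
across cohorts.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .genome import GenomeModel

_NUCLEOTIDES = ("A", "C", "G", "T")

PILEUP_COLUMNS = ["chrom", "pos", "sample", "A", "C", "G", "T", "phred"]


def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def pileup_long(pileup: pd.DataFrame) -> pd.DataFrame:
    """Wide cohort pileup -> long (chrom, pos, sample, allele, count, phred)."""
    long = pileup.melt(id_vars=["chrom", "pos", "sample", "phred"],
                       value_vars=list(_NUCLEOTIDES),
                       var_name="allele", value_name="count")
    long = long[long["count"] > 0]
    return (long[["chrom", "pos", "sample", "allele", "count", "phred"]]
            .sort_values(["chrom", "pos", "sample", "allele"])
            .reset_index(drop=True))


def pileup_wide(long: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`pileup_long`; absent alleles get count 0."""
    wide = (long.pivot_table(index=["chrom", "pos", "sample", "phred"],
                             columns="allele", values="count",
                             aggfunc="sum", fill_value=0)
            .reset_index())
    for b in _NUCLEOTIDES:
        if b not in wide.columns:
            wide[b] = 0
    return wide[PILEUP_COLUMNS].sort_values(
        ["chrom", "pos", "sample"]).reset_index(drop=True)


def write_pileup_vcf(path: str | Path, genome: GenomeModel,
                     cohort_pileups: dict[str, pd.DataFrame]) -> Path:
    """Write cohort pileups as a multi-sample VCF v4.2 with DP/AD/SQ."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    for c in genome.chromosomes:
        header.contigs.add(c.name, length=c.length_bp)
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt...)")
    header.formats.add("SQ", 1, "Float", "Site quality (phred)")
    samples = list(cohort_pileups)
    for s in samples:
        header.add_sample(s)

    indexed = {
        s: {(t.chrom, int(t.pos)): (int(t.A), int(t.C), int(t.G), int(t.T),
                                    float(t.phred))
            for t in df.itertuples(index=False)}
        for s, df in cohort_pileups.items()
    }
    nuc_idx = {b: i for i, b in enumerate(_NUCLEOTIDES)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for site in genome.sites.itertuples(index=False):
            chrom, pos = site.chrom, int(site.pos)
            ref, donor = site.recurrent, site.donor
            alts = [donor]
            for s in samples:
                row = indexed[s].get((chrom, pos))
                if row is None:
                    continue
                for b in _NUCLEOTIDES:
                    if b not in (ref, donor) and row[nuc_idx[b]] > 0 and b not in alts:
                        alts.append(b)
            rec = vcf.new_record(contig=chrom, start=pos - 1, stop=pos,
                                 alleles=tuple([ref] + alts))
            quals = []
            for s in samples:
                row = indexed[s].get((chrom, pos))
                if row is None:
                    rec.samples[s]["DP"] = 0
                    rec.samples[s]["AD"] = tuple([0] * (1 + len(alts)))
                    continue
                rec.samples[s]["DP"] = int(sum(row[:4]))
                rec.samples[s]["AD"] = tuple(row[nuc_idx[b]] for b in [ref] + alts)
                rec.samples[s]["SQ"] = row[4]
                quals.append(row[4])
            if quals:
                rec.qual = min(quals)
            vcf.write(rec)
    return path


def read_pileup_vcf(path: str | Path) -> dict[str, pd.DataFrame]:
    """Read a DP/AD(/SQ) VCF back into per-cohort wide pileup tables."""
    out: dict[str, list] = {}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for s in samples:
            out[s] = []
        for rec in vcf:
            alleles = rec.alleles
            for s in samples:
                fmt = rec.samples[s]
                ad = fmt.get("AD")
                if ad is None:
                    continue
                counts = dict.fromkeys(_NUCLEOTIDES, 0)
                for allele, c in zip(alleles, ad):
                    if allele in counts and c is not None:
                        counts[allele] = int(c)
                sq = fmt.get("SQ")
                phred = float(sq) if sq is not None else (
                    float(rec.qual) if rec.qual is not None else np.nan)
                out[s].append((rec.contig, rec.pos, s,
                               counts["A"], counts["C"], counts["G"], counts["T"],
                               phred))
    return {s: pd.DataFrame(rows, columns=PILEUP_COLUMNS)
            for s, rows in out.items()}


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Genes-in-rows expression TSV (first column gene id, header of samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError("duplicate gene ids in expression matrix")
    return df


def read_gene_list(path: str | Path) -> list[str]:
    genes = [line.strip() for line in Path(path).read_text().splitlines()]
    return [g for g in genes if g and not g.startswith("#")]
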