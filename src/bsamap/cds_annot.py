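"""Codon arithmetic and amino-acid-effect prediction for CDS substitutions.

CDS positions are 1-based from the translation start (the A of ATG is
position 1) and count spliced CDS bases, so position p falls in codon
``(p-1)//3 + 1`` at within-codon offset ``(p-1) % 3``.  When only the
reference amino acid (not the full CDS) is known, the set of possible
reference codons is constrained to those coding that amino acid with the
observed reference base at the observed offset; the substitution is applied
to each and translated with the standard nuclear code, yielding a (usually
singleton) set of alternative amino acids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable
from Bio.SeqUtils import seq1, seq3

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: Dayhoff substitution groups; a change within a group is annotated
#: "conservative" (this reproduces the conventional call that Asp->Asn,
#: an acidic->amide change, is conservative).
DAYHOFF_GROUPS = {
    "small": set("AGPST"),
    "acid/amide": set("DENQ"),
    "basic": set("HKR"),
    "hydrophobic": set("ILMV"),
    "aromatic": set("FWY"),
    "cysteine": set("C"),
}


def _to_one_letter(aa: str) -> str:
    aa = aa.strip()
    if len(aa) == 1:
        return aa.upper()
    return seq1(aa.capitalize())


def codon_of(cds_position: int) -> tuple[int, int]:
    """Map a 1-based CDS position to (codon index, within-codon offset 0..2)."""
    if cds_position < 1:
        raise ValueError("cds_position must be >= 1")
    return ((cds_position - 1) // 3 + 1, (cds_position - 1) % 3)


def dayhoff_group(aa_one: str) -> str:
    for name, members in DAYHOFF_GROUPS.items():
        if aa_one in members:
            return name
    raise KeyError(f"unknown amino acid {aa_one!r}")


def is_conservative(ref_aa: str, alt_aa: str) -> bool:
    return dayhoff_group(_to_one_letter(ref_aa)) == dayhoff_group(_to_one_letter(alt_aa))


@dataclass
class CdsSubstitution:
    """A single-base CDS substitution with derived codon coordinates."""

    cds_position: int
    ref_base: str
    alt_base: str
    ref_aa: str | None = None  # 3- or 1-letter
    codon_index: int = field(init=False)
    codon_offset: int = field(init=False)

    def __post_init__(self):
        self.ref_base = self.ref_base.upper()
        self.alt_base = self.alt_base.upper()
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt bases must differ")
        for b in (self.ref_base, self.alt_base):
            if b not in "ACGT":
                raise ValueError(f"not a nucleotide: {b!r}")
        self.codon_index, self.codon_offset = codon_of(self.cds_position)


def predict_aa_change(sub: CdsSubstitution) -> tuple[set[str], bool]:
    """Predict the amino-acid effect of a CDS substitution.

    Returns (set of possible alternative amino acids, 3-letter; synonymous
    flag).  Synonymous means every compatible reference codon yields the
    reference amino acid after substitution.  Raises ``ValueError`` when no
    codon of ``ref_aa`` carries ``ref_base`` at the required offset.
    """
    if sub.ref_aa is None:
        raise ValueError("predict_aa_change requires ref_aa (or use a full CDS)")
    ref_one = _to_one_letter(sub.ref_aa)
    candidates = [c for c, aa in _STANDARD.forward_table.items()
                  if aa == ref_one and c[sub.codon_offset] == sub.ref_base]
    if not candidates:
        raise ValueError(
            f"no codon of {sub.ref_aa} has {sub.ref_base} at offset "
            f"{sub.codon_offset} (CDS position {sub.cds_position})")
    alts = set()
    for codon in candidates:
        mutated = (codon[:sub.codon_offset] + sub.alt_base
                   + codon[sub.codon_offset + 1:])
        if mutated in _STANDARD.stop_codons:
            alts.add("Ter")
        else:
            alts.add(seq3(_STANDARD.forward_table[mutated]))
    synonymous = alts == {seq3(ref_one)}
    return alts, synonymous


def annotate_substitutions(table: pd.DataFrame) -> pd.DataFrame:
    """Annotate a substitution table (columns: position, ref, alt, ref_aa).

    Adds codon index/offset, predicted amino-acid change, synonymy and a
    conservative/non-conservative label (Dayhoff groups).  Ambiguous
    predictions list every possible target amino acid joined by '/'.
    """
    rows = []
    for _, r in table.iterrows():
        sub = CdsSubstitution(int(r["position"]), r["ref"], r["alt"],
                              r.get("ref_aa"))
        alt_aas, syn = predict_aa_change(sub)
        alt_label = "/".join(sorted(alt_aas))
        change = (f"{seq3(_to_one_letter(r['ref_aa']))} to {alt_label}"
                  if not syn else "synonymous")
        conservative = (all(a != "Ter" and is_conservative(r["ref_aa"], a)
                            for a in alt_aas) and not syn)
        rows.append((int(r["position"]), sub.codon_index, sub.codon_offset,
                     f"{sub.ref_base}/{sub.alt_base}", change, syn, conservative))
    return pd.DataFrame(rows, columns=[
        "position", "codon", "codon_offset", "snp", "aa_change",
        "synonymous", "conservative"])
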