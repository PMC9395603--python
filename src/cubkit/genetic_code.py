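"""Standard genetic code tables used throughout the package.

Everything here is derived from NCBI translation table 1.  Codons are DNA
triplets (T, not U); conversion to the mRNA alphabet happens locally where a
statistic is defined on mRNA (e.g. the translational-selection P2 classes).
"""

from __future__ import annotations

from Bio.Data import CodonTable

BASES = ("A", "C", "G", "T")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_table = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, 61 sense codons
CODON_TO_AA: dict[str, str] = dict(_table.forward_table)

ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in BASES for b in BASES for c in BASES
)

#: amino acid -> tuple of synonymous codons (sorted), all 20 residues
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CODON_TO_AA.items():
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
SYNONYMOUS_FAMILIES = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa))
    for aa in SYNONYMOUS_FAMILIES
}

#: amino acids encoded by two or more codons (18 of 20; Met and Trp excluded)
MULTI_CODON_AAS: tuple[str, ...] = tuple(
    sorted(aa for aa, fam in SYNONYMOUS_FAMILIES.items() if len(fam) > 1)
)

#: the 59 codons that belong to multi-codon synonymous families
INFORMATIVE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in CODON_TO_AA.items() if len(SYNONYMOUS_FAMILIES[aa]) > 1)
)

#: degeneracy of the family a codon belongs to
DEGENERACY: dict[str, int] = {
    c: len(SYNONYMOUS_FAMILIES[aa]) for c, aa in CODON_TO_AA.items()
}
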