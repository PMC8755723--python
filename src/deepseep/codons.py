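"""Genetic-code tables shared by the synthetic generators and the growth module.

Only the 59 *informative* codons enter codon-usage statistics: the 61 sense
codons of the standard code minus ATG (Met) and TGG (Trp), whose amino acids
have a single codon and therefore carry no synonymous-choice signal. Stop
codons are never part of a family but internal stops are counted separately
as a data-quality flag.
"""

from __future__ import annotations

STANDARD_CODE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in STANDARD_CODE.items() if aa == "*")

#: amino acid -> ordered tuple of synonymous codons (multi-codon families only
#: for Met/Trp exclusion; Ser is one six-codon family).
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in STANDARD_CODE.items():
    if _aa in ("*", "M", "W"):
        continue
    FAMILIES.setdefault(_aa, ())
    FAMILIES[_aa] += (_codon,)
FAMILIES = {aa: tuple(sorted(cods)) for aa, cods in FAMILIES.items()}

#: the 59 informative codons, sorted, fixed vector order
INFORMATIVE_CODONS: tuple[str, ...] = tuple(
    sorted(c for cods in FAMILIES.values() for c in cods)
)
assert len(INFORMATIVE_CODONS) == 59

#: One fixed "translationally optimized" codon per family, used by the
#: synthetic generator to inject codon-usage bias into ribosomal genes.
#: The choices follow the major codons of fast-growing bacteria (E. coli
#: class-II genes); any fixed one-hot table would serve the same purpose.
OPTIMIZED_CODON: dict[str, str] = {
    "A": "GCT", "C": "TGC", "D": "GAC", "E": "GAA", "F": "TTC",
    "G": "GGT", "H": "CAC", "I": "ATC", "K": "AAA", "L": "CTG",
    "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGT", "S": "TCT",
    "T": "ACC", "V": "GTT", "Y": "TAC",
}
assert set(OPTIMIZED_CODON) == set(FAMILIES)
for _aa, _c in OPTIMIZED_CODON.items():
    assert _c in FAMILIES[_aa]
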