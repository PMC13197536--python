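"""Protein-variant reconstruction from skin-color gene alleles.

The coding strand of the candidate gene is the reverse complement of the
genomic template, translated in frame 1 (the paper's "3'–5' frame 1").
Each AGC repeat unit of the intragenic SSR contributes one alanine to a
polyalanine tract, so the four SSR sizes 108/111/114/120 bp encode
tracts of 4/5/6/8 residues.  Two SNPs are non-synonymous: at each, G
specifies histidine and A tyrosine, at residue 195 (SNP3) and residue
146 (SNP4) of the reconstructed protein.  This is reconstruction, not
ORF calling: stop codons are rendered '*' and translation continues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

from Bio.Seq import Seq

from .seqrecon import NAMED_ALLELES, AlleleCall

__all__ = [
    "ProteinVariant",
    "UnknownSubstitutionError",
    "FrameShiftWarning",
    "NonAcgtWarning",
    "NAMED_PROTEINS",
    "PROTEIN_BY_ALLELE",
    "REFERENCE_AMPLICON_SIZE",
    "REFERENCE_POLYALA_LENGTH",
    "translate_reverse_frame1",
    "polyalanine_tract",
    "variant_residue",
    "protein_variant",
]

#: SSR amplicon size of the reference allele and its tract length; each
#: 3 bp above the reference adds one alanine.
REFERENCE_AMPLICON_SIZE = 108
REFERENCE_POLYALA_LENGTH = 4

#: name -> (polyalanine length, residue 195, residue 146)
NAMED_PROTEINS: Mapping[str, tuple[int, str, str]] = {
    "Protein 1": (4, "Y", "Y"),
    "Protein 2": (5, "H", "H"),
    "Protein 3": (6, "Y", "H"),
    "Protein 4": (8, "Y", "H"),
}

PROTEIN_BY_ALLELE: Mapping[str, str] = {
    "Allele 1": "Protein 1",
    "Allele 2": "Protein 2",
    "Allele 3": "Protein 3",
    "Allele 4": "Protein 4",
}


class UnknownSubstitutionError(ValueError):
    """Raised for a variant-residue base outside the documented G/A toggle."""


class FrameShiftWarning(UserWarning):
    """SSR size difference not a multiple of 3: the reading frame would shift."""


class NonAcgtWarning(UserWarning):
    """Non-ACGT symbols were translated as 'X'."""


@dataclass(frozen=True)
class ProteinVariant:
    """A reconstructed protein isoform of the skin-color gene.

    ``residue_195`` and ``residue_146`` are the amino acids at the two
    variable positions (His/Tyr toggles driven by SNP3 and SNP4); they
    are resolved from the SNP states, with the surrogate reference
    numbering placing them at 1-based positions 195 and 146.
    ``sequence`` is present only when a nucleotide sequence was supplied.
    """

    variant_name: str  # "Protein 1".."Protein 4" or "novel"
    polyala_length: int | None
    polyala_start: int | None  # 0-based residue index
    residue_195: str
    residue_146: str
    sequence: str | None = None


def translate_reverse_frame1(seq: str) -> str:
    """Translate the reverse complement of ``seq`` from its first base.

    The trailing partial codon is dropped; stop codons are rendered '*'
    and translation continues.  Non-ACGT symbols yield 'X' residues and a
    :class:`NonAcgtWarning`.
    """
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    seq = seq.upper()
    if set(seq) - set("ACGT"):
        warnings.warn("non-ACGT symbols translated as X", NonAcgtWarning, stacklevel=2)
        seq = "".join(c if c in "ACGT" else "N" for c in seq)
    rc = str(Seq(seq).reverse_complement())
    rc = rc[: len(rc) - len(rc) % 3]
    return str(Seq(rc).translate(table=1))


def polyalanine_tract(protein: str) -> tuple[int | None, int]:
    """(start, length) of the longest alanine run; leftmost on ties.

    Returns ``(None, 0)`` when the protein contains no alanine.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    best_start, best_len = None, 0
    i = 0
    while i < len(protein):
        if protein[i] == "A":
            j = i
            while j < len(protein) and protein[j] == "A":
                j += 1
            if j - i > best_len:
                best_start, best_len = i, j - i
            i = j
        else:
            i += 1
    return best_start, best_len


def variant_residue(base: str) -> str:
    """Amino acid encoded at a variable position: G → His, A → Tyr."""
    base = base.upper()
    if base == "G":
        return "H"
    if base == "A":
        return "Y"
    raise UnknownSubstitutionError(
        f"base {base!r} is outside the documented G(His)/A(Tyr) substitution"
    )


def _safe_residue(base: str) -> str:
    try:
        return variant_residue(base)
    except UnknownSubstitutionError:
        warnings.warn(
            f"variant base {base!r} not G/A; residue reported as X",
            NonAcgtWarning,
            stacklevel=3,
        )
        return "X"


def protein_variant(call: AlleleCall, sequence: str | None = None) -> ProteinVariant:
    """Protein isoform implied by an allele call.

    The four named alleles map onto Proteins 1–4.  Novel alleles get a
    computed polyalanine length, 4 + (SSR size − 108)/3, and residues
    from the G→His / A→Tyr toggle at SNP3 (residue 195) and SNP4
    (residue 146).  When the allele's nucleotide ``sequence`` is given it
    is translated and the tract measured on the protein, overriding the
    arithmetic; the two agree for all in-frame alleles.

    An SSR size not congruent to 108 modulo 3 would shift the reading
    frame (never observed in the published alleles) and triggers a
    :class:`FrameShiftWarning` with an undefined tract length.
    """
    name = PROTEIN_BY_ALLELE.get(call.allele_name, "novel")

    res195 = _safe_residue(call.snp_states[2])
    res146 = _safe_residue(call.snp_states[3])

    polyala_len: int | None
    polyala_start: int | None = None
    if (call.ssr_amplicon_size - REFERENCE_AMPLICON_SIZE) % 3 != 0:
        warnings.warn(
            f"SSR size {call.ssr_amplicon_size} shifts the reading frame",
            FrameShiftWarning,
            stacklevel=2,
        )
        polyala_len = None
    else:
        polyala_len = (
            REFERENCE_POLYALA_LENGTH
            + (call.ssr_amplicon_size - REFERENCE_AMPLICON_SIZE) // 3
        )

    prot_seq: str | None = None
    if sequence is not None:
        prot_seq = translate_reverse_frame1(sequence)
        polyala_start, measured = polyalanine_tract(prot_seq)
        polyala_len = measured

    return ProteinVariant(
        variant_name=name,
        polyala_length=polyala_len,
        polyala_start=polyala_start,
        residue_195=res195,
        residue_146=res146,
        sequence=prot_seq,
    )
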