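"""Reconstruction of candidate-gene alleles from sequence.

Four steps turn a locus sequence into a named allele call:

1. :func:`insilico_pcr` — exact-match electronic PCR with a marker's
   primer pair, sizing the SSR amplicon;
2. :func:`find_tandem_repeat` — detection of the longest perfect AGC
   tandem run (any motif phase);
3. :func:`extract_snp_states` — reading the four SNP bases after exact
   flank anchoring against the reference allele, with offsets downstream
   of the SSR shifted by the tract-length difference;
4. :func:`assemble_haplotype` — matching (SSR size, SNP states) against
   the four named alleles of the skin-color gene.

The primer model is exact (no mismatches or degeneracy), matching the
assumption behind the published assays.  All sequence coordinates are
0-based half-open on the query template.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .locus import (
    AMPLICON_SIZE_BASE,
    COL1_PRIMERS,
    REFERENCE_STATES,
    SNP4_PRIMERS,
    SNP_DEFINITIONS,
    SNP_ORDER,
    SSR_MOTIF,
    Locus,
    PrimerPair,
    SnpDefinition,
    reference_locus,
    revcomp,
)

__all__ = [
    "Amplicon",
    "RepeatTract",
    "AlleleCall",
    "SnpExtraction",
    "AlignmentAmbiguityError",
    "NAMED_ALLELES",
    "insilico_pcr",
    "find_tandem_repeat",
    "extract_snp_states",
    "assemble_haplotype",
    "reconstruct_allele",
    "COL1_PRIMERS",
    "SNP4_PRIMERS",
    "SNP_DEFINITIONS",
    "PrimerPair",
    "SnpDefinition",
    "reference_locus",
]

#: The four named alleles: name -> (SSR amplicon size, (SNP1..SNP4) states).
NAMED_ALLELES: Mapping[str, tuple[int, tuple[str, str, str, str]]] = {
    "Allele 1": (108, ("C", "G", "A", "A")),
    "Allele 2": (111, ("C", "G", "G", "G")),
    "Allele 3": (114, ("T", "T", "A", "G")),
    "Allele 4": (120, ("C", "G", "A", "G")),
}


class AlignmentAmbiguityError(ValueError):
    """Raised when a query cannot be anchored to the reference flanks."""


@dataclass(frozen=True)
class Amplicon:
    """One in-silico PCR product (primers included).

    ``start``/``end`` are 0-based half-open on the input template;
    ``strand`` is '+' when the forward primer matched the given strand.
    """

    sequence: str
    start: int
    end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RepeatTract:
    """A maximal perfect tandem run: ``motif`` repeated ``repeat_count`` times."""

    motif: str
    start: int
    repeat_count: int

    @property
    def span_bp(self) -> int:
        return len(self.motif) * self.repeat_count

    @property
    def end(self) -> int:
        return self.start + self.span_bp


@dataclass(frozen=True)
class SnpExtraction:
    """SNP bases read from a query, plus flags for non-ref/alt states."""

    states: tuple[str, str, str, str]
    novel: Mapping[str, str]  # short name -> unexpected base


@dataclass(frozen=True)
class AlleleCall:
    """A reconstructed haplotype mapped onto the named-allele table."""

    ssr_amplicon_size: int
    snp_states: tuple[str, str, str, str]
    allele_name: str  # "Allele 1".."Allele 4" or "novel"

    @property
    def is_novel(self) -> bool:
        return self.allele_name == "novel"


def _sites(template: str, primer: str) -> list[int]:
    """All start offsets of an exact primer match (overlaps included)."""
    out, i = [], template.find(primer)
    while i != -1:
        out.append(i)
        i = template.find(primer, i + 1)
    return out


def insilico_pcr(
    template: str,
    primers: PrimerPair,
    max_product: int = 5000,
) -> list[Amplicon]:
    """Exact-match electronic PCR of one template with one primer pair.

    On each strand, every occurrence of the forward primer is paired with
    every downstream occurrence of the reverse-complemented reverse
    primer (reverse site beginning at or after the forward site ends),
    and the spanned product — primers included — is emitted if no longer
    than ``max_product``.  No product is not an error: the list is empty.
    Coordinates are always reported on the input template; products found
    on the minus strand carry strand '-'.
    """
    template = template.upper()
    if set(template) - set("ACGT"):
        raise ValueError("template must be over ACGT")
    products: list[Amplicon] = []
    n = len(template)
    for strand, seq in (("+", template), ("-", revcomp(template))):
        f_sites = _sites(seq, primers.forward)
        r_sites = _sites(seq, revcomp(primers.reverse))
        for i in f_sites:
            for j in r_sites:
                if j < i + len(primers.forward):
                    continue
                end = j + len(primers.reverse)
                if end - i > max_product:
                    continue
                if strand == "+":
                    products.append(Amplicon(seq[i:end], i, end, "+"))
                else:
                    products.append(Amplicon(seq[i:end], n - end, n - i, "-"))
    return sorted(products, key=lambda p: (p.start, p.end, p.strand))


def _rotations(motif: str) -> list[str]:
    return [motif[i:] + motif[:i] for i in range(len(motif))]


def find_tandem_repeat(seq: str, motif: str = SSR_MOTIF) -> RepeatTract | None:
    """Longest maximal perfect tandem run of ``motif`` (any phase) in ``seq``.

    All rotations of the motif are scanned (AGC runs are equally GCA or
    CAG runs, offset by one base); ties go to the leftmost start.  Returns
    ``None`` when no occurrence of any phase exists.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if not seq:
        raise ValueError("sequence must be non-empty")
    seq = seq.upper()
    k = len(motif)
    best: RepeatTract | None = None
    for phase in _rotations(motif):
        i = 0
        while i <= len(seq) - k:
            if seq[i : i + k] == phase:
                j = i
                while seq[j : j + k] == phase:
                    j += k
                count = (j - i) // k
                if best is None or count > best.repeat_count or (
                    count == best.repeat_count and i < best.start
                ):
                    best = RepeatTract(motif=phase, start=i, repeat_count=count)
                i = j
            else:
                i += 1
    return best


def extract_snp_states(
    query: str,
    snps: Sequence[SnpDefinition] = SNP_DEFINITIONS,
    reference: Locus | None = None,
) -> SnpExtraction:
    """Read the four SNP bases from a locus sequence by exact flank anchoring.

    The query must equal the reference allele outside the SSR tract and
    the SNP offsets; the only length difference permitted is a whole
    number of motif units inside the tract.  SNP offsets downstream of
    the tract are shifted by (query tract span − reference tract span).
    A base other than ref/alt at a SNP offset is returned and flagged as
    novel, not raised; any other mismatch raises
    :class:`AlignmentAmbiguityError`.
    """
    if reference is None:
        reference = reference_locus()
    query = query.upper()
    ref = reference.template
    t0, t1 = reference.tract_span
    delta = len(query) - len(ref)
    if delta % len(SSR_MOTIF) != 0:
        raise AlignmentAmbiguityError(
            f"length difference {delta} is not a whole number of "
            f"{SSR_MOTIF} units; indels outside the tract are not handled"
        )
    snp_offsets = {s.offset for s in snps}
    # left flank: exact match (no documented SNP lies upstream of the tract)
    for i in range(t0):
        if query[i] != ref[i] and i not in snp_offsets:
            raise AlignmentAmbiguityError(f"left-flank mismatch at offset {i}")
    # tract: a perfect motif run of the adjusted span
    new_span = (t1 - t0) + delta
    if new_span < len(SSR_MOTIF):
        raise AlignmentAmbiguityError("tract contraction below one motif unit")
    if query[t0 : t0 + new_span] != SSR_MOTIF * (new_span // len(SSR_MOTIF)):
        raise AlignmentAmbiguityError("tract region is not a perfect motif run")
    # right flank: exact match except at (shifted) SNP offsets
    states: dict[str, str] = {}
    novel: dict[str, str] = {}
    by_offset = {s.offset: s for s in snps}
    for i in range(t1, len(ref)):
        q_base, r_base = query[i + delta], ref[i]
        snp = by_offset.get(i)
        if snp is not None:
            states[snp.short_name] = q_base
            if q_base not in (snp.ref_state, snp.alt_state):
                novel[snp.short_name] = q_base
        elif q_base != r_base:
            raise AlignmentAmbiguityError(f"right-flank mismatch at reference offset {i}")
    missing = [s.short_name for s in snps if s.short_name not in states]
    if missing:
        raise AlignmentAmbiguityError(f"SNP offsets outside the query: {missing}")
    ordered = tuple(states[name] for name in SNP_ORDER)
    return SnpExtraction(states=ordered, novel=novel)


def assemble_haplotype(
    ssr_size: int,
    snp_states: Sequence[str],
) -> AlleleCall:
    """Match an (SSR amplicon size, SNP1..SNP4 states) pair to a named allele.

    Anything outside the four published combinations is returned as a
    ``novel`` call with its fields preserved.
    """
    if ssr_size <= 0:
        raise ValueError("ssr_size must be positive")
    states = tuple(str(s).upper() for s in snp_states)
    if len(states) != 4:
        raise ValueError("snp_states must have exactly four entries")
    for name, (size, combo) in NAMED_ALLELES.items():
        if ssr_size == size and states == combo:
            return AlleleCall(ssr_size, states, name)  # type: ignore[arg-type]
    return AlleleCall(ssr_size, states, "novel")  # type: ignore[arg-type]


def reconstruct_allele(template: str, reference: Locus | None = None) -> AlleleCall:
    """Full locus-to-allele pipeline: PCR sizing, SNP extraction, assembly.

    Sizes the Col1 SSR amplicon by in-silico PCR, reads the SNP states
    from the locus sequence, and matches against the named-allele table.
    """
    products = insilico_pcr(template, COL1_PRIMERS)
    if len(products) != 1:
        raise AlignmentAmbiguityError(
            f"expected one Col1 product, got {len(products)}"
        )
    extraction = extract_snp_states(template, SNP_DEFINITIONS, reference)
    return assemble_haplotype(products[0].length, extraction.states)
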