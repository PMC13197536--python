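"""Surrogate AP2/ERF skin-color locus: coordinate map and template builder.

The candidate gene carries an intragenic AGC microsatellite plus four
SNPs (SNP1 = S3_22924169, SNP2 = S3_22924445, SNP3 = S3_22924252,
SNP4 = S3_22924316, 1-based coordinates on chromosome 3).  The published
record documents the marker-level facts — Col1 amplicon sizes
108/111/114/120 bp, the SNP4 HRM amplicon of 109 bp, the reverse-frame
translation in which each AGC unit adds one alanine and SNP3/SNP4 toggle
His/Tyr at residues 195 and 146 — but not the full nucleotide sequence of
the reference allele.  This module therefore builds a synthetic surrogate
locus that honors every documented constraint:

* length 1257 bp (the printed span of the Col1 region);
* the Col1 primer pair flanks the AGC tract and yields a 108-bp product
  on the reference allele (4 repeats), growing 3 bp per extra repeat;
* the SNP4 primer pair yields a 109-bp product containing SNP4;
* in the reverse-complement frame-1 translation, the tract encodes a
  polyalanine run (one Ala per repeat), SNP3 and SNP4 occupy the first
  codon position of residues 195 and 146 (G → His, A → Tyr), and SNP1 and
  SNP2 are synonymous.

The four SNPs keep their genomic ORDER along the template; their exact
spacing is adjusted to the above reading-frame constraints, which the
printed genomic coordinates alone cannot satisfy in a single exon.
All template indices are 0-based half-open; genomic positions on
``SnpDefinition`` are 1-based metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PrimerPair",
    "SnpDefinition",
    "Locus",
    "LocusBuildError",
    "COL1_PRIMERS",
    "SNP4_PRIMERS",
    "SNP_DEFINITIONS",
    "SNP_ORDER",
    "REFERENCE_STATES",
    "REFERENCE_REPEAT_COUNT",
    "SSR_MOTIF",
    "AMPLICON_SIZE_BASE",
    "revcomp",
    "reference_locus",
    "build_allele_template",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved per base)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerPair:
    """A PCR primer pair, both given 5'→3', with the expected product size."""

    marker_id: str
    forward: str
    reverse: str
    expected_size: int

    def __post_init__(self) -> None:
        for name, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if len(seq) < 15 or set(seq) - set("ACGT"):
                raise ValueError(f"{name} primer must be ≥15 bp over ACGT: {seq!r}")


@dataclass(frozen=True)
class SnpDefinition:
    """One SNP of the locus.

    ``genomic_position`` is the 1-based chromosome-3 coordinate encoded in
    the marker name (metadata); ``offset`` is the 0-based index of the SNP
    in the reference-allele template built here.
    """

    snp_id: str
    short_name: str
    genomic_position: int
    ref_state: str
    alt_state: str
    offset: int


# Published marker definitions -------------------------------------------------

COL1_PRIMERS = PrimerPair(
    marker_id="col1",
    forward="CCCCATCACCACCTCCTGAT",
    reverse="GGGAGAGGCATATCTGAGTCC",
    expected_size=108,  # reference allele (4 AGC repeats)
)

SNP4_PRIMERS = PrimerPair(
    marker_id="S3_22924316",
    forward="TCCTGCTTCTTCTTCCTGATGA",
    reverse="GCTCAAAGCAAGAAACAACAGC",
    expected_size=109,
)

SSR_MOTIF = "AGC"
REFERENCE_REPEAT_COUNT = 4
#: amplicon size of an allele with n repeats is AMPLICON_SIZE_BASE + 3 n
AMPLICON_SIZE_BASE = 96

#: SNP1..SNP4 states of the reference allele (the 'Currot'-like Allele 1).
REFERENCE_STATES = ("C", "G", "A", "A")
SNP_ORDER = ("SNP1", "SNP2", "SNP3", "SNP4")

# Template layout constants (reference allele, 0-based half-open) --------------
_LENGTH = 1257
_F1_START = 80  # Col1 forward primer site [80, 100)
_TRACT_START = 111  # AGC tract starts here; reference span [111, 123)
_R1RC_START = 167  # Col1 reverse-primer (revcomp) site [167, 188)
_F2_START = 760  # SNP4 forward primer site [760, 782)
_R2RC_START = 847  # SNP4 reverse-primer (revcomp) site [847, 869)

SNP_DEFINITIONS: tuple[SnpDefinition, ...] = (
    SnpDefinition("S3_22924169", "SNP1", 22924169, "C", "T", 315),
    SnpDefinition("S3_22924445", "SNP2", 22924445, "G", "T", 951),
    SnpDefinition("S3_22924252", "SNP3", 22924252, "A", "G", 674),
    SnpDefinition("S3_22924316", "SNP4", 22924316, "A", "G", 821),
)

# Fixed codon contexts making SNP1/SNP2 synonymous (third codon position,
# Leu CTN in the reverse frame) and SNP3/SNP4 first-codon-position His/Tyr
# toggles (template 5'-AT[A|G]-3' reads CAT/TAT in the reverse frame).
_SNP_CONTEXTS = {
    315: ("C", {316: "A", 317: "G"}),
    951: ("G", {952: "A", 953: "G"}),
    674: ("A", {672: "A", 673: "T"}),
    821: ("A", {819: "A", 820: "T"}),
}

_PHASES = ("AGC", "GCA", "CAG")
_FLANK_SEED = 20260922


class LocusBuildError(RuntimeError):
    """Raised when the surrogate template violates one of its constraints."""


@dataclass(frozen=True)
class Locus:
    """A concrete allele template plus its coordinate map.

    ``snp_offsets`` maps SNP short names to 0-based template offsets for
    THIS template (shifted relative to the reference when the repeat
    count differs).  ``tract_span`` is 0-based half-open.
    """

    template: str
    repeat_count: int
    snp_states: tuple[str, str, str, str]
    tract_span: tuple[int, int]
    snp_offsets: Mapping[str, int]

    @property
    def length(self) -> int:
        return len(self.template)

    @property
    def expected_amplicon_size(self) -> int:
        return AMPLICON_SIZE_BASE + 3 * self.repeat_count


def _phase_free_random(rng: np.random.Generator, n: int) -> list[str]:
    """Random ACGT bases with no AGC/GCA/CAG trinucleotide anywhere."""
    bases = "ACGT"
    out: list[str] = []
    while len(out) < n:
        c = bases[rng.integers(4)]
        if len(out) >= 2 and (out[-2] + out[-1] + c) in _PHASES:
            continue
        out.append(c)
    return out


def _tandem_runs(seq: str, unit: str) -> list[tuple[int, int]]:
    """All maximal (start, count) tandem runs of ``unit`` in ``seq``."""
    k = len(unit)
    runs = []
    i = 0
    while i <= len(seq) - k:
        if seq[i : i + k] == unit:
            j = i
            while seq[j : j + k] == unit:
                j += k
            runs.append((i, (j - i) // k))
            i = j
        else:
            i += 1
    return runs


def _translate_rev_frame1(seq: str) -> str:
    # minimal standard-code translation for build-time validation only;
    # the user-facing implementation lives in apricolor.protein
    from Bio.Seq import Seq

    rc = str(Seq(seq).reverse_complement())
    rc = rc[: len(rc) - len(rc) % 3]
    return str(Seq(rc).translate(table=1))


def _longest_a_runs(protein: str) -> list[tuple[int, int]]:
    runs = []
    i = 0
    while i < len(protein):
        if protein[i] == "A":
            j = i
            while j < len(protein) and protein[j] == "A":
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return sorted(runs, key=lambda r: (-r[1], r[0]))


def _assemble_reference(rng: np.random.Generator) -> str:
    t = _phase_free_random(rng, _LENGTH)

    def splice(start: int, seq: str) -> None:
        t[start : start + len(seq)] = list(seq)

    splice(_F1_START, COL1_PRIMERS.forward)
    splice(_R1RC_START, revcomp(COL1_PRIMERS.reverse))
    splice(_F2_START, SNP4_PRIMERS.forward)
    splice(_R2RC_START, revcomp(SNP4_PRIMERS.reverse))
    splice(_TRACT_START, SSR_MOTIF * REFERENCE_REPEAT_COUNT)
    t[_TRACT_START - 1] = "T"  # block a tied CAG/GCA-phase run starting upstream
    for offset, (state, context) in _SNP_CONTEXTS.items():
        t[offset] = state
        for pos, base in context.items():
            t[pos] = base
    return "".join(t)


def _validate_reference(template: str) -> None:
    if len(template) != _LENGTH:
        raise LocusBuildError("bad template length")
    if template[_TRACT_START : _TRACT_START + 12] != SSR_MOTIF * 4:
        raise LocusBuildError("tract not in place")
    # the tract must be the unique best tandem run in every motif phase
    for phase in _PHASES:
        for start, count in _tandem_runs(template, phase):
            inside = _TRACT_START - 2 <= start < _TRACT_START + 12
            if count > 1 and not inside:
                raise LocusBuildError(f"stray {phase} run of {count} at {start}")
    if any(phase in template[:_TRACT_START] for phase in _PHASES):
        raise LocusBuildError("motif phase upstream of the tract")
    # each primer site unique, on one strand only
    rc = revcomp(template)
    for site in (
        COL1_PRIMERS.forward,
        revcomp(COL1_PRIMERS.reverse),
        SNP4_PRIMERS.forward,
        revcomp(SNP4_PRIMERS.reverse),
    ):
        if template.count(site) != 1 or rc.count(site) != 0:
            raise LocusBuildError(f"primer site not unique: {site}")
    # protein-level constraints
    protein = _translate_rev_frame1(template)
    a_runs = _longest_a_runs(protein)
    if not a_runs or a_runs[0] != (378, 4):
        raise LocusBuildError(f"polyalanine tract misplaced: {a_runs[:2]}")
    if len(a_runs) > 1 and a_runs[1][1] > 2:
        raise LocusBuildError("competing alanine run in flanks")
    if protein[194] != "Y" or protein[145] != "Y":
        raise LocusBuildError("reference His/Tyr residues wrong")

    def mutate(offset: int, base: str) -> str:
        return template[:offset] + base + template[offset + 1 :]

    for snp in SNP_DEFINITIONS:
        mutant = _translate_rev_frame1(mutate(snp.offset, snp.alt_state))
        diffs = [i for i, (x, y) in enumerate(zip(protein, mutant)) if x != y]
        if snp.short_name in ("SNP1", "SNP2") and diffs:
            raise LocusBuildError(f"{snp.short_name} not synonymous: {diffs}")
        if snp.short_name == "SNP3" and diffs != [194]:
            raise LocusBuildError(f"SNP3 must change residue 195 only: {diffs}")
        if snp.short_name == "SNP4" and diffs != [145]:
            raise LocusBuildError(f"SNP4 must change residue 146 only: {diffs}")
        if snp.short_name in ("SNP3", "SNP4") and mutant[diffs[0]] != "H":
            raise LocusBuildError(f"{snp.short_name} G state must encode His")


@lru_cache(maxsize=1)
def _reference_template() -> str:
    # deterministic search: fixed base seed, bounded retries over sub-seeds
    for attempt in range(64):
        rng = np.random.default_rng(_FLANK_SEED + attempt)
        template = _assemble_reference(rng)
        try:
            _validate_reference(template)
        except LocusBuildError:
            continue
        return template
    raise LocusBuildError("could not satisfy surrogate-locus constraints")


def reference_locus() -> Locus:
    """The reference allele (Allele 1: 4 AGC repeats, SNP states C-G-A-A)."""
    return Locus(
        template=_reference_template(),
        repeat_count=REFERENCE_REPEAT_COUNT,
        snp_states=REFERENCE_STATES,
        tract_span=(_TRACT_START, _TRACT_START + 3 * REFERENCE_REPEAT_COUNT),
        snp_offsets={s.short_name: s.offset for s in SNP_DEFINITIONS},
    )


def build_allele_template(
    repeat_count: int,
    snp_states: Sequence[str],
) -> Locus:
    """Build an allele template with the given repeat count and SNP states.

    The flanks are those of the reference allele; only the tract length
    and the four SNP bases change, so every documented offset shifts by
    3·(repeat_count − 4) downstream of the tract.  ``snp_states`` is the
    (SNP1, SNP2, SNP3, SNP4) base tuple.
    """
    if repeat_count < 1:
        raise ValueError("repeat_count must be ≥ 1")
    states = tuple(str(s).upper() for s in snp_states)
    if len(states) != 4 or set("".join(states)) - set("ACGT"):
        raise ValueError(f"snp_states must be four ACGT bases, got {snp_states!r}")
    ref = _reference_template()
    t0, t1 = _TRACT_START, _TRACT_START + 3 * REFERENCE_REPEAT_COUNT
    delta = 3 * (repeat_count - REFERENCE_REPEAT_COUNT)
    chars = list(ref[:t0] + SSR_MOTIF * repeat_count + ref[t1:])
    offsets = {}
    for snp, state in zip(SNP_DEFINITIONS, states):
        off = snp.offset + delta  # all SNPs lie downstream of the tract
        chars[off] = state
        offsets[snp.short_name] = off
    return Locus(
        template="".join(chars),
        repeat_count=repeat_count,
        snp_states=states,  # type: ignore[arg-type]
        tract_span=(t0, t0 + 3 * repeat_count),
        snp_offsets=offsets,
    )
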