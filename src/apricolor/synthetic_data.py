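"""Synthetic cohorts and allele sequences for end-to-end validation.

Two generators, both pure functions of (config, seed):

* :func:`simulate_cohort` emits a genotype table, a replicate-level
  colorimeter table and the underlying truth for a cohort whose structure
  mirrors the validation panels: biallelic SNP genotypes drawn from
  configurable frequencies, class-conditional hue distributions for
  orange and yellow fruit, and a controllable genotype↔phenotype
  mislabel rate ε.  Mislabeling swaps the generating hue distribution
  (a phenotyping-error model), not the genotype.
* :func:`simulate_allele_sequence` emits a surrogate locus template for
  an arbitrary (repeat count, SNP states) allele, suitable for the full
  reconstruction round trip.

Default hue models are orange ~ N(73°, 2°) and yellow ~ N(88°, 2°),
truncated to (0°, 180°), spanning the hue ranges of the validation
populations; chroma is fixed at 50 when back-computing (a*, b*) from a
drawn hue, since hue is the only phenotype-bearing quantity here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import concordance
from .locus import Locus, build_allele_template
from .seqrecon import NAMED_ALLELES

__all__ = [
    "CohortConfig",
    "AlleleSpec",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_allele_sequence",
    "named_allele_specs",
    "DEFAULT_HUE_MODEL",
]

#: Class-conditional hue models (mean, sd) in degrees.
DEFAULT_HUE_MODEL: Mapping[str, tuple[float, float]] = {
    "orange": (73.0, 2.0),
    "yellow": (88.0, 2.0),
}

#: Genotype frequencies mirroring the seedling validation population
#: (21 C/T and 19 C/C of 40).
DEFAULT_GENOTYPE_FREQUENCIES: Mapping[str, float] = {
    "C/T": 0.525,
    "C/C": 0.475,
}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a simulated genotype–phenotype cohort.

    ``mislabel_rate`` is the probability that an individual's hue
    replicates are drawn from the opposite class distribution.
    ``replicates`` is (fruits per individual, sides per fruit); the
    default 3 × 2 reproduces the six-reading phenotyping protocol.
    """

    n_individuals: int = 57
    marker_id: str = "S3_22924169"
    genotype_frequencies: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENOTYPE_FREQUENCIES)
    )
    hue_model: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_HUE_MODEL)
    )
    replicates: tuple[int, int] = (3, 2)
    mislabel_rate: float = 0.0
    chroma: float = 50.0
    lightness: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.genotype_frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"genotype frequencies sum to {total}, not 1")
        if any(f < 0 for f in self.genotype_frequencies.values()):
            raise ValueError("negative genotype frequency")
        if not (0.0 <= self.mislabel_rate <= 1.0):
            raise ValueError("mislabel_rate must lie in [0, 1]")
        for cls, (_, sd) in self.hue_model.items():
            if sd <= 0:
                raise ValueError(f"hue sd for {cls} must be > 0")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be ≥ 1")


@dataclass(frozen=True)
class SimulatedCohort:
    """Output tables of :func:`simulate_cohort`."""

    genotypes: pd.DataFrame  # individual_id, marker_id, call
    colorimeter: pd.DataFrame  # individual_id, fruit, side, L, a, b
    truth: pd.DataFrame  # individual_id, call, true_class, emitted_class, mislabeled


def _truncated_hue(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    lo, hi = (0.0 - mean) / sd, (180.0 - mean) / sd
    return stats.truncnorm.rvs(lo, hi, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> SimulatedCohort:
    """Draw a cohort of genotyped, colorimeter-phenotyped individuals.

    Per individual: the genotype is drawn from ``genotype_frequencies``;
    its true binary class comes from the marker rule; with probability
    ε the hue-emitting distribution is swapped to the other class; hue
    replicates are drawn from the (possibly swapped) truncated normal and
    converted to (a*, b*) at fixed chroma.  Fully reproducible from
    (config, seed); ``seed`` overrides ``config.seed`` when given.
    """
    if config is None:
        config = CohortConfig()
    if seed is not None:
        config = replace(config, seed=int(seed))
    rng = np.random.default_rng(config.seed)
    marker = concordance.get_marker(config.marker_id)

    genos = list(config.genotype_frequencies)
    probs = np.array([config.genotype_frequencies[g] for g in genos], dtype=float)
    draws = rng.choice(len(genos), size=config.n_individuals, p=probs)
    mislabels = rng.random(config.n_individuals) < config.mislabel_rate

    n_fruits, n_sides = config.replicates
    n_reps = n_fruits * n_sides
    classes = list(config.hue_model)
    if set(classes) != {"orange", "yellow"}:
        raise ValueError("hue_model must define exactly the orange and yellow classes")

    geno_rows, color_rows, truth_rows = [], [], []
    for k in range(config.n_individuals):
        ind = f"S{k + 1:04d}"
        call = genos[draws[k]]
        record = concordance.parse_genotype(call, marker, ind)
        true_class = concordance.predict_phenotype(record, marker)
        emitted = true_class
        if mislabels[k]:
            emitted = "yellow" if true_class == "orange" else "orange"
        mean, sd = config.hue_model[emitted]
        hues = _truncated_hue(rng, mean, sd, n_reps)
        geno_rows.append({"individual_id": ind, "marker_id": marker.marker_id, "call": call})
        for r, hue in enumerate(hues):
            rad = np.deg2rad(hue)
            color_rows.append(
                {
                    "individual_id": ind,
                    "fruit": r // n_sides + 1,
                    "side": r % n_sides + 1,
                    "L": config.lightness,
                    "a": config.chroma * np.cos(rad),
                    "b": config.chroma * np.sin(rad),
                }
            )
        truth_rows.append(
            {
                "individual_id": ind,
                "call": call,
                "true_class": true_class,
                "emitted_class": emitted,
                "mislabeled": bool(mislabels[k]),
            }
        )

    return SimulatedCohort(
        genotypes=pd.DataFrame(geno_rows),
        colorimeter=pd.DataFrame(color_rows),
        truth=pd.DataFrame(truth_rows),
    )


@dataclass(frozen=True)
class AlleleSpec:
    """Specification of one synthetic allele of the skin-color locus."""

    repeat_count: int
    snp_states: tuple[str, str, str, str]
    name: str | None = None

    def __post_init__(self) -> None:
        if self.repeat_count < 1:
            raise ValueError("repeat_count must be ≥ 1")
        if len(self.snp_states) != 4:
            raise ValueError("snp_states must be a 4-tuple (SNP1..SNP4)")


def simulate_allele_sequence(spec: AlleleSpec) -> Locus:
    """Build the locus template for one allele spec.

    The template is the surrogate reference with the AGC tract resized to
    ``repeat_count`` units and the four SNP bases set to ``snp_states``;
    the returned :class:`~apricolor.locus.Locus` carries the template
    plus its documented offsets (tract span, per-SNP positions).  The
    Col1 amplicon of the result is 96 + 3·repeat_count bp.
    """
    return build_allele_template(spec.repeat_count, spec.snp_states)


def named_allele_specs() -> dict[str, AlleleSpec]:
    """Specs of the four named alleles (repeat counts 4, 5, 6 and 8)."""
    out = {}
    for name, (size, states) in NAMED_ALLELES.items():
        out[name] = AlleleSpec(repeat_count=(size - 96) // 3, snp_states=states, name=name)
    return out
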