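"""Genotype–phenotype concordance and classification-efficiency statistics.

A marker rule maps genotype calls (SNP base pairs such as ``C/T`` or SSR
fragment-size pairs such as ``108/114``) onto a predicted binary skin-color
group (orange or yellow).  Observed three-class hue phenotypes are
collapsed onto the same binary scale — light orange scores with the orange
group — and two efficiency statistics are reported:

* unweighted efficiency: percent of scored individuals whose prediction
  matches the observed group;
* weighted efficiency: the weight-0.5 mean of the per-group accuracies,
  correcting for the imbalance between orange and yellow cohort sizes.

Individuals with the no-amplification code ``X/X`` or a genotype absent
from the rule table are excluded from both numerator and denominator and
listed in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Mapping, Sequence

import yaml

from .colorimetry import HueClass, PhenotypeRecord

__all__ = [
    "GenotypeRecord",
    "MarkerRule",
    "EfficiencyReport",
    "GenotypeParseError",
    "NotScorableError",
    "UnknownGenotypeError",
    "WeightingError",
    "MISSING_CODE",
    "parse_genotype",
    "predict_phenotype",
    "collapse_observed",
    "score_concordance",
    "efficiency",
    "load_marker_rules",
    "builtin_marker_rules",
    "get_marker",
    "round_percent",
]

#: Genotype call emitted when no PCR product was detected.
MISSING_CODE = "X/X"

#: Binary groups used for scoring; light orange collapses into orange.
ORANGE_GROUP = "orange"
YELLOW_GROUP = "yellow"


class GenotypeParseError(ValueError):
    """Raised for a malformed call string or an allele foreign to the marker."""


class NotScorableError(ValueError):
    """Raised when a prediction is requested for a missing (X/X) record."""


class UnknownGenotypeError(KeyError):
    """Raised when a genotype is absent from the marker's rule table."""


class WeightingError(ValueError):
    """Raised when a weighted class has no scored members."""


@dataclass(frozen=True)
class GenotypeRecord:
    """One individual's canonicalized call at one marker.

    Alleles are order-insensitive and stored sorted, so ``T/C`` and
    ``C/T`` compare equal.  ``missing`` is true iff the call was the
    no-amplification code ``X/X``.
    """

    individual_id: str
    marker_id: str
    allele_1: str
    allele_2: str
    missing: bool = False

    @property
    def genotype(self) -> str:
        return f"{self.allele_1}/{self.allele_2}"


@dataclass(frozen=True)
class MarkerRule:
    """Marker definition plus its genotype → predicted-class lookup.

    For SNP markers ``genotype_to_class`` enumerates the genotypic
    classes explicitly.  For SSR markers prediction is allele-set based
    and orange-dominant: homozygous for a yellow allele → yellow, any
    orange allele present → orange.
    """

    marker_id: str
    marker_type: str  # "snp" | "ssr"
    alleles: frozenset[str] = frozenset()
    genotype_to_class: Mapping[str, str] = field(default_factory=dict)
    yellow_alleles: frozenset[str] = frozenset()
    orange_alleles: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.marker_type not in ("snp", "ssr"):
            raise ValueError(f"marker_type must be snp or ssr, got {self.marker_type!r}")
        for g, c in self.genotype_to_class.items():
            if c not in (ORANGE_GROUP, YELLOW_GROUP):
                raise ValueError(f"rule {self.marker_id}: genotype {g} maps to unknown class {c!r}")


def parse_genotype(call: str, marker: MarkerRule, individual_id: str = "") -> GenotypeRecord:
    """Parse an ``A/B`` call string into a canonical :class:`GenotypeRecord`.

    ``X/X`` yields a missing record.  For SNP markers, alleles outside
    the marker's two bases are rejected.
    """
    call = call.strip()
    if call == MISSING_CODE:
        return GenotypeRecord(individual_id, marker.marker_id, "X", "X", missing=True)
    parts = call.split("/")
    if len(parts) != 2 or not all(p.strip() for p in parts):
        raise GenotypeParseError(f"malformed genotype call {call!r} (expected 'A/B')")
    a1, a2 = sorted(p.strip() for p in parts)
    if marker.marker_type == "snp" and marker.alleles:
        for al in (a1, a2):
            if al not in marker.alleles:
                raise GenotypeParseError(
                    f"allele {al!r} not among marker {marker.marker_id} bases "
                    f"{sorted(marker.alleles)}"
                )
    return GenotypeRecord(individual_id, marker.marker_id, a1, a2, missing=False)


def predict_phenotype(record: GenotypeRecord, marker: MarkerRule) -> str:
    """Predicted binary skin-color group (``orange`` or ``yellow``) for a call.

    SNP markers use the explicit genotype lookup.  SSR markers are
    orange-dominant: yellow only when both alleles belong to the yellow
    set (e.g. 108/108); any orange-set allele predicts orange.
    """
    if record.missing:
        raise NotScorableError(f"{record.individual_id or record.marker_id}: X/X call is not scorable")
    if marker.marker_type == "snp":
        try:
            return marker.genotype_to_class[record.genotype]
        except KeyError:
            raise UnknownGenotypeError(
                f"genotype {record.genotype} absent from rule table of {marker.marker_id}"
            ) from None
    alleles = (record.allele_1, record.allele_2)
    if any(a in marker.orange_alleles for a in alleles):
        return ORANGE_GROUP
    if all(a in marker.yellow_alleles for a in alleles):
        return YELLOW_GROUP
    raise UnknownGenotypeError(
        f"SSR alleles {record.genotype} outside the allele sets of {marker.marker_id}"
    )


def collapse_observed(observed: HueClass | str) -> str:
    """Collapse the three-class phenotype onto the binary scoring scale.

    orange and light_orange form the orange group; yellow stands alone.
    """
    observed = HueClass(observed)
    if observed is HueClass.YELLOW:
        return YELLOW_GROUP
    return ORANGE_GROUP


def score_concordance(predicted: str, observed: HueClass | str) -> bool:
    """True iff the predicted binary group matches the collapsed observation."""
    if predicted not in (ORANGE_GROUP, YELLOW_GROUP):
        raise ValueError(f"predicted class must be binary, got {predicted!r}")
    return predicted == collapse_observed(observed)


def round_percent(fraction: float) -> float:
    """Percentage at one decimal, half-up (51/57 → 89.5)."""
    return float(Decimal(fraction * 100).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class EfficiencyReport:
    """Classification-efficiency summary for one marker on one cohort.

    Percent statistics are rounded half-up to one decimal; the exact
    fractions are retained in ``unweighted_fraction`` /
    ``per_class_accuracy``.
    """

    marker_id: str
    n_total: int
    n_scored: int
    n_correct: int
    per_class_accuracy: Mapping[str, float]
    per_class_counts: Mapping[str, tuple[int, int]]  # group -> (correct, scored)
    unweighted_fraction: float
    weighted_fraction: float | None
    misclassified_ids: tuple[str, ...]
    excluded_ids: tuple[str, ...]

    @property
    def unweighted_efficiency(self) -> float:
        return round_percent(self.unweighted_fraction)

    @property
    def weighted_efficiency(self) -> float | None:
        if self.weighted_fraction is None:
            return None
        return round_percent(self.weighted_fraction)

    def summary(self) -> str:
        lines = [
            f"marker {self.marker_id}: {self.n_correct}/{self.n_scored} concordant "
            f"({self.n_total - self.n_scored} excluded of {self.n_total})",
            f"  unweighted efficiency: {self.unweighted_efficiency}%",
        ]
        if self.weighted_efficiency is not None:
            lines.append(f"  weighted efficiency:   {self.weighted_efficiency}%")
        for group, (ok, n) in sorted(self.per_class_counts.items()):
            lines.append(f"  {group} group: {ok}/{n} correct")
        if self.misclassified_ids:
            lines.append("  misclassified: " + ", ".join(self.misclassified_ids))
        if self.excluded_ids:
            lines.append("  excluded: " + ", ".join(self.excluded_ids))
        return "\n".join(lines)


def efficiency(
    records: Sequence[tuple[GenotypeRecord, PhenotypeRecord]],
    marker: MarkerRule,
    weights: Mapping[str, float] | None = None,
) -> EfficiencyReport:
    """Score a cohort of (genotype, phenotype) pairs against a marker rule.

    Missing (``X/X``) and unknown genotypes are excluded from both the
    numerator and the denominator and listed as excluded.  The weighted
    efficiency is the weights-mean of per-group accuracies (default
    0.5/0.5 over the orange and yellow observed groups); it is an error,
    not a silent drop, for a weighted group to have no scored member.
    """
    if weights is None:
        weights = {ORANGE_GROUP: 0.5, YELLOW_GROUP: 0.5}
    if abs(sum(weights.values()) - 1.0) > 1e-9:
        raise WeightingError(f"class weights must sum to 1, got {dict(weights)}")

    n_total = len(records)
    n_scored = 0
    n_correct = 0
    group_scored: dict[str, int] = {g: 0 for g in weights}
    group_correct: dict[str, int] = {g: 0 for g in weights}
    misclassified: list[str] = []
    excluded: list[str] = []

    for geno, pheno in records:
        if geno.missing:
            excluded.append(geno.individual_id)
            continue
        try:
            predicted = predict_phenotype(geno, marker)
        except UnknownGenotypeError:
            excluded.append(geno.individual_id)
            continue
        group = collapse_observed(pheno.hue_class)
        n_scored += 1
        group_scored.setdefault(group, 0)
        group_correct.setdefault(group, 0)
        group_scored[group] += 1
        if predicted == group:
            n_correct += 1
            group_correct[group] += 1
        else:
            misclassified.append(geno.individual_id)

    if n_scored == 0:
        raise ValueError("no scorable records")

    per_class_accuracy = {
        g: (group_correct[g] / n) for g, n in group_scored.items() if n > 0
    }
    per_class_counts = {
        g: (group_correct[g], n) for g, n in group_scored.items() if n > 0
    }

    weighted: float | None
    try:
        weighted = 0.0
        for g, w in weights.items():
            if group_scored.get(g, 0) == 0:
                raise WeightingError(
                    f"weighted class {g!r} has no scored member; weighted efficiency undefined"
                )
            weighted += w * per_class_accuracy[g]
    except WeightingError:
        raise

    return EfficiencyReport(
        marker_id=marker.marker_id,
        n_total=n_total,
        n_scored=n_scored,
        n_correct=n_correct,
        per_class_accuracy=per_class_accuracy,
        per_class_counts=per_class_counts,
        unweighted_fraction=n_correct / n_scored,
        weighted_fraction=weighted,
        misclassified_ids=tuple(misclassified),
        excluded_ids=tuple(excluded),
    )


# ---------------------------------------------------------------------------
# marker-rule configuration


def load_marker_rules(source) -> dict[str, MarkerRule]:
    """Load marker rules from a YAML mapping (path, file object, or str).

    Layout::

        markers:
          S3_22924169:
            type: snp
            alleles: [C, T]
            genotype_to_class: {C/C: yellow, C/T: orange, T/T: orange}
          col1:
            type: ssr
            yellow_alleles: ['108']
            orange_alleles: ['111', '114', '120']
        aliases:
          snp1: S3_22924169
    """
    if hasattr(source, "read"):
        cfg = yaml.safe_load(source.read())
    else:
        text = str(source)
        if "\n" not in text and not text.lstrip().startswith("markers"):
            with open(text, "r", encoding="utf-8") as fh:
                cfg = yaml.safe_load(fh)
        else:
            cfg = yaml.safe_load(text)
    rules: dict[str, MarkerRule] = {}
    for mid, spec in cfg["markers"].items():
        mtype = spec["type"]
        if mtype == "snp":
            g2c = {
                "/".join(sorted(g.split("/"))): c
                for g, c in spec["genotype_to_class"].items()
            }
            rules[mid] = MarkerRule(
                marker_id=mid,
                marker_type="snp",
                alleles=frozenset(str(a) for a in spec["alleles"]),
                genotype_to_class=g2c,
            )
        else:
            rules[mid] = MarkerRule(
                marker_id=mid,
                marker_type="ssr",
                yellow_alleles=frozenset(str(a) for a in spec["yellow_alleles"]),
                orange_alleles=frozenset(str(a) for a in spec["orange_alleles"]),
            )
    for alias, target in (cfg.get("aliases") or {}).items():
        rules[alias] = rules[target]
    return rules


def builtin_marker_rules() -> dict[str, MarkerRule]:
    """The packaged marker rules (SNP S3_22924169, SNP4 S3_22924316, Col1)."""
    ref = resources.files("apricolor.data").joinpath("markers.yaml")
    return load_marker_rules(ref.read_text(encoding="utf-8"))


def get_marker(marker_id: str) -> MarkerRule:
    """Look up one packaged marker rule by id or alias."""
    rules = builtin_marker_rules()
    try:
        return rules[marker_id]
    except KeyError:
        raise KeyError(
            f"unknown marker {marker_id!r}; available: {sorted(rules)}"
        ) from None
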