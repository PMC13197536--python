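"""End-to-end marker-validation pipeline.

Ties the stages together: phenotype source (raw colorimeter readings or
a packaged validation fixture) → genotype source → marker rule →
efficiency report, logging every exclusion (missing ``X/X`` calls,
genotypes absent from the rule table) and every printed-label
disagreement.  The result is a pure function of (inputs, config).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import concordance, io_tables
from .colorimetry import HueClass, PhenotypeRecord, phenotype_table

__all__ = ["PipelineError", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("apricolor")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineResult:
    report: concordance.EfficiencyReport
    phenotypes: pd.DataFrame  # individual_id, hue_mean, hue_sd, n, hue_class
    genotypes: pd.DataFrame  # individual_id, marker_id, call
    label_mismatches: pd.DataFrame  # fixture rows whose printed label disagrees


def _phenotypes_from_source(config: Mapping) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Returns (phenotype table, label-mismatch rows)."""
    if "fixture" in config:
        fixture = io_tables.load_fixture(config["fixture"])
        tbl = fixture.table
        phen = pd.DataFrame(
            {
                "individual_id": tbl["individual_id"],
                "hue_mean": tbl["hue_mean"],
                "hue_sd": tbl["hue_sd"],
                "n": 6,
                "hue_class": tbl["hue_class"],
            }
        )
        mism = fixture.label_mismatches
        for r in mism.itertuples(index=False):
            logger.warning(
                "phenotype: %s printed label %r disagrees with threshold class %r (h°=%s)",
                r.individual_id,
                r.phenotype,
                r.hue_class,
                r.hue_mean,
            )
        return phen, mism
    if "colorimeter" in config:
        schema = {
            "individual_id": str,
            "fruit": int,
            "side": int,
            "L": float,
            "a": float,
            "b": float,
        }
        raw = config["colorimeter"]
        readings = raw if isinstance(raw, pd.DataFrame) else io_tables.read_table(raw, schema)
        return phenotype_table(readings), pd.DataFrame()
    raise PipelineError("phenotype stage: config needs a 'fixture' or 'colorimeter' source")


def _genotypes_from_source(config: Mapping, marker_id: str) -> pd.DataFrame:
    if "fixture" in config:
        tbl = io_tables.load_fixture(config["fixture"]).table
        return pd.DataFrame(
            {
                "individual_id": tbl["individual_id"],
                "marker_id": marker_id,
                "call": tbl["genotype"],
            }
        )
    if "table" in config:
        raw = config["table"]
        schema = {"individual_id": str, "marker_id": str, "call": str}
        geno = raw if isinstance(raw, pd.DataFrame) else io_tables.read_table(raw, schema)
        return geno[geno["marker_id"] == marker_id].reset_index(drop=True)
    raise PipelineError("genotype stage: config needs a 'fixture' or 'table' source")


def run_pipeline(
    config: Mapping,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run phenotype classification and marker concordance from a config.

    Config keys::

        marker: marker id or alias (e.g. S3_22924169, snp4, col1)
        phenotypes: {fixture: table2_cultivars} | {colorimeter: path-or-frame}
        genotypes:  {fixture: table2_cultivars} | {table: path-or-frame}
        weights:    optional {orange: w, yellow: w}  (default 0.5/0.5)

    When ``out_dir`` is given, the phenotype table and a per-individual
    concordance table are written there as CSV.
    """
    try:
        marker = concordance.get_marker(config["marker"])
    except KeyError as exc:
        raise PipelineError(f"marker stage: {exc}") from exc

    try:
        phen, mismatches = _phenotypes_from_source(config.get("phenotypes", {}))
    except (io_tables.TableFormatError, KeyError, ValueError) as exc:
        raise PipelineError(f"phenotype stage: {exc}") from exc

    try:
        geno = _genotypes_from_source(config.get("genotypes", {}), marker.marker_id)
    except (io_tables.TableFormatError, KeyError, ValueError) as exc:
        raise PipelineError(f"genotype stage: {exc}") from exc

    phen_by_id = {
        r.individual_id: PhenotypeRecord(
            r.individual_id, float(r.hue_mean), float(r.hue_sd), int(r.n), HueClass(r.hue_class)
        )
        for r in phen.itertuples(index=False)
    }
    pairs = []
    for r in geno.itertuples(index=False):
        if r.individual_id not in phen_by_id:
            logger.warning("concordance: %s has a genotype but no phenotype; skipped", r.individual_id)
            continue
        record = concordance.parse_genotype(r.call, marker, r.individual_id)
        pairs.append((record, phen_by_id[r.individual_id]))
    if not pairs:
        raise PipelineError("concordance stage: no (genotype, phenotype) pairs")

    try:
        report = concordance.efficiency(pairs, marker, config.get("weights"))
    except (concordance.WeightingError, ValueError) as exc:
        raise PipelineError(f"concordance stage: {exc}") from exc

    for ind in report.excluded_ids:
        logger.warning("concordance: %s excluded (missing or unknown genotype)", ind)
    for ind in report.misclassified_ids:
        logger.info("concordance: %s misclassified", ind)

    if out_dir is not None:
        out = Path(out_dir)
        io_tables.write_table(phen, out / "phenotypes.csv")
        rows = []
        for g, p in pairs:
            try:
                pred = concordance.predict_phenotype(g, marker) if not g.missing else ""
            except concordance.UnknownGenotypeError:
                pred = ""
            rows.append(
                {
                    "individual_id": g.individual_id,
                    "call": g.genotype,
                    "hue_mean": p.hue_mean,
                    "hue_class": p.hue_class.value,
                    "predicted": pred,
                    "concordant": (
                        concordance.score_concordance(pred, p.hue_class) if pred else ""
                    ),
                }
            )
        io_tables.write_table(pd.DataFrame(rows), out / "concordance.csv")

    return PipelineResult(
        report=report,
        phenotypes=phen,
        genotypes=geno,
        label_mismatches=mismatches,
    )
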