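#!/usr/bin/env python
"""Classify the two validation panels from their printed hue values.

Loads the packaged 40-seedling population and 57-cultivar panel, derives
the three-class skin-color phenotype from the hue thresholds (orange
h° < 77, light orange 77–83, yellow h° > 83), and cross-checks the
printed labels.  Writes the classified tables to results/.
"""

from pathlib import Path

from apricolor import io_tables

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    for name in io_tables.FIXTURE_NAMES:
        fixture = io_tables.load_fixture(name)
        cols = ["row_id", "individual_id", "genotype", "hue_mean", "hue_sd",
                "phenotype", "hue_class", "label_mismatch"]
        io_tables.write_table(fixture.table[cols], OUT / f"phenotypes_{name}.csv")
        counts = fixture.table["hue_class"].value_counts().to_dict()
        print(f"{name}: {len(fixture.table)} individuals, classes {counts}")
        for r in fixture.label_mismatches.itertuples(index=False):
            print(
                f"  label disagreement: {r.individual_id} printed {r.phenotype!r} "
                f"but h°={r.hue_mean} classifies as {r.hue_class}"
            )


if __name__ == "__main__":
    main()
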