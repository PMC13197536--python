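#!/usr/bin/env python
"""Score the SNP S3_22924169 marker on both validation panels.

Applies the genotype rule (C/C → yellow; C/T and T/T → orange) to the
seedling population and the cultivar panel, reporting unweighted and
0.5-weighted classification efficiency and listing misclassified
individuals.  Writes per-individual concordance tables under results/.
"""

import json
from pathlib import Path

from apricolor import pipeline

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    summary = {}
    for fixture in ("table1_gxc", "table2_cultivars"):
        result = pipeline.run_pipeline(
            {"marker": "S3_22924169",
             "phenotypes": {"fixture": fixture},
             "genotypes": {"fixture": fixture}},
            out_dir=OUT / f"concordance_{fixture}",
        )
        rep = result.report
        print(rep.summary())
        print()
        summary[fixture] = {
            "n_scored": rep.n_scored,
            "n_correct": rep.n_correct,
            "unweighted_efficiency_pct": rep.unweighted_efficiency,
            "weighted_efficiency_pct": rep.weighted_efficiency,
            "misclassified": list(rep.misclassified_ids),
        }
    (OUT / "marker_concordance.json").write_text(json.dumps(summary, indent=2) + "\n")


if __name__ == "__main__":
    main()
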