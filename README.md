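# apricolor

Marker-assisted selection of apricot (*Prunus armeniaca*) fruit skin color:
a tested pipeline for validating SNP and SSR markers against CIELAB hue
phenotypes, and for reconstructing the alleles and protein variants of the
candidate AP2/ERF gene underlying the skin-color QTL on chromosome 3.

Skin color (orange vs yellow) matters to breeders because market-preferred
orange seedlings must be selected years before the tree bears fruit. A
reliable intragenic marker lets the cross 'orange × yellow' be screened at
the seedling stage. This package implements the computational side of that
workflow, for breeders and genetics researchers:

* **colorimetry** — hue angle h° = atan2(b\*, a\*) in degrees from
  colorimeter readings; replicate aggregation (mean ± sd over six
  readings); three-class phenotype: orange (h° < 77), light orange
  (77 ≤ h° ≤ 83), yellow (h° > 83); UPOV peel-color category grouping.
* **concordance** — genotype parsing (`C/T` SNP calls, `108/114` SSR
  fragment sizes, `X/X` no-amplification code), rule-based phenotype
  prediction, and two efficiency statistics: unweighted
  (100 · n_correct / n_scored) and weighted
  (Σ_c w_c · accuracy_c with w = 0.5 per class), the latter correcting for
  the excess of orange cultivars in validation panels.
* **seqrecon** — exact-match in-silico PCR, AGC tandem-repeat detection,
  SNP-state extraction by flank anchoring against the reference allele,
  and haplotype assembly against the four named alleles:
  Allele 1 (SSR108, C–G–A–A), Allele 2 (SSR111, C–G–G–G),
  Allele 3 (SSR114, T–T–A–G), Allele 4 (SSR120, C–G–A–G).
* **protein** — reverse-complement frame-1 translation; polyalanine-tract
  measurement (one Ala per AGC repeat: tracts of 4/5/6/8 residues);
  His/Tyr variant residues at positions 195 (SNP3) and 146 (SNP4), with
  G encoding histidine and A tyrosine.
* **synthetic_data** — reproducible cohort and allele-sequence generators
  for end-to-end validation, including a controllable phenotype-mislabel
  rate ε.
* **io_tables / pipeline / cli** — strict CSV IO, the packaged validation
  panels (40 seedlings of 'Goldrich' × 'Currot'; 57 cultivars), and the
  `apricolor` command-line interface.

## Worked example

Score the SNP marker S3_22924169 (C/C → yellow; C/T, T/T → orange) on the
packaged 57-cultivar panel:

```bash
apricolor concord --fixture table2_cultivars --marker snp1
```

prints

```
marker S3_22924169: 51/57 concordant (0 excluded of 57)
  unweighted efficiency: 89.5%
  weighted efficiency:   93.6%
  orange group: 41/47 correct
  yellow group: 10/10 correct
  misclassified: Palsteyn, Tyrinthos, Lito, San Castrese, Bebeco, Bergeron
```

Reading: 51 of 57 cultivars have the hue class their genotype predicts
(light-orange observations score with the orange group). The six
discordant cultivars are all C/C (predicted yellow) with hue below 83°.
The weighted statistic averages the per-group accuracies (10/10 yellow,
41/47 orange) with weight 0.5 each, so the abundant orange group does not
dominate. On the 40-seedling breeding population
(`--fixture table1_gxc`) the same rule is 100% concordant.

The same stages are importable:

```python
from apricolor import pipeline
report = pipeline.run_pipeline({
    "marker": "snp1",
    "phenotypes": {"fixture": "table2_cultivars"},
    "genotypes": {"fixture": "table2_cultivars"},
}).report
print(report.unweighted_efficiency, report.weighted_efficiency)  # 89.5 93.6
```

Allele and protein reconstruction:

```bash
apricolor simulate allele --out-dir sim_out
apricolor reconstruct --fasta sim_out/alleles.fa
```

yields the four named alleles with SSR amplicons 108/111/114/120 bp, and
`analysis/04_protein_variants.py` translates them into Proteins 1–4 with
polyalanine tracts of 4/5/6/8 residues and the Y/Y, H/H, Y+H residue
patterns at positions 195 and 146.

## Analysis scripts

The `analysis/` directory holds the narrative drivers, each writing its
tables under `results/`:

1. `01_phenotype_classes.py` — hue classification of both panels and the
   printed-label cross-check (surfaces the 'Lito' disagreement).
2. `02_marker_concordance.py` — marker efficiency on both panels.
3. `03_allele_reconstruction.py` — the four-allele reconstruction round
   trip (PCR sizing, repeat counts, SNP haplotypes).
4. `04_protein_variants.py` — protein-variant table and FASTA.
5. `05_synthetic_validation.py` — mislabel-rate recovery on simulated
   cohorts.

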