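# Methods

## Phenotype model

Fruit skin color is quantified in CIELAB space. Each reading gives
(L\*, a\*, b\*); the hue angle is h° = atan2(b\*, a\*) expressed in degrees.
We use the two-argument arctangent wrapped to [0, 360) rather than
arctan(b\*/a\*) so that readings with a\* ≤ 0 remain well defined; apricot
skin lies in the first quadrant (a\*, b\* > 0, h° in (0, 90)), where the
two definitions agree. Hue is computed per reading and then averaged —
averaging a\*/b\* first and converting afterwards is a different statistic,
and the per-reading mean ± sd matches how replicate protocols (two sides
of three fruits, six readings) are reported. The spread is the sample
(n−1) standard deviation, defined as 0 for a single reading. Replicates
here stay far from the 0°/360° wrap, so a circular mean is unnecessary.

Classes: orange for h° < 77, yellow for h° > 83, light orange between.
The defining inequalities are strict on both sides, leaving h° = 77 and
h° = 83 unassigned; we place both boundaries in the transitional
light-orange class. The seven UPOV peel base-color categories collapse
onto the same three classes (not visible/white/yellowish/yellow-green →
yellow; light orange kept; medium/dark orange → orange).

## Concordance scoring and efficiency

Markers predict a binary group (orange or yellow). For scoring, the
observed three-class phenotype is collapsed to the same scale with
light orange joining the orange group. This collapse is not arbitrary:
of the two admissible binary collapses, only light_orange → orange
reproduces the 51/57 concordance of the published cultivar panel, and
the test suite verifies that uniqueness by brute force.

Two statistics are reported. Unweighted efficiency is
100 · n_correct / n_scored. Weighted efficiency is Σ_c w_c · accuracy_c
over the observed binary groups with w = 0.5 each, which removes the
effect of class imbalance (orange cultivars outnumber yellow roughly
5:1 in the panel); with equal class sizes the two statistics coincide,
and the weighted one is invariant under duplicating every member of one
class. Records with the no-amplification code `X/X`, or with a genotype
absent from the rule table, are excluded from numerator and denominator
and listed in the report; a weighted class with zero scored members is
an error, not a silent drop. Percentages are rounded half-up to one
decimal; exact fractions are retained.

On the 57-cultivar panel the recomputed weighted value is
0.5·(10/10) + 0.5·(41/47) = 93.62% → 93.6%, while the published summary
prints 93.5%. The 0.1-point gap is a rounding/presentation ambiguity in
the source; we report the recomputed value and do not force agreement.
Likewise the cultivar 'Lito' is printed as "Light Orange" at h° = 75.7,
which the 77° threshold classifies as orange; the fixture keeps both the
printed label and the derived class and the loader flags the
disagreement rather than resolving it.

SSR prediction is orange-dominant: 108/108 → yellow, any of
111/114/120 → orange. All heterozygous 108/x panel cultivars described
in the source are orange-skinned, consistent with dominance of the
longer alleles.

## Surrogate locus and allele reconstruction

The published record documents the skin-color gene at marker resolution
— Col1 primer pair, SSR amplicons of 108/111/114/120 bp reflecting AGC
repeat number, four SNPs (S3_22924169, S3_22924445, S3_22924252,
S3_22924316), the SNP4 HRM amplicon of 109 bp, and the protein-level
consequences — but not the full nucleotide sequence of any allele.
Reconstruction therefore runs against a synthetic surrogate reference
(labelled as such) that honors every documented constraint:

* 1257 bp, the printed span of the Col1 region;
* the Col1 primers flank the AGC tract, product 96 + 3·(repeat count) bp,
  so 4/5/6/8 repeats give exactly 108/111/114/120;
* the SNP4 primers produce a 109-bp amplicon containing SNP4;
* in the reverse-complement frame-1 translation, each AGC unit
  contributes one alanine (GCT codon) to a single polyalanine tract,
  SNP3 and SNP4 occupy the first codon position of residues 195 and 146
  (template context 5'-AT[A|G]-3', read as TAT = Tyr or CAT = His), and
  SNP1/SNP2 sit at third codon positions inside leucine codons, hence
  synonymous.

The four SNPs keep their genomic order. Their exact spacing is adjusted
to the frame constraints: the printed coordinates put SNP3 and SNP4
64 bp apart, which is not a multiple of 3, so no single-exon frame can
place both at first codon positions — presumably the published residue
numbering refers to the spliced transcript. We prioritize the
protein-level facts (the His/Tyr toggle at residues 195 and 146), which
the package reproduces exactly; genomic positions are carried as
metadata. Flanking sequence is drawn from a fixed-seed generator under
rejection constraints (no AGC/GCA/CAG phase words in flanks, unique
primer sites on one strand, no competing alanine run longer than two
residues, SNP1/SNP2 synonymy verified by mutation) and is fully
deterministic.

In-silico PCR uses exact primer matching — the assays assume perfect
priming — pairing every forward-primer occurrence with every downstream
reverse-site occurrence on both strands, product ≤ 5 kb; the
implementation is checked against an exhaustive placement oracle on
random templates. Tandem-repeat detection returns the longest maximal
perfect run over all three motif phases, leftmost on ties. SNP states
are read by exact flank anchoring: the query must equal the reference
outside the tract and the SNP offsets, the only permitted length
difference being whole AGC units inside the tract (offsets downstream
shift by that difference); anything else is rejected rather than
aligned heuristically, since a general aligner is out of scope. A base
other than ref/alt at a SNP offset is returned with a novel flag, not
raised. Haplotypes are matched exactly against the four named alleles;
any other combination is a `novel` call with its fields preserved.

Translation renders stop codons as `*` and continues: this is variant
reconstruction, not ORF calling. Non-ACGT symbols translate to `X` with
a warning. Named alleles map to Proteins 1–4; for novel in-frame alleles
the polyalanine length is 4 + (SSR size − 108)/3 (the 108-bp allele
anchors the tract at four residues, forcing 111 → 5, 114 → 6, 120 → 8),
and an SSR size not congruent to 108 mod 3 triggers a frame-shift
warning with undefined tract length.

## Synthetic cohorts

`simulate_cohort` emulates the validation panels: genotypes drawn from
configurable frequencies (default 0.525 C/T, 0.475 C/C, the seedling
population's proportions), true class from the marker rule, six hue
replicates per individual (3 fruits × 2 sides) from class-conditional
truncated normals — orange ~ N(73°, 2°), yellow ~ N(88°, 2°), truncated
to (0°, 180°), spanning the panels' hue ranges — and (a\*, b\*)
back-computed at fixed chroma 50, since hue is the only
phenotype-bearing quantity. With probability ε an individual's emitting
distribution is swapped to the other class: mislabeling is modelled as
phenotyping error, matching how the source attributes its mismatches,
so the expected unweighted efficiency is 100(1−ε) (the two hue
distributions are ~7.5 within-class sd apart at the class boundary, so
intrinsic overlap error is negligible). Generators are pure functions
of (config, seed).

What the simulation does not emulate: linkage/pedigree structure of the
F1 cross, ripening-stage drift in hue (the suspected cause of real
misclassifications), lightness/chroma variation, missing calls, and
melting-curve or electropherogram artifacts. Passing recovery tests
therefore show the statistics and plumbing are correct, not that real
phenotyping error is this well behaved.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: panels of 40 and 57
individuals as published; simulated cohorts of 2000 individuals at
ε ∈ {0, 0.05, 0.1, 0.2}, judged against the central 99% binomial
interval of 100(1−ε); property suites use 200 random 1-kb templates for
the PCR oracle and 1000 random sequences for the translation oracle.
Moment-recovery checks use 1000 individuals × 6 replicates (≥ 2500
draws per class) within three standard errors. Percent rounding is
decimal half-up. Ripening dates in the packaged tables are normalized
from printed dd/mm/yyyy to ISO and are metadata only.

## Known limitations

* The surrogate locus reproduces the documented marker and protein
  facts, not the literal cultivar nucleotides; reconstructing those
  would require the deposited genome assemblies, which are out of scope.
* Only the intended SNP/SSR alleles and X/X missingness are modelled in
  genotype calls; HRM curve interpretation and fragment-scoring noise
  are upstream of this package.
* Repeat detection guarantees recovery for tracts of ≥ 2 units (a
  single-unit tract can tie with isolated motif words elsewhere, where
  the leftmost rule still favors the tract in the packaged layout).
* Cultivar-level genotype tables for the Col1 and SNP4 assays were
  published only as figures, so their panel efficiencies (96.4%
  unweighted, 93.9% weighted) cannot be recomputed from data; the
  corresponding machinery is instead validated by the synthetic round
  trip and the property suites.
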