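# Declarative marker rules: genotype -> predicted binary skin-color group.
markers:
  S3_22924169:
    type: snp
    alleles: [C, T]
    genotype_to_class:
      C/C: yellow
      C/T: orange
      T/T: orange
  S3_22924316:
    type: snp
    alleles: [A, G]
    genotype_to_class:
      A/A: yellow
      A/G: orange
      G/G: orange
  col1:
    type: ssr
    yellow_alleles: ['108']
    orange_alleles: ['111', '114', '120']
aliases:
  snp1: S3_22924169
  snp4: S3_22924316
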