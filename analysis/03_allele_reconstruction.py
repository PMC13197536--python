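#!/usr/bin/env python
"""Reconstruct the four named alleles of the skin-color gene.

Builds each allele's surrogate locus, runs in-silico PCR with the Col1
SSR primers and the SNP4 HRM primers, counts AGC repeats, extracts the
four SNP states, and assembles the haplotypes against the named-allele
table.  Writes the allele table and the locus FASTA under results/.
"""

from pathlib import Path

import pandas as pd

from apricolor import io_tables, seqrecon, synthetic_data

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows, fasta = [], []
    for name, spec in synthetic_data.named_allele_specs().items():
        locus = synthetic_data.simulate_allele_sequence(spec)
        (col1,) = seqrecon.insilico_pcr(locus.template, seqrecon.COL1_PRIMERS)
        (snp4,) = seqrecon.insilico_pcr(locus.template, seqrecon.SNP4_PRIMERS)
        tract = seqrecon.find_tandem_repeat(col1.sequence)
        states = seqrecon.extract_snp_states(locus.template).states
        call = seqrecon.assemble_haplotype(col1.length, states)
        rows.append(
            {"allele": call.allele_name,
             "ssr_amplicon_bp": col1.length,
             "agc_repeats": tract.repeat_count,
             "snp_haplotype": "-".join(states),
             "snp4_amplicon_bp": snp4.length}
        )
        fasta.append(f">{name.replace(' ', '_')} repeats={locus.repeat_count}")
        fasta.append(locus.template)
    table = pd.DataFrame(rows)
    io_tables.write_table(table, OUT / "allele_table.csv")
    (OUT / "allele_loci.fa").write_text("\n".join(fasta) + "\n")
    print(table.to_string(index=False))
    print("\nall four alleles recovered:", set(table["allele"]) == {
        "Allele 1", "Allele 2", "Allele 3", "Allele 4"})


if __name__ == "__main__":
    main()
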