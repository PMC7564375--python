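"""Run the in-silico PCR + MvaI digest assay over every clone genotype.

Builds synthetic diploid allele pairs around the diagnostic exon-2 amplicon
(314 bp, primers included) and prints the digital-gel call for each: the
gene-corrected pair stays undigested, the heterozygous pair shows the
double band, the double-mutant pair is fully digested, a 102 bp insertion
shifts the product to 416 bp, and a lost primer site yields no product.
"""

from clonescreen import call_clone
from clonescreen.synthetic_sequences import GENOTYPES, make_diploid_alleles

for genotype in GENOTYPES:
    a, b = make_diploid_alleles(genotype, seed=11)
    call = call_clone(a, b)
    bands = ", ".join(f"{s} bp" for s in call.bands) or "none"
    extra = f" (product at {call.observed_length} bp)" if call.observed_length else ""
    print(f"{genotype:>13}: {call.label:<15} gel bands: {bands}{extra}")
# A 314 bp band means an uncut (site-free, corrected) allele; the ~100/~212 bp
# fragments come from cutting at the CCAGG site created by the c.88G>C mutation.
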