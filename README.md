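# clonescreen

Tools for the computational stages of a CRISPR–Cas9 single-cell isogenic
iPSC clone-selection workflow: whole-well high-content-screening (HCS)
classification of sorted fluorescent clones, in-silico PCR/restriction-digest
genotyping of the *SNCA* c.88G>C (p.A30P) locus, a piggyBac TTAA
footprint-free excision model, and a per-clone ledger that recomputes the
stage efficiencies of the quadruple selection strategy (QSS: antibiotic
resistance, single-cell FACS + HCS, PCR/digest selection, Sanger
sequencing).

The package is aimed at gene-editing groups who screen dual-reporter
knock-in clones on multiwell plates and validate them by restriction
fragment length polymorphism (RFLP): it lets the image classifier, the gel
logic and the bookkeeping be exercised and regression-tested end to end on
synthetic plates and synthetic alleles, without any microscopy data or
genomic sequence.

## The methods in brief

**Well classification.** Each well mosaic has blue/green/red channels.
The red channel is smoothed with a Gaussian kernel of size 21, σ = 7 and
thresholded at 125 digital numbers (`RedPositiveMask = RedLP > 125`); green
and blue are smoothed with size-60, σ = 20 kernels and thresholded at 200.
The clonal region of interest is `GreenPositiveMask OR RedPositiveMask`;
wells whose region is ≤ 20,000 px contain no clone. With the area
proportion AP_c = |mask_c| / |region|, the rules are (all strict):

- `Red`: AP_red > 0.9 and AP_green < 0.1
- `Green`: AP_red < 0.1 and AP_green > 0.9
- `RedGreen`: AP_red > 0.1 and AP_green > 0.1 — the pickable, putatively
  biallelic wells
- `Blue`: AP_blue > 0.1 — the tagBFP backbone marker flags random
  integration and vetoes every other label
- `Negative`: everything else

**Genotyping.** The c.88G>C mutation converts the codon-30 context GCAGG
into CCAGG, creating an MvaI/BstNI site (CCWGG, cut CC^WGG) inside the
diagnostic 314 bp exon-2 amplicon
(primers `CCCCGAAAGTTCTCATTCAA` / `GCGAATCCGTCGCTGTGCAT`). A diploid clone
is called from the pooled digital gel: all products full length →
`GENE_CORRECTED`; full length plus cut fragments → `HET_RETAINED` (double
band); no full-length band → `FULLY_DIGESTED`; product at an unexpected
size → `SIZE_SHIFT`; no amplification → `NO_PRODUCT`.

**Excision.** The selection cassette sits between piggyBac inverted
repeats; integration duplicates a genomic TTAA, and excision removes the
cassette plus one duplicate, restoring the locus exactly (footprint-free,
idempotent). The donor carries 1222 + 948 = 2170 bp of homology.

**Ledger.** A CSV with one row per recovered clone (PCR outcome, digest
outcome, sequencing, karyotype) and plate totals, from which the selection
funnel is recomputed — recovery, expansion, PCR pass, undigested
(gene-corrected candidate) fraction, sequencing confirmation, karyotype.

## Worked example

```bash
python examples/stage_efficiencies.py
```

prints the funnel recomputed from the packaged ledger
(192 sorted wells, 37 recovered clones):

```
      sorted:  37/192 =  19.27%
    expanded:  34/37  =  91.89%
         pcr:  31/34  =  91.18%
correct_edit:  12/34  =  35.29%
   sequenced:   5/5   = 100.00%
   karyotype:   2/3   =  66.67%
```

`correct_edit` is the headline number: 12 of 34 expanded clones gave an
undigested 314 bp product, i.e. carry no MvaI site on either allele and are
gene-corrected at codon 30. And

```bash
python examples/genotype_clones.py
```

shows the digital gel for every genotype:

```
    corrected: GENE_CORRECTED  gel bands: 314 bp
 heterozygous: HET_RETAINED    gel bands: 314 bp, 212 bp, 102 bp
       mutant: FULLY_DIGESTED  gel bands: 212 bp, 102 bp
    insertion: SIZE_SHIFT      gel bands: 416 bp, 314 bp (product at 416 bp)
   no_product: NO_PRODUCT      gel bands: none
```

The ~100 bp fragment is the familiar lower band of the digested mutant
product; 416 bp is the size shift produced by a 102 bp insertion.
`examples/classify_synthetic_plate.py` and `examples/excise_construct.py`
demonstrate the image classifier and the excision model the same way.

A `clonescreen` command wraps the same functions for shell use
(`simulate`, `classify-plate`, `genotype`, `report`, `run`); see
`clonescreen --help`.

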