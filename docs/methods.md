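# Methods

## Well classification model

Each well is one pre-stitched mosaic per fluorescence channel (blue, green,
red), integer camera digital numbers (DN), 8–16 bit. The classifier is a
fixed pipeline: Gaussian low-pass filter → strict threshold → area
proportions over the clonal region → rule set.

**Smoothing.** The red channel uses a size-21, σ = 7 kernel; green and blue
use size-60, σ = 20. Kernels are sampled symmetrically around
`(size − 1)/2` and normalised to unit sum, so constants and (in the
interior) affine ramps pass through unchanged. The filter is applied
separably with `scipy.ndimage.correlate1d`. A size-60 window has no central
sample; we keep the printed size and place the origin at index
`size // 2`, a half-pixel shift that is negligible against σ = 20 (a
size-61 window can be configured instead). Borders use symmetric
(reflect) extension so flat signal stays flat to the well edge and no
border darkening deletes mask pixels. The implementation is verified to
1e-9 relative agreement against a dense direct-convolution oracle in the
test suite.

**Masks, region and proportions.** `RedPositiveMask = RedLP > 125`,
`GreenPositiveMask = GreenLP > 200`, `BluePositiveMask = BlueLP > 200`, all
strictly greater, on the raw smoothed DN values with no normalisation. The
clonal region of interest is the elementwise OR of the green and red masks
— blue never contributes. The smoothing prescription names a green and a
blue low-passed image, so the (60, 20) kernel is applied to both green and
blue, red keeping (21, 7). Area proportions divide each channel's positive
pixel count by the region pixel count; the blue mask is intersected with
the region first (red/green are subsets of the region by construction,
blue is not), keeping all three proportions in [0, 1] with a common
denominator. Because the region is the union of the red and green masks,
AP_red + AP_green ≥ 1 whenever a region exists — a property test.

**Rules and precedence.** A region of ≤ 20,000 px is `NoClone` (the gate
applies to the total region across connected components, since the region —
not its components — is what the proportions are defined over). Otherwise:
`Blue` when AP_blue > 0.1, checked first — the tagBFP backbone marker
indicates random plasmid integration, which must veto expansion regardless
of the reporter signal; then `Red` (AP_red > 0.9 ∧ AP_green < 0.1),
`Green` (AP_red < 0.1 ∧ AP_green > 0.9), `RedGreen`
(AP_red > 0.1 ∧ AP_green > 0.1), else `Negative`. No explicit Blue formula
is given by the screening protocol, only the class name; the AP_blue > 0.1
rule with top precedence is this package's design choice. All cut-offs are
strict, so AP_red = 0.9 exactly is not Red; given the AP sum property,
`Negative` is reachable only on the decision boundaries. The pick list of
`classify_plate` is the `RedGreen` wells: dual-reporter, putatively
biallelic knock-in, not blue-vetoed.

## Synthetic plates

The generator plants soft-edged disc colonies (linear radial roll-off,
default edge 10 px) with per-channel peak amplitudes of ~1000 DN (±10%)
on a zero background, in 960 × 960 rasters; the 20,000 px gate corresponds
to a disc of radius ≈ 80 px, so planted radii default to 100–150 px.
Label recipes: Red/Green wells express one reporter; RedGreen wells are a
single colony expressing both (biallelic knock-in semantics, not two
adjacent colonies); Blue wells add the blue marker on top of both
reporters, as a random-integration event presents in an otherwise
dual-positive clone; `Negative` cannot be planted robustly (see the AP sum
property) and the generator refuses it. Noise is additive Gaussian read
noise plus optional Poisson shot noise, then rounding and clipping to
uint16 — enough to exercise threshold robustness. Not modelled: colony
texture, optics PSF beyond the soft edge, illumination gradients,
stitching seams; perfect recovery on these plates therefore demonstrates
the decision logic and its noise margins, not performance on real
microscopy.

## In-silico genotyping

Primer matching is exact (zero mismatches): the forward primer on the plus
strand, the reverse primer as its reverse complement downstream; the
amplicon includes both primers; more than one hit for either primer is an
ambiguity error, absence is no product. Coordinates are 0-based,
half-open. Site scanning expands the IUPAC pattern (CCWGG → CC[AT]GG) and
reports overlapping matches; CCWGG is strand-symmetric, so a plus-strand
scan is complete. Digestion cuts at site start + 2 on the top strand
(CC^WGG); the single-base 5′ extension of the staggered cut is irrelevant
at gel resolution. Fragments always sum to the amplicon length, with
count = cuts + 1.

The digital gel merges fragments closer than 10 bp (configurable) into one
band, since the assay reads band patterns ("double band", "lower band at
roughly 100 bp"), not exact sizes. Calls on a diploid pair: `NO_PRODUCT`
when neither allele amplifies; `SIZE_SHIFT` (with the observed length) when
any product deviates from the expected 314 bp — which is configuration, not
a constant, so the engine generalises to other RFLP screens;
`GENE_CORRECTED` / `HET_RETAINED` / `FULLY_DIGESTED` by whether zero, one
or both amplicons are cut.

Synthetic templates place the codon-30 context GCAGG at a configurable
offset inside the amplicon (default 100 bp from the 5′ end, putting the cut
at 102 bp and reproducing the ~100 bp lower band; the true genomic offset
is a parameter because only the band size, not the side, is known from the
assay read-out). Filler is random but scrubbed of stray CCWGG sites and
primer matches; templates are always built with the reference context and
the mutant derived by the single G>C substitution, so a same-seed pair
differs at exactly the edited base and the substitution creates exactly one
recognition site. No real genomic sequence ships with the package and none
is needed by any test.

**Excision model.** Integration inserts the cassette at a TTAA and
duplicates it (`left + TTAA + cassette + TTAA + right`); excision removes
the cassette and one duplicate, restoring the input exactly. A cassette
without TTAA flanks is non-excisable (error); a sequence without the
cassette is returned unchanged with a flag, making excision idempotent.
The cassette generator keeps TTAA and the primers out of the cassette so
boundaries stay unambiguous. Donor geometry is bookkeeping:
`homology_span = left arm (1222) + right arm (948) = 2170 bp`.

## Ledger semantics

The ledger stores wells-seeded and clones-recovered as separate explicit
totals (a seeded well need not yield a clone). Stage definitions that are
genuinely open and were fixed here:

- **PCR pass** counts only products at the expected size; a size-shifted
  product (e.g. 416 bp from a 102 bp insertion) is recorded with its length
  but counts as a PCR failure for the funnel — the only reading under which
  the per-clone records and the stage totals are mutually consistent. Its
  digest column is `NOT_TESTED`, since digest interpretation presupposes
  the expected product.
- **Sequencing** is confirmed/sequenced-among-undigested; control
  sequencing of non-passing clones is recorded but excluded from the stage
  statistic. **Karyotype** is normal/karyotyped.
- Clones lost during expansion carry `NOT_TESTED` PCR outcomes (an
  extra enum value for rows that never reached the assay).
- Percentages are exact in JSON and rounded to two decimals in markdown;
  comparisons against externally printed two-decimal values should use an
  absolute tolerance of 0.01, which absorbs display-rounding differences
  (e.g. 12/34 = 35.294…%).

Zero denominators report `undefined` (None), never 0%. Statistics are
permutation-invariant in the row order.

## Problem sizes and numerical choices

The test suite and the acceptance script regenerate all inputs: the
full-plate check uses one 96-well plate at 960 × 960 px with 12 wells each
of Red/Green/RedGreen/Blue under σ = 50 DN read noise (5% of the planted
amplitude) plus shot noise; genotype-call accuracy is measured over 20
freshly seeded diploid pairs (5 seeds × 4 genotypes); oracle-equivalence
checks use 64 × 64 random rasters, where the dense direct convolution is
exact but affordable. All randomness flows through
`numpy.random.default_rng` seeds; every rendered plate, template and report
is reproducible from (seed, configuration), and pipeline artifacts are
stamped with a configuration hash.

## Known limitations

- The classifier operates on pre-stitched mosaics; field-of-view stitching,
  illumination correction and nucleus-level segmentation are out of scope.
- PCR is modelled as exact string matching — no melting temperature,
  mismatch tolerance or amplification efficiency.
- The genotype caller deliberately stays at the band-pattern level; it does
  not distinguish biallelic point mutation from NHEJ-derived alleles behind
  a `FULLY_DIGESTED` pattern.
- Camera bit depth behind the 125/200 DN thresholds is taken as given;
  rasters are accepted as 8–16-bit without normalisation.
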