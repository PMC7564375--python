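"""In-silico PCR, restriction digestion and genotype calling for clone triage.

The screen exploits a fortunate property of the SNCA c.88G>C (p.A30P)
point mutation: the G>C substitution converts the local context GCAGG into
CCAGG, creating an MvaI/BstNI recognition site (CCWGG, cut CC^WGG) inside
the diagnostic exon-2 amplicon.  A gene-corrected allele therefore yields an
undigested product, a retained mutant allele is cut, and a heterozygous
clone shows a double band on the gel.

This module models that assay on nucleotide strings: exact-match primer
search, amplicon extraction, IUPAC site scanning, top-strand digestion, and
a digital-gel genotype caller over a diploid pair of allele templates.  It
also models the piggyBac transposon geometry of the donor construct:
cassette integration duplicates a genomic TTAA tetranucleotide and
excision-only transposase removes the cassette together with one duplicate,
leaving a footprint-free locus.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "NucleotideSequence",
    "PrimerPair",
    "RestrictionEnzyme",
    "ENZYMES",
    "Amplicon",
    "DigestResult",
    "GenotypeCall",
    "DonorConstruct",
    "ExcisionResult",
    "AmbiguousPrimingError",
    "NonExcisableError",
    "amplify",
    "scan_sites",
    "digest",
    "merge_bands",
    "call_clone",
    "classify_edit",
    "integrate_cassette",
    "excise_cassette",
    "homology_span",
    "read_fasta",
    "write_fasta",
    "revcomp",
]

_IUPAC = {k.upper(): v.upper() for k, v in ambiguous_dna_values.items()}


class AmbiguousPrimingError(ValueError):
    """A primer matches the template at more than one position."""


class NonExcisableError(ValueError):
    """The cassette is present but not flanked by TTAA on both sides."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A named nucleotide sequence over the IUPAC alphabet."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", self.bases.upper())
        if not self.bases:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.bases) - set(_IUPAC)
        if bad:
            raise ValueError(f"sequence {self.id!r} has non-IUPAC symbols {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.bases)


def revcomp(bases: str) -> str:
    return str(Seq(bases).reverse_complement())


@dataclass(frozen=True)
class PrimerPair:
    """Diagnostic PCR primers; defaults amplify SNCA exon 2 (314 bp)."""

    forward: str = "CCCCGAAAGTTCTCATTCAA"
    reverse: str = "GCGAATCCGTCGCTGTGCAT"
    expected_product_length: int = 314

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise ValueError("both primers must be non-empty")
        if self.expected_product_length <= len(self.forward) + len(self.reverse):
            raise ValueError("expected product must be longer than the primers combined")


@dataclass(frozen=True)
class RestrictionEnzyme:
    """IUPAC recognition pattern with a top-strand cut offset.

    The default is MvaI (isoschizomer BstNI): CCWGG, cutting between the
    second C and the W (CC^WGG).
    """

    name: str = "MvaI"
    recognition: str = "CCWGG"
    cut_offset: int = 2

    def __post_init__(self) -> None:
        bad = set(self.recognition.upper()) - set(_IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC code(s) {sorted(bad)} in recognition pattern")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut_offset must lie within the recognition pattern")

    def regex(self) -> re.Pattern[str]:
        # lookahead so overlapping sites are all reported
        expanded = "".join(
            f"[{_IUPAC[c]}]" if len(_IUPAC[c]) > 1 else _IUPAC[c]
            for c in self.recognition.upper()
        )
        return re.compile(f"(?={expanded})")


#: Built-in enzyme registry; extensible through configuration.
ENZYMES: dict[str, RestrictionEnzyme] = {
    "MvaI": RestrictionEnzyme("MvaI", "CCWGG", 2),
    "BstNI": RestrictionEnzyme("BstNI", "CCWGG", 2),
}


@dataclass(frozen=True)
class Amplicon:
    """A PCR product with its template coordinates (0-based, half-open)."""

    sequence: str
    start: int
    end: int
    template_id: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("amplicon coordinates inconsistent with its sequence")


@dataclass(frozen=True)
class DigestResult:
    """Cut positions within an amplicon and the resulting fragment lengths."""

    cut_positions: tuple[int, ...]
    fragment_lengths: tuple[int, ...]

    @property
    def is_digested(self) -> bool:
        return bool(self.cut_positions)


@dataclass(frozen=True)
class GenotypeCall:
    """Digital-gel call for a diploid clone.

    ``bands`` are merged gel band sizes (bp, descending); ``observed_length``
    is set for SIZE_SHIFT calls.
    """

    label: str  # GENE_CORRECTED | HET_RETAINED | FULLY_DIGESTED | SIZE_SHIFT | NO_PRODUCT
    bands: tuple[int, ...] = ()
    amplicon_lengths: tuple[int, ...] = ()
    observed_length: int | None = None


@dataclass(frozen=True)
class DonorConstruct:
    """Knock-in donor geometry: homology arms around a TTAA-flanked cassette.

    The homology arms (1222 bp left, 948 bp right by default, 2170 bp total)
    carry the wild-type locus; the selection cassette between piggyBac
    inverted repeats integrates at a TTAA tetranucleotide and can be removed
    without a footprint.  The reporter distinguishes the two donor plasmids
    used for biallelic targeting; tagBFP on the backbone (outside the arms)
    flags random integration.
    """

    left_arm_length: int = 1222
    right_arm_length: int = 948
    cassette: str = ""
    reporter: str = "dTOMATO"
    backbone_marker: str = "tagBFP"

    def __post_init__(self) -> None:
        if self.left_arm_length < 0 or self.right_arm_length < 0:
            raise ValueError("arm lengths must be >= 0")
        if self.reporter not in ("dTOMATO", "EGFP"):
            raise ValueError("reporter must be dTOMATO or EGFP")


@dataclass(frozen=True)
class ExcisionResult:
    sequence: NucleotideSequence
    excised: bool


def homology_span(construct: DonorConstruct) -> int:
    """Total homology to the target locus: left arm + right arm, in bp."""
    return construct.left_arm_length + construct.right_arm_length


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def amplify(template: NucleotideSequence, primers: PrimerPair = PrimerPair()) -> Amplicon | None:
    """Exact-match in-silico PCR.

    The forward primer is searched on the plus strand; the reverse primer as
    its reverse complement downstream of the forward site.  The amplicon
    includes both primer sequences.  Returns ``None`` (no product) when
    either site is absent or the orientation is wrong; raises
    :class:`AmbiguousPrimingError` when either primer hits more than once.
    """
    fwd_hits = _find_all(template.bases, primers.forward.upper())
    rev_hits = _find_all(template.bases, revcomp(primers.reverse.upper()))
    if len(fwd_hits) > 1 or len(rev_hits) > 1:
        raise AmbiguousPrimingError(
            f"template {template.id!r}: forward primer at {fwd_hits}, "
            f"reverse-complement site at {rev_hits}"
        )
    if not fwd_hits or not rev_hits:
        return None
    start = fwd_hits[0]
    end = rev_hits[0] + len(primers.reverse)
    if end <= start + len(primers.forward):
        return None  # reverse site upstream of the forward primer
    return Amplicon(template.bases[start:end], start, end, template.id)


def scan_sites(seq: NucleotideSequence | str, enzyme: RestrictionEnzyme = ENZYMES["MvaI"]) -> list[int]:
    """Sorted plus-strand start positions of the recognition pattern.

    Overlapping matches are included.  For palindromic-degenerate patterns
    such as CCWGG the site set coincides on both strands, so a plus-strand
    scan is complete.
    """
    bases = seq.bases if isinstance(seq, NucleotideSequence) else seq.upper()
    return [m.start() for m in enzyme.regex().finditer(bases)]


def digest(amplicon: Amplicon, enzyme: RestrictionEnzyme = ENZYMES["MvaI"]) -> DigestResult:
    """Cut the amplicon at every recognition site (top-strand cut offsets).

    Fragment lengths are successive differences of the cut positions
    including both ends; they always sum to the amplicon length.
    """
    n = amplicon.length
    cuts = sorted(
        {s + enzyme.cut_offset for s in scan_sites(amplicon.sequence, enzyme)
         if 0 < s + enzyme.cut_offset < n}
    )
    bounds = [0, *cuts, n]
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return DigestResult(tuple(cuts), fragments)


def merge_bands(fragment_lengths: Iterable[int], resolution: int = 10) -> tuple[int, ...]:
    """Merge fragment lengths into gel bands.

    Fragments whose sizes differ by less than ``resolution`` bp are
    indistinguishable on the diagnostic gel and merge into a single band,
    reported at the largest member's size.  Bands are returned descending.
    """
    sizes = sorted(set(int(x) for x in fragment_lengths))
    bands: list[int] = []
    for s in sizes:
        if bands and s - bands[-1] < resolution:
            bands[-1] = s
        else:
            bands.append(s)
    return tuple(sorted(bands, reverse=True))


def call_clone(
    allele_a: NucleotideSequence,
    allele_b: NucleotideSequence,
    primers: PrimerPair = PrimerPair(),
    enzyme: RestrictionEnzyme = ENZYMES["MvaI"],
    band_resolution: int = 10,
) -> GenotypeCall:
    """Genotype a diploid clone from its two allele templates.

    Both alleles are amplified and digested; the pooled fragments form a
    digital gel.  Calls follow the diagnostic band-pattern vocabulary:

    * ``NO_PRODUCT``     — neither allele amplifies (primer site lost);
    * ``SIZE_SHIFT``     — a product appears at other than the expected size
      (e.g. 416 bp from a 102 bp insertion into the 314 bp amplicon);
    * ``GENE_CORRECTED`` — every product is full length and uncut
      (no recognition site: the mutation is repaired on both alleles);
    * ``HET_RETAINED``   — full-length plus shorter fragments (double band:
      one allele still carries the site);
    * ``FULLY_DIGESTED`` — no full-length band (both alleles cut).
    """
    amplicons = [a for a in (amplify(allele_a, primers), amplify(allele_b, primers)) if a]
    if not amplicons:
        return GenotypeCall("NO_PRODUCT")
    lengths = tuple(a.length for a in amplicons)
    off_size = [a for a in amplicons if a.length != primers.expected_product_length]
    if off_size:
        return GenotypeCall(
            "SIZE_SHIFT",
            bands=merge_bands(lengths, band_resolution),
            amplicon_lengths=lengths,
            observed_length=off_size[0].length,
        )
    digests = [digest(a, enzyme) for a in amplicons]
    fragments = [f for d in digests for f in d.fragment_lengths]
    bands = merge_bands(fragments, band_resolution)
    n_cut = sum(d.is_digested for d in digests)
    if n_cut == 0:
        label = "GENE_CORRECTED"
    elif n_cut == len(digests):
        label = "FULLY_DIGESTED"
    else:
        label = "HET_RETAINED"
    return GenotypeCall(label, bands=bands, amplicon_lengths=lengths)


def classify_edit(
    ref: NucleotideSequence,
    alt: NucleotideSequence,
    enzyme: RestrictionEnzyme = ENZYMES["MvaI"],
) -> str:
    """Compare recognition sites between a reference and an edited sequence.

    Returns one of ``site_created``, ``site_destroyed``, ``both`` or
    ``no_change``.  Sequences must be of equal length (pre-aligned).
    """
    if len(ref) != len(alt):
        raise ValueError(
            f"ref ({len(ref)} bp) and alt ({len(alt)} bp) differ in length; "
            "supply aligned sequences"
        )
    ref_sites = set(scan_sites(ref, enzyme))
    alt_sites = set(scan_sites(alt, enzyme))
    created = bool(alt_sites - ref_sites)
    destroyed = bool(ref_sites - alt_sites)
    if created and destroyed:
        return "both"
    if created:
        return "site_created"
    if destroyed:
        return "site_destroyed"
    return "no_change"


def integrate_cassette(
    template: NucleotideSequence, construct: DonorConstruct, site_index: int | None = None
) -> NucleotideSequence:
    """Model piggyBac integration: insert the cassette at a TTAA, duplicating it.

    ``site_index`` is the start of the target TTAA in the template (the first
    occurrence by default).  The knock-in therefore reads
    ``left + TTAA + cassette + TTAA + right``.
    """
    if not construct.cassette:
        raise ValueError("construct has an empty cassette")
    if site_index is None:
        site_index = template.bases.find("TTAA")
        if site_index == -1:
            raise ValueError(f"template {template.id!r} contains no TTAA integration site")
    if template.bases[site_index : site_index + 4] != "TTAA":
        raise ValueError(f"no TTAA at position {site_index} of {template.id!r}")
    bases = (
        template.bases[: site_index + 4]
        + construct.cassette.upper()
        + template.bases[site_index:]
    )
    return NucleotideSequence(f"{template.id}_knockin", bases)


def excise_cassette(
    knockin_seq: NucleotideSequence, construct: DonorConstruct
) -> ExcisionResult:
    """Model excision-only transposase removal of the cassette.

    The cassette and one of its duplicated TTAA flanks are removed, leaving a
    single TTAA at the junction — a footprint-free locus.  A sequence without
    the cassette is returned unchanged (``excised=False``), which makes the
    operation idempotent; a cassette without TTAA flanks is non-excisable.
    """
    cassette = construct.cassette.upper()
    if not cassette:
        raise ValueError("construct has an empty cassette")
    start = knockin_seq.bases.find(cassette)
    if start == -1:
        return ExcisionResult(knockin_seq, excised=False)
    end = start + len(cassette)
    if knockin_seq.bases[start - 4 : start] != "TTAA" or knockin_seq.bases[end : end + 4] != "TTAA":
        raise NonExcisableError(
            f"cassette in {knockin_seq.id!r} is not flanked by TTAA on both sides"
        )
    bases = knockin_seq.bases[:start] + knockin_seq.bases[end + 4 :]
    return ExcisionResult(NucleotideSequence(knockin_seq.id, bases), excised=True)


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    return [NucleotideSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, seqs: Iterable[NucleotideSequence]) -> None:
    records = [SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")
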