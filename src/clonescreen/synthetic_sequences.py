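"""Synthetic allele templates for the diagnostic PCR/digest assay.

No genomic sequence is distributed with the package: templates are built at
run time around the real assay coordinates — the diagnostic primer pair, the
expected 314 bp product, and the codon-30 locus whose G>C substitution turns
the local context GCAGG into the MvaI site CCAGG.  Filler bases are random
but scrubbed so that no accidental recognition site or extra primer-binding
site confounds the assay; two alleles built from the same seed are identical
except at the edited base, mimicking a heterozygous locus.

The position of the created site within the amplicon is a free parameter;
the default of 100 bp from the 5' end reproduces the familiar "lower band at
roughly 100 bp" of the digested mutant product.
"""

from __future__ import annotations

import re

import numpy as np

from .genotyping import NucleotideSequence, PrimerPair, RestrictionEnzyme, ENZYMES, revcomp

__all__ = [
    "make_template",
    "make_diploid_alleles",
    "make_cassette",
    "GENOTYPES",
]

#: Codon-30 5-mer context: wild-type/corrected GCAGG, c.88G>C mutant CCAGG.
_CONTEXT_REF = "GCAGG"
_CONTEXT_MUT = "CCAGG"

GENOTYPES = ("corrected", "heterozygous", "mutant", "insertion", "no_product")

_BASES = np.array(list("ACGT"))


def _scrub(
    chars: list[str],
    protected: list[tuple[int, int]],
    forbidden: list[str],
    rng: np.random.Generator,
    max_rounds: int = 200,
) -> None:
    """Mutate filler bases until no forbidden motif survives outside protected spans.

    ``forbidden`` entries are plain regex patterns (already IUPAC-expanded);
    matches found with overlap are broken by resampling one unprotected base.
    """
    def is_protected(i: int) -> bool:
        return any(a <= i < b for a, b in protected)

    pattern = re.compile("|".join(f"(?=({p}))" for p in forbidden))
    for _ in range(max_rounds):
        dirty = False
        s = "".join(chars)
        for m in pattern.finditer(s):
            grp = next(g for g in m.groups() if g)
            span = range(m.start(), m.start() + len(grp))
            free = [i for i in span if not is_protected(i)]
            if not free:
                continue  # the intended site
            dirty = True
            i = int(rng.choice(free))
            chars[i] = str(rng.choice(_BASES[_BASES != chars[i]]))
        if not dirty:
            return
    raise RuntimeError("could not scrub forbidden motifs from synthetic template")


def make_template(
    seed: int = 0,
    mutant: bool = False,
    primers: PrimerPair = PrimerPair(),
    enzyme: RestrictionEnzyme = ENZYMES["MvaI"],
    site_offset: int = 100,
    flank: int = 30,
    insertion_length: int = 0,
    drop_forward_primer: bool = False,
    seq_id: str | None = None,
) -> NucleotideSequence:
    """Build one allele template around the diagnostic amplicon.

    Layout: ``flank + forward primer + filler + codon-30 context + filler
    [+ insertion] + revcomp(reverse primer) + TTAA + flank``.  The amplicon
    (primer to primer) has length ``expected_product_length +
    insertion_length``; the codon-30 context starts ``site_offset`` bases
    into the amplicon.  Identical seeds give identical filler, so a
    mutant/corrected pair from one seed differs at exactly one base.

    ``drop_forward_primer`` replaces the forward primer site with filler,
    modelling an allele on which the PCR fails.

    The template is always assembled and scrubbed with the reference
    context; the mutant allele is derived afterwards by the single G>C
    substitution.  A same-seed mutant/corrected pair therefore differs at
    exactly the edited base, and the substitution creates exactly one
    recognition site (no window overlapping the context can form CCWGG
    other than the context itself).
    """
    rng = np.random.default_rng(seed)
    fwd = primers.forward.upper()
    rc_rev = revcomp(primers.reverse.upper())
    inner = primers.expected_product_length - len(fwd) - len(rc_rev)
    if not len(fwd) <= site_offset <= primers.expected_product_length - len(rc_rev) - 5:
        raise ValueError("site_offset must place the codon-30 context between the primers")
    pre = site_offset - len(fwd)  # filler before the context, inside the amplicon
    post = inner - pre - 5 + insertion_length

    def rand(n: int) -> str:
        return "".join(rng.choice(_BASES, size=n))

    parts = [rand(flank), fwd, rand(pre), _CONTEXT_REF, rand(post), rc_rev, "TTAA", rand(flank)]
    chars = list("".join(parts))

    off = flank  # running offsets of the protected spans
    fwd_span = (off, off + len(fwd))
    ctx_start = flank + site_offset
    ctx_span = (ctx_start, ctx_start + 5)
    rc_start = flank + len(fwd) + inner + insertion_length
    rc_span = (rc_start, rc_start + len(rc_rev))
    protected = [fwd_span, ctx_span, rc_span]

    forbidden = [
        "CC[AT]GG",  # stray recognition sites
        re.escape(fwd),
        re.escape(rc_rev),
        re.escape(revcomp(fwd)),
        re.escape(primers.reverse.upper()),
    ]
    _scrub(chars, protected, forbidden, rng)

    if mutant:
        chars[ctx_start] = _CONTEXT_MUT[0]

    if drop_forward_primer:
        replacement = list(rand(len(fwd)))
        chars[fwd_span[0] : fwd_span[1]] = replacement
        _scrub(chars, [ctx_span, rc_span], forbidden, rng)

    if seq_id is None:
        seq_id = f"synthetic_allele_{'mut' if mutant else 'ref'}_{seed}"
    return NucleotideSequence(seq_id, "".join(chars))


def make_diploid_alleles(
    genotype: str,
    seed: int = 0,
    primers: PrimerPair = PrimerPair(),
    site_offset: int = 100,
    insertion_length: int = 102,
) -> tuple[NucleotideSequence, NucleotideSequence]:
    """Build a pair of allele templates realising one clone genotype.

    ``corrected``     — both alleles carry the repaired context (no site);
    ``heterozygous``  — one repaired, one mutant allele (double band);
    ``mutant``        — both alleles carry the created site;
    ``insertion``     — one allele with an in-amplicon insertion
    (default 102 bp, giving a 416 bp product from the 314 bp assay);
    ``no_product``    — forward primer site lost on both alleles.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; choose from {GENOTYPES}")
    kw = dict(seed=seed, primers=primers, site_offset=site_offset)
    if genotype == "corrected":
        pair = (make_template(mutant=False, **kw), make_template(mutant=False, **kw))
    elif genotype == "heterozygous":
        pair = (make_template(mutant=False, **kw), make_template(mutant=True, **kw))
    elif genotype == "mutant":
        pair = (make_template(mutant=True, **kw), make_template(mutant=True, **kw))
    elif genotype == "insertion":
        pair = (
            make_template(mutant=False, insertion_length=insertion_length, **kw),
            make_template(mutant=False, **kw),
        )
    else:  # no_product
        pair = (
            make_template(mutant=True, drop_forward_primer=True, **kw),
            make_template(mutant=True, drop_forward_primer=True, **kw),
        )
    a, b = pair
    return (
        NucleotideSequence(f"{genotype}_{seed}_a", a.bases),
        NucleotideSequence(f"{genotype}_{seed}_b", b.bases),
    )


def make_cassette(seed: int = 0, length: int = 300) -> str:
    """Random selection-cassette sequence for integration/excision models.

    Kept free of the diagnostic primer sites and of TTAA so that cassette
    boundaries and the duplicated integration site stay unambiguous.
    """
    rng = np.random.default_rng(seed)
    chars = list("".join(rng.choice(_BASES, size=length)))
    primers = PrimerPair()
    forbidden = [
        "TTAA",
        re.escape(primers.forward),
        re.escape(revcomp(primers.reverse)),
    ]
    _scrub(chars, [], forbidden, rng)
    return "".join(chars)
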