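"""In-silico PCR, site scanning, digestion, and the digital-gel caller."""

import numpy as np
import pytest
from Bio.Restriction import BstNI
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from clonescreen.genotyping import (
    ENZYMES,
    Amplicon,
    AmbiguousPrimingError,
    DonorConstruct,
    NonExcisableError,
    NucleotideSequence,
    PrimerPair,
    RestrictionEnzyme,
    amplify,
    call_clone,
    classify_edit,
    digest,
    excise_cassette,
    homology_span,
    integrate_cassette,
    merge_bands,
    read_fasta,
    revcomp,
    scan_sites,
    write_fasta,
)
from clonescreen.synthetic_sequences import make_cassette, make_diploid_alleles, make_template

PRIMERS = PrimerPair()
MVAI = ENZYMES["MvaI"]

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


def _seq(bases, sid="s"):
    return NucleotideSequence(sid, bases)


class TestAmplify:
    def test_constructed_template_yields_expected_length(self):
        rng = np.random.default_rng(0)
        filler = "".join(rng.choice(list("ACGT"), 274))
        tpl = _seq("GG" + PRIMERS.forward + filler + revcomp(PRIMERS.reverse) + "AA")
        amp = amplify(tpl, PRIMERS)
        assert amp.length == 314
        assert amp.sequence.startswith(PRIMERS.forward)
        assert amp.sequence.endswith(revcomp(PRIMERS.reverse))
        assert amp.end - amp.start == 314

    def test_insertion_shifts_product_size(self):
        tpl = make_template(seed=1, insertion_length=102)
        assert amplify(tpl, PRIMERS).length == 416

    def test_missing_reverse_site_gives_no_product(self):
        tpl = _seq(PRIMERS.forward + "ACGT" * 50)
        assert amplify(tpl, PRIMERS) is None

    def test_wrong_orientation_gives_no_product(self):
        tpl = _seq(revcomp(PRIMERS.reverse) + "ACGT" * 50 + PRIMERS.forward)
        assert amplify(tpl, PRIMERS) is None

    def test_multiple_priming_sites_raise(self):
        base = make_template(seed=2).bases
        with pytest.raises(AmbiguousPrimingError, match="forward"):
            amplify(_seq(base + base), PRIMERS)


class TestScanSites:
    @pytest.mark.parametrize("bases, sites", [
        ("CCAGG", [0]),
        ("CCTGG", [0]),
        ("GCAGG", []),
        ("CCAGGCCTGG", [0, 5]),
        ("CCCTGG", [1]),
    ])
    def test_pattern_scan(self, bases, sites):
        assert scan_sites(bases, MVAI) == sites

    def test_codon30_context_gains_a_site_on_g_to_c(self):
        wild = "TTTGCAGGTTT"
        mutant = wild.replace("GCAGG", "CCAGG")
        assert scan_sites(wild, MVAI) == []
        assert scan_sites(mutant, MVAI) == [3]

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strand_symmetry_of_ccwgg(self, seed):
        rng = np.random.default_rng(seed)
        bases = "".join(rng.choice(list("ACGT"), 120))
        assert len(scan_sites(bases, MVAI)) == len(scan_sites(revcomp(bases), MVAI))

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_cut_positions_agree_with_biopython(self, seed):
        """Independent cross-check of site scan + cut offset against Bio.Restriction."""
        rng = np.random.default_rng(seed)
        bases = "".join(rng.choice(list("ACGT"), 200))
        ours = [s + MVAI.cut_offset for s in scan_sites(bases, MVAI)]
        theirs = [p - 1 for p in BstNI.search(Seq(bases))]  # 1-based -> 0-based
        assert ours == theirs

    def test_invalid_iupac_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            RestrictionEnzyme("bad", "CCQGG", 2)


class TestDigest:
    def _amplicon(self, bases):
        return Amplicon(bases, 0, len(bases))

    def test_no_sites_means_undigested(self):
        tpl = make_template(seed=3, mutant=False)
        res = digest(amplify(tpl, PRIMERS), MVAI)
        assert res.fragment_lengths == (314,)
        assert not res.is_digested

    def test_single_cut_fragments(self):
        tpl = make_template(seed=3, mutant=True, site_offset=98)
        res = digest(amplify(tpl, PRIMERS), MVAI)
        assert res.cut_positions == (100,)
        assert sorted(res.fragment_lengths) == [100, 214]

    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(10, 400))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_fragments_sum_to_length_and_count_cuts(self, seed, n):
        rng = np.random.default_rng(seed)
        amp = self._amplicon("".join(rng.choice(list("ACGT"), n)))
        res = digest(amp, MVAI)
        assert sum(res.fragment_lengths) == n
        assert len(res.fragment_lengths) == len(res.cut_positions) + 1

    def test_two_cuts_arithmetic(self):
        bases = "A" * 98 + "CCAGG" + "A" * 95 + "CCTGG" + "A" * 111  # cuts at 100 and 200
        res = digest(self._amplicon(bases), MVAI)
        assert res.cut_positions == (100, 200)
        assert res.fragment_lengths == (100, 100, 114)


def test_merge_bands_resolution():
    assert merge_bands([314, 314]) == (314,)
    assert merge_bands([100, 105, 214]) == (214, 105)  # 100 and 105 co-migrate
    assert merge_bands([100, 214, 314], resolution=10) == (314, 214, 100)


class TestCallClone:
    @pytest.mark.parametrize("genotype, label", [
        ("corrected", "GENE_CORRECTED"),
        ("heterozygous", "HET_RETAINED"),
        ("mutant", "FULLY_DIGESTED"),
        ("no_product", "NO_PRODUCT"),
    ])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_outcome_vocabulary(self, genotype, label, seed):
        a, b = make_diploid_alleles(genotype, seed=seed)
        assert call_clone(a, b, PRIMERS, MVAI).label == label

    def test_heterozygous_shows_double_band(self):
        a, b = make_diploid_alleles("heterozygous", seed=4)
        call = call_clone(a, b, PRIMERS, MVAI)
        assert 314 in call.bands and len(call.bands) == 3  # full length + two fragments

    def test_insertion_reports_size_shift_416(self):
        a, b = make_diploid_alleles("insertion", seed=4)
        call = call_clone(a, b, PRIMERS, MVAI)
        assert call.label == "SIZE_SHIFT" and call.observed_length == 416

    def test_correcting_the_mutant_base_flips_het_to_corrected(self):
        """Round trip: repairing c.88G>C on the mutant allele gives an undigested pair."""
        ref, mut = make_diploid_alleles("heterozygous", seed=5)
        assert call_clone(ref, mut, PRIMERS, MVAI).label == "HET_RETAINED"
        diff = [i for i, (x, y) in enumerate(zip(ref.bases, mut.bases)) if x != y]
        assert len(diff) == 1
        repaired = NucleotideSequence("repaired", ref.bases)
        assert call_clone(ref, repaired, PRIMERS, MVAI).label == "GENE_CORRECTED"


class TestClassifyEdit:
    def test_g_to_c_substitution_creates_site(self):
        ref = make_template(seed=6, mutant=False)
        alt = make_template(seed=6, mutant=True)
        assert classify_edit(ref, alt, MVAI) == "site_created"
        assert classify_edit(alt, ref, MVAI) == "site_destroyed"

    def test_identity_is_no_change(self):
        ref = make_template(seed=6)
        assert classify_edit(ref, ref, MVAI) == "no_change"

    def test_small_examples(self):
        assert classify_edit(_seq("CCAGG"), _seq("CAAGG"), MVAI) == "site_destroyed"
        assert classify_edit(_seq("GCAGG"), _seq("CCAGG"), MVAI) == "site_created"

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            classify_edit(_seq("ACGT"), _seq("ACGTA"), MVAI)


class TestExcision:
    def setup_method(self):
        self.template = make_template(seed=7)
        self.construct = DonorConstruct(cassette=make_cassette(seed=7))

    def test_knockin_then_excision_restores_template(self):
        ki = integrate_cassette(self.template, self.construct)
        assert self.construct.cassette in ki.bases
        res = excise_cassette(ki, self.construct)
        assert res.excised
        assert res.sequence.bases == self.template.bases  # footprint-free, one TTAA left

    def test_excision_is_idempotent(self):
        ki = integrate_cassette(self.template, self.construct)
        once = excise_cassette(ki, self.construct)
        twice = excise_cassette(once.sequence, self.construct)
        assert not twice.excised
        assert twice.sequence.bases == once.sequence.bases

    def test_sequence_without_cassette_returned_unchanged(self):
        res = excise_cassette(self.template, self.construct)
        assert not res.excised and res.sequence.bases == self.template.bases

    def test_cassette_without_ttaa_flanks_is_non_excisable(self):
        bad = _seq("GGGG" + self.construct.cassette + "GGGG")
        with pytest.raises(NonExcisableError):
            excise_cassette(bad, self.construct)


@pytest.mark.parametrize("left, right, span", [(1222, 948, 2170), (0, 0, 0), (1, 2, 3)])
def test_homology_span(left, right, span):
    assert homology_span(DonorConstruct(left_arm_length=left, right_arm_length=right)) == span


def test_fasta_round_trip(tmp_path):
    seqs = [make_template(seed=8), make_template(seed=8, mutant=True)]
    path = tmp_path / "alleles.fasta"
    write_fasta(path, seqs)
    back = read_fasta(path)
    assert [(s.id, s.bases) for s in back] == [(s.id, s.bases) for s in seqs]
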