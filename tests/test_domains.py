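import numpy as np
import pytest
from Bio.Seq import Seq

from ltrdyn.domains import (REQUIRED_DOMAINS, DomainLibrary, DomainLibraryEntry,
                            bundled_library, call_intact, read_domain_library,
                            scan_gag_pol, six_frame_translations,
                            write_domain_library)
from ltrdyn.model import GenomicInterval, LTRCandidate
from ltrdyn.simulate import _CODONS

from conftest import random_dna


@pytest.fixture(scope="module")
def library():
    return bundled_library(clades=("Del", "Sire"))


def encode(protein):
    return "".join(_CODONS[a] for a in protein)


def smith_waterman_score(a, b, matrix, gap_open=-11, gap_extend=-1):
    """Plain O(nm) affine-gap local alignment, independent of Bio.Align."""
    n, m = len(a), len(b)
    neg = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)
    F = np.full((n + 1, m + 1), neg)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] + gap_extend, H[i][j - 1] + gap_open)
            F[i][j] = max(F[i - 1][j] + gap_extend, H[i - 1][j] + gap_open)
            s = matrix[a[i - 1]][b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestScan:
    def test_planted_exact_domain_recovered(self, library, rng):
        rt = next(e for e in library.entries
                  if e.domain_name == "RT" and e.clade_label == "Del")
        coding = encode(rt.sequence)
        dna = random_dna(rng, 100) + coding + random_dna(rng, 200)
        hits = scan_gag_pol(dna, library)
        top = hits[0]
        assert top.domain_name == "RT" and top.clade_label == "Del"
        assert top.identity == 100.0
        assert top.query_coverage == 1.0
        assert top.frame == 2  # offset 100 -> second forward frame
        assert (top.location.start, top.location.end) == (100, 100 + len(coding))

    def test_random_sequence_yields_no_hits(self, library, rng):
        assert scan_gag_pol(random_dna(rng, 5000), library) == []

    def test_no_hit_agrees_with_independent_smith_waterman(self, rng):
        # brute-force local alignment over all frames confirms nothing in a
        # random 600-bp sequence approaches the E-value threshold
        from Bio.Align import substitution_matrices
        from ltrdyn.align import e_value
        lib = DomainLibrary([DomainLibraryEntry("RT", "Del", "Gypsy",
                                                bundled_library().entries[2].sequence[:80])])
        dna = random_dna(rng, 600)
        m = substitution_matrices.load("BLOSUM62")
        mat = {a: {b: m[a, b] for b in m.alphabet} for a in m.alphabet}
        best = max(
            smith_waterman_score(prot.replace("*", "X"),
                                 lib.entries[0].sequence, mat)
            for _, _, prot in six_frame_translations(dna))
        assert e_value(best, 200, 80, protein=True) > 1e-8
        assert scan_gag_pol(dna, lib) == []

    def test_coverage_threshold_boundary(self, library, rng):
        rt = next(e for e in library.entries
                  if e.domain_name == "RT" and e.clade_label == "Del")
        partial = encode(rt.sequence[:100])  # 40% of the 250-aa exemplar
        dna = random_dna(rng, 99) + partial + random_dna(rng, 99)
        assert scan_gag_pol(dna, library, min_coverage=0.5) == []
        hits = scan_gag_pol(dna, library, min_coverage=0.3)
        assert hits and hits[0].domain_name == "RT"

    def test_reverse_complement_mirrors_hits(self, library, rng):
        gag = next(e for e in library.entries
                   if e.domain_name == "GAG" and e.clade_label == "Sire")
        dna = random_dna(rng, 60) + encode(gag.sequence) + random_dna(rng, 60)
        fwd = scan_gag_pol(dna, library)
        rev = scan_gag_pol(str(Seq(dna).reverse_complement()), library)
        assert [h.domain_name for h in fwd] == [h.domain_name for h in rev]
        n = len(dna)
        for hf, hr in zip(fwd, rev):
            assert hr.frame == -hf.frame if hf.frame > 0 else hr.frame == -hf.frame
            assert (hr.location.start, hr.location.end) == \
                (n - hf.location.end, n - hf.location.start)

    def test_short_dna_and_empty_library_error(self, library):
        with pytest.raises(ValueError):
            scan_gag_pol("AC", library)
        with pytest.raises(ValueError):
            DomainLibrary([])


class TestCallIntact:
    def _candidate(self):
        return LTRCandidate(
            "e1", GenomicInterval("c", 0, 500),
            GenomicInterval("c", 5500, 6000),
            GenomicInterval("c", 500, 5500), 95.0)

    def _hit(self, name, clade="Del", start=600):
        from ltrdyn.model import DomainHit
        return DomainHit(name, clade, 1.0, 99.0, 100.0, 1e-30, 1,
                         GenomicInterval("c", start, start + 300))

    def test_all_five_domains_make_intact(self):
        hits = [self._hit(n, start=600 + 400 * i)
                for i, n in enumerate(("GAG", "PR", "RT", "RH", "INT"))]
        call = call_intact(self._candidate(), hits)
        assert call.is_intact
        assert call.best_clade == "Del"

    def test_partial_domain_set_not_intact(self):
        call = call_intact(self._candidate(),
                           [self._hit("RT"), self._hit("INT", start=1000)])
        assert not call.is_intact
        assert call.domains_found == {"RT", "INT"}

    def test_required_domains_configurable(self):
        call = call_intact(self._candidate(), [self._hit("RT")],
                           required_domains=frozenset({"RT"}))
        assert call.is_intact

    def test_hit_outside_internal_region_errors(self):
        with pytest.raises(ValueError):
            call_intact(self._candidate(), [self._hit("RT", start=5400)])

    def test_modal_clade_tie_breaks_lexicographically(self):
        hits = [self._hit("RT", "Tat"), self._hit("INT", "Del", start=1000)]
        assert call_intact(self._candidate(), hits).best_clade == "Del"


def test_library_round_trip(tmp_path, library):
    p = tmp_path / "lib.faa"
    write_domain_library(library, p)
    back = read_domain_library(p)
    assert [(e.domain_name, e.clade_label, e.superfamily, e.sequence)
            for e in back.entries] == \
        [(e.domain_name, e.clade_label, e.superfamily, e.sequence)
         for e in library.entries]
    assert REQUIRED_DOMAINS == {e.domain_name for e in back.entries}
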