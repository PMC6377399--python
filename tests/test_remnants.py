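import numpy as np
import pytest

from ltrdyn.detect import find_ltr_candidates
from ltrdyn.domains import bundled_library, scan_gag_pol, call_intact
from ltrdyn.model import (AMBIGUOUS, SOLO, TRUNCATED, GenomeSequence,
                          GenomicInterval, LTRCandidate, LTRHomolog,
                          RemnantCall)
from ltrdyn.remnants import (HomologyParams, classify_all, classify_remnant,
                             find_ltr_homologs)
from ltrdyn.simulate import _CODONS, evolve_sequence

from conftest import random_dna


@pytest.fixture(scope="module")
def library():
    return bundled_library(clades=("Del",))


def build_genome(rng, extra_parts, library=None):
    """One intact element plus caller-supplied extra loci, 16 kb apart."""
    ltr = random_dna(rng, 500)
    if library is not None:
        gag_pol = "".join("".join(_CODONS[a] for a in e.sequence)
                          for e in library.entries)
        internal = gag_pol + random_dna(rng, 5000 - len(gag_pol)) \
            if len(gag_pol) < 5000 else gag_pol
    else:
        internal = random_dna(rng, 5000)
    parts = [random_dna(rng, 16000), "ACGTA" + ltr + internal + ltr + "ACGTA"]
    extra_coords = []
    for make in extra_parts:
        parts.append(random_dna(rng, 16000))
        extra_coords.append(sum(len(p) for p in parts))
        parts.append(make(ltr, internal))
    parts.append(random_dna(rng, 16000))
    return GenomeSequence("chr1", "".join(parts)), ltr, internal, extra_coords


def detect_intact(genome):
    cands = find_ltr_candidates(genome)
    assert cands, "intact element must be detectable"
    return cands


class TestFindHomologs:
    def test_intact_loci_masked_and_extra_copy_found(self, rng):
        g, ltr, internal, coords = build_genome(
            rng, [lambda l, i: l])  # one exact solo copy of the LTR
        intact = detect_intact(g)
        homs = find_ltr_homologs(g, intact)
        assert len(homs) == 1
        h = homs[0]
        assert h.identity == pytest.approx(100.0)
        assert h.overlap == pytest.approx(1.0)
        assert (h.location.start, h.location.end) == (coords[0], coords[0] + 500)
        assert h.source_element_id == intact[0].element_id
        span = intact[0].span
        assert not h.location.overlaps(span)

    def test_identity_threshold_uses_realized_identity(self, rng):
        # plant a copy with 8% of positions mutated: realized global
        # identity stays above 90 -> accepted; 14% mutated -> rejected
        def mutate(frac):
            def make(l, i):
                arr = np.array(list(l))
                k = int(frac * len(l))
                for idx in rng.choice(len(l), k, replace=False):
                    arr[idx] = rng.choice([b for b in "ACGT" if b != arr[idx]])
                return "".join(arr)
            return make

        g, *_ = build_genome(rng, [mutate(0.08)])
        assert len(find_ltr_homologs(g, detect_intact(g))) == 1
        g2, *_ = build_genome(rng, [mutate(0.14)])
        assert find_ltr_homologs(g2, detect_intact(g2)) == []

    def test_truncated_copy_fails_overlap(self, rng):
        g, *_ = build_genome(rng, [lambda l, i: l[:400]])  # 80% of the LTR
        assert find_ltr_homologs(g, detect_intact(g)) == []

    def test_no_intact_elements_is_error(self, rng):
        g = GenomeSequence("chr1", random_dna(rng, 10000))
        with pytest.raises(ValueError):
            find_ltr_homologs(g, [])


class TestClassify:
    def test_planted_solo_and_truncated(self, rng, library):
        g, ltr, internal, coords = build_genome(
            rng,
            [lambda l, i: l,                       # fragmentation solo
             lambda l, i: l + i[:3000],            # 5' LTR + internal prefix
             lambda l, i: "GATCA" + l + "GATCA"],  # recombination solo + TSD
            library=library)
        intact = detect_intact(g)
        homs = find_ltr_homologs(g, intact)
        assert len(homs) == 3
        calls = classify_all(g, homs, library)
        by_start = sorted(zip(homs, calls), key=lambda hc: hc[0].location.start)
        frag, trunc, recomb = [c for _, c in by_start]
        assert frag.category == SOLO and frag.tsd is None
        assert trunc.category == TRUNCATED
        assert trunc.downstream_gagpol and not trunc.upstream_gagpol
        assert recomb.category == SOLO
        assert recomb.tsd == "GATCA"

    def test_upstream_fragment_flags_upstream(self, rng, library):
        g, *_ = build_genome(rng, [lambda l, i: i[-3000:] + l], library=library)
        intact = detect_intact(g)
        homs = find_ltr_homologs(g, intact)
        calls = classify_all(g, homs, library)
        assert calls[0].category == TRUNCATED
        assert calls[0].upstream_gagpol and not calls[0].downstream_gagpol

    def test_gagpol_both_sides_is_ambiguous(self, rng, library):
        g, *_ = build_genome(rng, [lambda l, i: i[-2000:] + l + i[:2000]],
                             library=library)
        intact = detect_intact(g)
        homs = find_ltr_homologs(g, intact)
        calls = classify_all(g, homs, library)
        assert calls[0].category == AMBIGUOUS

    def test_category_partition_is_exclusive(self, small_sim):
        _, (genome, truth, lib, _) = small_sim
        cands = find_ltr_candidates(genome)
        intact = [c for c in cands if call_intact(
            c, scan_gag_pol(genome.residues[c.internal.start:c.internal.end],
                            lib, seq_id=genome.seq_id,
                            offset=c.internal.start)).is_intact]
        homs = find_ltr_homologs(genome, intact)
        calls = classify_all(genome, homs, lib)
        assert len(calls) == len(homs)
        for c in calls:
            assert c.category in (SOLO, TRUNCATED, AMBIGUOUS)
        for h in homs:
            assert not any(h.location.overlaps(e.span) for e in intact)

    def test_homolog_spanning_whole_sequence_errors(self, rng, library):
        seq = random_dna(rng, 500)
        g = GenomeSequence("c", seq)
        h = LTRHomolog("h1", GenomicInterval("c", 0, 500), "e1", 100.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            classify_remnant(g, h, library)


def test_remnant_call_invariant_enforced():
    with pytest.raises(ValueError):
        RemnantCall("h", SOLO, upstream_gagpol=True, downstream_gagpol=False)
    call = RemnantCall("h", TRUNCATED, upstream_gagpol=True,
                       downstream_gagpol=False)
    assert call.category == TRUNCATED
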