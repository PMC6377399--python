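"""Genome-wide LTR homolog search and solo/truncated classification.

Each intact element's 5'-LTR is searched against the genome (with all
intact-element loci masked); hits passing the homology thresholds
(E <= 1e-10, >= 90% of the query LTR aligned, >= 90% identity) become LTR
homologs. For each homolog, 3 kb of flanking sequence on each side is
scanned for Gag-Pol protein homology: no hit on either side = solo-LTR,
a hit on exactly one side = truncated LTR-RT. Hits on both sides mark an
unannotated intact-like locus and are reported as AMBIGUOUS, outside the
S and T tallies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .align import e_value, local_align
from .detect import DetectionParams, tsd_at
from .domains import DomainLibrary, has_gag_pol
from .model import (AMBIGUOUS, SOLO, TRUNCATED, GenomeSequence,
                    GenomicInterval, LTRCandidate, LTRHomolog, RemnantCall)


@dataclass
class HomologyParams:
    max_evalue: float = 1e-10
    min_overlap: float = 0.90   # fraction of the query LTR length aligned
    min_identity: float = 90.0
    flank_len: int = 3000
    seed_len: int = 16

    def __post_init__(self) -> None:
        if not 0 < self.min_overlap <= 1:
            raise ValueError("min_overlap must be in (0, 1]")
        if not 0 < self.min_identity <= 100:
            raise ValueError("min_identity must be in (0, 100]")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")


def _genome_kmer_index(genome: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for j in range(len(genome) - k + 1):
        kmer = genome[j:j + k]
        if "N" not in kmer:
            index.setdefault(kmer, []).append(j)
    return index


def _seed_windows(genome_index: dict[str, list[int]], genome_len: int,
                  query: str, k: int) -> list[tuple[int, int]]:
    """Candidate genome windows sharing an exact k-mer with the query,
    grouped by alignment offset (genome position minus query position)."""
    offsets: set[int] = set()
    for i in range(len(query) - k + 1):
        for j in genome_index.get(query[i:i + k], ()):
            offsets.add(j - i)
    # merge nearby offsets into windows around [offset, offset + len(query))
    windows: list[tuple[int, int]] = []
    pad = max(50, len(query) // 10)
    for off in sorted(offsets):
        s = max(0, off - pad)
        e = min(genome_len, off + len(query) + pad)
        if windows and s <= windows[-1][1]:
            windows[-1] = (windows[-1][0], max(windows[-1][1], e))
        else:
            windows.append((s, e))
    return windows


def find_ltr_homologs(genome: GenomeSequence,
                      intact_elements: Sequence[LTRCandidate],
                      params: HomologyParams | None = None) -> list[LTRHomolog]:
    """Find homologs of intact elements' 5'-LTRs outside intact loci.

    Overlapping hits from different source elements are merged: the best
    scoring source wins (ties: higher identity, then longer alignment,
    then lowest source element id), so no locus is double counted.
    """
    if not intact_elements:
        raise ValueError("no intact elements: remnant classification undefined")
    params = params or HomologyParams()
    seq = genome.residues
    masked = [el.span for el in intact_elements if el.seq_id == genome.seq_id]

    index = _genome_kmer_index(seq, params.seed_len)
    raw: list[tuple[float, float, int, str, int, int, float, float]] = []
    for el in sorted(intact_elements, key=lambda e: e.element_id):
        if el.seq_id != genome.seq_id:
            continue
        ltr = seq[el.five_prime_ltr.start:el.five_prime_ltr.end]
        for ws, we in _seed_windows(index, len(seq), ltr, params.seed_len):
            summ = local_align(seq[ws:we], ltr)
            if summ.columns == 0:
                continue
            overlap = summ.query_aligned / len(ltr)
            ev = e_value(summ.score, len(seq), len(ltr), protein=False)
            if (overlap < params.min_overlap or summ.identity < params.min_identity
                    or ev > params.max_evalue):
                continue
            # extend to the full query extent: local alignment trims
            # mismatching terminal bases, which would misplace the element
            # boundary (and any anchored TSD) by a few bp
            q0, q1 = summ.query_range
            hs = max(0, ws + summ.target_range[0] - q0)
            he = min(len(seq), ws + summ.target_range[1] + (len(ltr) - q1))
            hit_iv = GenomicInterval(genome.seq_id, hs, he)
            if any(hit_iv.overlaps(m) for m in masked):
                continue
            raw.append((summ.score, summ.identity, summ.columns,
                        el.element_id, hs, he, overlap, ev))

    # merge overlapping hits: best (score, identity, length, id) wins
    raw.sort(key=lambda t: (-t[0], -t[1], -t[2], t[3], t[4]))
    kept: list[tuple[float, float, int, str, int, int, float, float]] = []
    occupied: list[tuple[int, int]] = []
    for hit in raw:
        hs, he = hit[4], hit[5]
        if any(hs < e and s < he for s, e in occupied):
            continue
        occupied.append((hs, he))
        kept.append(hit)
    kept.sort(key=lambda t: t[4])
    out = []
    for idx, (score, identity, _cols, src, hs, he, overlap, ev) in enumerate(kept, 1):
        out.append(LTRHomolog(
            homolog_id=f"{genome.seq_id}_hom{idx:04d}",
            location=GenomicInterval(genome.seq_id, hs, he),
            source_element_id=src, identity=identity, overlap=overlap, e_value=ev,
        ))
    return out


def classify_remnant(genome: GenomeSequence, homolog: LTRHomolog,
                     library: DomainLibrary,
                     params: HomologyParams | None = None,
                     min_coverage: float = 0.5, min_identity: float = 30.0,
                     max_evalue: float = 1e-8,
                     detection_params: DetectionParams | None = None) -> RemnantCall:
    """Classify one LTR homolog from Gag-Pol evidence in its 3-kb flanks.

    Flanks are clipped at sequence boundaries; a homolog spanning the whole
    sequence (both flanks empty) is an error. The TSD is looked up with the
    same anchored semantics as structural detection and kept descriptive.
    """
    params = params or HomologyParams()
    seq = genome.residues
    loc = homolog.location
    up = seq[max(0, loc.start - params.flank_len):loc.start]
    down = seq[loc.end:loc.end + params.flank_len]
    if not up and not down:
        raise ValueError(f"homolog {homolog.homolog_id} spans the whole sequence")
    kw = dict(min_coverage=min_coverage, min_identity=min_identity,
              max_evalue=max_evalue)
    up_hit = len(up) >= 3 and has_gag_pol(up, library, **kw)
    down_hit = len(down) >= 3 and has_gag_pol(down, library, **kw)
    n = int(up_hit) + int(down_hit)
    category = {0: SOLO, 1: TRUNCATED, 2: AMBIGUOUS}[n]
    tsd = tsd_at(seq, loc.start, loc.end, detection_params or DetectionParams())
    return RemnantCall(homolog.homolog_id, category, up_hit, down_hit, tsd)


def classify_all(genome: GenomeSequence, homologs: Sequence[LTRHomolog],
                 library: DomainLibrary, params: HomologyParams | None = None,
                 **scan_thresholds) -> list[RemnantCall]:
    return [classify_remnant(genome, h, library, params, **scan_thresholds)
            for h in homologs]
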