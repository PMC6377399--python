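"""De novo structural detection of LTR retrotransposon candidates.

The detector looks for pairs of near-identical direct repeats (the two
LTRs) whose geometry matches the structural rules used for plant LTR-RT
annotation: each LTR 100-3,000 bp, element span 1-15 kb, LTR-LTR identity
above 80%, and an optional 4-6 bp target site duplication (TSD) anchored
exactly at the element boundaries.

Algorithm: exact k-mer seeds shared between two genome positions are
grouped by diagonal (the distance between the two copies); each seed run
is extended into the maximal-scoring matching segment along that diagonal
(match +1 / mismatch -2), which delimits the repeat pair; boundaries are
then refined by searching a small window for an anchored TSD; finally the
two LTR sequences are globally aligned to obtain the reported identity.
Overlapping candidates are resolved by identity, then length, then
leftmost position, which also guarantees that no reported candidate is
contained in another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .align import global_align
from .model import GenomeSequence, GenomicInterval, LTRCandidate


@dataclass
class DetectionParams:
    """Structural constraints for candidate LTR-RTs (lengths in bp)."""

    min_ltr_len: int = 100
    max_ltr_len: int = 3000
    min_element_span: int = 1000
    max_element_span: int = 15000
    min_ltr_identity: float = 80.0
    tsd_min: int = 4
    tsd_max: int = 6
    tsd_search_window: int = 20
    seed_len: int = 20
    max_kmer_occurrences: int = 200  # skip hyper-repetitive seeds

    def __post_init__(self) -> None:
        for lo, hi, name in (
            (self.min_ltr_len, self.max_ltr_len, "ltr_len"),
            (self.min_element_span, self.max_element_span, "element_span"),
            (self.tsd_min, self.tsd_max, "tsd"),
        ):
            if not 0 < lo <= hi:
                raise ValueError(f"invalid {name} bounds [{lo}, {hi}]")
        if not 0 < self.min_ltr_identity <= 100:
            raise ValueError("min_ltr_identity must be in (0, 100]")
        if self.seed_len < 8:
            raise ValueError("seed_len must be >= 8")


def _seed_diagonals(seq: str, params: DetectionParams) -> dict[int, list[int]]:
    """Map diagonal d (= start distance between the two copies) to the
    positions of exact seed matches (position of the left copy)."""
    k = params.seed_len
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    diagonals: dict[int, list[int]] = {}
    d_min = params.min_ltr_len
    d_max = params.max_element_span
    for positions in index.values():
        m = len(positions)
        if m < 2 or m > params.max_kmer_occurrences:
            continue
        for a in range(m - 1):
            pa = positions[a]
            for b in range(a + 1, m):
                d = positions[b] - pa
                if d > d_max:
                    break
                if d >= d_min:
                    diagonals.setdefault(d, []).append(pa)
    return diagonals


def _max_scoring_segment(match: np.ndarray,
                         match_score: float = 1.0,
                         mismatch_score: float = -2.0) -> tuple[int, int]:
    """Kadane maximal-scoring contiguous segment [start, end) over a
    boolean match array; empty segment when no positive score exists."""
    score = np.where(match, match_score, mismatch_score)
    c = np.concatenate(([0.0], np.cumsum(score)))
    run_min = np.minimum.accumulate(c[:-1])
    gains = c[1:] - run_min
    end = int(np.argmax(gains)) + 1
    if gains[end - 1] <= 0:
        return 0, 0
    start = int(np.argmin(c[:end]))
    return start, end


def _trim_to_clean_runs(match: np.ndarray, s: int, e: int,
                        run: int = 4) -> tuple[int, int]:
    """Shrink segment [s, e) so each end starts with ``run`` consecutive
    matches, discarding chance single-base extensions beyond the repeat."""
    while e - s >= run and not match[s:s + run].all():
        s += 1
    while e - s >= run and not match[e - run:e].all():
        e -= 1
    return (s, e) if e - s >= run else (s, s)


def _refine_with_tsd(seq: str, x0: int, x1: int, d: int,
                     params: DetectionParams) -> tuple[int, int, Optional[str]]:
    """Search small boundary shifts for an anchored TSD.

    The candidate 5' start is ``x0`` and 3' end is ``x1 + d``; shifts up
    to the TSD search window are explored nearest-first, so a genuine TSD
    at the detected boundary beats chance repeats further away. A snap
    must satisfy three safeguards: only repeats of >= 5 bp count (4-mers
    recur too often by chance to move boundaries on); the 12 bp just
    inside each proposed boundary must still match between the two LTR
    copies on the detection diagonal (>= 7 of 12), so the boundary cannot
    leave the repeat; and the 12 bp just outside the TSD copies must not
    match near-perfectly on the diagonal (< 10 of 12), which is the
    signature of a boundary slid into the repeat's interior, where
    flanking sequence can by chance spell an anchored repeat. Returns
    possibly shifted (x0, x1) plus the TSD string, or the original
    boundaries and None.
    """
    w = params.tsd_search_window
    min_snap = max(5, params.tsd_min)
    probe = 12
    min_inside = 7    # of `probe` inside each boundary
    max_outside = 9   # of `probe` outside each TSD copy
    n = len(seq)

    def diag_matches(start: int, other: int, length: int) -> int:
        return sum(seq[start + i] == seq[other + i] for i in range(length))

    shifts = sorted(
        ((abs(d1) + abs(d2), d1, d2)
         for d1 in range(-w, w + 1) for d2 in range(-w, w + 1)),
        key=lambda t: (t[0], abs(t[1]), abs(t[2]), t[1], t[2]),
    )
    for _, d1, d2 in shifts:
        a = x0 + d1            # element 5' start
        b = x1 + d + d2        # element 3' end
        if b - a - d < probe or a + d + probe > n or b - d - probe < 0:
            continue
        for L in range(params.tsd_max, min_snap - 1, -1):
            if a - L < 0 or b + L > n:
                continue
            left = seq[a - L:a]
            if "N" in left or left != seq[b:b + L]:
                continue
            if diag_matches(a, a + d, probe) < min_inside:
                continue
            if diag_matches(b - probe, b - d - probe, probe) < min_inside:
                continue
            if (a - L - probe >= 0 and a + d - L - probe >= 0
                    and diag_matches(a - L - probe, a + d - L - probe,
                                     probe) > max_outside):
                continue
            if (b + L + probe <= n and b - d + L + probe <= n
                    and diag_matches(b + L, b - d + L, probe) > max_outside):
                continue
            return x0 + d1, x1 + d2, left
    return x0, x1, None


def find_ltr_candidates(genome: GenomeSequence,
                        params: DetectionParams | None = None) -> list[LTRCandidate]:
    """Detect candidate LTR-RTs on one genome sequence.

    Returns a deterministic, coordinate-sorted list of candidates that all
    satisfy the structural constraints in ``params``; overlapping raw
    detections are resolved to the higher-identity, then longer, then
    leftmost candidate, so no returned candidate contains another.
    """
    params = params or DetectionParams()
    seq = genome.residues
    if len(seq) <= params.min_element_span:
        return []
    diagonals = _seed_diagonals(seq, params)
    raw: list[tuple[float, int, int, int, Optional[str]]] = []
    seen_segments: set[tuple[int, int, int]] = set()
    for d, pos in sorted(diagonals.items()):
        pos = sorted(set(pos))
        # split seed positions on this diagonal into runs closer than max LTR
        runs: list[list[int]] = [[pos[0]]]
        for p in pos[1:]:
            if p - runs[-1][-1] <= params.max_ltr_len:
                runs[-1].append(p)
            else:
                runs.append([p])
        for run in runs:
            lo = max(0, run[0] - params.max_ltr_len)
            hi = min(len(seq) - d, run[-1] + params.seed_len + params.max_ltr_len)
            if hi <= lo:
                continue
            a1 = np.frombuffer(seq[lo:hi].encode(), dtype=np.uint8)
            a2 = np.frombuffer(seq[lo + d:hi + d].encode(), dtype=np.uint8)
            match = (a1 == a2) & (a1 != ord("N"))
            s, e = _max_scoring_segment(match)
            s, e = _trim_to_clean_runs(match, s, e)
            if e <= s:
                continue
            x0, x1 = lo + s, lo + e
            x1 = min(x1, x0 + d - 1)  # LTRs must not overlap; keep internal >= 1 bp
            key = (d, x0, x1)
            if x1 <= x0 or key in seen_segments:
                continue
            seen_segments.add(key)
            x0, x1, tsd = _refine_with_tsd(seq, x0, x1, d, params)
            L = x1 - x0
            span = d + L
            if not (params.min_ltr_len <= L <= min(params.max_ltr_len, d - 1)):
                continue
            if not (params.min_element_span <= span <= params.max_element_span):
                continue
            ltr5 = seq[x0:x1]
            ltr3 = seq[x0 + d:x1 + d]
            # low-complexity guard: a dinucleotide or homopolymer run
            # satisfies every structural rule yet is no LTR
            counts = sorted((ltr5.count(b) for b in "ACGT"), reverse=True)
            if len(set(ltr5) - {"N"}) < 3 or counts[0] + counts[1] >= 0.9 * L:
                continue
            identity = global_align(ltr5, ltr3).identity
            if identity < params.min_ltr_identity:
                continue
            raw.append((identity, x0, x1, d, tsd))

    # overlap resolution: identity desc, span length desc, leftmost
    raw.sort(key=lambda t: (-t[0], -((t[3] + (t[2] - t[1]))), t[1], t[3]))
    kept: list[tuple[float, int, int, int, Optional[str]]] = []
    occupied: list[tuple[int, int]] = []
    for cand in raw:
        _, x0, x1, d, _ = cand
        s0, s1 = x0, x1 + d
        if any(s0 < e and s < s1 for s, e in occupied):
            continue
        occupied.append((s0, s1))
        kept.append(cand)

    kept.sort(key=lambda t: t[1])
    out: list[LTRCandidate] = []
    sid = genome.seq_id
    for idx, (identity, x0, x1, d, tsd) in enumerate(kept, start=1):
        L = x1 - x0
        five = GenomicInterval(sid, x0, x1)
        three = GenomicInterval(sid, x0 + d, x1 + d)
        internal = GenomicInterval(sid, x1, x0 + d)
        tsd_iv = None
        if tsd is not None:
            tl = len(tsd)
            tsd_iv = (GenomicInterval(sid, x0 - tl, x0),
                      GenomicInterval(sid, x1 + d, x1 + d + tl))
        out.append(LTRCandidate(
            element_id=f"{sid}_elem{idx:04d}",
            five_prime_ltr=five, three_prime_ltr=three, internal=internal,
            ltr_identity=identity, tsd=tsd, tsd_intervals=tsd_iv,
        ))
    return out


def detect_tsd(genome: GenomeSequence, candidate: LTRCandidate,
               params: DetectionParams | None = None
               ) -> Optional[tuple[str, tuple[GenomicInterval, GenomicInterval]]]:
    """Longest exact direct repeat (tsd_min..tsd_max bp) anchored exactly at
    the element boundaries; None when absent.

    Unlike the boundary refinement inside :func:`find_ltr_candidates`, no
    shifting is applied here: the copies must end at the element's 5'
    boundary and begin at its 3' boundary.
    """
    params = params or DetectionParams()
    seq = genome.residues
    a = candidate.five_prime_ltr.start
    b = candidate.three_prime_ltr.end
    if a < 0 or b > len(seq):
        raise ValueError(f"candidate {candidate.element_id} outside genome bounds")
    tsd = tsd_at(seq, a, b, params)
    if tsd is None:
        return None
    L = len(tsd)
    return tsd, (GenomicInterval(genome.seq_id, a - L, a),
                 GenomicInterval(genome.seq_id, b, b + L))


def tsd_at(seq: str, a: int, b: int, params: DetectionParams) -> Optional[str]:
    """Longest anchored TSD string around the span [a, b), or None."""
    for L in range(params.tsd_max, params.tsd_min - 1, -1):
        if a - L < 0 or b + L > len(seq):
            continue
        left = seq[a - L:a]
        if "N" not in left and left == seq[b:b + L]:
            return left
    return None
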