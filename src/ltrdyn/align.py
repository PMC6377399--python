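"""Pairwise alignment helpers and Karlin-Altschul E-value statistics.

Nucleotide alignments use a fixed, documented scoring scheme
(match +2 / mismatch -3 / gap open -5 / gap extend -2) so that every
identity threshold in the pipeline is reproducible. Protein alignments use
BLOSUM62 with affine gaps (open -11 / extend -1). E-values follow
Karlin-Altschul statistics: the nucleotide lambda is solved from the score
matrix at import time; the protein constants are the standard gapped
BLOSUM62 values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.optimize import brentq

NUC_MATCH = 2.0
NUC_MISMATCH = -3.0
NUC_OPEN = -5.0
NUC_EXTEND = -2.0

PROT_OPEN = -11.0
PROT_EXTEND = -1.0

# Gapped BLOSUM62 Karlin-Altschul parameters (BLAST defaults for -11/-1).
PROT_LAMBDA = 0.267
PROT_K = 0.041

# Ungapped-theory lambda for the nucleotide scheme, with a fixed heuristic K.
NUC_K = 0.1


@lru_cache(maxsize=1)
def nuc_lambda() -> float:
    """Solve sum_ij p_i p_j exp(lambda*s_ij) = 1 for equal base frequencies."""
    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * NUC_MATCH) + 0.75 * math.exp(lam * NUC_MISMATCH) - 1.0
    return brentq(f, 1e-6, 5.0)


def bit_score(raw: float, protein: bool) -> float:
    lam, k = (PROT_LAMBDA, PROT_K) if protein else (nuc_lambda(), NUC_K)
    return (lam * raw - math.log(k)) / math.log(2.0)


def e_value(raw: float, m: int, n: int, protein: bool) -> float:
    """Expected chance hits of raw score >= ``raw`` in an m x n search space."""
    return m * n * 2.0 ** (-bit_score(raw, protein))


def dna_aligner(mode: str = "global") -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = mode
    a.match_score = NUC_MATCH
    a.mismatch_score = NUC_MISMATCH
    a.open_gap_score = NUC_OPEN
    a.extend_gap_score = NUC_EXTEND
    return a


def protein_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = PROT_OPEN
    a.extend_gap_score = PROT_EXTEND
    return a


@dataclass
class AlignmentSummary:
    score: float
    identity: float       # percent, matches / alignment columns * 100
    columns: int
    matches: int
    target_range: tuple[int, int]  # aligned span on the first sequence
    query_range: tuple[int, int]   # aligned span on the second sequence
    target_aligned: int   # non-gap target positions inside the alignment
    query_aligned: int


def summarize(alignment) -> AlignmentSummary:
    counts = alignment.counts()
    blocks = alignment.aligned
    if blocks.size:
        t0, t1 = int(blocks[0][0][0]), int(blocks[0][-1][1])
        q0, q1 = int(blocks[1][0][0]), int(blocks[1][-1][1])
        t_aln = int(sum(b - a for a, b in blocks[0]))
        q_aln = int(sum(b - a for a, b in blocks[1]))
    else:
        t0 = t1 = q0 = q1 = t_aln = q_aln = 0
    cols = int(alignment.length)
    matches = counts.identities
    denom = cols if cols else 1
    return AlignmentSummary(
        score=float(alignment.score),
        identity=100.0 * matches / denom,
        columns=int(cols),
        matches=int(matches),
        target_range=(t0, t1),
        query_range=(q0, q1),
        target_aligned=t_aln,
        query_aligned=q_aln,
    )


def global_align(a: str, b: str) -> AlignmentSummary:
    """Best global nucleotide alignment under the package scoring."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = dna_aligner("global")
    return summarize(aligner.align(a, b)[0])


def local_align(a: str, b: str) -> AlignmentSummary:
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = dna_aligner("local")
    alns = aligner.align(a, b)
    if len(alns) == 0 or alns.score <= 0:
        return AlignmentSummary(0.0, 0.0, 0, 0, (0, 0), (0, 0), 0, 0)
    return summarize(alns[0])


def global_identity(a: str, b: str) -> float:
    """Percent identity (matches / alignment columns) of a global alignment."""
    return global_align(a, b).identity


_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def classify_substitution(x: str, y: str) -> str:
    """Classify one aligned column: 'match', 'transition', 'transversion',
    or 'excluded' (gap or ambiguous base)."""
    if x in "-." or y in "-." or x == "N" or y == "N":
        return "excluded"
    if x == y:
        return "match"
    if (x in _PURINES and y in _PURINES) or (x in _PYRIMIDINES and y in _PYRIMIDINES):
        return "transition"
    return "transversion"


def count_site_pattern(alignment) -> tuple[int, int, int, int]:
    """(n_sites, transitions, transversions, aligned_len) over the columns
    of a Bio.Align alignment, excluding gap and N columns."""
    inds = np.asarray(alignment.indices)
    t, q = alignment.target, alignment.query
    n_sites = ti = tv = 0
    aligned_len = inds.shape[1]
    for k in range(aligned_len):
        i, j = inds[0, k], inds[1, k]
        cx = t[i] if i >= 0 else "-"
        cy = q[j] if j >= 0 else "-"
        kind = classify_substitution(cx, cy)
        if kind == "excluded":
            continue
        n_sites += 1
        if kind == "transition":
            ti += 1
        elif kind == "transversion":
            tv += 1
    return n_sites, ti, tv, aligned_len
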