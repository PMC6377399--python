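"""Insertion-age estimation from LTR-LTR divergence.

At insertion the two LTRs of a retrotransposon are identical; each then
accumulates substitutions independently at rate mu (substitutions per site
per year). The Kimura two-parameter (K2P) distance between the aligned
LTRs,

    K = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q),

with P and Q the transition and transversion proportions, therefore
estimates 2*mu*T, giving the insertion time T = K / (2 mu).
"""

from __future__ import annotations

import math
from typing import Optional

from .align import count_site_pattern, dna_aligner
from .model import AgeEstimate, LTRPairAlignment

DEFAULT_MU = 1.3e-8  # substitutions per site per year


def align_ltr_pair(ltr5: str, ltr3: str, element_id: str = "_") -> LTRPairAlignment:
    """Globally align an element's two LTRs and count site patterns.

    Columns containing a gap or an N are excluded from ``n_sites`` (the
    denominator of the transition proportion P and transversion proportion
    Q), standard practice for K2P counting.
    """
    if not ltr5 or not ltr3:
        raise ValueError("cannot align an empty LTR sequence")
    aln = dna_aligner("global").align(ltr5, ltr3)[0]
    n_sites, ti, tv, aligned_len = count_site_pattern(aln)
    if n_sites == 0:
        return LTRPairAlignment(element_id, aligned_len, 0, 0.0, 0.0)
    return LTRPairAlignment(element_id, aligned_len, n_sites,
                            ti / n_sites, tv / n_sites)


def k2p_distance(aln: LTRPairAlignment) -> tuple[Optional[float], bool]:
    """(K, saturated) for a counted LTR pair alignment.

    Returns ``(None, True)`` when the log arguments are non-positive
    (saturation); raises when there are no informative sites at all.
    """
    if aln.n_sites == 0:
        raise ValueError(f"element {aln.element_id}: no informative sites")
    return k2p_from_proportions(aln.P, aln.Q)


def k2p_from_proportions(P: float, Q: float) -> tuple[Optional[float], bool]:
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return None, True
    return -0.5 * math.log(w1) - 0.25 * math.log(w2), False


def insertion_time(K: Optional[float], mu: float = DEFAULT_MU,
                   element_id: str = "_", saturated: bool = False) -> AgeEstimate:
    """T = K / (2 mu); saturated inputs yield a missing age, never a number."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if saturated or K is None:
        return AgeEstimate(element_id, None, None, None, mu, True)
    if K < 0:
        raise ValueError("K must be non-negative")
    t_years = K / (2.0 * mu)
    return AgeEstimate(element_id, K, t_years, t_years / 1e6, mu, False)


def date_ltr_pair(ltr5: str, ltr3: str, mu: float = DEFAULT_MU,
                  element_id: str = "_") -> tuple[LTRPairAlignment, AgeEstimate]:
    """Convenience: align, count, correct and convert in one call."""
    aln = align_ltr_pair(ltr5, ltr3, element_id)
    if aln.n_sites == 0:
        return aln, AgeEstimate(element_id, None, None, None, mu, True)
    K, sat = k2p_distance(aln)
    return aln, insertion_time(K, mu, element_id, saturated=sat)
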