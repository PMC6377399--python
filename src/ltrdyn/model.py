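"""Core domain types shared across the pipeline.

Coordinates are 0-based, half-open throughout the package; conversion to
GFF3's 1-based inclusive convention happens only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


@dataclass(frozen=True)
class GenomeSequence:
    """A genome sequence with normalized residues (uppercase ACGTN only)."""

    seq_id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    interval: GenomicInterval


@dataclass
class LTRCandidate:
    """A structurally detected LTR retrotransposon candidate.

    The element is the span from ``five_prime_ltr.start`` to
    ``three_prime_ltr.end``; the target site duplication, when present,
    lies immediately outside that span on both sides.
    """

    element_id: str
    five_prime_ltr: GenomicInterval
    three_prime_ltr: GenomicInterval
    internal: GenomicInterval
    ltr_identity: float
    tsd: Optional[str] = None
    tsd_intervals: Optional[tuple[GenomicInterval, GenomicInterval]] = None
    strand: str = "."

    @property
    def seq_id(self) -> str:
        return self.five_prime_ltr.seq_id

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.seq_id, self.five_prime_ltr.start, self.three_prime_ltr.end
        )


@dataclass
class DomainHit:
    """A Gag-Pol domain alignment inside a translated nucleotide region."""

    domain_name: str
    clade_label: str
    query_coverage: float
    identity: float
    score: float  # bit score
    e_value: float
    frame: int
    location: GenomicInterval


@dataclass
class IntactnessCall:
    element_id: str
    is_intact: bool
    domains_found: frozenset[str]
    best_clade: Optional[str]


@dataclass
class LTRHomolog:
    """A genome locus homologous to an intact element's 5'-LTR."""

    homolog_id: str
    location: GenomicInterval
    source_element_id: str
    identity: float
    overlap: float
    e_value: float


SOLO = "SOLO"
TRUNCATED = "TRUNCATED"
AMBIGUOUS = "AMBIGUOUS"


@dataclass
class RemnantCall:
    homolog_id: str
    category: str  # SOLO | TRUNCATED | AMBIGUOUS
    upstream_gagpol: bool
    downstream_gagpol: bool
    tsd: Optional[str] = None

    def __post_init__(self) -> None:
        n = int(self.upstream_gagpol) + int(self.downstream_gagpol)
        expected = {0: SOLO, 1: TRUNCATED, 2: AMBIGUOUS}[n]
        if self.category != expected:
            raise ValueError(
                f"category {self.category} inconsistent with flank flags "
                f"({self.upstream_gagpol}, {self.downstream_gagpol})"
            )


@dataclass
class LTRPairAlignment:
    """Site counts from the global alignment of an element's two LTRs.

    ``P`` and ``Q`` are the transition and transversion proportions over
    the ``n_sites`` ungapped, unambiguous columns.
    """

    element_id: str
    aligned_len: int
    n_sites: int
    P: float
    Q: float


@dataclass
class AgeEstimate:
    element_id: str
    K: Optional[float]  # K2P substitutions per site; None when saturated
    T_years: Optional[float]
    T_mya: Optional[float]
    mu: float
    saturated: bool


@dataclass
class LTRCluster:
    """A single-linkage family/superfamily of LTR sequences."""

    cluster_id: str
    members_I: list[str] = field(default_factory=list)
    members_S: list[str] = field(default_factory=list)
    members_T: list[str] = field(default_factory=list)

    @property
    def n_I(self) -> int:
        return len(self.members_I)

    @property
    def n_S(self) -> int:
        return len(self.members_S)

    @property
    def n_T(self) -> int:
        return len(self.members_T)
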