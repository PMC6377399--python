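"""Gag-Pol protein domain scanning and intactness calling.

The internal region of an intact LTR retrotransposon encodes the Gag-Pol
polyprotein, whose domains (GAG capsid, PR protease, RT reverse
transcriptase, RH RNase H, INT integrase) diagnose element completeness.
This module translates a nucleotide region in all six frames and aligns
each translation locally (BLOSUM62, affine gaps) against a library of
domain exemplar proteins, keeping hits that simultaneously pass coverage,
identity and E-value thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from .align import e_value, bit_score, protein_aligner, summarize
from .model import DomainHit, GenomicInterval, IntactnessCall, LTRCandidate

DOMAIN_NAMES = ("GAG", "PR", "RT", "RH", "INT")
REQUIRED_DOMAINS = frozenset(DOMAIN_NAMES)

#: nominal exemplar lengths (aa) for the synthetic bundled library
_DOMAIN_LENGTHS = {"GAG": 400, "PR": 120, "RT": 250, "RH": 150, "INT": 280}

GYPSY_CLADES = ("Del", "Tat", "Galadriel", "Reina")
COPIA_CLADES = ("Sire", "Tork", "Oryco", "Retrofit")

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class DomainLibraryEntry:
    domain_name: str
    clade_label: str
    superfamily: str
    sequence: str


@dataclass
class DomainLibrary:
    entries: list[DomainLibraryEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("domain library is empty")
        for e in self.entries:
            bad = set(e.sequence) - set(_AA + "X")
            if bad:
                raise ValueError(
                    f"non-amino-acid characters in {e.domain_name}|{e.clade_label}: "
                    f"{sorted(bad)}"
                )

    @property
    def total_length(self) -> int:
        return sum(len(e.sequence) for e in self.entries)


def bundled_library(clades: tuple[str, ...] | None = None,
                    seed: int = 902210) -> DomainLibrary:
    """A SYNTHETIC exemplar library: one deterministically generated random
    protein per domain per clade, labelled with GyDB-style clade names.

    These sequences are stand-ins for real Gag-Pol exemplars and carry no
    biological signal; they exist so the pipeline and its simulator share a
    self-contained library. Supply a real exemplar FASTA for genuine
    genomes via :func:`read_domain_library`.
    """
    clades = clades or (GYPSY_CLADES + COPIA_CLADES)
    rng = np.random.default_rng(seed)
    aa = np.array(list(_AA))
    entries = []
    for clade in GYPSY_CLADES + COPIA_CLADES:
        superfamily = "Gypsy" if clade in GYPSY_CLADES else "Copia"
        for name in DOMAIN_NAMES:
            seq = "".join(rng.choice(aa, _DOMAIN_LENGTHS[name]))
            if clade in clades:
                entries.append(DomainLibraryEntry(name, clade, superfamily, seq))
    return DomainLibrary(entries)


def read_domain_library(path: str) -> DomainLibrary:
    """Read a protein FASTA with ``>NAME|CLADE|SUPERFAMILY`` headers."""
    entries = []
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    entries.append(_entry_from(name, "".join(chunks)))
                name, chunks = line[1:], []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        entries.append(_entry_from(name, "".join(chunks)))
    return DomainLibrary(entries)


def _entry_from(header: str, seq: str) -> DomainLibraryEntry:
    parts = header.split()[0].split("|")
    if len(parts) != 3:
        raise ValueError(f"domain FASTA header must be NAME|CLADE|SUPERFAMILY: {header!r}")
    return DomainLibraryEntry(parts[0], parts[1], parts[2], seq)


def write_domain_library(library: DomainLibrary, path: str) -> None:
    with open(path, "w") as fh:
        for e in library.entries:
            fh.write(f">{e.domain_name}|{e.clade_label}|{e.superfamily}\n")
            for i in range(0, len(e.sequence), 80):
                fh.write(e.sequence[i:i + 80] + "\n")


def six_frame_translations(dna: str) -> list[tuple[int, int, str]]:
    """(frame, forward-strand offset of codon 0, protein) for all 6 frames.

    Frames +1/+2/+3 read the forward strand at offsets 0/1/2; -1/-2/-3 read
    the reverse complement at offsets 0/1/2 of the reversed sequence.
    """
    out = []
    rc = str(Seq(dna).reverse_complement())
    for off in range(3):
        for frame_sign, s in ((1, dna), (-1, rc)):
            sub = s[off:]
            sub = sub[:len(sub) - len(sub) % 3]
            if not sub:
                continue
            prot = str(Seq(sub).translate())
            out.append((frame_sign * (off + 1), off, prot))
    return out


def _dna_span(frame: int, off: int, aa_start: int, aa_end: int, n: int) -> tuple[int, int]:
    """Forward-strand coordinates of the codons [aa_start, aa_end)."""
    s = off + 3 * aa_start
    e = off + 3 * aa_end
    if frame > 0:
        return s, e
    return n - e, n - s


def scan_gag_pol(dna: str, library: DomainLibrary,
                 min_coverage: float = 0.5, min_identity: float = 30.0,
                 max_evalue: float = 1e-8,
                 seq_id: str = "_", offset: int = 0) -> list[DomainHit]:
    """Align six-frame translations of ``dna`` against every library entry.

    A hit is kept only when the aligned fraction of the library protein is
    at least ``min_coverage``, the alignment identity exceeds
    ``min_identity`` percent, and the Karlin-Altschul E-value is at most
    ``max_evalue``. Hits are returned sorted by ascending E-value;
    ``location`` is in forward-strand coordinates of ``dna`` shifted by
    ``offset`` (so callers can pass genome coordinates).
    """
    if len(dna) < 3:
        raise ValueError("sequence shorter than one codon")
    if not library.entries:
        raise ValueError("empty domain library")
    aligner = protein_aligner()
    n = len(dna)
    m_eff = n // 3  # effective translated length per strand position
    hits: list[DomainHit] = []
    frames = six_frame_translations(dna)
    for entry in library.entries:
        for frame, off, prot in frames:
            if not prot:
                continue
            alns = aligner.align(prot.replace("*", "X"), entry.sequence)
            if len(alns) == 0 or alns.score <= 0:
                continue
            summ = summarize(alns[0])
            coverage = summ.query_aligned / len(entry.sequence)
            ev = e_value(summ.score, m_eff, library.total_length, protein=True)
            if coverage < min_coverage or summ.identity <= min_identity or ev > max_evalue:
                continue
            s, e = _dna_span(frame, off, *summ.target_range, n)
            hits.append(DomainHit(
                domain_name=entry.domain_name, clade_label=entry.clade_label,
                query_coverage=coverage, identity=summ.identity,
                score=bit_score(summ.score, protein=True), e_value=ev,
                frame=frame,
                location=GenomicInterval(seq_id, offset + s, offset + e),
            ))
    hits.sort(key=lambda h: (h.e_value, -h.score, h.domain_name, h.clade_label))
    return hits


def has_gag_pol(dna: str, library: DomainLibrary,
                min_coverage: float = 0.5, min_identity: float = 30.0,
                max_evalue: float = 1e-8) -> bool:
    """True when any qualifying Gag-Pol hit exists in ``dna``.

    Early-exits on the first qualifying hit and screens each frame/entry
    pair by raw score (E-value) before computing the full alignment.
    """
    if len(dna) < 3 or not library.entries:
        return False
    aligner = protein_aligner()
    m_eff = len(dna) // 3
    frames = six_frame_translations(dna)
    for entry in library.entries:
        for frame, off, prot in frames:
            if not prot:
                continue
            target = prot.replace("*", "X")
            score = aligner.score(target, entry.sequence)
            if score <= 0 or e_value(score, m_eff, library.total_length,
                                     protein=True) > max_evalue:
                continue
            summ = summarize(aligner.align(target, entry.sequence)[0])
            coverage = summ.query_aligned / len(entry.sequence)
            if coverage >= min_coverage and summ.identity > min_identity:
                return True
    return False


def call_intact(candidate: LTRCandidate, hits: list[DomainHit],
                required_domains: frozenset[str] = REQUIRED_DOMAINS) -> IntactnessCall:
    """Call an element intact when every required domain has a hit.

    All hits must lie inside the candidate's internal region. The clade is
    the modal clade label among hits, ties broken lexicographically.
    """
    internal = candidate.internal
    for h in hits:
        loc = h.location
        if loc.seq_id != internal.seq_id or loc.start < internal.start or loc.end > internal.end:
            raise ValueError(
                f"hit {h.domain_name}|{h.clade_label} at "
                f"[{loc.start},{loc.end}) outside internal region of {candidate.element_id}"
            )
    found = frozenset(h.domain_name for h in hits)
    best_clade = None
    if hits:
        tally: dict[str, int] = {}
        for h in hits:
            tally[h.clade_label] = tally.get(h.clade_label, 0) + 1
        best_clade = min(tally, key=lambda c: (-tally[c], c))
    return IntactnessCall(
        element_id=candidate.element_id,
        is_intact=required_domains <= found,
        domains_found=found,
        best_clade=best_clade,
    )
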