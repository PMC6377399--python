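"""FASTA / GFF3 / tabular input-output with one coordinate convention.

Internally every interval is 0-based half-open; GFF3 files are written and
read as 1-based inclusive (the GFF3 standard). Residues are normalized on
read: uppercased, U mapped to T, every other IUPAC ambiguity code collapsed
to N so that downstream divergence counts only ever see {A, C, G, T, N}.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

from .model import GeneAnnotation, GenomeSequence, GenomicInterval, LTRCandidate

_VALID = set("ACGTN")
_NORMALIZE = str.maketrans(
    {c: ("T" if c == "U" else c if c in "ACGT" else "N")
     for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZ"}
)


def normalize_residues(raw: str) -> str:
    """Uppercase, map U->T and non-ACGT IUPAC codes to N."""
    s = raw.upper().translate(_NORMALIZE)
    bad = set(s) - _VALID
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return s


def read_fasta(path: str | os.PathLike) -> list[GenomeSequence]:
    """Read a multi-record FASTA into normalized :class:`GenomeSequence`.

    Raises on a missing or empty file and on duplicate record ids.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id in {path}: {rec.id!r}")
        seen.add(rec.id)
        records.append(GenomeSequence(rec.id, normalize_residues(str(rec.seq))))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(seqs: Iterable[tuple[str, str]], path: str | os.PathLike,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_gff3_genes(path: str | os.PathLike) -> list[GeneAnnotation]:
    """Extract features of type ``gene`` from a GFF3 file.

    GFF3 1-based inclusive coordinates become internal 0-based half-open.
    Malformed rows (wrong column count, end < start) raise, naming the line.
    """
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(os.fspath(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(
                    f"{path} line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            seq_id, _, ftype, start_s, end_s, _, strand, _, attrs = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"{path} line {lineno}: non-integer coordinates")
            if end1 < start1:
                raise ValueError(f"{path} line {lineno}: end < start")
            if ftype != "gene":
                continue
            gene_id = _attr(attrs, "ID") or f"gene_line{lineno}"
            if gene_id in seen:
                raise ValueError(f"{path} line {lineno}: duplicate gene ID {gene_id!r}")
            seen.add(gene_id)
            strand = strand if strand in ("+", "-") else "."
            genes.append(
                GeneAnnotation(gene_id, GenomicInterval(seq_id, start1 - 1, end1, strand))
            )
    return genes


def _attr(attrs: str, key: str) -> Optional[str]:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1:]
    return None


def _fmt_attrs(pairs: Sequence[tuple[str, object]]) -> str:
    return ";".join(f"{k}={v}" for k, v in pairs if v is not None) or "."


def write_element_gff3(
    elements: Sequence[LTRCandidate],
    path: str | os.PathLike,
    categories: Optional[dict[str, str]] = None,
    ages_mya: Optional[dict[str, float]] = None,
) -> None:
    """Write annotated elements as GFF3 with Sequence Ontology feature types.

    Each element produces an ``LTR_retrotransposon`` row spanning the whole
    element, two ``long_terminal_repeat`` child rows and, when a TSD was
    detected, two ``target_site_duplication`` rows. Rows are ordered by
    (seq_id, start) regardless of input order.
    """
    categories = categories or {}
    ages_mya = ages_mya or {}
    ordered = sorted(elements, key=lambda e: (e.seq_id, e.span.start, e.element_id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for el in ordered:
            span = el.span
            attrs = _fmt_attrs([
                ("ID", el.element_id),
                ("ltr_identity", f"{el.ltr_identity:.2f}"),
                ("category", categories.get(el.element_id)),
                ("age_mya", None if el.element_id not in ages_mya
                 else f"{ages_mya[el.element_id]:.4f}"),
                ("tsd", el.tsd),
            ])
            fh.write(_row(span, "LTR_retrotransposon", el.strand, attrs))
            for tag, iv in (("5p", el.five_prime_ltr), ("3p", el.three_prime_ltr)):
                fh.write(_row(iv, "long_terminal_repeat", el.strand,
                              f"ID={el.element_id}_ltr{tag};Parent={el.element_id}"))
            if el.tsd_intervals is not None:
                for tag, iv in zip(("up", "down"), el.tsd_intervals):
                    fh.write(_row(iv, "target_site_duplication", el.strand,
                                  f"ID={el.element_id}_tsd{tag};Parent={el.element_id}"))


def _row(iv: GenomicInterval, ftype: str, strand: str, attrs: str) -> str:
    return (f"{iv.seq_id}\tltrdyn\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
            f"{strand if strand in '+-' else '.'}\t.\t{attrs}\n")


def read_element_gff3(path: str | os.PathLike) -> list[LTRCandidate]:
    """Re-read a file produced by :func:`write_element_gff3`."""
    spans: dict[str, dict] = {}
    order: list[str] = []
    with open(os.fspath(path)) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 row in {path}: {line!r}")
            seq_id, _, ftype, s, e, _, strand, _, attrs = cols
            iv = GenomicInterval(seq_id, int(s) - 1, int(e), strand if strand in "+-" else ".")
            if ftype == "LTR_retrotransposon":
                eid = _attr(attrs, "ID")
                spans[eid] = {"span": iv, "ltrs": [], "tsds": [],
                              "identity": float(_attr(attrs, "ltr_identity") or 0.0),
                              "tsd": _attr(attrs, "tsd")}
                order.append(eid)
            elif ftype == "long_terminal_repeat":
                spans[_attr(attrs, "Parent")]["ltrs"].append(iv)
            elif ftype == "target_site_duplication":
                spans[_attr(attrs, "Parent")]["tsds"].append(iv)
    out = []
    for eid in order:
        rec = spans[eid]
        ltrs = sorted(rec["ltrs"], key=lambda i: i.start)
        if len(ltrs) != 2:
            raise ValueError(f"element {eid} lacks two LTR rows in {path}")
        internal = GenomicInterval(ltrs[0].seq_id, ltrs[0].end, ltrs[1].start)
        tsds = sorted(rec["tsds"], key=lambda i: i.start) or None
        out.append(LTRCandidate(
            element_id=eid, five_prime_ltr=ltrs[0], three_prime_ltr=ltrs[1],
            internal=internal, ltr_identity=rec["identity"], tsd=rec["tsd"],
            tsd_intervals=tuple(tsds) if tsds else None, strand=rec["span"].strand,
        ))
    return out
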