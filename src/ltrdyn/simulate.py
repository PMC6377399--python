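"""Synthetic genomes with planted LTR retrotransposon histories.

The simulator emulates the observable structure that the pipeline is built
to recover: a GC-parameterized random background (GC 35.8%, matching the
assembly the analysis model targets) carrying, per family, intact elements
(TSD + LTR + Gag-Pol-coding internal + LTR + TSD), solo-LTRs produced
either by unequal recombination (single LTR retaining its TSD) or by
fragmentation (single LTR, no TSD), and truncated elements (one LTR plus a
partial internal region, no TSD). Each element carries a true insertion
age drawn from a mixture of uniform components mirroring an ancient
2-10 Mya amplification peak plus a recent <1 Mya component; sequences
diverge from their family ancestor under an exact Kimura two-parameter
substitution process, so the dating stage's estimator is consistent
against the planted truth.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .domains import (DOMAIN_NAMES, DomainLibrary, bundled_library,
                      write_domain_library, GYPSY_CLADES, COPIA_CLADES)
from .io import write_fasta
from .model import GenomeSequence, GenomicInterval

_BASES = np.array(list("ACGT"))
_BASE_IDX = {b: i for i, b in enumerate("ACGT")}
# transition partner of A,C,G,T; transversion partners are the other two
_TRANSITION = np.array([2, 3, 0, 1])
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])

_CODONS = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


@dataclass
class AgeMixtureComponent:
    weight: float
    lo_mya: float
    hi_mya: float


@dataclass
class FamilyCounts:
    n_intact: int = 10
    n_solo_recomb: int = 12
    n_solo_fragment: int = 8
    n_truncated: int = 5


@dataclass
class SimConfig:
    """Study conditions for one simulated genome."""

    genome_len: int = 2_000_000
    gc_content: float = 0.358
    n_families: int = 2
    counts: FamilyCounts = field(default_factory=FamilyCounts)
    ltr_len: int = 500
    internal_len: int = 5000
    age_model: list[AgeMixtureComponent] = field(default_factory=lambda: [
        AgeMixtureComponent(0.7, 2.0, 10.0),
        AgeMixtureComponent(0.3, 0.0, 1.0),
    ])
    kappa: float = 2.0
    mu: float = 1.3e-8
    tsd_len: int = 5
    min_spacing: int = 16000  # > max element span: no cross-locus LTR pairing
    spacing_jitter: int = 4000
    gene_len: int = 1500
    gene_distance_range: tuple[int, int] = (200, 8000)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        w = sum(c.weight for c in self.age_model)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"age mixture weights sum to {w}, not 1")
        for c in dataclasses.astuple(self.counts):
            if c < 0:
                raise ValueError("counts must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        if "counts" in d:
            d["counts"] = FamilyCounts(**d["counts"])
        if "age_model" in d:
            d["age_model"] = [AgeMixtureComponent(**c) for c in d["age_model"]]
        if "gene_distance_range" in d:
            d["gene_distance_range"] = tuple(d["gene_distance_range"])
        return cls(**d)


@dataclass
class TruthRecord:
    truth_id: str
    category: str                 # INTACT | SOLO | TRUNCATED
    mechanism: str                # insertion | unequal_recombination | fragmentation
    family_label: str
    seq_id: str
    start: int                    # element span, 0-based half-open (TSD excluded)
    end: int
    ltr5: Optional[tuple[int, int]]
    ltr3: Optional[tuple[int, int]]
    true_age_mya: float
    tsd: Optional[str]


@dataclass
class SimTruth:
    records: list[TruthRecord]

    def by_category(self, category: str) -> list[TruthRecord]:
        return [r for r in self.records if r.category == category]


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _k2p_site_probs(t_years: float, mu: float, kappa: float
                    ) -> tuple[float, float]:
    """(P_transition, P_each_transversion) after time t under K2P with
    total substitution rate mu and transition/transversion ratio kappa."""
    beta = mu / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * t_years)
    e2 = np.exp(-2.0 * (alpha + beta) * t_years)
    p_ti = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    return p_ti, p_tv


def evolve_sequence(seq: str, age_mya: float, mu: float, kappa: float,
                    rng: np.random.Generator) -> str:
    """Evolve one copy for ``age_mya`` under the exact K2P process."""
    if age_mya < 0:
        raise ValueError("age must be non-negative")
    if age_mya == 0:
        return seq
    t = age_mya * 1e6
    p_ti, p_tv = _k2p_site_probs(t, mu, kappa)
    idx = np.array([_BASE_IDX[b] for b in seq])
    u = rng.random(len(idx))
    out = idx.copy()
    ti_mask = u < p_ti
    tv1_mask = (u >= p_ti) & (u < p_ti + p_tv)
    tv2_mask = (u >= p_ti + p_tv) & (u < p_ti + 2 * p_tv)
    out[ti_mask] = _TRANSITION[idx[ti_mask]]
    out[tv1_mask] = _TRANSVERSIONS[idx[tv1_mask], 0]
    out[tv2_mask] = _TRANSVERSIONS[idx[tv2_mask], 1]
    return "".join(_BASES[out])


def evolve_ltr_pair(ancestral_ltr: str, age_mya: float, mu: float = 1.3e-8,
                    kappa: float = 2.0,
                    rng: np.random.Generator | int | None = None
                    ) -> tuple[str, str]:
    """Two independently evolved copies of one ancestral LTR (the state of
    an element's LTR pair ``age_mya`` million years after insertion)."""
    if age_mya < 0:
        raise ValueError("age must be non-negative")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return (evolve_sequence(ancestral_ltr, age_mya, mu, kappa, rng),
            evolve_sequence(ancestral_ltr, age_mya, mu, kappa, rng))


def encode_proteins(library: DomainLibrary, clade: str, internal_len: int,
                    rng: np.random.Generator, gc: float) -> str:
    """Internal region: the clade's five domains in frame, GAG first and
    INT last, separated by random spacers summing to ``internal_len``."""
    blocks = []
    for name in DOMAIN_NAMES:
        entry = next(e for e in library.entries
                     if e.domain_name == name and e.clade_label == clade)
        blocks.append("".join(_CODONS[a] for a in entry.sequence))
    coding = sum(len(b) for b in blocks)
    spare = internal_len - coding
    if spare < 0:
        raise ValueError(
            f"internal_len {internal_len} too short for coding content {coding}"
        )
    # split the spare length into 4 inter-domain spacers (none at the ends,
    # so any >=20% truncation fragment still covers most of one domain)
    cuts = np.sort(rng.integers(0, spare + 1, size=3))
    spacers = [int(cuts[0]), int(cuts[1] - cuts[0]), int(cuts[2] - cuts[1]),
               int(spare - cuts[2])]
    parts = []
    for i, b in enumerate(blocks):
        parts.append(b)
        if i < 4:
            parts.append(random_dna(rng, spacers[i], gc))
    return "".join(parts)


def _draw_age(rng: np.random.Generator, model: list[AgeMixtureComponent]) -> float:
    u = rng.random()
    acc = 0.0
    for c in model:
        acc += c.weight
        if u <= acc:
            return float(rng.uniform(c.lo_mya, c.hi_mya))
    return float(rng.uniform(model[-1].lo_mya, model[-1].hi_mya))


def simulate_genome(config: SimConfig, out_dir: str | os.PathLike | None = None
                    ) -> tuple[GenomeSequence, SimTruth, DomainLibrary, list]:
    """Build a genome with planted loci and full ground truth.

    Returns (genome, truth, domain library, gene annotations); when
    ``out_dir`` is given also writes genome.fasta, truth.tsv, truth.gff3,
    domains.faa, genes.gff3 and a config echo, byte-identical for
    identical configs.
    """
    rng = np.random.default_rng(config.seed)
    clade_cycle = (GYPSY_CLADES + COPIA_CLADES)
    clades = tuple(clade_cycle[i % len(clade_cycle)]
                   for i in range(config.n_families))
    library = bundled_library(clades=tuple(sorted(set(clades))))

    # family ancestors
    ancestors = []
    for fam_i, clade in enumerate(clades):
        ltr = random_dna(rng, config.ltr_len, config.gc_content)
        internal = encode_proteins(library, clade, config.internal_len,
                                   rng, config.gc_content)
        ancestors.append((f"fam{fam_i:02d}_{clade}", ltr, internal))

    # build loci (sequence + metadata), then place them
    c = config.counts
    loci: list[dict] = []
    for fam_label, anc_ltr, anc_internal in ancestors:
        for cat, mech, n in (("INTACT", "insertion", c.n_intact),
                             ("SOLO", "unequal_recombination", c.n_solo_recomb),
                             ("SOLO", "fragmentation", c.n_solo_fragment),
                             ("TRUNCATED", "fragmentation", c.n_truncated)):
            for _ in range(n):
                age = _draw_age(rng, config.age_model)
                tsd = (random_dna(rng, config.tsd_len, config.gc_content)
                       if mech in ("insertion", "unequal_recombination") else None)
                if cat == "INTACT":
                    ltr5, ltr3 = (evolve_sequence(anc_ltr, age, config.mu,
                                                  config.kappa, rng)
                                  for _ in range(2))
                    internal = evolve_sequence(anc_internal, age, config.mu,
                                               config.kappa, rng)
                    core = ltr5 + internal + ltr3
                    parts = ("ltr5", len(ltr5), "internal", len(internal),
                             "ltr3", len(ltr3))
                elif cat == "SOLO":
                    ltr = evolve_sequence(anc_ltr, age, config.mu,
                                          config.kappa, rng)
                    core = ltr
                    parts = ("ltr5", len(ltr))
                else:  # TRUNCATED: LTR plus a 20-80% prefix or suffix of internal
                    ltr = evolve_sequence(anc_ltr, age, config.mu,
                                          config.kappa, rng)
                    frag_len = int(round(rng.uniform(0.2, 0.8)
                                         * len(anc_internal)))
                    internal = evolve_sequence(anc_internal, age, config.mu,
                                               config.kappa, rng)
                    if rng.random() < 0.5:   # 5' LTR retained, internal prefix
                        core = ltr + internal[:frag_len]
                        parts = ("ltr5", len(ltr), "internal", frag_len)
                    else:                    # internal suffix, 3' LTR retained
                        core = internal[-frag_len:] + ltr
                        parts = ("internal", frag_len, "ltr3", len(ltr))
                loci.append(dict(category=cat, mechanism=mech, family=fam_label,
                                 age=age, tsd=tsd, core=core, parts=parts))

    order = rng.permutation(len(loci))
    loci = [loci[i] for i in order]

    total_core = sum(len(l["core"]) + 2 * (len(l["tsd"]) if l["tsd"] else 0)
                     for l in loci)
    n_gaps = len(loci) + 1
    base_gaps = [int(config.min_spacing + rng.integers(0, config.spacing_jitter + 1))
                 for _ in range(n_gaps)]
    leftover = config.genome_len - total_core - sum(base_gaps)
    if leftover < 0:
        raise ValueError(
            f"genome_len {config.genome_len} too small for planted material "
            f"({total_core} bp in loci plus {sum(base_gaps)} bp spacing)"
        )
    extra = rng.multinomial(leftover, np.full(n_gaps, 1.0 / n_gaps))
    gaps = [g + int(x) for g, x in zip(base_gaps, extra)]

    chunks: list[str] = []
    records: list[TruthRecord] = []
    genes: list[tuple[str, int, int]] = []
    pos = 0
    seq_id = "chr1"
    for i, locus in enumerate(loci):
        gap = random_dna(rng, gaps[i], config.gc_content)
        # plant a gene annotation inside the gap, at a known distance
        # upstream of the locus that follows it
        lo_d, hi_d = config.gene_distance_range
        if gaps[i] > config.gene_len + hi_d + 100:
            dist = int(rng.integers(lo_d, hi_d + 1))
            g_end = pos + gaps[i] - dist
            genes.append((f"gene{len(genes):03d}", g_end - config.gene_len, g_end))
        chunks.append(gap)
        pos += gaps[i]
        tsd = locus["tsd"]
        if tsd:
            chunks.append(tsd)
            pos += len(tsd)
        start = pos
        parts = locus["parts"]
        coords: dict[str, tuple[int, int]] = {}
        p = pos
        for name, ln in zip(parts[::2], parts[1::2]):
            coords[name] = (p, p + ln)
            p += ln
        chunks.append(locus["core"])
        pos += len(locus["core"])
        end = pos
        if tsd:
            chunks.append(tsd)
            pos += len(tsd)
        records.append(TruthRecord(
            truth_id=f"truth{i:04d}", category=locus["category"],
            mechanism=locus["mechanism"], family_label=locus["family"],
            seq_id=seq_id, start=start, end=end,
            ltr5=coords.get("ltr5"), ltr3=coords.get("ltr3"),
            true_age_mya=locus["age"], tsd=tsd,
        ))
    chunks.append(random_dna(rng, gaps[-1], config.gc_content))
    pos += gaps[-1]
    pad = config.genome_len - pos
    if pad > 0:
        chunks.append(random_dna(rng, pad, config.gc_content))

    genome = GenomeSequence(seq_id, "".join(chunks))
    truth = SimTruth(records)
    gene_annotations = [
        (gid, GenomicInterval(seq_id, s, e, "+")) for gid, s, e in genes
    ]

    if out_dir is not None:
        _write_outputs(config, genome, truth, library, gene_annotations, out_dir)
    return genome, truth, library, gene_annotations


def _write_outputs(config, genome, truth, library, gene_annotations, out_dir):
    os.makedirs(out_dir, exist_ok=True)
    write_fasta([(genome.seq_id, genome.residues)],
                os.path.join(out_dir, "genome.fasta"))
    write_domain_library(library, os.path.join(out_dir, "domains.faa"))
    with open(os.path.join(out_dir, "truth.tsv"), "w") as fh:
        fh.write("truth_id\tcategory\tmechanism\tfamily\tseq_id\tstart\tend\t"
                 "ltr5_start\tltr5_end\tltr3_start\tltr3_end\tage_mya\ttsd\n")
        for r in truth.records:
            l5 = r.ltr5 or ("", "")
            l3 = r.ltr3 or ("", "")
            fh.write(f"{r.truth_id}\t{r.category}\t{r.mechanism}\t"
                     f"{r.family_label}\t{r.seq_id}\t{r.start}\t{r.end}\t"
                     f"{l5[0]}\t{l5[1]}\t{l3[0]}\t{l3[1]}\t"
                     f"{r.true_age_mya:.6f}\t{r.tsd or ''}\n")
    with open(os.path.join(out_dir, "truth.gff3"), "w") as fh:
        fh.write("##gff-version 3\n")
        for r in truth.records:
            fh.write(f"{r.seq_id}\tltrdyn_sim\tLTR_retrotransposon\t"
                     f"{r.start + 1}\t{r.end}\t.\t+\t.\t"
                     f"ID={r.truth_id};category={r.category};"
                     f"mechanism={r.mechanism};family={r.family_label};"
                     f"age_mya={r.true_age_mya:.6f}\n")
    with open(os.path.join(out_dir, "genes.gff3"), "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, iv in gene_annotations:
            fh.write(f"{iv.seq_id}\tltrdyn_sim\tgene\t{iv.start + 1}\t{iv.end}"
                     f"\t.\t+\t.\tID={gid}\n")
    with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
        d = dataclasses.asdict(config)
        d["gene_distance_range"] = list(d["gene_distance_range"])
        yaml.safe_dump(d, fh, sort_keys=True)
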