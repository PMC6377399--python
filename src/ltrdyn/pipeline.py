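"""Single-command orchestration: detect -> scan -> classify -> date ->
cluster -> stats, with a config file, per-stage logging and a content-hash
manifest so a rerun with identical inputs is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import yaml

from . import io as gio
from .cluster import (ClusterParams, assign_remnants_to_clusters,
                      build_similarity_edges, single_linkage_clusters)
from .dating import DEFAULT_MU, date_ltr_pair
from .detect import DetectionParams, find_ltr_candidates
from .domains import (REQUIRED_DOMAINS, call_intact, read_domain_library,
                      scan_gag_pol)
from .model import SOLO, TRUNCATED
from .remnants import HomologyParams, classify_all, find_ltr_homologs
from .stats import build_report

logger = logging.getLogger("ltrdyn")


@dataclass
class ScanParams:
    min_coverage: float = 0.5
    min_identity: float = 30.0
    max_evalue: float = 1e-8
    required_domains: tuple[str, ...] = tuple(sorted(REQUIRED_DOMAINS))

    def __post_init__(self) -> None:
        if not 0 < self.min_coverage <= 1:
            raise ValueError("min_coverage must be in (0, 1]")
        if not 0 < self.min_identity <= 100:
            raise ValueError("min_identity must be in (0, 100]")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")


@dataclass
class PipelineConfig:
    """Every numeric threshold of the analysis, in one serializable place."""

    detection: DetectionParams = field(default_factory=DetectionParams)
    scan: ScanParams = field(default_factory=ScanParams)
    homology: HomologyParams = field(default_factory=HomologyParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    mu: float = DEFAULT_MU
    age_bin_width_mya: float = 1.0
    age_max_mya: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.age_bin_width_mya <= 0 or self.age_max_mya <= 0:
            raise ValueError("age binning parameters must be positive")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sub = {"detection": DetectionParams, "scan": ScanParams,
               "homology": HomologyParams, "cluster": ClusterParams}
        kwargs = {}
        for key, value in d.items():
            if key in sub:
                fields = {f.name for f in dataclasses.fields(sub[key])}
                bad = set(value) - fields
                if bad:
                    raise ValueError(f"unknown config keys under {key}: {sorted(bad)}")
                if key == "scan" and "required_domains" in value:
                    value["required_domains"] = tuple(value["required_domains"])
                kwargs[key] = sub[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_yaml(self, path: str | os.PathLike) -> None:
        d = dataclasses.asdict(self)
        d["scan"]["required_domains"] = list(d["scan"]["required_domains"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(genome_path: str, domains_path: str, out_dir: str,
                 genes_path: Optional[str] = None,
                 config: Optional[PipelineConfig] = None) -> dict:
    """Run every stage on one genome; returns the manifest dict.

    Writes, under ``out_dir``: elements.gff3, intact.tsv, remnants.tsv,
    ages.tsv, clusters.tsv, report.json, config.yaml, run.log and
    manifest.json. Any stage failure aborts with the stage name.
    """
    config = config or PipelineConfig()
    os.makedirs(out_dir, exist_ok=True)
    log_path = os.path.join(out_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(genome_path, domains_path, out_dir, genes_path, config)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(genome_path, domains_path, out_dir, genes_path, config) -> dict:
    stage = "load"
    try:
        genomes = gio.read_fasta(genome_path)
        library = read_domain_library(domains_path)
        genes = gio.read_gff3_genes(genes_path) if genes_path else []
        logger.info("loaded %d sequence(s), %d library entries, %d genes",
                    len(genomes), len(library.entries), len(genes))

        stage = "detect"
        candidates = []
        for g in genomes:
            candidates.extend(find_ltr_candidates(g, config.detection))
        logger.info("detect: %d candidate elements", len(candidates))

        stage = "scan"
        by_seq = {g.seq_id: g for g in genomes}
        intact_els, calls = [], {}
        sc = config.scan
        for c in candidates:
            g = by_seq[c.seq_id]
            hits = scan_gag_pol(
                g.residues[c.internal.start:c.internal.end], library,
                min_coverage=sc.min_coverage, min_identity=sc.min_identity,
                max_evalue=sc.max_evalue, seq_id=c.seq_id, offset=c.internal.start)
            call = call_intact(c, hits, frozenset(sc.required_domains))
            calls[c.element_id] = call
            if call.is_intact:
                intact_els.append(c)
        logger.info("scan: %d of %d candidates intact",
                    len(intact_els), len(candidates))

        stage = "classify"
        homologs, remnant_calls = [], []
        for g in genomes:
            els = [e for e in intact_els if e.seq_id == g.seq_id]
            if not els:
                continue
            homs = find_ltr_homologs(g, els, config.homology)
            homologs.extend(homs)
            remnant_calls.extend(classify_all(
                g, homs, library, config.homology,
                min_coverage=sc.min_coverage, min_identity=sc.min_identity,
                max_evalue=sc.max_evalue))
        n_solo = sum(1 for r in remnant_calls if r.category == SOLO)
        n_trunc = sum(1 for r in remnant_calls if r.category == TRUNCATED)
        logger.info("classify: %d homologs -> %d solo, %d truncated, %d ambiguous",
                    len(homologs), n_solo, n_trunc,
                    len(remnant_calls) - n_solo - n_trunc)

        stage = "date"
        ages, ages_rows, saturated = {}, [], []
        for c in intact_els:
            g = by_seq[c.seq_id]
            aln, age = date_ltr_pair(
                g.residues[c.five_prime_ltr.start:c.five_prime_ltr.end],
                g.residues[c.three_prime_ltr.start:c.three_prime_ltr.end],
                mu=config.mu, element_id=c.element_id)
            ages_rows.append((c.element_id, aln, age))
            if age.saturated:
                saturated.append(c.element_id)
            else:
                ages[c.element_id] = age.T_mya
        logger.info("date: %d elements dated, %d saturated",
                    len(ages), len(saturated))

        stage = "cluster"
        ltr_seqs = {c.element_id:
                    by_seq[c.seq_id].residues[c.five_prime_ltr.start:c.five_prime_ltr.end]
                    for c in intact_els}
        edges = build_similarity_edges(ltr_seqs, config.cluster)
        clusters = single_linkage_clusters(sorted(ltr_seqs), edges)
        rem_seqs = {h.homolog_id:
                    by_seq[h.location.seq_id].residues[h.location.start:h.location.end]
                    for h in homologs}
        rem_cats = {r.homolog_id: r.category for r in remnant_calls}
        clusters, unassigned = assign_remnants_to_clusters(
            rem_seqs, rem_cats, clusters, ltr_seqs, config.cluster)
        logger.info("cluster: %d clusters at %s level, %d remnants unassigned",
                    len(clusters), config.cluster.level_label, len(unassigned))

        stage = "stats"
        tsd_by_cat = {
            "INTACT": [c.tsd is not None for c in intact_els],
            "SOLO": [r.tsd is not None for r in remnant_calls if r.category == SOLO],
            "TRUNCATED": [r.tsd is not None for r in remnant_calls
                          if r.category == TRUNCATED],
        }
        elements_iv = {c.element_id: c.span for c in intact_els}
        report = build_report(
            clusters, ages, saturated, tsd_by_cat,
            elements=elements_iv if genes else None, genes=genes or None,
            bin_width=config.age_bin_width_mya, max_age=config.age_max_mya)
        logger.info("stats: totals I=%d S=%d T=%d",
                    report.totals["I"], report.totals["S"], report.totals["T"])

        stage = "write"
        categories = {c.element_id: ("INTACT" if calls[c.element_id].is_intact
                                     else "CANDIDATE") for c in candidates}
        outputs = _write_outputs(out_dir, config, candidates, categories, calls,
                                 homologs, remnant_calls, ages_rows, clusters,
                                 unassigned, report, ages)
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config_sha256": _sha256(os.path.join(out_dir, "config.yaml")),
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
        "counts": {
            "candidates": len(candidates), "intact": len(intact_els),
            "homologs": len(homologs), "solo": n_solo, "truncated": n_trunc,
            "ambiguous": len(remnant_calls) - n_solo - n_trunc,
            "dated": len(ages), "saturated": len(saturated),
            "clusters": len(clusters), "unassigned_remnants": len(unassigned),
        },
        "complete": True,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _write_outputs(out_dir, config, candidates, categories, calls, homologs,
                   remnant_calls, ages_rows, clusters, unassigned, report,
                   ages) -> dict[str, str]:
    paths = {}

    def p(name):
        paths[name] = os.path.join(out_dir, name)
        return paths[name]

    config.to_yaml(p("config.yaml"))
    gio.write_element_gff3(candidates, p("elements.gff3"),
                           categories=categories, ages_mya=ages)
    with open(p("intact.tsv"), "w") as fh:
        fh.write("element_id\tseq_id\tstart\tend\tltr_identity\tis_intact\t"
                 "domains_found\tbest_clade\ttsd\n")
        for c in sorted(candidates, key=lambda c: (c.seq_id, c.span.start)):
            call = calls[c.element_id]
            fh.write(f"{c.element_id}\t{c.seq_id}\t{c.span.start}\t{c.span.end}\t"
                     f"{c.ltr_identity:.2f}\t{call.is_intact}\t"
                     f"{','.join(sorted(call.domains_found))}\t"
                     f"{call.best_clade or ''}\t{c.tsd or ''}\n")
    rc = {r.homolog_id: r for r in remnant_calls}
    with open(p("remnants.tsv"), "w") as fh:
        fh.write("homolog_id\tseq_id\tstart\tend\tcategory\tsource_element\t"
                 "identity\toverlap\te_value\tup_gagpol\tdown_gagpol\ttsd\n")
        for h in homologs:
            r = rc[h.homolog_id]
            fh.write(f"{h.homolog_id}\t{h.location.seq_id}\t{h.location.start}\t"
                     f"{h.location.end}\t{r.category}\t{h.source_element_id}\t"
                     f"{h.identity:.2f}\t{h.overlap:.3f}\t{h.e_value:.3g}\t"
                     f"{r.upstream_gagpol}\t{r.downstream_gagpol}\t{r.tsd or ''}\n")
    with open(p("ages.tsv"), "w") as fh:
        fh.write("element_id\tn_sites\tP\tQ\tK\tsaturated\tT_mya\n")
        for eid, aln, age in ages_rows:
            k = "" if age.K is None else f"{age.K:.6f}"
            t = "" if age.T_mya is None else f"{age.T_mya:.4f}"
            fh.write(f"{eid}\t{aln.n_sites}\t{aln.P:.6f}\t{aln.Q:.6f}\t{k}\t"
                     f"{age.saturated}\t{t}\n")
    with open(p("clusters.tsv"), "w") as fh:
        fh.write("cluster_id\tmember_id\tcategory\n")
        for cl in clusters:
            for mid in sorted(cl.members_I):
                fh.write(f"{cl.cluster_id}\t{mid}\tI\n")
            for mid in sorted(cl.members_S):
                fh.write(f"{cl.cluster_id}\t{mid}\tS\n")
            for mid in sorted(cl.members_T):
                fh.write(f"{cl.cluster_id}\t{mid}\tT\n")
        for mid in sorted(unassigned):
            fh.write(f"unassigned\t{mid}\t-\n")
    report.to_json(p("report.json"))
    return paths
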