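"""Removal-rate ratios, TSD rates, age distributions and gene proximity.

The S:I ratio (solo-LTRs per intact element) and its companions T:I and
(S+T):I proxy the rate at which a genome deletes LTR retrotransposons:
high ratios mean elements are being converted to solo or truncated relics
faster than new intact copies accumulate. Genome-wide ratios are ratios of
summed counts, never means of per-cluster ratios.
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import GeneAnnotation, GenomicInterval, LTRCluster


@dataclass
class ClusterRatios:
    cluster_id: str
    I: int
    S: int
    T: int
    S_to_I: Optional[float]
    T_to_I: Optional[float]
    ST_to_I: Optional[float]


@dataclass
class GeneProximityRow:
    element_id: str
    nearest_gene_id: Optional[str]
    distance_bp: Optional[int]
    overlapping: bool


@dataclass
class AgeHistogram:
    bin_width: float
    max_age: float
    counts: list[int]            # per bin [k*w, (k+1)*w), then overflow last
    overflow: int
    saturated: int


@dataclass
class DynamicsReport:
    per_cluster: list[ClusterRatios]
    totals: dict
    prop_clusters_SI_gt3: Optional[float]
    tsd_rates: dict
    age_histogram: Optional[AgeHistogram]
    gene_proximity: list[GeneProximityRow] = field(default_factory=list)

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "DynamicsReport":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            per_cluster=[ClusterRatios(**r) for r in d["per_cluster"]],
            totals=d["totals"],
            prop_clusters_SI_gt3=d["prop_clusters_SI_gt3"],
            tsd_rates=d["tsd_rates"],
            age_histogram=(AgeHistogram(**d["age_histogram"])
                           if d["age_histogram"] is not None else None),
            gene_proximity=[GeneProximityRow(**r) for r in d["gene_proximity"]],
        )


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def compute_dynamics_ratios(clusters: Sequence[LTRCluster]
                            ) -> tuple[list[ClusterRatios], dict, Optional[float]]:
    """Per-cluster and genome-wide S:I / T:I / (S+T):I ratios.

    Clusters without intact members contribute to the genome totals but
    are excluded from per-cluster ratios and from the denominator of the
    proportion of clusters with S:I > 3.
    """
    if not clusters:
        raise ValueError("no clusters")
    rows = []
    for cl in sorted(clusters, key=lambda c: c.cluster_id):
        i, s, t = cl.n_I, cl.n_S, cl.n_T
        rows.append(ClusterRatios(
            cl.cluster_id, i, s, t,
            _ratio(s, i), _ratio(t, i), _ratio(s + t, i),
        ))
    ti = sum(r.I for r in rows)
    ts = sum(r.S for r in rows)
    tt = sum(r.T for r in rows)
    if ti == 0:
        warnings.warn("no intact elements: genome-wide ratios are undefined "
                      "and reported absent", stacklevel=2)
    totals = {
        "I": ti, "S": ts, "T": tt,
        "S_to_I": _ratio(ts, ti),
        "T_to_I": _ratio(tt, ti),
        "ST_to_I": _ratio(ts + tt, ti),
    }
    with_i = [r for r in rows if r.I > 0]
    prop = (sum(1 for r in with_i if r.S_to_I > 3) / len(with_i)
            if with_i else None)
    return rows, totals, prop


def age_histogram(ages_mya: Sequence[float], bin_width: float = 1.0,
                  max_age: float = 20.0, n_saturated: int = 0) -> AgeHistogram:
    """Bin ages into half-open 1-Mya bins with an overflow bin at max_age."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    ages = np.asarray(list(ages_mya), dtype=float)
    if (ages < 0).any():
        raise ValueError("negative age")
    n_bins = int(math.ceil(max_age / bin_width))
    idx = np.floor(ages / bin_width).astype(int)
    overflow = int((idx >= n_bins).sum())
    counts = np.bincount(idx[idx < n_bins], minlength=n_bins)
    return AgeHistogram(bin_width, max_age, [int(c) for c in counts],
                        overflow, n_saturated)


def gene_proximity(elements: dict[str, GenomicInterval],
                   genes: Sequence[GeneAnnotation]) -> list[GeneProximityRow]:
    """Distance from each element to its nearest gene on the same sequence.

    Distance is the gap in bp (0 with overlapping=True when the intervals
    intersect); ties go to the lower-coordinate gene; elements on
    sequences without genes get an absent distance.
    """
    by_seq: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_seq.setdefault(g.interval.seq_id, []).append(g)
    for gl in by_seq.values():
        gl.sort(key=lambda g: (g.interval.start, g.gene_id))
    rows = []
    for eid in sorted(elements):
        iv = elements[eid]
        best: Optional[tuple[int, int, str, bool]] = None
        for g in by_seq.get(iv.seq_id, []):
            gi = g.interval
            ov = iv.overlaps(gi)
            if ov:
                gap = 0
            elif gi.end <= iv.start:
                gap = iv.start - gi.end
            else:
                gap = gi.start - iv.end
            key = (gap, gi.start, g.gene_id, ov)
            if best is None or key[:3] < best[:3]:
                best = key
        if best is None:
            rows.append(GeneProximityRow(eid, None, None, False))
        else:
            rows.append(GeneProximityRow(eid, best[2], best[0], best[3]))
    return rows


def tsd_rates(tsd_by_category: dict[str, list[bool]]) -> dict:
    """Fraction of elements with a detected TSD per category."""
    out = {}
    for cat, flags in sorted(tsd_by_category.items()):
        out[cat] = (sum(flags) / len(flags)) if flags else None
    return out


def build_report(clusters: Sequence[LTRCluster],
                 ages_mya: dict[str, float],
                 saturated_ids: Sequence[str] = (),
                 tsd_by_category: Optional[dict[str, list[bool]]] = None,
                 elements: Optional[dict[str, GenomicInterval]] = None,
                 genes: Optional[Sequence[GeneAnnotation]] = None,
                 bin_width: float = 1.0, max_age: float = 20.0) -> DynamicsReport:
    """Assemble the full dynamics report; ids must be consistent: every
    dated element must be a cluster member."""
    members = set()
    for cl in clusters:
        members.update(cl.members_I)
    for eid in list(ages_mya) + list(saturated_ids):
        if eid not in members:
            raise ValueError(f"dated element {eid} is not a cluster member")
    per_cluster, totals, prop = compute_dynamics_ratios(clusters)
    hist = age_histogram(list(ages_mya.values()), bin_width, max_age,
                         n_saturated=len(saturated_ids))
    prox = gene_proximity(elements, genes) if elements and genes else []
    return DynamicsReport(
        per_cluster=per_cluster, totals=totals, prop_clusters_SI_gt3=prop,
        tsd_rates=tsd_rates(tsd_by_category or {}),
        age_histogram=hist, gene_proximity=prox,
    )


def per_cluster_table(report: DynamicsReport) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in report.per_cluster])


def gene_proximity_table(report: DynamicsReport) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in report.gene_proximity])


def plot_age_histogram(hist: AgeHistogram, path: str | os.PathLike,
                       title: str = "LTR-RT insertion ages") -> None:
    """Write a bar chart of the binned insertion ages (Mya) to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    edges = [k * hist.bin_width for k in range(len(hist.counts))]
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.bar(edges, hist.counts, width=hist.bin_width * 0.9, align="edge",
           color="#4477aa")
    if hist.overflow:
        ax.bar([hist.max_age], [hist.overflow], width=hist.bin_width * 0.9,
               align="edge", color="#cc6677",
               label=f">= {hist.max_age:g} Mya")
        ax.legend(frameon=False)
    ax.set_xlabel("insertion time (Mya)")
    ax.set_ylabel("elements")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


#: summary distance bins (bp) expressing the "3-5 kb from genes" pattern
DISTANCE_BINS = (0, 1000, 3000, 5000, 10000)


def distance_bin_label(distance: Optional[int], overlapping: bool) -> str:
    if distance is None:
        return "no_gene"
    if overlapping:
        return "overlap"
    edges = DISTANCE_BINS
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo <= distance < hi:
            return f"{lo // 1000}-{hi // 1000}kb"
    return f">{edges[-1] // 1000}kb"
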