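"""Single-linkage family/superfamily clustering of LTR sequences.

Two 5'-LTRs belong to the same cluster when their best local alignment
mutually covers at least 70% of BOTH sequences' lengths with an identity
of at least 60% (superfamily level) or 80% (family level); clusters are
the connected components of the resulting graph, so any chain of
qualifying matches merges groups. Solo and truncated remnants are then
attached to the cluster of their most similar intact 5'-LTR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx

from .align import local_align
from .model import LTRCluster


@dataclass
class ClusterParams:
    min_mutual_coverage: float = 0.70
    min_identity: float = 60.0          # 60 = superfamily, 80 = family
    level_label: str = "superfamily"

    def __post_init__(self) -> None:
        if not 0 < self.min_mutual_coverage <= 1:
            raise ValueError("min_mutual_coverage must be in (0, 1]")
        if not 0 < self.min_identity <= 100:
            raise ValueError("min_identity must be in (0, 100]")

    @classmethod
    def family(cls) -> "ClusterParams":
        return cls(min_identity=80.0, level_label="family")

    @classmethod
    def superfamily(cls) -> "ClusterParams":
        return cls(min_identity=60.0, level_label="superfamily")


Edge = tuple[str, str, float, float, float]  # id_a, id_b, identity, cov_a, cov_b


def qualifying_alignment(seq_a: str, seq_b: str, params: ClusterParams
                         ) -> Optional[tuple[float, float, float, float]]:
    """(score, identity, cov_a, cov_b) of the best local alignment when it
    passes the mutual-coverage and identity thresholds, else None."""
    summ = local_align(seq_a, seq_b)
    if summ.columns == 0:
        return None
    cov_a = summ.target_aligned / len(seq_a)
    cov_b = summ.query_aligned / len(seq_b)
    if cov_a < params.min_mutual_coverage or cov_b < params.min_mutual_coverage:
        return None
    if summ.identity < params.min_identity:
        return None
    return summ.score, summ.identity, cov_a, cov_b


def build_similarity_edges(ltr_seqs: dict[str, str],
                           params: ClusterParams | None = None) -> list[Edge]:
    """All-vs-all comparison of 5'-LTR sequences into qualifying edges."""
    if not ltr_seqs:
        raise ValueError("no LTR sequences to compare")
    params = params or ClusterParams()
    ids = sorted(ltr_seqs)
    edges: list[Edge] = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            q = qualifying_alignment(ltr_seqs[a], ltr_seqs[b], params)
            if q is not None:
                _, identity, cov_a, cov_b = q
                edges.append((a, b, identity, cov_a, cov_b))
    return edges


def single_linkage_clusters(nodes: list[str], edges: list[Edge]) -> list[LTRCluster]:
    """Connected components of the qualifying-edge graph (Silix semantics).

    The cluster id is the lexicographically smallest member id; clusters
    are returned sorted by cluster id, members sorted within.
    """
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from((a, b) for a, b, *_ in edges)
    clusters = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        clusters.append(LTRCluster(cluster_id=members[0], members_I=members))
    clusters.sort(key=lambda c: c.cluster_id)
    return clusters


def assign_remnants_to_clusters(
    remnant_seqs: dict[str, str],
    remnant_categories: dict[str, str],
    clusters: list[LTRCluster],
    intact_ltrs: dict[str, str],
    params: ClusterParams | None = None,
) -> tuple[list[LTRCluster], list[str]]:
    """Attach each remnant to the cluster of its best-aligning intact 5'-LTR.

    Best = highest alignment score, ties broken by higher identity then
    lowest intact id; the remnant-to-intact alignment must itself satisfy
    the clustering thresholds, otherwise the remnant is left unassigned.
    Returns (clusters, unassigned remnant ids); cluster I membership is
    unchanged.
    """
    params = params or ClusterParams()
    by_member: dict[str, LTRCluster] = {}
    for cl in clusters:
        for m in cl.members_I:
            by_member[m] = cl
    unassigned: list[str] = []
    for rid in sorted(remnant_seqs):
        best: Optional[tuple[float, float, str]] = None
        for iid in sorted(intact_ltrs):
            q = qualifying_alignment(remnant_seqs[rid], intact_ltrs[iid], params)
            if q is None:
                continue
            score, identity, *_ = q
            key = (-score, -identity, iid)
            if best is None or key < best:
                best = key
        if best is None:
            unassigned.append(rid)
            continue
        target = by_member[best[2]]
        cat = remnant_categories.get(rid, "SOLO")
        if cat == "SOLO":
            target.members_S.append(rid)
        elif cat == "TRUNCATED":
            target.members_T.append(rid)
        else:  # AMBIGUOUS remnants are not counted in S or T
            unassigned.append(rid)
    return clusters, unassigned
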