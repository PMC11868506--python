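"""Nested, taxonomically-informed clustering of ASVs from kingdom to species.

Within each cluster at the previous rank, ASVs carrying an assigned name at
the current rank seed *cluster cores*.  Unidentified ASVs are matched to
their nearest core member; matches above the rank's similarity cut-off (and
coverage requirement at genus/species) join the core and extend it, and the
pass repeats until no new matches are found — approximate single-linkage
growth.  The residue is clustered de novo by single linkage (connected
components of the thresholded similarity graph) and each de novo cluster
receives a unique pseudotaxon name anchored to its nearest named supertaxon,
e.g. ``pseudo_class_Ascomycota_1234``.  Species-level clusters are OTUs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .assigner import COVERAGE_REQUIREMENTS, AssignmentResult
from .cutoffs import CutoffTable
from .io_formats import RANKS, UNIDENTIFIED, Lineage


@dataclass
class Cluster:
    rank: str | None  # None for the synthetic root
    taxon_name: str
    lineage: Lineage
    member_asv_ids: list[str]
    parent_cluster_id: str | None = None
    is_core_named: bool = False
    cluster_id: str = ""


@dataclass
class OtuRecord:
    otu_id: str
    representative_asv_id: str
    member_asv_ids: list[str]
    lineage: Lineage
    total_count: int = 0


class PseudotaxonNamer:
    """Allocates run-unique pseudotaxon serials, one counter per rank."""

    def __init__(self) -> None:
        self._serials: dict[str, int] = {}

    def next_serial(self, rank: str) -> int:
        self._serials[rank] = self._serials.get(rank, 0) + 1
        return self._serials[rank]


def nearest_named_anchor(parent_lineage: Lineage) -> str:
    """Deepest non-pseudo, identified name in the parent lineage.

    Falls back to the kingdom name, or ``"root"`` for fully unidentified
    parents (non-fungal residue under the synthetic root).
    """
    for i in range(6, -1, -1):
        name = parent_lineage.names[i]
        if name != UNIDENTIFIED and not parent_lineage.pseudotaxon[i]:
            return name
    return "root"


def name_pseudotaxon(rank: str, parent_lineage: Lineage, serial: int) -> str:
    """``pseudo_<rank>_<nearest named supertaxon>_<serial>``."""
    return f"pseudo_{rank}_{nearest_named_anchor(parent_lineage)}_{serial}"


def _passes(scorer, a: str, b: str, cutoff: float, cov_req: float | None) -> tuple[bool, float]:
    hit = scorer.pair(a, b)
    if hit is None:
        return False, 0.0
    if cov_req is not None and hit.coverage < cov_req:
        return False, hit.score
    return hit.score >= cutoff, hit.score


def closed_reference_pass(
    unassigned: Sequence[str],
    cores: Mapping[str, Sequence[str]],
    cutoff: float,
    cov_req: float | None,
    scorer,
) -> tuple[dict[str, str], list[str]]:
    """Iteratively match unassigned ASVs to their nearest cluster core.

    All cores compete simultaneously within a pass (batch update): each
    unassigned ASV whose best qualifying score against any current core
    member clears the cut-off joins that core; newly joined members extend
    the core for the next pass, so chains form (approximate single linkage).
    Ties between cores: highest score, then larger core, then
    lexicographically smallest taxon name.

    Returns the asv -> core-name mapping and the residue, both
    deterministically ordered.
    """
    cores_now: dict[str, list[str]] = {
        name: sorted(members) for name, members in cores.items()
    }
    remaining = sorted(unassigned)
    assignments: dict[str, str] = {}
    if not cores_now:
        return assignments, remaining
    while remaining:
        joins: list[tuple[str, str]] = []
        for asv in remaining:
            best: tuple[float, int, str] | None = None  # (score, core size, name)
            for name in sorted(cores_now):
                members = cores_now[name]
                for member in members:
                    ok, score = _passes(scorer, asv, member, cutoff, cov_req)
                    if not ok:
                        continue
                    cand = (score, len(members), name)
                    if best is None or (
                        (cand[0], cand[1]) > (best[0], best[1])
                        or ((cand[0], cand[1]) == (best[0], best[1]) and cand[2] < best[2])
                    ):
                        best = cand
            if best is not None:
                joins.append((asv, best[2]))
        if not joins:
            break
        for asv, name in joins:  # batch update after the pass
            assignments[asv] = name
            cores_now[name].append(asv)
            remaining.remove(asv)
        for name in cores_now:
            cores_now[name].sort()
    return assignments, remaining


def denovo_single_linkage(
    asvs: Sequence[str],
    cutoff: float,
    cov_req: float | None,
    scorer,
) -> list[list[str]]:
    """Single-linkage de novo clusters: connected components of the
    thresholded similarity graph.  Deterministic ordering by smallest member
    id; members sorted within clusters."""
    ids = sorted(asvs)
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            ok, _ = _passes(scorer, a, b, cutoff, cov_req)
            if ok:
                graph.add_edge(a, b)
    comps = [sorted(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: c[0])
    return comps


def nested_cluster(
    asv_ids: Sequence[str],
    assignments: Mapping[str, AssignmentResult],
    cutoff_table: CutoffTable,
    scorer,
    totals: Mapping[str, int] | None = None,
    drop_nonfungal_root: bool = False,
) -> tuple[dict[str, list[Cluster]], list[OtuRecord]]:
    """Cluster ASVs rank by rank within each parent cluster; species clusters
    become OTUs.

    ``totals`` (ASV -> total read count) selects the most abundant member as
    OTU representative (ties -> smallest id).  ASVs unidentified at kingdom
    are clustered within a synthetic root parent; with
    ``drop_nonfungal_root=True`` their clusters are excluded from the OTU set.
    """
    namer = PseudotaxonNamer()
    totals = totals or {}
    root = Cluster(
        rank=None,
        taxon_name="root",
        lineage=Lineage.unidentified(),
        member_asv_ids=sorted(asv_ids),
        cluster_id="root",
    )
    parents = [root]
    by_rank: dict[str, list[Cluster]] = {}
    for rank in RANKS:
        cov_req = COVERAGE_REQUIREMENTS.get(rank)
        children: list[Cluster] = []
        for parent in parents:
            entry = cutoff_table.lookup(parent.lineage, rank)
            cutoff = entry.cutoff
            cores: dict[str, list[str]] = {}
            unassigned: list[str] = []
            for asv in parent.member_asv_ids:
                name = assignments[asv].lineage.name_at(rank)
                if name != UNIDENTIFIED:
                    cores.setdefault(name, []).append(asv)
                else:
                    unassigned.append(asv)
            joined, residue = closed_reference_pass(
                unassigned, cores, cutoff, cov_req, scorer
            )
            for asv, name in joined.items():
                cores[name].append(asv)
            for name in sorted(cores):
                children.append(
                    Cluster(
                        rank=rank,
                        taxon_name=name,
                        lineage=parent.lineage.extended(rank, name),
                        member_asv_ids=sorted(cores[name]),
                        parent_cluster_id=parent.cluster_id,
                        is_core_named=True,
                    )
                )
            for comp in denovo_single_linkage(residue, cutoff, cov_req, scorer):
                serial = namer.next_serial(rank)
                name = name_pseudotaxon(rank, parent.lineage, serial)
                children.append(
                    Cluster(
                        rank=rank,
                        taxon_name=name,
                        lineage=parent.lineage.extended(rank, name, pseudo=True),
                        member_asv_ids=comp,
                        parent_cluster_id=parent.cluster_id,
                        is_core_named=False,
                    )
                )
        # canonical ordering and ids; partition sanity check
        children.sort(key=lambda c: c.member_asv_ids[0])
        seen: set[str] = set()
        for i, c in enumerate(children, start=1):
            c.cluster_id = f"{rank}_{i:05d}"
            for m in c.member_asv_ids:
                if m in seen:
                    raise AssertionError(
                        f"ASV {m} in multiple clusters at rank {rank}"
                    )
                seen.add(m)
        if seen != set(asv_ids):
            raise AssertionError(f"clusters at rank {rank} do not cover all ASVs")
        by_rank[rank] = children
        parents = children

    otus: list[OtuRecord] = []
    n = 0
    for cluster in by_rank["species"]:
        if drop_nonfungal_root and nearest_named_anchor(cluster.lineage) == "root":
            continue
        n += 1
        rep = min(cluster.member_asv_ids, key=lambda a: (-totals.get(a, 0), a))
        otus.append(
            OtuRecord(
                otu_id=f"OTU_{n:05d}",
                representative_asv_id=rep,
                member_asv_ids=list(cluster.member_asv_ids),
                lineage=cluster.lineage,
                total_count=sum(totals.get(a, 0) for a in cluster.member_asv_ids),
            )
        )
    return by_rank, otus
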