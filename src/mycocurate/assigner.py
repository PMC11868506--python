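"""Three-step consensus taxonomy assignment of ASVs from reference hits.

Step 1 — score: hits against the reference database (full, and the
species-only subset) carry coverage-adjusted similarity scores; the top five
per reference set are retained.

Step 2 — filter per rank: a hit supports an assignment at rank *r* only if
its score clears the taxon-specific cut-off for the most specific cut-off
entry matching the subject's lineage, and its coverage clears 90% at genus /
95% at species (no coverage requirement above genus).

Step 3 — consensus: ranks are processed kingdom -> species.  At each rank
the evaluation pool is the species-only retained hits when at least one
survives filtering, otherwise the combined retained hits.  The modal name is
accepted iff its share of the pool is strictly greater than the consensus
threshold (2/3 by default).  The first failing rank truncates the lineage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import pandas as pd

from .cutoffs import CutoffTable, RefDb
from .io_formats import RANKS, UNIDENTIFIED, Lineage
from .pairwise_scoring import Hit

#: Strictly-greater-than consensus threshold ("over 66%" read as > 2/3).
CONSENSUS_THRESHOLD = Fraction(2, 3)

#: Minimum alignment coverage per rank (no requirement above genus).
COVERAGE_REQUIREMENTS: dict[str, float] = {"genus": 0.90, "species": 0.95}

TOP_N_HITS = 5

ARBUSCULAR_PHYLUM = "Glomeromycota"
ARBUSCULAR_LIFESTYLE = "arbuscular_mycorrhizal"


class CutoffConfigError(KeyError):
    """No cut-off found for a (lineage, rank) after all fallbacks."""


@dataclass
class RankDecision:
    retained_hit_count: int
    consensus_fraction: float
    cutoff_used: float | None
    coverage_req_used: float | None
    pool: str  # "species_only" | "combined" | "empty"


@dataclass
class AssignmentResult:
    asv_id: str
    lineage: Lineage
    per_rank: dict[str, RankDecision] = field(default_factory=dict)
    lowest_assigned_rank: str | None = None


def collect_hits(
    asv_id: str,
    refdb: RefDb,
    scorer,
    species_only: RefDb | None = None,
    top_n: int = TOP_N_HITS,
    min_score: float = 0.0,
) -> tuple[list[Hit], list[Hit]]:
    """Top-``top_n`` hits of an ASV against the full and species-only sets.

    Ranked by adjusted score descending, ties by higher coverage then
    lexicographic subject id.  An ASV with no hits returns empty lists (it
    will remain fully unidentified) — never an error.
    """

    def top(db: RefDb) -> list[Hit]:
        hits = []
        for seq, _lin in db.entries:
            if seq.id == asv_id:
                continue
            hit = scorer.pair(asv_id, seq.id)
            if hit is not None and hit.score > min_score:
                hits.append(hit)
        hits.sort(key=lambda h: (-h.score, -h.coverage, h.subject_id))
        return hits[:top_n]

    hits_full = top(refdb)
    hits_sp = top(species_only) if species_only is not None else []
    return hits_full, hits_sp


def filter_hits_for_rank(
    hits: Sequence[Hit],
    rank: str,
    cutoff_table: CutoffTable,
    subject_lineages: Mapping[str, Lineage],
) -> list[Hit]:
    """Hits retained as support at ``rank``: score and coverage rules applied."""
    cov_req = COVERAGE_REQUIREMENTS.get(rank)
    retained = []
    for h in hits:
        lin = subject_lineages[h.subject_id]
        try:
            entry = cutoff_table.lookup(lin, rank)
        except KeyError as exc:
            raise CutoffConfigError(
                f"no cut-off for rank {rank!r} under subject lineage "
                f"{'/'.join(lin.names)}"
            ) from exc
        if h.score < entry.cutoff:
            continue
        if cov_req is not None and h.coverage < cov_req:
            continue
        retained.append(h)
    return retained


def consensus_assign(
    asv_id: str,
    hits_full: Sequence[Hit],
    hits_species_only: Sequence[Hit],
    cutoff_table: CutoffTable,
    subject_lineages: Mapping[str, Lineage],
    consensus_threshold: Fraction | float = CONSENSUS_THRESHOLD,
) -> AssignmentResult:
    """Assign taxonomy rank by rank with species-only preference.

    The modal name's share must be *strictly* greater than the threshold; the
    share denominator is the whole pool, so hits unidentified at the rank
    vote against consensus.  Processing stops at the first failing rank.
    """
    result = AssignmentResult(asv_id=asv_id, lineage=Lineage.unidentified())
    names: list[str] = []
    accession: str | None = None
    for rank in RANKS:
        cov_req = COVERAGE_REQUIREMENTS.get(rank)
        pool_sp = filter_hits_for_rank(
            hits_species_only, rank, cutoff_table, subject_lineages
        )
        if pool_sp:
            pool, pool_name = pool_sp, "species_only"
        else:
            pool = filter_hits_for_rank(
                hits_full, rank, cutoff_table, subject_lineages
            )
            pool_name = "combined" if pool else "empty"
        if not pool:
            result.per_rank[rank] = RankDecision(0, 0.0, None, cov_req, "empty")
            break
        votes = pd.Series(
            [subject_lineages[h.subject_id].name_at(rank) for h in pool]
        )
        named = votes[votes != UNIDENTIFIED]
        cutoff_used = min(
            cutoff_table.lookup(subject_lineages[h.subject_id], rank).cutoff
            for h in pool
        )
        if named.empty:
            result.per_rank[rank] = RankDecision(
                len(pool), 0.0, cutoff_used, cov_req, pool_name
            )
            break
        top = named.value_counts()
        share = Fraction(int(top.iloc[0]), len(pool))
        result.per_rank[rank] = RankDecision(
            len(pool), float(share), cutoff_used, cov_req, pool_name
        )
        if share > consensus_threshold:
            names.append(str(top.index[0]))
            best = min(
                (h for h in pool
                 if subject_lineages[h.subject_id].name_at(rank) == top.index[0]),
                key=lambda h: (-h.score, h.subject_id),
            )
            ref_lin = subject_lineages[best.subject_id]
            accession = ref_lin.reference_accession or best.subject_id
        else:
            break
    result.lineage = Lineage.from_names(names, reference_accession=accession)
    result.lowest_assigned_rank = result.lineage.lowest_assigned_rank
    return result


def assign_all(
    asv_ids: Sequence[str],
    refdb: RefDb,
    scorer,
    cutoff_table: CutoffTable,
    consensus_threshold: Fraction | float = CONSENSUS_THRESHOLD,
) -> dict[str, AssignmentResult]:
    """Consensus-assign every ASV against a reference database."""
    try:
        species_db = refdb.species_only()
    except ValueError:
        species_db = None
    lineages = refdb.lineages
    out: dict[str, AssignmentResult] = {}
    for asv_id in asv_ids:
        hits_full, hits_sp = collect_hits(asv_id, refdb, scorer, species_db)
        out[asv_id] = consensus_assign(
            asv_id,
            hits_full,
            hits_sp,
            cutoff_table,
            lineages,
            consensus_threshold=consensus_threshold,
        )
    return out


def annotate_traits(lineage: Lineage, trait_table: pd.DataFrame) -> dict[str, str]:
    """Join trait annotations on genus name.

    Glomeromycota override: all members of that phylum are arbuscular
    mycorrhizal regardless of genus match (their genus is often
    unidentified).  Unmatched genera yield empty traits.
    """
    traits: dict[str, str] = {c: "" for c in trait_table.columns}
    genus = lineage.name_at("genus")
    if genus != UNIDENTIFIED and genus in trait_table.index:
        traits.update(trait_table.loc[genus].to_dict())
    if lineage.name_at("phylum") == ARBUSCULAR_PHYLUM:
        traits["primary_lifestyle"] = ARBUSCULAR_LIFESTYLE
    return traits
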