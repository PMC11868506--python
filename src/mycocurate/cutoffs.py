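"""Taxon-specific similarity cut-off prediction by F-measure optimisation.

For a set of reference sequences labelled at some rank (the *subrank*), a
similarity threshold ``t`` classifies every unordered sequence pair as
conspecific (score >= t) or not.  Against the true labels this yields

    TP = same-taxon pairs with score >= t      FP = different-taxon, score >= t
    FN = same-taxon pairs with score <  t

and the usual precision/recall/F-measure.  The predicted cut-off is the grid
threshold maximising F, ties broken toward the largest (most conservative)
threshold; the best F achieved is reported as the *confidence*.

Cut-offs are predicted *locally* for every eligible supertaxon-subrank
combination across all higher ranks (species cut-offs for a genus are
predicted within the genus, its family, order, class and phylum), and the
highest-confidence prediction is retained per combination.  Where no local
scope is eligible, *global* cut-offs per phylogenetic group (Dikarya,
terrestrial early-diverging fungi, zoosporic fungi) provide the fallback for
ranks class to species; phylum-level cut-offs are predicted over all fungi
and the kingdom-level entry is derived from (copied from) that phylum entry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import RANKS, RANK_INDEX, UNIDENTIFIED, AsvSeq, Lineage
from .pairwise_scoring import InternalScorer

logger = logging.getLogger(__name__)

ALL_FUNGI = "Fungi"

#: Phylogenetic groups used for global cut-off prediction (class -> species),
#: countering the bias of all-fungi predictions toward Dikarya.
PHYLO_GROUPS: dict[str, frozenset[str]] = {
    "dikarya": frozenset({"Ascomycota", "Basidiomycota", "Entorrhizomycota"}),
    "terrestrial_edf": frozenset(
        {
            "Basidiobolomycota",
            "Calcarisporiellomycota",
            "Entomophthoromycota",
            "Glomeromycota",
            "Kickxellomycota",
            "Mortierellomycota",
            "Mucoromycota",
            "Zoopagomycota",
        }
    ),
    "zoosporic": frozenset(
        {
            "Aphelidiomycota",
            "Blastocladiomycota",
            "Chytridiomycota",
            "Monoblepharomycota",
            "Neocallimastigomycota",
            "Olpidiomycota",
            "Rozellomycota",
            "Sanchytriomycota",
            "GS01",
        }
    ),
}

DEFAULT_GRID = np.round(np.arange(0.500, 1.0005, 0.001), 3)


class IneligibleScopeError(ValueError):
    """The evaluation set does not satisfy the local cut-off eligibility rule."""


@dataclass(frozen=True)
class CutoffEntry:
    supertaxon: str
    supertaxon_rank: str
    subrank: str
    cutoff: float
    confidence: float
    scope: str  # "local" | "global"
    n_taxa: int
    n_seqs: int

    def __post_init__(self) -> None:
        if not 0.5 <= self.cutoff <= 1.0:
            raise ValueError(f"cutoff {self.cutoff} outside [0.5, 1.0]")
        if self.scope not in ("local", "global"):
            raise ValueError(f"unknown scope {self.scope!r}")


@dataclass
class RefDb:
    """Reference database: sequences with 7-rank lineages (UNITE-like)."""

    entries: list[tuple[AsvSeq, Lineage]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("empty reference database")
        for seq, lin in self.entries:
            if lin.name_at("kingdom") == UNIDENTIFIED:
                raise ValueError(f"reference {seq.id} lacks a kingdom assignment")

    @property
    def seqs(self) -> dict[str, str]:
        return {s.id: s.sequence for s, _ in self.entries}

    @property
    def lineages(self) -> dict[str, Lineage]:
        return {s.id: lin for s, lin in self.entries}

    def species_only(self) -> "RefDb":
        """Subset with species-rank names (all 7 ranks assigned)."""
        subset = [
            (s, lin) for s, lin in self.entries if lin.is_assigned_at("species")
        ]
        if not subset:
            raise ValueError("no species-level entries in reference database")
        return RefDb(subset)


# ---------------------------------------------------------------------------
# F-measure machinery
# ---------------------------------------------------------------------------


def pairwise_fmeasure(
    scores: Sequence[float], same_taxon: Sequence[bool], t: float
) -> tuple[float, float, float]:
    """Precision, recall and F-measure of threshold ``t`` on labelled pairs.

    ``scores`` are adjusted similarities of all unordered pairs in the
    evaluation set; ``same_taxon`` marks pairs whose members share the taxon
    at the subrank.  0/0 ratios are defined as 0.
    """
    scores = np.asarray(scores, dtype=float)
    same = np.asarray(same_taxon, dtype=bool)
    if scores.shape != same.shape:
        raise ValueError("scores and labels differ in length")
    if scores.size == 0:
        raise ValueError("need at least one pair (two sequences)")
    pos = scores >= t
    tp = int(np.sum(pos & same))
    fp = int(np.sum(pos & ~same))
    fn = int(np.sum(~pos & same))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f


def optimize_threshold(
    scores: np.ndarray, same_taxon: np.ndarray, grid: np.ndarray = DEFAULT_GRID
) -> tuple[float, float]:
    """Grid threshold maximising F; ties broken toward the largest threshold."""
    scores = np.asarray(scores, dtype=float)
    same = np.asarray(same_taxon, dtype=bool)
    if scores.size == 0:
        raise ValueError("need at least one pair (two sequences)")
    same_sorted = np.sort(scores[same])
    diff_sorted = np.sort(scores[~same])
    n_same = same_sorted.size
    # pairs with score >= t, via sorted counts
    tp = n_same - np.searchsorted(same_sorted, grid, side="left")
    fp = diff_sorted.size - np.searchsorted(diff_sorted, grid, side="left")
    fn = n_same - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        recall = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
        denom = precision + recall
        f = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    best_f = f.max()
    # ties -> largest grid threshold (most conservative)
    best_idx = np.flatnonzero(f == best_f)[-1]
    return float(grid[best_idx]), float(best_f)


def check_eligibility(
    labels: Sequence[str],
    min_taxa: int = 10,
    min_seqs: int = 30,
    max_taxon_fraction: float = 0.5,
    min_seqs_per_taxon: int | None = None,
) -> None:
    """Raise :class:`IneligibleScopeError` unless the evaluation set qualifies.

    Default reading: >= ``min_taxa`` distinct taxa AND >= ``min_seqs``
    sequences in total, with no single taxon holding >= ``max_taxon_fraction``
    of the sequences.  ``min_seqs_per_taxon`` switches on the stricter
    per-taxon reading.
    """
    counts = pd.Series(list(labels)).value_counts()
    n_seqs = int(counts.sum())
    if len(counts) < min_taxa:
        raise IneligibleScopeError(
            f"only {len(counts)} taxa (< {min_taxa} required)"
        )
    if n_seqs < min_seqs:
        raise IneligibleScopeError(f"only {n_seqs} sequences (< {min_seqs})")
    if counts.iloc[0] / n_seqs >= max_taxon_fraction:
        raise IneligibleScopeError(
            f"taxon {counts.index[0]!r} holds {counts.iloc[0] / n_seqs:.0%} "
            f"of sequences (>= {max_taxon_fraction:.0%})"
        )
    if min_seqs_per_taxon is not None and counts.min() < min_seqs_per_taxon:
        raise IneligibleScopeError(
            f"some taxa have < {min_seqs_per_taxon} sequences"
        )


def _pair_data(
    members: Sequence[tuple[str, str]],
    scorer,
    max_pairs: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Adjusted scores and same-taxon flags over all unordered member pairs.

    ``members`` is (sequence id, taxon label).  For very large scopes the
    pair set is subsampled uniformly with a fixed seed (``max_pairs``).
    """
    n = len(members)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[k] for k in sorted(idx)]
    scores = np.empty(len(pairs))
    same = np.empty(len(pairs), dtype=bool)
    for k, (i, j) in enumerate(pairs):
        scores[k] = scorer.score(members[i][0], members[j][0])
        same[k] = members[i][1] == members[j][1]
    return scores, same


def predict_cutoff(
    refset: Sequence[tuple[str, str]],
    subrank: str,
    scorer,
    supertaxon: str,
    supertaxon_rank: str,
    grid: np.ndarray = DEFAULT_GRID,
    scope: str = "local",
    eligibility: bool = True,
    max_pairs: int | None = None,
    seed: int = 0,
    **eligibility_kwargs,
) -> CutoffEntry:
    """Predict the cut-off for one (supertaxon, subrank) evaluation set.

    ``refset`` is (sequence id, taxon label at subrank) for every sequence in
    the supertaxon's scope that is labelled at the subrank.
    """
    if len(refset) < 2:
        raise IneligibleScopeError("fewer than 2 sequences in scope")
    labels = [lab for _, lab in refset]
    if eligibility:
        check_eligibility(labels, **eligibility_kwargs)
    if len(set(labels)) < 2:
        raise IneligibleScopeError("only one taxon in scope")
    scores, same = _pair_data(refset, scorer, max_pairs=max_pairs, seed=seed)
    cutoff, best_f = optimize_threshold(scores, same, grid)
    return CutoffEntry(
        supertaxon=supertaxon,
        supertaxon_rank=supertaxon_rank,
        subrank=subrank,
        cutoff=cutoff,
        confidence=best_f,
        scope=scope,
        n_taxa=len(set(labels)),
        n_seqs=len(refset),
    )


# ---------------------------------------------------------------------------
# cut-off table
# ---------------------------------------------------------------------------


@dataclass
class CutoffTable:
    """(supertaxon, subrank) -> cut-off, with hierarchical lookup fallback."""

    entries: dict[tuple[str, str], CutoffEntry] = field(default_factory=dict)
    group_of_phylum: dict[str, str] = field(default_factory=dict)

    def add(self, key_taxon: str, entry: CutoffEntry) -> None:
        self.entries[(key_taxon, entry.subrank)] = entry

    def get(self, supertaxon: str, subrank: str) -> CutoffEntry | None:
        return self.entries.get((supertaxon, subrank))

    def lookup(self, lineage: Lineage, subrank: str) -> CutoffEntry:
        """Most specific applicable cut-off for assigning/clustering ``subrank``.

        Fallback order: named supertaxa of the lineage from most specific to
        kingdom, then the phylogenetic-group global, then the all-fungi
        entry.  Pseudotaxon supertaxa are skipped (they carry no reference
        signal).
        """
        sub_i = RANK_INDEX[subrank]
        for i in range(sub_i - 1, -1, -1):
            name = lineage.names[i]
            if name == UNIDENTIFIED or lineage.pseudotaxon[i]:
                continue
            entry = self.entries.get((name, subrank))
            if entry is not None:
                return entry
        phylum = lineage.name_at("phylum")
        group = self.group_of_phylum.get(phylum)
        if group is not None:
            entry = self.entries.get((group, subrank))
            if entry is not None:
                return entry
        entry = self.entries.get((ALL_FUNGI, subrank))
        if entry is not None:
            return entry
        raise KeyError(
            f"no cut-off available for subrank {subrank!r} under lineage "
            f"{'/'.join(lineage.names)}"
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "supertaxon": key_taxon,
                "supertaxon_rank": e.supertaxon_rank,
                "subrank": e.subrank,
                "cutoff": e.cutoff,
                "confidence": e.confidence,
                "scope": e.scope,
                "n_taxa": e.n_taxa,
                "n_seqs": e.n_seqs,
            }
            for (key_taxon, _), e in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path, group_of_phylum: dict[str, str] | None = None) -> "CutoffTable":
        df = pd.read_csv(path, sep="\t")
        table = cls(group_of_phylum=group_of_phylum or {})
        for row in df.itertuples(index=False):
            entry = CutoffEntry(
                supertaxon=row.supertaxon,
                supertaxon_rank=row.supertaxon_rank,
                subrank=row.subrank,
                cutoff=float(row.cutoff),
                confidence=float(row.confidence),
                scope=row.scope,
                n_taxa=int(row.n_taxa),
                n_seqs=int(row.n_seqs),
            )
            table.add(row.supertaxon, entry)
        return table


def _group_membership(groups: Mapping[str, Iterable[str]]) -> dict[str, str]:
    out: dict[str, str] = {}
    for group, phyla in groups.items():
        for p in phyla:
            if p in out:
                raise ValueError(f"phylum {p!r} in multiple phylogenetic groups")
            out[p] = group
    return out


def select_cutoffs(
    refdb: RefDb,
    groups: Mapping[str, Iterable[str]] = PHYLO_GROUPS,
    scorer=None,
    grid: np.ndarray = DEFAULT_GRID,
    max_pairs: int | None = 200_000,
    seed: int = 0,
    **eligibility_kwargs,
) -> CutoffTable:
    """Predict and retain cut-offs for the whole reference database.

    1. Local entries for every eligible (supertaxon, subrank) combination,
       computed across all higher ranks; per combination the
       highest-confidence prediction among the supertaxon and its ancestors
       is retained (ties -> most specific scope).
    2. Global entries per phylogenetic group for subranks class -> species
       (fallback where no local entry matched).
    3. A phylum-level entry over all fungi; the kingdom-level entry is
       derived from it by copying.
    """
    if scorer is None:
        scorer = InternalScorer(refdb.seqs)
    lineages = refdb.lineages
    membership = _group_membership(groups)

    # taxa per rank with their member sequence ids
    taxa_members: dict[tuple[str, str], list[str]] = {}
    for sid, lin in lineages.items():
        for i, rank in enumerate(RANKS):
            name = lin.names[i]
            if name != UNIDENTIFIED and not lin.pseudotaxon[i]:
                taxa_members.setdefault((rank, name), []).append(sid)

    def labelled(members: Iterable[str], subrank: str) -> list[tuple[str, str]]:
        out = []
        for sid in members:
            lab = lineages[sid].name_at(subrank)
            if lab != UNIDENTIFIED:
                out.append((sid, lab))
        return out

    # raw local predictions per (scope taxon, subrank)
    raw: dict[tuple[str, str], CutoffEntry] = {}
    for (rank, name), members in taxa_members.items():
        rank_i = RANK_INDEX[rank]
        for subrank in RANKS[rank_i + 1 :]:
            if subrank == "phylum":
                continue  # phylum cut-offs are predicted over all fungi only
            refset = labelled(members, subrank)
            try:
                entry = predict_cutoff(
                    refset,
                    subrank,
                    scorer,
                    supertaxon=name,
                    supertaxon_rank=rank,
                    grid=grid,
                    max_pairs=max_pairs,
                    seed=seed,
                    **eligibility_kwargs,
                )
            except IneligibleScopeError:
                continue
            raw[(name, subrank)] = entry

    table = CutoffTable(group_of_phylum=membership)

    # retain per (supertaxon, subrank) the highest-confidence prediction among
    # the supertaxon's own scope and its ancestors; ties -> most specific
    for (rank, name), _members in taxa_members.items():
        any_member = _members[0]
        lin = lineages[any_member]
        rank_i = RANK_INDEX[rank]
        for subrank in RANKS[rank_i + 1 :]:
            if subrank == "phylum":
                continue
            candidates: list[tuple[float, int, CutoffEntry]] = []
            # walk from this taxon (most specific) up through its ancestors
            for i in range(rank_i, -1, -1):
                anc = lin.names[i]
                if anc == UNIDENTIFIED or lin.pseudotaxon[i]:
                    continue
                e = raw.get((anc, subrank))
                if e is not None:
                    candidates.append((e.confidence, i, e))
            if not candidates:
                continue
            # highest confidence; ties toward the deepest (most specific) scope
            best = max(candidates, key=lambda c: (c[0], c[1]))[2]
            table.add(name, best)

    # global entries per phylogenetic group, class -> species
    for group, phyla in groups.items():
        members = [
            sid for sid, lin in lineages.items() if lin.name_at("phylum") in phyla
        ]
        for subrank in ("class", "order", "family", "genus", "species"):
            refset = labelled(members, subrank)
            try:
                entry = predict_cutoff(
                    refset,
                    subrank,
                    scorer,
                    supertaxon=group,
                    supertaxon_rank="kingdom",
                    grid=grid,
                    scope="global",
                    eligibility=False,
                    max_pairs=max_pairs,
                    seed=seed,
                )
            except IneligibleScopeError as exc:
                logger.info("no global %s cut-off for %s: %s", subrank, group, exc)
                continue
            table.add(group, entry)

    # all-fungi entries: phylum level plus class->species fallbacks
    all_ids = list(lineages)
    for subrank in ("phylum", "class", "order", "family", "genus", "species"):
        refset = labelled(all_ids, subrank)
        try:
            entry = predict_cutoff(
                refset,
                subrank,
                scorer,
                supertaxon=ALL_FUNGI,
                supertaxon_rank="kingdom",
                grid=grid,
                scope="global",
                eligibility=False,
                max_pairs=max_pairs,
                seed=seed,
            )
        except IneligibleScopeError as exc:
            logger.info("no all-fungi %s cut-off: %s", subrank, exc)
            continue
        table.add(ALL_FUNGI, entry)

    # kingdom-level cut-off derived from the all-fungi phylum entry
    phylum_entry = table.get(ALL_FUNGI, "phylum")
    if phylum_entry is not None:
        table.add(
            ALL_FUNGI,
            CutoffEntry(
                supertaxon=ALL_FUNGI,
                supertaxon_rank="kingdom",
                subrank="kingdom",
                cutoff=phylum_entry.cutoff,
                confidence=phylum_entry.confidence,
                scope="global",
                n_taxa=phylum_entry.n_taxa,
                n_seqs=phylum_entry.n_seqs,
            ),
        )

    return table
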