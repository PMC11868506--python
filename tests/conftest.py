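"""Shared fixtures: a seeded synthetic reference database / community set and
lightweight scorer stubs for exercising clustering and assignment logic
without alignments."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mycocurate.cutoffs import ALL_FUNGI, CutoffEntry, CutoffTable, PHYLO_GROUPS
from mycocurate.io_formats import RANKS, CountMatrix
from mycocurate.pairwise_scoring import Hit, InternalScorer
from mycocurate.simdata import SimConfig, make_communities, make_reference_db


class DictScorer:
    """Scorer stub returning preset adjusted scores (full coverage)."""

    def __init__(self, scores: dict[tuple[str, str], float], seq_len: int = 100):
        self._scores = {}
        for (a, b), s in scores.items():
            self._scores[(a, b)] = s
            self._scores[(b, a)] = s
        self._len = seq_len

    def pair(self, a: str, b: str) -> Hit:
        s = self._scores.get((a, b), 0.0)
        return Hit(
            query_id=a,
            subject_id=b,
            identity=s,
            aln_len=self._len,
            query_len=self._len,
            subject_len=self._len,
        )

    def score(self, a: str, b: str) -> float:
        return self.pair(a, b).score


def flat_cutoff_table(cutoff: float = 0.9, per_rank: dict | None = None) -> CutoffTable:
    """All-fungi global cut-off table with one entry per rank."""
    table = CutoffTable(group_of_phylum={p: g for g, ps in PHYLO_GROUPS.items() for p in ps})
    for rank in RANKS:
        table.add(
            ALL_FUNGI,
            CutoffEntry(
                supertaxon=ALL_FUNGI,
                supertaxon_rank="kingdom",
                subrank=rank,
                cutoff=(per_rank or {}).get(rank, cutoff),
                confidence=1.0,
                scope="global",
                n_taxa=2,
                n_seqs=2,
            ),
        )
    return table


def small_matrix(
    counts: dict[str, dict[str, int]],
    library: dict[str, str] | str = "LIB01",
    role: dict[str, str] | None = None,
    plot: dict[str, str] | None = None,
    region: dict[str, str] | str = "australia",
) -> CountMatrix:
    """Build a CountMatrix from nested dicts with minimal metadata."""
    df = pd.DataFrame(counts).T.fillna(0).astype("int64")
    samples = list(df.index)
    meta = pd.DataFrame(
        {
            "library_id": [
                library[s] if isinstance(library, dict) else library for s in samples
            ],
            "plot_id": [(plot or {}).get(s, f"plot_{s}") for s in samples],
            "role": [(role or {}).get(s, "specimen") for s in samples],
            "region": [
                region[s] if isinstance(region, dict) else region for s in samples
            ],
        },
        index=samples,
    )
    return CountMatrix(df, meta)


@pytest.fixture(scope="session")
def sim_cfg() -> SimConfig:
    return SimConfig(rng_seed=7)


@pytest.fixture(scope="session")
def refdb(sim_cfg):
    return make_reference_db(sim_cfg)


@pytest.fixture(scope="session")
def communities(sim_cfg, refdb):
    return make_communities(sim_cfg, refdb)


@pytest.fixture(scope="session")
def ref_scorer(refdb):
    return InternalScorer(refdb.seqs)


@pytest.fixture()
def rng():
    # fresh, fixed-seed generator per test so tests stay order-independent
    return np.random.default_rng(20240901)
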