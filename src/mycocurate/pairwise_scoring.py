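"""Coverage- and length-adjusted similarity scoring of sequence pairs.

Short local alignments can report near-perfect percent identity while
covering only a fraction of either sequence, inflating apparent similarity.
Every score in this toolkit is therefore the *adjusted similarity*::

    coverage = min(1, alignment_length / min(query_length, subject_length))
    score    = identity                if coverage >= 1
             = identity * coverage    otherwise

so that a partial alignment can never outscore a full-length one at the same
identity.  Scores live in [0, 1].

Two backends satisfy the all-vs-all scoring contract:

* ``internal`` — a deterministic global (Needleman-Wunsch) aligner built on
  edlib; identity = matched columns / total alignment columns.
* ``import``  — pre-computed 12-column hit tables (BLAST ``outfmt 6``)
  parsed by :mod:`mycocurate.io_formats` with sequence lengths attached.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


class BackendUnavailableError(RuntimeError):
    """Raised when the requested scoring backend cannot run.

    The remedy is to import a pre-computed hit table instead
    (``scoring.backend = "import"``).
    """


@dataclass(frozen=True)
class Hit:
    """One pairwise alignment record.

    ``identity`` is a fraction in [0, 1]; ``aln_len`` counts alignment
    columns.  ``query_len``/``subject_len`` are required for ``coverage`` and
    ``score`` and may be attached after parsing with :func:`with_lengths`.
    The remaining fields carry the imported tabular dialect and are never
    recomputed.
    """

    query_id: str
    subject_id: str
    identity: float
    aln_len: int
    query_len: int | None = None
    subject_len: int | None = None
    mismatch: int | None = None
    gapopen: int | None = None
    qstart: int | None = None
    qend: int | None = None
    sstart: int | None = None
    send: int | None = None
    evalue: float | None = None
    bitscore: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0, 1]")
        if self.aln_len <= 0:
            raise ValueError(f"alignment length must be positive, got {self.aln_len}")

    @property
    def coverage(self) -> float:
        """Fraction of the shorter sequence covered by the alignment, capped at 1."""
        if self.query_len is None or self.subject_len is None:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id} lacks sequence lengths; "
                "attach them with with_lengths()"
            )
        if self.query_len <= 0 or self.subject_len <= 0:
            raise ValueError("sequence lengths must be positive")
        return min(1.0, self.aln_len / min(self.query_len, self.subject_len))

    @property
    def score(self) -> float:
        """Adjusted similarity: identity down-weighted by coverage."""
        cov = self.coverage
        return self.identity if cov >= 1.0 else self.identity * cov


def coverage(hit: Hit, query_len: int | None = None, subject_len: int | None = None) -> float:
    """Coverage of the shorter sequence; lengths override the hit's own."""
    if query_len is not None or subject_len is not None:
        hit = replace(hit, query_len=query_len, subject_len=subject_len)
    return hit.coverage


def adjusted_similarity(hit: Hit) -> float:
    """Identity multiplied by coverage when coverage < 1, identity otherwise."""
    return hit.score


def with_lengths(hits: Iterable[Hit], lengths: Mapping[str, int]) -> list[Hit]:
    """Attach query/subject sequence lengths (e.g. from FASTA) to parsed hits."""
    out = []
    for h in hits:
        out.append(
            replace(
                h,
                query_len=lengths[h.query_id],
                subject_len=lengths[h.subject_id],
            )
        )
    return out


# ---------------------------------------------------------------------------
# internal aligner backend
# ---------------------------------------------------------------------------


def align_pair(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Globally align two sequences; return (identity, alignment columns).

    Unit-cost Needleman-Wunsch via edlib; identity is matched columns over
    total columns of the optimal alignment path.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequences")
    res = edlib.align(seq_a, seq_b, mode="NW", task="path")
    columns = 0
    matches = 0
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n)
        columns += n
        if op == "=":
            matches += n
    return matches / columns, columns


class InternalScorer:
    """Cached pairwise scorer over an in-memory set of sequences.

    ``pair(a, b)`` returns a :class:`Hit` for the ordered pair (alignment is
    symmetric, so the cache is keyed on the unordered pair).
    """

    def __init__(self, seqs: Mapping[str, str]):
        if not seqs:
            raise ValueError("scorer requires at least one sequence")
        self._seqs = dict(seqs)
        self._cache: dict[tuple[str, str], tuple[float, int]] = {}

    @property
    def ids(self) -> list[str]:
        return list(self._seqs)

    def has(self, seq_id: str) -> bool:
        return seq_id in self._seqs

    def pair(self, query_id: str, subject_id: str) -> Hit:
        key = (query_id, subject_id) if query_id <= subject_id else (subject_id, query_id)
        cached = self._cache.get(key)
        if cached is None:
            cached = align_pair(self._seqs[query_id], self._seqs[subject_id])
            self._cache[key] = cached
        identity, columns = cached
        return Hit(
            query_id=query_id,
            subject_id=subject_id,
            identity=identity,
            aln_len=columns,
            query_len=len(self._seqs[query_id]),
            subject_len=len(self._seqs[subject_id]),
        )

    def score(self, a: str, b: str) -> float:
        return self.pair(a, b).score


class HitTableScorer:
    """Scorer backed by an imported hit table (best hit per ordered pair)."""

    def __init__(self, hits: Iterable[Hit]):
        self._best: dict[tuple[str, str], Hit] = {}
        for h in hits:
            key = (h.query_id, h.subject_id)
            prev = self._best.get(key)
            if prev is None or h.score > prev.score:
                self._best[key] = h

    def pair(self, query_id: str, subject_id: str) -> Hit | None:
        hit = self._best.get((query_id, subject_id))
        if hit is None:
            hit = self._best.get((subject_id, query_id))
            if hit is not None:
                hit = replace(
                    hit,
                    query_id=query_id,
                    subject_id=subject_id,
                    query_len=hit.subject_len,
                    subject_len=hit.query_len,
                )
        return hit

    def score(self, a: str, b: str) -> float:
        hit = self.pair(a, b)
        return 0.0 if hit is None else hit.score


def all_vs_all_scores(
    seqs: Mapping[str, str] | Iterable, min_score: float = 0.0
) -> list[Hit]:
    """Score every ordered pair of distinct sequences with the internal aligner.

    Returns one :class:`Hit` per ordered pair whose adjusted score is
    >= ``min_score`` (both directions; self-hits excluded).
    """
    if not isinstance(seqs, Mapping):
        seqs = {s.id: s.sequence for s in seqs}
    if len(seqs) < 2:
        raise ValueError("all-vs-all scoring requires at least 2 sequences")
    if not 0.0 <= min_score <= 1.0:
        raise ValueError(f"min_score {min_score} outside [0, 1]")
    scorer = InternalScorer(seqs)
    ids = sorted(seqs)
    out: list[Hit] = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            hit = scorer.pair(a, b)
            if hit.score >= min_score:
                out.append(hit)
                out.append(
                    replace(
                        hit,
                        query_id=b,
                        subject_id=a,
                        query_len=hit.subject_len,
                        subject_len=hit.query_len,
                    )
                )
    return out
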