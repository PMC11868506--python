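"""Readers and writers for every external representation the toolkit touches.

Formats are deliberately plain text: FASTA for sequences, 12-column
tab-separated alignment hit tables (the BLAST ``outfmt 6`` dialect),
tab-separated count matrices with a companion per-sample metadata table, and
tab-separated taxonomy / trait tables.  All parsers validate strictly and
never silently drop rows.

Conventions
-----------
* Count matrices are oriented samples x features (rows x columns).
* Percent identity is normalised to a fraction in [0, 1] at parse time so
  every similarity score in the toolkit lives on one scale.
* Alignment coordinates in hit rows are 1-based inclusive; they are carried
  through but only the alignment length is interpreted.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

import pandas as pd
from Bio import SeqIO

from .pairwise_scoring import Hit

PathLike = Union[str, Path, TextIO]

RANKS: tuple[str, ...] = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)
RANK_INDEX: dict[str, int] = {r: i for i, r in enumerate(RANKS)}
UNIDENTIFIED = "unidentified"

#: Minimum usable marker length after ITS1 extraction (bases).  Shorter
#: fragments are too noisy to assign; applied by the simulator and pipeline,
#: not by the raw FASTA parser.
MIN_ITS1_LENGTH = 50

PSEUDO_NAME_RE = re.compile(
    r"^pseudo_(kingdom|phylum|class|order|family|genus|species)_.+_\d+$"
)

SAMPLE_ROLES = ("specimen", "positive_control")

HIT_TABLE_COLUMNS = (
    "qid sid pident length mismatch gapopen qstart qend sstart send evalue bitscore"
).split()


class FormatError(ValueError):
    """Raised when an on-disk representation violates the format contract."""


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

_IUPAC_DNA = set("ACGTN")


@dataclass(frozen=True)
class AsvSeq:
    """A denoised amplicon sequence variant (or reference sequence)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.sequence:
            raise FormatError(f"empty sequence for record {self.id!r}")
        for pos, base in enumerate(self.sequence, start=1):
            if base not in _IUPAC_DNA:
                raise FormatError(
                    f"non-IUPAC character {base!r} at position {pos} "
                    f"in record {self.id!r}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


def _as_handle(path_or_stream: PathLike, mode: str = "r"):
    if isinstance(path_or_stream, (str, Path)):
        return open(path_or_stream, mode), True
    return path_or_stream, False


def parse_fasta(path_or_stream: PathLike) -> list[AsvSeq]:
    """Parse a FASTA file into a list of :class:`AsvSeq`, order preserved.

    The first whitespace-delimited token of each header is the record id.
    Sequences are uppercased.  Duplicate ids, empty sequences and non-IUPAC
    characters raise :class:`FormatError`.
    """
    handle, close = _as_handle(path_or_stream)
    try:
        records = []
        seen: set[str] = set()
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise FormatError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            records.append(AsvSeq(id=rec.id, sequence=str(rec.seq).upper()))
        return records
    finally:
        if close:
            handle.close()


def write_fasta(seqs: Iterable[AsvSeq], path_or_stream: PathLike, width: int = 80) -> None:
    handle, close = _as_handle(path_or_stream, "w")
    try:
        for s in seqs:
            handle.write(f">{s.id}\n")
            for i in range(0, len(s.sequence), width):
                handle.write(s.sequence[i : i + width] + "\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# lineages
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Lineage:
    """A 7-rank taxonomy (kingdom -> species) with pseudotaxon flags.

    Names are real taxon names, pseudotaxon names (``pseudo_<rank>_<anchor>_<n>``)
    produced by de novo clustering, or the sentinel ``"unidentified"``.
    Truncation is monotone: once a rank is unidentified, all deeper ranks are.
    """

    names: tuple[str, ...]
    pseudotaxon: tuple[bool, ...] = field(default=(False,) * 7)
    reference_accession: str | None = None

    def __post_init__(self) -> None:
        if len(self.names) != 7 or len(self.pseudotaxon) != 7:
            raise FormatError("Lineage requires exactly 7 rank slots")
        truncated = False
        for i, name in enumerate(self.names):
            if name == UNIDENTIFIED:
                truncated = True
            elif truncated:
                raise FormatError(
                    f"lineage not monotone-truncated: {RANKS[i]}={name!r} "
                    "below an unidentified rank"
                )
        for i, flag in enumerate(self.pseudotaxon):
            if flag and not PSEUDO_NAME_RE.match(self.names[i]):
                raise FormatError(
                    f"pseudotaxon flag set at {RANKS[i]} but name "
                    f"{self.names[i]!r} does not match the pseudo-name pattern"
                )

    @classmethod
    def from_names(
        cls,
        names: Sequence[str],
        reference_accession: str | None = None,
    ) -> "Lineage":
        """Build a lineage, padding missing deep ranks with ``unidentified``.

        Pseudotaxon flags are inferred from the name pattern.
        """
        padded = list(names) + [UNIDENTIFIED] * (7 - len(names))
        flags = tuple(bool(PSEUDO_NAME_RE.match(n)) for n in padded)
        return cls(tuple(padded), flags, reference_accession)

    @classmethod
    def unidentified(cls) -> "Lineage":
        return cls((UNIDENTIFIED,) * 7)

    def name_at(self, rank: str) -> str:
        return self.names[RANK_INDEX[rank]]

    def is_assigned_at(self, rank: str) -> bool:
        return self.names[RANK_INDEX[rank]] != UNIDENTIFIED

    @property
    def lowest_assigned_rank(self) -> str | None:
        lowest = None
        for rank, name in zip(RANKS, self.names):
            if name != UNIDENTIFIED:
                lowest = rank
        return lowest

    def truncated_at(self, rank: str) -> "Lineage":
        """Return a copy with ``rank`` and all deeper ranks unidentified."""
        i = RANK_INDEX[rank]
        names = self.names[:i] + (UNIDENTIFIED,) * (7 - i)
        flags = self.pseudotaxon[:i] + (False,) * (7 - i)
        return Lineage(names, flags, self.reference_accession)

    def without_pseudotaxa(self) -> "Lineage":
        """Rewrite pseudotaxon names as ``unidentified`` (the public dialect)."""
        names = list(self.names)
        cut = 7
        for i, flag in enumerate(self.pseudotaxon):
            if flag:
                cut = min(cut, i)
        if cut == 7:
            return self
        names = self.names[:cut] + (UNIDENTIFIED,) * (7 - cut)
        return Lineage(names, (False,) * 7, self.reference_accession)

    def extended(self, rank: str, name: str, pseudo: bool = False) -> "Lineage":
        i = RANK_INDEX[rank]
        names = list(self.names)
        flags = list(self.pseudotaxon)
        names[i] = name
        flags[i] = pseudo
        return Lineage(tuple(names), tuple(flags), self.reference_accession)

    def with_accession(self, accession: str | None) -> "Lineage":
        return replace(self, reference_accession=accession)


# ---------------------------------------------------------------------------
# hit tables (BLAST outfmt-6 dialect)
# ---------------------------------------------------------------------------


def parse_hit_table(path_or_stream: PathLike) -> list[Hit]:
    """Parse a 12-column tab-separated alignment hit table.

    Percent identity (column 3, 0-100) is stored as a fraction.  Row order is
    preserved, including multiple hits per query.  Query/subject lengths are
    not part of the dialect; attach them with
    :func:`mycocurate.pairwise_scoring.with_lengths` before deriving coverage.
    """
    handle, close = _as_handle(path_or_stream)
    hits: list[Hit] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            pident = float(fields[2])
            if not 0.0 <= pident <= 100.0:
                raise FormatError(
                    f"line {lineno}: percent identity {pident} outside [0, 100]"
                )
            hits.append(
                Hit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    identity=pident / 100.0,
                    aln_len=int(fields[3]),
                    mismatch=int(fields[4]),
                    gapopen=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            )
        return hits
    finally:
        if close:
            handle.close()


def write_hit_table(hits: Iterable[Hit], path_or_stream: PathLike) -> None:
    handle, close = _as_handle(path_or_stream, "w")
    try:
        for h in hits:
            handle.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.identity * 100:.3f}",
                        str(h.aln_len),
                        str(h.mismatch if h.mismatch is not None else 0),
                        str(h.gapopen if h.gapopen is not None else 0),
                        str(h.qstart if h.qstart is not None else 1),
                        str(h.qend if h.qend is not None else h.aln_len),
                        str(h.sstart if h.sstart is not None else 1),
                        str(h.send if h.send is not None else h.aln_len),
                        f"{h.evalue if h.evalue is not None else 0.0:g}",
                        f"{h.bitscore if h.bitscore is not None else 0.0:g}",
                    ]
                )
                + "\n"
            )
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """A sample x feature matrix of non-negative integer counts plus metadata.

    ``counts`` is indexed by sample id (rows) with feature ids as columns.
    ``meta`` is indexed by sample id and must carry at least ``library_id``,
    ``plot_id``, ``role`` and ``region``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.astype("int64")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("count matrix contains negative cells")
        if self.counts.index.has_duplicates:
            raise FormatError("duplicate sample ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise FormatError("duplicate feature ids in count matrix")
        missing = set(self.counts.index) - set(self.meta.index)
        if missing:
            raise FormatError(
                f"samples missing from metadata: {sorted(missing)[:5]}"
            )
        for col in ("library_id", "plot_id", "role", "region"):
            if col not in self.meta.columns:
                raise FormatError(f"metadata lacks required column {col!r}")
        bad_roles = set(self.meta["role"]) - set(SAMPLE_ROLES)
        if bad_roles:
            raise FormatError(f"unknown sample roles: {sorted(bad_roles)}")
        # keep metadata aligned with (and restricted to) the count rows
        self.meta = self.meta.loc[self.counts.index]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.columns)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def richness(self) -> pd.Series:
        return (self.counts > 0).sum(axis=1)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[list(sample_ids)].copy(), self.meta.copy()
        )

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.counts.copy(), self.meta.copy())


def read_count_matrix(counts_path: PathLike, meta_path: PathLike) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="sample_id")
    if counts.isna().any().any():
        raise FormatError("count matrix contains missing cells")
    if (counts.to_numpy() < 0).any():
        raise FormatError("count matrix contains negative cells")
    counts.index.name = None
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id", dtype=str)
    meta.index.name = None
    missing = set(counts.index) - set(meta.index)
    if missing:
        raise FormatError(f"samples missing from metadata: {sorted(missing)[:5]}")
    return CountMatrix(counts.astype("int64"), meta)


def write_count_matrix(matrix: CountMatrix, counts_path, meta_path) -> None:
    matrix.counts.to_csv(counts_path, sep="\t", index_label="sample_id")
    matrix.meta.to_csv(meta_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# taxonomy and trait tables
# ---------------------------------------------------------------------------


def write_taxonomy_table(
    lineages: Mapping[str, Lineage],
    path: PathLike,
    keep_pseudotaxa: bool = True,
) -> None:
    """Write feature-id -> 7-rank taxonomy as TSV.

    With ``keep_pseudotaxa=False`` pseudotaxon names are rewritten as
    ``unidentified`` (the dialect suitable for biodiversity platforms).
    """
    rows = []
    for fid, lin in lineages.items():
        if not keep_pseudotaxa:
            lin = lin.without_pseudotaxa()
        rows.append(
            [fid, *lin.names, lin.reference_accession or ""]
        )
    df = pd.DataFrame(rows, columns=["feature_id", *RANKS, "reference_accession"])
    df.to_csv(path, sep="\t", index=False)


def read_taxonomy_table(path: PathLike) -> dict[str, Lineage]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    expected = ["feature_id", *RANKS]
    if list(df.columns[:8]) != expected:
        raise FormatError(f"taxonomy table must start with columns {expected}")
    out: dict[str, Lineage] = {}
    has_acc = "reference_accession" in df.columns
    for _, row in df.iterrows():
        names = tuple(row[r] or UNIDENTIFIED for r in RANKS)
        acc = (row["reference_accession"] if has_acc else "") or None
        fid = row["feature_id"]
        if fid in out:
            raise FormatError(f"duplicate feature id {fid!r} in taxonomy table")
        flags = tuple(bool(PSEUDO_NAME_RE.match(n)) for n in names)
        out[fid] = Lineage(names, flags, acc)
    return out


def read_trait_table(path: PathLike) -> pd.DataFrame:
    """Read a genus -> trait table (FungalTraits-like), indexed by genus."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "genus" not in df.columns:
        raise FormatError("trait table lacks a 'genus' column")
    if df["genus"].duplicated().any():
        dups = df.loc[df["genus"].duplicated(), "genus"].tolist()
        raise FormatError(f"duplicate genus entries in trait table: {dups[:5]}")
    return df.set_index("genus")


def write_trait_table(traits: pd.DataFrame, path: PathLike) -> None:
    traits.to_csv(path, sep="\t", index_label="genus")


def parse_fasta_str(text: str) -> list[AsvSeq]:
    """Convenience wrapper: parse FASTA from an in-memory string."""
    return parse_fasta(io.StringIO(text))
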