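"""End-to-end orchestration: simulate -> score -> cutoffs -> assign ->
cluster -> curate -> diagnose, reproducing the full product set at fixture
scale.

Every stage is a pure transform over matrices/tables and can be run
standalone on files; the orchestrator wires them together, records a run
manifest (config hash and seed) sufficient to reproduce outputs bit-exactly,
and writes the standard product set:

1. sample metadata table
2. curation report (JSON)
3. curated sample-by-OTU matrix (absolute counts)
4. sample-by-OTU matrix rarefied to the minimum retained depth
5. representative OTU sequences (FASTA)
6. taxonomy table without pseudotaxon names (pseudotaxa as ``unidentified``)
7. taxonomy table with pseudotaxon names

plus a diagnostics summary (JSON).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .assigner import assign_all, annotate_traits
from .clusterer import nested_cluster
from .curator import CurationConfig, curate, mould_score, flag_mould, rarefy
from .cutoffs import select_cutoffs
from .diagnostics import (
    DiagnosticsSummary,
    depth_richness_r2,
    environmental_control_check,
    mock_richness_check,
    rarefaction_curve,
)
from .io_formats import (
    CountMatrix,
    write_count_matrix,
    write_fasta,
    write_taxonomy_table,
    write_trait_table,
)
from .pairwise_scoring import InternalScorer
from .simdata import SimConfig, make_communities, make_reference_db, make_trait_table

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, completed: list[str], cause: Exception):
        super().__init__(
            f"pipeline stage {stage!r} failed after completing {completed}: {cause}"
        )
        self.stage = stage
        self.completed = completed


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: Path = Path("mycocurate_run")
    sim: SimConfig | None = None
    curation: CurationConfig | None = None
    apply_curation: bool = True
    drop_nonfungal: bool = True
    expected_mock_richness: int = 10
    log_level: str = "INFO"

    def resolved(self) -> "PipelineConfig":
        sim = self.sim or SimConfig(rng_seed=self.seed)
        curation = self.curation or CurationConfig(rng_seed=self.seed)
        return dataclasses.replace(self, sim=sim, curation=curation)

    def config_hash(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(dataclasses.replace(self, outdir=Path("."))),
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    otu_matrix: CountMatrix
    otu_matrix_rarefied: CountMatrix
    otus: list
    assignments: dict
    cutoff_table: object
    curation_report: object
    diagnostics: DiagnosticsSummary
    truth: object
    asv_matrix_raw: CountMatrix
    asv_matrix_curated: CountMatrix
    paths: dict[str, Path] = field(default_factory=dict)


def build_otu_matrix(asv_matrix: CountMatrix, otus) -> CountMatrix:
    """Aggregate an ASV matrix to OTU level by summing member columns."""
    data = {}
    present = set(asv_matrix.feature_ids)
    for otu in otus:
        members = [m for m in otu.member_asv_ids if m in present]
        if members:
            data[otu.otu_id] = asv_matrix.counts[members].sum(axis=1)
    counts = pd.DataFrame(data, index=asv_matrix.counts.index).astype("int64")
    return CountMatrix(counts, asv_matrix.meta.copy())


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config = config.resolved()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    stage = "simulate"
    try:
        refdb = make_reference_db(config.sim)
        traits = make_trait_table(config.sim)
        asv_matrix, asv_seqs, truth = make_communities(config.sim, refdb)
        completed.append(stage)

        stage = "curate"
        if config.apply_curation:
            curated, report = curate(asv_matrix, config.curation)
        else:
            from .curator import CurationReport

            curated, report = asv_matrix.copy(), CurationReport()
        completed.append(stage)

        stage = "score"
        combined = dict(refdb.seqs)
        combined.update({s.id: s.sequence for s in asv_seqs})
        scorer = InternalScorer(combined)
        completed.append(stage)

        stage = "cutoffs"
        cutoff_table = select_cutoffs(refdb, scorer=scorer, seed=config.seed)
        completed.append(stage)

        stage = "assign"
        asv_ids = [s.id for s in asv_seqs]
        assignments = assign_all(asv_ids, refdb, scorer, cutoff_table)
        completed.append(stage)

        stage = "cluster"
        totals = {a: int(curated.counts[a].sum()) if a in curated.counts else 0
                  for a in asv_ids}
        _by_rank, otus = nested_cluster(
            asv_ids,
            assignments,
            cutoff_table,
            scorer,
            totals=totals,
            drop_nonfungal_root=config.drop_nonfungal,
        )
        completed.append(stage)

        stage = "otu_matrix"
        otu_matrix = build_otu_matrix(curated, otus)
        otu_lineages = {o.otu_id: o.lineage for o in otus if o.otu_id in otu_matrix.counts}
        scores = mould_score(otu_matrix, otu_lineages, config.curation) if len(
            otu_matrix.counts
        ) else pd.Series(dtype=float)
        if len(scores):
            flags, threshold = flag_mould(scores, config.curation)
            report.mould_scores = {s: float(v) for s, v in scores.items()}
            report.mould_threshold = threshold
            report.mould_flags = {s: bool(v) for s, v in flags.items()}
        rarefied = rarefy(otu_matrix, config.curation)
        completed.append(stage)

        stage = "diagnose"
        diag = DiagnosticsSummary()
        diag.sample_depth = {s: int(v) for s, v in otu_matrix.sample_totals().items()}
        diag.sample_richness = {s: int(v) for s, v in otu_matrix.richness().items()}
        try:
            diag.r2_percent_by_group = depth_richness_r2(otu_matrix)
        except ValueError as exc:
            logger.warning("depth-richness R2 unavailable: %s", exc)
        mock = mock_richness_check(asv_matrix, config.expected_mock_richness)
        diag.control_richness = {s: int(v) for s, v in mock["observed"].items()}
        n_occ, _ = environmental_control_check(
            otu_matrix, otu_lineages, traits
        )
        diag.environmental_control_occurrences = n_occ
        if len(otu_matrix.counts):
            first = otu_matrix.counts.index[0]
            row = otu_matrix.counts.loc[first].to_numpy()
            grid = [d for d in (100, 500, 1000, 2500, 5000) if d <= row.sum()]
            diag.rarefaction[first] = rarefaction_curve(
                row, grid, reps=20, seed=config.seed
            )
        completed.append(stage)

        stage = "write"
        paths = _write_products(
            outdir, config, asv_matrix, curated, otu_matrix, rarefied,
            otus, otu_lineages, asv_seqs, traits, report, diag, cutoff_table,
        )
        completed.append(stage)
    except Exception as exc:  # noqa: BLE001 - stage context is the contract
        if isinstance(exc, PipelineStageError):
            raise
        raise PipelineStageError(stage, completed, exc) from exc

    return PipelineResult(
        otu_matrix=otu_matrix,
        otu_matrix_rarefied=rarefied,
        otus=otus,
        assignments=assignments,
        cutoff_table=cutoff_table,
        curation_report=report,
        diagnostics=diag,
        truth=truth,
        asv_matrix_raw=asv_matrix,
        asv_matrix_curated=curated,
        paths=paths,
    )


def _write_products(
    outdir, config, asv_matrix, curated, otu_matrix, rarefied, otus,
    otu_lineages, asv_seqs, traits, report, diag, cutoff_table,
) -> dict[str, Path]:
    paths: dict[str, Path] = {}

    def p(name: str) -> Path:
        paths[name] = outdir / name
        return paths[name]

    otu_matrix.meta.to_csv(p("sample_metadata.tsv"), sep="\t", index_label="sample_id")
    report.to_json(p("curation_report.json"))
    write_count_matrix(otu_matrix, p("otu_matrix.tsv"), p("otu_matrix_meta.tsv"))
    write_count_matrix(
        rarefied, p("otu_matrix_rarefied.tsv"), p("otu_matrix_rarefied_meta.tsv")
    )
    seq_of = {s.id: s for s in asv_seqs}
    present = set(otu_matrix.feature_ids)
    reps = [
        dataclasses.replace(seq_of[o.representative_asv_id], id=o.otu_id)
        for o in otus
        if o.otu_id in present
    ]
    write_fasta(reps, p("otu_representatives.fasta"))
    write_taxonomy_table(otu_lineages, p("otu_taxonomy_pseudotaxa.tsv"), keep_pseudotaxa=True)
    write_taxonomy_table(otu_lineages, p("otu_taxonomy.tsv"), keep_pseudotaxa=False)
    write_trait_table(traits, p("genus_traits.tsv"))
    cutoff_table.write(p("cutoffs.tsv"))
    diag.to_json(p("diagnostics.json"))
    manifest = {
        "toolkit_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "products": sorted(str(v.name) for v in paths.values()),
    }
    with open(p("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return paths
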