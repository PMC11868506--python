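"""Technical-validation diagnostics for curated metabarcoding matrices.

Covers the standard QC battery: per-sample rarefaction curves, the fraction
of richness variance explained by (log) sequencing depth per region,
positive-control (mock community) richness versus the seeded expectation,
and the *environmental control* check — counting occurrences of a guild in a
region where it is biologically impossible (ectomycorrhizal fungi in
Antarctica), a direct in-situ assay of residual index switching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
import json
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountMatrix, Lineage

logger = logging.getLogger(__name__)


@dataclass
class RarefactionPoint:
    depth: int
    mean_richness: float
    sd_richness: float
    reps: int


@dataclass
class DiagnosticsSummary:
    sample_depth: dict[str, int] = field(default_factory=dict)
    sample_richness: dict[str, int] = field(default_factory=dict)
    r2_percent_by_group: dict[str, float | None] = field(default_factory=dict)
    control_richness: dict[str, int] = field(default_factory=dict)
    environmental_control_occurrences: int = 0
    rarefaction: dict[str, list[RarefactionPoint]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)


def rarefaction_curve(
    sample_counts: np.ndarray,
    depth_grid: list[int],
    reps: int = 100,
    seed: int = 0,
) -> list[RarefactionPoint]:
    """Mean and SD of subsampled richness at each depth over ``reps`` draws.

    Depths exceeding the sample total are skipped with a warning.  At the
    full depth the subsample is the sample itself, so richness equals
    observed richness with SD 0.
    """
    counts = np.asarray(sample_counts, dtype=np.int64)
    total = int(counts.sum())
    rng = np.random.default_rng(seed)
    points: list[RarefactionPoint] = []
    for depth in depth_grid:
        if depth > total:
            logger.warning("depth %d exceeds sample total %d; skipped", depth, total)
            continue
        if depth == total:
            rich = np.repeat(int((counts > 0).sum()), reps)
        else:
            rich = np.array(
                [
                    int((rng.multivariate_hypergeometric(counts, depth) > 0).sum())
                    for _ in range(reps)
                ]
            )
        points.append(
            RarefactionPoint(
                depth=int(depth),
                mean_richness=float(rich.mean()),
                sd_richness=float(rich.std(ddof=1)) if reps > 1 else 0.0,
                reps=reps,
            )
        )
    return points


def depth_richness_r2(
    matrix: CountMatrix, group_by_region: bool = True
) -> dict[str, float | None]:
    """Percent of OTU-richness variance explained by log10 sequencing depth.

    Ordinary least squares of richness on log10(depth) per region group.
    Groups with fewer than 3 samples raise; constant depth makes R²
    undefined (reported as ``None``).
    """
    richness = matrix.richness()
    depth = matrix.sample_totals()
    groups: dict[str, list[str]] = {}
    if group_by_region:
        for region, idx in matrix.meta.groupby("region").groups.items():
            groups[str(region)] = list(idx)
    else:
        groups["all"] = list(matrix.counts.index)
    out: dict[str, float | None] = {}
    for name, samples in groups.items():
        if len(samples) < 3:
            raise ValueError(f"group {name!r} has fewer than 3 samples")
        x = np.log10(depth[samples].to_numpy(dtype=float))
        y = richness[samples].to_numpy(dtype=float)
        if np.allclose(x, x[0]) or np.allclose(y, y[0]):
            out[name] = None
            continue
        fit = stats.linregress(x, y)
        out[name] = float(fit.rvalue**2 * 100.0)
    return out


def mock_richness_check(
    matrix: CountMatrix, expected_richness: int = 10
) -> pd.DataFrame:
    """Observed richness per positive control versus the seeded expectation.

    Run on a matrix that still retains the positive controls (i.e. before
    they are dropped in curation).  Returns one row per control with the
    observed richness and the excess over expectation.
    """
    controls = matrix.meta.index[matrix.meta["role"] == "positive_control"]
    controls = [s for s in controls if s in matrix.counts.index]
    if not controls:
        logger.warning("no positive-control samples present")
        return pd.DataFrame(columns=["observed", "expected", "excess"])
    observed = (matrix.counts.loc[controls] > 0).sum(axis=1)
    df = pd.DataFrame(
        {
            "observed": observed,
            "expected": expected_richness,
            "excess": observed - expected_richness,
        }
    )
    return df


def environmental_control_check(
    matrix: CountMatrix,
    lineages: Mapping[str, Lineage],
    traits: Mapping[str, Mapping[str, str]] | pd.DataFrame,
    control_region: str = "antarctica",
    guild: str = "ectomycorrhizal",
) -> tuple[int, list[tuple[str, str]]]:
    """Count (sample, OTU) presence pairs of a guild inside the control region.

    ``traits`` is either a genus-indexed trait table (joined onto each
    feature's lineage, with the Glomeromycota override) or a pre-built
    feature id -> trait record mapping; ``primary_lifestyle`` keys the guild.
    In a region where the guild's hosts are absent, every such occurrence is
    an artefact; on fully curated data the count should be 0.
    """
    if isinstance(traits, pd.DataFrame):
        from .assigner import annotate_traits

        vocabulary = set()
        for col in ("primary_lifestyle", "secondary_lifestyle"):
            if col in traits.columns:
                vocabulary |= set(traits[col])
        vocabulary.add("arbuscular_mycorrhizal")  # Glomeromycota override
        traits = {
            f: annotate_traits(lineages[f], traits) for f in matrix.feature_ids
        }
    else:
        vocabulary = {rec.get("primary_lifestyle", "") for rec in traits.values()}
        vocabulary |= {
            rec.get("secondary_lifestyle", "") for rec in traits.values()
        }
    if guild not in vocabulary:
        raise ValueError(
            f"guild {guild!r} absent from the trait vocabulary of this table"
        )
    guild_features = {
        f
        for f in matrix.feature_ids
        if traits.get(f, {}).get("primary_lifestyle") == guild
    }
    control_samples = [
        s
        for s in matrix.counts.index
        if str(matrix.meta.loc[s, "region"]) == control_region
    ]
    occurrences: list[tuple[str, str]] = []
    for s in control_samples:
        row = matrix.counts.loc[s]
        for f in sorted(guild_features):
            if row[f] > 0:
                occurrences.append((s, f))
    return len(occurrences), occurrences


def guild_occurrences(
    matrix: CountMatrix,
    traits: Mapping[str, Mapping[str, str]],
    guild: str = "ectomycorrhizal",
) -> int:
    """Total (sample, OTU) presence pairs of a guild across the whole matrix."""
    guild_features = [
        f
        for f in matrix.feature_ids
        if traits.get(f, {}).get("primary_lifestyle") == guild
    ]
    if not guild_features:
        return 0
    return int((matrix.counts[guild_features] > 0).to_numpy().sum())
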