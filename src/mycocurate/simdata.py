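"""Deterministic, seeded generator of every input the toolkit consumes.

Emulates the structure of a multi-library soil ITS metabarcoding experiment
at desk scale:

* a reference database with planted hierarchical divergence — sequences of
  the same species differ by ~0.5%, congeneric species by ~3%, confamilial
  genera by ~8% and so on, so that cut-off prediction has a known answer;
* multi-library sample-by-ASV count matrices with log-normal specimen
  communities, 10-taxon mock-community positive controls, plot replicates,
  index-switching *bleed-through* (a fixed fraction of each ASV's
  library-wide reads redistributed into non-source samples), mould spikes,
  and a host-free region (Antarctic-like samples) that can truly contain no
  ectomycorrhizal taxa — so any ECM occurrence there is, by construction, an
  index-switching artefact;
* full ground truth (:class:`SimTruth`) recording, for every non-zero cell,
  whether it is a true source occurrence or bleed-through, making the
  two-tier filter exactly evaluable.

The mutation model is substitutions-only by default so identity arithmetic
is exact.  All randomness flows from a single seed; identical configs yield
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cutoffs import RefDb
from .io_formats import AsvSeq, CountMatrix, Lineage

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Planted maximum pairwise divergence within a taxon of each rank, plus the
#: between-phylum ("root") divergence.  Strictly increasing with rank height.
DEFAULT_RADII: dict[str, float] = {
    "species": 0.005,
    "genus": 0.03,
    "family": 0.08,
    "order": 0.12,
    "class": 0.16,
    "phylum": 0.22,
    "root": 0.30,
}

#: Reference-database shape: phylum -> class -> order -> family -> genus ->
#: (n species, sequences per species).  Includes one data-rich ECM genus
#: (eligible for local species cut-offs), a second ECM genus sized like the
#: classic agaric case, a 10-genus family (eligible for local genus
#: cut-offs), the mould taxa (Mortierellales, Trichoderma), Glomeromycota
#: for the arbuscular override, and a zoosporic phylum.
DEFAULT_DB_SHAPE: dict = {
    "Basidiomycota": {
        "Agaricomycetes": {
            "Agaricales": {
                "Cortinariaceae": {"Cortinarius": (12, 3)},
                "Amanitaceae": {"Amanita": (10, 3)},
                "Tricholomataceae": {
                    f"Tricholomoid{i:02d}": (2, 2) for i in range(1, 11)
                },
            }
        }
    },
    "Ascomycota": {
        "Sordariomycetes": {
            "Hypocreales": {
                "Hypocreaceae": {"Trichoderma": (4, 3)},
                "Nectriaceae": {"Fusarium": (4, 3)},
            }
        }
    },
    "Mortierellomycota": {
        "Mortierellomycetes": {
            "Mortierellales": {"Mortierellaceae": {"Mortierella": (5, 3)}}
        }
    },
    "Glomeromycota": {
        "Glomeromycetes": {
            "Glomerales": {"Glomeraceae": {"Rhizophagus": (3, 2), "Glomus": (3, 2)}}
        }
    },
    "Chytridiomycota": {
        "Chytridiomycetes": {
            "Rhizophydiales": {"Rhizophydiaceae": {"Rhizophydium": (4, 2)}}
        }
    },
}

#: Primary lifestyle per genus (FungalTraits-like).
DEFAULT_GUILDS: dict[str, str] = {
    "Cortinarius": "ectomycorrhizal",
    "Amanita": "ectomycorrhizal",
    "Trichoderma": "mycoparasite",
    "Fusarium": "plant_pathogen",
    "Mortierella": "soil_saprotroph",
    "Rhizophagus": "arbuscular_mycorrhizal",
    "Glomus": "arbuscular_mycorrhizal",
    "Rhizophydium": "unspecified_saprotroph",
    **{f"Tricholomoid{i:02d}": "litter_saprotroph" for i in range(1, 11)},
}

TRAIT_COLUMNS = [
    "primary_lifestyle",
    "secondary_lifestyle",
    "ectomycorrhizal_exploration_type",
    "growth_form",
    "fruitbody_type",
    "hymenium_type",
    "mold_trait",
    "decay_substrate",
    "decay_type",
    "aquatic_habitat",
    "animal_biotrophic_capacity",
    "plant_pathogenic_capacity",
    "endophytic_interaction_capability",
    "specific_hosts",
    "sporocarp_tissue",
    "evolutionary_origin",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic experiment (one seed rules all)."""

    rng_seed: int = 0
    n_libraries: int = 4
    samples_per_library: int = 24
    controls_per_library: int = 2
    antarctic_per_library: int = 6
    replicate_plots_per_library: int = 1
    mock_taxa: int = 10
    taxa_per_sample: tuple[int, int] = (25, 40)
    abundance_sigma: float = 1.0
    depth_range: tuple[int, int] = (12000, 20000)
    bleed_rate: float = 0.003
    bleed_fanout: int = 10
    mould_spike: tuple[int, float] = (2, 0.5)
    seq_length: int = 800
    radii: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RADII)
    )
    db_shape: Mapping = field(default_factory=lambda: DEFAULT_DB_SHAPE)
    guilds: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_GUILDS))
    #: fraction of each genus's reference entries stripped to genus level
    #: (populating the full-database-only stratum); applied to the *last*
    #: entries of each genus so representative sequences keep species names
    genus_only_fraction: float = 0.1
    within_species_asv_noise: int = 0  # substitutions added to ASV copies

    def __post_init__(self) -> None:
        for f in ("bleed_rate", "genus_only_fraction"):
            if not 0.0 <= getattr(self, f) <= 1.0:
                raise ValueError(f"{f} outside [0, 1]")
        radii = [self.radii[r] for r in
                 ("species", "genus", "family", "order", "class", "phylum", "root")]
        if not all(a < b for a, b in zip(radii, radii[1:])):
            raise ValueError("divergence radii must be strictly increasing with rank height")
        if self.bleed_fanout >= self.samples_per_library:
            raise ValueError("bleed_fanout must be < samples_per_library")


@dataclass
class SimTruth:
    """Ground-truth provenance of every synthetic count."""

    true_cells: set[tuple[str, str]] = field(default_factory=set)
    bled_cells: dict[tuple[str, str], dict] = field(default_factory=dict)
    asv_lineage: dict[str, Lineage] = field(default_factory=dict)
    asv_guild: dict[str, str] = field(default_factory=dict)
    asv_species: dict[str, str] = field(default_factory=dict)
    mock_samples: list[str] = field(default_factory=list)
    mock_species: list[str] = field(default_factory=list)
    mould_spiked_samples: list[str] = field(default_factory=list)

    def status(self, sample: str, asv: str) -> str:
        if (sample, asv) in self.bled_cells:
            return "bled"
        if (sample, asv) in self.true_cells:
            return "true_source"
        return "absent"


def _mutate(seq: np.ndarray, n_subs: int, rng: np.random.Generator) -> np.ndarray:
    """Substitute ``n_subs`` distinct positions with a different base."""
    if n_subs == 0:
        return seq.copy()
    out = seq.copy()
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    for p in pos:
        choices = _BASES[_BASES != out[p]]
        out[p] = rng.choice(choices)
    return out


def make_reference_db(config: SimConfig) -> RefDb:
    """Generate a reference database with planted per-rank divergence.

    Ancestor sequences are generated per clade and descendants mutated so
    the expected pairwise divergence between two sequences whose most recent
    common ancestor sits at rank *r* equals the radius planted for *r*
    (branch substitution counts follow the half-difference of consecutive
    radii; substitutions land at independently drawn positions, so realised
    divergences sit within a few substitutions of the plant).
    """
    rng = np.random.default_rng(config.rng_seed)
    L = config.seq_length
    radii = dict(config.radii)
    levels = ["root", "phylum", "class", "order", "family", "genus", "species"]
    div = {lvl: radii[lvl] for lvl in levels}

    def branch_subs(child_level: str) -> int:
        # divergence accrued below the child's parent level
        i = levels.index(child_level)
        upper = div[levels[i - 1]]
        lower = div[child_level] if child_level != "leaf" else 0.0
        return round(L * (upper - lower) / 2)

    def leaf_subs() -> int:
        return round(L * div["species"] / 2)

    root = rng.choice(_BASES, size=L)
    entries: list[tuple[AsvSeq, Lineage]] = []
    counter = 0
    for phylum, classes in config.db_shape.items():
        p_anc = _mutate(root, branch_subs("phylum"), rng)
        for cls, orders in classes.items():
            c_anc = _mutate(p_anc, branch_subs("class"), rng)
            for order, families in orders.items():
                o_anc = _mutate(c_anc, branch_subs("order"), rng)
                for family, genera in families.items():
                    f_anc = _mutate(o_anc, branch_subs("family"), rng)
                    for genus, (n_species, n_seqs) in genera.items():
                        g_anc = _mutate(f_anc, branch_subs("genus"), rng)
                        genus_entries: list[tuple[AsvSeq, Lineage]] = []
                        for si in range(1, n_species + 1):
                            s_anc = _mutate(g_anc, branch_subs("species"), rng)
                            species = f"{genus}_sp{si:02d}"
                            for _k in range(n_seqs):
                                counter += 1
                                seq = _mutate(s_anc, leaf_subs(), rng)
                                sid = f"REF_{counter:04d}"
                                lin = Lineage.from_names(
                                    [
                                        "Fungi",
                                        phylum,
                                        cls,
                                        order,
                                        family,
                                        genus,
                                        species,
                                    ],
                                    reference_accession=sid,
                                )
                                genus_entries.append(
                                    (
                                        AsvSeq(sid, seq.tobytes().decode()),
                                        lin,
                                    )
                                )
                        # strip a fraction of this genus's entries to genus
                        # level (full-database-only stratum); every k-th
                        # entry, so no species loses its representative
                        if config.genus_only_fraction > 0:
                            every = max(2, round(1 / config.genus_only_fraction))
                            for j in range(every - 1, len(genus_entries), every):
                                seq, lin = genus_entries[j]
                                genus_entries[j] = (seq, lin.truncated_at("species"))
                        entries.extend(genus_entries)
    return RefDb(entries)


def make_trait_table(config: SimConfig) -> pd.DataFrame:
    """Genus -> trait table (FungalTraits-like, 16 trait columns)."""
    rows = {}
    for genus, guild in config.guilds.items():
        row = {c: "" for c in TRAIT_COLUMNS}
        row["primary_lifestyle"] = guild
        if guild == "ectomycorrhizal":
            row["ectomycorrhizal_exploration_type"] = "medium-distance"
            row["growth_form"] = "agaricoid"
        rows[genus] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "genus"
    return df


def _species_catalogue(refdb: RefDb) -> dict[str, tuple[str, Lineage]]:
    """species name -> (representative reference sequence, species lineage).

    The representative is the first (never genus-stripped) entry of the
    species.
    """
    catalogue: dict[str, tuple[str, Lineage]] = {}
    for seq, lin in refdb.entries:
        sp = lin.name_at("species")
        if sp != "unidentified" and sp not in catalogue:
            catalogue[sp] = (seq.sequence, lin)
    return catalogue


def make_communities(
    config: SimConfig, refdb: RefDb
) -> tuple[CountMatrix, list[AsvSeq], SimTruth]:
    """Simulate the multi-library sample-by-ASV matrix with ground truth.

    One ASV per reference species (its representative sequence, optionally
    with within-species substitution noise).  Specimen communities are
    log-normal multinomials at drawn depths; positive controls carry exactly
    ``mock_taxa`` seeded taxa at near-even abundance; host-free (Antarctic)
    samples draw from a pool excluding ectomycorrhizal genera.  Bleed then
    moves ``bleed_rate`` of every ASV's library-wide reads into
    ``bleed_fanout`` uniformly chosen non-source samples (floor per
    recipient, remainder staying at the source), conserving per-ASV library
    totals exactly.
    """
    rng = np.random.default_rng(config.rng_seed + 1)
    truth = SimTruth()
    catalogue = _species_catalogue(refdb)
    species_names = sorted(catalogue)

    # one ASV per species
    asv_seqs: list[AsvSeq] = []
    asv_of_species: dict[str, str] = {}
    for i, sp in enumerate(species_names, start=1):
        asv_id = f"ASV_{i:04d}"
        seq, lin = catalogue[sp]
        if config.within_species_asv_noise:
            arr = np.frombuffer(seq.encode(), dtype="S1")
            seq = _mutate(arr, config.within_species_asv_noise, rng).tobytes().decode()
        asv_seqs.append(AsvSeq(asv_id, seq))
        asv_of_species[sp] = asv_id
        truth.asv_lineage[asv_id] = lin.with_accession(None)
        truth.asv_species[asv_id] = sp
        genus = lin.name_at("genus")
        truth.asv_guild[asv_id] = config.guilds.get(genus, "")

    ecm_species = {
        sp
        for sp in species_names
        if config.guilds.get(catalogue[sp][1].name_at("genus")) == "ectomycorrhizal"
    }
    mould_species = sorted(
        sp
        for sp in species_names
        if catalogue[sp][1].name_at("order") == "Mortierellales"
        or catalogue[sp][1].name_at("genus") == "Trichoderma"
    )
    # mock community: first species of `mock_taxa` distinct non-ECM genera
    mock_species: list[str] = []
    seen_genera: set[str] = set()
    for sp in species_names:
        genus = catalogue[sp][1].name_at("genus")
        if sp in ecm_species or genus in seen_genera:
            continue
        seen_genera.add(genus)
        mock_species.append(sp)
        if len(mock_species) == config.mock_taxa:
            break
    if len(mock_species) < config.mock_taxa:
        raise ValueError("reference database too small for the mock design")
    truth.mock_species = mock_species

    pool_all = species_names
    pool_host_free = [sp for sp in species_names if sp not in ecm_species]

    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    counts: dict[str, dict[str, int]] = {}
    lo, hi = config.taxa_per_sample
    d_lo, d_hi = config.depth_range
    for lib in range(1, config.n_libraries + 1):
        library_id = f"LIB{lib:02d}"
        n_specimens = config.samples_per_library - config.controls_per_library
        for k in range(1, config.samples_per_library + 1):
            sid = f"{library_id}_S{k:02d}"
            sample_ids.append(sid)
            is_control = k > n_specimens
            is_antarctic = (not is_control) and (
                k > n_specimens - config.antarctic_per_library
            )
            # plot replicates: the first pair of specimen samples shares a plot
            if (
                config.replicate_plots_per_library
                and not is_control
                and k <= 2 * config.replicate_plots_per_library
            ):
                plot = f"{library_id}_plot{(k + 1) // 2:02d}"
            else:
                plot = f"{library_id}_plot{k:02d}" if not is_control else f"{library_id}_ctrl{k:02d}"
            meta_rows.append(
                {
                    "sample_id": sid,
                    "library_id": library_id,
                    "plot_id": plot,
                    "role": "positive_control" if is_control else "specimen",
                    "region": "antarctica" if is_antarctic else "australia",
                    "collection_date": "",
                }
            )
            depth = int(rng.integers(d_lo, d_hi + 1))
            if is_control:
                chosen = mock_species
                weights = np.ones(len(chosen))
                truth.mock_samples.append(sid)
            else:
                pool = pool_host_free if is_antarctic else pool_all
                n_taxa = int(rng.integers(lo, min(hi, len(pool)) + 1))
                idx = rng.choice(len(pool), size=n_taxa, replace=False)
                chosen = [pool[i] for i in sorted(idx)]
                weights = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n_taxa)
            draws = rng.multinomial(depth, weights / weights.sum())
            row = {}
            for sp, c in zip(chosen, draws):
                if c > 0:
                    asv = asv_of_species[sp]
                    row[asv] = int(c)
                    truth.true_cells.add((sid, asv))
            counts[sid] = row

    # mould spikes on Australian specimen samples
    n_spike, spike_frac = config.mould_spike
    if n_spike and mould_species:
        australian = [
            m["sample_id"]
            for m in meta_rows
            if m["role"] == "specimen" and m["region"] == "australia"
        ]
        spike_idx = rng.choice(len(australian), size=min(n_spike, len(australian)), replace=False)
        for i in sorted(spike_idx):
            sid = australian[i]
            total = sum(counts[sid].values())
            add_total = int(round(spike_frac / (1 - spike_frac) * total))
            per = add_total // len(mould_species)
            for sp in mould_species:
                asv = asv_of_species[sp]
                counts[sid][asv] = counts[sid].get(asv, 0) + per
                truth.true_cells.add((sid, asv))
            truth.mould_spiked_samples.append(sid)

    all_asvs = [s.id for s in asv_seqs]
    matrix = pd.DataFrame(0, index=sample_ids, columns=all_asvs, dtype="int64")
    for sid, row in counts.items():
        for asv, c in row.items():
            matrix.at[sid, asv] = c

    # index-switching bleed: per library, redistribute a fixed fraction of
    # each ASV's library-wide reads into non-source samples
    if config.bleed_rate > 0:
        meta_df = pd.DataFrame(meta_rows).set_index("sample_id")
        for library_id, lib_samples in meta_df.groupby("library_id").groups.items():
            lib_samples = list(lib_samples)
            block = matrix.loc[lib_samples]
            for asv in all_asvs:
                col = block[asv]
                total = int(col.sum())
                per_recipient = int(config.bleed_rate * total) // config.bleed_fanout
                if per_recipient < 1:
                    continue
                non_source = [s for s in lib_samples if matrix.at[s, asv] == 0]
                if not non_source:
                    continue
                n_rec = min(config.bleed_fanout, len(non_source))
                rec_idx = rng.choice(len(non_source), size=n_rec, replace=False)
                recipients = [non_source[i] for i in sorted(rec_idx)]
                moved = per_recipient * len(recipients)
                source = col.idxmax()  # deduct from the dominant source cell
                if matrix.at[source, asv] <= moved:
                    continue  # would empty the source; leave this ASV unbled
                matrix.at[source, asv] -= moved
                for r in recipients:
                    matrix.at[r, asv] += per_recipient
                    truth.bled_cells[(r, asv)] = {
                        "reads": per_recipient,
                        "source": source,
                    }

    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    cm = CountMatrix(matrix, meta)
    return cm, asv_seqs, truth
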