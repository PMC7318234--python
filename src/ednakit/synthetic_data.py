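"""Ground-truthed synthetic inputs with the statistical structure the pipeline assumes.

Emulates a regional seawater eDNA survey: a pool of vertebrate species with
a full taxonomic hierarchy and reference accessions; habitat-structured site
occupancy (sites grouped into up to six habitat types, three water samples
per site, four PCR replicates per sample); BLAST-style hit tables whose
percent identities decay with taxonomic distance (same species >= same
genus >= same family >= same order on average); lognormal-Poisson read
counts with gamma-distributed per-replicate depths; and field, extraction
and PCR negative controls carrying cross-contamination at a configurable
rate, injected both into controls and (at a lower rate) into samples so the
control-frequency filter has true positives and true negatives to find.

Home habitats are assigned per genus, so congeneric species share a habitat
and a sequence variant that can only be resolved to genus level does not
blur the habitat signal.

One seed governs everything through stage-keyed RNG streams, so identical
configurations give bit-identical outputs and each stage is reproducible in
isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    HABITATS,
    BlastHit,
    Checklist,
    Lineage,
    ReadCountTable,
    SampleSheet,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_reference_and_hits",
    "simulate_read_counts",
    "simulate_study",
    "draw_abundance_rates",
    "stage_rng",
]


def stage_rng(seed: int, *keys) -> np.random.Generator:
    """A generator for one named simulation stage, split off the master seed."""
    entropy = [int(seed) & 0x7FFFFFFF] + [
        zlib.crc32(str(k).encode()) for k in keys
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and distributional parameters of the synthetic survey.

    Defaults mirror the emulated survey: five surface habitat types with
    about four sites each, three 1-L water samples per site, four PCR
    replicates per sample, and identity levels that place the calibrated
    thresholds near the 89/93/99 bands.
    """

    n_species_pool: int = 150
    n_habitats: int = 5
    n_sites_per_habitat: int = 4
    n_water_samples_per_site: int = 3
    n_pcr_reps_per_sample: int = 4
    habitat_specificity: float = 0.8
    mean_log_abundance: float = 4.0
    sd_log_abundance: float = 1.0
    contamination_rate: float = 0.02
    sample_contamination_rate: float = 0.002
    seed: int = 0
    # identity structure used to fabricate BLAST hits
    within_species_identity: float = 99.7
    within_genus_identity: float = 96.0
    within_family_identity: float = 93.0
    within_order_identity: float = 89.0
    identity_sd: float = 0.4
    # occupancy probabilities
    home_occupancy: float = 0.9
    away_occupancy: float = 0.25
    # per-replicate depth variation (gamma with mean 1)
    depth_gamma_shape: float = 4.0
    # optional per-habitat weights on home-pool size (None = uniform)
    habitat_weights: tuple | None = None

    def __post_init__(self) -> None:
        for name in (
            "n_species_pool", "n_habitats", "n_sites_per_habitat",
            "n_water_samples_per_site", "n_pcr_reps_per_sample",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 1 <= self.n_habitats <= len(HABITATS):
            raise ValueError(f"n_habitats must be in [1, {len(HABITATS)}]")
        for name in ("habitat_specificity", "home_occupancy", "away_occupancy"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        for name in ("contamination_rate", "sample_contamination_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.habitat_weights is not None and len(self.habitat_weights) != self.n_habitats:
            raise ValueError("habitat_weights must have n_habitats entries")

    @property
    def habitats(self) -> tuple[str, ...]:
        return HABITATS[: self.n_habitats]


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    lineages: dict[str, Lineage]              # accession -> lineage
    species: list[str]                        # regional pool species
    accessions_by_species: dict[str, list[str]]
    occupancy: pd.DataFrame                   # species x site, bool
    site_habitat: pd.Series                   # site -> habitat
    home_habitat: pd.Series                   # species -> habitat
    identity_levels: dict[str, float]
    contaminants: list[str]                   # control-borne contaminant species
    blacklist_species: list[str]              # domestic-animal species
    blacklist: set[str]                       # names to blacklist (genus level)
    leak_species: list[str]                   # real species leaking into controls
    asv_species: dict[str, dict[str, str]] = field(default_factory=dict)

    def checklist(self) -> Checklist:
        by_genus = {
            sp: next(l.genus for l in self.lineages.values() if l.species == sp)
            for sp in self.species
        }
        return Checklist(by_genus)


# ---------------------------------------------------------------------------
# Taxonomy, occupancy, hits
# ---------------------------------------------------------------------------

_DOMESTIC = [
    ("Bos taurus", "Bos", "Bovidae", "Artiodactyla", "Mammalia"),
    ("Sus scrofa", "Sus", "Suidae", "Artiodactyla", "Mammalia"),
    ("Gallus gallus", "Gallus", "Phasianidae", "Galliformes", "Aves"),
]

_SPECIES_PER_GENUS = 2
_GENERA_PER_FAMILY = 3
_FAMILIES_PER_ORDER = 3


def _build_taxonomy(cfg: SimulationConfig):
    """Deterministic pool hierarchy plus domestic and contaminant outgroups."""
    lineages: dict[str, Lineage] = {}
    accessions_by_species: dict[str, list[str]] = {}
    species: list[str] = []
    acc_counter = 0

    def add_species(name, genus, family, order, klass, n_acc=2):
        nonlocal acc_counter
        accs = []
        for _ in range(n_acc):
            acc = f"ACC{acc_counter:06d}"
            acc_counter += 1
            lineages[acc] = Lineage(
                accession=acc, species=name, genus=genus,
                family=family, order=order, class_=klass,
            )
            accs.append(acc)
        accessions_by_species[name] = accs

    for i in range(cfg.n_species_pool):
        g = i // _SPECIES_PER_GENUS
        f = g // _GENERA_PER_FAMILY
        o = f // _FAMILIES_PER_ORDER
        genus = f"Genus{g:03d}"
        name = f"{genus} sp{i % _SPECIES_PER_GENUS + 1}"
        add_species(name, genus, f"Family{f:02d}", f"Order{o:02d}", "Actinopterygii")
        species.append(name)

    contaminants = []
    for j in range(3):
        name = f"Harbourfish{j} catchi"
        add_species(name, f"Harbourfish{j}", f"HarbourFam{j}", "OrderX", "Actinopterygii",
                    n_acc=1)
        contaminants.append(name)
    blacklist_species = []
    for name, genus, family, order, klass in _DOMESTIC:
        add_species(name, genus, family, order, klass, n_acc=1)
        blacklist_species.append(name)
    return lineages, species, accessions_by_species, contaminants, blacklist_species


def _build_truth(cfg: SimulationConfig) -> GroundTruth:
    (lineages, species, accs, contaminants, blacklist_species) = _build_taxonomy(cfg)
    habitats = cfg.habitats
    sites = [
        f"{hab}_S{s + 1}"
        for hab in habitats
        for s in range(cfg.n_sites_per_habitat)
    ]
    site_habitat = pd.Series(
        {site: site.rsplit("_S", 1)[0] for site in sites}, name="habitat"
    )

    rng = stage_rng(cfg.seed, "occupancy")
    n_genera = (cfg.n_species_pool + _SPECIES_PER_GENUS - 1) // _SPECIES_PER_GENUS
    weights = (
        np.asarray(cfg.habitat_weights, dtype=float)
        if cfg.habitat_weights is not None
        else np.ones(len(habitats))
    )
    weights = weights / weights.sum()
    genus_home = rng.choice(len(habitats), size=n_genera, p=weights)
    home = pd.Series(
        {sp: habitats[genus_home[i // _SPECIES_PER_GENUS]] for i, sp in enumerate(species)}
    )
    specialist = rng.random(len(species)) < cfg.habitat_specificity
    occ = pd.DataFrame(False, index=species, columns=sites)
    for i, sp in enumerate(species):
        for site in sites:
            if site_habitat[site] == home[sp]:
                occ.loc[sp, site] = rng.random() < cfg.home_occupancy
            elif not specialist[i]:
                occ.loc[sp, site] = rng.random() < cfg.away_occupancy

    leak_rng = stage_rng(cfg.seed, "leaks")
    occupied = [sp for sp in species if occ.loc[sp].any()]
    by_breadth = sorted(occupied, key=lambda sp: -int(occ.loc[sp].sum()))
    leak_species = by_breadth[:2] if len(by_breadth) >= 2 else by_breadth
    del leak_rng  # breadth choice is deterministic; stream reserved

    return GroundTruth(
        lineages=lineages,
        species=species,
        accessions_by_species=accs,
        occupancy=occ,
        site_habitat=site_habitat,
        home_habitat=home,
        identity_levels={
            "same_species": cfg.within_species_identity,
            "same_genus": cfg.within_genus_identity,
            "same_family": cfg.within_family_identity,
            "same_order": cfg.within_order_identity,
        },
        contaminants=contaminants,
        blacklist_species=blacklist_species,
        blacklist={g for _, g, *_ in _DOMESTIC},
        leak_species=leak_species,
    )


_BARCODE_LENGTH = {"mifish": 170, "riaz": 100}


def simulate_reference_and_hits(
    cfg: SimulationConfig,
    barcode: str = "mifish",
    truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, list[BlastHit], GroundTruth]:
    """Fabricate the taxonomy table and a screened-format BLAST hit table.

    One query sequence variant per detectable species (pool species occupying
    at least one site, plus contaminant and domestic species). Hit identities
    are drawn around the configured level means, so same-species hits exceed
    same-genus hits exceed same-family hits exceed same-order hits on
    average; each query also receives low-coverage and low-identity decoy
    hits that the screening step must discard. At most 40 hits per query.
    """
    if truth is None:
        truth = _build_truth(cfg)
    rng = stage_rng(cfg.seed, "hits", barcode)
    length = _BARCODE_LENGTH.get(barcode, 150)
    by_species_lineage = {
        l.species: l for l in truth.lineages.values() if l.species
    }
    genus_members: dict[str, list[str]] = {}
    family_members: dict[str, list[str]] = {}
    order_members: dict[str, list[str]] = {}
    for sp, lin in by_species_lineage.items():
        genus_members.setdefault(lin.genus, []).append(sp)
        family_members.setdefault(lin.family, []).append(sp)
        order_members.setdefault(lin.order, []).append(sp)

    detectable = [sp for sp in truth.species if truth.occupancy.loc[sp].any()]
    detectable += truth.contaminants + truth.blacklist_species

    def draw_identity(mean: float, lo: float = 0.0, hi: float = 100.0) -> float:
        return float(np.clip(rng.normal(mean, cfg.identity_sd), lo, hi))

    hits: list[BlastHit] = []
    asv_map: dict[str, str] = {}
    for i, sp in enumerate(detectable):
        qid = f"{barcode}_asv{i:04d}"
        asv_map[qid] = sp
        lin = by_species_lineage[sp]
        qhits: list[BlastHit] = []

        def add(acc: str, ident: float, cov: float) -> None:
            bits = round(length * ident / 100.0 * 1.8, 1)
            qhits.append(BlastHit(
                query_id=qid, subject_accession=acc,
                percent_identity=round(ident, 3), query_coverage=round(cov, 2),
                alignment_length=length, evalue=1e-40, bitscore=bits,
            ))

        for acc in truth.accessions_by_species[sp]:
            ident = draw_identity(
                cfg.within_species_identity,
                lo=99.0 if cfg.within_species_identity >= 99.0 else 0.0,
            )
            add(acc, ident, rng.uniform(95, 100))
        for other in genus_members.get(lin.genus, []):
            if other == sp:
                continue
            add(truth.accessions_by_species[other][0],
                draw_identity(cfg.within_genus_identity),
                rng.uniform(92, 100))
        relatives = [
            s for s in family_members.get(lin.family, [])
            if by_species_lineage[s].genus != lin.genus
        ]
        for other in relatives[:4]:
            add(truth.accessions_by_species[other][0],
                draw_identity(cfg.within_family_identity),
                rng.uniform(92, 100))
        cousins = [
            s for s in order_members.get(lin.order, [])
            if by_species_lineage[s].family != lin.family
        ]
        for other in cousins[:4]:
            add(truth.accessions_by_species[other][0],
                draw_identity(cfg.within_order_identity),
                rng.uniform(92, 100))
        # decoys that screening must discard: low coverage, then low identity
        for other in (relatives[4:6] or [sp]):
            add(truth.accessions_by_species[other][0],
                draw_identity(cfg.within_family_identity),
                rng.uniform(50, 89.5))
        add(truth.accessions_by_species[sp][0], rng.uniform(60, 79.5),
            rng.uniform(92, 100))
        rng.shuffle(qhits)
        hits.extend(qhits[:40])
    truth.asv_species[barcode] = asv_map

    taxonomy = pd.DataFrame(
        [
            {
                "accession": l.accession, "species": l.species, "genus": l.genus,
                "family": l.family, "order": l.order, "class": l.class_,
            }
            for l in truth.lineages.values()
        ]
    )
    return taxonomy, hits, truth


# ---------------------------------------------------------------------------
# Read counts
# ---------------------------------------------------------------------------

def draw_abundance_rates(cfg: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Lognormal per-species Poisson rates (the marginal abundance model)."""
    return rng.lognormal(cfg.mean_log_abundance, cfg.sd_log_abundance, size=n)


def _expected_replicate_depth(cfg: SimulationConfig, truth: GroundTruth) -> float:
    mean_occupying = float(truth.occupancy.sum(axis=0).mean())
    return mean_occupying * float(
        np.exp(cfg.mean_log_abundance + 0.5 * cfg.sd_log_abundance**2)
    )


def simulate_read_counts(
    cfg: SimulationConfig,
    truth: GroundTruth,
    barcode: str = "mifish",
    season: str = "2016",
) -> ReadCountTable:
    """Replicate-structured read counts for one barcode and season.

    Per occupying species and water sample a lognormal rate is drawn; each
    PCR replicate adds Poisson noise and a gamma-distributed depth factor.
    Control columns (two field, one extraction, one PCR control, each with
    the full replicate structure) contain only contamination draws:
    contaminant taxa at ``contamination_rate``, domestic taxa concentrated
    in the PCR controls, and two real "leak" species at a much lower rate.
    Samples receive the same contaminant taxa at
    ``sample_contamination_rate``. Replicate ids are shared across barcodes
    so per-replicate counts can be merged by summation.
    """
    if barcode not in truth.asv_species:
        raise ValueError(
            f"no ASVs for barcode {barcode!r}; run simulate_reference_and_hits first"
        )
    rng = stage_rng(cfg.seed, "counts", barcode, season)
    asv_map = truth.asv_species[barcode]
    species_asv = {sp: asv for asv, sp in asv_map.items()}
    sites = list(truth.occupancy.columns)

    rows = []
    for site in sites:
        hab = truth.site_habitat[site]
        for w in range(cfg.n_water_samples_per_site):
            ws = f"{site}_W{w + 1}"
            for r in range(cfg.n_pcr_reps_per_sample):
                rows.append((f"{ws}_R{r + 1}", ws, site, hab, season, "sample"))
    controls = [
        ("FC1", "CTRL_FIELD", "field_control"),
        ("FC2", "CTRL_FIELD", "field_control"),
        ("EC1", "CTRL_EXTR", "extraction_control"),
        ("PC1", "CTRL_PCR", "pcr_control"),
    ]
    for ws, site, role in controls:
        for r in range(cfg.n_pcr_reps_per_sample):
            rows.append((f"{ws}_R{r + 1}", ws, site, "", season, role))
    sheet = SampleSheet(pd.DataFrame(
        rows,
        columns=["replicate_id", "water_sample_id", "site_id", "habitat",
                 "season", "role"],
    ))

    rep_ids = sheet.replicate_ids
    depth_factor = pd.Series(
        rng.gamma(cfg.depth_gamma_shape, 1.0 / cfg.depth_gamma_shape, len(rep_ids)),
        index=rep_ids,
    )
    all_asvs = sorted(asv_map)
    counts = pd.DataFrame(0, index=all_asvs, columns=rep_ids, dtype=np.int64)

    # real communities
    for site in sites:
        occupying = truth.occupancy.index[truth.occupancy[site]]
        for w in range(cfg.n_water_samples_per_site):
            ws = f"{site}_W{w + 1}"
            lam = draw_abundance_rates(cfg, len(occupying), rng)
            for r in range(cfg.n_pcr_reps_per_sample):
                rep = f"{ws}_R{r + 1}"
                draws = rng.poisson(lam * depth_factor[rep])
                for sp, c in zip(occupying, draws):
                    if c:
                        counts.loc[species_asv[sp], rep] += int(c)

    e_depth = _expected_replicate_depth(cfg, truth)

    def inject(sp: str, rep: str, rate: float) -> None:
        if rate <= 0 or sp not in species_asv:
            return
        c = rng.poisson(rate * e_depth * depth_factor[rep])
        if c:
            counts.loc[species_asv[sp], rep] += int(c)

    sample_reps = sheet.sample_ids
    for rep in sample_reps:
        for sp in truth.contaminants + truth.blacklist_species:
            inject(sp, rep, cfg.sample_contamination_rate * 0.5)
    for ws, site, role in controls:
        for r in range(cfg.n_pcr_reps_per_sample):
            rep = f"{ws}_R{r + 1}"
            for sp in truth.contaminants:
                inject(sp, rep, cfg.contamination_rate)
            for sp in truth.blacklist_species:
                inject(sp, rep, cfg.contamination_rate
                       if role == "pcr_control" else 0.1 * cfg.contamination_rate)
            for sp in truth.leak_species:
                if role in ("field_control", "extraction_control"):
                    inject(sp, rep, 0.005 * cfg.contamination_rate)

    counts = counts.loc[counts.sum(axis=1) > 0]
    return ReadCountTable(counts, sheet)


def simulate_study(
    cfg: SimulationConfig,
    barcodes: tuple[str, ...] = ("mifish", "riaz"),
    season: str = "2016",
) -> dict:
    """Generate a complete single-season study: taxonomy, hits and counts per barcode.

    Returns a dict with keys ``truth``, ``taxonomy``, ``checklist``,
    ``blacklist``, ``hits`` (per barcode) and ``counts`` (per barcode).
    """
    truth = None
    taxonomy = None
    hits: dict[str, list[BlastHit]] = {}
    for bc in barcodes:
        taxonomy, hits[bc], truth = simulate_reference_and_hits(cfg, bc, truth)
    counts = {bc: simulate_read_counts(cfg, truth, bc, season) for bc in barcodes}
    return {
        "truth": truth,
        "taxonomy": taxonomy,
        "checklist": truth.checklist(),
        "blacklist": set(truth.blacklist),
        "hits": hits,
        "counts": counts,
    }
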