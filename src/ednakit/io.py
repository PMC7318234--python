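"""Readers, writers and in-memory containers for the pipeline's external formats.

Formats handled here:

* BLAST tabular hits, ``outfmt "6 std qcovhsp"`` (13 columns);
* a taxonomy TSV mapping reference accessions to lineages;
* read-count TSV tables (rows = sequence variants or taxa, columns = PCR
  replicates) with an accompanying sample-sheet TSV;
* a regional species/genus checklist TSV;
* Newick serialisation of clustering trees;
* a flat ``key=value`` configuration file carrying every pipeline threshold;
* a machine-readable audit log of filtering decisions.

Readers are strict: rows that violate a container invariant (identity outside
[0, 100], negative or non-integer counts, unknown replicate columns) raise
:class:`FormatError` rather than being coerced or dropped.
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "BLAST_COLUMNS",
    "HABITATS",
    "ROLES",
    "BlastHit",
    "Lineage",
    "SampleSheet",
    "ReadCountTable",
    "Checklist",
    "PipelineConfig",
    "AuditLog",
    "read_blast_table",
    "write_blast_table",
    "read_taxonomy",
    "write_taxonomy",
    "taxon_lineages",
    "read_counts",
    "write_counts",
    "read_checklist",
    "write_newick",
]


class FormatError(ValueError):
    """An input file violates the format contract or a container invariant."""


#: Column order of the extended BLAST tabular format ("6 std qcovhsp").
BLAST_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "qcovhsp",
)

#: Habitat vocabulary of the sampling design (five surface habitat types plus
#: the deep stratum of the offshore sand-bottom sites).
HABITATS = (
    "seagrass", "coral_reef", "mangrove", "inshore_sand",
    "offshore_sand_surface", "offshore_sand_deep",
)

#: Roles a replicate column can have in the sample sheet.
ROLES = ("sample", "field_control", "extraction_control", "pcr_control", "mock")

#: Roles counted as negative controls by the decontamination filters.
CONTROL_ROLES = ("field_control", "extraction_control", "pcr_control")


# ---------------------------------------------------------------------------
# BLAST hits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlastHit:
    """One query-to-subject alignment record from a BLAST tabular file."""

    query_id: str
    subject_accession: str
    percent_identity: float
    query_coverage: float
    alignment_length: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise FormatError(
                f"percent_identity {self.percent_identity} outside [0, 100] "
                f"for query {self.query_id!r}"
            )
        if not (0.0 <= self.query_coverage <= 100.0):
            raise FormatError(
                f"query_coverage {self.query_coverage} outside [0, 100] "
                f"for query {self.query_id!r}"
            )
        if self.evalue < 0:
            raise FormatError(f"negative evalue for query {self.query_id!r}")


def read_blast_table(path: str | Path) -> list[BlastHit]:
    """Parse an ``outfmt "6 std qcovhsp"`` BLAST table into a hit list.

    Malformed rows raise :class:`FormatError` with their line number; an
    empty file yields an empty list.
    """
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(BLAST_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(BLAST_COLUMNS)} "
                    f"tab-separated fields, got {len(parts)}"
                )
            try:
                hit = BlastHit(
                    query_id=parts[0],
                    subject_accession=parts[1],
                    percent_identity=float(parts[2]),
                    query_coverage=float(parts[12]),
                    alignment_length=int(parts[3]),
                    evalue=float(parts[10]),
                    bitscore=float(parts[11]),
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_blast_table(hits: list[BlastHit], path: str | Path) -> None:
    """Write hits in the 13-column tabular dialect read by :func:`read_blast_table`.

    Alignment bookkeeping columns not carried by :class:`BlastHit` (mismatch,
    gapopen, coordinates) are filled with values consistent with the identity
    and alignment length.
    """
    with open(path, "w") as fh:
        for h in hits:
            mismatch = round(h.alignment_length * (100.0 - h.percent_identity) / 100.0)
            row = (
                h.query_id, h.subject_accession, f"{h.percent_identity:.3f}",
                str(h.alignment_length), str(mismatch), "0",
                "1", str(h.alignment_length), "1", str(h.alignment_length),
                f"{h.evalue:.2e}", f"{h.bitscore:.1f}", f"{h.query_coverage:.2f}",
            )
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Taxonomy / lineages
# ---------------------------------------------------------------------------

_RANKS = ("species", "genus", "family", "order", "class_")


@dataclass(frozen=True)
class Lineage:
    """Taxonomic path of a reference accession (empty above the lowest known rank).

    Rank completeness is monotone upward: a nonempty ``species`` implies a
    nonempty ``genus``, and so on.
    """

    accession: str
    species: str = ""
    genus: str = ""
    family: str = ""
    order: str = ""
    class_: str = ""

    def __post_init__(self) -> None:
        vals = [getattr(self, r) for r in _RANKS]
        for lower, upper in zip(vals, vals[1:]):
            if lower and not upper:
                raise FormatError(
                    f"lineage for {self.accession!r} has a gap: a named rank "
                    "requires all broader ranks to be named"
                )

    def rank_name(self, rank: str) -> str:
        return getattr(self, "class_" if rank == "class" else rank)


_TAXONOMY_COLUMNS = ("accession", "species", "genus", "family", "order", "class")


def read_taxonomy(path: str | Path) -> dict[str, Lineage]:
    """Read a taxonomy TSV into a mapping of accession to :class:`Lineage`."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(_TAXONOMY_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"taxonomy table missing columns: {sorted(missing)}")
    out: dict[str, Lineage] = {}
    for _, row in df.iterrows():
        acc = row["accession"]
        if acc in out:
            raise FormatError(f"duplicate accession {acc!r} in taxonomy table")
        out[acc] = Lineage(
            accession=acc, species=row["species"], genus=row["genus"],
            family=row["family"], order=row["order"], class_=row["class"],
        )
    return out


def write_taxonomy(lineages: dict[str, Lineage], path: str | Path) -> None:
    rows = [
        {
            "accession": l.accession, "species": l.species, "genus": l.genus,
            "family": l.family, "order": l.order, "class": l.class_,
        }
        for l in lineages.values()
    ]
    pd.DataFrame(rows, columns=list(_TAXONOMY_COLUMNS)).to_csv(path, sep="\t", index=False)


def taxon_lineages(lineages: dict[str, Lineage]) -> dict[str, Lineage]:
    """Index lineages by taxon *name* at every rank.

    Species names map to their full lineage; genus/family/order names map to
    partial lineages truncated at that rank. Used to resolve the lineage of a
    collapsed taxon row (which may sit at any rank) for ancestor-aware
    filtering.
    """
    by_name: dict[str, Lineage] = {}
    for lin in lineages.values():
        if lin.species and lin.species not in by_name:
            by_name[lin.species] = lin
        if lin.genus and lin.genus not in by_name:
            by_name[lin.genus] = Lineage(
                accession="", genus=lin.genus, family=lin.family,
                order=lin.order, class_=lin.class_,
            )
        if lin.family and lin.family not in by_name:
            by_name[lin.family] = Lineage(
                accession="", family=lin.family, order=lin.order, class_=lin.class_,
            )
        if lin.order and lin.order not in by_name:
            by_name[lin.order] = Lineage(accession="", order=lin.order, class_=lin.class_)
    return by_name


# ---------------------------------------------------------------------------
# Sample sheet and read-count table
# ---------------------------------------------------------------------------

_SHEET_COLUMNS = ("replicate_id", "water_sample_id", "site_id", "habitat", "season", "role")


class SampleSheet:
    """Per-replicate metadata: water sample, site, habitat, season and role.

    Wraps a DataFrame indexed by ``replicate_id``. Each water sample must map
    to exactly one site, and every role must come from :data:`ROLES`.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if frame.index.name != "replicate_id":
            if "replicate_id" in frame.columns:
                frame = frame.set_index("replicate_id")
            else:
                raise FormatError("sample sheet needs a replicate_id column")
        missing = {c for c in _SHEET_COLUMNS[1:]} - set(frame.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        if frame.index.duplicated().any():
            dups = frame.index[frame.index.duplicated()].tolist()
            raise FormatError(f"duplicate replicate ids in sample sheet: {dups}")
        bad_roles = set(frame["role"]) - set(ROLES)
        if bad_roles:
            raise FormatError(f"unknown roles in sample sheet: {sorted(bad_roles)}")
        is_sample = frame["role"] == "sample"
        bad_hab = set(frame.loc[is_sample, "habitat"]) - set(HABITATS)
        if bad_hab:
            raise FormatError(f"unknown habitats in sample sheet: {sorted(bad_hab)}")
        sites_per_ws = frame.groupby("water_sample_id")["site_id"].nunique()
        multi = sites_per_ws[sites_per_ws > 1]
        if not multi.empty:
            raise FormatError(
                f"water samples mapped to multiple sites: {multi.index.tolist()}"
            )
        self.frame = frame

    @classmethod
    def read(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype=str).fillna(""))

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t")

    @property
    def replicate_ids(self) -> list[str]:
        return list(self.frame.index)

    def ids_with_role(self, *roles: str) -> list[str]:
        return list(self.frame.index[self.frame["role"].isin(roles)])

    @property
    def sample_ids(self) -> list[str]:
        return self.ids_with_role("sample")

    @property
    def control_ids(self) -> list[str]:
        return self.ids_with_role(*CONTROL_ROLES)

    def subset(self, replicate_ids) -> "SampleSheet":
        return SampleSheet(self.frame.loc[list(replicate_ids)])

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleSheet) and self.frame.equals(other.frame)


_INT_RE = re.compile(r"^\d+$")


class ReadCountTable:
    """Taxa-or-variant rows by PCR-replicate columns of non-negative integer counts.

    ``depths`` records the per-replicate sequencing depth at construction time
    and is carried unchanged through row-removal filters, so that relative
    abundances stay referenced to the replicate's original total reads.
    ``row_meta`` optionally carries per-row annotations (e.g. assigned rank).
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        sheet: SampleSheet,
        depths: pd.Series | None = None,
        row_meta: pd.DataFrame | None = None,
    ):
        counts = counts.copy()
        counts.index.name = "taxon"
        if counts.index.duplicated().any():
            dups = counts.index[counts.index.duplicated()].tolist()
            raise FormatError(f"duplicate row identifiers: {dups}")
        unknown = set(counts.columns) - set(sheet.replicate_ids)
        missing = set(sheet.replicate_ids) - set(counts.columns)
        if unknown or missing:
            raise FormatError(
                f"column/sheet mismatch: unknown columns {sorted(unknown)}, "
                f"missing columns {sorted(missing)}"
            )
        counts = counts[sheet.replicate_ids]
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise FormatError("read counts must be integers")
            counts = counts.astype(np.int64)
            arr = counts.to_numpy()
        if (arr < 0).any():
            raise FormatError("read counts must be non-negative")
        self.counts = counts.astype(np.int64)
        self.sheet = sheet
        self.depths = (
            depths.reindex(self.counts.columns)
            if depths is not None
            else self.counts.sum(axis=0).astype(np.int64)
        )
        self.row_meta = row_meta.loc[self.counts.index] if row_meta is not None else None

    # -- construction helpers -------------------------------------------------
    def with_counts(self, counts: pd.DataFrame, keep_depths: bool = True) -> "ReadCountTable":
        """New table sharing this table's sheet (and, by default, depths)."""
        meta = self.row_meta.loc[counts.index] if self.row_meta is not None else None
        return ReadCountTable(
            counts, self.sheet,
            depths=self.depths if keep_depths else None,
            row_meta=meta,
        )

    def drop_rows(self, rows) -> "ReadCountTable":
        return self.with_counts(self.counts.drop(index=list(rows)))

    # -- accessors ------------------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_columns(self) -> pd.DataFrame:
        return self.counts[self.sheet.sample_ids]

    @property
    def control_columns(self) -> pd.DataFrame:
        return self.counts[self.sheet.control_ids]

    def relative_abundance(self) -> pd.DataFrame:
        """Counts divided by original per-replicate depths (0/0 -> 0)."""
        depths = self.depths.to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = self.counts.to_numpy(dtype=float) / depths[None, :]
        rel = np.nan_to_num(rel, nan=0.0, posinf=0.0)
        return pd.DataFrame(rel, index=self.counts.index, columns=self.counts.columns)

    def write(self, path: str | Path, sheet_path: str | Path | None = None) -> None:
        out = self.counts.copy()
        out.index.name = "taxon"
        out.to_csv(path, sep="\t")
        if sheet_path is not None:
            self.sheet.write(sheet_path)


def read_counts(path: str | Path, samplesheet_path: str | Path) -> ReadCountTable:
    """Read a count TSV plus sample sheet into a :class:`ReadCountTable`.

    Counts are validated strictly: any cell that is not a plain non-negative
    integer literal (e.g. contains a decimal point) is an error.
    """
    sheet = SampleSheet.read(samplesheet_path)
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    for col in raw.columns:
        bad = raw.index[~raw[col].fillna("").str.match(_INT_RE)]
        if len(bad):
            raise FormatError(
                f"{path}: column {col!r} has non-integer counts at rows "
                f"{list(bad[:5])}"
            )
    counts = raw.astype(np.int64)
    return ReadCountTable(counts, sheet)


def write_counts(table: ReadCountTable, path: str | Path, sheet_path: str | Path) -> None:
    table.write(path, sheet_path)


# ---------------------------------------------------------------------------
# Regional checklist
# ---------------------------------------------------------------------------

class Checklist:
    """Species and genera flagged as regionally present.

    Species membership implies membership of the species' genus, so the
    constructor requires a genus for every species entry.
    """

    def __init__(self, species_to_genus: dict[str, str], extra_genera: set[str] = frozenset()):
        for sp, g in species_to_genus.items():
            if not g:
                raise FormatError(f"checklist species {sp!r} has no genus")
        self.species = set(species_to_genus)
        self.species_to_genus = dict(species_to_genus)
        self.genera = set(species_to_genus.values()) | set(extra_genera)

    @classmethod
    def read(cls, path: str | Path) -> "Checklist":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        if not {"name", "rank"} <= set(df.columns):
            raise FormatError("checklist needs columns: name, rank[, genus]")
        sp = {}
        extra = set()
        for row in df.itertuples(index=False):
            if row.rank == "species":
                sp[row.name] = getattr(row, "genus", "")
            elif row.rank == "genus":
                extra.add(row.name)
            else:
                raise FormatError(f"checklist rank must be species or genus, got {row.rank!r}")
        return cls(sp, extra)

    def write(self, path: str | Path) -> None:
        rows = [
            {"name": s, "rank": "species", "genus": g}
            for s, g in sorted(self.species_to_genus.items())
        ]
        rows += [
            {"name": g, "rank": "genus", "genus": ""}
            for g in sorted(self.genera - set(self.species_to_genus.values()))
        ]
        pd.DataFrame(rows, columns=["name", "rank", "genus"]).to_csv(path, sep="\t", index=False)

    def has(self, taxon: str, rank: str) -> bool:
        if rank == "species":
            return taxon in self.species
        if rank == "genus":
            return taxon in self.genera
        return False


# ---------------------------------------------------------------------------
# Newick serialisation
# ---------------------------------------------------------------------------

_NEWICK_UNSAFE = re.compile(r"[\s,():;'\[\]]")


def _newick_label(name: str) -> str:
    if _NEWICK_UNSAFE.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(tree) -> str:
    """Serialise a binary tree with branch lengths to a Newick string.

    ``tree`` is a :class:`skbio.TreeNode` (or any object with ``children``,
    ``name`` and ``length`` attributes). Leaf names containing Newick
    metacharacters are single-quoted; duplicate leaf names are an error.
    """
    seen: set[str] = set()

    def fmt(node) -> str:
        if not node.children:
            name = node.name or ""
            if name in seen:
                raise FormatError(f"duplicate leaf name {name!r}")
            seen.add(name)
            label = _newick_label(name)
        else:
            label = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name:
                label += _newick_label(node.name)
        if node.length is not None:
            label += ":" + format(float(node.length), "g")
        return label

    return fmt(tree) + ";"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, with the study defaults.

    Serialises to a flat ``key=value`` text file.
    """

    # hit screening
    min_coverage: float = 90.0
    min_identity: float = 80.0
    max_hits_per_query: int = 40
    # threshold calibration
    calibration_percentile: float = 95.0
    calibration_min_n: int = 5
    calibration_mapping: str = "adjacent"
    species_band_low: float = 99.0
    species_band_high: float = 100.0
    default_genus_min: float = 93.0
    default_family_min: float = 89.0
    # decontamination
    min_replicates: int = 2
    replicate_scope: str = "dataset"
    frequency_mode: str = "relative"
    # community matrices
    rarefaction_depth: str = "median"
    drop_below_depth: bool = False
    # beta diversity / multivariate
    raup_crick_sims: int = 9999
    raup_crick_null: str = "frequency_weighted"
    n_permutations: int = 999
    # accumulation
    accumulation_permutations: int = 1000
    extrapolate_to: int = 200
    seed: int = 0

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def read(cls, path: str | Path) -> "PipelineConfig":
        kwargs = {}
        ftypes = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise FormatError(f"{path}:{lineno}: expected key=value")
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in ftypes:
                    raise FormatError(f"{path}:{lineno}: unknown config key {key!r}")
                current = getattr(defaults, key)
                if isinstance(current, bool):
                    kwargs[key] = value.lower() in ("1", "true", "yes")
                elif isinstance(current, int):
                    kwargs[key] = int(value)
                elif isinstance(current, float):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Audit log
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AuditRecord:
    stage: str
    taxon: str
    action: str
    reason: str
    details: str = ""


class AuditLog:
    """Machine-readable ledger of every filtering decision.

    Each removed (or zeroed, or flagged) taxon contributes one record with a
    reason code and the numbers behind the decision.
    """

    def __init__(self) -> None:
        self.records: list[AuditRecord] = []

    def add(self, stage: str, taxon: str, action: str, reason: str, details: str = "") -> None:
        self.records.append(AuditRecord(stage, taxon, action, reason, details))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(r) for r in self.records],
            columns=["stage", "taxon", "action", "reason", "details"],
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.records)
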