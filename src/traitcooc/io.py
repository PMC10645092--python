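"""Reading, validation and filtering of incidence matrices and trait tables.

An *incidence matrix* is one watershed's binary species-by-lakes
presence/absence table. The *trait table* carries, per species, the
three traits used downstream: body size (total length, cm), temperature
preference (°C, may be missing before imputation) and trophic level
(dimensionless, ≥1). Missing temperature preferences are imputed as the
unweighted mean over congeners (species sharing the genus label).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRAIT_COLUMNS = ("body_size", "temp_pref", "trophic_level")


class ValidationError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass(frozen=True, eq=False)
class IncidenceMatrix:
    """One watershed's binary species × lakes presence/absence matrix.

    ``cells[i, j] == 1`` iff species ``species_ids[i]`` occurs in lake
    ``lake_ids[j]``. Rows of all zeros (species never observed in the
    watershed) are dropped at read time.
    """

    watershed_id: str
    species_ids: tuple[str, ...]
    lake_ids: tuple[str, ...]
    cells: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=np.int8)
        if cells.shape != (len(self.species_ids), len(self.lake_ids)):
            raise ValidationError(
                f"{self.watershed_id}: cells shape {cells.shape} does not match "
                f"{len(self.species_ids)} species × {len(self.lake_ids)} lakes"
            )
        if not np.isin(cells, (0, 1)).all():
            raise ValidationError(f"{self.watershed_id}: non-binary cell values")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValidationError(f"{self.watershed_id}: duplicate species ids")
        if len(set(self.lake_ids)) != len(self.lake_ids):
            raise ValidationError(f"{self.watershed_id}: duplicate lake ids")
        object.__setattr__(self, "species_ids", tuple(self.species_ids))
        object.__setattr__(self, "lake_ids", tuple(self.lake_ids))
        cells.setflags(write=False)
        object.__setattr__(self, "cells", cells)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IncidenceMatrix):
            return NotImplemented
        return (
            self.watershed_id == other.watershed_id
            and self.species_ids == other.species_ids
            and self.lake_ids == other.lake_ids
            and np.array_equal(self.cells, other.cells)
        )

    def __hash__(self) -> int:
        return hash((self.watershed_id, self.species_ids, self.lake_ids))

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_lakes(self) -> int:
        return len(self.lake_ids)

    def row_sums(self) -> np.ndarray:
        """Per-species occupancy (number of lakes occupied)."""
        return self.cells.sum(axis=1)

    def col_sums(self) -> np.ndarray:
        """Per-lake richness (number of species present)."""
        return self.cells.sum(axis=0)

    def species_index(self, species: str) -> int:
        try:
            return self.species_ids.index(species)
        except ValueError:
            raise KeyError(
                f"species {species!r} not in watershed {self.watershed_id}"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.asarray(self.cells),
            index=pd.Index(self.species_ids, name="species_id"),
            columns=list(self.lake_ids),
        )

    def with_cells(self, cells: np.ndarray) -> "IncidenceMatrix":
        """Copy of this matrix with new cell values (same labels)."""
        return replace(self, cells=np.array(cells, dtype=np.int8))


@dataclass(frozen=True)
class TraitTable:
    """Per-species trait records, indexed by species id.

    ``data`` columns: genus, body_size, temp_pref, trophic_level.
    ``temp_missing`` marks species whose temperature preference was
    absent in the source file (NaN until imputed).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        required = ["genus", *TRAIT_COLUMNS]
        missing_cols = [c for c in required if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"trait table missing columns: {missing_cols}")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate species_id in trait table: {dups}")
        if df["body_size"].isna().any() or df["trophic_level"].isna().any():
            bad = df.index[
                df["body_size"].isna() | df["trophic_level"].isna()
            ].tolist()
            raise ValidationError(
                f"body_size/trophic_level must be complete; missing for {bad}"
            )
        if (df["body_size"] <= 0).any():
            raise ValidationError("body_size must be > 0")
        if (df["trophic_level"] < 1).any():
            raise ValidationError("trophic_level must be >= 1")

    @property
    def species_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def temp_missing(self) -> pd.Series:
        return self.data["temp_pref"].isna()

    @property
    def complete(self) -> bool:
        return not self.temp_missing.any()

    def subset(self, species: list[str]) -> "TraitTable":
        missing = sorted(set(species) - set(self.data.index))
        if missing:
            raise KeyError(f"species not in trait table: {missing}")
        return TraitTable(self.data.loc[list(species)].copy())


# ---------------------------------------------------------------------------
# incidence I/O


def _read_one_incidence(watershed_id: str, path: Path) -> IncidenceMatrix:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.columns[0] != "species_id":
        raise ValidationError(
            f"{path}: first column must be 'species_id', got {df.columns[0]!r}"
        )
    species = df["species_id"].tolist()
    lakes = df.columns[1:].tolist()
    raw = df.iloc[:, 1:].to_numpy()
    cells = np.empty(raw.shape, dtype=np.int8)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            v = raw[i, j].strip()
            if v not in ("0", "1"):
                raise ValidationError(
                    f"{path}: non-binary value {raw[i, j]!r} at species "
                    f"{species[i]!r}, lake {lakes[j]!r}"
                )
            cells[i, j] = int(v)
    keep = cells.sum(axis=1) > 0
    if not keep.all():
        dropped = [s for s, k in zip(species, keep) if not k]
        logger.warning(
            "%s: dropping %d all-zero species row(s): %s",
            watershed_id,
            len(dropped),
            ", ".join(dropped),
        )
        species = [s for s, k in zip(species, keep) if k]
        cells = cells[keep]
    return IncidenceMatrix(watershed_id, tuple(species), tuple(lakes), cells)


def read_incidence(path: str | Path) -> list[IncidenceMatrix]:
    """Read presence/absence matrices from a directory or a manifest CSV.

    A directory is scanned for ``*.csv`` files (watershed id = file
    stem); a manifest is a two-column CSV ``watershed_id,path`` with
    paths resolved relative to the manifest location. Each incidence CSV
    has a ``species_id`` first column, lake ids as remaining headers and
    0/1 cells. All-zero species rows are dropped with a warning;
    non-binary cells and duplicate ids are hard errors.
    """
    path = Path(path)
    if path.is_dir():
        entries = sorted((p.stem, p) for p in path.glob("*.csv"))
    elif path.is_file():
        man = pd.read_csv(path, dtype=str)
        if list(man.columns[:2]) != ["watershed_id", "path"]:
            raise ValidationError(
                f"{path}: manifest must have columns watershed_id,path"
            )
        entries = [
            (row.watershed_id, path.parent / row.path) for row in man.itertuples()
        ]
    else:
        raise FileNotFoundError(f"no such file or directory: {path}")
    if not entries:
        raise ValidationError(f"{path}: no incidence CSV files found")
    seen: set[str] = set()
    matrices = []
    for wid, p in entries:
        if wid in seen:
            raise ValidationError(f"duplicate watershed id {wid!r}")
        seen.add(wid)
        matrices.append(_read_one_incidence(wid, Path(p)))
    return matrices


def write_incidence(matrix: IncidenceMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path)


def write_manifest(
    matrices: list[IncidenceMatrix], directory: str | Path
) -> Path:
    """Write one CSV per watershed plus a ``manifest.csv`` into *directory*."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for m in matrices:
        fname = f"{m.watershed_id}.csv"
        write_incidence(m, directory / fname)
        rows.append({"watershed_id": m.watershed_id, "path": fname})
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def filter_watersheds(
    matrices: list[IncidenceMatrix],
    min_lakes: int = 20,
    min_species: int = 20,
) -> list[IncidenceMatrix]:
    """Keep watersheds with at least *min_lakes* lakes and *min_species* species.

    The thresholds are inclusive: a 20 × 20 matrix is retained with the
    defaults. Species counts refer to species actually occurring in the
    watershed (all-zero rows were already dropped at read time).
    """
    kept = []
    for m in matrices:
        ok = m.n_lakes >= min_lakes and m.n_species >= min_species
        logger.info(
            "watershed %s: %d lakes, %d species -> %s",
            m.watershed_id,
            m.n_lakes,
            m.n_species,
            "retained" if ok else "removed",
        )
        if ok:
            kept.append(m)
    if not kept:
        raise ValidationError(
            f"no watershed satisfies >= {min_lakes} lakes and "
            f">= {min_species} species"
        )
    return kept


# ---------------------------------------------------------------------------
# trait I/O


def read_traits(path: str | Path) -> TraitTable:
    """Read the species trait CSV.

    Expected columns: species_id, genus, body_size, temp_pref,
    trophic_level. ``temp_pref`` may be empty (flagged missing, to be
    filled by :func:`impute_temperature`); the other traits must be
    complete.
    """
    df = pd.read_csv(path)
    required = ["species_id", "genus", *TRAIT_COLUMNS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: trait CSV missing columns {missing}")
    df = df.set_index("species_id")
    for col in ("body_size", "trophic_level"):
        if df[col].isna().any():
            bad = df.index[df[col].isna()].tolist()
            raise ValidationError(f"{path}: missing {col} for {bad}")
    return TraitTable(df[["genus", *TRAIT_COLUMNS]].copy())


def impute_temperature(traits: TraitTable) -> TraitTable:
    """Fill missing temperature preferences from congeneric means.

    Each missing value becomes the unweighted arithmetic mean of the
    non-missing temperature preferences of species sharing its genus.
    A missing species with no informative congener is a hard error.
    Non-missing values are never altered.
    """
    df = traits.data.copy()
    missing = df.index[df["temp_pref"].isna()]
    if len(missing) == 0:
        return traits
    genus_means = (
        df.loc[df["temp_pref"].notna()].groupby("genus")["temp_pref"].mean()
    )
    for sp in missing:
        genus = df.at[sp, "genus"]
        if genus not in genus_means.index:
            raise ValidationError(
                f"cannot impute temp_pref for {sp!r}: no congener in genus "
                f"{genus!r} has a known value"
            )
        df.at[sp, "temp_pref"] = genus_means[genus]
        logger.info(
            "imputed temp_pref for %s from genus %s mean %.3f",
            sp,
            genus,
            genus_means[genus],
        )
    return TraitTable(df)


def check_coverage(
    matrices: list[IncidenceMatrix], traits: TraitTable
) -> tuple[list[IncidenceMatrix], TraitTable]:
    """Verify every species in any matrix has a complete trait record.

    Returns the inputs unchanged on success; raises listing uncovered
    species (or species still missing a trait value) otherwise.
    """
    if not matrices:
        raise ValidationError("no incidence matrices to check")
    occurring: set[str] = set()
    for m in matrices:
        occurring.update(m.species_ids)
    uncovered = sorted(occurring - set(traits.species_ids))
    if uncovered:
        raise ValidationError(f"species without trait records: {uncovered}")
    still_missing = sorted(
        occurring & set(traits.data.index[traits.temp_missing])
    )
    if still_missing:
        raise ValidationError(
            f"species with missing temp_pref (run imputation first): "
            f"{still_missing}"
        )
    return matrices, traits
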