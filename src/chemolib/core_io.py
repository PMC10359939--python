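"""Domain types, table readers/writers and configuration.

All tables are long-format CSV/TSV with mandated header names; the delimiter
is inferred from the file extension (``.tsv``/``.tab`` → tab, otherwise
comma).  Potency values are always nanomolar — no unit parsing is attempted.

Readers validate every row against the type invariants and reject offending
rows with their (0-based, header-excluded) row index, so that malformed
extracts from bioactivity databases fail loudly rather than silently
propagating bad records into the filters.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("chemolib")
if not logger.handlers:  # logs to stderr, level configurable by callers
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

#: The four multi-dose potency assay types, in canonical (enum) order.
ASSAY_TYPES: tuple[str, ...] = ("IC50", "EC50", "Ki", "Kd")

#: Canonical well roles on a screening plate.
WELL_ROLES: tuple[str, ...] = ("treated", "dmso", "positive_control")

_ROLE_ALIASES = {
    "treated": "treated",
    "sample": "treated",
    "dmso": "dmso",
    "negative_control": "dmso",
    "positive_control": "positive_control",
    "positive-control": "positive_control",
    "staurosporine": "positive_control",
}


class SchemaError(ValueError):
    """A table is missing required columns or is otherwise unreadable."""


class ValidationError(ValueError):
    """One or more rows violate a type invariant; indices are reported."""

    def __init__(self, message: str, bad_rows: Sequence[int] = ()):
        super().__init__(message)
        self.bad_rows = list(bad_rows)


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass
class CompoundRecord:
    """A small molecule: identifier, optional SMILES and vendor metadata.

    ``available`` is a tri-state: True/False when known, None when unknown.
    Availability filtering treats unknown as unavailable (conservative).
    """

    compound_id: str
    smiles: str | None = None
    available: bool | None = None
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValidationError("compound_id must be non-empty")
        if self.smiles is not None and not self.smiles:
            raise ValidationError(f"{self.compound_id}: smiles present but empty")


@dataclass
class TargetRecord:
    """A protein target (gene symbol or accession), possibly a mutant variant."""

    target_id: str
    is_cancer_associated: bool = False
    mutant_of: str | None = None
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.target_id:
            raise ValidationError("target_id must be non-empty")


@dataclass(frozen=True)
class BioactivityRecord:
    compound_id: str
    target_id: str
    assay_type: str
    value_nM: float

    def __post_init__(self) -> None:
        if self.assay_type not in ASSAY_TYPES:
            raise ValidationError(
                f"assay_type {self.assay_type!r} not one of {ASSAY_TYPES}")
        if not self.value_nM > 0:
            raise ValidationError(
                f"value_nM must be positive, got {self.value_nM!r}")


_BIO_COLUMNS = ["compound_id", "target_id", "assay_type", "value_nM"]


class BioactivityTable:
    """Long-format compound x target x assay-type potency records (nM).

    Thin wrapper around a validated :class:`pandas.DataFrame` with columns
    ``compound_id, target_id, assay_type, value_nM``; the substrate every
    activity filter operates on.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        if validate:
            df = _validate_bioactivity_frame(df)
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable) -> "BioactivityTable":
        rows = []
        for r in records:
            if isinstance(r, BioactivityRecord):
                rows.append((r.compound_id, r.target_id, r.assay_type, r.value_nM))
            else:
                rows.append(tuple(r))
        return cls(pd.DataFrame(rows, columns=_BIO_COLUMNS))

    @property
    def records(self) -> list[BioactivityRecord]:
        return [BioactivityRecord(*row) for row in self.df.itertuples(index=False)]

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BioactivityTable):
            return NotImplemented
        a = self.df.sort_values(_BIO_COLUMNS).reset_index(drop=True)
        b = other.df.sort_values(_BIO_COLUMNS).reset_index(drop=True)
        return a.equals(b)

    def __repr__(self) -> str:
        return (f"BioactivityTable({len(self.df)} records, "
                f"{self.df['compound_id'].nunique()} compounds, "
                f"{self.df['target_id'].nunique()} targets)")


def _validate_bioactivity_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _BIO_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"bioactivity table missing columns: {missing}")
    df = df[_BIO_COLUMNS].copy()
    df["value_nM"] = pd.to_numeric(df["value_nM"], errors="coerce")
    bad = df.index[
        ~df["assay_type"].isin(ASSAY_TYPES)
        | df["value_nM"].isna()
        | (df["value_nM"] <= 0)
    ].tolist()
    if bad:
        raise ValidationError(
            f"invalid bioactivity rows (bad assay_type or non-positive "
            f"value_nM) at indices {bad[:20]}", bad_rows=bad)
    return df


_PLATE_COLUMNS = ["plate_id", "patient_id", "well", "role",
                  "compound_id", "concentration_nM", "nuclei_count"]


class ScreenPlateSet:
    """Well-level nuclei counts from 384-well imaging plates.

    Every plate must carry at least one DMSO (negative-control) well, since
    all readouts are normalised per plate to the DMSO mean.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        if validate:
            df = _validate_plate_frame(df)
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def plates(self) -> list[str]:
        return sorted(self.df["plate_id"].unique())

    @property
    def patients(self) -> list[str]:
        return sorted(self.df["patient_id"].unique())

    def __repr__(self) -> str:
        return (f"ScreenPlateSet({len(self.df)} wells, "
                f"{self.df['plate_id'].nunique()} plates, "
                f"{self.df['patient_id'].nunique()} patients)")


def _validate_plate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"plate table missing columns: {missing}")
    df = df[_PLATE_COLUMNS].copy()
    roles = df["role"].astype(str).str.strip().str.lower().str.replace(" ", "_")
    canon = roles.map(_ROLE_ALIASES)
    bad_role = df.index[canon.isna()].tolist()
    if bad_role:
        raise ValidationError(
            f"unknown well role at rows {bad_role[:20]} "
            f"(expected one of {WELL_ROLES})", bad_rows=bad_role)
    df["role"] = canon
    df["nuclei_count"] = pd.to_numeric(df["nuclei_count"], errors="coerce")
    bad_count = df.index[df["nuclei_count"].isna() | (df["nuclei_count"] < 0)].tolist()
    if bad_count:
        raise ValidationError(
            f"negative or non-numeric nuclei_count at rows {bad_count[:20]}",
            bad_rows=bad_count)
    df["concentration_nM"] = pd.to_numeric(df["concentration_nM"], errors="coerce")
    treated = df["role"] == "treated"
    bad_treat = df.index[treated & (
        df["compound_id"].isna() | df["concentration_nM"].isna()
        | (df["concentration_nM"] <= 0))].tolist()
    if bad_treat:
        raise ValidationError(
            f"treated wells lacking compound or positive concentration at rows "
            f"{bad_treat[:20]}", bad_rows=bad_treat)
    no_dmso = [p for p, g in df.groupby("plate_id") if (g["role"] == "dmso").sum() == 0]
    if no_dmso:
        raise ValidationError(
            f"plates without any DMSO well (normalization impossible): {no_dmso}")
    return df


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class FilterConfig:
    """Tunables for the library-reduction filters and the similarity scan.

    Defaults follow the published workflow: a liberal 1000 nM potency
    ceiling, 80th-percentile target-specific filtering, 95th-percentile
    global filtering, 0.99 near-duplicate cutoff, and a 10% compound
    subsample scanned over thresholds 0.10..0.99 (step 0.01) with 3 seeds.
    """

    potency_cutoff_nM: float = 1000.0
    target_percentile: float = 80.0
    global_percentile: float = 95.0
    dedupe_cutoff: float = 0.99
    subsample_fraction: float = 0.10
    grid_lo: float = 0.10
    grid_hi: float = 0.99
    grid_step: float = 0.01
    n_seeds: int = 3
    min_pairs: int = 5

    def __post_init__(self) -> None:
        if not self.potency_cutoff_nM > 0:
            raise ValidationError("potency_cutoff_nM must be positive")
        for name in ("target_percentile", "global_percentile"):
            v = getattr(self, name)
            if not (0 < v <= 100):
                raise ValidationError(f"{name} must be in (0, 100]")
        if not (0 < self.dedupe_cutoff <= 1):
            raise ValidationError("dedupe_cutoff must be in (0, 1]")
        if not (0 < self.subsample_fraction <= 1):
            raise ValidationError("subsample_fraction must be in (0, 1]")
        if not self.grid_lo < self.grid_hi:
            raise ValidationError("grid_lo must be < grid_hi")
        if not self.grid_step > 0:
            raise ValidationError("grid_step must be positive")
        if self.n_seeds < 1 or self.min_pairs < 1:
            raise ValidationError("n_seeds and min_pairs must be positive")


@dataclass
class ScreenConfig:
    """Screen-analysis settings.

    ``hit_percentile`` is the percentile of the fitted background Gaussian
    used as the activity threshold; the default 0.01 means the 0.01th
    percentile, i.e. lower-tail probability 1e-4.
    """

    concentrations_nM: tuple[float, ...] = (3.0, 30.0, 300.0, 3000.0)
    hit_percentile: float = 0.01
    readout: str = "survival_fraction"

    def __post_init__(self) -> None:
        conc = tuple(float(c) for c in self.concentrations_nM)
        if len(conc) < 2 or any(c <= 0 for c in conc):
            raise ValidationError("need >=2 positive concentrations")
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise ValidationError("concentrations must be strictly increasing")
        self.concentrations_nM = conc
        if not (0 < self.hit_percentile < 100):
            raise ValidationError("hit_percentile must be in (0, 100)")
        if self.readout not in ("survival_fraction", "zscore"):
            raise ValidationError("readout must be survival_fraction or zscore")


def load_config(path: str | Path, kind: type) -> "FilterConfig | ScreenConfig":
    """Load a FilterConfig or ScreenConfig from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise SchemaError(f"{path}: expected a mapping of config fields")
    return kind(**data)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def _read_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path))
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty table") from None
    if df.empty:
        raise SchemaError(f"{path}: table has a header but no rows")
    return df


def read_bioactivity_table(path: str | Path) -> BioactivityTable:
    """Read a validated bioactivity table from CSV/TSV."""
    return BioactivityTable(_read_frame(path))


def read_plate_table(path: str | Path) -> ScreenPlateSet:
    """Read a validated screening-plate table from CSV/TSV."""
    return ScreenPlateSet(_read_frame(path))


def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read compounds from CSV/TSV (compound_id, optional smiles/available)."""
    df = _read_frame(path)
    if "compound_id" not in df.columns:
        raise SchemaError(f"{path}: missing compound_id column")
    known = {"compound_id", "smiles", "available"}
    out = []
    for _, row in df.iterrows():
        smiles = row.get("smiles")
        avail = row.get("available")
        meta = {k: str(row[k]) for k in df.columns
                if k not in known and pd.notna(row[k])}
        out.append(CompoundRecord(
            compound_id=str(row["compound_id"]),
            smiles=None if pd.isna(smiles) else str(smiles),
            available=None if pd.isna(avail) else bool(avail),
            metadata=meta))
    return out


def read_smiles_file(path: str | Path) -> list[CompoundRecord]:
    """Read a .smi file: one ``SMILES<whitespace>compound_id`` per line."""
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise ValidationError(f"line {i}: expected 'SMILES id'", bad_rows=[i])
        out.append(CompoundRecord(compound_id=parts[1].strip(), smiles=parts[0]))
    if not out:
        raise SchemaError(f"{path}: no SMILES records")
    return out


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Read a protein-interaction edge list (TSV: source, dest)."""
    df = _read_frame(path)
    cols = list(df.columns[:2])
    return [(str(a), str(b)) for a, b in df[cols].itertuples(index=False)]


def write_table(obj, path: str | Path) -> None:
    """Write a table (BioactivityTable/ScreenPlateSet/DataFrame) to CSV/TSV."""
    path = Path(path)
    df = obj.df if hasattr(obj, "df") else obj
    df.to_csv(path, sep=_sep_for(path), index=False)
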