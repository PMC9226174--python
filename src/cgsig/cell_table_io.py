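"""Read, validate, normalize and write per-cell feature tables and cohort tables.

A *cell table* is a delimited text file (CSV or TSV, autodetected from the
extension) with one row per segmented cell: pixel coordinates ``x, y`` and
the 35 node attributes of :class:`~cgsig.schema.FeatureSchema`.  A *patient
table* holds one row per patient: id, overall survival in months, event
indicator (1 = deceased) and AJCC TNM stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import DEFAULT_SCHEMA, FeatureSchema

logger = logging.getLogger(__name__)

TNM_STAGES = (
    "IA", "IB", "IIA", "IIB", "IIIA", "IIIB", "IIIC", "IVA", "IVB",
    "I", "II", "III", "IV",
)


class SchemaError(ValueError):
    """A table does not conform to the feature schema."""


@dataclass
class CellTable:
    """All segmented cells of one patient image.

    ``coords`` is an (n, 2) float array of pixel positions; ``features`` is
    (n, 35) in schema order with Boolean attributes stored as 0/1.
    """

    patient_id: str
    coords: np.ndarray
    features: np.ndarray
    schema: FeatureSchema = field(default_factory=lambda: DEFAULT_SCHEMA)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.features = np.asarray(self.features, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise SchemaError("coords must be an (n, 2) array")
        if len(self.coords) == 0:
            raise SchemaError(f"no cells in table for patient {self.patient_id!r}")
        if self.features.shape != (len(self.coords), self.schema.n_features):
            raise SchemaError(
                f"feature matrix must be (n, {self.schema.n_features}), "
                f"got {self.features.shape}"
            )
        if (self.coords < 0).any():
            raise SchemaError("negative pixel coordinates")
        bool_idx = [self.schema.feature_index(c) for c in self.schema.boolean_features]
        bvals = self.features[:, bool_idx]
        if not np.isin(bvals, (0.0, 1.0)).all():
            raise SchemaError("Boolean attributes must be 0 or 1")

    def __len__(self) -> int:
        return len(self.coords)

    def to_frame(self) -> pd.DataFrame:
        data = np.hstack([self.coords, self.features])
        return pd.DataFrame(data, columns=self.schema.columns)


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    os_months: float
    event: int
    tnm_stage: str | None = None
    sex: str | None = None
    age: float | None = None

    def __post_init__(self) -> None:
        if self.os_months < 0:
            raise ValueError(f"negative OS time for {self.patient_id!r}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0/1, got {self.event!r}")
        if self.tnm_stage is not None and self.tnm_stage not in TNM_STAGES:
            raise ValueError(f"unknown TNM stage {self.tnm_stage!r}")


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    return pd.read_csv(path, sep=sep)


def read_cell_table(
    path: str | Path,
    schema: FeatureSchema = DEFAULT_SCHEMA,
    patient_id: str | None = None,
) -> CellTable:
    """Parse a per-cell table, validating header and value types.

    ``schema.header_map`` maps raw column headers (e.g. HALO exports) onto the
    canonical names before validation.  The patient id defaults to the file
    stem.
    """
    path = Path(path)
    df = _read_delimited(path)
    if schema.header_map:
        df = df.rename(columns=schema.header_map)
    missing = [c for c in schema.columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    if len(df) == 0:
        raise SchemaError(f"{path.name}: no cells")
    sub = df[schema.columns]
    bad = sub.apply(pd.to_numeric, errors="coerce")
    if bad.isna().values.any():
        row = int(np.argwhere(bad.isna().values)[0, 0])
        raise SchemaError(f"{path.name}: non-numeric value in data row {row}")
    arr = bad.to_numpy(dtype=float)
    return CellTable(
        patient_id=patient_id or path.stem,
        coords=arr[:, :2],
        features=arr[:, 2:],
        schema=schema,
    )


def write_cell_table(table: CellTable, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    table.to_frame().to_csv(path, sep=sep, index=False, float_format="%.6g")


@dataclass
class Normalizer:
    """Per-feature min-max scaler mapping fitted data into [0, 1].

    Constant features (max == min) are flagged and mapped to 0; values outside
    the fitted range (e.g. on held-out data) are clamped into [0, 1].
    """

    minimum: np.ndarray | None = None
    maximum: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.minimum is not None

    @property
    def constant_mask(self) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("normalizer is not fitted")
        return self.maximum == self.minimum

    def fit(self, tables: list[CellTable]) -> "Normalizer":
        if not tables:
            raise ValueError("fit_normalizer requires at least one table")
        stacked = np.vstack([t.features for t in tables])
        self.minimum = stacked.min(axis=0)
        self.maximum = stacked.max(axis=0)
        n_const = int(self.constant_mask.sum())
        if n_const:
            logger.info("normalizer: %d constant feature(s) will map to 0", n_const)
        return self

    def transform(self, table: CellTable) -> CellTable:
        if not self.fitted:
            raise RuntimeError("apply_normalizer called before fitting")
        span = np.where(self.constant_mask, 1.0, self.maximum - self.minimum)
        scaled = (table.features - self.minimum) / span
        scaled[:, self.constant_mask] = 0.0
        np.clip(scaled, 0.0, 1.0, out=scaled)
        return CellTable(table.patient_id, table.coords.copy(), scaled, table.schema)


def fit_normalizer(tables: list[CellTable]) -> Normalizer:
    return Normalizer().fit(tables)


def apply_normalizer(norm: Normalizer, table: CellTable) -> CellTable:
    return norm.transform(table)


def read_patient_table(path: str | Path) -> list[PatientRecord]:
    """Parse a cohort table (id, os_months, event, tnm_stage[, sex, age]).

    Rows whose event column reads ``lost to follow-up`` (any case) are dropped
    with a logged count, mirroring standard cohort curation.
    """
    df = _read_delimited(path)
    required = {"patient_id", "os_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"patient table missing column(s) {sorted(missing)}")
    lost = df["event"].astype(str).str.strip().str.lower() == "lost to follow-up"
    if lost.any():
        logger.info("dropping %d patient(s) lost to follow-up", int(lost.sum()))
        df = df[~lost]
    ids = df["patient_id"].astype(str)
    dup = ids[ids.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate patient id(s): {list(dup)}")
    records = []
    for _, row in df.iterrows():
        stage = row.get("tnm_stage")
        stage = None if pd.isna(stage) or stage == "" else str(stage)
        age = row.get("age")
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                os_months=float(row["os_months"]),
                event=int(row["event"]),
                tnm_stage=stage,
                sex=None if pd.isna(row.get("sex")) else str(row.get("sex")),
                age=None if pd.isna(age) else float(age),
            )
        )
    return records


def write_patient_table(patients: list[PatientRecord], path: str | Path) -> None:
    rows = [
        {
            "patient_id": p.patient_id,
            "os_months": p.os_months,
            "event": p.event,
            "tnm_stage": p.tnm_stage or "",
        }
        for p in patients
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
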