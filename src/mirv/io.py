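"""Reading, validating and writing the tabular inputs and outputs.

The package is image-free: it consumes per-lesion radiomic feature tables
(one row per lesion-timepoint) as emitted by standard radiomics extractors,
plus a per-patient clinical table. Column names are mapped through a small
schema so arbitrary extractor output can be ingested without renaming files.

Lesion volume (the extractor's ``VoxelVolume``) is carried alongside the
feature matrix but is never part of the candidate radiomic feature set: it
is the confounder the reduction stage de-correlates against, not a feature.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import DataIntegrityError, SchemaError

BASELINE = "baseline"
FOLLOWUP = "followup"
VALID_TIMEPOINTS = (BASELINE, FOLLOWUP)

CTDNA_VALUES = ("positive", "negative", "missing")


@dataclass(frozen=True)
class TableSchema:
    """Maps the package's canonical column roles onto file column names."""

    patient_col: str = "patient_id"
    lesion_col: str = "lesion_id"
    timepoint_col: str = "timepoint"
    volume_col: str = "voxel_volume"
    # clinical columns
    histology_col: str = "histology"
    age_ge_65_col: str = "age_ge_65"
    performance_status_col: str = "performance_status"
    recist_col: str = "recist"
    ctdna_pre_col: str = "ctdna_pre"
    ctdna_post_col: str = "ctdna_post"
    os_years_col: str = "os_years"
    os_event_col: str = "os_event"
    # if True, unknown ctDNA strings map to "missing" instead of erroring
    ctdna_coerce_unknown: bool = False

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "TableSchema":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown schema keys: {sorted(unknown)}")
        return cls(**d)  # type: ignore[arg-type]


@dataclass
class FeatureMatrix:
    """Lesion × feature matrix for one timepoint.

    Rows are indexed by (patient_id, lesion_id), sorted; ``volumes`` is the
    aligned per-lesion voxel volume in mm^3 and is deliberately not a column
    of ``values``.
    """

    values: pd.DataFrame  # index: MultiIndex (patient_id, lesion_id); columns: features
    volumes: pd.Series  # aligned to values.index, mm^3
    volume_column: str = "voxel_volume"

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.volumes.index):
            raise DataIntegrityError("volumes index is not aligned to the feature matrix")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise DataIntegrityError(f"duplicate feature names: {dups}")
        if self.values.isna().any().any():
            bad = [
                (str(idx), str(col))
                for idx, col in zip(*np.where(self.values.isna()))
            ]
            raise DataIntegrityError(f"missing feature values at (row, column): {bad}")
        if (self.volumes <= 0).any():
            bad_rows = self.volumes.index[self.volumes <= 0].tolist()
            raise DataIntegrityError(f"nonpositive voxel_volume for lesions: {bad_rows}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_lesions(self) -> int:
        return len(self.values)

    def patients(self) -> list[str]:
        return list(self.values.index.get_level_values(0).unique())

    def subset_features(self, names: Iterable[str]) -> "FeatureMatrix":
        names = list(names)
        return replace(self, values=self.values[names], volumes=self.volumes)

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.values.copy(), self.volumes.copy(), self.volume_column)


@dataclass(frozen=True)
class ClinicalRecord:
    patient_id: str
    histology: str
    age_ge_65: int
    performance_status: int
    recist: str
    ctdna_pre: str = "missing"
    ctdna_post: str = "missing"
    os_years: float = 0.0
    os_event: int = 0

    def __post_init__(self) -> None:
        if self.os_years < 0:
            raise DataIntegrityError(
                f"patient {self.patient_id}: os_years must be >= 0, got {self.os_years}"
            )
        if self.os_event not in (0, 1):
            raise DataIntegrityError(
                f"patient {self.patient_id}: os_event must be 0/1, got {self.os_event}"
            )
        for name, val in (("ctdna_pre", self.ctdna_pre), ("ctdna_post", self.ctdna_post)):
            if val not in CTDNA_VALUES:
                raise DataIntegrityError(
                    f"patient {self.patient_id}: {name} must be one of {CTDNA_VALUES}, got {val!r}"
                )


def clinical_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    """Tabular view of clinical records, indexed by patient_id."""
    df = pd.DataFrame([vars(r) for r in records])
    return df.set_index("patient_id").sort_index()


# ---------------------------------------------------------------------------
# readers


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_feature_table(
    path: str | Path, schema: TableSchema | None = None
) -> dict[str, FeatureMatrix]:
    """Read a per-lesion feature CSV and return one validated matrix per timepoint.

    Feature columns are every column not named by the schema. Rows are sorted
    by (patient_id, lesion_id) so load is insensitive to input row order.
    """
    schema = schema or TableSchema()
    path = Path(path)
    if not path.is_file():
        raise SchemaError(f"feature table not found: {path}")
    df = pd.read_csv(path, dtype={schema.patient_col: str, schema.lesion_col: str})
    id_cols = [schema.patient_col, schema.lesion_col, schema.timepoint_col, schema.volume_col]
    _require_columns(df, id_cols, str(path))

    bad_tp = set(df[schema.timepoint_col].unique()) - set(VALID_TIMEPOINTS)
    if bad_tp:
        raise SchemaError(
            f"{path}: timepoint values must be in {VALID_TIMEPOINTS}, found {sorted(bad_tp)}"
        )

    dup = df.duplicated(subset=[schema.patient_col, schema.lesion_col, schema.timepoint_col])
    if dup.any():
        keys = df.loc[dup, [schema.patient_col, schema.lesion_col, schema.timepoint_col]]
        raise DataIntegrityError(
            f"{path}: duplicate (patient, lesion, timepoint) rows: {keys.values.tolist()}"
        )

    feature_cols = [c for c in df.columns if c not in id_cols]
    if not feature_cols:
        raise SchemaError(f"{path}: no feature columns found")

    # itemized missing/non-numeric report
    numeric = df[feature_cols].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        rows, cols = np.where(bad.to_numpy())
        items = [
            (df[schema.patient_col].iat[r], df[schema.lesion_col].iat[r], feature_cols[c])
            for r, c in zip(rows, cols)
        ]
        raise DataIntegrityError(
            f"{path}: missing or non-numeric feature cells (patient, lesion, feature): {items}"
        )

    out: dict[str, FeatureMatrix] = {}
    for tp, sub in df.groupby(schema.timepoint_col, sort=True):
        sub = sub.sort_values([schema.patient_col, schema.lesion_col], kind="mergesort")
        idx = pd.MultiIndex.from_frame(
            sub[[schema.patient_col, schema.lesion_col]].astype(str),
            names=["patient_id", "lesion_id"],
        )
        values = pd.DataFrame(
            numeric.loc[sub.index].to_numpy(dtype=float), index=idx, columns=feature_cols
        )
        volumes = pd.Series(
            pd.to_numeric(sub[schema.volume_col]).to_numpy(dtype=float),
            index=idx,
            name=schema.volume_col,
        )
        out[str(tp)] = FeatureMatrix(values, volumes, schema.volume_col)
    return out


def read_clinical_table(
    path: str | Path, schema: TableSchema | None = None
) -> list[ClinicalRecord]:
    """Read the per-patient clinical CSV into validated records.

    The ctDNA columns are optional; when absent every record carries
    ``missing``. Unknown ctDNA strings error unless the schema opts into
    coercion.
    """
    schema = schema or TableSchema()
    path = Path(path)
    if not path.is_file():
        raise SchemaError(f"clinical table not found: {path}")
    df = pd.read_csv(path, dtype={schema.patient_col: str})
    required = [
        schema.patient_col,
        schema.histology_col,
        schema.age_ge_65_col,
        schema.performance_status_col,
        schema.recist_col,
        schema.os_years_col,
        schema.os_event_col,
    ]
    _require_columns(df, required, str(path))
    if df[schema.patient_col].duplicated().any():
        dups = df.loc[df[schema.patient_col].duplicated(), schema.patient_col].tolist()
        raise DataIntegrityError(f"{path}: duplicate patient_id rows: {dups}")

    def _ctdna(row: pd.Series, col: str) -> str:
        if col not in df.columns:
            return "missing"
        val = row[col]
        if pd.isna(val) or val == "":
            return "missing"
        val = str(val).strip().lower()
        if val not in CTDNA_VALUES:
            if schema.ctdna_coerce_unknown:
                return "missing"
            raise DataIntegrityError(f"{path}: unknown ctDNA value {val!r} (column {col})")
        return val

    records = []
    for _, row in df.sort_values(schema.patient_col, kind="mergesort").iterrows():
        records.append(
            ClinicalRecord(
                patient_id=str(row[schema.patient_col]),
                histology=str(row[schema.histology_col]),
                age_ge_65=int(row[schema.age_ge_65_col]),
                performance_status=int(row[schema.performance_status_col]),
                recist=str(row[schema.recist_col]),
                ctdna_pre=_ctdna(row, schema.ctdna_pre_col),
                ctdna_post=_ctdna(row, schema.ctdna_post_col),
                os_years=float(row[schema.os_years_col]),
                os_event=int(row[schema.os_event_col]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# writers

FLOAT_FORMAT = "%.10g"  # fixed text representation => byte-identical re-runs


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> pd.DataFrame:
    """Write named result tables as CSV with stable column order.

    Returns the manifest (file name, row count), which is also written to
    ``manifest.csv`` in the output directory.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for name in sorted(tables):
        df = tables[name]
        fname = f"{name}.csv"
        df.to_csv(out_dir / fname, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")
        rows.append({"file": fname, "n_rows": len(df)})
    manifest = pd.DataFrame(rows, columns=["file", "n_rows"])
    manifest.to_csv(out_dir / "manifest.csv", index=False, lineterminator="\n")
    return manifest


def feature_matrix_to_frame(fm: FeatureMatrix, timepoint: str) -> pd.DataFrame:
    """Long-form frame matching the on-disk feature-table schema."""
    df = fm.values.reset_index()
    df.insert(2, "timepoint", timepoint)
    df.insert(3, fm.volume_column, fm.volumes.to_numpy())
    return df


# ---------------------------------------------------------------------------
# config

def load_config_file(path: str | Path) -> dict:
    """Load a YAML or JSON run-configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    loaded = yaml.safe_load(text)
    if not isinstance(loaded, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return loaded


def config_hash(config: Mapping) -> str:
    """Stable short hash of a config mapping, for run logs."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
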