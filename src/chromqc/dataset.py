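"""Quality-measurement feature tables: assembly, cleaning, preprocessing.

A quality table has one row per compound with the four signal-quality
measurements (ΔtR, SNR, skewness, peak area), the two sequence descriptors
(length, sulfur count), the prediction target tR and optional injection-
volume metadata.  Clustering uses the six independent variables; tR is never
a clustering feature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chromatogram import CSV_FLOAT_FORMAT
from .errors import AssemblyError, DegenerateFeatureError, EmptyTableError, ParameterError

#: Quality-row CSV dialect (column order is the external interface).
TABLE_COLUMNS = [
    "compound_id",
    "sequence",
    "delta_tr",
    "snr",
    "skewness",
    "peak_area",
    "length",
    "sulfur_count",
    "tr",
    "injection_volume",
]

#: Independent variables used for clustering; the target tR is excluded.
CLUSTER_FEATURES = ["delta_tr", "snr", "skewness", "peak_area", "length", "sulfur_count"]

#: Features the per-cluster regressor uses to predict tR.
REGRESSION_FEATURES = ["delta_tr", "snr", "skewness", "peak_area", "length", "sulfur_count"]

TARGET = "tr"


@dataclass
class QualityTable:
    """Feature table wrapper: a DataFrame plus the recorded feature order
    and provenance tags."""

    data: pd.DataFrame
    feature_names: list = field(default_factory=lambda: list(CLUSTER_FEATURES))
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.data["compound_id"].duplicated().any():
            dupes = self.data.loc[self.data["compound_id"].duplicated(), "compound_id"]
            raise AssemblyError(f"duplicated compound ids: {sorted(set(dupes))[:5]}")

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        for col in TABLE_COLUMNS:
            if col not in out.columns:
                out[col] = np.nan
        out[TABLE_COLUMNS].to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)

    @classmethod
    def from_csv(cls, path, provenance=None) -> "QualityTable":
        df = pd.read_csv(path)
        missing = set(TABLE_COLUMNS) - {"sequence", "injection_volume"} - set(df.columns)
        if missing:
            raise ParameterError(f"quality CSV missing columns: {sorted(missing)}")
        return cls(df, provenance=provenance or {"source": str(path)})


def rows_from_measurements(peak_rows) -> pd.DataFrame:
    """Convert :class:`chromqc.metrics.PeakRow` objects to a measurement
    frame (one row per compound; failed metrics are NaN)."""
    records = []
    for row in peak_rows:
        m = row.measurement
        records.append(
            {
                "compound_id": row.compound_id,
                "delta_tr": row.delta_tr.delta if row.delta_tr is not None else np.nan,
                "snr": m.snr if m is not None else np.nan,
                "skewness": m.skewness if m is not None else np.nan,
                "peak_area": m.area if m is not None else np.nan,
                "tr": m.apex_time if m is not None else np.nan,
                "flags": "; ".join(row.flags),
            }
        )
    return pd.DataFrame(records)


def assemble_quality_table(measurements: pd.DataFrame, metadata: pd.DataFrame) -> tuple:
    """Join per-compound measurements with compound metadata.

    ``metadata`` must carry compound_id, length and sulfur_count (sequence
    and injection_volume optional).  Returns ``(QualityTable, orphans)``
    where ``orphans`` lists compound ids present in only one input.
    """
    for df, name in ((measurements, "measurements"), (metadata, "metadata")):
        if df["compound_id"].duplicated().any():
            raise AssemblyError(f"duplicated compound ids in {name}")
    merged = measurements.merge(metadata, on="compound_id", how="inner")
    ids_m = set(measurements["compound_id"])
    ids_d = set(metadata["compound_id"])
    orphans = sorted(ids_m.symmetric_difference(ids_d))
    for col in ("sequence", "injection_volume"):
        if col not in merged.columns:
            merged[col] = np.nan
    table = QualityTable(
        merged.reset_index(drop=True),
        provenance={"n_measurements": len(measurements), "n_metadata": len(metadata),
                    "orphans": orphans},
    )
    return table, orphans


def drop_incomplete(table: QualityTable, columns=None) -> tuple:
    """Remove rows with any missing feature or target (the non-null subset).

    Returns ``(clean_table, report)`` where the report maps dropped compound
    ids to their missing fields.  Idempotent.
    """
    cols = list(columns) if columns is not None else list(table.feature_names) + [TARGET]
    df = table.data
    isna = df[cols].isna()
    bad = isna.any(axis=1)
    report = {
        str(df.loc[i, "compound_id"]): [c for c in cols if isna.loc[i, c]]
        for i in df.index[bad]
    }
    clean = df.loc[~bad].reset_index(drop=True)
    if clean.empty:
        raise EmptyTableError("no complete rows remain after dropping missing values")
    out = QualityTable(clean, feature_names=list(table.feature_names),
                       provenance={**table.provenance, "dropped": sorted(report)})
    return out, report


@dataclass
class FeatureTransform:
    """Per-feature z-score followed by per-feature min-max to [0, 1].

    Both stages are fitted on the same rows.  Because each stage is affine
    per feature, the composition is itself affine; the fitted statistics are
    kept separately so either stage can be inspected or applied alone.
    """

    feature_names: list
    means: np.ndarray
    sds: np.ndarray
    z_mins: np.ndarray
    z_maxs: np.ndarray

    @classmethod
    def fit(cls, df: pd.DataFrame, feature_names) -> "FeatureTransform":
        X = df[list(feature_names)].to_numpy(float)
        if len(X) == 0:
            raise EmptyTableError("cannot fit a transform on zero rows")
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=0)
        for j, name in enumerate(feature_names):
            if sds[j] == 0:
                raise DegenerateFeatureError(name)
        Z = (X - means) / sds
        return cls(
            feature_names=list(feature_names),
            means=means,
            sds=sds,
            z_mins=Z.min(axis=0),
            z_maxs=Z.max(axis=0),
        )

    def zscore(self, df: pd.DataFrame) -> np.ndarray:
        X = df[self.feature_names].to_numpy(float)
        return (X - self.means) / self.sds

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        Z = self.zscore(df)
        span = self.z_maxs - self.z_mins
        return (Z - self.z_mins) / span

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": self.feature_names,
                "means": self.means.tolist(),
                "sds": self.sds.tolist(),
                "z_mins": self.z_mins.tolist(),
                "z_maxs": self.z_maxs.tolist(),
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureTransform":
        d = json.loads(text)
        return cls(
            feature_names=list(d["feature_names"]),
            means=np.asarray(d["means"], float),
            sds=np.asarray(d["sds"], float),
            z_mins=np.asarray(d["z_mins"], float),
            z_maxs=np.asarray(d["z_maxs"], float),
        )


def preprocess(table: QualityTable, feature_subset=None, fit_rows=None):
    """Fit the standardize-then-normalize transform and apply it.

    ``fit_rows`` (positional indices) restricts the rows the statistics are
    fitted on; the transform is then applied to the whole table.  Returns
    ``(transform, matrix)``.
    """
    features = list(feature_subset) if feature_subset is not None else list(table.feature_names)
    df = table.data
    fit_df = df.iloc[list(fit_rows)] if fit_rows is not None else df
    if len(fit_df) == 0:
        raise EmptyTableError("fit_rows is empty")
    transform = FeatureTransform.fit(fit_df, features)
    return transform, transform.transform(df)
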