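"""Reading and writing NPX tables, sample metadata, metabolite and genotype files.

The on-disk NPX format is the long "Olink-export" layout: one row per
(sample, protein) with columns ``SampleID, Assay, Panel, NPX, LOD, PlateID,
QC_Warning, SampleType``.  Comma and tab delimiters are auto-detected and
can be overridden.
"""

from __future__ import annotations

import json
import os
import warnings
from collections import namedtuple

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, MetaboliteTable, NPXMatrix
from .exceptions import IntegrityError, SchemaError

NPX_COLUMNS = ["SampleID", "Assay", "Panel", "NPX", "LOD", "PlateID", "QC_Warning", "SampleType"]

#: default recoding applied by read_metadata; keys are column names, values
#: map raw spellings onto canonical levels.
DEFAULT_CODEBOOK = {
    "sex": {
        "M": "male", "F": "female", "m": "male", "f": "female",
        "male": "male", "female": "female", "Male": "male", "Female": "female",
    },
    "season": {},
    "residency": {"urban": "urban", "rural": "rural", "Urban": "urban", "Rural": "rural"},
}

#: declared levels for categorical metadata columns; values outside these
#: are kept but recoded to "unknown" with a warning.
DEFAULT_LEVELS = {
    "sex": {"male", "female"},
    "residency": {"urban", "rural"},
}


def _detect_sep(path, sep=None) -> str:
    if sep is not None:
        return sep
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_npx_long(path, cohort_label: str, sep: str | None = None) -> NPXMatrix:
    """Read a long-format NPX export into an :class:`NPXMatrix`.

    Duplicate (sample, protein) pairs are rejected; identifiers are trimmed
    of surrounding whitespace (case preserved) and sorted so the result is
    stable regardless of row order in the file.
    """
    sep = _detect_sep(path, sep)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in NPX_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    for col in ("SampleID", "Assay", "Panel", "PlateID", "SampleType"):
        df[col] = df[col].astype(str).str.strip()
    dup = df.duplicated(subset=["SampleID", "Assay"], keep=False)
    if dup.any():
        offenders = df.loc[dup, ["SampleID", "Assay"]].drop_duplicates().values.tolist()
        raise IntegrityError(f"duplicate (sample, protein) records: {offenders[:10]}")
    bad_type = set(df["SampleType"].unique()) - {"study", "bridge"}
    if bad_type:
        raise SchemaError(f"SampleType must be study|bridge, got: {sorted(bad_type)}")

    wide = df.pivot(index="SampleID", columns="Assay", values="NPX")
    wide = wide.sort_index().sort_index(axis=1)
    wide = wide.astype(float)

    # per-protein LOD; tolerate record-level jitter by taking the median
    lod = df.groupby("Assay")["LOD"].median().reindex(wide.columns).astype(float)
    n_lod_levels = df.groupby("Assay")["LOD"].nunique()
    if (n_lod_levels > 1).any():
        warnings.warn(
            f"{int((n_lod_levels > 1).sum())} protein(s) had record-level LOD variation; "
            "per-protein median used",
            stacklevel=2,
        )

    per_sample = df.drop_duplicates("SampleID").set_index("SampleID")
    plate_of = per_sample["PlateID"].reindex(wide.index)
    sample_type_of = per_sample["SampleType"].reindex(wide.index)

    n_bridge_warn = int(
        ((df["SampleType"] == "bridge") & (df["QC_Warning"].astype(str).str.lower() == "warn")).sum()
    )
    if n_bridge_warn:
        warnings.warn(f"{n_bridge_warn} bridge record(s) carry a QC warning flag", stacklevel=2)

    m = NPXMatrix(wide, lod, plate_of, sample_type_of, cohort=cohort_label)
    m.n_records_ingested = len(df)
    return m


def write_npx_long(m: NPXMatrix, path, panel: str = "inflammation") -> None:
    """Write an :class:`NPXMatrix` back to the long layout (+ JSON schema sidecar).

    Delimiter follows the file extension (``.tsv`` -> tab, else comma).
    """
    long = m.values.stack(future_stack=True).rename("NPX").reset_index()
    long.columns = ["SampleID", "Assay", "NPX"]
    long = long.dropna(subset=["NPX"])
    long["Panel"] = panel
    long["LOD"] = m.lod.reindex(long["Assay"]).to_numpy()
    long["PlateID"] = m.plate_of.reindex(long["SampleID"]).to_numpy()
    long["QC_Warning"] = "pass"
    long["SampleType"] = m.sample_type_of.reindex(long["SampleID"]).to_numpy()
    long = long[NPX_COLUMNS].sort_values(["SampleID", "Assay"], kind="mergesort")
    sep = "\t" if str(path).endswith(".tsv") else ","
    long.to_csv(path, sep=sep, index=False, float_format="%.17g")  # lossless floats
    manifest = {
        "format": "npx_long",
        "columns": NPX_COLUMNS,
        "cohort": m.cohort,
        "n_samples": int(m.n_samples),
        "n_proteins": int(m.n_proteins),
        "npx_scale": "log2",
    }
    with open(str(path) + ".schema.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


MergedCohorts = namedtuple("MergedCohorts", "a b common_proteins only_a only_b")


def merge_cohorts(a: NPXMatrix, b: NPXMatrix) -> MergedCohorts:
    """Pair two cohorts on their shared protein panel (no values mutated).

    Returns views of both matrices restricted to the sorted intersection,
    plus the per-cohort-only protein lists.
    """
    if a.n_proteins == 0 or b.n_proteins == 0:
        raise IntegrityError("cannot merge an empty NPX matrix")
    common = a.proteins.intersection(b.proteins).sort_values()
    if len(common) == 0:
        raise IntegrityError("cohorts share no proteins")
    only_a = a.proteins.difference(b.proteins).sort_values().tolist()
    only_b = b.proteins.difference(a.proteins).sort_values().tolist()
    return MergedCohorts(
        a.subset_proteins(common), b.subset_proteins(common), common.tolist(), only_a, only_b
    )


def read_metadata(path, codebook: dict | None = None, sep: str | None = None) -> pd.DataFrame:
    """Read the per-sample metadata table, recoding levels via a codebook.

    The codebook maps column -> {raw value: canonical level}.  Levels not in
    the declared set for a column are kept as the explicit level
    ``"unknown"`` with a warning, so downstream joins never lose samples.
    """
    sep = _detect_sep(path, sep)
    df = pd.read_csv(path, sep=sep)
    if "sample_id" not in df.columns:
        raise SchemaError("missing required column(s): sample_id")
    df["sample_id"] = df["sample_id"].astype(str).str.strip()
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise IntegrityError(f"duplicate sample ids in metadata: {dupes[:5]}")
    df = df.set_index("sample_id")

    book = dict(DEFAULT_CODEBOOK)
    if codebook:
        for col, mapping in codebook.items():
            book[col] = {**book.get(col, {}), **mapping}
    for col, mapping in book.items():
        if col in df.columns and mapping:
            df[col] = df[col].map(lambda v: mapping.get(v, v))
    for col, levels in DEFAULT_LEVELS.items():
        if col not in df.columns:
            continue
        mask = df[col].notna() & ~df[col].isin(levels)
        if mask.any():
            warnings.warn(
                f"column {col!r}: {int(mask.sum())} record(s) with unknown level "
                f"{sorted(df.loc[mask, col].unique())[:5]} recoded to 'unknown'",
                stacklevel=2,
            )
            df.loc[mask, col] = "unknown"

    if "age" in df.columns and (df["age"].dropna() <= 0).any():
        bad = df.index[df["age"] <= 0].tolist()
        raise IntegrityError(f"age must be positive; offending samples: {bad[:5]}")
    if "bmi" in df.columns and (df["bmi"].dropna() <= 0).any():
        bad = df.index[df["bmi"] <= 0].tolist()
        raise IntegrityError(f"bmi must be positive; offending samples: {bad[:5]}")
    return df


def join_metadata(m: NPXMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Metadata aligned to the study samples of an NPX matrix.

    Raises if there is no overlap at all (wrong file / wrong cohort).
    """
    study = m.study_values().index
    overlap = study.intersection(meta.index)
    if len(overlap) == 0:
        raise IntegrityError("metadata shares no sample ids with the NPX matrix")
    return meta.reindex(study)


def read_metabolites(matrix_path, annotation_path, sep: str | None = None) -> MetaboliteTable:
    """Read a samples x metabolites intensity matrix and its annotation table."""
    msep = _detect_sep(matrix_path, sep)
    values = pd.read_csv(matrix_path, sep=msep, index_col=0, float_precision="round_trip")
    values.index = values.index.astype(str)
    asep = _detect_sep(annotation_path, sep)
    ann = pd.read_csv(annotation_path, sep=asep, index_col=0)
    required = ["formula", "putative_name", "chem_class", "food_derived"]
    missing = [c for c in required if c not in ann.columns]
    if missing:
        raise SchemaError(f"metabolite annotation missing column(s): {', '.join(missing)}")
    ann["food_derived"] = ann["food_derived"].astype(bool)
    return MetaboliteTable(values, ann)


def write_metabolites(t: MetaboliteTable, matrix_path, annotation_path) -> None:
    t.values.to_csv(matrix_path, float_format="%.17g")
    t.annotation.to_csv(annotation_path)


def read_genotypes(path, sep: str | None = None) -> GenotypeMatrix:
    """Read a samples x SNPs dosage CSV (values in [0, 2])."""
    sep = _detect_sep(path, sep)
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    return GenotypeMatrix(df.astype(float))
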