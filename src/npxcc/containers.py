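"""In-memory containers for NPX panels, QC output and cluster assignments.

The central object is :class:`NPXMatrix`: a samples x proteins matrix of
log2 NPX values for one cohort, together with the per-protein limit of
detection (LOD), the plate each sample was run on, and whether each sample
is a study participant or a pooled bridge control.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import IntegrityError

SAMPLE_TYPES = ("study", "bridge")


@dataclass
class NPXMatrix:
    """Wide NPX matrix for one cohort (samples x proteins, log2 scale).

    Parameters
    ----------
    values : DataFrame
        Rows are samples, columns are proteins (assay identifiers), entries
        are NPX on the log2 scale.  Missing measurements are NaN.
    lod : Series
        Per-protein limit of detection on the same log2 scale.
    plate_of : Series
        Plate identifier per sample.
    sample_type_of : Series
        ``"study"`` or ``"bridge"`` per sample.
    cohort : str
        Cohort label (e.g. ``"TZ"`` / ``"NL"``).
    """

    values: pd.DataFrame
    lod: pd.Series
    plate_of: pd.Series
    sample_type_of: pd.Series
    cohort: str = ""

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise IntegrityError(f"duplicate sample ids: {list(dupes)[:5]}")
        if not self.values.columns.is_unique:
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise IntegrityError(f"duplicate protein ids: {list(dupes)[:5]}")
        self.lod = self.lod.reindex(self.values.columns)
        for name, mapping in (("plate_of", self.plate_of), ("sample_type_of", self.sample_type_of)):
            missing = self.values.index.difference(mapping.index)
            if len(missing):
                raise IntegrityError(f"{name} missing for samples: {list(missing)[:5]}")
        self.plate_of = self.plate_of.reindex(self.values.index)
        self.sample_type_of = self.sample_type_of.reindex(self.values.index)
        bad = set(self.sample_type_of.unique()) - set(SAMPLE_TYPES)
        if bad:
            raise IntegrityError(f"unknown sample types: {sorted(bad)}")

    # -- views ------------------------------------------------------------
    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def proteins(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.values.shape[1]

    def study_values(self) -> pd.DataFrame:
        """NPX values of study participants only."""
        return self.values.loc[self.sample_type_of == "study"]

    def bridge_values(self) -> pd.DataFrame:
        """NPX values of pooled bridge controls only."""
        return self.values.loc[self.sample_type_of == "bridge"]

    # -- transforms (never in place) --------------------------------------
    def copy(self) -> "NPXMatrix":
        return NPXMatrix(
            self.values.copy(),
            self.lod.copy(),
            self.plate_of.copy(),
            self.sample_type_of.copy(),
            self.cohort,
        )

    def subset_proteins(self, proteins) -> "NPXMatrix":
        proteins = pd.Index(proteins)
        missing = proteins.difference(self.proteins)
        if len(missing):
            raise IntegrityError(f"unknown proteins: {list(missing)[:5]}")
        return NPXMatrix(
            self.values.loc[:, proteins].copy(),
            self.lod.loc[proteins].copy(),
            self.plate_of.copy(),
            self.sample_type_of.copy(),
            self.cohort,
        )

    def drop_samples(self, sample_ids) -> "NPXMatrix":
        keep = self.samples.difference(pd.Index(sample_ids))
        keep = self.samples[self.samples.isin(keep)]  # preserve order
        return NPXMatrix(
            self.values.loc[keep].copy(),
            self.lod.copy(),
            self.plate_of.loc[keep].copy(),
            self.sample_type_of.loc[keep].copy(),
            self.cohort,
        )

    def equals(self, other: "NPXMatrix") -> bool:
        return (
            self.cohort == other.cohort
            and self.values.equals(other.values)
            and self.lod.equals(other.lod)
            and self.plate_of.equals(other.plate_of)
            and self.sample_type_of.equals(other.sample_type_of)
        )


@dataclass
class BridgeOffsets:
    """Per-protein bridging offsets X = median(bridge A) - median(bridge B)."""

    offset_x: pd.Series
    n_bridge_a: int
    n_bridge_b: int
    undefined: list = field(default_factory=list)

    def __post_init__(self) -> None:
        defined = self.offset_x.dropna()
        if not np.isfinite(defined.to_numpy()).all():
            raise IntegrityError("bridge offsets must be finite")


@dataclass
class PCScores:
    """Principal-component scores with provenance of centering/scaling."""

    scores: pd.DataFrame  # samples x components, columns PC1, PC2, ...
    explained_variance: np.ndarray  # fraction per component
    centered: bool
    scaled: bool
    dropped_features: list = field(default_factory=list)


@dataclass
class QCReport:
    """Machine-readable record of every pre-analytical decision."""

    below_lod_fraction: pd.DataFrame  # index protein; columns frac_<cohortA>, frac_<cohortB>
    excluded_proteins: list = field(default_factory=list)  # dicts: protein, cohort, reason
    outlier_samples: pd.DataFrame = field(default_factory=pd.DataFrame)
    bridge_offsets: Optional[BridgeOffsets] = None
    counts: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "below_lod_fraction": {
                str(k): {c: float(v) for c, v in row.items()}
                for k, row in self.below_lod_fraction.iterrows()
            },
            "excluded_proteins": self.excluded_proteins,
            "outlier_samples": self.outlier_samples.to_dict(orient="records"),
            "counts": self.counts,
            "config": self.config,
        }
        if self.bridge_offsets is not None:
            d["bridge_offsets"] = {
                "offset_x": {str(k): float(v) for k, v in self.bridge_offsets.offset_x.items()},
                "n_bridge_a": self.bridge_offsets.n_bridge_a,
                "n_bridge_b": self.bridge_offsets.n_bridge_b,
                "undefined": list(self.bridge_offsets.undefined),
            }
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_tsv(self, directory) -> None:
        """Human-readable TSV views of the report."""
        import os

        os.makedirs(directory, exist_ok=True)
        self.below_lod_fraction.to_csv(os.path.join(directory, "below_lod_fraction.tsv"), sep="\t")
        pd.DataFrame(self.excluded_proteins).to_csv(
            os.path.join(directory, "excluded_proteins.tsv"), sep="\t", index=False
        )
        self.outlier_samples.to_csv(os.path.join(directory, "outlier_samples.tsv"), sep="\t", index=False)


@dataclass
class ClusterAssignment:
    """Sample -> cluster labels with method provenance.

    Labels are canonical: cluster 1 is the cluster with the lower mean of
    the clustered (standardized) data; ties broken by cluster size
    (larger first), then by smallest member id.
    """

    labels: pd.Series  # sample -> int in 1..k
    k: int
    method: str  # "hierarchical_ward" | "kmeans"
    distance: str = "euclidean"
    inertia: Optional[float] = None
    seed: Optional[int] = None

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


@dataclass
class MetaboliteTable:
    """Samples x metabolites intensity matrix plus per-metabolite annotation."""

    values: pd.DataFrame  # samples x metabolites, log-scale intensities
    annotation: pd.DataFrame  # index metabolite id; formula, putative_name, chem_class, food_derived

    def __post_init__(self) -> None:
        missing = self.values.columns.difference(self.annotation.index)
        if len(missing):
            raise IntegrityError(f"metabolites without annotation: {list(missing)[:5]}")
        self.annotation = self.annotation.loc[self.values.columns]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive dosage matrix (0..2)."""

    dosages: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy(dtype=float)
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 2:
            raise IntegrityError("dosages must lie in [0, 2]")

    @property
    def maf(self) -> pd.Series:
        """Minor-allele frequency per SNP (folded to (0, 0.5])."""
        af = self.dosages.mean(axis=0) / 2.0
        return np.minimum(af, 1.0 - af)


def asdict_shallow(obj) -> dict:
    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}
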