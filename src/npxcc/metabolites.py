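"""Food-derived metabolite x inflammatory protein association matrix.

For every (metabolite, protein) pair an OLS model

    protein ~ metabolite + age + sex

is fitted on the overlapping samples; betas are standardized (both analyte
and metabolite z-scored) so they are comparable across pairs, and the FDR
is controlled across the whole pair matrix with Benjamini-Hochberg (a
per-protein family is available by flag).  Chemical-class summaries
aggregate the scan without new inference.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import MetaboliteTable, NPXMatrix
from .diffexp import bh_fdr, build_design, fit_linear_models
from .exceptions import IntegrityError
from .scans import stars


def select_food_metabolites(t: MetaboliteTable) -> MetaboliteTable:
    """Subset to the metabolites annotated as food-derived (flag is input,
    curated upstream from ontology)."""
    flag = t.annotation["food_derived"].astype(bool)
    keep = t.annotation.index[flag]
    if len(keep) == 0:
        raise IntegrityError("no metabolites carry the food_derived flag")
    return MetaboliteTable(t.values.loc[:, keep].copy(), t.annotation.loc[keep].copy())


class MetaboliteProteinScan:
    """Model object for the metabolite x protein regression matrix."""

    def __init__(
        self,
        metab: MetaboliteTable,
        npx: NPXMatrix | pd.DataFrame,
        meta: pd.DataFrame,
        covariates: Sequence[str] = ("age", "sex"),
        standardized: bool = True,
        fdr_family: str = "matrix",
        min_overlap: int = 50,
    ):
        if fdr_family not in ("matrix", "per_protein"):
            raise IntegrityError(f"unknown fdr family: {fdr_family!r}")
        values = npx.study_values() if isinstance(npx, NPXMatrix) else npx
        overlap = values.index.intersection(metab.values.index)
        if len(overlap) < min_overlap:
            raise IntegrityError(
                f"only {len(overlap)} overlapping samples (minimum {min_overlap})"
            )
        self.npx = values.loc[overlap]
        self.metab = metab.values.loc[overlap]
        self.annotation = metab.annotation
        self.meta = meta.reindex(overlap)
        self.covariates = tuple(covariates)
        self.standardized = standardized
        self.fdr_family = fdr_family

    def fit(self) -> pd.DataFrame:
        y = self.npx
        if self.standardized:
            y = (y - y.mean()) / y.std(ddof=1)
        base = build_design(self.meta, self.covariates)
        frames, skipped = [], []
        for mtb in self.metab.columns:
            x = self.metab[mtb].astype(float)
            if x.dropna().std(ddof=1) == 0 or x.dropna().nunique() < 2:
                skipped.append({"metabolite": mtb, "reason": "zero variance"})
                continue
            if self.standardized:
                x = (x - x.mean()) / x.std(ddof=1)
            design = base.copy()
            design.insert(1, "metabolite", x)
            fits = fit_linear_models(y, design)
            j = fits.coef_index("metabolite")
            with np.errstate(divide="ignore", invalid="ignore"):
                t = fits.beta[:, j] / fits.se[:, j]
            p = 2.0 * sps.t.sf(np.abs(t), np.maximum(fits.df_resid, 1))
            frames.append(
                pd.DataFrame(
                    {
                        "metabolite": mtb,
                        "protein": fits.proteins,
                        "beta": fits.beta[:, j],
                        "se": fits.se[:, j],
                        "p": p,
                        "n_used": fits.n_used,
                    }
                )
            )
        if not frames:
            raise IntegrityError("no metabolite with variance to scan")
        out = pd.concat(frames, ignore_index=True)
        if self.fdr_family == "matrix":
            out["fdr"] = bh_fdr(out["p"].to_numpy())
        else:
            out["fdr"] = out.groupby("protein")["p"].transform(lambda s: bh_fdr(s.to_numpy()))
        out["stars"] = stars(out["fdr"].to_numpy())
        ann = self.annotation[["formula", "putative_name", "chem_class"]]
        out = out.merge(ann, left_on="metabolite", right_index=True, how="left")
        out.attrs["skipped"] = skipped
        return out


def metabolite_protein_scan(
    metab: MetaboliteTable,
    npx,
    meta: pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex"),
    standardized: bool = True,
    fdr_family: str = "matrix",
    min_overlap: int = 50,
) -> pd.DataFrame:
    """Metabolite x protein association matrix (functional wrapper)."""
    return MetaboliteProteinScan(
        metab, npx, meta, covariates, standardized, fdr_family, min_overlap
    ).fit()


def class_summary(scan: pd.DataFrame, fdr_cut: float = 0.05) -> pd.DataFrame:
    """Per chemical-class aggregate of the scan: median beta, fraction of
    significant pairs, pair count.  No new inference."""
    if "chem_class" not in scan.columns:
        raise IntegrityError("scan result lacks a chem_class column")
    grouped = scan.groupby("chem_class")
    out = pd.DataFrame(
        {
            "median_beta": grouped["beta"].median(),
            "frac_significant": grouped["fdr"].apply(lambda s: float((s < fdr_cut).mean())),
            "n_pairs": grouped.size(),
        }
    )
    return out.sort_values("median_beta")


def top_pairs(scan: pd.DataFrame, top: int = 50) -> pd.DataFrame:
    """Display filter: the ``top`` most significant pairs (full matrix is
    always exported; this only selects rows for presentation)."""
    return scan.sort_values(["fdr", "p"]).head(top).copy()
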