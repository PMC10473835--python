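"""Factor-by-protein and SNP-by-protein association scans.

Each scan fits, per protein, an OLS model of the analyte on one factor of
interest plus adjustment covariates, then controls the FDR across proteins
within the (factor, cohort) family with Benjamini-Hochberg.  Significance
stars follow the three-bin convention *** < 0.0001, ** < 0.005, * < 0.05
(strict inequalities).

The pQTL scan regresses each protein on additive SNP dosage and reports
unadjusted p-values, flagging pairs that cross the genome-wide (5e-8) and
suggestive (5e-6) thresholds.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, NPXMatrix
from .diffexp import bh_fdr, build_design, fit_linear_models
from .exceptions import IntegrityError

STAR_BINS = ((0.0001, "***"), (0.005, "**"), (0.05, "*"))
GENOME_WIDE_P = 5e-8
SUGGESTIVE_P = 5e-6

#: default adjustment per factor: the other two of {age, sex, bmi};
#: environmental exposures are adjusted for age and sex.
CORE_FACTORS = ("age", "sex", "bmi")


def stars(q) -> np.ndarray:
    """Significance stars for a vector of (adjusted) p-values."""
    q = np.asarray(q, dtype=float)
    out = np.full(q.shape, "", dtype=object)
    for cut, label in reversed(STAR_BINS):  # widest bin first, then overwrite
        out[q < cut] = label
    out[~np.isfinite(q)] = ""
    return out


def default_covariates(factor: str) -> tuple:
    if factor in CORE_FACTORS:
        return tuple(c for c in CORE_FACTORS if c != factor)
    return ("age", "sex")


class FactorScan:
    """Per-protein OLS scan of one host/environment factor.

    Works on any analyte matrix on a log scale (NPX panel or absolute
    concentrations).  With ``standardized=True`` the analyte (and a
    continuous factor) are z-scored so betas are scale-free.
    """

    def __init__(
        self,
        m: NPXMatrix | pd.DataFrame,
        meta: pd.DataFrame,
        factor: str,
        covariates: Sequence[str] | None = None,
        standardized: bool = False,
        cohort: str = "",
    ):
        values = m.study_values() if isinstance(m, NPXMatrix) else m
        self.cohort = cohort or (m.cohort if isinstance(m, NPXMatrix) else "")
        covariates = default_covariates(factor) if covariates is None else tuple(covariates)
        if factor in covariates:
            raise IntegrityError(f"factor {factor!r} cannot also be a covariate")
        meta = meta.reindex(values.index)
        if factor not in meta.columns:
            raise IntegrityError(f"factor {factor!r} not found in metadata")
        fcol = meta[factor]
        if fcol.dropna().nunique() < 2:
            raise IntegrityError(f"factor {factor!r} has no variance in cohort {self.cohort!r}")

        if pd.api.types.is_numeric_dtype(fcol):
            fval = fcol.astype(float)
            if standardized:
                fval = (fval - fval.mean()) / fval.std(ddof=1)
            factor_cols = {factor: fval}
        else:
            levels = sorted(fcol.dropna().unique())
            ref = "male" if factor == "sex" and "male" in levels else levels[0]
            factor_cols = {}
            for lev in levels:
                if lev == ref:
                    continue
                dummy = (fcol == lev).astype(float)
                dummy[fcol.isna()] = np.nan
                factor_cols[f"{factor}[{lev}]"] = dummy

        design = build_design(meta, covariates)
        for name, col in factor_cols.items():
            design.insert(1, name, col)
        self.design = design
        self.factor = factor
        self.factor_terms = list(factor_cols)
        self.values = (
            (values - values.mean()) / values.std(ddof=1) if standardized else values
        )
        self.standardized = standardized

    def fit(self) -> pd.DataFrame:
        fits = fit_linear_models(self.values, self.design)
        frames = []
        for term in self.factor_terms:
            j = fits.coef_index(term)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = fits.beta[:, j] / fits.se[:, j]
            from scipy import stats as sps

            p = 2.0 * sps.t.sf(np.abs(t), np.maximum(fits.df_resid, 1))
            p = np.where(fits.df_resid >= 1, p, np.nan)
            frames.append(
                pd.DataFrame(
                    {
                        "factor": term,
                        "cohort": self.cohort,
                        "protein": fits.proteins,
                        "beta": fits.beta[:, j],
                        "se": fits.se[:, j],
                        "p": p,
                        "n_used": fits.n_used,
                    }
                )
            )
        out = pd.concat(frames, ignore_index=True)
        out["fdr"] = bh_fdr(out["p"].to_numpy())
        out["stars"] = stars(out["fdr"].to_numpy())
        return out


def factor_scan(
    m,
    meta: pd.DataFrame,
    factor: str,
    covariates: Sequence[str] | None = None,
    standardized: bool = False,
    cohort: str = "",
) -> pd.DataFrame:
    """Scan one factor against every protein (functional wrapper)."""
    return FactorScan(m, meta, factor, covariates, standardized, cohort).fit()


def pqtl_scan(
    g: GenotypeMatrix,
    m: NPXMatrix | pd.DataFrame,
    meta: pd.DataFrame | None = None,
    covariates: Sequence[str] = ("age", "sex"),
    min_overlap: int = 30,
) -> pd.DataFrame:
    """Additive-dosage linear model for every (SNP, protein) pair.

    p-values are reported unadjusted; pairs crossing the genome-wide
    (5e-8) and suggestive (5e-6) thresholds are flagged.  Monomorphic SNPs
    (zero dosage variance in the overlapping samples) are skipped.
    """
    values = m.study_values() if isinstance(m, NPXMatrix) else m
    overlap = values.index.intersection(g.dosages.index)
    if len(overlap) < min_overlap:
        raise IntegrityError(
            f"only {len(overlap)} samples overlap between genotypes and NPX "
            f"(minimum {min_overlap})"
        )
    values = values.loc[overlap]
    dosages = g.dosages.loc[overlap]
    if meta is not None and covariates:
        meta = meta.reindex(overlap)
        base = build_design(meta, covariates)
    else:
        base = pd.DataFrame({"intercept": pd.Series(1.0, index=overlap)})

    frames, skipped = [], []
    for snp in dosages.columns:
        dose = dosages[snp]
        if dose.std(ddof=1) == 0 or dose.nunique() < 2:
            skipped.append({"snp": snp, "reason": "monomorphic"})
            continue
        design = base.copy()
        design.insert(1, "dosage", dose.astype(float))
        fits = fit_linear_models(values, design)
        j = fits.coef_index("dosage")
        from scipy import stats as sps

        with np.errstate(divide="ignore", invalid="ignore"):
            t = fits.beta[:, j] / fits.se[:, j]
        p = 2.0 * sps.t.sf(np.abs(t), np.maximum(fits.df_resid, 1))
        frames.append(
            pd.DataFrame(
                {
                    "snp": snp,
                    "protein": fits.proteins,
                    "beta": fits.beta[:, j],
                    "se": fits.se[:, j],
                    "p": p,
                    "n_used": fits.n_used,
                }
            )
        )
    if not frames:
        out = pd.DataFrame(columns=["snp", "protein", "beta", "se", "p", "n_used"])
    else:
        out = pd.concat(frames, ignore_index=True)
    out["genome_wide"] = out["p"] < GENOME_WIDE_P if len(out) else pd.Series(dtype=bool)
    out["suggestive"] = out["p"] < SUGGESTIVE_P if len(out) else pd.Series(dtype=bool)
    out.attrs["skipped"] = skipped
    return out
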