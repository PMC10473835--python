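"""Covariate-adjusted differential expression with empirical-Bayes moderation.

Per protein, a linear model is fitted to the log2 NPX values:

    npx ~ cohort + age + sex + bmi (+ ...)

The cohort coefficient is the log2 fold change (log2 FC).  Residual
variances are shrunk toward a panel-wide prior with the standard
scaled-inverse-chi-squared empirical-Bayes construction: the prior degrees
of freedom d0 and prior variance s0^2 are estimated by moment matching on
the log residual variances, each protein's posterior variance is

    s2_post = (d0 * s0^2 + df * s2) / (d0 + df)

and the moderated t statistic is beta / (stdev_unscaled * sqrt(s2_post))
with d0 + df degrees of freedom.  With d0 = 0 this reduces exactly to the
classical OLS t test; with d0 = inf every variance is replaced by s0^2.
Multiple testing is controlled with Benjamini-Hochberg FDR; proteins with
FDR < 0.05 are called differentially expressed.

The public surface is statsmodels-flavoured: :class:`CohortContrast` (and
:class:`PairedContrast`) are model objects whose ``fit()`` returns a
results object with a ``summary()`` table; ``run_de`` / ``paired_de`` are
functional wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import NPXMatrix
from .exceptions import IntegrityError

DEFAULT_COVARIATES = ("age", "sex", "bmi")
FDR_CUT = 0.05
FC_CUT = 0.5  # display threshold for volcano plots, not a significance gate


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def build_design(
    meta: pd.DataFrame,
    covariates: Sequence[str] = (),
    contrast: pd.Series | None = None,
    contrast_name: str = "contrast",
) -> pd.DataFrame:
    """Intercept + optional contrast indicator + reference-coded covariates.

    Categorical covariates are dummy-coded against a declared reference
    level: ``male`` for sex, otherwise the first sorted level.  Rows with
    missing entries are NOT dropped here (handled pairwise downstream).
    """
    cols: dict[str, pd.Series] = {"intercept": pd.Series(1.0, index=meta.index)}
    if contrast is not None:
        cols[contrast_name] = contrast.reindex(meta.index).astype(float)
    for cov in covariates:
        if cov not in meta.columns:
            raise IntegrityError(f"covariate {cov!r} not found in metadata")
        col = meta[cov]
        if pd.api.types.is_numeric_dtype(col):
            cols[cov] = col.astype(float)
        else:
            levels = sorted(col.dropna().unique())
            ref = "male" if cov == "sex" and "male" in levels else (levels[0] if levels else None)
            if ref is None or len(levels) < 2:
                raise IntegrityError(f"covariate {cov!r} has fewer than two levels")
            for lev in levels:
                if lev == ref:
                    continue
                dummy = (col == lev).astype(float)
                dummy[col.isna()] = np.nan
                cols[f"{cov}[{lev}]"] = dummy
    design = pd.DataFrame(cols)
    complete = design.dropna()
    if len(complete) and np.linalg.matrix_rank(complete.to_numpy()) < design.shape[1]:
        raise IntegrityError("design matrix is not of full column rank")
    return design


# ---------------------------------------------------------------------------
# per-protein OLS
# ---------------------------------------------------------------------------

@dataclass
class ProteinFits:
    """OLS fits for a panel of proteins sharing one design."""

    proteins: pd.Index
    coef_names: list
    beta: np.ndarray  # proteins x coefficients
    stdev_unscaled: np.ndarray  # proteins x coefficients (se = stdev_unscaled * sigma)
    sigma2: np.ndarray  # residual variance per protein
    df_resid: np.ndarray
    n_used: np.ndarray
    skipped: dict = field(default_factory=dict)  # protein -> reason

    @property
    def se(self) -> np.ndarray:
        return self.stdev_unscaled * np.sqrt(self.sigma2)[:, None]

    def coef_index(self, name: str) -> int:
        return self.coef_names.index(name)


def _ols_block(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """OLS of every column of y on x (complete data). Returns beta, unscaled
    stdev of the coefficients, residual variances, df."""
    n, k = x.shape
    q, r = np.linalg.qr(x)
    beta = np.linalg.solve(r, q.T @ y)  # k x p
    resid = y - x @ beta
    df = n - k
    sigma2 = (resid**2).sum(axis=0) / df if df > 0 else np.full(y.shape[1], np.nan)
    rinv = np.linalg.inv(r)
    unscaled = np.sqrt((rinv**2).sum(axis=1))  # sqrt(diag((X'X)^-1))
    return beta.T, np.tile(unscaled, (y.shape[1], 1)), sigma2, df


def fit_linear_models(y: pd.DataFrame | NPXMatrix, design: pd.DataFrame) -> ProteinFits:
    """Ordinary least squares per protein against a shared design matrix.

    Samples with missing design entries are dropped for every protein;
    samples with a missing response are dropped per protein (pairwise
    complete).  Proteins with fewer residual degrees of freedom than 1 are
    skipped with a recorded reason.
    """
    if isinstance(y, NPXMatrix):
        y = y.study_values()
    y = y.loc[design.index.intersection(y.index)]
    design = design.loc[y.index]
    keep = design.notna().all(axis=1)
    y, design = y.loc[keep], design.loc[keep]

    x = design.to_numpy(dtype=float)
    ymat = y.to_numpy(dtype=float)
    n, k = x.shape
    proteins = y.columns
    p = len(proteins)
    beta = np.full((p, k), np.nan)
    unscaled = np.full((p, k), np.nan)
    sigma2 = np.full(p, np.nan)
    df_resid = np.zeros(p)
    n_used = np.zeros(p, dtype=int)
    skipped: dict = {}

    complete_cols = ~np.isnan(ymat).any(axis=0)
    if complete_cols.any():
        b, u, s2, df = _ols_block(x, ymat[:, complete_cols])
        idx = np.where(complete_cols)[0]
        if df < 1:
            for j in idx:
                skipped[proteins[j]] = "df_resid < 1"
        else:
            beta[idx], unscaled[idx], sigma2[idx] = b, u, s2
            df_resid[idx] = df
            n_used[idx] = n
    for j in np.where(~complete_cols)[0]:
        ok = ~np.isnan(ymat[:, j])
        nj = int(ok.sum())
        if nj - k < 1:
            skipped[proteins[j]] = "df_resid < 1"
            continue
        xj = x[ok]
        if np.linalg.matrix_rank(xj) < k:
            skipped[proteins[j]] = "design rank-deficient after missing-data alignment"
            continue
        b, u, s2, df = _ols_block(xj, ymat[ok][:, [j]])
        beta[j], unscaled[j], sigma2[j] = b[0], u[0], s2[0]
        df_resid[j] = df
        n_used[j] = nj

    return ProteinFits(
        proteins=proteins,
        coef_names=list(design.columns),
        beta=beta,
        stdev_unscaled=unscaled,
        sigma2=sigma2,
        df_resid=df_resid,
        n_used=n_used,
        skipped=skipped,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderation
# ---------------------------------------------------------------------------

@dataclass
class ModerationParams:
    d0: float  # prior degrees of freedom (may be inf)
    s0_sq: float  # prior variance, log2^2 units
    low_confidence: bool = False


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < 1e-10:
            break
    return float(x)


def estimate_moderation(fits: ProteinFits) -> ModerationParams:
    """Moment-matching estimate of the variance prior (d0, s0^2).

    Works on log residual variances: under s2 ~ s0^2 * chi2_df / df scaled
    by an inverse-chi2(d0) prior, log s2 - digamma(df/2) + log(df/2) has
    variance trigamma(df/2) + trigamma(d0/2).  Any excess spread of the
    observed log variances over the trigamma(df/2) term identifies d0; no
    excess means a common variance (d0 = inf).
    """
    ok = (fits.df_resid >= 1) & (fits.sigma2 > 0) & np.isfinite(fits.sigma2)
    s2 = fits.sigma2[ok]
    df = fits.df_resid[ok]
    if len(s2) == 0:
        raise IntegrityError("no proteins with positive residual variance")
    low_confidence = len(s2) < 10
    if low_confidence:
        warnings.warn(
            f"moderation prior estimated from only {len(s2)} proteins; low confidence",
            stacklevel=2,
        )
    z = np.log(s2)
    if np.ptp(z) == 0:  # exactly equal variances: no spread to moment-match
        return ModerationParams(d0=np.inf, s0_sq=float(s2[0]), low_confidence=low_confidence)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    if len(e) < 2:
        return ModerationParams(d0=np.inf, s0_sq=float(np.exp(emean)), low_confidence=True)
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return ModerationParams(d0=np.inf, s0_sq=float(np.exp(emean)), low_confidence=low_confidence)
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return ModerationParams(d0=float(d0), s0_sq=float(s0_sq), low_confidence=low_confidence)


def moderate(
    fits: ProteinFits, params: ModerationParams, coef: str
) -> pd.DataFrame:
    """Moderated t and two-sided p for one coefficient of every fitted protein.

    s2_post = (d0*s0^2 + df*s2)/(d0 + df); t = beta/(stdev_unscaled*s_post);
    p from a t distribution with d0 + df degrees of freedom.  d0 = 0 gives
    classical OLS inference, d0 = inf gives s2_post = s0^2 everywhere.
    """
    j = fits.coef_index(coef)
    beta = fits.beta[:, j]
    unscaled = fits.stdev_unscaled[:, j]
    df = fits.df_resid
    if np.isinf(params.d0):
        s2_post = np.full_like(fits.sigma2, params.s0_sq)
        df_total = np.full_like(df, np.inf)
    else:
        s2_post = (params.d0 * params.s0_sq + df * fits.sigma2) / (params.d0 + df)
        df_total = params.d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / (unscaled * np.sqrt(s2_post))
    p = np.where(
        np.isfinite(t),
        2.0 * stats.t.sf(np.abs(t), np.where(np.isinf(df_total), 1e12, df_total)),
        np.nan,
    )
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    p = np.where(np.isfinite(t), p, np.nan)
    return pd.DataFrame(
        {"beta": beta, "t_mod": t, "p": p, "s2_post": s2_post, "df_total": df_total},
        index=fits.proteins,
    )


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class CohortContrast:
    """Two-cohort differential-expression model on the shared protein panel.

    The contrast column is an indicator that is 1 for cohort ``a`` and 0
    for cohort ``b``; its coefficient is the log2 FC of cohort a over
    cohort b.  Bridge samples never enter the fit.
    """

    def __init__(
        self,
        a: NPXMatrix,
        b: NPXMatrix,
        metadata: pd.DataFrame,
        covariates: Sequence[str] = DEFAULT_COVARIATES,
    ):
        from .io import merge_cohorts

        merged = merge_cohorts(a, b)
        self.only_a, self.only_b = merged.only_a, merged.only_b
        ya, yb = merged.a.study_values(), merged.b.study_values()
        self.y = pd.concat([ya, yb])
        self.cohort_a, self.cohort_b = a.cohort, b.cohort
        meta = metadata.reindex(self.y.index)
        for cov in covariates:
            if cov not in meta.columns:
                raise IntegrityError(f"covariate {cov!r} not found in metadata")
            for label, idx in ((a.cohort, ya.index), (b.cohort, yb.index)):
                if meta.loc[idx, cov].isna().all():
                    raise IntegrityError(f"covariate {cov!r} entirely missing in cohort {label}")
        contrast = pd.Series(0.0, index=self.y.index)
        contrast[ya.index] = 1.0
        self.design = build_design(meta, covariates, contrast=contrast, contrast_name="cohort")
        self.covariates = tuple(covariates)

    def fit(
        self, moderated: bool = True, fdr_cut: float = FDR_CUT, fc_cut: float = FC_CUT
    ) -> "DEResults":
        fits = fit_linear_models(self.y, self.design)
        params = (
            estimate_moderation(fits) if moderated else ModerationParams(d0=0.0, s0_sq=1.0)
        )
        mod = moderate(fits, params, "cohort")
        fdr = bh_fdr(mod["p"].to_numpy())
        direction = np.where(
            fdr < fdr_cut, np.where(mod["beta"] > 0, "up", "down"), "ns"
        )
        direction = np.where(np.isfinite(fdr), direction, "ns")
        table = pd.DataFrame(
            {
                "log2_fc": mod["beta"],
                "t_mod": mod["t_mod"],
                "p": mod["p"],
                "fdr": fdr,
                "direction": direction,
            },
            index=fits.proteins,
        )
        table.index.name = "protein"
        return DEResults(
            table=table,
            params=params,
            fits=fits,
            fdr_cut=fdr_cut,
            fc_cut=fc_cut,
            moderated=moderated,
            contrast=f"{self.cohort_a} vs {self.cohort_b}",
            excluded_proteins={"only_in_a": self.only_a, "only_in_b": self.only_b},
        )


@dataclass
class DEResults:
    """Differential-expression results: one row per protein."""

    table: pd.DataFrame  # log2_fc, t_mod, p, fdr, direction
    params: ModerationParams
    fits: ProteinFits
    fdr_cut: float
    fc_cut: float
    moderated: bool
    contrast: str
    excluded_proteins: dict = field(default_factory=dict)

    @property
    def counts(self) -> dict:
        vc = self.table["direction"].value_counts()
        return {k: int(vc.get(k, 0)) for k in ("up", "down", "ns")}

    def volcano_table(self) -> pd.DataFrame:
        """log2 FC vs -log10 FDR coordinates plus display thresholds."""
        out = self.table[["log2_fc", "fdr", "direction"]].copy()
        out["neg_log10_fdr"] = -np.log10(out["fdr"])
        out["beyond_fc_cut"] = out["log2_fc"].abs() > self.fc_cut
        return out

    def summary(self) -> pd.DataFrame:
        """Per-protein summary ordered by FDR (most significant first)."""
        return self.table.sort_values(["fdr", "p"]).copy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")

    def plot_volcano(self, ax=None):
        """Volcano plot (log2 FC vs -log10 FDR) with the display cut-offs."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        tab = self.volcano_table()
        colors = tab["direction"].map({"up": "#c0392b", "down": "#16a085", "ns": "0.7"})
        ax.scatter(tab["log2_fc"], tab["neg_log10_fdr"], c=colors, s=12)
        for x in (-self.fc_cut, self.fc_cut):
            ax.axvline(x, ls=":", c="0.4")
        ax.axhline(-np.log10(self.fdr_cut), ls=":", c="0.4")
        ax.set_xlabel("log2 fold change")
        ax.set_ylabel("-log10 FDR")
        ax.set_title(self.contrast)
        return ax


def run_de(
    a: NPXMatrix,
    b: NPXMatrix,
    meta: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    moderated: bool = True,
    fdr_cut: float = FDR_CUT,
    fc_cut: float = FC_CUT,
) -> DEResults:
    """Fit the cohort contrast on preprocessed matrices (functional wrapper)."""
    return CohortContrast(a, b, meta, covariates).fit(
        moderated=moderated, fdr_cut=fdr_cut, fc_cut=fc_cut
    )


# ---------------------------------------------------------------------------
# paired pre/post contrast
# ---------------------------------------------------------------------------

class PairedContrast:
    """Within-subject pre/post contrast (e.g. a dietary-switch intervention).

    ``pairing`` maps each post sample id to its pre sample id.  Per protein
    the effect is the mean within-subject difference (post - pre); a
    negative beta is a reduction after the switch.
    """

    def __init__(self, pre: NPXMatrix, post: NPXMatrix, pairing: dict | pd.Series):
        pairing = pd.Series(dict(pairing))
        post_ids = post.study_values().index
        unpaired = post_ids.difference(pairing.index).tolist()
        missing_pre = [
            v for v in pairing.values if v not in pre.study_values().index
        ]
        if unpaired or missing_pre:
            raise IntegrityError(
                f"unpaired samples: post without pairing {unpaired[:5]}, "
                f"pre ids not found {missing_pre[:5]}"
            )
        common = pre.proteins.intersection(post.proteins)
        self.diffs = (
            post.study_values().loc[pairing.index, common].to_numpy()
            - pre.study_values().loc[pairing.to_numpy(), common].to_numpy()
        )
        self.proteins = common

    def fit(self) -> pd.DataFrame:
        """Per-protein (beta, t, p, n) from the paired t-test."""
        d = self.diffs
        n = d.shape[0]
        beta = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t), n - 1)
        all_zero = (d == 0).all(axis=0)
        p = np.where(all_zero, 1.0, p)
        t = np.where(all_zero, 0.0, t)
        out = pd.DataFrame(
            {"beta": beta, "t": t, "p": p, "n": n, "degenerate": all_zero},
            index=self.proteins,
        )
        out.index.name = "protein"
        return out


def paired_de(pre: NPXMatrix, post: NPXMatrix, pairing) -> pd.DataFrame:
    """Paired pre/post differential expression (functional wrapper)."""
    return PairedContrast(pre, post, pairing).fit()
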