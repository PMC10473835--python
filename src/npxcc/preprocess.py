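"""Pre-analytical chain: bridging normalization, LOD filtering, PCA outlier removal.

Bridging removes between-cohort technical offsets using pooled plasma
controls measured in both cohorts (two per plate, four plates per cohort,
i.e. eight bridge samples each).  For every protein the offset is

    X = median(bridge NPX, cohort A) - median(bridge NPX, cohort B)

and X is subtracted from every cohort-A value (study and bridge) and from
cohort A's LOD, so below-LOD status is invariant under bridging.

Values below the LOD are kept as measured; proteins are excluded only when
the fraction of study samples below LOD exceeds a threshold (default 25%,
strictly greater).  Samples are screened once with PCA: any sample whose
PC1 or PC2 score lies more than 3 SD from that component's mean is dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import BridgeOffsets, NPXMatrix, PCScores, QCReport
from .exceptions import ConfigError, IntegrityError


def compute_bridge_offsets(a: NPXMatrix, b: NPXMatrix) -> BridgeOffsets:
    """Per-protein median difference X between the cohorts' bridge samples.

    Proteins with fewer than two bridge measurements in either cohort get an
    undefined (NaN) offset and are listed in ``undefined``.
    """
    common = a.proteins.intersection(b.proteins)
    bridge_a = a.bridge_values()[common]
    bridge_b = b.bridge_values()[common]
    if bridge_a.shape[0] == 0 or bridge_b.shape[0] == 0:
        raise IntegrityError("both cohorts need bridge samples to compute offsets")
    n_a = bridge_a.notna().sum(axis=0)
    n_b = bridge_b.notna().sum(axis=0)
    offset = bridge_a.median(axis=0) - bridge_b.median(axis=0)
    undefined = common[(n_a < 2) | (n_b < 2)].tolist()
    offset[undefined] = np.nan
    return BridgeOffsets(
        offset_x=offset,
        n_bridge_a=int(bridge_a.shape[0]),
        n_bridge_b=int(bridge_b.shape[0]),
        undefined=undefined,
    )


def apply_bridge(a: NPXMatrix, offsets: BridgeOffsets) -> NPXMatrix:
    """Subtract the per-protein offset X from every cohort-A value and LOD.

    Proteins without a defined offset pass through unadjusted with a warning.
    """
    out = a.copy()
    x = offsets.offset_x.reindex(out.proteins)
    missing = out.proteins[x.isna()].tolist()
    if missing:
        warnings.warn(
            f"{len(missing)} protein(s) without a defined bridge offset passed through "
            f"unadjusted: {missing[:5]}",
            stacklevel=2,
        )
    x = x.fillna(0.0)
    out.values = out.values.sub(x, axis=1)
    out.lod = out.lod.sub(x)
    return out


def below_lod_fraction(m: NPXMatrix) -> pd.Series:
    """Fraction of study samples strictly below the per-protein LOD.

    Bridge samples are excluded from the denominator; values below LOD are
    never imputed (they stay as measured) — this only counts them.
    """
    study = m.study_values()
    below = study.lt(m.lod, axis=1)
    return below.sum(axis=0) / study.notna().sum(axis=0)


def lod_filter(
    frac_a: pd.Series,
    frac_b: pd.Series,
    threshold: float = 0.25,
    mode: str = "both",
) -> dict:
    """Apply the >threshold below-LOD exclusion rule.

    mode="both": exclude a protein only when the fraction exceeds the
    threshold in *both* cohorts (one shared exclusion list).
    mode="either": exclude when it exceeds in either cohort.
    mode="per_cohort": exclude per cohort independently, so the cohorts can
    retain different protein sets.

    The rule is strictly "more than": a fraction exactly equal to the
    threshold is retained.
    """
    if not 0 < threshold < 1:
        raise ConfigError(f"lod threshold must be in (0, 1), got {threshold}")
    if mode not in ("both", "either", "per_cohort"):
        raise ConfigError(f"unknown lod filter mode: {mode!r}")
    proteins = frac_a.index
    if not proteins.equals(frac_b.index):
        raise IntegrityError("LOD fractions must cover the same protein universe")
    over_a = frac_a > threshold
    over_b = frac_b > threshold
    if mode == "both":
        excl = proteins[over_a & over_b]
        excluded_a = excluded_b = excl.tolist()
    elif mode == "either":
        excl = proteins[over_a | over_b]
        excluded_a = excluded_b = excl.tolist()
    else:
        excluded_a = proteins[over_a].tolist()
        excluded_b = proteins[over_b].tolist()
    return {
        "mode": mode,
        "threshold": threshold,
        "excluded_a": excluded_a,
        "excluded_b": excluded_b,
        "retained_a": proteins.difference(excluded_a).tolist(),
        "retained_b": proteins.difference(excluded_b).tolist(),
    }


def pca_scores(
    m: pd.DataFrame,
    center: bool = True,
    scale: bool = True,
    n_components: int | None = None,
) -> PCScores:
    """PC scores via SVD of the (optionally centered/unit-variance) matrix.

    Component signs follow the convention that the loading of largest
    magnitude on each component is positive.  Zero-variance features are
    dropped (with a warning) when scaling is requested.
    """
    if m.shape[0] < 3 or m.shape[1] < 2:
        raise IntegrityError("PCA needs at least 3 samples and 2 features")
    x = m.to_numpy(dtype=float)
    if np.isnan(x).any():
        col_means = np.nanmean(x, axis=0)
        idx = np.where(np.isnan(x))
        x = x.copy()
        x[idx] = np.take(col_means, idx[1])
    dropped = []
    sd = x.std(axis=0, ddof=1)
    if scale:
        zero = sd == 0
        if zero.any():
            dropped = m.columns[zero].tolist()
            warnings.warn(f"dropping {len(dropped)} zero-variance feature(s) before scaled PCA", stacklevel=2)
            x = x[:, ~zero]
            sd = sd[~zero]
    if center:
        x = x - x.mean(axis=0)
    if scale:
        x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    u = u * flip
    scores = u * s
    var = s**2
    explained = var / var.sum() if var.sum() > 0 else var
    k = n_components or scores.shape[1]
    cols = [f"PC{i + 1}" for i in range(min(k, scores.shape[1]))]
    return PCScores(
        scores=pd.DataFrame(scores[:, : len(cols)], index=m.index, columns=cols),
        explained_variance=explained[: len(cols)],
        centered=center,
        scaled=scale,
        dropped_features=dropped,
    )


def flag_outliers(scores: PCScores, k_sd: float = 3.0, components: int = 2) -> pd.DataFrame:
    """Samples whose score on any of the first ``components`` PCs is > k_sd SDs
    from that component's mean (single pass, no re-iteration).

    A component with zero SD contributes no flags.  Returns a frame with the
    flagged samples' scores and z-values.
    """
    use = scores.scores.iloc[:, :components]
    mean = use.mean(axis=0)
    sd = use.std(axis=0, ddof=1)
    z = (use - mean).div(sd.replace(0.0, np.nan), axis=1)
    flagged = (z.abs() > k_sd).any(axis=1)
    out = use.loc[flagged].copy()
    out.columns = [c.lower() for c in out.columns]
    for i, c in enumerate(use.columns):
        out[f"z{i + 1}"] = z.loc[flagged, c]
    return out.reset_index(names="sample_id")


@dataclass
class PreprocessConfig:
    """Thresholds and mode switches for the pre-analytical chain."""

    lod_max_frac: float = 0.25
    lod_mode: str = "per_cohort"
    outlier_sd: float = 3.0
    outlier_components: int = 2
    pca_center: bool = True
    pca_scale: bool = True
    bridge: bool = True
    extra: dict = field(default_factory=dict)


def preprocess_pipeline(
    a: NPXMatrix, b: NPXMatrix, config: PreprocessConfig | None = None
) -> tuple[NPXMatrix, NPXMatrix, QCReport]:
    """Run bridge -> LOD filter -> PCA outlier removal; record every decision.

    Cohort A receives the bridge offsets (the offset-receiving cohort is a
    config choice made when calling; pass the cohorts accordingly).  Outlier
    screening runs per cohort on study samples.  At fixed thresholds the
    pipeline is idempotent: re-running it on its own output changes nothing.
    """
    cfg = config or PreprocessConfig()
    counts: dict = {
        "samples_in": {a.cohort: int(a.n_samples), b.cohort: int(b.n_samples)},
        "proteins_in": {a.cohort: int(a.n_proteins), b.cohort: int(b.n_proteins)},
    }

    offsets = None
    if cfg.bridge and a.bridge_values().shape[0] and b.bridge_values().shape[0]:
        offsets = compute_bridge_offsets(a, b)
        a = apply_bridge(a, offsets)

    frac_a = below_lod_fraction(a)
    frac_b = below_lod_fraction(b)
    common = frac_a.index.intersection(frac_b.index)
    filt = lod_filter(frac_a[common], frac_b[common], cfg.lod_max_frac, cfg.lod_mode)
    excluded = [
        {"protein": p, "cohort": a.cohort, "reason": "below_lod",
         "fraction": float(frac_a[p]), "threshold": cfg.lod_max_frac}
        for p in filt["excluded_a"]
    ] + [
        {"protein": p, "cohort": b.cohort, "reason": "below_lod",
         "fraction": float(frac_b[p]), "threshold": cfg.lod_max_frac}
        for p in filt["excluded_b"]
    ]
    a = a.subset_proteins([p for p in a.proteins if p not in set(filt["excluded_a"])])
    b = b.subset_proteins([p for p in b.proteins if p not in set(filt["excluded_b"])])

    outlier_frames = []
    clean = {}
    for m in (a, b):
        study = m.study_values()
        scores = pca_scores(study, center=cfg.pca_center, scale=cfg.pca_scale)
        flags = flag_outliers(scores, cfg.outlier_sd, cfg.outlier_components)
        flags.insert(1, "cohort", m.cohort)
        outlier_frames.append(flags)
        clean[m.cohort] = m.drop_samples(flags["sample_id"].tolist())
    outliers = pd.concat(outlier_frames, ignore_index=True)

    clean_a, clean_b = clean[a.cohort], clean[b.cohort]
    counts["samples_out"] = {clean_a.cohort: int(clean_a.n_samples), clean_b.cohort: int(clean_b.n_samples)}
    counts["proteins_out"] = {clean_a.cohort: int(clean_a.n_proteins), clean_b.cohort: int(clean_b.n_proteins)}
    counts["samples_excluded"] = {
        c: counts["samples_in"][c] - counts["samples_out"][c] for c in counts["samples_in"]
    }
    counts["proteins_excluded"] = {
        c: counts["proteins_in"][c] - counts["proteins_out"][c] for c in counts["proteins_in"]
    }

    frac = pd.DataFrame({f"frac_{a.cohort}": frac_a, f"frac_{b.cohort}": frac_b})
    report = QCReport(
        below_lod_fraction=frac,
        excluded_proteins=excluded,
        outlier_samples=outliers,
        bridge_offsets=offsets,
        counts=counts,
        config={
            "lod_max_frac": cfg.lod_max_frac,
            "lod_mode": cfg.lod_mode,
            "outlier_sd": cfg.outlier_sd,
            "outlier_components": cfg.outlier_components,
            "pca_center": cfg.pca_center,
            "pca_scale": cfg.pca_scale,
            "bridge": cfg.bridge,
        },
    )
    return clean_a, clean_b, report
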