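"""Synthetic two-cohort NPX study with known ground truth.

The generator emulates the structure of a two-cohort Olink-style study:

* two cohorts (defaults 318 and 416 study samples) measured on a 92-protein
  log2 NPX panel, four plates per cohort with two pooled bridge controls
  per plate (eight bridge samples per cohort);
* a cohort-wide technical offset plus small residual per-plate offsets
  (inter-plate control normalization is assumed to have happened upstream,
  so residual plate effects are small);
* sparse biological cohort effects spanning -0.8 .. +1.9 log2 units
  (35 proteins up, 20 down by default);
* age / sex / BMI covariate effects on protein subsets;
* per-protein LOD censoring marks (values below LOD are kept as measured;
  the LOD is stored so filters act on flags, not imputation) — by default
  18 proteins exceed the 25% rule in both cohorts and 2 more in cohort A
  only;
* a small fraction of multivariate outliers, planted in PC-score space at
  6 SD on both of the first two components so the 3-SD screening rule has
  a well-defined expected catch;
* per-protein noise variances drawn from a scaled-inverse-chi-squared
  family (d0 = 4, s0^2 = 0.25), the same family the moderation engine
  assumes;
* a cohort-A metabolite matrix with two latent diet clusters coupled to a
  protein subset, and six Hardy-Weinberg SNPs for the pQTL scan.

Everything injected is recorded in :class:`SimTruth`, and all randomness
derives from integer-indexed generator streams spawned from one seed, so
identical configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, MetaboliteTable, NPXMatrix
from .exceptions import ConfigError

CHEM_CLASSES = (
    "polyphenols",
    "carboxylic acids and derivatives",
    "organooxygen compounds",
    "prenol lipids",
    "amino acids and derivatives",
    "fatty acyls",
)


def _protein_ids(n: int) -> list:
    return [f"prot{i:03d}" for i in range(1, n + 1)]


def _metab_ids(n: int) -> list:
    return [f"mtb{i:04d}" for i in range(1, n + 1)]


def default_cohort_effects(n_proteins: int = 92) -> dict:
    """Sparse cohort effects mirroring a strongly contrasted two-cohort panel:
    35 up-regulated proteins spanning 0.3..1.9 log2 and 20 down-regulated
    spanning -0.8..-0.3 (indices truncated for small panels)."""
    ids = _protein_ids(n_proteins)
    effects: dict = {}
    up_idx = [i for i in range(30, 65) if i < n_proteins]
    down_idx = [i for i in range(65, 85) if i < n_proteins]
    if up_idx:
        for i, e in zip(up_idx, np.linspace(0.3, 1.9, len(up_idx))):
            effects[ids[i]] = float(e)
    if down_idx:
        for i, e in zip(down_idx, np.linspace(-0.8, -0.3, len(down_idx))):
            effects[ids[i]] = float(e)
    return effects


def default_covariate_effects(n_proteins: int = 92) -> dict:
    ids = _protein_ids(n_proteins)
    pick = lambda lo, hi: [ids[i] for i in range(lo, min(hi, n_proteins))]
    eff = {}
    if pick(20, 30):
        eff["age"] = (pick(20, 30), 0.01)  # log2 units per year
    if pick(30, 40):
        eff["sex"] = (pick(30, 40), -0.2)  # female relative to male
    if pick(40, 50):
        eff["bmi"] = (pick(40, 50), 0.02)  # log2 units per kg/m^2
    return eff


def default_lod_quantile(n_proteins: int = 92) -> dict:
    """Per-protein (cohort A, cohort B) censoring fractions: 18 proteins over
    the 25% rule in both cohorts, 2 more in cohort A only, rest ~2%."""
    ids = _protein_ids(n_proteins)
    q = {}
    for i, pid in enumerate(ids):
        if i < 18:
            q[pid] = (0.30, 0.30)
        elif i < 20:
            q[pid] = (0.30, 0.02)
        else:
            q[pid] = (0.02, 0.02)
    return q


@dataclass
class SimConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    n_a: int = 318
    n_b: int = 416
    n_proteins: int = 92
    plates_per_cohort: int = 4
    bridge_per_plate: int = 2
    cohort_a: str = "TZ"
    cohort_b: str = "NL"
    cohort_effects: Optional[dict] = None  # protein -> log2 FC (A over B); None = defaults
    covariate_effects: Optional[dict] = None  # factor -> (protein list, slope)
    technical_offset: float | dict = 0.5  # cohort-wide shift of A, log2
    plate_sd: float = 0.05  # residual per-plate per-protein offsets
    bridge_noise_sd: float = 0.05  # technical replicate noise of the pooled controls
    lod_quantile: Optional[dict] = None  # protein -> (frac_a, frac_b); None = defaults
    outlier_frac: float = 0.016
    outlier_sd: float = 6.0
    noise_d0: float = 4.0
    noise_s0_sq: float = 0.25
    # metabolome
    n_metab: int = 400
    n_food: int = 288
    n_shifted_metab: int = 80
    metab_cluster_shift: float = 1.5
    metab_noise_sd: float = 1.0
    cluster_protein_shift: float = 0.5
    n_cluster_proteins: int = 30
    couplings: Optional[list] = None  # (metabolite, protein, beta per SD)
    # genotypes
    n_snps: int = 6
    maf: tuple = (0.1, 0.15, 0.2, 0.25, 0.3, 0.4)
    snp_effects: list = field(default_factory=list)  # (snp, protein, beta per dose)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_a, self.n_b, self.n_proteins, self.plates_per_cohort) <= 0:
            raise ConfigError("sample/protein/plate counts must be positive")
        if not 0 <= self.outlier_frac < 1:
            raise ConfigError("outlier_frac must be in [0, 1)")
        if self.noise_d0 <= 0 or self.noise_s0_sq < 0:
            raise ConfigError("noise d0 must be positive and s0_sq non-negative")
        if self.cohort_effects is None:
            self.cohort_effects = default_cohort_effects(self.n_proteins)
        if self.covariate_effects is None:
            self.covariate_effects = default_covariate_effects(self.n_proteins)
        if self.lod_quantile is None:
            self.lod_quantile = default_lod_quantile(self.n_proteins)
        if self.couplings is None:
            ids = _protein_ids(self.n_proteins)
            targets = [ids[i] for i in range(85, min(90, self.n_proteins))]
            self.couplings = [(_metab_ids(self.n_food)[0], p, -0.3) for p in targets]
        ids = set(_protein_ids(self.n_proteins))
        for key in list(self.cohort_effects):
            if key not in ids:
                raise ConfigError(f"cohort effect references unknown protein {key!r}")
        for mtb, prot, _ in self.couplings:
            if prot not in ids:
                raise ConfigError(f"coupling references unknown protein {prot!r}")


def null_config(**overrides) -> SimConfig:
    """A configuration with no injected effects, offsets, censoring or outliers."""
    base = dict(
        cohort_effects={},
        covariate_effects={},
        technical_offset=0.0,
        plate_sd=0.0,
        lod_quantile={},
        outlier_frac=0.0,
        couplings=[],
    )
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class SimTruth:
    """Every injected quantity, sufficient to reconstruct expected values."""

    cohort_effects: dict
    covariate_effects: dict
    technical_offset: dict
    plate_offsets: dict  # (cohort, plate) -> list per protein
    sigma2: dict  # protein -> noise variance
    baseline: dict
    lod: dict  # cohort -> protein -> lod value
    lod_quantile: dict
    outliers: dict  # cohort -> list of sample ids
    diet_cluster: dict = field(default_factory=dict)  # sample -> 1|2
    shifted_metabolites: list = field(default_factory=list)
    cluster_shifted_proteins: list = field(default_factory=list)
    couplings: list = field(default_factory=list)
    snp_effects: list = field(default_factory=list)
    maf: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path=None) -> str:
        def _clean(obj):
            if isinstance(obj, dict):
                return {str(k): _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, (np.floating, float)):
                return float(obj)
            if isinstance(obj, (np.integer, int)):
                return int(obj)
            return obj

        text = json.dumps(_clean(dataclasses.asdict(self)), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _simulate_metadata(cfg: SimConfig) -> pd.DataFrame:
    """Per-sample metadata emulating a Tanzanian-style (cohort A) and a
    Dutch-style (cohort B) population."""
    rng = _rng(cfg, 1)
    rows = []
    for cohort, n, age_med, age_sig, bmi_med, bmi_sig, p_female in (
        (cfg.cohort_a, cfg.n_a, 30.0, 0.41, 23.8, 0.18, 0.513),
        (cfg.cohort_b, cfg.n_b, 23.0, 0.16, 22.3, 0.12, 0.514),
    ):
        ids = [f"{cohort}S{i:04d}" for i in range(1, n + 1)]
        age = np.clip(np.exp(rng.normal(np.log(age_med), age_sig, n)), 18, 70)
        bmi = np.clip(np.exp(rng.normal(np.log(bmi_med), bmi_sig, n)), 15, 45)
        sex = np.where(rng.random(n) < p_female, "female", "male")
        df = pd.DataFrame({"sample_id": ids, "cohort": cohort, "age": np.round(age, 1),
                           "sex": sex, "bmi": np.round(bmi, 1)})
        if cohort == cfg.cohort_a:
            df["season"] = np.where(rng.random(n) < 0.5, "rainy", "dry")
            df["residency"] = np.where(rng.random(n) < 0.786, "urban", "rural")
            df["toilet"] = np.where(rng.random(n) < 0.236, "pit_latrine", "water_closet")
            df["cooking_fuel"] = np.where(rng.random(n) < 0.355, "smoky", "non_smoky")
            df["animal_exposure"] = np.where(rng.random(n) < 0.434, "yes", "no")
            df["antibiotics"] = rng.choice(
                ["none", "1-3_courses", ">3_courses"], size=n, p=[0.406, 0.507, 0.087]
            )
            df["water_source"] = np.where(rng.random(n) < 0.972, "tap", "well_or_river")
        else:
            df["season"] = rng.choice(["winter", "spring", "summer", "autumn"], size=n)
        rows.append(df)
    meta = pd.concat(rows, ignore_index=True).set_index("sample_id")
    return meta


def _plant_outliers(
    m: np.ndarray,
    study_ids: list,
    proteins: list,
    retained: list,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> list:
    """Move a random subset of study samples to +/- ``outlier_sd`` SD on both
    of the first two PCs (computed on the retained-protein z-scored data).
    Mutates ``m`` in place; returns the planted sample ids."""
    from .preprocess import pca_scores

    n = len(study_ids)
    n_out = int(round(cfg.outlier_frac * n))
    if n_out == 0:
        return []
    ret_cols = [proteins.index(p) for p in retained]
    df = pd.DataFrame(m[:, ret_cols], index=study_ids, columns=retained)
    pcs = pca_scores(df, center=True, scale=True)
    col_sd = df.std(ddof=1).to_numpy()
    col_sd[col_sd == 0] = 1.0
    z = ((df - df.mean()) / col_sd).to_numpy()
    u1 = pcs.scores["PC1"].to_numpy()
    u2 = pcs.scores["PC2"].to_numpy()
    sd1, sd2 = u1.std(ddof=1), u2.std(ddof=1)
    # loading vectors recovered by regression of z on the scores
    v1 = z.T @ u1 / (u1 @ u1)
    v2 = z.T @ u2 / (u2 @ u2)
    picks = rng.choice(n, size=n_out, replace=False)
    signs = rng.choice([-1.0, 1.0], size=(n_out, 2))
    out_ids = []
    for row, (s1, s2) in zip(picks, signs):
        target = (
            (s1 * cfg.outlier_sd * sd1 - u1[row]) * v1
            + (s2 * cfg.outlier_sd * sd2 - u2[row]) * v2
        )
        m[row, ret_cols] += target * col_sd
        out_ids.append(study_ids[row])
    return sorted(out_ids)


def _retained_proteins(cfg: SimConfig, proteins: list, is_a: bool) -> list:
    """Proteins whose configured censoring stays at or under the 25% rule."""
    return [
        p for p in proteins
        if (cfg.lod_quantile.get(p, (0.0, 0.0))[0 if is_a else 1]) <= 0.25
    ]


def simulate_cohorts(
    cfg: SimConfig, plant_outliers: bool = True
) -> tuple[NPXMatrix, NPXMatrix, pd.DataFrame, SimTruth]:
    """Generate the two-cohort NPX panels, metadata and ground truth.

    ``plant_outliers=False`` skips outlier injection so a caller that adds
    further structure (metabolome couplings) can plant them afterwards on
    the finished matrix; :func:`simulate_study` does exactly that.
    """
    proteins = _protein_ids(cfg.n_proteins)
    rng_base = _rng(cfg, 0)
    baseline = rng_base.uniform(2.0, 9.0, cfg.n_proteins)
    # per-protein variances from a scaled-inverse-chi-squared(d0, s0^2)
    sigma2 = cfg.noise_d0 * cfg.noise_s0_sq / rng_base.chisquare(cfg.noise_d0, cfg.n_proteins)
    sigma = np.sqrt(sigma2)

    if isinstance(cfg.technical_offset, dict):
        tech = np.array([cfg.technical_offset.get(p, 0.0) for p in proteins])
    else:
        tech = np.full(cfg.n_proteins, float(cfg.technical_offset))
    cohort_eff = np.array([cfg.cohort_effects.get(p, 0.0) for p in proteins])

    meta = _simulate_metadata(cfg)
    truth = SimTruth(
        cohort_effects=dict(cfg.cohort_effects),
        covariate_effects={k: (list(v[0]), float(v[1])) for k, v in cfg.covariate_effects.items()},
        technical_offset={p: float(t) for p, t in zip(proteins, tech)},
        plate_offsets={},
        sigma2={p: float(s) for p, s in zip(proteins, sigma2)},
        baseline={p: float(b) for p, b in zip(proteins, baseline)},
        lod={},
        lod_quantile={p: tuple(map(float, q)) for p, q in cfg.lod_quantile.items()},
        outliers={},
        couplings=list(cfg.couplings),
        snp_effects=list(cfg.snp_effects),
        seed=cfg.seed,
    )

    matrices = {}
    for k, (cohort, n, is_a) in enumerate(
        ((cfg.cohort_a, cfg.n_a, True), (cfg.cohort_b, cfg.n_b, False))
    ):
        rng = _rng(cfg, 10 + k)
        study_ids = [f"{cohort}S{i:04d}" for i in range(1, n + 1)]
        plates = [f"{cohort}P{j % cfg.plates_per_cohort + 1}" for j in range(n)]
        bridge_ids, bridge_plates = [], []
        for plate in range(1, cfg.plates_per_cohort + 1):
            for r in range(1, cfg.bridge_per_plate + 1):
                bridge_ids.append(f"{cohort}B{plate}{r}")
                bridge_plates.append(f"{cohort}P{plate}")

        plate_names = [f"{cohort}P{j}" for j in range(1, cfg.plates_per_cohort + 1)]
        plate_off = {
            pl: rng.normal(0.0, cfg.plate_sd, cfg.n_proteins) if cfg.plate_sd > 0
            else np.zeros(cfg.n_proteins)
            for pl in plate_names
        }
        truth.plate_offsets.update({f"{pl}": plate_off[pl].tolist() for pl in plate_names})

        base_row = baseline + (tech if is_a else 0.0)
        # study samples: biology + covariates + noise
        m = np.tile(base_row, (n, 1))
        if is_a:
            m += cohort_eff
        sub = meta.loc[study_ids]
        for factor, (targets, slope) in cfg.covariate_effects.items():
            cols = [proteins.index(p) for p in targets]
            if factor == "sex":
                x = (sub["sex"] == "female").to_numpy(dtype=float)
            else:
                x = sub[factor].to_numpy(dtype=float)
            m[:, cols] += slope * x[:, None]
        m += np.array([plate_off[pl] for pl in plates])
        m += rng.normal(0.0, 1.0, m.shape) * sigma

        # bridge samples: shared pool + technical terms + replicate noise
        bm = np.tile(base_row, (len(bridge_ids), 1))
        bm += np.array([plate_off[pl] for pl in bridge_plates])
        bm += rng.normal(0.0, cfg.bridge_noise_sd, bm.shape)

        # LOD from the configured per-protein censoring quantile
        lod = np.full(cfg.n_proteins, -np.inf)
        for j, p in enumerate(proteins):
            q = cfg.lod_quantile.get(p)
            if q is None:
                continue
            frac = q[0] if is_a else q[1]
            if frac > 0:
                lod[j] = np.quantile(m[:, j], frac)
        finite_min = m.min(axis=0)
        lod = np.where(np.isinf(lod), finite_min - 1.0, lod)
        truth.lod[cohort] = {p: float(v) for p, v in zip(proteins, lod)}

        # multivariate outliers planted in PC-score space; the displacement is
        # confined to proteins that survive the 25% LOD rule so the screen
        # operates on the coordinates that carry it
        out_ids: list = []
        if plant_outliers:
            out_ids = _plant_outliers(
                m, study_ids, proteins,
                _retained_proteins(cfg, proteins, is_a),
                cfg, _rng(cfg, 40 + k),
            )
        truth.outliers[cohort] = out_ids

        values = pd.DataFrame(
            np.vstack([m, bm]), index=study_ids + bridge_ids, columns=proteins
        )
        matrices[cohort] = NPXMatrix(
            values=values,
            lod=pd.Series(lod, index=proteins),
            plate_of=pd.Series(plates + bridge_plates, index=study_ids + bridge_ids),
            sample_type_of=pd.Series(
                ["study"] * n + ["bridge"] * len(bridge_ids), index=study_ids + bridge_ids
            ),
            cohort=cohort,
        )

    return matrices[cfg.cohort_a], matrices[cfg.cohort_b], meta, truth


def simulate_metabolome(
    cfg: SimConfig, a: NPXMatrix, meta: pd.DataFrame, truth: SimTruth
) -> tuple[MetaboliteTable, NPXMatrix]:
    """Cohort-A metabolite matrix with two latent diet clusters.

    Cluster 2 samples get ``metab_cluster_shift`` added to a subset of
    food-derived metabolites and ``cluster_protein_shift`` added to a
    protein subset of the (returned, updated) NPX matrix; configured
    (metabolite, protein) couplings add beta * z(metabolite) to proteins.
    """
    rng = _rng(cfg, 20)
    study = a.study_values()
    samples = study.index
    n = len(samples)
    mtb_ids = _metab_ids(cfg.n_metab)
    food = np.zeros(cfg.n_metab, dtype=bool)
    food[: cfg.n_food] = True

    base = rng.uniform(8.0, 14.0, cfg.n_metab)
    vals = base + rng.normal(0.0, cfg.metab_noise_sd, (n, cfg.n_metab))
    cluster = rng.choice([1, 2], size=n)
    shifted = mtb_ids[: min(cfg.n_shifted_metab, cfg.n_food)]
    shift_cols = [mtb_ids.index(m_) for m_ in shifted]
    vals[:, shift_cols] += cfg.metab_cluster_shift * (cluster == 2)[:, None]

    values = pd.DataFrame(vals, index=samples, columns=mtb_ids)
    classes = [CHEM_CLASSES[i % len(CHEM_CLASSES)] for i in range(cfg.n_metab)]
    annotation = pd.DataFrame(
        {
            "formula": [f"C{6 + i % 20}H{8 + i % 24}O{2 + i % 9}" for i in range(cfg.n_metab)],
            "putative_name": [f"synthetic metabolite {i + 1}" for i in range(cfg.n_metab)],
            "chem_class": classes,
            "food_derived": food,
        },
        index=mtb_ids,
    )

    out = a.copy()
    proteins = list(out.proteins)
    cluster_targets = [
        p for p in _protein_ids(cfg.n_proteins)[30 : 30 + cfg.n_cluster_proteins] if p in proteins
    ]
    cols = [proteins.index(p) for p in cluster_targets]
    arr = out.values.loc[samples].to_numpy()
    arr[:, cols] += cfg.cluster_protein_shift * (cluster == 2)[:, None]
    for mtb, prot, beta in cfg.couplings:
        x = values[mtb]
        zx = (x - x.mean()) / x.std(ddof=1)
        arr[:, proteins.index(prot)] += beta * zx.to_numpy()
    out.values.loc[samples] = arr

    truth.diet_cluster = {s: int(c) for s, c in zip(samples, cluster)}
    truth.shifted_metabolites = list(shifted)
    truth.cluster_shifted_proteins = cluster_targets
    return MetaboliteTable(values, annotation), out


def simulate_genotypes(
    cfg: SimConfig, a: NPXMatrix, truth: SimTruth
) -> tuple[GenotypeMatrix, NPXMatrix]:
    """Hardy-Weinberg SNP dosages for cohort-A study samples, with optional
    additive effects added to named proteins."""
    rng = _rng(cfg, 30)
    maf = np.asarray(cfg.maf[: cfg.n_snps], dtype=float)
    if len(maf) < cfg.n_snps:
        raise ConfigError("need one MAF per SNP")
    if (maf <= 0).any() or (maf > 0.5).any():
        raise ConfigError("MAF must lie in (0, 0.5]")
    samples = a.study_values().index
    n = len(samples)
    snps = [f"snp{i + 1}" for i in range(cfg.n_snps)]
    dosages = rng.binomial(2, maf, size=(n, cfg.n_snps)).astype(float)
    g = pd.DataFrame(dosages, index=samples, columns=snps)

    out = a.copy()
    for snp, prot, beta in cfg.snp_effects:
        out.values.loc[samples, prot] = out.values.loc[samples, prot] + beta * g[snp].to_numpy()
    truth.maf = {s: float(f) for s, f in zip(snps, maf)}
    truth.snp_effects = list(cfg.snp_effects)
    return GenotypeMatrix(g), out


def simulate_study(cfg: SimConfig):
    """Full bundle: NPX cohorts (with metabolite couplings applied), metadata,
    metabolome, genotypes and truth.

    Outliers are planted last, on the finished matrices, so they are extreme
    relative to every injected structure (including the diet-cluster protein
    shift) and the PC screen sees them on its leading components.
    """
    a, b, meta, truth = simulate_cohorts(cfg, plant_outliers=False)
    metab, a = simulate_metabolome(cfg, a, meta, truth)
    geno, a = simulate_genotypes(cfg, a, truth)
    proteins = _protein_ids(cfg.n_proteins)
    for k, (m, is_a) in enumerate(((a, True), (b, False))):
        study_ids = list(m.study_values().index)
        arr = m.values.loc[study_ids].to_numpy()
        ids = _plant_outliers(
            arr, study_ids, proteins,
            _retained_proteins(cfg, proteins, is_a),
            cfg, _rng(cfg, 40 + k),
        )
        m.values.loc[study_ids] = arr
        truth.outliers[m.cohort] = ids
    return a, b, meta, metab, geno, truth
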