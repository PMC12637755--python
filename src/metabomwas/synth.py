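"""Synthetic multiethnic brain-metabolomics cohorts with planted ground truth.

The generator emulates the joint structure of a multi-site postmortem study:
ethnoracial groups unevenly distributed across study sites (including sites
contributing zero samples of a group), covariate imbalance (age, APOE4
frequency) between groups, per-site location/scale measurement artifacts on
the log2 scale, per-sample multiplicative dilution, sporadic extreme values,
and 10-35% missing cells.  The neuropathological outcome (Braak stage) is
drawn from a cumulative-logit (proportional-odds) model whose metabolite
slopes differ by ethnoracial group for a designated set of interaction
metabolites.  The interaction metabolites form a co-regulated pathway
module: they share a latent pathology factor (pairwise correlation
``interaction_correlation``), and the outcome conditions on that shared
factor with a group-specific slope.  This mirrors how coordinated lipid
remodeling behaves in real brain cohorts and makes the configured slope
(log-odds per SD of abundance) approximately equal to each member
metabolite's *marginal* slope — the quantity the per-metabolite screen
estimates.  (Conditioning the outcome jointly on many independent
metabolites instead would both attenuate every marginal slope and
invalidate the single-metabolite proportional-odds model.)  Every planted
quantity is recorded in a :class:`SyntheticTruth` so downstream stages can
be tested for recovery.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from metabomwas.containers import AbundanceMatrix

# Default cohort composition: three ethnoracial groups over four study sites,
# with two structural zeros (one site contributes no Hispanic Americans, one
# no non-Hispanic Whites), mirroring the published multiethnic DLPFC cohort.
DEFAULT_GROUPS = ("NHAA", "HA", "NHW")
DEFAULT_SITES = ("Emory", "Mayo", "MtSinai", "RADC")
DEFAULT_N_PER_GROUP = {"NHAA": 220, "HA": 148, "NHW": 177}
DEFAULT_SITE_ASSIGNMENT = {
    "NHAA": (40 / 220, 29 / 220, 28 / 220, 123 / 220),
    "HA": (0.0, 73 / 148, 27 / 148, 48 / 148),
    "NHW": (37 / 177, 15 / 177, 0.0, 125 / 177),
}
# APOE4 allele-count frequencies and female fraction per group.
DEFAULT_APOE4_PROBS = {
    "NHAA": (106 / 220, 91 / 220, 23 / 220),
    "HA": (104 / 148, 35 / 148, 9 / 148),
    "NHW": (126 / 177, 42 / 177, 9 / 177),
}
DEFAULT_FEMALE_FRAC = {"NHAA": 141 / 220, "HA": 88 / 148, "NHW": 127 / 177}
# Age at death: the NHW group skews older (median ~90 vs ~81-82 y).
DEFAULT_AGE_MEAN = {"NHAA": 82.0, "HA": 80.0, "NHW": 88.0}
DEFAULT_AGE_SD = 9.0

# Super-pathway composition of a typical untargeted brain metabolomics panel
# (fractions of the analysis-ready metabolite set).
SUPER_PATHWAY_FRACTIONS = {
    "Lipid": 0.455,
    "Amino Acid": 0.192,
    "Nucleotide": 0.065,
    "Carbohydrate": 0.050,
    "Cofactors and Vitamins": 0.043,
    "Peptide": 0.043,
    "Xenobiotics": 0.036,
    "Energy": 0.011,
    "Unknown": 0.105,
}
SUB_PATHWAYS = {
    "Lipid": (
        "Sphingomyelins",
        "Ceramides",
        "Dihydroceramides",
        "Hexosylceramides (HCER)",
        "Phosphatidylserine (PS)",
        "Phosphatidylcholine (PC)",
        "Long Chain Fatty Acid",
        "Lysophospholipid",
    ),
    "Amino Acid": (
        "Tryptophan Metabolism",
        "Urea cycle; Arginine and Proline Metabolism",
        "Glutamate Metabolism",
        "Leucine, Isoleucine and Valine Metabolism",
    ),
    "Nucleotide": ("Purine Metabolism", "Pyrimidine Metabolism"),
    "Carbohydrate": ("Glycogen Metabolism", "Glycolysis and Gluconeogenesis"),
    "Cofactors and Vitamins": ("Pantothenate and CoA Metabolism", "Nicotinate and Nicotinamide Metabolism"),
    "Peptide": ("Dipeptides", "Gamma-glutamyl Amino Acid"),
    "Xenobiotics": ("Food Component/Plant", "Chemical"),
    "Energy": ("TCA Cycle", "Oxidative Phosphorylation"),
    "Unknown": ("Unknown",),
}
# Sub-pathways favoured when picking interaction metabolites, so that the
# end-to-end demo reproduces a sphingolipid/dipeptide/energy-flavoured hit list.
INTERACTION_SUB_PATHWAYS = ("Sphingomyelins", "Ceramides", "Dipeptides", "TCA Cycle")


@dataclass
class SynthConfig:
    """Configuration of the synthetic cohort generator.

    Defaults describe the "stated world": group sizes 220/148/177 over four
    sites with the published imbalance, 900 metabolites of which 20 carry a
    group-specific Braak slope (log-odds per SD of abundance: HA 0.8,
    NHW 0.3, NHAA 0.0), site location shifts of SD 0.25 log2 units, site
    scale factors with SD 0.15 on the natural-log scale, 10% missing cells,
    per-sample log2 dilution SD 0.2, and a 5e-4 extreme-value rate.
    """

    n_per_group: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_N_PER_GROUP))
    sites: Sequence[str] = DEFAULT_SITES
    site_assignment: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {g: tuple(p) for g, p in DEFAULT_SITE_ASSIGNMENT.items()}
    )
    n_metabolites: int = 900
    n_interaction_metabolites: int = 20
    slope_by_group: Mapping[str, float] = field(
        default_factory=lambda: {"HA": 0.8, "NHW": 0.3, "NHAA": 0.0}
    )
    interaction_correlation: float = 0.8
    covariate_effect_sizes: Mapping[str, float] = field(
        default_factory=lambda: {"sex": 0.2, "age_at_death": 0.03, "pmi": 0.0, "apoe4_count": 0.5}
    )
    site_shift_sd: float = 0.25
    site_scale_sd: float = 0.15
    group_effect_sd: float = 0.2
    covariate_abundance_sd: float = 0.05
    missing_frac: float = 0.10
    missing_mechanism: str = "uniform"
    dilution_sd: float = 0.2
    outlier_rate: float = 5e-4
    n_braak_levels: int = 6
    annotate_interactions: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not self.n_per_group or any(n <= 0 for n in self.n_per_group.values()):
            raise ValueError("all group counts must be positive")
        if self.n_metabolites <= 0 or self.n_braak_levels < 2:
            raise ValueError("n_metabolites and n_braak_levels must be positive")
        if not 0 <= self.n_interaction_metabolites <= self.n_metabolites:
            raise ValueError("n_interaction_metabolites out of range")
        if not 0 <= self.interaction_correlation < 1:
            raise ValueError("interaction_correlation must be in [0, 1)")
        if not 0 <= self.missing_frac < 1:
            raise ValueError("missing_frac must be in [0, 1)")
        if self.missing_mechanism not in ("uniform", "intensity_dependent"):
            raise ValueError(f"unknown missing mechanism {self.missing_mechanism!r}")
        for g in self.n_per_group:
            if g not in self.site_assignment:
                raise ValueError(f"site_assignment lacks a row for group {g!r}")
            probs = np.asarray(self.site_assignment[g], dtype=float)
            if probs.shape != (len(self.sites),):
                raise ValueError(f"site_assignment row for {g!r} has wrong length")
            if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-8:
                raise ValueError(f"site_assignment row for {g!r} must sum to 1")
            if g not in self.slope_by_group:
                raise ValueError(f"slope_by_group lacks group {g!r}")

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.n_per_group)

    @property
    def n_samples(self) -> int:
        return int(sum(self.n_per_group.values()))


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort (recovery-test oracle)."""

    true_site_shift: pd.DataFrame  # site x metabolite additive log2 shifts
    true_site_scale: pd.DataFrame  # site x metabolite multiplicative noise scales
    interaction_metabolites: list[str]
    true_slopes: pd.DataFrame  # group x metabolite outcome slopes
    group_offsets: pd.DataFrame  # group x metabolite log2 abundance offsets
    dilution: pd.Series  # per-sample multiplicative dilution factor (> 0)
    missing_mask: pd.DataFrame  # True where a cell was removed
    outlier_mask: pd.DataFrame  # True where a cell was replaced by an extreme
    braak_thresholds: np.ndarray

    def __post_init__(self) -> None:
        if (self.dilution <= 0).any():
            raise ValueError("dilution factors must be positive")
        missing = set(self.interaction_metabolites) - set(self.true_slopes.columns)
        if missing:
            raise ValueError(f"interaction metabolites not in slope matrix: {sorted(missing)}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_site_shift": self.true_site_shift.to_dict(orient="index"),
            "true_site_scale": self.true_site_scale.to_dict(orient="index"),
            "interaction_metabolites": list(self.interaction_metabolites),
            "true_slopes": self.true_slopes.to_dict(orient="index"),
            "group_offsets": self.group_offsets.to_dict(orient="index"),
            "dilution": self.dilution.to_dict(),
            "missing_cells": [
                [str(i), str(j)] for i, j in zip(*np.nonzero(self.missing_mask.to_numpy()))
            ],
            "braak_thresholds": self.braak_thresholds.tolist(),
        }
        Path(path).write_text(json.dumps(payload))


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """One global seed fans out into deterministic per-stage child generators."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _sample_metadata(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for group, n in config.n_per_group.items():
        site_probs = np.asarray(config.site_assignment[group], dtype=float)
        sites = rng.choice(list(config.sites), size=n, p=site_probs)
        apoe_probs = DEFAULT_APOE4_PROBS.get(group)
        if apoe_probs is None:
            apoe_probs = (0.6, 0.33, 0.07)
        apoe = rng.choice([0, 1, 2], size=n, p=np.asarray(apoe_probs) / np.sum(apoe_probs))
        female = rng.random(n) < DEFAULT_FEMALE_FRAC.get(group, 0.6)
        age = np.clip(rng.normal(DEFAULT_AGE_MEAN.get(group, 82.0), DEFAULT_AGE_SD, size=n), 55, 105)
        pmi = np.exp(rng.normal(np.log(8.0), 0.55, size=n))
        for i in range(n):
            rows.append(
                {
                    "group": group,
                    "site": sites[i],
                    "sex": "F" if female[i] else "M",
                    "age_at_death": round(float(age[i]), 1),
                    "pmi": round(float(pmi[i]), 2),
                    "apoe4_count": int(apoe[i]),
                    "region": "DLPFC",
                }
            )
    meta = pd.DataFrame(rows)
    meta.index = pd.Index([f"S{i + 1:04d}" for i in range(len(meta))], name="sample_id")
    return meta


def _annotation(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    supers = list(SUPER_PATHWAY_FRACTIONS)
    fracs = np.asarray([SUPER_PATHWAY_FRACTIONS[s] for s in supers], dtype=float)
    counts = np.floor(fracs / fracs.sum() * config.n_metabolites).astype(int)
    counts[-1] += config.n_metabolites - counts.sum()  # remainder to "Unknown"
    super_labels: list[str] = []
    sub_labels: list[str] = []
    for s, c in zip(supers, counts):
        subs = SUB_PATHWAYS[s]
        super_labels.extend([s] * c)
        sub_labels.extend([subs[i % len(subs)] for i in range(c)])
    met_ids = [f"M{i + 1:04d}" for i in range(config.n_metabolites)]
    order = rng.permutation(config.n_metabolites)
    return pd.DataFrame(
        {
            "super_pathway": np.asarray(super_labels)[order],
            "sub_pathway": np.asarray(sub_labels)[order],
        },
        index=pd.Index(met_ids, name="metabolite_id"),
    )


def _pick_interaction_metabolites(
    config: SynthConfig, annotation: pd.DataFrame, rng: np.random.Generator
) -> list[str]:
    k = config.n_interaction_metabolites
    if k == 0:
        return []
    ids = annotation.index.to_numpy()
    if config.annotate_interactions:
        favoured = annotation.index[annotation["sub_pathway"].isin(INTERACTION_SUB_PATHWAYS)]
        n_fav = min(len(favoured), int(round(0.6 * k)))
        chosen = list(rng.choice(favoured.to_numpy(), size=n_fav, replace=False))
        rest = np.setdiff1d(ids, np.asarray(chosen))
        chosen += list(rng.choice(rest, size=k - n_fav, replace=False))
        return sorted(chosen)
    return sorted(rng.choice(ids, size=k, replace=False))


def _braak_from_latent(eta: np.ndarray, n_levels: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sample an ordinal outcome from a proportional-odds model.

    Thresholds are equally spaced over ±1.4 total latent SDs around the mean
    linear predictor so that every level is populated at realistic n.
    """
    sd_tot = float(np.sqrt(np.var(eta) + np.pi**2 / 3))
    center = float(np.mean(eta))
    thresholds = np.linspace(center - 1.4 * sd_tot, center + 1.4 * sd_tot, n_levels - 1)
    latent = eta + rng.logistic(size=eta.shape)
    y = np.searchsorted(thresholds, latent) + 1
    return y.astype(int), thresholds


def generate_cohort(
    config: SynthConfig,
) -> tuple[AbundanceMatrix, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate a synthetic cohort.

    Returns ``(abundance, metadata, annotation, truth)``.  Abundance is
    simulated on the log2 scale as covariate effects + per-group offsets +
    per-site additive shift + per-site scale x unit noise, exponentiated,
    multiplied by a per-sample dilution factor, contaminated with extreme
    cells, and holed according to ``missing_frac``.  Braak stage is sampled
    from a proportional-odds model whose metabolite slopes differ by group
    exactly for the planted interaction metabolites.
    """
    from metabomwas.preprocess import derive_diagnosis

    config.validate()
    rng_meta, rng_ab, rng_out, rng_miss, rng_outlier, rng_annot = _child_rngs(config.seed, 6)

    metadata = _sample_metadata(config, rng_meta)
    annotation = _annotation(config, rng_annot)
    met_ids = annotation.index
    n, m = len(metadata), config.n_metabolites
    groups = list(config.groups)
    sites = list(config.sites)

    # --- biological log2 abundance -------------------------------------
    mu = rng_ab.uniform(16.0, 24.0, size=m)
    beta_sex = rng_ab.normal(0.0, config.covariate_abundance_sd, size=m)
    beta_age = rng_ab.normal(0.0, config.covariate_abundance_sd, size=m)
    group_offsets = rng_ab.normal(0.0, config.group_effect_sd, size=(len(groups), m))
    group_offsets -= group_offsets.mean(axis=0, keepdims=True)  # identifiable contrasts
    eps = rng_ab.normal(size=(n, m))

    sex_z = (metadata["sex"] == "F").to_numpy(float) - 0.5
    age_z = (metadata["age_at_death"] - metadata["age_at_death"].mean()).to_numpy() / 10.0
    g_idx = np.asarray([groups.index(g) for g in metadata["group"]])
    s_idx = np.asarray([sites.index(s) for s in metadata["site"]])

    bio = (
        mu[None, :]
        + np.outer(sex_z, beta_sex)
        + np.outer(age_z, beta_age)
        + group_offsets[g_idx]
        + eps
    )

    # --- ordinal outcome (cumulative-logit with group-specific slopes) ---
    # Interaction metabolites are a co-regulated module: a shared latent
    # pathology factor replaces part of their independent noise, and the
    # outcome conditions on that factor with the group-specific slope.
    interaction = _pick_interaction_metabolites(config, annotation, rng_out)
    slopes = np.zeros((len(groups), m))
    col_of = {mid: j for j, mid in enumerate(met_ids)}
    inter_cols = [col_of[mid] for mid in interaction]
    for mid in interaction:
        for gi, g in enumerate(groups):
            slopes[gi, col_of[mid]] = float(config.slope_by_group[g])

    factor = rng_out.normal(size=n)
    if inter_cols:
        rho = config.interaction_correlation
        eps[:, inter_cols] = np.sqrt(rho) * factor[:, None] + np.sqrt(1 - rho) * eps[:, inter_cols]
        bio = (
            mu[None, :]
            + np.outer(sex_z, beta_sex)
            + np.outer(age_z, beta_age)
            + group_offsets[g_idx]
            + eps
        )

    # The configured slope is the marginal log-odds per SD of a member
    # metabolite.  A module member carries the factor with loading sqrt(rho),
    # and conditioning on one member leaves latent factor variance
    # s^2 (1 - rho) unexplained, which attenuates logistic coefficients by
    # sqrt(L / (L + s^2 (1 - rho))) with L = pi^2/3.  Solving
    #   beta = s sqrt(rho) sqrt(L / (L + s^2 (1 - rho)))
    # for the factor slope s plants the configured value as the marginal one.
    L = np.pi**2 / 3
    rho = config.interaction_correlation
    group_slope = np.empty(len(groups))
    for gi, g in enumerate(groups):
        beta = float(config.slope_by_group[g])
        denom = rho * L - beta**2 * (1 - rho)
        if denom <= 0:
            raise ValueError(
                f"slope {beta} for group {g!r} is unattainable as a marginal slope "
                f"at interaction_correlation={rho}"
            )
        group_slope[gi] = beta * np.sqrt(L / denom)
    es = config.covariate_effect_sizes
    eta = (
        float(es.get("sex", 0.0)) * sex_z * 2.0  # sex coded -1/+1 internally
        + float(es.get("age_at_death", 0.0)) * (metadata["age_at_death"] - metadata["age_at_death"].mean()).to_numpy()
        + float(es.get("pmi", 0.0)) * (metadata["pmi"] - metadata["pmi"].mean()).to_numpy()
        + float(es.get("apoe4_count", 0.0)) * metadata["apoe4_count"].to_numpy(float)
        + (group_slope[g_idx] * factor if inter_cols else 0.0)
    )
    braak, thresholds = _braak_from_latent(eta, config.n_braak_levels, rng_out)
    metadata["braak"] = braak

    # CERAD tracks Braak severity with noise; CERAD 1 = most severe plaques.
    braak_z = (braak - braak.mean()) / braak.std()
    cerad_latent = 0.8 * braak_z + rng_out.normal(0.0, 0.6, size=n)
    cerad_cuts = np.quantile(cerad_latent, [0.25, 0.5, 0.75])
    metadata["cerad"] = 4 - np.searchsorted(cerad_cuts, cerad_latent)
    # NIA-Reagan likelihood from Braak + CERAD (1 = high likelihood .. 4 = none)
    reagan = np.full(n, 3)
    reagan[(braak >= 5) & (metadata["cerad"] <= 2)] = 1
    reagan[(braak >= 3) & (metadata["cerad"] <= 3) & (reagan == 3)] = 2
    reagan[(braak <= 2) & (metadata["cerad"] == 4)] = 4
    metadata["reagan"] = reagan
    metadata["diagnosis"] = derive_diagnosis(metadata["braak"], metadata["cerad"]).to_numpy()

    # --- measurement layer: site artifacts, dilution, outliers, holes ----
    site_shift = rng_ab.normal(0.0, config.site_shift_sd, size=(len(sites), m))
    site_scale = np.exp(rng_ab.normal(0.0, config.site_scale_sd, size=(len(sites), m)))
    observed_log2 = bio - eps + site_shift[s_idx] + site_scale[s_idx] * eps
    dilution = 2.0 ** rng_ab.normal(0.0, config.dilution_sd, size=n)
    raw = 2.0**observed_log2 * dilution[:, None]

    outlier_mask = rng_outlier.random(size=(n, m)) < config.outlier_rate
    if outlier_mask.any():
        sign = rng_outlier.choice([-1.0, 1.0], size=int(outlier_mask.sum()))
        raw[outlier_mask] = raw[outlier_mask] * 2.0 ** (8.0 * sign)

    raw_df = pd.DataFrame(raw, index=metadata.index, columns=met_ids)
    matrix, missing_mask = inject_missingness(
        raw_df, config.missing_frac, config.missing_mechanism, rng=rng_miss
    )

    truth = SyntheticTruth(
        true_site_shift=pd.DataFrame(site_shift, index=sites, columns=met_ids),
        true_site_scale=pd.DataFrame(site_scale, index=sites, columns=met_ids),
        interaction_metabolites=list(interaction),
        true_slopes=pd.DataFrame(slopes, index=groups, columns=met_ids),
        group_offsets=pd.DataFrame(group_offsets, index=groups, columns=met_ids),
        dilution=pd.Series(dilution, index=metadata.index, name="dilution"),
        missing_mask=missing_mask,
        outlier_mask=pd.DataFrame(outlier_mask, index=metadata.index, columns=met_ids),
        braak_thresholds=thresholds,
    )
    return AbundanceMatrix(matrix, scale_tag="raw"), metadata, annotation, truth


def inject_missingness(
    matrix: pd.DataFrame,
    frac: float,
    mechanism: str = "uniform",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hole a matrix at a target missing fraction.

    ``"uniform"`` removes cells independently with probability ``frac``;
    ``"intensity_dependent"`` preferentially removes low-abundance cells
    (probability proportional to the within-metabolite reverse rank) while
    keeping the expected overall fraction at ``frac``.  Returns the holed
    matrix (NaN cells) and the boolean mask of removed cells.
    """
    if not 0 <= frac < 1:
        raise ValueError("frac must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    values = matrix.to_numpy(dtype=float)
    if frac == 0:
        mask = np.zeros_like(values, dtype=bool)
    elif mechanism == "uniform":
        mask = rng.random(values.shape) < frac
    elif mechanism == "intensity_dependent":
        n = values.shape[0]
        ranks = np.argsort(np.argsort(values, axis=0), axis=0)  # 0 = lowest
        prob = 2.0 * frac * (n - ranks) / (n + 1)
        mask = rng.random(values.shape) < np.clip(prob, 0.0, 1.0)
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    holed = values.copy()
    holed[mask] = np.nan
    all_gone = np.isnan(holed).all(axis=0)
    if all_gone.any():
        warnings.warn(f"{int(all_gone.sum())} metabolites are fully missing after holing")
    return (
        pd.DataFrame(holed, index=matrix.index, columns=matrix.columns),
        pd.DataFrame(mask, index=matrix.index, columns=matrix.columns),
    )
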