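"""QC chain from raw metabolite intensities to an analysis-ready matrix.

Stage order (fixed by :func:`preprocess_pipeline`):

1. remove metabolites with more than ``max_missing_frac`` missing values,
2. probabilistic quotient normalization (PQN) against the metabolite-wise
   median reference to correct per-sample dilution,
3. log2 transform,
4. k-nearest-neighbour imputation of the remaining holes,
5. local-outlier-factor (LOF) sample-outlier removal,
6. extreme-value flagging at ``|z| > |Phi^-1(alpha / n)|`` per metabolite
   (a Bonferroni-style per-sample correction of a two-tailed ``2*alpha``
   band), followed by
7. a second kNN imputation round for the newly masked cells.

Cohort harmonization (brain-region restriction, minimum ethnoracial group
size, complete-covariate requirement) and the Braak/CERAD-based case-control
diagnosis rule also live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.impute import KNNImputer
from sklearn.neighbors import LocalOutlierFactor

from metabomwas.containers import AbundanceMatrix, COVARIATE_COLUMNS


@dataclass
class PreprocessConfig:
    max_missing_frac: float = 0.25
    knn_k: int = 10
    lof_n_neighbors: int = 20
    lof_threshold: float = 1.5
    outlier_alpha: float = 0.0125
    min_group_size: int = 15
    region_keep: str = "DLPFC"

    def __post_init__(self) -> None:
        if not 0 < self.max_missing_frac < 1:
            raise ValueError("max_missing_frac must be in (0, 1)")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


def derive_diagnosis(braak, cerad) -> pd.Series:
    """Binary neuropathological AD diagnosis from Braak stage and CERAD score.

    Case: Braak >= 4 and CERAD <= 2.  Control: Braak <= 3 and CERAD >= 3.
    Samples meeting neither rule are "other"; missing inputs give "missing".
    """
    braak = pd.Series(braak).astype(float)
    cerad = pd.Series(cerad, index=braak.index).astype(float)
    for name, vals, lo, hi in (("braak", braak, 1, 6), ("cerad", cerad, 1, 4)):
        obs = vals.dropna()
        if len(obs) and not obs.between(lo, hi).all():
            raise ValueError(f"{name} values out of range [{lo}, {hi}]")
    out = pd.Series("other", index=braak.index, dtype=object)
    out[(braak >= 4) & (cerad <= 2)] = "case"
    out[(braak <= 3) & (cerad >= 3)] = "control"
    out[braak.isna() | cerad.isna()] = "missing"
    return out


def harmonize_cohort(
    metadata: pd.DataFrame,
    region_keep: str = "DLPFC",
    min_group_size: int = 15,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the cohort inclusion rules; return (retained metadata, exclusion log).

    Rules are applied in order — brain region, then missing/undersized
    ethnoracial group, then incomplete covariates — and the log records the
    first matching reason per excluded sample.
    """
    log: list[tuple[str, str]] = []
    meta = metadata.copy()

    if "region" in meta:
        bad = meta.index[meta["region"] != region_keep]
        log += [(s, "region") for s in bad]
        meta = meta.drop(index=bad)

    missing_group = meta.index[meta["group"].isna()]
    log += [(s, "group_missing") for s in missing_group]
    meta = meta.drop(index=missing_group)
    sizes = meta["group"].value_counts()
    small = sizes.index[sizes < min_group_size]
    bad = meta.index[meta["group"].isin(small)]
    log += [(s, "small_group") for s in bad]
    meta = meta.drop(index=bad)

    covar_cols = [c for c in COVARIATE_COLUMNS if c in meta]
    bad = meta.index[meta[covar_cols].isna().any(axis=1)]
    log += [(s, "covariate") for s in bad]
    meta = meta.drop(index=bad)

    if meta.empty:
        raise ValueError("no samples survive cohort harmonization")
    log_df = pd.DataFrame(log, columns=["sample_id", "reason"]).set_index("sample_id")
    return meta, log_df


def filter_missing(matrix: AbundanceMatrix, max_missing_frac: float = 0.25) -> AbundanceMatrix:
    """Drop metabolites with strictly more than ``max_missing_frac`` missing values."""
    frac = matrix.mask.mean(axis=0)
    keep = frac.index[frac <= max_missing_frac]
    return matrix.subset(metabolites=keep)


def pqn_normalize(matrix: AbundanceMatrix) -> tuple[AbundanceMatrix, pd.Series]:
    """Probabilistic quotient normalization against the median reference.

    Each sample is divided by the median over metabolites of its quotient to
    the reference spectrum (the metabolite-wise median across samples).
    Missing cells are ignored in the quotients and preserved in the output.
    Returns the normalized matrix and the estimated per-sample quotients
    (proportional to each sample's dilution factor).
    """
    if matrix.scale_tag != "raw":
        raise ValueError("PQN expects a raw (pre-log) matrix")
    values = matrix.values.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        reference = np.nanmedian(values, axis=0)
        quotients = np.nanmedian(values / reference[None, :], axis=1)
    if np.isnan(quotients).any():
        bad = matrix.sample_ids[np.isnan(quotients)].tolist()
        raise ValueError(f"samples share no observed metabolites with the reference: {bad}")
    normalized = values / quotients[:, None]
    out = pd.DataFrame(normalized, index=matrix.sample_ids, columns=matrix.metabolite_ids)
    return (
        AbundanceMatrix(out, scale_tag="normalized"),
        pd.Series(quotients, index=matrix.sample_ids, name="pqn_quotient"),
    )


def log2_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    if matrix.scale_tag == "log2":
        raise ValueError("matrix is already on the log2 scale")
    values = matrix.values.to_numpy(dtype=float)
    if np.nanmin(values) <= 0:
        raise ValueError("log2 transform requires strictly positive observed values")
    out = pd.DataFrame(np.log2(values), index=matrix.sample_ids, columns=matrix.metabolite_ids)
    return AbundanceMatrix(out, scale_tag="log2")


def knn_impute(matrix: AbundanceMatrix, k: int = 10) -> AbundanceMatrix:
    """Impute missing cells from the k nearest samples.

    Distances are Euclidean over mutually observed metabolites, rescaled by
    the number of shared features; the imputed value is the unweighted mean
    of the neighbours' observed values.  Observed cells are never altered.
    """
    if matrix.scale_tag != "log2":
        raise ValueError("kNN imputation expects a log2 matrix")
    if matrix.is_complete():
        return matrix
    if matrix.mask.all(axis=0).any():
        bad = matrix.metabolite_ids[matrix.mask.all(axis=0)].tolist()
        raise ValueError(f"metabolites with no observed values cannot be imputed: {bad}")
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(matrix.values.to_numpy(dtype=float))
    out = pd.DataFrame(filled, index=matrix.sample_ids, columns=matrix.metabolite_ids)
    return AbundanceMatrix(out, scale_tag="log2")


def detect_sample_outliers(
    matrix: AbundanceMatrix, n_neighbors: int = 20, threshold: float = 1.5
) -> pd.Index:
    """Flag samples whose local-outlier-factor score exceeds ``threshold``.

    The LOF score is the ratio of the average local reachability density of a
    sample's neighbours to its own; values well above 1 mark samples sitting
    in regions much sparser than their neighbourhood.
    """
    if not matrix.is_complete():
        raise ValueError("LOF requires a complete matrix")
    if n_neighbors >= matrix.n_samples:
        raise ValueError("n_neighbors must be smaller than the number of samples")
    lof = LocalOutlierFactor(n_neighbors=n_neighbors)
    lof.fit(matrix.values.to_numpy(dtype=float))
    scores = -lof.negative_outlier_factor_
    return matrix.sample_ids[scores > threshold]


def flag_extreme_values(
    matrix: AbundanceMatrix, alpha: float = 0.0125
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Mask per-metabolite extreme values at the ``|z| > |Phi^-1(alpha/n)|`` cutoff.

    Per metabolite, values are centred and scaled (mean 0, SD 1); a cell is
    set to missing when its |z| exceeds ``q = |Phi^-1(alpha / n)|`` with
    ``n`` the number of samples — a two-tailed ``2*alpha`` band with a
    Bonferroni-style division by the sample count.  Zero-variance
    metabolites are skipped with a warning.  Returns the masked matrix and
    the boolean flag mask; the pipeline driver re-imputes the new holes.
    """
    if not matrix.is_complete():
        raise ValueError("extreme-value flagging expects a complete matrix")
    if matrix.scale_tag != "log2":
        raise ValueError("extreme-value flagging expects a log2 matrix")
    values = matrix.values.to_numpy(dtype=float)
    n = values.shape[0]
    q = extreme_value_cutoff(alpha, n)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(f"skipping {int(degenerate.sum())} zero-variance metabolites")
        sd = np.where(degenerate, 1.0, sd)
    z = (values - mean[None, :]) / sd[None, :]
    flags = np.abs(z) > q
    flags[:, degenerate] = False
    masked = values.copy()
    masked[flags] = np.nan
    out = pd.DataFrame(masked, index=matrix.sample_ids, columns=matrix.metabolite_ids)
    flag_df = pd.DataFrame(flags, index=matrix.sample_ids, columns=matrix.metabolite_ids)
    return AbundanceMatrix(out, scale_tag="log2"), flag_df


def extreme_value_cutoff(alpha: float, n: int) -> float:
    """The z cutoff ``q = |Phi^-1(alpha / n)|`` for ``n`` samples."""
    if n < 1 or not 0 < alpha < 0.5:
        raise ValueError("need n >= 1 and 0 < alpha < 0.5")
    return float(abs(norm.ppf(alpha / n)))


def preprocess_pipeline(
    matrix: AbundanceMatrix,
    config: PreprocessConfig | None = None,
) -> tuple[AbundanceMatrix, dict]:
    """Run the full QC chain in its fixed order; return matrix + QC report."""
    cfg = config or PreprocessConfig()
    report: dict = {"stages": []}

    def note(stage: str, mat: AbundanceMatrix, **extra) -> None:
        report["stages"].append(
            {"stage": stage, "n_samples": mat.n_samples, "n_metabolites": mat.n_metabolites, **extra}
        )

    note("input", matrix, n_missing=int(matrix.mask.to_numpy().sum()))
    n_before = matrix.n_metabolites
    matrix = filter_missing(matrix, cfg.max_missing_frac)
    note("filter_missing", matrix, n_removed=n_before - matrix.n_metabolites)

    matrix, quotients = pqn_normalize(matrix)
    note("pqn", matrix, quotient_median=float(quotients.median()))

    matrix = log2_transform(matrix)
    note("log2", matrix)

    matrix = knn_impute(matrix, cfg.knn_k)
    note("knn_impute", matrix)

    outliers = detect_sample_outliers(matrix, cfg.lof_n_neighbors, cfg.lof_threshold)
    matrix = matrix.subset(samples=matrix.sample_ids.difference(outliers, sort=False))
    note("lof", matrix, outliers=list(map(str, outliers)))

    matrix, flags = flag_extreme_values(matrix, cfg.outlier_alpha)
    note("flag_extremes", matrix, n_flagged=int(flags.to_numpy().sum()))

    matrix = knn_impute(matrix, cfg.knn_k)
    note("knn_impute_2", matrix)
    report["pqn_quotients"] = {str(k): float(v) for k, v in quotients.items()}
    return matrix, report
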