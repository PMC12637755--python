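"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Metadata columns required by the association screen.
COVARIATE_COLUMNS = ("sex", "age_at_death", "pmi", "apoe4_count")

#: Ordinal / binary outcomes the screen understands.
OUTCOME_COLUMNS = ("braak", "cerad", "reagan", "diagnosis")

OUTCOME_LEVELS = {"braak": (1, 6), "cerad": (1, 4), "reagan": (1, 4)}


@dataclass
class AbundanceMatrix:
    """Samples x metabolites abundance matrix with an explicit missing mask.

    ``values`` is a :class:`pandas.DataFrame` indexed by sample id with
    metabolite ids as columns; missing cells are ``NaN``.  ``scale_tag``
    tracks where the matrix sits in the preprocessing chain:
    ``"raw"`` (positive intensities), ``"normalized"`` (PQN-scaled, still
    positive), or ``"log2"``.
    """

    values: pd.DataFrame
    scale_tag: str = "raw"

    _SCALES = ("raw", "normalized", "log2")

    def __post_init__(self) -> None:
        if self.scale_tag not in self._SCALES:
            raise ValueError(f"scale_tag must be one of {self._SCALES}, got {self.scale_tag!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate metabolite ids")
        if self.scale_tag in ("raw", "normalized"):
            vals = self.values.to_numpy(dtype=float)
            observed = ~np.isnan(vals)
            if observed.any() and np.nanmin(vals) <= 0:
                raise ValueError("raw/normalized intensities must be strictly positive where observed")

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missing-value indicator, True where the cell is missing."""
        return self.values.isna()

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def metabolite_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def is_complete(self) -> bool:
        return not bool(self.values.isna().to_numpy().any())

    def with_values(self, values: pd.DataFrame, scale_tag: str | None = None) -> "AbundanceMatrix":
        return AbundanceMatrix(values=values, scale_tag=scale_tag or self.scale_tag)

    def subset(self, samples=None, metabolites=None) -> "AbundanceMatrix":
        vals = self.values
        if samples is not None:
            vals = vals.loc[samples]
        if metabolites is not None:
            vals = vals.loc[:, metabolites]
        return replace(self, values=vals)


def validate_metadata(metadata: pd.DataFrame, require_outcomes: bool = False) -> None:
    """Sanity-check a sample metadata table.

    Raises ``ValueError`` on out-of-range ordinal scores or APOE4 counts;
    missing values are allowed everywhere (they are handled by
    ``harmonize_cohort`` and the per-outcome sample filters).
    """
    if metadata.index.has_duplicates:
        raise ValueError("duplicate sample ids in metadata")
    if "apoe4_count" in metadata:
        bad = metadata["apoe4_count"].dropna()
        if not bad.isin([0, 1, 2]).all():
            raise ValueError("apoe4_count must be in {0, 1, 2}")
    for col, (lo, hi) in OUTCOME_LEVELS.items():
        if col in metadata:
            vals = metadata[col].dropna()
            if len(vals) and not vals.between(lo, hi).all():
                raise ValueError(f"{col} values must lie in [{lo}, {hi}]")
    if require_outcomes:
        missing = [c for c in OUTCOME_COLUMNS if c not in metadata]
        if missing:
            raise ValueError(f"metadata lacks outcome columns: {missing}")
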