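"""CSV/JSON readers and writers for the pipeline artifacts.

Abundance matrices are stored samples-in-rows with a header row of
metabolite ids, the first column holding sample ids, and missing cells left
empty.  Metadata and annotation tables are plain CSV keyed by their first
column.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from metabomwas.containers import AbundanceMatrix


def write_abundance(matrix: AbundanceMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, index_label="sample_id")


def read_abundance(path: str | Path, scale_tag: str = "raw") -> AbundanceMatrix:
    values = pd.read_csv(path, index_col=0)
    values.index = values.index.astype(str)
    return AbundanceMatrix(values, scale_tag=scale_tag)


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, index_label="sample_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, index_col=0)
    meta.index = meta.index.astype(str)
    return meta


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, index_label="metabolite_id")


def read_annotation(path: str | Path) -> pd.DataFrame:
    annot = pd.read_csv(path, index_col=0)
    annot.index = annot.index.astype(str)
    return annot


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
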