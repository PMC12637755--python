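"""Metabolite-class over-representation of screen hits.

For each annotation class the 2x2 table (hits in/out of class vs. non-hits
in/out of class) is tested with the one-sided Fisher's exact test
(hypergeometric upper tail, over-representation); a two-sided variant is
available by flag.  The universe is the metabolite set that entered the
screen, not the full platform list.  The same machinery serves arbitrary
grouping columns, e.g. sphingolipid chain-length/saturation strata.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom

from metabomwas.assoc import bh_adjust


def class_enrichment(
    hit_ids,
    universe_ids,
    annotation: pd.DataFrame,
    class_col: str = "sub_pathway",
    alternative: str = "greater",
) -> pd.DataFrame:
    """Per-class Fisher's exact over-representation of hits in the universe.

    Returns one row per class with the 2x2 counts (``a`` hits in class,
    ``b`` hits outside, ``c`` non-hits in class, ``d`` non-hits outside),
    the sample odds ratio, the Fisher p-value and its BH adjustment across
    classes, sorted by p.
    """
    universe = pd.Index(universe_ids).unique()
    if len(universe) == 0:
        raise ValueError("empty universe")
    hits = pd.Index(hit_ids).unique()
    if not hits.isin(universe).all():
        raise ValueError("hits must be a subset of the universe")
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")

    classes = annotation[class_col].reindex(universe).fillna("unknown")
    n_hits, n_universe = len(hits), len(universe)
    rows = []
    for cls, members in classes.groupby(classes).groups.items():
        class_size = len(members)
        a = int(hits.isin(members).sum())
        b = n_hits - a
        c = class_size - a
        d = n_universe - class_size - b
        if alternative == "greater":
            # P(X >= a) for X ~ Hypergeom(N=universe, K=class, n=hits)
            p = float(hypergeom.sf(a - 1, n_universe, class_size, n_hits))
        else:
            p = float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
        odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
        rows.append(
            {"class": cls, "a": a, "b": b, "c": c, "d": d,
             "class_size": class_size, "odds_ratio": odds, "p": p}
        )
    table = pd.DataFrame(rows).set_index("class")
    table["q"] = bh_adjust(table["p"].to_numpy())
    return table.sort_values("p")


def compose_class_profile(
    annotation: pd.DataFrame, ids, class_col: str = "super_pathway"
) -> pd.DataFrame:
    """Class counts and percentages for a metabolite id list, sorted descending."""
    ids = pd.Index(ids)
    if len(ids) == 0:
        return pd.DataFrame(columns=["count", "percent"])
    classes = annotation[class_col].reindex(ids).fillna("unknown")
    counts = classes.value_counts()
    return pd.DataFrame(
        {"count": counts, "percent": 100.0 * counts / len(ids)}
    ).sort_values("count", ascending=False)
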