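"""Counting (B-W score) analysis of best-worst scaling responses.

The counting approach tallies, per item, the number of times it was
chosen most worrisome ("best") and least worrisome ("worst") across all
respondents and choice sets.  The B-W score is the difference of the
two totals; dividing by the number of respondents gives the mean B-W
score on which items are ranked.  At the individual level the same
difference is bounded by +-r, the design replication (+-4 for the
13-item, block-size-4 instrument), and its per-item mean/SD describes
how consistently the sample places an item.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import BWSDesign
from .synthetic_data import ResponseDataset

__all__ = [
    "aggregate_counts",
    "bw_scores",
    "individual_scores",
    "score_summary",
    "counting_table",
]


def aggregate_counts(dataset: ResponseDataset) -> pd.DataFrame:
    """Per-item best/worst totals over all records.

    Returns a frame indexed by item in catalog order with columns
    ``total_best`` and ``total_worst``; items never chosen get zeros.
    """
    items = list(dataset.design.catalog.items)
    best = dataset.records["best_item"].value_counts()
    worst = dataset.records["worst_item"].value_counts()
    return pd.DataFrame(
        {
            "total_best": best.reindex(items, fill_value=0).astype(int),
            "total_worst": worst.reindex(items, fill_value=0).astype(int),
        },
        index=pd.Index(items, name="item"),
    )


def _rank(table: pd.DataFrame, catalog_order: list[str]) -> pd.Series:
    # descending mean_bw; ties by larger total_best, then catalog order
    order = sorted(
        catalog_order,
        key=lambda it: (
            -table.loc[it, "mean_bw"],
            -table.loc[it, "total_best"],
            catalog_order.index(it),
        ),
    )
    return pd.Series(
        {item: pos + 1 for pos, item in enumerate(order)}, name="rank"
    ).reindex(table.index)


def bw_scores(
    totals: pd.DataFrame, n_respondents: int, stratum: str = ""
) -> pd.DataFrame:
    """B-W scores and ranks from best/worst totals.

    ``bw_score = total_best - total_worst``; ``mean_bw = bw_score / n``;
    rank 1 is the most worrisome item (highest mean).  Ties rank by
    larger ``total_best``, then catalog order.
    """
    if n_respondents <= 0:
        raise ValueError("n_respondents must be positive")
    table = totals[["total_best", "total_worst"]].copy()
    table["bw_score"] = table["total_best"] - table["total_worst"]
    table["mean_bw"] = table["bw_score"] / n_respondents
    table["rank"] = _rank(table, list(table.index))
    table.attrs["n_respondents"] = int(n_respondents)
    table.attrs["stratum"] = stratum
    return table


def individual_scores(
    dataset: ResponseDataset, design: BWSDesign | None = None
) -> pd.DataFrame:
    """Respondent x item B-W scores (times best minus times worst).

    Each score lies in [-r, +r] where r is the number of blocks
    answered that contain the item (at most the design replication, 4
    in the study instrument).  Rows sum to zero for respondents who
    answered every block.
    """
    design = design or dataset.design
    items = list(design.catalog.items)
    item_codes = {it: i for i, it in enumerate(items)}
    rec = dataset.records
    unknown = set(rec["best_item"]) | set(rec["worst_item"])
    unknown -= set(items)
    if unknown:
        raise KeyError(f"records reference items outside the catalog: {sorted(unknown)}")

    resp, resp_idx = np.unique(rec["respondent_id"].to_numpy(), return_inverse=True)
    v = len(items)
    best_flat = resp_idx * v + rec["best_item"].map(item_codes).to_numpy()
    worst_flat = resp_idx * v + rec["worst_item"].map(item_codes).to_numpy()
    counts = np.bincount(best_flat, minlength=len(resp) * v) - np.bincount(
        worst_flat, minlength=len(resp) * v
    )
    return pd.DataFrame(
        counts.reshape(len(resp), v),
        index=pd.Index(resp, name="respondent_id"),
        columns=pd.Index(items, name="item"),
    )


def score_summary(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-item mean and sample SD (n-1 denominator) of individual scores.

    On complete data the mean equals ``mean_bw`` from :func:`bw_scores`
    exactly.  The mean-SD pair per item describes importance versus
    agreement: a high mean with low SD marks a consensually worrisome
    outcome.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 respondents for a sample SD")
    return pd.DataFrame(
        {"mean": scores.mean(axis=0), "sd": scores.std(axis=0, ddof=1)}
    )


def counting_table(dataset: ResponseDataset, stratum: str = "") -> pd.DataFrame:
    """Full counting analysis of one dataset: totals, B-W scores, mean,
    individual-score SD and rank, ready for a published-style table.

    ``mean_bw`` divides by the number of respondents with at least one
    record.
    """
    totals = aggregate_counts(dataset)
    table = bw_scores(totals, dataset.n_respondents, stratum=stratum)
    if dataset.n_respondents >= 2:
        table["sd_bw"] = score_summary(individual_scores(dataset))["sd"]
    else:
        table["sd_bw"] = np.nan
    return table[["total_best", "total_worst", "bw_score", "mean_bw", "sd_bw", "rank"]]
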