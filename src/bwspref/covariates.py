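"""Regression of individual preference scores on respondent covariates.

The motivating study asked whether demographic or clinical
characteristics shift how worrisome an outcome is perceived to be, and
found no significant association.  This module reproduces that
analysis: for a chosen outcome, the respondent-level B-W score (the
times the respondent picked it best minus worst, in [-r, r]) is
regressed by ordinary least squares on dummy-coded covariates.  No
multiple-testing correction is applied (none was applied in the
original analysis); reports flag this.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .counting import individual_scores
from .synthetic_data import ResponseDataset, RespondentProfile, profiles_frame

__all__ = [
    "OLSResult",
    "build_design_matrix",
    "ols_fit",
    "regress_item_scores",
    "regress_all_items",
]


@dataclass
class OLSResult:
    """Classical OLS estimates with t-based inference."""

    params: pd.Series
    se: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    resid_var: float
    n: int
    columns: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.params,
                "se": self.se,
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )


def build_design_matrix(
    profiles: Sequence[RespondentProfile] | pd.DataFrame,
    coding: Mapping[str, str],
    numeric: Sequence[str] = ("age",),
) -> pd.DataFrame:
    """Intercept + dummy design matrix from respondent covariates.

    ``coding`` maps each categorical covariate to its reference level;
    every other observed level becomes one indicator column named
    ``covariate[level]``, levels in sorted order, covariates in coding
    order.  Covariates listed in ``numeric`` enter linearly.  Constant
    (single-level) covariates and unseen reference levels are rejected.
    """
    frame = (
        profiles
        if isinstance(profiles, pd.DataFrame)
        else profiles_frame(profiles).set_index("respondent_id")
    )
    if "respondent_id" in frame.columns:
        frame = frame.set_index("respondent_id")

    X = pd.DataFrame(index=frame.index)
    X["intercept"] = 1.0
    for cov in numeric:
        if cov in frame.columns:
            X[cov] = frame[cov].astype(float)
    for cov, ref in coding.items():
        if cov not in frame.columns:
            raise KeyError(f"covariate {cov!r} not in profiles")
        levels = sorted(map(str, frame[cov].unique()))
        if ref not in levels:
            raise ValueError(
                f"reference level {ref!r} for {cov!r} not observed (levels: {levels})"
            )
        if len(levels) < 2:
            raise ValueError(f"covariate {cov!r} is constant; rank-deficient design")
        for level in levels:
            if level != ref:
                X[f"{cov}[{level}]"] = (frame[cov].astype(str) == level).astype(float)
    return X


def ols_fit(y: np.ndarray | pd.Series, X: pd.DataFrame) -> OLSResult:
    """Classical OLS via a stable decomposition (statsmodels pinv path).

    Standard errors are homoskedastic; t statistics and two-sided
    p-values use the t distribution with n - p degrees of freedom.
    Rank-deficient design matrices and n <= p are rejected.
    """
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n={n} observations cannot identify p={p} coefficients")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < p:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {p} columns)"
        )
    res = sm.OLS(y, X).fit()
    return OLSResult(
        params=res.params,
        se=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        resid_var=float(res.mse_resid),
        n=n,
        columns=list(X.columns),
    )


DEFAULT_CODING: dict[str, str] = {
    "sex": "male",
    "education": "none",
    "statin_use": "never",
    "morbidity": "no",
}


def observed_coding(
    profiles: Sequence[RespondentProfile] | pd.DataFrame,
    covariates: Sequence[str] = tuple(DEFAULT_CODING),
) -> dict[str, str]:
    """Coding spec with the most frequent observed level as reference.

    Robust for small samples where a nominal reference level (e.g. the
    3% "no schooling" category) may be absent.
    """
    frame = (
        profiles
        if isinstance(profiles, pd.DataFrame)
        else profiles_frame(profiles)
    )
    return {
        cov: str(frame[cov].value_counts().idxmax())
        for cov in covariates
        if cov in frame.columns
    }


def regress_item_scores(
    dataset: ResponseDataset,
    item: str,
    coding: Mapping[str, str] | None = None,
    numeric: Sequence[str] = ("age",),
) -> OLSResult:
    """OLS of one item's individual B-W scores on respondent covariates."""
    coding = dict(coding) if coding is not None else dict(DEFAULT_CODING)
    scores = individual_scores(dataset)
    if item not in scores.columns:
        raise KeyError(f"item {item!r} not in the design catalog")
    X = build_design_matrix(dataset.profiles, coding, numeric=numeric)
    y = scores[item].reindex(X.index)
    if y.isna().any():
        missing = y.index[y.isna()].tolist()[:5]
        raise ValueError(f"profiles without responses, e.g. {missing}")
    return ols_fit(y, X)


def regress_all_items(
    dataset: ResponseDataset,
    coding: Mapping[str, str] | None = None,
    numeric: Sequence[str] = ("age",),
) -> pd.DataFrame:
    """Per-item covariate regressions stacked into one long table.

    Columns: item, predictor, coefficient, se, t, p.  p-values are
    unadjusted for multiple testing.
    """
    frames = []
    for item in dataset.design.catalog.items:
        result = regress_item_scores(dataset, item, coding, numeric)
        tab = result.to_frame().reset_index(names="predictor")
        tab.insert(0, "item", item)
        frames.append(tab)
    out = pd.concat(frames, ignore_index=True)
    out.attrs["multiple_testing_correction"] = "none"
    return out
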