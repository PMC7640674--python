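"""Maximum-difference (maxdiff) conditional-logit estimation.

Each answered choice set of size k is expanded into a choice among the
k(k-1) ordered (best, worst) pairs of its items (12 pairs for k = 4).
Under the maxdiff random-utility model the pair (i, j) is chosen with
probability

    P(i, j | S) = exp(b_i - b_j) / sum_{(a, c) in S, a != c} exp(b_a - b_c),

a conditional logit on the design-difference vectors e_i - e_j.  The
utilities b are identified up to an additive constant, fixed by pinning
a reference item at 0 (the least worrisome item, myopathy, in the
motivating study); exp(b_i) is then the odds of naming item i most
worrisome relative to the reference.

The log-likelihood is globally concave; it is maximised by BFGS with
the exact analytic gradient from beta = 0, and Wald standard errors come
from the inverse observed information (central-difference Hessian of
the negative log-likelihood at the optimum).  Situations are treated as
independent (the published analysis reports plain conditional-logit
CIs); cluster-robust SEs by respondent are available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .design import BWSDesign, pairs_per_block
from .synthetic_data import ResponseDataset

__all__ = [
    "PairChoiceTable",
    "MaxDiffFit",
    "SeparationWarning",
    "expand_to_pairs",
    "loglik",
    "fit_maxdiff",
    "odds_vs_ref",
]


class SeparationWarning(UserWarning):
    """An item is never (or always) chosen; its coefficient diverges."""


@dataclass
class PairChoiceTable:
    """Responses expanded to pair-choice situations.

    One situation per response record; situation s offers alternatives
    a = 0..k(k-1)-1 with linear predictor
    ``beta_full[pair_best[s, a]] - beta_full[pair_worst[s, a]]`` where
    ``beta_full`` carries the reference coefficient 0 at index
    ``ref_index``.  ``weights`` allows collapsing identical situations.
    """

    items: tuple[str, ...]
    ref_index: int
    pair_best: np.ndarray   # (S, A) int item indices
    pair_worst: np.ndarray  # (S, A) int item indices
    chosen: np.ndarray      # (S,) int alternative index
    weights: np.ndarray     # (S,) float situation multiplicities
    respondent_ids: np.ndarray | None = None  # (S,) for cluster-robust SEs

    @property
    def n_situations(self) -> int:
        return int(self.weights.sum())

    @property
    def n_alternatives(self) -> int:
        return self.pair_best.shape[1]

    @property
    def reference(self) -> str:
        return self.items[self.ref_index]

    @property
    def free_items(self) -> list[str]:
        """Non-reference items, in catalog order: the coefficient basis."""
        return [it for i, it in enumerate(self.items) if i != self.ref_index]

    def beta_full(self, beta: np.ndarray) -> np.ndarray:
        """Insert the reference zero into a (v-1)-vector of coefficients."""
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (len(self.items) - 1,):
            raise ValueError(
                f"beta has shape {beta.shape}, expected ({len(self.items) - 1},)"
            )
        return np.insert(beta, self.ref_index, 0.0)

    def difference_vector(self, situation: int, alternative: int) -> np.ndarray:
        """Design-difference vector e_best - e_worst of one alternative in
        the (v-1)-dimensional non-reference basis."""
        x = np.zeros(len(self.items))
        x[self.pair_best[situation, alternative]] += 1.0
        x[self.pair_worst[situation, alternative]] -= 1.0
        return np.delete(x, self.ref_index)

    def collapsed(self) -> "PairChoiceTable":
        """Merge situations with identical (block-pair-set, choice).

        With a shared design and no covariates there are at most
        b * k(k-1) distinct situations, which makes likelihood
        evaluations independent of sample size.
        """
        key = np.concatenate(
            [self.pair_best, self.pair_worst, self.chosen[:, None]], axis=1
        )
        uniq, inverse = np.unique(key, axis=0, return_inverse=True)
        weights = np.bincount(inverse, weights=self.weights)
        a = self.pair_best.shape[1]
        return PairChoiceTable(
            items=self.items,
            ref_index=self.ref_index,
            pair_best=uniq[:, :a],
            pair_worst=uniq[:, a : 2 * a],
            chosen=uniq[:, -1],
            weights=weights,
            respondent_ids=None,
        )


@dataclass
class MaxDiffFit:
    """Conditional-logit estimates relative to a reference item."""

    reference: str
    coefficients: dict[str, float]
    se: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    loglik: float
    null_loglik: float
    converged: bool
    n_iter: int
    n_situations: int
    separated_items: list[str] = field(default_factory=list)
    cluster_robust: bool = False

    def to_frame(self) -> pd.DataFrame:
        """Published-style coefficient table, sorted by coefficient."""
        items = sorted(self.coefficients, key=self.coefficients.get, reverse=True)
        return pd.DataFrame(
            {
                "coefficient": [self.coefficients[i] for i in items],
                "se": [self.se[i] for i in items],
                "ci_low": [self.ci_low[i] for i in items],
                "ci_high": [self.ci_high[i] for i in items],
                "reference": [i == self.reference for i in items],
            },
            index=pd.Index(items, name="item"),
        )


def expand_to_pairs(
    dataset: ResponseDataset, design: BWSDesign | None = None, reference: str | None = None
) -> PairChoiceTable:
    """Expand response records into pair-choice situations.

    One situation per record, each with k(k-1) ordered (best, worst)
    alternatives; the chosen alternative is the recorded pair.  The
    reference item defaults to the item with the lowest mean B-W score.
    """
    design = design or dataset.design
    items = tuple(design.catalog.items)
    if reference is None:
        from .counting import aggregate_counts, bw_scores

        table = bw_scores(aggregate_counts(dataset), max(dataset.n_respondents, 1))
        reference = table["mean_bw"].idxmin()
    if reference not in items:
        raise ValueError(f"reference item {reference!r} not in catalog")
    ref_index = items.index(reference)
    item_code = {it: i for i, it in enumerate(items)}

    k = design.k
    n_alt = pairs_per_block(k)
    # per-block alternative layout: ordered pairs of member indices
    block_pairs = {}
    for bi, bid in enumerate(design.block_ids):
        members = [item_code[it] for it in design.block_items(bi)]
        pairs = [(a, c) for a in members for c in members if a != c]
        block_pairs[bid] = (
            np.array([p[0] for p in pairs]),
            np.array([p[1] for p in pairs]),
            {p: idx for idx, p in enumerate(pairs)},
        )

    rec = dataset.records
    n = len(rec)
    pair_best = np.empty((n, n_alt), dtype=np.int64)
    pair_worst = np.empty((n, n_alt), dtype=np.int64)
    chosen = np.empty(n, dtype=np.int64)
    for s, row in enumerate(rec.itertuples()):
        try:
            pb, pw, index = block_pairs[row.block_id]
        except KeyError:
            raise KeyError(f"record {s} references unknown block {row.block_id!r}")
        pair_best[s] = pb
        pair_worst[s] = pw
        try:
            chosen[s] = index[(item_code[row.best_item], item_code[row.worst_item])]
        except KeyError:
            raise ValueError(
                f"record {s}: pair ({row.best_item!r}, {row.worst_item!r}) "
                f"is not an alternative of block {row.block_id}"
            )
    return PairChoiceTable(
        items=items,
        ref_index=ref_index,
        pair_best=pair_best,
        pair_worst=pair_worst,
        chosen=chosen,
        weights=np.ones(n),
        respondent_ids=rec["respondent_id"].to_numpy(),
    )


def loglik(beta: np.ndarray, table: PairChoiceTable) -> tuple[float, np.ndarray]:
    """Weighted log-likelihood and its exact gradient.

    ``value = sum_s w_s [ eta_chosen(s) - log sum_a exp(eta_a(s)) ]``
    with ``eta_a = beta_best(a) - beta_worst(a)``; log-sum-exp is
    computed stably.  The gradient is the weighted sum of observed-
    minus-expected design-difference vectors, restricted to the
    non-reference basis.
    """
    bf = table.beta_full(beta)
    eta = bf[table.pair_best] - bf[table.pair_worst]            # (S, A)
    lse = logsumexp(eta, axis=1)                                # (S,)
    rows = np.arange(eta.shape[0])
    value = float(np.sum(table.weights * (eta[rows, table.chosen] - lse)))

    p = np.exp(eta - lse[:, None]) * table.weights[:, None]     # (S, A)
    v = len(table.items)
    grad_full = np.zeros(v)
    np.add.at(grad_full, table.pair_best[rows, table.chosen],
              table.weights)
    np.subtract.at(grad_full, table.pair_worst[rows, table.chosen],
                   table.weights)
    grad_full -= np.bincount(table.pair_best.ravel(), weights=p.ravel(), minlength=v)
    grad_full += np.bincount(table.pair_worst.ravel(), weights=p.ravel(), minlength=v)
    return value, np.delete(grad_full, table.ref_index)


def _hessian(beta: np.ndarray, table: PairChoiceTable, step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of the log-likelihood from the analytic
    gradient; symmetrised."""
    p = len(beta)
    H = np.empty((p, p))
    for j in range(p):
        h = step * max(1.0, abs(beta[j]))
        bp, bm = beta.copy(), beta.copy()
        bp[j] += h
        bm[j] -= h
        _, gp = loglik(bp, table)
        _, gm = loglik(bm, table)
        H[:, j] = (gp - gm) / (2 * h)
    return (H + H.T) / 2


def _check_separation(table: PairChoiceTable) -> list[str]:
    rows = np.arange(len(table.chosen))
    best_idx = table.pair_best[rows, table.chosen]
    worst_idx = table.pair_worst[rows, table.chosen]
    v = len(table.items)
    nb = np.bincount(best_idx, weights=table.weights, minlength=v)
    nw = np.bincount(worst_idx, weights=table.weights, minlength=v)
    flagged = [
        table.items[i]
        for i in range(v)
        if i != table.ref_index and (nb[i] == 0 or nw[i] == 0)
    ]
    return flagged


def fit_maxdiff(
    dataset: ResponseDataset,
    design: BWSDesign | None = None,
    reference: str | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    cluster_robust: bool = False,
    ci_level: float = 0.95,
) -> MaxDiffFit:
    """Maximum-likelihood maxdiff conditional-logit fit.

    BFGS with the analytic gradient from beta = 0; convergence is a
    gradient norm below ``tol``.  SEs come from the inverse observed
    information; with ``cluster_robust`` a respondent-clustered sandwich
    is used instead.  Items never chosen best or never chosen worst are
    reported with infinite CIs under a :class:`SeparationWarning`.
    """
    from scipy.stats import norm

    table = expand_to_pairs(dataset, design, reference)
    separated = _check_separation(table)
    if separated:
        warnings.warn(
            f"items never chosen best or never chosen worst: {separated}; "
            "their coefficients diverge and are reported with infinite CIs",
            SeparationWarning,
            stacklevel=2,
        )

    work = table.collapsed()  # likelihood-equivalent, sample-size-free
    p = len(table.items) - 1
    total_w = float(work.weights.sum())

    # optimise the mean log-likelihood so the gradient tolerance is
    # scale-free in the number of situations
    def negloglik(beta: np.ndarray) -> tuple[float, np.ndarray]:
        value, grad = loglik(beta, work)
        return -value / total_w, -grad / total_w

    res = minimize(
        negloglik,
        x0=np.zeros(p),
        jac=True,
        method="BFGS",
        options={"gtol": tol, "maxiter": max_iter},
    )
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(grad_norm < max(tol, 1e-7)) and not separated

    beta_hat = res.x
    ll_hat, _ = loglik(beta_hat, work)
    ll_null, _ = loglik(np.zeros(p), work)

    H = _hessian(beta_hat, work)  # Hessian of loglik (negative definite)
    info = -H
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    if cluster_robust and table.respondent_ids is not None:
        cov = _cluster_robust_cov(beta_hat, table, cov)

    se_vec = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    z = norm.ppf(0.5 + ci_level / 2)

    free = table.free_items
    coefficients = {table.reference: 0.0}
    se = {table.reference: 0.0}
    ci_low = {table.reference: 0.0}
    ci_high = {table.reference: 0.0}
    for name, b, s in zip(free, beta_hat, se_vec):
        if name in separated:
            coefficients[name] = float(b)
            se[name] = np.inf
            ci_low[name], ci_high[name] = -np.inf, np.inf
        else:
            coefficients[name] = float(b)
            se[name] = float(s)
            ci_low[name] = float(b - z * s)
            ci_high[name] = float(b + z * s)

    return MaxDiffFit(
        reference=table.reference,
        coefficients=coefficients,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        loglik=float(ll_hat),
        null_loglik=float(ll_null),
        converged=converged,
        n_iter=int(res.nit),
        n_situations=table.n_situations,
        separated_items=separated,
        cluster_robust=cluster_robust,
    )


def _cluster_robust_cov(
    beta: np.ndarray, table: PairChoiceTable, bread: np.ndarray
) -> np.ndarray:
    """Respondent-clustered sandwich covariance H^-1 (sum_r g_r g_r^T) H^-1."""
    bf = table.beta_full(beta)
    eta = bf[table.pair_best] - bf[table.pair_worst]
    lse = logsumexp(eta, axis=1)
    prob = np.exp(eta - lse[:, None])
    rows = np.arange(eta.shape[0])
    v = len(table.items)

    # per-situation score in the full basis: x_chosen - E[x]
    scores = np.zeros((eta.shape[0], v))
    np.add.at(scores, (rows, table.pair_best[rows, table.chosen]), 1.0)
    np.add.at(scores, (rows, table.pair_worst[rows, table.chosen]), -1.0)
    for a in range(eta.shape[1]):
        np.add.at(scores, (rows, table.pair_best[:, a]), -prob[:, a])
        np.add.at(scores, (rows, table.pair_worst[:, a]), prob[:, a])
    scores = np.delete(scores, table.ref_index, axis=1)

    groups = pd.factorize(table.respondent_ids)[0]
    g = np.zeros((groups.max() + 1, scores.shape[1]))
    np.add.at(g, groups, scores * table.weights[:, None])
    meat = g.T @ g
    return bread @ meat @ bread


def odds_vs_ref(fit: MaxDiffFit) -> dict[str, float]:
    """exp(coefficient) per item: the odds of naming the item most
    worrisome relative to the reference (reference maps to 1)."""
    if not fit.converged:
        warnings.warn("fit did not converge; odds ratios may be unreliable")
    return {item: float(np.exp(b)) for item, b in fit.coefficients.items()}
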