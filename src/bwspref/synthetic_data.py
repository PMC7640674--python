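"""Synthetic respondents, BWS responses and VAS scores.

The generator emulates the structure of the motivating survey: a
stratified sample (urban / rural general population, primary-care
providers) with realistic covariate marginals, best-worst responses
drawn from a maxdiff random-utility model, and per-item visual-analog
severity ratings on [0, 1].

Response model.  Under the maxdiff conditional logit, a respondent shown
block S picks the ordered pair (best=i, worst=j) with probability

    P(i, j | S) = exp(u_i - u_j) / sum_{(a,b) in S, a != b} exp(u_a - u_b),

where u are latent item utilities identified up to a constant (the
reference item is pinned at 0).  Simulating from exactly this model
makes the downstream conditional-logit estimator consistent for u by
construction.  A sequential best-then-worst mode is available for
robustness studies.

Reproducibility protocol: one root seed; each respondent's choices come
from an independent substream keyed by a stable hash of the respondent
id, so enlarging the sample never perturbs existing respondents.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import BWSDesign
from .study_data import PROFILE_MARGINALS, utilities_for

__all__ = [
    "UtilityConfig",
    "RespondentProfile",
    "ResponseRecord",
    "ResponseDataset",
    "VASRecord",
    "simulate_profiles",
    "profiles_frame",
    "maxdiff_pair_prob",
    "block_pair_probabilities",
    "simulate_bws_responses",
    "simulate_vas",
    "study_utilities",
]

STRATA = ("urban", "rural", "provider")


@dataclass(frozen=True)
class UtilityConfig:
    """Latent utilities and link parameters driving the simulator.

    Parameters
    ----------
    utilities
        Item -> latent utility (dimensionless); the reference item's
        utility is exactly 0.
    reference
        The item pinned at zero utility.
    covariate_effects
        Optional ``(field, value) -> {item: shift}`` map: respondents
        whose profile attribute ``field`` equals ``value`` get the given
        additive utility shifts.  Defaults to no effects (the motivating
        study found no covariate association); nonzero effects are
        opt-in for power studies.
    vas_link
        ``(intercept, slope)`` of the logistic map from utility to the
        mean VAS score.
    vas_noise_sd
        SD of the pre-link Gaussian noise on the VAS linear predictor.
    """

    utilities: dict[str, float]
    reference: str = "myopathy"
    covariate_effects: dict[tuple[str, object], dict[str, float]] = field(
        default_factory=dict
    )
    vas_link: tuple[float, float] = (-3.0, 1.0)
    vas_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.reference not in self.utilities:
            raise ValueError(f"reference item {self.reference!r} missing from utilities")
        if self.utilities[self.reference] != 0.0:
            raise ValueError("reference item utility must be exactly 0")
        if self.vas_noise_sd < 0:
            raise ValueError("vas_noise_sd must be >= 0")

    def shifted(self, profile: "RespondentProfile") -> dict[str, float]:
        """Utilities for one respondent after covariate shifts."""
        if not self.covariate_effects:
            return self.utilities
        u = dict(self.utilities)
        for (fld, value), shifts in self.covariate_effects.items():
            if profile.attribute(fld) == value:
                for item, delta in shifts.items():
                    u[item] += delta
        return u


def study_utilities(stratum: str = "total") -> UtilityConfig:
    """Default utility configuration: the published conditional-logit
    coefficients of the requested stratum, myopathy as reference."""
    return UtilityConfig(utilities=utilities_for(stratum))


@dataclass(frozen=True)
class RespondentProfile:
    """One simulated survey participant."""

    respondent_id: str
    stratum: str
    sex: str
    age: float
    education: str
    statin_use: str
    morbidity: str
    family_history: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stratum not in STRATA:
            raise ValueError(f"unknown stratum {self.stratum!r}")
        if self.age < 18:
            raise ValueError("respondents are adults (age >= 18)")

    def attribute(self, name: str):
        if name.startswith("fh_"):
            return self.family_history.get(name)
        return getattr(self, name)


@dataclass(frozen=True)
class ResponseRecord:
    """One (respondent, block) best/worst selection."""

    respondent_id: str
    block_id: str
    best_item: str
    worst_item: str

    def __post_init__(self) -> None:
        if self.best_item == self.worst_item:
            raise ValueError(
                f"best and worst must differ (respondent {self.respondent_id}, "
                f"block {self.block_id})"
            )


@dataclass
class ResponseDataset:
    """Raw elicitation data: responses plus respondent profiles.

    ``records`` is a long-format frame with columns respondent_id,
    block_id, best_item, worst_item — one row per answered choice set.
    """

    design: BWSDesign
    records: pd.DataFrame
    profiles: list[RespondentProfile] = field(default_factory=list)

    RECORD_COLUMNS = ("respondent_id", "block_id", "best_item", "worst_item")

    def __post_init__(self) -> None:
        missing = set(self.RECORD_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"records frame missing columns {sorted(missing)}")
        self.records = self.records.reset_index(drop=True)

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def respondent_ids(self) -> list[str]:
        return list(pd.unique(self.records["respondent_id"]))

    @property
    def n_respondents(self) -> int:
        """Respondents contributing at least one record."""
        return self.records["respondent_id"].nunique()

    def validate(self) -> list[str]:
        """Row-numbered violations of the response invariants."""
        block_members = {
            bid: set(self.design.block_items(i))
            for i, bid in enumerate(self.design.block_ids)
        }
        violations: list[str] = []
        seen: set[tuple[str, str]] = set()
        for row in self.records.itertuples():
            rownum = row.Index
            if row.block_id not in block_members:
                violations.append(f"row {rownum}: unknown block {row.block_id!r}")
                continue
            members = block_members[row.block_id]
            if row.best_item == row.worst_item:
                violations.append(f"row {rownum}: best equals worst ({row.best_item!r})")
            for role, item in (("best", row.best_item), ("worst", row.worst_item)):
                if item not in members:
                    violations.append(
                        f"row {rownum}: {role} item {item!r} not in block {row.block_id}"
                    )
            key = (row.respondent_id, row.block_id)
            if key in seen:
                violations.append(
                    f"row {rownum}: duplicate (respondent {row.respondent_id!r}, "
                    f"block {row.block_id!r})"
                )
            seen.add(key)
        return violations

    def record_objects(self) -> list[ResponseRecord]:
        return [
            ResponseRecord(r.respondent_id, r.block_id, r.best_item, r.worst_item)
            for r in self.records.itertuples()
        ]


@dataclass(frozen=True)
class VASRecord:
    """One visual-analog severity rating, normalised to [0, 1]."""

    respondent_id: str
    item_id: str
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"VAS score {self.score} outside [0, 1]")


def _substream(root_seed: int, respondent_id: str) -> np.random.Generator:
    # stable across sessions (unlike hash()); 8 bytes of sha256 keeps the
    # entropy well clear of collisions at survey sample sizes
    digest = hashlib.sha256(respondent_id.encode()).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng([root_seed, key])


def _check_marginal(name: str, probs: Mapping[str, float]) -> None:
    total = float(sum(probs.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"probabilities for {name!r} sum to {total}, expected 1")
    if any(p < 0 for p in probs.values()):
        raise ValueError(f"negative probability in marginal {name!r}")


def simulate_profiles(
    n: int,
    marginals: Mapping[str, object] | None = None,
    stratum: str = "urban",
    seed: int = 0,
    id_prefix: str | None = None,
) -> list[RespondentProfile]:
    """Draw ``n`` respondent profiles from per-covariate marginals.

    Covariates are drawn independently (the generator reproduces the
    sample's marginal frequencies, not its joint structure).  ``age``
    marginals are ``(mean, sd, lower_bound)`` of a truncated normal;
    categorical marginals are category -> probability maps summing to 1
    within 1e-9.  Deterministic under ``seed``.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if marginals is None:
        marginals = PROFILE_MARGINALS[stratum]
    rng = np.random.default_rng([int(seed), 0x9E3779B9])
    prefix = id_prefix if id_prefix is not None else stratum[0]
    if n == 0:
        return []

    draws: dict[str, np.ndarray] = {}
    for name, spec in marginals.items():
        if name == "age":
            mean, sd, lo = spec  # type: ignore[misc]
            age = rng.normal(mean, sd, size=n)
            while True:  # resample below-truncation draws
                bad = age < lo
                if not bad.any():
                    break
                age[bad] = rng.normal(mean, sd, size=int(bad.sum()))
            draws[name] = np.round(age, 1)
        else:
            _check_marginal(name, spec)  # type: ignore[arg-type]
            cats = np.array(list(spec.keys()), dtype=object)  # type: ignore[union-attr]
            p = np.array(list(spec.values()), dtype=float)  # type: ignore[union-attr]
            draws[name] = cats[rng.choice(len(cats), size=n, p=p / p.sum())]

    profiles = []
    for i in range(n):
        fh = {
            name: str(draws[name][i])
            for name in marginals
            if name.startswith("fh_")
        }
        profiles.append(
            RespondentProfile(
                respondent_id=f"{prefix}{i:05d}",
                stratum=stratum,
                sex=str(draws["sex"][i]) if "sex" in draws else "female",
                age=float(draws["age"][i]) if "age" in draws else 50.0,
                education=str(draws["education"][i]) if "education" in draws else "primary",
                statin_use=str(draws["statin_use"][i]) if "statin_use" in draws else "never",
                morbidity=str(draws["morbidity"][i]) if "morbidity" in draws else "no",
                family_history=fh,
            )
        )
    return profiles


def profiles_frame(profiles: Sequence[RespondentProfile]) -> pd.DataFrame:
    """Respondent profiles as a covariate table (one column per covariate)."""
    rows = []
    for p in profiles:
        row = {
            "respondent_id": p.respondent_id,
            "stratum": p.stratum,
            "sex": p.sex,
            "age": p.age,
            "education": p.education,
            "statin_use": p.statin_use,
            "morbidity": p.morbidity,
        }
        row.update(p.family_history)
        rows.append(row)
    return pd.DataFrame(rows)


def block_pair_probabilities(
    utilities: Mapping[str, float], block: Sequence[str]
) -> tuple[list[tuple[str, str]], np.ndarray]:
    """All ordered (best, worst) pairs of a block with their maxdiff
    probabilities; probabilities sum to 1."""
    items = list(block)
    if len(set(items)) != len(items):
        raise ValueError("block contains repeated items")
    missing = [it for it in items if it not in utilities]
    if missing:
        raise KeyError(f"no utility for design items {missing}")
    pairs = [(i, j) for i in items for j in items if i != j]
    diffs = np.array([utilities[i] - utilities[j] for i, j in pairs])
    w = np.exp(diffs - diffs.max())
    return pairs, w / w.sum()


def maxdiff_pair_prob(
    utilities: UtilityConfig | Mapping[str, float],
    block: Sequence[str],
    i: str,
    j: str,
) -> float:
    """P(best=i, worst=j | block) under the maxdiff conditional logit:
    exp(u_i - u_j) normalised over all ordered pairs in the block."""
    u = utilities.utilities if isinstance(utilities, UtilityConfig) else utilities
    if i == j:
        raise ValueError("best and worst must differ")
    if i not in block or j not in block:
        raise ValueError(f"items ({i!r}, {j!r}) must both belong to the block")
    pairs, probs = block_pair_probabilities(u, block)
    return float(probs[pairs.index((i, j))])


def _sequential_pair_probabilities(
    utilities: Mapping[str, float], block: Sequence[str]
) -> tuple[list[tuple[str, str]], np.ndarray]:
    # best drawn with probability softmax(u), worst from the remainder
    # with softmax(-u); a robustness alternative, not the default
    items = list(block)
    u = np.array([utilities[i] for i in items])
    pb = np.exp(u - u.max())
    pb /= pb.sum()
    pairs, probs = [], []
    for bi, b_item in enumerate(items):
        rest = [x for x in range(len(items)) if x != bi]
        pw = np.exp(-u[rest] - (-u[rest]).max())
        pw /= pw.sum()
        for wi, ri in enumerate(rest):
            pairs.append((b_item, items[ri]))
            probs.append(pb[bi] * pw[wi])
    return pairs, np.array(probs)


def simulate_bws_responses(
    design: BWSDesign,
    utilities: UtilityConfig,
    profiles: Sequence[RespondentProfile],
    seed: int = 0,
    missing_rate: float = 0.0,
    sequential: bool = False,
) -> ResponseDataset:
    """Draw one (best, worst) pair per respondent x block.

    Each answered block is an independent draw from the maxdiff pair
    distribution (or the sequential best-then-worst model when
    ``sequential``).  Blocks are independently skipped with probability
    ``missing_rate``.  Respondent substreams make the output invariant
    to adding or removing *other* respondents.
    """
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must be in [0, 1]")
    pair_model = _sequential_pair_probabilities if sequential else block_pair_probabilities

    block_items = [design.block_items(i) for i in range(design.b)]
    block_ids = design.block_ids
    base_tables = None
    if not utilities.covariate_effects:
        base_tables = [pair_model(utilities.utilities, blk) for blk in block_items]
        cum = np.array([np.cumsum(p) for _, p in base_tables])
        cum[:, -1] = 1.0  # guard against fp undershoot at the last edge

    rows: list[tuple[str, str, str, str]] = []
    for profile in profiles:
        rng = _substream(int(seed), profile.respondent_id)
        if base_tables is None:
            u_r = utilities.shifted(profile)
            tables = [pair_model(u_r, blk) for blk in block_items]
            cum_r = np.array([np.cumsum(p) for _, p in tables])
            cum_r[:, -1] = 1.0
        else:
            tables, cum_r = base_tables, cum
        keep = np.ones(design.b, dtype=bool)
        if missing_rate > 0:
            keep = rng.random(design.b) >= missing_rate
        u01 = rng.random(design.b)
        for bi in np.flatnonzero(keep):
            choice = int(np.searchsorted(cum_r[bi], u01[bi], side="right"))
            best, worst = tables[bi][0][choice]
            rows.append((profile.respondent_id, block_ids[bi], best, worst))

    records = pd.DataFrame(rows, columns=list(ResponseDataset.RECORD_COLUMNS))
    return ResponseDataset(design=design, records=records, profiles=list(profiles))


def simulate_vas(
    utilities: UtilityConfig,
    profiles: Sequence[RespondentProfile],
    items: Iterable[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-item VAS severity scores for each respondent.

    ``score = logistic(intercept + slope * u_item + eps)`` with
    ``eps ~ N(0, vas_noise_sd)``; the logistic link keeps scores inside
    (0, 1).  Returns a long frame (respondent_id, item_id, score).
    """
    item_list = list(items) if items is not None else list(utilities.utilities)
    intercept, slope = utilities.vas_link
    rows = []
    for profile in profiles:
        rng = _substream(int(seed) + 0x5A5A5A, profile.respondent_id)
        u_r = utilities.shifted(profile)
        eta = np.array([intercept + slope * u_r[item] for item in item_list])
        if utilities.vas_noise_sd > 0:
            eta = eta + rng.normal(0.0, utilities.vas_noise_sd, size=len(item_list))
        scores = expit(eta)
        rows.extend(
            (profile.respondent_id, item, float(s))
            for item, s in zip(item_list, scores)
        )
    return pd.DataFrame(rows, columns=["respondent_id", "item_id", "score"])
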