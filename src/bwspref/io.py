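"""File formats, configuration and the end-to-end analysis pipeline.

All files are UTF-8 comma-separated text with "." decimals; items are
always serialised by string identifier, never by index.

Formats
-------
responses.csv   respondent_id, block_id, best_item, worst_item
design.csv      block_id, position (1..k), item_id
catalog.csv     item_id, label
profiles.csv    respondent_id + one column per covariate
vas.csv         respondent_id, item_id, score

``run_pipeline`` chains design construction, simulation (or loading),
the counting analysis per stratum, the maxdiff conditional-logit fit,
the VAS/BWS comparison and the covariate regressions, writing one CSV
per stage plus a JSON manifest.  The manifest carries the seed, package
version and a config hash but no timestamp, so identical configs
produce byte-identical output trees.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .counting import counting_table, individual_scores
from .covariates import regress_all_items
from .design import (
    BWSDesign,
    ItemCatalog,
    KNOWN_BASE_BLOCKS,
    develop_design,
    statin_outcome_design,
    validate_design,
)
from .maxdiff import fit_maxdiff, odds_vs_ref
from .synthetic_data import (
    ResponseDataset,
    UtilityConfig,
    simulate_bws_responses,
    simulate_profiles,
    simulate_vas,
    study_utilities,
    profiles_frame,
)
from .vas_compare import dispersion_overlap, rank_by_median, rank_agreement, scores_by_item

__all__ = [
    "PipelineConfig",
    "read_responses",
    "write_responses",
    "read_design",
    "write_design",
    "run_pipeline",
]

log = logging.getLogger("bwspref")

RESPONSE_COLUMNS = ["respondent_id", "block_id", "best_item", "worst_item"]


class ResponseFileError(ValueError):
    """A response CSV violates the schema; messages carry row numbers."""


def read_responses(path: str | Path, design: BWSDesign) -> ResponseDataset:
    """Load and validate a long-format response CSV against a design.

    Violations (best = worst, item not in its block, unknown block,
    duplicate respondent x block) abort with row-numbered messages.  An
    empty file with a valid header yields an empty dataset and a
    warning in the log.
    """
    frame = pd.read_csv(path, dtype=str)
    missing = set(RESPONSE_COLUMNS) - set(frame.columns)
    if missing:
        raise ResponseFileError(f"{path}: missing columns {sorted(missing)}")
    dataset = ResponseDataset(design=design, records=frame[RESPONSE_COLUMNS])
    violations = dataset.validate()
    if violations:
        raise ResponseFileError(f"{path}: " + "; ".join(violations[:20]))
    if dataset.n_records == 0:
        log.warning("%s: no response rows (header only)", path)
    return dataset


def write_responses(dataset: ResponseDataset, path: str | Path) -> Path:
    path = Path(path)
    dataset.records[RESPONSE_COLUMNS].to_csv(path, index=False)
    return path


def write_design(design: BWSDesign, path: str | Path) -> Path:
    """Design CSV: one row per item-slot (block_id, position, item_id)."""
    rows = [
        {"block_id": bid, "position": pos + 1, "item_id": item}
        for bi, bid in enumerate(design.block_ids)
        for pos, item in enumerate(design.block_items(bi))
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_design(path: str | Path, catalog: ItemCatalog) -> BWSDesign:
    """Load a design CSV and re-derive (v, k, lambda); validates balance."""
    frame = pd.read_csv(path, dtype={"block_id": str, "item_id": str})
    blocks = []
    for _, grp in frame.sort_values(["block_id", "position"]).groupby("block_id"):
        blocks.append(tuple(sorted(catalog.index(i) for i in grp["item_id"])))
    v = len(catalog)
    k = len(blocks[0])
    lambda_, rem = divmod(sum(len(b) * (len(b) - 1) // 2 for b in blocks), v * (v - 1) // 2)
    if rem:
        raise ValueError(f"{path}: block sizes incompatible with any pair balance")
    design = BWSDesign(catalog=catalog, v=v, k=k, lambda_=lambda_, blocks=tuple(blocks))
    report = validate_design(design)
    if not report.valid:
        raise ValueError(f"{path}: not a balanced design: " + "; ".join(report.violations[:5]))
    return design


def write_catalog(catalog: ItemCatalog, path: str | Path) -> Path:
    pd.DataFrame(
        {
            "item_id": catalog.items,
            "label": [catalog.descriptions.get(i, i) for i in catalog.items],
        }
    ).to_csv(path, index=False)
    return Path(path)


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end analysis run.

    ``n_per_stratum`` requests simulation; alternatively
    ``responses_file`` (plus ``profiles_file``) loads collected data.
    """

    outdir: str | Path = "bwspref_out"
    seed: int | None = None
    n_per_stratum: dict[str, int] = field(
        default_factory=lambda: {"urban": 449, "rural": 464, "provider": 172}
    )
    utilities: dict[str, float] | None = None
    reference_item: str | None = "myopathy"
    missing_rate: float = 0.0
    vas_noise_sd: float = 0.5
    ci_level: float = 0.95
    responses_file: str | None = None
    strata: tuple[str, ...] = ("total", "urban", "rural", "provider")

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.responses_file is None and self.seed is None:
            raise ValueError("simulation requested but no seed given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "strata" in raw:
            raw["strata"] = tuple(raw["strata"])
        return cls(**raw)

    def canonical(self) -> str:
        # outdir is a location, not an analysis parameter: leave it out
        # so runs into different directories hash (and byte-compare) equal
        data = dataclasses.asdict(self)
        data.pop("outdir")
        return json.dumps(data, sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def _utility_config(config: PipelineConfig) -> UtilityConfig:
    if config.utilities is None:
        base = study_utilities("total")
    else:
        ref = config.reference_item or min(config.utilities, key=config.utilities.get)
        base = UtilityConfig(utilities=dict(config.utilities), reference=ref)
    return dataclasses.replace(base, vas_noise_sd=config.vas_noise_sd)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run design -> data -> counting -> maxdiff -> VAS -> covariates.

    Returns the manifest dict (also written to ``manifest.json``).
    Re-running with an identical config reproduces every output file
    byte for byte.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "bwspref",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "outputs": {},
        "stages": {},
    }

    log.info("=== stage: design ===")
    design = statin_outcome_design()
    report = validate_design(design)
    if not report.valid:
        raise RuntimeError("design: internal design failed validation")
    write_design(design, outdir / "design.csv")
    write_catalog(design.catalog, outdir / "catalog.csv")
    manifest["stages"]["design"] = {"b": design.b, "k": design.k, "r": design.r}
    manifest["outputs"]["design"] = "design.csv"

    log.info("=== stage: data ===")
    util = _utility_config(config)
    if config.responses_file:
        dataset = read_responses(config.responses_file, design)
        vas = None
        strata_sets = {"total": dataset}
    else:
        assert config.seed is not None
        profiles = []
        for stratum, n in config.n_per_stratum.items():
            profiles.extend(
                simulate_profiles(n, stratum=stratum, seed=config.seed, id_prefix=stratum[0])
            )
        dataset = simulate_bws_responses(
            design, util, profiles, seed=config.seed, missing_rate=config.missing_rate
        )
        write_responses(dataset, outdir / "responses.csv")
        profiles_frame(profiles).to_csv(outdir / "profiles.csv", index=False)
        vas = simulate_vas(util, profiles, items=list(design.catalog.items), seed=config.seed)
        vas.to_csv(outdir / "vas.csv", index=False, float_format="%.6f")
        manifest["outputs"].update(
            {"responses": "responses.csv", "profiles": "profiles.csv", "vas": "vas.csv"}
        )
        strata_sets = {"total": _subset(dataset, ("urban", "rural"))}
        for stratum in config.n_per_stratum:
            strata_sets[stratum] = _subset(dataset, (stratum,))
    manifest["stages"]["data"] = {
        "n_respondents": dataset.n_respondents,
        "n_records": dataset.n_records,
    }

    log.info("=== stage: counting ===")
    tables = []
    for stratum in config.strata:
        if stratum not in strata_sets:
            continue
        sub = strata_sets[stratum]
        if sub.n_respondents == 0:
            continue
        tab = counting_table(sub, stratum=stratum).reset_index()
        tab.insert(0, "stratum", stratum)
        tables.append(tab)
    counting_out = pd.concat(tables, ignore_index=True)
    counting_out.to_csv(outdir / "counting.csv", index=False, float_format="%.6f")
    manifest["outputs"]["counting"] = "counting.csv"
    manifest["stages"]["counting"] = {"strata": [t["stratum"].iat[0] for t in tables]}

    log.info("=== stage: maxdiff ===")
    fit = fit_maxdiff(
        strata_sets["total"],
        design,
        reference=config.reference_item,
        ci_level=config.ci_level,
    )
    fit_table = fit.to_frame().reset_index()
    fit_table["odds_vs_ref"] = fit_table["item"].map(odds_vs_ref(fit))
    fit_table.to_csv(outdir / "maxdiff.csv", index=False, float_format="%.6f")
    sidecar = {
        "reference": fit.reference,
        "loglik": fit.loglik,
        "null_loglik": fit.null_loglik,
        "n_situations": fit.n_situations,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "separated_items": fit.separated_items,
    }
    (outdir / "maxdiff.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    manifest["outputs"]["maxdiff"] = "maxdiff.csv"
    manifest["stages"]["maxdiff"] = {"converged": fit.converged, "loglik": fit.loglik}

    if vas is not None:
        log.info("=== stage: vas_compare ===")
        bws_scores = individual_scores(strata_sets["total"])
        bws_by_item = {c: bws_scores[c].to_numpy(dtype=float) for c in bws_scores.columns}
        vas_by_item = scores_by_item(vas)
        rank_bws = rank_by_median(bws_by_item, method="BWS-median")
        rank_vas = rank_by_median(vas_by_item, method="VAS-median")
        rho, tau = rank_agreement(rank_bws, rank_vas)
        agreement = pd.DataFrame(
            {
                "item": list(rank_bws.ranks),
                "rank_bws_median": [rank_bws.ranks[i] for i in rank_bws.ranks],
                "rank_vas_median": [rank_vas.ranks[i] for i in rank_bws.ranks],
            }
        )
        agreement.to_csv(outdir / "rank_agreement.csv", index=False, float_format="%.6f")
        overlap = {
            "spearman_rho": rho,
            "kendall_tau_b": tau,
            "iqr_overlap_bws": dispersion_overlap(bws_by_item),
            "iqr_overlap_vas": dispersion_overlap(vas_by_item),
            "note": "IQR-overlap fraction is this package's operationalisation "
            "of box-plot separation; lower = better separated",
        }
        (outdir / "vas_compare.json").write_text(json.dumps(overlap, indent=2, sort_keys=True))
        manifest["outputs"]["rank_agreement"] = "rank_agreement.csv"
        manifest["stages"]["vas_compare"] = {
            "spearman_rho": rho,
            "kendall_tau_b": tau,
        }

        log.info("=== stage: covariates ===")
        general = _subset(dataset, ("urban", "rural"))
        if general.n_respondents and general.profiles:
            from .covariates import observed_coding

            reg = regress_all_items(general, coding=observed_coding(general.profiles))
            reg.to_csv(outdir / "covariates.csv", index=False, float_format="%.6f")
            manifest["outputs"]["covariates"] = "covariates.csv"
            manifest["stages"]["covariates"] = {
                "n_tests": len(reg),
                "multiple_testing_correction": "none",
            }

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["outputs"]["manifest"] = "manifest.json"
    return manifest


def _subset(dataset: ResponseDataset, strata: tuple[str, ...]) -> ResponseDataset:
    """Restrict a dataset to respondents of the given strata."""
    if not dataset.profiles:
        return dataset
    keep = {p.respondent_id for p in dataset.profiles if p.stratum in strata}
    records = dataset.records[dataset.records["respondent_id"].isin(keep)]
    profiles = [p for p in dataset.profiles if p.respondent_id in keep]
    return ResponseDataset(design=dataset.design, records=records, profiles=profiles)
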