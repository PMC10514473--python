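"""End-to-end orchestration from one structured config file.

A run executes any subset of the stages

    simulate -> select -> mr -> sensitivity -> gnova -> mediate

and writes tab-separated report tables under the configured output
directory: ``summary.tsv`` (one row per MR method with theta, OR, CI, p and
the shared heterogeneity/pleiotropy diagnostics), ``heterogeneity.tsv``,
``loo.tsv``, ``funnel.tsv``, ``rg.tsv``, ``mediation.tsv``, plus a
``manifest.json`` recording package and library versions, seeds, row counts
and SHA-256 checksums of every written table.  The same config and seed
produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, mr, sensitivity
from .genetic_correlation import estimate_rg
from .gwas_io import harmonize, kept_pairs, read_ld_scores, read_summary_table, write_summary_table
from .instruments import select_instruments
from .mediation import run_mediation
from .synthetic import MRTriplet, SimulationConfig, ZPairConfig, simulate_mr_triplet, simulate_z_pairs

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "select", "mr", "sensitivity", "gnova", "mediate")
ALL_METHODS = ("ivw", "max_likelihood", "egger", "weighted_median", "raps", "presso")


def _from_dict(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}")
    return cls(**data)


@dataclass
class SelectionParams:
    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_kb: float = 10_000
    maf_min: float = 0.01
    f_min: float = 10.0
    missing_ld: str = "retain"


@dataclass
class InputPaths:
    exposure: str | None = None
    mediator: str | None = None
    outcome: str | None = None
    ld_scores: str | None = None
    zpairs: str | None = None


@dataclass
class RunConfig:
    """Everything one pipeline run needs; round-trips through YAML unchanged."""

    outdir: str = "results/run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    methods: list[str] = field(default_factory=lambda: list(ALL_METHODS))
    ivw_model: str = "random"
    raps_loss: str = "l2"
    n_boot: int = 1000
    presso_sims: int = 1000
    palindrome_eaf_window: float = 0.08
    selection: SelectionParams = field(default_factory=SelectionParams)
    simulate: SimulationConfig | None = None
    zpairs: ZPairConfig | None = None
    paths: InputPaths = field(default_factory=InputPaths)

    def validate(self) -> None:
        for s in self.stages:
            if s not in ALL_STAGES:
                raise ValueError(f"unknown stage {s!r}; expected subset of {ALL_STAGES}")
        for m in self.methods:
            if m not in ALL_METHODS:
                raise ValueError(f"unknown method {m!r}; expected subset of {ALL_METHODS}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sub: dict[str, Any] = {}
        if "selection" in data:
            sub["selection"] = _from_dict(SelectionParams, data.pop("selection"), "selection")
        if data.get("simulate") is not None:
            sub["simulate"] = _from_dict(SimulationConfig, data.pop("simulate"), "simulate")
        if data.get("zpairs") is not None:
            sub["zpairs"] = _from_dict(ZPairConfig, data.pop("zpairs"), "zpairs")
        if "paths" in data:
            sub["paths"] = _from_dict(InputPaths, data.pop("paths"), "paths")
        data.pop("simulate", None)
        data.pop("zpairs", None)
        cfg = _from_dict(cls, {**data, **sub}, "run config")
        cfg.validate()
        return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run config, rejecting unknown keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, sep="\t", index=False)
    manifest["outputs"][path.name] = {"rows": int(len(df)), "sha256": _sha256(path)}


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages; returns the in-memory report bundle.

    Raises on a hard failure in any requested stage, naming the stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(config.stages)
    bundle: dict[str, Any] = {}
    manifest: dict[str, Any] = {
        "clockmr_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "stages": stages,
        "outputs": {},
    }
    if not stages:
        logger.warning("run_pipeline: no stages requested; writing empty bundle")
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return bundle

    exposure = mediator = outcome = None
    zpairs_tab = None
    triplet: MRTriplet | None = None

    try:
        if "simulate" in stages:
            sim_cfg = config.simulate or SimulationConfig()
            triplet = simulate_mr_triplet(sim_cfg, seed=config.seed)
            exposure, mediator, outcome = triplet.exposure, triplet.mediator, triplet.outcome
            for name, tab in (
                ("exposure.tsv", exposure), ("mediator.tsv", mediator), ("outcome.tsv", outcome)
            ):
                write_summary_table(tab, outdir / name)
                manifest["outputs"][name] = {
                    "rows": int(len(tab)), "sha256": _sha256(outdir / name)
                }
            if config.zpairs is not None:
                zpairs_tab = simulate_z_pairs(config.zpairs, seed=config.seed + 1)
                _write(zpairs_tab, outdir / "zpairs.tsv", manifest)
        else:
            p = config.paths
            if p.exposure:
                exposure = read_summary_table(p.exposure)
            if p.mediator:
                mediator = read_summary_table(p.mediator)
            if p.outcome:
                outcome = read_summary_table(p.outcome)
            if p.zpairs:
                zpairs_tab = pd.read_csv(p.zpairs, sep="\t")
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' (inputs) failed: {exc}") from exc

    sel = dataclasses.asdict(config.selection)
    instruments = None
    if "select" in stages:
        try:
            if exposure is None:
                raise ValueError("no exposure table available")
            instruments = select_instruments(exposure, **sel)
            _write(instruments, outdir / "instruments.tsv", manifest)
        except Exception as exc:
            raise RuntimeError(f"stage 'select' failed: {exc}") from exc
        bundle["instruments"] = instruments

    pairs = None
    if instruments is not None and outcome is not None and len(instruments) >= 2:
        pairs = kept_pairs(
            harmonize(instruments, outcome, palindrome_eaf_window=config.palindrome_eaf_window)
        )

    het = None
    if "mr" in stages:
        try:
            if pairs is None or len(pairs) < 2:
                raise ValueError("fewer than 2 harmonized instruments")
            het = sensitivity.cochran_q(pairs)
            rows = []
            egger_int_p = np.nan
            presso_global_p = np.nan
            for method in config.methods:
                if method == "ivw":
                    est = mr.ivw(pairs, model=config.ivw_model)
                elif method == "max_likelihood":
                    est = mr.max_likelihood(pairs)
                elif method == "egger":
                    est = mr.egger(pairs)
                    egger_int_p = est.extras["intercept_pval"]
                elif method == "weighted_median":
                    est = mr.weighted_median(pairs, n_boot=config.n_boot, seed=config.seed)
                elif method == "raps":
                    est = mr.raps(pairs, loss=config.raps_loss)
                else:
                    pres = mr.presso(
                        pairs, n_sim=config.presso_sims, seed=config.seed,
                        model=config.ivw_model,
                    )
                    est = pres.estimate
                    presso_global_p = pres.global_pval
                    bundle["presso"] = pres
                row = est.to_dict()
                row["q"] = het.q
                row["q_pval"] = het.pval
                row["extras"] = json.dumps(est.extras, default=float)
                rows.append(row)
            summary = pd.DataFrame(rows)
            summary["egger_intercept_p"] = egger_int_p
            summary["presso_global_p"] = presso_global_p
            _write(summary, outdir / "summary.tsv", manifest)
            bundle["summary"] = summary
        except Exception as exc:
            raise RuntimeError(f"stage 'mr' failed: {exc}") from exc

    if "sensitivity" in stages:
        try:
            if pairs is None or len(pairs) < 3:
                raise ValueError("fewer than 3 harmonized instruments")
            het = het or sensitivity.cochran_q(pairs)
            het_tab = pd.DataFrame(
                [{"q": het.q, "df": het.df, "pval": het.pval, "i2": het.i2}]
            )
            _write(het_tab, outdir / "heterogeneity.tsv", manifest)
            loo = sensitivity.leave_one_out(pairs, model=config.ivw_model)
            _write(loo.table, outdir / "loo.tsv", manifest)
            funnel = sensitivity.funnel_data(pairs)
            _write(funnel.points, outdir / "funnel.tsv", manifest)
            bundle["heterogeneity"] = het
            bundle["leave_one_out"] = loo
            bundle["funnel"] = funnel
        except Exception as exc:
            raise RuntimeError(f"stage 'sensitivity' failed: {exc}") from exc

    if "gnova" in stages:
        try:
            if zpairs_tab is None:
                raise ValueError("no z-pair table available (configure zpairs or paths.zpairs)")
            zc = config.zpairs or ZPairConfig()
            rg = estimate_rg(
                zpairs_tab["z1"], zpairs_tab["z2"], zpairs_tab["ldscore"],
                n1=zc.n1, n2=zc.n2,
            )
            rg_tab = pd.DataFrame([{
                "rho_g": rg.rho_g, "h2_1": rg.h2_1, "h2_2": rg.h2_2, "rg": rg.rg,
                "se_rg": rg.se_rg, "pval": rg.pval, "m_snps": rg.m_snps,
                "n_blocks": rg.n_blocks,
            }])
            _write(rg_tab, outdir / "rg.tsv", manifest)
            bundle["rg"] = rg
        except Exception as exc:
            raise RuntimeError(f"stage 'gnova' failed: {exc}") from exc

    if "mediate" in stages:
        try:
            if exposure is None or mediator is None or outcome is None:
                raise ValueError("mediation needs exposure, mediator and outcome tables")
            cis = triplet.mediator_cis_ids if triplet is not None else None
            med = run_mediation(
                exposure, mediator, outcome,
                selection=sel, palindrome_eaf_window=config.palindrome_eaf_window,
                mediator_cis_ids=cis, model=config.ivw_model,
            )
            med_tab = pd.DataFrame([med.to_dict()])
            _write(med_tab, outdir / "mediation.tsv", manifest)
            bundle["mediation"] = med
        except Exception as exc:
            raise RuntimeError(f"stage 'mediate' failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    return bundle
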