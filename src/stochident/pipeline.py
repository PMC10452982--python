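"""End-to-end identifiability pipeline and backend comparison.

``run_pipeline`` drives one model through one sensitivity backend into an
:class:`~stochident.identify.IdentifiabilityReport`, writing the per-table
CSV artifacts, a JSON report and a run manifest; ``compare_backends`` merges
several runs of the same model into side-by-side tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .analytic import cle_pathwise_sensitivity, rre_sensitivity
from .fd import FDConfig, estimate_sensitivity
from .fixtures import FIXTURE_NAMES, fixture
from .identify import (CI_THRESHOLD, DELTA_THRESHOLD, build_concatenated,
                       delta_msqr, normalize_columns,
                       select_identifiable_subsets)
from .network import ModelConfigError, load_model
from .simulate import uniform_grid

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "compare_backends"]

log = logging.getLogger("stochident")

BACKENDS = ("CFD", "CRP", "CRN", "CLE", "RRE")
FD_BACKENDS = ("CFD", "CRP", "CRN")

# Default grid density per backend class: the deterministic / diffusion
# analyses resolve the transient finely; the jump-process Monte Carlo runs
# use a coarser grid since each column already carries sampling error.
DEFAULT_GRID_POINTS = {"RRE": 500, "CLE": 500, "CFD": 50, "CRP": 50, "CRN": 50}


class PipelineError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    model: str                          # fixture name or model-file path
    backend: str = "RRE"
    R: int = 10_000
    theta: float | None = None          # required for FD backends
    perturbation_mode: str = "relative"
    grid_points: int | None = None
    horizon: float | None = None
    dt: float = 1e-3                    # CLE backend only
    delta_threshold: float = DELTA_THRESHOLD
    ci_threshold: float = CI_THRESHOLD
    mask_tol: float | None = None
    rank_tol: float | None = None
    zero_tol: float | None = None
    max_subset_size: int | None = None
    observed: list | None = None        # species names; None = all
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.backend not in BACKENDS:
            raise ModelConfigError(
                f"unknown backend {self.backend!r}; expected one of {BACKENDS}")
        if self.backend in FD_BACKENDS and self.theta is None:
            raise ModelConfigError(
                f"backend {self.backend} requires a perturbation theta")


def _load(config):
    if config.model in FIXTURE_NAMES:
        net, c, x0, T = fixture(config.model)
    else:
        net, c, x0, T = load_model(config.model)
    if config.horizon is not None:
        T = float(config.horizon)
    return net, c, x0, T


def _sensitivities(config, net, c, x0, grid):
    backend = config.backend
    if backend == "RRE":
        sol = rre_sensitivity(net, c, x0.astype(float), grid)
        return sol.sens, sol.states, {"R": None, "theta": None}
    if backend == "CLE":
        ens = cle_pathwise_sensitivity(net, c, x0.astype(float), grid,
                                       dt=config.dt, R=config.R,
                                       seed=config.seed)
        return ens.mean_sens, ens.mean_states, {"R": config.R, "theta": None}
    fdc = FDConfig(estimator=backend, R=config.R, theta=config.theta,
                   perturbation_mode=config.perturbation_mode,
                   seed=config.seed)

    def progress(k, r):
        log.info("parameter %d: %d/%d coupled pairs", k, r, config.R)

    tensor, means = estimate_sensitivity(net, c, x0, grid, fdc,
                                         progress=progress)
    return tensor.values, means.means, {"R": config.R,
                                        "theta": list(tensor.theta)}


def _ci_json(ci):
    if ci is None:
        return None
    if math.isinf(ci):
        return "inf"
    return ci


def _report_dict(report, net, meta):
    return {
        "parameters": list(net.param_names),
        "delta_msqr": {name: float(d) for name, d in
                       zip(net.param_names, report.delta)},
        "ranked_parameters": [net.param_names[k] for k in report.ranked_params],
        "subsets": [{
            "parameters": [net.param_names[k] for k in s.indices],
            "collinearity_index": _ci_json(s.ci),
            "determinant_measure": s.rho,
            "identifiable": s.identifiable,
        } for s in report.subsets],
        "singular_values": [float(v) for v in report.singular_values],
        "rank": report.rank,
        "thresholds": {"delta": report.delta_threshold,
                       "ci": report.ci_threshold},
        "warnings": report.warnings,
        **meta,
    }


def _write_tables(report, net, outdir):
    paths = []
    p = outdir / "delta.csv"
    pd.DataFrame({"parameter": list(net.param_names),
                  "delta_msqr": report.delta}).to_csv(p, index=False)
    paths.append(p)
    by_size = {}
    for s in report.subsets:
        by_size.setdefault(len(s.indices), []).append(s)
    for k, subsets in sorted(by_size.items()):
        p = outdir / f"collinearity_k{k}.csv"
        pd.DataFrame([{
            "subset": " ".join(net.param_names[i] for i in s.indices),
            "collinearity_index": ("*" if s.ci is None else s.ci),
            "determinant_measure": s.rho,
            "identifiable": s.identifiable,
        } for s in subsets]).to_csv(p, index=False)
        paths.append(p)
    p = outdir / "svd.csv"
    pd.DataFrame({"singular_value": report.singular_values}).to_csv(p, index=False)
    paths.append(p)
    return paths


def run_pipeline(config):
    """Run model -> sensitivities -> identifiability report (+ artifacts).

    Deterministic given (config, seed). Returns ``(report, artifacts)`` where
    ``artifacts`` maps artifact names to paths (empty when no outdir is set).
    On error, partially written outputs are removed and a
    :class:`PipelineError` naming the failing stage is raised.
    """
    t0 = time.perf_counter()
    stage = "load_model"
    written = []
    try:
        net, c, x0, T = _load(config)
        L = config.grid_points or DEFAULT_GRID_POINTS[config.backend]
        grid = uniform_grid(T, L)
        log.info("model %s: N=%d species, M=%d reactions, P=%d parameters, "
                 "T=%g, L=%d", config.model, net.n_species, net.n_reactions,
                 net.n_params, T, L)

        stage = "sensitivity"
        sens, means, meta = _sensitivities(config, net, c, x0, grid)
        log.info("sensitivity backend %s done in %.1fs", config.backend,
                 time.perf_counter() - t0)

        stage = "identifiability"
        observed = None
        if config.observed is not None:
            observed = [net.species_names.index(s) for s in config.observed]
        concat = build_concatenated(
            type("S", (), {"values": sens, "grid": grid})(), means, c,
            mask_tol=config.mask_tol, observed=observed)
        delta = delta_msqr(concat)
        normalized = normalize_columns(concat, zero_tol=config.zero_tol)
        report = select_identifiable_subsets(
            normalized, delta, delta_threshold=config.delta_threshold,
            ci_threshold=config.ci_threshold,
            max_subset_size=config.max_subset_size,
            rank_tol=config.rank_tol, raw=concat.matrix)

        artifacts = {}
        if config.outdir is not None:
            stage = "write_outputs"
            outdir = Path(config.outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            written = _write_tables(report, net, outdir)
            meta_full = {"backend": config.backend, "model": config.model,
                         "grid_points": L, "horizon": T, "seed": config.seed,
                         **meta}
            p = outdir / "report.json"
            with open(p, "w") as fh:
                json.dump(_report_dict(report, net, meta_full), fh, indent=2)
            written.append(p)
            p = outdir / "manifest.json"
            cfg = asdict(config)
            with open(p, "w") as fh:
                json.dump({
                    "config": cfg,
                    "config_sha256": hashlib.sha256(
                        json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
                    "versions": _versions(),
                    "wall_clock_s": time.perf_counter() - t0,
                }, fh, indent=2)
            written.append(p)
            artifacts = {p.name: p for p in written}
        log.info("pipeline done in %.1fs", time.perf_counter() - t0)
        return report, artifacts
    except Exception as e:
        for p in written:
            try:
                Path(p).unlink()
            except OSError:
                pass
        if isinstance(e, PipelineError):
            raise
        raise PipelineError(stage, e) from e


def _versions():
    import numba
    import scipy

    from . import __version__
    return {"stochident": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "numba": numba.__version__}


def compare_backends(configs):
    """Run several backends on one model/grid; merge CI and delta tables.

    Returns ``(delta_table, ci_table)`` DataFrames with one column per
    backend, mirroring the side-by-side layout used to validate stochastic
    estimates against deterministic ones.
    """
    if not configs:
        raise ModelConfigError("no configurations given")
    base = configs[0]
    for cfg in configs[1:]:
        if cfg.model != base.model:
            raise ModelConfigError("compare_backends requires one model")
        if (cfg.grid_points or DEFAULT_GRID_POINTS[cfg.backend]) != \
                (base.grid_points or DEFAULT_GRID_POINTS[base.backend]):
            raise ModelConfigError("compare_backends requires one grid")
        if (cfg.delta_threshold, cfg.ci_threshold) != \
                (base.delta_threshold, base.ci_threshold):
            raise ModelConfigError("compare_backends requires shared thresholds")
    net, _, _, _ = _load(base)
    names = net.param_names
    delta_cols, ci_cols = {}, {}
    for cfg in configs:
        report, _ = run_pipeline(cfg)
        label = cfg.backend
        delta_cols[label] = {names[k]: float(report.delta[k])
                             for k in range(len(names))}
        ci_cols[label] = {
            " ".join(names[i] for i in s.indices):
                ("*" if s.ci is None else s.ci)
            for s in report.subsets}
    delta_table = pd.DataFrame(delta_cols)
    delta_table.index.name = "parameter"
    ci_table = pd.DataFrame(ci_cols)
    ci_table.index.name = "subset"
    if base.outdir is not None:
        outdir = Path(base.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        delta_table.to_csv(outdir / "compare_delta.csv")
        ci_table.to_csv(outdir / "compare_ci.csv")
    return delta_table, ci_table
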