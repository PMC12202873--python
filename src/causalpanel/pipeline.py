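"""End-to-end orchestration: config, staged execution, outputs, manifest."""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .granger import granger_scan, scan_to_frame
from .panel import read_panel_csv, write_panel_csv
from .pcmci import run_pcmciplus
from .preprocessing import DEFAULT_PERIODS, preprocess, report_to_frame, stationarity_report
from .robustness import DEFAULT_ALPHA_GRID, DEFAULT_TAU_GRID, link_persistence, persistence_to_frame
from .graphs import write_graph_json

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

log = logging.getLogger("causalpanel")


@dataclass
class PipelineConfig:
    """Flat run configuration; defaults reproduce the study settings."""

    periods: tuple[float, ...] = DEFAULT_PERIODS
    detrend_bandwidth: int = 365
    tau_max: int = 7
    alpha: float = 0.05
    granger_lags: tuple[int, ...] = tuple(range(1, 8))
    granger_sink: str = "background_checks"
    persistence_tau_grid: tuple[int, ...] = DEFAULT_TAU_GRID
    persistence_alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        self.periods = tuple(float(p) for p in self.periods)
        self.granger_lags = tuple(int(l) for l in self.granger_lags)
        self.persistence_tau_grid = tuple(int(t) for t in self.persistence_tau_grid)
        self.persistence_alpha_grid = tuple(float(a) for a in self.persistence_alpha_grid)
        if any(p <= 0 for p in self.periods):
            raise ValueError("periods must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.tau_max < 1:
            raise ValueError("tau_max must be >= 1")
        if any(not (0.0 < a < 1.0) for a in self.persistence_alpha_grid):
            raise ValueError("persistence alphas must lie in (0, 1)")
        if any(l < 1 for l in self.granger_lags):
            raise ValueError("granger lags must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}


@dataclass
class RunManifest:
    config: dict
    input_path: str
    input_sha256: str
    outputs: dict[str, str]
    timings_s: dict[str, float]
    version: str = __version__
    seed: int = 0

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, input_path, outdir) -> RunManifest:
    """preprocess -> stationarity report -> discovery -> persistence -> Granger.

    Writes ``clean.csv``, ``stationarity.csv``, ``graph.json``,
    ``persistence.csv``, ``granger.csv`` and ``manifest.json`` under
    ``outdir``; never mutates the input file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    timings: dict[str, float] = {}

    def stage(name: str):
        log.info("stage %s starting", name)
        return time.perf_counter()

    try:
        t0 = stage("preprocess")
        panel = read_panel_csv(input_path)
        clean = preprocess(panel, config.periods, bandwidth=config.detrend_bandwidth)
        write_panel_csv(clean, outdir / "clean.csv")
        outputs["clean"] = str(outdir / "clean.csv")
        timings["preprocess"] = time.perf_counter() - t0

        t0 = stage("stationarity")
        reports = stationarity_report(clean, alpha=config.alpha)
        report_to_frame(reports).to_csv(outdir / "stationarity.csv", index=False)
        outputs["stationarity"] = str(outdir / "stationarity.csv")
        timings["stationarity"] = time.perf_counter() - t0
        for rep in reports:
            if not rep.verdict:
                log.warning("series %s failed the stationarity gate", rep.variable)

        t0 = stage("discovery")
        graph = run_pcmciplus(clean, tau_max=config.tau_max, alpha=config.alpha)
        write_graph_json(graph, outdir / "graph.json")
        outputs["graph"] = str(outdir / "graph.json")
        timings["discovery"] = time.perf_counter() - t0
        log.info("discovery found %d links (%d cross)", len(graph.links), len(graph.cross_links()))

        t0 = stage("persistence")
        records = link_persistence(
            clean, config.persistence_tau_grid, config.persistence_alpha_grid
        )
        persistence_to_frame(records).to_csv(outdir / "persistence.csv", index=False)
        outputs["persistence"] = str(outdir / "persistence.csv")
        timings["persistence"] = time.perf_counter() - t0

        t0 = stage("granger")
        sink = (
            clean.names.index(config.granger_sink)
            if config.granger_sink in clean.names
            else clean.n_vars - 1
        )
        results = granger_scan(clean, sink, config.granger_lags)
        scan_to_frame(results).to_csv(outdir / "granger.csv", index=False)
        outputs["granger"] = str(outdir / "granger.csv")
        timings["granger"] = time.perf_counter() - t0
    except Exception as err:  # surface the failing stage
        done = set(timings)
        stage_order = ["preprocess", "stationarity", "discovery", "persistence", "granger"]
        current = next((s for s in stage_order if s not in done), "granger")
        raise RuntimeError(f"pipeline stage '{current}' failed: {err}") from err

    outputs["manifest"] = str(outdir / "manifest.json")
    manifest = RunManifest(
        config=config.as_dict(),
        input_path=str(input_path),
        input_sha256=_sha256(input_path),
        outputs=outputs,
        timings_s=timings,
        seed=config.seed,
    )
    manifest.write(outdir / "manifest.json")
    return manifest
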