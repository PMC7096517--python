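"""End-to-end benchmark driver.

Simulates replicate datasets for the requested values of ``f``, runs the
requested selection and group methods, and reports median-over-replicates
metrics per (f, method) plus per-group selection frequencies.  Every
replicate's raw result is written to the output directory as JSON, so an
interrupted run resumes where it stopped.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import (
    band_sensitivity,
    false_positive_rate,
    selection_frequency,
    variable_sensitivity,
)
from .groups import GroupParams, groups_from_library, select_lefe, select_pe
from .selection import SELECTION_DISPATCH, AnalysisParams
from .simulate import (
    SimulationConfig,
    build_library,
    library_rng,
    replicate_rng,
    simulate_replicate,
    spectral_grid,
)

__all__ = ["BenchmarkConfig", "BenchmarkReport", "run_benchmark"]

SELECTION_METHODS = SELECTION_DISPATCH
GROUP_METHODS = {"lefe": select_lefe, "pe": select_pe}


@dataclass
class BenchmarkConfig:
    """Benchmark run configuration (YAML-loadable).

    ``scaled`` defaults keep a desk-size footprint: 10 replicates and
    500 trees for the selection methods, 200 trees and 50 permutations
    for the group methods; the full-scale study values (50 replicates,
    10000 / 1000 trees, 100 permutations) are plain config settings.
    """

    f_values: tuple[float, ...] = (0.8, 0.5, 0.2, 0.05, 0.0)
    methods: tuple[str, ...] = ("vita", "boruta", "md", "smd")
    group_methods: tuple[str, ...] = ()
    n_replicates: int = 10
    n_per_group: int = 500
    selection_ntree: int = 500
    group_ntree: int = 200
    n_permutations: int = 50
    sample_runs: int = 25
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BenchmarkConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("f_values", "methods", "group_methods"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class BenchmarkReport:
    metrics: pd.DataFrame  # per (f, method): median metrics
    group_frequencies: pd.DataFrame | None
    provenance: dict
    failures: list[dict] = field(default_factory=list)


def _replicate_payload(path: Path):
    if path.exists():
        return json.loads(path.read_text())
    return None


def run_benchmark(config: BenchmarkConfig, out_dir: str | Path | None = None) -> BenchmarkReport:
    """Run the configured benchmark; medians are over the replicates run.

    Per-replicate JSON results are cached in ``out_dir`` (when given) and
    reused on re-runs.  Failures are recorded in the report instead of
    being silently dropped.
    """
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    group_rows = []
    failures = []
    for f in config.f_values:
        sim = SimulationConfig(
            f=f,
            n_replicates=config.n_replicates,
            n_per_group=config.n_per_group,
            seed=config.seed,
        )
        grid = spectral_grid()
        library = build_library(grid, library_rng(sim), sim)
        groups = groups_from_library(library, grid, sim.band_extent_k)
        for rep in range(1, config.n_replicates + 1):
            cache = (
                out_dir / f"f{f:g}_rep{rep:03d}.json" if out_dir is not None else None
            )
            payload = _replicate_payload(cache) if cache is not None else None
            if payload is None:
                payload = {"f": f, "replicate": rep, "methods": {}, "groups": {}}
                ds = simulate_replicate(library, sim, rep, replicate_rng(sim, rep))
                char_masks = ds.characteristic_band_masks
                seed_rep = config.seed + 1000 * rep
                for m in config.methods:
                    try:
                        res = SELECTION_METHODS[m](
                            ds.spectra,
                            ds.labels,
                            AnalysisParams(ntree=config.selection_ntree),
                            random_state=seed_rep,
                        )
                        payload["methods"][m] = {
                            "selected": res.selected.astype(int).tolist(),
                            "variable_sensitivity": variable_sensitivity(
                                res.selected, ds.char_band_mask
                            ),
                            "band_sensitivity": band_sensitivity(
                                res.selected, char_masks
                            ),
                            "false_positive_rate": false_positive_rate(
                                res.selected, ds.char_band_mask
                            ),
                        }
                    except Exception as exc:  # pragma: no cover - logged, not dropped
                        failures.append(
                            {"f": f, "replicate": rep, "method": m, "error": str(exc)}
                        )
                gp = GroupParams(
                    ntree=config.group_ntree,
                    n_permutations=config.n_permutations,
                    sample_runs=config.sample_runs,
                )
                for m in config.group_methods:
                    try:
                        res = GROUP_METHODS[m](
                            ds.spectra, ds.labels, groups, gp, random_state=seed_rep
                        )
                        payload["groups"][m] = {
                            "names": res.names,
                            "selected": res.selected.astype(int).tolist(),
                        }
                    except Exception as exc:  # pragma: no cover
                        failures.append(
                            {"f": f, "replicate": rep, "method": m, "error": str(exc)}
                        )
                if cache is not None:
                    cache.write_text(json.dumps(payload))
            for m, res in payload["methods"].items():
                rows.append(
                    {
                        "f": f,
                        "method": m,
                        "replicate": payload["replicate"],
                        "variable_sensitivity": res["variable_sensitivity"],
                        "band_sensitivity": res["band_sensitivity"],
                        "false_positive_rate": res["false_positive_rate"],
                    }
                )
            for m, res in payload["groups"].items():
                for name, sel in zip(res["names"], res["selected"]):
                    group_rows.append(
                        {
                            "f": f,
                            "method": m,
                            "replicate": payload["replicate"],
                            "group": name,
                            "selected": sel,
                        }
                    )
    metrics = pd.DataFrame(rows)
    if not metrics.empty:
        metrics = (
            metrics.groupby(["f", "method"])[
                ["variable_sensitivity", "band_sensitivity", "false_positive_rate"]
            ]
            .median()
            .reset_index()
        )
    group_freq = None
    if group_rows:
        gdf = pd.DataFrame(group_rows)
        group_freq = (
            gdf.groupby(["f", "method", "group"])["selected"].mean().reset_index()
        ).rename(columns={"selected": "selection_frequency"})
    provenance = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(config).items()},
        "package_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
    }
    report = BenchmarkReport(metrics, group_freq, provenance, failures)
    if out_dir is not None:
        metrics.to_csv(out_dir / "metrics.tsv", sep="\t", index=False)
        if group_freq is not None:
            group_freq.to_csv(out_dir / "group_frequencies.tsv", sep="\t", index=False)
        (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))
        if failures:
            (out_dir / "failures.json").write_text(json.dumps(failures, indent=2))
    return report
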