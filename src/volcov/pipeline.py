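"""End-to-end orchestration: simulate → network → metrics → statistics.

A single :class:`PipelineConfig` (YAML/JSON) drives the whole run; every
source of randomness derives deterministically from its one ``seed``, and
the run directory plus the on-disk intermediates are the only state, so any
stage can be re-run from the files of the previous one.  Each stage logs one
structured line with its parameters and the SHA-256 of every file it wrote.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np

from . import __version__
from .core_data import (
    MetricReport,
    load_region_atlas,
    read_volume_table,
    write_metrics,
    write_network,
    write_volume_table,
)
from .graph_metrics import NullModelConfig, metrics_over_range
from .network_construction import build_network
from .statistics import anova_per_region, bland_altman, compare_network_metrics, icc, whole_brain_volume
from .synthetic_data import CohortConfig, generate_cohort, generate_repeats

__all__ = ["PipelineConfig", "run_all", "load_config"]

logger = logging.getLogger("volcov")


@dataclass
class PipelineConfig:
    """Single configuration for an end-to-end synthetic run."""

    seed: int
    n_subjects: int = 22
    n_modules: int = 4
    within_module_corr: float = 0.6
    between_module_corr: float = 0.1
    repeat_sd: float = 1.0
    n_repeats: int = 2
    sparsity_min: float = 0.10
    sparsity_max: float = 0.46
    sparsity_step: float = 0.02
    shrinkage: str | float = "auto"
    edge_rule: str = "positive"
    n_null: int = 100
    rewires_per_edge: int = 10
    lambda_tol: float = 1.5
    alpha: float = 0.05
    adjustment: str = "none"
    n_perm: int = 200

    def sparsity_range(self) -> tuple[float, ...]:
        n = int(round((self.sparsity_max - self.sparsity_min) / self.sparsity_step)) + 1
        return tuple(round(self.sparsity_min + k * self.sparsity_step, 10) for k in range(n))

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            n_subjects=self.n_subjects,
            seed=self.seed,
            n_modules=self.n_modules,
            within_module_corr=self.within_module_corr,
            between_module_corr=self.between_module_corr,
            repeat_sd=self.repeat_sd,
        )

    def null_config(self) -> NullModelConfig:
        return NullModelConfig(
            n_null=self.n_null,
            rewires_per_edge=self.rewires_per_edge,
            seed=self.seed,
            lambda_tol=self.lambda_tol,
        )


def config_from_mapping(mapping: dict) -> PipelineConfig:
    """Build a validated config, naming any missing/unknown key and its type."""
    known = {f.name: f for f in fields(PipelineConfig)}
    unknown = sorted(set(mapping) - set(known))
    if unknown:
        raise KeyError(f"unknown config keys: {unknown}")
    if "seed" not in mapping:
        raise KeyError("missing required config key 'seed' (expected type: int)")
    kwargs = {}
    for name, value in mapping.items():
        f = known[name]
        if name in ("seed", "n_subjects", "n_modules", "n_repeats", "n_null",
                    "rewires_per_edge", "n_perm"):
            if not isinstance(value, int) or isinstance(value, bool):
                raise TypeError(f"config key {name!r} expects type int, got {value!r}")
        kwargs[name] = value
    return PipelineConfig(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from a YAML or JSON file."""
    import yaml

    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)  # YAML is a JSON superset
    if not isinstance(data, dict):
        raise TypeError(f"{path}: config must be a mapping")
    return config_from_mapping(data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log_stage(stage: str, params: dict, outputs: list[Path]) -> None:
    sums = {p.name: _sha256(p)[:16] for p in outputs}
    logger.info("stage=%s params=%s outputs=%s", stage, json.dumps(params), json.dumps(sums))


def run_all(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run the full synthetic pipeline; returns the output directory.

    Outputs: per-workflow volume tables and networks, per-workflow metric
    reports, repeated-measurement tables with ICC and Bland–Altman results,
    the per-region ANOVA, the permutation comparison of network metrics, a
    run manifest (config hash, seed, versions) and a log.  A stage failure
    aborts with the stage named; outputs of completed stages are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    atlas = load_region_atlas()
    stage = "simulate"
    try:
        # --- simulate ------------------------------------------------------
        cohort_cfg = config.cohort_config()
        tables = generate_cohort(cohort_cfg)
        (out / "volumes").mkdir(exist_ok=True)
        vol_paths = []
        for wf, table in tables.items():
            p = out / "volumes" / f"{wf}.csv"
            write_volume_table(table, p)
            vol_paths.append(p)
        repeats = generate_repeats(cohort_cfg, config.n_repeats)
        (out / "repeats").mkdir(exist_ok=True)
        for rep in repeats:
            p = out / "repeats" / f"measurement_{rep.measurement_id}.csv"
            write_volume_table(rep, p)
            vol_paths.append(p)
        _log_stage(stage, {"seed": config.seed, "n_subjects": config.n_subjects}, vol_paths)

        # --- network -------------------------------------------------------
        stage = "network"
        grid = config.sparsity_range()
        networks = {}
        net_paths = []
        for wf in tables:
            t = read_volume_table(out / "volumes" / f"{wf}.csv", atlas, workflow=wf)
            networks[wf] = build_network(t, grid, config.shrinkage, config.edge_rule)
            d = out / "networks" / wf
            write_network(networks[wf], d)
            net_paths.append(d / "weights.csv")
        _log_stage(stage, {"sparsity": list(grid), "shrinkage": str(config.shrinkage)}, net_paths)

        # --- metrics -------------------------------------------------------
        stage = "metrics"
        (out / "metrics").mkdir(exist_ok=True)
        met_paths = []
        for wf, net in networks.items():
            report = metrics_over_range(net, config.null_config())
            p = out / "metrics" / f"{wf}.json"
            write_metrics(report, p)
            met_paths.append(p)
        _log_stage(stage, {"n_null": config.n_null}, met_paths)

        # --- repeatability -------------------------------------------------
        stage = "repeatability"
        rep_tables = [
            read_volume_table(
                out / "repeats" / f"measurement_{k}.csv", atlas,
                workflow="iBEAT_corrected", measurement_id=k,
            )
            for k in range(1, config.n_repeats + 1)
        ]
        icc_res = icc(rep_tables)
        ba = bland_altman(
            whole_brain_volume(rep_tables[0]), whole_brain_volume(rep_tables[1])
        )
        stat_paths = []
        with open(out / "icc.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "model": icc_res.model,
                    "average": icc_res.average,
                    "per_region": dict(
                        zip(icc_res.region_names, icc_res.per_region.tolist())
                    ),
                    "degenerate_regions": icc_res.degenerate_regions,
                },
                fh, indent=2,
            )
        with open(out / "bland_altman.json", "w", encoding="utf-8") as fh:
            json.dump(vars(ba), fh, indent=2)
        stat_paths += [out / "icc.json", out / "bland_altman.json"]
        _log_stage(stage, {"n_repeats": config.n_repeats, "repeat_sd": config.repeat_sd}, stat_paths)

        # --- anova ---------------------------------------------------------
        stage = "anova"
        comp = anova_per_region(tables, alpha=config.alpha, adjustment=config.adjustment)
        with open(out / "anova.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "alpha": comp.alpha,
                    "adjustment": comp.adjustment,
                    "n_significant": comp.n_significant,
                    "per_region": {
                        name: {"F": float(f), "p": float(p)}
                        for name, f, p in zip(
                            comp.region_names, comp.f_statistic, comp.p_value
                        )
                    },
                },
                fh, indent=2,
            )
        _log_stage(stage, {"alpha": config.alpha}, [out / "anova.json"])

        # --- network comparison -------------------------------------------
        stage = "compare"
        comparisons = compare_network_metrics(
            tables, grid, config.shrinkage, config.edge_rule,
            n_perm=config.n_perm, seed=config.seed,
        )
        with open(out / "comparison.json", "w", encoding="utf-8") as fh:
            json.dump(
                [
                    {
                        "pair": list(c.pair),
                        "observed_auc_diff": c.observed,
                        "p_value": c.p_value,
                        "n_perm": c.n_perm,
                    }
                    for c in comparisons
                ],
                fh, indent=2,
            )
        _log_stage(stage, {"n_perm": config.n_perm}, [out / "comparison.json"])

        # --- manifest ------------------------------------------------------
        cfg_dict = asdict(config)
        cfg_json = json.dumps(cfg_dict, sort_keys=True)
        manifest = {
            "config": cfg_dict,
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "seed": config.seed,
            "versions": {
                "volcov": __version__,
                "numpy": np.__version__,
            },
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2)
    except Exception as exc:
        logger.error("stage=%s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
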