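"""Configuration, orchestration and reporting for desk-scale pipeline runs.

A run config declares experiment blocks (simulate a design and analyse it,
or analyse an existing CSV) and an optional guarding-model block (naive vs
experienced parameters plus sweeps).  ``run_pipeline`` executes the blocks
in order, derives every random stream from the single global seed, isolates
per-block failures as structured errors, and returns a machine-readable
bundle that serialises losslessly to JSON.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .fecundity import paternity_share, records_from_table, relative_ratio
from .guarding import (
    GuardingParams,
    classify_regime,
    optimal_guarding_time,
    parameter_sweep,
    predict_smd,
)
from .simulate import (
    AssayDesign,
    CrossDesign,
    FecundityDesign,
    FluorescenceDesign,
    generate_calexa,
    generate_fecundity,
    generate_md_assay,
    generate_paternity,
)
from .stats import compare_experiment, normalize_fluorescence

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "write_report", "read_report", "read_table"]

log = logging.getLogger("mateguard")

#: Paper-derived defaults, centralised: minimum group size, the one-hour
#: inclusion window (s), bootstrap resamples and the star thresholds.
DEFAULTS = {
    "n_per_group": 36,
    "mating_window_s": 3600.0,
    "n_resamples": 5000,
    "star_thresholds": {"***": 0.001, "**": 0.01, "*": 0.05},
}

TABLE_SCHEMAS = {
    "md": ["fly_id", "genotype", "condition", "mating_duration_s", "copulation_latency_s"],
    "fecundity": ["female_id", "arm", "eggs_24h", "progeny"],
    "paternity": ["female_id", "mother_gt", "sire1_gt", "sire2_gt", "n_sepia", "n_wildtype"],
    "calexa": ["fly_id", "condition", "segment", "gfp", "autofluorescence"],
}

_DESIGNS = {
    "md": (AssayDesign, generate_md_assay),
    "fecundity": (FecundityDesign, generate_fecundity),
    "paternity": (CrossDesign, generate_paternity),
    "calexa": (FluorescenceDesign, generate_calexa),
}


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    experiments: tuple[dict, ...] = ()
    model: dict | None = None
    output_dir: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {"seed", "experiments", "model", "output_dir", "log_level"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        exps = tuple(d.get("experiments", ()))
        for i, block in enumerate(exps):
            if "name" not in block or "kind" not in block:
                raise ValueError(f"experiment block {i} needs 'name' and 'kind'")
            if block["kind"] not in _DESIGNS:
                raise ValueError(f"block {block['name']!r}: unknown kind {block['kind']!r}")
            if "design" not in block and "input_csv" not in block:
                raise ValueError(f"block {block['name']!r}: needs 'design' or 'input_csv'")
            if "input_csv" in block and not Path(block["input_csv"]).exists():
                raise ValueError(f"block {block['name']!r}: input_csv not found")
        return cls(
            seed=int(d.get("seed", 0)),
            experiments=exps,
            model=d.get("model"),
            output_dir=d.get("output_dir"),
            log_level=d.get("log_level", "INFO"),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class ReportBundle:
    provenance: dict
    experiments: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "experiments": self.experiments,
            "model": self.model,
            "errors": self.errors,
        }


def _jsonable(obj: Any) -> Any:
    """Recursively convert results (dataclasses, numpy, frames) to JSON types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _config_hash(config: RunConfig) -> str:
    canon = json.dumps(
        {
            "seed": config.seed,
            "experiments": list(config.experiments),
            "model": config.model,
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _run_experiment(block: dict, seed: int) -> dict:
    kind = block["kind"]
    if "input_csv" in block:
        table = read_table(block["input_csv"], kind)
    else:
        design_cls, generator = _DESIGNS[kind]
        design_kwargs = dict(block.get("design", {}))
        design_kwargs.setdefault("seed", seed)
        if kind == "md" and "groups" in design_kwargs:
            design_kwargs["groups"] = tuple(tuple(g) for g in design_kwargs["groups"])
        table = generator(design_cls(**design_kwargs))
    plan = dict(block.get("plan", {}))
    out: dict = {"n_rows": int(len(table))}

    if kind == "md":
        result = compare_experiment(
            table,
            metric=plan.get("metric", "mating_duration_s"),
            group_by=tuple(plan.get("group_by", ("condition",))),
            groups=plan.get("groups"),
            reference=plan.get("reference"),
            window=plan.get("window", DEFAULTS["mating_window_s"]),
            n_resamples=plan.get("n_resamples", DEFAULTS["n_resamples"]),
            seed=seed,
        )
        out["comparison"] = _jsonable(result[0])
        out["estimation"] = _jsonable(result[1])
        if len(result) > 2:
            out["multi_group"] = _jsonable(result[2])
    elif kind == "fecundity":
        arms = sorted(table["arm"].unique())
        naive_default = next((a for a in arms if "naive" in a), arms[0])
        exp_default = next((a for a in arms if a != naive_default), arms[-1])
        naive_arm = plan.get("naive_arm", naive_default)
        exp_arm = plan.get("experienced_arm", exp_default)
        for qty in ("eggs_24h", "progeny"):
            out[f"{qty}_ratio"] = relative_ratio(
                table.loc[table["arm"] == naive_arm, qty],
                table.loc[table["arm"] == exp_arm, qty],
                seed=seed,
            )
    elif kind == "paternity":
        out["paternity"] = _jsonable(paternity_share(records_from_table(table)))
    elif kind == "calexa":
        table = table.assign(
            normalized=normalize_fluorescence(table["gfp"], table["autofluorescence"])
        )
        out["segments"] = {}
        for segment, sub in table.groupby("segment"):
            comparison, estimation = compare_experiment(
                sub,
                metric="normalized",
                group_by=("condition",),
                reference=plan.get("reference", "naive"),
                window=None,
                n_resamples=plan.get("n_resamples", DEFAULTS["n_resamples"]),
                seed=seed,
            )
            out["segments"][segment] = {
                "comparison": _jsonable(comparison),
                "estimation": _jsonable(estimation),
            }
    return out


def _run_model_block(model: dict) -> dict:
    solver = dict(model.get("solver", {}))
    method = solver.get("method", "closed_form")
    grid_size = int(solver.get("grid_size", 10_000))
    tolerance = float(solver.get("tolerance", 1e-8))
    out: dict = {}
    naive = GuardingParams(**model["naive"]) if "naive" in model else None
    if naive is not None:
        opt = optimal_guarding_time(naive, method, grid_size, tolerance)
        out["naive"] = {**_jsonable(opt), "regime": classify_regime(naive)}
    if naive is not None and "experienced" in model:
        experienced = GuardingParams(**model["experienced"])
        pred = predict_smd(naive, experienced, method, grid_size, tolerance)
        out["prediction"] = _jsonable(pred)
    for sweep in model.get("sweeps", ()):
        base = GuardingParams(**sweep.get("base", model.get("naive", {})))
        grid = sweep.get("grid")
        if grid is None:
            grid = np.linspace(sweep["from"], sweep["to"], int(sweep["steps"])).tolist()
        table = parameter_sweep(base, sweep["which"], grid, method, grid_size, tolerance)
        out.setdefault("sweeps", {})[sweep.get("name", sweep["which"])] = _jsonable(table)
    return out


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute all declared blocks; a failing block is recorded, not fatal."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    bundle = ReportBundle(
        provenance={
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "package_version": __version__,
            "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        }
    )
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    for i, block in enumerate(config.experiments):
        name = block["name"]
        block_seed = (config.seed + 1000003 * (i + 1)) % (2**31)
        try:
            result = _run_experiment(block, block_seed)
            bundle.experiments[name] = result
            log.info("block %s done", name)
        except Exception as exc:  # per-block isolation is the contract
            bundle.errors[name] = {"type": type(exc).__name__, "message": str(exc)}
            log.error("block %s failed: %s", name, exc)
    if config.model:
        try:
            bundle.model = _run_model_block(config.model)
        except Exception as exc:
            bundle.errors["model"] = {"type": type(exc).__name__, "message": str(exc)}
            log.error("model block failed: %s", exc)
    if outdir:
        write_report(bundle, outdir / "report.json")
    return bundle


def write_report(bundle: ReportBundle, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(bundle.to_dict()), fh, indent=2)


def read_report(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read a pipeline CSV, validating the documented schema for its kind."""
    if kind not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    table = pd.read_csv(path)
    missing = [c for c in TABLE_SCHEMAS[kind] if c not in table.columns]
    if missing:
        raise ValueError(
            f"{path}: line 1: missing required column(s) {missing} for kind {kind!r}"
        )
    return table
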