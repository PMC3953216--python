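"""Declarative configuration: YAML flow problems, output directories,
registries and scenarios.

A problem file names its layer files (paths relative to the YAML file),
the benefit semantics and the router::

    source: source.asc
    sink: sink.asc
    use: use.asc
    benefit: {benefit_type: provisioning, rivalness: rival,
              carrier: water, units: "m3/yr"}
    router: {mode: d8_downslope, dem: dem.asc}

Outputs are written as one ``.asc`` file per map plus ``summary.json``
with every total and the run log, and a plain-text ISO-8601 log.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path

import yaml

from .errors import ConfigError, DomainError
from .raster import RasterLayer, read_ascii_grid, write_ascii_grid
from .span import BenefitSpec, RouterSpec, SpanOutputs, SpanProblem

__all__ = ["load_problem", "save_problem", "write_outputs", "read_outputs"]


def load_problem(path: str | Path) -> SpanProblem:
    path = Path(path)
    try:
        cfg = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path} is not a mapping")
    base = path.parent

    def layer(key: str) -> RasterLayer:
        if key not in cfg:
            raise ConfigError(f"problem file lacks the {key!r} layer")
        return read_ascii_grid(base / cfg[key], semantics=key)

    try:
        benefit = BenefitSpec(**cfg.get("benefit", {}))
    except (TypeError, DomainError) as exc:
        raise ConfigError(f"invalid benefit block: {exc}") from exc
    rcfg = dict(cfg.get("router", {}))
    mode = rcfg.pop("mode", None)
    if mode is None:
        raise ConfigError("router block lacks a mode")
    for aux in ("dem", "cost"):
        if aux in rcfg:
            rcfg[aux] = read_ascii_grid(base / rcfg[aux], semantics=aux)
    try:
        router = RouterSpec(mode=mode, **rcfg)
        return SpanProblem(layer("source"), layer("sink"), layer("use"),
                           benefit, router)
    except TypeError as exc:
        raise ConfigError(f"invalid router block: {exc}") from exc


def save_problem(problem: SpanProblem, directory: str | Path,
                 name: str = "problem.yaml") -> Path:
    """Write a problem's layers and YAML description into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg: dict = {}
    for key, lyr in (("source", problem.source), ("sink", problem.sink),
                     ("use", problem.use)):
        write_ascii_grid(lyr, directory / f"{key}.asc")
        cfg[key] = f"{key}.asc"
    b = problem.benefit
    cfg["benefit"] = {"benefit_type": b.benefit_type, "rivalness": b.rivalness,
                      "carrier": b.carrier, "units": b.units}
    r = problem.router
    rcfg: dict = {"mode": r.mode}
    if r.dem is not None:
        write_ascii_grid(r.dem, directory / "dem.asc")
        rcfg["dem"] = "dem.asc"
    if r.cost is not None:
        write_ascii_grid(r.cost, directory / "cost.asc")
        rcfg["cost"] = "cost.asc"
    if r.max_distance is not None:
        rcfg["max_distance"] = float(r.max_distance)
    if r.max_cost is not None:
        rcfg["max_cost"] = float(r.max_cost)
    cfg["router"] = rcfg
    out = directory / name
    out.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return out


def write_outputs(outputs: SpanOutputs, directory: str | Path) -> Path:
    """Write every output map as .asc plus summary.json and run.log."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, layer in outputs.as_dict().items():
        write_ascii_grid(layer, directory / f"{name}.asc")
    summary = {"totals": outputs.totals(), "run_log": outputs.run_log}
    (directory / "summary.json").write_text(json.dumps(summary, indent=2))
    stamp = datetime.datetime.now(datetime.timezone.utc).isoformat()
    with open(directory / "run.log", "a") as fh:
        fh.write(f"{stamp} wrote {len(outputs.MAP_NAMES)} maps\n")
    return directory


def read_outputs(directory: str | Path) -> SpanOutputs:
    """Rebuild a SpanOutputs from a directory written by write_outputs."""
    directory = Path(directory)
    layers = {}
    for name in SpanOutputs.MAP_NAMES:
        f = directory / f"{name}.asc"
        if not f.exists():
            raise ConfigError(f"output directory lacks {f.name}")
        layers[name] = read_ascii_grid(f, semantics=name)
    summary_file = directory / "summary.json"
    run_log = {}
    if summary_file.exists():
        run_log = json.loads(summary_file.read_text()).get("run_log", {})
    return SpanOutputs(**layers, run_log=run_log)
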