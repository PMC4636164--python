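"""Run specification, validation, orchestration and structured outputs.

A run is described by a :class:`RunSpec` — command, model kind, parameter
source (preset plus dimensional overrides), grids/ranges, variant, solver
options and output directory — loadable from a YAML config file or built
by the CLI.  :func:`execute` dispatches to the library, writes CSV/JSON
artifacts plus a JSON run manifest recording every effective parameter,
and returns a process exit status (0 success, 1 validation failure,
2 runtime failure).
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from . import detailed as det
from . import regimes as rg
from .dynamics import SolverOptions, find_steady_state, integrate
from .params import (DimensionalDetailedParams, DimensionalSimpleParams,
                     nondimensionalize_detailed, nondimensionalize_simple,
                     params_to_dict, preset, with_overrides)
from .simple import coexistence_boundary, delta_thresholds, fixed_points

__all__ = ["RunSpec", "ValidationError", "load_run_spec", "execute",
           "COMMANDS"]

COMMANDS = ("simulate", "fixed-points", "thresholds", "continue",
            "boundary", "sweep", "compare-variants")


class ValidationError(ValueError):
    """A RunSpec field failed validation; the message names the key."""


@dataclass
class RunSpec:
    """Fully validated, fully explicit description of one run."""

    command: str
    preset: str = "benchmark-simple"
    overrides: dict = field(default_factory=dict)  # dimensional fields
    horizon: Optional[float] = None
    initial_state: dict = field(default_factory=dict)
    variant: str = "baseline"
    mode: str = "quota"
    # continuation / boundary / sweep controls
    param: Optional[str] = None  # 1-d continuation parameter
    param_x: Optional[str] = None
    param_y: Optional[str] = None
    range: Optional[list] = None  # [lo, hi]
    range_x: Optional[list] = None
    range_y: Optional[list] = None
    steps: int = 25
    resolution: int = 11
    beta_grid: Optional[list] = None
    Gc_grid: Optional[list] = None
    delta: Optional[float] = None
    variants: list = field(default_factory=lambda: ["baseline", "no-abi"])
    # solver
    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-12
    out: str = "runs"

    def solver_options(self) -> SolverOptions:
        return SolverOptions(method=self.method, rtol=self.rtol,
                             atol=self.atol,
                             variant=det.VariantSpec.parse(self.variant),
                             mode=self.mode)


_NUMERIC_KEYS = {"horizon", "rtol", "atol", "delta"}


def load_run_spec(source) -> RunSpec:
    """Build and validate a RunSpec from a YAML path or a mapping.

    Unknown keys, out-of-range values (``delta`` outside [0, 1], negative
    rates) and missing presets raise :class:`ValidationError` naming the
    offending key.  All defaults are made explicit in the returned record
    so a run is reproducible from its manifest alone.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source or {})
    valid = set(RunSpec.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
    if "command" not in data:
        raise ValidationError("missing required key: command")
    spec = RunSpec(**data)
    _validate(spec)
    return spec


def _validate(spec: RunSpec) -> None:
    if spec.command not in COMMANDS:
        raise ValidationError(
            f"command: unknown command {spec.command!r}; "
            f"choose from {COMMANDS}")
    try:
        base = preset(spec.preset)
    except KeyError as exc:
        raise ValidationError(f"preset: {exc.args[0]}") from None
    # apply overrides now so that range errors surface before any work
    try:
        p = with_overrides(base, **{k: float(v)
                                    for k, v in spec.overrides.items()})
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"overrides: {exc}") from None
    if spec.delta is not None and not (0.0 <= spec.delta <= 1.0):
        raise ValidationError(
            f"delta: must lie in [0, 1], got {spec.delta}")
    if spec.horizon is not None and spec.horizon <= 0:
        raise ValidationError(f"horizon: must be > 0, got {spec.horizon}")
    for key in ("range", "range_x", "range_y"):
        r = getattr(spec, key)
        if r is not None and (len(r) != 2 or not r[0] < r[1]):
            raise ValidationError(f"{key}: need [lo, hi] with lo < hi, "
                                  f"got {r!r}")
    if spec.steps < 2:
        raise ValidationError(f"steps: need >= 2, got {spec.steps}")
    if spec.resolution < 2:
        raise ValidationError(
            f"resolution: need >= 2, got {spec.resolution}")
    for key in ("beta_grid", "Gc_grid"):
        g = getattr(spec, key)
        if g is not None and len(g) == 0:
            raise ValidationError(f"{key}: grid must be nonempty")
    det.VariantSpec.parse(spec.variant)
    for v in spec.variants:
        det.VariantSpec.parse(v)
    spec._params = p  # stash the resolved dimensional record


def _model_kind(p) -> str:
    return "simple" if isinstance(p, DimensionalSimpleParams) else "detailed"


def _nondim(p):
    if isinstance(p, DimensionalSimpleParams):
        return nondimensionalize_simple(p)
    return nondimensionalize_detailed(p)


def _default_state(model):
    if model == "simple":
        return np.array([rg.DEFAULT_INITIAL_STATE["P"], 0.0,
                         rg.DEFAULT_INITIAL_STATE["V"]])
    return det.make_state(**rg.DEFAULT_INITIAL_STATE)


def execute(spec: RunSpec) -> int:
    """Run a validated RunSpec; write artifacts; return the exit status."""
    t_start = time.time()
    outdir = Path(spec.out)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        print(f"validation failure: output directory: {exc}")
        return 1
    dim = getattr(spec, "_params", None)
    if dim is None:
        try:
            _validate(spec)
        except ValidationError as exc:
            print(f"validation failure: {exc}")
            return 1
        dim = spec._params
    model = _model_kind(dim)
    p = _nondim(dim)
    if spec.delta is not None:
        p = with_overrides(p, delta=spec.delta)
    opts = spec.solver_options()
    artifacts = {}
    try:
        if spec.command == "simulate":
            s0 = _default_state(model)
            if spec.initial_state:
                names = (["P", "Q", "V"] if model == "simple"
                         else list(det.STATE_NAMES))
                for k, v in spec.initial_state.items():
                    s0[names.index(k)] = float(v)
            traj = integrate(model, p, s0, horizon=spec.horizon, opts=opts)
            df = traj.to_frame()
            df.to_csv(outdir / "trajectory.csv", index=False)
            artifacts["trajectory"] = "trajectory.csv"
            with open(outdir / "events.json", "w") as fh:
                json.dump({"events": [[float(t), lab]
                                      for t, lab in traj.events],
                           "clipped": traj.meta["clipped"]}, fh, indent=2)
            artifacts["events"] = "events.json"
        elif spec.command == "fixed-points":
            if model == "simple":
                recs = fixed_points(p)
            else:
                recs = [det.phage_free_fixed_point(p, opts.variant)]
            rows = [r.as_dict() for r in recs]
            _dump_json(outdir / "fixed_points.json", rows)
            import pandas as pd

            pd.DataFrame(rows).to_csv(outdir / "fixed_points.csv",
                                      index=False)
            artifacts["fixed_points"] = "fixed_points.json"
        elif spec.command == "thresholds":
            if model == "simple":
                d1, d2 = delta_thresholds(p)
                payload = {"delta1": d1, "delta2": d2}
                try:
                    b = coexistence_boundary(p)
                    payload.update(K1=b.K1, K2=b.K2,
                                   validity_ratio=b.validity_ratio)
                except ValueError as exc:
                    payload["boundary"] = str(exc)
            else:
                payload = {"delta_max": det.delta_max(p)}
            _dump_json(outdir / "thresholds.json", payload)
            artifacts["thresholds"] = "thresholds.json"
        elif spec.command == "continue":
            if spec.param is None or spec.range is None:
                raise ValidationError("continue requires param and range")
            branches = rg.continue_fixed_point_1d(
                model, p, spec.param, spec.range, spec.steps)
            import pandas as pd

            pd.concat([b.to_frame() for b in branches],
                      ignore_index=True).to_csv(
                outdir / "branches.csv", index=False)
            _dump_json(outdir / "special_points.json",
                       {b.kind: b.special_points for b in branches})
            artifacts["branches"] = "branches.csv"
        elif spec.command == "boundary":
            if None in (spec.param_x, spec.param_y, spec.range_x,
                        spec.range_y):
                raise ValidationError(
                    "boundary requires param_x/param_y and range_x/range_y")
            curve = rg.trace_boundary_2d(
                model, p, spec.param_x, spec.param_y,
                (tuple(spec.range_x), tuple(spec.range_y)),
                spec.resolution, opts=opts)
            curve.to_frame().to_csv(outdir / "boundary.csv", index=False)
            artifacts["boundary"] = "boundary.csv"
            if curve.note:
                artifacts["note"] = curve.note
        elif spec.command == "sweep":
            if model != "detailed":
                raise ValidationError("sweep requires the detailed model")
            beta_grid = spec.beta_grid or np.logspace(-2, 2, 10).tolist()
            Gc_grid = spec.Gc_grid or np.logspace(0, 8, 10).tolist()
            delta = spec.delta if spec.delta is not None else p.delta
            rm = rg.sweep_regimes(p, beta_grid, Gc_grid, delta,
                                  variant=opts.variant, opts=opts)
            rm.to_frame().to_csv(outdir / "regime_map.csv", index=False)
            artifacts["regime_map"] = "regime_map.csv"
        elif spec.command == "compare-variants":
            if model != "detailed":
                raise ValidationError(
                    "compare-variants requires the detailed model")
            beta_grid = spec.beta_grid or np.logspace(-2, 2, 8).tolist()
            Gc_grid = spec.Gc_grid or np.logspace(0, 8, 8).tolist()
            delta = spec.delta if spec.delta is not None else p.delta
            cmp_ = rg.compare_variants(p, beta_grid, Gc_grid, delta,
                                       spec.variants, opts=opts)
            cmp_.to_frame().to_csv(outdir / "variant_maps.csv", index=False)
            artifacts["variant_maps"] = "variant_maps.csv"
    except ValidationError as exc:
        print(f"validation failure: {exc}")
        return 1
    except Exception as exc:  # noqa: BLE001 - surfaced via exit status
        print(f"runtime failure: {type(exc).__name__}: {exc}")
        return 2

    manifest = {
        "version": __version__,
        "command": spec.command,
        "spec": {k: v for k, v in asdict(spec).items()
                 if not k.startswith("_")},
        "dimensional_params": params_to_dict(dim),
        "nondimensional_params": params_to_dict(p),
        "artifacts": artifacts,
        "wall_time_s": round(time.time() - t_start, 3),
    }
    _dump_json(outdir / "manifest.json", manifest)
    return 0


def _dump_json(path, payload) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, float) and not np.isfinite(o):
            return str(o)
        return str(o)

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=default)
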