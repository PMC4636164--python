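"""Fixed-point continuation, critical-boundary tracing, parameter sweeps
and regime classification.

Four qualitative regimes organize the detailed model in the
(beta, G_C, delta) space:

* **I** — spacer deletion overwhelms acquisition; CRISPR offers no
  immune advantage and hosts sit at the phage-limited density.
* **II** — both restriction and abortive infection operate; hosts reach
  their highest densities and phages are driven very low.
* **III** — the free-cell activation constraint (delta < delta_max) is
  violated; hosts go extinct.
* **IV** — active spacers are deleted but self-targeting spacers still
  accumulate: CRISPR acts as a pure abortive-infection system.

The classifier keys on the immune-advantage decomposition
``(G_Qp*Y_QA* + G_Qphi*Y_QS*)/G_Qv``: regime I below ``eps_adv``, then II
if the restriction share ``G_Qp*Y_QA*/G_Qv`` exceeds ``eps_restrict``,
else IV; regime III whenever the host is extinct.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import detailed as det
from .dynamics import SolverOptions, find_steady_state
from .params import DetailedParams, SimpleParams, with_overrides
from .simple import FixedPointRecord, _newton_refine, assess_stability, \
    fixed_points

__all__ = [
    "Branch", "CriticalCurve", "RegimeMap", "VariantComparison",
    "continue_fixed_point_1d", "trace_boundary_2d", "classify_outcome",
    "classify_steady_state", "sweep_regimes", "compare_variants",
    "UnclassifiableError", "DEFAULT_INITIAL_STATE",
]

#: default inoculum for detailed-model time courses and sweeps
DEFAULT_INITIAL_STATE = {"P": 0.1, "V": 0.01}

#: immune-advantage threshold below which a cell is regime I
EPS_ADV = 1e-3
#: restriction-share threshold separating regime II from IV
EPS_RESTRICT = 1e-3


class UnclassifiableError(ValueError):
    """Steady state did not converge; no regime label can be assigned."""


# ---------------------------------------------------------------------------
# One-parameter continuation
# ---------------------------------------------------------------------------

@dataclass
class Branch:
    """A fixed-point family tracked across one parameter.

    ``special_points`` is a list of ``(parameter value, label)`` with
    labels among {"fold/collision", "zero-crossing", "infeasibility"}.
    """

    kind: str
    param_name: str
    values: np.ndarray
    states: np.ndarray
    stability: list
    feasible: list
    special_points: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states,
                          columns=["P", "Q", "V"][:self.states.shape[1]])
        df.insert(0, self.param_name, self.values)
        df["kind"] = self.kind
        df["stability"] = self.stability
        df["feasible"] = self.feasible
        return df


def continue_fixed_point_1d(model: str, p, param_name: str,
                            prange: Sequence[float],
                            steps: int) -> list[Branch]:
    """Natural-parameter continuation of the analytic fixed-point families.

    For the simple model the E*, F* and C* families are tracked; C* is
    Newton-refined at each point seeded from the previous branch point.
    For the detailed model the analytic phage-free family is tracked.
    Collisions between branches (state distance < 1e-6), coordinate
    zero-crossings, and feasibility losses are recorded as special
    points.
    """
    lo, hi = prange
    if steps < 2:
        raise ValueError("continuation needs steps >= 2")
    if not np.isfinite([lo, hi]).all() or lo >= hi:
        raise ValueError(f"empty or invalid range {prange!r}")
    values = np.linspace(lo, hi, steps)

    if model == "simple":
        kinds = ("E", "F", "C")
        records_per_value = []
        prev_C = None
        for v in values:
            pv = with_overrides(p, **{param_name: float(v)})
            recs = {r.kind: r for r in fixed_points(pv)}
            C = recs.get("C")
            if C is not None and C.state is not None and prev_C is not None:
                # re-seed from the previous branch point for continuity
                refined, ok = _newton_refine(prev_C, pv)
                if ok and np.linalg.norm(refined - C.state) < \
                        0.5 * (1.0 + np.linalg.norm(C.state)):
                    C.state = refined
                    C.feasible = bool(np.all(refined >= -1e-12)
                                      and 0.0 < refined[0] < 1.0)
                    assess_stability(C, pv)
            if C is not None and C.state is not None:
                prev_C = C.state
            records_per_value.append(recs)
    elif model == "detailed":
        kinds = ("F",)
        records_per_value = []
        for v in values:
            pv = with_overrides(p, **{param_name: float(v)})
            records_per_value.append({"F": det.phage_free_fixed_point(pv)})
    else:
        raise ValueError(f"unknown model {model!r}")

    branches = []
    for kind in kinds:
        states, stab, feas = [], [], []
        for recs in records_per_value:
            r = recs.get(kind)
            if r is None or r.state is None:
                states.append(None)
            else:
                states.append(np.asarray(r.state, dtype=float))
                stab.append(r.stability)
                feas.append(r.feasible)
        present = [i for i, s in enumerate(states) if s is not None]
        if not present:
            continue
        vv = values[present]
        ss = np.vstack([states[i] for i in present])
        br = Branch(kind=kind, param_name=param_name, values=vv, states=ss,
                    stability=stab, feasible=feas)
        # feasibility loss / zero-crossings along the branch
        for i in range(1, len(vv)):
            if feas[i] != feas[i - 1]:
                br.special_points.append((float(vv[i]), "infeasibility"))
            if np.any(np.sign(ss[i]) * np.sign(ss[i - 1]) < 0) or (
                    np.any((ss[i] == 0) != (ss[i - 1] == 0))):
                br.special_points.append((float(vv[i]), "zero-crossing"))
        branches.append(br)

    # collisions between distinct branches (e.g. C* meeting F* at delta2,
    # or F* meeting E* at delta1): record the branch-distance minimum when
    # the branches actually come together
    for i, b1 in enumerate(branches):
        for b2 in branches[i + 1:]:
            common, i1, i2 = np.intersect1d(b1.values, b2.values,
                                            return_indices=True)
            if common.size == 0:
                continue
            d = np.linalg.norm(b1.states[i1] - b2.states[i2], axis=1)
            k = int(np.argmin(d))
            if d[k] < 1e-2:
                pt = (float(common[k]), "fold/collision")
                b1.special_points.append(pt)
                b2.special_points.append(pt)
    return branches


# ---------------------------------------------------------------------------
# Outcome classification and two-parameter boundary tracing
# ---------------------------------------------------------------------------

def classify_outcome(model: str, p, opts: Optional[SolverOptions] = None,
                     method: str = "auto") -> str:
    """Qualitative long-run outcome for one parameter set.

    Returns one of ``"coexistence"``, ``"phage-free"``, ``"host-extinct"``.
    For the simple model the phage-free state decides analytically
    (``method="analytic"``, the default): if it is infeasible the host
    is extinct; if it is unstable the phage invades and persists — as a
    stable coexistence point or a limit cycle around an unstable one —
    and the outcome is coexistence; if it is stable the hosts evade the
    phage.  ``method="simulate"`` relaxes from the default inoculum
    instead, which is also the default route for the detailed model.
    """
    if method == "auto":
        method = "analytic" if model == "simple" else "simulate"
    if method == "analytic" and model == "simple":
        recs = {r.kind: r for r in fixed_points(p)}
        F = recs.get("F")
        if F is not None and F.state is not None and np.isfinite(F.state[0]):
            if F.state[0] <= 0:
                return "host-extinct"
            if F.stability == "unstable":
                return "coexistence"
            if F.stability == "stable":
                return "phage-free"
            # marginal: on the delta1 line F* merges with extinction; on
            # the delta2 line it merges with coexistence (phage-free side)
            return "phage-free" if F.state[0] > 1e-6 else "host-extinct"
        # degenerate parameters: fall through to simulation
    opts = opts or SolverOptions()
    if model == "simple":
        s0 = np.array([DEFAULT_INITIAL_STATE["P"], 0.0,
                       DEFAULT_INITIAL_STATE["V"]])
    else:
        s0 = det.make_state(**DEFAULT_INITIAL_STATE)
    ss = find_steady_state(model, p, s0, opts=opts)
    if ss.host_extinct:
        return "host-extinct"
    if ss.phage_extinct:
        return "phage-free"
    return "coexistence"


@dataclass
class CriticalCurve:
    """Refined boundary points between qualitative outcomes.

    ``points`` is an (n, 2) array in (param_x, param_y) coordinates;
    ``labels`` the outcome pair (side_low, side_high) for each point,
    where side_low is the outcome at the smaller scanned value along the
    bisection axis recorded in ``axes``.
    """

    param_x: str
    param_y: str
    points: np.ndarray
    labels: list
    axes: list
    note: str = ""

    def to_frame(self) -> pd.DataFrame:
        if len(self.points) == 0:
            return pd.DataFrame(columns=[self.param_x, self.param_y,
                                         "side_low", "side_high", "axis"])
        df = pd.DataFrame(self.points, columns=[self.param_x, self.param_y])
        df["side_low"] = [l[0] for l in self.labels]
        df["side_high"] = [l[1] for l in self.labels]
        df["axis"] = self.axes
        return df


def trace_boundary_2d(model: str, p, param_x: str, param_y: str,
                      rectangle, resolution,
                      opts: Optional[SolverOptions] = None,
                      method: str = "auto",
                      rel_tol: float = 1e-3,
                      classify: Optional[Callable] = None) -> CriticalCurve:
    """Trace outcome boundaries over a parameter rectangle.

    Classifies every node of a ``resolution x resolution`` grid (or
    ``(nx, ny)``) over ``rectangle = ((x_lo, x_hi), (y_lo, y_hi))``, then
    refines each sign change between adjacent nodes by bisection to a
    relative parameter tolerance of ``rel_tol``.  Returns an empty curve
    with a note when the outcome is uniform.
    """
    (x_lo, x_hi), (y_lo, y_hi) = rectangle
    nx, ny = (resolution, resolution) if np.isscalar(resolution) else resolution
    xs = np.linspace(x_lo, x_hi, nx)
    ys = np.linspace(y_lo, y_hi, ny)

    if classify is None:
        def classify(px, py):
            pv = with_overrides(p, **{param_x: float(px), param_y: float(py)})
            return classify_outcome(model, pv, opts=opts, method=method)

    grid = [[classify(x, y) for y in ys] for x in xs]

    points, labels, axes = [], [], []

    def bisect(lo, hi, lab_lo, lab_hi, fixed, axis):
        tol = rel_tol * max(abs(lo), abs(hi), 1e-12)
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            lab = classify(mid, fixed) if axis == "x" else classify(fixed, mid)
            if lab == lab_lo:
                lo = mid
            else:
                hi = mid
                lab_hi = lab
        return 0.5 * (lo + hi), (lab_lo, lab_hi)

    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            if i + 1 < nx and grid[i][j] != grid[i + 1][j]:
                xb, pair = bisect(xs[i], xs[i + 1], grid[i][j],
                                  grid[i + 1][j], y, "x")
                points.append((xb, y))
                labels.append(pair)
                axes.append("x")
            if j + 1 < ny and grid[i][j] != grid[i][j + 1]:
                yb, pair = bisect(ys[j], ys[j + 1], grid[i][j],
                                  grid[i][j + 1], x, "y")
                points.append((x, yb))
                labels.append(pair)
                axes.append("y")

    note = ""
    if not points:
        note = f"uniform outcome {grid[0][0]!r} over the rectangle"
    return CriticalCurve(param_x=param_x, param_y=param_y,
                         points=np.array(points).reshape(-1, 2),
                         labels=labels, axes=axes, note=note)


# ---------------------------------------------------------------------------
# Regime classification and sweeps
# ---------------------------------------------------------------------------

def classify_steady_state(s, p: DetailedParams,
                          eps_adv: float = EPS_ADV,
                          eps_restrict: float = EPS_RESTRICT,
                          variant=det.VariantSpec.baseline) -> str:
    """Regime label I-IV for a converged detailed-model steady state.

    ``s`` is a :class:`~crisprdyn.dynamics.SteadyStateResult` or a bare
    10-state.  Raises :class:`UnclassifiableError` on a non-converged
    result.

    When the phage (and with it the infected pool) is extinct, the frozen
    infected-cell quotas are history artifacts of the extinction
    transient, so the advantage decomposition is computed instead from
    the quota levels an infected cell's own kinetics would sustain —
    active ``(1 - mu_v)/G_C`` (protospacer supply against deletion) and
    self-targeting ``beta/G_C`` — which is what actually drove the phage
    out.  This keeps labels independent of the integration path.
    """
    thr = det.EXTINCT_THRESHOLD
    if hasattr(s, "state"):
        if not s.converged:
            raise UnclassifiableError(
                "steady state did not converge; unclassifiable")
        host_extinct = s.host_extinct
        state = s.state
    else:
        state = np.asarray(s, dtype=float)
        host_extinct = bool(state[0] < thr and state[1] < thr)
    if host_extinct:
        return "III"
    names = det.STATE_NAMES
    phage_extinct = bool(state[names.index("V")] < thr
                         and state[names.index("Q")] < thr)
    if phage_extinct:
        _, gcq, _ = det._variant_codes(p, variant)
        if gcq > 0:
            y_qa = (1.0 - p.mu_v) / gcq
            y_qs = p.beta / gcq
        else:  # no infected-cell deletion: spacers accumulate freely
            y_qa = y_qs = math.inf
    else:
        y_qa = float(state[names.index("Y_QA")])
        y_qs = float(state[names.index("Y_QS")])
    restrict = p.G_Qp * y_qa / p.G_Qv
    advantage = restrict + p.G_Qphi * y_qs / p.G_Qv
    if advantage < eps_adv:
        return "I"
    if restrict > eps_restrict:
        return "II"
    return "IV"


@dataclass
class RegimeMap:
    """Grid of steady-state summaries with regime labels.

    ``labels[i, j]`` corresponds to ``(beta_values[i], Gc_values[j])``;
    ``summary`` maps column names (P, V, Y_QA, Y_QS, Y_PS) to 2-D
    arrays of steady-state values (NaN for unclassifiable cells).
    """

    beta_values: np.ndarray
    Gc_values: np.ndarray
    delta: float
    variant: str
    labels: np.ndarray
    summary: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, b in enumerate(self.beta_values):
            for j, g in enumerate(self.Gc_values):
                rows.append({
                    "beta": b, "G_C": g, "delta": self.delta,
                    "variant": self.variant,
                    "P": self.summary["P"][i, j],
                    "V": self.summary["V"][i, j],
                    "Y_QA": self.summary["Y_QA"][i, j],
                    "Y_QS": self.summary["Y_QS"][i, j],
                    "Y_PS": self.summary["Y_PS"][i, j],
                    "regime": self.labels[i, j],
                })
        return pd.DataFrame(rows)


def sweep_regimes(p: DetailedParams, beta_grid, Gc_grid, delta: float,
                  variant=det.VariantSpec.baseline,
                  opts: Optional[SolverOptions] = None,
                  warm_start: bool = True) -> RegimeMap:
    """Steady-state sweep over a (beta, G_C) grid at fixed delta.

    Each cell relaxes from the default inoculum; with ``warm_start`` the
    slow spacer-quota variables are seeded from the neighbouring cell's
    terminal state (populations always restart from the inoculum, so an
    extinct neighbour cannot trap a viable cell at the absorbing extinct
    state).  Per-cell failures are recorded as ``"unclassifiable"``.
    """
    variant = det.VariantSpec.parse(variant)
    if not (0.0 <= delta <= 1.0):
        raise ValueError(f"delta must lie in [0, 1], got {delta}")
    beta_grid = np.atleast_1d(np.asarray(beta_grid, dtype=float))
    Gc_grid = np.atleast_1d(np.asarray(Gc_grid, dtype=float))
    if beta_grid.size == 0 or Gc_grid.size == 0:
        raise ValueError("sweep grids must be nonempty")
    opts = opts or SolverOptions(variant=variant)
    opts.variant = variant

    nb, ng = beta_grid.size, Gc_grid.size
    labels = np.full((nb, ng), "unclassifiable", dtype=object)
    summary = {k: np.full((nb, ng), np.nan)
               for k in ("P", "V", "Y_QA", "Y_QS", "Y_PS")}
    terminal = {}
    names = det.STATE_NAMES

    for i, b in enumerate(beta_grid):
        for j, g in enumerate(Gc_grid):
            pv = with_overrides(p, beta=float(b), G_C=float(g), delta=delta)
            cold = det.make_state(**DEFAULT_INITIAL_STATE)
            starts = [cold]
            if warm_start:
                prev = terminal.get((i, j - 1)) if j > 0 else \
                    terminal.get((i - 1, j))
                if prev is not None:
                    warm = cold.copy()
                    warm[3:] = prev[3:]  # carry only the slow quota block
                    starts.insert(0, warm)
            for s0 in starts:  # cold restart backs up a failed warm start
                try:
                    ss = find_steady_state("detailed", pv, s0, opts=opts)
                    labels[i, j] = classify_steady_state(ss, pv,
                                                        variant=variant)
                    terminal[(i, j)] = ss.state
                    for k in summary:
                        summary[k][i, j] = ss.state[names.index(k)]
                    break
                except (UnclassifiableError, RuntimeError, ValueError):
                    labels[i, j] = "unclassifiable"
    return RegimeMap(beta_values=beta_grid, Gc_values=Gc_grid, delta=delta,
                     variant=variant.value, labels=labels, summary=summary)


@dataclass
class VariantComparison:
    """Paired regime maps on a shared grid with per-cell differences."""

    maps: dict
    reference: str

    def diff(self, other: str, column: str = "V") -> np.ndarray:
        ref = self.maps[self.reference]
        return self.maps[other].summary[column] - ref.summary[column]

    def label_changes(self, other: str) -> np.ndarray:
        ref = self.maps[self.reference]
        return self.maps[other].labels != ref.labels

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([m.to_frame() for m in self.maps.values()],
                         ignore_index=True)


def compare_variants(p: DetailedParams, beta_grid, Gc_grid, delta: float,
                     variants,
                     opts: Optional[SolverOptions] = None) -> VariantComparison:
    """Run :func:`sweep_regimes` for several variants on identical grids."""
    variants = [det.VariantSpec.parse(v) for v in variants]
    if len(variants) < 2:
        raise ValueError("compare_variants needs at least two variants")
    maps = {}
    for v in variants:
        vopts = SolverOptions(**{**(opts.__dict__ if opts else {}),
                                 "variant": v})
        maps[v.value] = sweep_regimes(p, beta_grid, Gc_grid, delta,
                                      variant=v, opts=vopts)
    return VariantComparison(maps=maps, reference=variants[0].value)
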