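"""Numerical integration, steady-state detection and trajectory containers.

The detailed model mixes rate groups spanning O(1) to O(1e9) at the
reference kinetic parameters, so the default integrator is the
stiff-capable LSODA with tight tolerances (rtol 1e-8, atol 1e-12).
Negative excursions produced by the solver are clipped to zero in the
recorded trajectory (and counted); the RHS itself preserves the exact
fixed points at zero, which is why no log-transformed state is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root as _opt_root

from . import detailed as det
from .params import DetailedParams, SimpleParams
from .simple import simple_rhs

__all__ = [
    "SolverOptions", "Trajectory", "SteadyStateResult", "IntegrationError",
    "integrate", "find_steady_state", "extinction_events",
    "DEFAULT_HORIZON",
]

#: default integration horizons (nondimensional time units) per model
DEFAULT_HORIZON = {"simple": 50.0, "detailed": 100.0}


class IntegrationError(RuntimeError):
    """Integration failed; carries the last good time in ``last_time``."""

    def __init__(self, msg, last_time=None):
        super().__init__(msg)
        self.last_time = last_time


class _NfevLimit(Exception):
    """Internal: per-call RHS evaluation cap reached."""

    def __init__(self, t):
        super().__init__("nfev cap")
        self.t = t


@dataclass
class SolverOptions:
    """Options shared by :func:`integrate` and :func:`find_steady_state`."""

    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-12
    variant: det.VariantSpec = det.VariantSpec.baseline
    mode: str = "quota"  # "quota" | "totals" (detailed model only)
    n_points: Optional[int] = None  # sample count; None = solver steps
    tol_residual: float = 1e-8  # scaled residual for convergence
    tol_drift: float = 1e-6  # trailing-window relative drift
    max_rounds: int = 64  # growing-horizon rounds
    max_nfev: float = 3e6  # RHS-evaluation budget for steady-state search
    max_nfev_call: Optional[float] = None  # hard cap per solve_ivp call


@dataclass
class Trajectory:
    """Time-ordered states with event annotations.

    ``states`` has one row per time point, columns in the model's state
    order; ``events`` is a list of ``(time, label)`` pairs; ``meta``
    records model kind, parameters and solver settings.
    """

    times: np.ndarray
    states: np.ndarray
    events: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def column(self, name: str) -> np.ndarray:
        return self.states[:, self.meta["columns"].index(name)]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=self.meta["columns"])
        df.insert(0, "time", self.times)
        return df


@dataclass
class SteadyStateResult:
    """Terminal state of a converged (or not) relaxation run."""

    state: np.ndarray
    converged: bool
    residual: float  # max |rhs| scaled by the local Jacobian norm
    window_drift: float
    rounds: int = 0
    host_extinct: bool = False
    phage_extinct: bool = False


def _make_rhs(model: str, p, opts: SolverOptions):
    """(rhs(t, y), columns, transform_in, transform_out) for solve_ivp."""
    if model == "simple":
        def rhs(t, y):
            return simple_rhs(y, p)
        return rhs, ["P", "Q", "V"], None, None
    if model != "detailed":
        raise ValueError(f"unknown model {model!r}")
    c = det.pack_params(p, opts.variant)
    if opts.mode == "totals":
        core = det._rhs_totals_core

        def rhs(t, y):
            return core(y, c)
        return (rhs, list(det.STATE_NAMES),
                det.quotas_to_totals, det.totals_to_quotas)
    core = det._rhs_quota_core

    def rhs(t, y):
        return core(y, c)
    return rhs, list(det.STATE_NAMES), None, None


def integrate(model: str, p, s0, horizon: Optional[float] = None,
              opts: Optional[SolverOptions] = None,
              t0: float = 0.0) -> Trajectory:
    """Integrate either model from ``s0`` over ``horizon`` time units.

    ``s0`` is always given in the model's native (quota-mode) coordinates;
    the total-content mode converts internally.  Negative excursions in
    the recorded output are clipped to zero and counted in
    ``meta["clipped"]``; extinction events are annotated.
    """
    opts = opts or SolverOptions()
    if horizon is None:
        horizon = DEFAULT_HORIZON[model]
    if horizon <= 0:
        raise ValueError(f"horizon must be > 0, got {horizon}")
    s0 = np.asarray(s0, dtype=float)
    if np.isnan(s0).any():
        raise IntegrationError(f"NaN in initial state {s0!r}", last_time=t0)
    rhs, columns, fwd, back = _make_rhs(model, p, opts)
    if opts.max_nfev_call:
        cap = float(opts.max_nfev_call)
        counter = [0]
        inner = rhs

        def rhs(t, y):
            counter[0] += 1
            if counter[0] > cap:
                raise _NfevLimit(t)
            return inner(t, y)
    y0 = fwd(s0) if fwd else s0
    t_eval = (np.linspace(t0, t0 + horizon, opts.n_points)
              if opts.n_points else None)
    try:
        sol = solve_ivp(rhs, (t0, t0 + horizon), y0, method=opts.method,
                        rtol=opts.rtol, atol=opts.atol, t_eval=t_eval,
                        dense_output=False)
    except _NfevLimit as lim:
        raise IntegrationError(
            "integration failed: per-call evaluation cap reached",
            last_time=lim.t) from None
    if not sol.success:
        raise IntegrationError(
            f"integration failed: {sol.message}",
            last_time=sol.t[-1] if sol.t.size else t0)
    ys = sol.y.T
    if np.isnan(ys).any():
        raise IntegrationError("NaN state encountered during integration",
                               last_time=float(sol.t[-1]))
    if back:
        ys = np.apply_along_axis(back, 1, ys)
    clipped = int(np.count_nonzero(ys < 0))
    ys = np.clip(ys, 0.0, None)
    traj = Trajectory(
        times=sol.t, states=ys,
        meta={"model": model, "columns": columns, "params": p,
              "variant": det.VariantSpec.parse(opts.variant).value,
              "mode": opts.mode, "method": opts.method, "rtol": opts.rtol,
              "atol": opts.atol, "clipped": clipped,
              "nfev": int(sol.nfev)})
    traj.events = [(t, f"{species} extinct")
                   for species, t in extinction_events(traj)]
    return traj


def extinction_events(traj: Trajectory,
                      threshold: float = det.EXTINCT_THRESHOLD) -> list:
    """First time each population falls and stays below ``threshold``.

    Returns ``[(species, time), ...]`` for the species among P, Q, V that
    go extinct over the trajectory's horizon (a population is extinct
    when its density stays below the threshold for the rest of the run).
    """
    out = []
    for species in ("P", "Q", "V"):
        x = traj.column(species)
        below = x < threshold
        if not below[-1]:
            continue
        # last index where the density was at/above threshold
        above = np.nonzero(~below)[0]
        first = above[-1] + 1 if above.size else 0
        out.append((species, float(traj.times[first])))
    return out


def _fd_jacobian(rhs, state) -> np.ndarray:
    """Forward-difference Jacobian of ``rhs(0, .)`` at ``state``."""
    f0 = np.asarray(rhs(0.0, state), dtype=float)
    n = state.size
    J = np.empty((n, n))
    for j in range(n):
        h = 1e-7 * max(abs(state[j]), 1e-3)
        xp = state.copy()
        xp[j] += h
        J[:, j] = (np.asarray(rhs(0.0, xp)) - f0) / h
    return J


def _scaled_residual(rhs, state, J=None) -> float:
    """max over rows of |rhs_i| scaled by that row's own rate scale.

    With rate groups up to O(1e9) a raw residual conflates rate scale
    with distance from the fixed point, while one global scale would let
    a genuinely unbalanced *slow* equation (rates O(1e-2)) hide behind a
    fast row's O(1e9) norm.  Each row is therefore scaled by
    ``max(1, sum_j |J_ij|)``, making every component comparable to a
    state-space distance.
    """
    f0 = np.asarray(rhs(0.0, state), dtype=float)
    if J is None:
        J = _fd_jacobian(rhs, state)
    row_scale = np.maximum(1.0, np.sum(np.abs(J), axis=1))
    return float(np.max(np.abs(f0) / row_scale))


def find_steady_state(model: str, p, s0, opts: Optional[SolverOptions] = None,
                      horizon: Optional[float] = None) -> SteadyStateResult:
    """Relax to a steady state by growing-horizon integration rounds.

    Rounds start at a small fraction (1/16384) of the nominal horizon and grow fourfold up to
    ``max_rounds``; after each round a Newton polish of the RHS root is
    attempted from the terminal state and accepted when it converges to
    a nearby, nonnegative, linearly non-repelling root (confirmed by a
    short integration from the polished root).  This matters because
    several parameter regimes relax onto weakly damped stiff spirals
    where direct integration to full equilibrium is impractically
    expensive; polishing from the slow manifold reaches the same fixed
    point at a tiny fraction of the cost.  Without an accepted polish,
    convergence requires trailing-window relative drift below
    ``tol_drift`` and Jacobian-scaled residual below ``tol_residual``.
    Never raises on slow convergence: returns ``converged=False`` when
    the round or RHS-evaluation budget runs out.
    """
    from dataclasses import replace as _dc_replace

    opts = opts or SolverOptions()
    h0 = horizon if horizon is not None else DEFAULT_HORIZON[model]
    rhs, _, _, _ = _make_rhs(model, p, opts)
    state = np.asarray(s0, dtype=float).copy()
    t = 0.0
    drift = np.inf
    rounds = 0
    nfev = 0
    converged = False
    h = h0 / 16384.0
    # every solve_ivp call is hard-capped so a chunk that turns expensive
    # mid-flight (phage re-invasion restarting fast oscillations) cannot
    # stall the search; a capped round just ends the search unconverged
    # after the polish attempt below.
    ropts = _dc_replace(opts, max_nfev_call=min(
        3e5, opts.max_nfev_call or np.inf))
    for rounds in range(1, opts.max_rounds + 1):
        try:
            traj = integrate(model, p, state, horizon=h, opts=ropts, t0=t)
        except IntegrationError:
            # round hit the cap: retry with a much smaller chunk
            nfev += ropts.max_nfev_call
            if nfev > opts.max_nfev or h <= 1.01 * h0 / 16384.0:
                break
            h = max(h / 16.0, h0 / 16384.0)
            continue
        t = float(traj.times[-1])
        n_round = traj.meta["nfev"]
        nfev += n_round
        new_state = traj.final_state
        # trailing-window drift: relative change over the last 10% of the
        # round, always spanning at least the final solver step (a single
        # large step would otherwise make the window trivially flat)
        idx = np.searchsorted(traj.times, t - 0.1 * h)
        idx = min(idx, max(len(traj.times) - 2, 0))
        denom = np.maximum(np.abs(new_state), 1e-8)
        drift = float(np.max(np.abs(traj.states[idx:] - new_state) / denom))
        state = new_state
        hit = _polish_root(rhs, state)
        if hit is not None:
            polished, J = hit
            # confirm: from the root itself, a short run must not drift;
            # ~50 fast characteristic periods suffice and stay cheap even
            # when the fixed point is a stiff weakly damped spiral
            lam_fast = float(np.max(np.abs(np.linalg.eigvals(J))))
            h_conf = min(h0 / 256.0, 50.0 / max(1.0, lam_fast))
            try:
                ctraj = integrate(model, p, polished, horizon=h_conf,
                                  opts=ropts, t0=t)
            except IntegrationError:
                nfev += ropts.max_nfev_call
                continue
            nfev += ctraj.meta["nfev"]
            cden = np.maximum(np.abs(polished), 1e-8)
            cdrift = float(np.max(
                np.abs(ctraj.states - polished) / cden))
            if cdrift < opts.tol_drift:
                state, drift, converged = polished, cdrift, True
                break
        # drift-based convergence only counts once a single round spans the
        # nominal horizon; over tiny chunks slow dynamics would look flat
        if drift < opts.tol_drift and h >= h0:
            converged = True
            break
        if nfev > opts.max_nfev or t > 1024.0 * h0:
            break
        # cost-throttled growth: oscillatory stiff phases can cost ~1e6 RHS
        # evaluations per time unit, so chunks only grow while they stay
        # cheap; this bounds every solve_ivp call to a modest work unit
        if n_round < 1e5:
            h = min(h * 4.0, 512.0 * h0)
        else:
            h = max(h / 4.0, h0 / 16384.0)
    residual = _scaled_residual(rhs, state)
    converged = bool(converged and residual < opts.tol_residual
                     and drift < opts.tol_drift)
    thr = det.EXTINCT_THRESHOLD
    host_extinct = bool(state[0] < thr and state[1] < thr) if state.size >= 2 \
        else bool(state[0] < thr)
    phage_extinct = bool(state[2] < thr) if state.size >= 3 else False
    return SteadyStateResult(
        state=state, converged=converged,
        residual=residual, window_drift=drift, rounds=rounds,
        host_extinct=host_extinct, phage_extinct=phage_extinct)


def _polish_root(rhs, state):
    """Newton-polish the RHS root near ``state``; ``(root, J)`` or None.

    The polished root is accepted only when it converges, stays close to
    the integrated terminal state, is nonnegative (tiny negatives are
    clipped), and is not linearly repelling — an eigenvalue check with a
    tolerance tied to the finite-difference noise floor of the local
    Jacobian.  Otherwise the integrated state stands.
    """
    try:
        sol = _opt_root(lambda y: rhs(0.0, y), state, method="hybr",
                        options={"xtol": 1e-13})
    except Exception:
        return None
    if not sol.success:
        return None
    x = sol.x
    if np.min(x) < -1e-9:
        return None
    tol_move = 1e-2 * (1.0 + float(np.linalg.norm(state)))
    if np.linalg.norm(x - state) > tol_move:
        return None
    x = np.clip(x, 0.0, None)
    J = _fd_jacobian(rhs, x)
    if _scaled_residual(rhs, x, J=J) > 1e-8:
        return None  # hybr stalled short of a genuine root
    max_re = float(np.max(np.linalg.eigvals(J).real))
    noise = 1e-8 * max(1.0, float(np.max(np.abs(J))))
    if max_re > noise:
        return None
    return x, J
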