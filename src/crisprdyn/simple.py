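"""The three-variable regulated-autoimmunity model: RHS, fixed points,
survival thresholds, coexistence boundary, and linear stability.

State ``(P, Q, V)``: free cells, infected cells (both in carrying-capacity
units) and phage (also in carrying-capacity units here; the detailed model
measures phage in burst-size units).  Nondimensional dynamics::

    dP/dt = A_P*P*(1 - P - Q) - delta*G_Pphi*P + G_Qp*Q - P*V
    dQ/dt = P*V - (G_Qphi + G_Qp + G_Qv)*Q
    dV/dt = alpha_v*G_Qv*Q - G_V*V - P*V

Three steady states organize the dynamics: extinction ``E* = 0``, the
phage-free state ``F*`` with ``P_f = 1 - delta*G_Pphi/A_P``, and
coexistence ``C*``.  The closed form for ``C*`` neglects the ``-P*V``
adsorption sink in the phage equation and is exact only in the limit
``alpha_v*G_Qv/G_Q >> 1``; :func:`fixed_points` therefore reports it next
to a Newton-refined exact root, with their discrepancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .params import SimpleParams

__all__ = [
    "FixedPointRecord",
    "CoexistenceBoundary",
    "simple_rhs",
    "simple_jacobian",
    "fixed_points",
    "delta_thresholds",
    "coexistence_boundary",
    "assess_stability",
    "routh_hurwitz",
]

#: |Routh-Hurwitz quantity| or |max Re eigenvalue| below this is "marginal".
MARGIN_TOL = 1e-9


def simple_rhs(s, p: SimpleParams):
    """Time derivative ``(dP, dQ, dV)`` of the simple model at state ``s``."""
    P, Q, V = s
    dP = p.A_P * P * (1.0 - P - Q) - p.delta * p.G_Pphi * P + p.G_Qp * Q - P * V
    dQ = P * V - p.G_Q * Q
    dV = p.alpha_v * p.G_Qv * Q - p.G_V * V - P * V
    return np.array([dP, dQ, dV])


def simple_jacobian(s, p: SimpleParams) -> np.ndarray:
    """Analytic 3x3 Jacobian of :func:`simple_rhs`."""
    P, Q, V = s
    return np.array([
        [p.A_P * (1.0 - 2.0 * P - Q) - p.delta * p.G_Pphi - V,
         -p.A_P * P + p.G_Qp,
         -P],
        [V, -p.G_Q, P],
        [-V, p.alpha_v * p.G_Qv, -p.G_V - P],
    ])


@dataclass
class FixedPointRecord:
    """A steady state with feasibility and stability classification.

    ``kind`` is one of ``"E"`` (extinction), ``"F"`` (phage-free),
    ``"C"`` (coexistence).  For ``C``, ``closed_form`` holds the
    large-ratio approximation, ``state`` the (Newton-refined) exact root,
    and ``discrepancy`` their relative distance.
    """

    kind: str
    state: Optional[np.ndarray]
    feasible: bool = False
    stability: str = "unknown"  # stable | unstable | marginal | unknown
    closed_form: Optional[np.ndarray] = None
    discrepancy: Optional[float] = None
    diagnostics: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {"kind": self.kind, "feasible": self.feasible,
             "stability": self.stability}
        if self.state is not None:
            d.update(P=float(self.state[0]), Q=float(self.state[1]),
                     V=float(self.state[2]))
        if self.closed_form is not None:
            d.update(P_closed=float(self.closed_form[0]),
                     Q_closed=float(self.closed_form[1]),
                     V_closed=float(self.closed_form[2]),
                     discrepancy=self.discrepancy)
        d.update({k: v for k, v in self.diagnostics.items()
                  if np.isscalar(v)})
        return d


def _closed_form_coexistence(p: SimpleParams) -> np.ndarray:
    """Closed-form C* (drops the -P*V adsorption sink in dV/dt).

    ``P_c = (G_V/alpha_v)*(1 + (G_Qphi+G_Qp)/G_Qv)`` — the phage-limited
    level times the immune-advantage factor; ``V_c`` follows from dP/dt=0
    and ``Q_c = P_c*V_c/G_Q`` from dQ/dt=0.
    """
    adv = 1.0 + (p.G_Qphi + p.G_Qp) / p.G_Qv
    P_c = (p.G_V / p.alpha_v) * adv
    V_c = p.G_Q * (p.A_P * (1.0 - P_c) - p.delta * p.G_Pphi) / (
        p.A_P * P_c + p.G_Qphi + p.G_Qv)
    Q_c = P_c * V_c / p.G_Q
    return np.array([P_c, Q_c, V_c])


def _newton_refine(seed, p: SimpleParams, tol: float = 1e-12,
                   max_iter: int = 100):
    """Damped Newton refinement of a root of :func:`simple_rhs`.

    Returns ``(root, converged)``; on non-convergence the best iterate is
    returned with ``converged=False``.
    """
    x = np.asarray(seed, dtype=float).copy()
    for _ in range(max_iter):
        r = simple_rhs(x, p)
        if np.max(np.abs(r)) < tol:
            return x, True
        J = simple_jacobian(x, p)
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            return x, False
        lam = 1.0
        base = np.linalg.norm(r)
        for _ in range(30):
            xn = x + lam * step
            if np.linalg.norm(simple_rhs(xn, p)) < base:
                break
            lam *= 0.5
        else:
            return x, False
        x = xn
    return x, np.max(np.abs(simple_rhs(x, p))) < tol


def fixed_points(p: SimpleParams, refine: bool = True) -> list[FixedPointRecord]:
    """All three fixed-point families E*, F*, C* with stability assessed.

    C* is reported both in closed form and as a numerically refined exact
    root (the default ``state``); ``discrepancy`` is their relative
    distance.  When ``G_Qv = 0`` (no lysis) or ``alpha_v = 0`` the
    coexistence branch is reported absent with a reason.
    """
    records = []

    E = FixedPointRecord("E", np.zeros(3), feasible=True)
    records.append(assess_stability(E, p))

    P_f = 1.0 - p.delta * p.G_Pphi / p.A_P if p.A_P > 0 else (
        1.0 if p.delta * p.G_Pphi == 0 else -math.inf)
    F = FixedPointRecord("F", np.array([P_f, 0.0, 0.0]),
                         feasible=(0.0 <= P_f <= 1.0))
    if np.isfinite(P_f):
        records.append(assess_stability(F, p))
    else:
        F.diagnostics["absent_reason"] = "A_P = 0 with free-cell autoimmunity"
        records.append(F)

    if p.G_Qv <= 0 or p.alpha_v <= 0:
        records.append(FixedPointRecord(
            "C", None, feasible=False,
            diagnostics={"absent_reason":
                         "coexistence requires G_Qv > 0 and alpha_v > 0"}))
        return records

    closed = _closed_form_coexistence(p)
    if refine:
        exact, converged = _newton_refine(closed, p)
    else:
        exact, converged = closed.copy(), False
    if not converged:
        # fall back to the closed form; flag the record
        exact = closed.copy()
    denom = max(np.linalg.norm(exact), 1e-300)
    C = FixedPointRecord(
        "C", exact,
        feasible=bool(np.all(exact >= 0) and 0.0 < exact[0] < 1.0),
        closed_form=closed,
        discrepancy=float(np.linalg.norm(exact - closed) / denom),
        diagnostics={"refined": bool(refine and converged)},
    )
    records.append(assess_stability(
        C, p, residual_tol=1e-8 if converged else math.inf))
    return records


def delta_thresholds(p: SimpleParams):
    """Critical free-cell activation levels ``(delta1, delta2)``.

    ``delta1 = A_P/G_Pphi`` bounds host survival in the phage-free state;
    ``delta2 = A_P*(1 - P_c)/G_Pphi`` (closed-form ``P_c``) bounds
    coexistence feasibility and satisfies ``delta2 < delta1`` whenever
    ``0 < P_c < 1``.  With ``G_Pphi = 0`` both are unbounded (``inf``);
    ``delta2`` is ``None`` when the closed-form ``P_c`` is not in (0, 1).
    """
    if p.G_Pphi == 0:
        return math.inf, math.inf
    delta1 = p.A_P / p.G_Pphi
    delta2 = None
    if p.G_Qv > 0 and p.alpha_v > 0:
        P_c = _closed_form_coexistence(p)[0]
        if 0.0 < P_c < 1.0:
            delta2 = p.A_P * (1.0 - P_c) / p.G_Pphi
    return delta1, delta2


class NoCoexistenceWedgeError(ValueError):
    """The coexistence boundary is degenerate for these parameters."""


@dataclass
class CoexistenceBoundary:
    """Intercepts of the critical line delta/K1 + G_Qphi/K2 = 1.

    ``validity_ratio = alpha_v*G_Qv/G_Q`` must be >> 1 for the underlying
    closed form to hold; ``valid`` records the ratio > 100 rule of thumb.
    """

    K1: float
    K2: float
    validity_ratio: float

    @property
    def valid(self) -> bool:
        return self.validity_ratio > 100.0

    def delta_at(self, G_Qphi) -> np.ndarray:
        """delta on the critical line as a function of G_Qphi."""
        return self.K1 * (1.0 - np.asarray(G_Qphi, dtype=float) / self.K2)


def coexistence_boundary(p: SimpleParams) -> CoexistenceBoundary:
    """Critical line bounding coexistence in the (delta, G_Qphi) plane.

    ``K1 = (A_P/G_Pphi)*[1 - (G_V/alpha_v)*(1 + G_Qp/G_Qv)]`` and
    ``K2 = G_Qv*[alpha_v/G_V - (1 + G_Qp/G_Qv)]``.  Raises
    :class:`NoCoexistenceWedgeError` unless
    ``alpha_v/G_V > 1 + G_Qp/G_Qv``.
    """
    if p.G_V <= 0 or p.G_Qv <= 0 or p.alpha_v <= 0:
        raise NoCoexistenceWedgeError(
            "coexistence boundary needs G_V, G_Qv, alpha_v > 0")
    lysis_share = 1.0 + p.G_Qp / p.G_Qv
    if p.alpha_v / p.G_V <= lysis_share:
        raise NoCoexistenceWedgeError(
            f"no coexistence wedge: alpha_v/G_V = {p.alpha_v / p.G_V:g} "
            f"<= 1 + G_Qp/G_Qv = {lysis_share:g}")
    K1 = ((p.A_P / p.G_Pphi) if p.G_Pphi > 0 else math.inf) * (
        1.0 - (p.G_V / p.alpha_v) * lysis_share)
    K2 = p.G_Qv * (p.alpha_v / p.G_V - lysis_share)
    return CoexistenceBoundary(K1=K1, K2=K2,
                               validity_ratio=p.alpha_v * p.G_Qv / p.G_Q)


def routh_hurwitz(J: np.ndarray, tol: float = MARGIN_TOL):
    """Routh-Hurwitz verdict for a 3x3 Jacobian.

    The characteristic polynomial is ``lam^3 + a1*lam^2 + a2*lam + a3``
    with ``a1 = -tr(J)``, ``a2 = sum of principal 2x2 minors``,
    ``a3 = -det(J)``.  All eigenvalues have negative real part iff
    ``a1 > 0``, ``a3 > 0`` and ``a1*a2 - a3 > 0``.

    Returns ``(verdict, coeffs)`` with verdict in
    {"stable", "unstable", "marginal"} and coeffs ``(a1, a2, a3)``.
    """
    J = np.asarray(J, dtype=float)
    a1 = -np.trace(J)
    m01 = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
    m02 = J[0, 0] * J[2, 2] - J[0, 2] * J[2, 0]
    m12 = J[1, 1] * J[2, 2] - J[1, 2] * J[2, 1]
    a2 = m01 + m02 + m12
    a3 = -np.linalg.det(J)
    quantities = (a1, a3, a1 * a2 - a3)
    if any(abs(q) < tol for q in quantities):
        return "marginal", (a1, a2, a3)
    if all(q > 0 for q in quantities):
        return "stable", (a1, a2, a3)
    return "unstable", (a1, a2, a3)


def assess_stability(f: FixedPointRecord, p: SimpleParams,
                     residual_tol: float = 1e-8) -> FixedPointRecord:
    """Classify the stability of a fixed point by two independent routes.

    Routh-Hurwitz on the characteristic polynomial of the analytic
    Jacobian, cross-checked by a numerical eigensolve; a disagreement
    beyond the marginality tolerance downgrades the verdict to
    ``marginal`` with a diagnostic.  Raises ``ValueError`` if the state is
    not a root of the RHS to within ``residual_tol``.
    """
    residual = float(np.max(np.abs(simple_rhs(f.state, p))))
    if residual > residual_tol:
        raise ValueError(
            f"not a fixed point: max |rhs| = {residual:g} > {residual_tol:g}")
    J = simple_jacobian(f.state, p)
    rh_verdict, coeffs = routh_hurwitz(J)
    eigs = np.linalg.eigvals(J)
    max_re = float(np.max(eigs.real))
    if abs(max_re) < MARGIN_TOL:
        eig_verdict = "marginal"
    else:
        eig_verdict = "stable" if max_re < 0 else "unstable"
    if "marginal" in (rh_verdict, eig_verdict):
        verdict = "marginal"
    elif rh_verdict != eig_verdict:
        verdict = "marginal"
        f.diagnostics["stability_disagreement"] = (rh_verdict, eig_verdict)
    else:
        verdict = rh_verdict
    f.stability = verdict
    f.diagnostics.update(
        routh_hurwitz=coeffs, eigenvalues=eigs, max_real_eigenvalue=max_re,
        residual=residual)
    return f
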