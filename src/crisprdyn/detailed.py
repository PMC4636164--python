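"""The ten-variable CRISPR model: populations plus per-cell spacer quotas.

State ordering (all nonnegative)::

    (P, Q, V, X_A, Y_QA, Y_QI, Y_QS, Y_PA, Y_PI, Y_PS)

``P``/``Q`` are free/infected cell densities in carrying-capacity units,
``V`` is phage density in burst-size x carrying-capacity units, ``X_A`` is
the active phage-protospacer quota per infected cell, and the ``Y``s are
active / inactive (PAM-mutated) / self-targeting spacer quotas per
infected (``Y_Q*``) or free (``Y_P*``) cell, in units of the phage
protospacer complement ``pi_v``.  Time is measured in spacer-acquisition
units ``1/alpha_c``.

All CRISPR reactions in *free* cells (self-targeting acquisition,
deletion, autoimmunity) are scaled by the regulation factor ``delta``;
infected cells run them at full rate.  The per-capita mixing terms
``A_V*P*V/Q`` (infection inflow dilution) and ``G_Qp*Y_QA*Q/P``
(immune-survivor inheritance) are singular at empty populations.  The
quota equations only describe nonempty pools, so a pool whose density
falls below the extinction threshold has its entire per-cell quota rows
frozen (and the singular denominators are floored besides).  An
alternative *total-content* integration
mode evolves quota x population products, which stay finite at extinction,
and recovers quotas afterwards; the two modes agree on benchmark runs.

Model variants: ``no_abi`` removes infected-cell autoimmune loss from the
Q equation (free-cell autoimmunity retained); ``deletion_constitutive``
runs free-cell spacer deletion at full rate ``G_C`` instead of
``delta*G_C``; ``deletion_inverse`` additionally silences infected-cell
deletion (repressed when infected, fully active when uninfected).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .params import DetailedParams, SimpleParams
from .simple import FixedPointRecord

try:  # optional JIT: Table 2 groups span O(1)..O(1e9) and sweeps are hot
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is an optional extra
    def _njit(*a, **k):
        def deco(f):
            return f
        return deco(a[0]) if a and callable(a[0]) else deco

__all__ = [
    "STATE_NAMES", "VariantSpec", "make_state", "detailed_rhs",
    "detailed_rhs_totals", "quotas_to_totals", "totals_to_quotas",
    "phage_free_fixed_point", "delta_max", "reduce_to_simple",
    "ReductionMap",
]

STATE_NAMES = ("P", "Q", "V", "X_A", "Y_QA", "Y_QI", "Y_QS",
               "Y_PA", "Y_PI", "Y_PS")

#: populations below this density (carrying-capacity units) are treated as
#: empty when gating the singular per-capita quota terms.
EXTINCT_THRESHOLD = 1e-10
#: denominator floor for the per-capita terms, below the gate on purpose.
EPS_POP = 1e-12


class VariantSpec(enum.Enum):
    """Structural model variants."""

    baseline = "baseline"
    no_abi = "no-abi"
    deletion_constitutive = "del-const"
    deletion_inverse = "del-inverse"

    @classmethod
    def parse(cls, tag) -> "VariantSpec":
        if isinstance(tag, cls):
            return tag
        for v in cls:
            if tag in (v.name, v.value):
                return v
        raise ValueError(f"unknown variant {tag!r}; choose from "
                         f"{[v.value for v in cls]}")


def make_state(**kw) -> np.ndarray:
    """Build a state vector from named components, zero elsewhere."""
    s = np.zeros(len(STATE_NAMES))
    for k, v in kw.items():
        s[STATE_NAMES.index(k)] = v
    return s


def _variant_codes(p: DetailedParams, variant: VariantSpec):
    """(abi, Gc_infected, Gc_free) for a variant."""
    v = VariantSpec.parse(variant)
    abi = 0.0 if v is VariantSpec.no_abi else 1.0
    if v is VariantSpec.deletion_constitutive:
        return abi, p.G_C, p.G_C
    if v is VariantSpec.deletion_inverse:
        return abi, 0.0, p.G_C
    return abi, p.G_C, p.delta * p.G_C


def pack_params(p: DetailedParams, variant=VariantSpec.baseline) -> np.ndarray:
    """Flatten params + variant into the coefficient vector of the RHS cores."""
    abi, gcq, gcp = _variant_codes(p, variant)
    return np.array([p.A_P, p.A_V, p.G_Qp, p.G_Qphi, p.G_Qv, p.G_V,
                     p.M_V, p.beta, p.delta, p.mu_v, p.alpha_v,
                     gcq, gcp, abi, EXTINCT_THRESHOLD, EPS_POP])


@_njit(cache=True)
def _rhs_quota_core(y, c):  # pragma: no cover - exercised via wrapper
    A_P, A_V, G_Qp, G_Qphi, G_Qv, G_V = c[0], c[1], c[2], c[3], c[4], c[5]
    M_V, beta, delta, mu_v, alpha_v = c[6], c[7], c[8], c[9], c[10]
    gcq, gcp, abi, gate, eps = c[11], c[12], c[13], c[14], c[15]

    P, Q, V = y[0], y[1], y[2]
    X_A, Y_QA, Y_QI, Y_QS = y[3], y[4], y[5], y[6]
    Y_PA, Y_PI, Y_PS = y[7], y[8], y[9]

    inf_flux = A_V * P * V
    # the quota ODEs only describe nonempty pools: the per-cell quota rows
    # of an empty pool are frozen entirely (not just their singular terms)
    q_on = 1.0 if Q > gate else 0.0
    p_on = 1.0 if P > gate else 0.0
    rq = q_on * inf_flux / max(Q, eps)
    rp = p_on * G_Qp * Y_QA * Q / max(P, eps)

    out = np.empty(10)
    out[0] = (A_P * P * (1.0 - P - Q) + G_Qp * Y_QA * Q - inf_flux
              - delta * G_Qphi * Y_PS * P)
    out[1] = inf_flux - (G_Qp * Y_QA + abi * G_Qphi * Y_QS + G_Qv) * Q
    out[2] = G_Qv * Q - G_V * V - (A_V / alpha_v) * P * V
    out[3] = rq * ((1.0 - mu_v) - X_A)
    out[4] = q_on * (X_A + rq * (Y_PA - Y_QA) - gcq * Y_QA)
    out[5] = q_on * (rq * (Y_PI - Y_QI) - gcq * Y_QI)
    out[6] = q_on * (beta + rq * (Y_PS - Y_QS) - gcq * Y_QS)
    out[7] = p_on * (M_V * (Y_PI - Y_PA) + rp * (Y_QA - Y_PA) - gcp * Y_PA)
    out[8] = p_on * (M_V * (Y_PA - Y_PI) + rp * (Y_QI - Y_PI) - gcp * Y_PI)
    out[9] = p_on * (delta * beta + rp * (Y_QS - Y_PS) - gcp * Y_PS)
    return out


@_njit(cache=True)
def _rhs_totals_core(y, c):  # pragma: no cover - exercised via wrapper
    A_P, A_V, G_Qp, G_Qphi, G_Qv, G_V = c[0], c[1], c[2], c[3], c[4], c[5]
    M_V, beta, delta, mu_v, alpha_v = c[6], c[7], c[8], c[9], c[10]
    gcq, gcp, abi, gate, eps = c[11], c[12], c[13], c[14], c[15]

    P, Q, V = y[0], y[1], y[2]
    U_XA, U_QA, U_QI, U_QS = y[3], y[4], y[5], y[6]
    U_PA, U_PI, U_PS = y[7], y[8], y[9]

    Qf = max(Q, eps)
    Pf = max(P, eps)
    Y_QA = U_QA / Qf
    Y_QS = U_QS / Qf
    Y_PS = U_PS / Pf
    X_A = U_XA / Qf

    inf_flux = A_V * P * V
    # per-cell removal rate of infected cells
    Gamma_q = G_Qp * Y_QA + abi * G_Qphi * Y_QS + G_Qv
    # net per-cell balance of free cells, excluding the quota-neutral
    # immunity inflow (cancels exactly in the product rule)
    free_bal = A_P * (1.0 - P - Q) - A_V * V - delta * G_Qphi * Y_PS

    out = np.empty(10)
    out[0] = (A_P * P * (1.0 - P - Q) + G_Qp * U_QA - inf_flux
              - delta * G_Qphi * U_PS)
    out[1] = inf_flux - G_Qp * U_QA - abi * G_Qphi * U_QS - G_Qv * Q
    out[2] = G_Qv * Q - G_V * V - (A_V / alpha_v) * P * V
    out[3] = inf_flux * (1.0 - mu_v) - Gamma_q * U_XA
    out[4] = U_XA + A_V * V * U_PA - gcq * U_QA - Gamma_q * U_QA
    out[5] = A_V * V * U_PI - gcq * U_QI - Gamma_q * U_QI
    out[6] = beta * Q + A_V * V * U_PS - gcq * U_QS - Gamma_q * U_QS
    out[7] = (M_V * (U_PI - U_PA) + G_Qp * Y_QA * U_QA
              - gcp * U_PA + free_bal * U_PA)
    out[8] = (M_V * (U_PA - U_PI) + G_Qp * Y_QA * U_QI
              - gcp * U_PI + free_bal * U_PI)
    out[9] = (delta * beta * P + G_Qp * Y_QA * U_QS
              - gcp * U_PS + free_bal * U_PS)
    return out


def detailed_rhs(s, p: DetailedParams,
                 variant=VariantSpec.baseline) -> np.ndarray:
    """Time derivative of the 10-component quota-mode state.

    Pure function; raises ``ValueError`` on NaN input.
    """
    s = np.asarray(s, dtype=float)
    if np.isnan(s).any():
        raise ValueError(f"NaN in detailed-model state: {s!r}")
    return _rhs_quota_core(s, pack_params(p, variant))


def detailed_rhs_totals(s, p: DetailedParams,
                        variant=VariantSpec.baseline) -> np.ndarray:
    """Time derivative in total-content mode (quota x population products)."""
    s = np.asarray(s, dtype=float)
    if np.isnan(s).any():
        raise ValueError(f"NaN in detailed-model totals state: {s!r}")
    return _rhs_totals_core(s, pack_params(p, variant))


def quotas_to_totals(s) -> np.ndarray:
    """Map a quota-mode state to total-content mode (U = quota * population)."""
    s = np.asarray(s, dtype=float)
    out = s.copy()
    out[3:7] = s[3:7] * s[1]
    out[7:10] = s[7:10] * s[0]
    return out


def totals_to_quotas(s, floor: float = EXTINCT_THRESHOLD) -> np.ndarray:
    """Recover quotas from total contents; quotas of empty pools are zero."""
    s = np.asarray(s, dtype=float)
    out = s.copy()
    out[3:7] = s[3:7] / s[1] if s[1] > floor else 0.0
    out[7:10] = s[7:10] / s[0] if s[0] > floor else 0.0
    return out


class NoPhageFreeSteadyStateError(ValueError):
    """Self-targeting spacers accumulate without bound (G_C = 0)."""


def phage_free_fixed_point(p: DetailedParams,
                           variant=VariantSpec.baseline) -> FixedPointRecord:
    """Analytic phage-free steady state of the detailed model.

    With no phage (``V = Q = 0``) active and inactive spacers are
    progressively lost while self-targeting spacers balance acquisition
    against deletion: ``Y_PS* = beta/G_C`` (baseline; ``delta*beta/G_C``
    for the decoupled-deletion variants whose free-cell deletion runs at
    full rate), and ``P* = 1 - delta*G_Qphi*Y_PS*/A_P``.  Feasible iff
    ``P* > 0``, i.e. iff ``delta < delta_max``.
    """
    variant = VariantSpec.parse(variant)
    _, _, gcp = _variant_codes(p, variant)
    if p.delta * p.beta > 0 and gcp == 0:
        raise NoPhageFreeSteadyStateError(
            "no phage-free steady state: free-cell deletion rate is zero "
            "while delta*beta > 0, so Y_PS grows without bound")
    y_ps = (p.delta * p.beta / gcp) if gcp > 0 else 0.0
    P_star = 1.0 - p.delta * p.G_Qphi * y_ps / p.A_P if p.A_P > 0 else 0.0
    state = make_state(P=P_star, Y_PS=y_ps)
    return FixedPointRecord(
        kind="F", state=state, feasible=bool(P_star > 0),
        diagnostics={"Y_PS_star": y_ps, "variant": variant.value})


def delta_max(p: DetailedParams) -> float:
    """Critical free-cell CRISPR activation bound ``A_P*G_C/(G_Qphi*beta)``.

    Hosts survive the phage-free dynamics iff ``delta < delta_max``.
    Returns ``inf`` (unbounded) when ``beta = 0`` or ``G_Qphi = 0`` —
    with no self-targeting protospacers (perfect self vs non-self
    discrimination) or no autoimmunity there is no constraint.
    """
    if p.beta == 0 or p.G_Qphi == 0:
        return math.inf
    return p.A_P * p.G_C / (p.G_Qphi * p.beta)


@dataclass
class ReductionMap:
    """State/time conversion from the detailed to the simple model.

    The simple model uses the adsorption time unit and measures phage in
    carrying-capacity units, so detailed trajectories map by
    ``t_simple = t_detailed / time_scale`` and
    ``V_simple = phage_scale * V_detailed`` (P and Q are shared).
    """

    time_scale: float  # alpha_v / A_V = alpha_c/(alpha_q*Phi_p)
    phage_scale: float  # alpha_v

    def to_simple_state(self, s10) -> np.ndarray:
        s10 = np.asarray(s10, dtype=float)
        return np.array([s10[0], s10[1], self.phage_scale * s10[2]])


def reduce_to_simple(p: DetailedParams, quotas) -> tuple[SimpleParams, ReductionMap]:
    """Freeze spacer quotas and collapse to the simple model.

    ``quotas = (Y_QA*, Y_QS*, Y_PS*)`` fix the effective immunity and
    autoimmunity rate constants ``G_Qp*Y_QA*``, ``G_Qphi*Y_QS*`` and
    ``G_Qphi*Y_PS*``.  All groups are rescaled by
    ``c = alpha_v/A_V`` to the simple model's adsorption time unit so
    that ``simple_rhs`` on the mapped parameters reproduces the
    population block of ``detailed_rhs`` exactly (after the state/time
    map in the returned :class:`ReductionMap`).
    """
    y_qa, y_qs, y_ps = quotas
    if min(y_qa, y_qs, y_ps) < 0:
        raise ValueError("quotas must be nonnegative")
    if p.A_V <= 0:
        raise ValueError("reduction requires A_V > 0")
    c = p.alpha_v / p.A_V
    sp = SimpleParams(
        A_P=p.A_P * c,
        G_Pphi=p.G_Qphi * y_ps * c,
        G_Qphi=p.G_Qphi * y_qs * c,
        G_Qp=p.G_Qp * y_qa * c,
        G_Qv=p.G_Qv * c,
        G_V=p.G_V * c,
        alpha_v=p.alpha_v,
        delta=p.delta,
    )
    return sp, ReductionMap(time_scale=c, phage_scale=p.alpha_v)
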