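"""Parameter containers, nondimensionalization, and named presets.

Two model families are supported:

* a *simple* three-variable model of a prokaryotic immune system with a
  regulated autoimmunity side effect (free cells P, infected cells Q,
  phage V), and
* a *detailed* ten-variable model that additionally tracks per-cell CRISPR
  spacer quotas (active / inactive / self-targeting, in both cell pools)
  and the per-infected-cell phage protospacer quota.

Dimensional parameters carry SI-style units (hours, cells/ml); the
nondimensional groups are obtained by measuring cell densities in units of
the carrying capacity ``Phi_p`` and time in units of the adsorption
timescale ``1/(alpha_q*Phi_p)`` (simple model) or the spacer-acquisition
timescale ``1/alpha_c`` (detailed model).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Union

import yaml

__all__ = [
    "DimensionalSimpleParams",
    "SimpleParams",
    "DimensionalDetailedParams",
    "DetailedParams",
    "nondimensionalize_simple",
    "redimensionalize_simple",
    "nondimensionalize_detailed",
    "redimensionalize_detailed",
    "preset",
    "preset_names",
    "load_params",
    "save_params",
]


class DegenerateTimeScaleError(ValueError):
    """The chosen nondimensional time unit is zero (degenerate time scale)."""


def _require_nonneg(obj, names):
    for n in names:
        v = getattr(obj, n)
        if v < 0:
            raise ValueError(f"{type(obj).__name__}.{n} must be >= 0, got {v!r}")


def _require_unit_interval(obj, name):
    v = getattr(obj, name)
    if not (0.0 <= v <= 1.0):
        raise ValueError(f"{type(obj).__name__}.{name} must lie in [0, 1], got {v!r}")


@dataclass
class DimensionalSimpleParams:
    """Dimensional rates of the simple regulated-autoimmunity model.

    Units: rates in 1/hr, ``Phi_p`` in cells/ml, ``alpha_q`` in
    ml/(phage*hr); ``alpha_v`` (burst size) and ``delta`` (free-cell
    regulation scale) are dimensionless.
    """

    alpha_p: float  # free-cell growth rate (1/hr)
    Phi_p: float  # carrying capacity (cells/ml)
    alpha_q: float  # adsorption rate (ml/phage/hr)
    alpha_v: float  # burst size
    gamma_v: float  # phage deactivation rate (1/hr)
    gamma_qp: float  # immunity rate, infected -> free (1/hr)
    gamma_qphi: float  # infected-cell autoimmunity rate (1/hr)
    gamma_pphi: float  # free-cell autoimmunity rate (1/hr)
    gamma_qv: float  # lysis rate (1/hr)
    delta: float  # regulation scale in [0, 1]
    varied: frozenset = field(default_factory=frozenset, compare=False)

    def __post_init__(self):
        _require_nonneg(self, ["alpha_p", "alpha_q", "alpha_v", "gamma_v",
                               "gamma_qp", "gamma_qphi", "gamma_pphi", "gamma_qv"])
        if self.Phi_p <= 0:
            raise ValueError(f"Phi_p must be > 0, got {self.Phi_p!r}")
        _require_unit_interval(self, "delta")


@dataclass
class SimpleParams:
    """Nondimensional groups of the simple model.

    Each ``G_x = gamma_x / (alpha_q*Phi_p)`` and ``A_P =
    alpha_p / (alpha_q*Phi_p)``; ``alpha_v`` and ``delta`` pass through.
    ``G_Q`` is the overall removal rate of infected cells.
    """

    A_P: float
    G_Pphi: float
    G_Qphi: float
    G_Qp: float
    G_Qv: float
    G_V: float
    alpha_v: float
    delta: float

    def __post_init__(self):
        # delta > 1 (free-cell activity exceeding infected-cell activity) is
        # outside the regulatory interpretation but mathematically admissible;
        # bifurcation scans cross the extinction line there.
        _require_nonneg(self, ["A_P", "G_Pphi", "G_Qphi", "G_Qp", "G_Qv",
                               "G_V", "alpha_v", "delta"])

    @property
    def G_Q(self) -> float:
        """Overall infected-cell removal rate G_Qphi + G_Qp + G_Qv."""
        return self.G_Qphi + self.G_Qp + self.G_Qv


@dataclass
class DimensionalDetailedParams:
    """Dimensional rates of the detailed CRISPR model.

    Per-spacer rates ``gamma_qp`` and ``gamma_qphi`` have units
    1/((spacers/cell)*hr); ``alpha_c``/``gamma_c`` are the spacer
    acquisition/deletion rates (1/hr); ``pi_v`` is the number of
    protospacers per phage genome; ``beta`` scales the host self-targeting
    protospacer pool relative to ``pi_v``; ``mu_v`` is the phage mutation
    rate per protospacer.
    """

    alpha_p: float
    Phi_p: float
    alpha_q: float
    alpha_v: float
    gamma_v: float
    gamma_qv: float
    gamma_qp: float  # per active spacer per cell
    gamma_qphi: float  # per self-targeting spacer per cell
    alpha_c: float  # spacer acquisition rate (1/hr)
    gamma_c: float  # spacer deletion rate (1/hr)
    pi_v: float  # protospacers per phage genome
    beta: float  # host-to-phage protospacer ratio
    mu_v: float  # phage mutation rate per protospacer
    delta: float
    varied: frozenset = field(default_factory=frozenset, compare=False)

    def __post_init__(self):
        _require_nonneg(self, ["alpha_p", "alpha_q", "alpha_v", "gamma_v",
                               "gamma_qv", "gamma_qp", "gamma_qphi",
                               "alpha_c", "gamma_c", "beta"])
        if self.Phi_p <= 0:
            raise ValueError(f"Phi_p must be > 0, got {self.Phi_p!r}")
        if self.pi_v <= 0:
            raise ValueError(f"pi_v must be > 0, got {self.pi_v!r}")
        if not (0.0 <= self.mu_v < 1.0):
            raise ValueError(f"mu_v must lie in [0, 1), got {self.mu_v!r}")
        _require_unit_interval(self, "delta")


@dataclass
class DetailedParams:
    """Nondimensional groups of the detailed model (time unit 1/alpha_c).

    ``A_V = alpha_v*alpha_q*Phi_p/alpha_c`` couples infection to the phage
    pool; ``G_Qp = gamma_qp*pi_v/alpha_c`` and ``G_Qphi =
    gamma_qphi*pi_v/alpha_c`` are per-quota immunity/autoimmunity groups
    (quotas are measured in units of pi_v); ``G_C = gamma_c/alpha_c`` is
    the deletion-to-acquisition ratio; ``M_V = mu_v/alpha_c`` drives
    active<->inactive spacer interconversion through phage PAM mutation.
    """

    A_P: float
    A_V: float
    G_Qp: float
    G_Qphi: float
    G_Qv: float
    G_V: float
    G_C: float
    M_V: float
    beta: float
    delta: float
    mu_v: float
    alpha_v: float

    def __post_init__(self):
        # delta > 0 unrestricted here for the same scanning reason as in
        # SimpleParams; dimensional containers enforce the [0, 1] range.
        _require_nonneg(self, ["A_P", "A_V", "G_Qp", "G_Qphi", "G_Qv",
                               "G_V", "G_C", "M_V", "beta", "alpha_v",
                               "delta"])
        if not (0.0 <= self.mu_v < 1.0):
            raise ValueError(f"mu_v must lie in [0, 1), got {self.mu_v!r}")


def nondimensionalize_simple(p: DimensionalSimpleParams) -> SimpleParams:
    """Rescale the simple model by the adsorption time unit 1/(alpha_q*Phi_p)."""
    scale = p.alpha_q * p.Phi_p
    if scale == 0:
        raise DegenerateTimeScaleError(
            "degenerate time scale: alpha_q*Phi_p = 0")
    return SimpleParams(
        A_P=p.alpha_p / scale,
        G_Pphi=p.gamma_pphi / scale,
        G_Qphi=p.gamma_qphi / scale,
        G_Qp=p.gamma_qp / scale,
        G_Qv=p.gamma_qv / scale,
        G_V=p.gamma_v / scale,
        alpha_v=p.alpha_v,
        delta=p.delta,
    )


def redimensionalize_simple(p: SimpleParams, alpha_q: float,
                            Phi_p: float) -> DimensionalSimpleParams:
    """Inverse of :func:`nondimensionalize_simple` given the two scale setters."""
    scale = alpha_q * Phi_p
    if scale == 0:
        raise DegenerateTimeScaleError(
            "degenerate time scale: alpha_q*Phi_p = 0")
    return DimensionalSimpleParams(
        alpha_p=p.A_P * scale, Phi_p=Phi_p, alpha_q=alpha_q,
        alpha_v=p.alpha_v, gamma_v=p.G_V * scale,
        gamma_qp=p.G_Qp * scale, gamma_qphi=p.G_Qphi * scale,
        gamma_pphi=p.G_Pphi * scale, gamma_qv=p.G_Qv * scale,
        delta=p.delta,
    )


def nondimensionalize_detailed(p: DimensionalDetailedParams) -> DetailedParams:
    """Rescale the detailed model by the spacer-acquisition time unit 1/alpha_c.

    Cell densities are measured in Phi_p, phage in alpha_v*Phi_p, and
    spacer/protospacer quotas in pi_v, so the per-quota rates pick up a
    pi_v factor: G_Qp = gamma_qp*pi_v/alpha_c (and likewise G_Qphi).
    """
    if p.alpha_c == 0:
        raise DegenerateTimeScaleError(
            "degenerate CRISPR time scale: alpha_c = 0")
    ac = p.alpha_c
    return DetailedParams(
        A_P=p.alpha_p / ac,
        A_V=p.alpha_v * p.alpha_q * p.Phi_p / ac,
        G_Qp=p.gamma_qp * p.pi_v / ac,
        G_Qphi=p.gamma_qphi * p.pi_v / ac,
        G_Qv=p.gamma_qv / ac,
        G_V=p.gamma_v / ac,
        G_C=p.gamma_c / ac,
        M_V=p.mu_v / ac,
        beta=p.beta,
        delta=p.delta,
        mu_v=p.mu_v,
        alpha_v=p.alpha_v,
    )


def redimensionalize_detailed(p: DetailedParams, alpha_c: float, Phi_p: float,
                              alpha_q: float, pi_v: float) -> DimensionalDetailedParams:
    """Inverse of :func:`nondimensionalize_detailed` given the scale setters."""
    if alpha_c == 0:
        raise DegenerateTimeScaleError(
            "degenerate CRISPR time scale: alpha_c = 0")
    return DimensionalDetailedParams(
        alpha_p=p.A_P * alpha_c,
        Phi_p=Phi_p,
        alpha_q=alpha_q,
        alpha_v=p.alpha_v,
        gamma_v=p.G_V * alpha_c,
        gamma_qv=p.G_Qv * alpha_c,
        gamma_qp=p.G_Qp * alpha_c / pi_v,
        gamma_qphi=p.G_Qphi * alpha_c / pi_v,
        alpha_c=alpha_c,
        gamma_c=p.G_C * alpha_c,
        pi_v=pi_v,
        beta=p.beta,
        mu_v=p.mu_v,
        delta=p.delta,
    )


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _benchmark_simple() -> DimensionalSimpleParams:
    # Benchmark parameterization of the simple model.  The bifurcation-figure
    # caption fixes alpha_p, Phi_p, gamma_v, alpha_v and alpha_q; the
    # remaining rates are scan defaults: gamma_pphi = alpha_p puts the
    # host-extinction line exactly at delta = 1, and gamma_qp, gamma_qphi,
    # gamma_qv default to the detailed-model lysis scale (1/hr).
    return DimensionalSimpleParams(
        alpha_p=1.0, Phi_p=1e8, alpha_q=5e-9, alpha_v=50.0, gamma_v=5.0,
        gamma_qp=1.0, gamma_qphi=1.0, gamma_pphi=1.0, gamma_qv=1.0,
        delta=0.0,
        varied=frozenset({"gamma_qp", "gamma_qphi", "gamma_pphi", "delta"}),
    )


def _reference_detailed() -> DimensionalDetailedParams:
    # Reference kinetic parameterization of the detailed model.  gamma_c,
    # gamma_qphi and beta are swept in the analyses; their defaults here
    # (gamma_c = alpha_c, gamma_qphi = gamma_qp, beta = 1) are logged as
    # varied.  Burst size is not part of the kinetic table; 50 (the simple
    # benchmark's value) is the documented default.
    return DimensionalDetailedParams(
        alpha_p=1.0, Phi_p=1e8, alpha_q=5e-9, alpha_v=50.0, gamma_v=5.0,
        gamma_qv=1.0, gamma_qp=1.0, gamma_qphi=1.0,
        alpha_c=1e-6, gamma_c=1e-6, pi_v=1000.0, beta=1.0, mu_v=30e-8,
        delta=0.0,
        varied=frozenset({"gamma_c", "gamma_qphi", "beta", "delta",
                          "alpha_v"}),
    )


_PRESETS = {
    "benchmark-simple": _benchmark_simple,
    "reference-detailed": _reference_detailed,
}


def preset_names() -> list[str]:
    return sorted(_PRESETS)


def preset(name: str) -> Union[DimensionalSimpleParams, DimensionalDetailedParams]:
    """Return a named dimensional parameter record.

    Raises ``KeyError`` listing the available names on a registry miss.
    """
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"no such preset {name!r}; available presets: {preset_names()}"
        ) from None
    return factory()


# ---------------------------------------------------------------------------
# Flat key-value serialization (YAML)
# ---------------------------------------------------------------------------

_KIND_BY_CLASS = {
    DimensionalSimpleParams: "simple-dimensional",
    SimpleParams: "simple",
    DimensionalDetailedParams: "detailed-dimensional",
    DetailedParams: "detailed",
}
_CLASS_BY_KIND = {v: k for k, v in _KIND_BY_CLASS.items()}


def params_to_dict(p) -> dict:
    d = {"kind": _KIND_BY_CLASS[type(p)]}
    for f in fields(p):
        if f.name == "varied":
            d["varied"] = sorted(getattr(p, "varied"))
        else:
            d[f.name] = float(getattr(p, f.name))
    return d


def params_from_dict(d: dict):
    d = dict(d)
    kind = d.pop("kind")
    cls = _CLASS_BY_KIND[kind]
    if "varied" in d:
        d["varied"] = frozenset(d["varied"])
    return cls(**d)


def save_params(p, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_dict(p), fh, sort_keys=True)


def load_params(path):
    with open(path) as fh:
        return params_from_dict(yaml.safe_load(fh))


def with_overrides(p, **overrides):
    """Return a copy of a parameter record with fields replaced."""
    valid = {f.name for f in fields(p)}
    bad = set(overrides) - valid
    if bad:
        raise ValueError(f"unknown parameter(s) {sorted(bad)} for "
                         f"{type(p).__name__}; valid: {sorted(valid)}")
    return replace(p, **overrides)
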