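"""Leaf-level FvCB photosynthesis relations and local stroma rate laws.

Net CO2 assimilation follows the Farquhar-von Caemmerer-Berry (FvCB)
model,

    AN = (Cc - Gamma*) * X1 / (Cc + X2) - Rd,

where Cc is the CO2 partial pressure at the Rubisco carboxylation sites,
Gamma* the CO2 compensation point in the absence of day respiration, and
(X1, X2) depend on the limiting process: Rubisco-limited carboxylation
has X1 = Vcmax and X2 = KmC * (1 + O/KmO); electron-transport-limited
carboxylation has X1 = J/4 and X2 = 2 * Gamma*.  Under triose-phosphate
utilisation (TPU) limitation AN plateaus at 3*Tp - Rd.

Inside the reaction-diffusion model the same kinetics act pointwise in
the stroma as volumetric Michaelis-Menten sinks; the local gross
carboxylation is the smaller of the Rubisco- and electron-transport-
limited hyperbolae, and each unit of carboxylation at local pressure C
releases Gamma*/C units of photorespired CO2 (from Vo/Vc = 2 Gamma*/C
and half a CO2 per oxygenation).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

__all__ = [
    "KineticParams",
    "Limitation",
    "LimitationState",
    "gamma_star",
    "electron_transport",
    "fvcb_assimilation",
    "carbox_resistance",
    "local_rates",
    "tp_from_ap",
]

#: Michaelis-Menten constant of Rubisco carboxylation (Pa)
KMC_DEFAULT = 26.7
#: Michaelis-Menten constant of Rubisco oxygenation (kPa)
KMO_DEFAULT = 16.4
#: Rubisco CO2/O2 specificity (kPa Pa^-1)
SCO_DEFAULT = 2.6


def gamma_star(o: float, sco: float = SCO_DEFAULT) -> float:
    """CO2 compensation point without day respiration, Gamma* (Pa).

    Gamma* = 0.5 * O / Sc/o with O the oxygen partial pressure in kPa
    and Sc/o the Rubisco specificity in kPa Pa^-1.
    """
    if sco <= 0:
        raise ValueError("Rubisco specificity sco must be > 0")
    if o < 0:
        raise ValueError("oxygen partial pressure must be >= 0")
    return 0.5 * o / sco


def electron_transport(s_cal: float, iinc, phi2) -> float:
    """Linear electron transport rate J = s * Iinc * Phi2 (umol m-2 s-1)."""
    return s_cal * np.asarray(iinc, dtype=float) * np.asarray(phi2, dtype=float)


@dataclass(frozen=True)
class KineticParams:
    """FvCB kinetic parameters, all expressed per unit leaf area.

    ``vcmax``, ``rd`` and ``tp`` are rates in umol m^-2 s^-1; ``s_cal``
    is the dimensionless calibration factor linking irradiance and PSII
    quantum yield to electron transport (J = s_cal * Iinc * Phi2);
    ``kmc`` (Pa), ``kmo`` (kPa) and ``sco`` (kPa Pa^-1) are Rubisco
    constants.  ``tp`` may be None (no TPU cap).
    """

    vcmax: float = 120.0
    rd: float = 1.2
    tp: float | None = None
    s_cal: float = 0.45
    kmc: float = KMC_DEFAULT
    kmo: float = KMO_DEFAULT
    sco: float = SCO_DEFAULT

    def __post_init__(self) -> None:
        for name in ("vcmax", "s_cal", "kmc", "kmo", "sco"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.rd < 0:
            raise ValueError("rd must be >= 0")
        if self.tp is not None and self.tp <= 0:
            raise ValueError("tp must be > 0 when set")

    def gamma_star(self, o: float) -> float:
        return gamma_star(o, self.sco)

    def kmm_effective(self, o: float) -> float:
        """Effective Michaelis-Menten constant KmC * (1 + O/KmO) (Pa)."""
        return self.kmc * (1.0 + o / self.kmo)

    def with_(self, **kwargs) -> "KineticParams":
        return replace(self, **kwargs)


class Limitation(str, Enum):
    RUBISCO = "rubisco"
    ELECTRON_TRANSPORT = "electron_transport"
    TPU = "tpu"


@dataclass(frozen=True)
class LimitationState:
    """Resolved (X1, X2) pair for one limitation branch at given O."""

    limitation: Limitation
    x1: float  # umol m-2 s-1
    x2: float  # Pa

    @classmethod
    def rubisco(cls, params: KineticParams, o: float) -> "LimitationState":
        return cls(Limitation.RUBISCO, params.vcmax, params.kmm_effective(o))

    @classmethod
    def electron_transport(cls, j: float, gamma: float) -> "LimitationState":
        return cls(Limitation.ELECTRON_TRANSPORT, j / 4.0, 2.0 * gamma)


def fvcb_assimilation(cc, params: KineticParams, lim: LimitationState, o: float):
    """Net assimilation AN (umol m-2 s-1) at chloroplast pressure Cc (Pa).

    TPU limitation returns the plateau 3*Tp - Rd independent of Cc.
    """
    if lim.limitation is Limitation.TPU:
        if params.tp is None:
            raise ValueError("tpu limitation requires tp")
        return 3.0 * params.tp - params.rd
    cc = np.asarray(cc, dtype=float)
    if np.any(cc <= 0):
        raise ValueError("Cc must be > 0")
    if np.any(cc + lim.x2 <= 0):
        raise ValueError("Cc + X2 must be > 0")
    gamma = params.gamma_star(o)
    out = (cc - gamma) * lim.x1 / (cc + lim.x2) - params.rd
    return float(out) if out.ndim == 0 else out


def carbox_resistance(cc: float, lim: LimitationState) -> float:
    """Carboxylation resistance (Cc + X2)/X1 (Pa per umol m-2 s-1)."""
    if lim.x1 <= 0:
        raise ValueError("X1 must be > 0")
    return (cc + lim.x2) / lim.x1


@dataclass(frozen=True)
class VolumetricKinetics:
    """Stroma rate-law coefficients per unit stroma volume.

    ``vmax_vol`` and ``j_vol`` are umol m^-3 s^-1 (J expressed before
    the /4 electron-to-CO2 conversion); ``kmm`` = KmC(1 + O/KmO) in Pa
    and ``gamma`` = Gamma* in Pa.  Either capacity may be set to
    ``np.inf`` to disable that limitation branch.
    """

    vmax_vol: float
    j_vol: float
    kmm: float
    gamma: float


def local_rates(c, vol: VolumetricKinetics):
    """Pointwise stroma rates at CO2 pressure ``c`` (Pa).

    Returns ``(w_c, w_j, w, release)`` where ``w_c`` and ``w_j`` are the
    Rubisco- and electron-transport-limited carboxylation hyperbolae,
    ``w = min(w_c, w_j)`` the gross carboxylation, and ``release`` the
    photorespiratory CO2 release ``w * gamma / c`` (all umol m^-3 s^-1).
    """
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError("local CO2 pressure must be > 0")
    w_c = vol.vmax_vol * c / (c + vol.kmm)
    with np.errstate(invalid="ignore"):
        w_j = (vol.j_vol / 4.0) * c / (c + 2.0 * vol.gamma)
    w_j = np.where(np.isnan(w_j), np.inf, w_j)  # inf * 0/0 guard
    w = np.minimum(w_c, w_j)
    release = w * vol.gamma / c
    return w_c, w_j, w, release


def local_sink_coefficient(c, vol: VolumetricKinetics):
    """First-order linearisation k(c) with w = k * c (s^-1, volumetric).

    Uses the limiting branch at ``c``: k = X1v / (c + X2_branch).  This
    is the Picard coefficient of the finite-volume solver; at a fixed
    point k * c equals the exact Michaelis-Menten rate.
    """
    c = np.asarray(c, dtype=float)
    k_c = vol.vmax_vol / (c + vol.kmm)
    k_j = (vol.j_vol / 4.0) / (c + 2.0 * vol.gamma)
    return np.minimum(k_c, k_j)


def tp_from_ap(ap: float, rd: float, grouping: str = "sum") -> float:
    """Triose-phosphate utilisation rate from the high-Ca plateau.

    With the TPU plateau AN = 3*Tp - Rd, the observed plateau Ap gives
    Tp = (Ap + Rd)/3 (``grouping='sum'``, the default, consistent with
    the plateau form).  ``grouping='half'`` selects the alternative
    reading Tp = Ap + Rd/3.
    """
    if ap + rd <= 0:
        raise ValueError("Ap + Rd must be > 0")
    if grouping == "sum":
        return (ap + rd) / 3.0
    if grouping == "half":
        return ap + rd / 3.0
    raise ValueError("grouping must be 'sum' or 'half'")
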