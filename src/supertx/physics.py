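"""Pure physics kernels: torque response, polymerase stalling, initiation energetics.

Units are nanometers, seconds, radians and pN nm throughout.  Supercoiling
density sigma is dimensionless (excess twist per relaxed twist).

The torque response follows Marko's two-phase model of stretched supercoiled
DNA: below a critical density the DNA stores twist elastically (torque linear
in sigma), above a second critical density all excess linking is absorbed in
plectonemes (again linear, with a softer slope), and in between the two
phases coexist at a constant torque.  The three regimes and both critical
densities are derived in closed form from four mechanical constants (twist
persistence length, plectoneme twist stiffness, bending persistence length,
stretching force) via a common-tangent construction on the two phase
free-energy parabolas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

#: Relaxed B-DNA twist density, radians/nm (one helical turn per ~10.5 bp).
OMEGA0 = 1.85
#: Rise per base pair, nm.
BP_TO_NM = 0.34


class TorqueModelKind(str, Enum):
    """Which torque-response curve to use."""

    BASE_MARKO = "base_marko"
    NUCLEOSOME_BUFFERED = "nucleosome_buffered"


class InitiationModelKind(str, Enum):
    """How the polymerase initiation rate responds to local supercoiling."""

    SUPERCOILING_INDEPENDENT = "supercoiling_independent"
    FIRST_ORDER = "first_order"
    SECOND_ORDER = "second_order"
    SECOND_ORDER_WITH_HYPER_PENALTY = "second_order_with_hyper_penalty"


@dataclass(frozen=True)
class MarkoParams:
    """Mechanical constants of the two-phase torque response.

    Parameters
    ----------
    twist_stiffness : float
        Bare twist persistence length c of B-DNA, nm.
    plectoneme_stiffness : float
        Effective twist stiffness p of the plectonemic phase, nm.
    bend_stiffness : float
        Bending persistence length A, nm.
    force : float
        Stretching force on the DNA, pN.  In vivo tension is weak; the
        default (0.2 pN) places the buckling transition near sigma ~ 0.01
        and the coexistence torque near 5 pN nm.
    """

    twist_stiffness: float = 95.0
    plectoneme_stiffness: float = 24.0
    bend_stiffness: float = 50.0
    force: float = 0.2

    def effective_twist_stiffness(self, kBT: float) -> float:
        """Force-renormalized twist stiffness c_s of the stretched phase, nm.

        Thermal bending fluctuations at low force soften the apparent twist
        stiffness: c_s = c * (1 - (c / 4A) * sqrt(kBT / (A f))).
        """
        c, a, f = self.twist_stiffness, self.bend_stiffness, self.force
        return c * (1.0 - (c / (4.0 * a)) * math.sqrt(kBT / (a * f)))

    def stretching_free_energy(self, kBT: float) -> float:
        """Free energy per length g of the extended phase, pN (= pN nm / nm)."""
        a, f = self.bend_stiffness, self.force
        return f - math.sqrt(kBT * f / a)


@dataclass(frozen=True)
class PhysicalParams:
    """All physical constants of the polymerase/supercoiling model.

    Attributes
    ----------
    omega0 : float
        Relaxed DNA twist density, rad/nm.
    kBT : float
        Thermal energy, pN nm (4.11 at 298 K).
    v0 : float
        Unopposed polymerase translocation speed, nm/s (0.05 kb/s).
    tau_s, tau_w : float
        Stall torque and stall width of the sigmoidal velocity response,
        pN nm.
    chi : float
        Viscous resistance of DNA to local twisting, pN nm s.
    eta : float
        Rotational drag coefficient of the nascent RNA per unit length
        raised to ``n_drag``, pN nm s / nm**n_drag.
    n_drag : float
        Exponent of nascent-RNA length in the drag torque.
    marko : MarkoParams
        Constants of the torque response.
    alpha : float
        Coefficient of the quadratic initiation-energy correction.
    sigma_hyper_neg, sigma_hyper_pos : float
        Supercoiling densities beyond which stable structures (R-loops,
        G-quadruplexes) are assumed to block initiation entirely.
    nuc_plateau : tuple
        [sigma_lo, sigma_hi] band over which nucleosome buffering absorbs
        positive supercoiling at zero torque.
    penalty_energy_kbt : float
        Initiation energy (in units of kBT) assigned inside the hyper
        penalty region; large but finite so that exp() stays well defined.
    max_enhancement : float
        Cap on the supercoiling Boltzmann factor exp(-E/kBT) applied to
        initiation rates: beyond this fold-change, promoter output is
        limited by polymerase recruitment and open-complex formation
        rather than by binding energetics.
    """

    omega0: float = OMEGA0
    kBT: float = 4.11
    v0: float = 17.0
    tau_s: float = 12.0
    tau_w: float = 3.0
    chi: float = 1.0
    eta: float = 6.0e-4
    n_drag: float = 1.0
    marko: MarkoParams = field(default_factory=MarkoParams)
    alpha: float = 0.025
    sigma_hyper_neg: float = -0.06
    sigma_hyper_pos: float = 0.125
    nuc_plateau: tuple = (0.0, 0.031)
    penalty_energy_kbt: float = 1000.0
    max_enhancement: float = 40.0

    def __post_init__(self):
        if self.omega0 <= 0 or self.v0 <= 0 or self.tau_w <= 0:
            raise ValueError("omega0, v0 and tau_w must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if not (self.sigma_hyper_neg < 0.0 < self.sigma_hyper_pos):
            raise ValueError("hyper cutoffs must bracket zero")
        if not self.nuc_plateau[0] <= self.nuc_plateau[1]:
            raise ValueError("nuc_plateau bounds must be ordered")

    # -- derived torque-curve quantities ------------------------------------
    @property
    def c_s(self) -> float:
        """Effective twist stiffness of the stretched phase, nm."""
        return self.marko.effective_twist_stiffness(self.kBT)

    @property
    def sigma_s(self) -> float:
        """Supercoiling density at which plectonemes first nucleate."""
        c_s = self.c_s
        p = self.marko.plectoneme_stiffness
        g = self.marko.stretching_free_energy(self.kBT) / self.kBT
        return math.sqrt(2.0 * g * p / (c_s * (c_s - p))) / self.omega0

    @property
    def sigma_p(self) -> float:
        """Supercoiling density at which the DNA is fully plectonemic."""
        return self.sigma_s * self.c_s / self.marko.plectoneme_stiffness

    @property
    def tau0(self) -> float:
        """Coexistence (buckling-plateau) torque, pN nm.

        Also the scale factor of the quadratic initiation-energy term.
        """
        return self.kBT * self.c_s * self.omega0 * self.sigma_s

    def with_stall_disabled(self) -> "PhysicalParams":
        """Copy of the parameters with an unreachably large stall torque."""
        return replace(self, tau_s=1.0e9)


def torque(sigma, params: PhysicalParams, kind: TorqueModelKind = TorqueModelKind.BASE_MARKO):
    """DNA restoring torque at supercoiling density ``sigma``, pN nm.

    Odd-symmetric piecewise curve: linear (twisted phase) for
    |sigma| < sigma_s, constant +/- tau0 in the coexistence band
    sigma_s <= |sigma| <= sigma_p, and linear with the plectonemic slope
    beyond.  The nucleosome-buffered variant returns zero torque inside the
    buffering band ``params.nuc_plateau`` and translates the positive branch
    right by the band width, so the curve remains continuous.

    Accepts scalars or arrays; total on all finite inputs.
    """
    sig = np.asarray(sigma, dtype=float)
    kBT, w0 = params.kBT, params.omega0
    c_s = params.c_s
    p = params.marko.plectoneme_stiffness
    s_s, s_p, t0 = params.sigma_s, params.sigma_p, params.tau0

    def base(s):
        a = np.abs(s)
        return np.sign(s) * np.where(
            a < s_s, kBT * c_s * w0 * a, np.where(a <= s_p, t0, kBT * p * w0 * a)
        )

    if kind == TorqueModelKind.BASE_MARKO:
        out = base(sig)
    elif kind == TorqueModelKind.NUCLEOSOME_BUFFERED:
        lo, hi = params.nuc_plateau
        width = hi - lo
        out = np.where(
            sig < lo, base(sig), np.where(sig <= hi, 0.0, base(sig - width))
        )
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown torque model {kind!r}")
    if np.ndim(sigma) == 0:
        return float(out)
    return out


def velocity(tau_front, tau_behind, params: PhysicalParams):
    """Polymerase translocation speed under front/behind torques, nm/s.

    v = v0 / ((1 + e^{(|tau_f|-tau_s)/tau_w}) (1 + e^{(|tau_b|-tau_s)/tau_w}))

    Either a large front torque or a large behind torque stalls the
    polymerase independently.  Symmetric in the two arguments and in the
    sign of each torque; bounded by (0, v0].
    """
    tf = np.abs(np.asarray(tau_front, dtype=float))
    tb = np.abs(np.asarray(tau_behind, dtype=float))
    ef = np.exp(np.clip((tf - params.tau_s) / params.tau_w, -700.0, 700.0))
    eb = np.exp(np.clip((tb - params.tau_s) / params.tau_w, -700.0, 700.0))
    v = params.v0 / ((1.0 + ef) * (1.0 + eb))
    if np.ndim(tau_front) == 0 and np.ndim(tau_behind) == 0:
        return float(v)
    return v


def initiation_energy(
    sigma,
    params: PhysicalParams,
    kind: InitiationModelKind = InitiationModelKind.SECOND_ORDER,
    torque_kind: TorqueModelKind = TorqueModelKind.BASE_MARKO,
):
    """Supercoiling contribution to the polymerase binding energy, pN nm.

    The first-order term 1.2 * 2 pi * tau(sigma) is the work of inserting
    the ~1.2 turns of twist displaced by a bound polymerase against the
    local torque.  The second-order model adds alpha * tau0 * sigma**2,
    which moderates the unboundedly favorable energetics of strongly
    underwound DNA.  The hyper-penalty variant additionally returns a large
    finite energy outside (sigma_hyper_neg, sigma_hyper_pos), making
    initiation numerically impossible where stable non-B structures form.
    """
    sig = np.asarray(sigma, dtype=float)
    if kind == InitiationModelKind.SUPERCOILING_INDEPENDENT:
        out = np.zeros_like(sig)
    else:
        out = 1.2 * 2.0 * math.pi * np.asarray(torque(sig, params, torque_kind))
        if kind in (
            InitiationModelKind.SECOND_ORDER,
            InitiationModelKind.SECOND_ORDER_WITH_HYPER_PENALTY,
        ):
            out = out + params.alpha * params.tau0 * sig**2
        if kind == InitiationModelKind.SECOND_ORDER_WITH_HYPER_PENALTY:
            penalty = params.penalty_energy_kbt * params.kBT
            out = np.where(
                (sig < params.sigma_hyper_neg) | (sig > params.sigma_hyper_pos),
                penalty,
                out,
            )
    if np.ndim(sigma) == 0:
        return float(out)
    return out


def initiation_rate(
    sigma,
    base_rate,
    params: PhysicalParams,
    kind: InitiationModelKind = InitiationModelKind.SECOND_ORDER,
    torque_kind: TorqueModelKind = TorqueModelKind.BASE_MARKO,
):
    """Instantaneous initiation rate at supercoiling density ``sigma``, 1/s.

    rate = base_rate * exp(-E_sc / kBT), with the enhancement factor capped
    at ``params.max_enhancement`` (recruitment cannot outrun diffusion).
    Equals ``base_rate`` exactly at sigma = 0 for every model kind.
    """
    e = np.asarray(initiation_energy(sigma, params, kind, torque_kind))
    factor = np.exp(np.clip(-e / params.kBT, -700.0, math.log(params.max_enhancement)))
    rate = np.asarray(base_rate, dtype=float) * factor
    if np.ndim(sigma) == 0 and np.ndim(base_rate) == 0:
        return float(rate)
    return rate
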