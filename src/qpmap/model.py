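"""Two-compartment diffusion-weighted ASL signal model.

The model describes the perfusion-weighted (label minus control) signal of a
pseudo-continuous ASL acquisition with optional diffusion preparation. Labeled
arterial water arrives in the capillary bed after the arterial transit time
(ATT) and crosses the blood-brain barrier into tissue at the water exchange
rate k_W. Each acquired encode is characterised by its post-labeling delay
(PLD), diffusion weighting b, and number of averaged excitations (NEX). A
sufficiently strong diffusion preparation crushes the fast pseudo-diffusing
capillary signal, so a crushed encode sees only the tissue compartment while
an uncrushed encode sees the sum of both compartments::

    I = dM_b + (1 - crushed) * dM_c

With k = k_W / 60 (1/s), alpha = k + R1a and beta = k / (k + R1a - R1b),
t = delta + PLD:

    dM_b = 2 F eps M0 (beta/lam) [ e^{-(R1a-R1b) ATT} / R1b (e^{-R1b (t-delta)} - e^{-R1b t})
                                   - e^{k ATT} / alpha  (e^{-alpha (t-delta)} - e^{-alpha t}) ]
    dM_c = 2 F eps M0 e^{-(R1a-R1b) ATT} / (lam alpha) (e^{-alpha (t-delta)} - e^{-alpha t})

where F is the flow in mL/g/s (CBF / 6000 with CBF in mL/100 g/min). The
difference signals are stored as nonnegative perfusion-weighted magnitudes,
i.e. the forward model carries a +2 prefactor with the brackets ordered so
that physiologic parameters yield signals >= 0.

Units at the interface follow the perfusion literature: k_W in 1/min, CBF in
mL/100 g/min, ATT and PLD in seconds, relaxation rates in 1/s. Conversions to
SI-consistent rates happen inside this module only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np

__all__ = [
    "PhysicalConstants",
    "Encode",
    "AcquisitionSpec",
    "VoxelParams",
    "alpha_beta",
    "delta_M_b",
    "delta_M_c",
    "qpm_signal",
    "forward_series",
    "default_protocol",
    "DEFAULT_B_CRUSH",
]

#: b-value (s/mm^2) at and above which an encode is treated as capillary-crushed
DEFAULT_B_CRUSH = 10.0

#: tolerance below which the beta denominator k + R1a - R1b is degenerate (1/s)
_BETA_DEGENERACY_TOL = 1e-9
_BETA_PERTURBATION = 1e-6


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants of the labeling experiment.

    delta
        Labeling duration, seconds.
    epsilon
        Combined labeling efficiency: initial labeling efficiency times the
        label surviving background suppression (0.8 * 0.75 = 0.6 by default).
    lam
        Blood-brain partition coefficient, mL/g.
    r1a
        Longitudinal relaxation rate of arterial blood, 1/s.
    """

    delta: float = 1.5
    epsilon: float = 0.6
    lam: float = 0.9
    r1a: float = 0.6

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError(f"labeling duration must be positive, got {self.delta}")
        if not 0 < self.epsilon <= 1:
            raise ValueError(f"labeling efficiency must be in (0, 1], got {self.epsilon}")
        if not 0 < self.lam <= 1.2:
            raise ValueError(f"partition coefficient must be in (0, 1.2], got {self.lam}")
        if not self.r1a > 0:
            raise ValueError(f"blood relaxation rate must be positive, got {self.r1a}")


@dataclass(frozen=True)
class Encode:
    """One labeled-image acquisition: PLD (s), b (s/mm^2), NEX, crush flag."""

    pld: float
    b: float = 0.0
    nex: int = 1
    crush: bool = False

    def __post_init__(self) -> None:
        if not self.pld > 0:
            raise ValueError(f"PLD must be positive, got {self.pld}")
        if self.b < 0:
            raise ValueError(f"b-value must be nonnegative, got {self.b}")
        if self.nex < 1:
            raise ValueError(f"NEX must be >= 1, got {self.nex}")
        if self.crush and self.b == 0:
            raise ValueError("a b=0 encode cannot be crushed")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Ordered encodes plus physical constants.

    Encode order is the storage order of the 4-D series. Joint k_W/CBF/ATT
    estimation needs at least one crushed and one uncrushed encode; an
    unidentifiable protocol triggers a warning here (the fitter enforces it).
    """

    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    encodes: tuple[Encode, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "encodes", tuple(self.encodes))
        if self.encodes:
            crushed = [e.crush for e in self.encodes]
            if not (any(crushed) and not all(crushed)):
                warnings.warn(
                    "protocol has no crushed/uncrushed contrast; "
                    "k_W is not identifiable from these encodes",
                    stacklevel=2,
                )

    def __len__(self) -> int:
        return len(self.encodes)

    @property
    def plds(self) -> np.ndarray:
        return np.array([e.pld for e in self.encodes], dtype=float)

    @property
    def nex(self) -> np.ndarray:
        return np.array([e.nex for e in self.encodes], dtype=float)

    @property
    def crushed(self) -> np.ndarray:
        return np.array([e.crush for e in self.encodes], dtype=bool)


@dataclass(frozen=True)
class VoxelParams:
    """Kinetic state of one voxel.

    kw: water exchange rate, 1/min; cbf: cerebral blood flow, mL/100 g/min;
    att: arterial transit time, s; r1b: tissue relaxation rate, 1/s;
    m0: proton-density reference, arbitrary units.
    """

    kw: float
    cbf: float
    att: float
    r1b: float
    m0: float = 1.0

    def __post_init__(self) -> None:
        if self.kw < 0 or self.cbf < 0 or self.att < 0 or self.m0 < 0:
            raise ValueError("kw, cbf, att and m0 must be nonnegative")
        if not self.r1b > 0:
            raise ValueError(f"tissue relaxation rate must be positive, got {self.r1b}")


def default_protocol(
    constants: PhysicalConstants | None = None, b_crush: float = DEFAULT_B_CRUSH
) -> AcquisitionSpec:
    """The default 10-encode multi-PLD multi-b protocol.

    Five crushed encodes at b = 20 s/mm^2, PLD = 1.0, 1.5, 1.8, 2.0, 2.5 s
    (NEX = 3), followed by b = 0, 10, 20, 50, 100 s/mm^2 at PLD = 1.2 s
    (NEX = 1). Encodes with b >= ``b_crush`` are treated as crushed.
    """
    constants = constants or PhysicalConstants()
    encodes = [Encode(pld=p, b=20.0, nex=3, crush=20.0 >= b_crush) for p in (1.0, 1.5, 1.8, 2.0, 2.5)]
    encodes += [Encode(pld=1.2, b=b, nex=1, crush=b >= b_crush) for b in (0.0, 10.0, 20.0, 50.0, 100.0)]
    return AcquisitionSpec(constants=constants, encodes=tuple(encodes))


def alpha_beta(kw, r1a: float, r1b, warn: bool = True):
    """Compartment rates alpha = k + R1a (1/s) and extraction factor beta.

    ``kw`` is in 1/min and converted internally; ``beta = k / (k + R1a - R1b)``
    is evaluated by a small R1a perturbation where the denominator is
    degenerate (|k + R1a - R1b| < 1e-9).
    """
    kw = np.asarray(kw, dtype=float)
    r1b = np.asarray(r1b, dtype=float)
    k = kw / 60.0
    alpha = k + r1a
    denom = k + r1a - r1b
    degenerate = np.abs(denom) < _BETA_DEGENERACY_TOL
    if np.any(degenerate):
        if warn:
            warnings.warn(
                "beta denominator k_W/60 + R1a - R1b is degenerate; "
                "evaluating beta with R1a perturbed by 1e-6",
                stacklevel=2,
            )
        denom = np.where(degenerate, k + (r1a + _BETA_PERTURBATION) - r1b, denom)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(k == 0, 0.0, k / denom)
    if alpha.ndim == 0:
        return float(alpha), float(beta)
    return alpha, beta


def _compartments(kw, cbf, att, r1b, m0, c: PhysicalConstants, pld):
    """Vectorised tissue and capillary difference signals (broadcasting)."""
    kw, cbf, att, r1b, m0, pld = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (kw, cbf, att, r1b, m0, pld))
    )
    t = c.delta + pld
    alpha, beta = alpha_beta(kw, c.r1a, r1b)
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    k = kw / 60.0
    flow = cbf / 6000.0  # mL/g/s
    pref = 2.0 * flow * c.epsilon * m0 / c.lam
    decay_a = np.exp(-(c.r1a - r1b) * att)
    e_b = np.exp(-r1b * (t - c.delta)) - np.exp(-r1b * t)
    e_a = np.exp(-alpha * (t - c.delta)) - np.exp(-alpha * t)
    # e^{-(R1a - alpha) ATT} (e^{-alpha (t-delta)} - e^{-alpha t}) with the
    # exponents combined, so the k -> infinity limit underflows cleanly
    # instead of producing inf * 0; genuine overflow (enormous k_W with
    # ATT > PLD) saturates to inf, the mathematical limit
    with np.errstate(over="ignore"):
        term = (np.exp(k * att - alpha * (t - c.delta))
                - np.exp(k * att - alpha * t)) / alpha
    mb = pref * beta * (decay_a / r1b * e_b - term)
    mc = pref * decay_a / alpha * e_a
    return mb, mc


def delta_M_b(p: VoxelParams, c: PhysicalConstants, pld) -> float | np.ndarray:
    """Tissue-compartment difference signal at t = delta + PLD."""
    mb, _ = _compartments(p.kw, p.cbf, p.att, p.r1b, p.m0, c, pld)
    return mb if np.ndim(mb) else float(mb)


def delta_M_c(p: VoxelParams, c: PhysicalConstants, pld) -> float | np.ndarray:
    """Capillary-compartment difference signal at t = delta + PLD."""
    _, mc = _compartments(p.kw, p.cbf, p.att, p.r1b, p.m0, c, pld)
    return mc if np.ndim(mc) else float(mc)


def qpm_signal(p: VoxelParams, e: Encode, c: PhysicalConstants) -> float:
    """Signal of one encode: tissue plus, if uncrushed, capillary compartment."""
    mb, mc = _compartments(p.kw, p.cbf, p.att, p.r1b, p.m0, c, e.pld)
    return float(mb) if e.crush else float(mb + mc)


def forward_series(p: VoxelParams, spec: AcquisitionSpec) -> np.ndarray:
    """Noiseless signal vector over every encode of ``spec``, in order."""
    if not spec.encodes:
        raise ValueError("acquisition spec has no encodes")
    mb, mc = _compartments(p.kw, p.cbf, p.att, p.r1b, p.m0, spec.constants, spec.plds)
    return np.where(spec.crushed, mb, mb + mc)


def _signal_and_jac_batch(
    kw: np.ndarray,
    cbf: np.ndarray,
    att: np.ndarray,
    r1b: np.ndarray,
    m0: np.ndarray,
    spec: AcquisitionSpec,
):
    """Forward signals and analytic partials w.r.t. (kw, cbf, att).

    Returns ``f, df_dkw, df_dcbf, df_datt``, each of shape
    (n_voxels, n_encodes). Derivatives are chain-ruled through the
    compartment expressions; the kw derivative is taken per 1/min
    (internal rate k = kw/60 contributes the 1/60 factor).
    """
    c = spec.constants
    kw = np.reshape(np.asarray(kw, float), (-1, 1))
    cbf = np.reshape(np.asarray(cbf, float), (-1, 1))
    att = np.reshape(np.asarray(att, float), (-1, 1))
    r1b = np.reshape(np.asarray(r1b, float), (-1, 1))
    m0 = np.reshape(np.asarray(m0, float), (-1, 1))
    pld = spec.plds[None, :]
    uncrushed = (~spec.crushed)[None, :].astype(float)

    t = c.delta + pld
    k = kw / 60.0
    alpha = k + c.r1a
    denom = k + c.r1a - r1b
    degenerate = np.abs(denom) < _BETA_DEGENERACY_TOL
    denom = np.where(degenerate, k + (c.r1a + _BETA_PERTURBATION) - r1b, denom)
    beta = np.where(k == 0, 0.0, k / denom)
    dbeta_dk = (c.r1a - r1b) / denom**2
    # unit-flow prefactor: signal is linear in CBF
    pref_u = 2.0 * c.epsilon * m0 / (c.lam * 6000.0)
    pref = pref_u * cbf

    decay_a = np.exp(-(c.r1a - r1b) * att)
    e_b = np.exp(-r1b * (t - c.delta)) - np.exp(-r1b * t)
    e_a = np.exp(-alpha * (t - c.delta)) - np.exp(-alpha * t)
    de_a = -(t - c.delta) * np.exp(-alpha * (t - c.delta)) + t * np.exp(-alpha * t)
    # combined-exponent form of e^{k ATT} (e^{-alpha (t-delta)} - e^{-alpha t})
    e1 = np.exp(k * att - alpha * (t - c.delta))
    e2 = np.exp(k * att - alpha * t)
    term = (e1 - e2) / alpha

    bracket = decay_a / r1b * e_b - term
    cap = decay_a / alpha * e_a

    f_u = pref_u * (beta * bracket + uncrushed * cap)
    f = cbf * f_u

    dterm_dk = ((att - (t - c.delta)) * e1 - (att - t) * e2) / alpha - term / alpha
    dmb_dk = pref * (dbeta_dk * bracket - beta * dterm_dk)
    dmc_dk = pref * decay_a * (de_a / alpha - e_a / alpha**2)
    df_dkw = (dmb_dk + uncrushed * dmc_dk) / 60.0

    dmb_datt = pref * beta * (-(c.r1a - r1b) * decay_a / r1b * e_b - k * term)
    dmc_datt = -(c.r1a - r1b) * pref * cap
    df_datt = dmb_datt + uncrushed * dmc_datt

    return f, df_dkw, f_u, df_datt


def forward_series_batch(
    kw: np.ndarray,
    cbf: np.ndarray,
    att: np.ndarray,
    r1b: np.ndarray,
    m0: np.ndarray,
    spec: AcquisitionSpec,
) -> np.ndarray:
    """Forward model for many voxels at once: (n_voxels, n_encodes) array."""
    shp = (-1, 1)
    mb, mc = _compartments(
        np.reshape(kw, shp), np.reshape(cbf, shp), np.reshape(att, shp),
        np.reshape(r1b, shp), np.reshape(m0, shp), spec.constants,
        spec.plds[None, :],
    )
    return np.where(spec.crushed[None, :], mb, mb + mc)
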