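"""Physics-based synthetic force curves and thermal-noise records.

The retract trace is a superposition of

* single-bond loading ramps terminated by Bell-model ruptures.  A bond that
  engages at tip-sample separation ``s_j`` is loaded through the effective
  stiffness ``k_eff`` (cell and cantilever compliance in series), so the
  force ramps at rate ``r = k_eff * v`` and ruptures at a force drawn from
  the first-passage distribution of an escape rate ``k(F) = k0 *
  exp(F * x_beta / kBT)`` under the ramp;
* membrane-tether plateaus: a constant pulling force from engagement until
  an exponentially distributed detachment length, then an abrupt drop;
* Gaussian white deflection noise and a linear baseline drift.

Steps are instantaneous (single sample): a detector must not rely on
unobservable rise kinetics.  Every simulated curve comes with its
ground-truth event list so detection quality is measurable exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import thermal_energy
from .datamodel import CurveMetadata, ForceCurve, ForceMap, RuptureEvent
from .errors import DomainError, ValidationError

__all__ = [
    "BondModel",
    "TetherModel",
    "NoiseModel",
    "SimulationConfig",
    "sample_rupture_force",
    "bell_cdf",
    "bell_pdf",
    "bell_mode",
    "bell_median",
    "simulate_retract_curve",
    "simulate_force_map",
    "simulate_thermal_deflection",
]


@dataclass
class BondModel:
    """Generative parameters for receptor-bond ruptures.

    ``n_bonds`` is the Poisson mean of the number of bonds engaged per curve.
    ``k0`` (1/s) is the unstressed off-rate and ``x_beta`` (nm) the distance
    to the transition state of the escape path; together with the loading
    rate they set the rupture-force distribution.  ``k_eff`` (pN/nm) is the
    effective loading stiffness.  Bonds engage at separations drawn uniformly
    from ``[anchor_offset, anchor_offset + engagement_span]`` nm and rupture
    independently (each jump in a curve is one rupture event).
    """

    n_bonds: float = 3.0
    k0: float = 4.0
    x_beta: float = 0.1
    k_eff: float = 0.2
    anchor_offset: float = 100.0
    engagement_span: float = 400.0

    def validate(self, spring_constant_k: float | None = None) -> None:
        if not self.k0 > 0:
            raise ValidationError("k0 must be > 0")
        if not self.x_beta > 0:
            raise ValidationError("x_beta must be > 0")
        if not self.k_eff > 0:
            raise ValidationError("k_eff must be > 0")
        if spring_constant_k is not None and self.k_eff > spring_constant_k:
            raise ValidationError("k_eff cannot exceed the cantilever spring constant")


@dataclass
class TetherModel:
    """Membrane-tether plateaus: constant force, exponential detach length."""

    n_tethers: float = 1.0
    plateau_force: float = 30.0
    detach_length_scale: float = 1000.0
    engagement_span: float = 200.0

    def validate(self) -> None:
        if not self.plateau_force > 0:
            raise ValidationError("plateau_force must be > 0")
        if not self.detach_length_scale > 0:
            raise ValidationError("detach_length_scale must be > 0")


@dataclass
class NoiseModel:
    """White Gaussian deflection noise (nm) plus a linear baseline drift
    (pN of force per nm of piezo travel)."""

    deflection_sd: float = 0.05
    drift_slope: float = 0.002

    def validate(self) -> None:
        if self.deflection_sd < 0:
            raise ValidationError("deflection_sd must be >= 0")


@dataclass
class SimulationConfig:
    """Everything needed to generate one curve reproducibly.

    ``retract_length_nm`` is the piezo travel of the retract segment;
    ``contact_slope`` is the deflection picked up per nm of piezo travel
    while in contact (a soft cell under a stiff cantilever).  ``kBT`` is
    derived from the metadata temperature unless given explicitly.
    """

    metadata: CurveMetadata = field(default_factory=CurveMetadata)
    bond: BondModel = field(default_factory=BondModel)
    tether: TetherModel = field(default_factory=TetherModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    kBT: float | None = None
    retract_length_nm: float = 10000.0
    contact_slope: float = 0.5

    def thermal_energy(self) -> float:
        return self.kBT if self.kBT is not None else thermal_energy(self.metadata.temperature)

    def validate(self) -> None:
        self.metadata.validate()
        self.bond.validate(self.metadata.spring_constant_k)
        self.tether.validate()
        self.noise.validate()
        if not 0 < self.contact_slope <= 1:
            raise ValidationError("contact_slope must be in (0, 1]")


# ---------------------------------------------------------------------------
# Bell-model rupture forces under ramp loading
# ---------------------------------------------------------------------------

def sample_rupture_force(bond: BondModel, r: float, u, kBT: float) -> np.ndarray | float:
    """Inverse-CDF draw of the rupture force under a force ramp F(t) = r*t.

    With escape rate ``k(F) = k0 * exp(F * x_beta / kBT)`` the survival
    probability is ``S(F) = exp(-(k0*kBT/(x_beta*r)) * (exp(F*x_beta/kBT)-1))``
    and inverting ``S(F) = u`` for uniform ``u`` gives

        F = (kBT/x_beta) * ln(1 - (x_beta*r/(k0*kBT)) * ln u)

    which is > 0 for u in (0, 1) and tends to 0+ as u -> 1-.
    """
    if not r > 0:
        raise DomainError("loading rate r must be > 0")
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0) or np.any(u >= 1):
        raise DomainError("u must lie strictly inside (0, 1)")
    a = bond.x_beta / kBT
    out = np.log1p(-(a * r / bond.k0) * np.log(u)) / a
    return float(out) if out.ndim == 0 else out


def bell_cdf(f, bond: BondModel, r: float, kBT: float) -> np.ndarray:
    """Analytic rupture-force CDF under ramp loading at rate ``r`` (pN/s)."""
    if not r > 0:
        raise DomainError("loading rate r must be > 0")
    f = np.asarray(f, dtype=float)
    a = bond.x_beta / kBT
    beta = bond.k0 / (a * r)
    return np.where(f <= 0, 0.0, 1.0 - np.exp(-beta * np.expm1(a * np.maximum(f, 0.0))))


def bell_pdf(f, bond: BondModel, r: float, kBT: float) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    a = bond.x_beta / kBT
    beta = bond.k0 / (a * r)
    fpos = np.maximum(f, 0.0)
    dens = beta * a * np.exp(a * fpos) * np.exp(-beta * np.expm1(a * fpos))
    return np.where(f <= 0, 0.0, dens)


def bell_mode(bond: BondModel, r: float, kBT: float) -> float:
    """Most probable rupture force, (kBT/x_beta) * ln(r*x_beta/(k0*kBT)).

    Valid in the activated regime ``r*x_beta > k0*kBT`` (otherwise the
    density is monotone decreasing and the mode is 0)."""
    a = bond.x_beta / kBT
    arg = a * r / bond.k0
    return max(0.0, np.log(arg) / a)


def bell_median(bond: BondModel, r: float, kBT: float) -> float:
    """Median rupture force (inverse CDF at 1/2)."""
    a = bond.x_beta / kBT
    return float(np.log1p(a * r / bond.k0 * np.log(2.0)) / a)


# ---------------------------------------------------------------------------
# Retract-curve synthesis
# ---------------------------------------------------------------------------

def _child_rng(seed: int, map_id: str, curve_index: int) -> np.random.Generator:
    """Stable per-curve stream: hash of (seed, map_id, curve_index)."""
    key = zlib.crc32(map_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key, int(curve_index)]))


def simulate_retract_curve(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ForceCurve, list[RuptureEvent]]:
    """Generate one approach/dwell/retract cycle plus its ground truth.

    The approach is a linear contact ramp to the maximum load, the dwell is
    constant at maximum load, and the retract unloads through the contact
    region and then plays out bond ramps and tether plateaus on the
    separation axis.  Ground-truth events carry the true rupture force and
    class; their ``index`` is relative to the retract segment and points at
    the first post-step sample.
    """
    config.validate()
    meta = config.metadata
    if rng is None:
        rng = _child_rng(config.seed, "single", 0)
    kBT = config.thermal_energy()
    k = meta.spring_constant_k
    fs = meta.sampling_rate
    v_nm = meta.velocity_v * 1000.0  # nm/s
    dx = v_nm / fs  # nm of piezo travel per sample

    d0 = meta.max_load / k  # deflection at max load, nm
    unload_travel = d0 / config.contact_slope  # piezo travel to zero force
    # piezo travel at which the retract force crosses zero = true contact
    x0 = unload_travel

    n_ret = int(round(config.retract_length_nm / dx)) + 1
    x = np.arange(n_ret) * dx  # piezo travel since retract start
    s = x - x0  # nominal tip-sample separation (nm), <0 while in contact

    deflection = np.maximum(0.0, d0 - config.contact_slope * x)

    truth: list[RuptureEvent] = []

    def event_index(sep: float) -> int:
        # first sample at separation >= sep
        return int(np.ceil((sep + x0) / dx - 1e-9))

    # --- bonds: loaded ramps ending in Bell ruptures -----------------------
    n_b = rng.poisson(config.bond.n_bonds)
    r = config.bond.k_eff * v_nm  # loading rate, pN/s
    if n_b > 0:
        engage = config.bond.anchor_offset + config.bond.engagement_span * rng.random(n_b)
        u = rng.random(n_b)
        u = np.clip(u, 1e-300, 1 - 1e-16)
        forces = np.atleast_1d(sample_rupture_force(config.bond, r, u, kBT))
        for s_j, F_j in zip(engage, forces):
            s_rupt = s_j + F_j / config.bond.k_eff
            idx = event_index(s_rupt)
            if idx >= n_ret - 1:
                # bond survives to the end of the record: ramp, no rupture
                deflection -= np.where(s >= s_j, config.bond.k_eff * (s - s_j) / k, 0.0)
                continue
            ramp = np.where((s >= s_j) & (np.arange(n_ret) < idx), config.bond.k_eff * (s - s_j) / k, 0.0)
            deflection -= ramp
            truth.append(
                RuptureEvent(
                    curve_id=meta.curve_id,
                    index=idx,
                    separation_nm=float(s[idx]),
                    step_height_d=float(F_j / k),
                    force_F=float(F_j),
                    event_class="jump",
                    loading_rate_r=float(r),
                    pre_slope=float(config.bond.k_eff),
                )
            )

    # --- tethers: constant-force plateaus with exponential detach ----------
    n_t = rng.poisson(config.tether.n_tethers)
    if n_t > 0:
        engage_t = config.tether.engagement_span * rng.random(n_t)
        detach = engage_t + rng.exponential(config.tether.detach_length_scale, n_t)
        for s_j, s_d in zip(engage_t, detach):
            idx = event_index(s_d)
            if idx >= n_ret - 1:
                deflection -= np.where(s >= s_j, config.tether.plateau_force / k, 0.0)
                continue
            plateau = np.where((s >= s_j) & (np.arange(n_ret) < idx), config.tether.plateau_force / k, 0.0)
            deflection -= plateau
            truth.append(
                RuptureEvent(
                    curve_id=meta.curve_id,
                    index=idx,
                    separation_nm=float(s[idx]),
                    step_height_d=float(config.tether.plateau_force / k),
                    force_F=float(config.tether.plateau_force),
                    event_class="tether",
                    loading_rate_r=0.0,
                    pre_slope=0.0,
                )
            )

    # --- drift and noise ---------------------------------------------------
    if config.noise.drift_slope:
        deflection += (config.noise.drift_slope / k) * x

    truth.sort(key=lambda e: e.index)

    # --- assemble approach / dwell / retract -------------------------------
    approach_travel = 2.0 * unload_travel
    n_app = max(2, int(round(approach_travel / dx)))
    x_app = np.arange(n_app) * dx
    z_app = config.retract_length_nm - approach_travel + x_app
    d_app = np.maximum(0.0, config.contact_slope * (x_app - unload_travel))

    n_dwell = int(round(meta.dwell_time * fs))
    z_dwell = np.full(n_dwell, config.retract_length_nm)
    d_dwell = np.full(n_dwell, d0)

    z_ret = config.retract_length_nm - x

    z_all = np.concatenate([z_app, z_dwell, z_ret])
    d_all = np.concatenate([d_app, d_dwell, deflection])
    labels = np.concatenate(
        [
            np.repeat("approach", n_app),
            np.repeat("dwell", n_dwell),
            np.repeat("retract", n_ret),
        ]
    ).astype(object)
    if config.noise.deflection_sd > 0:
        d_all = d_all + rng.normal(0.0, config.noise.deflection_sd, d_all.size)
    time = np.arange(d_all.size) / fs

    curve = ForceCurve(time=time, z_position=z_all, deflection=d_all, segment_labels=labels, metadata=meta)
    curve.validate()
    return curve, truth


def simulate_force_map(
    config: SimulationConfig,
    n_curves: int = 24,
    map_id: str = "map0",
) -> tuple[ForceMap, list[RuptureEvent]]:
    """Simulate a force map of independent curves with a deterministic
    per-curve seed tree: curve ``i`` can be regenerated alone and is
    identical to curve ``i`` of the full map."""
    curves: list[ForceCurve] = []
    truth: list[RuptureEvent] = []
    for i in range(n_curves):
        meta_i = replace(config.metadata, curve_id=f"{map_id}_c{i}")
        cfg_i = replace(config, metadata=meta_i)
        rng = _child_rng(config.seed, map_id, i)
        curve, events = simulate_retract_curve(cfg_i, rng=rng)
        curves.append(curve)
        truth.extend(events)
    fmap = ForceMap(curves=curves, map_id=map_id)
    fmap.validate()
    return fmap, truth


# ---------------------------------------------------------------------------
# Thermal deflection noise (calibration input)
# ---------------------------------------------------------------------------

def simulate_thermal_deflection(
    k: float,
    kBT: float | None = None,
    f0: float = 2000.0,
    Q: float = 2.0,
    fs: float = 20000.0,
    duration: float = 1.0,
    seed: int = 0,
    floor_fraction: float = 0.0,
) -> np.ndarray:
    """Stationary Gaussian deflection series with a simple-harmonic-oscillator
    spectrum and total expected variance kBT/k (equipartition).

    ``floor_fraction`` adds a white spectral floor carrying that fraction of
    the total variance (optical readout noise).  Synthesised in the frequency
    domain: independent complex-Gaussian coefficients shaped by the SHO line,
    normalised so the expected sample variance is exactly kBT/k.
    """
    if kBT is None:
        kBT = thermal_energy()
    for name, val in (("k", k), ("f0", f0), ("Q", Q), ("fs", fs), ("duration", duration)):
        if not val > 0:
            raise DomainError(f"{name} must be > 0")
    if fs <= 2 * f0:
        raise DomainError("sampling rate must exceed twice the resonance frequency")
    n = int(round(fs * duration))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = f0**4 / ((freqs**2 - f0**2) ** 2 + (freqs * f0 / Q) ** 2)
    shape[0] = 0.0
    if floor_fraction > 0:
        sho_total = shape.sum()
        white = np.ones_like(shape)
        white[0] = 0.0
        shape = (1 - floor_fraction) * shape + floor_fraction * sho_total / white.sum() * white

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7E41]))
    coeff = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)) * np.sqrt(shape / 2.0)
    coeff[0] = 0.0
    if n % 2 == 0:
        coeff[-1] = coeff[-1].real * np.sqrt(2.0)
    # normalise expected variance of irfft output to kBT/k
    weights = np.full(freqs.size, 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0
    expected = (weights * (np.abs(shape) / 1.0)).sum() / n**2  # E|coeff|^2 = shape
    scale = np.sqrt((kBT / k) / expected)
    x = np.fft.irfft(coeff * scale, n=n)
    return x
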