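"""Physics-grounded synthetic FMCW beat-signal generator.

The radar illuminates a thin container of glucose solution backed by a
metal plate.  The received echo is modelled as the superposition of

* the s-polarised Fresnel reflection off the front air/solution interface,
  whose magnitude grows with the solution permittivity, and
* the wave transmitted into the solution, reflected by the metal back
  plate, and attenuated on the two-way path through the lossy dielectric.

Because the real permittivity of the solution increases with glucose
concentration while its loss tangent decreases, both terms grow with
concentration and the echo amplitude — hence the spectral energy of the
beat signal — is monotone increasing in concentration over the validity
range of the dielectric law.

The dechirped (beat) signal of an FMCW radar observing a static target is a
single low-frequency complex tone; the simulator emits that tone scaled by
the modelled echo amplitude, corrupted by high-frequency thermal noise and
by a per-power-cycle gain/offset drift that emulates the change in radar
working status after a power cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.constants import epsilon_0, mu_0

from glucowave.config import DielectricLaw, SimulationConfig


@dataclass(frozen=True)
class MediumProperties:
    """Electromagnetic constants of one medium at the carrier frequency.

    ``eps_real`` and ``eps_imag`` are relative (dimensionless) parts of the
    complex permittivity; ``sigma`` is the equivalent conductivity in S/m;
    ``mu`` is the relative permeability; ``loss_tangent`` is
    ``|eps_imag| / eps_real``.
    """

    eps_real: float
    eps_imag: float
    sigma: float
    mu: float = 1.0
    loss_tangent: float = 0.0

    def __post_init__(self) -> None:
        if self.eps_real <= 0:
            raise ValueError(f"eps_real must be positive, got {self.eps_real}")
        if self.loss_tangent < 0:
            raise ValueError("loss_tangent must be non-negative")
        expected = abs(self.eps_imag) / self.eps_real
        if abs(self.loss_tangent - expected) > 1e-12 * max(1.0, expected):
            raise ValueError(
                "loss_tangent inconsistent with eps_imag/eps_real: "
                f"{self.loss_tangent} vs {expected}"
            )

    @classmethod
    def from_loss_tangent(
        cls, eps_real: float, loss_tangent: float, omega: float, mu: float = 1.0
    ) -> "MediumProperties":
        """Build from (eps', tan delta) at angular frequency ``omega``."""
        eps_imag = loss_tangent * eps_real
        sigma = eps_imag * epsilon_0 * omega
        return cls(
            eps_real=eps_real,
            eps_imag=eps_imag,
            sigma=sigma,
            mu=mu,
            loss_tangent=loss_tangent,
        )


#: Free space / air, lossless with unit permittivity.
VACUUM = MediumProperties(eps_real=1.0, eps_imag=0.0, sigma=0.0)


@dataclass(frozen=True)
class SceneGeometry:
    """Geometry of the bench: incidence angle, solution path, back plate."""

    incidence_angle: float = 0.0  # radians
    solution_thickness: float = 0.006  # metres, one-way
    backplate_reflectivity: float = 0.9
    carrier_freq: float = 77e9  # Hz

    def __post_init__(self) -> None:
        if not 0 <= self.incidence_angle < math.pi / 2:
            raise ValueError("incidence angle must lie in [0, pi/2)")
        if self.solution_thickness <= 0:
            raise ValueError("solution thickness must be positive")
        if not 0 <= self.backplate_reflectivity <= 1:
            raise ValueError("backplate reflectivity must lie in [0, 1]")

    @property
    def omega(self) -> float:
        return 2 * math.pi * self.carrier_freq


@dataclass
class BeatSignal:
    """One complex beat-signal record with its acquisition metadata."""

    samples: np.ndarray
    antenna_id: int
    concentration: float
    power_cycle_id: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.complex128)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def concentration_to_medium(
    c: float, law: DielectricLaw | None = None, omega: float = 2 * math.pi * 77e9
) -> MediumProperties:
    """Map a glucose concentration to the solution's dielectric constants.

    The default affine law makes the real permittivity strictly increasing
    and the loss tangent strictly decreasing in concentration, matching the
    measured trend of aqueous glucose in the millimetre-wave band.

    Parameters
    ----------
    c : float
        Concentration in mg/mL; must lie in ``law.valid_range``.
    law : DielectricLaw, optional
        Coefficients of the affine law; defaults to the bench assumptions.
    omega : float
        Angular carrier frequency, used to convert the loss tangent into an
        equivalent conductivity.
    """
    law = law or DielectricLaw()
    lo, hi = law.valid_range
    if not lo <= c <= hi:
        raise ValueError(f"concentration {c} outside validity range [{lo}, {hi}]")
    return MediumProperties.from_loss_tangent(
        eps_real=law.eps_real(c), loss_tangent=law.loss_tangent(c), omega=omega
    )


def snell_angle(theta_i: float, eps1: float, eps2: float) -> float:
    """Refraction angle from the permittivity ratio of the two media.

    For non-magnetic media the ratio of sines equals ``sqrt(eps2/eps1)``,
    so ``sin(theta_t) = sin(theta_i) * sqrt(eps1/eps2)``.

    Raises
    ------
    ValueError
        If either permittivity is non-positive or the configuration is in
        total internal reflection.
    """
    if eps1 <= 0 or eps2 <= 0:
        raise ValueError("permittivities must be positive")
    s = math.sin(theta_i) * math.sqrt(eps1 / eps2)
    if s > 1.0:
        raise ValueError(
            f"total internal reflection: sin(theta_t) = {s:.4f} > 1"
        )
    return math.asin(s)


def reflection_coeff_s(
    theta_i: float,
    theta_t: float,
    m1: MediumProperties = VACUUM,
    m2: MediumProperties | None = None,
) -> float:
    """Magnitude of the s-polarised Fresnel reflection coefficient.

    Evaluated in the refractive-index form

        |r_s| = |n1 cos(theta_i) - n2 cos(theta_t)|
                / (n1 cos(theta_i) + n2 cos(theta_t)),   n = sqrt(eps * mu)

    which equals the sine form |sin(theta_i - theta_t) / sin(theta_i +
    theta_t)| at oblique incidence and remains regular at normal incidence,
    where the sine form degenerates to 0/0.
    """
    if m2 is None:
        raise ValueError("the transmission medium m2 is required")
    n1 = math.sqrt(m1.eps_real * m1.mu)
    n2 = math.sqrt(m2.eps_real * m2.mu)
    num = n1 * math.cos(theta_i) - n2 * math.cos(theta_t)
    den = n1 * math.cos(theta_i) + n2 * math.cos(theta_t)
    if den == 0:
        raise ZeroDivisionError("degenerate interface: zero impedance sum")
    return abs(num) / den


def propagation_constants(m: MediumProperties, omega: float) -> tuple[float, float]:
    """Attenuation and phase constants (alpha, beta) in a lossy dielectric.

    Standard lossy-medium expressions with loss ratio ``q = sigma /
    (omega * eps)``::

        beta  = omega * sqrt(mu*eps/2) * sqrt(sqrt(1 + q^2) + 1)
        alpha = omega * sqrt(mu*eps/2) * sqrt(sqrt(1 + q^2) - 1)

    so that ``beta^2 - alpha^2 = omega^2 * mu * eps`` identically and
    ``alpha = 0`` for a lossless medium.

    Returns
    -------
    (alpha, beta) : tuple of float
        Nepers/m and rad/m.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    eps = m.eps_real * epsilon_0
    mu = m.mu * mu_0
    q = m.sigma / (omega * eps)
    root = math.sqrt(1.0 + q * q)
    common = omega * math.sqrt(mu * eps / 2.0)
    beta = common * math.sqrt(root + 1.0)
    alpha = common * math.sqrt(max(root - 1.0, 0.0))
    return alpha, beta


def attenuated_field(
    E0: float, alpha: float, beta: float, r: float, omega: float = 0.0, t: float = 0.0
) -> complex:
    """Field after propagating a distance ``r`` through a lossy medium.

    ``E(r, t) = E0 * exp(-alpha r) * exp(i (omega t - beta r))``.
    """
    if r < 0:
        raise ValueError("propagation distance must be non-negative")
    return E0 * math.exp(-alpha * r) * complex(
        math.cos(omega * t - beta * r), math.sin(omega * t - beta * r)
    )


def echo_amplitude(
    c: float,
    geom: SceneGeometry | None = None,
    law: DielectricLaw | None = None,
) -> complex:
    """Complex echo amplitude of the two-path reflection model.

    ``echo = r_front + (1 - r_front^2) * R_b * exp(-alpha * L) *
    exp(-i beta * L)`` with ``L`` the two-way path through the solution.
    The ``(1 - r_front^2)`` factor accounts for the power transmitted into
    and back out of the solution; ``R_b`` is the back-plate reflectivity.

    Under the default dielectric law the magnitude is strictly increasing
    in concentration over the validity range: the front reflection grows
    with the permittivity and the back-plate return grows as the loss
    tangent falls.
    """
    geom = geom or SceneGeometry()
    law = law or DielectricLaw()
    medium = concentration_to_medium(c, law, omega=geom.omega)
    theta_t = snell_angle(geom.incidence_angle, VACUUM.eps_real, medium.eps_real)
    r_front = reflection_coeff_s(geom.incidence_angle, theta_t, VACUUM, medium)
    alpha, beta = propagation_constants(medium, geom.omega)
    # two-way path along the refracted ray
    path = 2.0 * geom.solution_thickness / math.cos(theta_t)
    back = (
        (1.0 - r_front**2)
        * geom.backplate_reflectivity
        * attenuated_field(1.0, alpha, beta, path)
    )
    return r_front + back


def _drift_factors(
    cfg: SimulationConfig, power_cycle_id: int, enabled: bool = True
) -> tuple[float, complex]:
    """Gain and complex DC offset of one power-on session.

    Both are drawn once per (master seed, power cycle id) pair, so every
    record tagged with the same session sees the same radar working status.
    """
    if not enabled or (cfg.drift_gain_sigma == 0 and cfg.drift_offset_sigma == 0):
        return 1.0, 0.0 + 0.0j
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=[int(cfg.seed), 7919, int(power_cycle_id)])
    )
    gain = float(rng.lognormal(mean=0.0, sigma=cfg.drift_gain_sigma))
    scale = cfg.drift_offset_sigma / math.sqrt(2.0)
    offset = complex(rng.normal(0.0, scale), rng.normal(0.0, scale))
    return gain, offset


def _highpass_noise(
    rng: np.random.Generator, n: int, noise_power: float
) -> np.ndarray:
    """Complex Gaussian noise band-limited to the upper half of the band.

    Thermal noise in the acquisition chain sits above the beat tone; it is
    synthesised white and then restricted to digital frequencies with
    ``|f| >= fs/4`` (FFT bins N/4 .. 3N/4), rescaled so that its expected
    per-sample power equals ``noise_power``.
    """
    white = (rng.standard_normal(n) + 1j * rng.standard_normal(n)) / math.sqrt(2.0)
    spec = np.fft.fft(white)
    mask = np.zeros(n)
    lo, hi = n // 4, (3 * n) // 4
    mask[lo : hi + 1] = 1.0
    kept = mask.sum() / n
    filtered = np.fft.ifft(spec * mask)
    return filtered * math.sqrt(noise_power / kept)


def synthesize_beat_signal(
    c: float,
    cfg: SimulationConfig | None = None,
    antenna_id: int = 1,
    power_cycle_id: int = 0,
    seed: int | np.random.SeedSequence = 0,
    noise: bool = True,
    drift: bool = True,
) -> BeatSignal:
    """Generate one seeded beat-signal record at concentration ``c``.

    The record is a length-N complex tone at the configured beat frequency
    whose amplitude is the physical echo amplitude for ``c``, scaled by the
    antenna gain and the session's drift gain, shifted by the session's DC
    offset, and corrupted by high-frequency thermal noise at the configured
    SNR.  Identical ``(c, seed, antenna_id, power_cycle_id)`` inputs yield
    bitwise-identical records.
    """
    cfg = cfg or SimulationConfig()
    if cfg.n_samples < 8:
        raise ValueError("record length must be at least 8 samples")
    if not 1 <= antenna_id <= len(cfg.antenna_gains):
        raise ValueError(f"antenna_id must be in 1..{len(cfg.antenna_gains)}")
    snr_lin = 10.0 ** (cfg.snr_db / 10.0)
    if snr_lin <= 0:
        raise ValueError("SNR must be positive in linear units")

    geom = SceneGeometry(
        incidence_angle=cfg.incidence_angle_rad,
        solution_thickness=cfg.thickness_m,
        backplate_reflectivity=cfg.backplate_reflectivity,
        carrier_freq=cfg.carrier_hz,
    )
    amp = echo_amplitude(c, geom, cfg.dielectric) * cfg.antenna_gains[antenna_id - 1]
    gain, offset = _drift_factors(cfg, power_cycle_id, enabled=drift)

    n = cfg.n_samples
    phase = 2.0 * math.pi * cfg.beat_freq_bins * np.arange(n) / n
    tone = gain * amp * np.exp(1j * phase) + gain * offset

    if noise:
        if isinstance(seed, np.random.SeedSequence):
            rng = np.random.default_rng(seed)
        else:
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=[int(seed), int(power_cycle_id)])
            )
        noise_power = (abs(amp) * gain) ** 2 / snr_lin
        tone = tone + _highpass_noise(rng, n, noise_power)

    return BeatSignal(
        samples=tone,
        antenna_id=antenna_id,
        concentration=c,
        power_cycle_id=power_cycle_id,
    )


def generate_dataset(
    cfg: SimulationConfig | None = None,
    seed: int | None = None,
    noise: bool = True,
    drift: bool = True,
) -> list[BeatSignal]:
    """Generate the full labelled dataset of beat-signal records.

    For each configured concentration, ``records_per_class`` records are
    produced.  Each record is assigned a transmit antenna (cycling over the
    three Tx channels) and a random power-on session out of
    ``n_power_cycles``, so the dataset interleaves working statuses the way
    a multi-session acquisition campaign does.
    """
    cfg = cfg or SimulationConfig()
    master = cfg.seed if seed is None else seed
    cfg_seeded = cfg if seed is None else _with_seed(cfg, seed)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=[int(master), 104729]))
    records: list[BeatSignal] = []
    for ci, c in enumerate(cfg.concentrations):
        for rep in range(cfg.records_per_class):
            cycle = int(rng.integers(cfg.n_power_cycles)) if drift else 0
            antenna = 1 + (rep % len(cfg.antenna_gains))
            record_seed = np.random.SeedSequence(
                entropy=[int(master), ci, rep, antenna]
            )
            records.append(
                synthesize_beat_signal(
                    c,
                    cfg_seeded,
                    antenna_id=antenna,
                    power_cycle_id=cycle,
                    seed=record_seed,
                    noise=noise,
                    drift=drift,
                )
            )
    return records


def _with_seed(cfg: SimulationConfig, seed: int) -> SimulationConfig:
    import dataclasses

    return dataclasses.replace(cfg, seed=int(seed))
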