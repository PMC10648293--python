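"""Synthetic SSEP session generator with a known dose-response structure.

The generator produces complete patient sessions — stimulation-locked trial
waveforms for four monitored nerves (left/right ulnar, left/right posterior
tibial) times three recording montages each, plus a per-minute end-tidal
sevoflurane concentration series — with a controllable, closed-form effect of
concentration on the waveforms:

* each evoked component is a Gaussian bump ``polarity * A0 * exp(-k_A*c) *
  exp(-(t - (L0 + k_L*c))^2 / (2*width^2))``, so amplitude attenuates
  multiplicatively-exponentially and latency shifts linearly with the
  concentration ``c`` (in vol%), matching the known direction of the
  sevoflurane dose effect (amplitude down, latency up);
* cortical ulnar channels carry N20+P30, the subcortical CS5-Fpz ulnar
  channel carries N13+P14, tibial channels carry P37+N45;
* additive noise is white Gaussian plus a spectrally shaped 1/f term.

All randomness descends from ``GeneratorConfig.seed`` through named
``numpy`` SeedSequence spawns, so identical configurations produce
bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .demographics import REFERENCE_COHORT
from .session import (
    NERVE_MONTAGES,
    AnesthesiaSeries,
    PatientSession,
    SSEPTrial,
    channel_class,
)


@dataclass(frozen=True)
class ComponentTemplate:
    """One evoked component: a polarity-signed Gaussian bump.

    ``base_latency`` (ms) and ``base_amplitude`` (uV) are the zero-concentration
    values; ``width`` is the Gaussian sigma in ms.
    """

    name: str
    polarity: int  # +1 positive (P*), -1 negative (N*)
    base_latency: float
    base_amplitude: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"{self.name}: width must be positive")
        if self.base_amplitude <= 0:
            raise ValueError(f"{self.name}: base_amplitude must be positive")
        expected = -1 if self.name.startswith("N") else +1
        if self.polarity != expected:
            raise ValueError(f"{self.name}: polarity {self.polarity} contradicts the component letter")


#: Default component templates. Nominal latencies follow the standard
#: component nomenclature (N20 = negative deflection at 20 ms, etc.).
#: Amplitudes and widths are desk-scale choices in the physiologic range;
#: widths are kept narrow enough that neighbouring components do not pull
#: each other's detected extremum off its nominal latency.
DEFAULT_COMPONENTS: dict[str, ComponentTemplate] = {
    "N20": ComponentTemplate("N20", -1, 20.0, 2.0, 2.5),
    "P30": ComponentTemplate("P30", +1, 30.0, 1.2, 3.0),
    "N13": ComponentTemplate("N13", -1, 13.0, 0.8, 1.5),
    "P14": ComponentTemplate("P14", +1, 14.0, 0.6, 1.5),
    "P37": ComponentTemplate("P37", +1, 37.0, 1.5, 2.5),
    "N45": ComponentTemplate("N45", -1, 45.0, 1.0, 2.5),
}

#: Components carried by each channel class.
CLASS_COMPONENTS: dict[str, tuple[str, str]] = {
    "cortical_ulnar": ("N20", "P30"),
    "subcortical_ulnar": ("N13", "P14"),
    "tibial": ("P37", "N45"),
}


@dataclass(frozen=True)
class ConcentrationProfile:
    """Phase parameters of the intraoperative sevoflurane profile.

    The profile is piecewise: a linear induction ramp from 0 to
    ``maintenance_mean`` over ``induction_minutes``, an AR(1)-fluctuating
    maintenance plateau (stationary SD ``maintenance_sd``, lag-1 correlation
    ``ar_rho``), and an exponential emergence decay at ``decay_per_min``
    over the final ``emergence_minutes``.
    """

    induction_minutes: float = 10.0
    maintenance_mean: float = 2.0
    maintenance_sd: float = 0.25
    emergence_minutes: float = 15.0
    decay_per_min: float = 0.25
    ar_rho: float = 0.9


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of a synthetic cohort."""

    n_patients: int = 10
    trials_per_nerve: int = 30
    sample_rate: float = 5000.0  # Hz
    window_ms: float = 100.0  # post-stimulus window, all nerves
    noise_sd: float = 0.01  # uV, white component
    pink_noise_sd: float = 0.01  # uV, 1/f component
    amp_atten_k: float = 0.3  # per vol%, amplitude attenuation k_A
    lat_shift_k: float = 1.0  # ms per vol%, latency prolongation k_L
    seed: int = 0
    session_minutes: float = 120.0
    concentration_profile: ConcentrationProfile = field(default_factory=ConcentrationProfile)
    components: dict[str, ComponentTemplate] = field(default_factory=lambda: dict(DEFAULT_COMPONENTS))

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.window_ms < 100.0:
            # the latest named component (N45) plus its search window must fit
            raise ValueError("window_ms must be >= 100 ms to contain all named components")
        if self.amp_atten_k < 0 or self.lat_shift_k < 0:
            raise ValueError("dose-effect coefficients must be non-negative")
        if self.noise_sd < 0 or self.pink_noise_sd < 0:
            raise ValueError("noise levels must be non-negative")

    def noiseless(self) -> "GeneratorConfig":
        """Copy of this config with both noise terms switched off."""
        return replace(self, noise_sd=0.0, pink_noise_sd=0.0)


def generate_concentration_profile(
    cfg: GeneratorConfig, patient_seed: int
) -> AnesthesiaSeries:
    """Per-minute end-tidal sevoflurane series for one patient.

    One reading per minute over ``cfg.session_minutes``; induction ramp,
    fluctuating maintenance plateau, exponential emergence decay; all values
    clipped at zero. Deterministic in ``(cfg.seed, patient_seed)``.
    """
    if cfg.session_minutes < 10:
        raise ValueError("session_minutes must be >= 10")
    prof = cfg.concentration_profile
    rng = np.random.default_rng([cfg.seed, int(patient_seed)])
    n = int(round(cfg.session_minutes))
    minutes = np.arange(n, dtype=float)
    c = np.full(n, prof.maintenance_mean)

    # AR(1) maintenance fluctuation with stationary SD = maintenance_sd
    if prof.maintenance_sd > 0:
        innov_sd = prof.maintenance_sd * np.sqrt(1.0 - prof.ar_rho**2)
        e = np.empty(n)
        e[0] = rng.normal(0.0, prof.maintenance_sd)
        for i in range(1, n):
            e[i] = prof.ar_rho * e[i - 1] + rng.normal(0.0, innov_sd)
        c = c + e

    if prof.induction_minutes > 0:
        ramp = np.clip(minutes / prof.induction_minutes, 0.0, 1.0)
        c = c * ramp
    if prof.emergence_minutes > 0:
        t_emerg = cfg.session_minutes - prof.emergence_minutes
        tail = minutes >= t_emerg
        c[tail] = c[tail] * np.exp(-prof.decay_per_min * (minutes[tail] - t_emerg))

    return AnesthesiaSeries(timestamps=minutes * 60.0, et_sevo=np.clip(c, 0.0, None))


def _pink_noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-shaped Gaussian noise with the requested standard deviation."""
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(spec * scale, n)
    return sd * shaped / shaped.std()


def synthesize_trial(
    nerve: str,
    montage: str,
    concentration: float,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    *,
    trial_id: str = "trial",
    timestamp: float = 0.0,
) -> SSEPTrial:
    """One trial waveform at a given end-tidal concentration.

    The waveform is the sum of the channel's component bumps, each with
    amplitude ``A0 * exp(-k_A * c)`` and center latency ``L0 + k_L * c``,
    plus white and 1/f noise.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    cls = channel_class(nerve, montage)  # raises SchemaError on bad pairing
    n = int(round(cfg.sample_rate * cfg.window_ms / 1000.0))
    t = np.arange(n) * 1000.0 / cfg.sample_rate  # ms post-stimulus
    wave = np.zeros(n)
    for comp_name in CLASS_COMPONENTS[cls]:
        comp = cfg.components[comp_name]
        amp = comp.base_amplitude * np.exp(-cfg.amp_atten_k * concentration)
        lat = comp.base_latency + cfg.lat_shift_k * concentration
        wave += comp.polarity * amp * np.exp(-((t - lat) ** 2) / (2.0 * comp.width**2))
    if cfg.noise_sd > 0:
        wave = wave + rng.normal(0.0, cfg.noise_sd, n)
    if cfg.pink_noise_sd > 0:
        wave = wave + _pink_noise(n, cfg.pink_noise_sd, rng)
    return SSEPTrial(
        trial_id=trial_id,
        nerve=nerve,
        montage=montage,
        timestamp=timestamp,
        samples=wave,
        sample_rate=cfg.sample_rate,
    )


def _trial_times(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Stimulation-event times (s): an even grid over the session with jitter."""
    n = cfg.trials_per_nerve
    start, end = 120.0, cfg.session_minutes * 60.0 - 120.0
    grid = np.linspace(start, end, n)
    spacing = (end - start) / max(n - 1, 1)
    jitter = rng.uniform(-0.3 * spacing, 0.3 * spacing, n)
    return np.sort(np.clip(grid + jitter, 0.0, cfg.session_minutes * 60.0 - 1.0))


def generate_patient(cfg: GeneratorConfig, index: int) -> PatientSession:
    """One synthetic patient session (index-th patient of the cohort)."""
    ref = REFERENCE_COHORT[index % len(REFERENCE_COHORT)]
    patient_id = f"P{index + 1:02d}"
    anesthesia = generate_concentration_profile(cfg, patient_seed=index)
    rng = np.random.default_rng([cfg.seed, 1_000_003, index])
    trials: list[SSEPTrial] = []
    for nerve in NERVE_MONTAGES:
        times = _trial_times(cfg, rng)
        for ev, ts in enumerate(times):
            # true concentration driving the waveform: the charted series
            # linearly interpolated to the stimulation time
            c = float(np.interp(ts, anesthesia.timestamps, anesthesia.et_sevo))
            for montage in NERVE_MONTAGES[nerve]:
                trials.append(
                    synthesize_trial(
                        nerve,
                        montage,
                        c,
                        cfg,
                        rng,
                        trial_id=f"{patient_id}-{nerve}-{montage}-{ev:03d}",
                        timestamp=float(ts),
                    )
                )
    return PatientSession(
        patient_id=patient_id,
        age=ref.age,
        sex=ref.sex,
        trials=trials,
        anesthesia=anesthesia,
    )


def generate_cohort(cfg: GeneratorConfig) -> list[PatientSession]:
    """A full synthetic cohort of ``cfg.n_patients`` sessions."""
    if cfg.n_patients < 3:
        raise ValueError("n_patients must be >= 3 (need train and test patients)")
    return [generate_patient(cfg, i) for i in range(cfg.n_patients)]
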