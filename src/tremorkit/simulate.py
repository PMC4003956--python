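"""Synthetic tremor recordings with class-specific statistical structure.

The simulator stands in for the haptic device and the patient cohort.  Each
recording is a 100 Hz, 3D position series composed of a voluntary
(minimum-jerk) traversal of the test pattern, a tremor displacement whose
process type depends on the diagnostic class, and white measurement noise:

- physiological (healthy) tremor: a zero-mean stationary linear stochastic
  process — an AR(2) resonance at the tremor frequency;
- Parkinsonian (PD) tremor: a harmonic carrier whose amplitude and phase
  are modulated by a chaotic driver (a smoothed logistic map, r = 3.9) and
  which carries a quadratically phase-coupled second harmonic, giving the
  nonzero bispectral signature expected of a nonlinear chaotic signal;
- essential tremor (ET): a harmonic carrier with linear-stochastic
  amplitude modulation — intermediate between the two.

Class centre frequencies and amplitudes (healthy 10 Hz / 0.3 mm, ET 7 Hz /
1.5 mm, PD 5 Hz / 3 mm) are modelling choices in the range movement-
disorder studies report, not measured constants.

When a pattern carries a virtual force field the trajectory is instead the
solution of a hand model — a 1 kg point mass with a critically damped
voluntary tracking controller (natural frequency 3 Hz) — driven by the
tremor disturbance force and the field load, integrated by semi-implicit
Euler at 1 kHz and decimated to the recording rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .forces import ForceKind, ForceSpec, clamp_force
from .patterns import Pattern, make_pattern

__all__ = [
    "DEFAULT_FS",
    "CLASS_LABELS",
    "Recording",
    "TremorModelSpec",
    "CohortSpec",
    "Cohort",
    "default_class_spec",
    "minimum_jerk_profile",
    "voluntary_motion",
    "tremor_component",
    "simulate_recording",
    "generate_cohort",
    "tremor_band_variance",
]

#: Recording sample rate, Hz (the device samples position 100 times per second).
DEFAULT_FS = 100.0
#: Internal integration rate for force-coupled simulation, Hz.
INTERNAL_FS = 1000.0

#: Diagnostic classes, in the classifier's output order (class 1, 2, 3).
CLASS_LABELS = ("ET", "PD", "healthy")

# hand model: point mass with critically damped tracking of the intent
HAND_MASS = 1.0           # kg
HAND_NATURAL_HZ = 3.0     # Hz

#: Class centre (tremor frequency Hz, tremor amplitude m) — modelling choices.
CLASS_BASE = {
    "healthy": (10.0, 0.0003),
    "ET": (7.0, 0.0015),
    "PD": (5.0, 0.003),
}


@dataclass
class Recording:
    """One test: a uniformly sampled 3D position series plus session metadata."""

    patient_id: str
    pattern_id: Optional[int]
    hand: str
    fs: float
    t: np.ndarray
    xyz: np.ndarray
    label: str = "unknown"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.xyz = np.asarray(self.xyz, float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.t.ndim != 1 or self.xyz.shape != (self.t.size, 3):
            raise ValueError("xyz must be (n, 3) matching t")
        if self.t.size < 2:
            raise ValueError("recording duration must be positive")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("positions must be finite")
        dt = np.diff(self.t)
        if not np.allclose(dt, 1.0 / self.fs, rtol=1e-6, atol=1e-9):
            raise ValueError("timestamps must be uniform at fs")
        if self.hand not in ("left", "right"):
            raise ValueError("hand must be 'left' or 'right'")
        if self.label not in CLASS_LABELS + ("unknown",):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class TremorModelSpec:
    """Generative parameters for one subject's tremor.

    ``ar_coeffs`` optionally fixes the healthy-class AR coefficients
    [a1, a2] (tied to the generation rate); by default they are derived
    from ``tremor_freq`` with a resonance bandwidth of ``ar_bandwidth_hz``
    so the process keeps its spectral shape at any sampling rate.
    ``chaos_params`` configures the PD chaotic modulator (logistic map
    rate, smoothing and modulation depths).
    """

    class_label: str
    tremor_freq: float
    tremor_amp: float
    ar_coeffs: Optional[Sequence[float]] = None
    ar_bandwidth_hz: float = 0.8
    chaos_params: Optional[dict] = None
    mod_depth: float = 0.4
    noise_sd: float = 5e-5
    process_weights: Optional[dict] = None
    seed: int = 0

    def __post_init__(self):
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"class_label must be one of {CLASS_LABELS}")
        if self.tremor_amp < 0:
            raise ValueError("tremor_amp must be non-negative")
        if self.process_weights is not None:
            w = np.array([self.process_weights[c] for c in ("healthy", "ET", "PD")])
            if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
                raise ValueError("process_weights must be non-negative and sum to 1")
        if self.ar_coeffs is not None:
            a1, a2 = self.ar_coeffs
            poles = np.roots([1.0, -a1, -a2])
            if np.any(np.abs(poles) >= 1.0):
                raise ValueError("AR coefficients are non-stationary "
                                 "(pole on/outside the unit circle)")


DEFAULT_CHAOS = {"r": 3.9, "rate_hz": 10.0, "smooth_hz": 3.0,
                 "depth_amp": 0.4, "depth_phase": 0.5, "harmonic": 0.4}


def default_class_spec(label: str, separation: float = 1.0,
                       noise_sd: float = 5e-5, seed: int = 0) -> TremorModelSpec:
    """Class-default tremor model, optionally shrunk toward the class mean.

    ``separation`` = 1 gives the class defaults (pure processes); smaller
    values move every class's frequency (linearly) and amplitude
    (log-linearly) toward the pooled mean and mix the class's canonical
    process with the other two (weights shrink toward uniform), producing
    progressively overlapping cohorts.
    """
    freqs = np.array([CLASS_BASE[c][0] for c in CLASS_BASE])
    amps = np.array([CLASS_BASE[c][1] for c in CLASS_BASE])
    f_bar = freqs.mean()
    log_a_bar = np.log(amps).mean()
    f0, a0 = CLASS_BASE[label]
    f = f_bar + separation * (f0 - f_bar)
    a = float(np.exp(log_a_bar + separation * (np.log(a0) - log_a_bar)))
    weights = None
    if separation < 1.0:
        weights = {c: separation * (1.0 if c == label else 0.0)
                   + (1.0 - separation) / 3.0
                   for c in ("healthy", "ET", "PD")}
    return TremorModelSpec(label, tremor_freq=f, tremor_amp=a,
                           noise_sd=noise_sd, process_weights=weights,
                           seed=seed)


def minimum_jerk_profile(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5."""
    tau = np.asarray(tau, float)
    return 10.0 * tau**3 - 15.0 * tau**4 + 6.0 * tau**5


def _voluntary_n(pattern: Pattern, n: int, fs: float) -> np.ndarray:
    """Minimum-jerk traversal sampled at n points; endpoints exact."""
    from .patterns import PathKind

    path = pattern.geometry
    if path.kind is PathKind.POINT:
        return np.broadcast_to(path.point_at(0.0), (n, 3)).copy()
    tau = np.arange(n) / (n - 1)
    s = minimum_jerk_profile(tau)
    # arc-length parametrization: invert cumulative length on a dense grid
    m = 4096
    ug = np.linspace(0.0, 1.0, m + 1)
    pts = path.point_at(ug)
    cum = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    if cum[-1] == 0.0:
        return np.broadcast_to(path.point_at(0.0), (n, 3)).copy()
    u = np.interp(s * cum[-1], cum, ug)
    u[0], u[-1] = 0.0, 1.0
    return path.point_at(u)


def voluntary_motion(pattern: Pattern, duration: float,
                     fs: float = DEFAULT_FS) -> np.ndarray:
    """Intended (tremor-free) hand trajectory for a test.

    A minimum-jerk traversal of the pattern's reference path from start to
    end over the full duration (or a hold at the target for static
    patterns); start and end samples coincide with the path endpoints.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError("duration too short for the sampling rate")
    return _voluntary_n(pattern, n, fs)


# ---------------------------------------------------------------------------
# tremor processes
# ---------------------------------------------------------------------------

def _ar2_series(n: int, f0: float, fs: float, bandwidth_hz: float,
                rng: np.random.Generator,
                coeffs: Optional[Sequence[float]] = None) -> np.ndarray:
    if coeffs is None:
        # pole radius set so the resonance keeps its bandwidth (Hz) at any fs
        radius = np.exp(-np.pi * bandwidth_hz / fs)
        w = 2.0 * np.pi * f0 / fs
        a1, a2 = 2.0 * radius * np.cos(w), -radius**2
    else:
        a1, a2 = coeffs
    burn = 500
    e = rng.standard_normal(n + burn)
    x = signal.lfilter([1.0], [1.0, -a1, -a2], e)[burn:]
    return x


def _chaotic_stream(n: int, fs: float, rng: np.random.Generator,
                    cp: dict) -> np.ndarray:
    """Smoothed logistic-map sequence resampled to fs, zero mean, unit std."""
    rate = cp["rate_hz"]
    n_map = int(np.ceil(n / fs * rate)) + 101
    z = np.empty(n_map)
    z[0] = 0.2 + 0.6 * rng.random()
    r = cp["r"]
    for k in range(1, n_map):
        z[k] = r * z[k - 1] * (1.0 - z[k - 1])
    z = z[100:]  # discard transient
    t_map = np.arange(z.size) / rate
    t = np.arange(n) / fs
    zi = np.interp(t, t_map, z)
    sos = signal.butter(2, cp["smooth_hz"], fs=fs, output="sos")
    zs = signal.sosfiltfilt(sos, zi)
    sd = zs.std()
    return (zs - zs.mean()) / sd if sd > 0 else np.zeros(n)


def _unit_rms(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return x / sd if sd > 0 else x


def _proc_linear(spec: TremorModelSpec, n: int, fs: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Physiological process: stationary AR(2) resonance, unit RMS."""
    return _unit_rms(_ar2_series(n, spec.tremor_freq, fs,
                                 spec.ar_bandwidth_hz, rng, spec.ar_coeffs))


def _proc_am_carrier(spec: TremorModelSpec, n: int, fs: float,
                     rng: np.random.Generator) -> np.ndarray:
    """ET process: carrier with linear-stochastic amplitude modulation, unit RMS."""
    t = np.arange(n) / fs
    phi0 = rng.uniform(0.0, 2.0 * np.pi)
    pole = np.exp(-2.0 * np.pi * 0.1 / fs)  # ~0.1 Hz envelope bandwidth
    env = _unit_rms(signal.lfilter([1.0], [1.0, -pole],
                                   rng.standard_normal(n + 500))[500:])
    x = (1.0 + spec.mod_depth * env) * np.sin(
        2.0 * np.pi * spec.tremor_freq * t + phi0)
    return _unit_rms(x)


def _proc_chaotic(spec: TremorModelSpec, n: int, fs: float,
                  rng: np.random.Generator) -> np.ndarray:
    """PD process: chaotically modulated carrier with a quadratically
    phase-coupled second harmonic, unit RMS."""
    cp = dict(DEFAULT_CHAOS)
    if spec.chaos_params:
        cp.update(spec.chaos_params)
    t = np.arange(n) / fs
    phi0 = rng.uniform(0.0, 2.0 * np.pi)
    ca = _chaotic_stream(n, fs, rng, cp)
    cphi = _chaotic_stream(n, fs, rng, cp)
    amp = np.clip(1.0 + cp["depth_amp"] * ca, 0.05, None)
    theta = 2.0 * np.pi * spec.tremor_freq * t + phi0 + cp["depth_phase"] * cphi
    return _unit_rms(amp * (np.sin(theta) + cp["harmonic"] * np.sin(2.0 * theta)))


_PROCESS_FNS = {"healthy": _proc_linear, "ET": _proc_am_carrier,
                "PD": _proc_chaotic}


def tremor_component(spec: TremorModelSpec, n: int, fs: float = DEFAULT_FS,
                     rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Class-conditional 3D tremor displacement series (n, 3), metres.

    Healthy: per-axis AR(2) scaled to RMS ``tremor_amp``.  PD: chaotic
    amplitude/phase-modulated carrier with a phase-coupled second harmonic
    (nonzero bispectral content).  ET: carrier with AR(1) (linear-
    stochastic) amplitude modulation.  When ``spec.process_weights`` is
    set, the series is a power-weighted mixture of the three canonical
    processes (used to emulate overlapping pathologies); a pure class by
    default.  Reproducible from ``spec.seed`` when ``rng`` is not given.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if spec.tremor_amp == 0.0:
        return np.zeros((n, 3))
    if spec.process_weights is None:
        weights = {c: (1.0 if c == spec.class_label else 0.0)
                   for c in ("healthy", "ET", "PD")}
    else:
        weights = spec.process_weights
    out = np.zeros((n, 3))
    for ax in range(3):
        sub = rng.spawn(3)
        for (proc, fn), r in zip(_PROCESS_FNS.items(), sub):
            w = weights[proc]
            if w > 0:
                out[:, ax] += np.sqrt(w) * fn(spec, n, fs, r)
        out[:, ax] *= spec.tremor_amp
    return out


# ---------------------------------------------------------------------------
# recording synthesis
# ---------------------------------------------------------------------------

def _hand_gains():
    wn = 2.0 * np.pi * HAND_NATURAL_HZ
    k = HAND_MASS * wn**2
    c = 2.0 * HAND_MASS * wn  # critical damping
    return k, c


def _integrate_forced(q: np.ndarray, d: np.ndarray, dt: float,
                      force: ForceSpec) -> np.ndarray:
    """Hand-model trajectory under intent q, tremor displacement d, field load.

    The tremor enters as the disturbance force that would reproduce d
    exactly on the force-free hand model, so the force-free solution is
    q + d and any added viscous/inertial load attenuates the tremor band.
    """
    k, c = _hand_gains()
    m = HAND_MASS
    qdot = np.gradient(q, dt, axis=0)
    ddot = np.gradient(d, dt, axis=0)
    dddot = np.gradient(ddot, dt, axis=0)
    f_trem = m * dddot + c * ddot + k * d

    Fc = np.zeros(3)
    K_f = B_f = M_f = 0.0
    direction = None
    if force.kind is ForceKind.CONSTANT:
        Fc = clamp_force(force.F_const)
    elif force.kind is ForceKind.SPRING:
        K_f, direction = force.K, force.direction
    elif force.kind is ForceKind.MASS_SPRING_DAMPER:
        K_f, B_f, M_f = force.K, force.B, force.M

    n = q.shape[0]
    x = np.empty((n, 3))
    x[0] = q[0] + d[0]
    vel = qdot[0] + ddot[0]
    for i in range(1, n):
        delta = x[i - 1] - q[i - 1]
        dvel = vel - qdot[i - 1]
        F = -k * delta - c * dvel + f_trem[i - 1] + Fc
        if K_f:
            disp = delta if direction is None else np.dot(delta, direction) * direction
            F = F - K_f * disp
        if B_f:
            F = F - B_f * vel
        a = F / (m + M_f)
        vel = vel + dt * a
        x[i] = x[i - 1] + dt * vel
    return x


def simulate_recording(pattern: Pattern, spec: TremorModelSpec,
                       duration: float = 20.0, fs: float = DEFAULT_FS,
                       patient_id: str = "sim", hand: str = "right",
                       metadata: Optional[dict] = None) -> Recording:
    """Synthesize one labelled recording of ``pattern`` for a subject.

    The position series is voluntary motion + tremor + white measurement
    noise; with a force field attached to the pattern the trajectory is the
    hand model's response integrated at 1 kHz and decimated to ``fs``.  The
    tremor and noise random streams are derived from ``spec.seed`` in a
    fixed order, so paired force/no-force runs share their disturbances.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError("duration too short for the sampling rate")
    ss = np.random.SeedSequence(spec.seed)
    rng_trem, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))

    factor = max(1, int(round(INTERNAL_FS / fs)))
    fs_hi = fs * factor
    n_hi = factor * (n - 1) + 1
    q_hi = _voluntary_n(pattern, n_hi, fs_hi)
    d_hi = tremor_component(spec, n_hi, fs_hi, rng_trem)

    force = pattern.force if pattern.force is not None else ForceSpec.none()
    if force.kind is ForceKind.NONE:
        xyz = (q_hi + d_hi)[::factor]
    else:
        xyz = _integrate_forced(q_hi, d_hi, 1.0 / fs_hi, force)[::factor]
    xyz = xyz + spec.noise_sd * rng_noise.standard_normal((n, 3))

    meta = {"remarks": f"synthetic {spec.class_label} tremor",
            "tremor_freq_hz": spec.tremor_freq,
            "tremor_amp_m": spec.tremor_amp}
    if metadata:
        meta.update(metadata)
    return Recording(patient_id=patient_id, pattern_id=pattern.id, hand=hand,
                     fs=fs, t=np.arange(n) / fs, xyz=xyz,
                     label=spec.class_label, metadata=meta)


def tremor_band_variance(recording: Recording, pattern: Pattern,
                         band=(4.0, 15.0)) -> float:
    """Variance of the tremor-band deviation from the intended trajectory.

    The voluntary trajectory is reconstructed, subtracted, band-passed
    (4th-order Butterworth, zero phase) and the per-axis variances summed.
    """
    n, fs = recording.n_samples, recording.fs
    q = _voluntary_n(pattern, n, fs)
    dev = recording.xyz - q
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, dev, axis=0)
    return float(filt.var(axis=0).sum())


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Composition and generative settings of a simulated patient cohort.

    ``n_healthy``/``n_ET``/``n_PD`` give the training-set composition (the
    default 210 + 34 + 120 = 364 cases); ``n_validation`` further cases are
    drawn with the same class proportions (largest-remainder rounding) and
    held out.  ``separation`` scales inter-class parameter differences (1 =
    class defaults; see :func:`default_class_spec`).
    """

    n_healthy: int = 210
    n_ET: int = 34
    n_PD: int = 120
    n_validation: int = 156
    pattern_id: int = 1
    duration: float = 20.0
    fs: float = DEFAULT_FS
    separation: float = 1.0
    freq_jitter: float = 0.4
    amp_jitter_log_sd: float = 0.2
    noise_sd: float = 5e-5
    master_seed: int = 0

    def __post_init__(self):
        if min(self.n_healthy, self.n_ET, self.n_PD) < 0 or self.n_validation < 0:
            raise ValueError("cohort counts must be non-negative")
        total = self.n_healthy + self.n_ET + self.n_PD
        if self.n_validation > 0 and total == 0:
            raise ValueError("validation split requested from an empty cohort")

    @property
    def train_counts(self) -> dict:
        return {"healthy": self.n_healthy, "ET": self.n_ET, "PD": self.n_PD}

    @property
    def validation_counts(self) -> dict:
        total = self.n_healthy + self.n_ET + self.n_PD
        if total == 0 or self.n_validation == 0:
            return {c: 0 for c in self.train_counts}
        exact = {c: self.n_validation * n / total
                 for c, n in self.train_counts.items()}
        counts = {c: int(np.floor(v)) for c, v in exact.items()}
        rem = self.n_validation - sum(counts.values())
        order = sorted(exact, key=lambda c: exact[c] - counts[c], reverse=True)
        for c in order[:rem]:
            counts[c] += 1
        return counts


@dataclass
class Cohort:
    """A labelled recording set with its stratified train/validation split."""

    recordings: list
    train_idx: np.ndarray
    validation_idx: np.ndarray

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.recordings])

    @property
    def train(self) -> list:
        return [self.recordings[i] for i in self.train_idx]

    @property
    def validation(self) -> list:
        return [self.recordings[i] for i in self.validation_idx]


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the labelled cohort and its stratified split, deterministically.

    Per-subject tremor parameters jitter around the class defaults
    (frequency uniformly within +-``freq_jitter`` Hz, amplitude
    log-normally).  Everything derives from ``master_seed``: two calls with
    the same spec are bit-identical.
    """
    pattern = make_pattern(spec.pattern_id)
    ss = np.random.SeedSequence(spec.master_seed)
    recordings = []
    train_idx, val_idx = [], []
    prefix = {"healthy": "H", "ET": "E", "PD": "P"}
    for split, counts in (("train", spec.train_counts),
                          ("validation", spec.validation_counts)):
        for label in CLASS_LABELS:
            n_sub = counts[label]
            if n_sub == 0:
                continue
            children = ss.spawn(n_sub)
            for j, child in enumerate(children):
                rng = np.random.default_rng(child)
                base = default_class_spec(label, spec.separation,
                                          noise_sd=spec.noise_sd)
                sub = replace(
                    base,
                    tremor_freq=base.tremor_freq + rng.uniform(-spec.freq_jitter,
                                                               spec.freq_jitter),
                    tremor_amp=base.tremor_amp * float(
                        np.exp(spec.amp_jitter_log_sd * rng.standard_normal())),
                    seed=int(child.generate_state(1)[0] % (2**31)),
                )
                pid = f"{prefix[label]}{'T' if split == 'train' else 'V'}{j:03d}"
                rec = simulate_recording(pattern, sub, spec.duration, spec.fs,
                                         patient_id=pid,
                                         metadata={"split": split})
                (train_idx if split == "train" else val_idx).append(len(recordings))
                recordings.append(rec)
    return Cohort(recordings, np.array(train_idx, int), np.array(val_idx, int))
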