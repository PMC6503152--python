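"""Synthetic inputs with known ground truth.

Three generators:

* :func:`generate_bursty_ecog` — an ECoG-like single-channel signal made of
  a 1/f background plus an intermittent beta-band carrier gated by a
  two-state Markov process, emulating the spontaneous low/high beta-power
  fluctuations of the parkinsonian motor cortex.  Burst onset/offset times
  are returned as ground truth for scoring the epoch classifier.
* :func:`simulate_timeseries` — fixed-step stochastic integration (Heun
  scheme with delay buffers) of the full nonlinear delayed circuit, driven
  by white+pink input noise whose PSD matches the forward model's G_u.
  This is the independent oracle for the linearized spectral predictions.
* :func:`generate_group_dataset` — model-based two-condition spectra for a
  synthetic group of subjects with known condition effects, for recovery
  tests of the inversion and group stages.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circuit import CircuitParameters, ModelSpec, POP_INDEX, build_connectivity
from .containers import CrossSpectralData
from .forward import (
    UnstableRegimeError,
    channel_noise_spectrum,
    find_fixed_point,
    input_spectrum,
    predict_csd,
)

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


__all__ = [
    "BurstGeneratorConfig",
    "generate_bursty_ecog",
    "colored_noise",
    "simulate_timeseries",
    "generate_group_dataset",
    "DEFAULT_GEN_LOG_GAIN",
    "REFERENCE_MODULATION",
]

#: Default log observation gain used when generating model-based spectral
#: data.  Chosen so the neural signal dominates the channel-noise floor by
#: ~two orders of magnitude in the beta band, emulating the high
#: signal-to-noise ratio of screw-electrode ECoG; well inside the prior on
#: log L (sd 8).
DEFAULT_GEN_LOG_GAIN = 7.5

#: Canonical generating pattern of condition effects for the winning model:
#: the low→high beta transition strengthens MP→SP, REL→RET, REL→DP and
#: REL→II and weakens SP→MP, RET→REL and the corticothalamic projections.
#: Magnitudes are weighted toward the connections with the dominant role in
#: beta enhancement; under this pattern every population's beta-band output
#: increases from LB to HB.
REFERENCE_MODULATION: dict = {
    ("MP", "SP"): +0.4,
    ("SP", "MP"): -0.1,
    ("REL", "RET"): +0.4,
    ("RET", "REL"): -0.05,
    ("DP", "REL"): -0.1,
    ("DP", "RET"): -0.05,
    ("REL", "DP"): +0.4,
    ("REL", "II"): +0.4,
}


# --------------------------------------------------------------------------
# coloured noise


def colored_noise(
    n: int, fs: float, white: float, pink: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with one-sided PSD  S(f) = white + pink/f  (units²/Hz).

    Synthesized in the frequency domain: independent complex-Gaussian
    Fourier coefficients with variance proportional to the target PSD, so
    the sample spectrum is exact on average at every DFT frequency.  The
    DC component is set to zero.
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    psd = np.zeros_like(freqs)
    psd[1:] = white + pink / freqs[1:]
    # one-sided PSD -> rfft coefficient variance
    amp = np.sqrt(psd * fs * n / 2.0)
    z = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    z *= amp / np.sqrt(2.0)
    z[0] = 0.0
    if n % 2 == 0:
        z[-1] = z[-1].real * np.sqrt(2.0)
    return np.fft.irfft(z, n=n)


# --------------------------------------------------------------------------
# bursty ECoG generator


@dataclass
class BurstGeneratorConfig:
    """Settings of the beta-burst surrogate recording.

    The defaults give a 120 s recording at 1 kHz with ~25 Hz bursts lasting
    ~300 ms on average, occurring ~0.4 times per second at three times the
    background amplitude over a 1/f background — enough epochs (240) for
    percentile-tail classification and heavy-tailed envelope-area spread.
    """

    fs: float = 1000.0
    duration: float = 120.0
    carrier_freq: float = 25.0
    burst_rate: float = 0.4  # bursts per second
    burst_duration: float = 0.3  # mean burst length, s
    burst_amplitude: float = 3.0  # carrier amplitude relative to background RMS
    background_exponent: float = 1.0  # 1/f^exponent background slope
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration < 30.0:
            raise ValueError("duration must be >= 30 s to yield enough epochs")
        if not 15.0 <= self.carrier_freq <= 35.0:
            raise ValueError("carrier frequency must lie in the beta band")
        if self.burst_rate <= 0 or self.burst_duration <= 0:
            raise ValueError("burst rate and duration must be positive")
        if self.burst_amplitude < 0:
            raise ValueError("burst amplitude must be non-negative")
        if self.fs < 200:
            raise ValueError("sampling rate too low for a 15-35 Hz carrier")


def generate_bursty_ecog(cfg: BurstGeneratorConfig):
    """Synthesize the recording; returns ``(signal, bursts)``.

    ``bursts`` is a list of (onset_s, offset_s) ground-truth intervals of
    the two-state Markov gate (on-rate = burst_rate, off-rate =
    1/burst_duration).  The gate is smoothed with a 50 ms Hann window so
    burst edges carry no broadband clicks.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.fs * cfg.duration))

    # 1/f^a background with unit RMS
    bg = _powerlaw_background(n, cfg.fs, cfg.background_exponent, rng)
    bg /= np.std(bg)

    # two-state Markov gate
    gate = np.zeros(n)
    bursts: list[tuple[float, float]] = []
    t = 0.0
    state = False
    while t < cfg.duration:
        if state:
            length = rng.exponential(cfg.burst_duration)
            onset = t
            t = min(t + length, cfg.duration)
            bursts.append((onset, t))
            gate[int(onset * cfg.fs) : int(t * cfg.fs)] = 1.0
            state = False
        else:
            t += rng.exponential(1.0 / cfg.burst_rate)
            state = True

    w = int(0.05 * cfg.fs)
    if w >= 2:
        win = np.hanning(2 * w + 1)
        gate = np.convolve(gate, win / win.sum(), mode="same")

    phase = 2 * np.pi * cfg.carrier_freq * np.arange(n) / cfg.fs
    phase += rng.uniform(0, 2 * np.pi)
    carrier = np.sin(phase)
    signal = bg + cfg.burst_amplitude * gate * carrier
    return signal, bursts


def _powerlaw_background(n, fs, exponent, rng):
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    psd = np.zeros_like(freqs)
    psd[1:] = freqs[1:] ** (-exponent)
    amp = np.sqrt(psd * fs * n / 2.0)
    z = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    z *= amp / np.sqrt(2.0)
    z[0] = 0.0
    return np.fft.irfft(z, n=n)


# --------------------------------------------------------------------------
# stochastic circuit simulation (oracle for the linearized spectra)


@njit(cache=True)
def _accel(v_now, w_now, v_lag_in, v_lag_ex, C_in, C_ex, R, T, u0, u1, inp_idx, out):  # pragma: no cover
    for m in range(6):
        fi = 1.0 / (1.0 + np.exp(-R[m] * v_lag_in[m])) - 0.5
        fe = 1.0 / (1.0 + np.exp(-R[m] * v_lag_ex[m])) - 0.5
        out[m] = fi  # reuse as scratch for firing-in
        out[6 + m] = fe
    for j in range(6):
        s = 0.0
        for m in range(6):
            s += C_in[j, m] * out[m] + C_ex[j, m] * out[6 + m]
        drive = 0.0
        if j == inp_idx[0]:
            drive = u0
        elif j == inp_idx[1]:
            drive = u1
        out[12 + j] = (s + drive - 2.0 * w_now[j] - v_now[j] / T[j]) / T[j]


@njit(cache=True)
def _integrate(v0, w0, C_in, C_ex, R, T, u, inp_idx, dt, lag_in, lag_ex):  # pragma: no cover
    # Heun (explicit trapezoidal) steps; delayed voltages are read from the
    # stored trajectory, which is valid because both conduction lags span
    # many integration steps.
    n_steps = u.shape[1]
    v = np.zeros((n_steps, 6))
    w = w0.copy()
    v[0] = v0
    scratch = np.zeros(18)
    vp = np.zeros(6)
    wp = np.zeros(6)
    for k in range(n_steps - 1):
        ki = k - lag_in if k >= lag_in else 0
        ke = k - lag_ex if k >= lag_ex else 0
        _accel(v[k], w, v[ki], v[ke], C_in, C_ex, R, T, u[0, k], u[1, k], inp_idx, scratch)
        a1 = scratch[12:].copy()
        for j in range(6):
            vp[j] = v[k, j] + dt * w[j]
            wp[j] = w[j] + dt * a1[j]
        ki2 = k + 1 - lag_in if k + 1 >= lag_in else 0
        ke2 = k + 1 - lag_ex if k + 1 >= lag_ex else 0
        _accel(vp, wp, v[ki2], v[ke2], C_in, C_ex, R, T, u[0, k + 1], u[1, k + 1], inp_idx, scratch)
        for j in range(6):
            v[k + 1, j] = v[k, j] + 0.5 * dt * (w[j] + wp[j])
            w[j] = w[j] + 0.5 * dt * (a1[j] + scratch[12 + j])
    return v


def simulate_timeseries(
    spec: ModelSpec,
    params: CircuitParameters,
    duration: float,
    fs: float = 10_000.0,
    seed: int = 0,
    condition: str = "LB",
    initial_state: np.ndarray | None = None,
    input_scale: float = 1.0,
    channel_noise: bool = True,
):
    """Euler–Maruyama integration of the delayed nonlinear circuit.

    ``fs`` is the integration rate (default 10 kHz, i.e. 0.1 ms steps, so
    the 1 ms and 8 ms conduction delays are exact multiples of the step).
    Inputs to MP and REL are independent noise processes with one-sided PSD
    ``input_scale² · G_u(f)``; channel noise with PSD G_n is added to the
    observed channel when requested.  Returns ``(t, voltages, observed)``
    with voltages of shape (n, 6) in population order.

    Raises ``RuntimeError`` naming the blow-up time if the trajectory
    diverges.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    dt = 1.0 / fs
    lag_in = int(round(params.d_intrinsic * fs))
    lag_ex = int(round(params.D_extrinsic * fs))
    if abs(lag_in - params.d_intrinsic * fs) > 1e-9 or abs(
        lag_ex - params.D_extrinsic * fs
    ) > 1e-9:
        raise ValueError("conduction delays must be integer multiples of the step")

    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)

    C, D, _ = build_connectivity(spec, params, condition)
    ext = D >= params.D_extrinsic - 1e-12
    C_in = np.ascontiguousarray(C * ~ext)
    C_ex = np.ascontiguousarray(C * ext)
    T = params.time_constants
    R = params.slopes

    a = np.exp(params.alpha_s) * input_scale**2
    b = np.exp(params.beta_s) * input_scale**2
    u = np.empty((2, n))
    u[0] = colored_noise(n, fs, a, b, rng)
    u[1] = colored_noise(n, fs, a, b, rng)

    if initial_state is None:
        initial_state = np.zeros(12)
    v0 = np.asarray(initial_state[:6], dtype=float)
    w0 = np.asarray(initial_state[6:], dtype=float)
    inp_idx = np.array([POP_INDEX["MP"], POP_INDEX["REL"]], dtype=np.int64)

    v = _integrate(v0, w0, C_in, C_ex, R.astype(float), T.astype(float), u,
                   inp_idx, dt, lag_in, lag_ex)

    if not np.all(np.isfinite(v)):
        bad = np.argwhere(~np.isfinite(v))[0, 0]
        raise RuntimeError(f"simulation diverged at t = {bad * dt:.4f} s")
    vmax = np.max(np.abs(v))
    if vmax > 1e6:
        bad = int(np.argmax(np.max(np.abs(v), axis=1) > 1e6))
        raise RuntimeError(f"simulation diverged at t = {bad * dt:.4f} s")

    obs = params.L * (
        params.J[0] * v[:, POP_INDEX["SP"]]
        + params.J[1] * v[:, POP_INDEX["MP"]]
        + params.J[2] * v[:, POP_INDEX["DP"]]
    )
    if channel_noise:
        obs = obs + colored_noise(
            n, fs, np.exp(params.alpha_c), np.exp(params.beta_c), rng
        )
    t = np.arange(n) * dt
    return t, v, obs


# --------------------------------------------------------------------------
# model-based group datasets


def generate_group_dataset(
    spec: ModelSpec,
    true_B: dict,
    n_subjects: int,
    subject_sd: float = 0.1,
    obs_noise: float = 0.0025,
    seed: int = 0,
    freqs: np.ndarray | None = None,
    base_params: CircuitParameters | None = None,
    log_gain: float = DEFAULT_GEN_LOG_GAIN,
):
    """Two-condition spectra for ``n_subjects`` with known condition effects.

    Per subject, the condition effects are drawn around ``true_B`` with
    between-subject sd ``subject_sd`` (also applied to the intrinsic
    thalamic and extrinsic log-couplings), spectra are predicted from the
    circuit, and multiplicative log-normal observation noise of sd
    ``obs_noise`` is applied per frequency.  Unstable draws are redrawn (up
    to 10 times each) and counted.

    Returns ``(datasets, truth)`` where ``truth`` records per-subject B
    values, the redraw count and the generator settings.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    from .forward import default_freqs

    if freqs is None:
        freqs = default_freqs()
    rng = np.random.default_rng(seed)
    base = (base_params or CircuitParameters.defaults()).copy()
    base.L = float(np.exp(log_gain))
    for edge in true_B:
        if edge not in spec.modulated_edges:
            raise ValueError(f"true_B edge {edge} is not modulated under this spec")

    datasets: list[CrossSpectralData] = []
    subject_B: list[dict] = []
    redraws = 0
    for _ in range(n_subjects):
        for attempt in range(10):
            p = base.copy()
            p.gamma_tcr = p.gamma_tcr * np.exp(rng.normal(0, subject_sd, 3))
            p.lam = p.lam * np.exp(rng.normal(0, subject_sd, 4))
            p.B = {
                e: true_B.get(e, 0.0) + rng.normal(0, subject_sd)
                for e in spec.modulated_edges
            }
            try:
                gL = predict_csd(spec, p, freqs, "LB")
                gH = predict_csd(spec, p, freqs, "HB")
            except UnstableRegimeError:
                redraws += 1
                continue
            if obs_noise > 0:
                gL = gL * np.exp(rng.normal(0, obs_noise, gL.size))
                gH = gH * np.exp(rng.normal(0, obs_noise, gH.size))
            datasets.append(
                CrossSpectralData(freqs=freqs.copy(), spectra={"LB": gL, "HB": gH})
            )
            subject_B.append({f"{s}->{t}": v for (s, t), v in p.B.items()})
            break
        else:
            raise RuntimeError("10 consecutive unstable subject draws")

    truth = {
        "spec": spec.label,
        "true_B": {f"{s}->{t}": v for (s, t), v in true_B.items()},
        "subject_B": subject_B,
        "subject_sd": subject_sd,
        "obs_noise": obs_noise,
        "log_gain": log_gain,
        "seed": seed,
        "redraws": redraws,
    }
    return datasets, truth
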