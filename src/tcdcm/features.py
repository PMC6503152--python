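"""From a raw single-channel recording to per-condition spectral features.

The chain mirrors how low- and high-beta episodes are isolated from a
continuous field-potential recording: band-pass the signal to 15–35 Hz
(2nd-order Butterworth, applied forward–backward so envelope timing is
unbiased), take the Hilbert envelope, cut it into non-overlapping 500 ms
epochs, compute each epoch's envelope area, and keep only the extreme
epochs — area strictly below the 5th percentile (low beta, LB) or strictly
above the 95th (high beta, HB).  A fixed number of epochs per condition is
then drawn at random, and per-condition power spectra are estimated by
averaging autoregressive (Burg) spectra across the selected epochs: raw
periodograms of 500 ms segments are unusably coarse at 2 Hz resolution.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from statsmodels.regression.linear_model import burg

from .containers import CrossSpectralData, Epoch, EpochSet

__all__ = [
    "bandpass_beta",
    "envelope",
    "segment_and_classify",
    "select_epochs",
    "estimate_condition_spectra",
    "extract_condition_data",
]

BETA_BAND = (15.0, 35.0)


def bandpass_beta(x: np.ndarray, fs: float, band=BETA_BAND, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth band-pass to the beta band."""
    x = np.asarray(x, dtype=float)
    if fs < 200.0:
        raise ValueError(f"sampling rate {fs} Hz too low for a {band} Hz band-pass")
    if x.size < fs:
        raise ValueError("signal must be at least 1 s long")
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def envelope(x: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic (Hilbert) signal of a filtered input."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    return np.abs(sps.hilbert(x))


def segment_and_classify(
    env: np.ndarray,
    fs: float,
    signal: np.ndarray | None = None,
    epoch_ms: float = 500.0,
    lo_pct: float = 5.0,
    hi_pct: float = 95.0,
) -> EpochSet:
    """Cut the envelope into epochs and label the extreme tails LB / HB.

    Epoch areas are Σ envelope · dt.  Percentile thresholds use linearly
    interpolated quantiles computed per recording; classification is strict
    (< for LB, > for HB) so area ties at a threshold are discarded along
    with the unremarkable middle.  The trailing partial epoch is dropped.

    ``signal`` optionally supplies the samples stored per epoch (e.g. the
    band-passed signal); by default the envelope itself is stored.
    """
    env = np.asarray(env, dtype=float)
    n_per = round(fs * epoch_ms / 1000.0)
    n_epochs = env.size // n_per
    if n_epochs < 20:
        raise ValueError(f"need at least 20 whole epochs, got {n_epochs}")
    src = env if signal is None else np.asarray(signal, dtype=float)
    if src.size != env.size:
        raise ValueError("signal and envelope lengths differ")

    areas = np.array(
        [env[i * n_per : (i + 1) * n_per].sum() / fs for i in range(n_epochs)]
    )
    if np.ptp(areas) == 0:
        raise ValueError("degenerate envelope: all epoch areas identical (zero spread)")
    lo = np.percentile(areas, lo_pct)
    hi = np.percentile(areas, hi_pct)

    epochs = []
    for i, a in enumerate(areas):
        if a < lo:
            label = "LB"
        elif a > hi:
            label = "HB"
        else:
            continue
        epochs.append(
            Epoch(
                label=label,
                samples=src[i * n_per : (i + 1) * n_per].copy(),
                envelope_area=float(a),
                index=i,
            )
        )
    return EpochSet(fs=fs, epochs=epochs, epoch_ms=epoch_ms)


def select_epochs(epoch_set: EpochSet, n: int = 5, seed: int = 0) -> EpochSet:
    """Uniform random subset of ``n`` epochs per condition, seeded."""
    rng = np.random.default_rng(seed)
    chosen: list[Epoch] = []
    for cond in ("LB", "HB"):
        pool = epoch_set.condition(cond)
        if len(pool) < n:
            counts = epoch_set.counts()
            raise ValueError(
                f"need {n} epochs per condition, have LB={counts['LB']}, HB={counts['HB']}"
            )
        idx = rng.choice(len(pool), size=n, replace=False)
        chosen.extend(pool[i] for i in sorted(idx))
    return EpochSet(fs=epoch_set.fs, epochs=chosen, epoch_ms=epoch_set.epoch_ms)


def _burg_psd(x: np.ndarray, fs: float, freqs: np.ndarray, order: int) -> np.ndarray:
    """One-sided AR(order) PSD of ``x`` on ``freqs`` via Burg's method."""
    rho, sigma2 = burg(x - x.mean(), order=order)
    # AR transfer: sigma2 / |1 - sum rho_k z^-k|^2, one-sided density
    z = np.exp(-2j * np.pi * freqs[:, None] / fs * np.arange(1, order + 1)[None, :])
    denom = np.abs(1.0 - z @ rho) ** 2
    return 2.0 * sigma2 / fs / denom


def estimate_condition_spectra(
    selected: EpochSet,
    freqs: np.ndarray,
    ar_order: int = 16,
) -> CrossSpectralData:
    """Average AR spectra of the selected epochs, per condition.

    The estimator is pluggable in principle; Burg autoregression of
    moderate order is the default because 500 ms epochs leave periodograms
    with only 2 Hz resolution and high variance.
    """
    freqs = np.asarray(freqs, dtype=float)
    n_per = round(selected.fs * selected.epoch_ms / 1000.0)
    # lowest resolvable frequency ~ one cycle per epoch
    if freqs[0] < selected.fs / n_per:
        raise ValueError(
            f"epochs of {n_per} samples cannot support {freqs[0]} Hz estimates"
        )
    spectra = {}
    for cond in ("LB", "HB"):
        pool = selected.condition(cond)
        if not pool:
            raise ValueError(f"no epochs for condition {cond}")
        acc = np.zeros_like(freqs)
        for ep in pool:
            acc += _burg_psd(ep.samples, selected.fs, freqs, ar_order)
        spectra[cond] = acc / len(pool)
    return CrossSpectralData(freqs=freqs, spectra=spectra)


def extract_condition_data(
    signal: np.ndarray,
    fs: float,
    freqs: np.ndarray,
    n_select: int = 5,
    seed: int = 0,
    ar_order: int = 16,
) -> tuple[CrossSpectralData, EpochSet]:
    """Full chain: filter → envelope → classify → select → spectra.

    Epoch samples retained for spectral estimation are taken from the raw
    (unfiltered) signal so the spectra keep their broadband background.
    """
    filt = bandpass_beta(signal, fs)
    env = envelope(filt)
    eps = segment_and_classify(env, fs, signal=np.asarray(signal, dtype=float))
    sel = select_epochs(eps, n=n_select, seed=seed)
    csd = estimate_condition_spectra(sel, freqs, ar_order=ar_order)
    return csd, sel
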