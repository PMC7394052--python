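"""EMG conditioning: heartbeat removal, high-pass + analytic rectification,
envelope extraction, stride time-normalization, and assembly of the
concatenated stride-normalized envelope matrix X.

X has SC*N rows (SC = subject x coordination-mode averages, N = 200 samples
per normalized stride) and 26 muscle columns, everything non-negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .gaitkin import GaitEvents
from .muscles import MUSCLES

N_SAMPLES_PER_STRIDE = 200

__all__ = [
    "EnvelopeMatrix",
    "remove_heartbeat",
    "highpass_rectify",
    "envelope",
    "time_normalize",
    "amplitude_normalize_average_concat",
]


@dataclass
class EnvelopeMatrix:
    """Concatenated stride-normalized envelope matrix.

    ``X`` is (SC*N, n_muscles); ``index`` records the (subject, mode) of each
    of the SC stacked average strides, in row order.
    """

    X: np.ndarray
    N: int
    index: list = field(default_factory=list)  # [(subject, mode), ...]
    muscle_labels: list = field(default_factory=lambda: list(MUSCLES))

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        if np.any(X < 0):
            raise ValueError("envelope matrix must be non-negative")
        if X.shape[0] != len(self.index) * self.N:
            raise ValueError("row count must equal SC * N")
        self.X = X

    @property
    def sc(self) -> int:
        return len(self.index)


# --------------------------------------------------------------------------

def remove_heartbeat(
    emg: np.ndarray,
    fs: float,
    enabled: bool = True,
    rate_band: tuple[float, float] = (0.8, 1.5),
    periodicity_min: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Suppress heartbeat contamination by ICA component rejection.

    Components whose rectified-envelope power spectrum peaks inside
    ``rate_band`` (Hz) and whose envelope autocorrelation is strongly
    periodic at that lag are zeroed before back-projection.  On separation
    failure the input is passed through with a warning.
    """
    if not enabled:
        return emg
    emg = np.asarray(emg, dtype=float)
    if emg.shape[1] < 8:
        raise ValueError("need >= 8 channels for source separation")
    from sklearn.decomposition import FastICA

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ica = FastICA(
                n_components=emg.shape[1],
                random_state=seed,
                max_iter=500,
                whiten="unit-variance",
            )
            sources = ica.fit_transform(emg)  # (samples, k)
    except Exception as exc:  # pragma: no cover - separation failure path
        warnings.warn(f"ICA failed ({exc}); passing EMG through", stacklevel=2)
        return emg

    drop = [
        k for k in range(sources.shape[1])
        if _is_heartbeat_component(sources[:, k], fs, rate_band, periodicity_min)
    ]
    if not drop:
        return emg
    sources = sources.copy()
    sources[:, drop] = 0.0
    return sources @ ica.mixing_.T + ica.mean_


def _is_heartbeat_component(
    s: np.ndarray, fs: float, rate_band: tuple[float, float], periodicity_min: float
) -> bool:
    """Beat-like iff the rectified envelope repeats at a lag inside the
    heart-rate band.

    The envelope of a spike train carries most power in harmonics, so the
    fundamental is located by autocorrelation rather than a PSD argmax; the
    half-lag check rejects components whose true period is half the
    candidate (i.e. whose fundamental lies above the band).
    """
    env = np.abs(signal.hilbert(s))
    # decimate the envelope: the autocorrelation scan needs ~ms resolution only
    step = max(1, int(fs / 200.0))
    env = env[::step]
    fs = fs / step
    env = env - env.mean()
    if np.all(env == 0):
        return False
    lags = np.arange(int(fs / rate_band[1]), int(fs / rate_band[0]) + 1)
    lags = lags[(lags > 0) & (lags < env.size // 2)]
    if lags.size == 0:
        return False
    acs = np.array([np.corrcoef(env[:-lag], env[lag:])[0, 1] for lag in lags])
    best = int(np.argmax(acs))
    if acs[best] <= periodicity_min:
        return False
    half = lags[best] // 2
    ac_half = np.corrcoef(env[:-half], env[half:])[0, 1] if half > 0 else -1.0
    return bool(ac_half < acs[best] - 0.2)


def highpass_rectify(emg: np.ndarray, fs: float, cutoff: float = 30.0) -> np.ndarray:
    """2nd-order bidirectional Butterworth high-pass, then the modulus of the
    analytic signal per channel.  Output is non-negative."""
    if fs <= 2 * cutoff:
        raise ValueError(f"sampling rate {fs} Hz too low for {cutoff} Hz high-pass")
    emg = np.asarray(emg, dtype=float)
    squeeze = emg.ndim == 1
    if squeeze:
        emg = emg[:, None]
    sos = signal.butter(2, cutoff, "highpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, emg, axis=0)
    rect = np.abs(signal.hilbert(filtered, axis=0))
    return rect[:, 0] if squeeze else rect


def envelope(rectified: np.ndarray, fs: float, cutoff: float = 10.0) -> np.ndarray:
    """2nd-order bidirectional Butterworth low-pass of the rectified EMG;
    filter undershoot is clipped to 0 (NMF needs non-negative input)."""
    rectified = np.asarray(rectified, dtype=float)
    if np.any(rectified < 0):
        raise ValueError("rectified input must be non-negative")
    sos = signal.butter(2, cutoff, "lowpass", fs=fs, output="sos")
    env = signal.sosfiltfilt(sos, rectified, axis=0)
    return np.clip(env, 0.0, None)


def time_normalize(
    env: np.ndarray, events: GaitEvents, fs: float, n: int = N_SAMPLES_PER_STRIDE
) -> np.ndarray:
    """Resample each inter-heel-strike segment to exactly ``n`` samples.

    Linear interpolation on the endpoint-preserving grid; gait-cycle
    coordinate runs 0-100% from one right heel strike to the next.
    Returns (n_strides, n, n_channels).
    """
    times = events.heel_strike_times
    if times.size < 2:
        raise ValueError("need at least 2 heel strikes to delimit a stride")
    env = np.asarray(env, dtype=float)
    if env.ndim == 1:
        env = env[:, None]
    t = np.arange(env.shape[0]) / fs
    strides = []
    for t0, t1 in zip(times[:-1], times[1:]):
        grid = np.linspace(t0, t1, n)
        strides.append(
            np.stack([np.interp(grid, t, env[:, j]) for j in range(env.shape[1])], axis=1)
        )
    return np.stack(strides)


def amplitude_normalize_average_concat(
    stride_stacks: dict,
    modes: dict,
    fastest_speed: float | None = None,
    mode_order: tuple = ("2:1", "T", "1:1"),
) -> EnvelopeMatrix:
    """Build X: normalize amplitudes per subject to the mean activity of the
    fastest-speed trial, average strides within each (subject, mode), and
    concatenate the SC average strides row-wise.

    ``stride_stacks`` maps (subject, speed) -> (n_strides, N, n_muscles);
    ``modes`` maps (subject, speed) -> coordination label.
    """
    subjects = sorted({s for s, _ in stride_stacks})
    if fastest_speed is None:
        fastest_speed = max(v for _, v in stride_stacks)
    first = next(iter(stride_stacks.values()))
    n = first.shape[1]
    n_muscles = first.shape[2]

    blocks, index = [], []
    for subject in subjects:
        if (subject, fastest_speed) not in stride_stacks:
            raise ValueError(
                f"subject {subject} has no fastest-speed ({fastest_speed}) trial"
            )
        ref = stride_stacks[(subject, fastest_speed)].mean(axis=(0, 1))  # per muscle
        if np.any(ref <= 0):
            raise ValueError("fastest-speed reference activity must be positive")
        per_mode: dict = {}
        for (subj, speed), stack in stride_stacks.items():
            if subj != subject:
                continue
            mode = modes[(subj, speed)]
            per_mode.setdefault(mode, []).append(stack / ref[None, None, :])
        for mode in mode_order:
            if mode not in per_mode:
                continue
            all_strides = np.concatenate(per_mode[mode], axis=0)
            blocks.append(all_strides.mean(axis=0))  # (N, n_muscles)
            index.append((subject, mode))

    X = np.concatenate(blocks, axis=0) if blocks else np.zeros((0, n_muscles))
    return EnvelopeMatrix(X=X, N=n, index=index, muscle_labels=list(MUSCLES)[:n_muscles])
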