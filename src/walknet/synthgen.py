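"""Synthetic gait-study generator with planted ground truth.

Emulates the statistical structure of a treadmill-walking dataset: 26-channel
surface EMG (2 kHz) whose envelopes are mixtures of a small number of planted
synergies, band-limited common inputs shared by chosen muscle subsets
(producing intermuscular coherence in chosen bands), a vertical ground
reaction force trace with recorded heel-strike onsets, and arm/leg kinematic
traces frequency-locked at 2:1 or 1:1 (or drifting between them).

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .muscles import MUSCLES, N_MUSCLES

MODES = ("2:1", "T", "1:1")

KIN_FS = 70.0
EMG_FS = 2000.0


# --------------------------------------------------------------------------
# ground truth containers
# --------------------------------------------------------------------------

@dataclass
class CommonInputBand:
    """Band-limited common input injected into a muscle subset."""

    f_lo: float
    f_hi: float
    muscles: tuple[int, ...]
    gain: float  # modulation depth (SNR-like, dimensionless)

    def validate(self, nyquist: float) -> None:
        if not (0.0 < self.f_lo < self.f_hi < nyquist):
            raise ValueError(
                f"band ({self.f_lo}, {self.f_hi}) Hz outside (0, {nyquist})"
            )


@dataclass
class GroundTruth:
    """Planted parameters of one synthetic trial (or a whole study)."""

    synergy_weights: np.ndarray  # (26, m_true), non-negative
    activation_peaks: np.ndarray  # (m_true,) % gait cycle of waveform peak
    activation_widths: np.ndarray  # (m_true,) % gait cycle
    common_input_bands: list[CommonInputBand] = field(default_factory=list)
    modes: dict = field(default_factory=dict)  # (subject, speed) -> label
    stride_times: np.ndarray = field(default_factory=lambda: np.array([]))
    heartbeat_rate: float = 1.2
    heartbeat_amp: float = 0.0
    seed: int = 0

    def validate(self, fs: float = EMG_FS) -> None:
        w = np.asarray(self.synergy_weights)
        if np.any(w < 0):
            raise ValueError("planted synergy weights must be non-negative")
        for band in self.common_input_bands:
            band.validate(fs / 2.0)
        st = np.asarray(self.stride_times)
        if st.size >= 2 and np.any(np.diff(st) <= 0):
            raise ValueError("stride_times must be strictly increasing")


@dataclass
class Recording:
    """One subject x speed trial."""

    subject: int
    speed: float
    emg: np.ndarray  # (samples, 26)
    fs_emg: float
    grf: np.ndarray  # (samples,) at fs_kin
    arm: np.ndarray
    leg: np.ndarray
    fs_kin: float
    ground_truth: GroundTruth | None = None

    @property
    def duration(self) -> float:
        return self.emg.shape[0] / self.fs_emg


# --------------------------------------------------------------------------
# planted defaults
# --------------------------------------------------------------------------

def default_planted_synergies(
    m_true: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint-support weights with near-equal Frobenius contributions.

    26 muscles are split into ``m_true`` contiguous groups; weights are
    uniform in [0.5, 1] inside the group and 0 outside, then rescaled so all
    rank-1 terms carry equal energy.  Column norm 0.5 puts a 0.05-sd noise
    floor at ~13% of the Frobenius norm, so the 80%/1.5% rank rule lands on
    the planted rank by construction.
    """
    rng = np.random.default_rng(seed)
    bounds = np.linspace(0, N_MUSCLES, m_true + 1).astype(int)
    W = np.zeros((N_MUSCLES, m_true))
    for s in range(m_true):
        lo, hi = bounds[s], bounds[s + 1]
        W[lo:hi, s] = rng.uniform(0.5, 1.0, size=hi - lo)
        W[:, s] *= 0.5 / np.linalg.norm(W[:, s])
    peaks = np.linspace(5.0, 85.0, m_true) + rng.uniform(-2, 2, m_true)
    widths = np.full(m_true, 8.0)
    return W, peaks, widths


def make_ground_truth(
    m_true: int = 5,
    common_input_bands: list[CommonInputBand] | None = None,
    heartbeat_amp: float = 0.0,
    heartbeat_rate: float = 1.2,
    seed: int = 0,
) -> GroundTruth:
    W, peaks, widths = default_planted_synergies(m_true, seed)
    gt = GroundTruth(
        synergy_weights=W,
        activation_peaks=peaks,
        activation_widths=widths,
        common_input_bands=list(common_input_bands or []),
        heartbeat_rate=heartbeat_rate,
        heartbeat_amp=heartbeat_amp,
        seed=seed,
    )
    gt.validate()
    return gt


def planted_activation(phase: np.ndarray, peak_pct: float, width_pct: float) -> np.ndarray:
    """Periodic Gaussian bump on the gait-cycle circle; phase in [0, 1)."""
    d = phase - peak_pct / 100.0
    d = (d + 0.5) % 1.0 - 0.5  # circular distance
    return np.exp(-0.5 * (d / (width_pct / 100.0)) ** 2)


# --------------------------------------------------------------------------
# kinematics + GRF
# --------------------------------------------------------------------------

def generate_kinematics(
    mode: str,
    stride_period: float,
    n_strides: int,
    noise_sd: float = 0.0,
    seed: int | None = None,
    fs: float = KIN_FS,
) -> dict:
    """Arm/leg anterior-posterior traces and a GRF trace with known onsets.

    The leg oscillates at the stride frequency; the arm at twice that
    frequency for mode '2:1', at the stride frequency for '1:1', and with a
    linearly drifting frequency (2x -> 1x) for the transition 'T'.  The GRF
    is the right-leg vertical force: one smoothed stance pulse (60% duty)
    per stride whose onsets are returned as ground-truth heel strikes.
    """
    if mode not in MODES:
        raise ValueError(f"unknown coordination mode {mode!r}; expected one of {MODES}")
    if n_strides < 2:
        raise ValueError("need at least 2 strides")
    if stride_period <= 0:
        raise ValueError("stride_period must be positive")

    rng = np.random.default_rng(seed)
    duration = n_strides * stride_period
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    f_leg = 1.0 / stride_period

    leg_phase = 2 * np.pi * f_leg * t
    if mode == "2:1":
        arm_phase = 2 * np.pi * (2 * f_leg) * t
    elif mode == "1:1":
        arm_phase = 2 * np.pi * f_leg * t
    else:  # 'T': instantaneous arm frequency sweeps 2f -> 1f
        arm_phase = 2 * np.pi * (2 * f_leg * t - f_leg * t**2 / (2 * duration))

    leg = np.sin(leg_phase) + noise_sd * rng.standard_normal(n)
    arm = np.sin(arm_phase) + noise_sd * rng.standard_normal(n)

    onsets = np.arange(n_strides) * stride_period
    grf = _grf_pulse_train(t, onsets, stance_frac=0.6, stride_period=stride_period)

    return {
        "t": t,
        "arm": arm,
        "leg": leg,
        "grf": grf,
        "fs": fs,
        "heel_strikes": onsets,
        "mode": mode,
    }


def _grf_pulse_train(
    t: np.ndarray, onsets: np.ndarray, stance_frac: float, stride_period: float,
    height: float = 100.0,
) -> np.ndarray:
    """Smoothed rectangular stance pulses; sharp onset so the 8%-of-mean
    threshold is crossed within one sample of the true onset."""
    fs = 1.0 / (t[1] - t[0])
    ramp = 2.0 / fs  # 2-sample raised-cosine edges
    stance = stance_frac * stride_period
    grf = np.zeros_like(t)
    for t0 in onsets:
        rel = t - t0
        in_rise = (rel >= 0) & (rel < ramp)
        in_flat = (rel >= ramp) & (rel < stance - ramp)
        in_fall = (rel >= stance - ramp) & (rel < stance)
        grf[in_rise] += height * 0.5 * (1 - np.cos(np.pi * rel[in_rise] / ramp))
        grf[in_flat] += height
        grf[in_fall] += height * 0.5 * (
            1 - np.cos(np.pi * (stance - rel[in_fall]) / ramp)
        )
    return grf


# --------------------------------------------------------------------------
# EMG
# --------------------------------------------------------------------------

def generate_emg(
    gt: GroundTruth,
    duration: float,
    fs: float = EMG_FS,
    noise_sd: float = 0.05,
    baseline: float = 0.02,
    seed: int | None = None,
) -> np.ndarray:
    """Multichannel EMG: planted-synergy envelopes amplitude-modulating
    broadband carriers, plus band-limited common-input modulation, channel
    noise, and an optional heartbeat artifact.

    Returns an (samples, 26) array.
    """
    gt.validate(fs)
    st = np.asarray(gt.stride_times, dtype=float)
    if st.size < 3 or st[-1] - st[0] <= 0:
        raise ValueError("ground truth must carry >= 3 stride times")
    if duration < 2 * np.median(np.diff(st)):
        raise ValueError("duration must cover at least 2 strides")

    rng = np.random.default_rng(seed if seed is not None else gt.seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    # piecewise-linear gait phase in [0, 1) from the stride times
    phase = np.interp(t, st, np.arange(st.size), left=0.0, right=st.size - 1.0) % 1.0

    W = np.asarray(gt.synergy_weights, dtype=float)
    m = W.shape[1]
    acts = np.stack(
        [
            planted_activation(phase, gt.activation_peaks[s], gt.activation_widths[s])
            for s in range(m)
        ]
    )  # (m, n)
    envelopes = W @ acts + baseline  # (26, n)

    # band-limited common-input modulations (shared across the subset)
    modulation = np.ones((N_MUSCLES, n))
    for band in gt.common_input_bands:
        shared = rng.standard_normal(n)
        sos = signal.butter(4, [band.f_lo, band.f_hi], "bandpass", fs=fs, output="sos")
        z = signal.sosfiltfilt(sos, shared)
        z /= np.std(z) + 1e-30
        for ch in band.muscles:
            modulation[ch] += band.gain * z
    np.clip(modulation, 0.0, None, out=modulation)

    carriers = rng.standard_normal((N_MUSCLES, n))
    emg = envelopes * modulation * carriers
    emg += noise_sd * rng.standard_normal((N_MUSCLES, n))

    # heartbeat artifact: spike train at heartbeat_rate, rank-1 across channels
    gains = rng.uniform(0.3, 1.0, N_MUSCLES)
    if gt.heartbeat_amp != 0.0:
        beat = _heartbeat_wave(t, gt.heartbeat_rate)
        emg += gt.heartbeat_amp * gains[:, None] * beat[None, :]

    return emg.T  # (samples, 26)


def _heartbeat_wave(t: np.ndarray, rate_hz: float) -> np.ndarray:
    """QRS-like train: Ricker wavelets repeating at the heart rate."""
    period = 1.0 / rate_hz
    tau = (t % period) - period / 2.0
    sigma = 0.02  # ~20 ms complex
    x = tau / sigma
    return (1 - x**2) * np.exp(-0.5 * x**2)


# --------------------------------------------------------------------------
# whole trials and studies
# --------------------------------------------------------------------------

def stride_period_for_speed(speed_kmh: float) -> float:
    """Stride period shrinking with treadmill speed (2.2 s @1 km/h, 1.1 s @4)."""
    return 1.1 + 1.1 * (4.0 - speed_kmh) / 3.0


def default_mode(speed_kmh: float) -> str:
    if speed_kmh < 1.5:
        return "2:1"
    if speed_kmh < 2.5:
        return "T"
    return "1:1"


def generate_trial(
    subject: int,
    speed: float,
    mode: str,
    gt_template: GroundTruth,
    n_strides: int = 15,
    kin_noise_sd: float = 0.05,
    emg_noise_sd: float = 0.05,
    seed: int | None = None,
) -> Recording:
    """One Recording with a trial-specific GroundTruth (stride times, mode)."""
    period = stride_period_for_speed(speed)
    ss = np.random.SeedSequence(
        seed if seed is not None else gt_template.seed, spawn_key=(subject, int(speed * 10))
    )
    kin_seed, emg_seed = ss.generate_state(2)
    kin = generate_kinematics(mode, period, n_strides, kin_noise_sd, seed=kin_seed)
    # stride times include the final stride end so phase covers the trial
    st = np.append(kin["heel_strikes"], n_strides * period)
    gt = dataclasses.replace(
        gt_template,
        stride_times=st,
        modes={(subject, speed): mode},
        seed=int(emg_seed),
    )
    emg = generate_emg(gt, duration=n_strides * period, noise_sd=emg_noise_sd, seed=emg_seed)
    return Recording(
        subject=subject,
        speed=speed,
        emg=emg,
        fs_emg=EMG_FS,
        grf=kin["grf"],
        arm=kin["arm"],
        leg=kin["leg"],
        fs_kin=kin["fs"],
        ground_truth=gt,
    )


def generate_study(config: dict) -> tuple[list[Recording], GroundTruth]:
    """Generate a study of ``n_subjects`` x ``speeds`` trials.

    Config keys: n_subjects, speeds (list of km/h), seed, n_strides,
    mode_table (optional {(subject, speed): label} or {speed: label}),
    m_true, common_input_bands, heartbeat_amp, kin_noise_sd, emg_noise_sd,
    out_dir (optional; write trial files + ground-truth sidecar).
    """
    n_subjects = int(config["n_subjects"])
    speeds = [float(s) for s in config["speeds"]]
    if n_subjects < 1 or not speeds:
        raise ValueError("study needs at least one subject and one speed")
    seed = int(config.get("seed", 0))
    n_strides = int(config.get("n_strides", 15))
    mode_table = config.get("mode_table", {})
    bands = [
        b if isinstance(b, CommonInputBand) else CommonInputBand(*b)
        for b in config.get("common_input_bands", [])
    ]
    gt_template = make_ground_truth(
        m_true=int(config.get("m_true", 5)),
        common_input_bands=bands,
        heartbeat_amp=float(config.get("heartbeat_amp", 0.0)),
        seed=seed,
    )

    recordings = []
    modes: dict = {}
    for subject in range(1, n_subjects + 1):
        for speed in speeds:
            mode = (
                mode_table.get((subject, speed))
                or mode_table.get(speed)
                or default_mode(speed)
            )
            rec = generate_trial(
                subject,
                speed,
                mode,
                gt_template,
                n_strides=n_strides,
                kin_noise_sd=float(config.get("kin_noise_sd", 0.05)),
                emg_noise_sd=float(config.get("emg_noise_sd", 0.05)),
                seed=seed,
            )
            recordings.append(rec)
            modes[(subject, speed)] = mode

    study_gt = dataclasses.replace(gt_template, modes=modes)
    out_dir = config.get("out_dir")
    if out_dir:
        write_study(recordings, study_gt, out_dir)
    return recordings, study_gt


# --------------------------------------------------------------------------
# planted coherence matrices (for frequency-component NMF tests)
# --------------------------------------------------------------------------

def planted_coherence_matrix(
    bands: list[tuple[float, float]] | None = None,
    freqs: np.ndarray | None = None,
    n_cols: int = 300,
    signal_frac: float = 0.6,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[tuple[float, float]]]:
    """Frequency x column coherence matrix with planted band components.

    Each column is dominated by one band; sparse non-negative noise (like
    empirically masked coherence, where most bins are exact zeros) is scaled
    so the planted part carries ``signal_frac`` of the squared Frobenius
    norm.  With the default 0.6 the profile mirrors noisy empirical
    coherence, where three components explain ~57%.

    Returns (C, column band labels, bands).
    """
    if bands is None:
        bands = [(4.0, 8.0), (8.0, 22.0), (22.0, 60.0)]
    if freqs is None:
        freqs = np.arange(4.0, 61.0)
    rng = np.random.default_rng(seed)
    profiles = []
    for f_lo, f_hi in bands:
        # FWHM ~ band width, so the half-max dominant band matches the plant
        p = np.exp(
            -0.5 * ((freqs - (f_lo + f_hi) / 2) / ((f_hi - f_lo) / 3.0)) ** 2
        )
        profiles.append(p / np.linalg.norm(p))
    P = np.stack(profiles, axis=1)  # (f, n_bands)
    labels = rng.integers(0, len(bands), size=n_cols)
    Wcols = np.zeros((len(bands), n_cols))
    for c, b in enumerate(labels):
        Wcols[b, c] = rng.uniform(0.5, 1.5)
    C_sig = P @ Wcols
    # sparse exponential noise: its mean carries almost no rank-1 energy
    mask = rng.random(C_sig.shape) < 0.1
    noise = mask * rng.exponential(1.0, C_sig.shape)
    noise *= np.linalg.norm(C_sig) / (np.linalg.norm(noise) + 1e-30) * np.sqrt(
        (1 - signal_frac) / signal_frac
    )
    return C_sig + noise, labels, bands


# --------------------------------------------------------------------------
# file I/O (long-format delimited text + JSON ground-truth sidecar)
# --------------------------------------------------------------------------

def write_trial(rec: Recording, path: str | Path) -> None:
    """Write one trial as long-format TSV: time_s, channel, value."""
    import pandas as pd

    path = Path(path)
    frames = []
    t_emg = np.arange(rec.emg.shape[0]) / rec.fs_emg
    for j, name in enumerate(MUSCLES):
        frames.append(
            pd.DataFrame({"time_s": t_emg, "channel": name, "value": rec.emg[:, j]})
        )
    t_kin = np.arange(rec.grf.shape[0]) / rec.fs_kin
    for name, trace in (("GRF", rec.grf), ("ARM_AP", rec.arm), ("LEG_AP", rec.leg)):
        frames.append(pd.DataFrame({"time_s": t_kin, "channel": name, "value": trace}))
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_trial(path: str | Path, meta: dict | None = None) -> Recording:
    """Read a long-format trial TSV back into a Recording."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    emg_cols = []
    for name in MUSCLES:
        emg_cols.append(df.loc[df["channel"] == name, "value"].to_numpy())
    emg = np.stack(emg_cols, axis=1)
    grf = df.loc[df["channel"] == "GRF", "value"].to_numpy()
    arm = df.loc[df["channel"] == "ARM_AP", "value"].to_numpy()
    leg = df.loc[df["channel"] == "LEG_AP", "value"].to_numpy()
    t_emg = df.loc[df["channel"] == MUSCLES[0], "time_s"].to_numpy()
    t_kin = df.loc[df["channel"] == "GRF", "time_s"].to_numpy()
    meta = meta or {}
    return Recording(
        subject=int(meta.get("subject", 0)),
        speed=float(meta.get("speed", 0.0)),
        emg=emg,
        fs_emg=1.0 / np.median(np.diff(t_emg)),
        grf=grf,
        arm=arm,
        leg=leg,
        fs_kin=1.0 / np.median(np.diff(t_kin)),
    )


def write_study(recordings: list[Recording], gt: GroundTruth, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        write_trial(rec, out_dir / f"trial_s{rec.subject:02d}_v{rec.speed:.1f}.tsv")
    sidecar = {
        "synergy_weights": np.asarray(gt.synergy_weights).tolist(),
        "activation_peaks": np.asarray(gt.activation_peaks).tolist(),
        "activation_widths": np.asarray(gt.activation_widths).tolist(),
        "common_input_bands": [
            {"f_lo": b.f_lo, "f_hi": b.f_hi, "muscles": list(b.muscles), "gain": b.gain}
            for b in gt.common_input_bands
        ],
        "modes": {f"{s}|{v}": m for (s, v), m in gt.modes.items()},
        "heartbeat_rate": gt.heartbeat_rate,
        "heartbeat_amp": gt.heartbeat_amp,
        "seed": gt.seed,
        "muscles": MUSCLES,
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(sidecar, indent=1))
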