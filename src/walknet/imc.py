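"""Bias-corrected, significance-masked intermuscular coherence and its
decomposition into frequency components.

Squared coherence C2 = |Pxy|^2 / (Pxx Pyy) is estimated with Welch's
periodogram (Hamming taper, 200 ms, ~50% overlap, FFT zero-padded to 256
samples -> 1 Hz bins at 256 Hz).  The estimate is corrected against a
zero-coherence null built from phase-randomized surrogates: the surrogate
mean per bin normalizes the raw value, 2*C2_raw/null_mean is referred to a
chi-squared distribution with two degrees of freedom, bins below the
alpha = 0.05 quantile are set to exactly 0, and surviving bins are reported
bias-subtracted (C2_raw - null_mean, clipped at 0).

Corrected spectra for all 325 muscle pairs are stacked into an
f x (SC * 325) matrix and decomposed by the same NMF engine as the synergy
analysis, with adjusted rank cutoffs (55% / 4%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.stats import chi2

from . import synergy as _synergy
from .muscles import N_MUSCLES, pair_index

__all__ = [
    "CoherenceSet",
    "CoherenceComponents",
    "WelchParams",
    "prepare",
    "welch_coherence",
    "surrogate_correct",
    "build_coherence_set",
    "nmf_frequency_components",
    "lowfreq_variant",
]

TARGET_FS = 256.0


@dataclass
class WelchParams:
    fs: float = TARGET_FS
    nperseg: int = 51  # 200 ms Hamming taper at 256 Hz
    nfft: int = 256  # zero-padded -> 1 Hz bins
    hop: int = 26  # ~50% overlap

    @classmethod
    def standard(cls, fs: float = TARGET_FS) -> "WelchParams":
        nperseg = int(round(0.2 * fs))
        return cls(fs=fs, nperseg=nperseg, nfft=max(256, nperseg), hop=(nperseg + 1) // 2)

    @classmethod
    def lowfreq(cls, fs: float = TARGET_FS, taper_s: float = 5.0) -> "WelchParams":
        nperseg = int(round(taper_s * fs))
        return cls(fs=fs, nperseg=nperseg, nfft=nperseg, hop=nperseg // 2)

    @property
    def freqs(self) -> np.ndarray:
        return np.fft.rfftfreq(self.nfft, d=1.0 / self.fs)

    def n_segments(self, n: int) -> int:
        if n < self.nperseg:
            return 0
        return 1 + (n - self.nperseg) // self.hop


@dataclass
class CoherenceSet:
    freqs: np.ndarray  # analysis-band frequency grid (Hz)
    C2: np.ndarray  # (n_freqs, SC * 325) corrected squared coherence
    pairs: list  # [(i, j), ...] i < j over muscles
    columns: list  # [(subject, condition, (i, j)), ...] per C2 column
    band: tuple = (4.0, 60.0)


@dataclass
class CoherenceComponents:
    W: np.ndarray  # (n_freqs, m) spectral profiles
    A: np.ndarray  # (m, n_columns) weights
    m: int
    lambda_profile: dict
    lambda_total: float
    dominant_bands: list = field(default_factory=list)  # [(f_lo, f_hi), ...]
    freqs: np.ndarray | None = None


# --------------------------------------------------------------------------
# preparation
# --------------------------------------------------------------------------

def prepare(
    segments: list[np.ndarray], fs_in: float, target_fs: float = TARGET_FS
) -> np.ndarray:
    """Anti-alias resample each rectified-EMG segment to ``target_fs``,
    mean-center per segment and channel, and concatenate."""
    if not segments:
        raise ValueError("empty condition: nothing to concatenate")
    from fractions import Fraction

    frac = Fraction(target_fs / fs_in).limit_denominator(1000)
    out = []
    for seg in segments:
        seg = np.asarray(seg, dtype=float)
        if seg.ndim == 1:
            seg = seg[:, None]
        if frac != 1:
            seg = signal.resample_poly(seg, frac.numerator, frac.denominator, axis=0)
        out.append(seg - seg.mean(axis=0, keepdims=True))
    return np.concatenate(out, axis=0)


# --------------------------------------------------------------------------
# Welch machinery (vectorized over channels)
# --------------------------------------------------------------------------

def _segment_ffts(x: np.ndarray, p: WelchParams) -> np.ndarray:
    """Windowed segment rFFTs.  x: (n,) or (n, ch) -> (ch, K, n_bins)."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    k = p.n_segments(n)
    if k < 1:
        raise ValueError("signal shorter than one taper")
    win = signal.get_window("hamming", p.nperseg)
    starts = np.arange(k) * p.hop
    # (K, nperseg, ch) view -> detrend per segment, window, FFT
    idx = starts[:, None] + np.arange(p.nperseg)[None, :]
    segs = x[idx]  # (K, nperseg, ch)
    segs = segs - segs.mean(axis=1, keepdims=True)
    segs = segs * win[None, :, None]
    F = np.fft.rfft(segs, n=p.nfft, axis=1)  # (K, n_bins, ch)
    return np.moveaxis(F, 2, 0)  # (ch, K, n_bins)


def _coherence_from_ffts(Fx: np.ndarray, Fy: np.ndarray) -> np.ndarray:
    """Squared coherence from (K, n_bins) segment FFTs of x and y."""
    pxx = np.mean(np.abs(Fx) ** 2, axis=0)
    pyy = np.mean(np.abs(Fy) ** 2, axis=0)
    pxy = np.mean(Fx * np.conj(Fy), axis=0)
    denom = pxx * pyy
    c2 = np.zeros_like(pxx)
    ok = denom > 0
    if not np.all(ok):
        warnings.warn("zero-power bins: coherence set to 0 there", stacklevel=3)
    c2[ok] = np.abs(pxy[ok]) ** 2 / denom[ok]
    return c2


def welch_coherence(
    x: np.ndarray,
    y: np.ndarray,
    fs: float = TARGET_FS,
    params: WelchParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw squared coherence of two equal-length signals on the padded grid."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    p = params or WelchParams.standard(fs)
    if p.n_segments(x.size) < 10:
        raise ValueError("need at least 10 Welch segments")
    Fx = _segment_ffts(x, p)[0]
    Fy = _segment_ffts(y, p)[0]
    return p.freqs, _coherence_from_ffts(Fx, Fy)


def phase_randomize(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Surrogate with identical amplitude spectrum and uniform random phases.

    Works column-wise for 2-D input (samples x channels).
    """
    x = np.asarray(x, dtype=float)
    one_d = x.ndim == 1
    if one_d:
        x = x[:, None]
    n = x.shape[0]
    X = np.fft.rfft(x, axis=0)
    nb = X.shape[0]
    phases = rng.uniform(0, 2 * np.pi, size=(nb, x.shape[1]))
    phases[0] = 0.0
    if n % 2 == 0:
        phases[-1] = 0.0
    Xs = np.abs(X) * np.exp(1j * phases)
    out = np.fft.irfft(Xs, n=n, axis=0)
    return out[:, 0] if one_d else out


def surrogate_correct(
    x: np.ndarray,
    y: np.ndarray,
    fs: float = TARGET_FS,
    n_surrogates: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    params: WelchParams | None = None,
) -> dict:
    """Bias-correct and significance-mask one pair's squared coherence.

    The null mean per bin comes from phase-randomized surrogates of both
    signals, which preserve the power spectra (and the overlap correlation
    of the Welch segments) while destroying all coherence.

    Returns dict with freqs, corrected, raw, null_mean, significant (bool).
    """
    if n_surrogates < 20:
        warnings.warn("fewer than 20 surrogates: unstable null", stacklevel=2)
    p = params or WelchParams.standard(fs)
    freqs, raw = welch_coherence(x, y, fs=fs, params=p)
    rng = np.random.default_rng(seed)
    null = np.zeros_like(raw)
    for _ in range(n_surrogates):
        xs = phase_randomize(np.asarray(x, dtype=float).ravel(), rng)
        ys = phase_randomize(np.asarray(y, dtype=float).ravel(), rng)
        Fx = _segment_ffts(xs, p)[0]
        Fy = _segment_ffts(ys, p)[0]
        null += _coherence_from_ffts(Fx, Fy)
    null /= max(n_surrogates, 1)
    corrected, significant = _mask_against_null(raw, null, alpha)
    return {
        "freqs": freqs,
        "corrected": corrected,
        "raw": raw,
        "null_mean": null,
        "significant": significant,
    }


def _mask_against_null(
    raw: np.ndarray, null_mean: np.ndarray, alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    stat = np.zeros_like(raw)
    ok = null_mean > 0
    stat[ok] = 2.0 * raw[ok] / null_mean[ok]
    thr = chi2.ppf(1.0 - alpha, df=2)
    significant = stat >= thr
    corrected = np.where(significant, np.clip(raw - null_mean, 0.0, None), 0.0)
    return corrected, significant


# --------------------------------------------------------------------------
# coherence sets over the full montage
# --------------------------------------------------------------------------

def _corrected_pairs(
    X: np.ndarray,
    p: WelchParams,
    n_surrogates: int,
    alpha: float,
    rng: np.random.Generator,
    pairs: list[tuple[int, int]],
) -> np.ndarray:
    """Corrected C2 for all channel pairs of one (subject, condition) block.

    Vectorized: segment FFTs are computed once per channel per surrogate.
    Returns (n_bins, n_pairs).
    """
    def _all_pair_c2(F: np.ndarray) -> np.ndarray:
        """(ch, K, nb) segment FFTs -> (nb, n_pairs) squared coherence."""
        k = F.shape[1]
        pxx = np.mean(np.abs(F) ** 2, axis=1)  # (ch, nb)
        Fb = np.ascontiguousarray(F.transpose(2, 0, 1))  # (nb, ch, K)
        pxy = Fb @ np.conj(Fb.transpose(0, 2, 1)) / k  # (nb, ch, ch)
        ii = np.array([i for i, _ in pairs])
        jj = np.array([j for _, j in pairs])
        num = np.abs(pxy[:, ii, jj].T) ** 2  # (n_pairs, nb)
        denom = pxx[ii] * pxx[jj]
        c2 = np.zeros_like(num)
        ok = denom > 0
        c2[ok] = num[ok] / denom[ok]
        return c2.T

    raw = _all_pair_c2(_segment_ffts(X, p))
    null = np.zeros_like(raw)
    for _ in range(n_surrogates):
        Xs = phase_randomize(X, rng)
        null += _all_pair_c2(_segment_ffts(Xs, p))
    null /= max(n_surrogates, 1)
    corrected = np.empty_like(raw)
    for c in range(raw.shape[1]):
        corrected[:, c], _ = _mask_against_null(raw[:, c], null[:, c], alpha)
    return corrected


def build_coherence_set(
    prepared: dict,
    band: tuple[float, float] = (4.0, 60.0),
    fs: float = TARGET_FS,
    n_surrogates: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    params: WelchParams | None = None,
    subject_order: list | None = None,
    condition_order: tuple = ("2:1", "T", "1:1"),
) -> CoherenceSet:
    """Corrected coherence spectra for every muscle pair, stacked into an
    f x (SC*325) matrix.

    ``prepared`` maps (subject, condition) -> (samples, 26) mean-centered
    signals at ``fs``.  Column order: subject-major, then condition, then
    pair (i < j) lexicographic.
    """
    p = params or WelchParams.standard(fs)
    pairs = pair_index(N_MUSCLES)
    freqs = p.freqs
    sel = (freqs >= band[0]) & (freqs <= band[1])
    subjects = subject_order or sorted({s for s, _ in prepared})
    cols, labels = [], []
    root = np.random.SeedSequence(seed)
    for subject in subjects:
        for cond in condition_order:
            if (subject, cond) not in prepared:
                continue
            X = np.asarray(prepared[(subject, cond)], dtype=float)
            if X.shape[1] != N_MUSCLES:
                raise ValueError(
                    f"expected {N_MUSCLES} channels, got {X.shape[1]} "
                    f"for {(subject, cond)}"
                )
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(subjects.index(subject),
                                                        condition_order.index(cond)))
            )
            corr = _corrected_pairs(X, p, n_surrogates, alpha, rng, pairs)
            cols.append(corr[sel])
            labels.extend((subject, cond, pr) for pr in pairs)
    if not cols:
        raise ValueError("no (subject, condition) blocks provided")
    C2 = np.concatenate(cols, axis=1)
    return CoherenceSet(freqs=freqs[sel], C2=C2, pairs=pairs, columns=labels, band=band)


# --------------------------------------------------------------------------
# frequency-component NMF
# --------------------------------------------------------------------------

def dominant_band(profile: np.ndarray, freqs: np.ndarray) -> tuple[float, float]:
    """Contiguous run of bins >= 50% of the profile max, containing the max.

    Edges are extended by half a bin on each side (a bin at f covers
    f +/- df/2).
    """
    profile = np.asarray(profile, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    peak = int(np.argmax(profile))
    above = profile >= 0.5 * profile.max()
    lo = peak
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = peak
    while hi < profile.size - 1 and above[hi + 1]:
        hi += 1
    half = 0.5 * float(np.median(np.diff(freqs))) if freqs.size > 1 else 0.0
    return float(freqs[lo]) - half, float(freqs[hi]) + half


def nmf_frequency_components(
    cset: CoherenceSet | np.ndarray,
    lambda_cutoff: float = 55.0,
    delta_cutoff: float = 4.0,
    max_rank: int = 10,
    n_restarts: int = 10,
    seed: int = 0,
    freqs: np.ndarray | None = None,
) -> CoherenceComponents:
    """Decompose the f x (SC*325) corrected-coherence matrix with the synergy
    NMF engine and the adjusted rank cutoffs."""
    if isinstance(cset, CoherenceSet):
        C = cset.C2
        freqs = cset.freqs
    else:
        C = np.asarray(cset, dtype=float)
        if freqs is None:
            freqs = np.arange(C.shape[0], dtype=float)
    criteria = _synergy.RankSelectionCriteria(
        lambda_cutoff=lambda_cutoff,
        delta_lambda_cutoff=delta_cutoff,
        max_rank=max_rank,
        n_restarts=n_restarts,
        seed=seed,
    )
    # synergy.select_rank factorizes X^T; feed C^T so W spans frequencies
    m, profile, factors = _synergy.select_rank(C.T, criteria)
    W, A = factors[m]
    bands = [dominant_band(W[:, s], freqs) for s in range(m)]
    order = np.argsort([b[0] for b in bands])
    return CoherenceComponents(
        W=W[:, order],
        A=A[order, :],
        m=m,
        lambda_profile=profile,
        lambda_total=profile[m],
        dominant_bands=[bands[o] for o in order],
        freqs=np.asarray(freqs),
    )


def lowfreq_variant(
    prepared: dict,
    fs: float = TARGET_FS,
    taper_s: float = 5.0,
    band: tuple[float, float] = (0.6, 4.0),
    n_surrogates: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    **kwargs,
) -> CoherenceSet:
    """Same coherence pipeline with a 5 s Hamming taper over 0.6-4 Hz, for
    comparison with the synergy networks."""
    p = WelchParams.lowfreq(fs, taper_s)
    for key, X in prepared.items():
        if np.asarray(X).shape[0] < 2 * p.nperseg:
            raise ValueError(f"record {key} shorter than 2 tapers ({2 * taper_s} s)")
    return build_coherence_set(
        prepared, band=band, fs=fs, n_surrogates=n_surrogates, alpha=alpha,
        seed=seed, params=p, **kwargs,
    )
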