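"""Statistics on 1-D gait-cycle waveforms and network metrics.

Waveform comparisons between coordination modes use pointwise paired
t-statistics with cluster-level inference by sign-flip permutation of the
subject differences (max-cluster-mass null).  Network metrics are compared
with a repeated-measures ANOVA (subject as random factor) plus paired
post-hoc t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "WaveformComparison",
    "bonferroni_alpha",
    "spm_paired",
    "metric_anova",
]


@dataclass
class Cluster:
    start_pct: float
    end_pct: float
    mass: float
    p_value: float


@dataclass
class WaveformComparison:
    alpha: float
    amplitude_clusters: list = field(default_factory=list)
    normalized_clusters: list = field(default_factory=list)


def bonferroni_alpha(
    base: float = 0.05, n_condition_pairs: int = 3, n_synergies: int = 5
) -> float:
    """base / (condition pairs x synergies); 0.05/(3*5) = 1/300."""
    if n_condition_pairs < 1 or n_synergies < 1:
        raise ValueError("comparison counts must be >= 1")
    return base / (n_condition_pairs * n_synergies)


# --------------------------------------------------------------------------
# 1-D sign-flip permutation SPM
# --------------------------------------------------------------------------

def _t_map(diffs: np.ndarray) -> np.ndarray:
    """Pointwise one-sample t statistic of (subjects x N) differences."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    sd = np.where(sd == 0, np.inf, sd)
    return mean / (sd / np.sqrt(n))


def _clusters(tmap: np.ndarray, t_crit: float) -> list[tuple[int, int, float]]:
    above = np.abs(tmap) > t_crit
    out = []
    start = None
    for i, a in enumerate(above):
        if a and start is None:
            start = i
        elif not a and start is not None:
            out.append((start, i - 1, float(np.abs(tmap[start:i]).sum())))
            start = None
    if start is not None:
        out.append((start, above.size - 1, float(np.abs(tmap[start:]).sum())))
    return out


def _cluster_test(
    diffs: np.ndarray, alpha: float, n_perm: int, rng: np.random.Generator
) -> list[Cluster]:
    n_sub, n_pts = diffs.shape
    t_crit = stats.t.ppf(1 - alpha / 2, df=n_sub - 1)
    observed = _clusters(_t_map(diffs), t_crit)
    if not observed:
        return []
    # sign-flip null of the max cluster mass (vectorized over permutations)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    null_max = np.zeros(n_perm)
    for r in range(n_perm):
        tmap = _t_map(diffs * flips[r][:, None])
        cl = _clusters(tmap, t_crit)
        null_max[r] = max((m for *_, m in cl), default=0.0)
    out = []
    scale = 100.0 / (n_pts - 1)
    for start, end, mass in observed:
        p = (np.sum(null_max >= mass) + 1) / (n_perm + 1)
        if p <= alpha:
            out.append(Cluster(start * scale, end * scale, mass, float(p)))
    return out


def spm_paired(
    waveforms_a: np.ndarray,
    waveforms_b: np.ndarray,
    alpha: float,
    n_perm: int = 1000,
    seed: int = 0,
) -> WaveformComparison:
    """Paired comparison of two (subjects x N) waveform sets along the gait
    cycle, run on raw amplitudes and on per-subject max-normalized waveforms.
    """
    A = np.asarray(waveforms_a, dtype=float)
    B = np.asarray(waveforms_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError("condition waveform arrays must have equal shape")
    if A.shape[0] < 3:
        raise ValueError("need at least 3 matched subjects")
    rng = np.random.default_rng(seed)
    amp = _cluster_test(A - B, alpha, n_perm, rng)

    def _maxnorm(X):
        peaks = np.abs(X).max(axis=1, keepdims=True)
        peaks = np.where(peaks == 0, 1.0, peaks)
        return X / peaks

    norm = _cluster_test(_maxnorm(A) - _maxnorm(B), alpha, n_perm, rng)
    return WaveformComparison(
        alpha=alpha, amplitude_clusters=amp, normalized_clusters=norm
    )


# --------------------------------------------------------------------------
# repeated-measures ANOVA on network metrics
# --------------------------------------------------------------------------

def metric_anova(
    values: np.ndarray,
    alpha: float = 0.05,
    posthoc_alpha: float = 0.005,
    condition_labels: list | None = None,
) -> dict:
    """Repeated-measures ANOVA (subject random factor) on a complete
    (subjects x conditions) table, with paired post-hoc t-tests.

    F = MS_condition / MS_(condition x subject); for 2 conditions this equals
    the squared paired t statistic.
    """
    Y = np.asarray(values, dtype=float)
    if Y.ndim != 2:
        raise ValueError("values must be a subjects x conditions table")
    n_sub, n_cond = Y.shape
    if n_cond < 2:
        raise ValueError("need at least 2 conditions")
    grand = Y.mean()
    cond_means = Y.mean(axis=0)
    subj_means = Y.mean(axis=1)
    ss_cond = n_sub * np.sum((cond_means - grand) ** 2)
    resid = Y - cond_means[None, :] - subj_means[:, None] + grand
    ss_err = np.sum(resid**2)
    df_cond = n_cond - 1
    df_err = (n_cond - 1) * (n_sub - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    tiny = 1e-12 * max(float(np.sum((Y - grand) ** 2)), 1.0)
    if ss_cond <= tiny:  # no condition effect (incl. numerically zero)
        F, p = 0.0, 1.0
    elif ss_err <= tiny:
        F, p = float("inf"), 0.0
    else:
        F = ms_cond / ms_err
        p = float(stats.f.sf(F, df_cond, df_err))

    labels = condition_labels or list(range(n_cond))
    posthoc = []
    for i in range(n_cond):
        for j in range(i + 1, n_cond):
            t, pt = stats.ttest_rel(Y[:, i], Y[:, j])
            posthoc.append(
                {
                    "pair": (labels[i], labels[j]),
                    "t": float(t),
                    "p": float(pt),
                    "significant": bool(pt <= posthoc_alpha),
                }
            )
    return {
        "F": float(F),
        "df": (df_cond, df_err),
        "p": p,
        "significant": bool(p <= alpha),
        "posthoc": posthoc,
    }
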