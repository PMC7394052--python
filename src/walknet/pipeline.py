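"""End-to-end orchestration: synthesize (or ingest) a study, classify
coordination modes, preprocess EMG, fit synergies, estimate coherence,
build networks, and run the statistics, emitting one JSON-serializable
report bundle.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import emgprep, gaitkin, imc, musclenet, synergy, synthgen, waveformstats
from .muscles import MUSCLES

log = logging.getLogger("walknet")

#: Defaults follow the study's printed parameters; generator sizes are scaled
#: down so the demo runs on one CPU in minutes.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "n_subjects": 3,
    "speeds": [1.0, 2.0, 4.0],
    "n_strides": 15,
    "m_true": 5,
    "common_input_bands": [
        [5.0, 8.0, list(range(0, 8)), 0.6],
        [10.0, 20.0, list(range(8, 18)), 0.6],
        [25.0, 45.0, list(range(18, 26)), 0.6],
    ],
    "heartbeat_amp": 0.0,
    "kin_noise_sd": 0.05,
    "emg_noise_sd": 0.02,
    "stages": {"synergy": True, "coherence": True, "networks": True, "stats": True},
    "heartbeat_removal": False,
    "samples_per_stride": 200,
    "synergy_criteria": {
        "lambda_cutoff": 80.0,
        "delta_lambda_cutoff": 1.5,
        "max_rank": 8,
        "n_restarts": 5,
    },
    "coherence": {
        "band": [4.0, 60.0],
        "n_surrogates": 25,
        "alpha": 0.05,
        "target_fs": 256.0,
    },
    "classifier": {"delta": 0.15, "circvar_max": 0.2},
    "stats": {
        "base_alpha": 0.05,
        "n_perm": 500,
        "anova_alpha": 0.05,
        "posthoc_alpha": 0.005,
    },
}


def _merge(base: dict, override: dict | None) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        import yaml

        cfg = _merge(cfg, yaml.safe_load(Path(path).read_text()) or {})
    return _merge(cfg, overrides)


# --------------------------------------------------------------------------

def run_study(config: dict | None = None, out_dir: str | Path | None = None) -> dict:
    """Execute the full chain on a synthetic study; returns the report dict.

    Stage order: generate -> classify modes -> preprocess -> synergies (+
    synergy network) -> coherence (+ components + coherence networks +
    metrics) -> statistics.  Deterministic given config['seed'].
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    seed = int(cfg["seed"])
    report: dict = {"config": cfg, "stages": {}}

    try:
        recordings, gt = synthgen.generate_study(cfg)
    except Exception as exc:
        raise RuntimeError(f"stage 'generate' failed: {exc}") from exc
    report["stages"]["generate"] = {
        "n_trials": len(recordings),
        "true_modes": {f"{s}|{v}": m for (s, v), m in gt.modes.items()},
    }

    # ---- classify modes + heel strikes -----------------------------------
    try:
        modes, events = {}, {}
        evidences = {}
        for rec in recordings:
            ev = gaitkin.classify_mode(
                rec.arm, rec.leg, rec.fs_kin, **cfg["classifier"]
            )
            modes[(rec.subject, rec.speed)] = ev.label
            evidences[f"{rec.subject}|{rec.speed}"] = {
                "overlap_21": ev.overlap_21,
                "overlap_11": ev.overlap_11,
                "circvar_21": ev.circvar_21,
                "circvar_11": ev.circvar_11,
                "label": ev.label,
            }
            events[(rec.subject, rec.speed)] = gaitkin.detect_heel_strikes(
                rec.grf, rec.fs_kin
            )
    except Exception as exc:
        raise RuntimeError(f"stage 'classify' failed: {exc}") from exc
    report["stages"]["classify"] = {"modes": evidences}

    # ---- preprocess -------------------------------------------------------
    try:
        n = int(cfg["samples_per_stride"])
        stride_stacks, rect_by_trial = {}, {}
        for rec in recordings:
            raw = rec.emg
            if cfg["heartbeat_removal"]:
                raw = emgprep.remove_heartbeat(raw, rec.fs_emg, seed=seed)
            rect = emgprep.highpass_rectify(raw, rec.fs_emg)
            env = emgprep.envelope(rect, rec.fs_emg)
            ev = events[(rec.subject, rec.speed)]
            stride_stacks[(rec.subject, rec.speed)] = emgprep.time_normalize(
                env, ev, rec.fs_emg, n=n
            )
            rect_by_trial[(rec.subject, rec.speed)] = rect
        X = emgprep.amplitude_normalize_average_concat(stride_stacks, modes)
    except Exception as exc:
        raise RuntimeError(f"stage 'preprocess' failed: {exc}") from exc
    report["stages"]["preprocess"] = {
        "sc": X.sc,
        "rows": int(X.X.shape[0]),
        "index": [list(map(str, ix)) for ix in X.index],
    }

    # ---- synergies --------------------------------------------------------
    model = None
    if cfg["stages"]["synergy"]:
        try:
            criteria = synergy.RankSelectionCriteria(
                seed=seed, **cfg["synergy_criteria"]
            )
            model = synergy.fit(X.X, criteria, n=n)
        except Exception as exc:
            raise RuntimeError(f"stage 'synergy' failed: {exc}") from exc
        report["stages"]["synergy"] = {
            "m": model.m,
            "lambda_total": model.lambda_total,
            "lambda_per_synergy": model.lambda_per_synergy.tolist(),
            "lambda_profile": {str(k): v for k, v in model.lambda_profile.items()},
            "W": model.W.tolist(),
            "muscles": MUSCLES,
        }

    # ---- coherence --------------------------------------------------------
    components, cset = None, None
    if cfg["stages"]["coherence"]:
        try:
            ccfg = cfg["coherence"]
            prepared = {}
            for rec in recordings:
                key = (rec.subject, modes[(rec.subject, rec.speed)])
                prepared.setdefault(key, []).append(rect_by_trial[(rec.subject, rec.speed)])
            prepared = {
                key: imc.prepare(segs, fs_in=recordings[0].fs_emg,
                                 target_fs=ccfg["target_fs"])
                for key, segs in prepared.items()
            }
            cset = imc.build_coherence_set(
                prepared,
                band=tuple(ccfg["band"]),
                fs=ccfg["target_fs"],
                n_surrogates=int(ccfg["n_surrogates"]),
                alpha=float(ccfg["alpha"]),
                seed=seed,
            )
            components = imc.nmf_frequency_components(cset, seed=seed)
        except Exception as exc:
            raise RuntimeError(f"stage 'coherence' failed: {exc}") from exc
        report["stages"]["coherence"] = {
            "m": components.m,
            "lambda_total": components.lambda_total,
            "dominant_bands": components.dominant_bands,
            "lambda_profile": {str(k): v for k, v in components.lambda_profile.items()},
            "freqs": cset.freqs.tolist(),
        }

    # ---- networks ---------------------------------------------------------
    if cfg["stages"]["networks"] and model is not None:
        try:
            net_report = {}
            syn_net = musclenet.synergy_layers(model, n=n)
            syn_part = musclenet.communities(syn_net, seed=seed)
            net_report["synergy"] = {
                "n_layers": len(syn_net.layers),
                "communities": syn_part.membership.tolist(),
                "modularity_per_layer": syn_part.modularity_per_layer,
            }
            if components is not None:
                coh_net = musclenet.coherence_layers(components, cset)
                coh_thr, tau, stats_thr = musclenet.minimally_connect(coh_net)
                coh_part = musclenet.communities(coh_thr, seed=seed)
                metrics = {
                    lab: vars(musclenet.layer_metrics(L))
                    for lab, L in zip(coh_thr.layer_labels, coh_thr.layers)
                }
                net_report["coherence"] = {
                    "n_layers": len(coh_net.layers),
                    "threshold": tau,
                    "threshold_stats": stats_thr,
                    "communities": coh_part.membership.tolist(),
                    "modularity_per_layer": coh_part.modularity_per_layer,
                    "layer_metrics": metrics,
                }
        except Exception as exc:
            raise RuntimeError(f"stage 'networks' failed: {exc}") from exc
        report["stages"]["networks"] = net_report

    # ---- statistics -------------------------------------------------------
    if cfg["stages"]["stats"] and model is not None:
        try:
            report["stages"]["stats"] = _stats_stage(X, model, cfg, n, seed)
        except Exception as exc:
            raise RuntimeError(f"stage 'stats' failed: {exc}") from exc

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report


def _stats_stage(X, model, cfg, n, seed) -> dict:
    """Compare synergy waveforms between every pair of modes over the
    subjects exhibiting both."""
    scfg = cfg["stats"]
    sc_index = X.index  # [(subject, mode)]
    modes_present = sorted({m for _, m in sc_index})
    pairs = [
        (a, b)
        for i, a in enumerate(modes_present)
        for b in modes_present[i + 1:]
    ]
    alpha = waveformstats.bonferroni_alpha(
        scfg["base_alpha"], max(len(pairs), 1), max(model.m, 1)
    )
    out = {"alpha": alpha, "comparisons": []}
    A = model.A  # (m, SC*n)
    for mode_a, mode_b in pairs:
        subj_a = {s for s, m in sc_index if m == mode_a}
        subj_b = {s for s, m in sc_index if m == mode_b}
        matched = sorted(subj_a & subj_b)
        if len(matched) < 3:
            out["comparisons"].append(
                {"pair": [mode_a, mode_b], "skipped": "fewer than 3 matched subjects"}
            )
            continue
        for s in range(model.m):
            waves = {}
            for mode in (mode_a, mode_b):
                rows = []
                for subj in matched:
                    block = sc_index.index((subj, mode))
                    rows.append(A[s, block * n:(block + 1) * n])
                waves[mode] = np.stack(rows)
            cmp_ = waveformstats.spm_paired(
                waves[mode_a], waves[mode_b], alpha=alpha,
                n_perm=int(scfg["n_perm"]), seed=seed,
            )
            out["comparisons"].append(
                {
                    "pair": [mode_a, mode_b],
                    "synergy": s + 1,
                    "amplitude_clusters": [vars(c) for c in cmp_.amplitude_clusters],
                    "normalized_clusters": [vars(c) for c in cmp_.normalized_clusters],
                }
            )
    return out


# --------------------------------------------------------------------------
# ground-truth validation
# --------------------------------------------------------------------------

def cosine_match(W_true: np.ndarray, W_est: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal column assignment (Hungarian on cosine similarity); returns
    (per-column cosine similarities, column permutation of W_est)."""
    Wt = np.asarray(W_true, dtype=float)
    We = np.asarray(W_est, dtype=float)
    nt = Wt / (np.linalg.norm(Wt, axis=0, keepdims=True) + 1e-30)
    ne = We / (np.linalg.norm(We, axis=0, keepdims=True) + 1e-30)
    sim = nt.T @ ne  # (m_true, m_est)
    rows, cols = linear_sum_assignment(-sim)
    return sim[rows, cols], cols


def band_jaccard(band_a: tuple[float, float], band_b: tuple[float, float]) -> float:
    lo = max(band_a[0], band_b[0])
    hi = min(band_a[1], band_b[1])
    inter = max(0.0, hi - lo)
    union = max(band_a[1], band_b[1]) - min(band_a[0], band_b[0])
    return inter / union if union > 0 else 0.0


def validate_against_ground_truth(report: dict, gt: synthgen.GroundTruth) -> dict:
    """Recovery scorecard for a synthetic run: mode-label accuracy, synergy
    rank/weight recovery, coherence-band Jaccard."""
    if not gt.modes:
        raise ValueError("ground truth carries no planted modes: not a synthetic run")
    score: dict = {}

    pred = report["stages"]["classify"]["modes"]
    true_modes = report["stages"]["generate"]["true_modes"]
    hits = [pred[k]["label"] == v for k, v in true_modes.items()]
    score["mode_accuracy"] = float(np.mean(hits)) if hits else float("nan")

    if "synergy" in report["stages"]:
        syn = report["stages"]["synergy"]
        m_true = np.asarray(gt.synergy_weights).shape[1]
        score["rank_match"] = bool(syn["m"] == m_true)
        sims, _ = cosine_match(gt.synergy_weights, np.asarray(syn["W"]))
        score["weight_cosine"] = sims.tolist()

    if "networks" in report["stages"] and "synergy" in report["stages"]:
        from sklearn.metrics import adjusted_rand_score

        planted_groups = np.argmax(np.asarray(gt.synergy_weights), axis=1)
        membership = report["stages"]["networks"]["synergy"]["communities"]
        score["partition_ari"] = float(
            adjusted_rand_score(planted_groups, np.asarray(membership))
        )

    if "coherence" in report["stages"] and gt.common_input_bands:
        coh = report["stages"]["coherence"]
        jac = []
        for b in gt.common_input_bands:
            best = max(
                (band_jaccard((b.f_lo, b.f_hi), tuple(db))
                 for db in coh["dominant_bands"]),
                default=0.0,
            )
            jac.append(best)
        score["band_jaccard"] = jac
    return score
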