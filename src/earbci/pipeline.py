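"""End-to-end study runners: the EC/EO alpha-SNR study and the MA/LC
classification study, with reproducible per-subject simulation.

Each runner simulates a cohort of synthetic subjects (per-subject seeds
and mildly jittered effect sizes, so group tables have realistic
between-subject spread), pushes every subject through the conditioning
and analysis chain, and aggregates group-level tables and statistics.
Outputs (CSV tables, NPZ maps, JSON manifest with the full configuration
and seeds) are written when an output directory is given; reruns with
the same configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import cross_validate, default_bands
from .montage import build_default_montage, generate_ec_eo_schedule, generate_main_schedule
from .preprocessing import (bandpass, baseline_correct, downsample,
                            extract_epochs, reject_peak_to_peak,
                            rereference_car, rereference_ear)
from .simulate import SimulationConfig, inject_blinks, simulate_recording
from .spectral import ec_eo_snr, erders_map, roi_average_map
from .stats import bonferroni, friedman_test, wilcoxon_signed_rank

__all__ = ["RunConfig", "run_ec_eo_study", "run_ma_lc_study"]

log = logging.getLogger("earbci")


@dataclass
class RunConfig:
    """Validated parameters of a full study run (units: Hz, s, uV)."""

    n_subjects: int = 5
    seed: int = 0
    # simulation
    sim: dict = field(default_factory=dict)     # overrides for SimulationConfig
    subject_jitter: float = 0.10                # lognormal spread of effect gains
    blink_rate: float = 0.4                     # events/min injected pre-rejection
    blink_amplitude: float = 180.0
    # paradigm
    sessions: int = 5
    trials_per_cond: int = 10
    rest_range_s: tuple[float, float] = (10.0, 15.0)
    ec_eo_block_s: float = 30.0
    ec_eo_reps: int = 6
    # preprocessing
    band: tuple[float, float] = (1.0, 50.0)
    filter_order: int = 4
    target_fs: float = 200.0
    epoch_window: tuple[float, float] = (-2.0, 10.0)
    baseline: tuple[float, float] = (-2.0, 0.0)
    reject_threshold_task: float = 126.67
    reject_threshold_eceo: float = 196.0
    # analysis
    alpha_band: tuple[float, float] = (8.0, 13.0)
    stft_win_s: float = 1.0
    stft_overlap: float = 0.5
    n_keep: int = 2
    cv_folds: int = 10
    cv_reps: int = 10
    include_scalp: bool = False
    compute_maps: bool = True

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0 < self.band[0] < self.band[1]:
            raise ValueError("invalid analysis band")
        if self.reject_threshold_task <= 0 or self.reject_threshold_eceo <= 0:
            raise ValueError("rejection thresholds must be > 0")
        if self.cv_folds < 2 or self.cv_reps < 1:
            raise ValueError("invalid cross-validation setup")
        SimulationConfig(**{**self.sim, "seed": 0})     # validates overrides

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("rest_range_s", "band", "epoch_window", "baseline", "alpha_band"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _subject_sim_config(config: RunConfig, base_seed: int, rng) -> SimulationConfig:
    """Per-subject simulation config with jittered condition effect sizes."""
    overrides = dict(config.sim)
    sim = SimulationConfig(**{**overrides, "seed": base_seed})
    j = config.subject_jitter
    if j > 0:
        def jitter(g):
            return float(g ** (1.0 + j * rng.standard_normal())) if g != 1.0 else 1.0
        sim = dataclasses.replace(
            sim,
            ec_alpha_gain=jitter(sim.ec_alpha_gain),
            ma_alpha_ers=jitter(sim.ma_alpha_ers),
            lc_alpha_gain=jitter(sim.lc_alpha_gain),
            ma_beta_gamma_erd=min(jitter(sim.ma_beta_gamma_erd), 1.0),
        )
    return sim


def _write_manifest(out_dir: Path, config: RunConfig, study: str, extra=None) -> None:
    manifest = {
        "study": study,
        "earbci_version": __version__,
        "config": config.to_dict(),
        **(extra or {}),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def run_ec_eo_study(config: RunConfig, out_dir=None) -> dict:
    """Simulate the EC/EO cohort and compute the per-ROI alpha SNR table."""
    montage = build_default_montage()
    schedule = generate_ec_eo_schedule(config.ec_eo_block_s, config.ec_eo_reps)
    ss = np.random.SeedSequence([config.seed, 0xEC])
    rows = []
    for subj, child in enumerate(ss.spawn(config.n_subjects)):
        seeds = child.generate_state(2) % (2**31)
        rng = np.random.default_rng(seeds[1])
        sim = _subject_sim_config(config, int(seeds[0]), rng)
        rec = simulate_recording(montage, schedule, sim)
        rec = downsample(bandpass(rec, *config.band, order=config.filter_order),
                         config.target_fs)
        snr = ec_eo_snr(rec, montage, alpha_band=config.alpha_band,
                        win_s=config.stft_win_s, overlap=config.stft_overlap)
        log.info("EC/EO subject %d: %s", subj,
                 {k: round(v.snr_db, 2) for k, v in snr.items()})
        for roi, res in snr.items():
            rows.append({"subject": subj, "roi": roi, "alpha_ec": res.alpha_ec,
                         "alpha_eo": res.alpha_eo, "snr_db": res.snr_db})
    per_subject = pd.DataFrame(rows)
    summary = (per_subject.groupby("roi", sort=False)["snr_db"]
               .agg(["mean", "std"]).reset_index()
               .rename(columns={"mean": "snr_db_mean", "std": "snr_db_std"}))
    result = {"per_subject": per_subject, "summary": summary}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        per_subject.to_csv(out_dir / "snr_per_subject.csv", index=False)
        summary.to_csv(out_dir / "snr_summary.csv", index=False)
        _write_manifest(out_dir, config, "ec_eo")
    return result


def _preprocess_subject(config: RunConfig, montage, schedule, sim, blink_seed: int):
    """simulate -> blinks -> filter -> downsample -> epoch -> baseline -> reject."""
    rec = simulate_recording(montage, schedule, sim)
    rec, blink_times = inject_blinks(rec, config.blink_rate,
                                     config.blink_amplitude, seed=blink_seed)
    rec = downsample(bandpass(rec, *config.band, order=config.filter_order),
                     config.target_fs)
    epochs = extract_epochs(rec, window=config.epoch_window)
    epochs = baseline_correct(epochs, window=config.baseline)
    roi_union = [ch for roi in montage.rois.values() for ch in roi]
    kept, report = reject_peak_to_peak(epochs, config.reject_threshold_task,
                                       channels=roi_union)
    rejected_labels = epochs.labels[report.rejected_indices]
    return kept, report, rejected_labels, blink_times


def run_ma_lc_study(config: RunConfig, out_dir=None) -> dict:
    """Simulate the MA/LC cohort; ERD/ERS maps, per-ROI CV accuracy, group stats.

    Returns a dict with the subject x region accuracy table, rejection
    accounting, the Friedman/Wilcoxon statistics over the four ROIs, and
    (optionally) the grand-average per-ROI ERD/ERS maps per condition.
    """
    montage = build_default_montage()
    regions = montage.analysis_groups(include_scalp=config.include_scalp)
    bands = default_bands()
    ss = np.random.SeedSequence([config.seed, 0x3A])
    acc_rows, reject_rows = [], []
    maps_acc: dict[tuple[str, str], list] = {}
    for subj, child in enumerate(ss.spawn(config.n_subjects)):
        seeds = child.generate_state(4) % (2**31)
        rng = np.random.default_rng(seeds[1])
        sim = _subject_sim_config(config, int(seeds[0]), rng)
        schedule = generate_main_schedule(config.sessions, config.trials_per_cond,
                                          config.rest_range_s, seed=int(seeds[2]))
        epochs, report, rejected_labels, _ = _preprocess_subject(
            config, montage, schedule, sim, blink_seed=int(seeds[3]))
        for cond in ("MA", "LC"):
            reject_rows.append({"subject": subj, "condition": cond,
                                "n_rejected": int(np.sum(rejected_labels == cond))})
        log.info("MA/LC subject %d: rejected %d/%d trials", subj,
                 report.n_rejected, len(report.peak_to_peak))
        for region, channels in regions.items():
            if region == "ear":
                data = rereference_ear(epochs.data, epochs.channels,
                                       montage.ear_left, montage.ear_right)
            else:
                data = rereference_car(epochs.data, epochs.channels, channels)
            sub = dataclasses.replace(epochs, data=data).select_channels(channels)
            cv = cross_validate(sub, k=config.cv_folds, reps=config.cv_reps,
                                n_keep=config.n_keep, bands=bands,
                                seed=int(seeds[1]))
            acc_rows.append({"subject": subj, "region": region,
                             "mean_acc": cv.mean, "std_acc": cv.std,
                             "n_trials_kept": sub.n_trials})
            if config.compute_maps:
                for cond in ("MA", "LC"):
                    cond_epochs = sub.select_trials(np.flatnonzero(sub.labels == cond))
                    ch_maps = erders_map(cond_epochs, baseline=config.baseline)
                    roi_map = roi_average_map(ch_maps, channels,
                                              name=f"{region}:{cond}")
                    maps_acc.setdefault((region, cond), []).append(roi_map)

    accuracies = pd.DataFrame(acc_rows)
    rejections = pd.DataFrame(reject_rows)

    # group statistics across the four ROIs (scalp reference excluded)
    roi_names = list(montage.rois)
    table = (accuracies[accuracies.region.isin(roi_names)]
             .pivot(index="subject", columns="region", values="mean_acc")
             [roi_names])
    stats_rows = []
    if config.n_subjects >= 2:
        fr = friedman_test(table.to_numpy())
        stats_rows.append({"comparison": "all_rois", "test": fr.test,
                           "statistic": fr.statistic, "p": fr.p,
                           "corrected_alpha": np.nan, "significant": fr.p < 0.05})
        pairs = list(combinations(roi_names, 2))
        alpha_corr = bonferroni(0.05, len(pairs))
        for a, b in pairs:
            try:
                wr = wilcoxon_signed_rank(table[a].to_numpy(), table[b].to_numpy())
            except ValueError:      # all differences zero
                continue
            stats_rows.append({"comparison": f"{a}_vs_{b}", "test": wr.test,
                               "statistic": wr.statistic, "p": wr.p,
                               "corrected_alpha": alpha_corr,
                               "significant": wr.p < alpha_corr})
    stats_df = pd.DataFrame(stats_rows)

    grand_maps = {key: roi_average_map(m_list, name=f"{key[0]}:{key[1]}")
                  for key, m_list in maps_acc.items()}

    result = {"accuracies": accuracies, "rejections": rejections,
              "stats": stats_df, "maps": grand_maps,
              "roi_mean_accuracy": table.mean(axis=0).to_dict()}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        accuracies.to_csv(out_dir / "accuracy_per_subject.csv", index=False)
        (accuracies.groupby("region", sort=False)["mean_acc"]
         .agg(["mean", "std"]).reset_index()
         .to_csv(out_dir / "accuracy_summary.csv", index=False))
        stats_df.to_csv(out_dir / "group_stats.csv", index=False)
        if grand_maps:
            np.savez_compressed(
                out_dir / "erders_maps.npz",
                **{f"{r}__{c}": m.values for (r, c), m in grand_maps.items()},
                freqs=next(iter(grand_maps.values())).freqs,
                times=next(iter(grand_maps.values())).times,
            )
        _write_manifest(out_dir, config, "ma_lc")
    return result
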