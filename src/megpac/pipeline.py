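"""End-to-end orchestration: simulate -> (sensor path) -> CFC -> stats -> predict.

Every stage's parameters default to the study's analysis settings (50 Hz
notch, 1-100 Hz band, 8-13 Hz phase grid at 1 Hz, 30-100 Hz amplitude grid,
coupling windows 0-50 ms and 100-200 ms, 1000 permutations, 50% responder
threshold). All randomness flows from one master seed. The group-statistics
stage restricts the amplitude axis to the 30-80 Hz gamma band by default,
matching the band analyzed for group contrasts, while the full grid remains
available through the cfc stage.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import cfc as _cfc
from .containers import Comodulogram, RoiSeries
from .predict import RocResult, combine_and_roc, correlate_features
from .preprocess import notch_and_bandpass, reject_high_variance
from .simulate import (
    SimulationConfig,
    SubjectRecord,
    make_toy_leadfield,
    project_to_sensors,
    simulate_cohort,
)
from .source import apply_filters, lcmv_filters, sensor_covariance, symmetric_orthogonalize
from .stats import ClusterTestResult, cluster_mean_strength, cluster_permutation


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulationBlock(_Block):
    """Overrides applied on top of SimulationConfig defaults."""

    n_responder: int = 32
    n_nonresponder: int = 33
    n_hc: int = 29
    n_trials: int = 40
    epoch_len_s: float = 3.0
    fs: float = 600.0
    alpha_freq: float = 10.0
    gamma_freq: float = 60.0
    kappa_responder: float = 0.6
    kappa_nonresponder: float = 0.2
    kappa_hc: float = 0.6
    kappa_sd: float = 0.1
    alpha_power_attenuation: float = 0.5
    noise_exponent: float = 1.0


class SensorBlock(_Block):
    enabled: bool = False
    n_sensors: int = 30
    sources_per_roi: int = 1
    snr_db: float = 10.0
    notch_hz: float = 50.0
    band: tuple[float, float] = (1.0, 100.0)
    on_short_epoch: Literal["error", "warn"] = "warn"
    z_thresh: float = 3.0
    reject: bool = False
    lcmv_reg: float = 0.05
    aggregate: Literal["sign-mean", "pc1"] = "sign-mean"
    orthogonalize: bool = True


class TfrBlock(_Block):
    """Band-power time-course contrasts (off by default: the coupling chain
    is the primary analysis; power contrasts are a supporting check)."""

    enabled: bool = False
    regions: tuple[str, ...] = ("rTHA", "rOFC", "rAMG")
    alpha_band: tuple[float, float] = (8.0, 13.0)
    gamma_band: tuple[float, float] = (30.0, 80.0)
    window: tuple[float, float] = (0.0, 0.2)
    t_step: float = 0.005
    q: float = 0.05


class CfcBlock(_Block):
    phase_freqs: tuple[float, float, float] = (8.0, 13.0, 1.0)   # start, stop, step
    amp_freqs: tuple[float, float, float] = (30.0, 100.0, 1.0)
    stats_amp_band: tuple[float, float] = (30.0, 80.0)


class StatsBlock(_Block):
    n_permutations: int = 1000
    cluster_alpha: float = 0.05
    significance_alpha: float = 0.05


class PredictBlock(_Block):
    pos_label: str = "non_responder"
    responder_threshold: float = 0.5


class RunConfig(_Block):
    """Configuration of an end-to-end run; unknown keys are rejected."""

    seed: int = 0
    simulation: SimulationBlock = SimulationBlock()
    sensor: SensorBlock = SensorBlock()
    tfr: TfrBlock = TfrBlock()
    cfc: CfcBlock = CfcBlock()
    stats: StatsBlock = StatsBlock()
    predict: PredictBlock = PredictBlock()


def _grid(spec: tuple[float, float, float]) -> np.ndarray:
    start, stop, step = spec
    return np.arange(start, stop + step / 2, step)


def simulation_config_from(block: SimulationBlock, seed: int) -> SimulationConfig:
    return SimulationConfig(
        n_responder=block.n_responder,
        n_nonresponder=block.n_nonresponder,
        n_hc=block.n_hc,
        n_trials=block.n_trials,
        epoch_len_s=block.epoch_len_s,
        fs=block.fs,
        alpha_freq=block.alpha_freq,
        gamma_freq=block.gamma_freq,
        kappa_by_group={
            "responder": block.kappa_responder,
            "non_responder": block.kappa_nonresponder,
            "HC": block.kappa_hc,
        },
        kappa_sd=block.kappa_sd,
        alpha_power_attenuation=block.alpha_power_attenuation,
        noise_exponent=block.noise_exponent,
        seed=seed,
    )


def subject_comodulograms(
    roi: RoiSeries,
    sim: SimulationConfig,
    phase_freqs: np.ndarray,
    amp_freqs: np.ndarray,
) -> dict[str, Comodulogram]:
    """Both pathway comodulograms for one subject, sharing envelope work."""
    cache: dict = {}
    out = {}
    for w in sim.coupling_windows:
        key = f"{w.phase_region}->{w.amp_region}@{w.t_start_s:g}-{w.t_end_s:g}s"
        out[key] = _cfc.comodulogram(
            roi,
            w.phase_region,
            w.amp_region,
            (w.t_start_s, w.t_end_s),
            phase_freqs=phase_freqs,
            amp_freqs=amp_freqs,
            _env_cache=cache,
        )
    return out


@dataclasses.dataclass
class RunReport:
    """Machine-readable summary of an end-to-end run."""

    seed: int
    n_subjects: int
    group_sizes: dict
    pathways: list
    cluster_p: dict
    cluster_mass: dict
    feature_correlations: dict          # pathway -> (r, p)
    roc: RocResult | None
    stage_seconds: dict
    fallback_masks: list = dataclasses.field(default_factory=list)
    band_power: dict | None = None      # region -> band -> stats arrays

    def to_json(self) -> str:
        d = {
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "group_sizes": self.group_sizes,
            "pathways": self.pathways,
            "cluster_p": self.cluster_p,
            "cluster_mass": self.cluster_mass,
            "feature_correlations": {k: list(v) for k, v in self.feature_correlations.items()},
            "auc": None if self.roc is None else self.roc.auc,
            "sensitivity": None if self.roc is None else self.roc.sensitivity,
            "specificity": None if self.roc is None else self.roc.specificity,
            "single_feature_aucs": None if self.roc is None else list(self.roc.single_feature_aucs),
            "stage_seconds": self.stage_seconds,
            "fallback_masks": self.fallback_masks,
        }
        if self.band_power is not None:
            d["band_power_significant_bins"] = {
                region: {band: int(v["mask"].sum()) for band, v in bands.items()}
                for region, bands in self.band_power.items()
            }
        return json.dumps(d, indent=2)


def run_all(config: RunConfig, out_dir: str | Path | None = None) -> RunReport:
    """Execute the full pipeline on a synthetic cohort.

    Stages: cohort simulation; optionally forward projection to sensors,
    filtering, variance rejection, LCMV source reconstruction and symmetric
    orthogonalization; per-subject pathway comodulograms; non-responder vs
    responder cluster permutation test per pathway; per-subject cluster
    strengths correlated with reduction ratios; OLS combination of the two
    pathway features scored by in-sample ROC.
    """
    timings: dict[str, float] = {}
    t_start = time.perf_counter()

    sim = simulation_config_from(config.simulation, config.seed)
    roi_list, records = simulate_cohort(sim)
    timings["simulate"] = time.perf_counter() - t_start

    if config.sensor.enabled:
        t0 = time.perf_counter()
        roi_list = _sensor_path(roi_list, records, sim, config.sensor)
        timings["sensor_path"] = time.perf_counter() - t0

    band_power_stats = None
    if config.tfr.enabled:
        t0 = time.perf_counter()
        band_power_stats = _band_power_stage(roi_list, records, config.tfr)
        timings["tfr"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    phase_freqs = _grid(config.cfc.phase_freqs)
    lo, hi = config.cfc.stats_amp_band
    amp_full = _grid(config.cfc.amp_freqs)
    amp_stats = amp_full[(amp_full >= lo) & (amp_full <= hi)]
    comods = [
        subject_comodulograms(roi, sim, phase_freqs, amp_stats) for roi in roi_list
    ]
    timings["cfc"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    pathways = list(comods[0].keys())
    is_nr = np.array([r.group == "non_responder" for r in records])
    is_r = np.array([r.group == "responder" for r in records])
    cluster_results: dict[str, ClusterTestResult] = {}
    features: dict[str, np.ndarray] = {}
    fallback = []
    for pi, path in enumerate(pathways):
        maps = np.stack([c[path].values for c in comods])
        res = cluster_permutation(
            maps[is_nr],
            maps[is_r],
            n_permutations=config.stats.n_permutations,
            cluster_alpha=config.stats.cluster_alpha,
            rng=np.random.default_rng([config.seed, 1000 + pi]),
        )
        cluster_results[path] = res
        sig_neg = res.significant(config.stats.significance_alpha, sign=-1)
        if sig_neg:
            best = min(sig_neg, key=lambda i: res.cluster_masses[i])
        else:
            neg = np.where(res.cluster_signs < 0)[0]
            if neg.size == 0:
                fallback.append(path)
                features[path] = maps.reshape(maps.shape[0], -1).mean(axis=1)
                continue
            best = int(neg[np.argmin(res.cluster_masses[neg])])
            fallback.append(path)
        mask = res.cluster_masks[best]
        features[path] = np.array([cluster_mean_strength(m, mask) for m in maps])
    timings["cluster_stats"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    patients = is_nr | is_r
    ratios = np.array([r.reduction_ratio for r in records])[patients]
    labels = np.array([r.group for r in records])[patients]
    corr = {}
    for path in pathways:
        r, p = correlate_features(features[path][patients], ratios)[0]
        corr[path] = (r, p)
    roc = None
    if len(pathways) >= 2:
        roc = combine_and_roc(
            features[pathways[0]][patients],
            features[pathways[1]][patients],
            labels,
            pos_label=config.predict.pos_label,
        )
    timings["predict"] = time.perf_counter() - t0

    report = RunReport(
        seed=config.seed,
        n_subjects=len(records),
        group_sizes={g: int(np.sum([r.group == g for r in records])) for g in ("responder", "non_responder", "HC")},
        pathways=pathways,
        cluster_p={
            p: [float(v) for v in cluster_results[p].p_values] for p in pathways if p in cluster_results
        },
        cluster_mass={
            p: [float(v) for v in cluster_results[p].cluster_masses] for p in pathways if p in cluster_results
        },
        feature_correlations=corr,
        roc=roc,
        stage_seconds={k: round(v, 3) for k, v in timings.items()},
        fallback_masks=fallback,
        band_power=band_power_stats,
    )

    if out_dir is not None:
        _write_outputs(Path(out_dir), records, features, patients, ratios, labels, report)
    return report


def _band_power_stage(roi_list, records, block: TfrBlock):
    """Per-region alpha/gamma band-power contrasts across the three groups.

    One-way F per time bin with BH-FDR within each band, plus post-hoc
    non-responder vs responder t on surviving bins.
    """
    from .spectral import band_power_timecourse, tfr_hanning, tfr_multitaper
    from .stats import pointwise_f_fdr, posthoc_t

    out: dict[str, dict] = {}
    groups = ("non_responder", "responder", "HC")
    idx = {g: [i for i, r in enumerate(records) if r.group == g] for g in groups}
    for region in block.regions:
        courses: dict[str, dict[str, np.ndarray]] = {"alpha": {}, "gamma": {}}
        per_subj: dict[str, list] = {"alpha": [], "gamma": []}
        for roi in roi_list:
            sub = RoiSeries(roi.data[:, [roi.region_index(region)], :], fs=roi.fs,
                            t0=roi.t0, region_labels=(region,))
            lo = tfr_hanning(sub, freqs=np.arange(block.alpha_band[0], block.alpha_band[1] + 1),
                             t_step=block.t_step)
            hi = tfr_multitaper(sub, freqs=np.arange(block.gamma_band[0], block.gamma_band[1] + 1, 2.0),
                                t_step=block.t_step)
            per_subj["alpha"].append(band_power_timecourse(lo, block.alpha_band, block.window)[0])
            per_subj["gamma"].append(band_power_timecourse(hi, block.gamma_band, block.window)[0])
        out[region] = {}
        for band in ("alpha", "gamma"):
            stacked = np.stack(per_subj[band])
            res = pointwise_f_fdr([stacked[idx[g]] for g in groups], q=block.q)
            entry = {"mask": res.mask, "f": res.f_values, "p": res.p_values}
            if res.mask.any():
                t, p = posthoc_t(stacked[idx["non_responder"]], stacked[idx["responder"]],
                                 bins=res.mask)
                entry["posthoc_t"] = t
                entry["posthoc_p"] = p
            out[region][band] = entry
    return out


def _sensor_path(roi_list, records, sim, block: SensorBlock):
    """Forward-project each subject, filter, beamform back to ROI series."""
    lf = make_toy_leadfield(
        sim.roi_labels, n_sensors=block.n_sensors,
        sources_per_roi=block.sources_per_roi, rng=sim.seed + 7,
    )
    out = []
    for i, roi in enumerate(roi_list):
        sens = project_to_sensors(roi, lf, snr_db=block.snr_db, rng=sim.seed * 100003 + i)
        sens = notch_and_bandpass(sens, block.notch_hz, block.band,
                                  on_short_epoch=block.on_short_epoch)
        if block.reject:
            sens, _ = reject_high_variance(sens, block.z_thresh)
        cov = sensor_covariance(sens)
        filters = lcmv_filters(lf, cov, reg=block.lcmv_reg)
        rec = apply_filters(sens, filters, lf, aggregate=block.aggregate)
        if block.orthogonalize:
            rec = symmetric_orthogonalize(rec)
        out.append(rec)
    return out


def _write_outputs(out_dir, records, features, patients, ratios, labels, report):
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([vars(r) for r in records]).to_csv(out_dir / "subjects.csv", index=False)
    feat = pd.DataFrame(features)
    feat.insert(0, "id", [r.id for r in records])
    feat["group"] = [r.group for r in records]
    feat.to_csv(out_dir / "features.csv", index=False)
    (out_dir / "report.json").write_text(report.to_json())
    if report.roc is not None:
        pd.DataFrame(
            {"fpr": report.roc.fpr, "tpr": report.roc.tpr, "threshold": report.roc.thresholds}
        ).to_csv(out_dir / "roc_curve.csv", index=False)


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; unknown keys raise a schema error."""
    import yaml

    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return RunConfig(**raw)
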