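"""End-to-end pipeline: simulate -> preprocess -> extract -> evaluate.

Every stage reads and writes only the :mod:`nirsmci.dataio` formats, so
the stages are individually re-runnable from their files and real data in
the documented schema can enter at any point.  A fixed configuration and
seed make the whole run deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataio import (
    AcquisitionSpec,
    read_feature_table,
    read_hemo,
    read_recording,
    write_feature_table,
    write_hemo,
    write_recording,
)
from .diagstats import DiagnosticReport, evaluate_biomarkers
from .features import FeatureConfig, extract_features
from .preprocess import MBLLParams, PreprocConfig, preprocess_recording
from .synth import BlockTimingSpec, CohortSpec, HrfSpec, NoiseSpec, generate_cohort

log = logging.getLogger("nirsmci")


class ConfigError(ValueError):
    """Invalid pipeline configuration (caught before any computation)."""


@dataclass
class PipelineConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    timing: BlockTimingSpec = field(default_factory=BlockTimingSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    hrf: HrfSpec = field(default_factory=HrfSpec)
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    mbll: MBLLParams = field(default_factory=MBLLParams)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    seed: int = 0

    def validate(self) -> None:
        try:
            self.preproc.validate(self.acquisition.sampling_rate, self.acquisition.n_channels)
            self.noise.validate_frequencies(self.acquisition.sampling_rate)
        except ValueError as err:
            raise ConfigError(str(err)) from err
        if self.features.min_trials > self.timing.n_blocks:
            raise ConfigError("min_trials exceeds the number of task blocks")

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, tuple):
                return list(obj)
            if isinstance(obj, dict):
                return {str(k): enc(v) for k, v in obj.items()}
            return obj

        d = {name: enc(getattr(self, name)) for name in
             ("cohort", "timing", "noise", "hrf", "acquisition", "mbll", "preproc", "features")}
        d["seed"] = self.seed
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def tupled(spec_cls, payload):
            if payload is None:
                return spec_cls()
            kwargs = {}
            for f in dataclasses.fields(spec_cls):
                if f.name not in payload:
                    continue
                v = payload[f.name]
                if isinstance(v, list):
                    v = tuple(v)
                kwargs[f.name] = v
            return spec_cls(**kwargs)

        acq_payload = dict(d.get("acquisition") or {})
        if "channel_region_map" in acq_payload:
            acq_payload["channel_region_map"] = {
                int(k): v for k, v in acq_payload["channel_region_map"].items()
            }
        mbll_payload = dict(d.get("mbll") or {})
        if isinstance(mbll_payload.get("extinction"), list):
            mbll_payload["extinction"] = np.asarray(mbll_payload["extinction"], float)
        feat_payload = dict(d.get("features") or {})
        if isinstance(feat_payload.get("baseline_window"), list):
            feat_payload["baseline_window"] = tuple(feat_payload["baseline_window"])
        try:
            return cls(
                cohort=tupled(CohortSpec, d.get("cohort")),
                timing=tupled(BlockTimingSpec, d.get("timing")),
                noise=tupled(NoiseSpec, d.get("noise")),
                hrf=tupled(HrfSpec, d.get("hrf")),
                acquisition=tupled(AcquisitionSpec, acq_payload),
                mbll=tupled(MBLLParams, mbll_payload),
                preproc=tupled(PreprocConfig, d.get("preproc")),
                features=tupled(FeatureConfig, feat_payload),
                seed=int(d.get("seed", 0)),
            )
        except (TypeError, ValueError) as err:
            raise ConfigError(str(err)) from err

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(payload)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(config: PipelineConfig, out_dir: Path) -> pd.DataFrame:
    """Generate the cohort and write raw recordings + the latent truth table."""
    recordings, truth = generate_cohort(
        cohort=config.cohort,
        timing=config.timing,
        hrf=config.hrf,
        noise=config.noise,
        acquisition=config.acquisition,
        seed=config.seed,
        mbll=config.mbll,
        preproc=config.preproc,
        feat=config.features,
    )
    raw_dir = out_dir / "raw"
    for rec in recordings:
        write_recording(rec, raw_dir / rec.subject_id)
    truth_path = out_dir / "latent_truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False, float_format="%.17g")
    log.info("simulated %d subjects (%d healthy, %d mci) -> %s",
             len(recordings), config.cohort.n_healthy, config.cohort.n_mci, raw_dir)
    return truth


def stage_preprocess(config: PipelineConfig, out_dir: Path) -> None:
    raw_dir = out_dir / "raw"
    hemo_dir = out_dir / "hemo"
    n_rejected = 0
    subject_dirs = sorted(p for p in raw_dir.iterdir() if p.is_dir())
    if not subject_dirs:
        raise FileNotFoundError(f"no subject directories under {raw_dir}")
    for sub in subject_dirs:
        rec = read_recording(sub)
        hemo = preprocess_recording(rec, mbll=config.mbll, config=config.preproc)
        rejected = [ch for ch, f in hemo.channel_qc.items() if f == "rejected"]
        if rejected:
            log.warning("subject %s: rejected channels %s", rec.subject_id, rejected)
            n_rejected += len(rejected)
        write_hemo(hemo, hemo_dir / rec.subject_id)
    log.info("preprocessed %d subjects, %d channels rejected in total",
             len(subject_dirs), n_rejected)


def stage_extract(config: PipelineConfig, out_dir: Path) -> pd.DataFrame:
    hemo_dir = out_dir / "hemo"
    subject_dirs = sorted(p for p in hemo_dir.iterdir() if p.is_dir())
    if not subject_dirs:
        raise FileNotFoundError(f"no subject directories under {hemo_dir}")
    hemos = [read_hemo(p) for p in subject_dirs]
    features = extract_features(hemos, config.features)
    write_feature_table(features, out_dir / "features.tsv")
    log.info("extracted features for %d subjects -> %s",
             len(features), out_dir / "features.tsv")
    return features


def stage_evaluate(out_dir: Path) -> DiagnosticReport:
    features = read_feature_table(out_dir / "features.tsv")
    report = evaluate_biomarkers(features)
    report.save(out_dir / "report.json")
    report_render(report, out_dir)
    log.info("evaluated %d candidates; ranking: %s",
             len(report.candidates), " > ".join(report.ranking))
    return report


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> DiagnosticReport:
    """Execute all stages under ``out_dir``; deterministic for fixed config+seed."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "config": config.to_dict(),
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    stage_simulate(config, out_dir)
    stage_preprocess(config, out_dir)
    stage_extract(config, out_dir)
    return stage_evaluate(out_dir)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_CANDIDATE_LABELS = {
    "moca_k": "MoCA-K score (point)",
    "mhbo_left": "mHbO left PFC",
    "mhbo_right": "mHbO right PFC",
    "mhbo_total": "mHbO total PFC",
}


def report_render(report: DiagnosticReport, out_dir: str | Path) -> dict[str, Path]:
    """Write human-readable TSV tables from a diagnostic report.

    Emits group statistics, discrimination metrics
    (sensitivity/specificity/Youden/AUC/cutoff), confusion matrices with
    predictive values under both conventions, and the MoCA-K correlations.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not report.candidates:
        raise ValueError("empty report: nothing to render")
    paths = {}

    rows = []
    for name, c in report.candidates.items():
        g = c["group_stats"]
        rows.append(
            {
                "measure": _CANDIDATE_LABELS.get(name, name),
                "healthy_mean_sd": f"{g['healthy_mean']:.3f} ({g['healthy_sd']:.3f})",
                "mci_mean_sd": f"{g['mci_mean']:.3f} ({g['mci_sd']:.3f})",
                "t": f"{c['t'].statistic:.3f}",
                "p": f"{c['t'].p_value:.3f}",
            }
        )
    paths["group_stats"] = out_dir / "table_group_stats.tsv"
    pd.DataFrame(rows).to_csv(paths["group_stats"], sep="\t", index=False)

    rows = []
    for name, c in report.candidates.items():
        m = c["metrics"]
        rows.append(
            {
                "measure": _CANDIDATE_LABELS.get(name, name),
                "sensitivity": f"{m.sensitivity:.3f}",
                "specificity": f"{m.specificity:.3f}",
                "youden_index": f"{m.youden_j:.3f}",
                "auc": f"{c['roc'].auc:.3f}",
                "cutoff": f"{m.cutoff:.3f}",
            }
        )
    paths["discrimination"] = out_dir / "table_discrimination.tsv"
    pd.DataFrame(rows).to_csv(paths["discrimination"], sep="\t", index=False)

    rows = []
    for name, c in report.candidates.items():
        hh, hm, mh, mm = c["confusion"].as_tuple()
        pv = c["predictive"]
        rows.append(
            {
                "measure": _CANDIDATE_LABELS.get(name, name),
                "predicted_healthy_true_healthy": hh,
                "predicted_healthy_true_mci": hm,
                "predicted_mci_true_healthy": mh,
                "predicted_mci_true_mci": mm,
                "healthy_positive": (
                    f"PPV: {100 * pv['healthy_positive']['ppv']:.2f}% / "
                    f"NPV: {100 * pv['healthy_positive']['npv']:.2f}%"
                ),
                "mci_positive": (
                    f"PPV: {100 * pv['mci_positive']['ppv']:.2f}% / "
                    f"NPV: {100 * pv['mci_positive']['npv']:.2f}%"
                ),
            }
        )
    paths["predictability"] = out_dir / "table_predictability.tsv"
    pd.DataFrame(rows).to_csv(paths["predictability"], sep="\t", index=False)

    rows = [
        {
            "measure": "MoCA-K score (point)",
            "region": _CANDIDATE_LABELS.get(name, name),
            "r": f"{c['r']:.3f}",
            "p": f"{c['p']:.3f}",
        }
        for name, c in report.correlations.items()
    ]
    paths["correlations"] = out_dir / "table_correlations.tsv"
    pd.DataFrame(rows).to_csv(paths["correlations"], sep="\t", index=False)
    return paths


def plot_roc_curves(report: DiagnosticReport, path: str | Path) -> Path:
    """Optional ROC figure (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, c in report.candidates.items():
        roc = c["roc"]
        ax.plot(1 - roc.specificity, roc.sensitivity,
                label=f"{_CANDIDATE_LABELS.get(name, name)} (AUC {roc.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
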