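"""Run configuration and the end-to-end pipeline.

``run_pipeline`` chains detection -> networks -> centrality -> features ->
classification over a cohort of recordings (or a pre-simulated feature
cohort), writing per-stage artifacts and a final JSON report. All
randomness flows from the single configuration seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from hfonet.centrality import (
    ChannelRanking,
    eigenvector_centrality,
    ordinal_rank_normalize,
    outcloseness_centrality,
)
from hfonet.detection import DetectorParams, rank_hfo_rate, redact_artifacts, staba_detect
from hfonet.exceptions import PipelineError
from hfonet.features import CREP_LEVELS, SOZ_STRATA, build_feature_table
from hfonet.networks import (
    NetworkParams,
    build_fcn,
    build_lan,
    derive_ulan_flan,
    pair_observations,
    preprocess_recording,
    rank_normalize_network,
    sample_background_windows,
    sample_event_windows,
)
from hfonet.outcome_model import SurgicalOutcomeModel
from hfonet.recording import Recording, common_average_reference

log = logging.getLogger("hfonet")


@dataclass
class FeatureParams:
    crep_levels: tuple[float, ...] = CREP_LEVELS
    soz_strata: tuple[str, ...] = SOZ_STRATA
    ds_threshold: float = 80.0


@dataclass
class ModelParams:
    feature_set: str = "CReP30"       # suffix of the feature-table columns to use
    posterior_threshold: float = 0.8
    n_boot: int = 10_000
    n_perm: int = 10_000


@dataclass
class RunConfig:
    """Complete, JSON-serializable configuration of one pipeline run."""

    detector: DetectorParams = field(default_factory=DetectorParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    features: FeatureParams = field(default_factory=FeatureParams)
    model: ModelParams = field(default_factory=ModelParams)
    seed: int = 0
    log_level: str = "INFO"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)

        def _tupled(d: dict, klass):
            kwargs = {}
            for f in dataclasses.fields(klass):
                if f.name in d:
                    v = d[f.name]
                    kwargs[f.name] = tuple(v) if isinstance(v, list) else v
            return klass(**kwargs)

        return cls(
            detector=_tupled(raw.get("detector", {}), DetectorParams),
            network=_tupled(raw.get("network", {}), NetworkParams),
            features=_tupled(raw.get("features", {}), FeatureParams),
            model=_tupled(raw.get("model", {}), ModelParams),
            seed=raw.get("seed", 0),
            log_level=raw.get("log_level", "INFO"),
        )


@dataclass
class PatientRecord:
    """One patient's inputs to the signal-level pipeline."""

    patient_id: str
    recording: Recording
    annotation: object                  # PatientAnnotation
    events: list | None = None          # optional precomputed HFO events


@dataclass
class PatientResult:
    patient_id: str
    rankings: dict[str, ChannelRanking]
    annotation: object


def analyze_patient(pat: PatientRecord, cfg: RunConfig) -> PatientResult:
    """Detect, build networks and rank channels for one patient."""
    t0 = time.time()
    rec = pat.recording
    try:
        car = common_average_reference(rec)
        events = pat.events
        if events is None:
            events = staba_detect(car, cfg.detector)
            events = redact_artifacts(events, car, cfg.detector)
        log.info("%s: %d events (%d accepted)", pat.patient_id, len(events),
                 sum(e.accepted for e in events))

        np_ = cfg.network
        rng = np.random.default_rng(np_.seed + cfg.seed)
        filtered = preprocess_recording(rec, np_)
        windows = sample_event_windows(rec, events, np_, filtered=filtered, rng=rng)
        bg = sample_background_windows(rec, events, np_, filtered=filtered, rng=rng)
        obs = pair_observations(windows, np_)
        fcn = build_fcn(windows, bg, rec.labels, np_)
        lan, _ = build_lan(windows, rec.labels, np_, observations=obs)
        ulan, flan = derive_ulan_flan(lan)
        if np_.rank_normalize:
            fcn = rank_normalize_network(fcn)
            ulan = rank_normalize_network(ulan)
            flan = rank_normalize_network(flan)

        rankings = {
            "fLAN-OUT": ChannelRanking.from_raw(
                "fLAN-OUT", rec.labels, outcloseness_centrality(flan.weights)),
            "uLAN-EIG": ChannelRanking.from_raw(
                "uLAN-EIG", rec.labels, eigenvector_centrality(ulan.weights)),
            "FCN-EIG": ChannelRanking.from_raw(
                "FCN-EIG", rec.labels, eigenvector_centrality(fcn.weights)),
            "HFO-RATE": rank_hfo_rate(events, rec.labels),
        }
    except Exception as exc:
        raise PipelineError(f"patient {pat.patient_id}: {exc}") from exc
    log.info("%s: analyzed in %.1f s", pat.patient_id, time.time() - t0)
    return PatientResult(pat.patient_id, rankings, pat.annotation)


def run_pipeline(cfg: RunConfig, patients: list[PatientRecord] | None = None,
                 cohort=None, out_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline and return (and optionally write) a report.

    Either ``patients`` (signal-level inputs) or ``cohort`` (a pre-built
    feature cohort with rankings and annotations) must be given. The report
    holds the feature table and, when both outcome classes have at least two
    trainable patients, the classifier results.
    """
    logging.basicConfig(level=cfg.log_level)
    if (patients is None) == (cohort is None):
        raise ValueError("provide exactly one of patients or cohort")

    if patients is not None:
        results = [analyze_patient(p, cfg) for p in patients]
    else:
        results = cohort.patients

    table = build_feature_table(results, cfg.features.crep_levels,
                                cfg.features.soz_strata)
    report: dict = {
        "n_patients": len(table),
        "feature_table": table.reset_index().to_dict(orient="records"),
    }

    train = table[table["class_group"] != "Class-2"]
    n_pos = int((train["class_group"] == "Class-1").sum())
    n_neg = int((train["class_group"] == "Class-3+").sum())
    if n_pos >= 2 and n_neg >= 2:
        cols = [c for c in table.columns if c.endswith(f"_{cfg.model.feature_set}")]
        model = SurgicalOutcomeModel.from_dataframe(table, feature_cols=cols)
        res = model.fit(thresholds=(cfg.model.posterior_threshold,),
                        n_boot=cfg.model.n_boot, seed=cfg.seed)
        report["classifier"] = {
            "feature_cols": cols,
            "posteriors": res.posteriors.tolist(),
            "labels": res.classifier.labels.astype(int).tolist(),
            "auc": res.auc,
            "auc_ci": list(res.auc_ci),
            "auc_p": res.auc_p,
            "ppv_at": {str(k): list(v) for k, v in res.classifier.ppv_at.items()},
            "hotelling": (None if res.group_test is None else
                          {"t2": res.group_test.t2, "f": res.group_test.f_stat,
                           "p": res.group_test.p_global}),
        }
    else:
        report["classifier"] = None
        log.info("classifier skipped: need >= 2 trainable patients per class "
                 "(have %d Class-1, %d Class-3+)", n_pos, n_neg)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "feature_table.csv")
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (out_dir / "config.json").write_text(cfg.to_json())
    return report
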