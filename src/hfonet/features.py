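"""Resection-overlap features and patient stratification.

Per patient, the four channel rankings (fLAN-OUT, uLAN-EIG, FCN-EIG,
HFO-RATE) are condensed into outcome-relevant scalars:

* **SOZ resection percentage** -- how much of the clinically defined seizure
  onset zone falls inside the resected volume; patients with >= 80% are the
  *definitive surgery* (DS) group, the rest *palliative* (PS).
* **SOZ feature scores** -- mean normalized rank over the whole SOZ (SOZALL),
  its highest-ranking 50% / 10% (SOZ50, SOZ10), or its single highest-ranked
  channel (SOZTOP).
* **CReP(X)** -- Critical Resection Percentage: of the ceiling(N * X%)
  highest-ranked channels, the fraction inside the planned resection, for
  X in {10, 20, 30, 40}. Its maximum is capped at min(|RV|, n_CReP)/n_CReP
  when fewer channels are resected than evaluated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hfonet.centrality import MEASURES, ChannelRanking

DS_THRESHOLD = 80.0           # % SOZ resection separating definitive from palliative
CREP_LEVELS = (10.0, 20.0, 30.0, 40.0)
SOZ_STRATA = ("ALL", "P50", "P10", "TOP")


@dataclass
class PatientAnnotation:
    """Channel table for one patient: labels, SOZ, resected volume, outcome.

    ``outcome`` is the Engel class (1-4); class I maps to the good-outcome
    group (Class-1), III/IV to the poor group (Class-3+), and class II is
    ambiguous and held out of classifier training.
    """

    channels: list[str]
    soz: set[str]
    rv: set[str]
    outcome: int

    def __post_init__(self) -> None:
        chans = set(self.channels)
        if len(chans) != len(self.channels):
            raise ValueError("duplicate channel labels")
        if len(self.channels) < 2:
            raise ValueError("at least 2 channels required")
        if not set(self.soz) <= chans:
            raise ValueError("soz must be a subset of channels")
        if not set(self.rv) <= chans:
            raise ValueError("rv must be a subset of channels")
        if self.outcome not in (1, 2, 3, 4):
            raise ValueError("outcome must be an Engel class 1-4")

    @property
    def class_group(self) -> str:
        return {1: "Class-1", 2: "Class-2"}.get(self.outcome, "Class-3+")


@dataclass
class PatientFeatures:
    """All per-patient scalar features derived from the four rankings."""

    patient_id: str
    soz_resection_pct: float
    surgery_type: str                       # DS | PS
    class_group: str                        # Class-1 | Class-2 | Class-3+
    soz_scores: dict[str, dict[str, float]] = field(default_factory=dict)  # measure -> stratum
    crep: dict[str, dict[float, float]] = field(default_factory=dict)      # measure -> X


def soz_resection_percentage(ann: PatientAnnotation) -> float:
    """Percentage of the SOZ inside the resected volume, in [0, 100]."""
    if not ann.soz:
        raise ValueError("SOZ resection percentage is undefined for an empty SOZ")
    return 100.0 * len(set(ann.soz) & set(ann.rv)) / len(ann.soz)


def classify_surgery(pct: float, threshold: float = DS_THRESHOLD) -> str:
    """Definitive (DS) vs palliative (PS) surgery at the resection threshold."""
    if not (0.0 <= pct <= 100.0):
        raise ValueError("SOZ resection percentage must lie in [0, 100]")
    return "DS" if pct >= threshold else "PS"


def _top_soz_channels(ranking: ChannelRanking, ann: PatientAnnotation,
                      k: int) -> list[str]:
    """The k highest-ranked SOZ channels (ties already resolved in rank01)."""
    soz = [c for c in ann.channels if c in ann.soz]
    soz.sort(key=lambda c: -ranking.rank_of(c))
    return soz[:k]


def soz_feature_score(ranking: ChannelRanking, ann: PatientAnnotation,
                      stratum: str) -> float:
    """Mean normalized rank over an SOZ stratum.

    Strata: ``ALL`` (every SOZ channel), ``P50`` / ``P10`` (the
    highest-ranking 50% / 10% of SOZ channels, subset size
    ``ceiling(fraction * |SOZ|)`` with a floor of one channel) and ``TOP``
    (the single highest-ranked SOZ channel).
    """
    if not ann.soz:
        raise ValueError("SOZ feature score is undefined for an empty SOZ")
    n_soz = len(ann.soz)
    if stratum == "ALL":
        k = n_soz
    elif stratum == "P50":
        k = max(1, math.ceil(0.5 * n_soz))
    elif stratum == "P10":
        k = max(1, math.ceil(0.1 * n_soz))
    elif stratum == "TOP":
        k = 1
    else:
        raise ValueError(f"unknown stratum {stratum!r}")
    top = _top_soz_channels(ranking, ann, k)
    return float(np.mean([ranking.rank_of(c) for c in top]))


def crep(ranking: ChannelRanking, ann: PatientAnnotation, x: float) -> float:
    """Critical Resection Percentage at level X, as a fraction in [0, 1].

    With ``n_CReP = ceiling(N * X / 100)``, the top-``n_CReP`` channels by
    normalized rank (ties resolved by the ranking's deterministic label-order
    policy) are intersected with the resected volume:
    ``CReP(X) = |top set ∩ RV| / n_CReP``. An empty resection gives 0; when
    fewer channels are resected than evaluated the maximum attainable value
    is ``|RV| / n_CReP``.
    """
    if not (0.0 < x <= 100.0):
        raise ValueError("CReP level X must lie in (0, 100]")
    n = len(ann.channels)
    if n < 2:
        raise ValueError("CReP requires at least 2 channels")
    n_crep = math.ceil(n * x / 100.0)
    order = sorted(ann.channels, key=lambda c: (-ranking.rank_of(c), c))
    top = set(order[:n_crep])
    return len(top & set(ann.rv)) / n_crep


def crep_candidate_size(n_channels: int, x: float) -> int:
    """Number of channels evaluated at CReP level X: ceiling(N * X%)."""
    if not (0.0 < x <= 100.0):
        raise ValueError("CReP level X must lie in (0, 100]")
    return math.ceil(n_channels * x / 100.0)


def patient_features(
    patient_id: str,
    rankings: dict[str, ChannelRanking],
    ann: PatientAnnotation,
    crep_levels: tuple[float, ...] = CREP_LEVELS,
    soz_strata: tuple[str, ...] = SOZ_STRATA,
) -> PatientFeatures:
    """All SOZ-stratified scores and CReP levels for one patient."""
    missing = [m for m in MEASURES if m not in rankings]
    if missing:
        raise ValueError(f"patient {patient_id}: missing ranking(s) {missing}")
    pct = soz_resection_percentage(ann)
    pf = PatientFeatures(patient_id, pct, classify_surgery(pct), ann.class_group)
    for m in MEASURES:
        pf.soz_scores[m] = {s: soz_feature_score(rankings[m], ann, s) for s in soz_strata}
        pf.crep[m] = {x: crep(rankings[m], ann, x) for x in crep_levels}
    return pf


def build_feature_table(
    cohort,
    crep_levels: tuple[float, ...] = CREP_LEVELS,
    soz_strata: tuple[str, ...] = SOZ_STRATA,
) -> pd.DataFrame:
    """One row per patient: SOZ scores, CReP levels, stratification, outcome.

    ``cohort`` is any iterable of objects with ``patient_id``, ``rankings``
    and ``annotation`` attributes (e.g. a simulated
    :class:`~hfonet.simulate.CohortDataset`). Columns are
    ``{measure}_SOZ{stratum}`` and ``{measure}_CReP{X}`` plus
    ``soz_resection_pct``, ``surgery_type`` and ``class_group``. Class-2
    patients are included in the table but flagged for exclusion from
    classifier training.
    """
    patients = getattr(cohort, "patients", cohort)
    rows = []
    for pat in patients:
        pf = patient_features(pat.patient_id, pat.rankings, pat.annotation,
                              crep_levels, soz_strata)
        row: dict[str, object] = {
            "patient_id": pf.patient_id,
            "soz_resection_pct": pf.soz_resection_pct,
            "surgery_type": pf.surgery_type,
            "class_group": pf.class_group,
        }
        for m in MEASURES:
            for s in soz_strata:
                row[f"{m}_SOZ{s}"] = pf.soz_scores[m][s]
            for x in crep_levels:
                row[f"{m}_CReP{int(x)}"] = pf.crep[m][x]
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")


def training_split(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a feature table into (trainable, held-out Class-2) rows."""
    held = table[table["class_group"] == "Class-2"]
    train = table[table["class_group"] != "Class-2"]
    return train, held
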