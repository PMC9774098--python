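"""End-to-end orchestration: recordings -> events -> features -> CV metrics.

``extract_patient_features`` runs detection and feature aggregation for
one patient; ``run_study`` simulates a cohort, extracts features for
every patient, performs leave-one-patient-out cross-validation with
fold-internal feature selection, and returns predictions plus per-patient
and mean metrics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from sozloc.classifier import leave_one_patient_out
from sozloc.contact_features import RegionalRates, build_feature_table, feature_table_manifest
from sozloc.hfo import DetectorParams, detect_hfos
from sozloc.io import Recording
from sozloc.metrics import per_patient_metrics
from sozloc.selection import ShapHTSelector
from sozloc.simulate import SimulationConfig, simulate_cohort
from sozloc.spikes import detect_spikes

__all__ = ["extract_patient_features", "run_study", "match_events"]


def extract_patient_features(
    recording: Recording,
    contacts: pd.DataFrame,
    detectors: tuple[str, ...] = ("reference",),
    params_ripple: DetectorParams | None = None,
    params_fr: DetectorParams | None = None,
    regional_rates: RegionalRates | None = None,
) -> pd.DataFrame:
    """Detect all biomarkers on one patient's recording and build the
    contact feature table."""
    hfo_events = detect_hfos(recording, params_ripple, params_fr)
    spike_events = {det: detect_spikes(recording, det) for det in detectors}
    return build_feature_table(
        recording, contacts, hfo_events, spike_events, regional_rates=regional_rates
    )


def match_events(detected, ground_truth, kind: str) -> tuple[float, float]:
    """Event-level sensitivity and precision by span overlap.

    A ground-truth event counts as hit when any detection of the same
    kind on the same contact overlaps it in time; a detection is a true
    positive when it overlaps any ground-truth event of the kind.
    """
    gts = [g for g in ground_truth if g.kind == kind]
    dets = list(detected)

    def overlaps(d, g):
        return d.contact == g.contact and d.start < g.onset + g.duration and g.onset < d.end

    hits = sum(1 for g in gts if any(overlaps(d, g) for d in dets))
    true_dets = sum(1 for d in dets if any(overlaps(d, g) for g in gts))
    sens = hits / len(gts) if gts else float("nan")
    prec = true_dets / len(dets) if dets else float("nan")
    return sens, prec


def run_study(
    n_patients: int = 10,
    config: SimulationConfig | None = None,
    seed: int = 0,
    detectors: tuple[str, ...] = ("reference",),
    use_selection: bool = True,
    classifier_params: dict | None = None,
) -> dict:
    """Simulate a cohort and run the full pipeline under LOPO-CV.

    Returns a dict with ``features`` (the pooled contact feature table),
    ``predictions``, ``per_patient`` metrics table, ``mean`` metrics and
    the ``folds`` plan.
    """
    config = config or SimulationConfig()
    cohort = simulate_cohort(n_patients, config, seed=seed)
    tables = []
    for patient in cohort:
        contacts = patient["contacts"]
        table = extract_patient_features(
            patient["recording"], contacts, detectors=detectors
        )
        tables.append(table)
    features = pd.concat(tables, ignore_index=True)
    feature_cols = feature_table_manifest(features)

    selector_factory = None
    if use_selection:
        def selector_factory():
            return ShapHTSelector(random_state=seed)

    predictions, folds = leave_one_patient_out(
        features,
        feature_cols,
        classifier_params=classifier_params,
        selector_factory=selector_factory,
        seed=seed,
    )
    per_patient, mean = per_patient_metrics(predictions)
    return {
        "features": features,
        "predictions": predictions,
        "per_patient": per_patient,
        "mean": mean,
        "folds": folds,
        "cohort": cohort,
    }
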