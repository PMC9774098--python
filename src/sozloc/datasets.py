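"""Published reference-cohort tables used as pipeline inputs.

A clinical reference cohort of ten drug-resistant-epilepsy patients
(hippocampal sclerosis, Engel I outcome after SEEG-guided surgery)
underpins the method's reported cross-validated performance.  The
printed per-patient tables -- cohort composition (SOZ/non-SOZ contact
counts), the per-patient confusion counts of the leave-one-patient-out
evaluation, and the regional physiological ripple-rate constants -- are
inputs to this package: the composition parameterizes the synthetic
cohort generator, the confusion counts feed the metrics module, and the
regional rates drive ripple normalization.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "reference_cohort_composition",
    "reference_confusion_counts",
    "reference_regional_rates",
]

# per-patient (SOZ contacts, non-SOZ contacts)
_COMPOSITION = {
    "Pt1": (15, 55),
    "Pt2": (13, 45),
    "Pt3": (11, 43),
    "Pt4": (15, 36),
    "Pt5": (4, 29),
    "Pt6": (14, 34),
    "Pt7": (14, 40),
    "Pt8": (12, 18),
    "Pt9": (8, 26),
    "Pt10": (14, 23),
}

# per-patient confusion counts (TP, TN, FP, FN) of the leave-one-patient-out
# evaluation on the reference cohort
_CONFUSION = {
    "Pt1": (14, 55, 0, 1),
    "Pt2": (13, 39, 6, 0),
    "Pt3": (8, 42, 1, 3),
    "Pt4": (14, 33, 3, 1),
    "Pt5": (3, 29, 0, 1),
    "Pt6": (14, 27, 7, 0),
    "Pt7": (14, 36, 4, 0),
    "Pt8": (10, 15, 3, 2),
    "Pt9": (6, 24, 2, 2),
    "Pt10": (14, 19, 4, 0),
}


def reference_cohort_composition() -> pd.DataFrame:
    """SOZ / non-SOZ contact counts per patient of the reference cohort."""
    return pd.DataFrame(
        [
            {"patient_id": pid, "n_soz": s, "n_nsoz": n}
            for pid, (s, n) in _COMPOSITION.items()
        ]
    )


def reference_confusion_counts() -> pd.DataFrame:
    """Per-patient confusion counts of the reference evaluation."""
    return pd.DataFrame(
        [
            {"patient_id": pid, "TP": tp, "TN": tn, "FP": fp, "FN": fn}
            for pid, (tp, tn, fp, fn) in _CONFUSION.items()
        ]
    )


def reference_regional_rates() -> dict[int, float]:
    """95th-percentile physiological ripple rate (events/min) per atlas
    region index, for the regions represented in the reference cohort."""
    return {2: 19.5, 7: 3.5, 8: 2.7, 9: 2.0}
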