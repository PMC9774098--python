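"""Aggregate event streams into the per-contact feature table.

One row per contact: biomarker rates per minute (spike rate per detector,
ripple rate, normalized pathological ripple rate, fast-ripple rate, R&FR
rate) and the median of the per-event energy features of each biomarker
kind.  The normalized ripple rate applies a regional correction (a
published 95th-percentile physiological ripple rate per atlas region is
subtracted), clamps negatives to zero, and zeroes the contacts whose
ripple count falls in the lowest 10% of the patient's per-contact count
distribution ("regional + 10% threshold").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sozloc.event_features import event_feature_vector, feature_names
from sozloc.hfo import EventOfInterest
from sozloc.io import Recording, SchemaError
from sozloc.spikes import SpikeEvent

__all__ = [
    "RegionalRates",
    "DEFAULT_REGIONAL_RATES",
    "biomarker_rate",
    "normalize_ripple_rate",
    "median_energy_features",
    "build_feature_table",
    "feature_table_manifest",
    "KIND_PREFIX",
]

#: published 95th-percentile physiological ripple rates (events/min) by
#: atlas region index: medial/basal temporal; superior/middle/orbital
#: frontal; middle/inferior temporal; anterior/middle cingulate.
DEFAULT_REGIONAL_RATES: dict[int, float] = {2: 19.5, 7: 3.5, 8: 2.7, 9: 2.0}

KIND_PREFIX = {"spike": "spike", "ripple": "r", "fast_ripple": "fr", "r_and_fr": "rfr"}

MISSING = np.nan  # sentinel before imputation


@dataclass(frozen=True)
class RegionalRates:
    """Region index -> physiological ripple rate (events/min)."""

    rates: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_REGIONAL_RATES))
    missing: str = "warn"  # "warn" -> constant 0 with warning; "raise"

    def rate(self, region: int, contact: str = "?") -> float:
        if region in self.rates:
            return self.rates[region]
        if self.missing == "raise":
            raise KeyError(
                f"no physiological ripple rate for region {region} (contact {contact})"
            )
        warnings.warn(
            f"region {region} (contact {contact}) has no published physiological "
            "ripple rate; using 0"
        )
        return 0.0


def biomarker_rate(n_events: int, duration_s: float) -> float:
    """Events per minute over the analysis window."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return n_events / (duration_s / 60.0)


def normalize_ripple_rate(
    ripple_rates: np.ndarray,
    ripple_counts: np.ndarray,
    regions: np.ndarray,
    regional_rates: RegionalRates | None = None,
    contacts: list[str] | None = None,
    percentile: float = 10.0,
    count_rule: str = "quantile",
) -> np.ndarray:
    """Regional + 10% threshold normalization of per-contact ripple rates.

    Steps: (1) subtract the regional physiological constant;
    (2) clamp negatives to zero; (3) zero contacts whose ripple count is
    strictly below the empirical ``percentile``-th percentile (linear
    interpolation) of the patient's per-contact counts -- boundary ties
    are kept.  ``count_rule="total_fraction"`` instead zeroes contacts
    with fewer ripples than ``percentile``% of the patient's total ripple
    count (the literal low-count reading, kept behind this flag).
    """
    regional_rates = regional_rates or RegionalRates()
    rates = np.asarray(ripple_rates, dtype=float)
    counts = np.asarray(ripple_counts, dtype=float)
    regions = np.asarray(regions)
    if not (rates.shape == counts.shape == regions.shape):
        raise ValueError("per-contact arrays must share shape")
    names = contacts or [f"#{i}" for i in range(rates.size)]
    corrected = np.array(
        [r - regional_rates.rate(int(g), c) for r, g, c in zip(rates, regions, names)]
    )
    corrected = np.maximum(corrected, 0.0)
    if rates.size:
        if count_rule == "quantile":
            cutoff = np.percentile(counts, percentile)
        elif count_rule == "total_fraction":
            cutoff = (percentile / 100.0) * counts.sum()
        else:
            raise ValueError(f"unknown count_rule {count_rule!r}")
        corrected[counts < cutoff] = 0.0
    return corrected


def median_energy_features(feature_vectors: list[dict[str, float]]) -> dict[str, float]:
    """Per-feature median over the event feature vectors of one contact."""
    if not feature_vectors:
        return {}
    names = list(feature_vectors[0])
    for vec in feature_vectors[1:]:
        if list(vec) != names:
            raise SchemaError("event feature vectors have inconsistent name sets")
    return {
        name: float(np.median([vec[name] for vec in feature_vectors])) for name in names
    }


def _event_segment(recording: Recording, ev: EventOfInterest) -> np.ndarray:
    fs = recording.sampling_rate
    i0 = max(int(round(ev.start * fs)), 0)
    i1 = min(int(round(ev.end * fs)), recording.n_samples)
    return recording.channel(ev.contact)[i0:i1]


def build_feature_table(
    recording: Recording,
    contact_table: pd.DataFrame,
    hfo_events: dict[str, list[EventOfInterest]],
    spike_events: dict[str, list[SpikeEvent]],
    regional_rates: RegionalRates | None = None,
    duration: float | None = None,
    subbands: tuple[str, ...] = ("a4", "d4"),
    impute: bool = True,
) -> pd.DataFrame:
    """One feature row per contact of one patient.

    ``hfo_events`` maps band -> events, ``spike_events`` maps detector id
    -> events.  ``duration`` defaults to the recording length; rates are
    per minute of that window.  Energy columns of contacts with no event
    of a kind are imputed with the per-patient column median (the imputed
    (contact, column) pairs are stored in ``table.attrs["imputed"]``); rate
    columns of event-free contacts are exactly 0.
    """
    duration = duration if duration is not None else recording.duration
    contacts = list(contact_table["contact"])
    known = set(contacts)
    for band, evs in hfo_events.items():
        for ev in evs:
            if ev.contact not in known:
                raise SchemaError(
                    f"{band} event on contact {ev.contact!r} absent from contact table"
                )
    for det, evs in spike_events.items():
        for ev in evs:
            if ev.contact not in known:
                raise SchemaError(
                    f"spike ({det}) on contact {ev.contact!r} absent from contact table"
                )

    rows = []
    fs = recording.sampling_rate
    for _, meta in contact_table.iterrows():
        c = meta["contact"]
        row: dict[str, float] = {
            "contact": c,
            "patient_id": meta["patient_id"],
            "region": int(meta["region"]),
        }
        for det in sorted(spike_events):
            n = sum(1 for ev in spike_events[det] if ev.contact == c)
            row[f"spike_rate_{det}"] = biomarker_rate(n, duration)
        for band, col in [
            ("ripple", "ripple_rate"),
            ("fast_ripple", "fr_rate"),
            ("r_and_fr", "rfr_rate"),
        ]:
            n = sum(1 for ev in hfo_events.get(band, []) if ev.contact == c)
            row[col] = biomarker_rate(n, duration)
            row[f"_count_{band}"] = n
        # energy medians
        for det in sorted(spike_events):
            vecs = [
                event_feature_vector(ev.segment, fs, "spike", subbands)
                for ev in spike_events[det]
                if ev.contact == c
            ]
            med = median_energy_features(vecs)
            for name in feature_names("spike", subbands):
                row[f"spike_{det}_{name}"] = med.get(name, MISSING)
        for band in ("ripple", "fast_ripple", "r_and_fr"):
            prefix = KIND_PREFIX[band]
            vecs = []
            for ev in hfo_events.get(band, []):
                if ev.contact != c:
                    continue
                seg = _event_segment(recording, ev)
                if seg.size >= 8:
                    vecs.append(event_feature_vector(seg, fs, band, subbands))
            med = median_energy_features(vecs)
            for name in feature_names(band, subbands):
                row[f"{prefix}_{name}"] = med.get(name, MISSING)
        if "soz_label" in meta:
            row["label"] = int(meta["soz_label"])
        rows.append(row)

    table = pd.DataFrame(rows)
    table["ripple_rate_normalized"] = normalize_ripple_rate(
        table["ripple_rate"].to_numpy(),
        table["_count_ripple"].to_numpy(),
        table["region"].to_numpy(),
        regional_rates,
        contacts=contacts,
    )
    table = table.drop(columns=[c for c in table.columns if c.startswith("_count_")])
    # column order: metadata, rates, normalized rate, energy, label
    meta_cols = ["contact", "patient_id", "region"]
    rate_cols = [
        c
        for c in table.columns
        if (c.endswith("_rate") or "_rate_" in c)
        and c not in meta_cols
        and c != "ripple_rate_normalized"
    ]
    other = [
        c
        for c in table.columns
        if c not in meta_cols + rate_cols + ["ripple_rate_normalized", "label"]
    ]
    ordered = meta_cols + rate_cols + ["ripple_rate_normalized"] + other
    if "label" in table.columns:
        ordered.append("label")
    table = table[ordered]

    if impute:
        energy_cols = other
        mask = table[energy_cols].isna()
        med = table[energy_cols].median()
        table.loc[:, energy_cols] = table[energy_cols].fillna(med).fillna(0.0)
        table.attrs["imputed"] = [
            (table.loc[i, "contact"], col)
            for col in energy_cols
            for i in table.index[mask[col]]
        ]
    return table


def feature_table_manifest(table: pd.DataFrame) -> list[str]:
    """The ordered feature-column names (excluding metadata and label)."""
    return [
        c
        for c in table.columns
        if c not in ("contact", "patient_id", "region", "label")
    ]
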