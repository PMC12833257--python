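"""End-to-end glue: per-recording feature extraction and cohort tables.

This is the path the analysis drivers, the CLI, and the acceptance checks
all share: generate (or load) a multimodal recording set, run each modality
through its feature extractor, and assemble the fusion feature table.
"""

from __future__ import annotations

import warnings

import pandas as pd

from neuroadapt.eeg_features import (
    BandDefinition, alpha_asymmetry, band_powers, theta_beta_ratio,
    coherence_msc,
)
from neuroadapt.synth.eeg import BANDS, FRONTAL_SITES, TEMPORAL_SITES
from neuroadapt.cardiac_features import detect_rpeaks, hrv_metrics
from neuroadapt.gaze_features import gaze_metrics
from neuroadapt.fusion import FeatureTable, assemble_features
from neuroadapt.synth.cohort import CohortBundle, RecordingSet


def eeg_feature_row(eeg) -> dict[str, float]:
    bp = band_powers(eeg, BANDS)
    row = {f"power.{ch}.{band}": bp.get(ch, band)
           for ch in eeg.labels for band in BANDS}
    row["tbr"] = theta_beta_ratio(bp)
    row["alpha_asymmetry"] = alpha_asymmetry(bp)
    row["gamma_coherence_ft"] = coherence_msc(
        eeg, list(FRONTAL_SITES), list(TEMPORAL_SITES),
        BandDefinition("gamma", 30.0, 45.0))
    return row


def ecg_feature_row(rr) -> dict[str, float]:
    return hrv_metrics(rr)


def gaze_feature_row(gaze, task: str = "freeview") -> dict[str, float]:
    return gaze_metrics(gaze, task=task)


def extract_features(rec: RecordingSet, use_detected_rr: bool = True,
                     gaze_task: str = "freeview") -> dict:
    """One fusion-table row from one multimodal recording set.

    ``use_detected_rr`` runs R-peak detection on the ECG trace (the honest
    pipeline); setting it False uses the generator's ground-truth RR.
    """
    rr = rec.rr
    if use_detected_rr:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            detected = detect_rpeaks(rec.ecg)
        if detected.n_beats >= 30:
            rr = detected
    return {
        "participant": rec.profile.pid,
        "group": rec.profile.group,
        "condition": rec.condition,
        "recruitment_order": rec.profile.recruitment_order,
        "eeg": eeg_feature_row(rec.eeg),
        "ecg": ecg_feature_row(rr),
        "gaze": gaze_feature_row(rec.gaze, task=gaze_task),
    }


def cohort_feature_table(bundle: CohortBundle,
                         use_detected_rr: bool = True) -> FeatureTable:
    rows = [extract_features(rec, use_detected_rr=use_detected_rr)
            for rec in bundle.recordings]
    return assemble_features(rows)


def feature_table_to_csv(table: FeatureTable, path) -> None:
    table.frame.to_csv(path, index=False, float_format="%.6g")


def feature_table_from_csv(path) -> FeatureTable:
    return FeatureTable(frame=pd.read_csv(path))
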