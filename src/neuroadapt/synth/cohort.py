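"""Cohort assembly: generate and (optionally) write full multimodal
recording sets for a stratified synthetic cohort.

The manifest (JSON) lists every (participant, condition) recording set with
its file paths and per-participant seed; the whole bundle is reproducible
bit-for-bit from the master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from neuroadapt.signatures import GROUPS, GROUP_PROPORTIONS, SignaturePanel
from neuroadapt.signals import ChannelTimeSeries, GazeStream, RRSeries
from neuroadapt.synth.profiles import ParticipantProfile, sample_profile
from neuroadapt.synth.eeg import synth_eeg
from neuroadapt.synth.cardiac import synth_rr, synth_ecg_trace
from neuroadapt.synth.gaze import synth_gaze


def group_counts(n_total: int,
                 proportions: dict[str, float] | None = None) -> dict[str, int]:
    """Largest-remainder apportionment of ``n_total`` over the four groups
    (default stratification ASD 26% / ADHD 22% / SLD 19% / TD 33%)."""
    props = proportions or GROUP_PROPORTIONS
    raw = {g: n_total * props[g] for g in GROUPS}
    counts = {g: int(np.floor(raw[g])) for g in GROUPS}
    rem = n_total - sum(counts.values())
    for g in sorted(GROUPS, key=lambda g: raw[g] - counts[g], reverse=True)[:rem]:
        counts[g] += 1
    return counts


@dataclass
class RecordingSet:
    profile: ParticipantProfile
    condition: str
    eeg: ChannelTimeSeries
    ecg: ChannelTimeSeries
    rr: RRSeries
    gaze: GazeStream


@dataclass
class CohortBundle:
    recordings: list[RecordingSet]
    master_seed: int
    manifest: list[dict] = field(default_factory=list)


def synth_cohort(
    n_per_group: int | dict[str, int],
    conditions: list[str],
    seed: int,
    out_dir: str | Path | None = None,
    panel: SignaturePanel | None = None,
    eeg_s: float = 60.0,
    ecg_s: float = 180.0,
    gaze_s: float = 60.0,
    gaze_task: str = "freeview",
) -> CohortBundle:
    """Generate a cohort of multimodal recording sets.

    ``n_per_group`` is either a per-group count or a dict of counts (use
    :func:`group_counts` for the stratified proportions). When ``out_dir``
    is given the recordings are written in the delimited text interchange
    formats with a ``manifest.json``.
    """
    if isinstance(n_per_group, int):
        if n_per_group < 1:
            raise ValueError("n_per_group must be at least 1")
        counts = {g: n_per_group for g in GROUPS}
    else:
        counts = dict(n_per_group)
    panel = panel or SignaturePanel.default()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(seed)
    recordings: list[RecordingSet] = []
    manifest: list[dict] = []
    order = 0
    for group in GROUPS:
        for i in range(counts.get(group, 0)):
            child_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            profile = sample_profile(group, panel, child_seed,
                                     pid=f"{group}{i:03d}")
            profile.recruitment_order = order
            order += 1
            for condition in conditions:
                rr = synth_rr(profile, condition, duration_s=ecg_s)
                rec = RecordingSet(
                    profile=profile, condition=condition,
                    eeg=synth_eeg(profile, condition, duration_s=eeg_s),
                    ecg=synth_ecg_trace(rr, fs=500.0, snr_db=20.0,
                                        seed=child_seed),
                    rr=rr,
                    gaze=synth_gaze(profile, condition, task=gaze_task,
                                    duration_s=gaze_s),
                )
                recordings.append(rec)
                entry = {
                    "participant": profile.pid, "group": group,
                    "condition": condition, "seed": child_seed,
                    "recruitment_order": profile.recruitment_order,
                }
                if out is not None:
                    stem = f"{profile.pid}_{condition}"
                    rec.eeg.to_files(out / f"{stem}_eeg")
                    rec.ecg.to_files(out / f"{stem}_ecg")
                    rec.rr.to_file(out / f"{stem}_rr.csv")
                    rec.gaze.to_files(out / f"{stem}_gaze")
                    entry["files"] = {
                        "eeg": f"{stem}_eeg.csv", "ecg": f"{stem}_ecg.csv",
                        "rr": f"{stem}_rr.csv", "gaze": f"{stem}_gaze.csv",
                    }
                manifest.append(entry)

    if out is not None:
        (out / "manifest.json").write_text(
            json.dumps({"seed": seed, "recordings": manifest}, indent=1,
                       sort_keys=True))
    return CohortBundle(recordings=recordings, master_seed=seed,
                        manifest=manifest)
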