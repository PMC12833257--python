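"""Generate the synthetic multimodal cohort.

Draws a stratified cohort (ASD 26% / ADHD 22% / SLD 19% / TD 33%) from the
default signature panel and synthesizes, per participant and condition,
EEG (9-channel, 256 Hz), a Lead-II-style ECG trace with its ground-truth RR
series, and 1200 Hz gaze. Recordings are written to scratch/cohort/ (bulky,
regenerable); the manifest summary goes to results/.
"""

import json
from pathlib import Path

from neuroadapt.synth import synth_cohort, group_counts

ROOT = Path(__file__).resolve().parents[1]
SEED = 42
N_TOTAL = 60


def main() -> None:
    counts = group_counts(N_TOTAL)
    print("cohort counts:", counts)
    out = ROOT / "scratch" / "cohort"
    bundle = synth_cohort(counts, ["traditional", "AR"], seed=SEED,
                          out_dir=out, eeg_s=60.0, ecg_s=180.0, gaze_s=60.0)
    print(f"wrote {len(bundle.recordings)} recording sets to {out}")

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    (results / "cohort_summary.json").write_text(json.dumps({
        "seed": SEED, "counts": counts,
        "n_recordings": len(bundle.recordings),
        "conditions": ["traditional", "AR"],
    }, indent=1))


if __name__ == "__main__":
    main()
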