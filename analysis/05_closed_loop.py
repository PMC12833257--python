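"""Three-condition closed-loop comparison.

Simulates 18 clinical-profile learners (6 ASD, 6 ADHD, 6 SLD) through
45-minute sessions under the adaptive, reactive, and fixed policies
(Latin-square condition order, 2 sessions per condition) and summarizes
learning efficiency, state occupancy, cognitive-load z-scores, detection
latency, and preventive-adjustment fractions per condition.

Expected pattern: the physiologically-adaptive controller masters the most
items per hour and keeps overload time lowest; the therapist-reactive
condition is intermediate (its corrections arrive a behavioral lag of
~41 s plus a reaction time late); the fixed schedule escalates difficulty
regardless of state and spends most of the session in overload.
"""

from pathlib import Path

from neuroadapt.adaptive import compare_conditions
from neuroadapt.signatures import SignaturePanel
from neuroadapt.synth import sample_profile

ROOT = Path(__file__).resolve().parents[1]
SEED = 11


def main() -> None:
    panel = SignaturePanel.default()
    profiles = [sample_profile(("ASD", "ADHD", "SLD")[i % 3], panel, 100 + i)
                for i in range(18)]
    per_session, summary = compare_conditions(profiles, n_sessions=2,
                                              seed=SEED)
    cols = ["items_per_hour", "pct_optimal", "pct_overload",
            "detection_latency_s", "preventive_pct", "mean_tbr_z"]
    for c in cols:
        m = summary[(c, "mean")]
        print(f"{c:22s} adaptive {m['adaptive']:7.2f}  "
              f"reactive {m['reactive']:7.2f}  fixed {m['fixed']:7.2f}")

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    per_session.to_csv(out / "closed_loop_sessions.csv", index=False,
                       float_format="%.4g")
    summary.to_csv(out / "closed_loop_summary.csv", float_format="%.4g")
    print("\nwrote", out / "closed_loop_summary.csv")


if __name__ == "__main__":
    main()
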