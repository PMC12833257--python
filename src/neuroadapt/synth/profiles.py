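"""Participant profiles: individual parameter draws around group means.

A profile fixes, for one synthetic participant, the individual target value
of every signature parameter under each condition. Individual values are
drawn as ``group mean + z * between_subject_SD`` with a *shared* standard
normal ``z`` per parameter across conditions, so a participant who sits high
in the group distribution under traditional instruction also sits high under
AR — the within-subject consistency paired designs rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields, asdict

import numpy as np

from neuroadapt.signatures import (
    CONDITIONS, GROUPS, GroupSignature, SignaturePanel,
)

# Truncation ranges keeping individual draws physiologically valid.
_BOUNDS = {
    "gamma_coherence": (0.02, 0.98),
    "alpha_asymmetry": (-0.95, 3.0),
    "on_task_pct": (5.0, 99.0),
    "regression_pct": (0.0, 95.0),
    "lf_hf": (0.2, 12.0),
    "sample_entropy": (0.2, 3.0),
    "resting_tbr": (0.3, 8.0),
}
_POSITIVE_FLOOR = 1e-3


@dataclass
class ParticipantProfile:
    """Individual signature targets for one synthetic participant.

    ``params[condition][field]`` is the participant's own target (a scalar;
    ``(mean, sd)`` panel pairs collapse to the individual mean). The resting
    TBR baseline keeps its (mean, SD) pair — the closed-loop controller
    z-scores live TBR against it.
    """

    pid: str
    group: str
    params: dict[str, dict[str, float]]
    resting_tbr: tuple[float, float]
    seed: int
    recruitment_order: int = 0

    def target(self, condition: str, name: str) -> float:
        return self.params[condition][name]


def _truncate(name: str, value: float) -> float:
    lo, hi = _BOUNDS.get(name, (_POSITIVE_FLOOR, np.inf))
    return float(np.clip(value, lo, hi))


def sample_profile(
    group: str,
    panel: SignaturePanel,
    rng_seed: int,
    pid: str | None = None,
    between_subject_scale: float = 1.0,
) -> ParticipantProfile:
    """Draw one participant's individual parameters.

    ``between_subject_scale`` multiplies every between-subject SD (0 gives a
    participant exactly at the group means). Deterministic given
    ``(group, panel, rng_seed)``.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    rng = np.random.default_rng(rng_seed)
    names = [f.name for f in dc_fields(GroupSignature)]
    zs = {name: rng.standard_normal() for name in names}

    params: dict[str, dict[str, float]] = {}
    tbr_pair = (1.0, 0.1)
    for condition in CONDITIONS:
        cell = asdict(panel.get(group, condition))
        drawn: dict[str, float] = {}
        for name in names:
            v = cell[name]
            if isinstance(v, (tuple, list)):
                mean, sd = v
            else:
                mean, sd = v, 0.12 * abs(v)  # scalar panel entries: mild spread
            value = mean + zs[name] * sd * between_subject_scale
            drawn[name] = _truncate(name, value)
        # individual beta tracks the individual theta/TBR pair
        drawn["beta"] = max(drawn["theta"] / drawn["resting_tbr"], _POSITIVE_FLOOR)
        params[condition] = drawn
        if condition == "traditional":
            within_sd = max(0.15 * drawn["resting_tbr"], 1e-3)
            tbr_pair = (drawn["resting_tbr"], within_sd)

    return ParticipantProfile(
        pid=pid if pid is not None else f"{group}-{rng_seed}",
        group=group, params=params, resting_tbr=tbr_pair, seed=rng_seed,
    )
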