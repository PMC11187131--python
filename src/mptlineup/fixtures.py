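"""Packaged response-frequency fixtures for the two published experiments.

Each experiment crossed lineup size (three vs. six members) with lineup
instructions (low-culprit-probability vs. neutral); every participant
responded to two culprit-present and two culprit-absent lineups, so each
tree total is twice the group's participant count. Experiment 1 used
sequential lineups, Experiment 2 simultaneous lineups.

Counts are ordered (suspect/culprit identification, filler identification,
lineup rejection).
"""

from __future__ import annotations

from .lineup import ABSENT, PRESENT, GroupSpec, study_groups, tree_name
from .mpt import FrequencyTable

# group label -> {present: (suspect, filler, rejection), absent: ...}
_EXP1 = {
    "three_low": {PRESENT: (212, 92, 200), ABSENT: (73, 124, 307)},
    "three_neutral": {PRESENT: (260, 122, 128), ABSENT: (131, 166, 213)},
    "six_low": {PRESENT: (126, 166, 218), ABSENT: (52, 205, 253)},
    "six_neutral": {PRESENT: (152, 214, 122), ABSENT: (72, 252, 164)},
}

_EXP2 = {
    "three_low": {PRESENT: (217, 62, 227), ABSENT: (78, 91, 337)},
    "three_neutral": {PRESENT: (255, 93, 170), ABSENT: (94, 140, 284)},
    "six_low": {PRESENT: (149, 99, 270), ABSENT: (39, 116, 363)},
    "six_neutral": {PRESENT: (186, 130, 196), ABSENT: (62, 177, 273)},
}

_RAW = {"exp1": _EXP1, "exp2": _EXP2}

#: participants per group, same ordering as study_groups()
PARTICIPANTS = {
    "exp1": {"three_low": 252, "three_neutral": 255, "six_low": 255, "six_neutral": 244},
    "exp2": {"three_low": 253, "three_neutral": 259, "six_low": 259, "six_neutral": 256},
}

#: total participants entering each experiment's sensitivity analysis
N_PARTICIPANTS = {"exp1": 1006, "exp2": 1027}
RESPONSES_PER_PARTICIPANT = 4

EXPERIMENTS = tuple(sorted(_RAW))


def available() -> tuple[str, ...]:
    return EXPERIMENTS


def fixture(experiment: str) -> tuple[list[GroupSpec], FrequencyTable]:
    """Group specifications and the observed frequency table of one
    experiment ("exp1" or "exp2")."""
    if experiment not in _RAW:
        raise KeyError(
            f"unknown experiment {experiment!r}; available: {', '.join(EXPERIMENTS)}"
        )
    raw = _RAW[experiment]
    groups = study_groups()
    counts: dict[str, dict[str, int]] = {}
    from .lineup import CATEGORIES

    for g in groups:
        for lt in (PRESENT, ABSENT):
            counts[tree_name(g.label, lt)] = dict(zip(CATEGORIES, raw[g.label][lt]))
    return groups, FrequencyTable(counts)
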