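"""Fixed vocabulary of the nine shared-decision-making skills.

The nine-item physician questionnaire (SDM-Q-Doc) rates, per consultation,
how strongly each behavioural skill was shown on a 0-5 Likert-type scale.
Skill indices are 1-based throughout the package and their semantics are
fixed; column names in rating tables are ``skill_1`` ... ``skill_9``.
"""

from __future__ import annotations

N_SKILLS = 9

#: 1-based skill index -> short behavioural label.
SKILL_NAMES: dict[int, str] = {
    1: "focusing the decision",
    2: "sharing the decision",
    3: "presenting options",
    4: "informing on options",
    5: "supporting comprehension",
    6: "eliciting preferences",
    7: "deliberating the decision",
    8: "selecting an option",
    9: "planning actions",
}

SKILL_COLUMNS: list[str] = [f"skill_{j}" for j in range(1, N_SKILLS + 1)]

ID_COLUMNS: list[str] = ["physician_id", "consultation_id"]

RATING_MIN = 0.0
RATING_MAX = 5.0

#: Network parameter types attached to each skill.
PARAM_TYPES = ("activation", "instrength", "outstrength")

#: Observer instruments rating recorded consultations, rescaled to 0-100.
INSTRUMENTS = ("OPTION-12", "OPTION-5", "4HCS")


def skill_column(j: int) -> str:
    """Column name for 1-based skill index ``j``."""
    if not 1 <= j <= N_SKILLS:
        raise ValueError(f"skill index must be in 1..{N_SKILLS}, got {j}")
    return f"skill_{j}"
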