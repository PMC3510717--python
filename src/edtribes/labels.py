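"""Community class labels shared by all analysis stages."""

from __future__ import annotations

import enum


class ClassLabel(str, enum.Enum):
    """Per-user community assignment.

    ``PRO_ANA`` users create and disseminate content with a positive,
    encouraging attitude toward eating disorders; ``PRO_RECOVERY`` users
    present eating disorders as diseases to recover from.  ``NEUTRAL`` users
    were rated but fall between the two camps; ``UNLABELED`` users received
    no usable ratings.
    """

    PRO_ANA = "pro_ana"
    PRO_RECOVERY = "pro_recovery"
    NEUTRAL = "neutral"
    UNLABELED = "unlabeled"

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.value


#: The two labels that define the antagonistic communities.
COMMUNITY_LABELS = (ClassLabel.PRO_ANA, ClassLabel.PRO_RECOVERY)


def other_class(label: ClassLabel) -> ClassLabel:
    """Return the opposing community label."""
    if label is ClassLabel.PRO_ANA:
        return ClassLabel.PRO_RECOVERY
    if label is ClassLabel.PRO_RECOVERY:
        return ClassLabel.PRO_ANA
    raise ValueError(f"{label} has no opposing community")
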