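"""Shared three-way verdict type used by every individual test in the design."""

from __future__ import annotations

from enum import Enum


class Verdict(str, Enum):
    """Outcome of a single statistical test against the M0/M1 model pair."""

    SUPPORT_M0 = "support_M0"
    SUPPORT_M1 = "support_M1"
    INCONCLUSIVE = "inconclusive"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def decisive(self) -> bool:
        return self is not Verdict.INCONCLUSIVE
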