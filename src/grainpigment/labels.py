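"""Pigment-composition labels.

A barley accession's seed coat may contain anthocyanins (blue/purple
flavonoids), melanin (gray/black polymer), both, or neither.  The label is
therefore a pair of presence flags, in bijection with the 4-class code
{NP, A, M, AM} used throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PigmentLabel", "CLASS_CODES"]

CLASS_CODES = ("NP", "A", "M", "AM")


@dataclass(frozen=True, order=True)
class PigmentLabel:
    """Presence flags for the two seed-coat pigments.

    The 4-class code mapping is a bijection:
    (False, False) = NP, (True, False) = A, (False, True) = M,
    (True, True) = AM.
    """

    anthocyanin: bool
    melanin: bool

    @property
    def code(self) -> str:
        if self.anthocyanin and self.melanin:
            return "AM"
        if self.anthocyanin:
            return "A"
        if self.melanin:
            return "M"
        return "NP"

    @classmethod
    def from_code(cls, code: str) -> "PigmentLabel":
        try:
            idx = CLASS_CODES.index(code.upper())
        except ValueError:
            raise ValueError(
                f"unknown pigment class code {code!r}; expected one of {CLASS_CODES}"
            ) from None
        return cls(anthocyanin=idx in (1, 3), melanin=idx in (2, 3))

    def as_pair(self) -> tuple[int, int]:
        """(anthocyanin, melanin) as 0/1 integers."""
        return int(self.anthocyanin), int(self.melanin)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code
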