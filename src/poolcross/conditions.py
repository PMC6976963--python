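"""Experimental conditions of the cross/selection design.

The design sequences 13 pooled samples: one shared founder pool (F0) plus,
for each of three insecticide lines (deltamethrin, bendiocarb, fenitrothion),
the F0 survivors of an LD80 exposure, the unexposed F2, and the F2 survivors
of LD25 and LD75 exposures.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Line(str, Enum):
    """Insecticide selection line; NONE marks the shared founder sample."""

    DELT = "Delt"
    BEND = "Bend"
    FENI = "Feni"
    NONE = "none"


class Stage(str, Enum):
    F0 = "F0"
    F0_LD80 = "F0_LD80"
    F2 = "F2"
    F2_LD25 = "F2_LD25"
    F2_LD75 = "F2_LD75"


SELECTED_LINES = (Line.DELT, Line.BEND, Line.FENI)
LINE_STAGES = (Stage.F0_LD80, Stage.F2, Stage.F2_LD25, Stage.F2_LD75)


@dataclass(frozen=True)
class Condition:
    """A (line, stage) label indexing one of the 13 pooled samples.

    Stage F0 is the shared founder pool and carries line NONE; every other
    stage belongs to a concrete insecticide line.
    """

    line: Line
    stage: Stage

    def __post_init__(self) -> None:
        if self.stage is Stage.F0:
            if self.line is not Line.NONE:
                raise ValueError("stage F0 is the shared founder sample (line none)")
        elif self.line is Line.NONE:
            raise ValueError(f"stage {self.stage.value} requires a concrete line")

    @property
    def label(self) -> str:
        if self.stage is Stage.F0:
            return "F0"
        return f"{self.line.value}_{self.stage.value}"

    @classmethod
    def from_label(cls, label: str) -> "Condition":
        if label == "F0":
            return cls(Line.NONE, Stage.F0)
        line_str, _, stage_str = label.partition("_")
        try:
            return cls(Line(line_str), Stage(stage_str))
        except ValueError as exc:
            raise ValueError(f"unknown condition label {label!r}") from exc

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


F0_CONDITION = Condition(Line.NONE, Stage.F0)

#: The 13 sequenced pools, in canonical column order.
ALL_CONDITIONS: tuple[Condition, ...] = (F0_CONDITION,) + tuple(
    Condition(line, stage) for line in SELECTED_LINES for stage in LINE_STAGES
)

ALL_LABELS: tuple[str, ...] = tuple(c.label for c in ALL_CONDITIONS)


def line_conditions(line: Line) -> tuple[Condition, ...]:
    """The five conditions of one line's trajectory: shared F0 + four stages."""
    if line not in SELECTED_LINES:
        raise ValueError(f"{line!r} is not a selected insecticide line")
    return (F0_CONDITION,) + tuple(Condition(line, s) for s in LINE_STAGES)
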