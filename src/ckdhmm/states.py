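"""State space for CKD stage progression.

Kidney function is staged by eGFR (ml/min/1.73m^2) into the clinical CKD
categories, with G1 and G2 pooled (both have eGFR > 60 and are not
distinguishable from eGFR alone).  Death from any cause is an absorbing
state.  The ordering G1/2 < G3a < G3b < G4 < G5 is total and fixed; "more
severe" always means a larger index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Canonical stage labels.  File formats use the underscore form G1_2 to avoid
# the slash of "G1/2".
G1_2 = "G1_2"
G3A = "G3A"
G3B = "G3B"
G4 = "G4"
G5 = "G5"
DEATH = "DEATH"

LIVING_STAGES: tuple[str, ...] = (G1_2, G3A, G3B, G4, G5)
ALL_STATES: tuple[str, ...] = LIVING_STAGES + (DEATH,)

N_LIVING = len(LIVING_STAGES)
N_STATES = len(ALL_STATES)
DEATH_INDEX = N_STATES - 1

#: eGFR range (lower, upper) in ml/min/1.73m^2 per living stage; the ranges
#: partition (0, inf).
EGFR_RANGES: dict[str, tuple[float, float]] = {
    G1_2: (60.0, float("inf")),
    G3A: (45.0, 60.0),
    G3B: (30.0, 45.0),
    G4: (15.0, 30.0),
    G5: (0.0, 15.0),
}

STATE_INDEX: dict[str, int] = {s: i for i, s in enumerate(ALL_STATES)}

#: Display labels (slash form) keyed by canonical label.
DISPLAY_LABELS: dict[str, str] = {G1_2: "G1/2", G3A: "G3a", G3B: "G3b",
                                  G4: "G4", G5: "G5", DEATH: "Death"}


@dataclass(frozen=True)
class StateSpace:
    """Ordered living stages plus the absorbing death state."""

    living_stages: tuple[str, ...] = LIVING_STAGES
    death_state: str = DEATH
    egfr_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(EGFR_RANGES))

    @property
    def states(self) -> tuple[str, ...]:
        return self.living_stages + (self.death_state,)

    @property
    def n_living(self) -> int:
        return len(self.living_stages)

    def index(self, stage: str) -> int:
        """Integer index 0..5 of a stage label."""
        try:
            return self.states.index(stage)
        except ValueError:
            raise KeyError(f"unknown stage label {stage!r}") from None

    def is_living(self, stage: str) -> bool:
        return stage in self.living_stages

    def stage_of_egfr(self, egfr: float) -> str:
        """Map a continuous eGFR value to its stage category."""
        if egfr <= 0:
            raise ValueError("eGFR must be positive")
        for stage, (lo, hi) in self.egfr_ranges.items():
            if lo < egfr <= hi or (hi == float("inf") and egfr > lo):
                return stage
        raise AssertionError("eGFR ranges must partition (0, inf)")


#: Module-level default instance; the state space is fixed for this model.
STATE_SPACE = StateSpace()


def validate_stage(stage: str) -> int:
    """Return the index of *stage*, raising ``KeyError`` for unknown labels."""
    return STATE_SPACE.index(stage)
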