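"""State space for multi-state models of cognitive frailty.

The five study states are normal state (NS), cognitive impairment only
(CI), physical frailty only (PF), cognitive frailty (CF, both CI and PF)
and death.  Death is absorbing.  Direct moves between NS and CF and
between CI and PF are structurally forbidden: both would require two
phenotype components to flip at exactly the same instant, which has
probability zero in continuous time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum


class State(IntEnum):
    """Integer labels of the five study states."""

    NS = 1
    CI = 2
    PF = 3
    CF = 4
    DEATH = 5


class StructuralZeroError(ValueError):
    """A rate was supplied for a transition the model forbids."""


@dataclass(frozen=True)
class StateSpace:
    """A finite state space with an explicit set of allowed direct transitions.

    Parameters
    ----------
    labels
        Mapping of integer state code (1-based) to a short name.
    allowed
        Ordered tuple of (from, to) pairs with a free transition intensity.
        Every pair not listed is a structural zero.
    absorbing
        State codes with no exits.
    """

    labels: dict[int, str]
    allowed: tuple[tuple[int, int], ...]
    absorbing: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        codes = set(self.labels)
        if codes != set(range(1, len(codes) + 1)):
            raise ValueError("state codes must be 1..n without gaps")
        for r, s in self.allowed:
            if r == s:
                raise ValueError(f"self-transition ({r},{r}) cannot carry a rate")
            if r not in codes or s not in codes:
                raise ValueError(f"transition ({r},{s}) uses an unknown state code")
            if r in self.absorbing:
                raise ValueError(f"absorbing state {r} cannot have exit ({r},{s})")
        if len(set(self.allowed)) != len(self.allowed):
            raise ValueError("duplicate transition in allowed set")

    @property
    def n_states(self) -> int:
        return len(self.labels)

    @property
    def transient(self) -> tuple[int, ...]:
        return tuple(c for c in sorted(self.labels) if c not in self.absorbing)

    def is_allowed(self, r: int, s: int) -> bool:
        return (r, s) in set(self.allowed)

    def name(self, code: int) -> str:
        return self.labels[code]

    def with_transitions(self, *extra: tuple[int, int]) -> "StateSpace":
        """Return a copy with additional allowed transitions (for nested-model
        comparisons, e.g. freeing the NS<->CF intensities)."""
        new = [t for t in extra if t not in self.allowed]
        return StateSpace(self.labels, self.allowed + tuple(new), self.absorbing)


#: The five-state cognitive-frailty space with its structural zeros
#: (no direct NS<->CF or CI<->PF moves) and absorbing death.
FIVE_STATE = StateSpace(
    labels={1: "NS", 2: "CI", 3: "PF", 4: "CF", 5: "Death"},
    allowed=(
        (1, 2), (1, 3), (1, 5),
        (2, 1), (2, 4), (2, 5),
        (3, 1), (3, 4), (3, 5),
        (4, 2), (4, 3), (4, 5),
    ),
    absorbing=frozenset({5}),
)

#: Sensitivity-analysis variant with the NS<->CF intensities freed.
FIVE_STATE_FREE_NSCF = FIVE_STATE.with_transitions((1, 4), (4, 1))
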