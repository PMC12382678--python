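"""Markov state space for the monthly cow life-cycle model.

A cow's state is the triple (parity, month in milk, month in pregnancy);
``month_in_pregnancy == 0`` denotes an open (non-pregnant) cow.  The state
space is finite and includes a single absorbing CULLED state, so every cow
is eventually removed and expected lifetime quantities are finite.
"""

from __future__ import annotations

from dataclasses import dataclass

GESTATION_MONTHS = 9
DEFAULT_P_MAX = 12
DEFAULT_M_MAX = 24


class ConfigurationError(ValueError):
    """Raised when state-space bounds cannot accommodate the biology."""


@dataclass(frozen=True, order=True)
class CowState:
    """One live state of the monthly cow life cycle.

    Attributes
    ----------
    parity : int
        Number of calvings so far (1 = first lactation).
    month_in_milk : int
        Months since the most recent calving, starting at 1 in the
        calving month.
    month_in_pregnancy : int
        Months since conception; 0 for an open cow, 1..9 while pregnant.
    """

    parity: int
    month_in_milk: int
    month_in_pregnancy: int = 0

    @property
    def open(self) -> bool:
        return self.month_in_pregnancy == 0

    def __str__(self) -> str:  # compact, used in edge lists / reports
        return f"p{self.parity}m{self.month_in_milk}g{self.month_in_pregnancy}"


def parity_class(parity: int) -> int:
    """Pool parities into the standard lactation-curve classes {1, 2, 3+}."""
    return min(int(parity), 3)


class StateSpace:
    """Enumeration of all live cow states plus the absorbing CULLED state.

    Live states are all (p, m, g) with 1 <= p <= p_max, 1 <= m <= m_max and
    0 <= g <= min(gestation, m - 1).  Indices 0..n_transient-1 address live
    states in a stable order; ``culled_index`` addresses the absorbing state.
    """

    def __init__(self, p_max: int = DEFAULT_P_MAX, m_max: int = DEFAULT_M_MAX,
                 gestation: int = GESTATION_MONTHS):
        if p_max < 1:
            raise ConfigurationError("p_max must be >= 1")
        if m_max < gestation + 1:
            raise ConfigurationError(
                f"m_max={m_max} cannot accommodate a full {gestation}-month gestation"
            )
        self.p_max = int(p_max)
        self.m_max = int(m_max)
        self.gestation = int(gestation)
        states: list[CowState] = []
        for p in range(1, self.p_max + 1):
            for m in range(1, self.m_max + 1):
                for g in range(0, min(self.gestation, m - 1) + 1):
                    states.append(CowState(p, m, g))
        self.states: tuple[CowState, ...] = tuple(states)
        self._index = {s: i for i, s in enumerate(states)}
        self.n_transient = len(states)
        self.culled_index = self.n_transient

    @property
    def n_states(self) -> int:
        return self.n_transient + 1

    def index(self, state: CowState) -> int:
        try:
            return self._index[state]
        except KeyError:
            raise KeyError(f"state {state} not in space "
                           f"(p_max={self.p_max}, m_max={self.m_max})") from None

    def state(self, index: int) -> CowState:
        return self.states[index]

    def __contains__(self, state: CowState) -> bool:
        return state in self._index

    def __len__(self) -> int:
        return self.n_states

    def conception_eligible(self, state: CowState) -> bool:
        """Open cows can conceive from month in milk 2, and only while a
        full gestation still fits inside the month-in-milk grid."""
        return (state.month_in_pregnancy == 0
                and 2 <= state.month_in_milk <= self.m_max - self.gestation)


def build_state_space(p_max: int = DEFAULT_P_MAX, m_max: int = DEFAULT_M_MAX,
                      gestation: int = GESTATION_MONTHS) -> StateSpace:
    """Build the enumerated state space (see :class:`StateSpace`)."""
    return StateSpace(p_max=p_max, m_max=m_max, gestation=gestation)
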