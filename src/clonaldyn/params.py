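"""Parameter containers for the single-progenitor (SP) model.

The SP model describes a single equipotential population of basal
progenitors. Each division produces two progenitors (PP), one progenitor
and one differentiating cell (PD), or two differentiating cells (DD).
A fate imbalance ``delta`` tilts the symmetric outcomes toward PP:

    P(PP) = r (1 + delta),  P(PD) = 1 - 2 r,  P(DD) = r (1 - delta)

so ``delta = 0`` recovers the balanced, homeostatic model and the mean
number of basal cells per induced clone grows asymptotically like
``exp(2 r lambda delta t)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

__all__ = ["SPParams", "SimConfig", "PUBLISHED_PARAMS"]


@dataclass(frozen=True)
class SPParams:
    """Rates of the single-progenitor fate model for one genotype.

    Parameters
    ----------
    r : float
        Probability of a symmetric division outcome, ``0 <= r <= 0.5``.
    division_rate : float
        Progenitor division rate ``lambda`` (divisions/week).
    stratification_rate : float
        Basal-exit rate ``Gamma`` of differentiating basal cells (/week).
    delta : float
        Fate imbalance, ``0 <= delta <= 1``; 0 is the neutral model.
    """

    r: float
    division_rate: float
    stratification_rate: float
    delta: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 0.5:
            raise ValueError(f"r must be in [0, 0.5], got {self.r}")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"delta must be in [0, 1], got {self.delta}")
        if self.division_rate < 0 or self.stratification_rate < 0:
            raise ValueError("rates must be non-negative")
        # total symmetric mass may not exceed 1
        if self.r * (1.0 + self.delta) + self.r * (1.0 - self.delta) > 1.0 + 1e-12:
            raise ValueError("2r > 1: invalid probability mass")

    @property
    def lam(self) -> float:
        return self.division_rate

    @property
    def gamma(self) -> float:
        return self.stratification_rate

    def outcome_probs(self, effective_delta: float | None = None) -> Tuple[float, float, float]:
        """(P(PP), P(PD), P(DD)) with an optional crowding-modified delta."""
        d = self.delta if effective_delta is None else effective_delta
        if abs(d) > 1.0:
            raise ValueError(f"|effective delta| must be <= 1, got {d}")
        return self.r * (1.0 + d), 1.0 - 2.0 * self.r, self.r * (1.0 - d)

    def growth_rate(self) -> float:
        """Asymptotic exponential growth rate ``2 r lambda delta`` (/week)."""
        return 2.0 * self.r * self.division_rate * self.delta


#: Published parameter combinations for mouse oesophageal epithelium
#: (r, Gamma/week, lambda/week, delta); all three encode growth rate
#: 2*r*lambda*delta ~ 0.11/week.
PUBLISHED_PARAMS: tuple[SPParams, ...] = (
    SPParams(r=0.1, division_rate=1.9, stratification_rate=3.5, delta=0.29),
    SPParams(r=0.06, division_rate=2.9, stratification_rate=3.7, delta=0.32),
    SPParams(r=0.1, division_rate=2.9, stratification_rate=5.4, delta=0.19),
)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one spatial cellular-automaton run.

    The default lattice is 100 x 100 = 10,000 sites, roughly 1% of the
    basal area of an adult mouse oesophagus, with periodic boundaries.
    """

    lattice_width: int = 100
    lattice_height: int = 100
    induction_fraction: float = 0.01
    duration: float = 52.0
    record_times: Sequence[float] = field(default_factory=tuple)
    seed: int = 0
    crowding_multiplier: float = 0.0

    def __post_init__(self) -> None:
        if self.lattice_width < 1 or self.lattice_height < 1:
            raise ValueError("lattice dimensions must be positive")
        if not 0.0 <= self.induction_fraction <= 1.0:
            raise ValueError(
                f"induction_fraction must be in [0, 1], got {self.induction_fraction}"
            )
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        rts = tuple(float(t) for t in self.record_times)
        if not rts:
            rts = (0.0, float(self.duration))
        if any(t < 0 or t > self.duration for t in rts):
            raise ValueError("record_times must lie within [0, duration]")
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("record_times must be strictly increasing")
        object.__setattr__(self, "record_times", rts)

    @property
    def n_sites(self) -> int:
        return self.lattice_width * self.lattice_height
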