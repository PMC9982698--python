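"""Domain types for trial design and classifier performance.

These are small frozen dataclasses with eager validation: every quantity is
a probability or a count, and silent out-of-range values are the classic way
power calculations go wrong.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum


def _check_prob(name: str, value: float, *, open_interval: bool = False) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if open_interval:
        if not (0.0 < value < 1.0):
            raise ValueError(f"{name} must lie strictly in (0, 1), got {value}")
    elif not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class TrialDesign:
    """A two-arm trial with a binary outcome.

    Parameters
    ----------
    n1, n2 : int
        Participants in the control and intervention arm.
    p1 : float
        True control-arm outcome probability, strictly in (0, 1).
    alpha : float
        Two-sided significance level.
    target_power : float
        Power at which the detectable risk difference is solved.
    """

    n1: int
    n2: int
    p1: float
    alpha: float = 0.05
    target_power: float = 0.80

    def __post_init__(self) -> None:
        for name, n in (("n1", self.n1), ("n2", self.n2)):
            if int(n) != n or n < 2:
                raise ValueError(f"{name} must be an integer >= 2, got {n!r}")
        _check_prob("p1", self.p1, open_interval=True)
        _check_prob("alpha", self.alpha, open_interval=True)
        _check_prob("target_power", self.target_power, open_interval=True)


@dataclass(frozen=True)
class ClassifierPerformance:
    """Sensitivity/specificity pair of a nondifferential outcome classifier.

    The pair is *identifiable* when ``sensitivity + specificity > 1``:
    otherwise the observed-proportion map is non-increasing in the true
    proportion and a detectable difference cannot be recovered.
    """

    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        _check_prob("sensitivity", self.sensitivity)
        _check_prob("specificity", self.specificity)

    @property
    def identifiable(self) -> bool:
        return self.sensitivity + self.specificity > 1.0

    @property
    def perfect(self) -> bool:
        return self.sensitivity == 1.0 and self.specificity == 1.0


PERFECT = ClassifierPerformance(1.0, 1.0)


class SolveStatus(str, Enum):
    """Outcome of a detectable-risk-difference solve.

    ``OK``               a root was found;
    ``NON_IDENTIFIABLE`` sensitivity + specificity <= 1, the problem is undefined;
    ``UNATTAINABLE``     power never reaches the target before p1 + rd hits 1.
    """

    OK = "ok"
    NON_IDENTIFIABLE = "non-identifiable"
    UNATTAINABLE = "unattainable"


@dataclass(frozen=True)
class PowerResult:
    """Power of one design/alternative pair, with the observed proportions."""

    power: float
    p2: float
    observed_p1: float
    observed_p2: float


@dataclass(frozen=True)
class RDSolution:
    """Detectable risk difference, as a fraction, with an explicit status.

    ``rd`` is NaN unless ``status`` is OK — sentinel states never silently
    become numbers.
    """

    rd: float
    status: SolveStatus

    @property
    def defined(self) -> bool:
        return self.status is SolveStatus.OK

    def __float__(self) -> float:
        return self.rd if self.defined else math.nan
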