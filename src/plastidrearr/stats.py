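"""Between-sample comparison of junction class counts.

Samples are compared on their raw +MH / -MH event counts with a Pearson
chi-square test of homogeneity on the 2x2 table (df = 1, no continuity
correction by default — raw counts, not coverage-normalized values, carry
the sampling model).  Coverage-normalized rates (events per genome copy)
are compared as fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats as sps

from .events import JunctionEvent, MH_CUTOFF

__all__ = ["MHCounts", "Chi2Result", "mh_chi2", "fold_change"]


@dataclass(frozen=True)
class MHCounts:
    """+MH / -MH unique-event counts for one sample, with coverage."""

    sample: str
    n_plus_mh: int
    n_minus_mh: int
    coverage: float

    def __post_init__(self):
        if self.n_plus_mh < 0 or self.n_minus_mh < 0:
            raise ValueError("counts must be >= 0")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")

    @property
    def rate_plus(self) -> float:
        """+MH events per genome copy."""
        return self.n_plus_mh / self.coverage

    @property
    def rate_minus(self) -> float:
        """-MH events per genome copy."""
        return self.n_minus_mh / self.coverage

    @classmethod
    def from_events(
        cls, sample: str, events: list[JunctionEvent], coverage: float,
        mh_cutoff: int = MH_CUTOFF,
    ) -> "MHCounts":
        plus = sum(1 for e in events if e.homology_len >= mh_cutoff)
        return cls(
            sample=sample, n_plus_mh=plus, n_minus_mh=len(events) - plus,
            coverage=coverage,
        )


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p_value: float


def mh_chi2(a: MHCounts, b: MHCounts, continuity: bool = False) -> Chi2Result:
    """Pearson chi-square on the 2x2 table [[a.+MH, a.-MH], [b.+MH, b.-MH]].

    Raises ValueError when a row or column is all zero (test undefined).
    """
    table = [[a.n_plus_mh, a.n_minus_mh], [b.n_plus_mh, b.n_minus_mh]]
    if any(sum(row) == 0 for row in table) or any(sum(col) == 0 for col in zip(*table)):
        raise ValueError("chi-square undefined: a row or column of the table is zero")
    res = sps.chi2_contingency(table, correction=continuity)
    return Chi2Result(statistic=float(res.statistic), df=int(res.dof), p_value=float(res.pvalue))


def fold_change(a: float, b: float) -> float:
    """Ratio a / b of two coverage-normalized rates."""
    if b == 0:
        raise ValueError("reference rate is zero; fold change undefined")
    return a / b
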