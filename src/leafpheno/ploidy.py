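"""Endoreduplication index (EI) from flow-cytometry ploidy-class counts.

Endoreduplication is genome duplication without mitosis; nuclei that have
undergone 0, 1, 2 or 3 endocycles carry 2C, 4C, 8C or 16C DNA content.
The EI is the mean number of endocycles per nucleus,

    EI = 0*f(2C) + 1*f(4C) + 2*f(8C) + 3*f(16C),

computed on class fractions so that samples with different nuclei totals
are comparable.  Input is pre-gated class counts (the instrument software
performs peak gating); classes above 16C are not accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PloidyDistribution", "endoreduplication_index", "ei_with_ci"]

#: endocycle count of each DNA class, in 2C/4C/8C/16C order
_ENDOCYCLES = np.array([0.0, 1.0, 2.0, 3.0])


@dataclass(frozen=True)
class PloidyDistribution:
    """Nuclei counts per DNA class 2C/4C/8C/16C."""

    n_2c: int
    n_4c: int
    n_8c: int
    n_16c: int

    def __post_init__(self):
        c = self.counts
        if np.any(c < 0):
            raise ValueError("ploidy counts must be non-negative")
        if c.sum() == 0:
            raise ValueError("ploidy distribution has zero nuclei")

    @property
    def counts(self) -> np.ndarray:
        return np.array([self.n_2c, self.n_4c, self.n_8c, self.n_16c])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def fractions(self) -> np.ndarray:
        c = self.counts
        return c / c.sum()


def endoreduplication_index(d: PloidyDistribution) -> float:
    """Mean endocycles per nucleus, in [0, 3]."""
    return float(np.dot(d.fractions, _ENDOCYCLES))


def ei_with_ci(
    d: PloidyDistribution,
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """EI point estimate with a multinomial-bootstrap percentile CI.

    The observed class counts are resampled ``n_boot`` times from a
    multinomial with the observed fractions and the observed total, and
    the percentile interval of the resampled EIs is returned.
    Deterministic given ``seed``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be positive")
    ei = endoreduplication_index(d)
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(d.total, d.fractions, size=n_boot)
    boots = draws @ _ENDOCYCLES / d.total
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return ei, (float(lo), float(hi))
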