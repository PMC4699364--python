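"""Fragment-length distributions for sonication-sheared libraries."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import ConfigError


@dataclass
class FragmentLengthDistribution:
    """Discrete distribution of fragment lengths on an integer support.

    The default model is a discretized gamma, truncated to [50, 500] bp and
    rescaled so that the truncated median hits the library's target (125 bp
    for a typical Covaris shear).
    """

    support: np.ndarray  # int lengths, ascending
    pmf: np.ndarray

    def __post_init__(self):
        self.support = np.asarray(self.support, dtype=np.int64)
        p = np.asarray(self.pmf, dtype=float)
        if p.size != self.support.size or p.size == 0:
            raise ConfigError("pmf and support must be equal-length, non-empty")
        if np.any(p < 0) or p.sum() <= 0:
            raise ConfigError("pmf must be non-negative with positive mass")
        self.pmf = p / p.sum()

    @classmethod
    def gamma(cls, median: float = 125.0, shape: float = 8.0,
              lo: int = 50, hi: int = 500) -> "FragmentLengthDistribution":
        """Discretized gamma on [lo, hi] with truncated median ``median``."""
        if not (lo < median < hi):
            raise ConfigError("median must sit inside the truncation bounds")
        support = np.arange(lo, hi + 1)

        def trunc_median(scale):
            w = stats.gamma.pdf(support, shape, scale=scale)
            cdf = np.cumsum(w) / w.sum()
            return support[np.searchsorted(cdf, 0.5)]

        scale = optimize.brentq(lambda s: trunc_median(s) - median,
                                median / (4 * shape), median * 4 / shape, xtol=1e-4)
        pmf = stats.gamma.pdf(support, shape, scale=scale)
        return cls(support, pmf)

    @classmethod
    def fixed(cls, length: int) -> "FragmentLengthDistribution":
        return cls(np.array([length]), np.array([1.0]))

    @property
    def min_length(self) -> int:
        return int(self.support[0])

    @property
    def max_length(self) -> int:
        return int(self.support[-1])

    def median(self) -> int:
        cdf = np.cumsum(self.pmf)
        return int(self.support[np.searchsorted(cdf, 0.5)])

    def survival(self, d_max: int | None = None) -> np.ndarray:
        """S(d) = P(L > d) for d = 0..d_max (defaults to max length)."""
        d_max = self.max_length if d_max is None else int(d_max)
        d = np.arange(d_max + 1)
        # P(L > d) = sum of pmf over support strictly greater than d
        tail = np.concatenate([np.cumsum(self.pmf[::-1])[::-1], [0.0]])
        idx = np.searchsorted(self.support, d, side="right")
        return tail[idx]

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.choice(self.support, size=size, p=self.pmf)

    def sample_length_biased(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Sample from pmf*(l) ∝ l·pmf(l).

        Under uniform shearing, the probability that a fragment covers a fixed
        genomic point is proportional to its length, so fragments placed
        conditionally on covering a chosen CpG must be drawn length-biased.
        """
        w = self.pmf * self.support
        return rng.choice(self.support, size=size, p=w / w.sum())
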