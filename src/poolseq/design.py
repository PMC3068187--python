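"""Pooled study design and its detection-regime arithmetic.

A pooled resequencing study sequences P pools of N diploid individuals
each, so every pool carries 2N chromosomes and a singleton variant (one
carrier chromosome) sits at within-pool frequency 1/(2N).  Pool size is
chosen so that this singleton frequency clears the platform's per-base
error rate with margin; ``detectability_margin`` quantifies that ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PoolDesign", "singleton_frequency", "detectability_margin"]


class InvalidDesignError(ValueError):
    """Raised for a structurally invalid pool design."""


@dataclass(frozen=True)
class PoolDesign:
    """Layout of a pooled sequencing study.

    Parameters
    ----------
    n_pools
        Number of pools sequenced.
    individuals_per_pool
        Diploid individuals per pool (N); each pool holds 2N chromosomes.
    dna_proportions
        Per-pool vector of per-individual DNA contribution fractions,
        shape ``(n_pools, individuals_per_pool)``.  Defaults to equimolar
        pooling (the uniform vector); non-uniform vectors model pooling
        imbalance.  Each row must be non-negative and sum to 1.
    """

    n_pools: int
    individuals_per_pool: int
    dna_proportions: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_pools < 1:
            raise InvalidDesignError("n_pools must be >= 1")
        if self.individuals_per_pool < 1:
            raise InvalidDesignError("individuals_per_pool must be >= 1")
        if self.dna_proportions is None:
            props = np.full(
                (self.n_pools, self.individuals_per_pool),
                1.0 / self.individuals_per_pool,
            )
            object.__setattr__(self, "dna_proportions", props)
        else:
            props = np.asarray(self.dna_proportions, dtype=float)
            if props.shape != (self.n_pools, self.individuals_per_pool):
                raise InvalidDesignError(
                    f"dna_proportions must have shape "
                    f"({self.n_pools}, {self.individuals_per_pool}); got {props.shape}"
                )
            if (props < 0).any():
                raise InvalidDesignError("dna_proportions must be non-negative")
            if not np.allclose(props.sum(axis=1), 1.0, atol=1e-9):
                raise InvalidDesignError("each dna_proportions row must sum to 1")
            object.__setattr__(self, "dna_proportions", props)

    @property
    def chromosomes_per_pool(self) -> int:
        return 2 * self.individuals_per_pool

    @property
    def total_chromosomes(self) -> int:
        return self.n_pools * self.chromosomes_per_pool


def singleton_frequency(design: PoolDesign) -> float:
    """Within-pool allele frequency of a singleton variant: 1/(2N)."""
    return 1.0 / design.chromosomes_per_pool


def detectability_margin(design: PoolDesign, error_rate: float) -> float:
    """Ratio of the singleton frequency to the sequencing error rate.

    Values > 1 mean the weakest real signal (a single carrier chromosome)
    sits above the error floor; the study's pool size was chosen to keep
    this comfortably above 1 for per-base error rates of 0.5-1%.
    """
    if not 0.0 < error_rate < 1.0:
        raise ValueError(f"error_rate must be in (0, 1): got {error_rate}")
    return singleton_frequency(design) / error_rate
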