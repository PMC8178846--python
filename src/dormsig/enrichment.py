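"""Hypergeometric over-representation test for gene-set overlaps."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from scipy import stats


@dataclass
class EnrichmentResult:
    """Overlap of a DE gene set with a reference set within a gene universe."""

    universe_size: int
    set_size: int
    de_size: int
    overlap: int
    p: float
    direction: str = ""

    def __post_init__(self) -> None:
        if self.overlap > min(self.set_size, self.de_size):
            raise ValueError("overlap exceeds the smaller set")
        if max(self.set_size, self.de_size) > self.universe_size:
            raise ValueError("set sizes exceed the universe")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


def overlap_test(
    de_genes: Iterable[str],
    reference_set: Iterable[str],
    universe: Iterable[str],
    direction: str = "",
) -> EnrichmentResult:
    """Upper-tail hypergeometric test of the overlap between two gene sets.

    With N = |universe|, K = |reference ∩ universe|, n = |DE genes| and
    k = |DE ∩ reference| the p-value is P(X >= k) for
    X ~ Hypergeom(N, K, n).  DE genes must be a subset of the universe;
    the reference set is intersected with the universe before testing.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    de = set(de_genes)
    stray = de - universe
    if stray:
        raise ValueError(
            f"DE genes outside the universe: {sorted(stray)[:5]}"
        )
    ref = set(reference_set) & universe
    n_univ, n_ref, n_de = len(universe), len(ref), len(de)
    k = len(de & ref)
    # sf(k-1) = P(X >= k)
    p = float(stats.hypergeom.sf(k - 1, n_univ, n_ref, n_de))
    return EnrichmentResult(
        universe_size=n_univ,
        set_size=n_ref,
        de_size=n_de,
        overlap=k,
        p=min(p, 1.0),
        direction=direction,
    )
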