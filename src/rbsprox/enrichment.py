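"""Association of site sets with genomic features.

Each feature class (genes, TSS/CpG windows, chromatin-mark domains or
peak-centre windows) is a set of merged half-open intervals.  The fraction
of integration sites falling inside the feature is compared with the
fraction of a large uniform random control set (default 100,000 sites) by a
two-tailed exact binomial test (tail doubling, capped at 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .proximity import GenomicSite


@dataclass
class FeatureSet:
    """Named per-contig sorted disjoint half-open intervals."""

    name: str
    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_intervals(
        cls,
        name: str,
        intervals: Iterable[tuple[str, int, int]],
        contig_lengths: Mapping[str, int] | None = None,
    ) -> "FeatureSet":
        """Build a feature set, merging overlaps and clipping to contig
        bounds when lengths are supplied."""
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, start, end in intervals:
            s, e = int(start), int(end)
            if contig_lengths is not None:
                L = contig_lengths.get(contig)
                if L is None:
                    continue
                s, e = max(0, s), min(L, e)
            if e > s:
                by_contig.setdefault(contig, []).append((s, e))
        merged: dict[str, np.ndarray] = {}
        for contig, ivs in by_contig.items():
            ivs.sort()
            acc: list[list[int]] = []
            for s, e in ivs:
                if acc and s <= acc[-1][1]:
                    acc[-1][1] = max(acc[-1][1], e)
                else:
                    acc.append([s, e])
            merged[contig] = np.array(acc, dtype=np.int64)
        return cls(name=name, intervals=merged)

    def total_bases(self) -> int:
        return int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.intervals.values()))

    def contains(self, contig: str, pos: int) -> bool:
        iv = self.intervals.get(contig)
        if iv is None or len(iv) == 0:
            return False
        i = int(np.searchsorted(iv[:, 0], pos, side="right"))
        return i > 0 and pos < iv[i - 1, 1]


@dataclass(frozen=True)
class EnrichmentResult:
    feature: str
    k: int           # sites inside the feature
    n: int           # total sites
    control_fraction: float
    p_two_tailed: float

    @property
    def observed_fraction(self) -> float:
        return self.k / self.n if self.n else 0.0


def windows_around(
    anchors: Sequence[GenomicSite] | Sequence[tuple[str, int, int]],
    flank: int,
    name: str = "windows",
    contig_lengths: Mapping[str, int] | None = None,
) -> FeatureSet:
    """Symmetric windows around point anchors or interval centres.

    A ChIP peak list becomes e.g. ``flank=2500`` -> 5 kb windows around peak
    centres; a TSS list with ``flank=2000`` becomes the tss +/- 2 kb class.
    Windows are clipped to contig bounds and merged.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    ivs: list[tuple[str, int, int]] = []
    for a in anchors:
        if isinstance(a, GenomicSite):
            contig, centre = a.contig, a.pos
        else:
            contig, start, end = a
            centre = (int(start) + int(end)) // 2
        ivs.append((contig, centre - flank, centre + flank))
    return FeatureSet.from_intervals(name, ivs, contig_lengths=contig_lengths)


def overlap_count(sites: Sequence[GenomicSite], features: FeatureSet) -> int:
    """Number of sites whose coordinate lies inside any feature interval."""
    return sum(features.contains(s.contig, s.pos) for s in sites)


def uniform_control_sites(
    contig_lengths: Mapping[str, int],
    n: int = 100_000,
    seed: int | np.random.Generator = 0,
    n_mask: Mapping[str, np.ndarray] | None = None,
) -> list[GenomicSite]:
    """Uniform random control sites over non-N genome bases.

    ``n_mask`` maps contig -> sorted (m, 2) intervals of N/gap bases to
    exclude; contigs are weighted by usable length.  Deterministic under a
    fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    contigs = list(contig_lengths)
    usable = []
    for c in contigs:
        L = contig_lengths[c]
        masked = 0
        if n_mask and c in n_mask and len(n_mask[c]):
            iv = np.asarray(n_mask[c])
            masked = int((iv[:, 1] - iv[:, 0]).sum())
        usable.append(L - masked)
    usable_arr = np.array(usable, dtype=float)
    if usable_arr.sum() <= 0:
        raise ValueError("genome entirely masked")
    counts = rng.multinomial(n, usable_arr / usable_arr.sum())
    out: list[GenomicSite] = []
    for c, k, u in zip(contigs, counts, usable):
        if k == 0:
            continue
        ranks = rng.integers(0, u, size=k)  # rank among usable bases
        if n_mask and c in n_mask and len(n_mask[c]):
            iv = np.asarray(n_mask[c])
            # map rank -> genomic position skipping masked intervals
            gap_starts = iv[:, 0]
            cum_masked = np.concatenate(([0], np.cumsum(iv[:, 1] - iv[:, 0])))
            usable_before_gap = gap_starts - cum_masked[:-1]
            j = np.searchsorted(usable_before_gap, ranks, side="right")
            pos = ranks + cum_masked[j]
        else:
            pos = ranks
        out.extend(GenomicSite(c, int(p), label="control") for p in pos)
    return out


def binomial_enrichment(k: int, n: int, p_hat: float, feature: str = "") -> EnrichmentResult:
    """Two-tailed exact binomial test of k/n against the control fraction.

    p = min(1, 2 * min(P(X <= k), P(X >= k))) for X ~ Binomial(n, p_hat);
    the doubling convention, capped at one.
    """
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if not (0 < p_hat < 1):
        raise ValueError("control fraction must be strictly inside (0, 1)")
    lower = float(stats.binom.cdf(k, n, p_hat))
    upper = float(stats.binom.sf(k - 1, n, p_hat))
    p = min(1.0, 2.0 * min(lower, upper))
    return EnrichmentResult(feature=feature, k=int(k), n=int(n),
                            control_fraction=float(p_hat), p_two_tailed=p)


def feature_enrichment(
    sites: Sequence[GenomicSite],
    features: FeatureSet,
    controls: Sequence[GenomicSite],
) -> EnrichmentResult:
    """Site-vs-control enrichment for one feature class.

    The control fraction is the realised fraction of the generated control
    set inside the feature, not a theoretical genome fraction.
    """
    if not sites:
        raise ValueError("empty site set")
    k = overlap_count(sites, features)
    kc = overlap_count(controls, features)
    p_hat = kc / len(controls)
    return binomial_enrichment(k, len(sites), p_hat, feature=features.name)
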