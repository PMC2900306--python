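"""Distances from genomic sites to the nearest motif occurrence, and tests
against null models.

Three null models are supported for the mean nearest-distance statistic:

``random_exact``
    Integration is equally likely at every position of every eligible
    contig.  The null mean and SD of the nearest-distance are computed in
    closed form by summing arithmetic series over the uncovered runs
    between merged motif-cover intervals, in exact integer arithmetic.

``restriction_matched``
    Junction retrieval requires a restriction site near the integration, so
    a non-uniform restriction-site landscape could bias distances.  For each
    observed site, its distance d to the closest cut site is preserved: each
    of m controls is placed at a uniformly chosen cut position +/- d.

``empirical_sites``
    Any user-supplied site set (e.g. a rep-independent vector dataset) used
    as background; its distance sample supplies mu and sigma.

Analyses are confined to contigs that contain at least one motif occurrence
("eligible" contigs), since the nearest distance is otherwise undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .motifs import OccurrenceIndex


@dataclass(frozen=True)
class GenomicSite:
    contig: str
    pos: int  # 0-based
    label: str = ""


@dataclass
class DistanceSample:
    """Distances of a site set to nearest motif occurrences (bp)."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        # sample SD (n-1) for an observed sample of sites
        return float(self.values.std(ddof=1)) if self.n > 1 else 0.0


@dataclass(frozen=True)
class BackgroundModel:
    kind: str  # random_exact | restriction_matched | empirical_sites
    mu: float
    sigma: float
    support: int
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.support < 1:
            raise ValueError("support must be >= 1")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    one_sided_p: float
    two_sided_p: float
    n: int
    mean: float
    comparison: str
    df: float | None = None

    @property
    def tier(self) -> str:
        """Significance tier: >0.05 not significant, <0.01 highly significant."""
        p = self.one_sided_p
        if p > 0.05:
            return "n.s."
        if p < 0.01:
            return "highly significant"
        return "significant"


class IneligibleContigError(ValueError):
    """Raised for a site on a contig with no motif occurrence; such sites
    must be excluded from the analysis."""


def _check_eligible(index: OccurrenceIndex, contig: str) -> np.ndarray:
    cover = index.cover.get(contig)
    if cover is None or len(cover) == 0:
        raise IneligibleContigError(
            f"contig {contig!r} contains no motif occurrence; exclude sites "
            "on it (analysis is confined to contigs with >=1 occurrence)"
        )
    return cover


def nearest_distance(site: GenomicSite, index: OccurrenceIndex) -> int:
    """bp distance from a site to the nearest covered base (0 if inside)."""
    cover = _check_eligible(index, site.contig)
    return int(_nearest_from_cover(np.array([site.pos]), cover)[0])


def _nearest_from_cover(pos: np.ndarray, cover: np.ndarray) -> np.ndarray:
    """Vectorised nearest-covered-base distance against a sorted disjoint
    cover array."""
    starts = cover[:, 0]
    ends = cover[:, 1]
    i = np.searchsorted(starts, pos, side="right")  # interval index to the left
    d_left = np.where(i > 0, pos - (ends[np.maximum(i - 1, 0)] - 1), np.iinfo(np.int64).max)
    d_right = np.where(i < len(starts), starts[np.minimum(i, len(starts) - 1)] - pos,
                       np.iinfo(np.int64).max)
    d = np.minimum(np.maximum(d_left, 0), np.maximum(d_right, 0))
    inside = (i > 0) & (pos < ends[np.maximum(i - 1, 0)])
    return np.where(inside, 0, d)


def distance_sample(
    sites: Sequence[GenomicSite],
    index: OccurrenceIndex,
    label: str = "",
    drop_ineligible: bool = False,
) -> tuple[DistanceSample, int]:
    """Distances for a site set; returns (sample, n_dropped).

    With ``drop_ineligible`` sites on contigs lacking any occurrence are
    silently dropped (their count is returned); otherwise they raise.
    """
    vals = []
    dropped = 0
    for s in sites:
        if not index.is_eligible(s.contig):
            if drop_ineligible:
                dropped += 1
                continue
            _check_eligible(index, s.contig)
        vals.append(nearest_distance(s, index))
    return DistanceSample(np.array(vals, dtype=float), label=label), dropped


def _series_sums(a: int) -> tuple[int, int]:
    """(sum, sum of squares) of 1..a."""
    return a * (a + 1) // 2, a * (a + 1) * (2 * a + 1) // 6


def exact_background(index: OccurrenceIndex) -> BackgroundModel:
    """Exact mean/SD of nearest-distance over ALL eligible-contig positions.

    Each maximal uncovered run contributes a tent (or one-sided ramp at
    contig edges) of integer distances whose sums are closed-form arithmetic
    series; covered bases contribute distance 0.  All accumulation is exact
    integer arithmetic; only the final mu and sigma are floats.
    """
    total_n = 0
    sum_d = 0
    sum_d2 = 0
    any_eligible = False
    for contig, cover in index.cover.items():
        if len(cover) == 0:
            continue
        any_eligible = True
        length = index.contig_lengths[contig]
        total_n += length
        # prefix before first cover interval: distances s0, s0-1, ..., 1
        s0 = int(cover[0, 0])
        s, s2 = _series_sums(s0)
        sum_d += s
        sum_d2 += s2
        # suffix after last interval: distances 1..(length - e_last)
        e_last = int(cover[-1, 1])
        s, s2 = _series_sums(length - e_last)
        sum_d += s
        sum_d2 += s2
        # interior gaps: tent of width g between covered bases
        for j in range(len(cover) - 1):
            g = int(cover[j + 1, 0]) - int(cover[j, 1])
            left = (g + 1) // 2
            right = g // 2
            sl, sl2 = _series_sums(left)
            sr, sr2 = _series_sums(right)
            sum_d += sl + sr
            sum_d2 += sl2 + sr2
    if not any_eligible:
        raise IneligibleContigError("no contig contains a motif occurrence")
    mu = sum_d / total_n
    var = sum_d2 / total_n - mu * mu
    sigma = math.sqrt(max(var, 0.0))
    return BackgroundModel(
        kind="random_exact", mu=mu, sigma=sigma, support=total_n,
        provenance=index.spec.name,
    )


def restriction_matched_controls(
    sites: Sequence[GenomicSite],
    cut_index: OccurrenceIndex,
    m: int = 1000,
    seed: int | np.random.Generator = 0,
    eligible_contigs: Iterable[str] | None = None,
    max_attempts: int = 1000,
) -> list[GenomicSite]:
    """Distance-matched control sites around random restriction cuts.

    For each observed site, its distance d to the closest cut is computed;
    each of the m controls is placed at (uniformly chosen cut genome-wide)
    +/- d with a random sign.  Controls falling outside contig bounds — or,
    when ``eligible_contigs`` is given, on contigs without a motif — are
    resampled.  Deterministic under a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eligible = set(eligible_contigs) if eligible_contigs is not None else None

    contigs = [c for c in cut_index.contig_lengths if cut_index.is_eligible(c)]
    if not contigs:
        raise ValueError("cut index has no cut sites")
    cut_pos = {c: np.array([o.start for o in cut_index.occurrences[c]]) for c in contigs}
    weights = np.array([len(cut_pos[c]) for c in contigs], dtype=float)
    weights /= weights.sum()

    out: list[GenomicSite] = []
    for site in sites:
        d = nearest_distance(site, cut_index)
        placed = 0
        attempts = 0
        while placed < m:
            if attempts > max_attempts * m:
                raise RuntimeError(
                    f"could not place matched controls for {site} after "
                    f"{attempts} attempts (d={d})"
                )
            attempts += 1
            ci = rng.choice(len(contigs), p=weights)
            contig = contigs[ci]
            if eligible is not None and contig not in eligible:
                continue
            cut = int(rng.choice(cut_pos[contig]))
            sign = 1 if rng.random() < 0.5 else -1
            pos = cut + sign * d
            if 0 <= pos < cut_index.contig_lengths[contig]:
                out.append(GenomicSite(contig, int(pos), label=f"ctrl:{site.label}"))
                placed += 1
    return out


def empirical_background(
    control_sites: Sequence[GenomicSite],
    index: OccurrenceIndex,
    kind: str = "empirical_sites",
    provenance: str = "",
) -> BackgroundModel:
    """mu/sigma (population SD) of a control site set's distance sample."""
    sample, dropped = distance_sample(control_sites, index, drop_ineligible=True)
    if sample.n < 2:
        raise ValueError("need >=2 control sites on eligible contigs")
    mu = sample.mean
    sigma = float(sample.values.std(ddof=0))  # population SD: full null distribution
    return BackgroundModel(kind=kind, mu=mu, sigma=sigma, support=sample.n,
                           provenance=provenance)


def z_test(sample: DistanceSample, bg: BackgroundModel) -> TestResult:
    """Z-test of the observed mean distance against a background model.

    The directional hypothesis is that sites lie *closer* to motifs than the
    background, so the one-sided p is the lower tail of z.
    """
    if sample.n < 1:
        raise ValueError("empty distance sample")
    if bg.sigma <= 0:
        raise ValueError("background sigma must be > 0 for a Z-test")
    z = (sample.mean - bg.mu) / (bg.sigma / math.sqrt(sample.n))
    lower = float(stats.norm.cdf(z))
    upper = float(stats.norm.sf(z))
    return TestResult(
        statistic=float(z),
        one_sided_p=lower,
        two_sided_p=min(1.0, 2.0 * min(lower, upper)),
        n=sample.n,
        mean=sample.mean,
        comparison=f"{sample.label or 'sites'} vs {bg.kind}"
                   + (f"({bg.provenance})" if bg.provenance else ""),
    )


def two_sample_t(a: DistanceSample, b: DistanceSample) -> TestResult:
    """Welch two-sample t-test between two site sets' distance samples
    (e.g. wild-type virus vs rep-deficient vector)."""
    if a.n < 2 or b.n < 2:
        raise ValueError("both samples need n >= 2")
    t, p2 = stats.ttest_ind(a.values, b.values, equal_var=False)
    va, vb = a.values.var(ddof=1), b.values.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean == b.mean:
            t, p2 = 0.0, 1.0
        else:
            raise ValueError("both samples have zero variance")
        df = float(a.n + b.n - 2)
    else:
        num = (va / a.n + vb / b.n) ** 2
        den = (va / a.n) ** 2 / (a.n - 1) + (vb / b.n) ** 2 / (b.n - 1)
        df = num / den
    t = float(t)
    p2 = float(p2)
    lower = p2 / 2 if t <= 0 else 1 - p2 / 2
    return TestResult(
        statistic=t, one_sided_p=lower, two_sided_p=p2,
        n=a.n, mean=a.mean,
        comparison=f"{a.label or 'a'} vs {b.label or 'b'}", df=df,
    )


def exclude_regions(
    sites: Sequence[GenomicSite],
    regions: Iterable[tuple[str, int, int]],
) -> list[GenomicSite]:
    """Remove sites falling inside any half-open (contig, start, end) region
    (e.g. hotspot exclusion for robustness reanalysis); order preserved."""
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, start, end in regions:
        by_contig.setdefault(contig, []).append((int(start), int(end)))
    out = []
    for s in sites:
        if any(a <= s.pos < b for a, b in by_contig.get(s.contig, ())):
            continue
        out.append(s)
    return out
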