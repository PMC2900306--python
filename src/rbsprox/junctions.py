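"""Junction-read filtering: from candidate alignments to integration sites.

A junction read is a chimeric sequence spanning the fusion of viral and
chromosomal DNA.  Candidate local alignments (BLAT PSL output, or the
built-in seed-and-extend aligner for synthetic data) are turned into
accepted integration sites by explicit criteria:

  (a) the chromosomal part is >= 100 bp at >= 98% identity, OR shows
      >= 25 bp of contiguous exact match;
  (b) part of the read is assignable to the virus;
  (c) unassigned read bases between the viral and chromosomal parts
      number <= 20;
  (d) reads matching multiple chromosomal regions (repeats) are discarded;
  and exact duplicate fusions (identical viral and chromosomal parts) are
  counted once.

The integration-site coordinate is the chromosomal base adjacent to the
viral junction on the read (the breakpoint), not the segment midpoint.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

from .motifs import revcomp
from .proximity import GenomicSite


@dataclass
class AlignmentRecord:
    """A local ungapped-or-blocked alignment with PSL semantics.

    Query coordinates are always on the plus strand of the read; ``strand``
    is the strand of the read relative to the target.  ``blocks`` is a list
    of (query_start, target_start, size) with query starts in plus-read
    coordinates, sorted and non-overlapping.
    """

    query_id: str
    query_start: int
    query_end: int
    query_size: int
    target_name: str
    target_start: int
    target_end: int
    strand: str
    matches: int
    mismatches: int
    blocks: list[tuple[int, int, int]] = field(default_factory=list)
    longest_exact: int | None = None  # known only when bases were compared

    def __post_init__(self) -> None:
        if self.matches + self.mismatches > self.query_end - self.query_start:
            raise ValueError(
                f"{self.query_id}: matches+mismatches exceed aligned query span"
            )

    @property
    def identity(self) -> float:
        tot = self.matches + self.mismatches
        return self.matches / tot if tot else 0.0

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    def guaranteed_exact_run(self) -> int:
        """Longest contiguous exact match guaranteed by the record.

        If mismatch positions are unknown (plain PSL), assume an adversarial
        placement of the known mismatch count across the gap-free blocks and
        return the largest run that must still exist.
        """
        if self.longest_exact is not None:
            return self.longest_exact
        sizes = [b[2] for b in self.blocks] or [self.query_span]
        m = self.mismatches
        if m == 0:
            return max(sizes)
        # adversary distributes m mismatches over blocks to minimise the
        # maximal run; greedily add each mismatch to the current worst block
        heap = [(-s, s, 0) for s in sizes]  # (-current worst run, size, mismatches)
        heapq.heapify(heap)
        for _ in range(m):
            _, s, k = heapq.heappop(heap)
            k += 1
            run = _ceil_div(s - k, k + 1) if s > k else 0
            heapq.heappush(heap, (-run, s, k))
        return -heap[0][0]


def _ceil_div(a: int, b: int) -> int:
    return -(-a // b)


@dataclass(frozen=True)
class CriteriaConfig:
    """Thresholds of the junction acceptance criteria."""

    min_long_len: int = 100
    min_identity: float = 0.98
    min_short_exact: int = 25
    max_gap: int = 20
    multimap_min_separation: int = 1000
    max_overlap: int = 5  # junction microhomology allowance

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        for name in ("min_long_len", "min_short_exact", "max_gap",
                     "multimap_min_separation"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


REJECTION_REASONS = (
    "short_human", "low_identity", "no_viral", "gap_too_long",
    "multimap", "duplicate",
)


@dataclass
class JunctionCall:
    read_id: str
    accepted: bool
    reason: str = ""
    human_segment: AlignmentRecord | None = None
    viral_segment: AlignmentRecord | None = None
    gap_len: int = 0
    site: GenomicSite | None = None

    def __post_init__(self) -> None:
        if self.accepted and (self.reason or self.site is None):
            raise ValueError("accepted call must have a site and no reason")
        if not self.accepted and self.reason not in REJECTION_REASONS:
            raise ValueError(f"unknown rejection reason {self.reason!r}")


# --- PSL -----------------------------------------------------------------

_PSL_COLUMNS = 21


def parse_psl(stream: IO[str] | Iterable[str]) -> list[AlignmentRecord]:
    """Read 21-column PSL (BLAT output), with or without the 5-line header.

    repMatches are folded into matches.  For minus-strand queries the
    per-block query starts are normalised to plus-strand read coordinates
    (PSL stores them in reversed-read coordinates).
    """
    records: list[AlignmentRecord] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("psLayout") or not any(ch.isdigit() for ch in line):
            continue  # header lines (banner, column names, dashes)
        fields = line.split("\t")
        if len(fields) != _PSL_COLUMNS:
            raise ValueError(
                f"PSL line {lineno}: expected {_PSL_COLUMNS} columns, "
                f"got {len(fields)}"
            )
        try:
            matches, mismatches, rep_matches, _n_count = map(int, fields[0:4])
            strand = fields[8]
            q_name = fields[9]
            q_size, q_start, q_end = map(int, fields[10:13])
            t_name = fields[13]
            _t_size, t_start, t_end = map(int, fields[14:17])
            block_count = int(fields[17])
            sizes = [int(x) for x in fields[18].rstrip(",").split(",") if x]
            q_starts = [int(x) for x in fields[19].rstrip(",").split(",") if x]
            t_starts = [int(x) for x in fields[20].rstrip(",").split(",") if x]
        except ValueError as exc:
            raise ValueError(f"PSL line {lineno}: non-numeric field ({exc})") from None
        if not (len(sizes) == len(q_starts) == len(t_starts) == block_count):
            raise ValueError(f"PSL line {lineno}: inconsistent block lists")
        qstrand = strand[0]
        blocks = []
        for size, qs, ts in zip(sizes, q_starts, t_starts):
            if qstrand == "-":
                qs = q_size - (qs + size)
            blocks.append((qs, ts, size))
        blocks.sort()
        records.append(AlignmentRecord(
            query_id=q_name,
            query_start=q_start, query_end=q_end, query_size=q_size,
            target_name=t_name, target_start=t_start, target_end=t_end,
            strand=qstrand,
            matches=matches + rep_matches, mismatches=mismatches,
            blocks=blocks,
        ))
    return records


# --- minimal seed-and-extend aligner ------------------------------------

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i


def _encode2(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class SeedAligner:
    """Exact-seed, ungapped-extension local aligner for synthetic reads.

    Builds a sorted k-mer index of the reference once; each read (and its
    reverse complement) is seeded, seed hits are grouped by diagonal, and
    each diagonal is extended ungapped to its maximal-scoring run
    (+1 match / -3 mismatch).  Not a BLAT replacement: no gaps, no splicing.
    """

    def __init__(self, reference: Mapping[str, str], seed_len: int = 11):
        if seed_len < 11:
            raise ValueError("seed_len must be >= 11")
        self.seed_len = seed_len
        self.contigs = {name: seq.upper() for name, seq in reference.items()}
        self._codes = {name: _encode2(seq) for name, seq in self.contigs.items()}
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for name, codes in self._codes.items():
            kmers = self._kmerize(codes)
            order = np.argsort(kmers, kind="stable")
            self._index[name] = (kmers[order], order.astype(np.int64))

    def _kmerize(self, codes: np.ndarray) -> np.ndarray:
        k = self.seed_len
        n = len(codes) - k + 1
        if n <= 0:
            return np.zeros(0, dtype=np.int64)
        val = np.zeros(n, dtype=np.int64)
        bad = np.zeros(n, dtype=bool)
        for j in range(k):
            c = codes[j:j + n]
            bad |= c == 255
            val = val * 4 + np.where(c == 255, 0, c).astype(np.int64)
        val[bad] = -1  # never looked up (queries with N skipped)
        return val

    def align(
        self,
        read_id: str,
        read: str,
        max_mismatch_rate: float = 0.05,
    ) -> list[AlignmentRecord]:
        read = read.upper()
        out: list[AlignmentRecord] = []
        seen: set[tuple] = set()
        for strand, oriented in (("+", read), ("-", revcomp(read))):
            q = _encode2(oriented)
            q_kmers = self._kmerize(q)
            for contig, (sorted_kmers, order) in self._index.items():
                t = self._codes[contig]
                diags: set[int] = set()
                for qpos in range(0, len(q_kmers), self.seed_len):
                    kv = q_kmers[qpos]
                    if kv < 0:
                        continue
                    lo = np.searchsorted(sorted_kmers, kv, side="left")
                    hi = np.searchsorted(sorted_kmers, kv, side="right")
                    for tpos in order[lo:hi]:
                        diags.add(int(tpos) - qpos)
                for d in diags:
                    aln = self._extend(read_id, oriented, q, contig, t, d,
                                       strand, len(read), max_mismatch_rate)
                    if aln is None:
                        continue
                    key = (aln.target_name, aln.strand, aln.target_start,
                           aln.target_end, aln.query_start)
                    if key not in seen:
                        seen.add(key)
                        out.append(aln)
        out.sort(key=lambda a: (-a.matches, a.target_name, a.target_start))
        return out

    def _extend(self, read_id, oriented, q, contig, t, d, strand, read_len,
                max_mismatch_rate):
        q_lo = max(0, -d)
        q_hi = min(len(q), len(t) - d)
        if q_hi - q_lo < self.seed_len:
            return None
        qs = q[q_lo:q_hi]
        ts = t[d + q_lo:d + q_hi]
        match = (qs == ts) & (qs != 255) & (ts != 255)
        score = np.where(match, 1, -3)
        # Kadane: maximal-scoring contiguous run on this diagonal
        best, best_lo, best_hi = 0, 0, 0
        cur, cur_lo = 0, 0
        for i, sc in enumerate(score):
            if cur <= 0:
                cur, cur_lo = sc, i
            else:
                cur += sc
            if cur > best:
                best, best_lo, best_hi = cur, cur_lo, i + 1
        if best_hi - best_lo < self.seed_len:
            return None
        win = match[best_lo:best_hi]
        n_match = int(win.sum())
        span = best_hi - best_lo
        if n_match / span < 1 - max_mismatch_rate:
            return None
        # longest exact run inside the window
        runs = np.flatnonzero(np.diff(np.concatenate(([0], win.view(np.int8), [0]))))
        longest = int((runs[1::2] - runs[::2]).max(initial=0))
        oq_start = q_lo + best_lo
        oq_end = q_lo + best_hi
        if strand == "+":
            rq_start, rq_end = oq_start, oq_end
        else:  # map back to plus-read coordinates
            rq_start = read_len - oq_end
            rq_end = read_len - oq_start
        t_start = d + oq_start
        t_end = d + oq_end
        return AlignmentRecord(
            query_id=read_id,
            query_start=rq_start, query_end=rq_end, query_size=read_len,
            target_name=contig, target_start=t_start, target_end=t_end,
            strand=strand, matches=n_match, mismatches=span - n_match,
            blocks=[(rq_start, t_start, span)],
            longest_exact=longest,
        )


def align_read(
    read: str,
    reference: Mapping[str, str],
    seed_len: int = 11,
    max_mismatch_rate: float = 0.05,
    read_id: str = "read",
) -> list[AlignmentRecord]:
    """One-shot convenience wrapper around :class:`SeedAligner`."""
    return SeedAligner(reference, seed_len).align(read_id, read, max_mismatch_rate)


# --- criteria ------------------------------------------------------------

def _qualifies(a: AlignmentRecord, cfg: CriteriaConfig) -> bool:
    long_ok = a.query_span >= cfg.min_long_len and a.identity >= cfg.min_identity
    exact_ok = a.guaranteed_exact_run() >= cfg.min_short_exact
    return long_ok or exact_ok


def call_junction(
    read_id: str,
    human_alns: Sequence[AlignmentRecord],
    viral_alns: Sequence[AlignmentRecord],
    cfg: CriteriaConfig = CriteriaConfig(),
) -> JunctionCall:
    """Apply the acceptance criteria to one read's candidate alignments."""
    qualifying = [a for a in human_alns if _qualifies(a, cfg)]
    if not qualifying:
        reason = "short_human"
        for a in human_alns:
            if a.query_span >= cfg.min_long_len and a.identity < cfg.min_identity:
                reason = "low_identity"
                break
        return JunctionCall(read_id, accepted=False, reason=reason)

    best = max(qualifying, key=lambda a: a.matches)

    # repeat-region discard: a second qualifying chromosomal locus far away
    for a in qualifying:
        if a is best:
            continue
        if (a.target_name != best.target_name
                or abs(a.target_start - best.target_start) >= cfg.multimap_min_separation):
            return JunctionCall(read_id, accepted=False, reason="multimap",
                                human_segment=best)

    if not viral_alns:
        return JunctionCall(read_id, accepted=False, reason="no_viral",
                            human_segment=best)
    viral = max(viral_alns, key=lambda a: a.matches)

    # unassigned read bases between the two segments (or microhomology overlap)
    if viral.query_start >= best.query_end:     # human left of viral
        gap = viral.query_start - best.query_end
        viral_left = False
    elif best.query_start >= viral.query_end:   # viral left of human
        gap = best.query_start - viral.query_end
        viral_left = True
    else:
        overlap = (min(best.query_end, viral.query_end)
                   - max(best.query_start, viral.query_start))
        if overlap > cfg.max_overlap:
            return JunctionCall(read_id, accepted=False, reason="gap_too_long",
                                human_segment=best, viral_segment=viral,
                                gap_len=0)
        gap = 0
        viral_left = viral.query_start <= best.query_start
    if gap > cfg.max_gap:
        return JunctionCall(read_id, accepted=False, reason="gap_too_long",
                            human_segment=best, viral_segment=viral,
                            gap_len=gap)

    # breakpoint: the chromosomal base adjacent to the viral junction
    if viral_left:
        pos = best.target_start if best.strand == "+" else best.target_end - 1
    else:
        pos = best.target_end - 1 if best.strand == "+" else best.target_start
    site = GenomicSite(best.target_name, int(pos), label=read_id)
    return JunctionCall(read_id, accepted=True, human_segment=best,
                        viral_segment=viral, gap_len=gap, site=site)


def collapse_duplicates(calls: Sequence[JunctionCall]) -> list[JunctionCall]:
    """Count identical fusions (same viral AND same chromosomal part) once.

    Calls sharing the chromosomal site but differing in the viral part are
    retained separately (independent proviruses may fuse at the same base).
    """
    seen: set[tuple] = set()
    out: list[JunctionCall] = []
    for c in calls:
        if not c.accepted:
            out.append(c)
            continue
        h, v = c.human_segment, c.viral_segment
        key = (
            h.target_name, h.target_start, h.target_end, h.strand,
            v.target_name, v.target_start, v.target_end, v.strand,
        )
        if key in seen:
            out.append(JunctionCall(c.read_id, accepted=False, reason="duplicate",
                                    human_segment=h, viral_segment=v,
                                    gap_len=c.gap_len))
            continue
        seen.add(key)
        out.append(c)
    return out


def rejection_tally(calls: Sequence[JunctionCall]) -> dict[str, int]:
    """Per-criterion rejection counts, plus 'accepted'."""
    tally: dict[str, int] = {"accepted": 0}
    for r in REJECTION_REASONS:
        tally[r] = 0
    for c in calls:
        if c.accepted:
            tally["accepted"] += 1
        else:
            tally[c.reason] += 1
    return tally
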