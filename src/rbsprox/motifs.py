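"""Degenerate motif scanning with bounded mismatches.

Rep-binding sites (RBS) are tandem GAGY/GAGC tetranucleotide repeats; the
paperless way to say it: the motifs of interest are short IUPAC strings
(e.g. ``GAGCGAGC``, ``GAGYGAGCGAGC``) that must be located genome-wide on
both strands, optionally allowing a fixed number of mismatches.  This module
compiles such motifs, scans sequences, builds a per-contig occurrence index
with a merged strand-agnostic cover (the substrate for nearest-distance
queries), and answers tandem-repeat queries.

Coordinates are 0-based, half-open throughout (BED-compatible).  ``N`` bases
in the *genome* never match any pattern character, so assembly gaps cannot
produce motif hits; ``N`` in a *pattern* matches A/C/G/T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

# IUPAC nucleotide codes as 4-bit sets over (A=1, C=2, G=4, T=8).
IUPAC_BITS: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 1 | 2 | 4 | 8,
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

# genome base byte -> bit code; anything unknown (incl. N) -> 0, which
# matches no pattern character.
_BASE_LUT = np.zeros(256, dtype=np.uint8)
for _b, _bits in (("A", 1), ("C", 2), ("G", 4), ("T", 8)):
    _BASE_LUT[ord(_b)] = _bits
    _BASE_LUT[ord(_b.lower())] = _bits


def revcomp_pattern(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern string."""
    return "".join(_COMPLEMENT[c] for c in reversed(pattern.upper()))


def revcomp(seq: str) -> str:
    """Reverse complement of a plain nucleotide sequence (N preserved)."""
    return "".join(_COMPLEMENT.get(c, "N") for c in reversed(seq.upper()))


@dataclass(frozen=True)
class MotifSpec:
    """A degenerate motif with a mismatch budget.

    Parameters
    ----------
    pattern : str
        IUPAC string, whitespace already stripped, upper case.
    max_mismatch : int
        Number of mismatching positions tolerated; must be < len(pattern).
    label : str
        Free-text name used in BED output.
    """

    pattern: str
    max_mismatch: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        bad = [c for c in self.pattern if c not in IUPAC_BITS]
        if bad:
            raise ValueError(f"non-IUPAC character(s) in pattern: {bad!r}")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        if self.max_mismatch >= len(self.pattern):
            raise ValueError(
                f"max_mismatch ({self.max_mismatch}) must be smaller than "
                f"pattern length ({len(self.pattern)})"
            )

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def name(self) -> str:
        if self.label:
            return self.label
        if self.max_mismatch:
            return f"{self.pattern}/{self.max_mismatch}mm"
        return self.pattern


def compile_motif(pattern: str, max_mismatch: int = 0, label: str = "") -> MotifSpec:
    """Validate and normalise a motif.

    Whitespace is stripped so motifs may be written as spaced
    tetranucleotides, e.g. ``"GAGY GAGC GAGC"``.
    """
    cleaned = "".join(pattern.split()).upper()
    return MotifSpec(pattern=cleaned, max_mismatch=int(max_mismatch), label=label)


@dataclass(frozen=True, order=True)
class MotifOccurrence:
    contig: str
    start: int  # 0-based inclusive
    end: int    # exclusive; end - start == len(pattern)
    strand: str  # '+' or '-'
    mismatches: int


def _pattern_masks(pattern: str) -> np.ndarray:
    return np.array([IUPAC_BITS[c] for c in pattern], dtype=np.uint8)


def _encode(sequence: str) -> np.ndarray:
    return _BASE_LUT[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _mismatch_counts(codes: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Mismatch count of every window of len(masks) against the pattern."""
    L = len(masks)
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.zeros(0, dtype=np.int32)
    mism = np.zeros(n_win, dtype=np.int32)
    for j in range(L):
        mism += (codes[j:j + n_win] & masks[j]) == 0
    return mism


def scan_sequence(
    sequence: str,
    spec: MotifSpec,
    strands: str = "both",
    contig: str = "",
) -> list[MotifOccurrence]:
    """All windows within the mismatch budget, on the requested strand(s).

    Minus-strand occurrences are found by scanning the reverse-complement
    pattern on the plus strand, so their coordinates are already plus-strand.
    Overlapping occurrences are all reported.
    """
    if strands not in ("+", "-", "both"):
        raise ValueError(f"strands must be '+', '-' or 'both', got {strands!r}")
    codes = _encode(sequence)
    out: list[MotifOccurrence] = []
    L = len(spec)
    jobs = []
    if strands in ("+", "both"):
        jobs.append(("+", _pattern_masks(spec.pattern)))
    if strands in ("-", "both"):
        jobs.append(("-", _pattern_masks(revcomp_pattern(spec.pattern))))
    for strand, masks in jobs:
        mism = _mismatch_counts(codes, masks)
        for i in np.flatnonzero(mism <= spec.max_mismatch):
            out.append(MotifOccurrence(contig, int(i), int(i) + L, strand, int(mism[i])))
    out.sort(key=lambda o: (o.start, o.strand))
    return out


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> np.ndarray:
    """Merge possibly-overlapping half-open intervals into a sorted disjoint
    (m, 2) array."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged, dtype=np.int64).reshape(-1, 2)


@dataclass
class OccurrenceIndex:
    """Genome-wide occurrences of one motif, with the merged cover.

    ``cover[contig]`` is a sorted disjoint (m, 2) int array whose union
    equals the union of the occurrence intervals on both strands.  A contig
    with no occurrence is *ineligible*: nearest-distance queries on it are
    undefined.
    """

    spec: MotifSpec
    occurrences: dict[str, list[MotifOccurrence]] = field(default_factory=dict)
    cover: dict[str, np.ndarray] = field(default_factory=dict)
    contig_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def eligible_contigs(self) -> list[str]:
        return [c for c in self.contig_lengths if len(self.occurrences.get(c, ())) > 0]

    def is_eligible(self, contig: str) -> bool:
        return len(self.occurrences.get(contig, ())) > 0

    def iter_occurrences(self) -> Iterator[MotifOccurrence]:
        for contig in self.occurrences:
            yield from self.occurrences[contig]

    def total_covered_bases(self) -> int:
        return int(sum((c[:, 1] - c[:, 0]).sum() for c in self.cover.values()))


def build_occurrence_index(
    genome: Mapping[str, str],
    spec: MotifSpec,
    strands: str = "both",
) -> OccurrenceIndex:
    """Scan every contig and assemble the sorted occurrence lists and the
    merged strand-agnostic cover."""
    names = list(genome)
    if len(set(names)) != len(names):
        raise ValueError("duplicate contig names in genome")
    if not names:
        raise ValueError("empty genome")
    idx = OccurrenceIndex(spec=spec)
    for name in names:
        seq = genome[name]
        occs = scan_sequence(seq, spec, strands=strands, contig=name)
        idx.contig_lengths[name] = len(seq)
        idx.occurrences[name] = occs
        idx.cover[name] = _merge_intervals((o.start, o.end) for o in occs)
    return idx


def motif_frequency(index: OccurrenceIndex) -> int:
    """Total occurrence count across contigs and strands."""
    return sum(len(v) for v in index.occurrences.values())


def longest_tandem_run(sequence: str, unit: str) -> int:
    """Maximal number of consecutive abutting exact matches of ``unit``.

    Windows are non-overlapping and abutting (stride = len(unit)); this is
    how tandem tetranucleotide repeats such as GAGY runs are counted.  Only
    the forward strand of the given sequence is considered.
    """
    u = compile_motif(unit, 0)
    L = len(u)
    codes = _encode(sequence)
    masks = _pattern_masks(u.pattern)
    hit = _mismatch_counts(codes, masks) == 0
    n = len(hit)
    if n == 0:
        return 0
    # runs[i] = number of abutting matches starting at i
    runs = np.zeros(n + L, dtype=np.int64)
    for i in range(n - 1, -1, -1):
        if hit[i]:
            runs[i] = 1 + runs[i + L]
    return int(runs[:n].max(initial=0))


# --- restriction enzymes -------------------------------------------------

#: blunt cutters used for junction retrieval; cut coordinate is the centre
#: of the 6 bp palindromic recognition site (offset +3 from its start).
RESTRICTION_ENZYMES: dict[str, tuple[str, int]] = {
    "PvuII": ("CAGCTG", 3),
    "EcoRV": ("GATATC", 3),
    "DraI": ("TTTAAA", 3),
}


def restriction_cut_index(genome: Mapping[str, str], enzyme: str) -> OccurrenceIndex:
    """Single-bp cut positions of a blunt cutter, as an occurrence index.

    The recognition sites are palindromic, so a plus-strand scan finds every
    site; each cut is represented as a 1 bp interval at the blunt-cut centre.
    """
    try:
        recog, offset = RESTRICTION_ENZYMES[enzyme]
    except KeyError:
        raise ValueError(
            f"unknown enzyme {enzyme!r}; known: {sorted(RESTRICTION_ENZYMES)}"
        ) from None
    spec = compile_motif(recog, 0, label=enzyme)
    idx = OccurrenceIndex(spec=spec)
    for name, seq in genome.items():
        occs = scan_sequence(seq, spec, strands="+", contig=name)
        cuts = [
            MotifOccurrence(name, o.start + offset, o.start + offset + 1, "+", 0)
            for o in occs
        ]
        idx.contig_lengths[name] = len(seq)
        idx.occurrences[name] = cuts
        idx.cover[name] = _merge_intervals((c.start, c.end) for c in cuts)
    return idx


#: The six-motif panel of putative Rep-binding sites used throughout:
#: minimal GAGC GAGC, GAGT GAGC, optimised GAGY GAGC GAGC, the triple
#: GAGC repeat with 1 or 2 mismatches, and the 3'-A variant GAGY GAGC GAGA.
DEFAULT_MOTIF_PANEL: tuple[tuple[str, int], ...] = (
    ("GAGC GAGC", 0),
    ("GAGT GAGC", 0),
    ("GAGY GAGC GAGC", 0),
    ("GAGC GAGC GAGC", 1),
    ("GAGC GAGC GAGC", 2),
    ("GAGY GAGC GAGA", 0),
)
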