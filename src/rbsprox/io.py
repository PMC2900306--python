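"""Reading and writing the plain-text formats used throughout.

FASTA goes through Biopython; sites and intervals are exchanged as BED
(0-based half-open) and tab-separated tables as pandas DataFrames.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import MotifOccurrence, OccurrenceIndex
from .proximity import GenomicSite


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-contig FASTA (optionally gzipped) -> {name: sequence}."""
    with _open_text(path) as fh:
        genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    if not genome:
        raise ValueError(f"no sequences in {path}")
    return genome


def write_fasta(path: str | Path, seqs: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_sites_bed(path: str | Path) -> list[GenomicSite]:
    """BED of single-base sites; the interval start is the site coordinate.
    Column 4, when present, becomes the site label."""
    sites = []
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            label = f[3] if len(f) > 3 else ""
            sites.append(GenomicSite(f[0], int(f[1]), label=label))
    return sites


def write_sites_bed(path: str | Path, sites: Sequence[GenomicSite]) -> None:
    with _open_text(path, "wt") as fh:
        for s in sites:
            fh.write(f"{s.contig}\t{s.pos}\t{s.pos + 1}\t{s.label or '.'}\n")


def read_intervals_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_occurrences_bed(path: str | Path, index: OccurrenceIndex) -> None:
    """Occurrences as 6-column BED: name = motif label, score = mismatches."""
    with _open_text(path, "wt") as fh:
        for occ in index.iter_occurrences():
            fh.write(
                f"{occ.contig}\t{occ.start}\t{occ.end}\t{index.spec.name}\t"
                f"{occ.mismatches}\t{occ.strand}\n"
            )


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)
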