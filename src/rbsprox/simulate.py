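"""Synthetic genomes, integration sites and junction reads with ground truth.

The generator emulates the data a junction-retrieval experiment produces:

* a multi-contig random genome with Rep-binding-site-like motifs planted at
  Poisson positions (restriction sites for the blunt cutters arise naturally
  from base composition), optionally with a duplicated block that creates
  repeat-region multimappers;
* integration sites drawn from a mixture: with probability pi ("targeted
  fraction") a site is placed at an Exponential(lambda)-distributed offset
  from a uniformly chosen motif occurrence, otherwise uniformly over the
  genome;
* junction reads built as viral segment + short unassigned insert (0..20 bp)
  + chromosomal segment in random orientation, plus decoy classes (pure
  rearranged virus, 24 bp chromosomal stubs, 21 bp gaps, exact duplicates,
  repeat-region reads) that the calling criteria must reject.

Every artifact is deterministic under the config seed: each stage draws
from its own named substream of ``numpy.random.default_rng([seed, stage])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import (MotifOccurrence, OccurrenceIndex, build_occurrence_index,
                     compile_motif, revcomp, IUPAC_BITS)
from .proximity import GenomicSite

_BASES = "ACGT"
_BITS_TO_BASES = {c: [b for b in _BASES if IUPAC_BITS[b] & IUPAC_BITS[c]]
                  for c in IUPAC_BITS}

# substream ids
_S_GENOME, _S_SITES, _S_READS, _S_VIRAL = 1, 2, 3, 4


@dataclass
class SimConfig:
    """Study conditions for the synthetic pipeline.

    Defaults describe the reference scenario: a 5 Mb genome (four contigs),
    human-like GC, the minimal Rep-binding motif planted at one occurrence
    per 50 kb, 117 integration sites of which 30% are motif-targeted with a
    500 bp exponential kernel, and reads whose chromosomal part comfortably
    satisfies the 100 bp acceptance criterion.
    """

    seed: int = 0
    contig_lengths: tuple[int, ...] = (1_250_000, 1_250_000, 1_250_000, 1_250_000)
    gc: float = 0.41
    motif: str = "GAGCGAGC"
    motif_rate: float = 1.0 / 50_000     # planted occurrences per bp
    n_sites: int = 117
    targeted_fraction: float = 0.3       # pi
    kernel_scale: float = 500.0          # lambda, bp
    viral_len: tuple[int, int] = (60, 200)
    human_len: tuple[int, int] = (120, 400)
    max_gap: int = 20
    # decoy read counts
    n_pure_viral: int = 5
    n_short_human: int = 5
    n_long_gap: int = 5
    n_duplicate: int = 5
    n_repeat: int = 5
    short_human_len: int = 24
    repeat_block_len: int = 2000         # 0 disables the duplicated block
    viral_length: int = 4700
    itr_len: int = 145

    def __post_init__(self) -> None:
        if not (0 <= self.targeted_fraction <= 1):
            raise ValueError("targeted_fraction must be in [0, 1]")
        if self.kernel_scale <= 0:
            raise ValueError("kernel_scale must be > 0")
        if any(l <= 0 for l in self.contig_lengths):
            raise ValueError("contig lengths must be positive")
        if not (0 < self.gc < 1):
            raise ValueError("gc must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("contig_lengths", "viral_len", "human_len"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=p)


def _instantiate(pattern: str, rng: np.random.Generator) -> str:
    """Resolve IUPAC degeneracy to a concrete sequence."""
    return "".join(rng.choice(_BITS_TO_BASES[c]) for c in pattern)


def make_viral_reference(seed: int = 0, length: int = 4700,
                         itr_len: int = 145) -> str:
    """A synthetic 4.7 kb viral genome with inverted-terminal-repeat-like
    ends carrying an embedded GAGCGAGCGAGCGCGC Rep-binding block.

    This is a synthetic stand-in with the structural features the read
    simulator needs (terminal repeats, an RBS-like block); a real viral
    reference FASTA may be supplied to the pipeline instead.
    """
    rng = np.random.default_rng([seed, _S_VIRAL])
    itr = _random_bases(rng, itr_len, 0.6)
    rbs = b"GAGCGAGCGAGCGCGC"
    itr[20:20 + len(rbs)] = np.frombuffer(rbs, dtype=np.uint8)
    left = itr.tobytes().decode()
    core = _random_bases(rng, length - 2 * itr_len, 0.44).tobytes().decode()
    return left + core + revcomp(left)


def make_genome(cfg: SimConfig) -> tuple[dict[str, str], list[MotifOccurrence]]:
    """Random genome with planted motif instances (and the repeat block).

    Returns the genome and the list of planted occurrences (plus strand,
    before any chance hits the scanner may additionally find).
    """
    rng = np.random.default_rng([cfg.seed, _S_GENOME])
    pattern = compile_motif(cfg.motif).pattern
    L = len(pattern)
    genome: dict[str, str] = {}
    planted: list[MotifOccurrence] = []
    for ci, length in enumerate(cfg.contig_lengths):
        name = f"contig{ci + 1}"
        arr = _random_bases(rng, length, cfg.gc)
        n_plant = rng.poisson(cfg.motif_rate * length)
        if n_plant * L > length // 2:
            raise ValueError("planting rate too high for non-overlapping motifs")
        taken: list[tuple[int, int]] = []
        placed = 0
        attempts = 0
        while placed < n_plant:
            attempts += 1
            if attempts > 100 * n_plant + 100:
                raise ValueError("could not place motifs without overlap")
            pos = int(rng.integers(0, length - L + 1))
            if any(pos < e and pos + L > s for s, e in taken):
                continue
            inst = _instantiate(pattern, rng)
            arr[pos:pos + L] = np.frombuffer(inst.encode(), dtype=np.uint8)
            taken.append((pos, pos + L))
            planted.append(MotifOccurrence(name, pos, pos + L, "+", 0))
            placed += 1
        genome[name] = arr.tobytes().decode()
    if cfg.repeat_block_len > 0 and len(cfg.contig_lengths) >= 1:
        genome = _plant_repeat_block(genome, cfg, rng)
    planted.sort(key=lambda o: (o.contig, o.start))
    return genome, planted


#: placement of the duplicated block: (source contig idx, source offset,
#: destination contig idx, destination offset) as genome-length fractions
_REPEAT_SRC_FRAC, _REPEAT_DST_FRAC = 0.25, 0.75


def _plant_repeat_block(genome: dict[str, str], cfg: SimConfig,
                        rng: np.random.Generator) -> dict[str, str]:
    names = list(genome)
    src_name = names[0]
    dst_name = names[-1]
    src_seq = genome[src_name]
    src_off = int(len(src_seq) * _REPEAT_SRC_FRAC)
    block = src_seq[src_off:src_off + cfg.repeat_block_len]
    dst_seq = genome[dst_name]
    dst_off = int(len(dst_seq) * _REPEAT_DST_FRAC)
    genome[dst_name] = (dst_seq[:dst_off] + block
                        + dst_seq[dst_off + len(block):])
    return genome


def repeat_block_regions(cfg: SimConfig) -> list[tuple[str, int, int]]:
    """Coordinates of the duplicated block's two copies (for truth checks)."""
    if cfg.repeat_block_len <= 0:
        return []
    n = len(cfg.contig_lengths)
    src = (f"contig1", int(cfg.contig_lengths[0] * _REPEAT_SRC_FRAC))
    dst = (f"contig{n}", int(cfg.contig_lengths[-1] * _REPEAT_DST_FRAC))
    return [(src[0], src[1], src[1] + cfg.repeat_block_len),
            (dst[0], dst[1], dst[1] + cfg.repeat_block_len)]


def plant_sites(
    genome: Mapping[str, str],
    index: OccurrenceIndex,
    cfg: SimConfig,
) -> tuple[list[GenomicSite], pd.DataFrame]:
    """Integration sites from the uniform/motif-targeted mixture.

    Targeted sites sit at ``round(Exponential(kernel_scale))`` bp to a random
    side of a uniformly chosen occurrence (offset 0 = inside the motif),
    clipped to the contig.  Ground truth is returned as a DataFrame.
    """
    rng = np.random.default_rng([cfg.seed, _S_SITES])
    occs = list(index.iter_occurrences())
    if cfg.targeted_fraction > 0 and not occs:
        raise ValueError("targeted_fraction > 0 but the motif index is empty")
    names = list(genome)
    lengths = np.array([len(genome[c]) for c in names], dtype=float)
    weights = lengths / lengths.sum()
    sites: list[GenomicSite] = []
    rows = []
    for i in range(cfg.n_sites):
        targeted = rng.random() < cfg.targeted_fraction
        if targeted:
            occ = occs[int(rng.integers(0, len(occs)))]
            off = int(round(rng.exponential(cfg.kernel_scale)))
            if rng.random() < 0.5:
                pos = occ.start - off
            else:
                pos = occ.end - 1 + off
            pos = int(np.clip(pos, 0, len(genome[occ.contig]) - 1))
            contig = occ.contig
            motif_start = occ.start
        else:
            ci = int(rng.choice(len(names), p=weights))
            contig = names[ci]
            pos = int(rng.integers(0, len(genome[contig])))
            motif_start = -1
            off = -1
        label = f"site{i:04d}"
        sites.append(GenomicSite(contig, pos, label=label))
        rows.append({"site_id": label, "contig": contig, "pos": pos,
                     "targeted": targeted, "motif_start": motif_start,
                     "offset": off})
    return sites, pd.DataFrame(rows)


def make_junction_reads(
    sites: Sequence[GenomicSite],
    genome: Mapping[str, str],
    viral: str,
    cfg: SimConfig,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Junction reads for every site, plus the configured decoy classes.

    Clean read anatomy: viral 3'-end segment + uniform random insert of
    g in [0, max_gap] bp + chromosomal segment starting at the site
    coordinate, in random orientation.
    """
    rng = np.random.default_rng([cfg.seed, _S_READS])
    reads: dict[str, str] = {}
    rows = []
    compl = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def human_segment(contig: str, pos: int, h: int) -> tuple[str, bool]:
        seq = genome[contig]
        fwd = rng.random() < 0.5
        # keep the full length near contig edges by flipping orientation
        if fwd and pos + h > len(seq):
            fwd = False
        if not fwd and pos + 1 < h:
            fwd = True
        if fwd:
            return seq[pos:pos + h], True
        return revcomp(seq[pos - h + 1:pos + 1]), False

    def force_junction(prefix: str, contig: str, pos: int, fwd: bool) -> str:
        """Mutate up to the last 4 prefix bases so the chromosomal alignment
        cannot coincidentally extend across the junction — clean reads have
        an unambiguous breakpoint by construction."""
        seq = genome[contig]
        chars = list(prefix)
        for k in range(1, min(4, len(chars)) + 1):
            gpos = pos - k if fwd else pos + k
            if not (0 <= gpos < len(seq)):
                break
            expected = seq[gpos] if fwd else compl[seq[gpos]]
            if chars[-k] == expected:
                choices = [b for b in "ACGT" if b != expected]
                chars[-k] = choices[int(rng.integers(0, 3))]
        return "".join(chars)

    def viral_segment() -> str:
        v = int(rng.integers(cfg.viral_len[0], cfg.viral_len[1] + 1))
        return viral[-v:]

    def insert(g: int) -> str:
        return _random_bases(rng, g, 0.5).tobytes().decode() if g else ""

    for i, site in enumerate(sites):
        rid = f"read{i:04d}"
        h = int(rng.integers(cfg.human_len[0], cfg.human_len[1] + 1))
        g = int(rng.integers(0, cfg.max_gap + 1))
        seg, fwd = human_segment(site.contig, site.pos, h)
        prefix = force_junction(viral_segment() + insert(g),
                                site.contig, site.pos, fwd)
        reads[rid] = prefix + seg
        rows.append({"read_id": rid, "site_id": site.label, "class": "clean",
                     "contig": site.contig, "pos": site.pos, "gap": g})

    counter = len(sites)

    def decoy(clazz: str, seq: str) -> None:
        nonlocal counter
        rid = f"read{counter:04d}"
        counter += 1
        reads[rid] = seq
        rows.append({"read_id": rid, "site_id": "", "class": clazz,
                     "contig": "", "pos": -1, "gap": -1})

    for _ in range(cfg.n_pure_viral):
        # rearranged pure virus: 3'-end segment fused to an internal piece
        a = viral_segment()
        mid = int(rng.integers(cfg.itr_len, len(viral) // 2))
        b = viral[mid:mid + int(rng.integers(*cfg.viral_len))]
        decoy("pure_viral", a + b)

    for _ in range(cfg.n_short_human):
        contig = list(genome)[int(rng.integers(0, len(genome)))]
        pos = int(rng.integers(1, len(genome[contig]) - cfg.short_human_len))
        stub = genome[contig][pos:pos + cfg.short_human_len]
        decoy("short_human",
              force_junction(viral_segment(), contig, pos, True) + stub)

    for _ in range(cfg.n_long_gap):
        contig = list(genome)[int(rng.integers(0, len(genome)))]
        h = int(rng.integers(*cfg.human_len))
        pos = int(rng.integers(0, len(genome[contig]) - h))
        prefix = force_junction(viral_segment() + insert(cfg.max_gap + 1),
                                contig, pos, True)
        decoy("long_gap", prefix + genome[contig][pos:pos + h])

    clean_ids = [r["read_id"] for r in rows if r["class"] == "clean"]
    for j in range(cfg.n_duplicate):
        if not clean_ids:
            break
        src = clean_ids[j % len(clean_ids)]
        decoy("duplicate", reads[src])

    regions = repeat_block_regions(cfg)
    for _ in range(cfg.n_repeat):
        if not regions:
            break
        contig, bs, be = regions[0]
        h = int(rng.integers(cfg.human_len[0], min(cfg.human_len[1],
                                                   be - bs - 1) + 1))
        pos = int(rng.integers(bs, be - h))
        g = int(rng.integers(0, cfg.max_gap + 1))
        prefix = force_junction(viral_segment() + insert(g), contig, pos, True)
        decoy("repeat", prefix + genome[contig][pos:pos + h])

    return reads, pd.DataFrame(rows)


def simulate_dataset(cfg: SimConfig, outdir: str | Path | None = None):
    """Run the full generator; optionally write FASTA/BED/TSV artifacts.

    Returns (genome, planted occurrences, sites, site truth, reads,
    read truth, viral reference).
    """
    genome, planted = make_genome(cfg)
    spec = compile_motif(cfg.motif)
    index = build_occurrence_index(genome, spec)
    sites, site_truth = plant_sites(genome, index, cfg)
    viral = make_viral_reference(cfg.seed, cfg.viral_length, cfg.itr_len)
    reads, read_truth = make_junction_reads(sites, genome, viral, cfg)
    if outdir is not None:
        from . import io as rio
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rio.write_fasta(outdir / "genome.fa", genome)
        rio.write_fasta(outdir / "viral.fa", {"viral": viral})
        rio.write_fasta(outdir / "reads.fa", reads)
        with open(outdir / "planted_motifs.bed", "w") as fh:
            for o in planted:
                fh.write(f"{o.contig}\t{o.start}\t{o.end}\t{cfg.motif}\t0\t+\n")
        rio.write_sites_bed(outdir / "sites.bed", sites)
        site_truth.to_csv(outdir / "site_truth.tsv", sep="\t", index=False)
        read_truth.to_csv(outdir / "read_truth.tsv", sep="\t", index=False)
        with open(outdir / "config.tsv", "w") as fh:
            for k, v in cfg.to_dict().items():
                fh.write(f"{k}\t{v}\n")
    return genome, planted, sites, site_truth, reads, read_truth, viral
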