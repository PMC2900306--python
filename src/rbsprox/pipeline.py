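"""End-to-end orchestration: simulate -> call -> scan -> test -> enrich.

``run_pipeline`` produces, for every motif x background-model combination,
the observed mean nearest-distance with its SD, the null mean/SD, the Z (or
t) statistic and one-/two-sided p-values with the significance tier
(p > 0.05 "n.s.", p < 0.01 "highly significant"), optionally repeated with
hotspot regions excluded; plus a feature-enrichment table and a cluster
(hotspot) summary.  All randomness flows from one top-level seed through
named substreams, so reports are byte-identical across runs.
"""

from __future__ import annotations

import json
import zlib
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as rio
from .enrichment import FeatureSet, feature_enrichment, uniform_control_sites
from .junctions import (CriteriaConfig, JunctionCall, SeedAligner,
                        call_junction, collapse_duplicates, parse_psl,
                        rejection_tally)
from .motifs import (DEFAULT_MOTIF_PANEL, build_occurrence_index,
                     compile_motif, motif_frequency, restriction_cut_index)
from .proximity import (BackgroundModel, GenomicSite, distance_sample,
                        empirical_background, exact_background,
                        exclude_regions, restriction_matched_controls, z_test)


@dataclass
class RunConfig:
    genome_fasta: str
    sites_bed: str
    motifs: tuple[tuple[str, int], ...] = DEFAULT_MOTIF_PANEL
    backgrounds: tuple[str, ...] = ("random",)
    controls_per_site: int = 1000
    exclude_bed: str | None = None
    feature_beds: tuple[str, ...] = ()
    n_feature_controls: int = 100_000
    cluster_window: int = 8000
    cluster_min_sites: int = 3
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not self.motifs:
            raise ValueError("at least one motif is required")


@dataclass(frozen=True)
class Cluster:
    contig: str
    start: int
    end: int
    n_sites: int


@dataclass
class ClusterReport:
    window: int
    min_sites: int
    clusters: list[Cluster] = field(default_factory=list)


def find_clusters(sites: Sequence[GenomicSite], window: int,
                  min_sites: int) -> ClusterReport:
    """Hotspot summary: maximal windows of span <= ``window`` bp holding at
    least ``min_sites`` sites; overlapping qualifying windows are merged."""
    if window <= 0:
        raise ValueError("window must be > 0")
    if min_sites < 2:
        raise ValueError("min_sites must be >= 2")
    by_contig: dict[str, list[int]] = defaultdict(list)
    for s in sites:
        by_contig[s.contig].append(s.pos)
    report = ClusterReport(window=window, min_sites=min_sites)
    for contig in sorted(by_contig):
        pos = sorted(by_contig[contig])
        qualifying: list[tuple[int, int]] = []
        j = 0
        for i in range(len(pos)):
            if j < i:
                j = i
            while j + 1 < len(pos) and pos[j + 1] - pos[i] + 1 <= window:
                j += 1
            if j - i + 1 >= min_sites:
                qualifying.append((pos[i], pos[j] + 1))
        merged: list[list[int]] = []
        for s, e in qualifying:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            n = sum(1 for p in pos if s <= p < e)
            report.clusters.append(Cluster(contig, s, e, n))
    return report


def call_reads(
    reads: Mapping[str, str],
    human_ref: Mapping[str, str],
    viral_ref: Mapping[str, str],
    cfg: CriteriaConfig = CriteriaConfig(),
    seed_len: int = 11,
) -> list[JunctionCall]:
    """Align every read against both references with the built-in seed
    aligner and apply the acceptance criteria, collapsing duplicates."""
    human_aligner = SeedAligner(human_ref, seed_len)
    viral_aligner = SeedAligner(viral_ref, seed_len)
    calls = []
    for rid, seq in reads.items():
        h = human_aligner.align(rid, seq)
        v = viral_aligner.align(rid, seq)
        calls.append(call_junction(rid, h, v, cfg))
    return collapse_duplicates(calls)


def call_psl(
    human_psl_path: str | Path,
    viral_psl_path: str | Path,
    cfg: CriteriaConfig = CriteriaConfig(),
) -> list[JunctionCall]:
    """Junction calling from BLAT PSL files (one vs the chromosomal
    assembly, one vs the viral reference)."""
    with open(human_psl_path) as fh:
        human = parse_psl(fh)
    with open(viral_psl_path) as fh:
        viral = parse_psl(fh)
    by_read_h: dict[str, list] = defaultdict(list)
    by_read_v: dict[str, list] = defaultdict(list)
    for a in human:
        by_read_h[a.query_id].append(a)
    for a in viral:
        by_read_v[a.query_id].append(a)
    calls = []
    for rid in sorted(set(by_read_h) | set(by_read_v)):
        calls.append(call_junction(rid, by_read_h.get(rid, []),
                                   by_read_v.get(rid, []), cfg))
    return collapse_duplicates(calls)


def _background_models(
    name: str,
    genome: Mapping[str, str],
    index,
    sites: Sequence[GenomicSite],
    controls_per_site: int,
    seed: int,
) -> BackgroundModel:
    if name == "random":
        return exact_background(index)
    if name.startswith("enzyme:"):
        enzyme = name.split(":", 1)[1]
        cut_idx = restriction_cut_index(genome, enzyme)
        eligible = set(index.eligible_contigs)
        usable = [s for s in sites if index.is_eligible(s.contig)]
        controls = restriction_matched_controls(
            usable, cut_idx, m=controls_per_site,
            seed=np.random.default_rng([seed, zlib.crc32(enzyme.encode())]),
            eligible_contigs=eligible,
        )
        bg = empirical_background(controls, index, kind="restriction_matched",
                                  provenance=enzyme)
        return bg
    if name.startswith("sites:"):
        path = name.split(":", 1)[1]
        control_sites = rio.read_sites_bed(path)
        return empirical_background(control_sites, index,
                                    kind="empirical_sites", provenance=path)
    raise ValueError(f"unknown background model {name!r}")


def _stats_table(genome, sites, cfg: RunConfig, label: str):
    rows = []
    skipped = []
    for pattern, mm in cfg.motifs:
        spec = compile_motif(pattern, mm)
        index = build_occurrence_index(genome, spec)
        if motif_frequency(index) == 0:
            skipped.append({"motif": spec.name,
                            "reason": "no occurrence in any contig"})
            continue
        sample, dropped = distance_sample(sites, index, label=label,
                                          drop_ineligible=True)
        if sample.n == 0:
            skipped.append({"motif": spec.name,
                            "reason": "no site on an eligible contig"})
            continue
        for bg_name in cfg.backgrounds:
            bg = _background_models(bg_name, genome, index, sites,
                                    cfg.controls_per_site, cfg.seed)
            res = z_test(sample, bg)
            rows.append({
                "motif": spec.name, "mismatches": mm, "background": bg_name,
                "n": sample.n, "dropped": dropped,
                "mean_bp": round(sample.mean, 3), "sd_bp": round(sample.sd, 3),
                "mu_bp": round(bg.mu, 3), "sigma_bp": round(bg.sigma, 3),
                "z": round(res.statistic, 4),
                "p_one_sided": float(f"{res.one_sided_p:.6g}"),
                "p_two_sided": float(f"{res.two_sided_p:.6g}"),
                "tier": res.tier,
            })
    return rows, skipped


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis and return (and optionally write) the
    machine-readable report."""
    genome = rio.read_fasta(cfg.genome_fasta)
    sites = rio.read_sites_bed(cfg.sites_bed)
    if not sites:
        raise ValueError(f"no sites in {cfg.sites_bed}")

    report: dict = {"config": {
        "genome": str(cfg.genome_fasta), "sites": str(cfg.sites_bed),
        "motifs": [list(m) for m in cfg.motifs],
        "backgrounds": list(cfg.backgrounds), "seed": cfg.seed,
    }}

    rows, skipped = _stats_table(genome, sites, cfg, label="all_sites")
    report["distance_tests"] = rows
    report["skipped_motifs"] = skipped

    if cfg.exclude_bed:
        regions = rio.read_intervals_bed(cfg.exclude_bed)
        kept = exclude_regions(sites, regions)
        rows_x, skipped_x = _stats_table(genome, kept, cfg,
                                         label="hotspots_excluded")
        report["distance_tests_hotspots_excluded"] = rows_x
        report["n_excluded_sites"] = len(sites) - len(kept)

    if cfg.feature_beds:
        lengths = {c: len(s) for c, s in genome.items()}
        controls = uniform_control_sites(
            lengths, n=cfg.n_feature_controls,
            seed=np.random.default_rng([cfg.seed, 7]))
        feats = []
        for path in cfg.feature_beds:
            fs = FeatureSet.from_intervals(Path(path).stem,
                                           rio.read_intervals_bed(path),
                                           contig_lengths=lengths)
            res = feature_enrichment(sites, fs, controls)
            feats.append({
                "feature": fs.name, "k": res.k, "n": res.n,
                "pct_sites": round(100 * res.observed_fraction, 2),
                "pct_controls": round(100 * res.control_fraction, 2),
                "p_two_tailed": float(f"{res.p_two_tailed:.6g}"),
            })
        report["feature_enrichment"] = feats

    clusters = find_clusters(sites, cfg.cluster_window, cfg.cluster_min_sites)
    report["clusters"] = [
        {"contig": c.contig, "start": c.start, "end": c.end,
         "n_sites": c.n_sites}
        for c in clusters.clusters
    ]

    if cfg.outdir:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        pd.DataFrame(report["distance_tests"]).to_csv(
            outdir / "distance_tests.tsv", sep="\t", index=False)
        if "feature_enrichment" in report:
            pd.DataFrame(report["feature_enrichment"]).to_csv(
                outdir / "feature_enrichment.tsv", sep="\t", index=False)
        pd.DataFrame(report["clusters"]).to_csv(
            outdir / "clusters.tsv", sep="\t", index=False)
    return report
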