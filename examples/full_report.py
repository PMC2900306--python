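"""The full pipeline: simulate, scan the motif panel, test, cluster.

Generates a dataset with GAGCGAGC-targeted sites, then runs the report over
a two-motif panel: the planted motif should be flagged highly significant
and the unplanted GAGTGAGC panel should stay n.s.  Also prints the hotspot
cluster summary.
"""

import json
import tempfile
from pathlib import Path

from rbsprox import RunConfig, SimConfig, run_pipeline, simulate_dataset

workdir = Path(tempfile.mkdtemp(prefix="rbsprox_demo_"))
cfg = SimConfig(seed=17, contig_lengths=(400_000, 400_000), n_sites=60,
                targeted_fraction=0.3, kernel_scale=500.0,
                motif_rate=1 / 25_000, repeat_block_len=0,
                n_pure_viral=0, n_short_human=0, n_long_gap=0,
                n_duplicate=0, n_repeat=0)
simulate_dataset(cfg, workdir)

report = run_pipeline(RunConfig(
    genome_fasta=str(workdir / "genome.fa"),
    sites_bed=str(workdir / "sites.bed"),
    motifs=(("GAGC GAGC", 0), ("GAGT GAGC", 0)),
    backgrounds=("random",),
    cluster_window=8000, cluster_min_sites=3,
    seed=17, outdir=str(workdir / "report")))

print(f"{'motif':<12}{'n':>5}{'mean bp':>10}{'null mu':>10}"
      f"{'z':>8}{'p(1-sided)':>12}  tier")
for row in report["distance_tests"]:
    print(f"{row['motif']:<12}{row['n']:>5}{row['mean_bp']:>10.0f}"
          f"{row['mu_bp']:>10.0f}{row['z']:>8.2f}"
          f"{row['p_one_sided']:>12.2e}  {row['tier']}")

print("\nclusters (>=3 sites within 8 kb):")
for c in report["clusters"]:
    print(f"  {c['contig']}:{c['start']}-{c['end']}  {c['n_sites']} sites")

print(f"\nfull JSON report written to {workdir/'report'/'report.json'}")
print(
    "Only the motif actually shaping the site distribution rejects the "
    "uniform null; clusters mark candidate integration hotspots."
)
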