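"""Are integration sites closer to Rep-binding motifs than chance?

Plants 30% of sites near GAGCGAGC occurrences, then tests the mean
nearest-distance against (i) the exactly computed uniform null and (ii) a
PvuII restriction-site-matched control background.
"""

import numpy as np

from rbsprox import (SimConfig, build_occurrence_index, compile_motif,
                     distance_sample, empirical_background, exact_background,
                     make_genome, plant_sites, restriction_cut_index,
                     restriction_matched_controls, z_test)

cfg = SimConfig(seed=7, contig_lengths=(1_000_000, 1_000_000),
                targeted_fraction=0.3, kernel_scale=500.0,
                repeat_block_len=0)
genome, _ = make_genome(cfg)
index = build_occurrence_index(genome, compile_motif(cfg.motif))
sites, truth = plant_sites(genome, index, cfg)
sample, dropped = distance_sample(sites, index, drop_ineligible=True)
print(f"n={sample.n} sites, mean distance {sample.mean:,.0f} bp "
      f"(SD {sample.sd:,.0f})")

bg = exact_background(index)
res = z_test(sample, bg)
print(f"uniform null: mu={bg.mu:,.0f} sigma={bg.sigma:,.0f}  "
      f"z={res.statistic:.2f}  one-sided p={res.one_sided_p:.2e}  [{res.tier}]")

cuts = restriction_cut_index(genome, "PvuII")
controls = restriction_matched_controls(sites, cuts, m=200, seed=7,
                                        eligible_contigs=index.eligible_contigs)
bg_pvu = empirical_background(controls, index, kind="restriction_matched",
                              provenance="PvuII")
res_pvu = z_test(sample, bg_pvu)
print(f"PvuII-matched: mu={bg_pvu.mu:,.0f} sigma={bg_pvu.sigma:,.0f}  "
      f"z={res_pvu.statistic:.2f}  one-sided p={res_pvu.one_sided_p:.2e}")

print(
    "\nA negative z with small one-sided p means the observed sites sit "
    "closer to the motif landscape than both null models allow by chance; "
    "proximity is claimed only when every configured background rejects."
)
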