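"""Map a fully penetrant dominant locus in a simulated F2 intercross.

Simulates a 564-bird F2 between two inbred-like lines with chip-scale
marker content, runs QC, the kinship-corrected association scan with the
trait-at-birth covariate, a conditional re-scan on the top SNP, and the
Bonferroni threshold.
"""

import numpy as np

from mbsv.assoc import (
    assoc_scan, bonferroni_threshold, compute_kinship, conditional_scan, qc_filter,
)
from mbsv.syndata import CrossConfig, simulate_cross

bp = list(range(100_000, 5_100_000, 250_000))
cfg = CrossConfig(
    n_f2=564,
    marker_positions_bp=bp,
    marker_positions_cM=[b / 50_000 for b in bp],
    causal_locus_bp=1_600_000,
    penetrance=1.0,
    seed=7,
    n_background_chromosomes=27,
    background_markers_per_chrom=1600,  # ~43k markers total, as on the chip
)
res = simulate_cross(cfg)
gm, report = qc_filter(res.genotypes, res.pedigree)
print(report.to_frame().to_string(index=False))

f2 = np.array([i.startswith("F2") for i in gm.individuals])
gm = gm.subset(ind_mask=f2)
kin = compute_kinship(gm)
scan = assoc_scan(gm, res.phenotypes, kin)
peak = scan.table.set_index("marker").loc[scan.peak_marker]
thr = bonferroni_threshold(gm.n_markers)
print(f"\npeak SNP {scan.peak_marker} at {int(peak['bp']):,} bp: "
      f"p = {peak['p']:.2e} (-log10 p = {peak['neg_log10_p']:.1f})")
print(f"Bonferroni threshold for {gm.n_markers:,} tests: {thr:.2e}")

cond = conditional_scan(gm, res.phenotypes, kin, scan.peak_marker)
print(f"after conditioning on the peak SNP, smallest p = "
      f"{np.nanmin(cond.table['p']):.3g} -> no second locus on the chromosome")
print("\nThe peak p-value far below 1e-19 and the silent conditional scan "
      "are the single-dominant-locus signature.")
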