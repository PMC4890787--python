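"""In-silico diagnostic PCR across a breakpoint junction.

A primer pair straddling the CNV1-CNV3 junction amplifies only from the
derived (Mb) haplotype: the two binding sites are megabases apart on the
wild-type chromosome but adjacent on the rearranged allele.
"""

from Bio.Seq import Seq

from mbsv.genodx import insilico_pcr
from mbsv.syndata import build_derived_haplotype, mb_toy_reference

ref, spec = mb_toy_reference(seed=11)
derived = build_derived_haplotype(ref, spec)

j_left = spec.insertion_after            # CNV1 3' end (toy frame)
cnv3_start = spec.source_intervals[0][0]  # CNV3 5' start
fwd = ref.slice(j_left - 19, j_left)
rev = str(Seq(ref.slice(cnv3_start + 30, cnv3_start + 49)).reverse_complement())

for name, genome in (("wild-type", ref), ("Mb derived", derived)):
    products = insilico_pcr(fwd, rev, genome)
    if products:
        p = products[0]
        print(f"{name:>10}: {len(products)} product, {p.length} bp at "
              f"{p.start:,}-{p.end:,}")
    else:
        print(f"{name:>10}: no product")

print("\nAmplification only from the derived haplotype makes this a "
      "presence/absence test for the Mb allele, independent of dosage.")
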