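"""Single-end read simulation from a (possibly rearranged) haplotype.

Uniform start positions, fixed read length, independent per-base
substitution errors; quality strings are flat.  This is all the split-read
junction detector needs — base-quality realism and paired ends are out of
scope by design.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from mbsv.errors import ConfigurationError
from mbsv.syndata.genome import ToyGenome

_BASES = np.array(list("ACGT"))


def simulate_junction_reads(
    hap: ToyGenome,
    read_len: int = 150,
    coverage: float = 30.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[SeqRecord]:
    """Draw reads uniformly from ``hap`` at the requested mean coverage.

    The expected number of reads is ``coverage * length / read_len``; zero
    reads is a valid outcome at tiny coverages.
    """
    if coverage <= 0:
        raise ConfigurationError("coverage must be > 0")
    if read_len > hap.length:
        raise ConfigurationError("read length exceeds haplotype length")

    rng = np.random.default_rng(seed)
    n_reads = rng.poisson(coverage * hap.length / read_len)
    starts = rng.integers(0, hap.length - read_len + 1, size=n_reads)
    seq_arr = np.frombuffer(hap.sequence.encode(), dtype="S1")
    records = []
    for i, s in enumerate(sorted(starts)):
        read = seq_arr[s : s + read_len].astype("U1")
        if error_rate > 0:
            err = rng.random(read_len) < error_rate
            if err.any():
                read = read.copy()
                read[err] = _BASES[rng.integers(0, 4, size=int(err.sum()))]
        rec = SeqRecord(
            Seq("".join(read)),
            id=f"read_{i:06d}_pos{s + 1}",
            description="",
        )
        rec.letter_annotations["phred_quality"] = [40] * read_len
        records.append(rec)
    return records
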