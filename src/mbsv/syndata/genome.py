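"""Toy genomes and the derived (rearranged) haplotype builder.

The rearrangement model is a cassette of duplicated segments inserted back
into the reference chromosome: each duplicated segment keeps its original
copy in place, and one extra copy of each is concatenated (in a specified
order, all in forward orientation) and inserted after a given reference
position.  Consecutive pieces of the cassette are joined either across a
microhomology block of ``k`` bases shared by the two flanks, or across a
short untemplated insertion.  This is the architecture of the Mb allele:
a tandem duplication of one segment with two distant segments translocated
between the two tandem copies.

External coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from mbsv.errors import CoordinateError, GenerationError

_ALPHABET = "ACGT"


@dataclass(frozen=True)
class ToyGenome:
    """A single-chromosome genome over the A/C/G/T alphabet."""

    chrom_name: str
    sequence: str

    def __post_init__(self):
        bad = set(self.sequence) - set(_ALPHABET)
        if bad:
            raise GenerationError(f"non-ACGT characters in sequence: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """Subsequence for a 1-based inclusive interval."""
        if not (1 <= start <= end <= self.length):
            raise CoordinateError(
                f"interval {start}-{end} outside {self.chrom_name}:1-{self.length}"
            )
        return self.sequence[start - 1 : end]

    def to_seqrecord(self) -> SeqRecord:
        return SeqRecord(Seq(self.sequence), id=self.chrom_name, description="")


@dataclass(frozen=True)
class Junction:
    """Spec for one cassette adjacency: microhomology of ``homology`` bases
    (the flanks share the block, written once in the derived sequence) or an
    untemplated ``insertion`` between the flanks.  Both zero/empty = blunt."""

    homology: int = 0
    insertion: str = ""

    def __post_init__(self):
        if self.homology < 0:
            raise GenerationError("homology length must be >= 0")
        if self.homology and self.insertion:
            raise GenerationError("a junction is homology OR insertion, not both")
        if set(self.insertion) - set(_ALPHABET):
            raise GenerationError("insertion must be over A/C/G/T")


@dataclass(frozen=True)
class SVSpec:
    """Cassette architecture: ``source_intervals`` in cassette order (1-based
    inclusive reference coordinates), inserted after ``insertion_after``.
    ``junctions[i]`` joins the preceding flank to segment ``i``; the adjacency
    after the last segment is reference-like (blunt) by construction."""

    source_intervals: list[tuple[int, int]]
    insertion_after: int
    junctions: list[Junction] = field(default_factory=list)

    def __post_init__(self):
        for s, e in self.source_intervals:
            if s > e:
                raise GenerationError(f"degenerate interval ({s}, {e})")
        if len(self.junctions) != len(self.source_intervals):
            raise GenerationError(
                "need exactly one junction spec per cassette segment "
                f"({len(self.junctions)} junctions, {len(self.source_intervals)} segments)"
            )

    @property
    def segment_lengths(self) -> list[int]:
        return [e - s + 1 for s, e in self.source_intervals]

    @property
    def length_gain(self) -> int:
        """Derived-minus-reference length under the junction model."""
        return (
            sum(self.segment_lengths)
            - sum(j.homology for j in self.junctions)
            + sum(len(j.insertion) for j in self.junctions)
        )


def random_genome(length: int, seed: int, chrom_name: str = "chrT") -> ToyGenome:
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(_ALPHABET), size=length))
    return ToyGenome(chrom_name, seq)


def _check_spec_bounds(ref: ToyGenome, spec: SVSpec) -> None:
    for s, e in spec.source_intervals:
        if not (1 <= s <= e <= ref.length):
            raise CoordinateError(f"segment {s}-{e} outside reference of length {ref.length}")
    if not (1 <= spec.insertion_after <= ref.length):
        raise CoordinateError(f"insertion point {spec.insertion_after} outside reference")


def _other_base(*avoid: str) -> str:
    for b in _ALPHABET:
        if b not in avoid:
            return b
    raise AssertionError("unreachable: alphabet exhausted")


def enforce_junction_homology(ref: ToyGenome, spec: SVSpec, exact: bool = False) -> ToyGenome:
    """Edit the reference so every homology(k) junction is realisable.

    A homology junction requires the last ``k`` bases of the left flank to
    equal the first ``k`` bases of the next segment; the generator copies the
    left-flank bases onto the segment start so the two joined ends genuinely
    share the block (the microhomology is then present in both reference
    copies, as at a real rearrangement).

    With ``exact=True`` the bases immediately flanking every junction are
    additionally mutated so that no exact match can extend past the specified
    breakpoint by chance, making the spec the *canonical* (maximal-overlap)
    description of each junction: split-read detection then recovers the
    printed coordinates and homology/insertion lengths bit-exactly.
    """
    _check_spec_bounds(ref, spec)
    seq = list(ref.sequence)
    left_end = spec.insertion_after
    for (s, e), junc in zip(spec.source_intervals, spec.junctions):
        if junc.homology:
            k = junc.homology
            if k > left_end or k > (e - s + 1):
                raise GenerationError(f"homology {k} longer than a joined flank")
            block = seq[left_end - k : left_end]
            seq[s - 1 : s - 1 + k] = block
        left_end = e

    if exact:
        left_end = spec.insertion_after
        for (s, e), junc in zip(spec.source_intervals, spec.junctions):
            k = junc.homology
            # first derived base after the junction must mismatch the
            # reference continuation of the left flank...
            first_after = junc.insertion[0] if junc.insertion else seq[s - 1 + k]
            if left_end < len(seq) and seq[left_end] == first_after:
                seq[left_end] = _other_base(first_after)
            # ...and the derived base preceding the right segment must
            # mismatch the reference base before the segment start.
            last_before = junc.insertion[-1] if junc.insertion else seq[left_end - k - 1]
            if s >= 2 and seq[s - 2] == last_before:
                seq[s - 2] = _other_base(last_before)
            left_end = e
    return ToyGenome(ref.chrom_name, "".join(seq))


def build_derived_haplotype(ref: ToyGenome, spec: SVSpec) -> ToyGenome:
    """Build the rearranged haplotype carrying the duplication cassette.

    The original copy of every source interval stays at its reference
    position; the cassette (segments joined per the junction specs) is
    inserted immediately after ``insertion_after``.  Raises
    :class:`GenerationError` if a homology junction's flanks do not actually
    share the requested block (run :func:`enforce_junction_homology` first).
    """
    _check_spec_bounds(ref, spec)
    if not spec.source_intervals:
        return ToyGenome(ref.chrom_name, ref.sequence)

    pieces = [ref.sequence[: spec.insertion_after]]
    left_seq = pieces[0]
    for (s, e), junc in zip(spec.source_intervals, spec.junctions):
        seg = ref.slice(s, e)
        if junc.homology:
            k = junc.homology
            if left_seq[-k:] != seg[:k]:
                raise GenerationError(
                    f"homology({k}) junction requested but flanks do not share "
                    f"the block ({left_seq[-k:]!r} vs {seg[:k]!r})"
                )
            piece = seg[k:]
        else:
            piece = junc.insertion + seg
        pieces.append(piece)
        left_seq = seg
    pieces.append(ref.sequence[spec.insertion_after :])
    derived = "".join(pieces)
    assert len(derived) == ref.length + spec.length_gain
    return ToyGenome(ref.chrom_name + "_derived", derived)


def copy_number_track(ref_length: int, spec: SVSpec, window: int = 1000) -> np.ndarray:
    """Per-window copy number (diploid homozygous-derived) on the reference
    grid: 2 everywhere, 4 across every duplicated interval.  Windows partially
    covered get the coverage-weighted mean."""
    n_win = (ref_length + window - 1) // window
    per_base = np.full(ref_length, 2.0)
    for s, e in spec.source_intervals:
        per_base[s - 1 : e] = 4.0
    track = np.empty(n_win)
    for i in range(n_win):
        track[i] = per_base[i * window : (i + 1) * window].mean()
    return track
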