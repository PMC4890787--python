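"""Breakpoint-junction detection and derived-allele reconstruction.

Split reads from a rearranged haplotype align to the reference in two
maximal exact pieces: a prefix anchored at the left side of a novel
adjacency and a suffix anchored at the right side.  Reads voting for the
same adjacency are clustered; the consensus read-through sequence is
classified as a microhomology join (a block assignable to both flanks),
an untemplated insertion (bases matching neither flank), or a blunt join.
Junctions plus CNV copy counts define an adjacency graph whose unique
copy-count-consistent walk is the derived allele; the original-vs-duplicate
identity of tandem copies is resolved from a recombinant individual whose
phenotype and copy-specific genotype are only compatible with one
assignment.

All reported coordinates are 1-based: ``left_end`` is the last reference
base before the junction, ``right_start`` the first reference base after.
"""

from __future__ import annotations

import itertools
import logging
from collections import defaultdict
from dataclasses import dataclass, replace

from Bio.SeqRecord import SeqRecord

from mbsv.errors import (
    AmbiguousAssemblyError,
    AssemblyError,
    ClassificationError,
    ConfigurationError,
    EvidenceError,
)
from mbsv.syndata.genome import ToyGenome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BreakpointJunction:
    """A non-reference adjacency joining reference base ``left_end`` to
    reference base ``right_start`` (forward orientation on both sides)."""

    left_end: int
    right_start: int
    homology_len: int = 0
    inserted_seq: str = ""
    support: int = 0

    def __post_init__(self):
        if self.homology_len < 0:
            raise ConfigurationError("homology length must be >= 0")
        if self.homology_len > 0 and self.inserted_seq:
            raise ConfigurationError("homology and insertion are mutually exclusive")


class _KmerIndex:
    """Exact-match seed index over the reference (all k-mers -> positions)."""

    def __init__(self, seq: str, k: int):
        self.seq = seq
        self.k = k
        self.index: dict[str, list[int]] = defaultdict(list)
        for i in range(len(seq) - k + 1):
            self.index[seq[i : i + k]].append(i)

    def extend_prefix(self, read: str) -> tuple[int, int]:
        """Longest exact match of a read prefix (anchored at read start).

        Returns (ref_start_0based, match_len); (-1, 0) when no seed hits.
        Ties on length break toward the smaller reference coordinate.
        """
        best = (-1, 0)
        for pos in self.index.get(read[: self.k], ()):
            n = self.k
            while (
                pos + n < len(self.seq)
                and n < len(read)
                and self.seq[pos + n] == read[n]
            ):
                n += 1
            if n > best[1]:
                best = (pos, n)
        return best

    def extend_suffix(self, read: str) -> tuple[int, int]:
        """Longest exact match of a read suffix (anchored at read end).

        Returns (ref_end_0based_exclusive, match_len)."""
        best = (-1, 0)
        for pos in self.index.get(read[-self.k :], ()):
            end = pos + self.k
            n = self.k
            while (
                pos - (n - self.k) > 0
                and n < len(read)
                and self.seq[pos - (n - self.k) - 1] == read[-(n + 1)]
            ):
                n += 1
            if n > best[1]:
                best = (end, n)
        return best


def _read_breakpoint(read: str, idx: _KmerIndex, min_anchor: int):
    """Per-read junction vote, or None for concordant/unanchored reads."""
    pre_pos, pre_len = idx.extend_prefix(read)
    if pre_len >= len(read):
        return None  # fully concordant
    suf_end, suf_len = idx.extend_suffix(read)
    if pre_len < min_anchor or suf_len < min_anchor:
        return None
    left_end = pre_pos + pre_len          # 1-based last matched ref base
    right_start = suf_end - suf_len + 1   # 1-based first matched ref base
    if right_start == left_end + 1:
        return None  # reference adjacency
    p = pre_len                            # read index after prefix (0-based)
    q = len(read) - suf_len                # read index of suffix start
    if q >= p:
        homology, inserted = 0, read[p:q]
    else:
        homology, inserted = p - q, ""
    return (left_end, right_start, homology, inserted)


def detect_junctions(
    reads: list[SeqRecord] | list[str],
    ref: ToyGenome,
    min_anchor: int = 20,
    min_support: int = 2,
    cluster_tol: int = 2,
) -> list[BreakpointJunction]:
    """Split-read detection of non-reference adjacencies.

    Each read's maximal exact prefix and suffix matches to the reference are
    found by seed-and-extend; reads whose two anchors are discordant vote
    for a junction.  Votes within ``cluster_tol`` bp are clustered; clusters
    reaching ``min_support`` are reported with majority-vote consensus
    coordinates (ties toward the smaller coordinate).
    """
    if ref.length < min_anchor:
        raise ConfigurationError("reference shorter than min_anchor")
    idx = _KmerIndex(ref.sequence, min_anchor)
    votes = []
    for rec in reads:
        seq = str(rec.seq) if isinstance(rec, SeqRecord) else str(rec)
        if len(seq) < 2 * min_anchor:
            continue
        v = _read_breakpoint(seq, idx, min_anchor)
        if v is not None:
            votes.append(v)

    clusters: list[list[tuple]] = []
    for v in sorted(votes):
        for cl in clusters:
            if abs(cl[0][0] - v[0]) <= cluster_tol and abs(cl[0][1] - v[1]) <= cluster_tol:
                cl.append(v)
                break
        else:
            clusters.append([v])

    junctions = []
    for cl in clusters:
        if len(cl) < min_support:
            continue

        def consensus(values):
            counts = defaultdict(int)
            for x in values:
                counts[x] += 1
            top = max(counts.values())
            return min(v for v, c in counts.items() if c == top)

        junctions.append(
            BreakpointJunction(
                left_end=consensus([v[0] for v in cl]),
                right_start=consensus([v[1] for v in cl]),
                homology_len=consensus([v[2] for v in cl]),
                inserted_seq=consensus([v[3] for v in cl]),
                support=len(cl),
            )
        )
    junctions.sort(key=lambda j: (j.left_end, j.right_start))
    return junctions


def classify_junction(
    left_flank: str,
    right_flank: str,
    junction_consensus: str,
    min_anchor: int = 20,
) -> tuple[int, str]:
    """Classify a junction read-through against its two flanks.

    ``left_flank`` must end at the junction's left side and ``right_flank``
    begin at its right side.  The maximal consensus prefix that is a suffix
    of the left flank and the maximal consensus suffix that is a prefix of
    the right flank partition the consensus: an overlap of the two matched
    regions is microhomology, a gap is an untemplated insertion, and an
    exact meeting is a blunt join.
    """
    cons = junction_consensus
    a = 0
    for k in range(1, min(len(cons), len(left_flank)) + 1):
        if cons[:k] == left_flank[-k:]:
            a = k
    b = 0
    for k in range(1, min(len(cons), len(right_flank)) + 1):
        if cons[-k:] == right_flank[:k]:
            b = k
    if a < min_anchor or b < min_anchor:
        raise ClassificationError(
            f"consensus anchors ({a}, {b}) below min_anchor={min_anchor}; "
            "consensus inconsistent with the flanks"
        )
    if a + b > len(cons):
        return a + b - len(cons), ""
    if a + b == len(cons):
        return 0, ""
    return 0, cons[a : len(cons) - b]


@dataclass(frozen=True)
class SegmentCopy:
    interval: tuple[int, int]
    copy_index: int
    original: bool | None = None  # None = unresolved


@dataclass
class DerivedAlleleModel:
    """Ordered segment copies along the derived allele with the junction
    joining each copy to the previous piece (reference flank for the first)."""

    insertion_after: int
    copies: list[SegmentCopy]
    junctions: list[BreakpointJunction]

    def order(self) -> list[tuple[int, int]]:
        return [c.interval for c in self.copies]

    def diagram(self, names: dict[tuple[int, int], str] | None = None) -> str:
        names = names or {}

        def nm(iv):
            return names.get(iv, f"{iv[0]}-{iv[1]}")

        cassette = list(self.copies)
        parts = []
        if len(cassette) == len(self.junctions) + 1:
            lead = cassette.pop(0)
            flag = {True: "*orig", False: "*dup", None: ""}[lead.original]
            parts.append(f"ref:[{nm(lead.interval)}{flag}]")
        else:
            parts.append(f"ref:...{self.insertion_after}]")
        for c, j in zip(cassette, self.junctions):
            tag = (
                f"hom{j.homology_len}" if j.homology_len
                else (f"ins{len(j.inserted_seq)}" if j.inserted_seq else "blunt")
            )
            flag = {True: "*orig", False: "*dup", None: ""}[c.original]
            parts.append(f"={tag}=> [{nm(c.interval)}{flag}]")
        parts.append(f"=ref=> [{self.insertion_after + 1}...")
        return " ".join(parts)


def _match(a: int, b: int, tol: int) -> bool:
    return abs(a - b) <= tol


def assemble_allele(
    junctions: list[BreakpointJunction],
    cnv_intervals: list[tuple[int, int]],
    insertion_locus_hint: int | None = None,
    tol: int = 2,
) -> DerivedAlleleModel:
    """Order the duplicated segments into the unique junction-consistent walk.

    Nodes are one extra copy of each gained interval (copy counts from the
    CNV calls); edges are the detected junctions plus the reference
    adjacency closing the cassette back onto the backbone.  All insertion
    sites and segment permutations are enumerated; exactly one must be
    consistent with every junction.  Only forward-orientation duplications
    are modelled — a junction whose ends cannot be read as (segment end ->
    segment start / backbone) in forward orientation is rejected.
    """
    if not junctions:
        raise AssemblyError("no junctions to assemble")
    ends = {iv: iv[1] for iv in cnv_intervals}
    starts = {iv: iv[0] for iv in cnv_intervals}
    for j in junctions:
        if not any(_match(j.right_start, s, tol) for s in starts.values()):
            raise AssemblyError(
                f"junction {j.left_end}->{j.right_start} does not land on a "
                "duplicated-segment start in forward orientation"
            )

    candidates = (
        [insertion_locus_hint]
        if insertion_locus_hint is not None
        else sorted({j.left_end for j in junctions})
    )
    solutions = []
    for site in candidates:
        for perm in itertools.permutations(cnv_intervals):
            used, chain_ok = [], True
            left = site  # current left-flank end coordinate
            for iv in perm:
                hit = [
                    j
                    for j in junctions
                    if _match(j.left_end, left, tol) and _match(j.right_start, iv[0], tol)
                ]
                if not hit:
                    chain_ok = False
                    break
                used.append(hit[0])
                left = iv[1]
            # cassette must close back onto the backbone via the reference
            # adjacency: last segment's end coincides with the insertion site
            if chain_ok and _match(left, site, tol) and len(set(used)) == len(junctions):
                solutions.append((site, perm, used))

    if not solutions:
        raise AssemblyError("no walk consistent with the junctions and copy counts")
    uniq = {tuple(s[1]) for s in solutions}
    if len(uniq) > 1:
        raise AmbiguousAssemblyError(sorted(uniq))
    site, perm, used = solutions[0]
    copies = [SegmentCopy(interval=iv, copy_index=1) for iv in perm]
    # when the cassette inserts at the end of a duplicated interval, the
    # walk reads through that interval's in-place copy first (the tandem
    # context: in-place copy, cassette, duplicate copy of the same interval)
    leading = next((iv for iv in cnv_intervals if _match(iv[1], site, tol)), None)
    if leading is not None:
        copies = [SegmentCopy(interval=leading, copy_index=0)] + copies
    return DerivedAlleleModel(insertion_after=site, copies=copies, junctions=used)


@dataclass
class RecombinantEvidence:
    individual: str
    affected: bool
    site_bp: int
    site_genotype: tuple[str, str]   # e.g. ("T", "C")
    breakpoint_bp: int
    ref_allele: str = "T"
    alt_allele: str = "C"


def resolve_copy_order(
    model: DerivedAlleleModel,
    evidence: RecombinantEvidence,
    tandem_interval: tuple[int, int] | None = None,
) -> DerivedAlleleModel:
    """Decide which tandem copy is the original using a recombinant bird.

    The derived allele carries two copies of one interval (the original at
    its reference position and the cassette-terminal duplicate), differing
    at a copy-specific site.  A crossover at ``breakpoint_bp`` in a carrier
    parent produced a gamete that is wild type on one side of the breakpoint
    and variant-derived on the other; depending on which physical copy the
    crossover entered, the recombinant haplotype either retains the whole
    cassette (and causes the phenotype) or keeps only the single chimeric
    copy (no phenotype).  Each hypothesis (variant allele on proximal or
    distal copy) x (crossover entering proximal or distal copy) predicts the
    individual's phenotype and site genotype; the unique consistent
    hypothesis fixes the original/duplicate labels.
    """
    if tandem_interval is None:
        # the tandem pair is the interval whose copy closes the cassette at
        # the insertion site (its end coincides with the insertion point)
        tandem_interval = next(
            (c.interval for c in model.copies if abs(c.interval[1] - model.insertion_after) <= 2),
            model.copies[-1].interval,
        )
    s, e = tandem_interval
    if not (s <= evidence.site_bp <= e):
        raise EvidenceError("copy-specific site outside the tandem interval")
    carries_alt = evidence.alt_allele in evidence.site_genotype
    if not carries_alt:
        return replace_unresolved(model, reason="evidence homozygous reference")

    site_after_bp = evidence.site_bp >= evidence.breakpoint_bp
    consistent = []
    for variant_on in ("proximal", "distal"):
        for crossover_into in ("proximal", "distal"):
            # recombinant gamete: wild-type sequence up to the breakpoint,
            # then the derived haplotype from where the crossover enters the
            # hypothesised physical copy
            if crossover_into == "proximal":
                # gamete keeps the rest of the proximal copy plus the whole
                # cassette (with the full distal copy) -> still causes the
                # phenotype; carries the variant unless it sits on the
                # proximal copy upstream of the breakpoint
                predicted_affected = True
                gamete_has_alt = (variant_on == "distal") or site_after_bp
            else:
                # gamete is a single chimeric copy: wild type up to the
                # breakpoint, distal-copy sequence after -> no cassette
                predicted_affected = False
                gamete_has_alt = (variant_on == "distal") and site_after_bp
            if predicted_affected == evidence.affected and gamete_has_alt == carries_alt:
                consistent.append((variant_on, crossover_into))

    variant_sides = {v for v, _ in consistent}
    if not consistent:
        raise EvidenceError("recombinant evidence contradicts every copy assignment")
    if len(variant_sides) > 1:
        logger.info("copy order unresolved: both assignments consistent")
        return replace_unresolved(model, reason="both assignments consistent")
    variant_on = variant_sides.pop()
    # the variant-carrying copy is the newly acquired (duplicate) copy:
    # copy_index 0 is the proximal in-place copy, cassette copies are distal
    copies = []
    for c in model.copies:
        if c.interval == tandem_interval:
            is_proximal = c.copy_index == 0
            proximal_is_original = variant_on == "distal"
            copies.append(replace(c, original=is_proximal == proximal_is_original))
        else:
            copies.append(replace(c, original=False))
    return DerivedAlleleModel(
        insertion_after=model.insertion_after, copies=copies, junctions=model.junctions
    )


def replace_unresolved(model: DerivedAlleleModel, reason: str) -> DerivedAlleleModel:
    logger.info("copy order left unresolved: %s", reason)
    out = DerivedAlleleModel(
        insertion_after=model.insertion_after,
        copies=[replace(c, original=None) for c in model.copies],
        junctions=model.junctions,
    )
    out.unresolved_reason = reason
    return out
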