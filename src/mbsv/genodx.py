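"""Copy-specific variant discovery and dosage genotyping.

A site inside the tandem-duplicated interval is present in 2 + k copies in
a bird carrying k derived alleles.  If the duplicated copy carries a
variant allele absent from wild-type haplotypes, pyrosequencing peak
heights at that site are proportional to allele copy counts:

    mb/mb -> T:2 C:0 (T peak only)
    Mb/mb -> T:2 C:1 (T twice the height of C)
    Mb/Mb -> T:2 C:2 (equal peaks)

Genotypes are called by chi-squared goodness of fit of the observed peak
heights against each class's expected proportions; a unique surviving
class is the call, anything else is reported ambiguous (the diagnostic
junction PCR backstops the assay).  In-silico PCR predicts which primer
pairs amplify from which haplotype, giving the presence/absence diagnostic
that is perfectly associated with the phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from Bio.Seq import Seq

from mbsv.errors import ConfigurationError, CoordinateError, MbsvError
from mbsv.syndata.genome import ToyGenome


@dataclass(frozen=True)
class CopySpecificVariant:
    position: int
    ref_allele: str
    alt_allele: str
    carrying_copy: int  # index of the copy whose sequence shows the alt


def find_copy_specific_variants(
    copy_sequences: list[str],
    interval_start: int,
    panel_haplotypes: list[str],
) -> list[CopySpecificVariant]:
    """Sites where the two copies differ and the copy-specific allele is
    absent from every wild-type panel haplotype.

    ``copy_sequences`` are the per-copy amplicon consensus sequences over
    the duplicated interval (same frame); ``panel_haplotypes`` the same
    region from non-carrier birds.  Positions are reported 1-based on the
    reference (``interval_start`` anchors the frame).
    """
    if len(copy_sequences) < 2:
        raise ConfigurationError("need >= 2 copy sequences to compare")
    lens = {len(s) for s in copy_sequences} | {len(s) for s in panel_haplotypes}
    if len(lens) != 1:
        raise CoordinateError("copy/panel sequences do not share a frame")
    out = []
    for i in range(len(copy_sequences[0])):
        alleles = [s[i] for s in copy_sequences]
        if len(set(alleles)) == 1:
            continue
        panel = {h[i] for h in panel_haplotypes}
        # the duplicate-specific allele must be absent from the panel
        novel = [(ci, a) for ci, a in enumerate(alleles) if a not in panel]
        if len(novel) == 1:
            ci, alt = novel[0]
            ref = next(a for a in alleles if a in panel)
            out.append(
                CopySpecificVariant(
                    position=interval_start + i,
                    ref_allele=ref,
                    alt_allele=alt,
                    carrying_copy=ci,
                )
            )
    return sorted(out, key=lambda v: v.position)


@dataclass
class DosageModel:
    """Allele copy counts per genotype class at the diagnostic site."""

    classes: dict[str, dict[str, int]] = field(
        default_factory=lambda: {
            "mb/mb": {"T": 2, "C": 0},
            "Mb/mb": {"T": 2, "C": 1},
            "Mb/Mb": {"T": 2, "C": 2},
        }
    )

    def expected_proportions(self, genotype_class: str) -> dict[str, float]:
        counts = self.classes[genotype_class]
        total = sum(counts.values())
        return {nt: c / total for nt, c in counts.items()}


def expected_allele_ratio(genotype_class: str, dm: DosageModel | None = None) -> float | str:
    """Ratio of the reference-allele to variant-allele copy count; the
    zero-denominator class is reported as ``"T only"``."""
    dm = dm or DosageModel()
    if genotype_class not in dm.classes:
        raise ConfigurationError(f"unknown genotype class {genotype_class!r}")
    counts = dm.classes[genotype_class]
    (ref_nt, ref_n), (alt_nt, alt_n) = list(counts.items())
    if alt_n == 0:
        return f"{ref_nt} only"
    return ref_n / alt_n


@dataclass
class GenotypeCall:
    genotype: str  # class name or "ambiguous"
    p_values: dict[str, float]


def call_genotype_pyro(
    signal: dict[str, float],
    dm: DosageModel | None = None,
    alpha: float = 0.05,
    effective_count: float = 100.0,
    zero_copy_floor: float = 0.03,
) -> GenotypeCall:
    """Chi-squared goodness-of-fit genotype call from peak heights.

    Heights are rescaled to ``effective_count`` pseudo-counts so the test is
    well defined and scale invariant.  Classes expecting zero copies of an
    allele are tested against a small noise-floor proportion
    (``zero_copy_floor``) for that allele: the floor must stay below the
    chi-squared critical value in pseudo-counts (else a cleanly absent
    allele, observed height 0, would reject the true class) while leaving
    room for baseline signal noise.  Classes with p > alpha survive; a
    unique survivor is the call, otherwise the result is ambiguous — the
    workflow never forces a call, since the junction PCR diagnostic
    backstops the assay.
    """
    dm = dm or DosageModel()
    total = sum(signal.values())
    if total <= 0:
        raise ConfigurationError("zero total pyrosequencing signal")
    nts = sorted(signal)
    obs = np.array([signal[nt] for nt in nts]) / total * effective_count
    p_values = {}
    for cls in dm.classes:
        props = dm.expected_proportions(cls)
        exp = np.array([props.get(nt, 0.0) for nt in nts])
        exp = np.where(exp == 0.0, zero_copy_floor, exp)
        exp = exp / exp.sum() * effective_count
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        p_values[cls] = float(stats.chi2.sf(chi2, df=len(nts) - 1))
    surviving = [cls for cls, p in p_values.items() if p > alpha]
    genotype = surviving[0] if len(surviving) == 1 else "ambiguous"
    return GenotypeCall(genotype=genotype, p_values=p_values)


@dataclass(frozen=True)
class PCRProduct:
    start: int   # 1-based position of the forward primer's first base
    end: int     # 1-based position of the reverse primer's first base (plus strand)
    length: int


def insilico_pcr(
    forward_primer: str,
    reverse_primer: str,
    genome: ToyGenome,
    max_product: int = 10_000,
    min_primer_len: int = 15,
) -> list[PCRProduct]:
    """Exact-match in-silico PCR on a (possibly rearranged) haplotype.

    Products are all loci where the forward primer matches the plus strand
    and the reverse complement of the reverse primer matches downstream
    within ``max_product`` bases.  Junction-spanning primer pairs therefore
    amplify only from haplotypes carrying the junction.
    """
    for p in (forward_primer, reverse_primer):
        if set(p) - set("ACGT"):
            raise MbsvError(f"primer {p!r} contains non-ACGT characters")
        if len(p) < min_primer_len:
            raise MbsvError(f"primer shorter than {min_primer_len} nt")
    seq = genome.sequence
    rc = str(Seq(reverse_primer).reverse_complement())

    def find_all(needle):
        out, i = [], seq.find(needle)
        while i != -1:
            out.append(i)
            i = seq.find(needle, i + 1)
        return out

    fwd_hits = find_all(forward_primer)
    rev_hits = find_all(rc)
    products = []
    for f in fwd_hits:
        for r in rev_hits:
            end = r + len(rc)  # product ends at the last base of the rc match
            if end > f and end - f <= max_product:
                products.append(PCRProduct(start=f + 1, end=end, length=end - f))
    return sorted(products, key=lambda p: (p.start, p.end))


def cohort_concordance(
    calls: pd.Series | dict,
    phenotypes: pd.Series | dict,
) -> tuple[pd.DataFrame, bool]:
    """Cross-tabulate a diagnostic result against the phenotype.

    Returns (table, perfect) where ``perfect`` is True when every positive
    diagnostic is an affected bird and vice versa (zero off-diagonals).
    """
    calls = pd.Series(calls)
    phenotypes = pd.Series(phenotypes)
    if set(calls.index) != set(phenotypes.index):
        raise MbsvError("diagnostic calls and phenotypes cover different ids")
    table = pd.crosstab(
        calls.rename("diagnostic"), phenotypes.loc[calls.index].rename("phenotype")
    )
    joined = pd.DataFrame({"call": calls, "pheno": phenotypes.loc[calls.index]})
    discordant = int((joined["call"].astype(bool) != joined["pheno"].astype(bool)).sum())
    return table, discordant == 0
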