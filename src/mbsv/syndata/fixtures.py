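"""Canonical Mb-locus study conditions in full-scale and toy coordinates.

The derived Mb allele consists of three duplicated segments on GGA27:

* CNV1: 1,702,269-1,721,521 (19,253 bp), duplicated in tandem;
* CNV2: 3,578,409-3,592,890 (14,482 bp), translocated;
* CNV3: 4,470,331-4,503,417 (33,087 bp), translocated.

The extra copies form a cassette CNV3-CNV2-CNV1 inserted immediately after
the original CNV1 copy, so the derived allele reads
CNV1 - CNV3 - CNV2 - CNV1 along the chromosome.  The three novel
adjacencies carry, in order, a 2-nt microhomology, a 2-nt untemplated
insertion and an 8-nt untemplated insertion.  The diagnostic copy-specific
SNP (T-to-C) sits at 1,707,859 inside CNV1.

For simulation the whole frame is scaled down by ``TOY_SCALE`` (default
1/100) onto a random toy chromosome, preserving the architecture, the
junction classes and the gene content.
"""

from __future__ import annotations

import pandas as pd

from mbsv.syndata.genome import (
    Junction,
    SVSpec,
    ToyGenome,
    enforce_junction_homology,
    random_genome,
)

# printed GGA27 breakpoints (1-based inclusive)
CNV1 = (1_702_269, 1_721_521)
CNV2 = (3_578_409, 3_592_890)
CNV3 = (4_470_331, 4_503_417)
COPY_SPECIFIC_SNP_BP = 1_707_859
RECOMBINATION_BP = 1_702_798

TOY_SCALE = 100
TOY_CHROM_LEN = 50_000


def mb_sv_spec(scale: int = 1) -> SVSpec:
    """Cassette spec for the Mb allele, optionally scaled down by ``scale``.

    Insertion sequences are arbitrary fixed strings of the printed lengths
    (the untemplated bases themselves are not part of the architecture).
    """

    def sc(iv):
        return (iv[0] // scale, iv[1] // scale)

    return SVSpec(
        source_intervals=[sc(CNV3), sc(CNV2), sc(CNV1)],
        insertion_after=CNV1[1] // scale,
        junctions=[
            Junction(homology=2),
            Junction(insertion="CA"),
            Junction(insertion="TGCATGCA"),
        ],
    )


def mb_toy_reference(seed: int = 0) -> tuple[ToyGenome, SVSpec]:
    """Toy chromosome + scaled Mb cassette spec, harmonised so junction
    detection recovers the scaled breakpoints exactly."""
    spec = mb_sv_spec(scale=TOY_SCALE)
    ref = random_genome(TOY_CHROM_LEN, seed=seed, chrom_name="chrT")
    ref = enforce_junction_homology(ref, spec, exact=True)
    return ref, spec


def mb_gene_fixture(scale: int = TOY_SCALE) -> pd.DataFrame:
    """Gene content of the duplicated segments (toy coordinates).

    Seven genes lie within the three duplicated intervals; three of them
    (PSMC5, KRT222, CCR7) are truncated by the segment boundaries.  Gene
    spans are placed inside the scaled intervals to preserve the counts and
    the truncation pattern, not the real gene sizes.
    """
    c1s, c1e = CNV1[0] // scale, CNV1[1] // scale
    c2s, c2e = CNV2[0] // scale, CNV2[1] // scale
    c3s, c3e = CNV3[0] // scale, CNV3[1] // scale

    def inside(s, e, f0, f1):
        span = e - s
        return (s + int(span * f0), s + int(span * f1))

    rows = []
    for gene, (start, end) in {
        # CNV1: HOX cluster genes and the 3' part of PSMC5
        "PSMC5": (c1s - 30, c1s + 20),  # 3' end inside CNV1, rest outside
        "HOXB8": inside(c1s, c1e, 0.25, 0.45),
        "HOXB7": inside(c1s, c1e, 0.55, 0.70),
        # CNV2
        "SMARCD2": inside(c2s, c2e, 0.15, 0.75),
        # CNV3: SMARCE1, 3' of KRT222, 5' (first exons) of CCR7
        "KRT222": (c3s - 40, c3s + 30),
        "SMARCE1": inside(c3s, c3e, 0.30, 0.60),
        "CCR7": (c3e - 25, c3e + 45),
    }.items():
        rows.append({"gene": gene, "start": start, "end": end})
    return pd.DataFrame(rows)


def genes_in_intervals(genes: pd.DataFrame, intervals: list[tuple[int, int]]) -> list[str]:
    """Genes whose span overlaps any of the (1-based inclusive) intervals."""
    hits = []
    for row in genes.itertuples():
        if any(row.start <= e and row.end >= s for s, e in intervals):
            hits.append(row.gene)
    return sorted(hits)


def mb_expression_panel() -> pd.DataFrame:
    """True relative-expression pattern for the seven-gene qPCR panel.

    Mirrors the observed facial/dorsal skin patterns: HOXB8 ectopically
    expressed in Mb facial skin at every stage and silent in wild type;
    CCR7/SMARCE1/KRT222 up only in adult (and 2wk) Mb facial skin; SMARCD2
    up mostly in dorsal skin during development with a modest adult facial
    difference; HOXB7 and PSMC5 flat.  Values are fold changes relative to
    the wild-type dorsal-skin calibrator.
    """
    stages = ["E7.5", "E8.5", "E9.5", "E10.5", "2wk", "adult"]
    embryonic = {"E7.5", "E8.5", "E9.5", "E10.5"}
    rows = []

    def add(gene, genotype, tissue, stage, rel):
        rows.append(
            {"gene": gene, "genotype": genotype, "tissue": tissue, "stage": stage, "rel": rel}
        )

    for stage in stages:
        for tissue in ("facial", "dorsal"):
            # HOXB8: ectopic in Mb facial skin throughout; silent otherwise
            add("HOXB8", "Mb/Mb", tissue, stage, 40.0 if tissue == "facial" else 0.02)
            add("HOXB8", "mb/mb", tissue, stage, 0.02)
            # CCR7 and kin: differential only postnatally
            late = stage in ("2wk", "adult")
            for gene in ("CCR7", "SMARCE1", "KRT222"):
                add(gene, "Mb/Mb", tissue, stage, 8.0 if (late and tissue == "facial") else 1.0)
                add(gene, "mb/mb", tissue, stage, 1.0)
            # SMARCD2: dorsal during development, 2-fold adult facial
            if tissue == "dorsal" and stage in embryonic:
                add("SMARCD2", "Mb/Mb", tissue, stage, 6.0)
            elif tissue == "facial" and stage == "adult":
                add("SMARCD2", "Mb/Mb", tissue, stage, 2.0)
            else:
                add("SMARCD2", "Mb/Mb", tissue, stage, 1.0)
            add("SMARCD2", "mb/mb", tissue, stage, 1.0)
            for gene in ("HOXB7", "PSMC5"):
                add(gene, "Mb/Mb", tissue, stage, 1.0)
                add(gene, "mb/mb", tissue, stage, 1.0)
    return pd.DataFrame(rows)
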