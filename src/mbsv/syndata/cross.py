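"""F2 intercross simulation between two inbred-like founder lines.

The cross emulates the Huiyang-Bearded (line H, carrying the dominant Mb
allele) x broiler (line L) design: founders fixed for alternative alleles
at every marker, F1s all heterozygous, F2s produced by random F1 x F1
matings.  Meiosis uses the Haldane map function (independent crossovers,
no interference): between consecutive positions d cM apart a gamete
switches parental strand with probability r = (1 - exp(-2d/100)) / 2.

Genotype codes count copies of the line-H allele (0/1/2).  The phenotype
is dominant: an F2 expresses the trait iff it carries >= 1 line-H allele
at the causal position, with probability ``penetrance``.  A correlated
binary "trait visible at birth" covariate is generated for carriers with
probability ``birth_covariate_rate`` (the adult trait is what the scan
maps; the birth record enters the models as a covariate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mbsv.errors import ConfigurationError


@dataclass
class CrossConfig:
    n_f2: int = 585
    marker_positions_bp: list[int] = field(default_factory=list)
    marker_positions_cM: list[float] = field(default_factory=list)
    causal_locus_bp: int | None = None
    penetrance: float = 1.0
    birth_covariate_rate: float = 0.8
    marker_informativeness: float = 1.0
    # unlinked chip markers on other chromosomes: these carry the
    # genome-wide Mendelian-sampling relatedness the kinship matrix is meant
    # to capture.  The focal chromosome must be a small fraction of the
    # kinship markers (as on a 60k chip), else the polygenic term absorbs
    # the causal signal.  0 background chromosomes = focal chromosome only.
    n_background_chromosomes: int = 0
    background_markers_per_chrom: int = 30
    background_chrom_length_cM: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if len(self.marker_positions_bp) != len(self.marker_positions_cM):
            raise ConfigurationError("marker bp and cM lists must be equal length")
        if not self.marker_positions_bp:
            raise ConfigurationError("marker map must not be empty")
        if list(self.marker_positions_bp) != sorted(self.marker_positions_bp) or any(
            b - a <= 0 for a, b in zip(self.marker_positions_bp, self.marker_positions_bp[1:])
        ):
            raise ConfigurationError("marker bp positions must be strictly increasing")
        if any(
            b - a < 0 for a, b in zip(self.marker_positions_cM, self.marker_positions_cM[1:])
        ):
            raise ConfigurationError("marker cM positions must be nondecreasing")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ConfigurationError("penetrance must be in [0, 1]")


def haldane_r(d_cM: float) -> float:
    """Recombination fraction for a map distance in centiMorgan."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cM / 100.0))


@dataclass
class CrossResult:
    pedigree: pd.DataFrame          # id, sire, dam, sex, generation
    genotypes: "GenotypeMatrix"     # F2 + founders + F1, line-H allele dosage
    phenotypes: pd.DataFrame        # id, mb_week10, mb_at_birth (F2 only)
    true_origin: pd.DataFrame       # F2 x marker line-H allele count (0/1/2)
    causal_origin: pd.Series        # F2 line-H allele count at the causal bp
    config: CrossConfig = None


# GenotypeMatrix lives in assoc (it is that stage's input contract); the
# import is deferred to avoid a cycle at module load.
def _genotype_matrix(calls, individuals, markers):
    from mbsv.assoc import GenotypeMatrix

    return GenotypeMatrix(calls=calls, individuals=individuals, markers=markers)


def _interp_cM(cfg: CrossConfig, bp: int) -> float:
    return float(
        np.interp(bp, cfg.marker_positions_bp, cfg.marker_positions_cM)
    )


def _gamete(rng, cM: np.ndarray) -> np.ndarray:
    """Strand indicator (0/1 = which parental haplotype) at each position."""
    n = len(cM)
    strand = np.empty(n, dtype=np.int8)
    strand[0] = rng.integers(2)
    if n > 1:
        r = haldane_r(np.diff(cM))
        flips = rng.random(n - 1) < r
        strand[1:] = (strand[0] + np.cumsum(flips)) % 2
    return strand


def simulate_cross(cfg: CrossConfig) -> CrossResult:
    """Simulate the pedigree, F2 genotypes, phenotypes and the ground-truth
    line-origin tracks.  All randomness flows from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n_mark = len(cfg.marker_positions_bp)
    causal_bp = (
        cfg.causal_locus_bp
        if cfg.causal_locus_bp is not None
        else cfg.marker_positions_bp[0]
    )
    # augmented position list: markers plus the causal locus (latent)
    pos_cM = np.asarray(cfg.marker_positions_cM, dtype=float)
    causal_cM = _interp_cM(cfg, causal_bp)
    aug_cM = np.insert(pos_cM, np.searchsorted(pos_cM, causal_cM), causal_cM)
    causal_idx = int(np.searchsorted(pos_cM, causal_cM))
    marker_idx = np.delete(np.arange(n_mark + 1), causal_idx)

    informative = rng.random(n_mark) < cfg.marker_informativeness

    # F1 haplotype pair is always (H, L); an F2 haplotype's line origin at a
    # position equals the strand indicator of the gamete that produced it.
    n = cfg.n_f2
    origin = np.empty((n, n_mark + 1), dtype=np.int8)  # line-H allele count
    for i in range(n):
        pat = _gamete(rng, aug_cM)  # 0 => line H strand
        mat = _gamete(rng, aug_cM)
        origin[i] = (pat == 0).astype(np.int8) + (mat == 0).astype(np.int8)

    origin_markers = origin[:, marker_idx]
    origin_causal = origin[:, causal_idx]

    # observed genotypes: line-H dosage at informative markers; at diluted
    # (uninformative) markers both lines carry the same allele -> code 2
    geno_f2 = origin_markers.astype(float)
    geno_f2[:, ~informative] = 2.0

    carrier = origin_causal >= 1
    expressed = carrier & (rng.random(n) < cfg.penetrance)
    at_birth = expressed & (rng.random(n) < cfg.birth_covariate_rate)

    f2_ids = [f"F2_{i:04d}" for i in range(n)]
    founder_ids = ["H_sire", "H_dam", "L_sire", "L_dam"]
    f1_ids = ["F1_sire", "F1_dam"]
    ped_rows = [
        {"id": "H_sire", "sire": "0", "dam": "0", "sex": "M", "generation": 0},
        {"id": "H_dam", "sire": "0", "dam": "0", "sex": "F", "generation": 0},
        {"id": "L_sire", "sire": "0", "dam": "0", "sex": "M", "generation": 0},
        {"id": "L_dam", "sire": "0", "dam": "0", "sex": "F", "generation": 0},
        {"id": "F1_sire", "sire": "H_sire", "dam": "L_dam", "sex": "M", "generation": 1},
        {"id": "F1_dam", "sire": "L_sire", "dam": "H_dam", "sex": "F", "generation": 1},
    ]
    sexes = rng.choice(["M", "F"], size=n)
    for i, fid in enumerate(f2_ids):
        ped_rows.append(
            {"id": fid, "sire": "F1_sire", "dam": "F1_dam", "sex": sexes[i], "generation": 2}
        )
    pedigree = pd.DataFrame(ped_rows)

    # background chromosomes: independent meioses, fully informative markers
    n_bg_chr = cfg.n_background_chromosomes
    m_bg = cfg.background_markers_per_chrom
    if n_bg_chr and m_bg:
        bg_cM = np.linspace(0.0, cfg.background_chrom_length_cM, m_bg)
        bg = np.empty((n, n_bg_chr * m_bg), dtype=float)
        for i in range(n):
            cols = []
            for _ in range(n_bg_chr):
                pat = _gamete(rng, bg_cM)
                mat = _gamete(rng, bg_cM)
                cols.append((pat == 0).astype(float) + (mat == 0).astype(float))
            bg[i] = np.concatenate(cols)
        geno_f2 = np.hstack([geno_f2, bg])

    n_total = geno_f2.shape[1]
    n_bg = n_total - n_mark
    founder_h = np.concatenate([np.where(informative, 2.0, 2.0), np.full(n_bg, 2.0)])
    founder_l = np.concatenate([np.where(informative, 0.0, 2.0), np.full(n_bg, 0.0)])
    f1_row = np.concatenate([np.where(informative, 1.0, 2.0), np.full(n_bg, 1.0)])
    calls = np.vstack([founder_h, founder_h, founder_l, founder_l, f1_row, f1_row, geno_f2])
    individuals = founder_ids + f1_ids + f2_ids
    markers = pd.DataFrame(
        {
            "marker": [f"M{j:04d}" for j in range(n_mark)],
            "chrom": "chrT",
            "bp": cfg.marker_positions_bp,
            "cM": cfg.marker_positions_cM,
        }
    )
    if n_bg:
        bg_rows = pd.DataFrame(
            {
                "marker": [f"B{j:04d}" for j in range(n_bg)],
                "chrom": [f"bg{j // m_bg + 1:02d}" for j in range(n_bg)],
                "bp": [int(1e6 * (j % m_bg + 1)) for j in range(n_bg)],
                "cM": np.tile(bg_cM, n_bg_chr),
            }
        )
        markers = pd.concat([markers, bg_rows], ignore_index=True)

    phenotypes = pd.DataFrame(
        {
            "id": f2_ids,
            "mb_week10": expressed.astype(int),
            "mb_at_birth": at_birth.astype(int),
        }
    )
    true_origin = pd.DataFrame(
        origin_markers, index=f2_ids, columns=markers["marker"].iloc[:n_mark]
    )
    return CrossResult(
        pedigree=pedigree,
        genotypes=_genotype_matrix(calls.astype(float), individuals, markers),
        phenotypes=phenotypes,
        true_origin=true_origin,
        causal_origin=pd.Series(origin_causal, index=f2_ids, name="causal_h_alleles"),
        config=cfg,
    )
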