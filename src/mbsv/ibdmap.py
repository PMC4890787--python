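"""Line-origin inference and shared-IBD fine-mapping of a dominant locus.

Each F2 chromosome is a mosaic of founder-line segments.  A 3-state HMM
over {HH, HL, LL} (both alleles from line H / one each / both from line L)
with Haldane transition probabilities and a genotyping-error emission
parameter yields posterior line-origin probabilities at every marker,
interpolated onto a 1-cM grid.  A 2-df F-scan (additive + dominance
expectations of line origin, trait-at-birth covariate) locates the locus;
its genome-wide threshold comes from a phenotype-randomization test.
Finally, under a single-locus dominant model, the locus must lie where
every affected bird carries >= 1 line-H allele and every unaffected bird
carries none: intersecting hard-called tracks gives the fine-mapped
interval, bounded by the recombinant individuals that define each edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mbsv.assoc import GenotypeMatrix
from mbsv.errors import ConfigurationError
from mbsv.syndata.cross import haldane_r

logger = logging.getLogger(__name__)

STATES = ("HH", "HL", "LL")
_PRIOR = np.array([0.25, 0.5, 0.25])


@dataclass
class LineOriginTrack:
    """Posterior origin-class probabilities per individual on a common grid.

    ``probs`` has shape (n_individuals, n_positions, 3) ordered (HH, HL, LL);
    ``grid`` carries the positions (cM and interpolated bp).
    """

    individuals: list[str]
    grid: pd.DataFrame  # columns: cM, bp (+ marker where grid = marker set)
    probs: np.ndarray
    marker_posteriors: "LineOriginTrack | None" = None

    def h_allele_dose(self) -> np.ndarray:
        """Expected number of line-H alleles at each position."""
        return 2.0 * self.probs[:, :, 0] + self.probs[:, :, 1]

    def hard_calls(self, threshold: float = 0.99) -> np.ndarray:
        """Argmax class where the posterior exceeds ``threshold``, else -1."""
        arg = self.probs.argmax(axis=2)
        conf = self.probs.max(axis=2) >= threshold
        return np.where(conf, arg, -1)


def _transition(r: float) -> np.ndarray:
    """Two independent meioses, each switching lines with probability r."""
    s, t = (1 - r) ** 2, r * (1 - r)
    return np.array(
        [
            [s, 2 * t, r**2],
            [t, s + r**2, t],
            [r**2, 2 * t, s],
        ]
    )


def _emission(call: float, informative: bool, error_rate: float) -> np.ndarray:
    """P(observed dosage | state).  With fully informative founders the true
    dosage equals 2/1/0 for HH/HL/LL; a symmetric error moves the call to
    either other code with probability ``error_rate``."""
    if not informative or np.isnan(call):
        return np.ones(3)
    e = error_rate
    probs = np.empty(3)
    for k, true_dose in enumerate((2.0, 1.0, 0.0)):
        probs[k] = (1 - e) if call == true_dose else e / 2.0
    return probs


def infer_line_origin(
    gm: GenotypeMatrix,
    ped: pd.DataFrame,
    genetic_map: pd.DataFrame | None = None,
    error_rate: float = 0.001,
    grid_step_cM: float = 1.0,
    individuals: list[str] | None = None,
    chrom: str | None = "chrT",
) -> LineOriginTrack:
    """Forward-backward posteriors over {HH, HL, LL} for each F2.

    Markers are informative when the founder lines are fixed for alternative
    alleles (inferred from generation-0 pedigree entries when available,
    otherwise all markers with dosage coding are taken as informative).
    Posteriors are computed at the markers and linearly interpolated onto a
    ``grid_step_cM`` grid.
    """
    if chrom is not None:
        gm = gm.subset(marker_mask=(gm.markers["chrom"] == chrom).to_numpy())
    markers = genetic_map if genetic_map is not None else gm.markers
    if "cM" not in markers.columns:
        raise ConfigurationError("genetic map must provide a cM column")
    cM = markers["cM"].to_numpy(float)
    bp = markers["bp"].to_numpy(float)

    known = set(ped["id"])
    if individuals is None:
        gen = ped.set_index("id")["generation"] if "generation" in ped.columns else None
        individuals = [
            i for i in gm.individuals if gen is None or (i in known and gen.get(i) == 2)
        ]
    for ind in individuals:
        if ind not in known:
            raise ConfigurationError(f"individual {ind!r} absent from pedigree")

    # founder-informativeness: markers where line-H founders are fixed 2 and
    # line-L founders fixed 0 (dosage coding); others carry no line signal
    founder_ids = (
        ped.loc[ped.get("generation", pd.Series(dtype=int)) == 0, "id"].tolist()
        if "generation" in ped.columns
        else []
    )
    informative = np.ones(len(markers), dtype=bool)
    f_rows = [gm.individuals.index(f) for f in founder_ids if f in gm.individuals]
    if f_rows:
        fcalls = gm.calls[f_rows]
        with np.errstate(invalid="ignore"):
            informative = (np.nanmax(fcalls, axis=0) == 2.0) & (
                np.nanmin(fcalls, axis=0) == 0.0
            )

    n_mark = len(markers)
    trans = [ _transition(haldane_r(d)) for d in np.diff(cM) ]

    rows = []
    post_all = np.empty((len(individuals), n_mark, 3))
    for ii, ind in enumerate(individuals):
        calls = gm.calls[gm.individuals.index(ind)]
        em = np.vstack(
            [_emission(calls[j], bool(informative[j]), error_rate) for j in range(n_mark)]
        )
        # forward
        alpha = np.empty((n_mark, 3))
        a = _PRIOR * em[0]
        alpha[0] = a / a.sum()
        for j in range(1, n_mark):
            a = (alpha[j - 1] @ trans[j - 1]) * em[j]
            alpha[j] = a / a.sum()
        # backward
        beta = np.ones((n_mark, 3))
        for j in range(n_mark - 2, -1, -1):
            b = trans[j] @ (em[j + 1] * beta[j + 1])
            beta[j] = b / b.sum()
        post = alpha * beta
        post /= post.sum(axis=1, keepdims=True)
        post_all[ii] = post

    grid_cM = np.arange(cM[0], cM[-1] + 1e-9, grid_step_cM)
    grid_bp = np.interp(grid_cM, cM, bp)
    probs = np.empty((len(individuals), len(grid_cM), 3))
    for k in range(3):
        for ii in range(len(individuals)):
            probs[ii, :, k] = np.interp(grid_cM, cM, post_all[ii, :, k])
    probs /= probs.sum(axis=2, keepdims=True)

    track = LineOriginTrack(
        individuals=list(individuals),
        grid=pd.DataFrame({"cM": grid_cM, "bp": grid_bp}),
        probs=probs,
    )
    track.marker_posteriors = LineOriginTrack(  # posteriors at the markers
        individuals=list(individuals),
        grid=pd.DataFrame({"cM": cM, "bp": bp, "marker": markers["marker"].to_numpy()}),
        probs=post_all,
    )
    return track


@dataclass
class FStatProfile:
    grid: pd.DataFrame
    f_values: np.ndarray
    threshold: float | None = None
    df: tuple[int, int] | None = None

    @property
    def peak_cM(self) -> float:
        return float(self.grid["cM"].iloc[int(np.nanargmax(self.f_values))])


def _align_phenotypes(tracks: LineOriginTrack, ph: pd.DataFrame):
    phi = ph.set_index("id")
    missing = [i for i in tracks.individuals if i not in phi.index]
    if missing:
        raise ConfigurationError(f"phenotypes missing for {len(missing)} individuals")
    y = phi.loc[tracks.individuals, "mb_week10"].to_numpy(float)
    cov = phi.loc[tracks.individuals, "mb_at_birth"].to_numpy(float)
    return y, cov


def _f_profile(tracks: LineOriginTrack, y: np.ndarray, cov: np.ndarray) -> tuple[np.ndarray, tuple]:
    """2-df F statistic (additive + dominance line-origin expectations vs the
    covariate-only model) at each grid position."""
    n, n_pos, _ = tracks.probs.shape
    add = tracks.probs[:, :, 0] - tracks.probs[:, :, 2]
    dom = tracks.probs[:, :, 1]
    ones = np.ones(n)
    X0 = np.column_stack([ones, cov])
    if np.linalg.matrix_rank(X0) < X0.shape[1]:
        X0 = ones[:, None]
    beta0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    rss0 = float(((y - X0 @ beta0) ** 2).sum())
    fvals = np.empty(n_pos)
    df_used = None
    for j in range(n_pos):
        X1 = np.column_stack([X0, add[:, j], dom[:, j]])
        rank1 = np.linalg.matrix_rank(X1)
        q = rank1 - X0.shape[1]
        if q <= 0:
            fvals[j] = 0.0
            continue
        beta1, *_ = np.linalg.lstsq(X1, y, rcond=None)
        rss1 = float(((y - X1 @ beta1) ** 2).sum())
        dfe = n - rank1
        if dfe <= 0 or rss1 <= 0:
            fvals[j] = np.inf if rss0 > rss1 else 0.0
            continue
        fvals[j] = max(0.0, (rss0 - rss1) / q / (rss1 / dfe))
        if df_used is None:
            df_used = (q, dfe)
        if q == 1 and df_used[0] == 2:
            logger.info("grid point %d rank-deficient; 1-df test used", j)
    return fvals, (df_used or (2, n - 4))


def linkage_scan(tracks: LineOriginTrack, ph: pd.DataFrame) -> FStatProfile:
    """Genome (chromosome) scan of the line-origin F statistic."""
    y, cov = _align_phenotypes(tracks, ph)
    fvals, df = _f_profile(tracks, y, cov)
    return FStatProfile(grid=tracks.grid, f_values=fvals, df=df)


def randomization_threshold(
    tracks: LineOriginTrack,
    ph: pd.DataFrame,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """(1 - alpha) quantile of max-F over phenotype permutations.

    Phenotype and covariate rows are permuted together against the genetic
    tracks, preserving their mutual association.
    """
    if n_perm < 100:
        raise ConfigurationError("n_perm must be >= 100 for a stable threshold")
    y, cov = _align_phenotypes(tracks, ph)
    if np.all(y == y[0]):
        raise ConfigurationError("constant phenotype: randomization degenerate")
    rng = np.random.default_rng(seed)
    max_f = np.empty(n_perm)
    for b in range(n_perm):
        order = rng.permutation(len(y))
        fv, _ = _f_profile(tracks, y[order], cov[order])
        max_f[b] = np.nanmax(fv)
    return float(np.quantile(max_f, 1.0 - alpha))


@dataclass
class IBDInterval:
    chrom: str
    start_bp: int
    end_bp: int
    flanking_markers: tuple[str | None, str | None]
    recombinants: dict
    empty: bool = False
    positions: np.ndarray | None = None


def shared_ibd_interval(
    tracks: LineOriginTrack,
    ph: pd.DataFrame,
    hard_call_threshold: float = 0.99,
    chrom: str = "chrT",
) -> IBDInterval:
    """Intersection fine-mapping under a fully dominant single-locus model.

    Qualifying positions are those where every affected individual carries
    >= 1 line-H allele (state HH or HL) and every unaffected individual
    carries none (state LL); positions whose posterior fails the hard-call
    threshold for an individual are uninformative for that individual and
    cannot veto.  Returns the minimal enclosing bp interval snapped outward
    to the flanking positions, with the recombinants defining each boundary.
    """
    phi = ph.set_index("id")
    affected = np.array([phi.loc[i, "mb_week10"] == 1 for i in tracks.individuals])
    if not affected.any():
        raise ConfigurationError("no affected individuals: shared-IBD undefined")

    calls = tracks.hard_calls(hard_call_threshold)  # 0=HH 1=HL 2=LL -1=unknown
    carries_h = calls <= 1  # HH or HL
    known = calls >= 0
    veto_aff = (~carries_h) & known   # affected without an H allele
    veto_un = carries_h & known       # unaffected with an H allele
    ok = ~(veto_aff[affected].any(axis=0) | veto_un[~affected].any(axis=0))

    grid = tracks.grid
    if not ok.any():
        logger.info("shared-IBD intersection empty (phenocopy or penetrance < 1)")
        return IBDInterval(chrom, 0, 0, (None, None), {}, empty=True)

    idx = np.where(ok)[0]
    lo, hi = int(idx.min()), int(idx.max())
    # snap outward to the nearest flanking positions (recombination edges)
    lo_out, hi_out = max(lo - 1, 0), min(hi + 1, len(grid) - 1)
    marker_col = grid["marker"] if "marker" in grid.columns else None

    def boundary_recombinants(inside: int, outside: int) -> list[str]:
        """Individuals whose incompatible state just outside the interval is
        what stops it from extending — the boundary-defining recombinants."""
        if inside == outside:
            return []
        out_veto = np.where(affected, veto_aff[:, outside], veto_un[:, outside])
        return [tracks.individuals[i] for i in np.where(out_veto)[0]]

    return IBDInterval(
        chrom=chrom,
        start_bp=int(round(grid["bp"].iloc[lo_out])),
        end_bp=int(round(grid["bp"].iloc[hi_out])),
        flanking_markers=(
            marker_col.iloc[lo_out] if marker_col is not None else None,
            marker_col.iloc[hi_out] if marker_col is not None else None,
        ),
        recombinants={
            "left": boundary_recombinants(lo, lo_out),
            "right": boundary_recombinants(hi, hi_out),
        },
        positions=idx,
    )
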