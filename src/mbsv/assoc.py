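"""SNP-chip QC and kinship-corrected association scan.

The association model is a two-stage (GRAMMAR-style) approximation to a
per-marker linear mixed model: first fit

    y = X beta + g + e,   g ~ N(0, sg^2 K),  e ~ N(0, se^2 I)

by maximum likelihood on the eigendecomposition of the genomic kinship
matrix K, then score-test each marker against the environmental residuals
``e_hat = se^2 V^{-1} (y - X beta_hat)``.  The binary trait is analysed on
the linear (0/1) scale with the trait-at-birth record as a fixed covariate.
This trades a small, documented loss of exactness for a single spectral
decomposition instead of one REML fit per marker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from mbsv.errors import ConfigurationError, ModelError

logger = logging.getLogger(__name__)


@dataclass
class GenotypeMatrix:
    """Allele-dosage calls (0/1/2 copies of the designated allele, NaN for
    missing) for ``individuals`` x ``markers`` (marker, chrom, bp columns)."""

    calls: np.ndarray
    individuals: list[str]
    markers: pd.DataFrame

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.individuals), len(self.markers)):
            raise ConfigurationError("calls shape inconsistent with ids/markers")
        valid = np.isin(self.calls, (0.0, 1.0, 2.0)) | np.isnan(self.calls)
        if not valid.all():
            raise ConfigurationError("genotype codes must be 0/1/2 or missing")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset(self, ind_mask=None, marker_mask=None) -> "GenotypeMatrix":
        ind_mask = np.ones(self.n_individuals, bool) if ind_mask is None else ind_mask
        marker_mask = np.ones(self.n_markers, bool) if marker_mask is None else marker_mask
        return GenotypeMatrix(
            calls=self.calls[np.ix_(ind_mask, marker_mask)],
            individuals=[i for i, m in zip(self.individuals, ind_mask) if m],
            markers=self.markers.loc[marker_mask].reset_index(drop=True),
        )

    def marker_index(self, marker: str) -> int:
        idx = self.markers.index[self.markers["marker"] == marker]
        if len(idx) == 0:
            raise KeyError(f"marker {marker!r} not in matrix")
        return int(idx[0])


@dataclass
class QCReport:
    steps: list[dict] = field(default_factory=list)

    def log(self, step: str, removed_individuals: int = 0, removed_markers: int = 0,
            calls_set_missing: int = 0):
        self.steps.append(
            {
                "step": step,
                "removed_individuals": removed_individuals,
                "removed_markers": removed_markers,
                "calls_set_missing": calls_set_missing,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def _mendel_inconsistent(off: np.ndarray, sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Elementwise Mendelian inconsistency for dosage-coded trios.

    A trio call is inconsistent when the offspring cannot receive one allele
    from each parent: e.g. parent 0 x parent 0 -> offspring must be 0;
    parent 2 x anything -> offspring carries >= 1 copy.  Missing calls are
    never flagged.
    """
    with np.errstate(invalid="ignore"):
        min_from = np.where(sire == 2, 1, 0) + np.where(dam == 2, 1, 0)
        max_from = np.where(sire == 0, 0, 1) + np.where(dam == 0, 0, 1)
        bad = (off < min_from) | (off > max_from)
    bad &= ~(np.isnan(off) | np.isnan(sire) | np.isnan(dam))
    return bad


def qc_filter(
    gm: GenotypeMatrix,
    ped: pd.DataFrame,
    call_rate_ind: float = 0.9,
    call_rate_snp: float = 0.9,
    maf_min: float = 0.05,
    mendel_max: float = 0.05,
) -> tuple[GenotypeMatrix, QCReport]:
    """Chip QC mirroring the study's filters.

    Removes individuals with call rate <= ``call_rate_ind`` and SNPs with
    call rate <= ``call_rate_snp`` (strict inequalities kept, as stated);
    drops SNPs with minor allele frequency below ``maf_min``; computes
    pedigree Mendelian-inconsistency rates and removes individuals/SNPs
    exceeding ``mendel_max``, otherwise blanking the offending calls; drops
    W-linked markers entirely and blanks heterozygous Z calls in females.
    """
    report = QCReport()
    calls = gm.calls.copy()
    ids = list(gm.individuals)
    markers = gm.markers.copy()

    # individual call rate
    cr_ind = 1.0 - np.isnan(calls).mean(axis=1)
    keep_ind = cr_ind > call_rate_ind
    report.log("individual_call_rate", removed_individuals=int((~keep_ind).sum()))
    calls, ids = calls[keep_ind], [i for i, k in zip(ids, keep_ind) if k]
    if not ids:
        raise ConfigurationError("QC removed every individual")

    # SNP call rate
    cr_snp = 1.0 - np.isnan(calls).mean(axis=0)
    keep_snp = cr_snp > call_rate_snp
    report.log("snp_call_rate", removed_markers=int((~keep_snp).sum()))
    calls, markers = calls[:, keep_snp], markers.loc[keep_snp].reset_index(drop=True)

    # minor allele frequency
    with np.errstate(invalid="ignore"):
        p = np.nanmean(calls, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep_snp = ~(maf < maf_min)
    report.log("maf", removed_markers=int((~keep_snp).sum()))
    calls, markers = calls[:, keep_snp], markers.loc[keep_snp].reset_index(drop=True)

    # Mendelian consistency from the pedigree
    ped_idx = {r.id: i for i, r in enumerate(ped.itertuples())}
    pos = {iid: i for i, iid in enumerate(ids)}
    trio_rows = []
    for r in ped.itertuples():
        if r.id in pos and r.sire in pos and r.dam in pos:
            trio_rows.append((pos[r.id], pos[r.sire], pos[r.dam]))
    if trio_rows:
        bad = np.zeros_like(calls, dtype=bool)
        checked = np.zeros_like(calls, dtype=bool)
        for o, s, d in trio_rows:
            row_bad = _mendel_inconsistent(calls[o], calls[s], calls[d])
            row_checked = ~(
                np.isnan(calls[o]) | np.isnan(calls[s]) | np.isnan(calls[d])
            )
            bad[o] |= row_bad
            checked[o] |= row_checked
        with np.errstate(invalid="ignore"):
            err_ind = np.where(checked.sum(1) > 0, bad.sum(1) / np.maximum(checked.sum(1), 1), 0.0)
            err_snp = np.where(checked.sum(0) > 0, bad.sum(0) / np.maximum(checked.sum(0), 1), 0.0)
        drop_ind = err_ind > mendel_max
        drop_snp = err_snp > mendel_max
        n_blank = int(bad[~drop_ind][:, ~drop_snp].sum())
        calls = calls.copy()
        calls[bad] = np.nan
        report.log(
            "mendelian",
            removed_individuals=int(drop_ind.sum()),
            removed_markers=int(drop_snp.sum()),
            calls_set_missing=n_blank,
        )
        calls, ids = calls[~drop_ind], [i for i, k in zip(ids, drop_ind) if not k]
        calls, markers = calls[:, ~drop_snp], markers.loc[~drop_snp].reset_index(drop=True)
        if not ids:
            raise ConfigurationError("QC removed every individual")

    # sex chromosomes: drop W-linked; blank heterozygous Z calls in females
    is_w = markers["chrom"].astype(str).str.upper().eq("W").to_numpy()
    report.log("w_linked", removed_markers=int(is_w.sum()))
    calls, markers = calls[:, ~is_w], markers.loc[~is_w].reset_index(drop=True)
    is_z = markers["chrom"].astype(str).str.upper().eq("Z").to_numpy()
    if is_z.any():
        sex = {r.id: getattr(r, "sex", None) for r in ped.itertuples()}
        female = np.array([sex.get(i) == "F" for i in ids])
        het_z = np.zeros_like(calls, dtype=bool)
        het_z[np.ix_(female, is_z)] = calls[np.ix_(female, is_z)] == 1.0
        calls = calls.copy()
        calls[het_z] = np.nan
        report.log("z_het_females", calls_set_missing=int(het_z.sum()))
    else:
        report.log("z_het_females")

    return GenotypeMatrix(calls=calls, individuals=ids, markers=markers), report


def compute_kinship(gm: GenotypeMatrix) -> pd.DataFrame:
    """Marker-based realised relatedness (centred/scaled cross-product
    averaged over markers; missing calls mean-imputed per marker)."""
    if gm.n_individuals < 2 or gm.n_markers < 1:
        raise ConfigurationError("kinship needs >= 2 individuals and >= 1 marker")
    calls = gm.calls.copy()
    with np.errstate(invalid="ignore"):
        p = np.nanmean(calls, axis=0) / 2.0
    var = 2.0 * p * (1.0 - p)
    poly = var > 0
    if not poly.any():
        raise ModelError("all markers monomorphic; kinship undefined")
    calls, p, var = calls[:, poly], p[poly], var[poly]
    inds = np.where(np.isnan(calls))
    calls[inds] = (2.0 * p)[inds[1]]
    z = (calls - 2.0 * p) / np.sqrt(var)
    k = z @ z.T / z.shape[1]
    return pd.DataFrame(k, index=gm.individuals, columns=gm.individuals)


@dataclass
class AssocResult:
    table: pd.DataFrame          # marker, chrom, bp, stat, p, neg_log10_p, r2_with_peak
    peak_marker: str
    h2: float                    # polygenic variance fraction from stage 1

    def __getitem__(self, marker: str) -> pd.Series:
        return self.table.set_index("marker").loc[marker]


def _fit_variance_components(y, X, K):
    """ML fit of y = Xb + g + e on the spectrum of K; returns (beta, U,
    per-eigenvalue variances, sg2, se2)."""
    lam, U = np.linalg.eigh(K)
    lam = np.clip(lam, 0.0, None)
    yt, Xt = U.T @ y, U.T @ X

    def negll(log_delta):
        delta = np.exp(log_delta)  # se2 / sg2
        d = lam + delta
        beta, *_ = np.linalg.lstsq(Xt / np.sqrt(d)[:, None], yt / np.sqrt(d), rcond=None)
        r = yt - Xt @ beta
        n = len(y)
        sg2 = float((r**2 / d).sum() / n)
        if sg2 <= 0:
            return np.inf
        return 0.5 * (n * np.log(sg2) + np.log(d).sum() + n)

    res = optimize.minimize_scalar(negll, bounds=(-10.0, 10.0), method="bounded")
    delta = float(np.exp(res.x))
    d = lam + delta
    beta, *_ = np.linalg.lstsq(Xt / np.sqrt(d)[:, None], yt / np.sqrt(d), rcond=None)
    r = yt - Xt @ beta
    sg2 = float((r**2 / d).sum() / len(y))
    se2 = sg2 * delta
    return beta, U, d, sg2, se2, lam


def _grammar_residuals(y, X, K):
    beta, U, d, sg2, se2, lam = _fit_variance_components(y, X, K)
    if not np.isfinite(se2) or se2 <= 0:
        raise ModelError("variance-component fit degenerate")
    # e_hat = se2 V^{-1}(y - X beta) computed in the eigenbasis
    r_rot = (U.T @ (y - X @ beta)) / d
    resid = se2 / sg2 * (U @ r_rot)
    h2 = sg2 * lam.mean() / (sg2 * lam.mean() + se2)
    return resid, h2


def _score_test(resid: np.ndarray, calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker score test of the residuals against genotype dosage,
    missing genotypes excluded pairwise (vectorised complete-marker path)."""
    n, n_mark = calls.shape
    stat = np.full(n_mark, np.nan)
    has_nan = np.isnan(calls).any(axis=0)

    complete = ~has_nan
    if complete.any():
        G = calls[:, complete]
        G = G - G.mean(axis=0)
        denom = (G**2).sum(axis=0)
        rv = resid - resid.mean()
        s2 = float(rv @ rv) / n
        with np.errstate(invalid="ignore", divide="ignore"):
            st = (G.T @ rv) ** 2 / (denom * s2)
        st[denom <= 0] = np.nan
        if s2 <= 0:
            st[:] = np.nan
        stat[complete] = st

    for j in np.where(has_nan)[0]:
        g = calls[:, j]
        ok = ~np.isnan(g)
        gj, rj = g[ok], resid[ok]
        gj = gj - gj.mean()
        denom = float(gj @ gj)
        if denom <= 0 or len(rj) < 3:
            continue
        rv = rj - rj.mean()
        s2 = float(rv @ rv) / len(rj)
        if s2 <= 0:
            continue
        stat[j] = float(gj @ rv) ** 2 / (denom * s2)
    p = stats.chi2.sf(stat, df=1)
    return stat, p


def _build_design(ph: pd.DataFrame, ids: list[str], extra: np.ndarray | None = None):
    ph = ph.set_index("id").loc[ids]
    y = ph["mb_week10"].to_numpy(float)
    X = np.column_stack([np.ones(len(ids)), ph["mb_at_birth"].to_numpy(float)])
    if extra is not None:
        X = np.column_stack([X, extra])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelError(
            "design matrix singular (covariate confounded with intercept or "
            "conditioning marker)"
        )
    return y, X


def assoc_scan(
    gm: GenotypeMatrix,
    ph: pd.DataFrame,
    kin: pd.DataFrame,
    condition_on: str | None = None,
) -> AssocResult:
    """Kinship-corrected genome scan; optionally conditions on one marker."""
    ids = [i for i in gm.individuals if i in set(ph["id"])]
    mask = np.array([i in set(ids) for i in gm.individuals])
    gm = gm.subset(ind_mask=mask)
    ids = gm.individuals
    K = kin.loc[ids, ids].to_numpy()

    extra = None
    skip_idx = None
    if condition_on is not None:
        j = gm.marker_index(condition_on)
        g = gm.calls[:, j].copy()
        g[np.isnan(g)] = np.nanmean(g)
        extra = g[:, None]
        skip_idx = j

    y, X = _build_design(ph, ids, extra)
    resid, h2 = _grammar_residuals(y, X, K)
    stat, p = _score_test(resid, gm.calls)

    if skip_idx is not None:
        # conditioning marker (and its exact duplicates) is not a valid test
        dup = np.array(
            [
                np.array_equal(gm.calls[:, j], gm.calls[:, skip_idx], equal_nan=True)
                for j in range(gm.n_markers)
            ]
        )
        if dup.sum() > 1:
            logger.info("conditional scan: skipping %d markers identical to %s",
                        int(dup.sum()), condition_on)
        stat[dup], p[dup] = np.nan, np.nan

    table = gm.markers.copy()
    table["stat"] = stat
    table["p"] = p
    with np.errstate(divide="ignore"):
        table["neg_log10_p"] = -np.log10(p)
    finite = table["p"].notna()
    if not finite.any():
        raise ModelError("no testable markers")
    peak = table.loc[finite, "p"].idxmin()
    peak_marker = table.loc[peak, "marker"]
    peak_idx = gm.marker_index(peak_marker)
    table["r2_with_peak"] = _r2_with(gm.calls, peak_idx)
    return AssocResult(table=table, peak_marker=peak_marker, h2=h2)


def _r2_with(calls: np.ndarray, idx: int) -> np.ndarray:
    """r^2 of every marker with one reference marker (pairwise complete)."""
    r2 = np.full(calls.shape[1], np.nan)
    has_nan = np.isnan(calls).any(axis=0)
    peak = calls[:, idx]
    complete = ~has_nan
    if not np.isnan(peak).any() and complete.any():
        G = calls[:, complete] - calls[:, complete].mean(axis=0)
        pv = peak - peak.mean()
        denom = np.sqrt((G**2).sum(axis=0) * (pv @ pv))
        with np.errstate(invalid="ignore", divide="ignore"):
            r2[complete] = ((G.T @ pv) / denom) ** 2
    loop_cols = np.where(has_nan | np.isnan(peak))[0] if np.isnan(peak).any() else np.where(has_nan)[0]
    for j in loop_cols:
        r2[j] = ld_r2_from_calls(calls[:, j], peak)
    return r2


def conditional_scan(gm, ph, kin, top_marker: str) -> AssocResult:
    """Re-scan with the top marker's genotype as an additional covariate."""
    return assoc_scan(gm, ph, kin, condition_on=top_marker)


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    if n_tests < 1:
        raise ConfigurationError("n_tests must be >= 1")
    return alpha / n_tests


def ld_r2_from_calls(a: np.ndarray, b: np.ndarray) -> float:
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def ld_r2(gm: GenotypeMatrix, marker_a: str, marker_b: str) -> float:
    """Squared genotype correlation between two markers."""
    a = gm.calls[:, gm.marker_index(marker_a)]
    b = gm.calls[:, gm.marker_index(marker_b)]
    r2 = ld_r2_from_calls(a, b)
    if np.isnan(r2):
        raise ModelError("LD undefined for monomorphic marker")
    return r2
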