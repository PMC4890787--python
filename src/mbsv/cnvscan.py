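"""Windowed read-depth comparison between two sequencing pools.

Depth and mapping quality are averaged in non-overlapping 1-kb windows;
low-mappability windows are filtered by the mean-minus-3SD MQ rule; each
pool is normalised by its own genome-wide median depth and compared as a
log2 fold-change; runs of elevated/depressed windows are merged into CNV
calls.  Duplicated segments present on the variant haplotype but not the
reference show up as gains in the carrier pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mbsv.errors import ConfigurationError, GridError, ModelError


def window_depth(
    per_base_depth: np.ndarray,
    per_base_mq: np.ndarray | None = None,
    window: int = 1000,
    chrom: str = "chrT",
) -> pd.DataFrame:
    """Tile per-base depth (and optional MQ) into fixed-width window means.

    The last window may be short; coordinates are 1-based inclusive.
    """
    if window < 1:
        raise ConfigurationError("window must be >= 1")
    depth = np.asarray(per_base_depth, dtype=float)
    n = depth.size
    starts = np.arange(0, n, window)
    rows = {
        "chrom": chrom,
        "start": starts + 1,
        "end": np.minimum(starts + window, n),
        "depth": [depth[s : s + window].mean() for s in starts],
    }
    if per_base_mq is not None:
        mq = np.asarray(per_base_mq, dtype=float)
        if mq.size != n:
            raise GridError("depth and MQ vectors differ in length")
        rows["mq"] = [mq[s : s + window].mean() for s in starts]
    return pd.DataFrame(rows)


def mq_filter(track: pd.DataFrame, n_sd: float = 3.0) -> tuple[np.ndarray, float]:
    """Flag windows whose mean MQ falls below mean(MQ) - ``n_sd`` * SD(MQ).

    Returns (mask of flagged windows, threshold).  The strict inequality
    means a constant-MQ track flags nothing.
    """
    if len(track) < 2:
        raise ConfigurationError("MQ filter needs >= 2 windows (SD undefined)")
    mq = track["mq"].to_numpy(float)
    threshold = float(mq.mean() - n_sd * mq.std(ddof=0))
    return mq < threshold, threshold


def log2_fold_change(
    track_a: pd.DataFrame,
    track_b: pd.DataFrame,
    filter_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Median-normalised log2 depth ratio per window (pool a over pool b).

    Windows in ``filter_mask`` (e.g. the union of both pools' MQ filters) or
    with zero depth in either pool are marked filtered and get NaN fold
    change rather than +/- infinity.
    """
    if len(track_a) != len(track_b) or not (
        track_a["start"].to_numpy() == track_b["start"].to_numpy()
    ).all():
        raise GridError("pool tracks are not on the same window grid")
    da = track_a["depth"].to_numpy(float)
    db = track_b["depth"].to_numpy(float)
    med_a, med_b = np.median(da), np.median(db)
    if med_a <= 0 or med_b <= 0:
        raise ModelError("zero median depth: normalization undefined")
    filtered = np.zeros(len(track_a), dtype=bool)
    if filter_mask is not None:
        filtered |= np.asarray(filter_mask, dtype=bool)
    filtered |= (da == 0) | (db == 0)
    fc = np.full(len(track_a), np.nan)
    ok = ~filtered
    fc[ok] = np.log2((da[ok] / med_a) / (db[ok] / med_b))
    out = track_a[["chrom", "start", "end"]].copy()
    out["log2fc"] = fc
    out["filtered"] = filtered
    return out


@dataclass
class CNVCall:
    chrom: str
    start: int
    end: int
    direction: str       # "gain_a" (higher depth in pool a) or "gain_b"
    mean_log2fc: float
    n_windows: int
    window_index: list[int] = None

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def segment_cnv(
    fc: pd.DataFrame,
    min_abs_log2fc: float = 0.58,
    min_windows: int = 3,
    max_gap: int = 1,
    edge_threshold_frac: float = 0.5,
) -> list[CNVCall]:
    """Merge maximal same-direction runs of qualifying windows into calls.

    A window qualifies when unfiltered and |log2FC| >= ``min_abs_log2fc``;
    up to ``max_gap`` consecutive non-qualifying windows may be bridged.
    Calls shorter than ``min_windows`` qualifying windows are dropped.
    Call edges are then extended (hysteresis) through adjacent windows whose
    same-sign |log2FC| exceeds ``edge_threshold_frac`` of the main threshold,
    so a single noisy boundary window does not truncate the call.
    Deterministic; an empty call list is a valid result.
    """
    vals = fc["log2fc"].to_numpy(float)
    sign = np.where(np.isnan(vals), 0, np.sign(vals)) * (
        np.abs(np.nan_to_num(vals)) >= min_abs_log2fc
    )
    low = min_abs_log2fc * edge_threshold_frac
    calls: list[CNVCall] = []
    i, n = 0, len(fc)
    while i < n:
        if sign[i] == 0:
            i += 1
            continue
        s = int(sign[i])
        members = [i]
        j, gap = i + 1, 0
        while j < n:
            if sign[j] == s:
                members.append(j)
                gap = 0
            elif sign[j] == -s:
                break
            else:
                gap += 1
                if gap > max_gap:
                    break
            j += 1
        if len(members) >= min_windows:
            floor = calls[-1].window_index[-1] + 1 if calls else 0
            while (
                members[0] > floor
                and not np.isnan(vals[members[0] - 1])
                and s * vals[members[0] - 1] >= low
            ):
                members.insert(0, members[0] - 1)
            while (
                members[-1] < n - 1
                and not np.isnan(vals[members[-1] + 1])
                and s * vals[members[-1] + 1] >= low
            ):
                members.append(members[-1] + 1)
            rows = fc.iloc[members]
            calls.append(
                CNVCall(
                    chrom=str(fc["chrom"].iloc[members[0]]),
                    start=int(rows["start"].iloc[0]),
                    end=int(rows["end"].iloc[-1]),
                    direction="gain_a" if s > 0 else "gain_b",
                    mean_log2fc=float(rows["log2fc"].mean()),
                    n_windows=len(members),
                    window_index=members,
                )
            )
        i = members[-1] + 1
    return calls
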