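"""Pooled read-depth and mapping-quality track simulation.

Two sequencing pools (one per founder line) are emulated at their study
coverages (95x and 97x).  Window depth is drawn from a negative binomial
with mean ``mean_depth * copy_number / 2`` (Poisson in the zero
overdispersion limit); window mean MQ is Gaussian, depressed inside
declared low-mappability regions, which is what the mean-minus-3SD MQ
filter downstream is meant to catch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mbsv.errors import ConfigurationError, GridError


@dataclass
class DepthSimConfig:
    window_size: int = 1000
    mean_depth_pool_a: float = 95.0
    mean_depth_pool_b: float = 97.0
    overdispersion: float = 0.01
    read_len: int = 150  # converts depth to window read counts for sampling
    mq_mean: float = 50.0
    mq_sd: float = 3.0
    low_mq_regions: list[tuple[int, int]] = field(default_factory=list)
    low_mq_value: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.window_size < 1:
            raise ConfigurationError("window_size must be >= 1")
        if self.mean_depth_pool_a <= 0 or self.mean_depth_pool_b <= 0:
            raise ConfigurationError("pool mean depths must be > 0")
        if self.overdispersion < 0:
            raise ConfigurationError("overdispersion must be >= 0")


def _nb_draw(rng, mean: np.ndarray, alpha: float) -> np.ndarray:
    if alpha == 0:
        return rng.poisson(mean).astype(float)
    # NB with var = mu + alpha mu^2, parameterised as Gamma-Poisson
    shape = 1.0 / alpha
    lam = rng.gamma(shape, mean * alpha)
    return rng.poisson(lam).astype(float)


def _windows_frame(n_win: int, window: int, chrom: str) -> pd.DataFrame:
    start = np.arange(n_win) * window + 1
    return pd.DataFrame({"chrom": chrom, "start": start, "end": start + window - 1})


def simulate_pool_depth(
    copy_number_track_a: np.ndarray,
    copy_number_track_b: np.ndarray,
    cfg: DepthSimConfig,
    chrom: str = "chrT",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-window depth/MQ tracks for two pools on a shared grid.

    Returns two window tracks (chrom, start, end, depth, mq); coordinates
    1-based inclusive on the ``cfg.window_size`` tiling.
    """
    a = np.asarray(copy_number_track_a, dtype=float)
    b = np.asarray(copy_number_track_b, dtype=float)
    if a.shape != b.shape:
        raise GridError(f"copy-number tracks differ in length ({a.size} vs {b.size})")
    if (a < 0).any() or (b < 0).any():
        raise ConfigurationError("copy numbers must be >= 0")

    rng = np.random.default_rng(cfg.seed)
    # sampling operates on window read counts (depth * window / read_len):
    # the count scale sets the Poisson noise floor, as in real coverage data
    reads_per_window = cfg.window_size / cfg.read_len
    tracks = []
    for cn, mean_depth in ((a, cfg.mean_depth_pool_a), (b, cfg.mean_depth_pool_b)):
        frame = _windows_frame(cn.size, cfg.window_size, chrom)
        counts = _nb_draw(
            rng, mean_depth * reads_per_window * cn / 2.0, cfg.overdispersion
        )
        frame["depth"] = counts / reads_per_window
        mq = rng.normal(cfg.mq_mean, cfg.mq_sd, size=cn.size)
        for s, e in cfg.low_mq_regions:
            hit = (frame["end"] >= s) & (frame["start"] <= e)
            mq[hit.to_numpy()] = rng.normal(cfg.low_mq_value, cfg.mq_sd, size=int(hit.sum()))
        frame["mq"] = np.clip(mq, 0.0, 60.0)
        tracks.append(frame)
    return tracks[0], tracks[1]
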