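"""Pyrosequencing peak-height simulation.

At the diagnostic copy-specific site the assay dispenses the two alleles'
nucleotides; each allele copy contributes ``signal_per_copy`` units of
peak height, plus Gaussian noise truncated at zero.  A wild-type bird
(two T copies, no duplication) shows a T peak only; a heterozygote carries
two T copies and one C copy (T twice the height of C); a homozygous
carrier has two of each (equal peaks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mbsv.errors import ConfigurationError


@dataclass
class PyroSimConfig:
    signal_per_copy: float = 100.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.signal_per_copy <= 0:
            raise ConfigurationError("signal_per_copy must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


def simulate_pyro_signal(copy_config: dict[str, int], cfg: PyroSimConfig) -> dict[str, float]:
    """Peak heights for a copy configuration like ``{"T": 2, "C": 1}``."""
    if any(c < 0 for c in copy_config.values()):
        raise ConfigurationError("copy counts must be >= 0")
    if sum(copy_config.values()) == 0:
        raise ConfigurationError("at least one allele copy required")
    rng = np.random.default_rng(cfg.seed)
    return {
        nt: float(max(0.0, cfg.signal_per_copy * n + rng.normal(0.0, cfg.noise_sd)))
        if cfg.noise_sd > 0
        else float(cfg.signal_per_copy * n)
        for nt, n in copy_config.items()
    }
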