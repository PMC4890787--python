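"""qPCR Ct-table simulation for the candidate-gene expression panel.

Each (gene, genotype, tissue, stage) cell has a true relative expression
(fold change vs the calibrator cell); target Ct is generated as
``base_ct - log2(rel)`` plus Gaussian noise, the reference gene at a fixed
Ct, six replicates per cell as in the study design.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mbsv.errors import ConfigurationError

REFERENCE_GENE = "GAPDH"
N_REPLICATES = 6


def simulate_ct_table(
    pattern_spec: pd.DataFrame,
    seed: int = 0,
    noise_sd: float = 0.15,
    base_ct: float = 28.0,
    ref_ct: float = 18.0,
    n_replicates: int = N_REPLICATES,
) -> pd.DataFrame:
    """Generate a replicate-level Ct table from a true-expression pattern.

    ``pattern_spec`` columns: gene, genotype, tissue, stage, rel (true fold
    change, > 0).  Output columns: sample, gene, genotype, tissue, stage,
    replicate, ct — including reference-gene rows for every sample.
    """
    if (pattern_spec["rel"] <= 0).any():
        raise ConfigurationError("relative expression must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    samples = pattern_spec[["genotype", "tissue", "stage"]].drop_duplicates()
    for srow in samples.itertuples():
        sample = f"{srow.genotype}|{srow.tissue}|{srow.stage}"
        cells = pattern_spec[
            (pattern_spec["genotype"] == srow.genotype)
            & (pattern_spec["tissue"] == srow.tissue)
            & (pattern_spec["stage"] == srow.stage)
        ]
        for rep in range(n_replicates):
            rows.append(
                {
                    "sample": sample,
                    "gene": REFERENCE_GENE,
                    "genotype": srow.genotype,
                    "tissue": srow.tissue,
                    "stage": srow.stage,
                    "replicate": rep,
                    "ct": ref_ct + (rng.normal(0, noise_sd) if noise_sd else 0.0),
                }
            )
        for crow in cells.itertuples():
            mu = base_ct - float(np.log2(crow.rel))
            for rep in range(n_replicates):
                rows.append(
                    {
                        "sample": sample,
                        "gene": crow.gene,
                        "genotype": srow.genotype,
                        "tissue": srow.tissue,
                        "stage": srow.stage,
                        "replicate": rep,
                        "ct": mu + (rng.normal(0, noise_sd) if noise_sd else 0.0),
                    }
                )
    return pd.DataFrame(rows)
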