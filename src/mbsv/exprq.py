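"""Relative expression by the 2^-ddCt method and candidate-gene triage.

For each sample, dCt = mean Ct(target) - mean Ct(reference gene); ddCt
subtracts the mean dCt of the calibrator group; fold change is 2^-ddCt.
Group comparisons use Welch's t-test on the ddCt scale with the
conventional significance tiers (*** p<0.001, ** p<0.01, * p<0.05).

The candidate classifier encodes what a gene causing a dominant feather
phenotype established during embryogenesis must show: a significant
carrier-vs-wild-type difference in facial skin at every assayed embryonic
stage and in the adult, with essentially no wild-type facial expression
(ectopic activation).  Genes differential only postnatally, only in dorsal
skin, or nowhere, are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mbsv.errors import ConfigurationError, MbsvError

EMBRYONIC_STAGES = ("E7.5", "E8.5", "E9.5", "E10.5")


def delta_delta_ct(
    ct: pd.DataFrame,
    ref_gene: str = "GAPDH",
    calibrator_group: dict | None = None,
) -> pd.DataFrame:
    """Per-sample dCt/ddCt/fold-change table.

    ``ct`` columns: sample, gene, genotype, tissue, stage, replicate, ct.
    ``calibrator_group`` selects the calibrator cells per gene, e.g.
    ``{"genotype": "mb/mb", "tissue": "dorsal", "stage": "adult"}``; by
    default the first (genotype, tissue, stage) cell of each gene in table
    order calibrates that gene.
    """
    if ref_gene not in set(ct["gene"]):
        raise ConfigurationError(f"reference gene {ref_gene!r} absent from the table")
    ref_ct = (
        ct[ct["gene"] == ref_gene].groupby("sample")["ct"].mean().rename("ref_ct")
    )
    tgt = ct[ct["gene"] != ref_gene]
    rows = (
        tgt.groupby(["gene", "sample", "genotype", "tissue", "stage"])["ct"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .join(ref_ct, on="sample")
    )
    if rows["ref_ct"].isna().any():
        raise ConfigurationError("some samples lack reference-gene Ct values")
    rows["dct"] = rows["mean"] - rows["ref_ct"]

    out = []
    for gene, sub in rows.groupby("gene", sort=False):
        if calibrator_group is not None:
            mask = np.ones(len(sub), dtype=bool)
            for k, v in calibrator_group.items():
                mask &= (sub[k] == v).to_numpy()
            cal = sub.loc[mask]
            if cal.empty:
                raise ConfigurationError(f"empty calibrator group for gene {gene!r}")
        else:
            cal = sub.iloc[[0]]
        sub = sub.copy()
        sub["ddct"] = sub["dct"] - cal["dct"].mean()
        sub["fold"] = 2.0 ** (-sub["ddct"])
        out.append(sub)
    rel = pd.concat(out, ignore_index=True)
    return rel.rename(columns={"std": "ct_sd", "count": "n_replicates"})


@dataclass
class GroupComparison:
    p_value: float
    tier: str
    estimate_log2_fold: float


def _tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_groups(
    ct: pd.DataFrame,
    gene: str,
    group_a: dict,
    group_b: dict,
    ref_gene: str = "GAPDH",
) -> GroupComparison:
    """Welch t-test between two cells on the replicate ddCt scale.

    Replicate-level dCt values (target Ct minus the sample's mean reference
    Ct) are compared between the two groups; a plate-wide Ct shift cancels.
    """
    ref_ct = ct[ct["gene"] == ref_gene].groupby("sample")["ct"].mean()

    def dct_values(sel: dict) -> np.ndarray:
        sub = ct[ct["gene"] == gene]
        for k, v in sel.items():
            sub = sub[sub[k] == v]
        if len(sub) < 2:
            raise MbsvError(f"fewer than 2 replicates for {gene} in {sel}")
        return (sub["ct"] - sub["sample"].map(ref_ct)).to_numpy(float)

    a, b = dct_values(group_a), dct_values(group_b)
    if np.allclose(a.var() + b.var(), 0.0):
        p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    # log2 fold change of group_b relative to group_a (= -(dCt_b - dCt_a))
    return GroupComparison(
        p_value=p, tier=_tier(p), estimate_log2_fold=float(a.mean() - b.mean())
    )


@dataclass
class PatternCall:
    gene: str
    mb_consistent: bool
    evidence: pd.DataFrame  # per (tissue, stage): p, tier, wild/carrier fold


def classify_candidate(
    ct: pd.DataFrame,
    gene: str,
    carrier: str = "Mb/Mb",
    wild_type: str = "mb/mb",
    tissue: str = "facial",
    stages: tuple[str, ...] | None = None,
    alpha: float = 0.05,
    silent_floor: float = 0.05,
    ref_gene: str = "GAPDH",
) -> PatternCall:
    """Is the gene's expression pattern consistent with causing the trait?

    Requires (a) a significant carrier-vs-wild difference in facial skin at
    every assayed embryonic stage and in the adult, and (b) wild-type facial
    expression below ``silent_floor`` of the carrier level (ectopic
    activation rather than mere modulation).
    """
    present = set(ct.loc[ct["gene"] == gene, "stage"])
    if stages is None:
        embryonic = [s for s in EMBRYONIC_STAGES if s in present]
        if not embryonic or "adult" not in present:
            raise MbsvError(
                f"{gene}: need >= 1 embryonic stage and adult facial data"
            )
        stages = (*embryonic, "adult")
    rows = []
    consistent = True
    for stage in stages:
        cmp = compare_groups(
            ct,
            gene,
            {"genotype": wild_type, "tissue": tissue, "stage": stage},
            {"genotype": carrier, "tissue": tissue, "stage": stage},
            ref_gene=ref_gene,
        )
        # estimate_log2_fold is carrier-over-wild; invert for the floor test
        wt_over_carrier = 2.0 ** (-cmp.estimate_log2_fold)
        significant = cmp.p_value < alpha
        silent = wt_over_carrier < silent_floor
        rows.append(
            {
                "tissue": tissue,
                "stage": stage,
                "p": cmp.p_value,
                "tier": cmp.tier,
                "wt_over_carrier_fold": wt_over_carrier,
                "significant": significant,
                "wild_type_silent": silent,
            }
        )
        consistent &= significant and silent
    return PatternCall(gene=gene, mb_consistent=consistent, evidence=pd.DataFrame(rows))
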