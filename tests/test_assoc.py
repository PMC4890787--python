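"""Chip QC, kinship, and the mixed-model association scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mbsv.assoc import (
    GenotypeMatrix,
    assoc_scan,
    bonferroni_threshold,
    compute_kinship,
    conditional_scan,
    ld_r2,
    qc_filter,
)
from mbsv.errors import ConfigurationError, ModelError


def _gm(calls, chrom="1", ids=None):
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    ids = ids or [f"I{i}" for i in range(n)]
    markers = pd.DataFrame(
        {"marker": [f"S{j}" for j in range(m)], "chrom": chrom, "bp": np.arange(m) * 1000 + 1}
    )
    return GenotypeMatrix(calls=calls, individuals=ids, markers=markers)


def _ped(ids, trios=()):
    sire = {o: s for o, s, d in trios}
    dam = {o: d for o, s, d in trios}
    return pd.DataFrame(
        {
            "id": ids,
            "sire": [sire.get(i, "0") for i in ids],
            "dam": [dam.get(i, "0") for i in ids],
            "sex": "M",
            "generation": [2 if i in sire else 0 for i in ids],
        }
    )


class TestQC:
    def test_clean_matrix_unchanged(self, rng):
        calls = rng.integers(0, 3, size=(30, 40)).astype(float)
        # force every marker common: balance 0s and 2s
        calls[:15] = 2 - calls[15:]
        gm = _gm(calls)
        out, report = qc_filter(gm, _ped(gm.individuals))
        assert np.array_equal(out.calls, gm.calls)
        assert out.markers.equals(gm.markers)

    def test_low_call_rate_individual_removed(self, rng):
        calls = np.tile([0.0, 1.0, 2.0, 1.0], (20, 25))[:, :100]
        calls[0, :15] = np.nan  # 85% call rate
        gm = _gm(calls)
        out, _ = qc_filter(gm, _ped(gm.individuals))
        assert "I0" not in out.individuals
        assert len(out.individuals) == 19

    def test_mendel_offender_removed(self, rng):
        # offspring I0 is 2 while both parents are 0 at 6% of SNPs
        m = 100
        base = np.tile([0.0, 1.0, 2.0, 1.0], (12, 25))
        calls = base.copy()
        calls[1] = 0.0  # sire
        calls[2] = 0.0  # dam
        calls[0] = 0.0
        calls[0, :6] = 2.0  # 6 impossible calls out of 100
        # keep markers polymorphic
        gm = _gm(calls)
        ped = _ped(gm.individuals, trios=[("I0", "I1", "I2")])
        out, report = qc_filter(gm, ped)
        assert "I0" not in out.individuals

    def test_mendel_minor_offense_blanked(self):
        # 25 offspring of one 0x0 pair, one with two impossible calls (2%
        # per-individual, 4% per-SNP: both under the 5% removal bar), plus
        # unrelated allele carriers keeping the markers common
        n_off, m = 25, 100
        calls = np.zeros((n_off + 2 + 10, m))
        calls[0, :2] = 2.0
        calls[n_off + 2 :] = 2.0  # unrelated carriers
        gm = _gm(calls)
        trios = [(f"I{i}", f"I{n_off}", f"I{n_off + 1}") for i in range(n_off)]
        out, _ = qc_filter(gm, _ped(gm.individuals, trios=trios))
        assert "I0" in out.individuals
        assert "S0" in set(out.markers["marker"])
        row = out.calls[out.individuals.index("I0")]
        assert np.isnan(row[:2]).all()
        assert not np.isnan(row[2:]).any()

    def test_w_linked_markers_dropped_and_z_hets_blanked(self):
        calls = np.tile([0.0, 1.0, 2.0, 1.0], (8, 3))[:, :10]
        markers = pd.DataFrame(
            {
                "marker": [f"S{j}" for j in range(10)],
                "chrom": ["1"] * 7 + ["W", "Z", "Z"],
                "bp": np.arange(10) * 1000 + 1,
            }
        )
        gm = GenotypeMatrix(calls=calls, individuals=[f"I{i}" for i in range(8)], markers=markers)
        ped = _ped(gm.individuals)
        ped.loc[ped["id"] == "I1", "sex"] = "F"
        out, _ = qc_filter(gm, ped)
        assert "W" not in set(out.markers["chrom"])
        z_cols = out.markers.index[out.markers["chrom"] == "Z"]
        female_row = out.calls[out.individuals.index("I1")]
        hets = [c for c in z_cols if female_row[c] == 1.0]
        assert not hets

    def test_qc_idempotent(self, rng):
        calls = rng.integers(0, 3, size=(40, 60)).astype(float)
        calls[rng.random(calls.shape) < 0.05] = np.nan
        gm = _gm(calls)
        ped = _ped(gm.individuals)
        once, _ = qc_filter(gm, ped)
        twice, _ = qc_filter(once, ped)
        assert np.array_equal(once.calls, twice.calls, equal_nan=True)
        assert once.markers.equals(twice.markers)


class TestKinship:
    def test_duplicate_individuals_entry_equals_diagonal(self, rng):
        calls = rng.integers(0, 3, size=(10, 200)).astype(float)
        calls[1] = calls[0]
        kin = compute_kinship(_gm(calls))
        assert kin.iloc[0, 1] == pytest.approx(kin.iloc[0, 0])

    def test_two_line_structure(self):
        # two inbred lines fixed for alternative alleles at half the markers
        line_a = np.tile([2.0, 0.0], (5, 50))
        line_b = np.tile([0.0, 2.0], (5, 50))
        kin = compute_kinship(_gm(np.vstack([line_a, line_b])))
        within = kin.iloc[0, 1]
        between = kin.iloc[0, 5]
        assert between < within

    def test_independent_genotypes_off_diagonal_near_zero(self, rng):
        # sample-centering biases entries by about -1/(n-1); at n=100 and
        # m=4000 unlinked markers the off-diagonals should sit near zero
        calls = rng.binomial(2, 0.5, size=(100, 4000)).astype(float)
        kin = compute_kinship(_gm(calls))
        off = kin.to_numpy()[~np.eye(100, dtype=bool)]
        assert np.abs(off).mean() < 0.05
        assert abs(off.mean()) < 0.02

    def test_monomorphic_only_rejected(self):
        with pytest.raises(ModelError):
            compute_kinship(_gm(np.full((5, 10), 2.0)))


def _null_dataset(rng, n=200, m=500):
    calls = rng.binomial(2, 0.5, size=(n, m)).astype(float)
    gm = _gm(calls)
    ph = pd.DataFrame(
        {
            "id": gm.individuals,
            "mb_week10": rng.integers(0, 2, n),
            "mb_at_birth": rng.integers(0, 2, n),
        }
    )
    return gm, ph


class TestScan:
    def test_null_pvalues_uniform(self, rng):
        gm, ph = _null_dataset(rng, n=300, m=1000)
        kin = compute_kinship(gm)
        res = assoc_scan(gm, ph, kin)
        ks = stats.kstest(res.table["p"].dropna(), "uniform")
        assert ks.pvalue > 0.01

    def test_identity_kinship_reduces_to_plain_score_test(self, rng):
        gm, ph = _null_dataset(rng, n=120, m=50)
        kin = pd.DataFrame(np.eye(120), index=gm.individuals, columns=gm.individuals)
        res = assoc_scan(gm, ph, kin)
        # closed-form plain score test on covariate-adjusted residuals
        y = ph["mb_week10"].to_numpy(float)
        X = np.column_stack([np.ones(120), ph["mb_at_birth"].to_numpy(float)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        g = gm.calls[:, 0] - gm.calls[:, 0].mean()
        rv = r - r.mean()
        stat = (g @ rv) ** 2 / ((g @ g) * (rv @ rv / 120))
        assert res.table["stat"].iloc[0] == pytest.approx(stat, rel=1e-6)

    def test_conditioning_on_causal_kills_peak(self, small_cross):
        res = small_cross
        mask = np.array([i.startswith("F2") for i in res.genotypes.individuals])
        gm = res.genotypes.subset(ind_mask=mask)
        kin = pd.DataFrame(
            np.eye(gm.n_individuals), index=gm.individuals, columns=gm.individuals
        )
        scan = assoc_scan(gm, res.phenotypes, kin)
        cond = conditional_scan(gm, res.phenotypes, kin, scan.peak_marker)
        thr = bonferroni_threshold(gm.n_markers)
        assert scan.table["p"].min() < thr
        assert np.isnan(cond.table.set_index("marker").loc[scan.peak_marker, "p"])
        assert np.nanmin(cond.table["p"]) > thr

    def test_conditioning_on_null_marker_keeps_peak(self, small_cross, rng):
        res = small_cross
        mask = np.array([i.startswith("F2") for i in res.genotypes.individuals])
        gm = res.genotypes.subset(ind_mask=mask)
        # append an independent null marker to condition on
        null = rng.binomial(2, 0.5, size=(gm.n_individuals, 1)).astype(float)
        markers = pd.concat(
            [gm.markers, pd.DataFrame({"marker": ["NULL"], "chrom": ["bg"], "bp": [1]})],
            ignore_index=True,
        )
        gm2 = GenotypeMatrix(
            calls=np.hstack([gm.calls, null]), individuals=gm.individuals, markers=markers
        )
        kin = pd.DataFrame(
            np.eye(gm2.n_individuals), index=gm2.individuals, columns=gm2.individuals
        )
        base = assoc_scan(gm2, res.phenotypes, kin)
        cond = conditional_scan(gm2, res.phenotypes, kin, "NULL")
        p0 = base.table.set_index("marker").loc[base.peak_marker, "p"]
        p1 = cond.table.set_index("marker").loc[base.peak_marker, "p"]
        assert abs(np.log10(p1) - np.log10(p0)) < 1.0


class TestThresholdAndLD:
    @pytest.mark.parametrize(
        "n, alpha, expected",
        [(1, 0.05, 0.05), (10, 0.10, 0.01), (43_493, 0.05, 0.05 / 43_493)],
    )
    def test_bonferroni(self, n, alpha, expected):
        assert bonferroni_threshold(n, alpha) == pytest.approx(expected)

    def test_bonferroni_rejects_zero_tests(self):
        with pytest.raises(ConfigurationError):
            bonferroni_threshold(0)

    def test_ld_with_self_is_one(self, rng):
        gm = _gm(rng.binomial(2, 0.5, size=(50, 3)).astype(float))
        assert ld_r2(gm, "S0", "S0") == pytest.approx(1.0)

    def test_ld_independent_markers_near_zero(self, rng):
        gm = _gm(rng.binomial(2, 0.5, size=(5000, 2)).astype(float))
        assert ld_r2(gm, "S0", "S1") < 0.01

    def test_ld_matches_hand_computed_haplotype_table(self):
        # haplotype counts: AB x 40, ab x 40, Ab x 10, aB x 10 -> D = .16-.01,
        # r^2 = D^2/(pA pa pB pb) = 0.36 on genotypes built from paired haps
        hapA = np.array([1] * 40 + [0] * 40 + [1] * 10 + [0] * 10)
        hapB = np.array([1] * 40 + [0] * 40 + [0] * 10 + [1] * 10)
        rng = np.random.default_rng(0)
        i1 = rng.permutation(100)
        i2 = rng.permutation(100)
        g1 = hapA[i1] + hapA[i2]
        g2 = hapB[i1] + hapB[i2]
        gm = _gm(np.column_stack([g1, g2]).astype(float))
        expected = np.corrcoef(g1, g2)[0, 1] ** 2  # brute-force from counts
        assert ld_r2(gm, "S0", "S1") == pytest.approx(expected)
        assert ld_r2(gm, "S1", "S0") == pytest.approx(expected)
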