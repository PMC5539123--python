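"""Single-marker association: MAF filter, structure axes, OLS scan,
Bonferroni threshold, Manhattan export."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from sicomp.errors import ValidationError
from sicomp.gwas import (
    GenotypeTable,
    bonferroni_threshold,
    maf_filter,
    manhattan_export,
    single_marker_scan,
    structure_covariates,
)


def table_from_dosages(D, lgs=None, cms=None, geno_ids=None):
    D = np.asarray(D, dtype=float)
    n_mark, n_geno = D.shape
    markers = [f"m{i}" for i in range(n_mark)]
    geno_ids = geno_ids or [f"g{j}" for j in range(n_geno)]
    mmap = pd.DataFrame(
        {
            "linkage_group": lgs if lgs is not None else ["1"] * n_mark,
            "position_cM": cms if cms is not None else np.arange(n_mark, dtype=float),
        },
        index=markers,
    )
    return GenotypeTable(
        dosages=pd.DataFrame(D, index=markers, columns=geno_ids),
        marker_map=mmap,
    )


class TestMafFilter:
    def test_counts_with_constructed_thresholded_table(self):
        rng = np.random.default_rng(1)
        n = 40
        low, high = [], []
        while len(low) < 200:
            # MAF below 0.05 at n=40: at most 3 minor alleles of 80
            k = rng.integers(0, 4)
            row = np.zeros(n)
            row[rng.choice(n, k, replace=False)] = 1
            m = min(row.sum(), 2 * n - row.sum()) / (2 * n)
            if m < 0.05:
                low.append(row)
        while len(high) < 2261:
            row = rng.integers(0, 3, size=n).astype(float)
            m = min(row.sum(), 2 * n - row.sum()) / (2 * n)
            if m >= 0.05:
                high.append(row)
        D = np.vstack(low + high)
        perm = rng.permutation(len(D))
        kept, report = maf_filter(table_from_dosages(D[perm]), threshold=0.05)
        assert len(kept.markers) == 2261
        assert (report["reason"] == "maf<0.05").sum() == 200

    def test_maf_half_not_filtered(self):
        D = np.tile([0, 2, 1, 1], (5, 1))
        kept, report = maf_filter(table_from_dosages(D))
        assert len(kept.markers) == 5
        assert (report["reason"] == "retained").all()

    def test_all_missing_marker_reported_no_data(self):
        D = np.array([[np.nan, np.nan, np.nan], [0, 1, 2]])
        kept, report = maf_filter(table_from_dosages(D))
        assert report.loc["m0", "reason"] == "no data"
        assert list(kept.markers) == ["m1"]

    def test_matches_brute_force_allele_counting(self):
        rng = np.random.default_rng(2)
        D = rng.integers(0, 3, size=(60, 30)).astype(float)
        D[rng.random(D.shape) < 0.1] = np.nan
        gt = table_from_dosages(D)
        kept, _ = maf_filter(gt, threshold=0.1)
        expected = []
        for i, row in enumerate(D):
            obs = row[~np.isnan(row)]
            p = obs.sum() / (2 * len(obs))
            if min(p, 1 - p) >= 0.1:
                expected.append(f"m{i}")
        assert list(kept.markers) == expected


class TestStructureCovariates:
    def test_two_subpopulations_separate_on_first_axis(self):
        rng = np.random.default_rng(3)
        n_mark, half = 100, 10
        pa = rng.uniform(0.05, 0.35, n_mark)
        pb = rng.uniform(0.65, 0.95, n_mark)
        D = np.empty((n_mark, 2 * half))
        for j in range(half):
            D[:, j] = rng.binomial(2, pa)
            D[:, half + j] = rng.binomial(2, pb)
        covs = structure_covariates(table_from_dosages(D), n_axes=2)
        axis1 = covs.iloc[:, 0].to_numpy()
        assert (axis1[:half].max() < axis1[half:].min()) or (
            axis1[:half].min() > axis1[half:].max()
        )

    def test_zero_axes_empty_frame(self):
        covs = structure_covariates(table_from_dosages(np.zeros((4, 6))), n_axes=0)
        assert covs.shape == (6, 0)

    def test_columns_centred(self):
        rng = np.random.default_rng(4)
        covs = structure_covariates(
            table_from_dosages(rng.integers(0, 3, (50, 12))), n_axes=3
        )
        np.testing.assert_allclose(covs.to_numpy().sum(axis=0), 0, atol=1e-9)

    def test_too_many_axes_rejected(self):
        with pytest.raises(ValidationError):
            structure_covariates(table_from_dosages(np.zeros((4, 3))), n_axes=3)


class TestSingleMarkerScan:
    def test_matches_statsmodels_ols(self):
        rng = np.random.default_rng(5)
        n, n_mark = 12, 30
        D = rng.integers(0, 3, size=(n_mark, n)).astype(float)
        gt = table_from_dosages(D)
        covs = pd.DataFrame(
            rng.normal(size=(n, 2)), index=gt.genotype_ids, columns=["c1", "c2"]
        )
        pheno = pd.Series(rng.normal(size=n), index=gt.genotype_ids)
        res = single_marker_scan(pheno, gt, covariates=covs)
        for k, marker in enumerate(gt.markers):
            x = D[k]
            if np.ptp(x) == 0:
                continue
            X = sm.add_constant(
                np.column_stack([x, covs.to_numpy()])
            )
            fit = sm.OLS(pheno.to_numpy(), X).fit()
            assert res.table.loc[marker, "p"] == pytest.approx(
                fit.pvalues[1], rel=1e-8
            )
            assert res.table.loc[marker, "beta"] == pytest.approx(
                fit.params[1], rel=1e-8
            )

    def test_constant_marker_skipped_with_reason(self):
        rng = np.random.default_rng(6)
        D = np.vstack([np.full(12, 2.0), rng.integers(0, 3, 12)])
        gt = table_from_dosages(D)
        pheno = pd.Series(rng.normal(size=12), index=gt.genotype_ids)
        res = single_marker_scan(pheno, gt)
        assert res.table.loc["m0", "reason"] == "collinear with covariates"
        assert res.m_tested == 1

    def test_perfect_fit_capped(self):
        D = np.array([[0, 0, 0, 1, 1, 1, 2, 2, 2, 0, 1, 2]], dtype=float)
        gt = table_from_dosages(D)
        pheno = pd.Series(D[0] * 2.0, index=gt.genotype_ids)
        res = single_marker_scan(pheno, gt)
        assert res.table.loc["m0", "neg_log10_p"] == 15.0
        assert res.table.loc["m0", "reason"] == "perfect fit (p capped)"

    def test_mean_and_complete_case_agree_without_missing(self):
        rng = np.random.default_rng(7)
        D = rng.integers(0, 3, size=(20, 15)).astype(float)
        gt = table_from_dosages(D)
        pheno = pd.Series(rng.normal(size=15), index=gt.genotype_ids)
        r1 = single_marker_scan(pheno, gt, impute="mean")
        r2 = single_marker_scan(pheno, gt, impute="complete")
        np.testing.assert_allclose(
            r1.table["p"].to_numpy(), r2.table["p"].to_numpy(), rtol=1e-9
        )

    def test_small_phenotype_rejected(self):
        gt = table_from_dosages(np.zeros((3, 12)))
        pheno = pd.Series(np.nan, index=gt.genotype_ids)
        pheno.iloc[:5] = 1.0
        with pytest.raises(ValidationError):
            single_marker_scan(pheno, gt)


class TestBonferroni:
    def test_known_values(self):
        assert bonferroni_threshold(0.05, 1) == pytest.approx(1.301, abs=1e-3)
        assert bonferroni_threshold(0.05, 2261) == pytest.approx(4.655, abs=1e-3)

    def test_monotone_in_m(self):
        ts = [bonferroni_threshold(0.05, m) for m in (10, 100, 1000, 10000)]
        assert all(a < b for a, b in zip(ts, ts[1:]))

    def test_invalid_alpha(self):
        with pytest.raises(ValidationError):
            bonferroni_threshold(1.5, 10)


class TestManhattanExport:
    def _scan(self):
        rng = np.random.default_rng(8)
        n_mark = 40
        D = rng.integers(0, 3, size=(n_mark, 20)).astype(float)
        lgs = ["2"] * 10 + ["1"] * 10 + ["U"] * 5 + ["3"] * 15
        cms = rng.uniform(0, 100, 40)
        cms[20:25] = np.nan  # unmapped markers carry no position
        gt = table_from_dosages(D, lgs=lgs, cms=cms)
        pheno = pd.Series(rng.normal(size=20), index=gt.genotype_ids)
        return single_marker_scan(pheno, gt), gt

    def test_ordering_matches_sort_oracle(self):
        res, gt = self._scan()
        out = manhattan_export(res, gt.marker_map)
        tested = res.table[res.table["reason"] != "collinear with covariates"]
        assert len(out) == len(tested)
        lg_order = [
            np.inf if l == "U" else float(l) for l in out["linkage_group"]
        ]
        assert lg_order == sorted(lg_order)
        for lg in set(out["linkage_group"]) - {"U"}:
            cm = out.loc[out["linkage_group"] == lg, "position_cM"].to_numpy()
            assert np.all(np.diff(cm) >= 0)
        # unmapped markers trail
        labels = list(out["linkage_group"])
        if "U" in labels:
            assert labels[-labels[::-1].index("U"):].count("U") == labels.count("U")

    def test_above_threshold_flag_consistent(self):
        res, gt = self._scan()
        out = manhattan_export(res, gt.marker_map)
        thr = res.threshold
        np.testing.assert_array_equal(
            out["above_threshold"].to_numpy(), out["neg_log10_p"].to_numpy() >= thr
        )
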