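"""Cohort statistics: Spearman, FDR, partial correlation, split-plot ANOVA, battery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

import cortrad as ct
from cortrad.stats import battery_frame


def _brute_spearman(x, y):
    """Independent oracle: explicit average ranks + product-moment formula."""
    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v)
        r = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


class TestSpearman:
    def test_perfect_monotone(self):
        r, p, n = ct.spearman([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert (r, p, n) == (1.0, 0.0, 5)
        r, p, _ = ct.spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert (r, p) == (-1.0, 0.0)

    def test_matches_rank_formula_and_t_approximation_oracles(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 4, size=6).astype(float)  # ties likely
            y = rng.normal(size=6)
            if np.ptp(x) == 0:
                continue
            r, p, n = ct.spearman(x, y)
            assert r == pytest.approx(_brute_spearman(x, y), abs=1e-12)
            if abs(r) < 1:
                t = r * np.sqrt((n - 2) / (1 - r * r))
                assert p == pytest.approx(2 * sps.t.sf(abs(t), n - 2), abs=1e-6)
            r2, p2 = sps.spearmanr(x, y)
            assert r == pytest.approx(r2, abs=1e-12)
            assert p == pytest.approx(p2, abs=1e-10)

    def test_invariant_under_strictly_monotone_transforms(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        r0, _, _ = ct.spearman(x, y)
        for fx, fy in [(np.exp, np.tanh), (lambda v: v**3, np.exp)]:
            r, _, _ = ct.spearman(fx(x), fy(y))
            assert r == pytest.approx(r0, abs=1e-12)

    def test_missing_values_deleted_pairwise(self):
        x = [1, 2, np.nan, 4, 5, 6]
        y = [2, 4, 6, np.nan, 10, 12]
        r, p, n = ct.spearman(x, y)
        assert n == 4 and r == 1.0

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ct.spearman([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="4"):
            ct.spearman([1, 2, 3], [3, 2, 1])


def _brute_fdr(pvals):
    """Direct enumeration oracle for the step-up adjustment."""
    n = len(pvals)
    out = []
    for i, p in enumerate(pvals):
        rank = sum(q < p for q in pvals) + sum(
            1 for j, q in enumerate(pvals) if q == p and j <= i
        )
        # adjusted = min over all entries with rank >= this entry's best rank
        candidates = []
        for q in pvals:
            if q >= p:
                rq = sum(v <= q for v in pvals)
                candidates.append(min(1.0, n * q / rq))
        out.append(min(candidates))
    return out


class TestFdrAdjust:
    def test_single_value_unchanged(self):
        assert ct.fdr_adjust([0.2])[0] == 0.2

    def test_four_values_match_enumeration_oracle(self):
        p = [0.01, 0.02, 0.03, 0.04]
        assert np.allclose(ct.fdr_adjust(p), _brute_fdr(p))
        # spot value: 4 * 0.04 / 4 = 0.04 -> all collapse to 0.04 by cummin
        assert np.allclose(ct.fdr_adjust(p), [0.04, 0.04, 0.04, 0.04])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_properties_and_statsmodels_agreement(self, pvals):
        import statsmodels.stats.multitest as smm

        adj = ct.fdr_adjust(pvals)
        p = np.asarray(pvals)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()
        # ranking preserved
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()
        ref = smm.multipletests(p, method="fdr_bh")[1]
        assert np.allclose(adj, ref, atol=1e-12)

    def test_tied_pvalues_share_adjusted_value(self):
        adj = ct.fdr_adjust([0.01, 0.01, 0.5])
        assert adj[0] == adj[1]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ct.fdr_adjust([0.1, 1.5])


class TestPartialCorrelation:
    def test_uncorrelated_control_leaves_r_unchanged(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = 0.6 * x + rng.normal(size=30)
        z0 = rng.normal(size=30)
        # orthogonalize z against x and y in-sample (r_xz = r_yz = 0)
        A = np.column_stack([np.ones(30), x, y])
        z = z0 - A @ np.linalg.lstsq(A, z0, rcond=None)[0]
        r_xy = np.corrcoef(x, y)[0, 1]
        r, p, n = ct.partial_correlation(x, y, z)
        assert r == pytest.approx(r_xy, abs=1e-12)

    def test_matches_residualization_oracle(self):
        rng = np.random.default_rng(3)
        x, y, z = rng.normal(size=(3, 20))
        r, _, _ = ct.partial_correlation(x, y, z)
        A = np.column_stack([np.ones(20), z])
        rx = x - A @ np.linalg.lstsq(A, x, rcond=None)[0]
        ry = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
        assert r == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-10)

    def test_control_identical_to_y_rejected(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=(2, 10))
        with pytest.raises(ValueError, match="degenerate|collinear"):
            ct.partial_correlation(x, y, y)

    def test_spearman_variant_rank_transforms_first(self):
        rng = np.random.default_rng(5)
        x, y, z = rng.normal(size=(3, 15))
        r1, _, _ = ct.partial_correlation(x, y, z, method="spearman")
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        rz = sps.rankdata(z)
        r2, _, _ = ct.partial_correlation(rx, ry, rz, method="pearson")
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestPairedT:
    def test_matches_textbook_formula_and_scipy(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=(2, 10))
        t, df, p = ct.paired_t(x, y)
        d = y - x
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(10))
        assert t == pytest.approx(t_ref, abs=1e-12)
        assert df == 9
        res = sps.ttest_rel(y, x)
        assert t == pytest.approx(res.statistic, abs=1e-12)
        assert p == pytest.approx(res.pvalue, abs=1e-12)

    def test_zero_variance_differences_rejected(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.raises(ValueError, match="zero-variance"):
            ct.paired_t(x, x + 2.0)  # constant shift
        with pytest.raises(ValueError, match="zero-variance"):
            ct.paired_t(x, x)


def _null_rm_table(rng, n_per_group=(9, 6), regions=("R1", "R2", "R3")):
    rows = []
    for g, n in zip(("case", "control"), n_per_group):
        for s in range(n):
            for reg in regions:
                rows.append({"subject": f"{g}{s}", "group": g,
                             "region": reg, "value": rng.normal()})
    return pd.DataFrame(rows)


class TestMixedRmAnova:
    def test_design_dfs_for_nine_plus_six_subjects_three_regions(self):
        rng = np.random.default_rng(7)
        res = ct.mixed_rm_anova(_null_rm_table(rng), dependent="any")
        by = {a.effect: a for a in res}
        assert (by["group"].df1, by["group"].df2) == (1, 13)
        assert (by["region"].df1, by["region"].df2) == (2, 26)
        assert (by["group x region"].df1, by["group x region"].df2) == (2, 26)

    def test_matches_pingouin_split_plot(self):
        import pingouin as pg

        rng = np.random.default_rng(8)
        df = _null_rm_table(rng)
        df["value"] += (df.group == "case") * 1.0  # add a group effect
        ours = {a.effect: a for a in ct.mixed_rm_anova(df, dependent="any")}
        ref = pg.mixed_anova(data=df, dv="value", within="region",
                             subject="subject", between="group")
        ref = ref.set_index("Source")
        assert ours["group"].F == pytest.approx(ref.loc["group", "F"], rel=1e-10)
        assert ours["region"].F == pytest.approx(ref.loc["region", "F"], rel=1e-10)
        assert ours["group x region"].F == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-10)

    def test_all_equal_observations_rejected(self):
        df = _null_rm_table(np.random.default_rng(9))
        df["value"] = 1.0
        with pytest.raises(ValueError, match="zero error variance"):
            ct.mixed_rm_anova(df, dependent="any")

    def test_missing_cell_rejected_naming_subject(self):
        df = _null_rm_table(np.random.default_rng(10))
        df = df[~((df.subject == "case0") & (df.region == "R3"))]
        with pytest.raises(ValueError, match="case0"):
            ct.mixed_rm_anova(df, dependent="any")

    def test_null_type_one_error_calibrated(self):
        # exact F test under normality: 5000-draw check at a loose band
        rng = np.random.default_rng(11)
        rej = sum(
            {a.effect: a.p for a in
             ct.mixed_rm_anova(_null_rm_table(rng), dependent="any")}["group"] < 0.05
            for _ in range(500)
        )
        assert 0.02 <= rej / 500 <= 0.08


def _synthetic_battery_cohort(rng, n=9, planted=None):
    """Tidy cohort with 5 metrics + 6 histology measures over 3 regions."""
    rows = []
    metrics = ct.stats.DIFFUSION_METRICS
    hists = ct.stats.BATTERY_HISTOLOGY
    for region in ("BA9", "BA41", "V1"):
        base = rng.normal(size=n)
        for s in range(n):
            for m in metrics:
                val = rng.normal()
                if planted and (region, m) == planted[:2]:
                    val = base[s]
                rows.append({"subject": f"S{s}", "region": region,
                             "measure": m, "value": val})
            for h in hists:
                val = rng.normal()
                if planted and (region, h) == (planted[0], planted[2]):
                    val = base[s]  # identical -> perfect association
                rows.append({"subject": f"S{s}", "region": region,
                             "measure": h, "value": val})
    return pd.DataFrame(rows)


class TestCorrelationBattery:
    def test_exactly_ninety_tests_enter_joint_adjustment(self):
        rng = np.random.default_rng(12)
        results = ct.correlation_battery(_synthetic_battery_cohort(rng))
        assert len(results) == 90
        frame = battery_frame(results)
        assert not frame.duplicated(["region", "metric", "histology"]).any()
        assert (frame["p_fdr"] >= frame["p"] - 1e-15).all()

    def test_planted_perfect_association_attains_smallest_adjusted_p(self):
        rng = np.random.default_rng(13)
        planted = ("BA9", "AngleR", "minicolumn_width")
        results = ct.correlation_battery(
            _synthetic_battery_cohort(rng, planted=planted))
        best = min(results, key=lambda c: (c.p_fdr, c.p))
        assert (best.region, best.metric, best.histology) == planted
        assert best.r == 1.0

    def test_missing_measure_rejected_by_name(self):
        rng = np.random.default_rng(14)
        df = _synthetic_battery_cohort(rng)
        df = df[df.measure != "bundle_width"]
        with pytest.raises(ValueError, match="bundle_width"):
            ct.correlation_battery(df)

    def test_deterministic_ordering(self):
        rng = np.random.default_rng(15)
        df = _synthetic_battery_cohort(rng)
        r1 = ct.correlation_battery(df)
        r2 = ct.correlation_battery(df.sample(frac=1.0, random_state=0))
        assert [(c.region, c.metric, c.histology) for c in r1] == \
            [(c.region, c.metric, c.histology) for c in r2]
        assert all(a.r == pytest.approx(b.r, abs=1e-12) for a, b in zip(r1, r2))

    def test_false_discovery_controlled_on_null_cohorts(self):
        # Global null over 200 simulated cohorts: the fraction of adjusted
        # p-values below 0.05 stays within the nominal level plus a
        # Monte-Carlo margin.  (The battery's 90 tests reuse the same metric
        # and histology vectors, so the *family-wise* exceedance is not
        # bounded by alpha under step-up adjustment — the dependence
        # scenario the conservative Benjamini-Yekutieli variant addresses.)
        n_sim = 200
        n_rejected = 0
        n_total = 0
        for k in range(n_sim):
            rng = np.random.default_rng(1000 + k)
            results = ct.correlation_battery(_synthetic_battery_cohort(rng))
            n_rejected += sum(c.p_fdr < 0.05 for c in results)
            n_total += len(results)
        margin = 2 * np.sqrt(0.05 * 0.95 / n_sim)
        assert n_rejected / n_total <= 0.05 + margin


class TestPublishedTable:
    def test_reference_table_shape_and_keys(self):
        tab = ct.published_correlation_table()
        assert len(tab) == 90
        assert set(tab.region) == {"BA9", "BA41", "V1"}
        assert set(tab.metric) == set(ct.stats.DIFFUSION_METRICS)
        assert set(tab.histology) == set(ct.stats.BATTERY_HISTOLOGY)
        assert tab.p.between(0, 1).all()
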