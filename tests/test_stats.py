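"""Differential-abundance statistics: filtering, normalization, imputation,
moderated t, permutation FDR, sanity check, iBAQ ranking."""

import itertools
import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sinode import stats
from sinode.stats import ImputationParams

from conftest import make_matrix


class TestCollapseIsoforms:
    def test_most_abundant_isoform_wins(self):
        m = make_matrix(
            [[5.0] * 6, [6.0] * 6],
            isoform_group=pd.Series(["g", "g"], index=pd.Index(["P0", "P1"], name="protein")),
        )
        out = stats.collapse_isoforms(m)
        assert list(out.protein_ids) == ["P1"]

    def test_no_shared_groups_only_drops_flagged(self):
        ids = pd.Index(["P0", "P1", "P2"], name="protein")
        m = make_matrix(
            np.full((3, 6), 20.0),
            reverse_flag=pd.Series([False, True, False], index=ids),
            contaminant_flag=pd.Series([False, False, True], index=ids),
        )
        out = stats.collapse_isoforms(m)
        assert list(out.protein_ids) == ["P0"]
        assert out.values.loc["P0"].equals(m.values.loc["P0"])

    def test_matches_brute_force_group_max(self):
        rng = np.random.default_rng(0)
        n = 40
        vals = rng.normal(20, 3, size=(n, 6))
        vals[rng.random(size=vals.shape) < 0.2] = np.nan
        groups = rng.integers(0, 12, size=n)
        ids = pd.Index([f"P{i}" for i in range(n)], name="protein")
        m = make_matrix(vals, isoform_group=pd.Series([f"g{g}" for g in groups], index=ids))
        out = stats.collapse_isoforms(m)
        # oracle: per group, row with max nan-sum
        expected = set()
        sums = np.nansum(np.nan_to_num(vals), axis=1)
        for g in np.unique(groups):
            rows = np.flatnonzero(groups == g)
            expected.add(f"P{rows[np.argmax(sums[rows])]}")
        assert set(out.protein_ids) == expected


class TestFilterProteins:
    def test_three_valid_in_one_group_retained(self):
        vals = np.full((1, 6), np.nan)
        vals[0, :3] = 20.0  # 3 valid SN, 0 valid RA
        m = make_matrix(vals)
        assert list(stats.filter_proteins(m).protein_ids) == ["P0"]

    def test_two_and_two_removed(self):
        vals = np.full((1, 6), np.nan)
        vals[0, [0, 1, 3, 4]] = 20.0
        m = make_matrix(vals)
        assert stats.filter_proteins(m).n_proteins == 0

    def test_min_peptides_enforced(self):
        ids = pd.Index(["P0", "P1"], name="protein")
        m = make_matrix(
            np.full((2, 6), 20.0), peptide_counts=pd.Series([1, 2], index=ids)
        )
        assert list(stats.filter_proteins(m).protein_ids) == ["P1"]

    def test_matches_direct_rule_on_random_patterns(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(20, 1, size=(1000, 6))
        vals[rng.random(size=vals.shape) < 0.5] = np.nan
        m = make_matrix(vals)
        kept = set(stats.filter_proteins(m).protein_ids)
        present = ~np.isnan(vals)
        oracle = {
            f"P{i}"
            for i in range(1000)
            if present[i, :3].sum() >= 3 or present[i, 3:].sum() >= 3
        }
        assert kept == oracle

    def test_too_few_samples_is_config_error(self):
        m = make_matrix(np.full((2, 4), 20.0), groups=("SN", "SN", "RA", "RA"))
        with pytest.raises(ValueError):
            stats.filter_proteins(m)


class TestQuantileNormalize:
    def test_identical_samples_unchanged(self):
        vals = np.tile(np.array([[18.0], [20.0], [22.0]]), (1, 6))
        m = make_matrix(vals)
        out = stats.quantile_normalize(m)
        assert np.allclose(out.values.to_numpy(), vals)

    def test_hand_computed_order_statistic_means(self):
        m = make_matrix(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]), groups=("SN", "RA"))
        out = stats.quantile_normalize(m).values.to_numpy()
        assert np.allclose(out[:, 0], [2.5, 3.5, 4.5])
        assert np.allclose(out[:, 1], [2.5, 3.5, 4.5])

    def test_complete_samples_share_sorted_vector_and_median(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.normal(20, 2, size=(50, 6)))
        out = stats.quantile_normalize(m).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 6):
            assert np.allclose(np.sort(out[:, j]), ref)
        assert np.allclose(np.median(out, axis=0), np.median(ref))

    def test_missing_entries_stay_missing(self):
        vals = np.array([[20.0, 21.0], [np.nan, 19.0], [22.0, np.nan]])
        m = make_matrix(vals, groups=("SN", "RA"))
        out = stats.quantile_normalize(m)
        assert out.missing_mask().to_numpy().tolist() == np.isnan(vals).tolist()

    def test_all_missing_sample_names_the_sample(self):
        vals = np.array([[20.0, np.nan], [21.0, np.nan]])
        m = make_matrix(vals, groups=("SN", "RA"))
        with pytest.raises(ValueError, match="RA1"):
            stats.quantile_normalize(m)

    def test_agrees_with_limma_normalizeQuantiles(self, tmp_path):
        # independent oracle: Bioconductor limma through Rscript
        rng = np.random.default_rng(3)
        vals = rng.normal(20, 2, size=(20, 4)).round(4)
        np.savetxt(tmp_path / "x.tsv", vals, delimiter="\t")
        r = textwrap.dedent(
            """
            suppressMessages(library(limma))
            x <- as.matrix(read.table(%r, sep="\t"))
            write.table(normalizeQuantiles(x), %r, sep="\t",
                        row.names=FALSE, col.names=FALSE)
            """
            % (str(tmp_path / "x.tsv"), str(tmp_path / "y.tsv"))
        )
        subprocess.run(["Rscript", "-e", r], check=True, capture_output=True)
        expected = np.loadtxt(tmp_path / "y.tsv", delimiter="\t")
        m = make_matrix(vals, groups=("SN", "SN", "RA", "RA"))
        out = stats.quantile_normalize(m).values.to_numpy()
        assert np.allclose(out, expected, atol=1e-8)


class TestDownshiftImputation:
    def test_no_missing_values_is_identity(self):
        rng = np.random.default_rng(4)
        m = make_matrix(rng.normal(20, 1, size=(30, 6)))
        out, mask = stats.impute_downshift(m)
        assert out.values.equals(m.values)
        assert not mask.to_numpy().any()

    def test_imputed_distribution_matches_downshifted_normal(self):
        # sample with mu=20, sigma=1: imputed ~ Normal(18.2, 0.3^2)
        rng = np.random.default_rng(5)
        n = 20_000
        vals = np.column_stack([rng.normal(20.0, 1.0, n), rng.normal(20.0, 1.0, n)])
        vals[:10_000, 0] = np.nan
        m = make_matrix(vals, groups=("SN", "RA"))
        out, mask = stats.impute_downshift(m, ImputationParams(seed=9))
        imputed = out.values.to_numpy()[mask.to_numpy()]
        assert imputed.size == 10_000
        obs = vals[10_000:, 0]
        mu, sigma = obs.mean(), obs.std(ddof=1)
        assert imputed.mean() == pytest.approx(mu - 1.8 * sigma, abs=4 * 0.3 / math.sqrt(1e4))
        assert imputed.std(ddof=1) == pytest.approx(0.3 * sigma, rel=0.05)

    def test_observed_entries_untouched_and_counts_match(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(20, 1, size=(200, 6))
        drop = rng.random(size=vals.shape) < 0.1
        vals[drop] = np.nan
        m = make_matrix(vals)
        out, mask = stats.impute_downshift(m)
        assert mask.to_numpy().sum() == drop.sum()
        keep = ~drop
        assert np.array_equal(out.values.to_numpy()[keep], vals[keep])

    def test_sample_with_one_observed_value_rejected(self):
        vals = np.array([[20.0, 20.0], [np.nan, 20.0], [np.nan, 21.0]])
        m = make_matrix(vals, groups=("SN", "RA"))
        with pytest.raises(ValueError):
            stats.impute_downshift(m)


class TestModeratedT:
    def test_equal_means_give_zero(self):
        d, p = stats.moderated_t([1.0, 2.0, 3.0], [3.0, 2.0, 1.0], s0=0.1)
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        # independent single-formula oracle in plain floats
        x, y, s0 = (1.0, 2.0, 3.0), (4.0, 5.0, 6.0), 0.1
        mx = sum(x) / 3
        my = sum(y) / 3
        vx = sum((v - mx) ** 2 for v in x) / 2
        vy = sum((v - my) ** 2 for v in y) / 2
        sp = math.sqrt(((2 * vx + 2 * vy) / 4) * (1 / 3 + 1 / 3))
        expected_d = (mx - my) / (sp + s0)
        d, p = stats.moderated_t(x, y, s0)
        assert d == pytest.approx(expected_d, abs=1e-12)
        from scipy import stats as sps

        expected_p = 2 * sps.t.sf(abs((mx - my) / sp), 4)
        assert p == pytest.approx(expected_p, abs=1e-12)

    def test_large_s0_shrinks_d_to_zero(self):
        d, _ = stats.moderated_t([1.0, 2.0, 3.0], [7.0, 8.0, 9.0], s0=1e9)
        assert abs(d) < 1e-7

    def test_zero_variance_zero_s0_is_error(self):
        with pytest.raises(ZeroDivisionError):
            stats.moderated_t([1.0, 1.0], [1.0, 1.0], s0=0.0)


def _oracle_volcano(vals, q, s0, offset=1.0):
    """Naive loop-based exhaustive Tusher procedure (3v3), independent of
    the vectorized implementation."""
    from scipy import stats as sps

    def d_stat(x, y):
        nx, ny = len(x), len(y)
        sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
        se = math.sqrt(sp2 * (1 / nx + 1 / ny))
        return (np.mean(x) - np.mean(y)) / (se + s0)

    obs = np.array([abs(d_stat(row[:3], row[3:])) for row in vals])
    perms = []
    for combo in itertools.combinations(range(6), 3):
        if combo == (0, 1, 2) or combo == (3, 4, 5):
            continue
        rest = [i for i in range(6) if i not in combo]
        perms.append(
            np.array([abs(d_stat(row[list(combo)], row[rest])) for row in vals])
        )
    curve = {}
    for t in sorted(set(obs)):
        obs_count = (obs >= t).sum()
        perm_count = np.mean([(p >= t).sum() for p in perms])
        curve[t] = (perm_count + offset) / obs_count
    sig_ts = [t for t, f in curve.items() if f <= q]
    thr = min(sig_ts) if sig_ts else math.inf
    return obs, curve, obs >= thr


class TestPermutationFDR:
    def test_duplicated_groups_yield_nothing(self):
        rng = np.random.default_rng(7)
        half = rng.normal(20, 1, size=(100, 3))
        m = make_matrix(np.hstack([half, half]))
        est = stats.permutation_fdr(m, seed=0)
        assert est.n_significant_ == 0

    def test_exhaustive_matches_independent_oracle(self, toy_matrix):
        est = stats.permutation_fdr(toy_matrix, seed=0)
        assert est.exhaustive_
        vals = toy_matrix.values.to_numpy()
        obs, curve, sig = _oracle_volcano(vals, 0.05, 0.1)
        assert np.allclose(np.abs(est.results_["d_stat"].to_numpy()), obs)
        got_curve = dict(
            zip(est.fdr_curve_["threshold"], est.fdr_curve_["fdr"])
        )
        for t, f in curve.items():
            assert got_curve[t] == pytest.approx(f, abs=1e-12)
        assert est.results_["significant"].to_numpy().tolist() == sig.tolist()

    def test_oracle_agreement_on_random_matrices(self):
        rng = np.random.default_rng(8)
        for trial in range(5):
            vals = rng.normal(20, 0.5, size=(30, 6))
            vals[:3, :3] += 3.0
            m = make_matrix(vals)
            est = stats.permutation_fdr(m, seed=trial)
            _, _, sig = _oracle_volcano(vals, 0.05, 0.1)
            assert est.results_["significant"].to_numpy().tolist() == sig.tolist()

    def test_direction_and_invariants(self, toy_matrix):
        est = stats.permutation_fdr(toy_matrix, seed=0)
        res = est.results_
        assert ((res["direction"] != "none") == res["significant"]).all()
        assert res["p_value"].between(0, 1).all()
        if res.loc["P0", "significant"]:
            assert res.loc["P0", "direction"] == "SN-higher"
        if res.loc["P1", "significant"]:
            assert res.loc["P1", "direction"] == "RA-higher"

    def test_few_permutations_recorded_as_warning(self, toy_matrix):
        with pytest.warns(UserWarning):
            est = stats.PermutationFDRVolcano(n_permutations=5, random_state=0).fit(
                toy_matrix
            )
        assert est.warnings_

    def test_incomplete_matrix_rejected(self):
        vals = np.full((3, 6), 20.0)
        vals[0, 0] = np.nan
        with pytest.raises(ValueError):
            stats.permutation_fdr(make_matrix(vals), seed=0)


class TestSanityCheck:
    def _fixture(self):
        # P0: significant with full quantification, P1: significant driven by
        # imputation (raw evidence contradicts the imputed fold change)
        raw = np.array(
            [
                [24.0, 24.1, 23.9, 20.0, 20.1, 19.9],
                [20.0, np.nan, np.nan, 20.1, 19.9, 20.0],
            ]
        )
        imputed = raw.copy()
        imputed[1, 1] = 14.0
        imputed[1, 2] = 14.2
        mask = np.isnan(raw)
        raw_m = make_matrix(raw)
        imp_m = make_matrix(imputed)
        mask_df = pd.DataFrame(mask, index=raw_m.protein_ids, columns=raw_m.samples)
        result = pd.DataFrame(
            {"significant": [True, True]}, index=raw_m.protein_ids
        )
        return result, raw_m, imp_m, mask_df

    def test_poorly_quantified_contradicted_protein_flagged(self):
        result, raw_m, imp_m, mask = self._fixture()
        flags = stats.imputation_sanity_check(result, raw_m, imp_m, mask)
        assert not flags["P0"]  # 3 valid per group: out of rule scope
        assert flags["P1"]

    def test_flags_report_not_remove(self):
        result, raw_m, imp_m, mask = self._fixture()
        flags = stats.imputation_sanity_check(result, raw_m, imp_m, mask)
        assert len(flags) == len(result)


class TestIbaqRank:
    def test_ascending_ranks_and_top_percentile(self):
        r = stats.ibaq_rank(pd.Series({"a": 1.0, "b": 10.0, "c": 100.0}))
        assert r["rank"].tolist() == [1.0, 2.0, 3.0]
        assert r.loc["c", "percentile"] == 1.0

    def test_ties_share_mean_rank(self):
        r = stats.ibaq_rank(pd.Series({"a": 5.0, "b": 5.0, "c": 1.0}))
        assert r.loc["a", "rank"] == r.loc["b", "rank"] == 2.5

    @given(st.lists(st.floats(0, 1e9), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_percentile_bounds(self, values):
        r = stats.ibaq_rank(pd.Series(values))
        assert (r["percentile"] > 0).all() and (r["percentile"] <= 1).all()
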