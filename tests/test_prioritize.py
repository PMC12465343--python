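"""Hub genes, candidate filtering, DE, meta-analysis, signature, CMAP filter."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from semburden import prioritize
from semburden.prioritize import (
    DEFAULT_CMAP_CELL_LINES,
    Signature,
    build_signature,
    candidate_genes,
    differential_expression,
    filter_cmap,
    hub_frequencies,
    meta_analyze,
    read_cmap_table,
    read_signature,
    write_signature,
)

from conftest import make_meta


@pytest.fixture
def twelve_tf_targets():
    """12 TFs; one master hub gene targeted by all 12, others sporadic."""
    rng = np.random.default_rng(3)
    genes = [f"G{i}" for i in range(40)]
    targets = {}
    for k in range(12):
        picks = set(rng.choice(genes, 10, replace=False))
        picks.add("HUB_ALL")
        targets[f"TF{k}"] = frozenset(picks)
    return targets


class TestHubFrequencies:
    def test_gene_in_all_targets_has_fraction_one(self, twelve_tf_targets):
        hub = hub_frequencies(list(twelve_tf_targets), twelve_tf_targets)
        row = hub.set_index("gene_id").loc["HUB_ALL"]
        assert row["n_tfs_targeting"] == 12
        assert row["fraction"] == pytest.approx(1.0)
        assert hub.iloc[0]["gene_id"] == "HUB_ALL"  # ranked first

    def test_untargeted_gene_absent(self, twelve_tf_targets):
        hub = hub_frequencies(list(twelve_tf_targets), twelve_tf_targets)
        assert "NOT_A_TARGET" not in set(hub["gene_id"])

    def test_counts_match_brute_force_scan(self, twelve_tf_targets):
        tfs = list(twelve_tf_targets)
        hub = hub_frequencies(tfs, twelve_tf_targets).set_index("gene_id")
        genes = set().union(*twelve_tf_targets.values())
        for g in genes:
            brute = sum(1 for tf in tfs if g in twelve_tf_targets[tf])
            assert hub.loc[g, "n_tfs_targeting"] == brute

    def test_missing_target_set_rejected(self, twelve_tf_targets):
        with pytest.raises(ValueError, match="no target set"):
            hub_frequencies(["TF0", "UNKNOWN"], twelve_tf_targets)


class TestCandidateGenes:
    def _hub(self):
        return pd.DataFrame({
            "gene_id": ["A", "B", "C"],
            "n_tfs_targeting": [6, 5, 12],
            "fraction": [6 / 12, 5 / 12, 1.0],
        })

    def test_half_boundary_inclusive(self):
        out = candidate_genes(self._hub(), min_fraction=0.5)
        assert "A" in out and "C" in out  # 6/12 included
        assert "B" not in out             # 5/12 excluded

    def test_monotone_in_threshold(self):
        hub = self._hub()
        sizes = [len(candidate_genes(hub, f)) for f in (0.1, 0.5, 0.9, 1.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_matches_threshold_scan_oracle(self, rng):
        hub = pd.DataFrame({
            "gene_id": [f"G{i}" for i in range(50)],
            "n_tfs_targeting": rng.integers(1, 13, 50),
        })
        hub["fraction"] = hub["n_tfs_targeting"] / 12
        out = set(candidate_genes(hub, 0.5))
        brute = {r.gene_id for r in hub.itertuples() if r.fraction >= 0.5}
        assert out == brute


class TestDifferentialExpression:
    def _expr(self, effect, seed=0, n_genes=30, noise=0.5):
        rng = np.random.default_rng(seed)
        meta = make_meta(timepoints=("Tend",))
        genes = [f"G{i}" for i in range(n_genes)]
        vals = rng.normal(7, noise, (n_genes, 44))
        shift = (meta.group == "NO_ID").to_numpy()
        vals[: n_genes // 2, shift] += effect
        return pd.DataFrame(vals, index=genes, columns=meta.sample_id), meta, genes

    def test_identical_means_not_significant(self):
        expr, meta, genes = self._expr(effect=0.0)
        de = differential_expression(expr, meta, genes)
        assert not de["significant"].any() or de["significant"].mean() < 0.2

    def test_welch_t_matches_hand_formula(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0, 7.0, 8.0, 10.0]],
            index=["G1"],
            columns=[f"s{i}" for i in range(6)],
        )
        meta = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(6)],
            "group": ["ID"] * 3 + ["NO_ID"] * 3,
        })
        de = differential_expression(expr, meta, ["G1"]).iloc[0]
        a = np.array([7.0, 8.0, 10.0])   # NO_ID
        b = np.array([1.0, 2.0, 3.0])    # ID
        se = np.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
        t = (a.mean() - b.mean()) / se
        df = se**4 / ((a.var(ddof=1) / 3) ** 2 / 2 + (b.var(ddof=1) / 3) ** 2 / 2)
        assert de["effect"] == pytest.approx(a.mean() - b.mean())
        assert de["t"] == pytest.approx(t)
        assert de["p"] == pytest.approx(2 * stats.t.sf(abs(t), df), rel=1e-10)
        # cross-check with the reference implementation
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert de["p"] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_synth_truth_recovered_with_fdr_control(self):
        hits = fdr_viol = 0
        n_seeds = 25
        for s in range(n_seeds):
            expr, meta, genes = self._expr(effect=2.0, seed=s, noise=0.5)
            de = differential_expression(expr, meta, genes, q_max=0.2)
            true = {f"G{i}" for i in range(15)}
            called = set(de.loc[de["significant"], "gene_id"])
            if len(called & true) >= 0.8 * len(true):
                hits += 1
            false_frac = len(called - true) / max(len(called), 1)
            fdr_viol += false_frac > 0.2
        assert hits == n_seeds                # effect 2 at noise 0.5 is easy
        assert fdr_viol / n_seeds <= 0.2      # empirical FDR held on average

    def test_label_permuted_fdr_controlled(self):
        sig = 0
        for s in range(60):
            expr, meta, genes = self._expr(effect=0.0, seed=1000 + s)
            de = differential_expression(expr, meta, genes, q_max=0.2)
            sig += int(de["significant"].any())
        # P(any false call) under BH at q=0.2 stays near or below 0.2
        assert sig / 60 <= 0.3

    def test_absent_gene_warned_and_skipped(self):
        expr, meta, genes = self._expr(effect=0.0)
        with pytest.warns(UserWarning, match="absent"):
            de = differential_expression(expr, meta, genes + ["MISSING"])
        assert "MISSING" not in set(de["gene_id"])


class TestMetaAnalyze:
    def test_identical_estimates_tau2_zero(self):
        per = pd.DataFrame({
            "gene_id": ["G1", "G1"], "study": ["a", "b"],
            "effect": [0.5, 0.5], "se": [0.1, 0.1],
        })
        out = meta_analyze(per).iloc[0]
        assert out["pooled_effect"] == pytest.approx(0.5)
        assert out["tau2"] == 0.0

    def test_opposite_effects_pool_to_zero(self):
        per = pd.DataFrame({
            "gene_id": ["G1", "G1"], "study": ["a", "b"],
            "effect": [0.8, -0.8], "se": [0.2, 0.2],
        })
        out = meta_analyze(per).iloc[0]
        assert out["pooled_effect"] == pytest.approx(0.0, abs=1e-12)
        assert out["tau2"] > 0  # heterogeneity detected

    def test_three_study_worked_oracle(self):
        y = np.array([0.30, 0.10, 0.50])
        se = np.array([0.10, 0.15, 0.20])
        w = 1 / se**2
        fixed = np.sum(w * y) / np.sum(w)
        q = np.sum(w * (y - fixed) ** 2)
        c = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - 2) / c)
        w_re = 1 / (se**2 + tau2)
        pooled = np.sum(w_re * y) / np.sum(w_re)
        pooled_se = np.sqrt(1 / np.sum(w_re))
        per = pd.DataFrame({
            "gene_id": ["G1"] * 3, "study": list("abc"),
            "effect": y, "se": se,
        })
        out = meta_analyze(per).iloc[0]
        assert out["pooled_effect"] == pytest.approx(pooled, rel=1e-12)
        assert out["pooled_se"] == pytest.approx(pooled_se, rel=1e-12)
        assert out["tau2"] == pytest.approx(tau2, rel=1e-12)
        z = pooled / pooled_se
        assert out["p"] == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-10)

    def test_consistent_direction_flag(self):
        per = pd.DataFrame({
            "gene_id": ["G1", "G1", "G2", "G2"], "study": ["a", "b"] * 2,
            "effect": [0.5, 0.4, -0.6, -0.5], "se": [0.1] * 4,
        })
        out = meta_analyze(per, reference_direction={"G1": "up", "G2": "up"})
        out = out.set_index("gene_id")
        assert bool(out.loc["G1", "consistent"]) is True
        assert bool(out.loc["G2", "consistent"]) is False

    def test_nonpositive_se_rejected(self):
        per = pd.DataFrame({
            "gene_id": ["G1", "G1"], "study": ["a", "b"],
            "effect": [0.1, 0.2], "se": [0.1, 0.0],
        })
        with pytest.raises(ValueError):
            meta_analyze(per)


class TestSignature:
    def _de(self, n_up=80, n_down=77):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(n_up):
            rows.append({"gene_id": f"UP{i}", "effect": rng.uniform(0.5, 3),
                         "direction": "up", "significant": True})
        for i in range(n_down):
            rows.append({"gene_id": f"DN{i}", "effect": -rng.uniform(0.5, 3),
                         "direction": "down", "significant": True})
        rows.append({"gene_id": "NS", "effect": 0.01, "direction": "up",
                     "significant": False})
        return pd.DataFrame(rows)

    def test_signature_file_line_counts(self, tmp_path):
        sig = write_signature(self._de(), tmp_path)
        assert len(sig.up) == 80 and len(sig.down) == 77
        assert len((tmp_path / "up.txt").read_text().splitlines()) == 80
        assert len((tmp_path / "down.txt").read_text().splitlines()) == 77
        gmt = (tmp_path / "signature.gmt").read_text().splitlines()
        assert len(gmt) == 2

    def test_round_trip(self, tmp_path):
        sig = write_signature(self._de(), tmp_path)
        back = read_signature(tmp_path)
        assert back.up == sig.up and back.down == sig.down

    def test_duplicate_gene_both_directions_rejected(self):
        with pytest.raises(ValueError, match="both directions"):
            Signature(up=("G1",), down=("G1",), provenance={})

    def test_empty_signature_rejected(self):
        de = self._de(0, 0)
        with pytest.raises(ValueError, match="no significant"):
            build_signature(de[~de["significant"]])

    def test_ordering_by_effect_magnitude(self):
        de = pd.DataFrame({
            "gene_id": ["A", "B", "C"],
            "effect": [0.5, 2.5, 1.5],
            "direction": ["up"] * 3,
            "significant": [True] * 3,
        })
        sig = build_signature(de)
        assert sig.up == ("B", "C", "A")


class TestCmapFilter:
    def test_published_table_all_rows_pass(self):
        import importlib.resources as res

        with res.as_file(
            res.files("semburden").joinpath("data/jia_cmap_query_results.tsv")
        ) as p:
            rows = read_cmap_table(p)
        kept = filter_cmap(rows)
        assert len(rows) == 12 and len(kept) == 12
        avicin = kept.loc[kept["compound_name"] == "avicin-g"].iloc[0]
        assert avicin["cell_name"] == "JURKAT"
        assert avicin["normalized_score"] == pytest.approx(-1.51)
        assert avicin["fdr_q"] == pytest.approx(4.47e-16)

    def test_positive_score_rejected(self):
        rows = pd.DataFrame({
            "cell_name": ["JURKAT"], "normalized_score": [1.2], "fdr_q": [1e-6],
        })
        assert filter_cmap(rows).empty

    def test_disallowed_cell_line_rejected(self):
        rows = pd.DataFrame({
            "cell_name": ["HELA"], "normalized_score": [-1.2], "fdr_q": [1e-6],
        })
        assert filter_cmap(rows).empty
        assert "HELA" not in DEFAULT_CMAP_CELL_LINES

    def test_q_threshold_strict(self):
        rows = pd.DataFrame({
            "cell_name": ["THP1", "THP1"],
            "normalized_score": [-1.0, -1.0],
            "fdr_q": [0.049, 0.05],
        })
        assert len(filter_cmap(rows, q_max=0.05)) == 1

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            filter_cmap(pd.DataFrame({"cell_name": ["JURKAT"]}))
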