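import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rhoscreen import (
    CountTable,
    CoverageDesign,
    EffectSpec,
    LibraryManifest,
    SimParams,
    analyze_screen,
    call_gene_hits,
    classify_candidates,
    competition_ratio,
    hf_founders_per_embryo,
    min_embryos_for_coverage,
    normality_dispatch,
    normalize_log2fc,
    replicate_correlation,
    shrna_test,
    simulate_screen,
)
from rhoscreen.library_io import ShrnaRecord
from rhoscreen.screen_stats import ComparisonDesign

pytestmark = pytest.mark.filterwarnings("ignore::RuntimeWarning")


def _manifest(genes):
    """genes: list of (shrna_id, gene); reg_class inferred."""
    recs = []
    for sid, gene in genes:
        cls = "SCR" if gene == "SCR" else "GTPASE"
        seq_num = abs(hash(sid)) % (4 ** 10)
        seq = "".join("ACGT"[(seq_num >> (2 * i)) % 4] for i in range(10))
        recs.append(ShrnaRecord(sid, gene, cls, (seq + "A" * 21)[:21]))
    return LibraryManifest(recs, allow_duplicate_seqs=True)


SIX_MANIFEST = _manifest([
    ("shA_1", "GeneA"), ("shA_2", "GeneA"),
    ("shB_1", "GeneB"), ("shB_2", "GeneB"),
    ("shScr_1", "SCR"), ("shScr_2", "SCR"),
])


def _table(data, columns):
    counts = pd.DataFrame(data, columns=columns,
                          index=pd.Index(list(data.keys()), name="shrna_id")
                          if isinstance(data, dict) else None)
    if isinstance(data, dict):
        counts = pd.DataFrame.from_dict(data, orient="index", columns=columns)
        counts.index.name = "shrna_id"
    return CountTable.from_counts(counts)


class TestNormalizeLog2fc:
    def test_global_doubling_is_absorbed(self):
        t0 = {"shA_1": 100, "shA_2": 150, "shB_1": 200, "shB_2": 250,
              "shScr_1": 120, "shScr_2": 180}
        table = _table({k: (v, 2 * v) for k, v in t0.items()}, ["T0", "EPI:1"])
        fc = normalize_log2fc(table, SIX_MANIFEST)
        assert np.allclose(fc["log2fc"], 0.0)

    def test_doubled_proportion_gives_log2fc_one(self):
        # scrambled unchanged, the test hairpin's depth-normalized abundance
        # doubles: normalized log2fc is exactly 1 (pseudocount 0)
        m = _manifest([("shX_1", "GeneX"), ("shScr_1", "SCR"),
                       ("shScr_2", "SCR"), ("shScr_3", "SCR")])
        table = _table({"shX_1": (100, 200), "shScr_1": (100, 100),
                        "shScr_2": (100, 100), "shScr_3": (100, 100)},
                       ["T0", "EPI:1"])
        fc = normalize_log2fc(table, m, pseudocount=0.0)
        x = fc.set_index("shrna_id")["log2fc"]
        assert x["shX_1"] == pytest.approx(1.0, abs=1e-12)

    def test_hand_worked_fixture(self):
        # frozen values from an independent spreadsheet-style computation
        # (CPM + 0.5 pseudocount, log2 vs T0, minus scrambled median)
        table = _table({"shA_1": (100, 400), "shA_2": (150, 500),
                        "shB_1": (200, 100), "shB_2": (250, 50),
                        "shScr_1": (120, 130), "shScr_2": (180, 160)},
                       ["T0", "EPI:1"])
        fc = normalize_log2fc(table, SIX_MANIFEST, pseudocount=0.5)
        got = fc.set_index("shrna_id")["log2fc"]
        expected = {"shA_1": 2.027217366074, "shA_2": 1.76418488142,
                    "shB_1": -0.97277177769, "shB_2": -2.294689485272,
                    "shScr_1": 0.142700804631, "shScr_2": -0.142700804631}
        for k, v in expected.items():
            assert got[k] == pytest.approx(v, abs=1e-9)

    def test_depth_scaling_invariance_is_exact(self):
        base = {"shA_1": (100, 400), "shA_2": (150, 500),
                "shB_1": (200, 100), "shB_2": (250, 50),
                "shScr_1": (120, 130), "shScr_2": (180, 160)}
        t1 = _table(base, ["T0", "EPI:1"])
        t2 = _table({k: (a, 7 * b) for k, (a, b) in base.items()},
                    ["T0", "EPI:1"])
        fc1 = normalize_log2fc(t1, SIX_MANIFEST)
        fc2 = normalize_log2fc(t2, SIX_MANIFEST)
        assert np.array_equal(fc1["log2fc"].to_numpy(), fc2["log2fc"].to_numpy())

    def test_scr_median_exactly_zero_per_sample(self, screen_manifest):
        table, _ = simulate_screen(
            SimParams(n_progenitors_per_embryo=5000, embryos_per_replicate=5,
                      reads_per_sample=200_000, seed=8), screen_manifest)
        fc = normalize_log2fc(table, screen_manifest)
        scr = fc[fc["gene"] == "SCR"]
        med = scr.groupby(["fraction", "replicate"])["log2fc"].median()
        assert np.allclose(med, 0.0)

    def test_missing_t0_rejected(self):
        table = _table({"shA_1": (1, 2)}, ["EPI:1", "EPI:2"])
        with pytest.raises(ValueError, match="T0"):
            normalize_log2fc(table, SIX_MANIFEST)


def _fc_frame(values_by_rep, gene="GeneA", fraction="HF"):
    rows = []
    for rep, vals in enumerate(values_by_rep, start=1):
        for sid, v in vals.items():
            rows.append((sid, gene if not sid.startswith("shScr") else "SCR",
                         fraction, rep, v))
    return pd.DataFrame(rows, columns=["shrna_id", "gene", "fraction",
                                       "replicate", "log2fc"])


class TestReplicateCorrelation:
    def test_identical_replicates_r2_one(self):
        vals = {f"hp{i}": float(i) for i in range(10)}
        fc = _fc_frame([vals, vals])
        r2 = replicate_correlation(fc)["HF"]
        assert r2.loc[1, 2] == pytest.approx(1.0)

    def test_anti_ranked_replicates_r2_one(self):
        a = {f"hp{i}": float(i) for i in range(10)}
        b = {f"hp{i}": float(-i) for i in range(10)}
        fc = _fc_frame([a, b])
        rho = stats.spearmanr([a[k] for k in a], [b[k] for k in a]).statistic
        assert rho == pytest.approx(-1.0)
        assert replicate_correlation(fc)["HF"].loc[1, 2] == pytest.approx(1.0)

    def test_equals_rank_correlation_oracle(self):
        rng = np.random.default_rng(3)
        a = {f"hp{i}": v for i, v in enumerate(rng.normal(size=30))}
        b = {f"hp{i}": v for i, v in enumerate(rng.normal(size=30))}
        fc = _fc_frame([a, b])
        ra = pd.Series(a).rank().to_numpy()
        rb = pd.Series(b).rank().to_numpy()
        oracle = np.corrcoef(ra, rb)[0, 1] ** 2
        assert replicate_correlation(fc)["HF"].loc[1, 2] == pytest.approx(oracle)

    def test_constant_vector_flagged(self):
        a = {f"hp{i}": float(i) for i in range(5)}
        b = {f"hp{i}": 1.0 for i in range(5)}
        with pytest.warns(UserWarning, match="constant"):
            r2 = replicate_correlation(_fc_frame([a, b]))["HF"]
        assert np.isnan(r2.loc[1, 2])


def _brute_bh(pvals):
    """Step-up Benjamini-Hochberg q-values, by the definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        q[i] = running
    return q


class TestShrnaTest:
    def test_all_zero_replicates_give_p_one(self):
        fc = _fc_frame([{"hp1": 0.0}, {"hp1": 0.0}, {"hp1": 0.0}])
        res = shrna_test(fc, mode="one_sample")
        assert res.loc[0, "p_value"] == 1.0
        assert res.loc[0, "q_value"] == 1.0

    def test_zero_variance_nonzero_mean_spiked(self):
        fc = _fc_frame([{"hp1": 1.0}, {"hp1": 1.0}, {"hp1": 1.0}])
        with pytest.warns(UserWarning, match="zero replicate variance"):
            res = shrna_test(fc, mode="one_sample")
        assert 0 < res.loc[0, "p_value"] < 1e-300

    def test_q_values_match_step_up_oracle(self, screen_manifest):
        table, _ = simulate_screen(
            SimParams(n_progenitors_per_embryo=5000, embryos_per_replicate=5,
                      reads_per_sample=200_000, seed=9), screen_manifest)
        fc = normalize_log2fc(table, screen_manifest)
        res = shrna_test(fc)
        for _, sub in res.groupby("fraction"):
            assert np.allclose(sub["q_value"], _brute_bh(sub["p_value"]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=50))
    def test_bh_oracle_matches_adjuster(self, pvals):
        from statsmodels.stats.multitest import multipletests
        assert np.allclose(multipletests(pvals, method="fdr_bh")[1],
                           _brute_bh(pvals))

    def test_identical_p_values_collapse_to_p0(self):
        assert np.allclose(_brute_bh([0.03] * 8), 0.03)

    def test_vs_scr_mode_gains_power_over_one_sample(self):
        rng = np.random.default_rng(11)
        reps = []
        for _ in range(3):
            vals = {f"shScr_{i}": rng.normal(0, 0.2) for i in range(20)}
            vals["hp1"] = rng.normal(-2.0, 0.2)
            reps.append(vals)
        fc = _fc_frame(reps)
        p_scr = shrna_test(fc, mode="vs_scr").set_index("shrna_id")["p_value"]
        p_one = shrna_test(fc, mode="one_sample").set_index("shrna_id")["p_value"]
        assert p_scr["hp1"] < p_one["hp1"]


def _tests_frame(rows):
    """rows: (shrna_id, gene, fraction, mean_log2fc, p, q)."""
    return pd.DataFrame(rows, columns=["shrna_id", "gene", "fraction",
                                       "mean_log2fc", "p_value", "q_value"])


class TestCallGeneHits:
    def test_two_supporting_shrnas_enrich(self):
        t = _tests_frame([
            ("a1", "A", "HF", 1.5, 0.001, 0.01),
            ("a2", "A", "HF", 2.1, 0.001, 0.01),
            ("a3", "A", "HF", 0.2, 0.5, 0.9),
        ])
        calls = call_gene_hits(t)
        assert calls.iloc[0]["direction"] == "ENRICHED"
        assert calls.iloc[0]["n_support"] == 2

    def test_opposing_shrna_vetoes_call(self):
        t = _tests_frame([
            ("a1", "A", "HF", 2.0, 0.001, 0.01),
            ("a2", "A", "HF", -2.0, 0.001, 0.01),
        ])
        assert call_gene_hits(t).iloc[0]["direction"] == "NONE"

    def test_single_supporter_insufficient(self):
        t = _tests_frame([
            ("a1", "A", "HF", 3.0, 0.001, 0.01),
            ("a2", "A", "HF", 0.1, 0.8, 0.9),
            ("a3", "A", "HF", -0.1, 0.8, 0.9),
        ])
        assert call_gene_hits(t).iloc[0]["direction"] == "NONE"

    def test_significance_requires_both_thresholds(self):
        # 2-fold movers failing q (or p) are not supporters
        t = _tests_frame([
            ("a1", "A", "HF", 2.0, 0.01, 0.5),
            ("a2", "A", "HF", 2.0, 0.01, 0.5),
        ])
        assert call_gene_hits(t).iloc[0]["direction"] == "NONE"


class TestClassifyCandidates:
    def _calls(self):
        return pd.DataFrame(
            [("A", "HF", "DEPLETED", 2, "a1;a2"),
             ("B", "HF", "ENRICHED", 2, "b1;b2"),
             ("B", "EPI", "ENRICHED", 2, "b1;b2"),
             ("A", "EPI", "NONE", 0, "")],
            columns=["gene", "fraction", "direction", "n_support",
                     "supporting_shrna_ids"])

    def _fc(self, a_epi=0.1, b_epi=2.0):
        rows = []
        for rep in (1, 2):
            rows += [("a1", "A", "EPI", rep, a_epi),
                     ("a2", "A", "EPI", rep, -a_epi),
                     ("b1", "B", "EPI", rep, b_epi),
                     ("b2", "B", "EPI", rep, b_epi)]
        return pd.DataFrame(rows, columns=["shrna_id", "gene", "fraction",
                                           "replicate", "log2fc"])

    def test_hf_only_quasi_neutral_epi_is_hf_specific(self):
        res = classify_candidates(self._calls(), self._fc()).set_index("gene")
        assert res.loc["A", "venn_class"] == "HF_ONLY"
        assert bool(res.loc["A", "hf_specific"])

    def test_both_fractions_not_hf_specific(self):
        res = classify_candidates(self._calls(), self._fc()).set_index("gene")
        assert res.loc["B", "venn_class"] == "BOTH"
        assert not bool(res.loc["B", "hf_specific"])

    def test_planted_venn_classes_recovered(self, screen_manifest):
        # 5 HF-only + 3 EPI-only + 4 shared 4-fold depletions; over 20 seeds
        # the recovered Venn classes must match the plan almost always.
        genes = screen_manifest.genes
        plan = ({g: (1.0, 0.25) for g in genes[:5]}
                | {g: (0.25, 1.0) for g in genes[5:8]}
                | {g: (0.25, 0.25) for g in genes[8:12]})
        expected = ({g: "HF_ONLY" for g in genes[:5]}
                    | {g: "EPI_ONLY" for g in genes[5:8]}
                    | {g: "BOTH" for g in genes[8:12]})
        correct = []
        for seed in range(20):
            table, _ = simulate_screen(SimParams(seed=300 + seed),
                                       screen_manifest, EffectSpec(plan))
            res = analyze_screen(table, screen_manifest)
            venn = res["classification"].set_index("gene")["venn_class"]
            correct.append(sum(venn.get(g) == cls for g, cls in expected.items()))
        assert np.mean(correct) >= 11


class TestCoverageDesign:
    def test_hf_founders_printed_figure(self):
        assert hf_founders_per_embryo(120_000, 0.10) == 12_000

    def test_hf_founders_edge_cases(self):
        assert hf_founders_per_embryo(5, 0.0) == 0
        assert hf_founders_per_embryo(100, 0.5) == 50

    def test_min_embryos_for_study_design(self):
        design = CoverageDesign(library_size=1000, target_coverage=100,
                                progenitors_per_embryo=120_000,
                                hf_founder_fraction=0.10,
                                transduction_rate=0.15)
        assert design.transduced_hf_founders_per_embryo == 1800
        n = min_embryos_for_coverage(design)
        assert n == 56
        assert n <= 60  # the study pooled 60 embryos per replicate

    def test_zero_coverage_needs_no_embryos(self):
        assert min_embryos_for_coverage(CoverageDesign(target_coverage=0)) == 0

    def test_minimal_design(self):
        d = CoverageDesign(library_size=1, target_coverage=1,
                           progenitors_per_embryo=1, hf_founder_fraction=1.0,
                           transduction_rate=1.0)
        assert min_embryos_for_coverage(d) == 1

    def test_no_founders_rejected(self):
        d = CoverageDesign(transduction_rate=0.0)
        with pytest.raises(ValueError):
            min_embryos_for_coverage(d)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(lib=st.integers(1, 5000), cov=st.integers(1, 500),
           founders=st.integers(1, 5000), delta=st.integers(1, 100))
    def test_monotone_in_library_coverage_founders(self, lib, cov, founders,
                                                   delta):
        def n_embryos(l, c, f):
            return min_embryos_for_coverage(CoverageDesign(
                library_size=l, target_coverage=c, progenitors_per_embryo=f,
                hf_founder_fraction=1.0, transduction_rate=1.0))
        base = n_embryos(lib, cov, founders)
        assert n_embryos(lib + delta, cov, founders) >= base
        assert n_embryos(lib, cov + delta, founders) >= base
        assert n_embryos(lib, cov, founders + delta) <= base


class TestCompetitionRatio:
    def test_neutral_expectation(self):
        assert competition_ratio((100, 100), (50, 50)) == pytest.approx(1.0)

    def test_halved_rfp(self):
        assert competition_ratio((100, 100), (100, 50)) == pytest.approx(0.5)

    def test_normalized_to_starting_mix(self):
        assert competition_ratio((100, 200), (50, 100)) == pytest.approx(1.0)

    def test_zero_reference_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(competition_ratio((0, 100), (50, 100)))


class TestNormalityDispatch:
    def test_identical_groups_p_one(self):
        g = [1.2, 3.4, 2.2, 5.1, 4.0]
        res = normality_dispatch(g, g, ComparisonDesign.UNPAIRED)
        assert res.p_value == pytest.approx(1.0)

    def test_non_normal_data_takes_mann_whitney_branch(self):
        rng = np.random.default_rng(5)
        expo = rng.exponential(1.0, size=60) ** 3  # heavily skewed
        norm = rng.normal(5.0, 1.0, size=60)
        assert stats.shapiro(expo).pvalue <= 0.05  # branch precondition
        res = normality_dispatch(expo, norm)
        assert res.test_name == "mann-whitney"

    def test_normal_data_takes_t_branch(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, size=30)
        b = rng.normal(1, 1, size=30)
        res = normality_dispatch(a, b)
        assert res.test_name == "unpaired t-test"
        assert res.shapiro_p[0] > 0.05 and res.shapiro_p[1] > 0.05

    def test_paired_design_uses_paired_t(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, size=12)
        res = normality_dispatch(a, a + rng.normal(0.5, 0.3, size=12),
                                 ComparisonDesign.PAIRED)
        assert res.test_name == "paired t-test"

    def test_distributions_design_matches_ecdf_oracle(self):
        rng = np.random.default_rng(8)
        a = np.degrees(rng.vonmises(0.0, 2.0, size=80))
        b = np.degrees(rng.vonmises(0.5, 2.0, size=70))
        res = normality_dispatch(a, b, ComparisonDesign.DISTRIBUTIONS)
        assert res.test_name == "kolmogorov-smirnov"
        grid = np.sort(np.r_[a, b])
        ecdf_gap = max(abs((a <= t).mean() - (b <= t).mean()) for t in grid)
        assert res.statistic == pytest.approx(ecdf_gap)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            normality_dispatch([1.0, 2.0], [1.0, 2.0, 3.0])
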