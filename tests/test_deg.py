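"""Differential-expression stage: filter, TMM, dispersion, NB GLM LRT, BH."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ionoflux.deg import (
    DEModel,
    NormalizationFactors,
    bh_adjust,
    call_degs,
    estimate_common_dispersion,
    filter_low_expression,
    nb_glm_lrt,
    tmm_factors,
)
from ionoflux.simulate import CountSimConfig, gen_count_matrix


def _counts(arr, genes=None, samples=None):
    arr = np.asarray(arr)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=samples)


class TestFilterLowExpression:
    def test_zero_threshold_is_identity(self, small_counts):
        counts, _, _ = small_counts
        kept, report = filter_low_expression(counts, cpm_threshold=0.0)
        assert kept.equals(counts)
        assert report["n_removed"] == 0

    def test_all_zero_gene_removed(self):
        counts = _counts([[0, 0, 0], [10, 20, 30]])
        kept, report = filter_low_expression(counts, cpm_threshold=1.0)
        assert list(kept.index) == ["g1"]
        assert report["fraction_removed"] == pytest.approx(0.5)

    def test_toy_matrix_matches_hand_cpm_oracle(self):
        counts = _counts(
            [[5, 0, 0], [100, 120, 90], [1, 1, 1],
             [0, 50, 0], [30, 0, 40], [2, 3, 2]]
        )
        lib = counts.sum(axis=0)
        keep_expected = []
        for g in counts.index:
            n_ok = sum(
                counts.loc[g, s] / lib[s] * 1e6 >= 100.0 for s in counts.columns
            )
            if n_ok >= 2:
                keep_expected.append(g)
        kept, _ = filter_low_expression(counts, cpm_threshold=100.0, min_samples=2)
        assert list(kept.index) == keep_expected

    def test_negative_threshold_rejected(self, small_counts):
        with pytest.raises(ValueError):
            filter_low_expression(small_counts[0], cpm_threshold=-1)


def _tmm_oracle(counts: pd.DataFrame, ref: str, trim_m=0.30, trim_a=0.05):
    """Independent step-by-step trimmed weighted mean (loop-based)."""
    lib = counts.sum(axis=0).astype(float)
    logf = {}
    for sample in counts.columns:
        ms, as_, ws = [], [], []
        for g in counts.index:
            y, yr = counts.loc[g, sample], counts.loc[g, ref]
            if y > 0 and yr > 0:
                p, pr = y / lib[sample], yr / lib[ref]
                ms.append(np.log2(p / pr))
                as_.append(0.5 * np.log2(p * pr))
                ws.append(
                    (lib[sample] - y) / (lib[sample] * y)
                    + (lib[ref] - yr) / (lib[ref] * yr)
                )
        ms, as_, ws = map(np.array, (ms, as_, ws))
        if np.max(np.abs(ms)) < 1e-6:
            logf[sample] = 0.0
            continue
        n = len(ms)
        rm = stats.rankdata(ms)
        ra = stats.rankdata(as_)
        keep = (
            (rm >= np.floor(n * trim_m) + 1) & (rm <= n - np.floor(n * trim_m))
            & (ra >= np.floor(n * trim_a) + 1) & (ra <= n - np.floor(n * trim_a))
        )
        logf[sample] = np.sum(ms[keep] / ws[keep]) / np.sum(1.0 / ws[keep])
    f = 2.0 ** np.array([logf[s] for s in counts.columns])
    return f / np.exp(np.mean(np.log(f)))


class TestTmmFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = _counts(np.tile([[10], [200], [3000], [50]], (1, 4)))
        norm = tmm_factors(counts)
        assert np.allclose(norm.factors, 1.0)

    def test_pure_depth_change_gives_unit_factors(self, rng):
        col = rng.integers(10, 1000, size=300)
        counts = _counts(np.column_stack([col, 3 * col]))
        norm = tmm_factors(counts)
        assert np.allclose(norm.factors, 1.0, atol=1e-12)

    def test_composition_shift_matches_independent_oracle(self, rng):
        base = rng.integers(5, 500, size=(60, 4))
        base[0, 0] = base[:, 0].sum()  # one gene consumes ~half of library 0
        counts = _counts(base)
        norm = tmm_factors(counts)
        oracle = _tmm_oracle(counts, ref=norm.reference)
        assert np.allclose(norm.factors.to_numpy(), oracle, atol=1e-8)

    def test_random_toys_match_oracle(self, rng):
        for _ in range(5):
            counts = _counts(rng.integers(0, 400, size=(80, 5)))
            counts.iloc[0] += 1  # keep every library positive
            norm = tmm_factors(counts)
            oracle = _tmm_oracle(counts, ref=norm.reference)
            assert np.allclose(norm.factors.to_numpy(), oracle, atol=1e-8)

    def test_geometric_mean_is_one(self, small_counts):
        norm = tmm_factors(small_counts[0])
        assert np.exp(np.mean(np.log(norm.factors))) == pytest.approx(1.0)

    def test_disjoint_library_rejected(self):
        counts = _counts([[10, 0], [20, 0], [0, 5], [0, 9]])
        with pytest.raises(ValueError, match="no positively expressed gene"):
            tmm_factors(counts, ref="s0")

    def test_matches_edger_reference_implementation(self, rng, tmp_path):
        """Cross-check against edgeR::calcNormFactors on a random matrix."""
        counts = _counts(rng.negative_binomial(5, 0.01, size=(200, 5)))
        counts.iloc[0] += 1
        path = tmp_path / "counts.tsv"
        counts.to_csv(path, sep="\t")
        script = textwrap.dedent(f"""
            suppressMessages(library(edgeR))
            x <- as.matrix(read.delim("{path}", row.names=1))
            f <- calcNormFactors(x, method="TMM")
            cat(sprintf("%.10f", f), sep="\\n")
        """)
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        edger = np.array([float(v) for v in out.stdout.split()])
        norm = tmm_factors(counts)
        assert np.allclose(norm.factors.to_numpy(), edger, atol=1e-6)


class TestCommonDispersion:
    def test_poisson_data_estimates_near_zero(self):
        cfg = CountSimConfig(n_genes=2000, dispersion=0.0, de_fraction=0.0, seed=10)
        counts, sheet, _ = gen_count_matrix(cfg)
        phi = estimate_common_dispersion(counts, sheet["group"].to_numpy())
        assert phi < 0.01

    def test_nb_dispersion_recovered(self):
        cfg = CountSimConfig(
            n_genes=2000, n_samples_per_group=3, dispersion=0.1,
            de_fraction=0.0, seed=11,
        )
        counts, sheet, _ = gen_count_matrix(cfg)
        phi = estimate_common_dispersion(counts, sheet["group"].to_numpy())
        assert 0.08 <= phi <= 0.12

    def test_single_replicate_group_rejected(self):
        counts = _counts([[10, 20, 30], [5, 5, 5]])
        with pytest.raises(ValueError, match="single replicate"):
            estimate_common_dispersion(counts, np.array(["a", "a", "b"]))


class TestNbGlmLrt:
    def test_planted_fold_change_recovered(self):
        cfg = CountSimConfig(
            n_genes=1000, de_fraction=0.1, planted_log2fc=2.0,
            dispersion=0.05, library_size_range=(2e6, 2e6), seed=12,
        )
        counts, sheet, truth = gen_count_matrix(cfg)
        norm = tmm_factors(counts)
        res = nb_glm_lrt(counts, sheet["group"].to_numpy(), factors=norm,
                         dispersion=0.05)
        planted = truth[truth["is_de"]]
        big = counts.loc[planted.index].min(axis=1) > 50  # large-count genes
        est = res.loc[planted.index[big], "log2FC"]
        tru = planted.loc[big, "true_log2fc"]
        # signed mean across planted genes recovers the planted effect
        assert np.mean(est * np.sign(tru)) == pytest.approx(2.0, abs=0.1)
        assert np.allclose(est, tru, atol=0.6)  # per-gene NB sampling scatter

    def test_poisson_limit_matches_statsmodels_glm(self, rng):
        import statsmodels.api as sm

        counts = _counts(rng.poisson(50, size=(12, 6)))
        groups = np.array(["control"] * 3 + ["WD"] * 3)
        lib = counts.sum(axis=0).to_numpy(dtype=float)
        mine = nb_glm_lrt(counts, groups, dispersion=0.0)
        X = np.column_stack([np.ones(6), (groups == "WD").astype(float)])
        for g in counts.index:
            y = counts.loc[g].to_numpy(dtype=float)
            full = sm.GLM(y, X, family=sm.families.Poisson(),
                          offset=np.log(lib)).fit()
            null = sm.GLM(y, X[:, :1], family=sm.families.Poisson(),
                          offset=np.log(lib)).fit()
            lrt = 2 * (full.llf - null.llf)
            p_sm = stats.chi2.sf(lrt, 1)
            assert mine.loc[g, "p_value"] == pytest.approx(p_sm, abs=1e-6)
            assert mine.loc[g, "log2FC"] == pytest.approx(
                full.params[1] / np.log(2), abs=1e-6
            )

    def test_all_zero_gene_flagged(self):
        counts = _counts([[0, 0, 0, 0], [10, 12, 30, 28]])
        res = nb_glm_lrt(counts, np.array(["control", "control", "WD", "WD"]),
                         dispersion=0.1)
        assert res.loc["g0", "p_value"] == 1.0
        assert res.loc["g0", "log2FC"] == 0.0
        assert bool(res.loc["g0", "all_zero"])

    def test_doubling_counts_and_libraries_preserves_log2fc(self, rng):
        counts = _counts(rng.poisson(80, size=(50, 8)))
        groups = np.array(["control"] * 4 + ["WD"] * 4)
        a = nb_glm_lrt(counts, groups, dispersion=0.0)
        b = nb_glm_lrt(counts * 2, groups, dispersion=0.0)
        assert np.allclose(a["log2FC"], b["log2FC"], atol=1e-10)

    def test_equivariant_to_gene_and_sample_reordering(self, small_counts, rng):
        counts, sheet, _ = small_counts
        groups = sheet["group"].to_numpy()
        res = nb_glm_lrt(counts, groups, dispersion=0.1)
        gperm = rng.permutation(len(counts))
        sperm = rng.permutation(counts.shape[1])
        shuffled = counts.iloc[gperm, sperm]
        res2 = nb_glm_lrt(shuffled, groups[sperm], dispersion=0.1)
        aligned = res2.loc[res.index]
        assert np.allclose(aligned["p_value"], res["p_value"], atol=1e-9)
        assert np.allclose(aligned["log2FC"], res["log2FC"], atol=1e-9)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_oracle(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_ranking_preserved_and_dominates_raw(self, rng):
        p = rng.random(100)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()
        # step-up: adjusted values are non-decreasing along the raw-p order
        assert (np.diff(adj[np.argsort(p)]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestCallDegs:
    def test_boundary_inclusive_at_alpha(self):
        res = pd.DataFrame(
            {"log2FC": [0.01, -1.0, 2.0], "p_value": [0.001, 0.01, 0.02],
             "p_adj": [0.05, 0.051, 0.001]},
            index=["a", "b", "c"],
        )
        out = call_degs(res, alpha=0.05)
        assert bool(out.loc["a", "deg"])        # == alpha: flagged
        assert not bool(out.loc["b", "deg"])    # just above: not flagged
        assert bool(out.loc["c", "deg"])
        assert out.loc["a", "direction"] == "up"   # tiny |log2FC| still called
        assert out.loc["b", "direction"] == "down"


class TestDEModel:
    def test_end_to_end_recovers_planted_degs(self, small_counts):
        counts, sheet, truth = small_counts
        res = DEModel(counts, sheet).fit()
        tab = res.tables["WD_vs_control"]
        flagged = set(tab.index[tab["deg"]])
        planted = set(truth.index[truth["is_de"]])
        sensitivity = len(flagged & planted) / len(planted)
        assert sensitivity > 0.9
        # directions of recovered genes match the planted signs
        rec = tab.loc[sorted(flagged & planted)]
        tru = truth.loc[rec.index, "true_log2fc"]
        assert (np.sign(rec["log2FC"]) == np.sign(tru)).all()

    def test_harvest_column_splits_contrasts(self, small_counts):
        counts, sheet, _ = small_counts
        sheet = sheet.copy()
        sheet["harvest"] = ["t1_40"] * 4 + ["t2_25"] * 1 + ["t1_40"] * 4 + ["t2_25"] * 1
        # only t1_40 has >= 2 samples per group
        model = DEModel(counts, sheet)
        assert list(model.contrasts()) == ["t1_40"]

    def test_non_integer_counts_rejected(self, small_counts):
        counts, sheet, _ = small_counts
        bad = counts.astype(float)
        bad.iloc[0, 0] = 1.5
        with pytest.raises(ValueError, match="integers"):
            DEModel(bad, sheet)
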