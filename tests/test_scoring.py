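"""TPM contract, Pearson, STAT scores, fold change, PCA oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from statscore import scoring
from statscore.errors import (
    DegenerateCorrelationError,
    DegenerateInputError,
    ParameterError,
    ValidationError,
)
from statscore.scoring import ScoreTable, pca_scores, pearson, score_fold_change, stat_score, tpm
from statscore.signatures import SignatureSet


def frame(values, genes=None, samples=None):
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestTpm:
    def test_single_gene_is_million(self):
        counts = frame([[7, 3000]])
        lengths = pd.Series([1234], index=["g0"])
        out = tpm(counts, lengths)
        np.testing.assert_allclose(out.to_numpy(), 1e6)

    def test_length_normalization_hand_example(self):
        counts = frame([[10], [10]])
        lengths = pd.Series([1000, 2000], index=["g0", "g1"])
        out = tpm(counts, lengths)
        np.testing.assert_allclose(
            out["s0"], [666_666.666_67, 333_333.333_33], rtol=1e-6
        )

    def test_scale_invariance(self):
        counts = frame([[3, 6], [9, 1], [2, 5]])
        lengths = pd.Series([500, 1500, 800], index=counts.index)
        doubled = counts.copy()
        doubled["s0"] *= 2
        pd.testing.assert_frame_equal(tpm(counts, lengths), tpm(doubled, lengths))

    def test_missing_or_bad_length_rejected(self):
        counts = frame([[1], [2]])
        with pytest.raises(ParameterError):
            tpm(counts, pd.Series([100], index=["g0"]))
        with pytest.raises(ParameterError):
            tpm(counts, pd.Series([100, 0], index=["g0", "g1"]))

    def test_all_zero_sample_rejected(self):
        counts = frame([[1, 0], [2, 0]])
        lengths = pd.Series([100, 100], index=counts.index)
        with pytest.raises(DegenerateInputError):
            tpm(counts, lengths)

    @given(
        hnp.arrays(
            np.int64,
            st.tuples(st.integers(2, 12), st.integers(1, 6)),
            elements=st.integers(0, 10_000),
        ).filter(lambda a: (a.sum(axis=0) > 0).all())
    )
    def test_columns_sum_to_million(self, arr):
        counts = frame(arr)
        rng = np.random.default_rng(0)
        lengths = pd.Series(
            rng.integers(200, 5000, arr.shape[0]), index=counts.index
        )
        out = tpm(counts, lengths)
        np.testing.assert_allclose(out.sum(axis=0), 1e6, rtol=1e-9)


class TestPearson:
    def test_identity_and_antilinearity(self):
        assert pearson([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)
        x = np.array([0.5, 1.5, 2.0, 4.0])
        assert pearson(x, -2 * x + 5) == pytest.approx(-1.0)

    def test_two_pass_oracle_equivalence(self):
        x, y = np.array([1.0, 2, 3]), np.array([1.0, 2, 4])
        xm, ym = x - x.mean(), y - y.mean()
        expected = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
        assert pearson(x, y) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(DegenerateCorrelationError):
            pearson([1, 1, 1], [1, 2, 3])
        with pytest.raises(ParameterError):
            pearson([1, 2], [1, 2])
        with pytest.raises(ParameterError):
            pearson([1, 2, 3], [1, 2])


def make_signature(genes, reference_conditions=("ref",)):
    return SignatureSet(
        "STAT3", {g: 1 for g in genes}, set(genes), list(reference_conditions)
    )


class TestStatScore:
    def test_identical_to_single_reference(self):
        genes = [f"g{i}" for i in range(12)]
        profile = np.arange(12.0) + 1
        refs = frame(profile[:, None], genes=genes, samples=["r1"])
        query = pd.Series(profile, index=genes, name="q1")
        res = stat_score(query, make_signature(genes), refs)
        assert res.score == pytest.approx(1.0)
        assert res.n_genes_used == 12 and res.n_reference_samples == 1

    def test_mean_of_plus_and_minus_one(self):
        genes = [f"g{i}" for i in range(12)]
        profile = np.arange(12.0) + 1
        refs = frame(
            np.column_stack([profile, -2 * profile + 30]),
            genes=genes,
            samples=["r1", "r2"],
        )
        query = pd.Series(profile, index=genes, name="q1")
        res = stat_score(query, make_signature(genes), refs)
        assert res.score == pytest.approx(0.0, abs=1e-12)
        assert res.n_reference_samples == 2

    def test_below_min_size_missing(self):
        genes = [f"g{i}" for i in range(5)]
        refs = frame(np.arange(5.0)[:, None], genes=genes, samples=["r1"])
        query = pd.Series(np.arange(5.0), index=genes, name="q1")
        res = stat_score(query, make_signature(genes), refs, min_size=10)
        assert res.score is None and res.n_genes_used == 5
        assert res.reason == scoring.REASON_TOO_FEW_GENES

    def test_self_exclusion_from_own_panel(self):
        genes = [f"g{i}" for i in range(12)]
        rng = np.random.default_rng(5)
        panel = frame(rng.random((12, 3)), genes=genes, samples=["r1", "r2", "r3"])
        query = panel["r2"].rename("r2")
        res = stat_score(query, make_signature(genes), panel)
        assert res.n_reference_samples == 2  # panel size minus itself
        assert res.score is not None

    def test_degenerate_references_dropped(self):
        genes = [f"g{i}" for i in range(12)]
        profile = np.arange(12.0)
        panel = frame(
            np.column_stack([profile, np.full(12, 4.0)]),
            genes=genes,
            samples=["r1", "r2"],
        )
        query = pd.Series(profile, index=genes, name="q")
        res = stat_score(query, make_signature(genes), panel)
        assert res.score == pytest.approx(1.0) and res.n_reference_samples == 1
        flat_panel = frame(np.full((12, 1), 4.0), genes=genes, samples=["r1"])
        res2 = stat_score(query, make_signature(genes), flat_panel)
        assert res2.score is None and res2.reason == scoring.REASON_NO_REFERENCE


def make_score_table(means, control="ctrl"):
    cm = pd.DataFrame(means).T  # conditions x stats
    per_sample = pd.DataFrame(columns=["sample", "condition", "stat", "score",
                                       "n_genes_used", "n_reference_samples", "reason"])
    return ScoreTable(per_sample, cm, control)


class TestScoreFoldChange:
    def test_ratio_and_identity(self):
        table = make_score_table(
            {"ctrl": {"STAT3": 0.4}, "high": {"STAT3": 0.8}, "same": {"STAT3": 0.4}}
        )
        fc = score_fold_change(table).set_index("condition")
        assert fc.loc["high", "fold_change"] == pytest.approx(2.0)
        assert fc.loc["same", "fold_change"] == pytest.approx(1.0)
        assert fc.loc["high", "difference"] == pytest.approx(0.4)

    def test_near_zero_control_guarded(self):
        table = make_score_table({"ctrl": {"STAT3": 0.01}, "x": {"STAT3": 0.5}})
        fc = score_fold_change(table, epsilon=0.05).set_index("condition")
        assert np.isnan(fc.loc["x", "fold_change"])
        assert fc.loc["x", "reason"] == "control_mean_below_epsilon"
        assert fc.loc["x", "difference"] == pytest.approx(0.49)

    def test_unknown_control_rejected(self):
        table = make_score_table({"ctrl": {"STAT3": 0.4}})
        with pytest.raises(ValidationError):
            score_fold_change(table, control="missing")


class TestPcaScores:
    def test_rank_one_variance(self):
        scores = pd.DataFrame(
            {
                "STAT1": [0.1, 0.3, 0.5, 0.9],
                "STAT3": [0.2, 0.2, 0.2, 0.2],
                "STAT5": [0.4, 0.4, 0.4, 0.4],
            },
            index=list("abcd"),
        )
        coords, frac = pca_scores(scores)
        assert frac.iloc[0] == pytest.approx(1.0)
        assert frac.sum() == pytest.approx(1.0)

    def test_identical_rows_degenerate(self):
        scores = pd.DataFrame(np.ones((3, 4)), columns=list("wxyz"))
        with pytest.raises(DegenerateInputError):
            pca_scores(scores)

    def test_eigendecomposition_oracle(self):
        """SVD coordinates match a covariance-eigendecomposition oracle to 1e-8."""
        rng = np.random.default_rng(17)
        x = rng.random((12, 4))
        scores = pd.DataFrame(x, index=[f"s{i}" for i in range(12)],
                              columns=[f"STAT{k}" for k in (1, 3, 5, 6)])
        coords, frac = pca_scores(scores)
        xc = x - x.mean(axis=0)
        evals, evecs = np.linalg.eigh(xc.T @ xc)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        np.testing.assert_allclose(frac.to_numpy(), evals / evals.sum(), atol=1e-8)
        oracle = xc @ evecs
        for k in range(4):
            a, b = coords.iloc[:, k].to_numpy(), oracle[:, k]
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)

    def test_permuting_samples_permutes_coordinates(self):
        rng = np.random.default_rng(18)
        scores = pd.DataFrame(rng.random((8, 4)), index=[f"s{i}" for i in range(8)])
        coords, _ = pca_scores(scores)
        perm = list(reversed(scores.index))
        coords_p, _ = pca_scores(scores.loc[perm])
        pd.testing.assert_frame_equal(coords_p, coords.loc[perm])

    def test_incomplete_rows_dropped(self):
        rng = np.random.default_rng(19)
        scores = pd.DataFrame(rng.random((5, 3)), index=[f"s{i}" for i in range(5)])
        scores.iloc[2, 1] = np.nan
        coords, _ = pca_scores(scores)
        assert list(coords.index) == ["s0", "s1", "s3", "s4"]
        with pytest.raises(DegenerateInputError):
            pca_scores(scores.iloc[:3].assign(extra=np.nan))


@pytest.fixture(scope="module")
def scored(default_run):
    out, _ = default_run
    per_sample = pd.read_csv(out / "scores.tsv", sep="\t")
    cond = pd.read_csv(out / "condition_scores.tsv", sep="\t")
    return per_sample, cond


class TestScoreAllOnSimulation:
    def test_scores_bounded_and_reasoned(self, scored):
        per_sample, _ = scored
        present = per_sample["score"].dropna()
        assert present.between(-1, 1).all()
        missing = per_sample[per_sample["score"].isna()]
        assert (missing["reason"] != "").all()

    def test_target_stat_dominates_single_stat_chimera(self, scored):
        _, cond = scored
        wide = cond.pivot(index="condition", columns="stat", values="mean_score")
        row = wide.loc["chimera_STAT3_a100"]
        assert row.idxmax() == "STAT3"
        assert row["STAT3"] > max(row["STAT1"], row["STAT5"], row["STAT6"])

    def test_reference_self_exclusion_bookkeeping(self, scored):
        per_sample, _ = scored
        il10 = per_sample[
            (per_sample["condition"] == "IL10") & (per_sample["stat"] == "STAT3")
        ]
        # STAT3 panel = IL10 + IL21 samples (6); own sample excluded -> 5
        assert (il10["n_reference_samples"] == 5).all()
        assert il10["score"].notna().all()
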