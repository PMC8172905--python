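import numpy as np
import pandas as pd
import pytest

from rsikit.enrichment import (
    _walk_es,
    gsva_score,
    kernel_expression_statistic,
    z_and_call,
)
from rsikit.errors import ValidationError
from rsikit.io import ExpressionMatrix
from rsikit.signatures import GeneSet


def _random_stats(n_genes=60, n_samples=8, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.uniform(size=(n_genes, n_samples)),
        index=[f"G{i:03d}" for i in range(n_genes)],
        columns=[f"S{j}" for j in range(n_samples)],
    )


def test_kernel_statistic_is_monotone_in_expression():
    m = ExpressionMatrix(pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"],
                                      columns=["a", "b", "c"]))
    stats = kernel_expression_statistic(m)
    assert stats.loc["g", "a"] < stats.loc["g", "b"] < stats.loc["g", "c"]


def test_kernel_statistic_constant_gene_is_half():
    m = ExpressionMatrix(pd.DataFrame([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]],
                                      index=["flat", "g"],
                                      columns=["a", "b", "c"]))
    stats = kernel_expression_statistic(m)
    assert (stats.loc["flat"] == 0.5).all()


def test_kernel_statistic_shift_invariant_per_gene():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(5, 10))
    m = ExpressionMatrix(pd.DataFrame(X, columns=[f"S{j}" for j in range(10)]))
    shifted = X.copy()
    shifted[2] += 37.5
    m2 = ExpressionMatrix(pd.DataFrame(shifted,
                                       columns=[f"S{j}" for j in range(10)]))
    pd.testing.assert_frame_equal(kernel_expression_statistic(m),
                                  kernel_expression_statistic(m2))


def test_kernel_statistic_needs_three_samples():
    m = ExpressionMatrix(pd.DataFrame([[1.0, 2.0]], index=["g"],
                                      columns=["a", "b"]))
    with pytest.raises(ValidationError):
        kernel_expression_statistic(m)


def test_top_loaded_set_beats_random_sets_of_same_size():
    stats = _random_stats(seed=11)
    set_genes = stats.index[:10]
    stats.loc[set_genes] += 10.0  # set genes top the ranking in every sample
    gs = GeneSet("top", tuple(set_genes))
    es = gsva_score(stats, gs)
    assert (es > 0).all()
    rng = np.random.default_rng(0)
    for _ in range(50):
        rand = GeneSet("r", tuple(rng.choice(stats.index, 10, replace=False)))
        assert (es >= gsva_score(stats, rand)).all()


def test_bottom_loaded_set_scores_negative():
    stats = _random_stats(seed=12)
    set_genes = stats.index[:10]
    stats.loc[set_genes] -= 10.0
    es = gsva_score(stats, GeneSet("bottom", tuple(set_genes)))
    assert (es < 0).all()


def _unweighted_ks_oracle(stats, set_genes):
    """ECDF-difference oracle for the tau=0 walk (no cumulative-sum path)."""
    genes = np.asarray(stats.index)
    in_set = np.isin(genes, list(set_genes))
    p = len(genes)
    n_in = in_set.sum()
    out = {}
    for s in stats.columns:
        order = np.argsort(-stats[s].to_numpy(), kind="stable")
        ecdf_in = np.cumsum(in_set[order]) / n_in
        ecdf_out = np.cumsum(~in_set[order]) / (p - n_in)
        d = ecdf_in - ecdf_out
        out[s] = max(d.max(), 0) + min(d.min(), 0)
    return pd.Series(out)


def test_tau_zero_matches_unweighted_ks_oracle():
    stats = _random_stats(n_genes=80, seed=21)
    gs = GeneSet("s", tuple(stats.index[::7][:8]))
    es = gsva_score(stats, gs, tau=0)
    oracle = _unweighted_ks_oracle(stats, gs.genes)
    np.testing.assert_allclose(es.to_numpy(), oracle.to_numpy(), atol=1e-12)


def test_singleton_walk_matches_closed_form():
    # |set| = 1: es = 1 - 2(k0-1)/(p-1) where k0 is the gene's position
    p = 25
    rng = np.random.default_rng(5)
    weights = rng.uniform(0.5, 2.0, p)
    for k0 in (1, 5, 25):
        order = np.arange(p)
        in_set = np.zeros(p, bool)
        in_set[order[k0 - 1]] = True
        es = _walk_es(order, in_set, weights, "max_diff")
        assert es == pytest.approx(1 - 2 * (k0 - 1) / (p - 1))


def test_es_ignores_relabelling_outside_the_set():
    stats = _random_stats(seed=31)
    gs = GeneSet("s", tuple(stats.index[5:15]))
    relabelled = stats.rename(index={g: f"X{g}" for g in stats.index[40:]})
    pd.testing.assert_series_equal(gsva_score(stats, gs),
                                   gsva_score(relabelled, gs))


def test_absent_genes_dropped_with_warning_and_empty_set_errors(caplog):
    stats = _random_stats(seed=41)
    gs = GeneSet("s", tuple(stats.index[:5]) + ("NOT_THERE",))
    with caplog.at_level("WARNING", logger="rsikit.enrichment"):
        gsva_score(stats, gs)
    assert any("NOT_THERE" in r.message for r in caplog.records)
    with pytest.raises(ValidationError):
        gsva_score(stats, GeneSet("none", ("A1", "A2")))


def test_z_and_call_moments_and_threshold_monotonicity():
    rng = np.random.default_rng(2)
    es = pd.Series(rng.normal(size=200), index=[f"S{j}" for j in range(200)])
    res = z_and_call(es)
    assert res.table["z"].mean() == pytest.approx(0, abs=1e-12)
    assert res.table["z"].std(ddof=0) == pytest.approx(1, abs=1e-12)
    assert (res.table["enriched"] == (res.table["z"] > 0.35)).all()
    fractions = [z_and_call(es, thr).fraction_enriched
                 for thr in (0.0, 0.32, 0.35, 1.0, 2.0)]
    assert all(a >= b for a, b in zip(fractions, fractions[1:]))


def test_single_extreme_sample_is_the_only_enriched_call():
    es = pd.Series(np.r_[np.zeros(99) + np.linspace(-0.01, 0.01, 99), 5.0],
                   index=[f"S{j}" for j in range(100)])
    res = z_and_call(es, 0.35)
    assert res.table["enriched"].sum() == 1
    assert res.table.loc[res.table["enriched"], "sample_id"].iloc[0] == "S99"


def test_z_and_call_degenerate_inputs_error():
    with pytest.raises(ValidationError):
        z_and_call(pd.Series([1.0]))
    with pytest.raises(ValidationError):
        z_and_call(pd.Series([1.0, 1.0, 1.0]))
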