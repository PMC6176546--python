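"""Moderated t against an independent direct-formula oracle (and the
reference R implementation), BH-FDR, chi-square enrichment, co-expression
and clustering."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats as sps

from swathcomp import (
    AbundanceMatrix,
    Design,
    SimulationConfig,
    bh_adjust,
    call_significant,
    correlation_matrix,
    enrichment_chisq,
    enrichment_from_counts,
    fit_moderated_t,
    hierarchical_cluster,
    simulate_dataset,
)
from swathcomp.stats import trigamma_inverse


# ---------------------------------------------------------------------------
# independent oracle: a direct transcription of the moment equations using
# generic root-finding (brentq), no code shared with the implementation
# ---------------------------------------------------------------------------


def oracle_moderated_t(x: np.ndarray, n_a: int):
    n_b = x.shape[1] - n_a
    d = n_a + n_b - 2
    ma = x[:, :n_a].mean(axis=1)
    mb = x[:, n_a:].mean(axis=1)
    s2 = (
        ((x[:, :n_a] - ma[:, None]) ** 2).sum(axis=1)
        + ((x[:, n_a:] - mb[:, None]) ** 2).sum(axis=1)
    ) / d
    e = np.log(s2) - special.digamma(d / 2) + np.log(d / 2)
    target = np.var(e, ddof=1) - special.polygamma(1, d / 2)
    if target > 0:
        half_d0 = optimize.brentq(
            lambda y: special.polygamma(1, y) - target, 1e-8, 1e8, xtol=1e-14, rtol=1e-14
        )
        d0 = 2 * half_d0
        s0_sq = np.exp(e.mean() + special.digamma(half_d0) - np.log(half_d0))
        post = (d0 * s0_sq + d * s2) / (d0 + d)
        t = (ma - mb) / np.sqrt(post * (1 / n_a + 1 / n_b))
        p = 2 * sps.t.sf(np.abs(t), df=d + d0)
    else:  # infinite prior df
        d0, s0_sq = np.inf, float(np.exp(e.mean()))
        t = (ma - mb) / np.sqrt(s0_sq * (1 / n_a + 1 / n_b))
        p = 2 * sps.norm.sf(np.abs(t))
    return d0, s0_sq, t, p


def test_moderated_t_matches_direct_formula_oracle(fixture_matrix, fixture_design):
    table, model = fit_moderated_t(fixture_matrix, fixture_design)
    d0, s0_sq, t, p = oracle_moderated_t(fixture_matrix.data.to_numpy(), n_a=10)
    assert model.d0 == pytest.approx(d0, rel=1e-6)
    assert model.s0_sq == pytest.approx(s0_sq, rel=1e-6)
    np.testing.assert_allclose(table["t"].to_numpy(), t, rtol=1e-6)
    np.testing.assert_allclose(table["p_value"].to_numpy(), p, rtol=1e-6)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
def test_moderated_t_matches_limma(fixture_matrix, fixture_design, tmp_path):
    """Reference implementation cross-check on the shipped fixture."""
    path = tmp_path / "m.tsv"
    fixture_matrix.data.to_csv(path, sep="\t", index_label="feature")
    script = (
        'suppressMessages(library(limma));'
        f'x <- as.matrix(read.delim("{path}", row.names=1));'
        'g <- factor(c(rep("A",10), rep("B",10)), levels=c("B","A"));'
        'fit <- eBayes(lmFit(x, model.matrix(~g)));'
        f'write.table(data.frame(t=fit$t[,2], p=fit$p.value[,2], d0=fit$df.prior,'
        f' s02=fit$s2.prior), "{tmp_path}/out.tsv", sep="\\t", quote=FALSE)'
    )
    proc = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
    if proc.returncode != 0:
        pytest.skip(f"limma unavailable: {proc.stderr[-200:]}")
    ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
    table, model = fit_moderated_t(fixture_matrix, fixture_design)
    assert model.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
    assert model.s0_sq == pytest.approx(ref["s02"].iloc[0], rel=1e-6)
    np.testing.assert_allclose(table["t"].to_numpy(), ref["t"].to_numpy(), rtol=1e-6)
    np.testing.assert_allclose(table["p_value"].to_numpy(), ref["p"].to_numpy(), rtol=1e-6)


def test_prior_df_zero_recovers_classical_t(fixture_matrix, fixture_design):
    table, model = fit_moderated_t(fixture_matrix, fixture_design, prior_df=0)
    x = fixture_matrix.data.to_numpy()
    t_classic, p_classic = sps.ttest_ind(x[:, :10], x[:, 10:], axis=1, equal_var=True)[:2]
    np.testing.assert_allclose(table["t"].to_numpy(), t_classic, rtol=1e-10)
    np.testing.assert_allclose(table["p_value"].to_numpy(), p_classic, rtol=1e-10)
    assert model.df_total == 18


def test_prior_df_limits(fixture_matrix, fixture_design):
    """d0 -> 0 gives the classical t; d0 -> inf a z-statistic with the prior
    variance."""
    x = fixture_matrix.data.to_numpy()
    table_inf, model_inf = fit_moderated_t(fixture_matrix, fixture_design, prior_df=np.inf)
    z = (x[:, :10].mean(axis=1) - x[:, 10:].mean(axis=1)) / np.sqrt(
        model_inf.s0_sq * (1 / 10 + 1 / 10)
    )
    np.testing.assert_allclose(table_inf["t"].to_numpy(), z, rtol=1e-10)
    # large finite d0 approaches the infinite limit continuously
    table_big, _ = fit_moderated_t(fixture_matrix, fixture_design, prior_df=1e9)
    np.testing.assert_allclose(table_big["t"].to_numpy(), z, rtol=1e-4)


def test_identical_group_means_give_t_zero_p_one():
    x = np.array(
        [[5.0, 6.0, 5.0, 6.0], [1.0, 1.0, 1.0, 1.0], [2.0, 4.0, 7.0, 9.0]]
    )
    mat = AbundanceMatrix(
        pd.DataFrame(x, index=["g1", "g2", "g3"], columns=["a1", "a2", "b1", "b2"]),
        scale="log2",
    )
    design = Design(
        pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "b1", "b2"],
                "species": ["x", "x", "y", "y"],
                "group": ["A", "A", "B", "B"],
            }
        ),
        contrast=("A", "B"),
    )
    table, _ = fit_moderated_t(mat, design)
    assert table.loc["g1", "t"] == 0.0
    assert table.loc["g1", "p_value"] == 1.0
    assert table.loc["g2", "t"] == 0.0 and table.loc["g2", "p_value"] == 1.0


def test_all_identical_variances_give_infinite_prior():
    rng = np.random.default_rng(0)
    # every gene has exactly the same within-group sample pattern -> equal s^2
    pattern = rng.normal(0, 1, 6)
    x = np.add.outer(rng.normal(10, 2, 30), pattern)
    mat = AbundanceMatrix(
        pd.DataFrame(x, columns=[f"s{i}" for i in range(6)]), scale="log2"
    )
    design = Design(
        pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(6)],
                "species": ["x"] * 3 + ["y"] * 3,
                "group": ["A"] * 3 + ["B"] * 3,
            }
        ),
        contrast=("A", "B"),
    )
    table, model = fit_moderated_t(mat, design)
    assert np.isinf(model.d0)
    assert np.isfinite(table["t"]).all()


def test_trigamma_inverse_roundtrip():
    for y in [1e-5, 0.1, 1.0, 7.3, 500.0]:
        x = float(special.polygamma(1, y))
        assert trigamma_inverse(x) == pytest.approx(y, rel=1e-6)


# ---------------------------------------------------------------------------
# BH and significance calls
# ---------------------------------------------------------------------------


def test_bh_hand_example_and_properties():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    np.testing.assert_allclose(bh_adjust([0.5]), [0.5])
    rng = np.random.default_rng(1)
    p = rng.random(500) ** 2
    adj = bh_adjust(p)
    assert (adj >= p).all() and (adj <= 1.0).all()
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


def test_call_significant_boundary_inclusive():
    table = pd.DataFrame(
        {
            "gene": ["g1", "g2", "g3"],
            "log2fc": [1.0, -1.0, 0.1],
            "direction": ["higher_in_A", "higher_in_B", "higher_in_A"],
            "adj_p_value": [0.005, 0.0049, 0.5],
        }
    )
    out, counts = call_significant(table, alpha=0.005)
    assert out["significant"].tolist() == [True, True, False]
    assert counts == {"unchanged": 1, "higher_in_A": 1, "higher_in_B": 1}


def test_null_simulation_controls_significance_rate():
    config = SimulationConfig(seed=101, n_genes=2000, de_fraction=0.0)
    dataset = simulate_dataset(config)
    from swathcomp import report_to_peptide_matrix, rollup_to_proteins, total_area_normalize

    matrix, gene_map = report_to_peptide_matrix(dataset.report)
    protein = rollup_to_proteins(total_area_normalize(matrix), gene_map).to_log2()
    design = Design(dataset.design, contrast=("rodent", "primate"))
    table, _ = fit_moderated_t(protein, design)
    table, counts = call_significant(table, alpha=0.005)
    assert table["significant"].mean() <= 0.01


# ---------------------------------------------------------------------------
# chi-square enrichment
# ---------------------------------------------------------------------------


def chisq_oracle(a, b, c, d):
    """Closed form N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    n = a + b + c + d
    stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return stat, float(sps.chi2.sf(stat, df=1))


def test_balanced_table_gives_zero_statistic():
    res = enrichment_from_counts(10, 20, 20, 40)
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)
    assert res.table.tolist() == [[10, 10], [10, 10]]


def test_chisq_matches_closed_form_oracle_exhaustively():
    rng = np.random.default_rng(2)
    for _ in range(300):
        a, b, c, d = rng.integers(1, 51, size=4)
        res = enrichment_from_counts(int(a), int(a + b), int(a + c), int(a + b + c + d))
        stat, p = chisq_oracle(int(a), int(b), int(c), int(d))
        assert res.statistic == pytest.approx(stat, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-9)


def test_enrichment_from_flags_and_validation():
    flags = pd.Series(
        [True, True, False, False, True, False],
        index=["A", "B", "C", "D", "E", "F"],
    )
    res = enrichment_chisq(flags, {"A", "B", "C"})
    assert res.table.sum() == 6
    assert res.table[0, 0] == 2  # A, B
    with pytest.raises(ValueError, match="overlap"):
        enrichment_chisq(flags, {"Z"})
    with pytest.raises(ValueError, match="universe"):
        enrichment_chisq(pd.Series(dtype=bool), {"A"})


def test_odds_ratio_haldane_on_zero_cell():
    res = enrichment_from_counts(0, 10, 10, 40)
    expected = (0.5 * 20.5) / (10.5 * 10.5)
    assert res.odds_ratio == pytest.approx(expected)


# ---------------------------------------------------------------------------
# co-expression and clustering
# ---------------------------------------------------------------------------


def test_correlation_matrix_proportional_and_antiproportional():
    samples = [f"s{i}" for i in range(5)]
    base = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
    data = pd.DataFrame(
        {s: [base[i], 3 * base[i], 1 / base[i]] for i, s in enumerate(samples)},
        index=["g1", "g2", "g3"],
    )
    corr = correlation_matrix(AbundanceMatrix(data, scale="linear"))
    assert corr.loc["g1", "g1"] == 1.0
    assert corr.loc["g1", "g2"] == pytest.approx(1.0)  # proportional -> r=1 on log scale
    assert corr.loc["g1", "g3"] == pytest.approx(-1.0)
    with pytest.raises(ValueError, match="not in matrix"):
        correlation_matrix(AbundanceMatrix(data, scale="linear"), genes=["nope"])


def test_cluster_duplicates_merge_first():
    rng = np.random.default_rng(3)
    x = rng.normal(10, 2, (50, 4))
    x[:, 1] = x[:, 0]  # exact duplicate samples
    mat = AbundanceMatrix(
        pd.DataFrame(x, columns=["s1", "s2", "s3", "s4"]), scale="log2"
    )
    result = hierarchical_cluster(mat)
    first_merge = result.linkage[0]
    merged = {result.labels[int(first_merge[0])], result.labels[int(first_merge[1])]}
    assert merged == {"s1", "s2"}
    assert first_merge[2] == pytest.approx(0.0, abs=1e-12)
    assert result.newick.endswith(";")


def test_cluster_recovers_species_at_low_noise():
    config = SimulationConfig(seed=51, n_genes=300, species_effect_sd=1.0, noise_cv=0.1)
    dataset = simulate_dataset(config)
    from swathcomp import report_to_peptide_matrix, rollup_to_proteins

    matrix, gene_map = report_to_peptide_matrix(dataset.report)
    protein = rollup_to_proteins(matrix, gene_map)
    result = hierarchical_cluster(protein)
    cut = result.cut(4)
    species_of = dataset.design.set_index("sample_id")["species"]
    clusters_by_species = {
        sp: {cut[s] for s in species_of.index[species_of == sp]}
        for sp in species_of.unique()
    }
    labels = [next(iter(v)) for v in clusters_by_species.values()]
    assert all(len(v) == 1 for v in clusters_by_species.values())
    assert len(set(labels)) == 4


def test_cluster_invariant_to_sample_order():
    rng = np.random.default_rng(5)
    x = pd.DataFrame(rng.normal(10, 1, (100, 6)), columns=list("fedcba"))
    a = hierarchical_cluster(AbundanceMatrix(x, scale="log2"))
    b = hierarchical_cluster(AbundanceMatrix(x[list("abcdef")], scale="log2"))
    assert a.newick == b.newick
    np.testing.assert_allclose(a.linkage, b.linkage)
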