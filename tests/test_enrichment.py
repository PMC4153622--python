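"""Outlier target calling, TF correlation ranking, and Fisher enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from oracles import hypergeom_two_sided
from senotf import (
    ExpressionMatrix,
    background_stats,
    candidate_targets,
    correlate_tf_targets,
    fisher_enrichment,
    fisher_two_sided_p,
    permutation_enrichment,
    rank_tfs,
)
from senotf.enrichment import any_site_targets


def _occ(counts: dict[str, list[int]], genes: list[str]) -> pd.DataFrame:
    return pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"))


def test_background_stats_sample_sd():
    occ = _occ({"m": [0, 1, 2, 3, 4]}, [f"g{i}" for i in range(5)])
    bg = background_stats(occ)
    assert bg.loc["m", "mean"] == pytest.approx(2.0)
    assert bg.loc["m", "sd"] == pytest.approx(np.sqrt(2.5))
    const = _occ({"m": [2, 2, 2]}, ["a", "b", "c"])
    bgc = background_stats(const)
    assert bgc.loc["m", "sd"] == 0.0
    with pytest.raises(ValueError):
        background_stats(_occ({"m": [1]}, ["a"]))


def test_candidate_targets_strict_mean_sd_rule():
    genes = [f"g{i}" for i in range(5)]
    occ = _occ({"m": [0, 1, 2, 3, 4]}, genes)
    cands = candidate_targets(occ, background_stats(occ))
    # thresholds 2 +- 1.5811: only counts 0 and 4 are outliers
    assert cands["m"] == {"g0", "g4"}
    const = _occ({"m": [2, 2, 2]}, ["a", "b", "c"])
    assert candidate_targets(const, background_stats(const))["m"] == set()
    # a count exactly at mean + SD is not a candidate (strict inequality)
    occ_b = _occ({"m": [0, 2, 2, 4]}, ["a", "b", "c", "d"])
    bg_b = background_stats(occ_b)
    assert bg_b.loc["m", "upper"] == pytest.approx(2 + np.sqrt(8 / 3))
    edge = _occ({"m": [1, 1, 1, 3]}, ["a", "b", "c", "d"])  # mean 1.5, sd 1
    cands_edge = candidate_targets(edge, background_stats(edge))
    assert cands_edge["m"] == {"d"}  # 3 > 2.5; the 1s are not < 0.5


def test_candidate_targets_invariant_under_promoter_permutation():
    rng = np.random.default_rng(5)
    genes = [f"g{i}" for i in range(50)]
    occ = _occ({"m": rng.poisson(2, 50).tolist()}, genes)
    perm = occ.sample(frac=1, random_state=1)
    c1 = candidate_targets(occ, background_stats(occ))
    c2 = candidate_targets(perm, background_stats(perm))
    assert c1 == c2


def _expr(values: dict[str, list[float]]) -> ExpressionMatrix:
    cols = len(next(iter(values.values())))
    samples = pd.DataFrame(
        {"sample_id": [f"s{i}" for i in range(cols)],
         "group": ["G1"] * (cols // 2) + ["G2"] * (cols - cols // 2),
         "replicate": list(range(cols))}
    ).set_index("sample_id")
    vals = pd.DataFrame(values, index=samples.index).T
    return ExpressionMatrix(vals, samples)


def test_correlation_identical_negated_and_closed_form():
    tf = list(range(1, 10))
    expr = _expr({
        "TF": [float(x) for x in tf],
        "same": [float(x) for x in tf],
        "anti": [float(x) for x in reversed(tf)],
        "flat": [1.0] * 9,
    })
    res = correlate_tf_targets(expr, "TF", {"same", "anti", "flat", "missing"})
    assert res.r["same"] == pytest.approx(1.0)
    assert res.r["anti"] == pytest.approx(-1.0)
    assert res.n_correlated == 2  # anti-correlation counts; flat is NaN r
    assert res.n_skipped == 1
    with pytest.raises(ValueError):
        correlate_tf_targets(expr, "nope", {"same"})


def test_rank_tfs_tie_breaking_and_invariance():
    report = pd.DataFrame({
        "tf_gene_id": ["tfD", "tfB", "tfC", "tfA"],
        "n_correlated": [1, 3, 3, 5],
        "p": [0.9, 0.5, 0.01, 0.2],
    }, index=["m4", "m2", "m3", "m1"])
    ranked = rank_tfs(report)
    assert list(ranked["tf_gene_id"]) == ["tfA", "tfC", "tfB", "tfD"]
    assert list(ranked["rank"]) == [1, 2, 3, 4]
    shuffled = rank_tfs(report.sample(frac=1, random_state=0))
    assert list(shuffled["tf_gene_id"]) == list(ranked["tf_gene_id"])
    single = rank_tfs(report.iloc[:1])
    assert list(single["rank"]) == [1]


def test_fisher_two_sided_matches_scipy_and_oracle(rng):
    for _ in range(200):
        a, b, c, d = (int(x) for x in rng.integers(0, 40, 4))
        p = fisher_two_sided_p(a, b, c, d)
        assert p == pytest.approx(fisher_exact([[a, b], [c, d]])[1], rel=1e-9, abs=1e-12)
        assert p == pytest.approx(hypergeom_two_sided(a, b, c, d), rel=1e-9, abs=1e-12)


def test_fisher_enrichment_table_and_conventions():
    universe = {f"g{i}" for i in range(550)}
    de = {f"g{i}" for i in range(50)}
    # proportional table: 5/45 in DE vs 50/450 outside -> OR 1, p 1
    target = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(100, 150)}
    rep = fisher_enrichment({"m": target}, de, universe)
    assert rep.loc["m", "odds_ratio"] == pytest.approx(1.0)
    assert rep.loc["m", "p"] == pytest.approx(1.0)
    assert not rep.loc["m", "enriched"]
    # margins conserved
    assert rep.loc["m", "a"] + rep.loc["m", "b"] == len(de)
    assert rep.loc["m", "c"] + rep.loc["m", "d"] == len(universe) - len(de)
    # a = 0 -> OR 0, never enriched
    rep0 = fisher_enrichment({"m": {"g100"}}, de, universe)
    assert rep0.loc["m", "odds_ratio"] == 0.0 and not rep0.loc["m", "enriched"]
    # empty DE set -> p = 1 by convention
    rep_e = fisher_enrichment({"m": target}, set(), universe)
    assert rep_e.loc["m", "p"] == 1.0
    with pytest.raises(ValueError):
        fisher_enrichment({"m": target}, de, set())
    with pytest.raises(ValueError):
        fisher_enrichment({"m": target}, {"not_in_universe"}, universe)


def test_fisher_enrichment_detects_planted_association():
    universe = {f"g{i}" for i in range(400)}
    de = {f"g{i}" for i in range(100)}
    target = {f"g{i}" for i in range(80)} | {f"g{i}" for i in range(390, 395)}
    rep = fisher_enrichment({"m": target}, de, universe)
    assert rep.loc["m", "enriched"]
    assert rep.loc["m", "odds_ratio"] > 1


def test_any_site_targets():
    occ = _occ({"m": [0, 1, 5]}, ["a", "b", "c"])
    assert any_site_targets(occ)["m"] == {"b", "c"}


def test_permutation_enrichment_detects_planted_and_handles_empty(rng):
    genes = [f"g{i}" for i in range(200)]
    counts = np.zeros(200, dtype=int)
    counts[:40] = rng.poisson(3, 40)      # DE genes carry more sites
    counts[40:] = rng.poisson(0.2, 160)
    occ = _occ({"m": counts.tolist(), "null": rng.poisson(1, 200).tolist()}, genes)
    de = set(genes[:40])
    rep = permutation_enrichment(occ, de, n_rounds=2000, seed=3)
    assert rep.loc["m", "p"] < 0.01 and rep.loc["m", "enriched"]
    assert rep.loc["null", "p"] > 0.05
    empty = permutation_enrichment(occ, set(), n_rounds=10, seed=0)
    assert (empty["p"] == 1.0).all()
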