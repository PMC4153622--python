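"""Synthetic-data generators: contracts, determinism, recorded truth."""

import numpy as np
import pandas as pd
import pytest

from senotf import (
    IUPACMotif,
    SimulationConfig,
    generate_ct_table,
    generate_expression,
    generate_promoters,
    normalize_nrq,
    plant_motif,
    scan,
)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_genes=0)
    with pytest.raises(ValueError):
        SimulationConfig(de_fraction=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(gc_content=-0.1)


def test_promoter_length_and_alphabet():
    cfg = SimulationConfig(n_genes=3, n_promoters=3, promoter_length=1000, seed=1)
    proms = generate_promoters(cfg)
    assert len(proms) == 3
    assert all(len(seq) == 1000 for _, seq in proms.items())


def test_gc_boundary_all_gc():
    cfg = SimulationConfig(n_genes=2, n_promoters=2, promoter_length=200,
                           gc_content=1.0, seed=1)
    proms = generate_promoters(cfg)
    assert all(set(seq) <= {"G", "C"} for _, seq in proms.items())


def test_empirical_gc_within_three_binomial_sds():
    cfg = SimulationConfig(n_genes=2000, n_promoters=2000, promoter_length=1000,
                           gc_content=0.4, seed=7)
    proms = generate_promoters(cfg)
    n_bases = 2000 * 1000
    gc = sum(seq.count("G") + seq.count("C") for _, seq in proms.items()) / n_bases
    sd = np.sqrt(0.4 * 0.6 / n_bases)
    assert abs(gc - 0.4) < 3 * sd


def test_generators_are_deterministic_under_seed():
    cfg = SimulationConfig(n_genes=50, n_promoters=50, promoter_length=100, seed=5)
    p1, p2 = generate_promoters(cfg), generate_promoters(cfg)
    assert dict(p1.items()) == dict(p2.items())
    (m1, t1), (m2, t2) = generate_expression(cfg), generate_expression(cfg)
    assert m1.values.equals(m2.values) and t1.equals(t2)


def test_plant_zero_rate_leaves_sequences_unchanged():
    cfg = SimulationConfig(n_genes=10, n_promoters=10, promoter_length=100,
                           plant_rate_target=0.0, plant_rate_background=0.0, seed=3)
    proms = generate_promoters(cfg)
    before = dict(proms.items())
    planted, counts = plant_motif(proms, IUPACMotif("tf", "ACGT"),
                                  set(proms.ids[:5]), cfg)
    assert dict(planted.items()) == before
    assert all(v == 0 for v in counts.values())


def test_planted_sites_are_findable_and_length_preserved():
    cfg = SimulationConfig(n_genes=20, n_promoters=20, promoter_length=1000,
                           plant_rate_target=3.0, plant_rate_background=0.0, seed=9)
    proms = generate_promoters(cfg)
    motif = IUPACMotif("tf", "TTTSSCGC")
    planted, counts = plant_motif(proms, motif, set(proms.ids), cfg)
    for gid, seq in planted.items():
        assert len(seq) == 1000
        # >= because chance background matches may add to the planted ones
        assert len(scan(seq, motif, "forward")) >= counts[gid]


def test_total_planted_count_within_three_poisson_sds():
    cfg = SimulationConfig(n_genes=100, n_promoters=100, promoter_length=1000,
                           plant_rate_target=3.0, plant_rate_background=0.0, seed=21)
    proms = generate_promoters(cfg)
    _, counts = plant_motif(proms, IUPACMotif("tf", "CACGTG"), set(proms.ids), cfg)
    total = sum(counts.values())
    assert abs(total - 300) < 3 * np.sqrt(300)


def test_de_count_uses_round_half_to_even():
    assert SimulationConfig(n_genes=5000, de_fraction=0.1).n_de == 500
    # 2.5 -> 2 and 3.5 -> 4 under banker's rounding
    assert SimulationConfig(n_genes=10, de_fraction=0.25).n_de == 2
    assert SimulationConfig(n_genes=14, de_fraction=0.25).n_de == 4


def test_expression_truth_and_noiseless_limit():
    cfg = SimulationConfig(n_genes=200, de_fraction=0.2, effect_size=1.0,
                           noise_sd=0.0, seed=13)
    matrix, truth = generate_expression(cfg)
    assert len(truth) == 200 and truth["is_de"].sum() == 40
    lfc = (matrix.group_values("PD54").mean(axis=1)
           - matrix.group_values("PD38").mean(axis=1))
    assert np.allclose(lfc, truth["true_log2fc_PD54"], atol=1e-12)
    # effect_size=0 => no gene has a nonzero true fold change
    cfg0 = SimulationConfig(n_genes=50, de_fraction=0.2, effect_size=0.0, seed=13)
    _, truth0 = generate_expression(cfg0)
    assert (truth0.filter(like="true_log2fc").abs().to_numpy() == 0).all()


def test_ct_table_closed_forms():
    # true fold 2 at E=2 and zero noise: target Ct exactly 1 cycle lower
    ct = generate_ct_table({"TGT": {"PD47": 2.0, "PD54": 2.0}},
                           ["REF1"], {"TGT": 2.0, "REF1": 2.0},
                           noise_sd=0.0, seed=1)
    tech = ct.groupby(["group", "gene_id", "sample_id"])["Ct"].mean().reset_index()
    # loading factors differ per sample; compare target against the reference
    # gene within the same sample, where loading cancels
    piv = tech.pivot(index="sample_id", columns="gene_id", values="Ct")
    grp = ct.drop_duplicates("sample_id").set_index("sample_id")["group"]
    dct = (piv["REF1"] - piv["TGT"]).groupby(grp).mean()
    assert np.isclose(dct["PD47"] - dct["PD38"], 1.0, atol=1e-9)
    # fold 1.5 at E=1.9: delta-Ct = log(1.5)/log(1.9)
    ct2 = generate_ct_table({"TGT": {"PD47": 1.5}}, ["REF1"],
                            {"TGT": 1.9, "REF1": 1.9}, noise_sd=0.0, seed=2,
                            groups=("PD38", "PD47"))
    piv2 = (ct2.groupby(["sample_id", "gene_id"])["Ct"].mean().unstack())
    grp2 = ct2.drop_duplicates("sample_id").set_index("sample_id")["group"]
    dct2 = (piv2["REF1"] - piv2["TGT"]).groupby(grp2).mean()
    assert np.isclose(dct2["PD47"] - dct2["PD38"], np.log(1.5) / np.log(1.9), atol=1e-9)


def test_ct_table_all_folds_one_gives_unit_nrq():
    ct = generate_ct_table({"TGT": {}}, ["REF1", "REF2"],
                           {"TGT": 2.0, "REF1": 2.0, "REF2": 2.0},
                           noise_sd=0.0, seed=4)
    nrq = normalize_nrq(ct, ["TGT"], ["REF1", "REF2"], "PD38")
    assert np.allclose(nrq["nrq"], 1.0, atol=1e-9)


def test_ct_table_rejects_bad_inputs():
    with pytest.raises(ValueError):
        generate_ct_table({"TGT": {"PD47": -1.0}}, ["R"], {"TGT": 2.0, "R": 2.0})
    with pytest.raises(ValueError):
        generate_ct_table({"TGT": {}}, ["R"], {"TGT": 2.5, "R": 2.0})
    with pytest.raises(ValueError):
        generate_ct_table({"TGT": {}}, [], {"TGT": 2.0})
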