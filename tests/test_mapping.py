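"""cis scan vs closed-form OLS, BH step-up oracle equivalence, eSNP selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

import eqtloverlap as eo
from eqtloverlap.mapping import bh_fdr, call_eqtls, cis_scan, weighted_z_meta
from eqtloverlap.pipeline import map_study


def scan_inputs(dosages, expr_rows, tss=0):
    """One gene, variants at positions 0, 1000, 2000, ..."""
    dosages = np.asarray(dosages)
    v = dosages.shape[0]
    geno = pd.DataFrame(dosages, index=[f"v{k}" for k in range(v)],
                        columns=[f"ind{k}" for k in range(dosages.shape[1])])
    vinfo = pd.DataFrame({"chrom": "chr1", "pos": np.arange(v) * 1000},
                         index=geno.index)
    expr_rows = np.atleast_2d(np.asarray(expr_rows, float))
    expr = pd.DataFrame(expr_rows, index=[f"g{k}" for k in range(len(expr_rows))],
                        columns=geno.columns)
    ann = pd.DataFrame({"gene_id": expr.index, "chrom": "chr1", "tss": tss})
    return geno, expr, ann, vinfo


def test_noiseless_fit_recovers_slope_exactly():
    dosage = np.array([[0, 1, 2, 0, 1, 2, 1, 0, 2, 1]])
    geno, expr, ann, vinfo = scan_inputs(dosage, 2.0 * dosage[0])
    rec = cis_scan(geno, expr, ann, variant_info=vinfo)
    assert len(rec) == 1
    assert rec["beta"].iloc[0] == pytest.approx(2.0)
    assert rec["p_value"].iloc[0] < 1e-12


def test_monomorphic_variant_skipped():
    dosage = np.array([[1, 1, 1, 1, 1, 1], [0, 1, 2, 0, 1, 2]])
    geno, expr, ann, vinfo = scan_inputs(dosage, [0.1, 0.9, 2.1, -0.1, 1.2, 1.8])
    rec = cis_scan(geno, expr, ann, variant_info=vinfo)
    assert set(rec["variant_id"]) == {"v1"}


def test_six_point_dataset_matches_closed_form_ols():
    dosage = np.array([[0, 0, 1, 1, 2, 2]])
    y = [0.1, -0.2, 0.9, 1.1, 2.2, 1.9]
    geno, expr, ann, vinfo = scan_inputs(dosage, y)
    rec = cis_scan(geno, expr, ann, variant_info=vinfo).iloc[0]
    lr = sps.linregress(dosage[0], y)
    assert rec["beta"] == pytest.approx(lr.slope, rel=1e-12)
    assert rec["se"] == pytest.approx(lr.stderr, rel=1e-10)
    assert rec["p_value"] == pytest.approx(lr.pvalue, rel=1e-10)
    # p consistent with the t statistic at n-2 df
    p_from_t = 2 * sps.t.sf(abs(rec["t_stat"]), 4)
    assert rec["p_value"] == pytest.approx(p_from_t, rel=1e-10)


def test_scan_matches_linregress_on_random_inputs(rng):
    for _ in range(25):
        n = int(rng.integers(4, 51))
        n_var = int(rng.integers(1, 5))
        n_gene = int(rng.integers(1, 4))
        dosage = rng.integers(0, 3, (n_var, n))
        if any(len(np.unique(row)) == 1 for row in dosage):
            continue
        expr_rows = rng.normal(size=(n_gene, n))
        geno, expr, ann, vinfo = scan_inputs(dosage, expr_rows)
        rec = cis_scan(geno, expr, ann, variant_info=vinfo)
        assert len(rec) == n_var * n_gene
        for row in rec.itertuples():
            g = int(row.gene_id[1:])
            v = int(row.variant_id[1:])
            lr = sps.linregress(dosage[v], expr_rows[g])
            assert row.beta == pytest.approx(lr.slope, rel=1e-9, abs=1e-12)
            assert row.p_value == pytest.approx(lr.pvalue, rel=1e-7, abs=1e-15)


def test_scan_requires_overlapping_individuals():
    geno, expr, ann, vinfo = scan_inputs(np.array([[0, 1, 2, 1]]), [1., 2., 3., 4.])
    expr.columns = ["x1", "x2", "x3", "x4"]
    with pytest.raises(ValueError, match="overlapping individuals"):
        cis_scan(geno, expr, ann, variant_info=vinfo)


def test_zero_variance_gene_skipped(caplog):
    import logging
    dosage = np.array([[0, 1, 2, 0, 1, 2]])
    geno, expr, ann, vinfo = scan_inputs(dosage, [[1, 1, 1, 1, 1, 1],
                                                  [0.1, 0.5, 1.9, 0.2, 1.0, 2.2]])
    with caplog.at_level(logging.WARNING):
        rec = cis_scan(geno, expr, ann, variant_info=vinfo)
    assert set(rec["gene_id"]) == {"g1"}


@pytest.mark.parametrize("p_values,q,n_reject,cutoff", [
    ([1.0, 1.0, 1.0], 0.05, 0, 0.0),
    ([0.01, 0.02, 0.03, 0.5], 0.05, 3, 0.03),
    ([0.04], 0.05, 1, 0.04),
])
def test_bh_step_up_hand_examples(p_values, q, n_reject, cutoff):
    reject, cut = bh_fdr(p_values, q)
    assert reject.sum() == n_reject
    assert cut == pytest.approx(cutoff)


def test_bh_empty_input():
    reject, cut = bh_fdr([], 0.05)
    assert reject.size == 0 and cut == 0.0


def bh_bruteforce(p, q):
    """Literal step-up definition, quadratic and slow on purpose."""
    p = np.asarray(p)
    m = len(p)
    ps = np.sort(p)
    k_star = 0
    for k in range(1, m + 1):
        if ps[k - 1] <= k * q / m:
            k_star = k
    if k_star == 0:
        return np.zeros(m, bool), 0.0
    return p <= ps[k_star - 1], ps[k_star - 1]


@given(st.lists(st.floats(1e-8, 1.0, exclude_min=False), min_size=1, max_size=60),
       st.sampled_from([0.01, 0.05, 0.1, 0.3]))
def test_bh_matches_bruteforce_and_statsmodels(p, q):
    reject, cut = bh_fdr(p, q)
    brute, brute_cut = bh_bruteforce(p, q)
    np.testing.assert_array_equal(reject, brute)
    assert cut == pytest.approx(brute_cut)
    sm_reject = multipletests(p, alpha=q, method="fdr_bh")[0]
    np.testing.assert_array_equal(reject, sm_reject)


@given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=40))
def test_bh_rejections_monotone_in_q(p):
    r1, _ = bh_fdr(p, 0.05)
    r2, _ = bh_fdr(p, 0.2)
    assert (r1 <= r2).all()


def _records(rows):
    return pd.DataFrame(rows, columns=["gene_id", "variant_id", "beta", "se",
                                       "t_stat", "p_value", "n",
                                       "distance_to_tss"])


def test_call_eqtls_picks_smallest_p_per_gene():
    rec = _records([
        ("g1", "a", 1, .1, 10, 1e-8, 50, 100),
        ("g1", "b", 1, .1, 10, 1e-6, 50, 50),
        ("g2", "c", 1, .1, 10, 0.9, 50, 10),
    ])
    study = call_eqtls(rec, q=0.05)
    assert dict(zip(study.records["gene_id"], study.records["variant_id"])) == {"g1": "a"}
    assert study.n_genes_with_eqtl == 1


def test_call_eqtls_tie_breaks_on_distance_then_id():
    rec = _records([
        ("g1", "far", 1, .1, 10, 1e-6, 50, 50_000),
        ("g1", "near", 1, .1, 10, 1e-6, 50, 5_000),
        ("g1", "near2", 1, .1, 10, 1e-6, 50, -5_000),
    ])
    study = call_eqtls(rec, q=0.05)
    assert study.records["variant_id"].iloc[0] == "near"  # |dist| tie -> lexicographic


def test_null_simulation_calls_few_genes():
    cfg = eo.SimulationConfig(n_genes=1000, n_individuals_i=150,
                              n_individuals_j=40, effect_beta=0.0,
                              n_haplotypes=400, seed=1)
    panel = eo.simulate_haplotype_panel(cfg)
    raw_i, *_ = eo.simulate_study_pair(panel, cfg)
    study = map_study(raw_i)
    frac = study.n_genes_with_eqtl / study.n_probes_tested
    assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / study.n_probes_tested)


@pytest.mark.parametrize("distance,expected", [
    (0, "cis"), (1_000_000, "cis"), (1_000_001, "trans"), (-999_999, "cis"),
])
def test_cis_trans_boundaries(distance, expected):
    ann = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"], "tss": [5_000_000]})
    record = {"gene_id": "g", "distance_to_tss": distance}
    assert eo.classify_cis_trans(record, ann) == expected


def test_cis_trans_other_chromosome_is_trans():
    ann = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"], "tss": [100]})
    record = {"gene_id": "g", "distance_to_tss": 0}
    assert eo.classify_cis_trans(record, ann, variant_chrom="chr2") == "trans"
    with pytest.raises(KeyError):
        eo.classify_cis_trans({"gene_id": "nope", "distance_to_tss": 0}, ann)


def test_weighted_z_examples():
    assert weighted_z_meta([1.7], [200]) == pytest.approx(1.7)
    assert weighted_z_meta([2, 2], [100, 100]) == pytest.approx(2.828427, abs=1e-6)
    assert weighted_z_meta([2, -2], [100, 100]) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        weighted_z_meta([1, 2], [100])
    with pytest.raises(ValueError):
        weighted_z_meta([1.0], [0])


def test_weighted_z_amplifies_concordant_signal():
    z = weighted_z_meta([1.5, 1.5, 1.5], [120, 80, 200])
    assert z >= 1.5


def test_study_from_summary_table():
    t = pd.DataFrame({
        "gene_id": ["g1", "g1", "g2"], "variant_id": ["a", "b", "c"],
        "p_value": [1e-6, 1e-4, 1e-5], "n_samples": [100, 100, 100],
    })
    study = eo.EqtlStudy.from_table(t, study_id="ext")
    assert study.n_genes_with_eqtl == 2
    assert study.alpha == pytest.approx(1e-4)
    assert study.best_esnp()["g1"] == "a"
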