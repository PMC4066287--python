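"""Generator properties: determinism, MAF, LD structure, sharing fraction, I/O."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import eqtloverlap as eo
from eqtloverlap.ld import read_haplotypes
from eqtloverlap.simulate import read_fixture_study, write_fixture_set


@pytest.mark.parametrize("field,value,message", [
    ("n_genes", 0, "n_genes"),
    ("pi_true", 1.5, "pi_true"),
    ("maf_range", (0.0, 0.5), "maf_range"),
    ("maf_range", (0.1, 0.6), "maf_range"),
    ("noise_sd", -1.0, "noise_sd"),
    ("n_haplotypes", 401, "even"),
    ("tissue_activity", "weird", "tissue_activity"),
    ("shared_beta_multiplier", -0.5, "shared_beta_multiplier"),
])
def test_config_validation_names_offending_field(field, value, message):
    with pytest.raises(ValueError, match=message):
        eo.SimulationConfig(**{field: value})


def test_same_seed_reproduces_everything():
    cfg = eo.SimulationConfig(n_genes=40, n_individuals_i=60, n_individuals_j=30,
                              n_haplotypes=200, seed=42)
    p1, p2 = eo.simulate_haplotype_panel(cfg), eo.simulate_haplotype_panel(cfg)
    assert np.array_equal(p1.haplotypes, p2.haplotypes)
    assert np.array_equal(p1.pos, p2.pos)
    a1 = eo.simulate_study_pair(p1, cfg)
    a2 = eo.simulate_study_pair(p2, cfg)
    for r1, r2 in zip(a1[:2], a2[:2]):
        assert np.array_equal(r1.genotypes, r2.genotypes)
        assert np.array_equal(r1.expression, r2.expression)
    pd.testing.assert_frame_equal(a1[2].table, a2[2].table)


def test_allele_frequencies_respect_maf_range():
    cfg = eo.SimulationConfig(n_genes=50, n_haplotypes=2000, seed=3)
    panel = eo.simulate_haplotype_panel(cfg)
    p = panel.allele_freq
    maf = np.minimum(p, 1 - p)
    slack = 3 * np.sqrt(0.25 / cfg.n_haplotypes)
    assert maf.min() >= cfg.maf_range[0] - slack
    assert maf.max() <= 0.5 + 1e-12


def test_perfect_ld_block_gives_identical_variants():
    cfg = eo.SimulationConfig(n_genes=1, n_blocks=1, snps_per_block=5,
                              within_block_r2=1.0, n_haplotypes=200, seed=0)
    panel = eo.simulate_haplotype_panel(cfg)
    for k in range(1, 5):
        assert eo.r2(panel, panel.variant_ids[0], panel.variant_ids[k]) == pytest.approx(1.0)


def test_zero_ld_blocks_are_independent():
    cfg = eo.SimulationConfig(n_genes=1, n_blocks=2, snps_per_block=1,
                              within_block_r2=0.0, n_haplotypes=10_000, seed=1)
    panel = eo.simulate_haplotype_panel(cfg)
    assert eo.r2(panel, panel.variant_ids[0], panel.variant_ids[1]) < 0.01


@pytest.mark.parametrize("target", [0.95, 0.6])
def test_within_block_r2_near_target_at_large_panels(target):
    cfg = eo.SimulationConfig(n_genes=4, n_blocks=8, snps_per_block=6,
                              within_block_r2=target, n_haplotypes=10_000, seed=7)
    panel = eo.simulate_haplotype_panel(cfg)
    vals = []
    for b in range(8):
        ids = panel.variant_ids[b * 6:(b + 1) * 6]
        vals.extend(eo.r2(panel, ids[i], ids[j])
                    for i in range(6) for j in range(i + 1, 6))
    assert abs(np.mean(vals) - target) < 0.05


def test_shared_fraction_recovers_pi_true_within_binomial_error():
    cfg = eo.SimulationConfig(n_genes=2000, n_individuals_i=50,
                              n_individuals_j=50, pi_true=0.3,
                              n_haplotypes=400, seed=7)
    panel = eo.simulate_haplotype_panel(cfg)
    *_, truth = eo.simulate_study_pair(panel, cfg)
    n = truth.n_active_both
    frac = len(truth.shared_genes) / n
    assert abs(frac - 0.3) < 3 * np.sqrt(0.3 * 0.7 / n)


def test_pi_true_one_shares_every_active_gene():
    cfg = eo.SimulationConfig(n_genes=100, n_individuals_i=40,
                              n_individuals_j=40, pi_true=1.0,
                              n_haplotypes=200, seed=5)
    panel = eo.simulate_haplotype_panel(cfg)
    *_, truth = eo.simulate_study_pair(panel, cfg)
    assert len(truth.shared_genes) == truth.n_active_both > 0
    shared_rows = truth.table[truth.table["shared_flag"]]
    per_gene = shared_rows.groupby("gene_id")["causal_variant"].nunique()
    assert (per_gene == 1).all()


def test_noiseless_expression_tracks_causal_dosage():
    cfg = eo.SimulationConfig(n_genes=40, n_individuals_i=50, n_individuals_j=30,
                              noise_sd=0.0, effect_beta=0.8, eqtl_gene_frac=1.0,
                              probe_overlap_frac=1.0, platform_snp_keep_i=1.0,
                              n_haplotypes=200, seed=2)
    panel = eo.simulate_haplotype_panel(cfg)
    raw_i, _, truth = eo.simulate_study_pair(panel, cfg)
    row = truth.table[truth.table["tissue"] == "tissue_i"].iloc[0]
    g_row = raw_i.probes.index[raw_i.probes["gene_id"] == row["gene_id"]][0]
    v_row = np.flatnonzero(raw_i.variant_ids == row["causal_variant"])[0]
    rho = stats.spearmanr(raw_i.expression[g_row], raw_i.genotypes[v_row]).statistic
    assert rho == pytest.approx(1.0)


def test_causal_variants_lie_within_cis_window():
    cfg = eo.SimulationConfig(n_genes=80, n_individuals_i=40, n_individuals_j=40,
                              n_haplotypes=200, seed=9)
    panel = eo.simulate_haplotype_panel(cfg)
    raw_i, _, truth = eo.simulate_study_pair(panel, cfg)
    tss = dict(zip(raw_i.annotation["gene_id"], raw_i.annotation["tss"]))
    pos = dict(zip(panel.variant_ids, panel.pos))
    for r in truth.table.itertuples():
        assert abs(pos[r.causal_variant] - tss[r.gene_id]) <= 1_000_000


def test_independent_activity_mode_decouples_tissues():
    cfg = eo.SimulationConfig(n_genes=2000, n_individuals_i=40, n_individuals_j=40,
                              pi_true=0.0, tissue_activity="independent",
                              n_haplotypes=200, seed=13)
    panel = eo.simulate_haplotype_panel(cfg)
    *_, truth = eo.simulate_study_pair(panel, cfg)
    assert not truth.shared_genes
    t = truth.table
    n_i = (t["tissue"] == "tissue_i").sum()
    n_j = (t["tissue"] == "tissue_j").sum()
    # both tissue rates near eqtl_gene_frac, joint rate near the product
    for n in (n_i, n_j):
        assert abs(n / 2000 - 0.5) < 3 * np.sqrt(0.25 / 2000)
    assert abs(truth.n_active_both / 2000 - 0.25) < 3 * np.sqrt(0.25 * 0.75 / 2000)


def test_all_typed_variants_missing_raises_listing_genes():
    cfg = eo.SimulationConfig(n_genes=5, n_individuals_i=20, n_individuals_j=20,
                              platform_snp_keep_i=0.0, n_haplotypes=100, seed=0)
    panel = eo.simulate_haplotype_panel(cfg)
    with pytest.raises(ValueError, match="gene_00000"):
        eo.simulate_study_pair(panel, cfg)


def test_fixture_roundtrip_and_manifest(tmp_path):
    cfg = eo.SimulationConfig(n_genes=20, n_individuals_i=30, n_individuals_j=20,
                              n_haplotypes=100, seed=21)
    panel = eo.simulate_haplotype_panel(cfg)
    raw_i, raw_j, truth = eo.simulate_study_pair(panel, cfg)
    manifest = write_fixture_set(panel, raw_i, raw_j, truth, tmp_path / "a")
    for name in manifest["file"]:
        assert (tmp_path / "a" / name).exists()

    back = read_fixture_study(tmp_path / "a", "study_i")
    assert np.array_equal(back.genotypes, raw_i.genotypes)
    np.testing.assert_allclose(back.expression, raw_i.expression)
    assert list(back.individuals) == list(raw_i.individuals)

    for fmt in ("panel.tsv", "panel.vcf"):
        p2 = read_haplotypes(tmp_path / "a" / fmt)
        assert np.array_equal(p2.haplotypes, panel.haplotypes)
        assert np.array_equal(p2.pos, panel.pos)
        assert list(p2.variant_ids) == list(panel.variant_ids)

    manifest2 = write_fixture_set(panel, raw_i, raw_j, truth, tmp_path / "b")
    assert list(manifest2["sha256"]) == list(manifest["sha256"])
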