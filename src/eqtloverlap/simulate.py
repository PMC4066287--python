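"""Synthetic paired-tissue eQTL studies with known ground truth.

Generates a phased haplotype reference panel with block LD structure, then a
pair of studies (unequal sample sizes, partially overlapping SNP platforms and
probe sets) in which a controlled fraction ``pi_true`` of eQTL-active genes
share their causal cis-variant between the two tissues. Every downstream stage
of the package (LD/proxy matching, cis mapping, harmonization, overlap
statistics, power adjustment) can therefore be tested against the truth.

Model
-----
Each gene occupies a two-block locus: block A holds the causal variant for
tissue *i* (and for both tissues when the eQTL is shared); block B, placed
``alt_block_offset_bp`` away (beyond the proxy window but inside the cis
window), holds the causal variant for a tissue-*j*-specific eQTL. Expression
is additive-cis: ``y = beta * dosage(causal) + Normal(0, noise_sd)``.
Haplotypes within a block are noisy copies of a per-haplotype founder allele,
with the copy probability set so the expected pairwise allelic r² equals
``within_block_r2``; distinct blocks are independent. Genotypes are dosages
0/1/2 from random pairing of panel haplotypes (Hardy-Weinberg, no population
structure).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ld import HaplotypePanel, write_haplotypes_tsv, write_haplotypes_vcf

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "RawStudyData",
    "simulate_haplotype_panel",
    "simulate_study_pair",
    "write_fixture_set",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one paired-tissue simulation; ``seed`` fixes all draws."""

    n_genes: int = 500
    n_individuals_i: int = 1000
    n_individuals_j: int = 200
    #: fraction of genes with an eQTL in both tissues whose causal variant is shared
    pi_true: float = 0.3
    #: per-allele effect in residual-SD units: a float, or (mean, sd) of |Normal|
    effect_beta: float | tuple[float, float] = (0.6, 0.15)
    noise_sd: float = 1.0
    #: None -> 2 * n_genes (one two-block locus per gene)
    n_blocks: int | None = None
    snps_per_block: int = 8
    within_block_r2: float = 0.95
    maf_range: tuple[float, float] = (0.1, 0.5)
    platform_snp_keep_i: float = 0.8
    platform_snp_keep_j: float = 0.7
    probe_overlap_frac: float = 0.8
    #: fraction of genes carrying an eQTL at all (the rest are beta=0 in both tissues)
    eqtl_gene_frac: float = 0.5
    #: multiplies the effect size of shared eQTL only; 1.0 keeps the
    #: equal-effect-size assumption of the power adjustment intact, values
    #: above 1 deliberately violate it (for bias-direction experiments)
    shared_beta_multiplier: float = 1.0
    #: "correlated": a gene is eQTL-active in both tissues or neither;
    #: "independent": per-tissue activity drawn independently (a true-null design)
    tissue_activity: str = "correlated"
    n_haplotypes: int = 2000
    loci_per_chrom: int = 500
    locus_spacing_bp: int = 1_500_000
    alt_block_offset_bp: int = 200_000
    snp_spacing_bp: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        # YAML configs deliver lists where the API uses tuples
        for name in ("effect_beta", "maf_range"):
            v = getattr(self, name)
            if isinstance(v, list):
                object.__setattr__(self, name, tuple(v))
        for name in ("n_genes", "n_individuals_i", "n_individuals_j",
                     "snps_per_block", "n_haplotypes", "loci_per_chrom",
                     "locus_spacing_bp", "alt_block_offset_bp", "snp_spacing_bp"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("pi_true", "probe_overlap_frac", "eqtl_gene_frac",
                     "platform_snp_keep_i", "platform_snp_keep_j",
                     "within_block_r2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.shared_beta_multiplier < 0:
            raise ValueError("shared_beta_multiplier must be >= 0, got "
                             f"{self.shared_beta_multiplier}")
        if self.n_blocks is not None and self.n_blocks < 1:
            raise ValueError(f"n_blocks must be >= 1, got {self.n_blocks}")
        if self.n_haplotypes % 2:
            raise ValueError("n_haplotypes must be even (phased diploid panel)")
        if self.tissue_activity not in ("correlated", "independent"):
            raise ValueError(f"tissue_activity must be 'correlated' or 'independent', "
                             f"got {self.tissue_activity!r}")
        if isinstance(self.effect_beta, tuple):
            if len(self.effect_beta) != 2 or self.effect_beta[1] < 0:
                raise ValueError(f"effect_beta spec must be (mean, sd>=0), got {self.effect_beta}")

    @property
    def resolved_n_blocks(self) -> int:
        return 2 * self.n_genes if self.n_blocks is None else self.n_blocks

    def beta_sampler(self, rng: np.random.Generator):
        if isinstance(self.effect_beta, tuple):
            mean, sd = self.effect_beta
            return lambda size: np.abs(rng.normal(mean, sd, size))
        value = float(self.effect_beta)
        return lambda size: np.full(size, value)


@dataclass
class GroundTruth:
    """True causal assignments of one simulated study pair.

    ``table`` has one row per (gene, tissue) with an eQTL:
    gene_id, tissue, causal_variant, beta, shared_flag.
    """

    table: pd.DataFrame
    n_active_both: int

    @property
    def shared_genes(self) -> set[str]:
        t = self.table
        return set(t.loc[t["shared_flag"], "gene_id"])

    def causal_variant(self, gene_id: str, tissue: str) -> str:
        t = self.table
        row = t[(t["gene_id"] == gene_id) & (t["tissue"] == tissue)]
        if row.empty:
            raise KeyError(f"no eQTL for ({gene_id}, {tissue})")
        return row["causal_variant"].iloc[0]


@dataclass
class RawStudyData:
    """One study's raw inputs: typed genotype dosages, expression, annotation."""

    study_id: str
    tissue_label: str
    individuals: list[str]
    variant_ids: np.ndarray          # typed variants only
    variant_chrom: np.ndarray
    variant_pos: np.ndarray
    genotypes: np.ndarray            # (n_typed_variants, n_individuals) int8 dosage
    probes: pd.DataFrame             # probe_id, gene_id, chrom, start, end
    expression: np.ndarray           # (n_probes, n_individuals) float
    annotation: pd.DataFrame         # gene_id, chrom, tss, exon_start, exon_end

    @property
    def n_samples(self) -> int:
        return len(self.individuals)

    def genotype_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.genotypes, index=self.variant_ids,
                            columns=self.individuals)

    def expression_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.expression, index=self.probes["probe_id"].to_numpy(),
                            columns=self.individuals)


def _locus_layout(config: SimulationConfig):
    """Per-block chromosome, start position, and per-gene locus assignment."""
    n_blocks = config.resolved_n_blocks
    n_loci = max(n_blocks // 2, 1)
    locus = np.arange(n_loci)
    chrom_idx = locus // config.loci_per_chrom
    within = locus % config.loci_per_chrom
    locus_start = 50_000 + within * config.locus_spacing_bp
    block_chrom = np.empty(n_blocks, dtype=int)
    block_start = np.empty(n_blocks, dtype=np.int64)
    for b in range(n_blocks):
        loc = min(b // 2, n_loci - 1)
        block_chrom[b] = chrom_idx[loc]
        offset = config.alt_block_offset_bp if (b % 2 == 1 and n_blocks > 1) else 0
        block_start[b] = locus_start[loc] + offset
    return block_chrom, block_start, n_loci


def simulate_haplotype_panel(config: SimulationConfig) -> HaplotypePanel:
    """Draw the phased reference panel implied by ``config``.

    Variants in the same block are correlated near ``within_block_r2`` (expected
    allelic r²); variants in different blocks are independent; each block's
    allele frequency is uniform in ``maf_range``.
    """
    rng = np.random.default_rng(config.seed)
    H = config.n_haplotypes
    B = config.resolved_n_blocks
    S = config.snps_per_block
    V = B * S

    p_block = rng.uniform(config.maf_range[0], config.maf_range[1], B)
    copy_rate = config.within_block_r2 ** 0.25
    founder = rng.random((H, B)) < p_block                    # latent per-block allele
    founder_sites = np.repeat(founder, S, axis=1)
    p_sites = np.repeat(p_block, S).astype(np.float32)
    # one uniform draw decides both whether a site copies its founder and, if
    # not, the fresh Bernoulli(p) allele: given u >= c, (u-c)/(1-c) is U(0,1)
    u = rng.random((H, V), dtype=np.float32)
    use_copy = u < np.float32(copy_rate)
    fresh = (u - np.float32(copy_rate)) < p_sites * np.float32(1.0 - copy_rate)
    haps = np.where(use_copy, founder_sites, fresh).astype(np.int8)
    del u, use_copy, fresh, founder_sites

    block_chrom, block_start, _ = _locus_layout(config)
    pos = (np.repeat(block_start, S)
           + np.tile(np.arange(S, dtype=np.int64) * config.snp_spacing_bp, B))
    chrom = np.array([f"chr{c + 1}" for c in np.repeat(block_chrom, S)])
    ids = np.array([f"snp_{i:06d}" for i in range(V)])
    return HaplotypePanel(variant_ids=ids, chrom=chrom, pos=pos, haplotypes=haps)


def _annotation_table(config: SimulationConfig) -> pd.DataFrame:
    block_chrom, block_start, n_loci = _locus_layout(config)
    rows = []
    span = (config.snps_per_block - 1) * config.snp_spacing_bp
    for g in range(config.n_genes):
        loc = g % n_loci
        b = 2 * loc if config.resolved_n_blocks > 1 else 0
        tss = int(block_start[b] + span // 2)
        rows.append({
            "gene_id": f"gene_{g:05d}",
            "chrom": f"chr{block_chrom[b] + 1}",
            "tss": tss,
            "exon_start": tss,
            "exon_end": tss + 2000,
        })
    return pd.DataFrame(rows)


def simulate_study_pair(
    panel: HaplotypePanel, config: SimulationConfig
) -> tuple[RawStudyData, RawStudyData, GroundTruth]:
    """Draw two studies (tissues *i* and *j*) on ``panel`` plus their truth."""
    if config.resolved_n_blocks < 2 or config.resolved_n_blocks % 2:
        raise ValueError("study simulation needs an even n_blocks >= 2 "
                         "(each gene locus uses a causal block and an alternative block)")
    if panel.n_variants != config.resolved_n_blocks * config.snps_per_block:
        raise ValueError("panel is inconsistent with config (variant count mismatch)")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    G = config.n_genes
    S = config.snps_per_block
    _, _, n_loci = _locus_layout(config)
    gene_ids = np.array([f"gene_{g:05d}" for g in range(G)])
    annotation = _annotation_table(config)

    # eQTL activity per tissue
    if config.tissue_activity == "correlated":
        active = rng.random(G) < config.eqtl_gene_frac
        active_i = active.copy()
        active_j = active.copy()
    else:
        active_i = rng.random(G) < config.eqtl_gene_frac
        active_j = rng.random(G) < config.eqtl_gene_frac
    both = active_i & active_j
    shared = both & (rng.random(G) < config.pi_true)

    # causal variants: tissue i from block A (index 2*locus), tissue-specific j
    # eQTL from block B (2*locus+1), shared eQTL identical in both tissues
    locus = np.arange(G) % n_loci
    pick_a = 2 * locus * S + rng.integers(0, S, G)
    pick_b = (2 * locus + 1) * S + rng.integers(0, S, G)
    causal_i = np.where(active_i, pick_a, -1)
    causal_j = np.where(shared, pick_a, np.where(active_j, pick_b, -1))

    sample_beta = config.beta_sampler(rng)
    beta_i = np.where(active_i, sample_beta(G), 0.0)
    beta_i = np.where(shared, beta_i * config.shared_beta_multiplier, beta_i)
    beta_j = np.where(shared, beta_i, np.where(active_j, sample_beta(G), 0.0))

    studies = []
    for study_id, tissue, n_ind, keep_frac, causal, beta, tag in (
        ("study_i", "tissue_i", config.n_individuals_i, config.platform_snp_keep_i,
         causal_i, beta_i, "i"),
        ("study_j", "tissue_j", config.n_individuals_j, config.platform_snp_keep_j,
         causal_j, beta_j, "j"),
    ):
        hap_a = rng.integers(0, panel.n_haplotypes, n_ind)
        hap_b = rng.integers(0, panel.n_haplotypes, n_ind)
        dosage = (panel.haplotypes[hap_a] + panel.haplotypes[hap_b]).T.astype(np.int8)

        typed = rng.random(panel.n_variants) < keep_frac
        missing = _genes_without_cis_variants(config, annotation, panel, typed)
        if missing:
            raise ValueError(
                f"{study_id}: cis window contains no typed variants for genes: "
                + ", ".join(missing[:10]))

        expr = rng.normal(0.0, config.noise_sd, (G, n_ind))
        has_eqtl = causal >= 0
        if has_eqtl.any():
            expr[has_eqtl] += beta[has_eqtl, None] * dosage[causal[has_eqtl]]

        # probe sets: probe_overlap_frac of genes assayed on both platforms,
        # remainder alternated between the two platforms
        studies.append((study_id, tissue, n_ind, dosage, typed, expr, tag))

    order = rng.permutation(G)
    n_both_probes = int(round(config.probe_overlap_frac * G))
    on_both = np.zeros(G, bool)
    on_both[order[:n_both_probes]] = True
    rest = order[n_both_probes:]
    only_i = np.zeros(G, bool)
    only_i[rest[::2]] = True
    only_j = np.zeros(G, bool)
    only_j[rest[1::2]] = True

    out = []
    for study_id, tissue, n_ind, dosage, typed, expr, tag in studies:
        assayed = on_both | (only_i if tag == "i" else only_j)
        probes = annotation.loc[assayed].copy()
        probes["probe_id"] = [f"{tag}_pr_{g}" for g in probes["gene_id"]]
        start_off, end_off = (100, 400) if tag == "i" else (500, 900)
        probes["start"] = probes["tss"] + start_off
        probes["end"] = probes["tss"] + end_off
        probes = probes[["probe_id", "gene_id", "chrom", "start", "end"]].reset_index(drop=True)
        individuals = [f"{tag}_ind_{k:05d}" for k in range(n_ind)]
        out.append(RawStudyData(
            study_id=study_id, tissue_label=tissue, individuals=individuals,
            variant_ids=panel.variant_ids[typed], variant_chrom=panel.chrom[typed],
            variant_pos=panel.pos[typed], genotypes=dosage[typed],
            probes=probes, expression=expr[assayed],
            annotation=annotation,
        ))

    rows = []
    for g in range(G):
        for tissue, causal, beta, act in (("tissue_i", causal_i, beta_i, active_i),
                                          ("tissue_j", causal_j, beta_j, active_j)):
            if act[g]:
                rows.append({
                    "gene_id": gene_ids[g], "tissue": tissue,
                    "causal_variant": panel.variant_ids[causal[g]],
                    "beta": beta[g], "shared_flag": bool(shared[g]),
                })
    truth = GroundTruth(
        table=pd.DataFrame(rows, columns=["gene_id", "tissue", "causal_variant",
                                          "beta", "shared_flag"]),
        n_active_both=int(both.sum()),
    )
    return out[0], out[1], truth


def _genes_without_cis_variants(config, annotation, panel, typed,
                                cis_window_bp: int = 1_000_000) -> list[str]:
    missing: list[str] = []
    pos = panel.pos[typed]
    chrom = panel.chrom[typed]
    for c in np.unique(annotation["chrom"]):
        cpos = np.sort(pos[chrom == c])
        sub = annotation[annotation["chrom"] == c]
        lo = np.searchsorted(cpos, sub["tss"].to_numpy() - cis_window_bp, "left")
        hi = np.searchsorted(cpos, sub["tss"].to_numpy() + cis_window_bp, "right")
        missing.extend(sub.loc[sub.index[hi <= lo], "gene_id"])
    return missing


# ---------------------------------------------------------------------------
# fixture writing

def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_set(
    panel: HaplotypePanel,
    study_i: RawStudyData,
    study_j: RawStudyData,
    truth: GroundTruth,
    directory: str | Path,
) -> pd.DataFrame:
    """Write all simulated inputs as plain-text files; return a checksum manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    p = directory / "panel.vcf"
    write_haplotypes_vcf(panel, p)
    files.append(p)
    p = directory / "panel.tsv"
    write_haplotypes_tsv(panel, p)
    files.append(p)

    for raw in (study_i, study_j):
        geno = raw.genotype_frame().reset_index(names="variant_id")
        path = directory / f"{raw.study_id}_genotypes.tsv"
        _write_tsv(geno, path)
        files.append(path)
        expr = raw.expression_frame().reset_index(names="probe_id")
        path = directory / f"{raw.study_id}_expression.tsv"
        _write_tsv(expr, path)
        files.append(path)
        path = directory / f"{raw.study_id}_probes.tsv"
        _write_tsv(raw.probes, path)
        files.append(path)

    ann = study_i.annotation.copy()
    ann["exons"] = [f"{s}-{e}" for s, e in zip(ann["exon_start"], ann["exon_end"])]
    path = directory / "gene_annotation.tsv"
    _write_tsv(ann[["chrom", "tss", "gene_id", "exons"]], path)
    files.append(path)

    path = directory / "ground_truth.tsv"
    _write_tsv(truth.table, path)
    files.append(path)

    manifest = pd.DataFrame({
        "file": [f.name for f in files],
        "sha256": [_sha256(f) for f in files],
        "n_bytes": [f.stat().st_size for f in files],
    })
    _write_tsv(manifest, directory / "MANIFEST.tsv")
    return manifest


def read_fixture_study(directory: str | Path, study_id: str,
                       tissue_label: str = "") -> RawStudyData:
    """Reconstruct a :class:`RawStudyData` from :func:`write_fixture_set` files."""
    directory = Path(directory)
    geno = pd.read_csv(directory / f"{study_id}_genotypes.tsv", sep="\t",
                       index_col="variant_id")
    expr = pd.read_csv(directory / f"{study_id}_expression.tsv", sep="\t",
                       index_col="probe_id")
    probes = pd.read_csv(directory / f"{study_id}_probes.tsv", sep="\t")
    ann = read_annotation(directory / "gene_annotation.tsv")
    panel_meta = pd.read_csv(directory / "panel.tsv", sep="\t",
                             usecols=["id", "chrom", "pos"]).set_index("id")
    meta = panel_meta.reindex(geno.index)
    if meta["pos"].isna().any():
        raise ValueError("genotype variants missing from panel.tsv")
    expr = expr.reindex(probes["probe_id"])
    return RawStudyData(
        study_id=study_id, tissue_label=tissue_label,
        individuals=list(geno.columns),
        variant_ids=geno.index.to_numpy(str),
        variant_chrom=meta["chrom"].to_numpy(str),
        variant_pos=meta["pos"].to_numpy(np.int64),
        genotypes=geno.to_numpy(np.int8),
        probes=probes, expression=expr.to_numpy(float), annotation=ann)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read the BED-like gene annotation written by :func:`write_fixture_set`."""
    ann = pd.read_csv(path, sep="\t")
    exons = ann["exons"].str.split("-", expand=True).astype(int)
    ann = ann.rename(columns={"tss": "tss"})
    ann["exon_start"] = exons[0]
    ann["exon_end"] = exons[1]
    return ann[["gene_id", "chrom", "tss", "exon_start", "exon_end"]]
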