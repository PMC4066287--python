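"""Power-adjusted overlap: subsampling power estimation and the adjustment.

The observed overlap fraction π_raw between a large discovery study *i* and a
smaller replication study *j* underestimates the true sharing fraction π
because study *j* is underpowered. The adjusted estimate is

    π_adjusted = (π_raw - a_j (1 - FDR_i)) / (power_j - a_j)            (1)
    power_j    = (power_j_raw - FDR_i a_j) / (1 - FDR_i)               (2)

where FDR_i is the discovery study's FDR level, a_j is the replication
study's chance-significance rate, and power_j_raw is estimated empirically:
repeatedly draw two disjoint individual subsets of study *i*, each of size
n_j, call eQTL in both at the same study-wide FDR, and record the proportion
of eQTL found in the first subset that are also significant in the second.
The (1 - FDR_i) factors correct for false discoveries contaminating both the
discovery list and the first subset's list.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .ld import HaplotypePanel, build_proxy_map
from .mapping import CisDesign, EqtlStudy, bh_fdr, build_cis_pairs, _scan_arrays
from .simulate import RawStudyData

logger = logging.getLogger(__name__)

__all__ = [
    "AdjustmentConfig",
    "PowerAdjustment",
    "power_j_from_raw",
    "pi_adjusted",
    "estimate_power_j_raw",
    "adjust_pair",
]


class UndefinedAdjustmentError(ValueError):
    """Raised when power_j <= a_j, leaving Eq. (1) without a finite estimate."""


def _clip_unit(value: float, label: str) -> float:
    if value < 0.0 or value > 1.0:
        warnings.warn(f"{label} = {value:.4f} outside [0, 1]; clipped "
                      "(sampling noise can push the estimator out of range)",
                      stacklevel=3)
        return float(min(max(value, 0.0), 1.0))
    return float(value)


def power_j_from_raw(power_j_raw: float, fdr_i: float, a_j: float) -> float:
    """Eq. (2): power_j = (power_j_raw - FDR_i * a_j) / (1 - FDR_i)."""
    if fdr_i >= 1.0:
        raise ZeroDivisionError("fdr_i must be < 1")
    for name, v in (("power_j_raw", power_j_raw), ("fdr_i", fdr_i), ("a_j", a_j)):
        if v < 0.0 or (name != "power_j_raw" and v >= 1.0) or power_j_raw > 1.0:
            raise ValueError(f"{name} = {v} out of range")
    return _clip_unit((power_j_raw - fdr_i * a_j) / (1.0 - fdr_i), "power_j")


def pi_adjusted(pi_raw: float, a_j: float, fdr_i: float, power_j: float) -> float:
    """Eq. (1): pi_adjusted = (pi_raw - a_j (1 - FDR_i)) / (power_j - a_j)."""
    if power_j <= a_j:
        raise UndefinedAdjustmentError(
            f"power_j ({power_j:.4f}) must exceed a_j ({a_j:.4f}) "
            "for a finite adjusted estimate")
    return _clip_unit((pi_raw - a_j * (1.0 - fdr_i)) / (power_j - a_j),
                      "pi_adjusted")


@dataclass(frozen=True)
class AdjustmentConfig:
    """Knobs of the subsampling power procedure and of Eqs. (1)-(2)."""

    fdr: float = 0.05
    n_reps: int = 20
    seed: int = 0
    cis_window_bp: int = 1_000_000
    #: replication match criterion inside the subsampling procedure
    match: str = "esnp"              # or "gene" / "proxy"
    #: how the chance-significance rate a_j is obtained:
    #: "realized_cutoff" (study j's BH p-value cutoff), "pair_rate"
    #: (significant pairs / tested pairs in study j), or "override"
    a_j_method: str = "realized_cutoff"
    a_j_override: float | None = None
    proxy_r2_threshold: float = 0.8
    proxy_window_bp: int = 100_000


@dataclass
class PowerAdjustment:
    """Everything Eqs. (1)-(2) consumed and produced for one study pair."""

    study_i: str
    study_j: str
    n_j: int
    fdr_i: float
    a_j: float
    power_j_raw: float
    power_j_raw_se: float
    power_j: float
    pi_raw: float
    pi_adjusted: float
    pi_adjusted_se: float
    n_subsample_reps: int
    seed: int

    def to_row(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _sig_gene_sets(design: CisDesign, X: np.ndarray, Y: np.ndarray, fdr: float,
                   collect_pairs: bool = False):
    """Fast path: best eSNP per significant gene, realized cutoff, and
    (optionally) the full set of significant (gene, variant) pairs."""
    beta, se, t, p, valid, *_ = _scan_arrays(design, X, Y, dtype=np.float32)
    idx = np.flatnonzero(valid)
    reject, cutoff = bh_fdr(p[idx], fdr)
    sig = idx[reject]
    if sig.size == 0:
        return {}, cutoff, set()
    pairs = (set(zip(design.gene_ids[design.gene_idx[sig]],
                     design.variant_ids[design.variant_idx[sig]]))
             if collect_pairs else set())
    gi = design.gene_idx[sig]
    order = np.lexsort((np.abs(design.distance[sig]), p[sig], gi))
    sig, gi = sig[order], gi[order]
    first = np.ones(len(sig), bool)
    first[1:] = gi[1:] != gi[:-1]
    best = {design.gene_ids[g]: design.variant_ids[design.variant_idx[s]]
            for g, s in zip(gi[first], sig[first])}
    return best, cutoff, pairs


def estimate_power_j_raw(
    large_study_raw: RawStudyData,
    n_j: int,
    fdr: float = 0.05,
    n_reps: int = 20,
    seed: int = 0,
    cis_window_bp: int = 1_000_000,
    match: str = "esnp",
    panel: HaplotypePanel | None = None,
    proxy_r2_threshold: float = 0.8,
    proxy_window_bp: int = 100_000,
    return_details: bool = False,
):
    """Estimate power_j_raw by disjoint subsampling of the large study.

    Per replicate: draw two mutually exclusive individual subsets of size
    ``n_j``, call eQTL in each at study-wide FDR ``fdr``, and score the
    proportion of the first subset's eQTL that are also significant in the
    second. ``match`` selects what "also significant" means: ``'esnp'``
    (default) requires the first subset's best gene-eSNP association itself
    to be significant in the second subset — the event whose probability is
    the slope-test power of that eSNP; ``'gene'`` accepts any significant cis
    association of the gene; ``'proxy'`` requires the two subsets' best
    eSNPs to share an LD proxy through ``panel``. Returns the mean over
    replicates and its standard error.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if match not in ("esnp", "gene", "proxy"):
        raise ValueError(f"unknown match criterion {match!r}")
    if match == "proxy" and panel is None:
        raise ValueError("match='proxy' requires a haplotype panel")
    n_avail = large_study_raw.n_samples
    if 2 * n_j > n_avail:
        raise ValueError(f"need 2*n_j <= {n_avail} individuals, got n_j = {n_j}")

    raw = large_study_raw
    design = build_cis_pairs(
        raw.variant_chrom, raw.variant_pos,
        raw.probes["gene_id"].to_numpy(), _gene_chrom(raw),
        _gene_tss(raw), raw.variant_ids, cis_window_bp)

    rng = np.random.default_rng(seed)
    props = []
    cutoffs2: list[float] = []
    n_eqtl1: list[int] = []
    for _ in range(n_reps):
        perm = rng.permutation(n_avail)
        s1, s2 = perm[:n_j], perm[n_j:2 * n_j]
        best1, _, _ = _sig_gene_sets(design, raw.genotypes[:, s1],
                                     raw.expression[:, s1], fdr)
        best2, cut2, pairs2 = _sig_gene_sets(design, raw.genotypes[:, s2],
                                             raw.expression[:, s2], fdr,
                                             collect_pairs=(match == "esnp"))
        cutoffs2.append(cut2)
        n_eqtl1.append(len(best1))
        if not best1:
            logger.warning("power replicate found no eQTL in subset 1; scored as 0")
            props.append(0.0)
            continue
        if match == "esnp":
            hits = sum(1 for g, v in best1.items() if (g, v) in pairs2)
        elif match == "gene":
            hits = sum(1 for g in best1 if g in best2)
        else:
            both = [g for g in best1 if g in best2]
            esnps = sorted({best1[g] for g in both} | {best2[g] for g in both})
            pm = build_proxy_map(panel, esnps, proxy_r2_threshold, proxy_window_bp)
            hits = sum(
                1 for g in both
                if set(pm.proxies(best1[g])) & set(pm.proxies(best2[g])))
        props.append(hits / len(best1))
    props = np.asarray(props)
    se = float(props.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else float("nan")
    if return_details:
        return float(props.mean()), se, {
            "replicate_proportions": props,
            "replication_cutoffs": np.asarray(cutoffs2),
            "n_eqtl_subset1": np.asarray(n_eqtl1),
        }
    return float(props.mean()), se


def _gene_chrom(raw: RawStudyData) -> np.ndarray:
    ann = raw.annotation.set_index("gene_id")
    return ann["chrom"].reindex(raw.probes["gene_id"]).to_numpy()


def _gene_tss(raw: RawStudyData) -> np.ndarray:
    ann = raw.annotation.set_index("gene_id")
    return ann["tss"].reindex(raw.probes["gene_id"]).to_numpy(np.int64)


def _chance_rate(study_j: EqtlStudy, config: AdjustmentConfig) -> float:
    if config.a_j_method == "override":
        if config.a_j_override is None:
            raise ValueError("a_j_method='override' requires a_j_override")
        return float(config.a_j_override)
    if config.a_j_method == "pair_rate":
        return study_j.n_significant_pairs / study_j.n_tests if study_j.n_tests else 0.0
    if config.a_j_method == "realized_cutoff":
        return float(study_j.alpha)
    raise ValueError(f"unknown a_j_method {config.a_j_method!r}")


def adjust_pair(
    study_i_raw: RawStudyData,
    study_j: EqtlStudy,
    pi_raw_value: float,
    config: AdjustmentConfig = AdjustmentConfig(),
    panel: HaplotypePanel | None = None,
) -> PowerAdjustment:
    """Chain Eq. (2) and Eq. (1) onto a subsampling power estimate.

    ``study_i_raw`` must be the larger (discovery) study; ``pi_raw_value`` is
    the observed overlap in the direction discovery -> replication.
    """
    n_j = study_j.n_samples
    power_raw, power_raw_se = estimate_power_j_raw(
        study_i_raw, n_j, fdr=config.fdr, n_reps=config.n_reps,
        seed=config.seed, cis_window_bp=config.cis_window_bp,
        match=config.match, panel=panel,
        proxy_r2_threshold=config.proxy_r2_threshold,
        proxy_window_bp=config.proxy_window_bp)
    a_j = _chance_rate(study_j, config)
    p_j = power_j_from_raw(power_raw, config.fdr, a_j)
    adj = pi_adjusted(pi_raw_value, a_j, config.fdr, p_j)
    # first-order propagation of the power SE through Eq. (1)-(2)
    if p_j > a_j and power_raw_se == power_raw_se:
        dpj = power_raw_se / (1.0 - config.fdr)
        adj_se = abs(adj / (p_j - a_j)) * dpj
    else:
        adj_se = float("nan")
    return PowerAdjustment(
        study_i=study_i_raw.study_id, study_j=study_j.study_id, n_j=n_j,
        fdr_i=config.fdr, a_j=a_j, power_j_raw=power_raw,
        power_j_raw_se=power_raw_se, power_j=p_j, pi_raw=pi_raw_value,
        pi_adjusted=adj, pi_adjusted_se=adj_se,
        n_subsample_reps=config.n_reps, seed=config.seed)
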