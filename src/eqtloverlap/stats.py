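"""Summary statistics for a pair of harmonized eQTL studies.

Turns gene-level overlap calls into the directional observed overlap π_raw
(overlap count divided by the directing study's eQTL-gene count within the
common universe), a chance expectation (product of the two studies' observed
per-gene eQTL proportions, the null rate of gene-level co-occurrence when
eQTL status is independent across studies), and a one-sided binomial
enrichment test of the observed co-occurrence against that chance rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .harmonize import GeneMatchTable
from .mapping import EqtlStudy

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapResult",
    "pi_raw",
    "chance_overlap",
    "overlap_enrichment_test",
    "summarize_pair",
]


@dataclass
class OverlapResult:
    """Directional overlap counts and fractions for one ordered study pair."""

    study_i: str
    study_j: str
    n_common_genes: int
    n_genes_eqtl_i: int              # within the common universe
    n_genes_eqtl_j: int
    n_shared_eqtl_genes: int         # eQTL in both studies (co-occurrence)
    n_overlap_direct: int
    n_overlap_proxy: int
    pi_raw_i_to_j: float | None
    pi_raw_j_to_i: float | None
    chance_expected: float
    enrichment_p: float
    mean_shared_snps_per_gene: float | None = None
    mean_esnp_tss_distance: float | None = None

    def to_row(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def pi_raw(calls: pd.DataFrame, n_eqtl_directing: int,
           method: str = "proxy") -> float | None:
    """Observed overlap fraction: matched genes / directing study's eQTL genes.

    Returns None (missing, not 0) when the directing study has no eQTL genes.
    """
    if method not in ("direct", "proxy"):
        raise ValueError(f"unknown overlap method {method!r}")
    if n_eqtl_directing == 0:
        logger.warning("pi_raw undefined: directing study has zero eQTL genes")
        return None
    col = "direct_match" if method == "direct" else "proxy_match"
    k = int(calls[col].sum()) if len(calls) else 0
    return k / n_eqtl_directing


def chance_overlap(prop_eqtl_i: float, prop_eqtl_j: float) -> float:
    """Expected fraction of common-universe genes with an eQTL in both studies
    under no true sharing: the product of the two eQTL proportions."""
    for name, v in (("prop_eqtl_i", prop_eqtl_i), ("prop_eqtl_j", prop_eqtl_j)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return prop_eqtl_i * prop_eqtl_j


def overlap_enrichment_test(k_overlap: int, n_shared: int,
                            chance_rate: float) -> float:
    """One-sided binomial upper tail P(X >= k | n, chance_rate)."""
    if not 0 <= k_overlap <= n_shared:
        raise ValueError("need 0 <= k_overlap <= n_shared")
    if not 0.0 <= chance_rate <= 1.0:
        raise ValueError(f"chance_rate must be in [0, 1], got {chance_rate}")
    if k_overlap == 0:
        return 1.0
    return float(sps.binom.sf(k_overlap - 1, n_shared, chance_rate))


def summarize_pair(
    study_i: EqtlStudy,
    study_j: EqtlStudy,
    table: GeneMatchTable,
    calls: pd.DataFrame,
) -> OverlapResult:
    """Assemble the pairwise summary from harmonized calls.

    ``calls`` is the output of :func:`eqtloverlap.harmonize.proxy_overlap`
    (carries both the direct and the proxy verdict per gene). The enrichment
    test is applied at the gene-co-occurrence level: k = genes with an eQTL in
    both studies, n = common universe, rate = chance_expected.
    """
    universe = table.genes
    genes_i = study_i.significant_genes() & universe
    genes_j = study_j.significant_genes() & universe
    n_common = table.n_common_genes
    n_both = len(genes_i & genes_j)
    n_direct = int(calls["direct_match"].sum()) if len(calls) else 0
    n_proxy = int(calls["proxy_match"].sum()) if len(calls) else 0
    prop_i = len(genes_i) / n_common if n_common else 0.0
    prop_j = len(genes_j) / n_common if n_common else 0.0
    chance = chance_overlap(prop_i, prop_j)
    enr = overlap_enrichment_test(n_both, n_common, chance) if n_common else 1.0

    mean_shared = mean_dist = None
    if len(calls):
        matched = calls[calls["proxy_match"]]
        if len(matched):
            if "n_shared_proxies" in matched.columns:
                mean_shared = float(matched["n_shared_proxies"].mean())
            dist = study_i.records.set_index("gene_id")["distance_to_tss"]
            d = dist.reindex(matched["gene_id"]).abs().dropna()
            if len(d):
                mean_dist = float(d.mean())
    return OverlapResult(
        study_i=study_i.study_id,
        study_j=study_j.study_id,
        n_common_genes=n_common,
        n_genes_eqtl_i=len(genes_i),
        n_genes_eqtl_j=len(genes_j),
        n_shared_eqtl_genes=n_both,
        n_overlap_direct=n_direct,
        n_overlap_proxy=n_proxy,
        pi_raw_i_to_j=pi_raw(calls, len(genes_i), "proxy"),
        pi_raw_j_to_i=pi_raw(calls, len(genes_j), "proxy"),
        chance_expected=chance,
        enrichment_p=enr,
        mean_shared_snps_per_gene=mean_shared,
        mean_esnp_tss_distance=mean_dist,
    )
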