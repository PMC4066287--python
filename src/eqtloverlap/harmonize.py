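"""Cross-study harmonization: exon-level probe matching and gene-level overlap.

Two studies' eQTL lists are aligned onto a common gene universe by requiring
each expression platform to carry at least one probe whose interval is
contained in the same annotated exon (0-based half-open coordinates). For
genes with a significant eQTL in both studies, overlap is then decided two
ways: directly (identical best-eSNP ids) and through LD-proxy sets built from
a shared reference panel (non-empty intersection of the two proxy sets, or
optionally membership of one eSNP in the other's set).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .ld import ProxyMap
from .mapping import EqtlStudy

logger = logging.getLogger(__name__)

__all__ = [
    "GeneMatchTable",
    "match_probes_to_genes",
    "shared_eqtl_genes",
    "direct_esnp_overlap",
    "proxy_overlap",
    "estimate_chance_overlap_rate",
]

CALL_COLUMNS = ["gene_id", "esnp_i", "esnp_j", "direct_match", "proxy_match",
                "best_shared_r2", "n_shared_proxies"]


@dataclass
class GeneMatchTable:
    """Genes represented by exon-compatible probes on both platforms."""

    pairs: pd.DataFrame  # gene_id, probe_id_i, probe_id_j, exon_id

    @property
    def n_common_genes(self) -> int:
        return len(self.pairs)

    @property
    def genes(self) -> set[str]:
        return set(self.pairs["gene_id"])


def _assign_probes(probes: pd.DataFrame, exons: pd.DataFrame) -> pd.DataFrame:
    """Map each probe to the gene exon containing it; ambiguous probes dropped.

    ``exons`` columns: gene_id, exon_id, chrom, start, end (half-open).
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in exons.groupby("chrom"):
        t = IntervalTree()
        for row in sub.itertuples(index=False):
            if row.end > row.start:
                t.addi(row.start, row.end, (row.gene_id, row.exon_id))
        trees[chrom] = t

    rows, ambiguous = [], 0
    for row in probes.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        hits = {iv.data for iv in tree.overlap(row.start, row.end)
                if iv.begin <= row.start and row.end <= iv.end}
        genes = {g for g, _ in hits}
        if len(genes) > 1:
            ambiguous += 1
            continue
        for gene_id, exon_id in hits:
            rows.append({"probe_id": row.probe_id, "gene_id": gene_id,
                         "exon_id": exon_id, "span": row.end - row.start})
    if ambiguous:
        logger.warning("excluded %d probes mapping to multiple genes", ambiguous)
    return pd.DataFrame(rows, columns=["probe_id", "gene_id", "exon_id", "span"])


def _exon_table(exon_annotation: pd.DataFrame) -> pd.DataFrame:
    ann = exon_annotation.copy()
    if "exon_id" not in ann.columns:
        ann["exon_id"] = [f"{g}_e0" for g in ann["gene_id"]]
    ann = ann.rename(columns={"exon_start": "start", "exon_end": "end"})
    return ann[["gene_id", "exon_id", "chrom", "start", "end"]]


def match_probes_to_genes(
    probes_i: pd.DataFrame,
    probes_j: pd.DataFrame,
    exon_annotation: pd.DataFrame,
) -> GeneMatchTable:
    """Match genes represented on both platforms via shared exon containment.

    A gene is matched iff each platform carries >= 1 probe contained in the
    same annotated exon; among several qualifying probes the one with the
    smallest genomic span is retained (ties by probe id).
    """
    exons = _exon_table(exon_annotation)
    ai = _assign_probes(probes_i, exons)
    aj = _assign_probes(probes_j, exons)
    if ai.empty or aj.empty:
        return GeneMatchTable(pairs=pd.DataFrame(
            columns=["gene_id", "probe_id_i", "probe_id_j", "exon_id"]))

    def best(df: pd.DataFrame) -> pd.DataFrame:
        df = df.sort_values(["span", "probe_id"], kind="stable")
        return df.drop_duplicates(["gene_id", "exon_id"], keep="first")

    merged = best(ai).merge(best(aj), on=["gene_id", "exon_id"],
                            suffixes=("_i", "_j"))
    # one row per gene: keep the exon with the smaller combined span
    merged["_span"] = merged["span_i"] + merged["span_j"]
    merged = merged.sort_values(["_span", "exon_id"], kind="stable")
    merged = merged.drop_duplicates("gene_id", keep="first")
    merged = merged.sort_values("gene_id", kind="stable").reset_index(drop=True)
    return GeneMatchTable(
        pairs=merged[["gene_id", "probe_id_i", "probe_id_j", "exon_id"]])


def shared_eqtl_genes(
    study_i: EqtlStudy, study_j: EqtlStudy, table: GeneMatchTable
) -> set[str]:
    """Genes of the common universe with a significant eQTL in both studies."""
    return table.genes & study_i.significant_genes() & study_j.significant_genes()


def _esnps_for(study: EqtlStudy, genes: list[str]):
    best = study.best_esnp()
    missing = [g for g in genes if g not in best.index]
    return best, missing


def direct_esnp_overlap(
    study_i: EqtlStudy, study_j: EqtlStudy, shared_genes: set[str]
) -> pd.DataFrame:
    """Per-gene direct comparison: match iff the best-eSNP ids are identical."""
    genes = sorted(shared_genes)
    best_i, miss_i = _esnps_for(study_i, genes)
    best_j, miss_j = _esnps_for(study_j, genes)
    if miss_i or miss_j:
        logger.warning("excluded %d shared genes missing a best eSNP",
                       len(set(miss_i) | set(miss_j)))
    rows = []
    for g in genes:
        if g not in best_i.index or g not in best_j.index:
            continue
        ei, ej = best_i[g], best_j[g]
        rows.append({"gene_id": g, "esnp_i": ei, "esnp_j": ej,
                     "direct_match": ei == ej, "proxy_match": ei == ej,
                     "best_shared_r2": 1.0 if ei == ej else None,
                     "n_shared_proxies": 1 if ei == ej else 0})
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def proxy_overlap(
    study_i: EqtlStudy,
    study_j: EqtlStudy,
    shared_genes: set[str],
    proxy_map_i: ProxyMap,
    proxy_map_j: ProxyMap,
    criterion: str = "intersect",
    all_significant: bool = False,
) -> pd.DataFrame:
    """Per-gene proxy-level comparison of the two studies' eSNPs.

    ``criterion='intersect'`` declares a match when the two proxy sets share
    any variant; ``criterion='contains'`` when eSNP_j itself lies in the proxy
    set of eSNP_i. ``best_shared_r2`` is the max over shared proxies of
    min(r² to eSNP_i, r² to eSNP_j). With ``all_significant`` the union of
    proxy sets over every significant SNP of the gene is used instead of the
    best eSNP's set only (sensitivity mode; requires studies called with
    ``mode='all_significant'``).
    """
    if criterion not in ("intersect", "contains"):
        raise ValueError(f"unknown proxy criterion {criterion!r}")
    genes = sorted(shared_genes)
    best_i, _ = _esnps_for(study_i, genes)
    best_j, _ = _esnps_for(study_j, genes)

    def esnp_sets(study: EqtlStudy, gene: str, fallback: str) -> list[str]:
        if all_significant and study.all_significant is not None:
            sub = study.all_significant
            snps = sorted(sub.loc[sub["gene_id"] == gene, "variant_id"])
            return snps or [fallback]
        return [fallback]

    rows = []
    for g in genes:
        if g not in best_i.index or g not in best_j.index:
            continue
        ei, ej = best_i[g], best_j[g]
        prox_i: dict[str, tuple[float, int]] = {}
        for s in esnp_sets(study_i, g, ei):
            for p, v in proxy_map_i.proxies(s).items():
                if p not in prox_i or v[0] > prox_i[p][0]:
                    prox_i[p] = v
        prox_j: dict[str, tuple[float, int]] = {}
        for s in esnp_sets(study_j, g, ej):
            for p, v in proxy_map_j.proxies(s).items():
                if p not in prox_j or v[0] > prox_j[p][0]:
                    prox_j[p] = v
        if criterion == "intersect":
            shared_prox = set(prox_i) & set(prox_j)
        else:
            shared_prox = {ej} if ej in prox_i else set()
        match = len(shared_prox) > 0
        best_r2 = max((min(prox_i.get(s, (1.0, 0))[0], prox_j.get(s, (1.0, 0))[0])
                       for s in shared_prox), default=None)
        rows.append({"gene_id": g, "esnp_i": ei, "esnp_j": ej,
                     "direct_match": ei == ej, "proxy_match": match or ei == ej,
                     "best_shared_r2": best_r2,
                     "n_shared_proxies": len(shared_prox)})
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def estimate_chance_overlap_rate(
    study_i: EqtlStudy,
    study_j: EqtlStudy,
    table: GeneMatchTable,
    panel,
    r2_threshold: float = 0.8,
    window_bp: int = 100_000,
) -> float:
    """Chance rate of the pipeline's overlap event, by decoy gene pairing.

    The power adjustment needs a_j: the probability that a discovery eQTL
    counts as overlapping in study j absent true sharing. Because overlap
    here means "gene significant in j AND best eSNPs share an LD proxy", that
    rate is estimated directly on the matching event: each discovery eQTL
    gene is paired with a decoy common-universe gene (index shifted by half
    the universe, so the pairing is unrelated to true sharing), and the rate
    is the fraction of decoy pairs where the decoy gene is significant in j
    and its eSNP proxy-matches the discovery eSNP.
    """
    from .ld import build_proxy_map

    universe = sorted(table.genes)
    n = len(universe)
    if n < 2:
        return 0.0
    best_i = study_i.best_esnp()
    best_j = study_j.best_esnp()
    sig_j = study_j.significant_genes()
    genes_i = [g for g in universe if g in best_i.index]
    if not genes_i:
        return 0.0
    pos = {g: k for k, g in enumerate(universe)}
    shift = max(1, n // 2)
    pairs = []
    for g in genes_i:
        decoy = universe[(pos[g] + shift) % n]
        if decoy == g:
            continue
        pairs.append((best_i[g], decoy))
    if not pairs:
        return 0.0
    esnps = sorted({e for e, _ in pairs}
                   | {best_j[d] for _, d in pairs if d in best_j.index})
    pm = build_proxy_map(panel, esnps, r2_threshold, window_bp)
    hits = 0
    for esnp_i, decoy in pairs:
        if decoy not in sig_j or decoy not in best_j.index:
            continue
        if set(pm.proxies(esnp_i)) & set(pm.proxies(best_j[decoy])):
            hits += 1
    return hits / len(pairs)
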