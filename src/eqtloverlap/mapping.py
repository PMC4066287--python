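"""cis-eQTL calling from genotype-dosage and expression matrices.

For every gene the scan regresses expression on additive dosage (0/1/2) at
every variant within a cis window of the transcription start site (default
±1 Mb, inclusive boundary), tests the slope with a two-sided t-test, applies
study-wide Benjamini-Hochberg FDR across all tested gene-variant pairs, and
keeps one best eSNP (smallest p) per significant gene. A sample-size-weighted
Z-score combiner is provided for multi-cohort discovery studies.

The scan is fully vectorised: closed-form simple-regression statistics over
index arrays of (gene, variant) pairs, chunked to bound memory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CisDesign",
    "EqtlStudy",
    "build_cis_pairs",
    "cis_scan",
    "bh_fdr",
    "call_eqtls",
    "classify_cis_trans",
    "weighted_z_meta",
]

RECORD_COLUMNS = ["gene_id", "variant_id", "beta", "se", "t_stat", "p_value",
                  "n", "distance_to_tss"]


@dataclass
class CisDesign:
    """Precomputed (gene, variant) cis pairs for one study's platform.

    Built once per study and reused across individual subsets (the power
    estimator re-scans many subsamples of the same matrices).
    """

    gene_idx: np.ndarray       # index into gene table, one entry per pair
    variant_idx: np.ndarray    # index into variant table, one entry per pair
    distance: np.ndarray       # signed variant_pos - tss per pair
    gene_ids: np.ndarray
    variant_ids: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.gene_idx)


def build_cis_pairs(
    variant_chrom: np.ndarray,
    variant_pos: np.ndarray,
    gene_ids: np.ndarray,
    gene_chrom: np.ndarray,
    gene_tss: np.ndarray,
    variant_ids: np.ndarray,
    cis_window_bp: int = 1_000_000,
) -> CisDesign:
    """Enumerate all (gene, variant) pairs with |pos - TSS| <= window, same chrom."""
    if cis_window_bp <= 0:
        raise ValueError(f"cis_window_bp must be > 0, got {cis_window_bp}")
    g_parts, v_parts, d_parts = [], [], []
    for c in np.unique(gene_chrom):
        vsel = np.flatnonzero(variant_chrom == c)
        if len(vsel) == 0:
            continue
        order = np.argsort(variant_pos[vsel], kind="stable")
        vsel = vsel[order]
        vpos = variant_pos[vsel]
        gsel = np.flatnonzero(gene_chrom == c)
        lo = np.searchsorted(vpos, gene_tss[gsel] - cis_window_bp, "left")
        hi = np.searchsorted(vpos, gene_tss[gsel] + cis_window_bp, "right")
        counts = hi - lo
        if counts.sum() == 0:
            continue
        g_rep = np.repeat(gsel, counts)
        v_local = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi)])
        v_rep = vsel[v_local]
        g_parts.append(g_rep)
        v_parts.append(v_rep)
        d_parts.append(variant_pos[v_rep] - gene_tss[g_rep])
    if not g_parts:
        gi = np.empty(0, int)
        return CisDesign(gi, gi.copy(), gi.copy(), gene_ids, variant_ids)
    return CisDesign(
        gene_idx=np.concatenate(g_parts),
        variant_idx=np.concatenate(v_parts),
        distance=np.concatenate(d_parts).astype(np.int64),
        gene_ids=np.asarray(gene_ids),
        variant_ids=np.asarray(variant_ids),
    )


def _scan_arrays(
    design: CisDesign,
    genotypes: np.ndarray,
    expression: np.ndarray,
    chunk_pairs: int = 100_000,
    dtype=np.float64,
):
    """Closed-form OLS over all design pairs; returns stat arrays and masks.

    ``dtype=np.float32`` halves memory traffic for large simulation sweeps;
    t-statistics then carry ~1e-4 relative error, immaterial for FDR calls.
    """
    n = genotypes.shape[1]
    if expression.shape[1] != n:
        raise ValueError("genotype and expression matrices disagree on individuals")
    if n < 3:
        raise ValueError(f"need >= 3 individuals, got {n}")
    X = genotypes.astype(dtype)
    Xc = X - X.mean(axis=1, keepdims=True, dtype=dtype)
    sxx = np.einsum("vn,vn->v", Xc, Xc).astype(np.float64)
    Y = expression.astype(dtype)
    Yc = Y - Y.mean(axis=1, keepdims=True, dtype=dtype)
    syy = np.einsum("gn,gn->g", Yc, Yc).astype(np.float64)

    mono_variant = sxx == 0.0
    flat_gene = syy == 0.0
    gi, vi = design.gene_idx, design.variant_idx
    valid = ~(mono_variant[vi] | flat_gene[gi])

    beta = np.full(design.n_pairs, np.nan)
    se = np.full(design.n_pairs, np.nan)
    tstat = np.full(design.n_pairs, np.nan)
    pval = np.full(design.n_pairs, np.nan)
    df = n - 2
    idx = np.flatnonzero(valid)
    for start in range(0, len(idx), chunk_pairs):
        sl = idx[start:start + chunk_pairs]
        sxy = np.einsum("pn,pn->p", Xc[vi[sl]], Yc[gi[sl]]).astype(np.float64)
        b = sxy / sxx[vi[sl]]
        sse = np.maximum(syy[gi[sl]] - sxy * b, 0.0)
        s = np.sqrt(sse / df / sxx[vi[sl]])
        with np.errstate(divide="ignore"):
            t = np.where(s > 0, b / s, np.sign(b) * np.inf)
        beta[sl], se[sl], tstat[sl] = b, s, t
        pval[sl] = 2.0 * stats.t.sf(np.abs(t), df)
    # two-sided p of exactly 0 only in the perfectly-noiseless limit
    np.clip(pval, np.nextafter(0, 1), 1.0, out=pval)
    return beta, se, tstat, pval, valid, mono_variant, flat_gene, n


def cis_scan(
    genotypes: pd.DataFrame | np.ndarray,
    expression: pd.DataFrame | np.ndarray,
    annotation: pd.DataFrame,
    variant_info: pd.DataFrame | None = None,
    cis_window_bp: int = 1_000_000,
    design: CisDesign | None = None,
    dtype=np.float64,
) -> pd.DataFrame:
    """Scan all cis (gene, variant) pairs; return association records.

    Parameters
    ----------
    genotypes
        (variants x individuals) dosage matrix; ``variant_info`` must be
        indexed like the genotype rows and carry ``chrom`` and ``pos``.
    expression
        (genes x individuals) matrix, rows aligned with ``annotation``.
    annotation
        per-gene table with ``gene_id``, ``chrom``, ``tss``.

    Monomorphic variants are skipped with a logged count; zero-variance genes
    are skipped with a warning. Individual columns must already be aligned.
    """
    if isinstance(genotypes, pd.DataFrame):
        variant_ids = genotypes.index.to_numpy()
        G = genotypes.to_numpy()
    else:
        if variant_info is None:
            raise ValueError("variant_info is required with array genotypes")
        variant_ids = variant_info.index.to_numpy()
        G = np.asarray(genotypes)
    if variant_info is None:
        raise ValueError("variant_info (chrom, pos per variant) is required")
    if isinstance(expression, pd.DataFrame):
        E = expression.to_numpy()
    else:
        E = np.asarray(expression)
    if isinstance(genotypes, pd.DataFrame) and isinstance(expression, pd.DataFrame):
        shared = genotypes.columns.intersection(expression.columns)
        if len(shared) == 0:
            raise ValueError("no overlapping individuals between matrices")
        if (len(shared) != genotypes.shape[1]
                or not genotypes.columns.equals(expression.columns)):
            G = genotypes[shared].to_numpy()
            E = expression[shared].to_numpy()

    gene_ids = annotation["gene_id"].to_numpy()
    if design is None:
        design = build_cis_pairs(
            variant_info["chrom"].to_numpy(), variant_info["pos"].to_numpy(np.int64),
            gene_ids, annotation["chrom"].to_numpy(),
            annotation["tss"].to_numpy(np.int64), variant_ids, cis_window_bp)

    beta, se, tstat, pval, valid, mono, flat, n = _scan_arrays(design, G, E,
                                                                dtype=dtype)
    if mono.any():
        logger.info("cis_scan: skipped %d monomorphic variants", int(mono.sum()))
    if flat.any():
        logger.warning("cis_scan: skipped %d zero-variance genes", int(flat.sum()))

    sl = np.flatnonzero(valid)
    return pd.DataFrame({
        "gene_id": design.gene_ids[design.gene_idx[sl]],
        "variant_id": design.variant_ids[design.variant_idx[sl]],
        "beta": beta[sl],
        "se": se[sl],
        "t_stat": tstat[sl],
        "p_value": pval[sl],
        "n": n,
        "distance_to_tss": design.distance[sl],
    })


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up: reject flags (input order) and realized cutoff.

    The realized cutoff is p(k) for the largest k with p(k) <= k*q/m, or 0.0
    when nothing is rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0, 1), got {q}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    thresh = np.arange(1, m + 1) * (q / m)
    below = np.flatnonzero(ps <= thresh)
    if below.size == 0:
        return np.zeros(m, dtype=bool), 0.0
    cutoff = float(ps[below[-1]])
    return p <= cutoff, cutoff


def _best_per_gene(records: pd.DataFrame) -> pd.DataFrame:
    """Smallest p per gene; ties by |distance_to_tss| then variant_id."""
    r = records.assign(_absdist=records["distance_to_tss"].abs())
    r = r.sort_values(["p_value", "_absdist", "variant_id"], kind="stable")
    best = r.drop_duplicates("gene_id", keep="first").drop(columns="_absdist")
    return best.sort_values("gene_id", kind="stable").reset_index(drop=True)


@dataclass
class EqtlStudy:
    """One study's harmonizable eQTL results plus tested-universe metadata."""

    study_id: str
    tissue_label: str
    n_samples: int
    records: pd.DataFrame            # significant, one best eSNP per gene
    n_probes_tested: int
    n_tests: int                     # tested gene-variant pairs
    n_significant_pairs: int
    fdr_level: float
    alpha: float                     # realized study-wide p-value cutoff
    all_significant: pd.DataFrame | None = None

    @property
    def n_genes_with_eqtl(self) -> int:
        return self.records["gene_id"].nunique()

    @classmethod
    def from_table(cls, table: pd.DataFrame, study_id: str | None = None,
                   fdr_level: float = 0.05,
                   n_probes_tested: int | None = None) -> "EqtlStudy":
        """Wrap an externally supplied significant-eQTL summary list.

        The list is reduced to one best eSNP per gene; the realized cutoff is
        taken as the largest listed p-value (the tightest bound a bare list
        supports). Tested-universe counts unavailable from a list are set to 0.
        """
        required = {"gene_id", "variant_id", "p_value"}
        if not required.issubset(table.columns):
            raise ValueError(f"summary table must carry columns {sorted(required)}")
        t = table.copy()
        if "distance_to_tss" not in t.columns:
            t["distance_to_tss"] = 0
        best = _best_per_gene(t)
        sid = study_id or (str(t["study_id"].iloc[0]) if "study_id" in t.columns
                           else "study")
        n = int(t["n_samples"].iloc[0]) if "n_samples" in t.columns else (
            int(t["n"].iloc[0]) if "n" in t.columns else 0)
        return cls(
            study_id=sid, tissue_label="", n_samples=n, records=best,
            n_probes_tested=n_probes_tested or best["gene_id"].nunique(),
            n_tests=0, n_significant_pairs=len(t), fdr_level=fdr_level,
            alpha=float(t["p_value"].max()))

    def significant_genes(self) -> set[str]:
        return set(self.records["gene_id"])

    def best_esnp(self) -> pd.Series:
        return self.records.set_index("gene_id")["variant_id"]

    def to_table(self, annotation: pd.DataFrame | None = None) -> pd.DataFrame:
        """Summary-list TSV shape (the pipeline's lingua franca)."""
        out = self.records.copy()
        out.insert(0, "study_id", self.study_id)
        out["n_samples"] = self.n_samples
        if annotation is not None:
            ann = annotation.set_index("gene_id")
            out["tss"] = ann["tss"].reindex(out["gene_id"]).to_numpy()
            out["chrom"] = ann["chrom"].reindex(out["gene_id"]).to_numpy()
        return out


def call_eqtls(
    records: pd.DataFrame,
    q: float = 0.05,
    mode: str = "best_per_gene",
    study_id: str = "study",
    tissue_label: str = "",
    n_probes_tested: int | None = None,
) -> EqtlStudy:
    """Apply study-wide BH-FDR over all tested pairs and select eSNPs.

    ``mode='best_per_gene'`` keeps, per significant gene, the record with the
    smallest p (documented tie-break); ``mode='all_significant'`` additionally
    retains every significant record in ``all_significant``.
    """
    if mode not in ("best_per_gene", "all_significant"):
        raise ValueError(f"unknown mode {mode!r}")
    reject, cutoff = bh_fdr(records["p_value"].to_numpy(), q)
    sig = records.loc[reject]
    best = _best_per_gene(sig) if len(sig) else sig.reset_index(drop=True)
    n_probes = records["gene_id"].nunique() if n_probes_tested is None else n_probes_tested
    n_samples = int(records["n"].iloc[0]) if len(records) else 0
    return EqtlStudy(
        study_id=study_id,
        tissue_label=tissue_label,
        n_samples=n_samples,
        records=best,
        n_probes_tested=n_probes,
        n_tests=len(records),
        n_significant_pairs=int(reject.sum()),
        fdr_level=q,
        alpha=cutoff,
        all_significant=sig.reset_index(drop=True) if mode == "all_significant" else None,
    )


def classify_cis_trans(
    record, annotation: pd.DataFrame, cis_window_bp: int = 1_000_000,
    variant_chrom: str | None = None, variant_pos: int | None = None,
) -> str:
    """'cis' iff the variant lies within ``cis_window_bp`` of the gene's TSS on
    the same chromosome (inclusive boundary); 'trans' otherwise."""
    ann = annotation.set_index("gene_id") if annotation.index.name != "gene_id" else annotation
    gene = record["gene_id"]
    if gene not in ann.index:
        raise KeyError(f"gene {gene!r} not in annotation")
    if variant_chrom is not None and variant_chrom != ann.loc[gene, "chrom"]:
        return "trans"
    dist = record["distance_to_tss"] if variant_pos is None else (
        variant_pos - ann.loc[gene, "tss"])
    return "cis" if abs(int(dist)) <= cis_window_bp else "trans"


def weighted_z_meta(z_scores, sample_sizes) -> float:
    """Sample-size-weighted Z combination: Z = sum(w_i z_i)/sqrt(sum w_i²),
    w_i = sqrt(n_i). Used to emulate multi-cohort discovery meta-analyses."""
    z = np.asarray(z_scores, dtype=float)
    n = np.asarray(sample_sizes, dtype=float)
    if z.shape != n.shape or z.ndim != 1 or z.size == 0:
        raise ValueError("z_scores and sample_sizes must be equal-length 1-D, non-empty")
    if np.any(n <= 0):
        raise ValueError("sample sizes must be positive")
    w = np.sqrt(n)
    return float(np.sum(w * z) / np.sqrt(np.sum(w * w)))
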