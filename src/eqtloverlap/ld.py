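"""Linkage disequilibrium from a phased haplotype panel and proxy-SNP maps.

The panel plays the role of an external reference (e.g. a 1000-Genomes-style
CEU panel): pairwise r² is computed from phased haplotype frequencies,
r² = D² / (pA(1-pA) pB(1-pB)) with D = pAB - pA*pB, and a proxy map lists, for
each eSNP, the panel variants in high LD (r² above a threshold) within a
physical window. Proxy maps are what lets eQTL hits be matched across studies
genotyped on different SNP arrays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HaplotypePanel",
    "ProxyMap",
    "read_haplotypes",
    "write_haplotypes_tsv",
    "write_haplotypes_vcf",
    "r2",
    "build_proxy_map",
]


class MonomorphicVariantError(ValueError):
    """LD is undefined when one of the variants carries a single allele."""


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes over positioned variants.

    ``haplotypes`` is (n_haplotypes, n_variants) with entries in {0, 1};
    positions are 0-based and strictly increasing within each chromosome.
    """

    variant_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    haplotypes: np.ndarray
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.variant_ids = np.asarray(self.variant_ids)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != len(self.variant_ids):
            raise ValueError("haplotypes must be (n_haplotypes, n_variants)")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("variant ids must be unique")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions must be strictly increasing within {c}")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def allele_freq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    @property
    def monomorphic(self) -> np.ndarray:
        p = self.allele_freq
        return (p == 0.0) | (p == 1.0)

    def index_of(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in panel") from None


def r2(panel: HaplotypePanel, a: str, b: str) -> float:
    """Haplotype-frequency r² between two panel variants (symmetric, in [0, 1])."""
    ia, ib = panel.index_of(a), panel.index_of(b)
    ha = panel.haplotypes[:, ia].astype(float)
    hb = panel.haplotypes[:, ib].astype(float)
    pa, pb = ha.mean(), hb.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise MonomorphicVariantError(
            f"r² undefined: monomorphic variant among ({a}, {b})")
    pab = (ha * hb).mean()
    d = pab - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def _r2_one_vs_many(haps: np.ndarray, idx: int, cand_idx: np.ndarray) -> np.ndarray:
    """Vectorised r² between variant ``idx`` and each candidate column."""
    h = haps[:, idx].astype(np.float64)
    cand = haps[:, cand_idx].astype(np.float64)
    n = haps.shape[0]
    pa = h.mean()
    pb = cand.mean(axis=0)
    pab = h @ cand / n
    d = pab - pa * pb
    denom = pa * (1 - pa) * pb * (1 - pb)
    out = np.full(len(cand_idx), np.nan)
    ok = denom > 0
    out[ok] = d[ok] ** 2 / denom[ok]
    return out


@dataclass
class ProxyMap:
    """Per-eSNP proxy sets: ``entries[esnp_id] -> {proxy_id: (r2, distance_bp)}``.

    Every eSNP maps to a set containing itself with r² = 1 and distance 0; all
    listed r² are >= ``r2_threshold`` and all distances <= ``window_bp``.
    """

    entries: dict[str, dict[str, tuple[float, int]]]
    r2_threshold: float
    window_bp: int

    def proxies(self, esnp_id: str) -> dict[str, tuple[float, int]]:
        """Proxy set of ``esnp_id``; unknown eSNPs degrade to a self-only set."""
        if esnp_id not in self.entries:
            logger.warning("eSNP %s absent from proxy map; using self-only set", esnp_id)
            return {esnp_id: (1.0, 0)}
        return self.entries[esnp_id]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"esnp_id": e, "proxy_id": p, "r2": v[0], "distance_bp": v[1]}
            for e, prox in self.entries.items() for p, v in prox.items()
        ]
        return pd.DataFrame(rows, columns=["esnp_id", "proxy_id", "r2", "distance_bp"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, r2_threshold: float, window_bp: int) -> "ProxyMap":
        df = pd.read_csv(path, sep="\t")
        entries: dict[str, dict[str, tuple[float, int]]] = {}
        for row in df.itertuples(index=False):
            entries.setdefault(row.esnp_id, {})[row.proxy_id] = (
                float(row.r2), int(row.distance_bp))
        return cls(entries=entries, r2_threshold=r2_threshold, window_bp=window_bp)


def build_proxy_map(
    panel: HaplotypePanel,
    esnps: list[str],
    r2_threshold: float = 0.8,
    window_bp: int = 100_000,
) -> ProxyMap:
    """Proxy sets for each eSNP: panel variants within ±``window_bp`` with
    r² >= ``r2_threshold`` (the eSNP itself always included).

    eSNPs absent from the panel get a self-only proxy set (with a warning), so
    platform-private SNPs degrade gracefully. Monomorphic partners are skipped.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError(f"r2_threshold must be in (0, 1], got {r2_threshold}")
    if window_bp < 0:
        raise ValueError(f"window_bp must be >= 0, got {window_bp}")

    mono = panel.monomorphic
    entries: dict[str, dict[str, tuple[float, int]]] = {}
    absent: list[str] = []
    # per-chromosome sorted position index for window queries
    chrom_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in np.unique(panel.chrom):
        sel = np.flatnonzero(panel.chrom == c)
        order = np.argsort(panel.pos[sel], kind="stable")
        idx = sel[order]
        chrom_cache[c] = (panel.pos[idx], idx)

    for esnp in esnps:
        if esnp not in panel._index:
            absent.append(esnp)
            entries[esnp] = {esnp: (1.0, 0)}
            continue
        i = panel.index_of(esnp)
        cpos, cidx = chrom_cache[panel.chrom[i]]
        epos = panel.pos[i]
        lo = np.searchsorted(cpos, epos - window_bp, "left")
        hi = np.searchsorted(cpos, epos + window_bp, "right")
        cand = cidx[lo:hi]
        cand = cand[(~mono[cand]) | (cand == i)]
        r2v = _r2_one_vs_many(panel.haplotypes, i, cand)
        keep = (r2v >= r2_threshold) & ~np.isnan(r2v)
        keep[cand == i] = True
        proxies: dict[str, tuple[float, int]] = {}
        for j, r in zip(cand[keep], r2v[keep]):          # cand is position-sorted
            dist = int(abs(panel.pos[j] - epos))
            proxies[str(panel.variant_ids[j])] = (1.0 if j == i else float(r), dist)
        entries[esnp] = proxies
    if absent:
        logger.warning("%d eSNPs absent from panel; self-only proxy sets used: %s",
                       len(absent), ", ".join(absent[:5]))
    return ProxyMap(entries=entries, r2_threshold=r2_threshold, window_bp=window_bp)


# ---------------------------------------------------------------------------
# I/O

def write_haplotypes_tsv(panel: HaplotypePanel, path: str | Path) -> None:
    """Plain TSV: id, chrom, pos, then one 0/1 column per haplotype."""
    cols = {"id": panel.variant_ids, "chrom": panel.chrom, "pos": panel.pos}
    df = pd.DataFrame(cols)
    hap_cols = pd.DataFrame(
        panel.haplotypes.T, columns=[f"h{k}" for k in range(panel.n_haplotypes)])
    pd.concat([df, hap_cols], axis=1).to_csv(path, sep="\t", index=False)


def write_haplotypes_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Minimal phased VCF (one ALT per record, GT only)."""
    n_ind = panel.n_haplotypes // 2
    if panel.n_haplotypes % 2:
        raise ValueError("VCF output needs an even number of haplotypes")
    samples = [f"ind_{k:05d}" for k in range(n_ind)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=eqtloverlap-synthetic\n")
        for c in pd.unique(pd.Series(panel.chrom)):
            length = int(panel.pos[panel.chrom == c].max()) + 10_000
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        hap = panel.haplotypes
        for v in range(panel.n_variants):
            gts = "\t".join(
                f"{hap[2 * k, v]}|{hap[2 * k + 1, v]}" for k in range(n_ind))
            fh.write(f"{panel.chrom[v]}\t{panel.pos[v] + 1}\t{panel.variant_ids[v]}"
                     f"\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def _read_haplotypes_tsv(path: Path) -> HaplotypePanel:
    df = pd.read_csv(path, sep="\t")
    if "chrom" in df.columns:
        meta, hap_start = df[["id", "chrom", "pos"]], 3
        chrom = meta["chrom"].to_numpy(str)
    else:
        meta, hap_start = df[["id", "pos"]], 2
        chrom = np.full(len(df), "chr1")
    haps = df.iloc[:, hap_start:].to_numpy()
    bad = ~np.isin(haps, (0, 1))
    if bad.any():
        line = int(np.argwhere(bad)[0, 0]) + 2  # header line is 1
        raise ValueError(f"{path}: non-binary haplotype entry at line {line}")
    return HaplotypePanel(
        variant_ids=df["id"].to_numpy(str), chrom=chrom,
        pos=df["pos"].to_numpy(np.int64), haplotypes=haps.T.astype(np.int8))


def _read_haplotypes_vcf(path: Path) -> HaplotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids, chroms, poss, haps = [], [], [], []
    skipped_unphased = skipped_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped_multi += 1
            continue
        g = np.asarray(var.genotypes)  # (n_samples, 3): a, b, phased flag
        if g.shape[1] < 3 or not np.all(g[:, 2]):
            skipped_unphased += 1
            continue
        if np.any(g[:, :2] < 0):
            skipped_unphased += 1
            continue
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS - 1)  # VCF is 1-based
        haps.append(g[:, :2].reshape(-1))
    if skipped_unphased:
        logger.warning("%s: skipped %d unphased/missing records", path, skipped_unphased)
    if skipped_multi:
        logger.warning("%s: skipped %d multi-allelic records", path, skipped_multi)
    if not ids:
        raise ValueError(f"{path}: no usable phased biallelic records")
    return HaplotypePanel(
        variant_ids=np.array(ids), chrom=np.array(chroms),
        pos=np.array(poss, dtype=np.int64),
        haplotypes=np.array(haps, dtype=np.int8).T)


def read_haplotypes(path: str | Path, format: str | None = None) -> HaplotypePanel:
    """Read a haplotype panel from a minimal phased VCF or the plain TSV format.

    Unphased or multi-allelic VCF records are skipped with a logged count.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() in (".vcf", ".gz", ".bcf") else "tsv"
    if format == "vcf":
        return _read_haplotypes_vcf(path)
    if format == "tsv":
        return _read_haplotypes_tsv(path)
    raise ValueError(f"unknown haplotype format {format!r}")
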