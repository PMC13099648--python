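"""snRNA-seq candidate-gene identification.

Cell-level QC, log-normalization, Wilcoxon rank-sum differential expression
at the stated detection/effect gates, APOE-expression-high cell
classification, the six-criterion multilevel candidate-gene filter, and
Jaccard-index cluster alignment across independently processed datasets.

The six criteria for a gene within a target neuronal cluster (raw p < 0.05
throughout, by explicit design to reduce stringency; adjusted p is still
reported):

1. DE between E4-KI and E3-KI at 5 months;
2. DE between E4-KI and E3-KI at 10 months, same direction;
3. DE between APOE-high cells of E4-KI vs E3-KI at 10 months, same direction;
4. NOT DE between fE4-KI/Syn1-Cre+ and E3-KI at 5 and 10 months;
5. NOT DE between E4-KI and E3-KI at 20 months;
6. DE between 20-month and 5-month E3-KI, same direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps

from .stats import fdr_bh

__all__ = [
    "CountMatrix",
    "DEResult",
    "CandidateReport",
    "CONTRAST_KEYS",
    "qc_filter",
    "lognormalize",
    "wilcoxon_de",
    "find_markers",
    "classify_apoe_high",
    "multilevel_filter",
    "jaccard_similarity",
    "greedy_cluster_match",
]

#: canonical contrast table keys consumed by :func:`multilevel_filter`
CONTRAST_KEYS = [
    "e4_vs_e3_05mo",
    "e4_vs_e3_10mo",
    "apoehigh_e4_vs_e3_10mo",
    "fe4_vs_e3_05mo",
    "fe4_vs_e3_10mo",
    "e4_vs_e3_20mo",
    "e3_20mo_vs_e3_05mo",
]

# filter order: (criterion label, contrast keys, required state)
_CRITERIA = [
    ("c1_de_e4_vs_e3_5mo", ["e4_vs_e3_05mo"], "de"),
    ("c2_de_e4_vs_e3_10mo", ["e4_vs_e3_10mo"], "de_same_sign"),
    ("c3_de_apoehigh_10mo", ["apoehigh_e4_vs_e3_10mo"], "de_same_sign"),
    ("c4_not_de_fe4_5_10mo", ["fe4_vs_e3_05mo", "fe4_vs_e3_10mo"], "not_de"),
    ("c5_not_de_e4_vs_e3_20mo", ["e4_vs_e3_20mo"], "not_de"),
    ("c6_de_e3_aging_same_sign", ["e3_20mo_vs_e3_05mo"], "de_same_sign"),
]


@dataclass
class CountMatrix:
    """UMI counts, genes x cells, with gene ids and cell barcodes."""

    counts: sp.csr_matrix
    genes: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError("counts shape must be (n_genes, n_cells)")
        if self.counts.nnz and (self.counts.data < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, idx: np.ndarray) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(self.counts[:, idx],
                           list(self.genes),
                           [self.barcodes[i] for i in idx])


@dataclass
class DEResult:
    """Per-gene differential-expression table for one contrast."""

    table: pd.DataFrame  # gene, log_fc, pct_1, pct_2, p_raw, p_adj, tested
    group_sizes: tuple[int, int] = (0, 0)

    def de_flags(self, alpha: float = 0.05) -> pd.Series:
        t = self.table.set_index("gene")
        return (t["tested"] & (t["p_raw"] < alpha))

    def signs(self) -> pd.Series:
        return np.sign(self.table.set_index("gene")["log_fc"])


@dataclass
class CandidateReport:
    target_cluster: str
    flags: pd.DataFrame            # gene x criterion booleans + candidate
    successive_counts: pd.Series   # genes remaining after each criterion
    candidates: list[str] = field(default_factory=list)


def qc_filter(
    counts: CountMatrix,
    meta: pd.DataFrame,
    gene_lo: int = 200,
    gene_hi: int = 2400,
    umi_lo: int = 500,
    umi_hi: int = 4500,
    mito_max: float = 0.0025,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Retain cells with gene_lo-gene_hi detected genes (inclusive),
    umi_lo-umi_hi UMIs (inclusive) and mito fraction strictly below
    ``mito_max`` (the "less than 0.25%" rule)."""
    if len(meta) != counts.n_cells:
        raise ValueError("metadata not aligned to count matrix")
    n_genes = meta["n_genes_detected"].to_numpy() if "n_genes_detected" in meta \
        else np.asarray((counts.counts > 0).sum(axis=0)).ravel()
    n_umi = meta["n_umi"].to_numpy() if "n_umi" in meta \
        else np.asarray(counts.counts.sum(axis=0)).ravel()
    mito = meta["mito_fraction"].to_numpy()
    keep = ((n_genes >= gene_lo) & (n_genes <= gene_hi)
            & (n_umi >= umi_lo) & (n_umi <= umi_hi)
            & (mito < mito_max))
    if not keep.any():
        raise ValueError("QC filter removed all cells")
    idx = np.flatnonzero(keep)
    return counts.subset_cells(idx), meta.iloc[idx].reset_index(drop=True)


def lognormalize(counts: CountMatrix, scale: float = 10_000.0) -> sp.csr_matrix:
    """Per-cell library-size normalization: x -> ln(1 + scale * x / total)."""
    totals = np.asarray(counts.counts.sum(axis=0)).ravel()
    if (totals == 0).any():
        raise ValueError("cell(s) with zero total counts; run qc_filter first")
    x = counts.counts.tocsc().astype(float)
    x = x.multiply(scale / totals[None, :]).tocsr()
    x.data = np.log1p(x.data)
    return x


def _group_stats(norm: sp.csr_matrix, idx: np.ndarray):
    sub = norm[:, idx]
    pct = np.asarray((sub > 0).sum(axis=1)).ravel() / idx.size
    mean_expm1 = np.asarray(sub.expm1().mean(axis=1)).ravel() if sp.issparse(sub) \
        else np.expm1(sub).mean(axis=1)
    return pct, mean_expm1


def wilcoxon_de(
    norm: sp.csr_matrix,
    cells_a: np.ndarray,
    cells_b: np.ndarray,
    genes: list[str],
    min_pct: float = 0.1,
    logfc_min: float = 0.05,
    base: str = "ln",
) -> DEResult:
    """Wilcoxon rank-sum DE between two cell populations.

    Genes enter testing iff detected in at least ``min_pct`` of cells in
    either population AND |log fold change| >= ``logfc_min``, where
    log_fc = log(mean(expm1(A)) + 1) - log(mean(expm1(B)) + 1) (natural log
    by default, ``base="log2"`` selectable).  Raw p from a tie-corrected
    rank-sum test; BH-adjusted p reported alongside.
    """
    cells_a = np.asarray(cells_a)
    cells_b = np.asarray(cells_b)
    if cells_a.size == 0 or cells_b.size == 0:
        raise ValueError("both cell groups must be non-empty")
    pct1, m1 = _group_stats(norm, cells_a)
    pct2, m2 = _group_stats(norm, cells_b)
    log = np.log if base == "ln" else np.log2
    log_fc = log(m1 + 1.0) - log(m2 + 1.0)
    tested = ((pct1 >= min_pct) | (pct2 >= min_pct)) & (np.abs(log_fc) >= logfc_min)

    p_raw = np.ones(len(genes))
    tidx = np.flatnonzero(tested)
    if tidx.size:
        a = np.asarray(norm[np.ix_(tidx, cells_a)].todense())
        b = np.asarray(norm[np.ix_(tidx, cells_b)].todense())
        with np.errstate(invalid="ignore"):
            res = sps.mannwhitneyu(a, b, axis=1, alternative="two-sided",
                                   method="asymptotic")
        p = np.asarray(res.pvalue)
        p = np.where(np.isfinite(p), p, 1.0)  # constant rows
        p_raw[tidx] = p

    p_adj = np.ones(len(genes))
    if tidx.size:
        p_adj[tidx] = fdr_bh(p_raw[tidx])[0]
    table = pd.DataFrame({
        "gene": genes,
        "log_fc": log_fc,
        "pct_1": pct1,
        "pct_2": pct2,
        "p_raw": p_raw,
        "p_adj": p_adj,
        "tested": tested,
    })
    return DEResult(table, (cells_a.size, cells_b.size))


def find_markers(
    norm: sp.csr_matrix,
    cluster_labels,
    genes: list[str],
    min_pct: float = 0.10,
    logfc_min: float = 0.25,
    alpha: float = 0.05,
    base: str = "log2",
) -> dict[str, list[str]]:
    """One-vs-rest positive marker genes per cluster.

    A marker must be detected in >= ``min_pct`` of the cluster's cells,
    show >= ``logfc_min`` (log2 by default) *higher* expression in the
    cluster than in all other cells, and reach BH-adjusted significance.
    Singleton clusters are skipped with a warning.
    """
    labels = np.asarray(cluster_labels)
    uniq = pd.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least two clusters")
    markers: dict[str, list[str]] = {}
    for cl in uniq:
        inside = np.flatnonzero(labels == cl)
        outside = np.flatnonzero(labels != cl)
        if inside.size < 2:
            warnings.warn(f"cluster {cl!r} has < 2 cells; skipped")
            markers[str(cl)] = []
            continue
        res = wilcoxon_de(norm, inside, outside, genes,
                          min_pct=1.1, logfc_min=0.0, base=base)  # gates below
        t = res.table
        keep = ((t["pct_1"] >= min_pct)
                & (t["log_fc"] >= logfc_min))
        # rerun significance only on the positively enriched set
        tested = np.flatnonzero(keep.to_numpy())
        sig = np.zeros(len(genes), dtype=bool)
        if tested.size:
            a = np.asarray(norm[np.ix_(tested, inside)].todense())
            b = np.asarray(norm[np.ix_(tested, outside)].todense())
            res2 = sps.mannwhitneyu(a, b, axis=1, alternative="two-sided",
                                    method="asymptotic")
            p = np.where(np.isfinite(res2.pvalue), res2.pvalue, 1.0)
            sig[tested] = fdr_bh(p)[1]
        markers[str(cl)] = [genes[i] for i in np.flatnonzero(sig)]
    return markers


def classify_apoe_high(
    norm: sp.csr_matrix,
    meta: pd.DataFrame,
    genes: list[str],
    apoe_gene: str = "Apoe",
    cell_type_col: str = "cluster_id",
    n_sd: float = 2.0,
) -> np.ndarray:
    """APOE-expression-high cells: level strictly above the cell-type median
    plus ``n_sd`` sample standard deviations, computed within each cell type.

    Cell types with fewer than 3 cells are labelled not-high with a warning.
    """
    if apoe_gene not in genes:
        raise ValueError(f"{apoe_gene!r} not in gene list")
    gi = genes.index(apoe_gene)
    level = np.asarray(norm[gi].todense()).ravel()
    high = np.zeros(len(meta), dtype=bool)
    for ct, sub in meta.groupby(cell_type_col):
        idx = sub.index.to_numpy()
        if idx.size < 3:
            warnings.warn(f"cell type {ct!r} has < 3 cells; none labelled APOE-high")
            continue
        x = level[idx]
        med = np.median(x)
        sd = x.std(ddof=1)
        high[idx] = x > med + n_sd * sd
    return high


def multilevel_filter(
    de_tables: dict[str, DEResult],
    target_cluster: str = "",
    alpha: float = 0.05,
) -> CandidateReport:
    """Six-criterion candidate-gene filter.

    "DE" = passed the testing gates AND raw p < ``alpha``; "not DE" is its
    negation.  The direction of effect must agree across all positive
    criteria (c1, c2, c3, c6).  Successive per-criterion pass counts are
    reported in filter order.
    """
    missing = [k for k in CONTRAST_KEYS if k not in de_tables]
    if missing:
        raise ValueError(f"missing contrast table(s): {missing}")

    genes = list(de_tables[CONTRAST_KEYS[0]].table["gene"])
    gset = set(genes)
    for k in CONTRAST_KEYS:
        if set(de_tables[k].table["gene"]) != gset:
            raise ValueError(f"contrast {k} gene universe differs")

    de = {k: de_tables[k].de_flags(alpha).reindex(genes) for k in CONTRAST_KEYS}
    sign = {k: de_tables[k].signs().reindex(genes) for k in CONTRAST_KEYS}
    ref_sign = sign["e4_vs_e3_05mo"]

    flags = pd.DataFrame(index=pd.Index(genes, name="gene"))
    for label, keys, mode in _CRITERIA:
        if mode == "de":
            ok = de[keys[0]]
        elif mode == "de_same_sign":
            ok = de[keys[0]] & (sign[keys[0]] * ref_sign > 0)
        elif mode == "not_de":
            ok = ~de[keys[0]]
            for k in keys[1:]:
                ok &= ~de[k]
        flags[label] = ok.to_numpy()

    passing = np.ones(len(genes), dtype=bool)
    counts = {}
    for label, _, _ in _CRITERIA:
        passing &= flags[label].to_numpy()
        counts[label] = int(passing.sum())
    flags["candidate"] = flags.all(axis=1)
    candidates = list(flags.index[flags["candidate"]])
    return CandidateReport(
        target_cluster=target_cluster,
        flags=flags,
        successive_counts=pd.Series(counts, name="genes_remaining"),
        candidates=candidates,
    )


def standard_contrasts(
    norm: sp.csr_matrix,
    meta: pd.DataFrame,
    genes: list[str],
    apoe_high: np.ndarray | pd.Series | None = None,
    min_pct: float = 0.1,
    logfc_min: float = 0.05,
) -> dict[str, DEResult]:
    """Build the seven DE tables feeding :func:`multilevel_filter`.

    ``apoe_high`` defaults to :func:`classify_apoe_high` on the data.  Cell
    groups are selected from ``meta`` columns genotype (E3 / E4 /
    fE4_Syn1Cre) and age_months.
    """
    if apoe_high is None:
        apoe_high = classify_apoe_high(norm, meta, genes)
    high = pd.Series(np.asarray(apoe_high), index=meta.index)

    def cells(gt, age, mask=None):
        m = (meta["genotype"] == gt) & (meta["age_months"] == age)
        if mask is not None:
            m &= mask
        return np.flatnonzero(m.to_numpy())

    arms = {
        "e4_vs_e3_05mo": (cells("E4", 5), cells("E3", 5)),
        "e4_vs_e3_10mo": (cells("E4", 10), cells("E3", 10)),
        "apoehigh_e4_vs_e3_10mo": (cells("E4", 10, high), cells("E3", 10, high)),
        "fe4_vs_e3_05mo": (cells("fE4_Syn1Cre", 5), cells("E3", 5)),
        "fe4_vs_e3_10mo": (cells("fE4_Syn1Cre", 10), cells("E3", 10)),
        "e4_vs_e3_20mo": (cells("E4", 20), cells("E3", 20)),
        "e3_20mo_vs_e3_05mo": (cells("E3", 20), cells("E3", 5)),
    }
    return {k: wilcoxon_de(norm, a, b, genes, min_pct, logfc_min)
            for k, (a, b) in arms.items()}


def jaccard_similarity(set_a, set_b) -> float:
    """|A ∩ B| / |A ∪ B|; 0 when both sets are empty (convention)."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def greedy_cluster_match(
    similarity: pd.DataFrame,
    sizes_new: dict | None = None,
    sizes_ref: dict | None = None,
    min_similarity: float = 0.0,
) -> tuple[dict, list]:
    """One-to-one greedy alignment of new clusters (rows) to reference
    clusters (columns) by descending Jaccard similarity.

    Ties are broken by the smaller relative size difference between the
    paired clusters (when sizes are given), then lexically.  Returns
    (mapping new->ref, list of unmatched new clusters).
    """
    sim = similarity.copy()
    mapping: dict = {}
    while not sim.empty and sim.shape[1] > 0:
        best = sim.stack()
        if best.empty or best.max() <= min_similarity:
            break
        top = best.max()
        cands = [(r, c) for (r, c), v in best.items() if v == top]
        if len(cands) > 1 and sizes_new and sizes_ref:
            def reldiff(pair):
                r, c = pair
                a, b = sizes_new.get(r, 0), sizes_ref.get(c, 0)
                return abs(a - b) / max(a, b, 1)
            cands.sort(key=lambda p: (reldiff(p), str(p[0]), str(p[1])))
        else:
            cands.sort(key=lambda p: (str(p[0]), str(p[1])))
        r, c = cands[0]
        mapping[r] = c
        sim = sim.drop(index=r, columns=c)
    unmatched = [r for r in similarity.index if r not in mapping]
    return mapping, unmatched
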