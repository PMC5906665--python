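"""Expression-side statistics: RPKM, Benjamini-Hochberg FDR, differential
gene filters, pathway rich factors, and qPCR relative expression (2^-ddCt).

Differential testing itself (count-model dispersion estimation) is out of
scope; this module consumes per-gene log2 fold changes and p-values and
applies the workflow's stated filters: the transcriptome-wide criterion
(linear fold change >= 2 and FDR < 0.05) and the pathway-screen criterion
(p < 0.05 and |log2 fold change| > 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "GeneRecord",
    "DEGRecord",
    "PathwayMap",
    "rpkm",
    "rpkm_table",
    "bh_fdr",
    "flag_degs",
    "rich_factor",
    "ddct",
    "ddct_table",
]


@dataclass(frozen=True)
class GeneRecord:
    """Per-gene read counts with transcript length."""

    gene_id: str
    length_bp: int
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"{self.gene_id}: length_bp must be positive")
        if any(c < 0 for c in self.counts):
            raise ValueError(f"{self.gene_id}: counts must be non-negative")


@dataclass(frozen=True)
class DEGRecord:
    """Per-gene differential statistics with the two significance flags."""

    gene_id: str
    log2fc: float
    pvalue: float
    fdr: float
    sig_global: bool
    sig_aa: bool


@dataclass(frozen=True)
class PathwayMap:
    """pathway id -> member gene ids, with the mapped-gene background."""

    pathways: Mapping[str, frozenset[str]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        for pid, genes in self.pathways.items():
            if not genes <= self.background:
                raise ValueError(f"pathway {pid}: genes outside the background")

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, str]]) -> "PathwayMap":
        d: dict[str, set[str]] = {}
        for pid, gid in pairs:
            d.setdefault(pid, set()).add(gid)
        background = frozenset(g for genes in d.values() for g in genes)
        return cls({p: frozenset(g) for p, g in d.items()}, background)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PathwayMap":
        df = pd.read_csv(path, sep="\t", header=None, names=["pathway_id", "gene_id"],
                         dtype=str, comment="#")
        return cls.from_pairs(list(df.itertuples(index=False, name=None)))


def rpkm(counts: int | np.ndarray, length_bp: int, lib_size: int) -> float | np.ndarray:
    """Reads per kilobase of transcript per million mapped reads:
    1e9 * counts / (lib_size * length_bp)."""
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    if lib_size <= 0:
        raise ValueError("lib_size must be positive")
    return 1e9 * np.asarray(counts, dtype=float) / (float(lib_size) * float(length_bp))


def rpkm_table(genes: Sequence[GeneRecord]) -> pd.DataFrame:
    """RPKM per gene and sample; library sizes are per-sample count totals."""
    counts = np.array([g.counts for g in genes], dtype=float)
    lib_sizes = counts.sum(axis=0)
    if np.any(lib_sizes <= 0):
        raise ValueError("every sample needs a positive library size")
    lengths = np.array([g.length_bp for g in genes], dtype=float)
    values = 1e9 * counts / (lib_sizes[None, :] * lengths[:, None])
    return pd.DataFrame(values, index=[g.gene_id for g in genes],
                        columns=[f"s{i+1}" for i in range(counts.shape[1])])


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def flag_degs(
    records: pd.DataFrame | Sequence[Mapping],
    fc_min: float = 2.0,
    fdr_max: float = 0.05,
    aa_lfc_min: float = 1.0,
    aa_p_max: float = 0.05,
) -> list[DEGRecord]:
    """Apply both significance criteria to per-gene statistics.

    ``sig_global``: linear fold change >= *fc_min* in either direction
    (i.e. 2^|log2fc| >= fc_min) AND fdr < *fdr_max*.
    ``sig_aa``: pvalue < *aa_p_max* AND |log2fc| strictly > *aa_lfc_min*.
    An ``fdr`` column is computed from the p-values when absent.
    """
    df = pd.DataFrame(records)
    required = {"gene_id", "log2fc", "pvalue"}
    if not required <= set(df.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    if "fdr" not in df.columns:
        df = df.assign(fdr=bh_fdr(df["pvalue"].to_numpy()))
    out = []
    for row in df.itertuples(index=False):
        linear_fc = 2.0 ** abs(row.log2fc)
        sig_global = (linear_fc >= fc_min) and (row.fdr < fdr_max)
        sig_aa = (row.pvalue < aa_p_max) and (abs(row.log2fc) > aa_lfc_min)
        out.append(
            DEGRecord(str(row.gene_id), float(row.log2fc), float(row.pvalue),
                      float(row.fdr), bool(sig_global), bool(sig_aa))
        )
    return out


def rich_factor(
    deg_ids: set[str] | frozenset[str],
    pmap: PathwayMap,
    hypergeometric: bool = False,
) -> pd.DataFrame:
    """Per-pathway DEG count and rich factor.

    The rich factor is |DEGs in pathway| / |genes mapped to pathway|; higher
    values mark more intensively regulated pathways.  Rows are sorted by rich
    factor (descending), ties by pathway id.  With ``hypergeometric=True`` an
    over-representation tail probability is attached (an extension beyond the
    ratio itself, off by default).
    """
    rows = []
    n_bg = len(pmap.background)
    n_deg_bg = len(set(deg_ids) & pmap.background)
    for pid, genes in pmap.pathways.items():
        if not genes:
            raise ValueError(f"pathway {pid} is empty")
        hits = len(set(deg_ids) & genes)
        row = {"pathway_id": pid, "deg_count": hits, "pathway_size": len(genes),
               "rich_factor": hits / len(genes)}
        if hypergeometric:
            row["pvalue"] = float(
                _stats.hypergeom.sf(hits - 1, n_bg, n_deg_bg, len(genes))
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(["rich_factor", "pathway_id"],
                          ascending=[False, True]).reset_index(drop=True)


def ddct(
    ct_target_tr: float, ct_ref_tr: float, ct_target_ctl: float, ct_ref_ctl: float
) -> float:
    """Relative expression by the 2^-ddCt method:
    2^-((Ct_target,treated - Ct_ref,treated) - (Ct_target,control - Ct_ref,control))."""
    for v in (ct_target_tr, ct_ref_tr, ct_target_ctl, ct_ref_ctl):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    delta_delta = (ct_target_tr - ct_ref_tr) - (ct_target_ctl - ct_ref_ctl)
    return float(2.0 ** (-delta_delta))


def ddct_table(ct: pd.DataFrame) -> pd.DataFrame:
    """Relative expression per treated replicate from a long-format Ct table.

    Expects columns condition ('treated'/'control'), ct_target, ct_reference.
    Control replicates are averaged into the calibrator delta-Ct; each treated
    replicate yields one 2^-ddCt value.
    """
    required = {"condition", "ct_target", "ct_reference"}
    if not required <= set(ct.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    ctl = ct[ct["condition"] == "control"]
    tr = ct[ct["condition"] == "treated"]
    if ctl.empty or tr.empty:
        raise ValueError("Ct table needs both treated and control rows")
    dct_ctl = (ctl["ct_target"] - ctl["ct_reference"]).mean()
    dct_tr = tr["ct_target"] - tr["ct_reference"]
    rel = 2.0 ** (-(dct_tr - dct_ctl))
    return pd.DataFrame({"replicate": tr.index, "relative_expression": rel.to_numpy()})
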