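"""Expressed-gene filtering, abundance binning and transcriptome-concentration
statistics, plus inter-tissue Pearson correlation with redundancy pruning.

A gene is *expressed* (EG) in a tissue when its FPKM is at least ``eg_min``
(1.0 by default, roughly one mRNA molecule per cell).  Expressed genes are
binned into four abundance classes -- LEG, MEG, HEG, VHEG -- by dataset-scale
FPKM interval edges; everything below ``eg_min`` is *trace*.  Two edge sets
ship as presets:

* :data:`POLLEN_SCHEME` -- edges (1, 10, 40, 400), suited to the 23-tissue
  developmental-atlas scale, where VHEG means >= 400 FPKM;
* :data:`ANTHER_SCHEME` -- edges (1, 50, 200, 2000) for the higher-FPKM
  79-tissue atlas, where VHEG means >= 2000 FPKM.

The concentration statistics quantify how much of a tissue's whole
transcriptome mass sits in its most abundant genes: mature pollen famously
puts ~75% of its transcript mass into its top 300 expressed genes, against
~30-47% for sporophytic tissues.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas_io import ExpressionAtlas

__all__ = [
    "TRACE",
    "AbundanceScheme",
    "POLLEN_SCHEME",
    "ANTHER_SCHEME",
    "TopNStat",
    "TissueSummary",
    "CorrelationMatrix",
    "classify_abundance",
    "summarize_tissue",
    "summarize_atlas",
    "correlation_matrix",
    "prune_redundant_tissues",
]

#: Label for genes below the expressed-gene threshold.
TRACE = "trace"


@dataclass(frozen=True)
class AbundanceScheme:
    """Expressed-gene threshold plus abundance bin edges.

    ``bin_edges[i]`` is the closed lower bound of ``bin_labels[i]``; each bin
    is half-open ``[edge_i, edge_{i+1})`` and the top bin is ``[last, inf)``,
    matching the ">= 400 FPKM" phrasing of the VHEG definition.  The first
    edge must equal ``eg_min`` so that the bins exactly partition the
    expressed range.
    """

    eg_min: float = 1.0
    bin_edges: tuple[float, ...] = (1.0, 10.0, 40.0, 400.0)
    bin_labels: tuple[str, ...] = ("LEG", "MEG", "HEG", "VHEG")

    def __post_init__(self) -> None:
        if len(self.bin_edges) != len(self.bin_labels):
            raise ValueError("bin_edges and bin_labels must have equal length")
        if not self.bin_edges:
            raise ValueError("at least one bin is required")
        if any(b <= a for a, b in zip(self.bin_edges, self.bin_edges[1:])):
            raise ValueError("bin_edges must be strictly increasing")
        if self.bin_edges[0] != self.eg_min:
            raise ValueError("bin_edges[0] must equal eg_min")


POLLEN_SCHEME = AbundanceScheme()
ANTHER_SCHEME = AbundanceScheme(1.0, (1.0, 50.0, 200.0, 2000.0))


def classify_abundance(fpkm: float, scheme: AbundanceScheme = POLLEN_SCHEME) -> str:
    """Map one FPKM value to its abundance label (or ``"trace"``).

    Every finite non-negative value maps to exactly one of
    ``{trace} | bin_labels``; bins are closed below, open above.
    """
    if not math.isfinite(fpkm) or fpkm < 0:
        raise ValueError(f"FPKM must be finite and >= 0, got {fpkm!r}")
    if fpkm < scheme.eg_min:
        return TRACE
    return scheme.bin_labels[bisect_right(scheme.bin_edges, fpkm) - 1]


@dataclass(frozen=True)
class TopNStat:
    """Concentration of transcript mass in the N most abundant expressed genes."""

    n: int                      # requested N
    n_used: int                 # min(N, number of expressed genes)
    mean_fpkm: float | None     # mean FPKM of the top-N expressed genes
    percent: float | None       # 100 * top-N FPKM mass / whole-transcriptome mass


@dataclass(frozen=True)
class TissueSummary:
    """Per-tissue expressed-gene and abundance-bin summary (Table-1 style)."""

    tissue: str
    n_eg: int
    bin_counts: Mapping[str, int]
    mean_fpkm_eg: float | None
    top_n_stats: Mapping[int, TopNStat]


def summarize_tissue(
    atlas: ExpressionAtlas,
    tissue: str,
    scheme: AbundanceScheme = POLLEN_SCHEME,
    top_ns: Sequence[int] = (300, 1000),
) -> TissueSummary:
    """Expressed-gene count, bin counts and top-N concentration for one tissue.

    The top-N percentage uses the *whole transcriptome* as denominator: the
    summed FPKM of all genes in the tissue, trace genes included.  When a
    tissue has no transcript mass at all the percentage is undefined and
    reported as ``None`` (never 0).  If ``N`` exceeds the number of expressed
    genes, all expressed genes are used.
    """
    if any(n < 1 for n in top_ns):
        raise ValueError("every top-N must be >= 1")
    col = atlas.tissue(tissue).to_numpy()
    eg = col[col >= scheme.eg_min]
    n_eg = int(eg.size)

    edges = list(scheme.bin_edges) + [np.inf]
    counts, _ = np.histogram(eg, bins=edges)
    bin_counts = {label: int(c) for label, c in zip(scheme.bin_labels, counts)}

    total_mass = float(col.sum())
    mean_eg = float(eg.mean()) if n_eg else None

    eg_sorted = np.sort(eg)[::-1]
    stats: dict[int, TopNStat] = {}
    for n in top_ns:
        n_used = min(int(n), n_eg)
        if n_used == 0:
            stats[int(n)] = TopNStat(int(n), 0, None, None)
            continue
        top = eg_sorted[:n_used]
        percent = 100.0 * float(top.sum()) / total_mass if total_mass > 0 else None
        stats[int(n)] = TopNStat(int(n), n_used, float(top.mean()), percent)

    return TissueSummary(tissue, n_eg, bin_counts, mean_eg, stats)


def summarize_atlas(
    atlas: ExpressionAtlas,
    scheme: AbundanceScheme = POLLEN_SCHEME,
    top_ns: Sequence[int] = (300, 1000),
) -> pd.DataFrame:
    """Table-1-style summary over every tissue of the atlas.

    One row per tissue: expressed-gene count, per-bin counts, mean FPKM of
    expressed genes, and mean/percent for each requested top-N.
    """
    rows = []
    for tissue in atlas.tissue_names:
        s = summarize_tissue(atlas, tissue, scheme, top_ns)
        row: dict[str, object] = {"tissue": s.tissue, "n_eg": s.n_eg}
        row.update({label: s.bin_counts[label] for label in scheme.bin_labels})
        row["mean_fpkm_eg"] = s.mean_fpkm_eg
        for n, st in s.top_n_stats.items():
            row[f"top{n}_mean_fpkm"] = st.mean_fpkm
            row[f"top{n}_percent"] = st.percent
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlation of tissue transcript profiles.

    ``r`` is a square DataFrame indexed by tissue in atlas order.  Tissues
    whose transformed profile has zero variance cannot be correlated; their
    rows/columns (diagonal included) are NaN and the tissue is listed in
    ``degenerate`` rather than being silently reported as r = 0.
    """

    r: pd.DataFrame = field(repr=False)
    degenerate: tuple[str, ...] = ()

    @property
    def tissue_names(self) -> list[str]:
        return list(self.r.columns)


def correlation_matrix(
    atlas: ExpressionAtlas,
    transform: str = "identity",
) -> CorrelationMatrix:
    """Pearson correlation between tissues over genes.

    ``transform`` is ``"identity"`` (raw FPKM, the default) or ``"log2p1"``
    (log2(x+1), useful because raw-FPKM correlation is dominated by the few
    largest genes).
    """
    if atlas.n_genes < 2:
        raise ValueError("correlation requires at least 2 genes")
    x = atlas.values.astype(float)
    if transform == "log2p1":
        x = np.log2(x + 1.0)
    elif transform != "identity":
        raise ValueError(f"unknown transform {transform!r}")

    std = x.std(axis=0)
    degenerate = [t for t, s in zip(atlas.tissue_names, std) if s == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    mask = std == 0
    r[mask, :] = np.nan
    r[:, mask] = np.nan
    idx = np.where(~mask)[0]
    r[idx, idx] = 1.0
    frame = pd.DataFrame(r, index=atlas.tissue_names, columns=atlas.tissue_names)
    return CorrelationMatrix(frame, tuple(degenerate))


def prune_redundant_tissues(
    matrix: CorrelationMatrix,
    r_threshold: float,
    priority: Sequence[str],
) -> list[str]:
    """Greedy redundancy pruning of near-duplicate tissue profiles.

    Tissues are scanned in ``priority`` order; a tissue is dropped iff its
    correlation with an already-retained tissue is >= ``r_threshold``.  The
    result is deterministic given the priority (first listed wins), trading
    optimality for auditability.  Missing correlations (degenerate tissues)
    never cause a drop.
    """
    if not (0 < r_threshold <= 1):
        raise ValueError(f"r_threshold must be in (0, 1], got {r_threshold!r}")
    if sorted(priority) != sorted(matrix.tissue_names):
        raise ValueError("priority must be a permutation of the matrix tissues")
    retained: list[str] = []
    for t in priority:
        redundant = any(
            not pd.isna(matrix.r.at[t, kept]) and matrix.r.at[t, kept] >= r_threshold
            for kept in retained
        )
        if not redundant:
            retained.append(t)
    return retained
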