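"""The tissue-specificity screen: ratio against the other tissues, specific and
abundant gene calls, set intersection, and known-gene recovery.

A gene is called *specific* to the target tissue when it clears two gates:

1. expression gate -- FPKM >= ``min_expr`` (default 1) in the target tissue;
2. ratio gate -- target FPKM at least ``fold`` times (default 100) the
   arithmetic mean FPKM over the other selected tissues.

The mean-of-others denominator is the default; a stricter ``"max"`` mode
compares against the maximum over the other tissues instead (i.e. requires
the fold change against *every* other tissue).  A gene expressed in the
target but in no other tissue has an infinite ratio and is specific: absence
of expression elsewhere is the strongest possible specificity evidence.  A
``pseudocount`` added to the denominator is available to soften that rule.

*Abundant* is an independent call: target FPKM >= ``abundant_min``
(400 FPKM for the pollen-scale dataset, 2000 for the anther-scale one).

This screen is a deterministic threshold rule, not a statistical test;
no variance modelling or multiple-testing correction applies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas_io import ExpressionAtlas

__all__ = [
    "SpecificityConfig",
    "GeneSet",
    "ScreenResult",
    "RecoveryResult",
    "screen_specific",
    "intersect",
    "known_recovery",
    "read_gene_set",
    "write_gene_set",
]


@dataclass(frozen=True)
class SpecificityConfig:
    """Thresholds of the specificity screen.

    ``fold=100`` is the default ratio threshold (10- and 50-fold being too
    permissive for clean tissue-specific sets); comparisons are non-strict
    (>= fold, >= min_expr, >= abundant_min).
    """

    min_expr: float = 1.0
    fold: float = 100.0
    abundant_min: float = 400.0
    pseudocount: float = 0.0
    denominator: str = "mean"   # "mean" | "max"

    def __post_init__(self) -> None:
        if self.min_expr < 0:
            raise ValueError("min_expr must be >= 0")
        if self.fold <= 0:
            raise ValueError("fold must be > 0")
        if self.abundant_min <= 0:
            raise ValueError("abundant_min must be > 0")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.denominator not in ("mean", "max"):
            raise ValueError("denominator must be 'mean' or 'max'")


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene ids (e.g. MPS, MAS, MPA, MAA, MAPS)."""

    name: str
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


@dataclass
class ScreenResult:
    """Per-gene records plus the specific and abundant sets for one target.

    ``records`` has one row per atlas gene: target_fpkm, mean_other (or max,
    per the configured denominator), ratio, is_specific, is_abundant.  Genes
    with no expression anywhere have an undefined (NaN) ratio and are never
    specific, but are still emitted for a full audit trail.
    """

    target: str
    config: SpecificityConfig
    records: pd.DataFrame = field(repr=False)
    specific: GeneSet = field(repr=False)
    abundant: GeneSet = field(repr=False)

    @property
    def n_specific(self) -> int:
        return len(self.specific)

    @property
    def n_abundant(self) -> int:
        return len(self.abundant)

    @property
    def n_specific_and_abundant(self) -> int:
        return len(self.specific.members & self.abundant.members)

    @property
    def pct_abundant_specific(self) -> float | None:
        """Percent of abundant genes that are also specific (None if no abundant)."""
        if self.n_abundant == 0:
            return None
        return 100.0 * self.n_specific_and_abundant / self.n_abundant


def screen_specific(
    atlas: ExpressionAtlas,
    target: str,
    cfg: SpecificityConfig = SpecificityConfig(),
) -> ScreenResult:
    """Screen every gene for target-tissue specificity and abundance.

    Ratio convention with zero pseudocount: denominator 0 with positive
    target FPKM gives ratio +inf (specific if the expression gate passes);
    denominator 0 with target 0 gives an undefined ratio, reported as NaN
    and not specific.  The result is invariant to the order of the
    non-target tissues and, with zero pseudocount, to a global rescaling
    of the atlas (abundance calls rescale as expected).
    """
    if target not in atlas.data.columns:
        raise ValueError(f"target tissue {target!r} not in atlas")
    if atlas.n_tissues < 2:
        raise ValueError("screen requires at least 2 tissues")

    t = atlas.data[target].to_numpy(dtype=float)
    others = atlas.data.drop(columns=[target]).to_numpy(dtype=float)
    if cfg.denominator == "mean":
        other_stat = others.mean(axis=1)
    else:
        other_stat = others.max(axis=1)
    denom = other_stat + cfg.pseudocount

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(denom > 0, t / denom,
                         np.where(t > 0, np.inf, np.nan))
    with np.errstate(invalid="ignore"):
        is_specific = (t >= cfg.min_expr) & (ratio >= cfg.fold)
    is_abundant = t >= cfg.abundant_min

    records = pd.DataFrame(
        {
            "gene": atlas.gene_ids,
            "target_fpkm": t,
            "mean_other": other_stat,
            "ratio": ratio,
            "is_specific": is_specific,
            "is_abundant": is_abundant,
        }
    )
    genes = np.asarray(atlas.gene_ids, dtype=object)
    specific = GeneSet(f"{target}-specific", frozenset(genes[is_specific]))
    abundant = GeneSet(f"{target}-abundant", frozenset(genes[is_abundant]))
    return ScreenResult(target, cfg, records, specific, abundant)


def intersect(a: GeneSet, b: GeneSet, name: str) -> GeneSet:
    """Intersection of two gene sets under a new name (commutative)."""
    return GeneSet(name, a.members & b.members)


@dataclass
class RecoveryResult:
    """How many independently known genes a candidate set recovers."""

    n_known: int
    n_recovered: int
    fraction: float
    table: pd.DataFrame = field(repr=False)  # columns: gene, recovered


def known_recovery(candidate: GeneSet, known: Sequence[str]) -> RecoveryResult:
    """Check a candidate set against an ordered list of known genes.

    Duplicate known ids are collapsed (keeping first occurrence) with a
    warning; an empty known list is an error.
    """
    if len(known) == 0:
        raise ValueError("known gene list is empty")
    deduped: list[str] = []
    seen: set[str] = set()
    for g in known:
        if g in seen:
            continue
        seen.add(g)
        deduped.append(g)
    if len(deduped) != len(known):
        warnings.warn(
            f"known gene list contains {len(known) - len(deduped)} duplicate id(s); "
            "collapsed",
            stacklevel=2,
        )
    flags = [g in candidate for g in deduped]
    table = pd.DataFrame({"gene": deduped, "recovered": flags})
    n_rec = int(sum(flags))
    return RecoveryResult(len(deduped), n_rec, n_rec / len(deduped), table)


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    """Write a gene set as one id per line (sorted for stable output)."""
    Path(path).write_text("".join(f"{g}\n" for g in sorted(gene_set.members)),
                          encoding="utf-8")


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-id-per-line gene set file (blank lines ignored)."""
    path = Path(path)
    members = frozenset(
        line.strip() for line in path.read_text(encoding="utf-8").splitlines()
        if line.strip()
    )
    return GeneSet(name or path.stem, members)
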