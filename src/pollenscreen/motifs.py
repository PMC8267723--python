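"""Cis-element registry, occurrence counting, and the enrichment index.

Motifs are short exact DNA patterns in which any position may be a single
base (A/C/G/T) or a bracketed character class such as ``[TA]`` (the
``[T/A]`` spelling is accepted as well).  Scanning is forward-strand only
and counts every overlapping window; a motif and its reverse complement are
separate registry entries (the pollen registry lists both AGAAA and TTTCT),
which avoids double-counting logic for double-strand scans.  N bases never
match anything.

The null model against which enrichment is judged is the uniform-sequence
expectation: a pattern matching ``m`` concrete words of length ``k`` is
expected ``L * m / 4**k`` times in ``L`` bp of random DNA -- e.g. a fully
specified 5-mer once per 4^5 = 1024 bp, a 7-mer once per 4^7 = 16384 bp.
The slightly smaller sliding-window expectation ``(L - k + 1) * m / 4**k``
is available as ``mode="windows"``; the difference (the edge-effect bias,
a factor (L-k+1)/L ~ 0.998 for k=5 and L=2000) is documented and tested.

The enrichment index of a motif over a promoter set is the mean observed
count per promoter divided by the mean expected count (per-promoter lengths
honoured); an index strictly greater than 1 is called enriched.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Motif",
    "MotifCountTable",
    "EnrichmentResult",
    "SiteTotals",
    "parse_motif",
    "count_occurrences",
    "count_table",
    "expected_count",
    "enrichment_index",
    "enrichment_table",
    "site_totals",
    "DEFAULT_MOTIFS",
    "load_registry",
    "write_registry",
]

_BASES = frozenset("ACGT")
_SEQ_OK = re.compile(r"^[ACGTN]*$")


@dataclass(frozen=True)
class Motif:
    """A named cis-element pattern.

    ``positions`` holds, for each of the ``k`` pattern positions, the sorted
    string of bases allowed there.  ``m`` is the number of concrete words the
    pattern matches (the product of class sizes).
    """

    name: str
    pattern: str
    positions: tuple[str, ...]
    category: str = ""
    source: str = ""

    @property
    def k(self) -> int:
        return len(self.positions)

    @property
    def m(self) -> int:
        m = 1
        for cls in self.positions:
            m *= len(cls)
        return m

    @property
    def regex(self) -> re.Pattern[str]:
        """Compiled overlap-counting (zero-width lookahead) pattern."""
        return _compile(self.positions, overlapping=True)

    def words(self) -> list[str]:
        """All concrete words the pattern matches, lexicographic order."""
        out = [""]
        for cls in self.positions:
            out = [w + b for w in out for b in cls]
        return out


def _compile(positions: tuple[str, ...], overlapping: bool) -> re.Pattern[str]:
    body = "".join(p if len(p) == 1 else f"[{p}]" for p in positions)
    return re.compile(f"(?={body})" if overlapping else body)


def parse_motif(name: str, pattern: str, category: str = "", source: str = "") -> Motif:
    """Parse a pattern string such as ``AGAAA``, ``[TA]AAAG`` or ``[T/A]AAAG``.

    Case-insensitive.  Errors on characters outside ``{A,C,G,T,[,],/}``, on
    empty or unterminated classes, and on empty patterns.
    """
    if not pattern:
        raise ValueError("empty motif pattern")
    up = pattern.upper()
    positions: list[str] = []
    i = 0
    while i < len(up):
        ch = up[i]
        if ch in _BASES:
            positions.append(ch)
            i += 1
        elif ch == "[":
            j = up.find("]", i)
            if j < 0:
                raise ValueError(f"unterminated class in motif pattern {pattern!r}")
            cls = {c for c in up[i + 1:j] if c != "/"}
            bad = cls - _BASES
            if bad:
                raise ValueError(
                    f"illegal character(s) {sorted(bad)} in motif pattern {pattern!r}"
                )
            if not cls:
                raise ValueError(f"empty class in motif pattern {pattern!r}")
            positions.append("".join(sorted(cls)))
            i = j + 1
        else:
            raise ValueError(
                f"illegal character {ch!r} in motif pattern {pattern!r}"
            )
    canonical = "".join(p if len(p) == 1 else f"[{p}]" for p in positions)
    return Motif(name, canonical, tuple(positions), category, source)


def count_occurrences(sequence: str, motif: Motif, overlapping: bool = True) -> int:
    """Count forward-strand occurrences of a motif in a sequence.

    Overlapping windows all count by default (``overlapping=False`` counts
    left-to-right non-overlapping matches instead).  The sequence may be any
    case over A/C/G/T/N; N matches nothing.
    """
    seq = sequence.upper()
    if not _SEQ_OK.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"illegal sequence character(s): {bad}")
    if len(seq) < motif.k:
        return 0
    pattern = _compile(motif.positions, overlapping)
    return sum(1 for _ in pattern.finditer(seq))


@dataclass
class MotifCountTable:
    """Occurrence counts: one row per promoter, one column per motif.

    ``lengths`` carries each promoter's actual sequence length so the
    expected counts honour truncated promoters.
    """

    counts: pd.DataFrame = field(repr=False)
    lengths: pd.Series = field(repr=False)
    motifs: dict[str, Motif] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.lengths.index):
            raise ValueError("counts and lengths must share the same promoter index")

    @property
    def motif_names(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_promoters(self) -> int:
        return self.counts.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Counts with gene and length columns, ready for writing as TSV."""
        out = self.counts.copy()
        out.insert(0, "length", self.lengths)
        out.insert(0, "gene", self.counts.index)
        return out.reset_index(drop=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   motifs: Iterable[Motif] = ()) -> "MotifCountTable":
        frame = frame.set_index("gene")
        lengths = frame.pop("length").astype(int)
        return cls(frame.astype(int), lengths, {m.name: m for m in motifs})


def count_table(
    promoters,
    motifs: Sequence[Motif],
    overlapping: bool = True,
) -> MotifCountTable:
    """Scan every promoter for every motif.

    ``promoters`` may be a :class:`~pollenscreen.promoters.PromoterSet` or
    any mapping of id -> sequence.
    """
    if hasattr(promoters, "sequences"):
        seqs = promoters.sequences()
    else:
        seqs = dict(promoters)
    data = {
        motif.name: [count_occurrences(seq, motif, overlapping)
                     for seq in seqs.values()]
        for motif in motifs
    }
    index = pd.Index(list(seqs), name="gene")
    counts = pd.DataFrame(data, index=index, dtype=int)
    lengths = pd.Series([len(s) for s in seqs.values()], index=index, dtype=int)
    return MotifCountTable(counts, lengths, {m.name: m for m in motifs})


def expected_count(motif: Motif, length: int, mode: str = "length") -> float:
    """Expected occurrences of a motif in ``length`` bp of uniform DNA.

    ``mode="length"`` (default) uses the L-based null ``L * m / 4**k``;
    ``mode="windows"`` uses the strict sliding-window count
    ``max(L - k + 1, 0) * m / 4**k``.
    """
    if length < 0:
        raise ValueError("length must be >= 0")
    if mode == "length":
        n_windows = length
    elif mode == "windows":
        n_windows = max(length - motif.k + 1, 0)
    else:
        raise ValueError(f"unknown expected-count mode {mode!r}")
    return n_windows * motif.m / 4 ** motif.k


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed vs expected frequency of one motif over a promoter set."""

    motif: str
    actual_mean: float
    expected_mean: float
    index: float
    enriched: bool  # strictly index > 1


def enrichment_index(
    table: MotifCountTable,
    motif: str | Motif,
    mode: str = "length",
) -> EnrichmentResult:
    """Enrichment index of one motif: mean observed / mean expected count.

    The expectation is averaged over the actual per-promoter lengths.  All
    promoters empty (expected mean 0) is an error rather than a division
    by zero.
    """
    if isinstance(motif, Motif):
        name, mot = motif.name, motif
    else:
        name = motif
        if name not in table.motifs:
            raise KeyError(f"motif {name!r} not in count table")
        mot = table.motifs[name]
    if name not in table.counts.columns:
        raise KeyError(f"motif {name!r} not in count table")
    if table.n_promoters < 1:
        raise ValueError("enrichment requires at least one promoter")

    actual_mean = float(table.counts[name].mean())
    expected_mean = float(
        np.mean([expected_count(mot, int(length), mode) for length in table.lengths])
    )
    if expected_mean == 0:
        raise ValueError("expected mean count is 0 (all promoters empty)")
    index = actual_mean / expected_mean
    return EnrichmentResult(name, actual_mean, expected_mean, index, index > 1)


def enrichment_table(
    table: MotifCountTable,
    mode: str = "length",
) -> pd.DataFrame:
    """Enrichment index for every motif of a count table, as a DataFrame."""
    rows = []
    for name in table.motif_names:
        res = enrichment_index(table, name, mode)
        mot = table.motifs.get(name)
        rows.append(
            {
                "motif": name,
                "pattern": mot.pattern if mot else "",
                "category": mot.category if mot else "",
                "actual_mean": res.actual_mean,
                "expected_mean": res.expected_mean,
                "enrichment_index": res.index,
                "enriched": res.enriched,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SiteTotals:
    """Per-promoter summed site counts over a motif subset."""

    per_promoter: pd.Series = field(repr=False)
    min: int = 0
    max: int = 0
    mean: float = 0.0


def site_totals(table: MotifCountTable, motif_subset: Sequence[str]) -> SiteTotals:
    """Total cis-element sites per promoter over a subset of motifs.

    Typical use: the pollen-specific registry category, to report the
    min/max/mean number of pollen CRE sites per promoter.
    """
    if len(motif_subset) == 0:
        raise ValueError("motif subset is empty")
    unknown = [m for m in motif_subset if m not in table.counts.columns]
    if unknown:
        raise KeyError(f"unknown motif name(s): {unknown}")
    totals = table.counts[list(motif_subset)].sum(axis=1)
    return SiteTotals(totals, int(totals.min()), int(totals.max()),
                      float(totals.mean()))


# ---------------------------------------------------------------------------
# Default registry: the well-characterised pollen-specific elements plus the
# JA- and ABA-responsive elements scanned alongside them.
# ---------------------------------------------------------------------------

_DEFAULT_ROWS = [
    ("AGAAA", "AGAAA", "pollen", "LAT52 pollen-specific element (tomato)"),
    ("TCCACCA", "TCCACCA", "pollen", "LAT52 second pollen-specific element (tomato)"),
    ("TGTGGTT", "TGTGGTT", "pollen", "LAT52/56 PB core motif (tomato)"),
    ("[TA]AAAG", "[TA]AAAG", "pollen", "Dof core element"),
    ("AAATGA", "AAATGA", "pollen", "NTP303 pollen-specific element (tobacco)"),
    ("TTTCT", "TTTCT", "pollen",
     "SBgLR element (potato); reverse complement of AGAAA"),
    ("TGTGA", "TGTGA", "pollen", "LAT56/59 box (tomato)"),
    ("AGGTCA", "AGGTCA", "pollen", "Zm13 Q-element (maize)"),
    ("GAAACG", "GAAACG", "pollen", "MGSA element"),
    ("GAATAT", "GAATAT", "pollen", "ACA7 cis-regulatory module element (Arabidopsis)"),
    ("GCCGCC", "GCCGCC", "JA", "GCC box, JA/ethylene-responsive"),
    ("CGTCA", "CGTCA", "JA", "CGTCA motif, MeJA-responsive"),
    ("TGACG", "TGACG", "JA", "TGACG motif, MeJA-responsive"),
    ("CCACC", "CCACC", "ABA", "ABRE coupling element 1 (ABRE-CE1)"),
]

#: The shipped registry: 10 pollen-specific elements, 3 JA-responsive, 1 ABA.
DEFAULT_MOTIFS: tuple[Motif, ...] = tuple(
    parse_motif(name, pattern, category, source)
    for name, pattern, category, source in _DEFAULT_ROWS
)


def load_registry(path: str | Path) -> list[Motif]:
    """Read a motif registry TSV with columns name, pattern, category, source."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"name", "pattern"}
    if not required.issubset(frame.columns):
        raise ValueError(f"registry must have columns {sorted(required)}")
    motifs = []
    for row in frame.itertuples(index=False):
        motifs.append(
            parse_motif(row.name, row.pattern,
                        getattr(row, "category", ""), getattr(row, "source", ""))
        )
    names = [m.name for m in motifs]
    if len(set(names)) != len(names):
        raise ValueError("registry contains duplicate motif names")
    return motifs


def write_registry(motifs: Sequence[Motif], path: str | Path) -> None:
    """Write a motif registry as TSV (name, pattern, category, source)."""
    frame = pd.DataFrame(
        [
            {"name": m.name, "pattern": m.pattern,
             "category": m.category, "source": m.source}
            for m in motifs
        ]
    )
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
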