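"""Strand-aware extraction of upstream-of-ATG promoter sequences.

The promoter of a gene is defined here as the 2 kb (configurable) of genomic
sequence immediately upstream of the translation start codon (ATG) of the
gene's representative transcript -- upstream of the ATG, not of the
transcription start site, which sidesteps incomplete 5' UTR annotation.

Coordinates follow GFF3 throughout: 1-based, fully closed intervals.  For a
+ strand gene with translation start ``s`` the promoter is
``contig[max(1, s-length) .. s-1]`` verbatim; for a - strand gene it is the
reverse complement of ``contig[s+1 .. min(L, s+length)]``.  Promoters cut
short by a contig edge are kept and flagged ``truncated`` rather than
dropped; downstream enrichment honours each promoter's actual length.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gffutils
from pyfaidx import Fasta

from .atlas_io import write_gene_table

__all__ = [
    "GeneModel",
    "PromoterRecord",
    "PromoterSet",
    "load_gene_models",
    "representative_translation_start",
    "extract_promoters",
    "reverse_complement",
    "write_promoters",
    "read_promoters",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an uppercase A/C/G/T/N sequence."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to what promoter extraction needs.

    ``translation_start`` is the 1-based contig coordinate of the first base
    of the start codon of the representative transcript (the transcript with
    the longest total CDS; ties broken by lexicographically smallest id).
    """

    gene: str
    contig: str
    strand: str
    translation_start: int
    transcript: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.translation_start < 1:
            raise ValueError("translation_start must be >= 1 (1-based)")


@dataclass(frozen=True)
class PromoterRecord:
    """One extracted promoter with provenance coordinates.

    ``start``/``end`` are the 1-based inclusive contig interval that was
    extracted (on the + strand of the contig; - strand promoters are the
    reverse complement of that interval).  An empty promoter (gene at the
    very contig edge) has end < start and length 0.
    """

    gene: str
    sequence: str
    contig: str
    strand: str
    start: int
    end: int
    truncated: bool

    @property
    def length(self) -> int:
        return len(self.sequence)


class PromoterSet:
    """Ordered collection of promoter records keyed by gene id."""

    def __init__(self, records: Iterable[PromoterRecord] = ()):
        self._records: dict[str, PromoterRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: PromoterRecord) -> None:
        if rec.gene in self._records:
            raise ValueError(f"duplicate promoter for gene {rec.gene!r}")
        self._records[rec.gene] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[PromoterRecord]:
        return iter(self._records.values())

    def __contains__(self, gene: str) -> bool:
        return gene in self._records

    def __getitem__(self, gene: str) -> PromoterRecord:
        return self._records[gene]

    @property
    def genes(self) -> list[str]:
        return list(self._records)

    def sequences(self) -> dict[str, str]:
        return {g: r.sequence for g, r in self._records.items()}


def _open_annotation(annotation: str | Path | gffutils.FeatureDB) -> gffutils.FeatureDB:
    if isinstance(annotation, gffutils.FeatureDB):
        return annotation
    return gffutils.create_db(
        str(annotation),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )


def representative_translation_start(
    annotation: str | Path | gffutils.FeatureDB,
    gene: str,
) -> GeneModel:
    """Locate the start-codon coordinate of a gene's representative transcript.

    The representative transcript is the mRNA with the longest summed CDS
    length; ties break to the lexicographically smallest transcript id.  The
    translation start is the minimum CDS coordinate on the + strand and the
    maximum CDS coordinate on the - strand.
    """
    db = _open_annotation(annotation)
    try:
        feature = db[gene]
    except gffutils.FeatureNotFoundError:
        raise ValueError(f"gene {gene!r} not found in annotation") from None

    best: tuple[int, str] | None = None  # (-cds_len, transcript_id) minimised
    best_cds: list[gffutils.Feature] = []
    for mrna in db.children(feature, featuretype="mRNA"):
        cds = list(db.children(mrna, featuretype="CDS"))
        if not cds:
            continue
        total = sum(c.end - c.start + 1 for c in cds)
        key = (-total, mrna.id)
        if best is None or key < best:
            best = key
            best_cds = cds
    if best is None:
        raise ValueError(f"gene {gene!r} has no mRNA with CDS features")

    strand = feature.strand
    if strand not in ("+", "-"):
        raise ValueError(f"gene {gene!r} has no usable strand ({strand!r})")
    if strand == "+":
        ts = min(c.start for c in best_cds)
    else:
        ts = max(c.end for c in best_cds)
    return GeneModel(gene, feature.seqid, strand, ts, transcript=best[1])


def load_gene_models(
    annotation: str | Path | gffutils.FeatureDB,
    genes: Sequence[str] | None = None,
) -> tuple[list[GeneModel], dict[str, str]]:
    """Resolve gene models for a list of genes (all genes if None).

    Returns the successfully resolved models plus a per-gene failure map
    (gene id -> reason) so that callers can report extraction failures and
    let the final counts fall where they may.
    """
    db = _open_annotation(annotation)
    if genes is None:
        genes = [f.id for f in db.features_of_type("gene")]
    models: list[GeneModel] = []
    failures: dict[str, str] = {}
    for gene in genes:
        try:
            models.append(representative_translation_start(db, gene))
        except ValueError as exc:
            failures[gene] = str(exc)
    return models, failures


def extract_promoters(
    genome: str | Path | Fasta,
    models: Iterable[GeneModel],
    length: int = 2000,
) -> PromoterSet:
    """Extract upstream-of-ATG promoters for a list of gene models.

    Sequences are uppercased; N bases are preserved.  A promoter shorter
    than ``length`` (contig edge) is flagged ``truncated``; a gene whose
    start codon sits at the very contig edge yields an empty promoter with a
    warning rather than an error.
    """
    if length < 1:
        raise ValueError("promoter length must be >= 1")
    fasta = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    promoters = PromoterSet()
    for model in models:
        if model.contig not in fasta:
            raise ValueError(
                f"contig {model.contig!r} (gene {model.gene!r}) not in genome FASTA"
            )
        contig = fasta[model.contig]
        contig_len = len(contig)
        s = model.translation_start
        if s > contig_len:
            raise ValueError(
                f"translation start {s} of gene {model.gene!r} beyond contig "
                f"{model.contig!r} length {contig_len}"
            )
        if model.strand == "+":
            start, end = max(1, s - length), s - 1
            seq = str(contig[start - 1:end]).upper() if end >= start else ""
        else:
            start, end = s + 1, min(contig_len, s + length)
            raw = str(contig[start - 1:end]).upper() if end >= start else ""
            seq = reverse_complement(raw)
        truncated = len(seq) < length
        if not seq:
            warnings.warn(
                f"gene {model.gene!r}: no upstream sequence at contig edge; "
                "empty promoter emitted",
                stacklevel=2,
            )
            start, end = s, s - 1  # canonical empty interval
        promoters.add(
            PromoterRecord(model.gene, seq, model.contig, model.strand,
                           start, end, truncated)
        )
    return promoters


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i:i + width] for i in range(0, len(seq), width)) or ""


def write_promoters(
    promoters: PromoterSet,
    fasta_path: str | Path,
    table_path: str | Path | None = None,
) -> None:
    """Write promoters as FASTA (plus an optional TSV provenance table).

    FASTA headers carry provenance: ``gene|contig:start-end(strand)|len=N``.
    """
    with Path(fasta_path).open("w", encoding="utf-8") as out:
        for rec in promoters:
            header = (f"{rec.gene}|{rec.contig}:{rec.start}-{rec.end}"
                      f"({rec.strand})|len={rec.length}")
            out.write(f">{header}\n")
            if rec.sequence:
                out.write(_wrap(rec.sequence) + "\n")
    if table_path is not None:
        rows = [
            {
                "gene": r.gene, "contig": r.contig, "strand": r.strand,
                "start": r.start, "end": r.end, "length": r.length,
                "truncated": r.truncated,
            }
            for r in promoters
        ]
        write_gene_table(rows, table_path,
                         columns=["gene", "contig", "strand", "start", "end",
                                  "length", "truncated"])


_HEADER_RE = re.compile(
    r"^(?P<gene>[^|]+)\|(?P<contig>[^:|]+):(?P<start>\d+)-(?P<end>\d+)"
    r"\((?P<strand>[+-])\)\|len=(?P<len>\d+)$"
)


def read_promoters(fasta_path: str | Path) -> PromoterSet:
    """Read a promoter FASTA written by :func:`write_promoters`.

    Plain FASTA (headers without provenance fields) is accepted too: the
    record id becomes the gene id and provenance defaults to the sequence
    itself on the + strand.
    """
    from Bio import SeqIO

    promoters = PromoterSet()
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(record.seq).upper()
        m = _HEADER_RE.match(record.description)
        if m:
            # the truncated flag lives in the provenance TSV, not the header
            rec = PromoterRecord(
                gene=m["gene"], sequence=seq, contig=m["contig"],
                strand=m["strand"], start=int(m["start"]), end=int(m["end"]),
                truncated=False,
            )
        else:
            rec = PromoterRecord(
                gene=record.id, sequence=seq, contig=record.id, strand="+",
                start=1, end=len(seq), truncated=False,
            )
        promoters.add(rec)
    return promoters
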