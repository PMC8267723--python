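"""Deterministic synthetic-data generators with known ground truth.

Every generator is a pure function of its spec (seed included): replaying
the same spec yields byte-identical output, and no global random state is
touched.  Three generators cover the pipeline end to end:

* :func:`simulate_atlas` -- a gene x tissue FPKM matrix with a designated
  target tissue emulating mature pollen: few expressed genes (a large trace
  fraction), extreme concentration of transcript mass in the top expressed
  genes, and a planted set of target-specific genes whose true ratio over
  the mean of the other tissues clears a known fold by construction, while
  background genes are guaranteed a true ratio below 10.
* :func:`simulate_paired_atlases` -- two atlases sharing gene ids (a
  pollen-scale and an anther-scale dataset, mirroring how the two published
  maize atlases are profiled separately and the anther atlas contains no
  pollen), with a configurable overlap between the two planted specific
  sets so the cross-dataset intersection has known ground truth.
* :func:`simulate_promoters` and :func:`simulate_genome_annotation` --
  promoter sequences with planted motif occurrences (truth counts recounted
  post-insertion by an independent brute-force scanner, so chance background
  hits are part of the truth), and a genome FASTA + GFF3 pair whose true
  promoter sequences are recorded at generation time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas_io import ExpressionAtlas
from .motifs import DEFAULT_MOTIFS, Motif, MotifCountTable
from .promoters import GeneModel, PromoterRecord, PromoterSet
from .specificity import GeneSet

__all__ = [
    "DEFAULT_POLLEN_TISSUES",
    "DEFAULT_ANTHER_TISSUES",
    "SynthAtlasSpec",
    "SynthPromoterSpec",
    "AtlasTruth",
    "PairedAtlases",
    "SimulatedGenome",
    "simulate_atlas",
    "simulate_paired_atlases",
    "simulate_promoters",
    "simulate_genome_annotation",
]

#: 12 tissues emulating the pollen-scale dataset selection (target first).
DEFAULT_POLLEN_TISSUES = (
    "mature_pollen", "primary_root", "secondary_root", "vegetative_meristem",
    "internode", "mature_leaf", "ear_primordium", "female_spikelet",
    "silk", "embryo", "endosperm", "pericarp_aleurone",
)

#: 14 tissues emulating the anther-scale dataset selection (no pollen).
DEFAULT_ANTHER_TISSUES = (
    "mature_anther", "primary_root", "secondary_root", "shoot_apex",
    "internode", "mature_leaf", "ear_primordium", "female_spikelet",
    "silk", "embryo", "endosperm", "pericarp_aleurone", "tassel", "husk",
)


@dataclass(frozen=True)
class SynthAtlasSpec:
    """Study conditions for one synthetic FPKM atlas.

    Background genes draw a per-gene log-normal base level that is shared
    across tissues and jittered per tissue by a bounded multiplicative
    factor in [1/2, 2], which caps every background gene's true
    target-vs-mean-of-others ratio at 4 (< 10 by construction).  Planted
    specific genes draw a log-normal target FPKM (clipped to at least
    ``planted_min``) and have every other tissue set below
    ``target / planted_fold``, so their true ratio clears ``planted_fold``
    exactly by construction.  ``trace_fraction`` of the background genes are
    forced below 1 FPKM in the target tissue only, reproducing the reduced
    transcriptome diversity of mature pollen; ``concentration`` is the exact
    fraction of the target tissue's transcript mass carried by its
    ``top_n`` most abundant genes (the generator solves the allocation
    analytically by whole-row rescaling, which leaves every true ratio
    untouched).
    """

    n_genes: int = 2000
    tissue_names: tuple[str, ...] = DEFAULT_POLLEN_TISSUES
    target: str = "mature_pollen"
    n_specific: int = 150
    planted_fold: float = 1000.0
    background_log_mean: float = math.log(60.0)
    background_sdlog: float = 1.0
    planted_log_mean: float = math.log(200.0)
    planted_sdlog: float = 1.0
    planted_min: float = 4.0  # headroom so concentration rescaling keeps >= 1 FPKM
    concentration: float = 0.755
    top_n: int = 300
    trace_fraction: float = 0.7
    abundant_min: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_specific >= self.n_genes:
            raise ValueError("n_specific must be < n_genes")
        if not 0 < self.concentration < 1:
            raise ValueError("concentration must be in (0, 1)")
        if not 0 <= self.trace_fraction < 1:
            raise ValueError("trace_fraction must be in [0, 1)")
        if self.target not in self.tissue_names:
            raise ValueError("target must be one of tissue_names")
        if len(set(self.tissue_names)) != len(self.tissue_names):
            raise ValueError("tissue_names must be unique")
        if len(self.tissue_names) < 2:
            raise ValueError("at least 2 tissues required")
        if self.planted_fold <= 0:
            raise ValueError("planted_fold must be > 0")
        if not 1 <= self.top_n < self.n_genes:
            raise ValueError("top_n must satisfy 1 <= top_n < n_genes")


@dataclass
class AtlasTruth:
    """A simulated atlas plus its planted ground truth."""

    atlas: ExpressionAtlas
    specific: GeneSet
    abundant: GeneSet


def _apply_concentration(
    matrix: np.ndarray,
    target_col: int,
    concentration: float,
    top_n: int,
    rel_tol: float = 1e-9,
) -> None:
    """Rescale whole gene rows so the target column's ``top_n`` most abundant
    genes carry ``concentration`` of its total mass.

    Whole-row scaling preserves every gene's target/mean-other ratio
    exactly.  Each step scales the current top set by the analytic factor
    ``alpha = c/(1-c) * s_rest/s_top``; when ``alpha >= 1`` the top set is
    preserved and one step is exact, when ``alpha < 1`` a few boundary genes
    may swap in or out, so the solve is iterated to convergence (the
    swapped-gene mass shrinks geometrically).
    """
    c = concentration
    for _ in range(200):
        col = matrix[:, target_col]
        order = np.argsort(col, kind="stable")[::-1]
        top = order[:top_n]
        s_top = float(col[top].sum())
        s_rest = float(col[order[top_n:]].sum())
        if s_rest <= 0 or s_top <= 0:
            raise ValueError("concentration infeasible: degenerate mass split")
        share = s_top / (s_top + s_rest)
        if abs(share - c) <= rel_tol:
            return
        alpha = c * s_rest / ((1.0 - c) * s_top)
        matrix[top, :] *= alpha
    col = matrix[:, target_col]
    order = np.argsort(col, kind="stable")[::-1]
    s_top = float(col[order[:top_n]].sum())
    share = s_top / float(col.sum())
    if abs(share - c) > 1e-4:  # pragma: no cover - pathological draw
        raise ValueError(
            f"concentration solve did not converge (share {share:.6f} vs "
            f"target {c:.6f})"
        )


def simulate_atlas(
    spec: SynthAtlasSpec,
    gene_ids: Sequence[str] | None = None,
    planted_ids: Sequence[str] | None = None,
) -> AtlasTruth:
    """Simulate one atlas with planted target-specific genes.

    ``gene_ids``/``planted_ids`` allow a caller (the paired-atlas generator)
    to fix the gene universe and the planted subset; by default ids are
    ``g00000 ...`` and the planted subset is drawn uniformly.
    """
    rng = np.random.default_rng(spec.seed)
    n, tissues = spec.n_genes, list(spec.tissue_names)
    t_col = tissues.index(spec.target)
    n_other = len(tissues) - 1

    if gene_ids is None:
        gene_ids = [f"g{i:05d}" for i in range(n)]
    else:
        gene_ids = list(gene_ids)
        if len(gene_ids) != n:
            raise ValueError("gene_ids length must equal n_genes")
    id_index = {g: i for i, g in enumerate(gene_ids)}

    if planted_ids is None:
        planted_idx = rng.choice(n, size=spec.n_specific, replace=False)
    else:
        if len(planted_ids) != spec.n_specific:
            raise ValueError("planted_ids length must equal n_specific")
        planted_idx = np.array([id_index[g] for g in planted_ids], dtype=int)
    planted_mask = np.zeros(n, dtype=bool)
    planted_mask[planted_idx] = True

    # background: shared base level x bounded per-tissue jitter in [1/2, 2]
    base = rng.lognormal(spec.background_log_mean, spec.background_sdlog, size=n)
    jitter = np.exp(rng.uniform(-math.log(2.0), math.log(2.0),
                                size=(n, len(tissues))))
    matrix = base[:, None] * jitter

    # planted rows: high in the target, below target/planted_fold elsewhere
    n_spec = spec.n_specific
    target_vals = np.maximum(
        rng.lognormal(spec.planted_log_mean, spec.planted_sdlog, size=n_spec),
        spec.planted_min,
    )
    other_vals = (target_vals[:, None] / spec.planted_fold
                  * rng.uniform(0.01, 0.9, size=(n_spec, n_other)))
    planted_rows = np.empty((n_spec, len(tissues)))
    other_cols = [j for j in range(len(tissues)) if j != t_col]
    planted_rows[:, t_col] = target_vals
    planted_rows[:, other_cols] = other_vals
    matrix[planted_idx, :] = planted_rows

    # trace genes: background genes forced below 1 FPKM in the target only
    bg_idx = np.where(~planted_mask)[0]
    n_trace = int(round(spec.trace_fraction * bg_idx.size))
    trace_idx = rng.choice(bg_idx, size=n_trace, replace=False)
    matrix[trace_idx, t_col] = rng.uniform(0.01, 0.95, size=n_trace)

    _apply_concentration(matrix, t_col, spec.concentration, spec.top_n)
    if matrix[planted_idx, t_col].min() < 1.0:
        raise ValueError(
            "infeasible spec: concentration rescaling pushed a planted gene "
            "below 1 FPKM in the target; raise planted_min or concentration"
        )

    frame = pd.DataFrame(matrix, index=pd.Index(gene_ids, name="gene_id"),
                         columns=tissues)
    atlas = ExpressionAtlas(frame)
    genes_arr = np.asarray(gene_ids, dtype=object)
    specific = GeneSet(f"{spec.target}-planted-specific",
                       frozenset(genes_arr[planted_mask]))
    abundant = GeneSet(f"{spec.target}-planted-abundant",
                       frozenset(genes_arr[matrix[:, t_col] >= spec.abundant_min]))
    return AtlasTruth(atlas, specific, abundant)


#: Anther-scale spec preset: higher FPKM regime, 14 tissues, VHEG-scale 2000.
ANTHER_ATLAS_SPEC = SynthAtlasSpec(
    tissue_names=DEFAULT_ANTHER_TISSUES,
    target="mature_anther",
    n_specific=120,
    background_log_mean=math.log(150.0),
    background_sdlog=1.0,
    planted_log_mean=math.log(3000.0),
    planted_sdlog=1.2,
    planted_min=25.0,
    concentration=0.40,
    trace_fraction=0.25,
    abundant_min=2000.0,
)


@dataclass
class PairedAtlases:
    """Two atlases over one gene universe with overlapping planted truth."""

    pollen: AtlasTruth
    anther: AtlasTruth
    overlap: GeneSet


def simulate_paired_atlases(
    pollen_spec: SynthAtlasSpec = SynthAtlasSpec(),
    anther_spec: SynthAtlasSpec = ANTHER_ATLAS_SPEC,
    n_overlap: int = 80,
    seed: int = 0,
) -> PairedAtlases:
    """Simulate a pollen-scale and an anther-scale atlas sharing gene ids.

    ``n_overlap`` gene ids are planted as specific in *both* atlases
    (emulating genes specific to mature pollen and to the mature anther that
    contains it, measured in two separate datasets); the remaining planted
    ids of each atlas are disjoint.  Ground truth therefore includes the
    exact expected intersection of the two specific sets.
    """
    if pollen_spec.n_genes != anther_spec.n_genes:
        raise ValueError("both atlases must share the same gene universe size")
    if n_overlap > min(pollen_spec.n_specific, anther_spec.n_specific):
        raise ValueError("n_overlap exceeds a planted set size")
    needed = (pollen_spec.n_specific + anther_spec.n_specific - n_overlap)
    if needed > pollen_spec.n_genes:
        raise ValueError("planted sets do not fit in the gene universe")

    rng = np.random.default_rng(seed)
    n = pollen_spec.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]
    perm = rng.permutation(n)
    shared = perm[:n_overlap]
    only_a = perm[n_overlap:pollen_spec.n_specific]
    only_b = perm[pollen_spec.n_specific:needed]
    planted_a = [gene_ids[i] for i in np.concatenate([shared, only_a])]
    planted_b = [gene_ids[i] for i in np.concatenate([shared, only_b])]

    seed_a, seed_b = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    pollen = simulate_atlas(replace(pollen_spec, seed=seed_a),
                            gene_ids=gene_ids, planted_ids=planted_a)
    anther = simulate_atlas(replace(anther_spec, seed=seed_b),
                            gene_ids=gene_ids, planted_ids=planted_b)
    overlap = GeneSet("planted-overlap",
                      frozenset(gene_ids[i] for i in shared))
    return PairedAtlases(pollen, anther, overlap)


# ---------------------------------------------------------------------------
# Promoter simulation
# ---------------------------------------------------------------------------

_BASE_ORDER = "ACGT"


def _brute_count(sequence: str, motif: Motif) -> int:
    """Independent brute-force sliding-window scan (counts overlaps).

    Deliberately implemented position-by-position, without the regex engine
    the production scanner uses, so it can serve as its oracle.
    """
    k = motif.k
    seq = sequence.upper()
    count = 0
    for i in range(len(seq) - k + 1):
        for j in range(k):
            if seq[i + j] not in motif.positions[j]:
                break
        else:
            count += 1
    return count


@dataclass(frozen=True)
class SynthPromoterSpec:
    """Study conditions for synthetic promoters with planted motif sites.

    ``planted`` maps motif name -> number of non-overlapping insertions per
    promoter (each insertion picks one concrete word of the motif uniformly).
    Truth counts are recomputed after insertion by the brute-force scanner,
    so chance hits created by the random background are part of the truth.
    """

    n_promoters: int = 618
    length: int = 2000
    planted: Mapping[str, int] = field(default_factory=dict)
    background_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    motifs: tuple[Motif, ...] = DEFAULT_MOTIFS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_promoters < 1:
            raise ValueError("n_promoters must be >= 1")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if abs(sum(self.background_freqs) - 1.0) > 1e-9:
            raise ValueError("background_freqs must sum to 1")
        names = {m.name: m for m in self.motifs}
        footprint = 0
        for name, count in self.planted.items():
            if name not in names:
                raise ValueError(f"planted motif {name!r} not in the registry")
            if count < 0:
                raise ValueError("planted insertion counts must be >= 0")
            footprint += count * names[name].k
        if footprint > self.length:
            raise ValueError("planted insertions do not fit within length")


def simulate_promoters(
    spec: SynthPromoterSpec,
) -> tuple[PromoterSet, MotifCountTable]:
    """Simulate promoters with planted motif occurrences and truth counts."""
    rng = np.random.default_rng(spec.seed)
    by_name = {m.name: m for m in spec.motifs}
    planted = [(by_name[name], count) for name, count in spec.planted.items()]
    freqs = np.asarray(spec.background_freqs)

    records = []
    truth_rows: dict[str, list[int]] = {m.name: [] for m in spec.motifs}
    for p in range(spec.n_promoters):
        seq = rng.choice(list(_BASE_ORDER), size=spec.length, p=freqs)
        occupied = np.zeros(spec.length, dtype=bool)
        for motif, count in planted:
            k = motif.k
            for _ in range(count):
                for _attempt in range(1000):
                    pos = int(rng.integers(0, spec.length - k + 1))
                    if not occupied[pos:pos + k].any():
                        break
                else:
                    raise RuntimeError(
                        f"could not place {motif.name!r} without overlap in "
                        f"promoter {p}"
                    )
                word = "".join(cls[rng.integers(0, len(cls))]
                               for cls in motif.positions)
                seq[pos:pos + k] = list(word)
                occupied[pos:pos + k] = True
        sequence = "".join(seq)
        gene = f"prom_{p:05d}"
        records.append(
            PromoterRecord(gene, sequence, "synthetic", "+",
                           1, spec.length, truncated=False)
        )
        for motif in spec.motifs:
            truth_rows[motif.name].append(_brute_count(sequence, motif))

    promoters = PromoterSet(records)
    index = pd.Index([r.gene for r in records], name="gene")
    counts = pd.DataFrame(truth_rows, index=index, dtype=int)
    lengths = pd.Series([r.length for r in records], index=index, dtype=int)
    truth = MotifCountTable(counts, lengths, dict(by_name))
    return promoters, truth


# ---------------------------------------------------------------------------
# Genome + annotation simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedGenome:
    """A synthetic contig with annotated genes and recorded truth promoters."""

    contig_name: str
    sequence: str = field(repr=False)
    models: list[GeneModel] = field(repr=False)
    gff3_text: str = field(repr=False)
    truth: PromoterSet = field(repr=False)

    def write(self, directory: str | Path) -> tuple[Path, Path]:
        """Write genome FASTA and GFF3; returns their paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        fasta = directory / "genome.fa"
        with fasta.open("w", encoding="utf-8") as out:
            out.write(f">{self.contig_name}\n")
            for i in range(0, len(self.sequence), 60):
                out.write(self.sequence[i:i + 60] + "\n")
        gff3 = directory / "annotation.gff3"
        gff3.write_text(self.gff3_text, encoding="utf-8")
        return fasta, gff3


def _truth_promoter(
    contig_seq: str, gene: str, contig: str, strand: str, s: int, length: int
) -> PromoterRecord:
    """Truth promoter computed by direct slicing with Biopython's reverse
    complement -- an implementation path independent of the extractor."""
    from Bio.Seq import Seq

    L = len(contig_seq)
    if strand == "+":
        start, end = max(1, s - length), s - 1
        seq = contig_seq[start - 1:end] if end >= start else ""
    else:
        start, end = s + 1, min(L, s + length)
        raw = contig_seq[start - 1:end] if end >= start else ""
        seq = str(Seq(raw).reverse_complement())
    if not seq:
        start, end = s, s - 1
    return PromoterRecord(gene, seq.upper(), contig, strand, start, end,
                          truncated=len(seq) < length)


def simulate_genome_annotation(
    n_genes: int = 12,
    contig_length: int | None = None,
    strand_mix: float = 0.5,
    seed: int = 0,
    promoter_length: int = 2000,
    truncated_genes: int = 1,
    contig_name: str = "chr_synth",
    gene_ids: Sequence[str] | None = None,
) -> SimulatedGenome:
    """Simulate a genome FASTA + GFF3 with known translation starts.

    Genes are laid out left to right on alternating random strands
    (``strand_mix`` = probability of the minus strand); the first
    ``truncated_genes`` genes are placed so close to the contig start that
    their promoters truncate.  Roughly every third gene receives a second,
    shorter mRNA isoform so the longest-CDS representative rule is
    exercised; some genes get a two-segment (spliced) CDS.  An ``ATG`` start
    codon is written at every translation start so the extracted promoter
    can be verified to abut the codon.  Truth promoters are recorded at
    generation time via an independent slicing path.

    ``contig_length`` defaults to the minimum the layout needs; passing a
    smaller value is a layout-infeasibility error.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0 <= strand_mix <= 1:
        raise ValueError("strand_mix must be in [0, 1]")
    if truncated_genes > n_genes:
        raise ValueError("truncated_genes cannot exceed n_genes")
    if gene_ids is not None and len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")

    rng = np.random.default_rng(seed)
    slot = 2 * (promoter_length + 200)  # room for promoter + CDS on each side

    # layout pass: decide strands, CDS structure and translation starts
    layouts = []
    cursor = 0
    for i in range(n_genes):
        strand = "-" if rng.random() < strand_mix else "+"
        cds_len = 3 * int(rng.integers(100, 300))
        spliced = i % 4 == 2
        if i < truncated_genes:
            # too close to the contig start for a full promoter
            s = int(rng.integers(50, max(51, promoter_length // 3)))
            strand = "+"  # truncation happens upstream, i.e. at the left edge
            anchor = s
        else:
            anchor = cursor + slot // 2
            s = anchor
        layouts.append((gene_ids[i] if gene_ids else f"sg{i:04d}",
                        strand, s, cds_len, spliced))
        cursor = max(cursor, anchor + cds_len) + slot

    required = cursor + promoter_length + 200
    if contig_length is None:
        contig_length = required
    elif contig_length < required:
        raise ValueError(
            f"layout infeasible: contig_length {contig_length} < required {required}"
        )

    seq = rng.choice(list(_BASE_ORDER), size=contig_length)

    gff_lines = ["##gff-version 3"]
    models: list[GeneModel] = []
    truth = PromoterSet()
    for gene, strand, s, cds_len, spliced in layouts:
        if strand == "+":
            cds_start, cds_end = s, s + cds_len - 1
            seq[s - 1:s + 2] = list("ATG")
        else:
            cds_start, cds_end = s - cds_len + 1, s
            seq[s - 3:s] = list("CAT")  # reverse complement of ATG
        # optionally split the CDS around an interior 60-bp intron; the gap
        # leaves min/max CDS coordinates (hence the translation start) intact
        if spliced:
            cut = cds_start + cds_len // 3
            segments = [(cds_start, cut - 1), (cut + 60, cds_end)]
        else:
            segments = [(cds_start, cds_end)]

        mrnas = [(f"{gene}.t1", segments)]
        if int(gene[-1], 36) % 3 == 0 and cds_len >= 300:
            # shorter second isoform starting further into the gene
            if strand == "+":
                alt = [(segments[0][0] + 90, segments[-1][1])]
            else:
                alt = [(segments[0][0], segments[-1][1] - 90)]
            mrnas.append((f"{gene}.t0", alt))  # shorter CDS despite smaller id

        gene_start = min(a for m in mrnas for a, _ in m[1])
        gene_end = max(b for m in mrnas for _, b in m[1])
        attrs = f"ID={gene}"
        gff_lines.append(
            f"{contig_name}\tsynth\tgene\t{gene_start}\t{gene_end}\t.\t{strand}\t.\t{attrs}"
        )
        for mrna_id, segs in mrnas:
            m_start = min(a for a, _ in segs)
            m_end = max(b for _, b in segs)
            gff_lines.append(
                f"{contig_name}\tsynth\tmRNA\t{m_start}\t{m_end}\t.\t{strand}\t."
                f"\tID={mrna_id};Parent={gene}"
            )
            for a, b in segs:
                gff_lines.append(
                    f"{contig_name}\tsynth\tCDS\t{a}\t{b}\t.\t{strand}\t0"
                    f"\tID={mrna_id}.cds;Parent={mrna_id}"
                )
        models.append(GeneModel(gene, contig_name, strand, s,
                                transcript=f"{gene}.t1"))

    contig_seq = "".join(seq)
    for model in models:
        truth.add(_truth_promoter(contig_seq, model.gene, contig_name,
                                  model.strand, model.translation_start,
                                  promoter_length))
    return SimulatedGenome(contig_name, contig_seq, models,
                           "\n".join(gff_lines) + "\n", truth)
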