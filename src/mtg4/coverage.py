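"""Strand-specific coverage, L/H-strand contribution and G4 metagene profiles.

Depth is kept per position and per template strand in reference orientation
and normalized by the total number of reads mapped to both strands of the
genome, so tracks from libraries of different depth are comparable.  Two
analyses sit on top:

* strand contribution -- the share of the (normalized) transcriptome that
  L-strand-templated vs H-strand-templated transcription contributes,
  summed over non-coding bases only and excluding positions antisense to
  rRNA or tRNA genes to avoid bleed-through from the opposite strand;
* metagene profiles -- per-offset treated/control coverage ratios in a
  window centered on G4 motifs, oriented 5'->3' along the motif-carrying
  transcript.  An exonuclease that degrades 3'->5' and stalls at a G4 leaves
  its footprint as accumulation upstream (negative offsets) of the motif.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from .g4scan import G4Motif
from .seqstats import CircularSequence, GenomicInterval

CODING_CLASSES = frozenset({"gene", "mRNA", "rRNA", "tRNA"})
ANTISENSE_EXCLUDED = frozenset({"rRNA", "tRNA"})


@dataclass
class StrandCoverageTrack:
    """Per-position read depth for each template strand, reference orientation.

    ``depth_plus`` covers transcripts whose sequence matches the reference
    strand; for human mtDNA (reference = L-strand) that is H-strand-templated
    transcription, and ``depth_minus`` the G-rich L-strand-templated RNAs.
    ``total_mapped`` (reads on both strands) is the normalization denominator.
    """

    genome_id: str
    depth_plus: np.ndarray
    depth_minus: np.ndarray
    total_mapped: float

    def __post_init__(self) -> None:
        self.depth_plus = np.asarray(self.depth_plus, dtype=float)
        self.depth_minus = np.asarray(self.depth_minus, dtype=float)
        if self.depth_plus.shape != self.depth_minus.shape:
            raise ValueError("per-strand depth arrays differ in length")
        if (self.depth_plus < 0).any() or (self.depth_minus < 0).any():
            raise ValueError("negative depth")

    @property
    def length(self) -> int:
        return len(self.depth_plus)

    def depth(self, strand: str) -> np.ndarray:
        return self.depth_plus if strand == "+" else self.depth_minus

    def normalized(self, strand: str) -> np.ndarray:
        if self.total_mapped <= 0:
            raise ValueError("total_mapped must be positive for normalized use")
        return self.depth(strand) / self.total_mapped


@dataclass
class AnnotationSet:
    """Genome features: (1-based inclusive interval, strand, feature class)."""

    features: list[tuple[GenomicInterval, str]]

    @classmethod
    def from_bed(cls, path: str | Path) -> "AnnotationSet":
        """BED6 with the feature class in the name column."""
        feats = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"BED6 line with <6 fields: {line!r}")
            feats.append(
                (GenomicInterval(int(f[1]) + 1, int(f[2]), f[5]), f[3])
            )
        return cls(feats)

    @classmethod
    def from_gff3(cls, path: str | Path, types: frozenset[str] = CODING_CLASSES) -> "AnnotationSet":
        feats = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 8:
                continue
            if f[2] in types:
                feats.append((GenomicInterval(int(f[3]), int(f[4]), f[6]), f[2]))
        return cls(feats)

    def mask(self, length: int, strand: str, classes: frozenset[str]) -> np.ndarray:
        """Boolean mask of positions covered by features of given classes on
        ``strand`` ('*' for either), wrapping origin-spanning intervals."""
        out = np.zeros(length, dtype=bool)
        for iv, cls_ in self.features:
            if cls_ not in classes:
                continue
            if strand != "*" and iv.strand != strand:
                continue
            s0 = iv.start - 1
            if iv.end >= iv.start:
                out[s0 : iv.end] = True
            else:  # origin-spanning
                out[s0:] = True
                out[: iv.end] = True
        return out


@dataclass
class StrandContributionSummary:
    eligible_bases_plus: int
    eligible_bases_minus: int
    fraction_L: float
    fraction_H: float
    sum_L: float
    sum_H: float


@dataclass
class MetageneProfile:
    """Per-offset mean treated/control coverage ratio around motif centers."""

    halfwidth: int
    offsets: np.ndarray
    ratio: np.ndarray
    n_motifs: int
    side: str  # 'sense' (motif-carrying transcripts) or 'antisense'


def _read_strand(read: pysam.AlignedSegment, strandedness: str) -> str:
    sense = "-" if read.is_reverse else "+"
    if read.is_paired and read.is_read2:
        sense = "+" if sense == "-" else "-"
    if strandedness == "r1-antisense":
        sense = "+" if sense == "-" else "-"
    return sense


def pileup(
    alignments: str | Path | tuple[str | Path, str | Path],
    genome: CircularSequence,
    strandedness: str = "r1-sense",
    min_mapq: int = 10,
) -> StrandCoverageTrack:
    """Build a strand-specific coverage track from a BAM/SAM file or from a
    (plus, minus) pair of BEDGraph paths.

    BAM/SAM: secondary/supplementary/unmapped reads are skipped, a mapping
    quality threshold applies (uniquely mapped input is assumed), and aligned
    positions are taken modulo the genome length so reads placed across the
    circular origin contribute to both ends.
    """
    n = len(genome)
    if isinstance(alignments, (tuple, list)):
        plus = read_bedgraph(alignments[0], n)
        minus = read_bedgraph(alignments[1], n)
        return StrandCoverageTrack(genome.id, plus, minus, float(plus.sum() + minus.sum()))
    if strandedness not in ("r1-sense", "r1-antisense"):
        raise ValueError(f"unknown strandedness {strandedness!r}")
    depth = {"+": np.zeros(n), "-": np.zeros(n)}
    total = 0
    mode = "rb" if str(alignments).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(alignments), mode, check_sq=False) as bam:
        for ref, rlen in zip(bam.references, bam.lengths):
            if ref == genome.id and rlen != n:
                raise ValueError(
                    f"reference {ref} length {rlen} != genome length {n}"
                )
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            positions = read.get_reference_positions()
            if not positions:
                continue
            np.add.at(depth[_read_strand(read, strandedness)], np.mod(positions, n), 1.0)
            total += 1
    if total == 0:
        raise ValueError(f"no usable alignments in {alignments}")
    return StrandCoverageTrack(genome.id, depth["+"], depth["-"], float(total))


def strand_contribution(
    track: StrandCoverageTrack,
    ann: AnnotationSet,
    coding_classes: frozenset[str] = CODING_CLASSES,
    strand_of_L: str = "-",
) -> StrandContributionSummary:
    """Share of L- vs H-strand-templated transcription over non-coding bases.

    Eligible positions on each strand exclude annotated functional
    transcripts on that strand and anything antisense to rRNA or tRNA genes
    (bleed-through guard).  Normalized depth is summed per strand; fractions
    refer to the two-strand total.  With the default convention the "-"
    track carries L-strand-templated transcripts.
    """
    n = track.length
    sums = {}
    eligible_counts = {}
    for s in "+-":
        other = "-" if s == "+" else "+"
        ineligible = ann.mask(n, s, coding_classes) | ann.mask(n, other, ANTISENSE_EXCLUDED)
        eligible = ~ineligible
        eligible_counts[s] = int(eligible.sum())
        sums[s] = float(track.normalized(s)[eligible].sum())
    total = sums["+"] + sums["-"]
    if total <= 0:
        raise ValueError("zero eligible coverage on both strands")
    frac_L = sums[strand_of_L] / total
    return StrandContributionSummary(
        eligible_counts["+"], eligible_counts["-"], frac_L, 1.0 - frac_L,
        sums[strand_of_L], total - sums[strand_of_L],
    )


def _window_indices(center: int, halfwidth: int, n: int, circular: bool) -> np.ndarray:
    idx = np.arange(center - halfwidth, center + halfwidth + 1)
    if circular:
        return np.mod(idx, n)
    return idx  # caller masks out-of-range positions


def metagene(
    treated: StrandCoverageTrack,
    control: StrandCoverageTrack,
    motifs: list[G4Motif],
    halfwidth: int = 500,
    pseudocount: float | None = None,
    side: str = "sense",
    circular: bool = True,
) -> MetageneProfile:
    """Motif-centered treated/control profile, averaged over motifs.

    For each motif the +/-halfwidth window around its center is taken on the
    motif's transcript strand (``side='antisense'`` uses the complementary
    strand) and oriented 5'->3' along that transcript.  Library-normalized
    depth is first averaged across motifs per offset and the treated/control
    ratio of those aggregate profiles is then formed (each side stabilized
    with a pseudocount, default 0.5 reads / total_mapped of the respective
    library) -- the aggregate-coverage convention of standard metagene
    tooling, which avoids the small-count bias of per-motif ratios.
    Treated == control gives a flat profile at 1.
    """
    if treated.length != control.length:
        raise ValueError("treated and control tracks are on different genomes")
    if not motifs:
        raise ValueError("no motifs to center on")
    n = treated.length
    if halfwidth >= n / 2:
        raise ValueError(f"halfwidth {halfwidth} >= genome length/2 ({n / 2:g})")
    if side not in ("sense", "antisense"):
        raise ValueError("side must be 'sense' or 'antisense'")
    pc_t = 0.5 / treated.total_mapped if pseudocount is None else pseudocount
    pc_c = 0.5 / control.total_mapped if pseudocount is None else pseudocount
    width = 2 * halfwidth + 1
    acc_t = np.zeros(width)
    acc_c = np.zeros(width)
    counts = np.zeros(width)
    for m in motifs:
        strand = m.strand if side == "sense" else ("-" if m.strand == "+" else "+")
        center = ((m.start + m.end) // 2) % n
        idx = _window_indices(center, halfwidth, n, circular)
        valid = (idx >= 0) & (idx < n)
        t = np.full(width, np.nan)
        c = np.full(width, np.nan)
        t[valid] = treated.normalized(strand)[idx[valid]]
        c[valid] = control.normalized(strand)[idx[valid]]
        if strand == "-":  # transcript 5' end sits at higher reference coords
            t, c = t[::-1], c[::-1]
        ok = ~np.isnan(t)
        acc_t[ok] += t[ok]
        acc_c[ok] += c[ok]
        counts[ok] += 1
    with np.errstate(invalid="ignore"):
        mean_t = np.where(counts > 0, acc_t / np.maximum(counts, 1), np.nan)
        mean_c = np.where(counts > 0, acc_c / np.maximum(counts, 1), np.nan)
        profile = (mean_t + pc_t) / (mean_c + pc_c)
    return MetageneProfile(
        halfwidth, np.arange(-halfwidth, halfwidth + 1), profile, len(motifs), side
    )


def metagene_profiles(
    treated: StrandCoverageTrack,
    control: StrandCoverageTrack,
    motifs: list[G4Motif],
    halfwidth: int = 500,
    pseudocount: float | None = None,
    circular: bool = True,
) -> dict[str, MetageneProfile]:
    """Profiles for motif-carrying transcripts and their antisense counterparts."""
    return {
        side: metagene(treated, control, motifs, halfwidth, pseudocount, side, circular)
        for side in ("sense", "antisense")
    }


def region_fold_change(
    treated: StrandCoverageTrack,
    control: StrandCoverageTrack,
    interval: GenomicInterval,
    strand: str,
) -> float:
    """Treated/control ratio of summed normalized depth over one region
    (e.g. the L-strand reads of the D-loop)."""
    n = treated.length
    s0 = interval.start - 1
    if interval.end >= interval.start:
        idx = np.arange(s0, interval.end)
    else:
        idx = np.concatenate([np.arange(s0, n), np.arange(0, interval.end)])
    t = treated.normalized(strand)[idx].sum()
    c = control.normalized(strand)[idx].sum()
    if c == 0:
        raise ValueError("zero control coverage in region")
    return float(t / c)


def read_bedgraph(path: str | Path, length: int) -> np.ndarray:
    """Read a BEDGraph (0-based half-open) into a per-position depth array."""
    depth = np.zeros(length)
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        start, end, value = int(f[1]), int(f[2]), float(f[3])
        if end > length:
            raise ValueError(f"BEDGraph interval [{start},{end}) beyond length {length}")
        depth[start:end] += value
    return depth


def write_bedgraph(depth: np.ndarray, chrom: str, path: str | Path) -> None:
    """Write a per-position array as run-length-compressed BEDGraph."""
    lines = []
    start = 0
    for i in range(1, len(depth) + 1):
        if i == len(depth) or depth[i] != depth[start]:
            if depth[start] != 0:
                lines.append(f"{chrom}\t{start}\t{i}\t{depth[start]:g}")
            start = i
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def contribution_tsv(summary: StrandContributionSummary, genome_id: str) -> str:
    return (
        "genome_id\teligible_bases_plus\teligible_bases_minus\tfraction_L\tfraction_H\n"
        f"{genome_id}\t{summary.eligible_bases_plus}\t{summary.eligible_bases_minus}"
        f"\t{summary.fraction_L:.6f}\t{summary.fraction_H:.6f}\n"
    )


def profile_tsv(profile: MetageneProfile) -> str:
    lines = ["offset\tratio"]
    for o, r in zip(profile.offsets, profile.ratio):
        lines.append(f"{o}\t{r:.6f}")
    return "\n".join(lines) + "\n"
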