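"""Full-length short-RNA reconstruction and non-templated 3' tail calling.

Short-RNA libraries sequenced in paired-end mode capture both ends of each
molecule.  A read pair whose mates overlap by at least five nucleotides can
be merged into the complete molecule; pairs without such an overlap are
rejected, which filters the data down to full-length RNA species.  Merged
molecules are located on the genome, grouped into species by their exact
genomic 5'/3' ends, and any 3' sequence that cannot be templated by the
genome is classified (C, CC, CCA, CCACCA, other) -- the CCA call identifies
tRNA-type post-transcriptional marking on non-tRNA species such as the 73-nt
tRNA-like RNA from the antisense strand of ND4.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from .seqstats import CircularSequence, GenomicInterval, revcomp

TAIL_LABELS = {"": "none", "C": "C", "CC": "CC", "CCA": "CCA", "CCACCA": "CCACCA"}


@dataclass
class ReadPair:
    """One paired-end read; r2 is stored as sequenced (reverse strand)."""

    r1_seq: str
    r2_seq: str

    def __post_init__(self) -> None:
        if not self.r1_seq or not self.r2_seq:
            raise ValueError("empty read in pair")


@dataclass
class MergeResult:
    sequence: str
    overlap: int
    mismatches: int


@dataclass
class TailCall:
    suffix: str
    label: str


@dataclass
class MergedSpecies:
    """A coordinate-defined full-length RNA species.

    ``five_prime``/``three_prime`` are 1-based genomic coordinates of the
    transcript ends (for a "-" species the 5' end is the higher reference
    coordinate); ``tail`` is the non-templated 3' addition shared by the
    supporting reads.
    """

    sequence: str
    five_prime: int
    three_prime: int
    strand: str
    read_count: int
    tail: TailCall
    overlaps_trna: bool = False


def merge_pair(
    pair: ReadPair, min_overlap: int = 5, max_mismatch: int = 0
) -> MergeResult | None:
    """Merge a pair via the 3'-of-r1 / 5'-of-rc(r2) overlap, or reject.

    r2 is reverse-complemented first (standard paired-end geometry).  Among
    overlap lengths >= ``min_overlap`` with <= ``max_mismatch`` mismatches
    the fewest-mismatch candidate wins, ties broken by the longest overlap.
    Returns ``None`` when no overlap qualifies (rejection, not an error).
    """
    r1 = pair.r1_seq
    r2 = revcomp(pair.r2_seq)
    best: tuple[int, int] | None = None  # (mismatches, overlap)
    limit = min(len(r1), len(r2))
    for olen in range(limit, min_overlap - 1, -1):
        a = r1[len(r1) - olen :]
        b = r2[:olen]
        mm = sum(1 for x, y in zip(a, b) if x != y)
        if mm <= max_mismatch and (best is None or mm < best[0]):
            best = (mm, olen)
            if mm == 0:
                break  # longest zero-mismatch overlap; nothing can beat it
    if best is None:
        return None
    mm, olen = best
    return MergeResult(r1 + r2[olen:], olen, mm)


def _find_core(
    seq: str, genome: CircularSequence, min_core: int = 16, max_tail: int = 8
) -> tuple[int, str, str] | None:
    """Locate ``seq`` on the genome allowing a non-templated 3' tail.

    Tries tail lengths from 0 upward (shortest tail wins, so anything the
    genome can template is attributed to the genome) and exact-matches the
    remaining core on both strands.  Returns (0-based core start on the
    matched strand's forward rendering, strand, suffix) or ``None``.
    """
    n = len(genome)
    fwd = genome.residues + (genome.residues[: n - 1] if genome.circular else "")
    rev = revcomp(genome.residues)
    rev = rev + (rev[: n - 1] if genome.circular else "")
    for tail_len in range(0, min(max_tail, len(seq) - min_core) + 1):
        core = seq[: len(seq) - tail_len] if tail_len else seq
        i = fwd.find(core)
        if i != -1 and i < n:
            return i, "+", seq[len(core) :]
        i = rev.find(core)
        if i != -1 and i < n:
            return i, "-", seq[len(core) :]
    return None


def classify_tail(
    seq: str, genome: CircularSequence, aligned_core: GenomicInterval
) -> TailCall:
    """Classify the non-templated 3' suffix of a merged sequence.

    ``aligned_core`` gives the genomic match of the sequence prefix (1-based
    inclusive; for strand "-" the interval is in reference coordinates and
    the core is its reverse complement).  The templated 3' extension is
    first pushed as far as the genome continues to match, so a genomically
    templated CCA yields label ``none``.
    """
    n = len(genome)
    core_len = _core_length(aligned_core, n)
    if core_len > len(seq):
        raise ValueError("aligned core longer than sequence")
    core = _genome_slice(genome, aligned_core)
    if seq[:core_len] != core:
        raise ValueError("aligned_core is not a prefix match of the sequence")
    i = core_len
    while i < len(seq) and _next_base(genome, aligned_core, i - core_len) == seq[i]:
        i += 1
    suffix = seq[i:]
    return TailCall(suffix, TAIL_LABELS.get(suffix, "other"))


def _core_length(iv: GenomicInterval, n: int) -> int:
    lo, hi = (iv.start, iv.end) if iv.strand == "+" else (iv.end, iv.start)
    if hi >= lo:
        return hi - lo + 1
    return n - lo + 1 + hi


def _genome_slice(genome: CircularSequence, iv: GenomicInterval) -> str:
    """Transcript-oriented residues of a 1-based inclusive interval."""
    n = len(genome)
    length = _core_length(iv, n)
    if iv.strand == "+":
        s0 = iv.start - 1
        return genome.fetch(s0, s0 + length)
    # for '-' the 5' end (iv.start) is the higher reference coordinate
    s0 = (iv.end - 1) % n
    return revcomp(genome.fetch(s0, s0 + length))


def _next_base(genome: CircularSequence, iv: GenomicInterval, k: int) -> str:
    """k-th genomic base past the 3' end of the core, transcript-oriented."""
    n = len(genome)
    if iv.strand == "+":
        pos = (iv.end - 1 + 1 + k) % n
        return genome.residues[pos]
    pos = (iv.end - 1 - 1 - k) % n
    return revcomp(genome.residues[pos])


def call_species(
    merged: list[str],
    genome: CircularSequence,
    min_count: int = 2,
    trna_annotation: "AnnotationSetLike | None" = None,
) -> tuple[list[MergedSpecies], list[str]]:
    """Group merged sequences into coordinate-defined species.

    Each sequence is located on the genome (exact match, shortest possible
    non-templated tail), grouped by identical (5' end, 3' end, strand) after
    tail trimming, and groups below ``min_count`` are discarded.  Returns
    (species sorted by read count, unalignable sequences).  Species
    overlapping annotated tRNAs are flagged, mirroring the exclusion of
    tRNAs from quantitative analysis.
    """
    n = len(genome)
    groups: dict[tuple[int, int, str], list[tuple[str, str]]] = {}
    unaligned: list[str] = []
    for seq in merged:
        hit = _find_core(seq, genome)
        if hit is None:
            unaligned.append(seq)
            continue
        i, strand, _ = hit
        core_len = len(seq) - len(hit[2])
        if strand == "+":
            five = i % n + 1
            three = (i + core_len - 1) % n + 1
            iv = GenomicInterval(five, three, "+")
        else:
            # match at i on rc(genome): reference span is [n-i-core_len, n-i)
            five = (n - i - 1) % n + 1
            three = (n - i - core_len) % n + 1
            iv = GenomicInterval(five, three, "-")
        tail = classify_tail(seq, genome, iv)
        groups.setdefault((five, three, strand), []).append((seq, tail.suffix))
    species: list[MergedSpecies] = []
    for (five, three, strand), members in groups.items():
        if len(members) < min_count:
            continue
        seq_counter = Counter(s for s, _ in members)
        tail_counter = Counter(t for _, t in members)
        suffix = tail_counter.most_common(1)[0][0]
        flagged = False
        if trna_annotation is not None:
            lo, hi = min(five, three), max(five, three)
            mask = trna_annotation.mask(n, "*", frozenset({"tRNA"}))
            flagged = bool(mask[lo - 1 : hi].any())
        species.append(
            MergedSpecies(
                seq_counter.most_common(1)[0][0],
                five,
                three,
                strand,
                len(members),
                TailCall(suffix, TAIL_LABELS.get(suffix, "other")),
                flagged,
            )
        )
    species.sort(key=lambda s: (-s.read_count, s.five_prime))
    return species, unaligned


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> list[ReadPair]:
    """Load paired FASTQ files into ReadPair objects (order defines pairing)."""
    from Bio import SeqIO

    r1 = [str(r.seq).upper() for r in SeqIO.parse(str(path1), "fastq")]
    r2 = [str(r.seq).upper() for r in SeqIO.parse(str(path2), "fastq")]
    if len(r1) != len(r2):
        raise ValueError(f"unpaired FASTQ files: {len(r1)} vs {len(r2)} reads")
    return [ReadPair(a, b) for a, b in zip(r1, r2)]


def species_table_tsv(species: list[MergedSpecies]) -> str:
    lines = ["five_prime\tthree_prime\tstrand\tlength\tread_count\ttail_label\ttail_suffix\toverlaps_trna"]
    for s in species:
        core_len = len(s.sequence) - len(s.tail.suffix)
        lines.append(
            f"{s.five_prime}\t{s.three_prime}\t{s.strand}\t{core_len}\t{s.read_count}"
            f"\t{s.tail.label}\t{s.tail.suffix or '-'}\t{int(s.overlaps_trna)}"
        )
    return "\n".join(lines) + "\n"


class AnnotationSetLike:  # typing aid only; AnnotationSet satisfies it
    def mask(self, length: int, strand: str, classes: frozenset[str]): ...
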