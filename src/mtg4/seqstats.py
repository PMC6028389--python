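"""Sequence I/O, circular-coordinate arithmetic and genome composition statistics.

Vertebrate mitochondrial genomes are small circular molecules with a
pronounced compositional asymmetry between strands: the reference (rCRS-style)
strand of human mtDNA is the C-rich light (L) strand, so its GC skew
(G-C)/(G+C) is strongly negative while the complementary heavy (H) strand is
G-rich.  Everything downstream (G4 scanning, composition-matched null
genomes, coverage profiles) builds on the primitives here: circular sequences,
exact nucleotide counts, AT content, GC skew, a sliding-window G-fraction
track and origin-aware interval arithmetic.

Coordinates are 0-based half-open internally and 1-based inclusive in every
user-facing report, matching the publication convention (e.g. the tRNA-like
species at nucleotides 11900-11972 of the 16,569-nt human genome, length 73).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class CircularSequence:
    """A nucleotide sequence with an explicit circular-topology flag.

    ``residues`` is uppercase over {A, C, G, T, N}; U is converted to T on
    load so RNA and DNA inputs are interchangeable.
    """

    id: str
    residues: str
    circular: bool = True

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.residues) if c in bad)
            raise ValueError(
                f"illegal character {self.residues[pos]!r} at position {pos + 1} "
                f"in sequence {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def fetch(self, start: int, end: int) -> str:
        """Slice [start, end) in 0-based coordinates, wrapping past the origin
        for circular sequences (``end`` may exceed the length)."""
        n = len(self.residues)
        if end <= n:
            return self.residues[start:end]
        if not self.circular:
            raise IndexError(f"slice [{start}, {end}) beyond linear sequence of length {n}")
        reps = (end - 1) // n + 1
        return (self.residues * reps)[start:end]


@dataclass(frozen=True)
class CompositionStats:
    """Exact base counts plus AT fraction and GC skew of one sequence.

    ``at_fraction`` excludes N from the denominator; ``gc_skew`` is NaN
    (missing, never 0) when the sequence contains no G or C.
    """

    length: int
    n_a: int
    n_c: int
    n_g: int
    n_t: int
    n_n: int
    at_fraction: float
    gc_skew: float


@dataclass
class WindowTrack:
    """Per-window base-fraction values from a sliding window.

    Windows containing N report the fraction over non-N bases and are flagged
    in ``has_n``.
    """

    window: int
    step: int
    start_positions: list[int]
    values: list[float]
    has_n: list[bool]


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive interval (report convention); ``end < start`` denotes
    an origin-spanning interval on a circular genome."""

    start: int
    end: int
    strand: str = "+"


def normalize_residues(raw: str, seq_id: str = "?") -> str:
    """Uppercase, convert U to T, and validate the alphabet.

    Raises ``ValueError`` naming the offending symbol and its 1-based
    position for anything outside {A, C, G, T, N, U}.
    """
    up = raw.upper().replace("U", "T")
    bad = set(up) - ALPHABET
    if bad:
        pos = next(i for i, c in enumerate(up) if c in bad)
        raise ValueError(
            f"illegal character {up[pos]!r} at position {pos + 1} in sequence {seq_id!r}"
        )
    return up


def read_fasta(path: str | Path, circular: bool = True) -> list[CircularSequence]:
    """Read FASTA into :class:`CircularSequence` records (uppercased, U->T).

    Empty records and characters outside {A, C, G, T, N, U} are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    out: list[CircularSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise ValueError(f"empty FASTA record {rec.id!r} in {path}")
        out.append(CircularSequence(rec.id, normalize_residues(str(rec.seq), rec.id), circular))
    if not out:
        raise ValueError(f"no FASTA records found in {path}")
    return out


def write_fasta(seqs: Iterable[CircularSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def composition(seq: CircularSequence) -> CompositionStats:
    """Base counts, AT fraction and GC skew of ``seq``.

    GC skew is computed on the strand as given (for human mtDNA the reference
    strand is the L-strand, so the skew is negative); the complementary
    strand's skew is the negation.
    """
    r = seq.residues
    n_a, n_c, n_g, n_t, n_n = (r.count(b) for b in "ACGTN")
    non_n = len(r) - n_n
    if non_n == 0:
        raise ValueError(f"sequence {seq.id!r} is all N; composition undefined")
    at = (n_a + n_t) / non_n
    gc = n_g + n_c
    skew = (n_g - n_c) / gc if gc > 0 else math.nan
    return CompositionStats(len(r), n_a, n_c, n_g, n_t, n_n, at, skew)


def reverse_complement(seq: CircularSequence) -> CircularSequence:
    """Watson-Crick reverse complement (N maps to N); an involution."""
    return CircularSequence(seq.id + "_rc", seq.residues[::-1].translate(_COMPLEMENT), seq.circular)


def revcomp(residues: str) -> str:
    """Reverse complement of a raw residue string."""
    return residues[::-1].translate(_COMPLEMENT)


def sliding_g_fraction(
    seq: CircularSequence, window: int = 50, step: int = 5, base: str = "G"
) -> WindowTrack:
    """Fraction of ``base`` in a ``window``-nt window slid in ``step``-nt steps.

    For circular sequences windows wrap past the origin so every position is
    covered; for linear sequences the last window ends at the sequence end.
    """
    n = len(seq)
    if window > n:
        raise ValueError(f"window {window} exceeds sequence length {n}")
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    if seq.circular:
        starts = list(range(0, n, step))
    else:
        starts = list(range(0, n - window + 1, step))
    values: list[float] = []
    flags: list[bool] = []
    for s in starts:
        w = seq.fetch(s, s + window)
        n_n = w.count("N")
        denom = window - n_n
        values.append(w.count(base) / denom if denom else math.nan)
        flags.append(n_n > 0)
    return WindowTrack(window, step, starts, values, flags)


def interval_length(iv: GenomicInterval | tuple[int, int], genome_length: int) -> int:
    """Length in nt of a 1-based inclusive interval, modulo the circular origin.

    ``end >= start`` gives ``end - start + 1``; ``end < start`` denotes an
    origin-spanning interval and gives ``genome_length - start + 1 + end``.
    Invariant under rotation of the circular origin.
    """
    start, end = (iv.start, iv.end) if isinstance(iv, GenomicInterval) else iv
    for name, coord in (("start", start), ("end", end)):
        if not 1 <= coord <= genome_length:
            raise ValueError(f"{name}={coord} outside [1, {genome_length}]")
    if end >= start:
        return end - start + 1
    return genome_length - start + 1 + end


def composition_tsv(stats: dict[str, CompositionStats]) -> str:
    """One row per genome: counts, AT fraction, GC skew (missing skew -> NA)."""
    lines = ["id\tlength\tn_A\tn_C\tn_G\tn_T\tn_N\tat_fraction\tgc_skew"]
    for sid, c in stats.items():
        skew = "NA" if math.isnan(c.gc_skew) else f"{c.gc_skew:.6f}"
        lines.append(
            f"{sid}\t{c.length}\t{c.n_a}\t{c.n_c}\t{c.n_g}\t{c.n_t}\t{c.n_n}"
            f"\t{c.at_fraction:.6f}\t{skew}"
        )
    return "\n".join(lines) + "\n"


def windowtrack_bedgraph(track: WindowTrack, chrom: str) -> str:
    """BEDGraph (0-based half-open) rendering of a window track; each window
    is reported at its start interval of ``step`` nt."""
    lines = []
    for s, v in zip(track.start_positions, track.values):
        lines.append(f"{chrom}\t{s}\t{s + track.step}\t{v:.6f}")
    return "\n".join(lines) + "\n"
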