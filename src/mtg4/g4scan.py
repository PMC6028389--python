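"""G-quadruplex consensus scanning, strand- and circularity-aware.

The consensus is the conservative pattern of four or more runs of at least
three guanines separated by 1-30 nt loops, expressed as the regular
expression ``(G{3,}[ACGTN]{1,30}){3,}G{3,}`` and evaluated with standard
leftmost-greedy, non-overlapping engine semantics.  Loops may themselves
contain Gs; the greedy engine decides the run/loop assignment, and the same
assignment is recovered here for reporting (count of G-runs, loop lengths).

Circular genomes are scanned on a sequence extended past the origin
(default 200 nt) and matches whose start maps beyond the genome length are
discarded, so an origin-spanning motif is reported exactly once.  Motifs on
the reverse strand are found by scanning the reverse complement and mapped
back to reference coordinates with strand "-".

For human mtDNA the reference strand is the C-rich L-strand, so consensus
matches fall essentially on the "-" scan, i.e. in the G-rich RNAs templated
by the L-strand -- the transcripts the surveillance machinery has to clear.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from .seqstats import CircularSequence, revcomp


@dataclass(frozen=True)
class ScanParams:
    """G4 consensus parameters: >= ``min_runs`` runs of >= ``min_run`` Gs
    separated by loops of ``loop_min``..``loop_max`` nt."""

    min_run: int = 3
    min_runs: int = 4
    loop_min: int = 1
    loop_max: int = 30
    circular_extension: int = 200

    def __post_init__(self) -> None:
        if self.min_run < 2:
            raise ValueError("min_run must be >= 2")
        if self.min_runs < 2:
            raise ValueError("min_runs must be >= 2")
        if self.loop_min < 1 or self.loop_max < self.loop_min:
            raise ValueError("require 1 <= loop_min <= loop_max")
        if self.circular_extension < 0:
            raise ValueError("circular_extension must be >= 0")

    def pattern(self) -> re.Pattern[str]:
        return re.compile(
            "(?:G{%d,}[ACGTN]{%d,%d}){%d,}G{%d,}"
            % (self.min_run, self.loop_min, self.loop_max, self.min_runs - 1, self.min_run)
        )


@dataclass
class G4Motif:
    """One consensus match.

    ``start``/``end`` are 0-based half-open on the reference; ``end`` may
    exceed the genome length for an origin-spanning motif on a circular
    genome (wrap implied).  ``sequence`` is the matched string on the motif's
    own strand (G-rich).
    """

    start: int
    end: int
    strand: str
    sequence: str
    g_runs: int
    loop_lengths: list[int]

    @property
    def length(self) -> int:
        return self.end - self.start

    def interval_1based(self, genome_length: int) -> tuple[int, int]:
        """(start, end) 1-based inclusive, wrapped modulo the genome."""
        return self.start % genome_length + 1, (self.end - 1) % genome_length + 1


@dataclass
class G4ScanResult:
    motifs: list[G4Motif]
    count_plus: int
    count_minus: int
    normalized_count: float | None = None
    transcript_class: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_STRAND_TO_TRANSCRIPT)
    )


# Human mtDNA convention: the reference strand is the L-strand, so motifs on
# the reference "+" would sit in transcripts templated by the H-strand, while
# "-" motifs sit in the G-rich transcripts templated by the L-strand.
DEFAULT_STRAND_TO_TRANSCRIPT = {
    "+": "H-strand-templated",
    "-": "L-strand-templated",
}


def _decompose(match: str, params: ScanParams) -> tuple[int, list[int]]:
    """Recover the greedy engine's run/loop assignment for a matched string.

    Replays the backtracking order of the pattern (more repetitions first,
    longer runs first, longer loops first) so that loops always satisfy the
    1..loop_max bound even when they contain Gs.
    """
    n = len(match)
    min_run, lo, hi = params.min_run, params.loop_min, params.loop_max
    need = params.min_runs - 1  # group repetitions before the final run

    run_ahead = [0] * (n + 1)  # length of the G-run starting at each position
    for i in range(n - 1, -1, -1):
        run_ahead[i] = run_ahead[i + 1] + 1 if match[i] == "G" else 0

    failed: set[tuple[int, int]] = set()

    def rec(i: int, reps: int) -> list[tuple[int, int | None]] | None:
        key = (i, min(reps, need))
        if key in failed:
            return None
        m = run_ahead[i]
        if m >= min_run:
            # greedy: try another (run, loop) repetition first
            for r in range(m, min_run - 1, -1):
                max_l = min(hi, n - (i + r))
                for l in range(max_l, lo - 1, -1):
                    rest = rec(i + r + l, reps + 1)
                    if rest is not None:
                        return [(r, l)] + rest
            # then the final run, which must consume the string exactly
            if reps >= need and m == n - i:
                return [(n - i, None)]
        failed.add(key)
        return None

    parts = rec(0, 0)
    if parts is None:  # cannot happen for a string the engine matched
        raise RuntimeError("run/loop decomposition failed for a matched string")
    runs = len(parts)
    loops = [l for _, l in parts if l is not None]
    return runs, loops


def _scan_linear(target: str, params: ScanParams) -> list[tuple[int, int, str]]:
    return [(m.start(), m.end(), m.group()) for m in params.pattern().finditer(target)]


def scan_g4(
    seq: CircularSequence, params: ScanParams = ScanParams(), strand: str = "+"
) -> list[G4Motif]:
    """Scan one strand for the G4 consensus; coordinates on the reference.

    Matches are leftmost, greedy and non-overlapping.  For circular inputs
    the scanned string is extended by ``circular_extension`` nt past the
    origin and matches starting at or beyond the genome length are dropped;
    a match running longer than the extension triggers a re-scan with the
    extension doubled.
    """
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    n = len(seq)
    target = seq.residues if strand == "+" else revcomp(seq.residues)
    ext = params.circular_extension
    while True:
        scanned = target + target[: min(ext, n)] if seq.circular else target
        raw = _scan_linear(scanned, params)
        if not seq.circular or not any(
            e - s > ext for s, e, _ in raw
        ):
            break
        warnings.warn(
            f"G4 match longer than circular extension {ext} nt on {seq.id}; "
            "re-scanning with doubled extension"
        )
        ext *= 2
    motifs: list[G4Motif] = []
    for s, e, text in raw:
        if s >= n:  # duplicate of a match already seen before the origin
            continue
        runs, loops = _decompose(text, params)
        if strand == "+":
            motifs.append(G4Motif(s, e, "+", text, runs, loops))
        else:
            # position i of the reverse complement is reference n-1-i
            ref_start = (n - e) % n
            motifs.append(G4Motif(ref_start, ref_start + (e - s), "-", text, runs, loops))
    return motifs


def scan_both_strands(
    seq: CircularSequence,
    params: ScanParams = ScanParams(),
    strand_to_transcript: dict[str, str] | None = None,
) -> G4ScanResult:
    """Scan both strands and report per-strand counts.

    The strand-to-transcript table labels which mitochondrial transcript
    class carries each motif (default: human convention, reference = L-strand).
    """
    plus = scan_g4(seq, params, "+")
    minus = scan_g4(seq, params, "-")
    mapping = dict(strand_to_transcript or DEFAULT_STRAND_TO_TRANSCRIPT)
    return G4ScanResult(
        motifs=plus + minus,
        count_plus=len(plus),
        count_minus=len(minus),
        transcript_class=mapping,
    )


def normalize_g4_count(count: int, genome_length: int, mean_length: float) -> float:
    """Genome-size-normalized G4 count: count / (genome_length / mean_length)."""
    if genome_length <= 0 or mean_length <= 0:
        raise ValueError("genome_length and mean_length must be positive")
    if count < 0:
        raise ValueError("count must be >= 0")
    return count / (genome_length / mean_length)


def motifs_to_bed(motifs: list[G4Motif], chrom: str, genome_length: int | None = None) -> str:
    """BED6 rendering (0-based half-open); name encodes the run/loop signature."""
    lines = []
    for m in sorted(motifs, key=lambda x: (x.start, x.strand)):
        start = m.start if genome_length is None else m.start % genome_length
        name = f"G4_runs{m.g_runs}_loops{','.join(map(str, m.loop_lengths))}"
        lines.append(f"{chrom}\t{start}\t{start + m.length}\t{name}\t0\t{m.strand}")
    return "\n".join(lines) + ("\n" if lines else "")


def scan_summary_tsv(result: G4ScanResult, genome_id: str, genome_length: int) -> str:
    norm = "" if result.normalized_count is None else f"{result.normalized_count:.4f}"
    return (
        "genome_id\tlength\tcount_plus\tcount_minus\tcount_total\tnormalized_count\n"
        f"{genome_id}\t{genome_length}\t{result.count_plus}\t{result.count_minus}"
        f"\t{result.count_plus + result.count_minus}\t{norm}\n"
    )
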