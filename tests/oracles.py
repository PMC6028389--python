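"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results from first principles (explicit
backtracking, exhaustive shift enumeration, direct recounts) rather than
calling the library code they check.
"""
from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def g4_match_end(
    s: str,
    i: int,
    min_run: int = 3,
    min_runs: int = 4,
    loop_min: int = 1,
    loop_max: int = 30,
) -> int | None:
    """End of the greedy G4 consensus match starting at position i, or None.

    Hand-rolled backtracking that replays standard regex semantics for
    (G{min_run,} loop{loop_min,loop_max}){min_runs-1,} G{min_run,}:
    the repetition group is greedy (more repetitions preferred), runs are
    greedy (longest first), loops are greedy (longest first), and the final
    run consumes its whole G stretch.
    """
    n = len(s)
    need = min_runs - 1

    def run_length(j: int) -> int:
        k = j
        while k < n and s[k] == "G":
            k += 1
        return k - j

    dead: set[tuple[int, int]] = set()

    def attempt(j: int, reps: int) -> int | None:
        key = (j, min(reps, need))
        if key in dead:
            return None
        m = run_length(j)
        if m >= min_run:
            for r in range(m, min_run - 1, -1):
                for l in range(min(loop_max, n - (j + r)), loop_min - 1, -1):
                    end = attempt(j + r + l, reps + 1)
                    if end is not None:
                        return end
            if reps >= need:
                return j + m
        dead.add(key)
        return None

    return attempt(i, 0)


def g4_findall(s: str, **kw) -> list[tuple[int, int]]:
    """Leftmost, greedy, non-overlapping matches over a linear string."""
    out = []
    i = 0
    n = len(s)
    while i < n:
        end = g4_match_end(s, i, **kw)
        if end is None:
            i += 1
        else:
            out.append((i, end))
            i = end
    return out


def g4_intervals_both_strands(
    residues: str, circular: bool, **kw
) -> set[tuple[int, int, str]]:
    """Reference-mapped (start mod L, length, strand) motif set.

    Circular sequences are scanned on the doubled string with duplicate
    matches (start >= L) discarded; reverse-strand matches are found on the
    reverse complement and mapped back independently of the implementation.
    """
    n = len(residues)
    out: set[tuple[int, int, str]] = set()
    for strand in "+-":
        target = residues if strand == "+" else rc(residues)
        scanned = target + target if circular else target
        for s, e in g4_findall(scanned, **kw):
            if s >= n:
                continue
            if strand == "+":
                out.add((s % n, e - s, "+"))
            else:
                out.add(((n - e) % n, e - s, "-"))
    return out


def window_base_count(residues: str, start: int, window: int, base: str) -> tuple[int, int]:
    """(count of base, count of N) in a circular window by direct recount."""
    n = len(residues)
    chars = [residues[(start + k) % n] for k in range(window)]
    return sum(c == base for c in chars), sum(c == "N" for c in chars)


def merge_all_shifts(
    r1: str, r2: str, min_overlap: int = 5, max_mismatch: int = 0
) -> tuple[str, int, int] | None:
    """Exhaustive all-shift merge oracle.

    Enumerates every overlap length between r1's 3' end and rc(r2)'s 5' end,
    keeps those within the mismatch budget, and selects fewest mismatches
    then longest overlap.  Returns (merged, overlap, mismatches) or None.
    """
    b = rc(r2)
    candidates = []
    for olen in range(min_overlap, min(len(r1), len(b)) + 1):
        tail = r1[len(r1) - olen :]
        head = b[:olen]
        mm = sum(1 for x, y in zip(tail, head) if x != y)
        if mm <= max_mismatch:
            candidates.append((mm, -olen))
    if not candidates:
        return None
    mm, neg = min(candidates)
    olen = -neg
    return r1 + b[olen:], olen, mm
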