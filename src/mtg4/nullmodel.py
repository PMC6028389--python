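"""Composition-matched random-genome null for G4 counts, and cohort tests.

The question the null answers: does a mitochondrial genome carry more G4
consensus sequences than expected from its length, AT content and GC skew
alone?  Replicate genomes are generated with those three statistics matched
("constraint" mode solves the base counts from length, AT fraction and skew
and places bases in uniformly random order; "permute" mode shuffles the
template's residues, conserving all four counts exactly), each replicate is
scanned on both strands, and the observed count is ranked against the
replicate counts.  The empirical p-value uses the add-one convention
p = (1 + #{replicates >= observed}) / (n + 1), which never returns zero.

Two-group cohort comparisons (e.g. GRSF1-positive vs -negative species) of
AT content, GC skew or the size-normalized G4 count use the two-sided
Wilcoxon rank-sum (Mann-Whitney) test.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .g4scan import ScanParams, normalize_g4_count, scan_both_strands
from .seqstats import CircularSequence, composition


@dataclass
class NullDistribution:
    n_replicates: int
    replicate_counts: np.ndarray
    observed: int
    null_mean: float
    null_sd: float
    z: float  # NaN when the null is degenerate (sd == 0)
    p_empirical: float


@dataclass
class GenomeCohortRecord:
    species_id: str
    group: str  # "positive" or "negative"
    length: int
    at_fraction: float
    gc_skew: float
    normalized_g4_count: float


@dataclass
class RankSumResult:
    statistic: float
    p_value: float
    medians: dict[str, float]
    n: dict[str, int]
    method: str


def _constraint_counts(
    length: int, at_fraction: float, gc_skew: float, at_ratio: float
) -> tuple[int, int, int, int]:
    """Solve (n_A, n_C, n_G, n_T) from length, AT fraction and GC skew.

    ``at_ratio`` = A/(A+T) controls the split the constraints leave free.
    """
    n_at = round(at_fraction * length)
    n_gc = length - n_at
    n_g = round(n_gc * (1 + gc_skew) / 2)
    n_c = n_gc - n_g
    n_a = round(n_at * at_ratio)
    n_t = n_at - n_a
    counts = (n_a, n_c, n_g, n_t)
    if any(c < 0 for c in counts):
        raise ValueError(
            f"infeasible composition constraints: length={length}, "
            f"at={at_fraction:.4f}, skew={gc_skew:.4f} -> counts {counts}"
        )
    return counts


def generate_matched(
    template: CircularSequence,
    mode: str = "constraint",
    rng_seed: int | np.random.Generator = 0,
    at_split: str = "template",
) -> CircularSequence:
    """One random genome matching the template's length, AT% and GC skew.

    ``constraint`` mode solves base counts from the three statistics (the
    A:T ratio, unconstrained by them, defaults to the template's; pass
    ``at_split='even'`` for a 50/50 split) and shuffles.  ``permute`` mode is
    a uniform permutation of the template residues, conserving all counts
    exactly.  Reproducible from ``rng_seed``.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    if mode == "permute":
        arr = np.frombuffer(template.residues.encode(), dtype="S1").copy()
        rng.shuffle(arr)
    elif mode == "constraint":
        comp = composition(template)
        if at_split == "even" or comp.n_a + comp.n_t == 0:
            ratio = 0.5
        else:
            ratio = comp.n_a / (comp.n_a + comp.n_t)
        if comp.n_g + comp.n_c == 0:
            # GC skew undefined; the constraints degenerate to an AT-only genome
            n_a, n_c, n_g, n_t = round(len(template) * ratio), 0, 0, 0
            n_t = len(template) - n_a
        else:
            n_a, n_c, n_g, n_t = _constraint_counts(
                len(template), comp.at_fraction, comp.gc_skew, ratio
            )
        arr = np.array(
            [b"A"] * n_a + [b"C"] * n_c + [b"G"] * n_g + [b"T"] * n_t, dtype="S1"
        )
        rng.shuffle(arr)
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'constraint' or 'permute'")
    return CircularSequence(
        f"{template.id}_{mode}", arr.tobytes().decode(), template.circular
    )


def null_distribution(
    genome: CircularSequence,
    params: ScanParams = ScanParams(),
    n: int = 10_000,
    mode: str = "constraint",
    rng_seed: int = 0,
) -> NullDistribution:
    """Distribution of both-strand G4 counts over ``n`` matched random genomes.

    Each replicate uses a deterministic child seed spawned from the master
    seed, so the run is reproducible and order-independent.
    """
    if n < 100:
        raise ValueError("need at least 100 replicates for an empirical p-value")
    observed = len(scan_both_strands(genome, params).motifs)
    children = np.random.SeedSequence(rng_seed).spawn(n)
    counts = np.empty(n, dtype=np.int64)
    for i, child in enumerate(children):
        rep = generate_matched(genome, mode, np.random.default_rng(child))
        counts[i] = len(scan_both_strands(rep, params).motifs)
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1))
    z = (observed - mean) / sd if sd > 0 else math.nan
    p = (1 + int((counts >= observed).sum())) / (n + 1)
    return NullDistribution(n, counts, observed, mean, sd, z, p)


def empirical_p(replicate_counts: np.ndarray, observed: float) -> float:
    """Add-one empirical upper-tail p-value against stored replicate counts."""
    n = len(replicate_counts)
    return (1 + int((np.asarray(replicate_counts) >= observed).sum())) / (n + 1)


def compare_groups(
    cohort: list[GenomeCohortRecord],
    variable: str,
    groups: tuple[str, str] = ("positive", "negative"),
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test of one statistic between two groups.

    Exact enumeration when both groups have <= 20 untied values; otherwise
    the tie-corrected normal approximation.  An all-tied degenerate input
    returns p = 1.
    """
    if variable not in ("at_fraction", "gc_skew", "normalized_g4_count", "length"):
        raise ValueError(f"unknown variable {variable!r}")
    vals: dict[str, np.ndarray] = {}
    for g in groups:
        v = np.array(
            [getattr(r, variable) for r in cohort if r.group == g], dtype=float
        )
        v = v[~np.isnan(v)]
        if len(v) == 0:
            raise ValueError(f"group {g!r} is empty or all-missing for {variable}")
        vals[g] = v
    x, y = vals[groups[0]], vals[groups[1]]
    pooled = np.concatenate([x, y])
    medians = {g: float(np.median(v)) for g, v in vals.items()}
    ns = {g: int(len(v)) for g, v in vals.items()}
    if np.all(pooled == pooled[0]):
        return RankSumResult(len(x) * len(y) / 2.0, 1.0, medians, ns, "degenerate")
    has_ties = len(np.unique(pooled)) < len(pooled)
    if max(len(x), len(y)) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return RankSumResult(float(res.statistic), float(res.pvalue), medians, ns, method)


def cohort_from_genomes(
    genomes: dict[str, tuple[CircularSequence, str]],
    params: ScanParams = ScanParams(),
    mean_length: float | None = None,
) -> list[GenomeCohortRecord]:
    """Build cohort records (composition + normalized G4 count) from genomes.

    ``genomes`` maps species_id -> (sequence, group).  The normalization
    denominator uses the mean genome length over the supplied cohort unless
    ``mean_length`` is given.
    """
    if not genomes:
        raise ValueError("empty cohort")
    if mean_length is None:
        mean_length = float(np.mean([len(s) for s, _ in genomes.values()]))
    records = []
    for sid, (seq, group) in genomes.items():
        comp = composition(seq)
        res = scan_both_strands(seq, params)
        count = res.count_plus + res.count_minus
        records.append(
            GenomeCohortRecord(
                sid,
                group,
                len(seq),
                comp.at_fraction,
                comp.gc_skew,
                normalize_g4_count(count, len(seq), mean_length),
            )
        )
    return records


def ranksum_table_tsv(results: dict[str, RankSumResult]) -> str:
    lines = [
        "variable\tU\tp_value\tmethod\tmedian_positive\tmedian_negative\tn_positive\tn_negative"
    ]
    for var, r in results.items():
        med = list(r.medians.values())
        n = list(r.n.values())
        lines.append(
            f"{var}\t{r.statistic:.1f}\t{r.p_value:.3e}\t{r.method}"
            f"\t{med[0]:.6f}\t{med[1]:.6f}\t{n[0]}\t{n[1]}"
        )
    return "\n".join(lines) + "\n"
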