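"""Seeded generators for every input class the pipeline consumes.

Each generator is a pure function of a :class:`SimConfig` (NumPy PCG64
streams spawned from one master seed) and records its ground truth alongside
the data, so every downstream stage is testable without external downloads.

What the defaults emulate: a vertebrate mitochondrial genome (16.6 kb
circular, AT fraction 0.556, reference-strand GC skew -0.41, matching the
human rCRS composition) whose G4 consensus motifs sit on the strand
transcribed into G-rich RNA; strand-specific coverage under a control and a
decay-deficient condition in which RNA accumulates upstream (5' side) of
each G4; paired-end 2x75 short-RNA libraries over species of known ends and
3' tails; and a TAP-MS replicate intensity table with planted bait-enriched
partners plus decoy classes exercising each filter criterion.

The background of a simulated genome is scrubbed of chance G4 consensus
occurrences (composition-preserving base swaps), so the planted motifs are
exactly the motifs present -- a test convenience, not a biological claim.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .g4scan import ScanParams, scan_both_strands
from .coverage import StrandCoverageTrack
from .seqstats import CircularSequence, revcomp
from .shortrna import ReadPair
from .tapms import (
    ProteinRecord,
    REASON_ENRICHMENT_PNP,
    REASON_ENRICHMENT_SUV3,
    REASON_NOT_MITOCHONDRIAL,
    REASON_PRESENCE,
)

_AT = np.frombuffer(b"AT", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic datasets (all seeded).

    Composition defaults match the human mitochondrial reference strand
    (AT 0.556, GC skew -0.41); coverage defaults (depth 50 reads/base,
    5-fold upstream accumulation in the decay-deficient condition) and the
    2x75 paired-end geometry mirror the experimental design the pipeline
    targets.
    """

    rng_seed: int = 0
    genome_length: int = 16_569
    at_fraction: float = 0.556
    gc_skew: float = -0.41
    n_planted_g4: int = 7
    g4_strand: str = "-"
    motif_spacing: int = 1600
    coverage_depth: float = 50.0
    accumulation_factor: float = 5.0
    upstream_extent: int = 350
    upstream_gap: int = 10
    read_length: int = 75
    n_read_pairs: int = 10_000
    n_species: int = 30
    n_unmergeable: int = 2
    tail_spec: tuple[tuple[str, float], ...] = (("", 0.4), ("CCA", 0.5), ("CCACCA", 0.1))
    tapms_n_proteins: int = 200
    tapms_n_true: int = 7
    scan_params: ScanParams = ScanParams()


def preset_genome(seed: int = 0) -> SimConfig:
    """Human-mtDNA-like genome with 7 planted minus-strand G4 motifs."""
    return SimConfig(rng_seed=seed)


def preset_coverage(seed: int = 0) -> SimConfig:
    """Metagene study condition: depth 50, 5-fold upstream accumulation.

    80 anchors on a 60-kb circular genome keep the per-offset sampling error
    of the mean ratio near 0.2/sqrt(80) ~ 2%, so a control-vs-control
    profile stays well inside a 10% band at every offset while anchors stay
    far enough apart (>= 700 nt) that upstream windows do not interfere.
    """
    return SimConfig(rng_seed=seed, genome_length=60_000, n_planted_g4=80, motif_spacing=700)


def preset_shortrna(seed: int = 0) -> SimConfig:
    return SimConfig(rng_seed=seed)


def preset_tapms(seed: int = 0) -> SimConfig:
    return SimConfig(rng_seed=seed)


@dataclass
class SpeciesDef:
    five_prime: int  # 1-based genomic coordinate of the transcript 5' end
    three_prime: int
    strand: str
    tail: str
    molecule: str  # genomic core + non-templated tail


@dataclass
class GroundTruth:
    """Recorded truth sufficient to compute every downstream expectation."""

    motifs: list[tuple[int, int, str]] = field(default_factory=list)
    expected_depth: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    species: list[SpeciesDef] = field(default_factory=list)
    pair_species_index: list[int] = field(default_factory=list)
    pair_true_overlap: list[int] = field(default_factory=list)
    pair_mergeable: list[bool] = field(default_factory=list)
    tapms_passers: list[str] = field(default_factory=list)
    tapms_decoy_reasons: dict[str, list[str]] = field(default_factory=dict)
    rng_algorithm: str = "numpy PCG64 via SeedSequence spawning"


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, stream]))


def _random_background(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    L = cfg.genome_length
    n_at = round(cfg.at_fraction * L)
    n_gc = L - n_at
    n_g = round(n_gc * (1 + cfg.gc_skew) / 2)
    n_c = n_gc - n_g
    n_a = n_at // 2
    n_t = n_at - n_a
    if min(n_a, n_c, n_g, n_t) < 0:
        raise ValueError("infeasible composition constraints")
    arr = np.array([b"A"] * n_a + [b"C"] * n_c + [b"G"] * n_g + [b"T"] * n_t, dtype="S1")
    rng.shuffle(arr)
    return arr


def _swap_out(
    arr: np.ndarray,
    pos: int,
    rng: np.random.Generator,
    reserved: np.ndarray | None = None,
) -> None:
    """Swap arr[pos] with a random A/T position (composition-preserving).

    Landing positions inside ``reserved`` regions (planted motifs and their
    flanks) are avoided so a displaced G/C cannot disturb a planted match.
    """
    at = np.isin(arr, _AT)
    if reserved is not None:
        at &= ~reserved
    targets = np.flatnonzero(at)
    q = int(rng.choice(targets))
    arr[pos], arr[q] = arr[q], arr[pos]


def _break_runs(
    arr: np.ndarray,
    lo: int,
    hi: int,
    base: bytes,
    min_run: int,
    rng: np.random.Generator,
    reserved: np.ndarray | None = None,
    immutable: np.ndarray | None = None,
) -> None:
    """Remove every run of >= min_run ``base`` inside [lo, hi) by swapping a
    base from each run out to a random A/T position (indices taken mod L).
    Positions flagged ``immutable`` (planted motif bodies) are never edited."""
    L = len(arr)
    run = 0
    for off in range(lo, hi):
        i = off % L
        if immutable is not None and immutable[i]:
            run = 0
            continue
        if arr[i] == base:
            run += 1
            if run == min_run:
                prev = (i - 1) % L
                src = prev if arr[prev] == base and not (
                    immutable is not None and immutable[prev]
                ) else i
                _swap_out(arr, src, rng, reserved)
                run = 0
        else:
            run = 0


def _clean(
    arr: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
    keep: set[tuple[int, int, str]] | None = None,
    reserved: np.ndarray | None = None,
    immutable: np.ndarray | None = None,
    max_iter: int = 500,
) -> bool:
    """Scrub chance G4 consensus matches from both strands in place,
    leaving the planted intervals in ``keep`` untouched.  Returns True when
    the motif set equals ``keep`` exactly."""
    params = cfg.scan_params
    keep = keep or set()
    L = len(arr)
    for _ in range(max_iter):
        seq = CircularSequence("bg", arr.tobytes().decode())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = scan_both_strands(seq, params)
        found = {(m.start % L, m.end - m.start, m.strand): m for m in res.motifs}
        if set(found) == keep:
            return True
        for key, m in found.items():
            if key in keep:
                continue
            sense = b"G" if m.strand == "+" else b"C"
            _break_runs(arr, m.start, m.end, sense, params.min_run, rng, reserved, immutable)
    return False


def _motif_string(params: ScanParams, rng: np.random.Generator) -> str:
    loops = rng.choice(list("ACT"), size=params.min_runs - 1)
    run = "G" * params.min_run
    return run + "".join(str(l) + run for l in loops)


def make_genome(cfg: SimConfig) -> tuple[CircularSequence, GroundTruth]:
    """Background drawn under (AT fraction, GC skew), scrubbed of chance G4
    consensus occurrences, with ``n_planted_g4`` minimal-consensus motifs
    inserted at recorded, well-separated positions on ``g4_strand``."""
    L = cfg.genome_length
    params = cfg.scan_params
    flank = params.loop_max + params.min_run
    if cfg.n_planted_g4 > 0 and cfg.n_planted_g4 * cfg.motif_spacing > L:
        raise ValueError("cannot place motifs without overlap at the requested spacing")
    for attempt in range(5):
        rng = _rng(cfg, 1000 + attempt)
        arr = _random_background(cfg, rng)
        if not _clean(arr, cfg, rng):
            continue
        truth = GroundTruth()
        if cfg.n_planted_g4:
            slot = L // cfg.n_planted_g4
            jitter = max(1, slot - cfg.motif_spacing)
            sense = b"G" if cfg.g4_strand == "+" else b"C"
            plants: list[tuple[int, str]] = []
            reserved = np.zeros(L, dtype=bool)
            immutable = np.zeros(L, dtype=bool)
            for i in range(cfg.n_planted_g4):
                motif = _motif_string(params, rng)
                mlen = len(motif)
                pos = min(i * slot + int(rng.integers(0, jitter)), L - mlen - flank - 1)
                plants.append((pos, motif))
                reserved[max(0, pos - flank - 1) : pos + mlen + flank + 1] = True
                immutable[pos : pos + mlen] = True
            for pos, motif in plants:
                mlen = len(motif)
                planted = motif if cfg.g4_strand == "+" else revcomp(motif)
                _break_runs(arr, pos - flank, pos, sense, params.min_run, rng, reserved)
                _break_runs(arr, pos + mlen, pos + mlen + flank, sense, params.min_run, rng, reserved)
                for edge in (pos - 1, pos + mlen):
                    if arr[edge % L] == sense:
                        _swap_out(arr, edge % L, rng, reserved)
                arr[pos : pos + mlen] = np.frombuffer(planted.encode(), dtype="S1")
                truth.motifs.append((pos, pos + mlen, cfg.g4_strand))
            keep = {(s, e - s, st) for s, e, st in truth.motifs}
            if not _clean(arr, cfg, rng, keep, reserved, immutable, max_iter=100):
                continue
        genome = CircularSequence(f"sim_{cfg.rng_seed}", arr.tobytes().decode())
        return genome, truth
    raise RuntimeError("planted motif verification failed after 5 attempts")


def simulate_coverage(
    genome: CircularSequence,
    truth: GroundTruth,
    condition: str,
    cfg: SimConfig,
    stream: int = 0,
) -> StrandCoverageTrack:
    """Poisson strand-specific coverage; the ``deficient`` condition boosts
    the motif-carrying strand ``accumulation_factor``-fold over a window
    upstream (transcript 5' direction) of each planted G4 center.

    Expected per-base means are recorded in ``truth.expected_depth`` under
    the condition name.  ``stream`` separates replicate samplings.
    """
    if condition not in ("control", "deficient"):
        raise ValueError(f"unknown condition {condition!r}")
    L = len(genome)
    expected = {s: np.full(L, cfg.coverage_depth) for s in "+-"}
    if condition == "deficient":
        for start, end, strand in truth.motifs:
            center = (start + end) // 2
            if strand == "+":
                lo, hi = center - cfg.upstream_extent, center - cfg.upstream_gap
            else:
                lo, hi = center + cfg.upstream_gap, center + cfg.upstream_extent
            idx = np.mod(np.arange(lo, hi + 1), L)
            expected[strand][idx] *= cfg.accumulation_factor
    truth.expected_depth[condition] = {s: expected[s].copy() for s in "+-"}
    rng = _rng(cfg, 2000 + stream)
    plus = rng.poisson(expected["+"]).astype(float)
    minus = rng.poisson(expected["-"]).astype(float)
    return StrandCoverageTrack(genome.id, plus, minus, float(plus.sum() + minus.sum()))


def _draw_tail(cfg: SimConfig, rng: np.random.Generator) -> str:
    tails, probs = zip(*cfg.tail_spec)
    return str(rng.choice(tails, p=np.array(probs) / sum(probs)))


def _overlap_candidates(r1: str, rc2: str, min_overlap: int) -> list[int]:
    """All overlap lengths >= min_overlap at which r1's 3' end exactly
    matches rc2's 5' end (construction-time uniqueness check)."""
    out = []
    for olen in range(min_overlap, min(len(r1), len(rc2)) + 1):
        if r1[len(r1) - olen :] == rc2[:olen]:
            out.append(olen)
    return out


def make_species(
    genome: CircularSequence, cfg: SimConfig, rng: np.random.Generator | None = None
) -> list[SpeciesDef]:
    """Short-RNA species with recorded ends and tails.

    Mergeable species are 60-90 nt (2x75 reads overlap by >= 60 nt); the
    ``n_unmergeable`` species are exactly 2*read_length - 4 nt long so their
    reads overlap by 4 nt and must be rejected by the >= 5 nt rule.  Tails
    are drawn from ``tail_spec``; a tail is only accepted when the genome
    does not continue with its first base (so it is genuinely
    non-templated) and the read geometry has no spurious longer overlap.
    """
    rng = rng or _rng(cfg, 3000)
    L = len(genome)
    rl = cfg.read_length
    species: list[SpeciesDef] = []
    used: set[tuple[int, int, str]] = set()
    total = cfg.n_species + cfg.n_unmergeable
    guard = 0
    while len(species) < total and guard < 10_000:
        guard += 1
        unmergeable = len(species) >= cfg.n_species
        length = 2 * rl - 4 if unmergeable else int(rng.integers(60, 91))
        start0 = int(rng.integers(0, L - length - 1))
        strand = "+" if rng.random() < 0.5 else "-"
        tail = "" if unmergeable else _draw_tail(cfg, rng)
        core = genome.fetch(start0, start0 + length)
        if strand == "-":
            core = revcomp(core)
            five, three = start0 + length, start0 + 1
            next_base = revcomp(genome.residues[(start0 - 1) % L])
        else:
            five, three = start0 + 1, start0 + length
            next_base = genome.residues[(start0 + length) % L]
        if tail and next_base == tail[0]:
            continue  # tail would be partially templated; resample
        if (five, three, strand) in used:
            continue
        molecule = core + tail
        r1 = molecule[:rl]
        rc2 = molecule[-min(rl, len(molecule)) :]
        true_olen = len(r1) + len(rc2) - len(molecule)
        cands = _overlap_candidates(r1, rc2, 5)
        if unmergeable and cands:
            continue  # coincidental >= 5 nt overlap; resample
        if not unmergeable and cands != [true_olen]:
            continue  # spurious alternative overlap; resample
        used.add((five, three, strand))
        species.append(SpeciesDef(five, three, strand, tail, molecule))
    if len(species) < total:
        raise RuntimeError("could not place the requested species")
    return species


def simulate_read_pairs(
    species: list[SpeciesDef], cfg: SimConfig, truth: GroundTruth | None = None
) -> tuple[list[ReadPair], GroundTruth]:
    """Paired-end reads over the species (r1 = 5' prefix, r2 = reverse
    complement of the 3' suffix, clipped to the molecule), with per-pair
    true overlap and mergeability recorded."""
    truth = truth or GroundTruth()
    truth.species = list(species)
    rl = cfg.read_length
    per_species = max(2, cfg.n_read_pairs // len(species))
    remainder = max(0, cfg.n_read_pairs - per_species * len(species))
    pairs: list[ReadPair] = []
    for si, sp in enumerate(species):
        mol = sp.molecule
        n = min(rl, len(mol))
        r1 = mol[:n]
        r2 = revcomp(mol[-n:])
        olen = 2 * n - len(mol)
        for _ in range(per_species + (1 if si < remainder else 0)):
            pairs.append(ReadPair(r1, r2))
            truth.pair_species_index.append(si)
            truth.pair_true_overlap.append(olen)
            truth.pair_mergeable.append(olen >= 5)
    return pairs, truth


def write_fastq_pairs(pairs: list[ReadPair], path1: str | Path, path2: str | Path) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for i, p in enumerate(pairs):
            f1.write(f"@pair{i}/1\n{p.r1_seq}\n+\n{'I' * len(p.r1_seq)}\n")
            f2.write(f"@pair{i}/2\n{p.r2_seq}\n+\n{'I' * len(p.r2_seq)}\n")


def simulate_tapms(cfg: SimConfig) -> tuple[list[ProteinRecord], GroundTruth]:
    """Replicate intensity table with planted degradosome partners.

    True partners are enriched 5-20-fold for both baits, present in all
    replicates and mitochondrial.  Decoy classes exercise each filter
    criterion: a bait replicate missing (presence), 100-fold enrichment
    without the mitochondrial flag, and control-absent proteins whose bait
    signal sits at the imputation floor (enrichment below threshold after
    floor imputation).  One plain decoy carries the global-floor sentinel
    intensity so the imputation floor is deterministic.
    """
    rng = _rng(cfg, 4000)
    if cfg.tapms_n_true > cfg.tapms_n_proteins - 7:
        raise ValueError("too many true partners for the table size")
    truth = GroundTruth()
    records: list[ProteinRecord] = []
    floor_value = 500.0

    def noisy(mean: float) -> np.ndarray:
        return mean * np.exp(rng.normal(0.0, 0.15, size=3))

    def base_intensity() -> float:
        return float(np.exp(rng.normal(16.0, 1.0)))

    def mw() -> float:
        return float(rng.uniform(20.0, 150.0))

    for i in range(cfg.tapms_n_true):
        b = base_intensity()
        enr = rng.uniform(5.0, 20.0, size=2)
        rec = ProteinRecord(
            f"TRUE{i:02d}", mw(),
            {"suv3": noisy(b * enr[0]), "pnp": noisy(b * enr[1]), "control": noisy(b)},
            True,
        )
        records.append(rec)
        truth.tapms_passers.append(rec.protein_id)

    for i in range(2):
        b = base_intensity()
        suv3 = noisy(b * 10.0)
        suv3[int(rng.integers(0, 3))] = 0.0
        rec = ProteinRecord(
            f"DECOY_PARTIAL{i}", mw(),
            {"suv3": suv3, "pnp": noisy(b * 10.0), "control": noisy(b)}, True,
        )
        records.append(rec)
        truth.tapms_decoy_reasons[rec.protein_id] = [REASON_PRESENCE]

    for i in range(2):
        b = base_intensity()
        rec = ProteinRecord(
            f"DECOY_NONMITO{i}", mw(),
            {"suv3": noisy(b * 100.0), "pnp": noisy(b * 100.0), "control": noisy(b)},
            False,
        )
        records.append(rec)
        truth.tapms_decoy_reasons[rec.protein_id] = [REASON_NOT_MITOCHONDRIAL]

    for i in range(2):
        rec = ProteinRecord(
            f"DECOY_NOCTRL{i}", mw(),
            {
                "suv3": np.full(3, 2.0 * floor_value),
                "pnp": np.full(3, 2.0 * floor_value),
                "control": np.zeros(3),
            },
            True,
        )
        records.append(rec)
        truth.tapms_decoy_reasons[rec.protein_id] = [
            REASON_ENRICHMENT_SUV3, REASON_ENRICHMENT_PNP,
        ]

    n_plain = cfg.tapms_n_proteins - len(records)
    for i in range(n_plain):
        b = base_intensity()
        rec = ProteinRecord(
            f"DECOY{i:03d}", mw(),
            {"suv3": noisy(b), "pnp": noisy(b), "control": noisy(b)},
            bool(rng.random() < 0.7),
        )
        records.append(rec)
    # global-floor sentinel: far below every lognormal intensity in the table
    records[-1].intensities["control"][2] = floor_value
    return records, truth
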