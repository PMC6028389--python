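"""Label-free TAP-MS candidate filter for degradosome partners.

Two bait purifications (hSuv3-TAP and PNPase-TAP) and a mitochondrially
targeted tag-only control (mt-TAP), three replicates each.  Protein
abundance is the mean signal intensity divided by molecular weight;
enrichment is the mean bait intensity over the mean control intensity.
A protein is nominated as a putative degradosome partner when it
(1) is present (nonzero intensity) in all three replicates of both baits,
(2) is enriched more than threshold-fold (default 3) for both baits, and
(3) is annotated as mitochondrial.

A control mean of zero is imputed with the smallest nonzero intensity in
the whole table (global floor) and flagged, which avoids infinite ratios
while preserving ranking.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

EXPERIMENTS = ("suv3", "pnp", "control")
BAITS = ("suv3", "pnp")

REASON_PRESENCE = "not present in all purifications"
REASON_ENRICHMENT_SUV3 = "enrichment not above threshold for hSuv3 bait"
REASON_ENRICHMENT_PNP = "enrichment not above threshold for PNPase bait"
REASON_NOT_MITOCHONDRIAL = "not annotated as mitochondrial"


@dataclass
class ProteinRecord:
    protein_id: str
    molecular_weight: float  # kDa
    intensities: dict[str, np.ndarray]  # experiment -> 3 replicate intensities
    is_mitochondrial: bool

    def __post_init__(self) -> None:
        for exp in EXPERIMENTS:
            v = np.asarray(self.intensities.get(exp, ()), dtype=float)
            if v.shape != (3,):
                raise ValueError(
                    f"{self.protein_id}: need exactly 3 replicate intensities for {exp}"
                )
            if (v < 0).any():
                raise ValueError(f"{self.protein_id}: negative intensity in {exp}")
            self.intensities[exp] = v


@dataclass
class EnrichmentResult:
    protein_id: str
    abundance: dict[str, float]
    enrichment_suv3: float
    enrichment_pnp: float
    control_imputed: bool
    present_all_suv3: bool
    present_all_pnp: bool
    is_mitochondrial: bool
    passes: bool
    fail_reasons: list[str] = field(default_factory=list)


def abundance(rec: ProteinRecord, experiment: str) -> float:
    """Mean replicate intensity divided by molecular weight (intensity/kDa)."""
    if rec.molecular_weight <= 0:
        raise ValueError(f"{rec.protein_id}: molecular weight must be positive")
    return float(rec.intensities[experiment].mean()) / rec.molecular_weight


def enrichment(
    rec: ProteinRecord, bait: str, floor: float | None = None
) -> tuple[float, bool]:
    """Mean bait intensity over mean control intensity.

    When the control mean is zero it is imputed with ``floor`` (the global
    smallest nonzero intensity of the table) and the result is flagged.
    Returns (ratio, control_imputed).
    """
    if bait not in BAITS:
        raise ValueError(f"unknown bait {bait!r}")
    bait_mean = float(rec.intensities[bait].mean())
    ctrl_mean = float(rec.intensities["control"].mean())
    if ctrl_mean > 0:
        return bait_mean / ctrl_mean, False
    if floor is None or floor <= 0:
        raise ValueError(
            f"{rec.protein_id}: control intensities are all zero and no "
            "imputation floor was supplied"
        )
    return bait_mean / floor, True


def global_floor(records: list[ProteinRecord]) -> float:
    """Smallest nonzero intensity anywhere in the table (imputation floor)."""
    values = np.concatenate([rec.intensities[e] for rec in records for e in EXPERIMENTS])
    nonzero = values[values > 0]
    if len(nonzero) == 0:
        raise ValueError("all intensities are zero")
    return float(nonzero.min())


def filter_candidates(
    records: list[ProteinRecord],
    threshold: float = 3.0,
    strict: bool = True,
) -> list[EnrichmentResult]:
    """Apply the three-criterion partner filter to every record.

    ``strict`` compares enrichment with ``>`` (the published candidate count
    used a strict cutoff); set False for ``>=``.  Results are sorted with
    passing candidates first, by min(bait enrichments) descending.
    """
    if not records:
        raise ValueError("empty protein table")
    floor = global_floor(records)
    out: list[EnrichmentResult] = []
    for rec in records:
        ab = {e: abundance(rec, e) for e in EXPERIMENTS}
        e_suv3, imp1 = enrichment(rec, "suv3", floor)
        e_pnp, imp2 = enrichment(rec, "pnp", floor)
        present_suv3 = bool((rec.intensities["suv3"] > 0).all())
        present_pnp = bool((rec.intensities["pnp"] > 0).all())
        reasons = []
        if not (present_suv3 and present_pnp):
            reasons.append(REASON_PRESENCE)
        ok = (lambda e: e > threshold) if strict else (lambda e: e >= threshold)
        if not ok(e_suv3):
            reasons.append(REASON_ENRICHMENT_SUV3)
        if not ok(e_pnp):
            reasons.append(REASON_ENRICHMENT_PNP)
        if not rec.is_mitochondrial:
            reasons.append(REASON_NOT_MITOCHONDRIAL)
        out.append(
            EnrichmentResult(
                rec.protein_id, ab, e_suv3, e_pnp, imp1 or imp2,
                present_suv3, present_pnp, rec.is_mitochondrial,
                passes=not reasons, fail_reasons=reasons,
            )
        )
    out.sort(key=lambda r: (not r.passes, -min(r.enrichment_suv3, r.enrichment_pnp)))
    return out


_COLUMNS = [
    "protein_id", "mw_kda",
    "suv3_1", "suv3_2", "suv3_3",
    "pnp_1", "pnp_2", "pnp_3",
    "control_1", "control_2", "control_3",
    "is_mitochondrial",
]


def read_table(path: str | Path) -> list[ProteinRecord]:
    """Read a TSV/CSV intensity table (one row per protein) into records."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"intensity table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            ProteinRecord(
                str(d["protein_id"]),
                float(d["mw_kda"]),
                {
                    exp: np.array([d[f"{exp}_{i}"] for i in (1, 2, 3)], dtype=float)
                    for exp in EXPERIMENTS
                },
                bool(d["is_mitochondrial"]),
            )
        )
    return records


def write_table(records: list[ProteinRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {"protein_id": r.protein_id, "mw_kda": r.molecular_weight}
        for exp in EXPERIMENTS:
            for i in (1, 2, 3):
                row[f"{exp}_{i}"] = r.intensities[exp][i - 1]
        row["is_mitochondrial"] = int(r.is_mitochondrial)
        rows.append(row)
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def results_tsv(results: list[EnrichmentResult]) -> str:
    lines = [
        "protein_id\tabundance_suv3\tabundance_pnp\tabundance_control"
        "\tenrichment_suv3\tenrichment_pnp\tcontrol_imputed\tpasses\tfail_reasons"
    ]
    for r in results:
        lines.append(
            f"{r.protein_id}\t{r.abundance['suv3']:.4f}\t{r.abundance['pnp']:.4f}"
            f"\t{r.abundance['control']:.4f}\t{r.enrichment_suv3:.3f}"
            f"\t{r.enrichment_pnp:.3f}\t{int(r.control_imputed)}\t{int(r.passes)}"
            f"\t{'; '.join(r.fail_reasons) or '-'}"
        )
    return "\n".join(lines) + "\n"
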