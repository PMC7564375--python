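"""Clone-selection ledger: per-clone fates and stage-efficiency accounting.

Every single-cell clone sorted into the plate is tracked through the
quadruple selection strategy (QSS): FACS sorting and image-based screening,
expansion, diagnostic PCR, restriction digest, Sanger sequencing, and
construct excision with molecular karyotyping.  The ledger is a plain CSV —
one row per recovered clone plus a metadata block for the plate totals —
from which the stage funnel is recomputed:

=================  ==========================================================
stage              ratio
=================  ==========================================================
sorted             clones recovered / wells sorted
expanded           clones surviving passaging / clones recovered
pcr                products at the expected size / clones expanded
correct_edit       undigested (site-free) products / clones expanded
sequenced          isogenic-confirmed / sequenced among the undigested
karyotype          normal genotype / karyotyped
=================  ==========================================================

A product at an unexpected size counts as a PCR failure for the funnel even
though it is recorded with its observed length, and sequencing performed on
non-passing clones (as a control) is recorded but excluded from the
sequencing stage statistic.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "CloneRecord",
    "Stage",
    "StageStats",
    "LedgerError",
    "load_ledger",
    "packaged_ledger_path",
    "stage_stats",
    "render_report",
]

PCR_OUTCOMES = ("EXPECTED_SIZE", "SHIFTED", "NO_PRODUCT", "NOT_TESTED")
DIGEST_OUTCOMES = ("UNDIGESTED", "DOUBLE_BAND", "LOWER_BAND", "NOT_TESTED")
SEQUENCING_OUTCOMES = ("ISOGENIC_CONFIRMED", "NOT_EDITED", "INSERTION_ERROR", "NOT_PERFORMED")
KARYOTYPE_OUTCOMES = ("NORMAL", "ABNORMAL", "NOT_PERFORMED")

STAGE_ORDER = ("sorted", "expanded", "pcr", "correct_edit", "sequenced", "karyotype")


class LedgerError(ValueError):
    """Malformed ledger file or inconsistent record."""


@dataclass(frozen=True)
class CloneRecord:
    """One clone's fate through the selection funnel."""

    clone_id: str
    survived_expansion: bool
    pcr_outcome: str
    pcr_length: int | None = None
    digest_outcome: str = "NOT_TESTED"
    sequencing: str = "NOT_PERFORMED"
    karyotype: str = "NOT_PERFORMED"
    note: str = ""

    def __post_init__(self) -> None:
        if self.pcr_outcome not in PCR_OUTCOMES:
            raise LedgerError(f"{self.clone_id}: unknown pcr_outcome {self.pcr_outcome!r}")
        if self.digest_outcome not in DIGEST_OUTCOMES:
            raise LedgerError(f"{self.clone_id}: unknown digest_outcome {self.digest_outcome!r}")
        if self.sequencing not in SEQUENCING_OUTCOMES:
            raise LedgerError(f"{self.clone_id}: unknown sequencing {self.sequencing!r}")
        if self.karyotype not in KARYOTYPE_OUTCOMES:
            raise LedgerError(f"{self.clone_id}: unknown karyotype {self.karyotype!r}")
        if self.digest_outcome != "NOT_TESTED" and self.pcr_outcome != "EXPECTED_SIZE":
            raise LedgerError(
                f"{self.clone_id}: digest recorded but PCR outcome is {self.pcr_outcome}"
            )
        if self.sequencing == "ISOGENIC_CONFIRMED" and self.digest_outcome != "UNDIGESTED":
            raise LedgerError(
                f"{self.clone_id}: isogenic confirmation requires an undigested product"
            )
        if not self.survived_expansion and self.pcr_outcome != "NOT_TESTED":
            raise LedgerError(
                f"{self.clone_id}: clone lost during expansion cannot have a PCR outcome"
            )


@dataclass(frozen=True)
class Stage:
    name: str
    numerator: int
    denominator: int

    @property
    def efficiency_percent(self) -> float | None:
        """Exact percentage, or None when the stage has an empty denominator."""
        if self.denominator == 0:
            return None
        return 100.0 * self.numerator / self.denominator

    def __post_init__(self) -> None:
        if not 0 <= self.numerator <= self.denominator:
            raise LedgerError(f"stage {self.name}: numerator out of range")


@dataclass(frozen=True)
class StageStats:
    stages: tuple[Stage, ...]

    def __getitem__(self, name: str) -> Stage:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)

    def as_dict(self) -> dict:
        return {
            s.name: {
                "numerator": s.numerator,
                "denominator": s.denominator,
                "efficiency_percent": s.efficiency_percent,
            }
            for s in self.stages
        }


def packaged_ledger_path() -> Path:
    """Path of the ledger fixture distributed with the package."""
    return Path(__file__).parent / "data" / "table1.csv"


def load_ledger(path: str | Path) -> tuple[list[CloneRecord], dict[str, int]]:
    """Read a ledger CSV: metadata block (``# key=value`` lines) + records.

    Returns the clone records and the plate totals (``wells_sorted``,
    ``clones_recovered``).  Unknown enumeration values and duplicate clone
    ids are rejected with the offending row number.
    """
    text = Path(path).read_text()
    meta: dict[str, int] = {}
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition("=")
            meta[key.strip()] = int(value.strip())
        elif line.strip():
            body_lines.append(line)
    if not body_lines:
        return [], meta
    df = pd.read_csv(io.StringIO("\n".join(body_lines)), dtype=str).fillna("")
    required = {"clone_id", "survived_expansion", "pcr_outcome"}
    if not required <= set(df.columns):
        raise LedgerError(f"ledger header must contain {sorted(required)}")
    records: list[CloneRecord] = []
    seen: set[str] = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        cid = d["clone_id"]
        if cid in seen:
            raise LedgerError(f"row {row_no}: duplicate clone_id {cid!r}")
        seen.add(cid)
        try:
            records.append(
                CloneRecord(
                    clone_id=cid,
                    survived_expansion=d["survived_expansion"].strip().lower()
                    in ("1", "true", "yes"),
                    pcr_outcome=d["pcr_outcome"].strip(),
                    pcr_length=int(d["pcr_length"]) if d.get("pcr_length", "").strip() else None,
                    digest_outcome=d.get("digest_outcome", "").strip() or "NOT_TESTED",
                    sequencing=d.get("sequencing", "").strip() or "NOT_PERFORMED",
                    karyotype=d.get("karyotype", "").strip() or "NOT_PERFORMED",
                    note=d.get("note", "").strip(),
                )
            )
        except LedgerError as e:
            raise LedgerError(f"row {row_no}: {e}") from None
    return records, meta


def stage_stats(records: list[CloneRecord], totals: dict[str, int]) -> StageStats:
    """Recompute the selection funnel from the per-clone records.

    ``totals`` must provide ``wells_sorted``; ``clones_recovered`` defaults
    to the record count (the ledger keeps both explicitly because the plate
    may seed wells that never yield a visible clone).
    """
    if "wells_sorted" not in totals:
        raise LedgerError("ledger metadata must provide wells_sorted")
    wells_sorted = totals["wells_sorted"]
    recovered = totals.get("clones_recovered", len(records))
    expanded = [r for r in records if r.survived_expansion]
    pcr_pass = [r for r in expanded if r.pcr_outcome == "EXPECTED_SIZE"]
    undigested = [r for r in expanded if r.digest_outcome == "UNDIGESTED"]
    sequenced = [r for r in undigested if r.sequencing != "NOT_PERFORMED"]
    confirmed = [r for r in sequenced if r.sequencing == "ISOGENIC_CONFIRMED"]
    karyotyped = [r for r in records if r.karyotype != "NOT_PERFORMED"]
    normal = [r for r in karyotyped if r.karyotype == "NORMAL"]
    return StageStats(
        (
            Stage("sorted", recovered, wells_sorted),
            Stage("expanded", len(expanded), recovered),
            Stage("pcr", len(pcr_pass), len(expanded)),
            Stage("correct_edit", len(undigested), len(expanded)),
            Stage("sequenced", len(confirmed), len(sequenced)),
            Stage("karyotype", len(normal), len(karyotyped)),
        )
    )


_STAGE_TITLES = {
    "sorted": "Sorted single-cell clones",
    "expanded": "Expanded single-cell clones",
    "pcr": "PCR amplification",
    "correct_edit": "Undigested (gene-corrected candidates)",
    "sequenced": "Sequenced isogenic-confirmed",
    "karyotype": "Normal genotype",
}


def render_report(stats: StageStats, records: list[CloneRecord]) -> tuple[str, dict]:
    """Render the funnel and per-clone listing as markdown and JSON.

    Percentages appear at two decimals in markdown and at full precision in
    JSON, so downstream comparisons are not bound to display rounding.
    """
    lines = [
        "| Stage | Absolute numbers | Efficiency |",
        "| --- | --- | --- |",
    ]
    for s in stats.stages:
        eff = "undefined" if s.efficiency_percent is None else f"{s.efficiency_percent:.2f}%"
        lines.append(f"| {_STAGE_TITLES[s.name]} | {s.numerator}/{s.denominator} | {eff} |")
    lines += ["", "| Clone | Expansion | PCR | Digest | Sequencing | Karyotype |",
              "| --- | --- | --- | --- | --- | --- |"]
    for r in records:
        pcr = r.pcr_outcome + (f" ({r.pcr_length} bp)" if r.pcr_length else "")
        lines.append(
            f"| {r.clone_id} | {'survived' if r.survived_expansion else 'lost'} "
            f"| {pcr} | {r.digest_outcome} | {r.sequencing} | {r.karyotype} |"
        )
    markdown = "\n".join(lines) + "\n"
    payload = {
        "stages": stats.as_dict(),
        "clones": [
            {
                "clone_id": r.clone_id,
                "survived_expansion": r.survived_expansion,
                "pcr_outcome": r.pcr_outcome,
                "pcr_length": r.pcr_length,
                "digest_outcome": r.digest_outcome,
                "sequencing": r.sequencing,
                "karyotype": r.karyotype,
                "note": r.note,
            }
            for r in records
        ],
    }
    json.dumps(payload)  # fail fast if anything is not serialisable
    return markdown, payload
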