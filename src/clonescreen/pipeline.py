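"""End-to-end orchestration: classify a plate, genotype picks, render reports.

Every artifact written by :func:`run_pipeline` is stamped with the
configuration hash and seed so that a run can be reproduced exactly from its
outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .genotyping import call_clone, read_fasta
from .hcs import classify_plate
from .ledger import load_ledger, render_report, stage_stats
from .plateio import read_plate

log = logging.getLogger("clonescreen")

__all__ = ["run_pipeline", "genotype_fasta"]


def genotype_fasta(alleles_fasta: str | Path, config: RunConfig) -> dict:
    """Genotype diploid clones from a FASTA of allele pairs.

    Records are grouped two by two in file order (allele A then allele B of
    each clone); the clone name is the longest common id prefix, trimmed of
    separator characters.
    """
    seqs = read_fasta(alleles_fasta)
    if len(seqs) % 2:
        raise ValueError(f"{alleles_fasta}: expected an even number of allele records")
    primers = config.primers.build()
    enzyme = config.enzyme.build()
    calls = {}
    for a, b in zip(seqs[::2], seqs[1::2]):
        name = "".join(x for x, y in zip(a.id, b.id) if x == y).rstrip("_-.") or a.id
        call = call_clone(a, b, primers, enzyme, config.band_resolution)
        calls[name] = {
            "label": call.label,
            "bands": list(call.bands),
            "amplicon_lengths": list(call.amplicon_lengths),
            "observed_length": call.observed_length,
        }
    return calls


def run_pipeline(
    config: RunConfig,
    layout_csv: str | Path,
    out_dir: str | Path,
    alleles_fasta: str | Path | None = None,
    ledger_csv: str | Path | None = None,
) -> dict:
    """Classify a plate, genotype picked clones, summarise the ledger.

    Returns the report dictionary; also writes ``report.json`` and the
    per-well classification CSV under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    classifier = config.classifier.build()

    mosaics = read_plate(layout_csv, config.channel_order)
    table, picks = classify_plate(mosaics, classifier)
    log.info("classified %d wells: %s", len(table), table["label"].value_counts().to_dict())
    table.to_csv(out / "classification.csv", index=False)

    report: dict = {
        "tool_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "wells": len(table),
        "label_counts": table["label"].value_counts().to_dict(),
        "pick_list": picks,
    }
    if alleles_fasta is not None:
        report["genotype_calls"] = genotype_fasta(alleles_fasta, config)
    if ledger_csv is not None:
        records, totals = load_ledger(ledger_csv)
        stats = stage_stats(records, totals)
        markdown, payload = render_report(stats, records)
        (out / "ledger_report.md").write_text(markdown)
        report["ledger"] = payload["stages"]
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
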