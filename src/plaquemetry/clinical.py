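"""Turesky-modified Quigley-Hein Plaque Index (TMQHPlI) records.

Each buccal tooth surface is scored 0-5 at three sites (mesial, central,
distal), separately for total disclosed plaque (TDP, pink + purple) and
dark disclosed plaque (DDP, purple only, presumed mature biofilm). The
per-surface summary is the mean of the three site scores; grouping for
plots/statistics uses the mean rounded to the nearest whole number
(ties at x.5 round up — the index defines no tie rule, so the convention
is fixed here and exposed as an argument).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ValidationError
from .io import SITES

log = logging.getLogger(__name__)


@dataclass
class TMQHPlIRecord:
    subject_id: str
    tooth_id: str
    variant: str  # TDP or DDP
    site_scores: tuple[int, int, int]  # (mesial, central, distal)
    mean_score: float
    rounded_score: int

    def __post_init__(self) -> None:
        if len(self.site_scores) != 3:
            raise ValidationError("exactly three site scores required")
        if any(not (0 <= s <= 5) for s in self.site_scores):
            raise ValidationError("site scores must be in 0..5")
        if not np.isclose(self.mean_score, sum(self.site_scores) / 3.0):
            raise ValidationError("mean_score inconsistent with site scores")
        if not (0 <= self.rounded_score <= 5):
            raise ValidationError("rounded score out of range")


def round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def summarize_scores(table: pd.DataFrame, rounding=round_half_up) -> list[TMQHPlIRecord]:
    """One record per (subject, tooth, variant) from a validated site table.

    Emits a consistency warning when a surface's DDP mean exceeds its TDP
    mean (dark plaque is a subset of total plaque in the two-tone scheme);
    such surfaces are kept, since real examiner noise produces them.
    """
    records: list[TMQHPlIRecord] = []
    site_order = {s: i for i, s in enumerate(SITES)}
    for (subj, tooth, variant), grp in table.groupby(["subject_id", "tooth_id", "variant"], sort=True):
        grp = grp.sort_values("site", key=lambda s: s.map(site_order))
        scores = tuple(int(x) for x in grp["score"])
        mean = sum(scores) / 3.0
        records.append(
            TMQHPlIRecord(
                subject_id=str(subj),
                tooth_id=str(tooth),
                variant=str(variant),
                site_scores=scores,  # type: ignore[arg-type]
                mean_score=mean,
                rounded_score=rounding(mean),
            )
        )
    by_surface: dict[tuple[str, str], dict[str, float]] = {}
    for r in records:
        by_surface.setdefault((r.subject_id, r.tooth_id), {})[r.variant] = r.mean_score
    for (subj, tooth), variants in by_surface.items():
        if {"TDP", "DDP"} <= set(variants) and variants["DDP"] > variants["TDP"]:
            log.warning(
                "surface %s/%s: DDP mean %.2f exceeds TDP mean %.2f (dark plaque should be a subset of total)",
                subj, tooth, variants["DDP"], variants["TDP"],
            )
    return records


def records_to_frame(records: list[TMQHPlIRecord]) -> pd.DataFrame:
    """Wide per-surface frame: tmqhpli_{tdp,ddp}_mean and rounded variants."""
    rows: dict[tuple[str, str], dict] = {}
    for r in records:
        row = rows.setdefault((r.subject_id, r.tooth_id), {"subject_id": r.subject_id, "tooth_id": r.tooth_id})
        key = r.variant.lower()
        row[f"tmqhpli_{key}_mean"] = r.mean_score
        row[f"tmqhpli_{key}_rounded"] = r.rounded_score
    return pd.DataFrame(sorted(rows.values(), key=lambda d: (d["subject_id"], d["tooth_id"])))
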