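"""Drug-likeness pre-filtering and the staged virtual-screening rank funnel.

The library pre-filter keeps compounds inside the oral drug-likeness
window: molecular weight 160-480 g/mol inclusive, TPSA < 140 A^2, fewer
than 5 hydrogen-bond donors and fewer than 10 acceptors (strict
inequalities mirror how the window is usually stated).

The funnel consumes externally produced per-stage score tables (docking,
rescoring, ...).  Raw scores are treated as relative within a stage: only
dense ranks matter, and each stage propagates its top-ranked survivors to
the next.  The first stage may consist of several method tables run in
tandem, in which case survivors are the union of the per-method cuts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ValidationError

__all__ = [
    "CompoundRecord",
    "ScoreTable",
    "FunnelSpec",
    "DruglikenessWindow",
    "druglike_filter",
    "rank_within_stage",
    "run_funnel",
    "read_compound_table",
    "read_score_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    mw: float | None
    tpsa: float | None
    hbd: int | None
    hba: int | None
    smiles: str | None = None


@dataclass(frozen=True)
class DruglikenessWindow:
    """Filter thresholds; MW bounds inclusive, the rest strict."""

    mw_min: float = 160.0
    mw_max: float = 480.0
    tpsa_max: float = 140.0
    hbd_max: int = 5
    hba_max: int = 10


@dataclass
class ScoreTable:
    """Per-stage compound scores; by convention lower is better."""

    stage_name: str
    entries: dict[str, float]
    lower_is_better: bool = True

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError(f"score table {self.stage_name!r} is empty")


@dataclass
class FunnelSpec:
    """Ordered stages with keep parameters.

    Each stage is ``(stage_name, keep)`` where an integer ``keep`` is a
    count and a float in (0, 1) is a fraction of the stage's scored
    survivors (rounded up, at least 1).
    """

    stages: list[tuple[str, float | int]]
    final_k: int = 100

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValidationError("funnel needs at least one stage")
        for name, keep in self.stages:
            if isinstance(keep, bool) or keep <= 0:
                raise ValidationError(f"stage {name!r} keep parameter must be positive")
            if isinstance(keep, float) and keep >= 1:
                raise ValidationError(
                    f"stage {name!r}: fractional keep must be in (0, 1)"
                )
        if self.final_k < 1:
            raise ValidationError("final_k must be >= 1")


def _missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def druglike_filter(
    records: Sequence[CompoundRecord],
    window: DruglikenessWindow = DruglikenessWindow(),
) -> tuple[list[CompoundRecord], list[tuple[CompoundRecord, list[str]]]]:
    """Partition compounds into (kept, rejected-with-reasons)."""
    if not records:
        raise ValidationError("no compound records supplied")
    kept: list[CompoundRecord] = []
    rejected: list[tuple[CompoundRecord, list[str]]] = []
    for rec in records:
        reasons: list[str] = []
        if any(_missing(v) for v in (rec.mw, rec.tpsa, rec.hbd, rec.hba)):
            reasons.append("missing_property")
        else:
            if not (window.mw_min <= rec.mw <= window.mw_max):
                reasons.append("mw_out_of_range")
            if not rec.tpsa < window.tpsa_max:
                reasons.append("tpsa_out_of_range")
            if not rec.hbd < window.hbd_max:
                reasons.append("hbd_out_of_range")
            if not rec.hba < window.hba_max:
                reasons.append("hba_out_of_range")
        if reasons:
            rejected.append((rec, reasons))
        else:
            kept.append(rec)
    return kept, rejected


def rank_within_stage(table: ScoreTable) -> dict[str, int]:
    """Dense ranks, best score = rank 1; tied scores share a rank."""
    sign = 1.0 if table.lower_is_better else -1.0
    scores = sorted({sign * v for v in table.entries.values()})
    rank_of_score = {s: i + 1 for i, s in enumerate(scores)}
    return {cid: rank_of_score[sign * v] for cid, v in table.entries.items()}


def _stage_cut(
    table: ScoreTable,
    survivors: set[str] | None,
    keep: float | int,
) -> list[str]:
    """Ordered top cut of a stage among current survivors.

    Ordering is (rank, compound_id): dense rank first, lexicographic id as
    the deterministic tie-break inside a shared rank.
    """
    pool = {
        cid: v
        for cid, v in table.entries.items()
        if survivors is None or cid in survivors
    }
    if survivors is not None:
        dropped = sorted(survivors - set(table.entries))
        for cid in dropped:
            logger.info(
                "compound %s has no score in stage %s; dropped", cid, table.stage_name
            )
    if not pool:
        return []
    ranks = rank_within_stage(
        ScoreTable(table.stage_name, pool, table.lower_is_better)
    )
    ordered = sorted(pool, key=lambda cid: (ranks[cid], cid))
    if isinstance(keep, float) and not isinstance(keep, bool) and keep < 1:
        k = max(1, math.ceil(keep * len(ordered)))
    else:
        k = int(keep)
    return ordered[:k]


def run_funnel(
    stage_tables: Sequence[ScoreTable | Sequence[ScoreTable]],
    spec: FunnelSpec,
) -> list[str]:
    """Run the rank-propagation funnel and return the final ranked ids.

    ``stage_tables[i]`` corresponds to ``spec.stages[i]``; the first stage
    may be a list of method tables whose top cuts are unioned.  Later
    stages must be single tables.  Compounds missing a score in a later
    stage are dropped (with a logged reason).  The final ranking is the
    last stage's rank order, truncated to ``spec.final_k``.
    """
    if len(stage_tables) != len(spec.stages):
        raise ValidationError(
            f"{len(stage_tables)} stage tables supplied for {len(spec.stages)} stages"
        )
    survivors: set[str] | None = None
    final_order: list[str] = []
    for i, (tables, (stage_name, keep)) in enumerate(zip(stage_tables, spec.stages)):
        if isinstance(tables, ScoreTable):
            tables = [tables]
        else:
            tables = list(tables)
            if i > 0 and len(tables) != 1:
                raise ValidationError(
                    "only the first stage may have multiple method tables"
                )
        for t in tables:
            if t.stage_name != stage_name:
                raise ValidationError(
                    f"stage {i}: table named {t.stage_name!r}, spec says {stage_name!r}"
                )
        if len(tables) == 1:
            cut = _stage_cut(tables[0], survivors, keep)
            final_order = cut
            survivors = set(cut)
        else:
            union: set[str] = set()
            for t in tables:
                union.update(_stage_cut(t, survivors, keep))
            survivors = union
            final_order = sorted(union)
    return final_order[: spec.final_k]



def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read a compound property CSV/TSV (header: compound_id, mw, tpsa, hbd,
    hba, optional smiles)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    required = {"compound_id", "mw", "tpsa", "hbd", "hba"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            CompoundRecord(
                compound_id=str(row.compound_id),
                mw=None if pd.isna(row.mw) else float(row.mw),
                tpsa=None if pd.isna(row.tpsa) else float(row.tpsa),
                hbd=None if pd.isna(row.hbd) else int(row.hbd),
                hba=None if pd.isna(row.hba) else int(row.hba),
                smiles=getattr(row, "smiles", None),
            )
        )
    return records


def read_score_table(
    path: str | Path,
    stage_name: str | None = None,
    lower_is_better: bool = True,
) -> ScoreTable:
    """Read a score CSV/TSV with columns compound_id, score."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    if not {"compound_id", "score"} <= set(df.columns):
        raise ValidationError(f"{path}: need columns compound_id, score")
    ids = df["compound_id"].astype(str)
    if ids.duplicated().any():
        raise ValidationError(f"{path}: duplicate compound ids")
    entries = dict(zip(ids, df["score"].astype(float)))
    return ScoreTable(
        stage_name=stage_name or path.stem,
        entries=entries,
        lower_is_better=lower_is_better,
    )
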