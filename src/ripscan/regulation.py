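"""Integration of bound transcripts with knockdown expression.

A bound transcript is called regulated when its knockdown/control ratio
differs more than ``threshold``-fold (strictly) in at least ``min_reps`` of
the replicate pairs — up if the ratio exceeds the threshold, down if it falls
below its reciprocal. Bound-and-regulated genes are tabulated with the
up/down split as counts and rounded percentages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import TranscriptSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegulationCall:
    gene: str
    fold_changes: tuple[float, ...]  # knockdown/control, linear scale
    direction: str  # up / down / none
    n_replicates_passing: int


def replicate_fold_changes(kd_expr: pd.DataFrame, ctrl_expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene knockdown/control ratio for each paired replicate.

    Both frames must share index (genes) and have the same number of
    replicate columns, matched by position.
    """
    if kd_expr.shape != ctrl_expr.shape:
        raise ValueError("knockdown and control frames differ in shape")
    if not kd_expr.index.equals(ctrl_expr.index):
        raise ValueError("knockdown and control frames cover different genes")
    ctrl = ctrl_expr.values.astype(float)
    if (ctrl <= 0).any():
        g = kd_expr.index[np.argwhere(ctrl <= 0)[0][0]]
        raise ValueError(f"non-positive control intensity for gene {g!r}")
    ratios = kd_expr.values.astype(float) / ctrl
    cols = [f"fc_{i + 1}" for i in range(kd_expr.shape[1])]
    return pd.DataFrame(ratios, index=kd_expr.index, columns=cols)


def call_regulated(
    ratios: tuple[float, ...] | list[float],
    gene: str = "",
    threshold: float = 4.0,
    min_reps: int = 2,
) -> RegulationCall:
    """Apply the replicate rule to one gene's ratio triplet.

    Up requires strictly more than ``threshold``-fold in >= ``min_reps``
    replicates; down requires strictly less than 1/``threshold``. A gene
    meeting both (pathological) is called none with a warning.
    """
    arr = np.asarray(ratios, dtype=float)
    n_up = int((arr > threshold).sum())
    n_down = int((arr < 1.0 / threshold).sum())
    if n_up >= min_reps and n_down >= min_reps:
        logger.warning("gene %r passes both up and down rules; calling none", gene)
        return RegulationCall(gene, tuple(arr), "none", 0)
    if n_up >= min_reps:
        return RegulationCall(gene, tuple(arr), "up", n_up)
    if n_down >= min_reps:
        return RegulationCall(gene, tuple(arr), "down", n_down)
    return RegulationCall(gene, tuple(arr), "none", 0)


def call_regulated_table(
    fold_changes: pd.DataFrame, threshold: float = 4.0, min_reps: int = 2
) -> pd.DataFrame:
    """Vector version over a fold-change frame; adds direction and n_passing."""
    calls = [
        call_regulated(row, gene=g, threshold=threshold, min_reps=min_reps)
        for g, row in zip(fold_changes.index, fold_changes.values)
    ]
    out = fold_changes.copy()
    out["direction"] = [c.direction for c in calls]
    out["n_replicates_passing"] = [c.n_replicates_passing for c in calls]
    return out


@dataclass
class IntegrationResult:
    table: pd.DataFrame  # bound-and-regulated genes with fold changes and direction
    n_up: int
    n_down: int
    pct_up: int  # rounded percentage of regulated bound genes
    pct_down: int


def integrate(bound: TranscriptSet, calls: pd.DataFrame) -> IntegrationResult:
    """Bound genes with a non-none regulation call, plus the up/down split.

    Percentages are 100 * count / (n_up + n_down), rounded to the nearest
    integer (an empty table reports 0/0).
    """
    regulated = calls[calls["direction"] != "none"]
    table = regulated.loc[regulated.index.intersection(sorted(bound.genes))]
    n_up = int((table["direction"] == "up").sum())
    n_down = int((table["direction"] == "down").sum())
    total = n_up + n_down
    pct_up = int(round(100.0 * n_up / total)) if total else 0
    pct_down = int(round(100.0 * n_down / total)) if total else 0
    return IntegrationResult(table=table, n_up=n_up, n_down=n_down, pct_up=pct_up, pct_down=pct_down)


def split_percentages(n_down: int, n_up: int) -> tuple[int, int]:
    """Rounded (pct_down, pct_up) for a reported down/up count pair."""
    total = n_down + n_up
    if total == 0:
        return 0, 0
    return int(round(100.0 * n_down / total)), int(round(100.0 * n_up / total))
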