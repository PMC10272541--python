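"""Spearman correlation and staged-dichotomy ROC-AUC evaluation.

Any parameter or index column can be scored against an ordinal grade or
stage: Spearman rank correlation (midranks for ties, t-approximation for
the p-value) plus one ROC-AUC per staged dichotomy ("01vs.234" labels
stages 0-1 as negative, 2-4 as positive).  AUC equals the Mann-Whitney
concordance probability with ties counted one half; when a dichotomy has
an empty side, the cell is NA.  AUCs are reported unflipped: orienting the
index is the model's job.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Dichotomies by target kind, named as in staging reports.
STEATOSIS_DICHOTOMIES = ("0vs.123", "01vs.23", "012vs.3")
FIBROSIS_DICHOTOMIES = ("0vs.1234", "01vs.234", "012vs.34", "0123vs.4")

_SPLIT_RE = re.compile(r"^(\d+)vs\.(\d+)$")


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with midranks; p by the t-approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("Spearman correlation is undefined for a constant vector")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def dichotomize(scores: Sequence[int], split: str) -> np.ndarray:
    """Binary labels from a named ordinal cutpoint such as ``"01vs.234"``."""
    m = _SPLIT_RE.match(split)
    if not m:
        raise ValueError(f"malformed split name {split!r}; expected e.g. '01vs.234'")
    left = {int(ch) for ch in m.group(1)}
    right = {int(ch) for ch in m.group(2)}
    if left & right:
        raise ValueError(f"split {split!r} repeats a score on both sides")
    scores = np.asarray(scores)
    allowed = left | right
    bad = set(np.unique(scores)) - allowed
    if bad:
        raise ValueError(f"scores {sorted(bad)} outside split {split!r}")
    return np.isin(scores, sorted(right)).astype(int)


def roc_auc(index: Sequence[float], labels: Sequence[int]) -> float:
    """AUC as the Mann-Whitney concordance probability (ties count 0.5).

    Returns ``nan`` (an NA cell) when either class is empty.
    """
    index = np.asarray(index, dtype=float)
    labels = np.asarray(labels)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n0 == 0 or n1 == 0:
        return float("nan")
    ranks = stats.rankdata(index)  # midranks
    r1 = ranks[labels == 1].sum()
    u = r1 - n1 * (n1 + 1) / 2
    return float(u / (n0 * n1))


@dataclass
class EvaluationReport:
    """Spearman row block plus one AUC row per dichotomy, columns = indices."""

    table: pd.DataFrame  # rows: dichotomies + Spearman_R/Spearman_p
    target: str

    def to_csv(self, path) -> None:
        self.table.to_csv(path, float_format="%.12g")


def evaluate_table(
    table: pd.DataFrame,
    columns: Sequence[str],
    target: str,
    dichotomies: Optional[Sequence[str]] = None,
) -> EvaluationReport:
    """Full Spearman + staged-AUC grid for the given index columns.

    Dichotomies default to the steatosis set for a ``grade`` target and
    the fibrosis set for a ``stage`` target; cells are NA whenever one
    side of a dichotomy is empty in the cohort.
    """
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise KeyError(f"unknown columns: {missing}")
    if target not in table.columns:
        raise KeyError(f"unknown target column: {target!r}")
    y = pd.to_numeric(table[target], errors="raise").to_numpy()
    if dichotomies is None:
        if "grade" in target:
            dichotomies = STEATOSIS_DICHOTOMIES
        elif "stage" in target:
            dichotomies = FIBROSIS_DICHOTOMIES
        else:
            hi = int(np.max(y))
            dichotomies = ["".join(map(str, range(k + 1))) + "vs." + "".join(map(str, range(k + 1, hi + 1))) for k in range(hi)]
    grid: dict[str, dict[str, float]] = {c: {} for c in columns}
    for col in columns:
        x = table[col].to_numpy(dtype=float)
        for split in dichotomies:
            labels = dichotomize(y, split)
            grid[col][split] = roc_auc(x, labels)
        try:
            r, p = spearman(x, y)
        except ValueError:
            r, p = float("nan"), float("nan")
        grid[col]["Spearman_R"] = r
        grid[col]["Spearman_p"] = p
    frame = pd.DataFrame(grid, columns=list(columns))
    frame = frame.reindex(list(dichotomies) + ["Spearman_R", "Spearman_p"])
    frame.index.name = "row"
    return EvaluationReport(table=frame, target=target)
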