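"""Correlation-ranked feature selection and linear staging indices.

Parameters are ranked per cohort by the magnitude of their Spearman
correlation with the histological score; features ranked high in every
cohort ("shared parameters") are combined into a linear index by ordinary
least squares on the z-scored features, the score being treated as a
numeric ordinal.  Downstream evaluation only uses the index through rank
statistics, so the OLS scale is immaterial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class CollinearityError(ValueError):
    """Design matrix is rank deficient."""

    def __init__(self, features):
        self.features = list(features)
        super().__init__(f"collinear or constant feature columns: {self.features}")


def rank_features(
    table: pd.DataFrame,
    target: str,
    features: Optional[Sequence[str]] = None,
) -> list[tuple[str, float, float]]:
    """Order features by |Spearman R| against the target score, descending.

    Ties are broken alphabetically; constant features are ranked last with
    R recorded as 0.  Returns ``(feature, |R|, p)`` tuples.
    """
    y = pd.to_numeric(table[target], errors="raise").to_numpy(dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 samples to rank features")
    if np.unique(y).size < 2:
        raise ValueError(f"target {target!r} is constant")
    if features is None:
        meta = {target, "sample_id", "group", "week", "grade", "stage"}
        features = [c for c in table.columns if c not in meta and pd.api.types.is_numeric_dtype(table[c])]
    scored = []
    for name in features:
        x = table[name].to_numpy(dtype=float)
        if np.unique(x).size < 2:
            scored.append((name, 0.0, 1.0, 0))  # constant: forced last
            continue
        r, p = stats.spearmanr(x, y)
        scored.append((name, float(abs(r)), float(p), 1))
    scored.sort(key=lambda t: (-t[3], -t[1], t[0]))
    return [(name, r, p) for name, r, p, _ in scored]


def select_shared(
    rankings: Mapping[str, Sequence[str]] | Sequence[Sequence[str]],
    top_k: int,
    step: int = 5,
) -> list[str]:
    """Intersect each cohort's top-k features; escalate k until non-empty.

    ``rankings`` maps group name to its ordered feature list (or is a bare
    sequence of ordered lists).  If the top-k intersection is empty, k is
    increased by ``step`` until a shared feature appears or all features
    are exhausted, in which case an error lists each group's top features.
    Returns the shared set ordered by mean rank.
    """
    if isinstance(rankings, Mapping):
        ordered = list(rankings.values())
        names = list(rankings.keys())
    else:
        ordered = list(rankings)
        names = [f"group{i}" for i in range(len(ordered))]
    if len(ordered) < 2:
        raise ValueError("select_shared needs rankings from at least 2 groups")
    max_len = max(len(r) for r in ordered)
    k = top_k
    while True:
        tops = [set(r[:k]) for r in ordered]
        shared = set.intersection(*tops)
        if shared:
            mean_rank = {
                f: np.mean([list(r).index(f) for r in ordered]) for f in shared
            }
            return sorted(shared, key=lambda f: (mean_rank[f], f))
        if k >= max_len:
            tops_repr = {n: list(r[:top_k]) for n, r in zip(names, ordered)}
            raise ValueError(f"no shared features at any k; per-group tops: {tops_repr}")
        k += step


@dataclass
class IndexModel:
    """A linear index: z-scored features combined by OLS coefficients."""

    feature_names: list[str]
    means: np.ndarray
    scales: np.ndarray
    coefficients: np.ndarray  # one per feature
    intercept: float
    target: str
    fit_groups: list[str] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "feature_names": self.feature_names,
                "means": list(map(float, self.means)),
                "scales": list(map(float, self.scales)),
                "coefficients": list(map(float, self.coefficients)),
                "intercept": float(self.intercept),
                "target": self.target,
                "fit_groups": self.fit_groups,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "IndexModel":
        text = Path(source).read_text() if isinstance(source, (str, Path)) and str(source).endswith(".json") else source
        data = json.loads(text)
        return cls(
            feature_names=data["feature_names"],
            means=np.asarray(data["means"], dtype=float),
            scales=np.asarray(data["scales"], dtype=float),
            coefficients=np.asarray(data["coefficients"], dtype=float),
            intercept=float(data["intercept"]),
            target=data["target"],
            fit_groups=list(data.get("fit_groups", [])),
        )


def fit_linear_index(
    table: pd.DataFrame,
    features: Sequence[str],
    target: str,
) -> IndexModel:
    """Ordinary least squares of the ordinal score on z-scored features."""
    features = list(features)
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise KeyError(f"features not in table: {missing}")
    X = table[features].to_numpy(dtype=float)
    y = pd.to_numeric(table[target], errors="raise").to_numpy(dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in selected columns")
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} samples to fit {p} features, got {n}")
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=0)
    zero_scale = [f for f, s in zip(features, scales) if s == 0]
    if zero_scale:
        raise CollinearityError(zero_scale)
    Z = (X - means) / scales
    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < p + 1:
        # name the features involved in the dependency via QR pivoting
        _, R = np.linalg.qr(design)
        dep = [features[j - 1] for j in range(1, p + 1) if abs(R[j, j]) < 1e-10 * max(abs(np.diag(R)).max(), 1)]
        raise CollinearityError(dep or features)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return IndexModel(
        feature_names=features,
        means=means,
        scales=scales,
        coefficients=beta[1:],
        intercept=float(beta[0]),
        target=target,
        fit_groups=sorted(map(str, table["group"].unique())) if "group" in table.columns else [],
    )


def apply_index(model: IndexModel, table: pd.DataFrame) -> np.ndarray:
    """Evaluate the fitted index on a parameter table, one score per row."""
    missing = [f for f in model.feature_names if f not in table.columns]
    if missing:
        raise KeyError(f"features not in table: {missing}")
    X = table[model.feature_names].to_numpy(dtype=float)
    Z = (X - model.means) / model.scales
    return Z @ model.coefficients + model.intercept
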