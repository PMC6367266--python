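"""Random-forest importance ranking and top-k feature selection.

Features are ranked by mean decrease in impurity averaged over the trees of
a random forest fitted on the labelled feature matrix; the top-k names are
kept. Ties are broken by ascending original column index so rankings are
deterministic given the forest seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier


@dataclass(frozen=True)
class SelectionConfig:
    """Top-k forest-importance selection parameters.

    scope='per_fold' fits the ranking forest on each cross-validation
    training split only (no selection leakage); scope='global' ranks once on
    the full dataset before folding.
    """

    k: int = 100
    forest_trees: int = 500
    seed: int = 0
    scope: Literal["per_fold", "global"] = "per_fold"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.forest_trees < 1:
            raise ValueError("forest_trees must be >= 1")
        if self.scope not in ("per_fold", "global"):
            raise ValueError(f"unknown selection scope {self.scope!r}")


@dataclass(frozen=True)
class FeatureRanking:
    """Features ordered by descending forest importance."""

    feature_names: tuple[str, ...]
    importances: np.ndarray
    forest_config: dict = field(default_factory=dict)
    fit_fingerprint: str = ""
    degenerate: bool = False  # True when the forest made no informative split

    def __len__(self) -> int:
        return len(self.feature_names)


def _as_matrix(X) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=np.float64), tuple(str(c) for c in X.columns)
    X = np.asarray(X, dtype=np.float64)
    return X, tuple(f"f{i}" for i in range(X.shape[1]))


def rank_by_forest_importance(
    X, y, config: SelectionConfig
) -> FeatureRanking:
    """Rank all columns of X by mean-impurity-decrease importance.

    X may be a pandas DataFrame (column names are used) or an array. The
    returned importances sum to 1 (forest convention) unless no split was
    informative, in which case the ranking is flagged ``degenerate``.
    """
    mat, names = _as_matrix(X)
    y = np.asarray(y)
    if mat.shape[0] != len(y):
        raise ValueError("X rows must match y length")
    if len(np.unique(y)) < 2:
        raise ValueError("ranking requires samples of both classes")
    if config.k > mat.shape[1]:
        raise ValueError(
            f"k={config.k} exceeds the number of features ({mat.shape[1]})"
        )
    forest = RandomForestClassifier(
        n_estimators=config.forest_trees,
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(mat, y)
    imp = forest.feature_importances_.astype(np.float64)
    degenerate = bool(imp.sum() == 0)
    order = np.lexsort((np.arange(len(imp)), -imp))
    fingerprint = hashlib.sha256(
        mat.tobytes() + y.tobytes() + repr(config).encode()
    ).hexdigest()
    return FeatureRanking(
        feature_names=tuple(names[i] for i in order),
        importances=imp[order],
        forest_config={
            "n_estimators": config.forest_trees,
            "random_state": config.seed,
            "max_features": "sqrt",
            "max_depth": None,
        },
        fit_fingerprint=fingerprint,
        degenerate=degenerate,
    )


def select_top_k(ranking: FeatureRanking, k: int) -> list[str]:
    """First k feature names of the ranking, order preserved."""
    if k < 1 or k > len(ranking):
        raise ValueError(f"k={k} out of range [1, {len(ranking)}]")
    return list(ranking.feature_names[:k])


def apply_selection(X: pd.DataFrame, names: Sequence[str]) -> pd.DataFrame:
    """Subset and reorder the columns of X to ``names``; rows unchanged."""
    missing = [n for n in names if n not in X.columns]
    if missing:
        raise KeyError(f"features not present in matrix: {missing}")
    return X.loc[:, list(names)]


def family_composition(names: Sequence[str]) -> dict[str, int]:
    """Count selected features per fusion family (GM/HM/PowRP/PowPR)."""
    counts = {"GM": 0, "HM": 0, "PowRP": 0, "PowPR": 0}
    for name in names:
        fam = name.split(":", 1)[0]
        if fam not in counts:
            raise ValueError(f"malformed complex-feature name {name!r}")
        counts[fam] += 1
    return counts


def save_ranking(ranking: FeatureRanking, path: str | Path) -> None:
    pd.DataFrame(
        {"feature_name": ranking.feature_names, "importance": ranking.importances}
    ).to_csv(path, sep="\t", index=False)


def load_ranking(path: str | Path) -> FeatureRanking:
    df = pd.read_csv(path, sep="\t")
    return FeatureRanking(
        feature_names=tuple(df["feature_name"].astype(str)),
        importances=df["importance"].to_numpy(dtype=np.float64),
    )


def save_selection(names: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(names) + "\n")


def load_selection(path: str | Path) -> list[str]:
    return [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
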