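"""Decision-level classification and per-setting permutation importance.

Each human choice in rounds ≥ 2 is one observation: did the participant
pick the innovation colour, given (f1) whether the innovation was their
initially assigned colour, (f2) whether the innovation is the majority
colour among all peers displayed to them, (f3) the innovation fraction
among their two displayed direct neighbours and (f4) among their two
displayed distance-k neighbours.  A bagged random forest predicts the
choice; feature relevance is measured by out-of-bag (OOB) permutation
importance computed per tree, Breiman-style: permute one feature within a
tree's OOB sample and record the increase in that tree's OOB error.

Importances are computed separately per setting — the information on offer
differs across settings (f4 does not exist in setting I), and so does how
participants weigh it.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from sklearn.tree import DecisionTreeClassifier

log = logging.getLogger(__name__)

FEATURES = ["f1_initial_innovation", "f2_innovation_majority", "f3_direct_fraction", "f4_distant_fraction"]

__all__ = ["FEATURES", "build_decision_table", "nested_cv_accuracy", "oob_permutation_importance"]


def build_decision_table(records: pd.DataFrame, *, include_bots: bool = False) -> pd.DataFrame:
    """One row per (human) decision from round 2 on.

    Round-1 choices are the assigned initialization, not decisions, and are
    used only to derive f1.  f2 is computed over the union of displayed
    peers, ties counting as not-majority.  Rows lacking display data are
    skipped with a log entry.
    """
    from .sessions import _decode_display  # tidy-frame display encoding

    rows = []
    init = (
        records[records["round"] == 1]
        .set_index(["session_id", "setting", "node"])["chosen_color"]
        .to_dict()
    )
    skipped = 0
    for rec in records[records["round"] >= 2].itertuples():
        if not include_bots and rec.role == "bot":
            continue
        direct = _decode_display(rec.displayed_direct)
        distant = _decode_display(rec.displayed_distant)
        if len(direct) == 0:
            skipped += 1
            continue
        shown = [c for _, c in direct] + [c for _, c in distant]
        f3 = float(np.mean([c for _, c in direct]))
        f4 = float(np.mean([c for _, c in distant])) if distant else 0.0
        rows.append(
            {
                "session_id": rec.session_id,
                "setting": rec.setting,
                "round": rec.round,
                "node": rec.node,
                "label": int(rec.chosen_color),
                "f1_initial_innovation": int(init[(rec.session_id, rec.setting, rec.node)]),
                "f2_innovation_majority": int(2 * sum(shown) > len(shown)),
                "f3_direct_fraction": f3,
                "f4_distant_fraction": f4,
            }
        )
    if skipped:
        log.info("skipped %d decision rows without display data", skipped)
    return pd.DataFrame(rows)


def nested_cv_accuracy(
    table: pd.DataFrame,
    seed: int,
    *,
    param_grid: dict | None = None,
) -> float:
    """Nested-cross-validated test accuracy of the random-forest classifier.

    Outer 5-fold CV estimates test accuracy; an inner 5-fold grid search
    picks the forest size and depth on each outer training split, so no
    information leaks from test folds into model selection.
    """
    if len(table) < 50:
        raise ValueError(f"need ≥ 50 decisions, got {len(table)}")
    X = table[FEATURES].to_numpy(float)
    y = table["label"].to_numpy(int)
    if len(np.unique(y)) < 2:
        raise ValueError("decision labels are single-class; nothing to classify")
    if param_grid is None:
        param_grid = {"n_estimators": [100, 300], "max_depth": [None, 5, 10]}
    inner = StratifiedKFold(5, shuffle=True, random_state=seed)
    outer = StratifiedKFold(5, shuffle=True, random_state=seed + 1)
    model = GridSearchCV(
        RandomForestClassifier(random_state=seed, oob_score=False),
        param_grid,
        cv=inner,
        scoring="accuracy",
        n_jobs=1,
    )
    scores = cross_val_score(model, X, y, cv=outer, scoring="accuracy", n_jobs=1)
    return float(scores.mean())


def _oob_importance_one(X: np.ndarray, y: np.ndarray, seed: int, n_estimators: int) -> np.ndarray:
    """Per-tree OOB permutation importance for one fitted bagged forest."""
    forest = BaggingClassifier(
        estimator=DecisionTreeClassifier(max_features="sqrt", random_state=seed),
        n_estimators=n_estimators,
        bootstrap=True,
        random_state=seed,
    ).fit(X, y)
    rng = np.random.default_rng(seed)
    n, p = X.shape
    increases = np.zeros((len(forest.estimators_), p))
    for t, (tree, samp) in enumerate(zip(forest.estimators_, forest.estimators_samples_)):
        oob = np.setdiff1d(np.arange(n), samp)
        if len(oob) == 0:
            continue
        Xo, yo = X[oob], y[oob]
        base_err = np.mean(tree.predict(Xo) != yo)
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = Xp[rng.permutation(len(oob)), j]
            increases[t, j] = np.mean(tree.predict(Xp) != yo) - base_err
    return increases.mean(axis=0)


def oob_permutation_importance(
    table: pd.DataFrame,
    seed: int,
    *,
    n_estimators: int = 200,
    per_setting: bool = True,
) -> pd.DataFrame:
    """Mean OOB-error increase per feature, per setting.

    Nonpositive importances are reported as-is (they signal an irrelevant
    feature); a constant feature draws a warning.  Returns a tidy frame
    with columns setting, feature, importance, rank.
    """
    groups = table.groupby("setting") if per_setting else [("all", table)]
    rows = []
    for setting, sub in groups:
        X = sub[FEATURES].to_numpy(float)
        y = sub["label"].to_numpy(int)
        for j, name in enumerate(FEATURES):
            if np.ptp(X[:, j]) == 0:
                warnings.warn(f"setting {setting}: feature {name} is constant; importance ≈ 0")
        imp = _oob_importance_one(X, y, seed, n_estimators)
        order = (-imp).argsort()
        rank = np.empty_like(order)
        rank[order] = np.arange(1, len(imp) + 1)
        for name, v, rk in zip(FEATURES, imp, rank):
            rows.append({"setting": setting, "feature": name, "importance": float(v), "rank": int(rk)})
    return pd.DataFrame(rows)
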