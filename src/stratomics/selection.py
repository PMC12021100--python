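"""Shadow-feature consensus selection with frequency voting.

The relevance test is Boruta-style: every candidate column is paired with a
permuted "shadow" copy, an ensemble importance learner is fitted repeatedly,
and a feature scores a hit whenever its importance exceeds the round's
maximum shadow importance.  Features are confirmed or rejected by a
two-sided binomial test of the hit count against chance (p = 0.5); rejected
features are dropped from later rounds, undecided features end unconfirmed.

Consensus selection repeats the shadow run over random feature subsets; a
feature's selection frequency is the fraction of iterations in which it was
sampled AND confirmed, and it is selected when that frequency reaches the
vote threshold (with a minimum-support floor on times sampled).

Importance is the random forest's impurity importance (mean decrease in
impurity); only the comparison against the shadow maximum matters, and the
impurity measure is both sensitive and cheap at these problem sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold

from .config import SelectionConfig


def shadow_run(X, y, seed: int = 0, *, max_rounds: int = 20, alpha: float = 0.05,
               n_trees: int = 25) -> set[str]:
    """One shadow-feature relevance run; returns the confirmed feature names."""
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        names = [f"f{j}" for j in range(X.shape[1])]
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("constant class labels")
    if X.shape[1] == 0:
        raise ValueError("empty feature subset")
    rng = np.random.default_rng(seed)
    p = X.shape[1]
    hits = np.zeros(p, dtype=int)
    tested = np.zeros(p, dtype=int)
    confirmed = np.zeros(p, dtype=bool)
    rejected = np.zeros(p, dtype=bool)
    n = X.shape[0]
    for rnd in range(max_rounds):
        undecided = np.where(~confirmed & ~rejected)[0]
        if len(undecided) == 0:
            break
        # confirmed features stay in the model (as in Boruta); only rejected
        # features are dropped, so survivors keep competing against a full
        # shadow block rather than against each other alone
        in_model = np.where(~rejected)[0]
        Xa = X[:, in_model]
        shadow = np.empty_like(Xa)
        for j in range(shadow.shape[1]):
            shadow[:, j] = Xa[rng.permutation(n), j]
        Xfull = np.hstack([Xa, shadow])
        model = RandomForestClassifier(
            n_estimators=n_trees, random_state=int(rng.integers(2 ** 31)), n_jobs=1)
        model.fit(Xfull, y)
        imp = model.feature_importances_
        k = len(in_model)
        shadow_max = imp[k:].max()
        col_of = {f: i for i, f in enumerate(in_model)}
        und_cols = np.array([col_of[f] for f in undecided])
        hits[undecided] += (imp[und_cols] > shadow_max).astype(int)
        tested[undecided] += 1
        # two-sided binomial decision (p = 0.5 is symmetric: doubled tail)
        h = hits[undecided]
        t = tested[undecided]
        pv = np.minimum(1.0, 2.0 * np.minimum(stats.binom.cdf(h, t, 0.5),
                                              stats.binom.sf(h - 1, t, 0.5)))
        sig = pv < alpha
        confirmed[undecided[sig & (h > t / 2)]] = True
        rejected[undecided[sig & (h <= t / 2)]] = True
    return {names[i] for i in np.where(confirmed)[0]}


@dataclass
class SelectionTrace:
    feature_ids: list[str]
    times_sampled: np.ndarray
    times_confirmed: np.ndarray
    vote: float
    min_support: int

    @property
    def frequency(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.times_sampled > 0,
                            self.times_confirmed / np.maximum(self.times_sampled, 1),
                            np.nan)

    @property
    def selected(self) -> list[str]:
        freq = self.frequency
        mask = (self.times_sampled >= self.min_support) & (freq >= self.vote)
        return [f for f, m in zip(self.feature_ids, mask) if m]

    def to_frame(self) -> pd.DataFrame:
        freq = self.frequency
        sel = set(self.selected)
        return pd.DataFrame({
            "times_sampled": self.times_sampled,
            "times_confirmed": self.times_confirmed,
            "frequency": freq,
            "selected": [f in sel for f in self.feature_ids],
        }, index=self.feature_ids)


def consensus_select(X: pd.DataFrame, y, config: SelectionConfig | None = None,
                     seed: int = 0) -> SelectionTrace:
    """Frequency-voted shadow selection over random feature subsets."""
    cfg = config or SelectionConfig()
    if cfg.subset_size > X.shape[1]:
        raise ValueError("subset_size exceeds number of features")
    rng = np.random.default_rng(seed)
    names = list(X.columns)
    p = len(names)
    sampled = np.zeros(p, dtype=int)
    confirmed_n = np.zeros(p, dtype=int)
    # when every feature fits in one subset the iteration equals a single run
    for _ in range(cfg.n_iter):
        idx = rng.choice(p, size=cfg.subset_size, replace=False)
        sampled[idx] += 1
        conf = shadow_run(X.iloc[:, idx], y, seed=int(rng.integers(2 ** 31)),
                          max_rounds=cfg.shadow_rounds, n_trees=cfg.n_trees)
        for f in conf:
            confirmed_n[names.index(f)] += 1
    min_support = cfg.min_support if cfg.n_iter >= cfg.min_support else 1
    return SelectionTrace(names, sampled, confirmed_n, cfg.vote, min_support)


@dataclass
class RFEvaluation:
    confusion: np.ndarray
    accuracy: float
    sensitivity: float
    specificity: float
    oob_error: float
    mtry: int
    classes: list


def final_evaluate(X: pd.DataFrame, y, *, n_trees: int = 700, repeats: int = 3,
                   folds: int = 10, mtry_grid=range(1, 16), seed: int = 0,
                   positive_class=None) -> RFEvaluation:
    """Repeated stratified cross-validation of a random-forest classifier
    over an mtry grid; pooled CV predictions give the confusion matrix and
    the out-of-bag error comes from a final full fit at the best mtry."""
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    y = np.asarray(y)
    if Xv.shape[1] == 0:
        raise ValueError("no selected features to evaluate")
    classes, counts = np.unique(y, return_counts=True)
    eff_folds = folds
    if counts.min() < folds:
        eff_folds = max(2, int(counts.min()))
        import warnings
        warnings.warn(f"smallest class has {counts.min()} members; folds reduced "
                      f"to {eff_folds}", stacklevel=2)
    grid = [m for m in mtry_grid if m <= Xv.shape[1]] or [Xv.shape[1]]
    best_mtry, best_acc, best_pred = grid[0], -1.0, None
    for mtry in grid:
        cv = RepeatedStratifiedKFold(n_splits=eff_folds, n_repeats=repeats,
                                     random_state=seed)
        preds = []
        trues = []
        for tr, te in cv.split(Xv, y):
            model = RandomForestClassifier(n_estimators=max(50, n_trees // 7),
                                           max_features=mtry, random_state=seed, n_jobs=1)
            model.fit(Xv[tr], y[tr])
            preds.append(model.predict(Xv[te]))
            trues.append(y[te])
        preds = np.concatenate(preds)
        trues = np.concatenate(trues)
        acc = float(np.mean(preds == trues))
        if acc > best_acc:
            best_acc, best_mtry, best_pred = acc, mtry, (trues, preds)
    trues, preds = best_pred
    conf = np.array([[np.sum((trues == a) & (preds == b)) for b in classes]
                     for a in classes], dtype=float)
    accuracy = float(np.trace(conf) / conf.sum())
    pos = positive_class if positive_class is not None else classes[-1]
    pos_i = list(classes).index(pos)
    neg_i = 1 - pos_i if len(classes) == 2 else None
    if neg_i is not None:
        sens = conf[pos_i, pos_i] / conf[pos_i].sum() if conf[pos_i].sum() else np.nan
        spec = conf[neg_i, neg_i] / conf[neg_i].sum() if conf[neg_i].sum() else np.nan
    else:  # pragma: no cover - multiclass not used by the study
        sens = spec = float("nan")
    final = RandomForestClassifier(n_estimators=n_trees, max_features=best_mtry,
                                   oob_score=True, random_state=seed, n_jobs=1)
    final.fit(Xv, y)
    return RFEvaluation(conf, accuracy, float(sens), float(spec),
                        1.0 - float(final.oob_score_), int(best_mtry), classes.tolist())
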