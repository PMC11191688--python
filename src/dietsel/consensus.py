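"""Consensus variable importance: elastic net + PLS-DA VIP + RF Gini, with
min-max score harmonization, total-score ranking, and a Kneedle cutoff.

For one two-group comparison, each of the three learners produces a
non-negative raw importance per variable:

* elastic net — absolute value of the logistic elastic-net coefficient at
  the cross-validated penalty (unselected variables score 0);
* PLS-DA — variable importance for projection,
  ``VIP_j = sqrt( p * sum_a(w_ja^2 * SSY_a) / sum_a(SSY_a) )``
  with unit-norm component weights ``w_a`` and ``SSY_a`` the class variance
  explained by component ``a`` (so mean(VIP^2) = 1);
* random forest — mean decrease in Gini impurity.

The three score vectors live on incommensurable scales, so each is min-max
normalized to [0, 1] before summation; the "total score" in [0, 3] ranks the
variables, ties broken by how many methods gave a positive score, then by
variable id.  The Kneedle algorithm then locates the knee of the sorted
total-score curve; variables at or above the knee form the selected set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .containers import Comparison, SampleTable
from .errors import AlignmentError, ConfigurationError, PreconditionError


@dataclass
class ImportanceVector:
    """Raw per-variable scores from one method, plus fit metadata."""

    method: str
    scores: pd.Series  # index = variable ids, values >= 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ConfigurationError(f"{self.method}: non-finite importance scores")
        if (vals < 0).any():
            raise ConfigurationError(f"{self.method}: negative importance scores")


@dataclass
class ConsensusRanking:
    """Normalized per-method scores, total score and rank per variable."""

    table: pd.DataFrame  # index = variable, sorted by rank

    @property
    def sorted_totals(self) -> np.ndarray:
        return self.table["total_score"].to_numpy()

    @property
    def variables(self) -> list[str]:
        return list(self.table.index)


@dataclass
class SelectionResult:
    """Ranked variables, knee index and selected subset for one comparison."""

    comparison: Comparison
    ranking: ConsensusRanking
    knee_index: int  # number of selected variables (1-based position of knee)
    selected: list[str]
    raw_scores: dict[str, pd.Series] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        out = self.ranking.table.copy()
        out["selected"] = [v in set(self.selected) for v in out.index]
        return out


def _check_two_class(y: np.ndarray) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ConfigurationError(
            f"binary comparison required, got {classes.size} class(es)"
        )
    if counts.min() < 3:
        raise ConfigurationError("each class needs >= 3 samples")


def elastic_net_scores(
    X: pd.DataFrame,
    y: np.ndarray,
    alpha_mix: float = 0.5,
    seed: int = 0,
    cv_folds: int = 5,
    n_penalties: int = 20,
    binary_scores: bool = False,
) -> ImportanceVector:
    """|coefficient| of a CV-tuned binomial elastic net, 0 if unselected.

    ``alpha_mix`` is the L1/L2 mixing parameter (1 = lasso, 0 = ridge);
    the penalty strength is chosen by stratified k-fold cross-validation.
    With ``binary_scores`` the vector is the 0/1 selection indicator instead
    of coefficient magnitudes.
    """
    yv = np.asarray(y)
    _check_two_class(yv)
    if not (0.0 <= alpha_mix <= 1.0):
        raise ConfigurationError(f"alpha_mix must be in [0, 1], got {alpha_mix}")
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    model = LogisticRegressionCV(
        Cs=n_penalties,
        cv=cv,
        solver="saga",
        l1_ratios=[alpha_mix],
        scoring="neg_log_loss",  # deviance-style CV criterion
        max_iter=20000,
        tol=1e-4,
        random_state=seed,
    )
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", FutureWarning)
        model.fit(X.to_numpy(), yv)
    coef = np.abs(model.coef_.ravel())
    if binary_scores:
        coef = (coef > 0).astype(float)
    return ImportanceVector(
        method="elastic_net",
        scores=pd.Series(coef, index=X.columns),
        metadata={
            "alpha_mix": alpha_mix,
            "cv_folds": cv_folds,
            "C": float(model.C_[0]),
            "seed": seed,
        },
    )


def plsda_vip(
    X: pd.DataFrame, y: np.ndarray, n_components: int = 2
) -> ImportanceVector:
    """VIP scores from a PLS regression of the 0/1 class indicator on X.

    Components whose explained class variance is numerically zero are
    dropped with a warning.  The VIP normalization identity
    ``mean(VIP^2) = 1`` holds by construction.
    """
    yv = np.asarray(y, dtype=float)
    _check_two_class(yv)
    n, p = X.shape
    max_comp = min(n - 1, p)
    if not (1 <= n_components <= max_comp):
        raise ConfigurationError(
            f"n_components must be in [1, {max_comp}], got {n_components}"
        )
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X.to_numpy(), yv - yv.mean())
    W = pls.x_weights_          # (p, A), unit-norm columns
    T = pls.x_scores_           # (n, A)
    q = pls.y_loadings_.ravel() # (A,)
    ssy = (q**2) * (T**2).sum(axis=0)  # class variance explained per component
    keep = ssy > 1e-12
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} degenerate PLS component(s) "
            "with zero explained class variance",
            stacklevel=2,
        )
        if not keep.any():
            raise ConfigurationError("all PLS components degenerate")
        W, ssy = W[:, keep], ssy[keep]
    w2 = W**2
    vip = np.sqrt(p * (w2 * ssy).sum(axis=1) / ssy.sum())
    return ImportanceVector(
        method="plsda_vip",
        scores=pd.Series(vip, index=X.columns),
        metadata={"n_components": int(keep.sum())},
    )


def rf_gini(
    X: pd.DataFrame,
    y: np.ndarray,
    n_trees: int = 500,
    seed: int = 0,
) -> ImportanceVector:
    """Mean decrease in Gini impurity from a random-forest classifier.

    ``mtry`` follows the classification default of sqrt(p) candidate
    variables per split.
    """
    yv = np.asarray(y)
    _check_two_class(yv)
    if n_trees < 100:
        raise ConfigurationError(f"n_trees must be >= 100, got {n_trees}")
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X.to_numpy(), yv)
    return ImportanceVector(
        method="rf_gini",
        scores=pd.Series(rf.feature_importances_, index=X.columns),
        metadata={"n_trees": n_trees, "seed": seed},
    )


def _minmax(scores: pd.Series) -> pd.Series:
    lo, hi = float(scores.min()), float(scores.max())
    if hi == lo:
        # no ranking information (e.g. all-zero elastic net at full shrinkage)
        return pd.Series(0.0, index=scores.index)
    return (scores - lo) / (hi - lo)


def consensus_rank(vectors: list[ImportanceVector]) -> ConsensusRanking:
    """Min-max normalize each method's scores, sum into a total score, rank.

    The returned table is sorted by total score descending, with ties broken
    by the number of methods that scored the variable positively, then by
    variable id.
    """
    if not vectors:
        raise ConfigurationError("consensus_rank needs at least one ImportanceVector")
    universe = set(vectors[0].scores.index)
    for vec in vectors[1:]:
        if set(vec.scores.index) != universe:
            raise AlignmentError(
                f"importance vectors cover different variable sets "
                f"({vec.method} differs)"
            )
    order = list(vectors[0].scores.index)
    table = pd.DataFrame(index=pd.Index(order, name="variable"))
    for vec in vectors:
        table[f"raw_{vec.method}"] = vec.scores.reindex(order)
        table[f"norm_{vec.method}"] = _minmax(vec.scores).reindex(order)
    norm_cols = [c for c in table.columns if c.startswith("norm_")]
    raw_cols = [c for c in table.columns if c.startswith("raw_")]
    table["total_score"] = table[norm_cols].sum(axis=1)
    table["methods_count"] = (table[raw_cols] > 0).sum(axis=1)
    table = table.sort_values(
        by=["total_score", "methods_count", "variable"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return ConsensusRanking(table=table)


def kneedle_cutoff(
    sorted_totals: np.ndarray | list[float],
    sensitivity: float = 1.0,
) -> int:
    """Offline Kneedle knee index of a non-increasing score curve.

    The curve is normalized to the unit square; the difference between the
    (flipped) curve and the diagonal chord is scanned for local maxima, and a
    local maximum is declared the knee if the difference curve drops below
    ``d_max - sensitivity * mean_x_spacing`` before a higher local maximum
    appears.  Returns the number of variables at or above the knee (the knee
    point is included).  If no knee exists — e.g. a perfectly linear curve —
    the full length is returned with a warning.
    """
    y = np.asarray(sorted_totals, dtype=float)
    n = y.size
    if n < 3:
        raise PreconditionError(f"curve needs >= 3 points, got {n}")
    if np.any(np.diff(y) > 1e-12):
        raise PreconditionError("curve must be non-increasing")
    rng_y = y[0] - y[-1]
    if rng_y <= 0:
        warnings.warn("constant curve: no knee, returning full length", stacklevel=2)
        return n
    x_norm = np.arange(n) / (n - 1)
    y_norm = (y - y[-1]) / rng_y
    # decreasing curve: flip so the knee becomes a peak of the difference curve
    diff = (1.0 - y_norm) - x_norm

    # local maxima of the difference curve (interior strict-or-plateau peaks)
    candidates = [
        i
        for i in range(1, n - 1)
        if diff[i] >= diff[i - 1] and diff[i] > diff[i + 1] and diff[i] > 1e-9
    ]
    if not candidates:
        warnings.warn("no knee found, returning full length", stacklevel=2)
        return n
    spacing = sensitivity * np.mean(np.diff(x_norm))
    knees: list[int] = []
    for ci, i in enumerate(candidates):
        threshold = diff[i] - spacing
        end = candidates[ci + 1] if ci + 1 < len(candidates) else n
        segment = diff[i + 1 : end]
        if segment.size == 0 or np.any(segment < threshold) or end == n:
            knees.append(i)
    if not knees:
        warnings.warn("no knee satisfied the sensitivity criterion", stacklevel=2)
        return n
    knee = max(knees, key=lambda i: diff[i])
    return knee + 1  # include the knee point itself


@dataclass(frozen=True)
class SelectionConfig:
    """Hyperparameters of one consensus-selection run (all logged)."""

    alpha_mix: float = 0.5
    cv_folds: int = 5
    n_components: int = 2
    n_trees: int = 500
    sensitivity: float = 1.0
    elastic_net_binary: bool = False
    seed: int = 0


def select_variables(
    table: SampleTable,
    comparison: Comparison,
    config: SelectionConfig = SelectionConfig(),
) -> SelectionResult:
    """Full consensus selection for one two-group comparison.

    ``table`` must already be preprocessed (imputed, pruned, scaled over all
    samples); rows are subset here to the comparison's two groups.
    """
    sub = table.subset_groups([comparison.test, comparison.reference])
    y = (sub.groups == comparison.test).to_numpy().astype(int)
    X = sub.data
    en = elastic_net_scores(
        X,
        y,
        alpha_mix=config.alpha_mix,
        seed=config.seed,
        cv_folds=config.cv_folds,
        binary_scores=config.elastic_net_binary,
    )
    vip = plsda_vip(X, y, n_components=config.n_components)
    rf = rf_gini(X, y, n_trees=config.n_trees, seed=config.seed)
    ranking = consensus_rank([en, vip, rf])
    knee = kneedle_cutoff(ranking.sorted_totals, sensitivity=config.sensitivity)
    selected = ranking.variables[:knee]
    return SelectionResult(
        comparison=comparison,
        ranking=ranking,
        knee_index=knee,
        selected=selected,
        raw_scores={v.method: v.scores for v in (en, vip, rf)},
    )
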