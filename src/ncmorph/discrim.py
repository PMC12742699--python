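"""Linear discriminant analysis at worker level.

The supervised half of the delimitation protocol: a Wilks'-lambda stepwise
variable selection followed by Fisher's two-class linear discriminant. The
discriminant score places the midpoint of the two group means at zero, so a
worker's species hypothesis is simply the sign of its score; nests are
classified by the mean score of their workers. Wild-card nests from the
unsupervised stage are assigned by training on the concordant nests only and
iterating until labels stabilise ("confirmative" LDA). Error rates are
reported as resubstitution (the convention for the published rates) and
leave-one-out percentages, per group, at worker and at nest level.

Also here: the equal-variance two-sample t-test table over CS and the 13
indices (with Holm-corrected significance flags) and the Pearson correlation
of discriminant scores with latitude.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .biogeo import holm
from .morphodata import CHARACTERS, INDICES


@dataclass
class StepwiseConfig:
    """Thresholds of the stepwise selection (classic F-to-enter/remove)."""

    f_enter: float = 3.84
    f_remove: float = 2.71
    max_steps: int = 28

    def __post_init__(self):
        if self.f_enter <= self.f_remove:
            raise ValueError("f_enter must exceed f_remove")


@dataclass
class DiscriminantModel:
    """A two-group linear discriminant with the decision boundary at zero."""

    variables: list
    coefficients: np.ndarray
    offset: float
    positive_group: object
    negative_group: object
    selection_log: list = field(default_factory=list)

    def score(self, data: pd.DataFrame) -> pd.Series:
        X = data[self.variables].to_numpy(dtype=float)
        return pd.Series(X @ self.coefficients + self.offset,
                         index=data.index, name="score")

    def classify(self, data: pd.DataFrame) -> pd.Series:
        s = self.score(data)
        labels = np.where(s > 0, self.positive_group,
                          np.where(s < 0, self.negative_group, None))
        return pd.Series(labels, index=data.index, name="label")

    def to_json(self, path=None) -> str:
        payload = {
            "variables": list(self.variables),
            "coefficients": [float(c) for c in self.coefficients],
            "offset": float(self.offset),
            "positive_group": str(self.positive_group),
            "negative_group": str(self.negative_group),
            "selection_log": self.selection_log,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _scatter_matrices(X: np.ndarray, y: np.ndarray):
    """Within-group and total scatter (cross-product) matrices."""
    total = X - X.mean(axis=0)
    T = total.T @ total
    W = np.zeros_like(T)
    for g in np.unique(y):
        Xg = X[y == g]
        dg = Xg - Xg.mean(axis=0)
        W += dg.T @ dg
    return W, T


def _wilks_lambda(X: np.ndarray, y: np.ndarray) -> float:
    if X.shape[1] == 0:
        return 1.0
    W, T = _scatter_matrices(X, y)
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_w <= 0 or sign_t <= 0:
        raise np.linalg.LinAlgError("singular scatter matrix")
    return float(np.exp(logdet_w - logdet_t))


def stepwise_select(data: pd.DataFrame, labels: pd.Series,
                    variables=None, config: StepwiseConfig | None = None):
    """Wilks'-lambda stepwise variable selection for a two-group LDA.

    At each step the candidate with the largest partial F-to-enter joins the
    model if it reaches ``f_enter``; then any entered variable whose partial
    F-to-remove falls below ``f_remove`` leaves. Stops when neither rule
    applies. Returns ``(selected, log)`` with the selection order.
    """
    config = config or StepwiseConfig()
    if variables is None:
        variables = [c for c in CHARACTERS if c in data.columns]
        if not variables:
            variables = list(data.select_dtypes("number").columns)
    y = np.asarray(labels)
    groups = np.unique(y)
    g = len(groups)
    if g != 2:
        raise ValueError(f"expected 2 groups, got {g}")
    for grp in groups:
        if np.sum(y == grp) < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 workers")
    n = len(y)
    selected: list = []
    log: list = []
    lam_current = 1.0

    def partial_f_enter(candidate):
        cols = selected + [candidate]
        lam_new = _wilks_lambda(data[cols].to_numpy(float), y)
        p = len(selected)
        f = (n - g - p) / (g - 1) * (lam_current / lam_new - 1.0)
        return f, lam_new

    def partial_f_remove(var):
        cols = [v for v in selected if v != var]
        lam_without = _wilks_lambda(data[cols].to_numpy(float), y)
        p = len(selected)
        f = (n - g - p + 1) / (g - 1) * (lam_without / lam_current - 1.0)
        return f, lam_without

    for _ in range(config.max_steps):
        changed = False
        best_f, best_var, best_lam = -np.inf, None, None
        for cand in variables:
            if cand in selected:
                continue
            try:
                f, lam_new = partial_f_enter(cand)
            except np.linalg.LinAlgError:
                continue  # collinear with entered set
            if f > best_f:
                best_f, best_var, best_lam = f, cand, lam_new
        if best_var is not None and best_f >= config.f_enter:
            selected.append(best_var)
            lam_current = best_lam
            log.append({"step": "enter", "variable": best_var,
                        "partial_F": float(best_f), "wilks_lambda": lam_current})
            changed = True
        # removal pass
        while len(selected) > 1:
            worst_f, worst_var, worst_lam = np.inf, None, None
            for var in selected:
                f, lam_without = partial_f_remove(var)
                if f < worst_f:
                    worst_f, worst_var, worst_lam = f, var, lam_without
            if worst_var is not None and worst_f < config.f_remove:
                selected.remove(worst_var)
                lam_current = worst_lam
                log.append({"step": "remove", "variable": worst_var,
                            "partial_F": float(worst_f),
                            "wilks_lambda": lam_current})
                changed = True
            else:
                break
        if not changed:
            break
    return selected, log


def fit_lda(data: pd.DataFrame, labels: pd.Series, variables,
            positive_group=None) -> DiscriminantModel:
    """Fisher two-class discriminant on the selected variables.

    Direction w = S_pooled^{-1} (mu_pos - mu_neg); the offset centres the
    midpoint of the two group means at score zero, and the orientation makes
    ``positive_group`` (by default the later of the two sorted labels) score
    positive on average.
    """
    variables = list(variables)
    y = pd.Series(labels, index=data.index)
    groups = sorted(pd.unique(y.dropna()), key=str)
    if len(groups) != 2:
        raise ValueError(f"expected 2 groups, got {groups}")
    if positive_group is None:
        positive_group = groups[1]
    if positive_group not in groups:
        raise ValueError(f"positive_group {positive_group!r} not among {groups}")
    negative_group = groups[0] if positive_group == groups[1] else groups[1]

    X = data[variables].to_numpy(dtype=float)
    pos = X[(y == positive_group).values]
    neg = X[(y == negative_group).values]
    n_pos, n_neg = len(pos), len(neg)
    S = ((pos - pos.mean(axis=0)).T @ (pos - pos.mean(axis=0))
         + (neg - neg.mean(axis=0)).T @ (neg - neg.mean(axis=0))) / (n_pos + n_neg - 2)
    diff = pos.mean(axis=0) - neg.mean(axis=0)
    try:
        w = np.linalg.solve(S, diff)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular pooled covariance on variables {variables}"
        ) from exc
    midpoint = (pos.mean(axis=0) + neg.mean(axis=0)) / 2.0
    offset = -float(w @ midpoint)
    return DiscriminantModel(variables=variables, coefficients=w, offset=offset,
                             positive_group=positive_group,
                             negative_group=negative_group)


def stepwise_lda(data: pd.DataFrame, labels: pd.Series, variables=None,
                 config: StepwiseConfig | None = None,
                 positive_group=None) -> DiscriminantModel:
    """Stepwise selection followed by the discriminant fit; logs the steps."""
    selected, log = stepwise_select(data, labels, variables, config)
    if not selected:
        raise ValueError("stepwise selection retained no variables")
    model = fit_lda(data, labels, selected, positive_group)
    model.selection_log = log
    return model


def error_rates(model: DiscriminantModel, data: pd.DataFrame, labels: pd.Series,
                nest_ids: pd.Series | None = None) -> pd.DataFrame:
    """Resubstitution misclassification percentages per group.

    Worker level: per cent of workers whose score sign contradicts their
    label. Nest level (when ``nest_ids`` given): same on the nest-mean score.
    """
    scores = model.score(data)
    y = pd.Series(labels, index=data.index)
    rows = []
    for group, want_positive in ((model.positive_group, True),
                                 (model.negative_group, False)):
        mask = (y == group).values
        s = scores[mask]
        wrong = (s <= 0) if want_positive else (s >= 0)
        rows.append({"group": group, "level": "worker", "n": int(mask.sum()),
                     "error_pct": 100.0 * wrong.mean() if mask.sum() else np.nan})
        if nest_ids is not None:
            nest_mean = s.groupby(pd.Series(nest_ids, index=data.index)[mask]).mean()
            wrong_n = (nest_mean <= 0) if want_positive else (nest_mean >= 0)
            rows.append({"group": group, "level": "nest", "n": len(nest_mean),
                         "error_pct": 100.0 * wrong_n.mean() if len(nest_mean) else np.nan})
    return pd.DataFrame(rows)


def loo_error_rates(data: pd.DataFrame, labels: pd.Series, variables,
                    positive_group=None) -> pd.DataFrame:
    """Leave-one-out worker-level misclassification percentages per group."""
    y = pd.Series(labels, index=data.index)
    wrong = pd.Series(False, index=data.index)
    for idx in data.index:
        train = data.index != idx
        model = fit_lda(data.loc[train], y.loc[train], variables, positive_group)
        pred = model.classify(data.loc[[idx]]).iloc[0]
        wrong.loc[idx] = pred != y.loc[idx]
    rows = []
    for group in pd.unique(y):
        mask = (y == group).values
        rows.append({"group": group, "level": "worker_loo", "n": int(mask.sum()),
                     "error_pct": 100.0 * wrong[mask].mean()})
    return pd.DataFrame(rows)


def iterate_confirmative(data: pd.DataFrame, nest_ids: pd.Series,
                         nest_labels: pd.Series, wildcards,
                         variables=None, config: StepwiseConfig | None = None,
                         positive_group=None, max_iter: int = 20):
    """Assign wild-card nests by iterated confirmative discriminant analysis.

    Train a stepwise LDA on the workers of concordantly clustered nests,
    classify wild-card nests by the majority sign of their workers' scores
    (ties broken by the mean nest score; an exact-zero mean is flagged
    unassignable), merge them into the training set, and repeat until the
    assignment is stable or ``max_iter`` is hit.

    Returns ``(labels, model, info)`` where ``labels`` maps every nest to a
    group, and ``info`` records iterations, convergence, and unassignable
    nests.
    """
    nest_ids = pd.Series(nest_ids, index=data.index)
    current = pd.Series(dict(nest_labels))  # nest -> label, wildcards excluded
    wildcards = list(wildcards)
    unassignable: list = []
    model = None
    converged = False
    n_iter = 0
    if not wildcards:
        worker_labels = nest_ids.map(current)
        model = stepwise_lda(data, worker_labels, variables, config, positive_group)
        return current, model, {"iterations": 1, "converged": True,
                                "unassignable": []}
    for n_iter in range(1, max_iter + 1):
        train_nests = set(current.index)
        train_mask = nest_ids.isin(train_nests).values
        worker_labels = nest_ids[train_mask].map(current)
        model = stepwise_lda(data.loc[train_mask], worker_labels,
                             variables, config, positive_group)
        assigned = {}
        unassignable = []
        for nest in wildcards:
            workers = data.loc[(nest_ids == nest).values]
            s = model.score(workers)
            votes_pos = int((s > 0).sum())
            votes_neg = int((s < 0).sum())
            if votes_pos > votes_neg:
                assigned[nest] = model.positive_group
            elif votes_neg > votes_pos:
                assigned[nest] = model.negative_group
            else:
                mean = s.mean()
                if mean > 0:
                    assigned[nest] = model.positive_group
                elif mean < 0:
                    assigned[nest] = model.negative_group
                else:
                    unassignable.append(nest)
        new = pd.concat([pd.Series(dict(nest_labels)), pd.Series(assigned)])
        if (len(new) == len(current)
                and new.sort_index().equals(current.sort_index())):
            converged = True
            current = new
            break
        current = new
    info = {"iterations": n_iter, "converged": converged,
            "unassignable": unassignable}
    return current.sort_index(), model, info


@dataclass
class CorrelationResult:
    R: float
    n: int
    p: float


def pvalue_from_r(r: float, n: int) -> float:
    """Two-sided p for a Pearson coefficient via t = r sqrt((n-2)/(1-r^2))."""
    if n < 3:
        raise ValueError("need n >= 3")
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def pearson_with_latitude(scores, latitudes) -> CorrelationResult:
    """Pearson correlation of discriminant scores with latitude (paired)."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(latitudes, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    dx, dy = x - x.mean(), y - y.mean()
    sx = np.sqrt((dx ** 2).sum())
    sy = np.sqrt((dy ** 2).sum())
    if sx == 0 or sy == 0:
        raise ValueError("zero variance; correlation undefined")
    r = float((dx * dy).sum() / (sx * sy))
    return CorrelationResult(R=r, n=n, p=pvalue_from_r(r, n))


def ttest_table(index_table: pd.DataFrame, species_col: str = "species",
                characters=None, alpha: float = 0.05) -> pd.DataFrame:
    """Per-character two-sample comparison of the two species.

    Equal-variance ("type 2") two-sided t-tests over CS and the 13 ratio
    indices, with mean +- SD and observed extremes per group, and a
    significance flag after Holm correction across the family of characters.
    """
    if characters is None:
        characters = ["CS"] + INDICES
    species = sorted(index_table[species_col].dropna().unique(), key=str)
    if len(species) != 2:
        raise ValueError(f"expected 2 species, got {species}")
    a_mask = index_table[species_col] == species[0]
    b_mask = index_table[species_col] == species[1]
    rows = []
    for char in characters:
        a = index_table.loc[a_mask, char].dropna()
        b = index_table.loc[b_mask, char].dropna()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"fewer than 2 workers per species for {char}")
        t, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append({
            "character": char,
            f"mean_{species[0]}": a.mean(), f"sd_{species[0]}": a.std(ddof=1),
            f"min_{species[0]}": a.min(), f"max_{species[0]}": a.max(),
            f"mean_{species[1]}": b.mean(), f"sd_{species[1]}": b.std(ddof=1),
            f"min_{species[1]}": b.min(), f"max_{species[1]}": b.max(),
            "t": float(t), "p": float(p),
        })
    table = pd.DataFrame(rows)
    table["p_holm"] = holm(table["p"].to_numpy())
    table["significant_holm"] = table["p_holm"] < alpha
    return table
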