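"""Variable selection and hyperparameter tuning.

The selection ladder mirrors standard presence-background practice:

1. group candidate predictors by pairwise Pearson correlation (|r| > 0.7,
   strict) over presence + background rows, keep one variable per group by
   univariate cross-validated test AUC;
2. stepwise jackknife reduction: repeatedly drop the variable whose omission
   yields the highest mean test AUC, stopping once every removal strictly
   hurts; retain the best state visited;
3. tune feature mode x regularization multiplier (3 x 6 = 18 combinations)
   by AICc computed from the grid-standardized raw likelihood with K = number
   of nonzero feature weights;
4. report per-variable percent contribution (optimizer-path gain
   attribution) and permutation importance, plus univariate response curves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import logsumexp

from .io import GridError, PredictorStack
from .maxent import (
    FeatureExpander,
    FeatureSpec,
    MaxentModel,
    compute_auc,
    compute_betas,
    expand_features,
    fit_maxent,
    predict,
)
from .prep import SampleTable

logger = logging.getLogger("growrisk")

_MODE_SIMPLICITY = {"lqp": 0, "hinge": 1, "auto": 2}  # tie order: simpler first


@dataclass
class VariableGroup:
    members: list[str]
    winner: str | None = None


@dataclass
class SelectionTrace:
    """Jackknife path: (removed variable, mean test AUC after removal)."""

    steps: list[tuple[str, float]]
    retained: list[str]
    full_auc: float
    retained_auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["removed", "mean_test_auc"])


@dataclass
class TuningResult:
    table: pd.DataFrame  # columns: mode, multiplier, K, LL, AICc, valid
    winner: tuple[str, float]  # (mode, multiplier)


@dataclass
class AICcResult:
    K: int
    LL: float
    AICc: float
    valid: bool


# ---------------------------------------------------------------------------
# Correlation grouping and univariate selection
# ---------------------------------------------------------------------------

def group_correlated(table: SampleTable, threshold: float = 0.7) -> list[VariableGroup]:
    """Connected components of the |Pearson r| > threshold graph (strict),
    computed over presence + background rows. Constant variables become
    singletons with a warning."""
    X = table.values("all")
    if X.shape[0] < 2:
        raise GridError("group_correlated needs at least 2 samples")
    names = table.variables
    sd = X.std(axis=0)
    constant = sd <= 0
    if constant.any():
        warnings.warn(
            f"constant variable(s) assigned singleton groups: "
            f"{[n for n, c in zip(names, constant) if c]}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R = np.nan_to_num(R, nan=0.0)
    np.fill_diagonal(R, 0.0)
    adj = csr_matrix(np.abs(R) > threshold)
    n_comp, labels = connected_components(adj, directed=False)
    groups = []
    for comp in range(n_comp):
        members = [names[i] for i in np.flatnonzero(labels == comp)]
        groups.append(VariableGroup(members=members))
    groups.sort(key=lambda g: names.index(g.members[0]))
    return groups


class CVEvaluator:
    """Cross-validated test-AUC evaluation of variable subsets.

    One feature expansion over the *full* candidate set is fitted per fold;
    sub-models select the columns whose source variables fall in the subset,
    so feature definitions (bounds, knots) are shared and AUC differences
    reflect the variables, not re-derived features.
    """

    def __init__(self, table: SampleTable, spec: FeatureSpec | None = None,
                 max_iter: int = 500, tol: float = 1e-5):
        if "fold" not in table.df.columns:
            raise GridError("sample table has no fold assignment")
        self.spec = spec or FeatureSpec()
        self.max_iter = max_iter
        self.tol = tol
        self.variables = table.variables
        pres = table.presence_df
        X_bg = table.values("background")
        self.folds = sorted(int(f) for f in pres["fold"].dropna().unique())
        self._per_fold = []
        for f in self.folds:
            train = pres[pres["fold"] != f][table.variables].to_numpy(float)
            test = pres[pres["fold"] == f][table.variables].to_numpy(float)
            exp = FeatureExpander.fit(train, X_bg, list(table.variables), self.spec)
            self._per_fold.append({
                "expander": exp,
                "F_train": exp.transform(train[:, [table.variables.index(v) for v in exp.variables]]),
                "F_test": exp.transform(test[:, [table.variables.index(v) for v in exp.variables]]),
                "F_bg": exp.transform(X_bg[:, [table.variables.index(v) for v in exp.variables]]),
            })

    def fold_metrics(self, variables, r: float = 1.0,
                     warm: list[np.ndarray] | None = None,
                     keep_lambdas: bool = False) -> pd.DataFrame:
        """Per-fold train/test AUC and 10% omission under the given settings.

        ``warm`` optionally holds per-fold full-length coefficient vectors
        used to warm-start the convex solve (e.g. from a superset model
        during jackknife reduction); warm starting changes only solver speed,
        not the optimum.
        """
        from .maxent import omission_rate  # late import: keeps module header lean

        rows = []
        if keep_lambdas:
            self.last_lambdas = []
        for i, (fold, fd) in enumerate(zip(self.folds, self._per_fold)):
            exp = fd["expander"]
            cols = exp.columns_for(variables)
            if cols.size == 0:
                raise GridError(f"no features for variable subset {variables}")
            classes = exp.feature_classes()[cols]
            betas = compute_betas(fd["F_train"][:, cols], classes, r)
            model = fit_maxent(
                F_presence=fd["F_train"][:, cols],
                F_background=fd["F_bg"][:, cols],
                betas=betas, r=r, max_iter=self.max_iter, tol=self.tol,
                warm_start=None if warm is None else warm[i][cols],
            )
            if keep_lambdas:
                full = np.zeros(exp.n_features)
                full[cols] = model.lambdas
                self.last_lambdas.append(full)
            train_scores = predict(model, fd["F_train"][:, cols], output="logistic")
            test_scores = predict(model, fd["F_test"][:, cols], output="logistic")
            bg_scores = predict(model, fd["F_bg"][:, cols], output="logistic")
            row = {
                "fold": fold,
                "test_auc": compute_auc(test_scores, bg_scores),
                "train_auc": compute_auc(train_scores, bg_scores),
            }
            try:
                row["omission_10pct"] = omission_rate(train_scores, test_scores)
            except GridError:
                row["omission_10pct"] = np.nan
            rows.append(row)
        return pd.DataFrame(rows)

    def fold_test_aucs(self, variables, r: float = 1.0) -> np.ndarray:
        return self.fold_metrics(variables, r=r)["test_auc"].to_numpy()

    def mean_test_auc(self, variables, r: float = 1.0) -> float:
        return float(self.fold_test_aucs(variables, r=r).mean())


def univariate_select(groups: list[VariableGroup], table: SampleTable,
                      evaluator: CVEvaluator | None = None,
                      max_iter: int = 500, tol: float = 1e-5) -> list[str]:
    """One variable per correlation group, chosen by mean univariate CV test
    AUC under default settings (auto features, multiplier 1); ties break
    lexicographically; singleton groups pass through without fitting."""
    if evaluator is None:
        evaluator = CVEvaluator(table, max_iter=max_iter, tol=tol)
    selected = []
    for g in groups:
        if len(g.members) == 1:
            g.winner = g.members[0]
        else:
            scores = {}
            for v in sorted(g.members):
                scores[v] = evaluator.mean_test_auc([v])
            best = max(scores.values())
            g.winner = min(v for v, s in scores.items() if s == best)
            logger.info("univariate_select: group %s -> %s (AUC %.3f)",
                        g.members, g.winner, best)
        selected.append(g.winner)
    return selected


# ---------------------------------------------------------------------------
# Stepwise jackknife reduction
# ---------------------------------------------------------------------------

def stepwise_jackknife(variables: list[str], evaluator: CVEvaluator) -> SelectionTrace:
    """Iteratively drop the variable whose omission yields the highest mean
    test AUC; stop when every removal strictly lowers AUC (or one variable
    remains); retain the best-AUC state visited."""
    current = list(variables)
    if len(current) == 0:
        raise GridError("stepwise_jackknife needs at least one variable")
    full_auc = float(
        evaluator.fold_metrics(current, keep_lambdas=True)["test_auc"].mean()
    )
    warm = evaluator.last_lambdas
    best_set, best_auc = list(current), full_auc
    steps: list[tuple[str, float]] = []
    auc_now = full_auc
    while len(current) > 1:
        candidates = {}
        for v in current:
            rest = [w for w in current if w != v]
            candidates[v] = float(
                evaluator.fold_metrics(rest, warm=warm)["test_auc"].mean()
            )
        top = max(candidates.values())
        if top < auc_now:
            break
        drop = min(v for v, s in candidates.items() if s == top)
        current.remove(drop)
        auc_now = top
        # refit the surviving set once to refresh the warm-start vectors
        evaluator.fold_metrics(current, warm=warm, keep_lambdas=True)
        warm = evaluator.last_lambdas
        steps.append((drop, auc_now))
        if auc_now > best_auc:
            best_set, best_auc = list(current), auc_now
    return SelectionTrace(steps=steps, retained=best_set,
                          full_auc=full_auc, retained_auc=best_auc)


# ---------------------------------------------------------------------------
# AICc and the 18-combination tuning grid
# ---------------------------------------------------------------------------

def aicc_formula(K: int, LL: float, n: int) -> float:
    return 2 * K - 2 * LL + 2 * K * (K + 1) / (n - K - 1)


def compute_aicc(model: MaxentModel, X_presence: np.ndarray,
                 X_grid: np.ndarray) -> AICcResult:
    """AICc from the raw output standardized to sum to one over the full
    projection grid; K counts nonzero feature weights."""
    exp = model.expander
    s_grid = exp.transform(X_grid) @ model.lambdas
    s_pres = exp.transform(X_presence) @ model.lambdas
    lse = logsumexp(s_grid)
    ll = float(np.sum(s_pres - lse))
    K = model.n_nonzero
    n = np.atleast_2d(X_presence).shape[0]
    if K >= n - 1:
        return AICcResult(K=K, LL=ll, AICc=np.nan, valid=False)
    return AICcResult(K=K, LL=ll, AICc=aicc_formula(K, ll, n), valid=True)


def tune_hyperparameters(table: SampleTable, variables: list[str],
                         stack: PredictorStack,
                         modes=("auto", "lqp", "hinge"),
                         multipliers=(0.5, 1.0, 1.5, 2.0, 3.0, 5.0),
                         n_hinge_knots: int = 50,
                         max_iter: int = 500, tol: float = 1e-5) -> TuningResult:
    """Fit every feature-mode x multiplier combination on the full training
    data and pick the minimum-AICc combination (ties: larger multiplier,
    then simpler mode)."""
    var_idx = [table.variables.index(v) for v in variables]
    Xp = table.values("presence")[:, var_idx]
    Xb = table.values("background")[:, var_idx]
    valid_cells = stack.combined_valid()
    X_grid = np.column_stack([stack[v].values[valid_cells] for v in variables])

    rows = []
    for mode in modes:
        spec = FeatureSpec(mode=mode, n_hinge_knots=n_hinge_knots)
        fm = expand_features(Xp, Xb, variables, spec)
        for r in multipliers:
            model = fit_maxent(fm, r=r, max_iter=max_iter, tol=tol)
            res = compute_aicc(model, Xp, X_grid)
            rows.append({"mode": mode, "multiplier": r, "K": res.K,
                         "LL": res.LL, "AICc": res.AICc, "valid": res.valid})
    df = pd.DataFrame(rows)
    valid = df[df["valid"]]
    if valid.empty:
        raise GridError("all tuning combinations are invalid (K >= n - 1)")
    best_aicc = valid["AICc"].min()
    tied = valid[valid["AICc"] == best_aicc]
    tied = tied.sort_values(
        by=["multiplier", "mode"],
        key=lambda s: -s if s.name == "multiplier"
        else s.map(_MODE_SIMPLICITY) if s.name == "mode" else s,
    )
    win = tied.iloc[0]
    return TuningResult(table=df, winner=(str(win["mode"]), float(win["multiplier"])))


# ---------------------------------------------------------------------------
# Variable contribution and permutation importance
# ---------------------------------------------------------------------------

def _objective_value(F_p, F_b, betas, lam, mean_p=None):
    if mean_p is None:
        mean_p = F_p.mean(axis=0)
    s_b = F_b @ lam
    return float(-(mean_p @ lam) + logsumexp(s_b) - np.log(F_b.shape[0])
                 + betas @ np.abs(lam))


def _contribution_gains(F_p, F_b, betas, meta, obj_ref,
                        max_sweeps: int = 50, gain_tol: float = 1e-5) -> dict[str, float]:
    """Cyclic coordinate-descent pass from zero, crediting each update's
    objective gain to the feature's source variable(s).

    This reproduces the path-dependent "percent contribution" bookkeeping of
    sequential-update maximum-entropy fitting; it is approximate by nature
    and documented as such.
    """
    n_b, n_feat = F_b.shape
    mean_p = F_p.mean(axis=0)
    lam = np.zeros(n_feat)
    s_b = np.zeros(n_b)
    gains: dict[str, float] = {}
    obj = _objective_value(F_p, F_b, betas, lam, mean_p)
    for _ in range(max_sweeps):
        sweep_gain = 0.0
        for j in range(n_feat):
            col = F_b[:, j]
            lse = logsumexp(s_b)
            q = np.exp(s_b - lse)
            e = q @ col
            g0 = e - mean_p[j]
            h = max(q @ col**2 - e**2, 1e-12)
            # soft-thresholded Newton step on the quadratic approximation
            z = h * lam[j] - g0
            new = np.sign(z) * max(abs(z) - betas[j], 0.0) / h
            delta = new - lam[j]
            if delta == 0.0:
                continue
            for _try in range(6):
                cand = lam[j] + delta
                s_try = s_b + delta * col
                obj_try = float(-(mean_p @ lam) - mean_p[j] * delta
                                + logsumexp(s_try) - np.log(n_b)
                                + betas @ np.abs(lam) - betas[j] * abs(lam[j])
                                + betas[j] * abs(cand))
                if obj_try < obj:
                    gain = obj - obj_try
                    v = meta[j]["vars"]
                    for name in v:
                        gains[name] = gains.get(name, 0.0) + gain / len(v)
                    lam[j] = cand
                    s_b = s_try
                    obj = obj_try
                    sweep_gain += gain
                    break
                delta *= 0.5
        if sweep_gain < gain_tol or obj <= obj_ref + 1e-4:
            break
    return gains


def variable_importance(model: MaxentModel, table: SampleTable,
                        variables: list[str] | None = None,
                        seed=None) -> pd.DataFrame:
    """Percent contribution (coordinate-path gain attribution) and
    permutation importance (drop in training AUC after permuting each
    variable across presence + background rows, floored at zero), each
    normalized to sum to 100."""
    exp = model.expander
    if exp is None:
        raise GridError("variable_importance requires a model with an expander")
    variables = variables or exp.variables
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    var_idx = [table.variables.index(v) for v in exp.variables]
    Xp = table.values("presence")[:, var_idx]
    Xb = table.values("background")[:, var_idx]
    F_p = exp.transform(Xp)
    F_b = exp.transform(Xb)

    obj_ref = _objective_value(F_p, F_b, model.betas, model.lambdas)
    gains = _contribution_gains(F_p, F_b, model.betas, exp.meta, obj_ref)
    contrib = np.array([max(gains.get(v, 0.0), 0.0) for v in exp.variables])
    contrib = 100 * contrib / contrib.sum() if contrib.sum() > 0 else contrib

    base_auc = compute_auc(predict(model, F_p, "raw"), predict(model, F_b, "raw"))
    drops = []
    X_all = np.vstack([Xp, Xb])
    n_p = Xp.shape[0]
    for i, v in enumerate(exp.variables):
        X_perm = X_all.copy()
        X_perm[:, i] = rng.permutation(X_perm[:, i])
        Fp2 = exp.transform(X_perm[:n_p])
        Fb2 = exp.transform(X_perm[n_p:])
        auc = compute_auc(predict(model, Fp2, "raw"), predict(model, Fb2, "raw"))
        drops.append(max(base_auc - auc, 0.0))
    drops = np.array(drops)
    if drops.sum() > 0:
        perm = 100 * drops / drops.sum()
    else:
        logger.warning("variable_importance: no permutation produced an AUC drop")
        perm = drops
    return pd.DataFrame({
        "variable": exp.variables,
        "percent_contribution": contrib,
        "permutation_importance": perm,
    })


# ---------------------------------------------------------------------------
# Response curves and extent comparison
# ---------------------------------------------------------------------------

def response_curve(table: SampleTable, variable: str, mode: str = "auto",
                   r: float = 1.0, n_points: int = 100,
                   n_hinge_knots: int = 50, max_iter: int = 500,
                   tol: float = 1e-5) -> pd.DataFrame:
    """Univariate response: the logistic output of a model trained on the
    variable alone, evaluated on an even grid spanning its training bounds."""
    if variable not in table.variables:
        raise GridError(f"unknown variable {variable!r}")
    i = table.variables.index(variable)
    Xp = table.values("presence")[:, [i]]
    Xb = table.values("background")[:, [i]]
    spec = FeatureSpec(mode=mode, n_hinge_knots=n_hinge_knots)
    fm = expand_features(Xp, Xb, [variable], spec)
    model = fit_maxent(fm, r=r, max_iter=max_iter, tol=tol)
    lo, hi = fm.expander.var_bounds[0]
    xs = np.linspace(lo, hi, n_points)
    ys = predict(model, fm.expander.transform(xs[:, None]), output="logistic")
    return pd.DataFrame({variable: xs, "logistic": ys})


def response_band_center(curve: pd.DataFrame, variable: str,
                         level: float = 0.5) -> float:
    """Band-center estimate from a univariate response curve: the midpoint
    of the half-maximum interval around the curve's main peak.

    For a peaked response this is close to the argmax; for a flat-topped
    (plateau) response it recovers the plateau midpoint, and it ignores
    spurious secondary lobes in data-sparse tails.
    """
    y = curve["logistic"].to_numpy()
    x = curve[variable].to_numpy()
    thr = y.min() + level * (y.max() - y.min())
    i = int(np.argmax(y))
    lo = i
    while lo > 0 and y[lo - 1] >= thr:
        lo -= 1
    hi = i
    while hi < len(y) - 1 and y[hi + 1] >= thr:
        hi += 1
    return float(0.5 * (x[lo] + x[hi]))


def compare_extent_models(table: SampleTable, k: int = 10, seed=None,
                          max_iter: int = 500, tol: float = 1e-5) -> pd.DataFrame:
    """Mean CV test AUC for the pooled extent and for each region.

    Presence rows must carry a ``region`` column; background rows with region
    labels are subset per region, otherwise all background is shared.
    Regions with fewer presences than folds are skipped with a warning.
    """
    from .prep import assign_folds  # local import to avoid cycle at import time

    if "region" not in table.df.columns:
        raise GridError("compare_extent_models requires a 'region' column")
    rows = []
    regions = sorted(table.presence_df["region"].dropna().unique())
    df = table.df
    bg_all = df[df["presence"] == 0]
    bg_labeled = bg_all["region"].notna().any()
    jobs = [("all", df)]
    for reg in regions:
        pres_sub = df[(df["presence"] == 1) & (df["region"] == reg)]
        bg_sub = bg_all[bg_all["region"] == reg] if bg_labeled else bg_all
        jobs.append((str(reg), pd.concat([pres_sub, bg_sub], ignore_index=True)))
    for name, df in jobs:
        n_pres = int((df["presence"] == 1).sum())
        if n_pres < k:
            warnings.warn(f"region {name!r} has {n_pres} presences < {k} folds; skipped")
            continue
        sub = SampleTable(df.reset_index(drop=True), table.variables)
        sub = assign_folds(sub, k=k, seed=seed)
        ev = CVEvaluator(sub, max_iter=max_iter, tol=tol)
        auc = ev.mean_test_auc(table.variables)
        rows.append({"region": name, "n_presences": n_pres, "mean_test_auc": auc})
    return pd.DataFrame(rows)
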