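"""Presence-background maximum-entropy model, from scratch.

The model is the Gibbs distribution over background locations
``q(i) = exp(lambda . f_i) / Z`` whose feature expectations match the
presence-sample means to within per-feature L1 bounds (the regularization
box). Fitting maximizes the penalized log-likelihood

    mean_presence(lambda . f)  -  log mean_background exp(lambda . f)
        - sum_j beta_j |lambda_j|

which is concave in ``lambda``; at the optimum the KKT conditions give
``|E_q[f_j] - mean_presence[f_j]| <= beta_j`` for every feature.

Features are linear, quadratic, product and hinge transforms of the
predictors, each rescaled to [0, 1] by its training bounds; projection-time
values are clamped into the training range. Per-feature penalties follow the
standard per-class schedule ``beta_j = r * c(class, m) * s_j / sqrt(m)`` with
``m`` presences, ``s_j`` the presence-sample feature standard deviation, and
``r`` the user-facing regularization multiplier.

Outputs: *raw* (the Gibbs probability, normalized to sum to one over the
training background) and *logistic*, ``e^H q / (1 + e^H q)`` with ``H`` the
entropy of the fitted distribution, which maps a uniform model to 0.5.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import rankdata

from .io import GridError, PredictorStack, Raster

logger = logging.getLogger("growrisk")

MODES = ("auto", "lqp", "hinge", "linear")  # 'linear' is a diagnostic mode

# default per-class regularization schedule c(class, m): piecewise-linear in
# the presence sample size m, clamped at the ends
_LQP_SCHEDULE = ([10.0, 17.0, 30.0, 100.0], [1.0, 0.6, 0.5, 0.05])
_HINGE_BETA = 0.5
_SD_FLOOR = 0.01  # floor on s_j so no feature is left entirely unpenalized
_ZERO_TOL = 1e-10
# cap on |lambda_j|: features live in [0,1], so useful weights are far below
# this; the cap only stops line-search excursions that overflow the objective
_LAMBDA_MAX = 1e3


def default_beta_class(feature_class: str, m: int) -> float:
    if feature_class == "hinge":
        return _HINGE_BETA
    xs, ys = _LQP_SCHEDULE
    return float(np.interp(m, xs, ys))


@dataclass(frozen=True)
class FeatureSpec:
    """Which feature types to build from the predictors."""

    mode: str = "auto"
    n_hinge_knots: int = 50

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")


class FeatureExpander:
    """Fitted feature construction: variable bounds, hinge knots, and
    per-feature [0, 1] scaling learned from training data."""

    def __init__(self, spec: FeatureSpec, variables: list[str],
                 var_bounds: np.ndarray, knots: dict[str, np.ndarray],
                 meta: list[dict], feat_lo: np.ndarray, feat_hi: np.ndarray):
        self.spec = spec
        self.variables = variables
        self.var_bounds = var_bounds  # (n_vars, 2)
        self.knots = knots            # var -> knots in scaled [0,1] space
        self.meta = meta              # per feature: {type, vars, knot}
        self.feat_lo = feat_lo
        self.feat_hi = feat_hi

    @property
    def n_features(self) -> int:
        return len(self.meta)

    @classmethod
    def fit(cls, X_presence: np.ndarray, X_background: np.ndarray,
            variables: list[str], spec: FeatureSpec) -> "FeatureExpander":
        """Learn bounds and knots from training data.

        Variable bounds come from presence + background rows; hinge knots are
        evenly spaced quantiles of the background. Constant variables are
        excluded with a warning.
        """
        X_presence = np.atleast_2d(np.asarray(X_presence, dtype=float))
        X_background = np.atleast_2d(np.asarray(X_background, dtype=float))
        X_all = np.vstack([X_presence, X_background])
        lo = X_all.min(axis=0)
        hi = X_all.max(axis=0)
        keep, dropped = [], []
        for j, name in enumerate(variables):
            if hi[j] - lo[j] <= 0:
                dropped.append(name)
            else:
                keep.append(j)
        if dropped:
            warnings.warn(f"constant variable(s) excluded from features: {dropped}")
        if not keep:
            raise GridError("no non-constant variables to expand")
        variables = [variables[j] for j in keep]
        var_bounds = np.column_stack([lo[keep], hi[keep]])

        U_bg = cls._scale_vars(X_background[:, keep], var_bounds)
        knots: dict[str, np.ndarray] = {}
        if spec.mode in ("auto", "hinge"):
            qs = np.linspace(0.0, 1.0, spec.n_hinge_knots)
            for v, name in enumerate(variables):
                k = np.unique(np.quantile(U_bg[:, v], qs))
                knots[name] = k

        meta = cls._build_meta(variables, knots, spec)
        tmp = cls(spec, variables, var_bounds, knots, meta,
                  feat_lo=None, feat_hi=None)
        raw_all = tmp._raw_features(
            cls._scale_vars(X_all[:, keep], var_bounds))
        feat_lo = raw_all.min(axis=0)
        feat_hi = raw_all.max(axis=0)
        degenerate = feat_hi - feat_lo <= 0
        feat_hi = np.where(degenerate, feat_lo + 1.0, feat_hi)
        tmp.feat_lo = feat_lo
        tmp.feat_hi = feat_hi
        return tmp

    @staticmethod
    def _scale_vars(X: np.ndarray, bounds: np.ndarray) -> np.ndarray:
        lo, hi = bounds[:, 0], bounds[:, 1]
        U = (np.clip(X, lo, hi) - lo) / (hi - lo)
        return U

    @staticmethod
    def _build_meta(variables, knots, spec) -> list[dict]:
        meta: list[dict] = []
        nv = len(variables)
        if spec.mode in ("auto", "lqp", "linear"):
            for v in variables:
                meta.append({"type": "linear", "vars": (v,), "knot": None})
        if spec.mode in ("auto", "lqp"):
            for v in variables:
                meta.append({"type": "quadratic", "vars": (v,), "knot": None})
            for i in range(nv):
                for j in range(i + 1, nv):
                    meta.append({"type": "product",
                                 "vars": (variables[i], variables[j]),
                                 "knot": None})
        if spec.mode in ("auto", "hinge"):
            for v in variables:
                for k in knots[v]:
                    if k < 1.0:
                        meta.append({"type": "fhinge", "vars": (v,), "knot": float(k)})
                for k in knots[v]:
                    if k > 0.0:
                        meta.append({"type": "rhinge", "vars": (v,), "knot": float(k)})
        return meta

    def _raw_features(self, U: np.ndarray) -> np.ndarray:
        idx = {v: i for i, v in enumerate(self.variables)}
        cols = np.empty((U.shape[0], len(self.meta)))
        for f, m in enumerate(self.meta):
            t = m["type"]
            if t == "linear":
                cols[:, f] = U[:, idx[m["vars"][0]]]
            elif t == "quadratic":
                cols[:, f] = U[:, idx[m["vars"][0]]] ** 2
            elif t == "product":
                cols[:, f] = U[:, idx[m["vars"][0]]] * U[:, idx[m["vars"][1]]]
            elif t == "fhinge":
                u = U[:, idx[m["vars"][0]]]
                k = m["knot"]
                cols[:, f] = np.maximum(0.0, (u - k) / (1.0 - k))
            elif t == "rhinge":
                u = U[:, idx[m["vars"][0]]]
                k = m["knot"]
                cols[:, f] = np.maximum(0.0, (k - u) / k)
        return cols

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Features in [0, 1]; out-of-range inputs are clamped (projection)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        U = self._scale_vars(X, self.var_bounds)
        raw = self._raw_features(U)
        F = (raw - self.feat_lo) / (self.feat_hi - self.feat_lo)
        return np.clip(F, 0.0, 1.0)

    def feature_classes(self) -> np.ndarray:
        return np.array(["hinge" if m["type"] in ("fhinge", "rhinge") else "lqp"
                         for m in self.meta])

    def source_variables(self) -> list[tuple[str, ...]]:
        return [m["vars"] for m in self.meta]

    def columns_for(self, variables) -> np.ndarray:
        """Indices of features whose source variables all lie in ``variables``
        (used to fit sub-models from one master expansion)."""
        allowed = set(variables)
        return np.array([f for f, m in enumerate(self.meta)
                         if set(m["vars"]) <= allowed], dtype=int)


@dataclass
class FeatureMatrix:
    """Expanded training features for presences and background."""

    expander: FeatureExpander
    presence: np.ndarray
    background: np.ndarray


def expand_features(X_presence, X_background, variables, spec: FeatureSpec | None = None,
                    ) -> FeatureMatrix:
    """Fit the feature expansion on training data and transform both sets."""
    spec = spec or FeatureSpec()
    variables = list(variables)
    exp = FeatureExpander.fit(X_presence, X_background, variables, spec)
    cols = [variables.index(v) for v in exp.variables]
    Xp = np.atleast_2d(np.asarray(X_presence, dtype=float))[:, cols]
    Xb = np.atleast_2d(np.asarray(X_background, dtype=float))[:, cols]
    return FeatureMatrix(exp, exp.transform(Xp), exp.transform(Xb))


@dataclass
class MaxentModel:
    """A fitted maximum-entropy model."""

    expander: FeatureExpander
    lambdas: np.ndarray
    log_Z: float
    entropy: float
    reg_multiplier: float
    betas: np.ndarray
    n_background: int
    converged: bool
    n_presence: int

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(np.abs(self.lambdas) > _ZERO_TOL))

    def to_json(self, path) -> None:
        exp = self.expander
        payload = {
            "mode": exp.spec.mode,
            "n_hinge_knots": exp.spec.n_hinge_knots,
            "variables": exp.variables,
            "var_bounds": exp.var_bounds.tolist(),
            "knots": {k: v.tolist() for k, v in exp.knots.items()},
            "meta": exp.meta,
            "feat_lo": exp.feat_lo.tolist(),
            "feat_hi": exp.feat_hi.tolist(),
            "lambdas": self.lambdas.tolist(),
            "log_Z": self.log_Z,
            "entropy": self.entropy,
            "reg_multiplier": self.reg_multiplier,
            "betas": self.betas.tolist(),
            "n_background": self.n_background,
            "n_presence": self.n_presence,
            "converged": self.converged,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "MaxentModel":
        d = json.loads(Path(path).read_text())
        spec = FeatureSpec(mode=d["mode"], n_hinge_knots=d["n_hinge_knots"])
        meta = [{"type": m["type"], "vars": tuple(m["vars"]), "knot": m["knot"]}
                for m in d["meta"]]
        exp = FeatureExpander(
            spec, d["variables"], np.array(d["var_bounds"]),
            {k: np.array(v) for k, v in d["knots"].items()}, meta,
            np.array(d["feat_lo"]), np.array(d["feat_hi"]),
        )
        return cls(exp, np.array(d["lambdas"]), d["log_Z"], d["entropy"],
                   d["reg_multiplier"], np.array(d["betas"]),
                   d["n_background"], d["converged"], d["n_presence"])


def compute_betas(F_presence: np.ndarray, feature_classes: np.ndarray,
                  r: float) -> np.ndarray:
    """Per-feature L1 penalties beta_j = r * c(class, m) * s_j / sqrt(m)."""
    m = F_presence.shape[0]
    s = F_presence.std(axis=0)
    s = np.maximum(s, _SD_FLOOR)
    c = np.array([default_beta_class(fc, m) for fc in feature_classes])
    return r * c * s / np.sqrt(m)


def fit_maxent(fm: FeatureMatrix | None = None, r: float = 1.0,
               max_iter: int = 500, tol: float = 1e-5,
               betas: np.ndarray | None = None,
               F_presence: np.ndarray | None = None,
               F_background: np.ndarray | None = None,
               expander: FeatureExpander | None = None,
               warm_start: np.ndarray | None = None) -> MaxentModel:
    """Fit the L1-penalized maximum-entropy model.

    Accepts either a :class:`FeatureMatrix` or explicit feature arrays (with
    an optional expander for later projection). ``betas`` overrides the
    default penalty schedule (useful for analytic test problems).

    The concave objective is solved with L-BFGS-B on the standard split
    ``lambda = a - b`` with ``a, b >= 0``, which handles the L1 term exactly
    and returns exact zeros for inactive features.
    """
    if fm is not None:
        F_p, F_b, expander = fm.presence, fm.background, fm.expander
    else:
        F_p, F_b = np.asarray(F_presence, float), np.asarray(F_background, float)
    n_p, n_feat = F_p.shape
    n_b = F_b.shape[0]
    if n_p < 2:
        raise GridError("fit_maxent needs at least 2 presences")
    if n_b < 10:
        raise GridError("fit_maxent needs at least 10 background points")
    if n_feat == 0:
        raise GridError("empty feature set")

    if betas is None:
        if expander is not None:
            classes = expander.feature_classes()
        else:
            classes = np.array(["lqp"] * n_feat)
        betas = compute_betas(F_p, classes, r)
    else:
        betas = np.broadcast_to(np.asarray(betas, dtype=float), (n_feat,)).copy()

    mean_p = F_p.mean(axis=0)

    def objective(theta):
        a = theta[:n_feat]
        b = theta[n_feat:]
        lam = a - b
        s_b = F_b @ lam
        lse = logsumexp(s_b)
        obj = -(mean_p @ lam) + lse - np.log(n_b) + betas @ (a + b)
        q = np.exp(s_b - lse)
        e_q = F_b.T @ q
        g = e_q - mean_p
        grad = np.concatenate([g + betas, -g + betas])
        return obj, grad

    theta0 = np.zeros(2 * n_feat)
    if warm_start is not None:
        lam0 = np.asarray(warm_start, dtype=float)
        theta0[:n_feat] = np.maximum(lam0, 0.0)
        theta0[n_feat:] = np.maximum(-lam0, 0.0)
    res = minimize(
        objective, theta0, jac=True, method="L-BFGS-B",
        bounds=[(0.0, _LAMBDA_MAX)] * (2 * n_feat),
        options={"maxiter": max_iter, "maxfun": 10 * max_iter,
                 "ftol": 1e-14, "gtol": tol},
    )
    if not res.success and res.status != 1:  # status 1 = iteration cap
        logger.warning("fit_maxent: optimizer reports %s", res.message)
    converged = bool(res.success)
    if not converged:
        warnings.warn(f"fit_maxent did not fully converge: {res.message}")

    lam = res.x[:n_feat] - res.x[n_feat:]
    s_b = F_b @ lam
    log_Z = float(logsumexp(s_b))
    q = np.exp(s_b - log_Z)
    with np.errstate(divide="ignore", invalid="ignore"):
        H = float(-np.sum(np.where(q > 0, q * np.log(q), 0.0)))
    return MaxentModel(
        expander=expander, lambdas=lam, log_Z=log_Z, entropy=H,
        reg_multiplier=r, betas=betas, n_background=n_b,
        converged=converged, n_presence=n_p,
    )


def predict(model: MaxentModel, F: np.ndarray, output: str = "logistic") -> np.ndarray:
    """Model predictions for pre-expanded features.

    ``raw`` is the Gibbs probability normalized over the training background;
    ``logistic`` is ``e^H q / (1 + e^H q)``, in (0, 1), equal to 0.5
    everywhere for the uniform (all-zero) model.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    if F.shape[1] != model.lambdas.size:
        raise GridError(
            f"feature mismatch: got {F.shape[1]} features, model has {model.lambdas.size}"
        )
    log_q = F @ model.lambdas - model.log_Z
    if output == "raw":
        return np.exp(log_q)
    if output == "logistic":
        # e^H q / (1 + e^H q), computed as expit(H + ln q) to avoid overflow
        return expit(model.entropy + log_q)
    raise ValueError("output must be 'raw' or 'logistic'")


def predict_points(model: MaxentModel, X: np.ndarray, output: str = "logistic") -> np.ndarray:
    """Predictions for raw predictor rows (clamped into training bounds)."""
    if model.expander is None:
        raise GridError("model has no feature expander attached")
    return predict(model, model.expander.transform(X), output=output)


def project(model: MaxentModel, stack: PredictorStack, output: str = "logistic") -> Raster:
    """Project the model over a predictor stack into a prediction raster."""
    if model.expander is None:
        raise GridError("model has no feature expander attached")
    grid = stack.grid
    valid = stack.combined_valid()
    X = np.column_stack([stack[v].values[valid] for v in model.expander.variables])
    pred = predict_points(model, X, output=output)
    out = np.full(grid.shape, np.nan)
    out[valid] = pred
    return Raster(grid, out, ~valid)


def compute_auc(presence_scores, background_scores) -> float:
    """Probability a random presence outscores a random background point
    (Mann-Whitney form; ties count one half)."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise GridError("compute_auc requires non-empty score sets")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


def omission_rate(train_presence_scores, test_presence_scores,
                  level: float = 0.10) -> float:
    """Fraction of test presences scoring strictly below the ``level``
    percentile of the training presence scores."""
    train = np.asarray(train_presence_scores, dtype=float)
    test = np.asarray(test_presence_scores, dtype=float)
    if train.size < 10:
        raise GridError("omission_rate needs at least 10 training presences")
    if test.size == 0:
        raise GridError("omission_rate: empty test set")
    threshold = np.percentile(train, 100 * level)
    return float(np.mean(test < threshold))
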