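"""From-scratch presence/background maximum-entropy suitability model.

The model is the Gibbs distribution over landscape cells,
q_lambda(x) = exp(lambda . f(x)) / Z, that maximizes entropy subject to the
fitted feature expectations matching the presence sample, estimated by
minimizing the convex L1-regularized objective

    J(lambda) = -(1/m) sum_presences lambda.f(x_i) + log Z(lambda)
                + sum_j penalty_j |lambda_j|,

with Z summed over the training background and
penalty_j = RM * beta0_j * sigma_j / sqrt(m): RM is the user-facing
regularization multiplier, beta0_j the per-feature-class default that
interpolates on presence count m, and sigma_j the presence-sample SD of
feature j. Optimization is monotone proximal-gradient descent with
Barzilai-Borwein step seeding and backtracking.

Features are the classic feature classes — linear, quadratic, product,
forward/reverse hinge, threshold — built from the training background and
min-max scaled to [0, 1] on it. Projection clamps variables to their
training ranges. Outputs: raw (normalized over background), logistic, and
cloglog transforms.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import mannwhitneyu

from .raster import RasterGrid, RasterStack

logger = logging.getLogger("popsdm")

FC_COMBOS = ("L", "LQ", "H", "LQH", "LQHP", "LQHPT")

_CLASS_OF_LETTER = {"L": "linear", "Q": "quadratic", "H": "hinge",
                    "P": "product", "T": "threshold"}


# ---------------------------------------------------------------------------
# Feature space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Feature:
    kind: str                     # linear|quadratic|product|hinge_fwd|hinge_rev|threshold
    vars: tuple[str, ...]         # one variable, or two for product
    knot: float | None = None

    @property
    def name(self) -> str:
        base = "*".join(self.vars)
        if self.knot is None:
            return f"{self.kind}({base})"
        return f"{self.kind}({base}@{self.knot:.6g})"

    @property
    def penalty_class(self) -> str:
        if self.kind in ("hinge_fwd", "hinge_rev"):
            return "hinge"
        if self.kind == "threshold":
            return "threshold"
        return "lqp"  # linear / quadratic / product share a default


@dataclass
class FeatureSpace:
    """Feature definitions plus the background-derived normalizers."""

    variables: list[str]
    features: list[Feature]
    var_min: np.ndarray           # training (background) variable ranges
    var_max: np.ndarray
    feat_min: np.ndarray          # per-feature background min/max for scaling
    feat_max: np.ndarray
    fc: str = "L"
    n_knots: int = 20

    def __len__(self) -> int:
        return len(self.features)

    def _raw(self, V: np.ndarray) -> np.ndarray:
        col = {v: j for j, v in enumerate(self.variables)}
        out = np.empty((V.shape[0], len(self.features)))
        for i, ft in enumerate(self.features):
            if ft.kind == "linear":
                out[:, i] = V[:, col[ft.vars[0]]]
            elif ft.kind == "quadratic":
                out[:, i] = V[:, col[ft.vars[0]]] ** 2
            elif ft.kind == "product":
                out[:, i] = V[:, col[ft.vars[0]]] * V[:, col[ft.vars[1]]]
            elif ft.kind == "hinge_fwd":
                j = col[ft.vars[0]]
                denom = self.var_max[j] - ft.knot
                out[:, i] = 0.0 if denom <= 0 else np.maximum(0.0, V[:, j] - ft.knot) / denom
            elif ft.kind == "hinge_rev":
                j = col[ft.vars[0]]
                denom = ft.knot - self.var_min[j]
                out[:, i] = 0.0 if denom <= 0 else np.maximum(0.0, ft.knot - V[:, j]) / denom
            elif ft.kind == "threshold":
                out[:, i] = (V[:, col[ft.vars[0]]] > ft.knot).astype(float)
            else:  # pragma: no cover
                raise ValueError(f"unknown feature kind {ft.kind!r}")
        return out

    def evaluate(self, X, clamp: bool = False) -> np.ndarray:
        """Feature matrix scaled to the background's [0, 1] per feature."""
        V = _as_matrix(X, self.variables)
        if not np.all(np.isfinite(V)):
            raise ValueError("non-finite values in the climate matrix")
        if clamp:
            V = np.clip(V, self.var_min, self.var_max)
        raw = self._raw(V)
        span = self.feat_max - self.feat_min
        scaled = np.zeros_like(raw)
        ok = span > 0
        scaled[:, ok] = (raw[:, ok] - self.feat_min[ok]) / span[ok]
        return scaled


def _as_matrix(X, variables: list[str]) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        missing = [v for v in variables if v not in X.columns]
        if missing:
            raise KeyError(f"climate matrix lacks variable(s) {missing}")
        return X[variables].to_numpy(dtype=float)
    A = np.asarray(X, dtype=float)
    if A.ndim != 2 or A.shape[1] != len(variables):
        raise ValueError("expected an (n, n_variables) matrix")
    return A


def build_features(background: pd.DataFrame, fc: str = "LQ",
                   n_knots: int = 20) -> FeatureSpace:
    """Construct the feature space of one feature-class combination.

    Hinge/threshold knots sit at ``n_knots`` equally spaced interior
    quantiles of the background distribution of each variable. Nonlinear
    features of constant variables are dropped with a warning.
    """
    if fc not in FC_COMBOS:
        raise ValueError(f"fc must be one of {FC_COMBOS}, got {fc!r}")
    background = pd.DataFrame(background)
    variables = list(background.columns)
    if not variables:
        raise ValueError("at least one variable required")
    V = background.to_numpy(dtype=float)
    vmin, vmax = V.min(axis=0), V.max(axis=0)
    constant = vmin == vmax
    if constant.any():
        logger.warning("build_features: constant variable(s) %s — nonlinear features dropped",
                       [v for v, c in zip(variables, constant) if c])

    classes = {_CLASS_OF_LETTER[c] for c in fc}
    feats: list[Feature] = []
    if "linear" in classes:
        feats += [Feature("linear", (v,)) for v in variables]
    if "quadratic" in classes:
        feats += [Feature("quadratic", (v,)) for v, c in zip(variables, constant) if not c]
    if "hinge" in classes:
        qs = np.linspace(0, 1, n_knots + 2)[1:-1]
        for j, v in enumerate(variables):
            if constant[j]:
                continue
            knots = np.quantile(V[:, j], qs)
            feats += [Feature("hinge_fwd", (v,), float(k)) for k in knots]
            feats += [Feature("hinge_rev", (v,), float(k)) for k in knots]
    if "product" in classes:
        for a, b in itertools.combinations(range(len(variables)), 2):
            if not (constant[a] or constant[b]):
                feats.append(Feature("product", (variables[a], variables[b])))
    if "threshold" in classes:
        qs = np.linspace(0, 1, n_knots + 2)[1:-1]
        for j, v in enumerate(variables):
            if constant[j]:
                continue
            knots = np.quantile(V[:, j], qs)
            feats += [Feature("threshold", (v,), float(k)) for k in knots]

    fs = FeatureSpace(variables, feats, vmin, vmax,
                      np.zeros(len(feats)), np.ones(len(feats)), fc=fc, n_knots=n_knots)
    raw = fs._raw(V)
    fs.feat_min = raw.min(axis=0)
    fs.feat_max = raw.max(axis=0)
    return fs


# ---------------------------------------------------------------------------
# Regularization defaults
# ---------------------------------------------------------------------------

def base_regularization(penalty_class: str, m: int) -> float:
    """Per-feature-class default L1 weight, interpolated on presence count."""
    if penalty_class == "lqp":
        return float(np.interp(m, [10, 30, 100], [1.0, 0.2, 0.05]))
    if penalty_class == "hinge":
        return 0.5
    if penalty_class == "threshold":
        return float(np.interp(m, [0, 100], [2.0, 1.0]))
    raise ValueError(penalty_class)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class MaxentModel:
    feature_space: FeatureSpace
    lam: np.ndarray
    log_z: float                 # log partition over training background
    entropy: float               # H of the fitted raw distribution
    rm: float
    m: int                       # presence count
    presence_means: np.ndarray   # per-variable presence means (response curves)
    converged: bool = True
    n_iter: int = 0
    objective: float = math.nan
    rm_floored: bool = False

    @property
    def fc(self) -> str:
        return self.feature_space.fc

    @property
    def n_parameters(self) -> int:
        return int(np.count_nonzero(self.lam))


def _objective_and_grad(lam, Fp_mean, Fb, penalties):
    s = Fb @ lam
    log_z = logsumexp(s)
    q = np.exp(s - log_z)
    smooth = -Fp_mean @ lam + log_z
    grad = -Fp_mean + Fb.T @ q
    return smooth + penalties @ np.abs(lam), smooth, grad, log_z, q


def fit_maxent(presence, background, feature_space: FeatureSpace | None = None,
               rm: float = 1.0, fc: str = "LQ", n_knots: int = 20,
               max_iter: int = 500, tol: float = 1e-7) -> MaxentModel:
    """Fit the L1-regularized maximum-entropy model.

    ``presence`` and ``background`` are climate matrices (DataFrame or
    array over the same variables). A ``feature_space`` built elsewhere can
    be passed to avoid rebuilding; otherwise one is built from the
    background with ``fc``/``n_knots``. RM = 0 is run at a 1e-6 numerical
    floor (recorded in ``rm_floored``) so the objective stays well-posed.
    """
    if rm < 0:
        raise ValueError("regularization multiplier must be >= 0")
    presence = pd.DataFrame(presence)
    background = pd.DataFrame(background)
    m = len(presence)
    if m < 2:
        raise ValueError("at least 2 presences required")
    if len(background) < 10 * m:
        logger.warning("fit_maxent: background (%d) < 10x presences (%d)",
                       len(background), m)
    fs = feature_space if feature_space is not None else build_features(
        background, fc=fc, n_knots=n_knots)

    Fp = fs.evaluate(presence)
    Fb = fs.evaluate(background)
    Fp_mean = Fp.mean(axis=0)
    sigma = Fp.std(axis=0, ddof=1) if m > 1 else np.zeros(len(fs))

    rm_floored = rm == 0
    eff_rm = 1e-6 if rm_floored else rm
    beta0 = np.array([base_regularization(ft.penalty_class, m) for ft in fs.features])
    penalties = eff_rm * beta0 * sigma / math.sqrt(m)

    lam = np.zeros(len(fs))
    obj, smooth, grad, log_z, q = _objective_and_grad(lam, Fp_mean, Fb, penalties)
    step = 1.0
    prev_lam, prev_grad = None, None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if prev_lam is not None:
            dl = lam - prev_lam
            dg = grad - prev_grad
            denom = dl @ dg
            if denom > 0:
                step = float(dl @ dl / denom)  # Barzilai-Borwein seed
        step = min(max(step, 1e-8), 1e8)
        # monotone backtracking proximal step
        while True:
            cand = np.sign(lam - step * grad) * np.maximum(
                np.abs(lam - step * grad) - step * penalties, 0.0)
            new_obj, new_smooth, new_grad, new_log_z, new_q = _objective_and_grad(
                cand, Fp_mean, Fb, penalties)
            d = cand - lam
            quad = smooth + grad @ d + d @ d / (2 * step) + penalties @ np.abs(cand)
            if new_obj <= quad + 1e-12 or step < 1e-12:
                break
            step *= 0.5
        prev_lam, prev_grad = lam, grad
        delta = obj - new_obj
        lam, obj, smooth, grad, log_z, q = cand, new_obj, new_smooth, new_grad, new_log_z, new_q
        if 0 <= delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("fit_maxent: not converged after %d iterations (last step %.3g)",
                       it, step)
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = float(-np.sum(np.where(q > 0, q * np.log(q), 0.0)))
    pres_means = _as_matrix(presence, fs.variables).mean(axis=0)
    return MaxentModel(fs, lam, float(log_z), entropy, rm, m, pres_means,
                       converged=converged, n_iter=it, objective=float(obj),
                       rm_floored=rm_floored)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

OUTPUT_TRANSFORMS = ("raw", "logistic", "cloglog")


def predict(model: MaxentModel, X, output: str = "cloglog",
            clamp: bool = True) -> np.ndarray | RasterGrid:
    """Suitability of climate rows or of every finite cell in a stack.

    raw(x) = exp(lambda.f(x)) / Z;  logistic = raw*e^H / (1 + raw*e^H);
    cloglog = 1 - exp(-raw*e^H). With ``clamp`` variables are truncated to
    their training ranges before feature evaluation.
    """
    if output not in OUTPUT_TRANSFORMS:
        raise ValueError(f"output must be one of {OUTPUT_TRANSFORMS}, got {output!r}")
    if isinstance(X, RasterStack):
        template = X.template
        finite = np.ones((template.nrows, template.ncols), dtype=bool)
        for g in X.values():
            finite &= g.finite_mask
        rows, cols = np.nonzero(finite)
        mat = np.stack([X[v].values[rows, cols] for v in model.feature_space.variables], axis=1)
        vals = np.full((template.nrows, template.ncols), np.nan)
        vals[rows, cols] = predict(model, mat, output=output, clamp=clamp)
        return template.copy_with(vals)

    F = model.feature_space.evaluate(X, clamp=clamp)
    log_raw = F @ model.lam - model.log_z
    if output == "raw":
        return np.exp(log_raw)
    z = np.exp(np.clip(log_raw + model.entropy, -700, 700))
    if output == "logistic":
        return z / (1.0 + z)
    return 1.0 - np.exp(-z)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def auc(presence_scores, background_scores) -> float:
    """Mann-Whitney AUC: fraction of presence/background pairs ranked
    correctly, ties counted one half."""
    x = np.asarray(presence_scores, dtype=float)
    y = np.asarray(background_scores, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both score sets must be nonempty")
    u = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").statistic
    return float(u / (x.size * y.size))


def aicc(model: MaxentModel, presence, landscape) -> dict:
    """Small-sample-corrected AIC with the raw output renormalized over the
    landscape (background plus presence cells).

    K counts nonzero coefficients; AICc is +inf when m <= K + 1.
    """
    fs = model.feature_space
    s_land = fs.evaluate(landscape) @ model.lam
    log_z_land = logsumexp(s_land)
    s_pres = fs.evaluate(presence) @ model.lam
    lnL = float(np.sum(s_pres - log_z_land))
    K = model.n_parameters
    m = len(pd.DataFrame(presence))
    if m <= K + 1:
        value = math.inf
    else:
        value = 2 * K - 2 * lnL + 2 * K * (K + 1) / (m - K - 1)
    return {"lnL": lnL, "K": K, "AICc": value, "m": m}


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

DEFAULT_RM_GRID = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)


@dataclass
class SelectionResult:
    rm: float
    fc: str
    scores: pd.DataFrame          # one row per (rm, fc) setting
    model: MaxentModel            # refit on all presences at the winner
    fallback: bool = False


def model_select(presence, background, rm_grid=DEFAULT_RM_GRID,
                 fc_combos=FC_COMBOS, n_eval_splits: int = 10,
                 seed: int = 0, n_knots: int = 20, top_fraction: float = 0.10,
                 max_iter: int = 500, tol: float = 1e-7) -> SelectionResult:
    """Tune (RM, FC) by mean test AUC then AICc.

    Every setting is scored with the same ``n_eval_splits`` random 50/50
    presence splits (test AUC against the shared background); settings in
    the top ``top_fraction`` (ceiling, at least one) by mean test AUC are
    then ranked by AICc of a full-presence fit, lowest wins. Ties break by
    smaller K, then smaller RM, then FC order. Deterministic given ``seed``.
    """
    presence = pd.DataFrame(presence)
    background = pd.DataFrame(background)
    if not len(rm_grid) or not len(fc_combos):
        raise ValueError("empty tuning grid")
    m = len(presence)
    rng = np.random.default_rng(seed)
    n_train = m // 2
    splits = [rng.permutation(m) for _ in range(n_eval_splits)]

    spaces = {fc: build_features(background, fc=fc, n_knots=n_knots) for fc in fc_combos}
    landscape = pd.concat([background, presence], ignore_index=True)

    rows = []
    full_models = {}
    for fc_i, fc in enumerate(fc_combos):
        fs = spaces[fc]
        for rm in rm_grid:
            train_aucs, test_aucs = [], []
            for perm in splits:
                tr = presence.iloc[perm[:n_train]]
                te = presence.iloc[perm[n_train:]]
                mod = fit_maxent(tr, background, feature_space=fs, rm=rm,
                                 max_iter=max_iter, tol=tol)
                bg_scores = predict(mod, background, output="raw", clamp=False)
                train_aucs.append(auc(predict(mod, tr, output="raw"), bg_scores))
                test_aucs.append(auc(predict(mod, te, output="raw"), bg_scores))
            full = fit_maxent(presence, background, feature_space=fs, rm=rm,
                              max_iter=max_iter, tol=tol)
            full_models[(rm, fc)] = full
            ic = aicc(full, presence, landscape)
            rows.append({"rm": rm, "fc": fc, "fc_order": fc_i,
                         "mean_train_auc": float(np.mean(train_aucs)),
                         "mean_test_auc": float(np.mean(test_aucs)),
                         "AICc": ic["AICc"], "K": ic["K"], "lnL": ic["lnL"]})
    scores = pd.DataFrame(rows)

    n_keep = max(1, math.ceil(top_fraction * len(scores)))
    top = scores.sort_values("mean_test_auc", ascending=False, kind="stable").head(n_keep)
    eligible = top[np.isfinite(top["AICc"])]
    fallback = eligible.empty
    if fallback:
        logger.warning("model_select: all top settings AICc-ineligible; "
                       "falling back to max mean test AUC")
        pick = top.sort_values(["mean_test_auc", "K", "rm", "fc_order"],
                               ascending=[False, True, True, True], kind="stable").iloc[0]
    else:
        pick = eligible.sort_values(["AICc", "K", "rm", "fc_order"],
                                    ascending=True, kind="stable").iloc[0]
    rm_best, fc_best = float(pick["rm"]), str(pick["fc"])
    return SelectionResult(rm_best, fc_best, scores.drop(columns="fc_order"),
                           full_models[(rm_best, fc_best)], fallback)


# ---------------------------------------------------------------------------
# Variable importance and response curves
# ---------------------------------------------------------------------------

def permutation_importance(model: MaxentModel, presence, background,
                           n_perm: int = 10, seed: int = 0) -> pd.Series:
    """Percent importance per variable from the mean training-AUC drop after
    jointly permuting that variable across presence and background rows.
    Percentages are normalized to sum to 100 (uniform, with a warning, when
    no permutation changes the AUC)."""
    presence = pd.DataFrame(presence)
    background = pd.DataFrame(background)
    variables = model.feature_space.variables
    both = pd.concat([presence[variables], background[variables]], ignore_index=True)
    n_p = len(presence)
    base_bg = predict(model, background[variables], output="raw")
    base_auc = auc(predict(model, presence[variables], output="raw"), base_bg)
    rng = np.random.default_rng(seed)
    drops = {}
    for v in variables:
        vals = []
        for _ in range(n_perm):
            shuffled = both.copy()
            shuffled[v] = rng.permutation(shuffled[v].to_numpy())
            scores = predict(model, shuffled, output="raw")
            vals.append(base_auc - auc(scores[:n_p], scores[n_p:]))
        drops[v] = float(np.mean(vals))
    s = pd.Series(drops)
    total = s.clip(lower=0).sum()
    if total <= 0:
        logger.warning("permutation_importance: no AUC drop for any variable; "
                       "reporting uniform percentages")
        return pd.Series(100.0 / len(s), index=s.index)
    return 100.0 * s.clip(lower=0) / total


def jackknife_importance(presence, background, rm: float, fc: str,
                         n_splits: int = 5, seed: int = 0, n_knots: int = 20,
                         max_iter: int = 500, tol: float = 1e-7) -> pd.DataFrame:
    """Mean test AUC of each variable fitted alone and of the model without
    it, over shared random 50/50 presence splits."""
    presence = pd.DataFrame(presence)
    background = pd.DataFrame(background)
    variables = list(presence.columns)
    if len(variables) < 2:
        raise ValueError("jackknife needs at least 2 variables")
    rng = np.random.default_rng(seed)
    m = len(presence)
    splits = [rng.permutation(m) for _ in range(n_splits)]

    def _mean_test_auc(cols: list[str]) -> float:
        fs = build_features(background[cols], fc=fc, n_knots=n_knots)
        vals = []
        for perm in splits:
            tr = presence[cols].iloc[perm[: m // 2]]
            te = presence[cols].iloc[perm[m // 2:]]
            mod = fit_maxent(tr, background[cols], feature_space=fs, rm=rm,
                             max_iter=max_iter, tol=tol)
            vals.append(auc(predict(mod, te, output="raw"),
                            predict(mod, background[cols], output="raw", clamp=False)))
        return float(np.mean(vals))

    rows = {v: {"only": _mean_test_auc([v]),
                "without": _mean_test_auc([u for u in variables if u != v])}
            for v in variables}
    return pd.DataFrame(rows).T


def response_curve(model: MaxentModel, variable: str, n_points: int = 100,
                   output: str = "cloglog") -> tuple[np.ndarray, np.ndarray]:
    """Predicted suitability along one variable's training range, the other
    variables held at their presence means."""
    fs = model.feature_space
    if variable not in fs.variables:
        raise KeyError(f"variable {variable!r} not in the model")
    j = fs.variables.index(variable)
    grid = np.linspace(fs.var_min[j], fs.var_max[j], n_points)
    X = np.tile(model.presence_means, (n_points, 1))
    X[:, j] = grid
    return grid, np.asarray(predict(model, X, output=output))


def threshold_range(grid: np.ndarray, values: np.ndarray,
                    cutoff: float = 0.2) -> tuple[float, float] | None:
    """Smallest and largest grid values with suitability above the cutoff,
    or None when the curve never exceeds it."""
    above = np.asarray(values) > cutoff
    if not above.any():
        return None
    g = np.asarray(grid)[above]
    return float(g.min()), float(g.max())


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def model_to_dict(model: MaxentModel) -> dict:
    fs = model.feature_space
    return {
        "variables": fs.variables,
        "fc": fs.fc,
        "n_knots": fs.n_knots,
        "features": [{"kind": f.kind, "vars": list(f.vars), "knot": f.knot}
                     for f in fs.features],
        "var_min": fs.var_min.tolist(), "var_max": fs.var_max.tolist(),
        "feat_min": fs.feat_min.tolist(), "feat_max": fs.feat_max.tolist(),
        "lam": model.lam.tolist(), "log_z": model.log_z, "entropy": model.entropy,
        "rm": model.rm, "m": model.m,
        "presence_means": model.presence_means.tolist(),
        "converged": model.converged, "n_iter": model.n_iter,
        "objective": model.objective, "rm_floored": model.rm_floored,
    }


def model_from_dict(d: dict) -> MaxentModel:
    fs = FeatureSpace(
        variables=list(d["variables"]),
        features=[Feature(f["kind"], tuple(f["vars"]), f["knot"]) for f in d["features"]],
        var_min=np.asarray(d["var_min"]), var_max=np.asarray(d["var_max"]),
        feat_min=np.asarray(d["feat_min"]), feat_max=np.asarray(d["feat_max"]),
        fc=d["fc"], n_knots=d["n_knots"],
    )
    return MaxentModel(fs, np.asarray(d["lam"]), d["log_z"], d["entropy"],
                       d["rm"], d["m"], np.asarray(d["presence_means"]),
                       converged=d["converged"], n_iter=d["n_iter"],
                       objective=d["objective"], rm_floored=d["rm_floored"])


def save_model(model: MaxentModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1)


def load_model(path) -> MaxentModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
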