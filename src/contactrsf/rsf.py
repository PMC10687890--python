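"""Used-available resource selection functions.

Builds individual-level used-available datasets (interpolated fixes vs 30
uniform points per fix inside the 95% home range), fits per-owner logistic
regressions, selects a model structure by cumulative-log-likelihood AIC
across owners, aggregates coefficients to a weighted population mean, and
cross-validates with the area-adjusted-frequency Spearman statistic.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import statsmodels.api as sm
from scipy.stats import spearmanr

from contactrsf.errors import (
    DegenerateInputError,
    FitFailureError,
    InsufficientDataError,
    InvalidArgumentError,
)
from contactrsf.homerange import HomeRange
from contactrsf.landscape import BINARY_LAYERS, EnvStack
from contactrsf.tracks import Trajectory

DEFAULT_RATIO = 30
COLLINEARITY_THRESHOLD = 0.6
_SEPARATION_BETA = 15.0
_RIDGE_LAMBDA = 1e-4
_AIC_TIE = 1e-9


# ---------------------------------------------------------------------------
# datasets


@dataclass
class UseAvailableDataset:
    """Labeled used/available rows with extracted, standardized covariates."""

    owner: str
    data: pd.DataFrame  # columns: used, x, y, date, <covariates>
    covariates: list[str]
    standardizers: dict[str, tuple[float, float]]
    ratio: int
    seed: int | None = None

    def __post_init__(self):
        n_used = int((self.data["used"] == 1).sum())
        n_avail = int((self.data["used"] == 0).sum())
        if n_used and n_avail / n_used > self.ratio + 1e-9:
            raise InvalidArgumentError("available:used ratio exceeds the cap")
        if not np.isfinite(self.data[self.covariates].to_numpy(dtype=float)).all():
            raise InvalidArgumentError("covariates must be finite")

    @property
    def n_used(self) -> int:
        return int((self.data["used"] == 1).sum())

    @property
    def n_available(self) -> int:
        return int((self.data["used"] == 0).sum())

    def to_csv(self, path) -> Path:
        path = Path(path)
        out = self.data.copy()
        out.insert(0, "owner", self.owner)
        out.to_csv(path, index=False)
        return path


def is_binary(name: str, values: np.ndarray) -> bool:
    return name in BINARY_LAYERS or np.isin(values, (0, 1)).all()


def standardize(df: pd.DataFrame, covariates) -> tuple[pd.DataFrame, dict]:
    """Scale continuous covariates to zero mean / unit SD; leave binaries."""
    out = df.copy()
    standardizers: dict[str, tuple[float, float]] = {}
    for name in covariates:
        vals = out[name].to_numpy(dtype=float)
        if is_binary(name, vals):
            continue
        mean = float(vals.mean())
        sd = float(vals.std())
        if sd == 0:
            # constant on this design (e.g. daily-constant weather over a
            # one-day window); leave raw, nothing to rescale
            continue
        out[name] = (vals - mean) / sd
        standardizers[name] = (mean, sd)
    return out, standardizers


def extract_covariates(x, y, dates, env: EnvStack, layers=None) -> pd.DataFrame:
    """Raw (unstandardized) covariates at the cells containing the points."""
    return env.extract(x, y, dates, layers=layers)


def sample_in_polygon(polygon: shapely.Geometry, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points inside a polygon by rejection from its bounding box."""
    if polygon.is_empty or polygon.area <= 0:
        raise DegenerateInputError("cannot sample from a degenerate polygon")
    minx, miny, maxx, maxy = polygon.bounds
    out = np.empty((n, 2))
    got = 0
    # acceptance rate is area/bbox-area; cap iterations defensively
    for _ in range(10_000):
        need = n - got
        batch = max(int(need / max(polygon.area / ((maxx - minx) * (maxy - miny)), 1e-6)) + 8, need)
        cand = np.column_stack(
            [rng.uniform(minx, maxx, batch), rng.uniform(miny, maxy, batch)]
        )
        keep = shapely.contains_xy(polygon, cand[:, 0], cand[:, 1])
        take = cand[keep][:need]
        out[got : got + len(take)] = take
        got += len(take)
        if got == n:
            return out
    raise DegenerateInputError("rejection sampling failed to fill the polygon")


def build_individual_dataset(
    itrack: Trajectory,
    hr95: HomeRange,
    env: EnvStack,
    ratio: int = DEFAULT_RATIO,
    seed: int | None = None,
    layers=None,
    owner: str | None = None,
    hr_level: float = 0.95,
) -> UseAvailableDataset:
    """Used = interpolated fixes; available = ``ratio`` uniform points per
    used point inside the 95% home-range polygon, inheriting the paired
    used point's date for dynamic covariates."""
    rng = np.random.default_rng(seed)
    polygon = hr95.polygon(hr_level)
    n_used = len(itrack)
    avail_xy = sample_in_polygon(polygon, ratio * n_used, rng)
    used_dates = itrack.dates
    avail_dates = np.repeat(used_dates, ratio)
    x = np.concatenate([itrack.x, avail_xy[:, 0]])
    y = np.concatenate([itrack.y, avail_xy[:, 1]])
    dates = np.concatenate([used_dates, avail_dates])
    label = np.concatenate([np.ones(n_used, dtype=int), np.zeros(ratio * n_used, dtype=int)])
    cov = extract_covariates(x, y, dates, env, layers=layers)
    df = pd.DataFrame({"used": label, "x": x, "y": y, "date": dates.astype("datetime64[D]")})
    df = pd.concat([df.reset_index(drop=True), cov.reset_index(drop=True)], axis=1)
    covariates = list(cov.columns)
    df, standardizers = standardize(df, covariates)
    return UseAvailableDataset(
        owner=owner or itrack.animal_id,
        data=df,
        covariates=covariates,
        standardizers=standardizers,
        ratio=ratio,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# collinearity screen


def screen_collinearity(dataset, threshold: float = COLLINEARITY_THRESHOLD, priority_order=None):
    """Iteratively drop the lower-priority member of every covariate pair
    with |Pearson r| at or above the threshold; returns the survivors.

    ``dataset`` may be a UseAvailableDataset, a DataFrame of covariates, or
    a list of datasets (pooled).  A 1e-9 slack absorbs floating-point
    rounding at the threshold.
    """
    if isinstance(dataset, UseAvailableDataset):
        frames = [dataset.data[dataset.covariates]]
    elif isinstance(dataset, pd.DataFrame):
        frames = [dataset]
    else:
        frames = [d.data[d.covariates] for d in dataset]
    pooled = pd.concat(frames, ignore_index=True)
    names = list(pooled.columns)
    if len(names) < 2:
        return names
    priority = list(priority_order) if priority_order is not None else list(names)

    def rank(name: str) -> int:
        return priority.index(name) if name in priority else len(priority)

    retained = list(names)
    while len(retained) > 1:
        sub = pooled[retained].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        corr = np.nan_to_num(np.abs(corr))
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] < threshold - 1e-9:
            break
        a, b = retained[i], retained[j]
        drop = b if rank(b) >= rank(a) else a
        retained.remove(drop)
    return retained


# ---------------------------------------------------------------------------
# logistic fits


@dataclass
class RSFModel:
    """One owner's fitted logistic used-available model."""

    owner: str
    formula: list[str]
    coef: dict[str, float]  # includes "intercept"
    se: dict[str, float]
    loglik: float
    k: int
    aic: float
    n_used: int
    n_available: int
    converged: bool = True
    penalized: bool = False

    def __post_init__(self):
        if not math.isclose(self.aic, 2 * self.k - 2 * self.loglik, rel_tol=0, abs_tol=1e-6):
            raise InvalidArgumentError("AIC must equal 2k - 2*loglik")
        for name, b in self.coef.items():
            if not math.isfinite(b):
                raise InvalidArgumentError(f"non-finite coefficient for {name!r}")

    def beta(self) -> np.ndarray:
        return np.array([self.coef[c] for c in self.formula])

    def beta_se(self) -> np.ndarray:
        return np.array([self.se[c] for c in self.formula])

    def to_dict(self) -> dict:
        return {
            "owner": self.owner,
            "formula": self.formula,
            "coef": self.coef,
            "se": self.se,
            "loglik": self.loglik,
            "k": self.k,
            "aic": self.aic,
            "n_used": self.n_used,
            "n_available": self.n_available,
            "converged": self.converged,
            "penalized": self.penalized,
        }


def _ridge_logit(X: np.ndarray, y: np.ndarray, lam: float):
    """Newton iterations for an L2-penalized logistic fit (no penalty on the
    intercept); returns (beta, se, loglik)."""
    n, p = X.shape
    beta = np.zeros(p)
    pen = np.full(p, lam)
    pen[0] = 0.0
    for _ in range(200):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        grad = X.T @ (y - mu) - pen * beta
        H = X.T @ (X * W[:, None]) + np.diag(pen)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = X @ beta
    ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    H = X.T @ (X * (1.0 / (1.0 + np.exp(-eta)) * (1.0 - 1.0 / (1.0 + np.exp(-eta))))[:, None])
    cov = np.linalg.inv(H + np.diag(pen))
    return beta, np.sqrt(np.diag(cov)), ll


def fit_rsf(dataset: UseAvailableDataset, formula) -> RSFModel:
    """ML logistic regression of used vs available on the formula covariates.

    Complete separation (non-convergence or any |beta| > 15) triggers a
    flagged refit with a small L2 penalty.
    """
    formula = list(formula)
    if not formula:
        raise InvalidArgumentError("empty formula")
    missing = [c for c in formula if c not in dataset.data.columns]
    if missing:
        raise InvalidArgumentError(f"formula covariates missing from dataset: {missing}")
    y = dataset.data["used"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise InvalidArgumentError("both labels must be present")
    X = np.column_stack([np.ones(len(y))] + [dataset.data[c].to_numpy(dtype=float) for c in formula])
    names = ["intercept"] + formula
    penalized = False
    converged = True
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        beta = res.params
        se = res.bse
        ll = float(res.llf)
        converged = bool(res.mle_retvals.get("converged", True))
    except Exception:
        converged = False
        beta = np.full(len(names), np.nan)
        se = beta
        ll = -np.inf
    if (not converged) or (not np.all(np.isfinite(beta))) or np.any(np.abs(beta) > _SEPARATION_BETA) or not np.all(np.isfinite(se)):
        beta, se, ll = _ridge_logit(X, y, _RIDGE_LAMBDA)
        penalized = True
        converged = True
    k = len(names)
    return RSFModel(
        owner=dataset.owner,
        formula=formula,
        coef=dict(zip(names, map(float, beta))),
        se=dict(zip(names, map(float, se))),
        loglik=float(ll),
        k=k,
        aic=float(2 * k - 2 * ll),
        n_used=dataset.n_used,
        n_available=dataset.n_available,
        converged=converged,
        penalized=penalized,
    )


def fit_intercept_only(dataset: UseAvailableDataset) -> tuple[float, float]:
    """Closed-form Bernoulli log-likelihood at the label mean (diagnostic)."""
    y = dataset.data["used"].to_numpy(dtype=float)
    p = y.mean()
    ll = float(len(y) * (p * math.log(p) + (1 - p) * math.log(1 - p)))
    return math.log(p / (1 - p)), ll


# ---------------------------------------------------------------------------
# model selection across owners


def select_model(candidate_formulas, datasets):
    """Pick the structure minimizing cumulative-log-likelihood AIC.

    For each candidate the log-likelihoods of all owners are summed and the
    parameter count is ``k_per_owner * n_owners``.  Owners failing any
    candidate are dropped from every candidate for fairness.  Ties break
    toward fewer parameters.  Returns ``(top_formula, score_table)``.
    """
    candidates = [list(f) for f in candidate_formulas]
    if not candidates:
        raise InvalidArgumentError("empty candidate list")
    fits: dict[int, dict[str, RSFModel]] = {i: {} for i in range(len(candidates))}
    bad_owners: set[str] = set()
    for i, formula in enumerate(candidates):
        for ds in datasets:
            try:
                fits[i][ds.owner] = fit_rsf(ds, formula)
            except (InvalidArgumentError, FitFailureError):
                bad_owners.add(ds.owner)
    owners = [ds.owner for ds in datasets if ds.owner not in bad_owners]
    if not owners:
        raise FitFailureError("no owner fits every candidate")
    rows = []
    for i, formula in enumerate(candidates):
        cum_ll = sum(fits[i][o].loglik for o in owners)
        k_per = len(formula) + 1
        cum_k = k_per * len(owners)
        rows.append(
            {
                "formula": "+".join(formula),
                "k_per_owner": k_per,
                "n_owners": len(owners),
                "cum_loglik": cum_ll,
                "cum_k": cum_k,
                "aic": 2 * cum_k - 2 * cum_ll,
            }
        )
    table = pd.DataFrame(rows)
    best = 0
    for i in range(1, len(candidates)):
        if table.aic[i] < table.aic[best] - _AIC_TIE or (
            abs(table.aic[i] - table.aic[best]) <= _AIC_TIE
            and table.k_per_owner[i] < table.k_per_owner[best]
        ):
            best = i
    return candidates[best], table


# ---------------------------------------------------------------------------
# population aggregation


@dataclass
class PopulationRSF:
    """Weighted mean coefficients aggregated across owners."""

    covariates: list[str]
    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    weights: dict[str, float]
    n_owners: int

    def __post_init__(self):
        w = np.array(list(self.weights.values()))
        if not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
            raise InvalidArgumentError("weights must sum to 1")

    def to_dict(self) -> dict:
        return {
            "covariates": self.covariates,
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "ci_low": self.ci_low.tolist(),
            "ci_high": self.ci_high.tolist(),
            "weights": self.weights,
            "n_owners": self.n_owners,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


def aggregate_population(
    models: list[RSFModel],
    owner_pair_counts: dict[str, float] | None = None,
    owner_sample_sizes: dict[str, float] | None = None,
) -> PopulationRSF:
    """Two-stage weighted mean: weight_i ∝ pair_count_i × sample_size_i.

    ``owner_pair_counts`` defaults to 1 per owner and ``owner_sample_sizes``
    to each model's used-point count.  SE(mean) = sqrt(sum w_i^2 se_i^2);
    95% CI = mean ± 1.96 SE.
    """
    if not models:
        raise InvalidArgumentError("no models to aggregate")
    formula = models[0].formula
    for m in models[1:]:
        if m.formula != formula:
            raise InvalidArgumentError("all models must share a formula")
    w = np.array(
        [
            (owner_pair_counts or {}).get(m.owner, 1.0)
            * (owner_sample_sizes.get(m.owner, m.n_used) if owner_sample_sizes else m.n_used)
            for m in models
        ],
        dtype=float,
    )
    if w.sum() <= 0:
        raise InvalidArgumentError("weights must be positive")
    w = w / w.sum()
    B = np.stack([m.beta() for m in models])
    S = np.stack([m.beta_se() for m in models])
    beta = w @ B
    se = np.sqrt((w[:, None] ** 2 * S**2).sum(axis=0))
    lo = B.min(axis=0) - 1e-12
    hi = B.max(axis=0) + 1e-12
    if not ((beta >= lo) & (beta <= hi)).all():
        raise InvalidArgumentError("weighted mean escaped the coefficient envelope")
    return PopulationRSF(
        covariates=list(formula),
        beta=beta,
        se=se,
        ci_low=beta - 1.96 * se,
        ci_high=beta + 1.96 * se,
        weights={m.owner: float(wi) for m, wi in zip(models, w)},
        n_owners=len(models),
    )


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVResult:
    owner: str
    fold_rs: list[float]
    mean_rs: float
    n_bins: int

    def __post_init__(self):
        for r in self.fold_rs:
            if math.isfinite(r) and not -1 <= r <= 1:
                raise InvalidArgumentError("Spearman r outside [-1, 1]")


def crossvalidate(
    dataset: UseAvailableDataset,
    formula,
    k: int = 5,
    n_bins: int = 10,
    seed: int | None = None,
) -> CVResult:
    """K-fold used-point withholding with area-adjusted-frequency validation.

    Folds partition the used points (~20% withheld each for k=5); available
    points stay in every training set.  Withheld used points are scored,
    binned on the equal-interval grid of the available-point score range,
    and the Spearman correlation of bin rank vs the availability-adjusted
    frequency is reported per fold.
    """
    rng = np.random.default_rng(seed)
    used_idx = np.flatnonzero(dataset.data["used"].to_numpy() == 1)
    avail_mask = dataset.data["used"].to_numpy() == 0
    if len(used_idx) < k:
        raise InsufficientDataError(f"need at least {k} used points for {k} folds")
    perm = rng.permutation(used_idx)
    folds = np.array_split(perm, k)
    rs_values = []
    X_all = np.column_stack(
        [np.ones(len(dataset.data))] + [dataset.data[c].to_numpy(dtype=float) for c in list(formula)]
    )
    y_all = dataset.data["used"].to_numpy(dtype=float)
    for fold in folds:
        test_mask = np.zeros(len(y_all), dtype=bool)
        test_mask[fold] = True
        train_mask = ~test_mask
        sub = UseAvailableDataset(
            owner=dataset.owner,
            data=dataset.data.loc[train_mask].reset_index(drop=True),
            covariates=dataset.covariates,
            standardizers=dataset.standardizers,
            ratio=dataset.ratio,
            seed=dataset.seed,
        )
        model = fit_rsf(sub, formula)
        beta = np.array([model.coef["intercept"]] + [model.coef[c] for c in list(formula)])
        scores = X_all @ beta
        avail_scores = scores[avail_mask]
        lo, hi = float(avail_scores.min()), float(avail_scores.max())
        if hi <= lo:
            raise DegenerateInputError("available scores are constant; cannot bin")
        edges = np.linspace(lo, hi, n_bins + 1)
        a_counts, _ = np.histogram(avail_scores, bins=edges)
        u_counts, _ = np.histogram(np.clip(scores[test_mask], lo, hi), bins=edges)
        nonzero = a_counts > 0
        if nonzero.sum() < 2:
            raise DegenerateInputError("fewer than 2 populated bins")
        adj = u_counts[nonzero] / a_counts[nonzero]
        ranks = np.arange(n_bins)[nonzero]
        r, _ = spearmanr(ranks, adj)
        rs_values.append(float(r))
    finite = [r for r in rs_values if math.isfinite(r)]
    mean_rs = float(np.mean(finite)) if finite else float("nan")
    return CVResult(owner=dataset.owner, fold_rs=rs_values, mean_rs=mean_rs, n_bins=n_bins)


# ---------------------------------------------------------------------------
# prediction


def predict_surface(
    pop: PopulationRSF,
    env: EnvStack,
    date,
    standardizers: dict[str, tuple[float, float]],
) -> np.ndarray:
    """Relative-selection surface ``exp(beta · x_std)`` rescaled to [0, 1].

    Continuous covariates are standardized with the supplied parameters; a
    flat linear predictor yields a uniform 0.5 surface.
    """
    eta = np.zeros((env.grid.n_rows, env.grid.n_cols))
    for name, b in zip(pop.covariates, pop.beta):
        layer = env.layer(name, date).astype(float)
        if name in standardizers:
            mean, sd = standardizers[name]
            layer = (layer - mean) / sd
        eta = eta + b * layer
    w = np.exp(eta - eta.max())  # stable; rescaling removes the shift
    lo, hi = float(w.min()), float(w.max())
    if hi <= lo:
        return np.full_like(w, 0.5)
    return (w - lo) / (hi - lo)
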