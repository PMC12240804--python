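"""Random-forest protocol for identifying predictors of regenerating-forest age.

Pipeline: stratified sampling of pixels by age year -> predictor extraction
at the sampled cells -> removal of highly correlated predictors
(|r| > 0.9, greedy) -> train/test split (75/25) -> hyperparameter search
(ntree, mtry) under k-fold cross-validation -> held-out R²/RMSE ->
corrected-impurity variable importance (shadow permuted-copy scheme) with
permutation importance as a cross-check -> partial-dependence curves.

Corrected impurity here means: every predictor is accompanied by a permuted
copy ("shadow") carrying the same marginal distribution but no signal; the
reported score is the raw impurity importance minus the shadow's, which
removes the bias impurity measures have towards high-cardinality or
frequently split variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .stack_io import AgeMap

logger = logging.getLogger("regrowage")


@dataclass(frozen=True)
class RFConfig:
    train_fraction: float = 0.75
    cv_folds: int = 7
    ntree_grid: tuple = (100, 500, 1000, 1500)
    mtry_grid: tuple = tuple(range(3, 30))
    final_ntree: int = 500
    final_mtry: int = 18
    search: bool = True   # False: skip CV and use the final_* values directly
    corr_threshold: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ntree_grid or not self.mtry_grid:
            raise ValueError("hyperparameter grids must be nonempty")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class RFReport:
    region: str
    ntree: int
    mtry: int
    r2: float
    rmse: float
    n_train: int
    n_test: int
    cv_results: pd.DataFrame | None = None
    importance: pd.DataFrame | None = None
    partial_dependence: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Sampling and extraction
# ---------------------------------------------------------------------------

def stratified_sample(
    age_map: AgeMap,
    n_per_age: int = 10_000,
    seed: int = 0,
    age_range: tuple[int, int] = (3, 34),
) -> pd.DataFrame:
    """Sample up to ``n_per_age`` pixels uniformly without replacement per age year.

    Strata with fewer pixels than requested are exhausted; empty strata are
    logged and skipped.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    ages = age_map.ages
    frames = []
    for a in range(age_range[0], age_range[1] + 1):
        rr, cc = np.nonzero(ages == a)
        if rr.size == 0:
            logger.debug("stratified_sample: no pixels of age %d", a)
            continue
        take = min(n_per_age, rr.size)
        idx = rng.choice(rr.size, size=take, replace=False)
        x, y = age_map.georef.pixel_center(rr[idx], cc[idx])
        frames.append(pd.DataFrame({"row": rr[idx], "col": cc[idx],
                                    "x": x, "y": y, "age": a}))
    if not frames:
        return pd.DataFrame(columns=["row", "col", "x", "y", "age"])
    return pd.concat(frames, ignore_index=True)


def extract_predictors(
    points: pd.DataFrame,
    rasters: dict[str, np.ndarray],
    nodata: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Nearest-cell predictor lookup at the sampled pixels.

    Adds one column per raster; rows hitting a NODATA value (as given per
    raster in ``nodata``, or NaN) are dropped with a logged count.
    """
    out = points.copy()
    for name, arr in rasters.items():
        if name in out.columns:
            raise ValueError(f"predictor name collision: {name!r}")
        out[name] = np.asarray(arr)[points["row"].to_numpy(), points["col"].to_numpy()]
        nd = (nodata or {}).get(name)
        if nd is not None:
            out.loc[out[name] == nd, name] = np.nan
    n0 = len(out)
    out = out.dropna(subset=list(rasters)).reset_index(drop=True)
    if len(out) < n0:
        logger.info("extract_predictors: dropped %d rows with missing values", n0 - len(out))
    return out


# ---------------------------------------------------------------------------
# Correlation filter
# ---------------------------------------------------------------------------

def filter_correlated(
    table: pd.DataFrame,
    predictors: list[str],
    threshold: float = 0.9,
):
    """Greedy removal of highly correlated predictors.

    While any pair exceeds ``threshold`` in |Pearson r|: among the worst
    (highest |r|) pair, drop the member with the larger mean absolute
    correlation to the remaining predictors.  Returns
    ``(reduced_table, kept, removed_log)``.
    """
    kept = list(predictors)
    removed: list[tuple[str, str, float]] = []
    while len(kept) > 1:
        corr = table[kept].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= threshold:
            break
        mean_i = corr[i].sum() / (len(kept) - 1)
        mean_j = corr[j].sum() / (len(kept) - 1)
        drop = kept[i] if mean_i >= mean_j else kept[j]
        other = kept[j] if drop == kept[i] else kept[i]
        removed.append((drop, other, float(corr[i, j])))
        kept.remove(drop)
    if removed:
        logger.info("filter_correlated: removed %s", [r[0] for r in removed])
    drop_cols = [r[0] for r in removed]
    return table.drop(columns=drop_cols), kept, removed


# ---------------------------------------------------------------------------
# Tuning, training and evaluation
# ---------------------------------------------------------------------------

def _age_strata(y: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Decile labels of the response for stratified splitting/folding."""
    qs = np.quantile(y, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(np.unique(qs), y, side="left")


def tune_and_train(
    table: pd.DataFrame,
    predictors: list[str],
    config: RFConfig = RFConfig(),
    response: str = "age",
):
    """Split, tune by cross-validated RMSE, refit, evaluate held-out.

    Returns ``(model, report, splits)`` where ``splits`` is the
    ``(train_index, test_index)`` pair used (for downstream importance work).
    """
    if any(m > len(predictors) for m in config.mtry_grid) and config.search:
        mtry_grid = tuple(m for m in config.mtry_grid if m <= len(predictors))
        if not mtry_grid:
            raise ValueError("mtry grid entirely exceeds predictor count")
    else:
        mtry_grid = config.mtry_grid
    if not config.search and config.final_mtry > len(predictors):
        raise ValueError(
            f"mtry {config.final_mtry} exceeds predictor count {len(predictors)}")

    X = table[predictors].to_numpy(float)
    y = table[response].to_numpy(float)
    strata = _age_strata(y)
    # guard: stratified split needs >=2 per class
    binc = np.bincount(strata)
    strat_arg = strata if (binc[binc > 0] >= 2).all() else None
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, train_size=config.train_fraction, random_state=config.seed,
        stratify=strat_arg)
    Xtr, ytr = X[train_idx], y[train_idx]

    cv_rows = []
    if config.search:
        skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                              random_state=config.seed)
        tr_strata = strata[train_idx]
        folds = list(skf.split(Xtr, tr_strata))
        best = (np.inf, None)
        for ntree in config.ntree_grid:
            for mtry in mtry_grid:
                rmses = []
                for f_tr, f_va in folds:
                    m = RandomForestRegressor(
                        n_estimators=ntree, max_features=mtry,
                        random_state=config.seed, n_jobs=1)
                    m.fit(Xtr[f_tr], ytr[f_tr])
                    pred = m.predict(Xtr[f_va])
                    rmses.append(float(np.sqrt(mean_squared_error(ytr[f_va], pred))))
                cv_rmse = float(np.mean(rmses))
                cv_rows.append({"ntree": ntree, "mtry": mtry, "cv_rmse": cv_rmse})
                if cv_rmse < best[0]:
                    best = (cv_rmse, (ntree, mtry))
        ntree, mtry = best[1]
    else:
        ntree, mtry = config.final_ntree, config.final_mtry

    model = RandomForestRegressor(n_estimators=ntree, max_features=mtry,
                                  random_state=config.seed, n_jobs=1)
    model.fit(Xtr, ytr)
    pred = model.predict(X[test_idx])
    report = RFReport(
        region="all",
        ntree=ntree,
        mtry=mtry,
        r2=float(r2_score(y[test_idx], pred)),
        rmse=float(np.sqrt(mean_squared_error(y[test_idx], pred))),
        n_train=len(train_idx),
        n_test=len(test_idx),
        cv_results=pd.DataFrame(cv_rows) if cv_rows else None,
    )
    model.feature_names_ = list(predictors)
    return model, report, (train_idx, test_idx)


# ---------------------------------------------------------------------------
# Importance
# ---------------------------------------------------------------------------

def importance(
    model: RandomForestRegressor,
    table: pd.DataFrame,
    predictors: list[str],
    response: str = "age",
    seed: int = 0,
    n_repeats: int = 5,
) -> pd.DataFrame:
    """Corrected-impurity importance via shadow predictors + permutation check.

    A clone of the fitted model is refit on the data augmented with one
    permuted copy of every predictor; the corrected score for a predictor is
    its raw impurity importance minus its shadow's.  Permutation importance
    (mean decrease in R² on the same table) is reported alongside.
    """
    rng = np.random.default_rng(seed)
    X = table[predictors].to_numpy(float)
    y = table[response].to_numpy(float)
    shadows = np.column_stack([rng.permutation(X[:, j]) for j in range(X.shape[1])])
    X_aug = np.hstack([X, shadows])
    aug = clone(model)
    # keep the candidate-per-split fraction comparable after doubling columns
    if isinstance(model.max_features, (int, np.integer)):
        aug.set_params(max_features=min(2 * model.max_features, X_aug.shape[1]))
    aug.set_params(random_state=seed)
    aug.fit(X_aug, y)
    raw = aug.feature_importances_[: len(predictors)]
    shadow = aug.feature_importances_[len(predictors):]

    perm = permutation_importance(model, X, y, n_repeats=n_repeats,
                                  random_state=seed, n_jobs=1)
    out = pd.DataFrame(
        {
            "predictor": predictors,
            "corrected_impurity": raw - shadow,
            "raw_impurity": raw,
            "shadow_impurity": shadow,
            "permutation_importance": perm.importances_mean,
            "permutation_sd": perm.importances_std,
        }
    )
    return out.sort_values("corrected_impurity", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# Partial dependence
# ---------------------------------------------------------------------------

def partial_dependence(
    model: RandomForestRegressor,
    table: pd.DataFrame,
    predictor: str,
    predictors: list[str] | None = None,
    grid_points: int = 50,
) -> pd.DataFrame:
    """Mean model prediction as one predictor sweeps its observed range.

    Every row of the table is re-predicted with ``predictor`` clamped to each
    of ``grid_points`` equally spaced values between the observed min and max
    (endpoints included).  The returned frame carries the curve plus deciles
    of the predictor's data distribution (the rug).
    """
    predictors = predictors or getattr(model, "feature_names_", None)
    if predictors is None:
        raise ValueError("predictor name list required")
    if predictor not in predictors:
        raise KeyError(f"unknown predictor {predictor!r}")
    X = table[predictors].to_numpy(float)
    j = predictors.index(predictor)
    vals = table[predictor].to_numpy(float)
    grid = np.linspace(vals.min(), vals.max(), grid_points)
    means = np.empty(grid_points)
    Xc = X.copy()
    for k, v in enumerate(grid):
        Xc[:, j] = v
        means[k] = float(model.predict(Xc).mean())
    rug = np.quantile(vals, np.linspace(0, 1, grid_points))
    return pd.DataFrame({"predictor": predictor, "value": grid,
                         "mean_prediction": means, "data_quantile": rug})


# ---------------------------------------------------------------------------
# Full per-region protocol
# ---------------------------------------------------------------------------

def run_rf_protocol(
    table: pd.DataFrame,
    predictors: list[str],
    config: RFConfig = RFConfig(),
    response: str = "age",
    region_column: str | None = None,
    top_k_pd: int = 6,
) -> dict[str, RFReport]:
    """One model per region (or a pooled one), with importance and PD curves."""
    groups = ([("all", table)] if region_column is None
              else list(table.groupby(region_column, sort=True)))
    reports: dict[str, RFReport] = {}
    for region, sub in groups:
        sub = sub.reset_index(drop=True)
        reduced, kept, _ = filter_correlated(sub, predictors, config.corr_threshold)
        model, report, _ = tune_and_train(reduced, kept, config, response)
        report.region = str(region)
        report.importance = importance(model, reduced, kept, response, seed=config.seed)
        for name in report.importance["predictor"].head(top_k_pd):
            report.partial_dependence[name] = partial_dependence(
                model, reduced, name, kept)
        reports[str(region)] = report
    return reports
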