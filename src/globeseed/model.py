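"""Regression-forest modeling of standardized seed bank responses.

Full models regress diversity or density on the 31 environmental covariates
with a 100-tree random forest.  Variable importance is reported two ways:
increase in node purity (the total decrease in residual sum of squares from
splits on the variable, summed over all trees) and percent increase in MSE
when the variable's values are shuffled among each tree's out-of-bag
samples.  A noise-thresholded stepwise forward procedure then selects the
variables whose OOB-error decrease exceeds the variation produced by adding
shuffled-copy noise variables; final models use only the selected set.

Diagnostics: Monte-Carlo K-fold cross-validation (99 iterations withholding
10% by default), partial-dependence effect curves, an empirical
semivariogram on great-circle distances, Kruskal-Wallis biome contrasts and
a per-biome hemisphere comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.ensemble._forest import (
    _generate_unsampled_indices,
    _get_n_samples_bootstrap,
)

from .core import SeedBankRecord

__all__ = [
    "ForestFit",
    "SelectionResult",
    "CVResult",
    "PartialEffect",
    "Semivariogram",
    "fit_forest",
    "select_variables",
    "kfold_cv",
    "partial_effect",
    "empirical_semivariogram",
    "kruskal_wallis_by_biome",
    "hemisphere_comparison",
    "haversine_km",
]

EARTH_RADIUS_KM = 6371.0

# A minimum node size of 5 (the regression-forest tradition) regularizes
# single- and few-variable models; all features are candidates at each split,
# which keeps null predictors out of the trees and partial effects flat.
RF_MAX_FEATURES = 1.0
RF_MIN_SAMPLES_LEAF = 5


def _make_forest(n_trees: int, seed, oob_score: bool = True) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=n_trees,
        oob_score=oob_score,
        bootstrap=True,
        max_features=RF_MAX_FEATURES,
        min_samples_leaf=RF_MIN_SAMPLES_LEAF,
        random_state=seed,
        n_jobs=1,
    )


@dataclass
class ForestFit:
    """A fitted regression forest plus its OOB diagnostics."""

    model: RandomForestRegressor
    response_name: str
    predictor_names: list[str]
    n_trees: int
    oob_mse: float
    oob_r2: float  # percent-variance-explained analogue (OOB pseudo-R2)
    seed: int | None
    n_used: int
    n_dropped_missing: int
    importance: pd.DataFrame | None = None
    X_train: pd.DataFrame | None = None

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.model.predict(X[self.predictor_names].to_numpy())


def _complete_cases(X: pd.DataFrame, y: np.ndarray):
    mask = ~(X.isna().any(axis=1).to_numpy() | np.isnan(y))
    return X.loc[mask], y[mask], int((~mask).sum())


def _node_purity_importance(forest: RandomForestRegressor, n_features: int) -> np.ndarray:
    """Total RSS decrease per feature, summed over all split nodes and trees.

    sklearn stores per-node impurity as a (weighted) mean squared error, so
    the RSS gain of a split is w*i - w_l*i_l - w_r*i_r with w the weighted
    node sample count.
    """
    total = np.zeros(n_features)
    for est in forest.estimators_:
        t = est.tree_
        for node in range(t.node_count):
            left, right = t.children_left[node], t.children_right[node]
            if left == -1:  # leaf
                continue
            gain = (
                t.weighted_n_node_samples[node] * t.impurity[node]
                - t.weighted_n_node_samples[left] * t.impurity[left]
                - t.weighted_n_node_samples[right] * t.impurity[right]
            )
            total[t.feature[node]] += gain
    return total


def _oob_indices(forest: RandomForestRegressor, n_samples: int) -> list[np.ndarray]:
    n_boot = _get_n_samples_bootstrap(n_samples, forest.max_samples, None)
    return [
        _generate_unsampled_indices(est.random_state, n_samples, n_boot, None)
        for est in forest.estimators_
    ]


def _permutation_increase(
    forest: RandomForestRegressor,
    X: np.ndarray,
    y: np.ndarray,
    repeats: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mean over trees of (OOB MSE with feature shuffled - OOB MSE)."""
    n, p = X.shape
    oob = _oob_indices(forest, n)
    increase = np.zeros(p)
    n_trees_used = 0
    for est, idx in zip(forest.estimators_, oob):
        if len(idx) == 0:
            continue
        n_trees_used += 1
        Xo, yo = X[idx], y[idx]
        base = np.mean((est.predict(Xo) - yo) ** 2)
        for j in range(p):
            inc = 0.0
            for _ in range(repeats):
                Xp = Xo.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                inc += np.mean((est.predict(Xp) - yo) ** 2) - base
            increase[j] += inc / repeats
    return increase / max(n_trees_used, 1)


def fit_forest(
    X: pd.DataFrame,
    y: Sequence[float],
    response_name: str = "response",
    n_trees: int = 100,
    seed: int | None = None,
    permutation_repeats: int = 5,
    compute_importance: bool = True,
    keep_training_data: bool = True,
) -> ForestFit:
    """Fit a regression forest and compute both importance metrics.

    Rows with any missing predictor (or response) are dropped and counted.
    Refuses to fit on fewer than 10 complete rows.  The importance table has
    one row per predictor with ``node_purity`` (summed RSS gain),
    ``pct_inc_mse`` (percent OOB MSE increase under shuffling, averaged over
    ``permutation_repeats`` seeded shuffles per tree) and the rank under
    each metric.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    y = np.asarray(y, dtype=float)
    X, y, n_dropped = _complete_cases(X, y)
    if len(y) < 10:
        raise ValueError(f"refusing to fit forest on {len(y)} < 10 complete rows")
    forest = _make_forest(n_trees, seed)
    Xa = X.to_numpy(dtype=float)
    forest.fit(Xa, y)
    oob_pred = forest.oob_prediction_
    oob_mse = float(np.mean((oob_pred - y) ** 2))
    var_y = float(np.var(y))
    oob_r2 = 1.0 - oob_mse / var_y if var_y > 0 else 0.0
    fit = ForestFit(
        model=forest,
        response_name=response_name,
        predictor_names=list(X.columns),
        n_trees=n_trees,
        oob_mse=oob_mse,
        oob_r2=float(oob_r2),
        seed=seed,
        n_used=len(y),
        n_dropped_missing=n_dropped,
        X_train=X if keep_training_data else None,
    )
    if compute_importance:
        rng = np.random.default_rng(seed)
        node_purity = _node_purity_importance(forest, Xa.shape[1])
        inc = _permutation_increase(forest, Xa, y, permutation_repeats, rng)
        pct = 100.0 * inc / oob_mse if oob_mse > 0 else np.zeros_like(inc)
        table = pd.DataFrame(
            {
                "predictor": fit.predictor_names,
                "node_purity": node_purity,
                "pct_inc_mse": pct,
            }
        )
        table["rank_node_purity"] = (
            table["node_purity"].rank(ascending=False, method="min").astype(int)
        )
        table["rank_pct_inc_mse"] = (
            table["pct_inc_mse"].rank(ascending=False, method="min").astype(int)
        )
        fit.importance = table.set_index("predictor")
    return fit


@dataclass
class SelectionResult:
    """Outcome of the noise-thresholded stepwise forward selection."""

    candidates: list[str]  # stage-1 survivors, in importance order
    selected: list[str]
    step_decreases: dict[str, float]  # OOB-error decrease when each kept/tried
    noise_threshold: float
    stage1_importances: dict[str, float]
    stage1_noise_max: float
    diagnostics: dict = field(default_factory=dict)


def _oob_error(X: np.ndarray, y: np.ndarray, n_trees: int, seed: int) -> float:
    f = _make_forest(n_trees, seed)
    f.fit(X, y)
    return float(np.mean((f.oob_prediction_ - y) ** 2))


def select_variables(
    X: pd.DataFrame,
    y: Sequence[float],
    n_trees: int = 50,
    n_noise: int = 10,
    rank_forests: int = 2,
    rank_trees: int = 30,
    threshold_multiplier: float = 2.0,
    seed: int | None = None,
) -> SelectionResult:
    """Two-stage variable selection against shuffled-copy noise variables.

    Stage 1 ranks candidates by per-tree OOB permutation importance averaged
    over ``rank_forests`` seeded forests fitted on the candidates plus
    ``n_noise`` shuffled copies of randomly chosen candidates, and discards
    every candidate whose mean importance does not exceed the largest mean
    importance among the noise copies.

    Stage 2 adds survivors in rank order and keeps a variable only when the
    decrease in OOB error exceeds a threshold calibrated as
    mean + ``threshold_multiplier`` * sd of the absolute OOB-error changes
    observed when appending noise copies to the current model.  The first
    survivor must beat the intercept-only error (the response variance) by
    the same margin.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 candidate predictors")
    y = np.asarray(y, dtype=float)
    X, y, _ = _complete_cases(X, y)
    rng = np.random.default_rng(seed)
    names = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    n, p = Xa.shape

    # --- stage 1: permutation-importance ranking against shuffled copies
    imp_real = np.zeros(p)
    imp_noise = np.zeros(n_noise)
    for _ in range(rank_forests):
        src = rng.integers(0, p, size=n_noise)
        noise = np.column_stack([rng.permutation(Xa[:, j]) for j in src])
        Xaug = np.hstack([Xa, noise])
        f = _make_forest(rank_trees, int(rng.integers(2**31 - 1)), oob_score=False)
        f.fit(Xaug, y)
        inc = _permutation_increase(f, Xaug, y, repeats=1, rng=rng)
        imp_real += inc[:p] / rank_forests
        imp_noise += inc[p:] / rank_forests
    noise_max = float(imp_noise.max()) if n_noise else 0.0
    order = np.argsort(-imp_real)
    candidates = [names[j] for j in order if imp_real[j] > noise_max]
    stage1 = {names[j]: float(imp_real[j]) for j in order}
    if not candidates:
        return SelectionResult(
            candidates=[], selected=[], step_decreases={}, noise_threshold=np.nan,
            stage1_importances=stage1, stage1_noise_max=noise_max,
            diagnostics={"reason": "stage 1 discarded every candidate"},
        )

    # --- noise calibration for the forward threshold
    cand_idx = {name: names.index(name) for name in candidates}
    base_cols = Xa[:, [cand_idx[candidates[0]]]]
    seed_fit = int(rng.integers(2**31 - 1))
    e_top1 = _oob_error(base_cols, y, n_trees, seed_fit)
    deltas = []
    for _ in range(n_noise):
        j = int(rng.integers(0, p))
        noise_col = rng.permutation(Xa[:, j])[:, None]
        e_noise = _oob_error(np.hstack([base_cols, noise_col]), y, n_trees, seed_fit)
        deltas.append(abs(e_top1 - e_noise))
    deltas = np.asarray(deltas)
    threshold = float(deltas.mean() + threshold_multiplier * deltas.std(ddof=1))

    # --- stage 2: forward addition in rank order
    selected: list[str] = []
    step_decreases: dict[str, float] = {}
    e_current = float(np.var(y))  # intercept-only baseline
    current_cols: list[int] = []
    for name in candidates:
        trial = current_cols + [cand_idx[name]]
        e_trial = _oob_error(Xa[:, trial], y, n_trees, seed_fit)
        decrease = e_current - e_trial
        step_decreases[name] = float(decrease)
        if decrease > threshold:
            selected.append(name)
            current_cols = trial
            e_current = e_trial
    return SelectionResult(
        candidates=candidates,
        selected=selected,
        step_decreases=step_decreases,
        noise_threshold=threshold,
        stage1_importances=stage1,
        stage1_noise_max=noise_max,
        diagnostics={"final_oob_error": e_current, "top1_oob_error": e_top1},
    )


@dataclass
class CVResult:
    """Monte-Carlo K-fold cross-validation summary."""

    iterations: int
    holdout_fraction: float
    mse: np.ndarray  # per-iteration held-out MSE
    r2: np.ndarray  # per-iteration held-out R2
    seed: int | None

    @property
    def mean_mse(self) -> float:
        return float(np.mean(self.mse))

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.r2))

    @property
    def sd_r2(self) -> float:
        return float(np.std(self.r2, ddof=1))


def kfold_cv(
    X: pd.DataFrame,
    y: Sequence[float],
    n_trees: int = 100,
    iterations: int = 99,
    holdout_fraction: float = 0.10,
    seed: int | None = None,
) -> CVResult:
    """Repeated random holdout: ``iterations`` refits each withholding
    ``holdout_fraction`` of the rows (defaults 99 x 10%)."""
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if not (0 < holdout_fraction < 1):
        raise ValueError("holdout fraction must be in (0, 1)")
    y = np.asarray(y, dtype=float)
    X, y, _ = _complete_cases(X, y)
    n = len(y)
    n_hold = int(round(n * holdout_fraction))
    if n_hold < 2:
        raise ValueError(f"holdout of {n_hold} rows is too small")
    rng = np.random.default_rng(seed)
    Xa = X.to_numpy(dtype=float)
    mses = np.empty(iterations)
    r2s = np.empty(iterations)
    for i in range(iterations):
        perm = rng.permutation(n)
        hold, train = perm[:n_hold], perm[n_hold:]
        f = _make_forest(n_trees, int(rng.integers(2**31 - 1)), oob_score=False)
        f.fit(Xa[train], y[train])
        pred = f.predict(Xa[hold])
        resid = pred - y[hold]
        mses[i] = np.mean(resid**2)
        var_h = np.var(y[hold])
        r2s[i] = 1.0 - mses[i] / var_h if var_h > 0 else 1.0 if mses[i] == 0 else 0.0
    return CVResult(
        iterations=iterations, holdout_fraction=holdout_fraction,
        mse=mses, r2=r2s, seed=seed,
    )


@dataclass
class PartialEffect:
    """Partial-dependence curve: marginal effect of one predictor."""

    predictor: str
    grid: np.ndarray
    effect: np.ndarray
    extrapolated: np.ndarray  # bool per grid point, outside training range


def partial_effect(
    fit: ForestFit,
    predictor: str,
    grid: Sequence[float] | None = None,
    m: int = 25,
) -> PartialEffect:
    """Mean prediction with ``predictor`` clamped to each grid value and the
    other columns left at their observed training values."""
    if predictor not in fit.predictor_names:
        raise ValueError(f"{predictor!r} is not in the fitted model")
    if fit.X_train is None:
        raise ValueError("fit was built without keep_training_data")
    col = fit.X_train[predictor].to_numpy(dtype=float)
    if grid is None:
        grid = np.linspace(col.min(), col.max(), m)
    grid = np.asarray(grid, dtype=float)
    if len(grid) < 2:
        raise ValueError("grid must have at least 2 values")
    Xa = fit.X_train.to_numpy(dtype=float).copy()
    j = fit.predictor_names.index(predictor)
    effect = np.empty(len(grid))
    for i, g in enumerate(grid):
        Xa[:, j] = g
        effect[i] = float(np.mean(fit.model.predict(Xa)))
    extrapolated = (grid < col.min()) | (grid > col.max())
    return PartialEffect(
        predictor=predictor, grid=grid, effect=effect, extrapolated=extrapolated
    )


def haversine_km(
    lat1: np.ndarray, lon1: np.ndarray, lat2: np.ndarray, lon2: np.ndarray
) -> np.ndarray:
    """Great-circle distance in kilometers."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


@dataclass
class Semivariogram:
    """Empirical semivariance by great-circle lag bin."""

    bin_edges: np.ndarray  # km, length nbins + 1
    gamma: np.ndarray  # semivariance per bin, NaN where empty
    counts: np.ndarray  # pair count per bin
    sample_variance: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def range_estimate(self, sill_fraction: float = 0.95) -> float | None:
        """First lag where gamma reaches ``sill_fraction`` of the sill
        (mean gamma over the upper half of the bins)."""
        valid = ~np.isnan(self.gamma)
        if valid.sum() < 3:
            return None
        upper = self.gamma[valid][len(self.gamma[valid]) // 2:]
        sill = float(np.nanmean(upper))
        if sill <= 0:
            return None
        centers = self.bin_centers
        for c, g, ok in zip(centers, self.gamma, valid):
            if ok and g >= sill_fraction * sill:
                return float(c)
        return float(centers[valid][-1])


def empirical_semivariogram(
    coordinates: np.ndarray,
    values: Sequence[float],
    bin_edges: Sequence[float] | None = None,
    max_lag_km: float | None = None,
    n_bins: int = 15,
) -> Semivariogram:
    """gamma(h) = (1 / 2N(h)) * sum over pairs in bin h of (z_i - z_j)^2.

    ``coordinates`` is (n, 2) [latitude, longitude] in degrees; distances are
    great-circle km.  Default bins: ``n_bins`` equal-width bins to half the
    maximum pairwise distance.
    """
    coords = np.asarray(coordinates, dtype=float)
    z = np.asarray(values, dtype=float)
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite values")
    i, j = np.triu_indices(len(z), k=1)
    d = haversine_km(coords[i, 0], coords[i, 1], coords[j, 0], coords[j, 1])
    sq = (z[i] - z[j]) ** 2
    if bin_edges is None:
        if max_lag_km is None:
            max_lag_km = float(d.max()) / 2.0
        bin_edges = np.linspace(0.0, max_lag_km, n_bins + 1)
    bin_edges = np.asarray(bin_edges, dtype=float)
    nb = len(bin_edges) - 1
    gamma = np.full(nb, np.nan)
    counts = np.zeros(nb, dtype=int)
    which = np.digitize(d, bin_edges) - 1  # [edge_k, edge_k+1)
    for b in range(nb):
        mask = which == b
        counts[b] = int(mask.sum())
        if counts[b]:
            gamma[b] = float(sq[mask].sum() / (2.0 * counts[b]))
    return Semivariogram(
        bin_edges=bin_edges,
        gamma=gamma,
        counts=counts,
        sample_variance=float(np.var(z, ddof=1)),
    )


def kruskal_wallis_by_biome(
    records: Sequence[SeedBankRecord], measure: str
) -> dict:
    """Tie-corrected Kruskal-Wallis contrast of a measure across biomes."""
    groups: dict[str, list[float]] = {}
    for r in records:
        if r.measure == measure:
            groups.setdefault(r.biome, []).append(r.value)
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 biomes with records")
    labels = sorted(groups)
    samples = [np.asarray(groups[b], dtype=float) for b in labels]
    try:
        h, p = stats.kruskal(*samples)
    except ValueError:  # all values identical across groups
        h, p = 0.0, 1.0
    return {
        "H": float(h),
        "df": len(labels) - 1,
        "p": float(p),
        "medians": {b: float(np.median(groups[b])) for b in labels},
        "n": {b: len(groups[b]) for b in labels},
    }


def hemisphere_comparison(
    records: Sequence[SeedBankRecord], measure: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-biome rank test (Mann-Whitney U) of a measure between hemispheres.

    One row per biome present in both hemispheres; biomes confined to one
    hemisphere are listed with ``skipped=True``.  Latitude 0 counts as
    northern.
    """
    by_biome: dict[str, dict[str, list[float]]] = {}
    for r in records:
        if r.measure != measure:
            continue
        hemi = "N" if r.latitude >= 0 else "S"
        by_biome.setdefault(r.biome, {"N": [], "S": []})[hemi].append(r.value)
    rows = []
    for biome in sorted(by_biome):
        north, south = by_biome[biome]["N"], by_biome[biome]["S"]
        if not north or not south:
            rows.append(
                {
                    "biome": biome, "n_north": len(north), "n_south": len(south),
                    "mean_north": float(np.mean(north)) if north else np.nan,
                    "mean_south": float(np.mean(south)) if south else np.nan,
                    "p": np.nan, "significant": False, "skipped": True,
                }
            )
            continue
        _, p = stats.mannwhitneyu(north, south, alternative="two-sided")
        rows.append(
            {
                "biome": biome, "n_north": len(north), "n_south": len(south),
                "mean_north": float(np.mean(north)), "mean_south": float(np.mean(south)),
                "p": float(p), "significant": bool(p < alpha), "skipped": False,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "biome", "n_north", "n_south", "mean_north", "mean_south",
            "p", "significant", "skipped",
        ],
    )
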