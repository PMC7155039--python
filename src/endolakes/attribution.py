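"""Climate / human-use driver attribution via random-forest permutation VIMP.

A regression forest is grown on watershed-year rows (response: annual
inundated area; predictors: water-year ET, PR, RO, SWE plus irrigated
fraction and population density). Importance of a predictor is the
Breiman-Cutler permutation measure: the mean increase in out-of-bag squared
error when that predictor's column is shuffled, per tree over its OOB rows,
averaged across trees. Confidence intervals come from double-bootstrap
subsampling: VIMP is recomputed on B subsamples (without replacement, size
ceil(n^0.8)) and the subsampling variance is rescaled by m/n for a normal
interval around the full-sample estimate.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeRegressor

log = logging.getLogger(__name__)

#: Predictor columns of the standard design table.
PREDICTORS = ("ET", "PR", "RO", "SWE", "irrigated_frac", "density_km2")
RESPONSE = "area_ha"

#: Last modeled year for monsoonal watersheds (incomplete final water year).
MONSOONAL_LAST_YEAR = 2017


def assemble_design(
    water: pd.DataFrame,
    climate: pd.DataFrame,
    human: pd.DataFrame,
    region: str,
    response_class: str = "lake",
) -> pd.DataFrame:
    """Inner-join annual water, climate, and human-use tables per watershed-year.

    Climate inputs are assumed already summarized on the region's water year.
    Rows with any missing field are dropped (count logged); monsoonal rows are
    truncated at 2017.
    """
    if region not in ("snowmelt", "monsoonal"):
        raise ValueError(f"region must be snowmelt or monsoonal, got {region!r}")
    if "scene_available" in water.columns:
        water = water[water["scene_available"]]
    resp = water[water["class"] == response_class][["watershed", "year", "area_ha"]]
    if resp.empty:
        raise ValueError(f"no rows of class {response_class!r} in water series")

    climate = climate.copy()
    human = human.copy()
    if "watershed" in climate.columns and "watershed" in human.columns:
        w_ids = set(resp["watershed"])
        for name, other in (("climate", climate), ("human", human)):
            if w_ids - set(other["watershed"]):
                raise ValueError(f"{name} table missing watershed ids {w_ids - set(other['watershed'])}")
        keys = ["watershed", "year"]
    else:
        keys = ["year"]

    table = resp.merge(climate, on=keys, how="inner").merge(human, on=keys, how="inner")
    if region == "monsoonal":
        table = table[table["year"] <= MONSOONAL_LAST_YEAR]
    missing = [c for c in PREDICTORS if c not in table.columns]
    if missing:
        raise ValueError(f"design table lacks predictors: {missing}")
    cols = ["year", RESPONSE, *PREDICTORS]
    if "watershed" in table.columns:
        cols = ["watershed", *cols]
    table = table[cols]
    n0 = len(table)
    table = table.dropna().reset_index(drop=True)
    if n0 - len(table):
        log.info("assemble_design: dropped %d incomplete row(s)", n0 - len(table))
    if table.empty:
        raise ValueError("empty join between water, climate, and human tables")
    table.attrs["region"] = region
    table.attrs["response_class"] = response_class
    return table


@dataclass
class RegressionForest:
    """Bagged regression trees with per-tree OOB bookkeeping.

    Each tree is grown on a bootstrap resample with random per-split predictor
    subsetting (ceil(p/3) candidates, minimum node size 5 by default), and the
    indices it did NOT see are retained for OOB prediction and permutation
    importance.
    """

    n_trees: int = 5000
    max_features: int | None = None
    min_samples_leaf: int = 5
    seed: int | None = None

    trees: list = field(default_factory=list, repr=False)
    oob_indices: list = field(default_factory=list, repr=False)
    X_: np.ndarray | None = field(default=None, repr=False)
    y_: np.ndarray | None = field(default=None, repr=False)
    feature_names: tuple[str, ...] | None = None
    _vimp_seed: int | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RegressionForest":
        X = np.ascontiguousarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float64)
        n, p = X.shape
        mf = self.max_features or max(1, math.ceil(p / 3))
        ss = np.random.SeedSequence(self.seed)
        boot_seed, tree_seed, vimp_seed = ss.spawn(3)
        rng = np.random.default_rng(boot_seed)
        tree_states = np.random.default_rng(tree_seed).integers(0, 2**31 - 1, self.n_trees)
        self._vimp_seed = int(np.random.default_rng(vimp_seed).integers(0, 2**31 - 1))
        self.trees, self.oob_indices = [], []
        all_idx = np.arange(n)
        for t in range(self.n_trees):
            boot = rng.integers(0, n, n)
            oob = np.setdiff1d(all_idx, boot, assume_unique=False)
            tree = DecisionTreeRegressor(
                max_features=mf,
                min_samples_leaf=self.min_samples_leaf,
                random_state=int(tree_states[t]),
            )
            tree.fit(X[boot], y[boot], check_input=False)
            self.trees.append(tree)
            self.oob_indices.append(oob)
        self.X_, self.y_ = X, y
        return self

    def _predict_tree(self, tree, X32: np.ndarray) -> np.ndarray:
        # bypass sklearn's per-call validation; X32 must be C-contig float32
        return tree.tree_.predict(X32).ravel()

    def oob_prediction(self) -> np.ndarray:
        """Mean prediction per row over trees for which it was out of bag."""
        n = len(self.y_)
        total = np.zeros(n)
        count = np.zeros(n)
        for tree, oob in zip(self.trees, self.oob_indices):
            if oob.size == 0:
                continue
            total[oob] += self._predict_tree(tree, self.X_[oob])
            count[oob] += 1
        pred = np.full(n, np.nan)
        seen = count > 0
        pred[seen] = total[seen] / count[seen]
        return pred

    def oob_r2(self) -> float:
        pred = self.oob_prediction()
        seen = np.isfinite(pred)
        y = self.y_[seen]
        ss_res = float(((y - pred[seen]) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            return 0.0
        return 1.0 - ss_res / ss_tot

    def predict(self, X: np.ndarray) -> np.ndarray:
        X32 = np.ascontiguousarray(X, dtype=np.float32)
        out = np.zeros(len(X32))
        for tree in self.trees:
            out += self._predict_tree(tree, X32)
        return out / len(self.trees)


def fit_forest(
    table: pd.DataFrame,
    response: str = RESPONSE,
    predictors: Sequence[str] = PREDICTORS,
    n_trees: int = 5000,
    max_features: int | None = None,
    min_samples_leaf: int = 5,
    seed: int | None = None,
) -> RegressionForest:
    """Grow a regression forest on a design table."""
    predictors = tuple(predictors)
    if len(table) < 10:
        raise ValueError("need at least 10 rows to fit a forest")
    if len(predictors) < 2:
        raise ValueError("need at least 2 predictors")
    X = table[list(predictors)].to_numpy(dtype=np.float64)
    y = table[response].to_numpy(dtype=np.float64)
    forest = RegressionForest(
        n_trees=n_trees,
        max_features=max_features,
        min_samples_leaf=min_samples_leaf,
        seed=seed,
    )
    forest.fit(X, y)
    forest.feature_names = predictors
    return forest


def permutation_vimp(forest: RegressionForest) -> pd.DataFrame:
    """Breiman-Cutler permutation importance (point estimates).

    Per tree: permute each predictor over the tree's OOB rows and record the
    increase in OOB mean squared error; average across trees. Returns a frame
    with columns ``predictor``, ``vimp``, ``vimp_se`` (SE over trees), and
    ``rank`` (1 = most important).
    """
    if forest.X_ is None:
        raise ValueError("forest is not fitted")
    X, y = forest.X_, forest.y_
    p = X.shape[1]
    rng = np.random.default_rng(forest._vimp_seed)
    increases = np.zeros((len(forest.trees), p))
    used = np.zeros(len(forest.trees), dtype=bool)
    for t, (tree, oob) in enumerate(zip(forest.trees, forest.oob_indices)):
        if oob.size == 0:
            continue
        used[t] = True
        Xo = X[oob]
        yo = y[oob]
        base = float(np.mean((forest._predict_tree(tree, Xo) - yo) ** 2))
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
            err = float(np.mean((forest._predict_tree(tree, Xp) - yo) ** 2))
            increases[t, j] = err - base
    inc = increases[used]
    vimp = inc.mean(axis=0)
    se = inc.std(axis=0, ddof=1) / math.sqrt(len(inc)) if len(inc) > 1 else np.zeros(p)
    names = forest.feature_names or tuple(f"x{j}" for j in range(p))
    order = np.argsort(-vimp)
    ranks = np.empty(p, dtype=int)
    ranks[order] = np.arange(1, p + 1)
    return pd.DataFrame(
        {"predictor": names, "vimp": vimp, "vimp_se": se, "rank": ranks}
    )


def vimp_confidence(
    table: pd.DataFrame,
    response: str = RESPONSE,
    predictors: Sequence[str] = PREDICTORS,
    B: int = 500,
    alpha: float = 0.05,
    seed: int | None = None,
    n_trees: int = 1000,
    subsample_trees: int = 500,
    min_samples_leaf: int = 5,
) -> pd.DataFrame:
    """Permutation VIMP with double-bootstrap subsampling intervals.

    The point estimate comes from a forest of ``n_trees``; each of the B
    subsamples (without replacement, size ceil(n^0.8)) refits a reduced forest
    of ``subsample_trees`` trees. The CI is a normal interval around the point
    estimate with SE = sqrt(m/n * var(subsample VIMPs)).
    """
    predictors = tuple(predictors)
    n = len(table)
    if n < 20:
        raise ValueError("subsampling confidence intervals need >=20 rows")
    if B < 50:
        warnings.warn(f"B={B} subsamples is low; intervals may be unstable")
    ss = np.random.SeedSequence(seed)
    point_seed, sub_seed = ss.spawn(2)
    forest = fit_forest(
        table, response, predictors,
        n_trees=n_trees, min_samples_leaf=min_samples_leaf,
        seed=int(point_seed.generate_state(1)[0]),
    )
    point = permutation_vimp(forest)

    m = math.ceil(n**0.8)
    rng = np.random.default_rng(sub_seed)
    sub_vimps = np.zeros((B, len(predictors)))
    for b in range(B):
        idx = rng.choice(n, size=m, replace=False)
        sub = table.iloc[idx]
        f_b = fit_forest(
            sub, response, predictors,
            n_trees=subsample_trees, min_samples_leaf=min_samples_leaf,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        sub_vimps[b] = permutation_vimp(f_b)["vimp"].to_numpy()

    se = np.sqrt((m / n) * sub_vimps.var(axis=0, ddof=1))
    z = stats.norm.ppf(1 - alpha / 2)
    out = point.copy()
    out["lo"] = out["vimp"] - z * se
    out["hi"] = out["vimp"] + z * se
    out["subsample_se"] = se
    out.attrs["B"] = B
    out.attrs["subsample_size"] = m
    out.attrs["alpha"] = alpha
    return out


def rank_predictors(
    results: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Order predictors by VIMP across watersheds with quartile summaries.

    ``results`` maps watershed (or panel) id -> a VIMP frame. Within each
    panel VIMP is standardized by its maximum so importance is comparable
    across panels; the report gives the median, quartiles, and 5th/95th
    percentiles of standardized VIMP per predictor, ordered by median.
    """
    if not results:
        raise ValueError("no VIMP results supplied")
    rows = []
    for panel, frame in results.items():
        peak = frame["vimp"].max()
        scale = peak if peak > 0 else 1.0
        for _, r in frame.iterrows():
            rows.append(
                {"panel": panel, "predictor": r["predictor"], "std_vimp": r["vimp"] / scale}
            )
    long = pd.DataFrame(rows)
    report = (
        long.groupby("predictor")["std_vimp"]
        .agg(
            median="median",
            q25=lambda s: s.quantile(0.25),
            q75=lambda s: s.quantile(0.75),
            p05=lambda s: s.quantile(0.05),
            p95=lambda s: s.quantile(0.95),
            mean="mean",
        )
        .sort_values("median", ascending=False)
        .reset_index()
    )
    report["rank"] = np.arange(1, len(report) + 1)
    return report


def plot_vimp(report: pd.DataFrame, path: str) -> None:
    """Horizontal quartile-box summary of standardized VIMP per predictor."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 0.6 * len(report) + 1.5))
    ypos = np.arange(len(report))[::-1]
    for y, (_, row) in zip(ypos, report.iterrows()):
        ax.plot([row["p05"], row["p95"]], [y, y], color="0.6", lw=1)
        ax.add_patch(
            plt.Rectangle(
                (row["q25"], y - 0.25), row["q75"] - row["q25"], 0.5,
                facecolor="#7da7c4", edgecolor="k", lw=0.8,
            )
        )
        ax.plot([row["median"]] * 2, [y - 0.25, y + 0.25], color="k", lw=2)
    ax.set_yticks(ypos)
    ax.set_yticklabels(report["predictor"])
    ax.set_xlabel("standardized VIMP")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
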