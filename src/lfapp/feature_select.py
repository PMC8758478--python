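"""Boruta all-relevant feature selection and the Boruta-vs-DEA contrast.

A from-scratch implementation of the shadow-feature scheme: each run
appends an independently permuted copy of every undecided real feature,
fits a random forest, scores a "hit" for each real feature whose
out-of-bag permutation importance exceeds the best shadow importance,
and decides features by exact binomial tail tests against
Binomial(n_runs, 1/2) with Bonferroni correction over the starting
feature count. Importance Z-scores are reported both as a feature's own
history mean/SD (`z_history`, the ranking statistic) and as a
population Z across features (`z_population`).

`compare_rankings` contrasts the Boruta ranking with a parametric DEA
ranking on the same genes and reports, per confirmed feature, how much
of the opposite-group signal is concentrated in its few most extreme
samples — the outlier structure that makes tree ensembles and
count-model tests disagree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .transcriptomics import DEAResult

__all__ = [
    "BorutaDecision",
    "RankComparison",
    "ensemble_importance",
    "boruta_select",
    "boruta_regress_pathology",
    "min_hits_to_confirm",
    "compare_rankings",
    "z_cumulative_probability",
]


# ---------------------------------------------------------------------------
# Random-forest OOB permutation importance
# ---------------------------------------------------------------------------

def _oob_permutation_importance(forest, x: np.ndarray, y: np.ndarray,
                                task: str, rng: np.random.Generator) -> np.ndarray:
    """Mean over trees of the OOB permutation importance of every feature.

    For each tree, the decrease in OOB accuracy (classification) or the
    increase in OOB mean squared error (regression) when one feature column
    is permuted among the tree's out-of-bag samples. Only features actually
    used by a tree's splits can change its predictions, so all other
    features contribute exactly zero for that tree; predictions go through
    the fitted trees' internal apply() for speed.
    """
    n_samples, n_features = x.shape
    imp = np.zeros(n_features)
    x32 = np.ascontiguousarray(x, dtype=np.float32)
    is_clf = task == "classify"
    for tree, inbag in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.setdiff1d(np.arange(n_samples), inbag)
        if oob.size == 0:
            continue
        x_oob = np.ascontiguousarray(x32[oob])
        y_oob = y[oob]
        t = tree.tree_
        leaves = t.apply(x_oob)
        if is_clf:
            pred = np.argmax(t.value[leaves, 0, :], axis=1)
            base = np.mean(pred == y_oob)
        else:
            pred = t.value[leaves, 0, 0]
            base = -np.mean((pred - y_oob) ** 2)
        used = np.unique(t.feature[t.feature >= 0])
        perm = rng.permutation(oob.size)
        for f in used:
            saved = x_oob[:, f].copy()
            x_oob[:, f] = saved[perm]
            leaves = t.apply(x_oob)
            if is_clf:
                pred = np.argmax(t.value[leaves, 0, :], axis=1)
                score = np.mean(pred == y_oob)
            else:
                pred = t.value[leaves, 0, 0]
                score = -np.mean((pred - y_oob) ** 2)
            x_oob[:, f] = saved
            imp[f] += base - score
    return imp / len(forest.estimators_)


def ensemble_importance(x: np.ndarray, y: np.ndarray, task: str = "classify",
                        n_trees: int = 300, seed: int = 0) -> np.ndarray:
    """Per-feature random-forest OOB permutation importance.

    Classification uses the OOB accuracy decrease, regression the OOB MSE
    increase, averaged over trees. Deterministic given `seed`. Noise
    features get importances centred on zero (the statistic is signed).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.shape[0] < 10:
        raise ValueError("need at least 10 samples")
    rng = np.random.default_rng(seed)
    rf_seed = int(rng.integers(0, 2 ** 31 - 1))
    if task == "classify":
        classes, y_enc = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise ValueError("labels are constant")
        forest = RandomForestClassifier(n_estimators=n_trees, max_features="sqrt",
                                        bootstrap=True, random_state=rf_seed,
                                        n_jobs=1)
        forest.fit(x, y_enc)
        return _oob_permutation_importance(forest, x, y_enc, task, rng)
    if task == "regress":
        y = y.astype(float)
        if np.var(y) == 0:
            raise ValueError("labels are constant")
        forest = RandomForestRegressor(n_estimators=n_trees, max_features="sqrt",
                                       bootstrap=True, random_state=rf_seed,
                                       n_jobs=1)
        forest.fit(x, y)
        return _oob_permutation_importance(forest, x, y, task, rng)
    raise ValueError("task must be 'classify' or 'regress'")


# ---------------------------------------------------------------------------
# Boruta
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BorutaDecision:
    """Per-feature Boruta outcome.

    `table` columns: feature, status (confirmed/tentative/rejected), hits,
    n_runs, z_history, z_population, rank (descending z_history among all
    features). `importance_history` maps feature -> list of per-run
    importances while the feature was undecided.
    """

    table: pd.DataFrame
    importance_history: dict[str, list[float]]
    n_runs: int
    alpha: float

    @property
    def confirmed(self) -> list[str]:
        t = self.table
        return list(t.loc[t["status"] == "confirmed", "feature"])


def min_hits_to_confirm(n_runs: int, alpha: float, n_features: int) -> int:
    """Smallest hit count whose upper binomial tail clears Bonferroni.

    Returns the least k with P(X >= k | n_runs, 1/2) <= alpha / n_features,
    or n_runs + 1 if no count suffices.
    """
    thresh = alpha / n_features
    for k in range(n_runs + 1):
        if stats.binom.sf(k - 1, n_runs, 0.5) <= thresh:
            return k
    return n_runs + 1


def boruta_select(x, y, task: str = "classify", max_runs: int = 100,
                  alpha: float = 0.05, seed: int = 0, n_trees: int = 300,
                  min_shadows: int = 5, resolve_tentative: bool = True,
                  feature_names: list[str] | None = None) -> BorutaDecision:
    """Shadow-feature all-relevant selection over random-forest importances.

    Each run appends one independently permuted shadow copy of every
    undecided real feature (at least `min_shadows` shadows), computes OOB
    permutation importances, and scores a hit for every undecided real
    feature whose importance exceeds the maximum shadow importance. After
    each run, features whose hit count clears the Bonferroni-corrected
    binomial upper tail (alpha over the starting feature count) are
    confirmed; those clearing the lower tail are rejected and leave the
    pool. Stops when all features are decided or `max_runs` is reached.

    Remaining tentative features are optionally resolved by comparing their
    median importance history against the median of the per-run shadow
    maxima. Two importance Z-scores are reported: z_history (mean/SD of a
    feature's own importance history) and z_population (how many SDs a
    feature's mean importance sits above the mean feature's); ranks are by
    descending z_population with z_history as tie-break.
    """
    if max_runs < 10:
        raise ValueError("max_runs must be >= 10")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if np.isnan(x).any():
        raise ValueError("feature matrix contains missing values")
    n_samples, m = x.shape
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(m)]
    rng = np.random.default_rng(seed)

    undecided = np.ones(m, dtype=bool)
    status = np.array(["tentative"] * m, dtype=object)
    hits = np.zeros(m, dtype=int)
    runs_participated = np.zeros(m, dtype=int)
    history: dict[str, list[float]] = {name: [] for name in feature_names}
    shadow_max_history: list[float] = []

    k_confirm_cache: dict[int, int] = {}

    n_runs_done = 0
    for _ in range(max_runs):
        idx = np.flatnonzero(undecided)
        if idx.size == 0:
            break
        # rejected features leave the model; confirmed ones stay in it
        active = np.flatnonzero(status != "rejected")
        # shadows: one permuted copy per undecided feature, at least min_shadows
        shadow_cols = [x[rng.permutation(n_samples), j] for j in idx]
        while len(shadow_cols) < min_shadows:
            j = idx[int(rng.integers(0, idx.size))]
            shadow_cols.append(x[rng.permutation(n_samples), j])
        x_run = np.column_stack([x[:, active]] + shadow_cols)
        imp = ensemble_importance(x_run, y, task=task, n_trees=n_trees,
                                  seed=int(rng.integers(0, 2 ** 31 - 1)))
        real_imp = imp[:active.size]
        shadow_best = float(np.max(imp[active.size:]))
        shadow_max_history.append(shadow_best)
        und_mask = undecided[active]
        hits[active[und_mask]] += real_imp[und_mask] > shadow_best
        runs_participated[active] += 1
        for j, v in zip(active, real_imp):
            history[feature_names[j]].append(float(v))
        n_runs_done += 1

        # binomial decisions (Bonferroni over the starting feature count)
        for j in idx:
            n_j = runs_participated[j]
            if n_j not in k_confirm_cache:
                k_confirm_cache[n_j] = min_hits_to_confirm(n_j, alpha, m)
            k_conf = k_confirm_cache[n_j]
            if hits[j] >= k_conf:
                status[j] = "confirmed"
                undecided[j] = False
            elif stats.binom.cdf(hits[j], n_j, 0.5) <= alpha / m:
                status[j] = "rejected"
                undecided[j] = False

    if n_runs_done > 0 and resolve_tentative and undecided.any():
        shadow_median = float(np.median(shadow_max_history))
        for j in np.flatnonzero(undecided):
            med = np.median(history[feature_names[j]])
            if med > shadow_median:
                status[j] = "confirmed"
            # else stays tentative

    z_hist = np.zeros(m)
    means = np.zeros(m)
    for j, name in enumerate(feature_names):
        h = np.asarray(history[name], dtype=float)
        if h.size:
            means[j] = h.mean()
            sd = h.std(ddof=1) if h.size > 1 else 0.0
            z_hist[j] = means[j] / sd if sd > 0 else 0.0
    pop_sd = means.std(ddof=1) if m > 1 else 0.0
    z_pop = (means - means.mean()) / pop_sd if pop_sd > 0 else np.zeros(m)

    # rank by the population Z ("SDs more important than the mean feature"),
    # ties broken by the history Z
    order = np.lexsort((-z_hist, -z_pop))
    rank = np.empty(m, dtype=int)
    rank[order] = np.arange(1, m + 1)

    table = pd.DataFrame({
        "feature": feature_names,
        "status": status,
        "hits": hits,
        "n_runs": runs_participated,
        "z_history": z_hist,
        "z_population": z_pop,
        "rank": rank,
    })
    if n_runs_done == max_runs and not (table["status"] != "tentative").any():
        import warnings
        warnings.warn("max_runs exhausted before any decision; all features tentative")
    return BorutaDecision(table=table, importance_history=history,
                          n_runs=n_runs_done, alpha=alpha)


def boruta_regress_pathology(x, burden, max_runs: int = 100, alpha: float = 0.05,
                             seed: int = 0, **kwargs) -> BorutaDecision:
    """Boruta in regression mode against a continuous pathology burden."""
    return boruta_select(x, np.asarray(burden, dtype=float), task="regress",
                         max_runs=max_runs, alpha=alpha, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# Ranking comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankComparison:
    """Boruta-vs-DEA ranking contrast on a shared gene universe.

    `table` columns: feature, boruta_rank, dea_rank, divergence
    (dea_rank - boruta_rank; large positive = feature the forest values
    far more than the count model). `overlap` counts confirmed features
    that are also FDR-significant DEGs. `outlier_sensitivity` gives, for
    each confirmed feature, the fraction of its total opposite-group
    signal carried by that group's top-k samples.
    """

    table: pd.DataFrame
    overlap: dict[str, float]
    outlier_sensitivity: pd.DataFrame | None


def compare_rankings(boruta: BorutaDecision, dea: DEAResult, top_k: int = 10,
                     fdr_cutoff: float = 0.05, counts: pd.DataFrame | None = None,
                     groups: pd.Series | None = None,
                     n_outlier: int = 4) -> RankComparison:
    """Contrast Boruta z-score ranks with DEA FDR ranks gene by gene.

    Requires the two analyses to share one gene universe. When `counts`
    (genes x samples) and `groups` are given, the outlier-sensitivity
    table reports, for each confirmed feature, the share of its total
    signal in the group opposite its fold-change direction that is
    concentrated in that group's `n_outlier` highest samples.
    """
    bt = boruta.table.set_index("feature")
    dt = dea.table.set_index("gene_id")
    if set(bt.index) != set(dt.index):
        raise ValueError("Boruta and DEA gene universes differ")
    dt = dt.loc[bt.index]

    table = pd.DataFrame({
        "feature": bt.index,
        "boruta_rank": bt["rank"].to_numpy(),
        "dea_rank": dt["rank"].to_numpy(),
    })
    table["divergence"] = table["dea_rank"] - table["boruta_rank"]

    confirmed = set(boruta.confirmed)
    degs = set(dt.index[dt["fdr"] < fdr_cutoff])
    overlap = {
        "n_confirmed": float(len(confirmed)),
        "n_degs": float(len(degs)),
        "n_overlap": float(len(confirmed & degs)),
        "top_k": float(top_k),
        "n_top_k_shared": float(len(
            set(table.nsmallest(top_k, "boruta_rank")["feature"])
            & set(table.nsmallest(top_k, "dea_rank")["feature"]))),
    }

    outlier_tab = None
    if counts is not None and groups is not None:
        groups = pd.Series(list(groups), index=counts.columns)
        rows = []
        for feat in sorted(confirmed):
            lfc = float(dt.loc[feat, "log2fc"])
            # opposite group: where the gene is lower on average
            level_means = {g: counts.loc[feat, groups == g].mean()
                           for g in pd.unique(groups)}
            opposite = min(level_means, key=level_means.get)
            vals = counts.loc[feat, groups == opposite].to_numpy(dtype=float)
            total = vals.sum()
            top = np.sort(vals)[::-1][:n_outlier].sum()
            rows.append({"feature": feat, "log2fc": lfc,
                         "opposite_group": opposite,
                         "top_sample_share": top / total if total > 0 else 0.0})
        outlier_tab = pd.DataFrame(rows)

    return RankComparison(table=table, overlap=overlap,
                          outlier_sensitivity=outlier_tab)


def z_cumulative_probability(z: float) -> float:
    """Standard-normal cumulative probability Phi(z)."""
    return float(stats.norm.cdf(z))
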