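"""Event-level cognitive-load features, boosted trees, and SHAP summaries.

Each modeling row expands an encounter trace into per-event-type features:
the average dwell time at an event type, the number of loops back to it
(occurrences minus one), and whether it was visited at all. Most providers
touch only a subset of the event catalog, so the matrix is mostly zeros.

A gradient-boosted decision-tree classifier (learning rate 0.1, stratified
70/15/15 train/validation/test splits, validation-based early stopping)
predicts initiation; the procedure repeats over fresh splits to give an
AUROC distribution with a percentile 95% CI.

Attribution uses exact Shapley values computed against a fixed
*zero-engagement reference row* (the counterfactual provider who touched
no events): for each row, the margin difference f(x) - f(reference) is
decomposed exactly across features (local accuracy holds to machine
precision). Attributing against a fixed reference — rather than the
self-centered path-dependent decomposition — makes the *sign* of a
feature's mean attribution meaningful: a monotone-increasing dependence
yields a positive mean, whereas any self-centered mean SHAP is ~0 by
construction for additive effects. Signed mean SHAP gives each feature's
direction, mean |SHAP| its global importance, and mean |SHAP| normalized
across features its relative contribution, also aggregated per metric kind
(avg time / loops / presence). The closed-form per-leaf computation is
validated in the test suite against brute-force Shapley subset enumeration.
"""

from __future__ import annotations

import warnings

import lightgbm as lgb
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .audit_log import DEFAULT_GAP_MINUTES

FEATURE_KINDS = ("avg_time_sec", "n_loops", "presence")
_SEP = "::"


def feature_name(event_type: str, kind: str) -> str:
    return f"{event_type}{_SEP}{kind}"


def split_feature_name(name: str) -> tuple[str, str]:
    event, kind = name.rsplit(_SEP, 1)
    return event, kind


def build_event_features(
    events: pd.DataFrame,
    gap_minutes: float = DEFAULT_GAP_MINUTES,
    drop_empty: bool = True,
) -> pd.DataFrame:
    """Per-encounter, per-event-type feature matrix.

    For each (encounter, event type): ``avg_time_sec`` = mean dwell over
    that type's occurrences (dwell = gap to the next event within the same
    segment; segment-final occurrences carry none), ``n_loops`` =
    occurrences - 1, ``presence`` = 1. Unvisited event types are zero in
    all three columns. Indexed by encounter_id.
    """
    if events.empty:
        raise ValueError("empty event log")
    df = events.sort_values(["encounter_id", "timestamp"], kind="stable")
    ts = df["timestamp"].astype("datetime64[s]").astype("int64").to_numpy()
    enc = df["encounter_id"].to_numpy()
    same = np.concatenate(([False], enc[1:] == enc[:-1]))
    gap_prev = np.diff(ts, prepend=ts[0]).astype(float)
    within = same & (gap_prev <= gap_minutes * 60.0)
    # dwell of row i = gap to row i+1 when that gap stays inside the segment
    dwell = np.full(len(df), np.nan)
    dwell[:-1] = np.where(within[1:], gap_prev[1:], np.nan)

    work = pd.DataFrame(
        {
            "encounter_id": df["encounter_id"].to_numpy(),
            "event_type": df["event_type"].to_numpy(),
            "dwell": dwell,
        }
    )
    g = work.groupby(["encounter_id", "event_type"], sort=True)
    agg = g.agg(count=("dwell", "size"), dwell_mean=("dwell", "mean"))
    agg["dwell_mean"] = agg["dwell_mean"].fillna(0.0)
    agg["loops"] = agg["count"] - 1

    avg = agg["dwell_mean"].unstack(fill_value=0.0)
    loops = agg["loops"].unstack(fill_value=0).astype(float)
    presence = (agg["count"] > 0).unstack(fill_value=False).astype(float)

    parts = []
    for frame, kind in ((avg, "avg_time_sec"), (loops, "n_loops"), (presence, "presence")):
        frame = frame.copy()
        frame.columns = [feature_name(c, kind) for c in frame.columns]
        parts.append(frame)
    X = pd.concat(parts, axis=1)
    X = X[sorted(X.columns)]
    if drop_empty:
        empty = [c for c in X.columns if (X[c] == 0).all()]
        if empty:
            warnings.warn(f"dropping {len(empty)} all-zero feature columns", stacklevel=2)
            X = X.drop(columns=empty)
    X.index.name = "encounter_id"
    return X


# --------------------------------------------------------------------------
# Baseline Shapley values for LightGBM trees against a single reference row.
#
# For one tree and one coalition S, the value function mixes the explained
# row x (features in S) with the reference z (features outside S). A leaf
# with path constraints satisfied only by x on feature set Ux and only by z
# on feature set Uz is reached exactly when Ux <= S and S does not meet Uz,
# so its Shapley contribution has the closed form
#   phi_j += w * (a-1)! b! / (a+b)!   for j in Ux     (a=|Ux|, b=|Uz|)
#   phi_j -= w * a! (b-1)! / (a+b)!   for j in Uz
# Features whose constraints both (or neither) points satisfy contribute
# nothing to phi_j for that leaf.
# --------------------------------------------------------------------------

_MAX_PATH = 64
_LOG_FACT = np.cumsum(np.concatenate(([0.0], np.log(np.arange(1, 2 * _MAX_PATH)))))


def _shapley_leaf_weight(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(a-1)! b! / (a+b)! elementwise, a >= 1."""
    return np.exp(_LOG_FACT[a - 1] + _LOG_FACT[b] - _LOG_FACT[a + b])


def _iter_leaves(node: dict, path: list):
    if "leaf_value" in node:
        yield node["leaf_value"], list(path)
        return
    feat, thr = node["split_feature"], node["threshold"]
    path.append((feat, thr, True))
    yield from _iter_leaves(node["left_child"], path)
    path.pop()
    path.append((feat, thr, False))
    yield from _iter_leaves(node["right_child"], path)
    path.pop()


def _accumulate_tree(
    root: dict, X: np.ndarray, z: np.ndarray, phi: np.ndarray
) -> None:
    n = X.shape[0]
    for leaf_value, path in _iter_leaves(root, []):
        if not path:  # constant tree: no feature credit
            continue
        # group constraints by feature: satisfied iff all node tests pass
        sat_x: dict[int, np.ndarray] = {}
        sat_z: dict[int, bool] = {}
        for feat, thr, go_left in path:
            cx = X[:, feat] <= thr if go_left else X[:, feat] > thr
            cz = z[feat] <= thr if go_left else z[feat] > thr
            sat_x[feat] = cx if feat not in sat_x else (sat_x[feat] & cx)
            sat_z[feat] = bool(cz) if feat not in sat_z else (sat_z[feat] and bool(cz))
        feats = list(sat_x)
        x_only = np.empty((len(feats), n), dtype=bool)
        z_only = np.empty((len(feats), n), dtype=bool)
        reachable = np.ones(n, dtype=bool)
        for i, feat in enumerate(feats):
            cx, cz = sat_x[feat], sat_z[feat]
            x_only[i] = cx & (not cz)
            z_only[i] = (~cx) & cz
            reachable &= cx | cz
        if not reachable.any():
            continue
        a = x_only.sum(axis=0)
        b = z_only.sum(axis=0)
        for i, feat in enumerate(feats):
            pos = reachable & x_only[i]
            if pos.any():
                phi[pos, feat] += leaf_value * _shapley_leaf_weight(a[pos], b[pos])
            neg = reachable & z_only[i]
            if neg.any():
                phi[neg, feat] -= leaf_value * _shapley_leaf_weight(b[neg], a[neg])


def baseline_shap(
    booster: lgb.Booster, X: np.ndarray, reference: np.ndarray
) -> np.ndarray:
    """Exact Shapley attribution of f(x) - f(reference) on the raw margin.

    Returns an (n, p+1) array; the last column is the base value
    f(reference). Row sums of the full array equal the raw-score
    predictions exactly (local accuracy).
    """
    X = np.asarray(X, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    n, p = X.shape
    if reference.shape != (p,):
        raise ValueError("reference must have one value per feature")
    phi = np.zeros((n, p + 1))
    dump = booster.dump_model()
    for tree in dump["tree_info"]:
        _accumulate_tree(tree["tree_structure"], X, reference, phi)
    phi[:, -1] = booster.predict(reference[None, :], raw_score=True)[0]
    return phi


class EventShapModel(BaseEstimator):
    """Repeated boosted-tree fits with TreeSHAP attribution summaries.

    Parameters
    ----------
    learning_rate : float
        Boosting learning rate (eta), 0.1 by default.
    n_repeats : int
        Number of independent stratified 70/15/15 splits; each yields one
        test AUROC and one SHAP attribution pass over all rows.
    val_size, test_size : float
        Validation and test fractions (train = 1 - val - test).
    max_depth, n_estimators, early_stopping_rounds, min_child_samples :
        Tree controls; early stopping monitors validation log-loss.
    reference : "zeros" or array-like
        Reference row the Shapley attribution is computed against; the
        default all-zeros row means "no engagement with any event".
    random_state : int
        Seeds splits and boosting; same seed => identical results.

    Fitted attributes
    -----------------
    auroc_distribution_ : ndarray of per-repeat held-out AUROCs
    auroc_ci_ : (lower, upper) percentile 95% CI of the AUROC
    shap_mean_by_repeat_ : DataFrame (repeat x feature) of signed mean SHAP
    shap_abs_by_repeat_ : DataFrame (repeat x feature) of mean |SHAP|
    booster_ : the last repeat's booster (for inspection)
    """

    def __init__(
        self,
        learning_rate: float = 0.1,
        n_repeats: int = 200,
        val_size: float = 0.15,
        test_size: float = 0.15,
        max_depth: int = 6,
        n_estimators: int = 500,
        early_stopping_rounds: int = 20,
        min_child_samples: int = 20,
        reference: str | np.ndarray = "zeros",
        random_state: int = 0,
    ):
        self.learning_rate = learning_rate
        self.n_repeats = n_repeats
        self.val_size = val_size
        self.test_size = test_size
        self.max_depth = max_depth
        self.n_estimators = n_estimators
        self.early_stopping_rounds = early_stopping_rounds
        self.min_child_samples = min_child_samples
        self.reference = reference
        self.random_state = random_state

    def _reference_row(self, n_features: int) -> np.ndarray:
        if isinstance(self.reference, str):
            if self.reference != "zeros":
                raise ValueError(f"unknown reference {self.reference!r}")
            return np.zeros(n_features)
        ref = np.asarray(self.reference, dtype=np.float64)
        if ref.shape != (n_features,):
            raise ValueError("reference must have one value per feature")
        return ref

    def _lgb_params(self, seed: int) -> dict:
        return {
            "objective": "binary",
            "learning_rate": self.learning_rate,
            "max_depth": self.max_depth,
            "num_leaves": 2**self.max_depth - 1,
            "min_child_samples": self.min_child_samples,
            "n_jobs": 1,
            "seed": seed,
            "deterministic": True,
            "force_row_wise": True,
            "verbosity": -1,
        }

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "EventShapModel":
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not 0 < self.val_size + self.test_size < 1:
            raise ValueError("split fractions must leave a non-empty training set")
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("need both outcome classes")
        Xv = X.to_numpy(dtype=np.float64)
        names = list(X.columns)
        rng = np.random.default_rng(self.random_state)
        aurocs = np.empty(self.n_repeats)
        mean_shap = np.empty((self.n_repeats, len(names)))
        mean_abs = np.empty((self.n_repeats, len(names)))
        booster = None
        ref = self._reference_row(len(names))
        for r in range(self.n_repeats):
            booster, auroc = self._fit_once(Xv, y, rng)
            aurocs[r] = auroc
            contrib = baseline_shap(booster, Xv, ref)
            shap_vals = contrib[:, :-1]  # last column is the base value
            mean_shap[r] = shap_vals.mean(axis=0)
            mean_abs[r] = np.abs(shap_vals).mean(axis=0)
        self.feature_names_ = names
        self.booster_ = booster
        self.auroc_distribution_ = aurocs
        self.auroc_ci_ = (
            float(np.percentile(aurocs, 2.5)),
            float(np.percentile(aurocs, 97.5)),
        )
        self.shap_mean_by_repeat_ = pd.DataFrame(mean_shap, columns=names)
        self.shap_abs_by_repeat_ = pd.DataFrame(mean_abs, columns=names)
        self.n_features_in_ = len(names)
        return self

    def _fit_once(
        self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator
    ) -> tuple[lgb.Booster, float]:
        for _attempt in range(20):
            seed = int(rng.integers(0, 2**31 - 1))
            idx = np.arange(len(y))
            try:
                tr, rest = train_test_split(
                    idx,
                    test_size=self.val_size + self.test_size,
                    stratify=y,
                    random_state=seed,
                )
                val, te = train_test_split(
                    rest,
                    test_size=self.test_size / (self.val_size + self.test_size),
                    stratify=y[rest],
                    random_state=seed + 1,
                )
            except ValueError:
                warnings.warn("stratified split failed; resampling", stacklevel=2)
                continue
            if min(len(np.unique(y[tr])), len(np.unique(y[val])), len(np.unique(y[te]))) < 2:
                warnings.warn("single-class split; resampling", stacklevel=2)
                continue
            dtrain = lgb.Dataset(X[tr], label=y[tr])
            dval = lgb.Dataset(X[val], label=y[val], reference=dtrain)
            booster = lgb.train(
                self._lgb_params(seed),
                dtrain,
                num_boost_round=self.n_estimators,
                valid_sets=[dval],
                callbacks=[
                    lgb.early_stopping(self.early_stopping_rounds, verbose=False)
                ],
            )
            pred = booster.predict(X[te])
            return booster, float(roc_auc_score(y[te], pred))
        raise RuntimeError("could not obtain a two-class split after 20 attempts")

    # ------------------------------------------------------------- summaries
    def shap_values(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Baseline-Shapley attributions of the last repeat's booster.

        Returns (n, p+1): per-feature contributions plus the base value
        f(reference) in the last column; rows sum to the raw margin.
        """
        check_is_fitted(self, "booster_")
        Xv = X.to_numpy(dtype=np.float64) if isinstance(X, pd.DataFrame) else np.asarray(X)
        return baseline_shap(self.booster_, Xv, self._reference_row(Xv.shape[1]))

    def shap_summary(self) -> pd.DataFrame:
        """Per-feature attribution table.

        Columns: event, metric, mean_shap (signed, averaged over repeats),
        mean_abs_shap, ci95_lower/upper (percentile CI of the per-repeat
        signed means), direction ("Increasing"/"Decreasing"), and
        relative_contribution = mean_abs_shap / sum(mean_abs_shap). Sorted
        by mean_abs_shap descending.
        """
        check_is_fitted(self, "shap_mean_by_repeat_")
        mean_shap = self.shap_mean_by_repeat_.mean(axis=0)
        mean_abs = self.shap_abs_by_repeat_.mean(axis=0)
        lo = self.shap_mean_by_repeat_.quantile(0.025, axis=0)
        hi = self.shap_mean_by_repeat_.quantile(0.975, axis=0)
        total = float(mean_abs.sum())
        rel = mean_abs / total if total > 0 else mean_abs * 0.0
        events, kinds = zip(*(split_feature_name(f) for f in self.feature_names_))
        out = pd.DataFrame(
            {
                "event": events,
                "metric": kinds,
                "mean_shap": mean_shap.to_numpy(),
                "mean_abs_shap": mean_abs.to_numpy(),
                "ci95_lower": lo.to_numpy(),
                "ci95_upper": hi.to_numpy(),
                "relative_contribution": rel.to_numpy(),
            },
            index=self.feature_names_,
        )
        out["direction"] = np.where(out["mean_shap"] >= 0, "Increasing", "Decreasing")
        out = out.sort_values("mean_abs_shap", ascending=False)
        out.insert(0, "rank", np.arange(1, len(out) + 1))
        return out


def shap_summary(model: EventShapModel) -> pd.DataFrame:
    """Function wrapper over :meth:`EventShapModel.shap_summary`."""
    return model.shap_summary()


def aggregate_by_metric(summary: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a SHAP summary over metric kinds.

    Sums relative contribution and reports the signed mean SHAP per metric
    category (avg time / loops / presence).
    """
    if "metric" not in summary.columns:
        raise ValueError("summary lacks metric-kind labels")
    unknown = set(summary["metric"]) - set(FEATURE_KINDS)
    if unknown:
        raise ValueError(f"unlabeled/unknown feature kinds: {sorted(unknown)}")
    agg = summary.groupby("metric").agg(
        relative_contribution=("relative_contribution", "sum"),
        mean_shap=("mean_shap", "mean"),
        n_features=("metric", "size"),
    )
    return agg.sort_values("relative_contribution", ascending=False)
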