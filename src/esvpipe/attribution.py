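"""Driver attribution: gradient-boosted tree ensemble + Shapley values.

The county-level driver table (HAI, GPP, Slope, DEM, POP, Temp, GDP, Pre, PM
against zone ESV) is fit with an additive gradient-boosted regression-tree
ensemble (XGBoost). Attribution uses exact interventional Shapley values: for
each background row z the prediction game v(S) = f(x_S, z_{S̄}) is solved in
closed form by enumerating tree paths, then averaged over the background.
Local accuracy — base + Σ φ = f(x) — holds by construction up to float
round-off. A 2^N brute-force subset-enumeration oracle provides the
independent cross-check.

Shapley closed form used per tree leaf: a leaf whose path requires the
feature subset A to follow x and B to follow z defines the unanimity-style
game v(S) = value·1[A ⊆ S, B ∩ S = ∅], whose Shapley values are
value·(|A|−1)!|B|!/(|A|+|B|)! for members of A and
−value·|A|!(|B|−1)!/(|A|+|B|)! for members of B (features that route
identically for x and z are null players).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from math import factorial

import numpy as np
import pandas as pd

from .classes import DRIVER_FEATURES

__all__ = [
    "FEATURES",
    "Tree",
    "TreeEnsemble",
    "AttributionMatrix",
    "assemble_table",
    "fit_model",
    "shapley",
    "brute_force_shapley",
    "brute_force_interactions",
    "importance_ranking",
    "dependence_table",
    "DEFAULT_HYPERPARAMS",
]

logger = logging.getLogger(__name__)

FEATURES: list[str] = list(DRIVER_FEATURES)

#: small-n tabular defaults, fixed for full determinism
DEFAULT_HYPERPARAMS: dict = {
    "n_estimators": 200,
    "max_depth": 3,
    "learning_rate": 0.1,
    "reg_lambda": 1.0,
    "subsample": 1.0,
    "colsample_bytree": 1.0,
    "min_child_weight": 1.0,
}

_BRUTE_FORCE_LIMIT = 15


@dataclass
class Tree:
    """One regression tree as flat arrays; node 0 is the root.

    ``feature[i] == -1`` marks a leaf whose prediction is ``value[i]``.
    The split rule is: go left iff x[feature] < threshold.
    """

    feature: np.ndarray  # int32
    threshold: np.ndarray  # float32
    left: np.ndarray  # int32
    right: np.ndarray  # int32
    value: np.ndarray  # float64

    def leaves(self) -> list[tuple[float, list[tuple[int, float, bool]]]]:
        """(leaf value, path constraints) pairs; constraint = (feature,
        threshold, goes_left)."""
        out: list[tuple[float, list[tuple[int, float, bool]]]] = []

        def walk(node: int, path: list[tuple[int, float, bool]]) -> None:
            f = int(self.feature[node])
            if f < 0:
                out.append((float(self.value[node]), list(path)))
                return
            thr = float(self.threshold[node])
            walk(int(self.left[node]), path + [(f, thr, True)])
            walk(int(self.right[node]), path + [(f, thr, False)])

        walk(0, [])
        return out


@dataclass
class TreeEnsemble:
    """Additive ensemble: prediction = base_value + Σ_k tree_k(x)."""

    trees: list[Tree]
    base_value: float
    feature_names: list[str]
    params: dict
    seed: int
    train_r2: float | None = None

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def predict(self, X) -> np.ndarray:
        X32 = _as_float32_matrix(X, self.feature_names)
        out = np.full(X32.shape[0], self.base_value, dtype=np.float64)
        rows = np.arange(X32.shape[0])
        for tree in self.trees:
            node = np.zeros(X32.shape[0], dtype=np.int64)
            while True:
                f = tree.feature[node]
                internal = f >= 0
                if not internal.any():
                    break
                fx = X32[rows, np.where(internal, f, 0)]
                go_left = fx < tree.threshold[node]
                node = np.where(
                    internal,
                    np.where(go_left, tree.left[node], tree.right[node]),
                    node,
                )
            out += tree.value[node]
        return out


@dataclass
class AttributionMatrix:
    """Per-instance, per-feature Shapley values plus the base value.

    ``base + phi.sum(axis=1)`` reconstructs the model prediction for every
    instance (local accuracy). ``interaction``, when present, is an
    (instance, feature, feature) array with symmetric off-diagonals whose
    rows sum to phi.
    """

    phi: pd.DataFrame
    base: float
    interaction: np.ndarray | None = field(default=None, repr=False)

    @property
    def features(self) -> list[str]:
        return list(self.phi.columns)

    def reconstructed(self) -> np.ndarray:
        return self.base + self.phi.to_numpy().sum(axis=1)


def _as_float32_matrix(X, feature_names: list[str]) -> np.ndarray:
    if isinstance(X, pd.Series):
        X = X.to_frame().T
    if isinstance(X, pd.DataFrame):
        missing = [f for f in feature_names if f not in X.columns]
        if missing:
            raise KeyError(f"feature columns missing from table: {missing}")
        X = X[feature_names].to_numpy(dtype=np.float64)
    X32 = np.asarray(X, dtype=np.float32)
    if X32.ndim == 1:
        X32 = X32[None, :]
    if X32.shape[1] != len(feature_names):
        raise ValueError(
            f"expected {len(feature_names)} features, got {X32.shape[1]}"
        )
    return X32


def assemble_table(
    esv: pd.DataFrame,
    hai: pd.DataFrame,
    drivers: pd.DataFrame,
) -> pd.DataFrame:
    """Join ESV response, HAI and driver covariates into one table.

    One row per (zone, year); the response column ``ESV`` is the zone's total
    ecosystem service value. Rows missing any driver are dropped with a
    logged warning.
    """
    response = (
        esv.groupby(["zone", "year"], sort=True)["yuan"].sum().rename("ESV")
    ).reset_index()
    table = response.merge(hai[["zone", "year", "hai"]], on=["zone", "year"], how="left")
    table = table.rename(columns={"hai": "HAI"})
    table = table.merge(drivers, on=["zone", "year"], how="left")

    feature_cols = [f for f in FEATURES]
    incomplete = table[feature_cols].isna().any(axis=1)
    if incomplete.any():
        for _, row in table.loc[incomplete, ["zone", "year"]].iterrows():
            logger.warning(
                "dropping zone %s year %s: missing driver value",
                row["zone"], row["year"],
            )
        table = table.loc[~incomplete]
    return table[["zone", "year", *feature_cols, "ESV"]].reset_index(drop=True)


def fit_model(
    table: pd.DataFrame,
    hyperparams: dict | None = None,
    seed: int = 0,
    features: list[str] | None = None,
    response: str = "ESV",
) -> TreeEnsemble:
    """Fit the gradient-boosted regression-tree ensemble.

    Deterministic given the seed (single-threaded training); the fitted
    ensemble is extracted into plain arrays so prediction and attribution are
    self-contained. Training R² is recorded on the ensemble.
    """
    import xgboost as xgb

    features = list(FEATURES if features is None else features)
    for col in [*features, response]:
        if col not in table.columns:
            raise KeyError(f"column missing from driver table: {col}")
        if not pd.api.types.is_numeric_dtype(table[col]):
            raise TypeError(f"non-numeric column in driver table: {col}")

    params = {**DEFAULT_HYPERPARAMS, **(hyperparams or {})}
    X = table[features].to_numpy(dtype=np.float32)
    y = table[response].to_numpy(dtype=np.float64)
    base_score = float(y.mean())

    model = xgb.XGBRegressor(
        **params,
        base_score=base_score,
        random_state=int(seed),
        n_jobs=1,
        tree_method="hist",
        objective="reg:squarederror",
    )
    model.fit(X, y)
    booster = model.get_booster()

    config = json.loads(booster.save_config())
    fitted_base = float(
        config["learner"]["learner_model_param"]["base_score"]
    )

    trees = [_parse_tree(json.loads(dump)) for dump in
             booster.get_dump(dump_format="json")]
    ensemble = TreeEnsemble(
        trees=trees,
        base_value=fitted_base,
        feature_names=features,
        params=params,
        seed=int(seed),
    )
    pred = ensemble.predict(table[features])
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ensemble.train_r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ensemble


def _parse_tree(node: dict) -> Tree:
    feature: list[int] = []
    threshold: list[float] = []
    left: list[int] = []
    right: list[int] = []
    value: list[float] = []

    def add(nd: dict) -> int:
        idx = len(feature)
        feature.append(0)
        threshold.append(0.0)
        left.append(-1)
        right.append(-1)
        value.append(0.0)
        if "leaf" in nd:
            feature[idx] = -1
            value[idx] = float(nd["leaf"])
            return idx
        name = nd["split"]
        feature[idx] = int(name[1:]) if name.startswith("f") else int(name)
        threshold[idx] = float(nd["split_condition"])
        children = {c["nodeid"]: c for c in nd["children"]}
        left[idx] = add(children[nd["yes"]])
        right[idx] = add(children[nd["no"]])
        return idx

    add(node)
    return Tree(
        feature=np.asarray(feature, dtype=np.int32),
        threshold=np.asarray(threshold, dtype=np.float32),
        left=np.asarray(left, dtype=np.int32),
        right=np.asarray(right, dtype=np.int32),
        value=np.asarray(value, dtype=np.float64),
    )


def _weight_tables(max_k: int) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form unanimity-game weights indexed by (|A|, |B|)."""
    wp = np.zeros((max_k + 1, max_k + 1))
    wn = np.zeros((max_k + 1, max_k + 1))
    for a in range(max_k + 1):
        for b in range(max_k + 1):
            if a >= 1:
                wp[a, b] = factorial(a - 1) * factorial(b) / factorial(a + b)
            if b >= 1:
                wn[a, b] = factorial(a) * factorial(b - 1) / factorial(a + b)
    return wp, wn


def shapley(
    model: TreeEnsemble,
    table: pd.DataFrame | np.ndarray,
    background: pd.DataFrame | np.ndarray,
) -> AttributionMatrix:
    """Exact interventional Shapley values for a tree ensemble.

    For every (instance, background row) pair the per-tree attribution is
    computed in closed form from the leaf paths, then averaged over the
    background. Satisfies local accuracy, the dummy property and symmetry
    exactly (up to float round-off).
    """
    X32 = _as_float32_matrix(table, model.feature_names)
    Z32 = _as_float32_matrix(background, model.feature_names)
    nx, nf = X32.shape
    nb = Z32.shape[0]

    max_k = max(
        (len({f for f, _, _ in path}) for tree in model.trees
         for _, path in tree.leaves()),
        default=0,
    )
    wp, wn = _weight_tables(max_k)

    phi = np.zeros((nx, nf), dtype=np.float64)
    for tree in model.trees:
        for leaf_value, path in tree.leaves():
            if not path:
                continue  # constant tree: cancels between f(x) and f(z)
            by_feature: dict[int, list[tuple[float, bool]]] = {}
            for f, thr, goes_left in path:
                by_feature.setdefault(f, []).append((thr, goes_left))

            feats = list(by_feature)
            x_ok = np.empty((len(feats), nx), dtype=bool)
            z_ok = np.empty((len(feats), nb), dtype=bool)
            for i, f in enumerate(feats):
                xo = np.ones(nx, dtype=bool)
                zo = np.ones(nb, dtype=bool)
                for thr, goes_left in by_feature[f]:
                    if goes_left:
                        xo &= X32[:, f] < thr
                        zo &= Z32[:, f] < thr
                    else:
                        xo &= ~(X32[:, f] < thr)
                        zo &= ~(Z32[:, f] < thr)
                x_ok[i] = xo
                z_ok[i] = zo

            on = x_ok[:, :, None] & ~z_ok[:, None, :]  # (k, nx, nb)
            off = ~x_ok[:, :, None] & z_ok[:, None, :]
            reach = ~(~x_ok[:, :, None] & ~z_ok[:, None, :]).any(axis=0)
            a = on.sum(axis=0)
            b = off.sum(axis=0)
            wpos = wp[a, b] * reach
            wneg = wn[a, b] * reach
            for i, f in enumerate(feats):
                contrib = (on[i] * wpos - off[i] * wneg).sum(axis=1)
                phi[:, f] += leaf_value * contrib

    phi /= nb
    base = float(model.predict(Z32).mean())
    index = table.index if isinstance(table, pd.DataFrame) else pd.RangeIndex(nx)
    return AttributionMatrix(
        phi=pd.DataFrame(phi, index=index, columns=model.feature_names),
        base=base,
    )


def _subset_values(
    model: TreeEnsemble, x: np.ndarray, background: np.ndarray
) -> np.ndarray:
    """v(S) for every subset bitmask: expected prediction with features in S
    pinned to the instance and the rest drawn from the background."""
    nf = model.n_features
    nb = background.shape[0]
    n_masks = 1 << nf
    hybrids = np.tile(background, (n_masks, 1))
    for mask in range(n_masks):
        block = slice(mask * nb, (mask + 1) * nb)
        for i in range(nf):
            if mask >> i & 1:
                hybrids[block, i] = x[i]
    preds = model.predict(hybrids)
    return preds.reshape(n_masks, nb).mean(axis=1)


def _check_brute_force_size(nf: int) -> None:
    if nf > _BRUTE_FORCE_LIMIT:
        raise ValueError(
            f"brute-force enumeration limited to {_BRUTE_FORCE_LIMIT} features"
            f" (got {nf})"
        )


def brute_force_shapley(
    model: TreeEnsemble,
    instance: pd.Series | np.ndarray,
    background: pd.DataFrame | np.ndarray,
) -> np.ndarray:
    """Classical Shapley values by full subset enumeration (cost 2^N).

    φ_i = Σ_{S ∌ i} |S|!(N−|S|−1)!/N! · (v(S∪{i}) − v(S)) with
    v(S) = E_z[f(x_S, z_{S̄})] over the background rows. Independent oracle
    for :func:`shapley`.
    """
    nf = model.n_features
    _check_brute_force_size(nf)
    x = _as_float32_matrix(instance, model.feature_names)[0].astype(np.float64)
    Z = _as_float32_matrix(background, model.feature_names).astype(np.float64)
    v = _subset_values(model, x, Z)

    w = np.array(
        [factorial(s) * factorial(nf - s - 1) / factorial(nf) for s in range(nf)]
    )
    phi = np.zeros(nf)
    for mask in range(1 << nf):
        s = bin(mask).count("1")
        for i in range(nf):
            if not mask >> i & 1:
                phi[i] += w[s] * (v[mask | (1 << i)] - v[mask])
    return phi


def brute_force_interactions(
    model: TreeEnsemble,
    instance: pd.Series | np.ndarray,
    background: pd.DataFrame | np.ndarray,
) -> np.ndarray:
    """Shapley interaction matrix by subset enumeration.

    Off-diagonals carry half the pairwise interaction index
    Σ_{R ⊆ P∖{m,n}} |R|!(N−|R|−2)!/(N−1)! · ε_mn(R) (so the matrix is
    symmetric); the diagonal is the main effect φ_m − Σ_{n≠m} φ_{m,n}, making
    every row sum to the Shapley value φ_m.
    """
    nf = model.n_features
    _check_brute_force_size(nf)
    x = _as_float32_matrix(instance, model.feature_names)[0].astype(np.float64)
    Z = _as_float32_matrix(background, model.feature_names).astype(np.float64)
    v = _subset_values(model, x, Z)

    inter = np.zeros((nf, nf))
    if nf >= 2:
        w2 = np.array(
            [
                factorial(r) * factorial(nf - r - 2) / factorial(nf - 1)
                for r in range(nf - 1)
            ]
        )
        for m in range(nf):
            for n in range(m + 1, nf):
                both = (1 << m) | (1 << n)
                total = 0.0
                for mask in range(1 << nf):
                    if mask & both:
                        continue
                    r = bin(mask).count("1")
                    eps = (
                        v[mask | both]
                        - v[mask | (1 << m)]
                        - v[mask | (1 << n)]
                        + v[mask]
                    )
                    total += w2[r] * eps
                inter[m, n] = inter[n, m] = total / 2.0

    phi = brute_force_shapley(model, instance, background)
    np.fill_diagonal(inter, phi - (inter.sum(axis=1) - np.diag(inter)))
    return inter


def importance_ranking(attr: AttributionMatrix) -> pd.DataFrame:
    """Features ordered by mean |φ| (descending; ties keep column order)."""
    if attr.phi.empty:
        raise ValueError("empty attribution matrix")
    imp = attr.phi.abs().mean(axis=0)
    order = np.argsort(-imp.to_numpy(), kind="stable")
    return pd.DataFrame(
        {
            "feature": [attr.features[i] for i in order],
            "mean_abs_shap": imp.to_numpy()[order],
        }
    )


def dependence_table(
    attr: AttributionMatrix,
    table: pd.DataFrame,
    feature: str,
    color_feature: str = "HAI",
) -> pd.DataFrame:
    """Per-instance (feature value, φ, color value) rows, sorted by feature.

    The color column exposes interactions: e.g. the share of instances with
    high color value and low feature value whose φ is positive.
    """
    for name in (feature, color_feature):
        if name not in attr.phi.columns or name not in table.columns:
            raise KeyError(f"unknown feature: {name}")
    out = pd.DataFrame(
        {
            feature: table[feature].to_numpy(),
            "shap_value": attr.phi[feature].to_numpy(),
            f"color_{color_feature}": table[color_feature].to_numpy(),
        }
    )
    return out.sort_values(feature, kind="stable", ignore_index=True)
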