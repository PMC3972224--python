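"""Multiblock partial least squares (MB-PLS) with block importance.

The model relates a response block Y (here: aroma-release parameters)
to B predictor blocks X_1..X_B (physiological measurements) through a
sequence of shared latent components. Each variable is first mean
centered and autoscaled, then every variable of block b is divided by
sqrt(p_b * (n - 1)) so each block contributes a total sum of squares of
exactly 1 — without this balancing, large blocks would dominate the
solution simply by having more variables.

For each dimension h the NIPALS-style iteration alternates

    w_b  ∝  X_b' u        (block weights, unit norm per block)
    t_b  =  X_b w_b       (block scores)
    a    ∝  T' u          (super weights over blocks, unit norm)
    t    =  T a           (super score)
    q    ∝  Y' t          (Y weights, unit norm)
    u    =  Y q           (Y score)

until the super score stabilizes. All X blocks and Y are then deflated
on the super score t. With this deflation scheme MB-PLS is exactly
equivalent to ordinary PLS2 on the column-concatenation of the scaled
blocks: the concatenated weight vector of dimension h is
(a_1 w_1, ..., a_B w_B), which has unit norm. That equivalence is the
cross-check used in the test suite.

The importance of block b on dimension h is the squared norm of its
portion of that unit concatenated weight vector, i.e. a_b(h)^2; the B
importances of a dimension sum to 1. Explained inertia (percentage of
a block's total variance captured per dimension) is computed against
the undeflated preprocessed blocks, as in a Table-of-inertia summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .blocks import MultiblockDataset, VariableBlock


class ConvergenceError(RuntimeError):
    """NIPALS iteration failed to stabilize within the iteration cap."""

    def __init__(self, dimension: int, iterations: int, last_change: float):
        self.dimension = dimension
        self.iterations = iterations
        self.last_change = last_change
        super().__init__(
            f"dimension {dimension}: no convergence after {iterations} "
            f"iterations (last relative score change {last_change:.3e})"
        )


@dataclass
class PreprocessedDataset:
    """Centered, autoscaled, block-balanced copies of all blocks.

    After preprocessing every column has mean 0 and every block has
    total sum of squares 1. Centers, per-variable scales and per-block
    factors are stored for the inverse transform used in prediction.
    """

    block_names: list[str]  # Y first, then X blocks in order
    arrays: dict[str, np.ndarray]
    centers: dict[str, np.ndarray]
    scales: dict[str, np.ndarray]  # per-variable autoscale (SD, ddof=1)
    block_factors: dict[str, float]  # sqrt(p_b * (n - 1))
    variable_names: dict[str, list[str]]
    n_rows: int

    def transform_block(self, name: str, values: np.ndarray) -> np.ndarray:
        return (values - self.centers[name]) / self.scales[name] / self.block_factors[name]

    def inverse_transform_block(self, name: str, values: np.ndarray) -> np.ndarray:
        return values * self.scales[name] * self.block_factors[name] + self.centers[name]


def preprocess(dataset: MultiblockDataset) -> PreprocessedDataset:
    """Center, autoscale, and block-balance all blocks.

    Requires complete data (imputation happens upstream); a
    zero-variance variable cannot be autoscaled and is a hard error.
    """
    n = dataset.n_rows
    names, arrays, centers, scales, factors, varnames = [], {}, {}, {}, {}, {}
    for blk in dataset.blocks:
        if blk.values.isna().any().any():
            bad = blk.values.columns[blk.values.isna().any()].tolist()
            raise ValueError(
                f"block {blk.name!r} contains missing values in {bad}; impute first"
            )
        X = blk.values.to_numpy(dtype=float)
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [c for c, s in zip(blk.variable_names, sd) if s == 0]
            raise ValueError(f"zero-variance variable(s) in block {blk.name!r}: {bad}")
        factor = float(np.sqrt(blk.n_variables * (n - 1)))
        names.append(blk.name)
        arrays[blk.name] = (X - mu) / sd / factor
        centers[blk.name] = mu
        scales[blk.name] = sd
        factors[blk.name] = factor
        varnames[blk.name] = blk.variable_names
    return PreprocessedDataset(
        block_names=names,
        arrays=arrays,
        centers=centers,
        scales=scales,
        block_factors=factors,
        variable_names=varnames,
        n_rows=n,
    )


@dataclass
class MBPLSModel:
    """A fitted multiblock PLS model.

    Attributes
    ----------
    super_scores
        n x H matrix of super scores t(h); columns mutually orthogonal.
    super_weights
        B x H matrix of block-combination weights a_b(h), unit-norm
        columns.
    block_weights, block_scores, x_block_loadings
        Per predictor block: variables x H unit-norm weights w_b(h),
        n x H block scores t_b(h), and deflation loadings p_b(h).
    y_weights, y_loadings
        Unit-norm Y weights q(h) and Y deflation/regression loadings
        c(h) (preprocessed scale).
    explained_inertia_y, explained_inertia_x
        Percentage of the preprocessed (undeflated) block variance
        captured per dimension.
    block_importance
        B x H matrix; column h gives each block's share of dimension
        h's unit-norm concatenated weight vector (sums to 1).
    """

    n_components: int
    x_block_names: list[str]
    preprocessing: PreprocessedDataset
    super_scores: np.ndarray
    super_weights: np.ndarray
    block_weights: dict[str, np.ndarray]
    block_scores: dict[str, np.ndarray]
    x_block_loadings: dict[str, np.ndarray]
    y_weights: np.ndarray
    y_loadings: np.ndarray
    explained_inertia_y: np.ndarray
    explained_inertia_x: dict[str, np.ndarray]
    block_importance: np.ndarray
    iterations: list[int] = field(default_factory=list)

    # concatenated-space vectors used for prediction
    _w_concat: np.ndarray = None
    _p_concat: np.ndarray = None

    @property
    def y_name(self) -> str:
        return self.preprocessing.block_names[0]

    # ------------------------------------------------------------ predict

    def _concat_new(self, x_blocks: dict[str, np.ndarray] | MultiblockDataset) -> np.ndarray:
        pp = self.preprocessing
        if isinstance(x_blocks, MultiblockDataset):
            x_blocks = {
                b.name: b.values.to_numpy(dtype=float) for b in x_blocks.x_blocks
            }
        cols = []
        problems = []
        for name in self.x_block_names:
            if name not in x_blocks:
                problems.append(f"missing block {name!r}")
                continue
            arr = np.atleast_2d(np.asarray(x_blocks[name], dtype=float))
            if arr.shape[1] != len(pp.variable_names[name]):
                problems.append(
                    f"block {name!r}: expected {len(pp.variable_names[name])} "
                    f"variables, got {arr.shape[1]}"
                )
                continue
            cols.append(pp.transform_block(name, arr))
        if problems:
            raise ValueError("prediction input mismatch: " + "; ".join(problems))
        return np.hstack(cols)

    def predict_preprocessed(
        self, x_blocks: dict[str, np.ndarray] | MultiblockDataset
    ) -> np.ndarray:
        """Per-component cumulative predictions on the preprocessed Y
        scale, shaped (H, n_new, p_y). Used by cross-validation."""
        X = self._concat_new(x_blocks)
        n_new = X.shape[0]
        p_y = self.y_loadings.shape[0]
        out = np.empty((self.n_components, n_new, p_y))
        acc = np.zeros((n_new, p_y))
        Xc = X.copy()
        for h in range(self.n_components):
            t = Xc @ self._w_concat[:, h]
            Xc -= np.outer(t, self._p_concat[:, h])
            acc += np.outer(t, self.y_loadings[:, h])
            out[h] = acc
        return out

    def predict(
        self,
        x_blocks: dict[str, np.ndarray] | MultiblockDataset,
        n_components: int | None = None,
    ) -> np.ndarray:
        """Predict Y on the original measurement scale."""
        h = self.n_components if n_components is None else n_components
        if not (1 <= h <= self.n_components):
            raise ValueError(f"n_components must lie in [1, {self.n_components}]")
        y_pre = self.predict_preprocessed(x_blocks)[h - 1]
        return self.preprocessing.inverse_transform_block(self.y_name, y_pre)

    # -------------------------------------------------------------- I/O

    def to_json(self) -> dict:
        pp = self.preprocessing
        return {
            "n_components": self.n_components,
            "x_block_names": self.x_block_names,
            "super_scores": self.super_scores.tolist(),
            "super_weights": self.super_weights.tolist(),
            "block_weights": {k: v.tolist() for k, v in self.block_weights.items()},
            "block_scores": {k: v.tolist() for k, v in self.block_scores.items()},
            "x_block_loadings": {k: v.tolist() for k, v in self.x_block_loadings.items()},
            "y_weights": self.y_weights.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "explained_inertia_y": self.explained_inertia_y.tolist(),
            "explained_inertia_x": {k: v.tolist() for k, v in self.explained_inertia_x.items()},
            "block_importance": self.block_importance.tolist(),
            "iterations": self.iterations,
            "preprocessing": {
                "block_names": pp.block_names,
                "centers": {k: v.tolist() for k, v in pp.centers.items()},
                "scales": {k: v.tolist() for k, v in pp.scales.items()},
                "block_factors": pp.block_factors,
                "variable_names": pp.variable_names,
                "n_rows": pp.n_rows,
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json()) + "\n")

    @classmethod
    def from_json(cls, payload: dict) -> "MBPLSModel":
        ppd = payload["preprocessing"]
        pp = PreprocessedDataset(
            block_names=ppd["block_names"],
            arrays={},
            centers={k: np.asarray(v) for k, v in ppd["centers"].items()},
            scales={k: np.asarray(v) for k, v in ppd["scales"].items()},
            block_factors={k: float(v) for k, v in ppd["block_factors"].items()},
            variable_names=ppd["variable_names"],
            n_rows=ppd["n_rows"],
        )
        model = cls(
            n_components=payload["n_components"],
            x_block_names=payload["x_block_names"],
            preprocessing=pp,
            super_scores=np.asarray(payload["super_scores"]),
            super_weights=np.asarray(payload["super_weights"]),
            block_weights={k: np.asarray(v) for k, v in payload["block_weights"].items()},
            block_scores={k: np.asarray(v) for k, v in payload["block_scores"].items()},
            x_block_loadings={
                k: np.asarray(v) for k, v in payload["x_block_loadings"].items()
            },
            y_weights=np.asarray(payload["y_weights"]),
            y_loadings=np.asarray(payload["y_loadings"]),
            explained_inertia_y=np.asarray(payload["explained_inertia_y"]),
            explained_inertia_x={
                k: np.asarray(v) for k, v in payload["explained_inertia_x"].items()
            },
            block_importance=np.asarray(payload["block_importance"]),
            iterations=payload["iterations"],
        )
        model._w_concat = np.vstack(
            [
                model.block_weights[name] * model.super_weights[i]
                for i, name in enumerate(model.x_block_names)
            ]
        )
        model._p_concat = np.vstack(
            [model.x_block_loadings[name] for name in model.x_block_names]
        )
        return model

    @classmethod
    def load(cls, path: str | Path) -> "MBPLSModel":
        return cls.from_json(json.loads(Path(path).read_text()))


def fit_mbpls(
    dataset: MultiblockDataset,
    n_components: int,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> MBPLSModel:
    """Fit an MB-PLS model with super-score deflation.

    ``n_components`` must not exceed min(n - 1, total predictor
    variables). The fit is fully deterministic: the Y score is
    initialized from the first Y column (all Y columns have equal
    variance after block scaling) and the sign of every dimension is
    fixed so that the largest-magnitude entry of the concatenated
    weight vector is positive.
    """
    pp = preprocess(dataset)
    y_name = pp.block_names[0]
    x_names = pp.block_names[1:]
    n = pp.n_rows
    p_total = sum(len(pp.variable_names[b]) for b in x_names)
    if not (1 <= n_components <= min(n - 1, p_total)):
        raise ValueError(
            f"n_components must lie in [1, min(n - 1, total X variables)] "
            f"= [1, {min(n - 1, p_total)}], got {n_components}"
        )

    Y0 = pp.arrays[y_name].copy()
    X0 = {b: pp.arrays[b].copy() for b in x_names}
    Y = Y0.copy()
    X = {b: X0[b].copy() for b in x_names}
    B = len(x_names)
    p_y = Y.shape[1]

    super_scores = np.zeros((n, n_components))
    super_weights = np.zeros((B, n_components))
    block_weights = {b: np.zeros((X[b].shape[1], n_components)) for b in x_names}
    block_scores = {b: np.zeros((n, n_components)) for b in x_names}
    x_loadings = {b: np.zeros((X[b].shape[1], n_components)) for b in x_names}
    y_weights = np.zeros((p_y, n_components))
    y_loadings = np.zeros((p_y, n_components))
    iterations = []

    for h in range(n_components):
        u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
        t_old = np.zeros(n)
        change = np.inf
        for it in range(1, max_iter + 1):
            ws, ts = [], []
            for b in x_names:
                w = X[b].T @ u
                nw = np.linalg.norm(w)
                if nw > 0:
                    w = w / nw
                ws.append(w)
                ts.append(X[b] @ w)
            T = np.column_stack(ts)
            a = T.T @ u
            na = np.linalg.norm(a)
            if na > 0:
                a = a / na
            t = T @ a
            q = Y.T @ t
            nq = np.linalg.norm(q)
            if nq > 0:
                q = q / nq
            u = Y @ q
            tnorm = np.linalg.norm(t)
            change = np.linalg.norm(t - t_old) / (tnorm if tnorm > 0 else 1.0)
            if change < tol:
                break
            t_old = t
        else:
            raise ConvergenceError(h + 1, max_iter, change)
        iterations.append(it)

        # sign convention: largest-|.| entry of the concatenated weight
        # vector (a_1 w_1, ..., a_B w_B) is positive
        w_concat = np.concatenate([a[i] * ws[i] for i in range(B)])
        if w_concat[int(np.argmax(np.abs(w_concat)))] < 0:
            ws = [-w for w in ws]
            ts = [-tb for tb in ts]
            t = -t
            q = -q
            w_concat = -w_concat

        tt = float(t @ t)
        c = Y.T @ t / tt
        for i, b in enumerate(x_names):
            p_b = X[b].T @ t / tt
            X[b] -= np.outer(t, p_b)
            block_weights[b][:, h] = ws[i]
            block_scores[b][:, h] = ts[i]
            x_loadings[b][:, h] = p_b
        Y -= np.outer(t, c)
        super_scores[:, h] = t
        super_weights[:, h] = a
        y_weights[:, h] = q
        y_loadings[:, h] = c

    # explained inertia against the undeflated preprocessed blocks
    # (each block has total SS exactly 1 by construction)
    ss_t = np.sum(super_scores**2, axis=0)
    inertia_y = 100.0 * ss_t * np.sum(y_loadings**2, axis=0) / np.sum(Y0**2)
    inertia_x = {
        b: 100.0 * ss_t * np.sum(x_loadings[b] ** 2, axis=0) / np.sum(X0[b] ** 2)
        for b in x_names
    }
    importance = super_weights**2

    model = MBPLSModel(
        n_components=n_components,
        x_block_names=x_names,
        preprocessing=pp,
        super_scores=super_scores,
        super_weights=super_weights,
        block_weights=block_weights,
        block_scores=block_scores,
        x_block_loadings=x_loadings,
        y_weights=y_weights,
        y_loadings=y_loadings,
        explained_inertia_y=inertia_y,
        explained_inertia_x=inertia_x,
        block_importance=importance,
        iterations=iterations,
    )
    model._w_concat = np.vstack(
        [block_weights[b] * super_weights[i] for i, b in enumerate(x_names)]
    )
    model._p_concat = np.vstack([x_loadings[b] for b in x_names])
    return model


def block_importance(model: MBPLSModel) -> pd.DataFrame:
    """Per-dimension share of each predictor block in the unit-norm
    concatenated weight vector; columns sum to 1."""
    return pd.DataFrame(
        model.block_importance,
        index=model.x_block_names,
        columns=[f"Dim{h + 1}" for h in range(model.n_components)],
    )


def explained_inertia(model: MBPLSModel) -> pd.DataFrame:
    """Percent of each block's total variance captured per dimension;
    rows are Y then the X blocks, columns Dim1..DimH."""
    rows = {model.y_name: model.explained_inertia_y}
    rows.update({b: model.explained_inertia_x[b] for b in model.x_block_names})
    return pd.DataFrame(
        rows, index=[f"Dim{h + 1}" for h in range(model.n_components)]
    ).T
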