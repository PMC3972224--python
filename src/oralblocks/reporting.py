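"""Result surfaces: correlation loadings, block-importance charts, and
inertia tables.

A correlation-loading plot places every variable at its Pearson
correlation with two retained super scores; variables near the unit
circle are well represented by the pair of dimensions. To keep the
display legible, predictor variables are shown only when their
correlation with at least one of the two plotted dimensions reaches a
threshold (0.45 by default, on |r|), while response variables are
always shown.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .blocks import BLOCK_LABELS, MultiblockDataset
from .mbpls import MBPLSModel, block_importance, explained_inertia
from .selection import CVResult

DISPLAY_THRESHOLD = 0.45

#: Block palette used in figures (keyed by block name; unknown blocks
#: fall back to matplotlib's cycle).
BLOCK_COLORS = {
    "Y": "tab:blue",
    "X1": "tab:green",
    "X2": "tab:orange",
    "X3": "tab:red",
    "X4": "tab:gray",
    "X5": "tab:purple",
}


@dataclass
class CorrelationLoadings:
    """Pearson correlations of every variable with each super score.

    ``table`` rows are variables (Y block first), with a ``block``
    column and one ``Dim<h>`` column per retained dimension; NaN marks
    a correlation undefined because the variable is constant.
    """

    table: pd.DataFrame

    @property
    def dims(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("Dim")]


def correlation_loadings(
    model: MBPLSModel, dataset: MultiblockDataset
) -> CorrelationLoadings:
    """Correlate each preprocessed variable with each super score."""
    T = model.super_scores
    H = model.n_components
    rows = []
    for blk in dataset.blocks:
        X = blk.values.to_numpy(dtype=float)
        Xc = X - X.mean(axis=0)
        sx = np.sqrt(np.sum(Xc**2, axis=0))
        Tc = T - T.mean(axis=0)
        st = np.sqrt(np.sum(Tc**2, axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Xc.T @ Tc) / np.outer(sx, st)
        r[sx == 0, :] = np.nan  # constant variable: correlation undefined
        for j, var in enumerate(blk.variable_names):
            rows.append(
                {
                    "variable": var,
                    "block": blk.name,
                    "role": blk.role,
                    **{f"Dim{h + 1}": r[j, h] for h in range(H)},
                }
            )
    table = pd.DataFrame(rows).set_index("variable")
    return CorrelationLoadings(table=table)


def filter_for_display(
    loadings: CorrelationLoadings,
    dims: tuple[int, int] = (1, 2),
    threshold: float = DISPLAY_THRESHOLD,
    always_show_response: bool = True,
) -> pd.Series:
    """Boolean mask of variables to draw on the (dims[0], dims[1]) plot.

    A predictor variable is shown iff max(|r|) over the two plotted
    dimensions reaches ``threshold``; response variables are always
    shown when ``always_show_response`` is set.
    """
    cols = [f"Dim{d}" for d in dims]
    for c in cols:
        if c not in loadings.table.columns:
            raise ValueError(f"dimension {c} not present in the loadings")
    r = loadings.table[cols].abs()
    mask = (r.max(axis=1) >= threshold).fillna(False)
    if always_show_response:
        mask |= loadings.table["role"] == "response"
    mask.name = "display"
    return mask


def _loading_plot(
    loadings: CorrelationLoadings,
    dims: tuple[int, int],
    threshold: float,
    path: Path,
) -> None:
    mask = filter_for_display(loadings, dims=dims, threshold=threshold)
    fig, ax = plt.subplots(figsize=(6, 6))
    for radius in (threshold, 1.0):
        circle = plt.Circle((0, 0), radius, fill=False, color="0.8", linestyle="--")
        ax.add_patch(circle)
    cols = [f"Dim{d}" for d in dims]
    for var, row in loadings.table[mask].iterrows():
        x, y = row[cols[0]], row[cols[1]]
        if np.isnan(x) or np.isnan(y):
            continue
        color = BLOCK_COLORS.get(row["block"], "black")
        ax.annotate(
            "", xy=(x, y), xytext=(0, 0),
            arrowprops={"arrowstyle": "->", "color": color, "lw": 1.2},
        )
        ax.text(x, y, var, color=color, fontsize=7)
    ax.set_xlim(-1.1, 1.1)
    ax.set_ylim(-1.1, 1.1)
    ax.axhline(0, color="0.9", lw=0.5)
    ax.axvline(0, color="0.9", lw=0.5)
    ax.set_xlabel(cols[0])
    ax.set_ylabel(cols[1])
    ax.set_title(f"Correlation loadings ({cols[0]} vs {cols[1]}, |r| >= {threshold})")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _importance_chart(model: MBPLSModel, path: Path) -> None:
    imp = block_importance(model) * 100.0
    fig, axes = plt.subplots(
        1, model.n_components, figsize=(3 * model.n_components, 3), sharey=True
    )
    axes = np.atleast_1d(axes)
    for h, ax in enumerate(axes):
        col = f"Dim{h + 1}"
        colors = [BLOCK_COLORS.get(b, "black") for b in imp.index]
        ax.bar(imp.index, imp[col], color=colors)
        ax.set_title(col)
        ax.set_ylabel("block importance (%)" if h == 0 else "")
        labels = [BLOCK_LABELS.get(b, b) for b in imp.index]
        ax.set_xticks(range(len(labels)))
        ax.set_xticklabels(labels, rotation=45, ha="right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def export_results(
    model: MBPLSModel,
    dataset: MultiblockDataset,
    cv: CVResult | None = None,
    selected_h: int | None = None,
    out_dir: str | Path = "results",
    threshold: float = DISPLAY_THRESHOLD,
) -> dict[str, str]:
    """Write the standard result files for one fitted analysis.

    Produces ``inertia.csv`` (rows Y then X blocks, columns Dim1..DimH),
    ``block_importance.csv`` (percent), ``correlation_loadings.csv``
    with per-plot display flags, optional ``cv.csv``, bar charts of
    block importance, loading plots for dimension pairs (1,2) and
    (1,3) when available, and a ``run_summary.json`` index. CSV output
    is deterministic: re-exporting the same model yields identical
    bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    inertia = explained_inertia(model)
    inertia.to_csv(out / "inertia.csv", index_label="block", float_format="%.6f")
    files["inertia"] = "inertia.csv"

    imp = block_importance(model) * 100.0
    imp.to_csv(out / "block_importance.csv", index_label="block", float_format="%.6f")
    files["block_importance"] = "block_importance.csv"

    loadings = correlation_loadings(model, dataset)
    table = loadings.table.copy()
    dim_pairs = [(1, 2)]
    if model.n_components >= 3:
        dim_pairs.append((1, 3))
    for pair in dim_pairs:
        table[f"show_dim{pair[0]}{pair[1]}"] = filter_for_display(
            loadings, dims=pair, threshold=threshold
        )
    table.to_csv(out / "correlation_loadings.csv", float_format="%.6f")
    files["correlation_loadings"] = "correlation_loadings.csv"

    if cv is not None:
        cv.to_frame().to_csv(out / "cv.csv", index=False, float_format="%.6f")
        files["cv"] = "cv.csv"

    _importance_chart(model, out / "block_importance.png")
    files["block_importance_chart"] = "block_importance.png"
    for pair in dim_pairs:
        name = f"loadings_dim{pair[0]}{pair[1]}.png"
        _loading_plot(loadings, pair, threshold, out / name)
        files[f"loadings_dim{pair[0]}{pair[1]}"] = name

    summary = {
        "n_components": model.n_components,
        "selected_components": selected_h,
        "display_threshold": threshold,
        "explained_inertia_y_pct": [round(v, 6) for v in model.explained_inertia_y],
        "block_importance_pct": {
            b: [round(v, 6) for v in imp.loc[b]] for b in imp.index
        },
        "files": files,
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    files["summary"] = "run_summary.json"
    return files
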