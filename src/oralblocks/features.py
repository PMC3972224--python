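"""Derived physiological variables and multiblock dataset assembly.

Three rules from the emulated protocol live here: replicate
measurements are collapsed to their median (robust to outliers in
triplicate designs), missing cells are imputed by the median of the
observed values for the same variable within the same group (e.g. the
same cheese product), and the bolus moistening percentage is derived
from bolus and cheese water/dry-matter composition by a dry-matter
mass balance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blocks import (
    ROLE_RESPONSE,
    MultiblockDataset,
    SchemaError,
    VariableBlock,
)

logger = logging.getLogger(__name__)


@dataclass
class CompositionMeasurement:
    """Water/dry-matter composition of a bolus and its source cheese.

    All four fields are percentages in (0, 100). Bolus and cheese
    fractions should each sum to ~100; a discrepancy beyond 1% raises a
    warning (measurement error), not an exception.
    """

    Bwc: float  # bolus water content (%)
    Bdm: float  # bolus dry matter (%)
    Cwc: float  # cheese water content (%)
    Cdm: float  # cheese dry matter (%)

    def __post_init__(self) -> None:
        for name in ("Bwc", "Bdm", "Cwc", "Cdm"):
            v = getattr(self, name)
            if not (0 < v < 100):
                raise ValueError(f"{name} must lie in (0, 100), got {v}")
        for label, total in (("bolus", self.Bwc + self.Bdm), ("cheese", self.Cwc + self.Cdm)):
            if abs(total - 100.0) > 1.0:
                warnings.warn(
                    f"{label} water + dry matter = {total:.2f}%, expected ~100%",
                    stacklevel=2,
                )


def compute_moistening(m: CompositionMeasurement) -> float:
    """Percentage of bolus water contributed by saliva.

    Under conservation of dry matter, the water the cheese itself brings
    into the bolus is Bdm * Cwc / Cdm (per unit bolus); the excess over
    that is saliva. Expressed as a fraction of total bolus water:

        Moist_% = 100 * (Bwc - Bdm * Cwc / Cdm) / Bwc

    Zero when the bolus has the same water:dry-matter ratio as the
    cheese; approaches 100% as saliva dominates.
    """
    if m.Cdm == 0 or m.Bwc == 0:
        raise ValueError("Cdm and Bwc must be nonzero")
    return 100.0 * (m.Bwc - m.Bdm * m.Cwc / m.Cdm) / m.Bwc


def aggregate_replicates(values) -> float:
    """Median of one subject's replicate measurements, ignoring missing
    replicates; NaN when every replicate is missing.

    Even counts take the midpoint of the two central values.
    """
    arr = np.asarray(values, dtype=float)
    if np.all(np.isnan(arr)):
        return float("nan")
    return float(np.nanmedian(arr))


def collapse_replicates(block: VariableBlock) -> VariableBlock:
    """Collapse a (subject, replicate)-indexed block to one median row
    per subject, preserving first-appearance subject order."""
    df = block.values
    if "replicate" not in (df.index.names or []):
        raise SchemaError(
            f"block {block.name!r} has no replicate level to collapse"
        )
    order = df.index.get_level_values("subject_id").unique()
    with warnings.catch_warnings():
        # all-NaN replicate sets legitimately propagate NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        collapsed = df.groupby(level="subject_id", sort=False).median().reindex(order)
    collapsed.index.name = "subject_id"
    return VariableBlock(block.name, block.role, collapsed)


def impute_missing(block: VariableBlock, groups: pd.Series) -> VariableBlock:
    """Replace each missing cell by the median of the observed values of
    the same variable within the same group.

    Observed cells are untouched; a variable with no observed value in
    some group is a hard error (there is nothing to impute from).
    """
    if not groups.index.equals(block.values.index):
        raise SchemaError("group labels do not match the block rows")
    df = block.values.copy()
    for g, sub in df.groupby(groups, sort=False):
        for col in df.columns:
            col_vals = sub[col]
            if col_vals.isna().all():
                raise ValueError(
                    f"cannot impute variable {col!r}: no observed value in group {g!r}"
                )
            if col_vals.isna().any():
                df.loc[col_vals.index[col_vals.isna()], col] = col_vals.median()
    return VariableBlock(block.name, block.role, df)


def assemble_dataset(
    tables: dict[str, pd.DataFrame],
    manifest: dict,
    groups: pd.Series | None = None,
) -> MultiblockDataset:
    """Align per-block subject tables into one multiblock dataset.

    ``manifest`` lists blocks in order as {"blocks": [{"name", "role",
    "variables"?}, ...]} with exactly one response entry. Subjects are
    restricted to the sorted intersection across all blocks (multiblock
    PLS needs complete rows); dropped subjects are logged.
    """
    entries = manifest["blocks"]
    roles = [e["role"] for e in entries]
    if roles.count(ROLE_RESPONSE) != 1:
        raise SchemaError("manifest must declare exactly one response block")
    unknown = [e["name"] for e in entries if e["name"] not in tables]
    if unknown:
        raise SchemaError(f"manifest names blocks absent from the input: {unknown}")

    common = None
    for e in entries:
        df = tables[e["name"]]
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise SchemaError(f"block {e['name']!r} has duplicate subject rows: {dupes}")
        ids = set(df.index)
        common = ids if common is None else common & ids
    if not common:
        raise SchemaError("no subject is present in every block")
    order = sorted(common)
    all_ids = set().union(*(set(tables[e["name"]].index) for e in entries))
    dropped = sorted(all_ids - common)
    if dropped:
        logger.info("dropping subjects absent from some block: %s", dropped)

    y = None
    xs = []
    for e in entries:
        df = tables[e["name"]].loc[order]
        if "variables" in e:
            missing_cols = [v for v in e["variables"] if v not in df.columns]
            if missing_cols:
                raise SchemaError(
                    f"block {e['name']!r} lacks declared variables {missing_cols}"
                )
            df = df[e["variables"]]
        blk = VariableBlock(e["name"], e["role"], df)
        if e["role"] == ROLE_RESPONSE:
            y = blk
        else:
            xs.append(blk)
    if groups is not None:
        groups = groups.loc[order]
    return MultiblockDataset(y=y, x_blocks=xs, groups=groups)


def prepare_dataset(replicate_dataset: MultiblockDataset) -> MultiblockDataset:
    """Full feature pipeline: median-collapse replicates, then impute
    remaining missing cells group-wise, returning a subject-level
    dataset ready for model fitting.

    Group labels are carried down from the replicate level (one label
    per subject; replicate rows of one subject must agree).
    """
    groups_rep = replicate_dataset.groups
    subj_groups = (
        groups_rep.groupby(level="subject_id", sort=False).first()
        if "replicate" in (groups_rep.index.names or [])
        else groups_rep
    )
    y = collapse_replicates(replicate_dataset.y)
    subj_groups = subj_groups.reindex(y.values.index)
    y = impute_missing(y, subj_groups) if y.values.isna().any().any() else y
    xs = []
    for blk in replicate_dataset.x_blocks:
        collapsed = collapse_replicates(blk)
        xs.append(impute_missing(collapsed, subj_groups))
    return MultiblockDataset(y=y, x_blocks=xs, groups=subj_groups)
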