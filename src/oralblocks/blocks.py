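"""Subject-aligned variable blocks and multiblock dataset containers.

A multiblock dataset couples one response block (the aroma-release
parameters extracted from nosespace curves) with an ordered set of
predictor blocks describing oral physiology: bolus rheology, mouth
coating / oral volume / bolus moistening, electromyography of the
masticatory muscles, and resting and stimulated saliva composition.
All blocks share the same subjects in the same row order, which is the
alignment multiblock PLS requires.

Datasets round-trip through plain text: one CSV per block plus a JSON
manifest, or a single wide CSV plus a JSON block-boundary index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ROLE_RESPONSE = "response"
ROLE_PREDICTOR = "predictor"

#: Default block schema of the study design: nine release parameters
#: explained by five physiological blocks.
DEFAULT_BLOCK_SCHEMA = {
    "Y": [
        "A1", "A2", "A1/A2",
        "Imax1", "Tmax1", "Imax1/Tmax1",
        "Imax2", "Tmax2", "Imax2/Tmax2",
    ],
    "X1": ["S_flow", "S_part", "H_part", "K_flow", "H_flow", "H_end", "S_end"],
    "X2": ["QRB_%", "Moist_%", "Oral_vol."],
    "X3": ["Nb_cycle", "Chew_time", "Ampl.", "W_total"],
    "X4": [
        "Sf_R", "Prot_R", "Lipolysis_R", "Amylase_R",
        "Lysozyme_R", "Proteolysis_R", "Na_R", "K_R",
    ],
    "X5": [
        "Sf_S", "Prot_S", "Lipolysis_S", "Amylase_S",
        "Lysozyme_S", "Proteolysis_S", "Na_S", "K_S",
    ],
}

#: Human-readable block labels used in reports and figures.
BLOCK_LABELS = {
    "Y": "aroma release",
    "X1": "rheology",
    "X2": "coating-volume-moistening",
    "X3": "EMG",
    "X4": "resting saliva",
    "X5": "stimulated saliva",
}


class SchemaError(ValueError):
    """Raised when block tables disagree with the declared schema."""


@dataclass
class VariableBlock:
    """One named block of variables for a common set of rows.

    ``values`` is a DataFrame whose index identifies rows (subjects, or
    subject/replicate pairs at the replicate level) and whose columns
    are the block's variables. Missing cells are NaN.
    """

    name: str
    role: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.role not in (ROLE_RESPONSE, ROLE_PREDICTOR):
            raise SchemaError(
                f"block {self.name!r}: role must be "
                f"{ROLE_RESPONSE!r} or {ROLE_PREDICTOR!r}, got {self.role!r}"
            )
        self.values = self.values.astype(float)

    @property
    def variable_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "VariableBlock":
        return VariableBlock(self.name, self.role, self.values.copy())


@dataclass
class MultiblockDataset:
    """One response block plus ordered predictor blocks, row-aligned.

    ``groups`` labels each row for group-wise imputation (e.g. the
    cheese product); a single shared label means dataset-wide medians.
    """

    y: VariableBlock
    x_blocks: list[VariableBlock]
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.y.role != ROLE_RESPONSE:
            raise SchemaError("y block must have role 'response'")
        idx = self.y.values.index
        for blk in self.x_blocks:
            if blk.role != ROLE_PREDICTOR:
                raise SchemaError(f"block {blk.name!r} must have role 'predictor'")
            if not blk.values.index.equals(idx):
                raise SchemaError(
                    f"block {blk.name!r} rows do not match the response block"
                )
        if self.groups is None:
            self.groups = pd.Series("all", index=idx, name="group")
        elif not self.groups.index.equals(idx):
            raise SchemaError("group labels do not match the block rows")

    @property
    def subject_ids(self) -> list:
        return list(self.y.values.index)

    @property
    def n_rows(self) -> int:
        return self.y.values.shape[0]

    @property
    def blocks(self) -> list[VariableBlock]:
        return [self.y, *self.x_blocks]

    def block(self, name: str) -> VariableBlock:
        for blk in self.blocks:
            if blk.name == name:
                return blk
        raise KeyError(name)

    def drop_rows(self, labels: Iterable) -> "MultiblockDataset":
        """Dataset without the given row labels (used by leave-one-out CV)."""
        labels = list(labels)
        return MultiblockDataset(
            y=VariableBlock(self.y.name, self.y.role, self.y.values.drop(index=labels)),
            x_blocks=[
                VariableBlock(b.name, b.role, b.values.drop(index=labels))
                for b in self.x_blocks
            ],
            groups=self.groups.drop(index=labels),
        )

    def select_rows(self, labels: Sequence) -> "MultiblockDataset":
        labels = list(labels)
        return MultiblockDataset(
            y=VariableBlock(self.y.name, self.y.role, self.y.values.loc[labels]),
            x_blocks=[
                VariableBlock(b.name, b.role, b.values.loc[labels])
                for b in self.x_blocks
            ],
            groups=self.groups.loc[labels],
        )

    # ---------------------------------------------------------------- I/O

    def to_wide(self) -> tuple[pd.DataFrame, dict]:
        """Single wide table plus a JSON-serializable block index."""
        frames = [b.values for b in self.blocks]
        wide = pd.concat(frames, axis=1)
        index = {
            "blocks": [
                {"name": b.name, "role": b.role, "variables": b.variable_names}
                for b in self.blocks
            ]
        }
        return wide, index

    def save(self, out_dir: str | Path) -> None:
        """Write ``dataset.csv`` (wide) + ``blocks.json`` + ``groups.csv``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        wide, index = self.to_wide()
        wide.to_csv(out / "dataset.csv", index_label="subject_id")
        (out / "blocks.json").write_text(json.dumps(index, indent=2) + "\n")
        self.groups.to_frame().to_csv(out / "groups.csv", index_label="subject_id")

    @classmethod
    def load(cls, in_dir: str | Path) -> "MultiblockDataset":
        in_dir = Path(in_dir)
        wide = pd.read_csv(in_dir / "dataset.csv", index_col="subject_id")
        index = json.loads((in_dir / "blocks.json").read_text())
        groups_path = in_dir / "groups.csv"
        groups = None
        if groups_path.exists():
            groups = pd.read_csv(groups_path, index_col="subject_id")["group"]
        y = None
        xs = []
        for entry in index["blocks"]:
            blk = VariableBlock(
                entry["name"], entry["role"], wide[entry["variables"]]
            )
            if entry["role"] == ROLE_RESPONSE:
                if y is not None:
                    raise SchemaError("manifest declares more than one response block")
                y = blk
            else:
                xs.append(blk)
        if y is None:
            raise SchemaError("manifest declares no response block")
        return cls(y=y, x_blocks=xs, groups=groups)
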