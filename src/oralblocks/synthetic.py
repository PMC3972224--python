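"""Synthetic multiblock datasets and analytic release curves.

The raw cohort behind the study design this package targets is not
publicly deposited, so every downstream stage is exercised against
simulated data with known ground truth. The generator emulates the
study layout: 48 subjects, one response block of nine aroma-release
parameters, five physiological predictor blocks of sizes 7/3/4/8/8,
triplicate measurements, and sporadic missing values.

Data are generated from a low-rank latent model

    X_b = Z L_b' + E_b,    Y = Z Q' + F,

with subject scores ``Z`` drawn i.i.d. standard normal and loading
columns drawn as unit-norm random vectors scaled by a configurable
magnitude. Blocks not carrying a component's signal receive a zero
loading column, so with no noise every block is exactly low rank. By
default the first latent component loads on the EMG-like block and the
second on the rheology-like block, mirroring the masticatory-dominance
structure the analysis is designed to detect.

Release curves are piecewise-linear two-phase archetypes (a chewing
triangle up to the first swallow, a post-swallow triangle back to
baseline). Real nosespace curves are smoother, but triangles have
closed-form areas, which makes the parameter-extraction contract
testable exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .blocks import (
    DEFAULT_BLOCK_SCHEMA,
    ROLE_PREDICTOR,
    ROLE_RESPONSE,
    MultiblockDataset,
    VariableBlock,
)
from .curves import ReleaseCurve


class ConfigError(ValueError):
    """Raised when a synthetic configuration violates its invariants."""


def _default_block_signal() -> dict[int, dict[str, float]]:
    # Component 1: dominant masticatory (EMG) signal; component 2: bolus
    # rheology. Remaining blocks carry noise only.
    return {0: {"X3": 3.0}, 1: {"X1": 2.0}}


def _default_y_signal() -> dict[int, float]:
    return {0: 2.0, 1: 1.5}


@dataclass
class SyntheticConfig:
    """Study-shaped generator settings.

    Parameters
    ----------
    n_subjects
        Cohort size; default 48 as in the emulated design.
    block_sizes
        Variables per block, ordered Y, X1..X5; defaults 9/7/3/4/8/8.
    n_latent
        Number of true latent components linking X blocks to Y.
    block_signal
        Per component, the predictor blocks carrying its signal and the
        loading magnitude (unitless).
    y_signal
        Per component, the loading magnitude onto the response block.
    noise_sd
        Standard deviation of the additive Gaussian noise, per block
        (same units as the generated variables).
    n_replicates
        Independent noisy realizations per subject (triplicates by
        default); downstream features collapse them by median.
    missing_rate
        Fraction of predictor cells set missing, uniformly at random.
    seed
        Seed for all randomness; identical configs generate identical
        data bit for bit.
    """

    n_subjects: int = 48
    block_sizes: tuple[int, ...] = (9, 7, 3, 4, 8, 8)
    n_latent: int = 2
    block_signal: dict[int, dict[str, float]] = field(
        default_factory=_default_block_signal
    )
    y_signal: dict[int, float] = field(default_factory=_default_y_signal)
    noise_sd: float = 0.5
    n_replicates: int = 3
    missing_rate: float = 0.02
    seed: int = 0

    @property
    def block_names(self) -> list[str]:
        return ["Y"] + [f"X{i}" for i in range(1, len(self.block_sizes))]

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("n_subjects: need at least 2 subjects")
        if len(self.block_sizes) < 2 or any(p < 1 for p in self.block_sizes):
            raise ConfigError("block_sizes: need Y plus >=1 X block, all sizes >= 1")
        if not (1 <= self.n_latent <= self.n_subjects - 1):
            raise ConfigError("n_latent: must lie in [1, n_subjects - 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd: must be >= 0")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates: must be >= 1")
        if not (0 <= self.missing_rate < 1):
            raise ConfigError("missing_rate: must lie in [0, 1)")
        names = set(self.block_names[1:])
        for comp, mapping in self.block_signal.items():
            if not (0 <= comp < self.n_latent):
                raise ConfigError(f"block_signal: component {comp} out of range")
            unknown = set(mapping) - names
            if unknown:
                raise ConfigError(f"block_signal: unknown blocks {sorted(unknown)}")
        for comp in self.y_signal:
            if not (0 <= comp < self.n_latent):
                raise ConfigError(f"y_signal: component {comp} out of range")


@dataclass
class SyntheticTruth:
    """The generating latent structure, recorded exactly as used."""

    latent_scores: np.ndarray  # n_subjects x n_latent
    block_loadings: dict[str, np.ndarray]  # per X block: p_b x n_latent
    y_loadings: np.ndarray  # p_y x n_latent

    def to_json(self) -> dict:
        return {
            "latent_scores": self.latent_scores.tolist(),
            "block_loadings": {k: v.tolist() for k, v in self.block_loadings.items()},
            "y_loadings": self.y_loadings.tolist(),
        }


def _variable_names(config: SyntheticConfig) -> dict[str, list[str]]:
    """Table-style variable names where the sizes match the study schema,
    generic names otherwise."""
    out = {}
    for name, p in zip(config.block_names, config.block_sizes):
        schema = DEFAULT_BLOCK_SCHEMA.get(name)
        if schema is not None and len(schema) == p:
            out[name] = list(schema)
        else:
            out[name] = [f"{name}_v{j + 1}" for j in range(p)]
    return out


def _loading_matrix(
    rng: np.random.Generator, p: int, magnitudes: dict[int, float], n_latent: int
) -> np.ndarray:
    """Unit-norm random columns scaled by the configured magnitudes;
    zero columns for components without signal in this block."""
    L = np.zeros((p, n_latent))
    for comp, mag in magnitudes.items():
        v = rng.standard_normal(p)
        v /= np.linalg.norm(v)
        L[:, comp] = mag * v
    return L


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[MultiblockDataset, SyntheticTruth]:
    """Simulate a replicate-level multiblock dataset with known truth.

    Rows of the returned dataset are (subject, replicate) pairs; the
    features stage collapses replicates by median and imputes missing
    predictor cells by group median, as the emulated protocol does.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = config.block_names
    var_names = _variable_names(config)

    Z = rng.standard_normal((config.n_subjects, config.n_latent))
    y_mags = {c: m for c, m in config.y_signal.items()}
    Q = _loading_matrix(rng, config.block_sizes[0], y_mags, config.n_latent)
    loadings: dict[str, np.ndarray] = {}
    for name, p in zip(names[1:], config.block_sizes[1:]):
        mags = {
            comp: mapping[name]
            for comp, mapping in config.block_signal.items()
            if name in mapping
        }
        loadings[name] = _loading_matrix(rng, p, mags, config.n_latent)
    truth = SyntheticTruth(latent_scores=Z, block_loadings=loadings, y_loadings=Q)

    subjects = [f"S{i + 1:02d}" for i in range(config.n_subjects)]
    index = pd.MultiIndex.from_product(
        [subjects, list(range(1, config.n_replicates + 1))],
        names=["subject_id", "replicate"],
    )

    def realize(signal: np.ndarray, p: int) -> np.ndarray:
        # signal: n_subjects x p; replicate as independent noise draws
        reps = []
        for _ in range(config.n_replicates):
            reps.append(signal + config.noise_sd * rng.standard_normal((len(subjects), p)))
        # interleave so rows follow the (subject, replicate) MultiIndex order
        stacked = np.stack(reps, axis=1)  # n_subjects x n_reps x p
        return stacked.reshape(len(subjects) * config.n_replicates, p)

    y_values = realize(Z @ Q.T, config.block_sizes[0])
    y_block = VariableBlock(
        "Y", ROLE_RESPONSE, pd.DataFrame(y_values, index=index, columns=var_names["Y"])
    )
    x_blocks = []
    for name, p in zip(names[1:], config.block_sizes[1:]):
        vals = realize(Z @ loadings[name].T, p)
        x_blocks.append(
            VariableBlock(
                name, ROLE_PREDICTOR, pd.DataFrame(vals, index=index, columns=var_names[name])
            )
        )

    if config.missing_rate > 0:
        _inject_missing(rng, x_blocks, config.missing_rate)

    groups = pd.Series("all", index=index, name="group")
    dataset = MultiblockDataset(y=y_block, x_blocks=x_blocks, groups=groups)
    return dataset, truth


def _inject_missing(
    rng: np.random.Generator, x_blocks: list[VariableBlock], rate: float, max_tries: int = 100
) -> None:
    """Blank round(rate * total X cells) cells uniformly at random.

    Redraws if any variable would lose all its observations for some
    subject's replicate set or entirely, so median aggregation and
    group-median imputation stay well-posed downstream.
    """
    sizes = [b.values.size for b in x_blocks]
    total = int(sum(sizes))
    n_missing = int(round(rate * total))
    offsets = np.cumsum([0] + sizes)
    for _ in range(max_tries):
        flat = rng.choice(total, size=n_missing, replace=False)
        masks = []
        ok = True
        for b, lo, hi in zip(x_blocks, offsets[:-1], offsets[1:]):
            local = flat[(flat >= lo) & (flat < hi)] - lo
            mask = np.zeros(b.values.shape, dtype=bool)
            mask[np.unravel_index(local, b.values.shape)] = True
            # per subject (replicate set) and variable: keep >= 1 observed
            df = pd.DataFrame(mask, index=b.values.index, columns=b.values.columns)
            if df.groupby(level="subject_id").all().any().any():
                ok = False
                break
            masks.append((b, mask))
        if ok:
            for b, mask in masks:
                b.values.values[mask] = np.nan
            return
    raise ConfigError(
        "missing_rate: could not place missing cells without emptying a "
        "subject/variable replicate set"
    )


# ------------------------------------------------------------------ curves


def generate_release_curve(
    a1_peak: float,
    t1_peak: float,
    swallow_time: float,
    a2_peak: float,
    t2_peak: float,
    end_time: float,
    sampling_dt: float = 0.1,
) -> ReleaseCurve:
    """Two-phase triangular release curve sampled on a regular grid.

    Intensity rises linearly from 0 to ``a1_peak`` at ``t1_peak``, falls
    to 0 at ``swallow_time`` (first swallow), rises again to ``a2_peak``
    at ``t2_peak`` and returns to 0 at ``end_time``. Times in seconds,
    intensities in arbitrary units.
    """
    if not (0 < t1_peak < swallow_time < t2_peak < end_time):
        raise ValueError(
            "time ordering must satisfy 0 < t1_peak < swallow_time < "
            "t2_peak < end_time"
        )
    if a1_peak < 0 or a2_peak < 0:
        raise ValueError("peak intensities must be >= 0")
    if sampling_dt <= 0:
        raise ValueError("sampling_dt must be > 0")
    time = np.arange(0.0, end_time + sampling_dt / 2, sampling_dt)
    knots_t = [0.0, t1_peak, swallow_time, t2_peak, end_time]
    knots_i = [0.0, a1_peak, 0.0, a2_peak, 0.0]
    intensity = np.interp(time, knots_t, knots_i)
    return ReleaseCurve(time=time, intensity=intensity, swallow_time=swallow_time)


# ------------------------------------------------------------------- I/O


def save_replicate_dataset(
    dataset: MultiblockDataset, truth: SyntheticTruth | None, out_dir: str | Path
) -> None:
    """One CSV per block (rows = subject x replicate, empty cell = missing),
    a JSON manifest, and the generating truth as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"blocks": []}
    for blk in dataset.blocks:
        fname = f"{blk.name}.csv"
        blk.values.to_csv(out / fname)
        manifest["blocks"].append(
            {"name": blk.name, "file": fname, "role": blk.role}
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    if truth is not None:
        (out / "truth.json").write_text(json.dumps(truth.to_json()) + "\n")


def load_replicate_dataset(in_dir: str | Path) -> MultiblockDataset:
    """Inverse of :func:`save_replicate_dataset` (truth not required)."""
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    y = None
    xs = []
    for entry in manifest["blocks"]:
        df = pd.read_csv(
            in_dir / entry["file"], index_col=["subject_id", "replicate"]
        )
        blk = VariableBlock(entry["name"], entry["role"], df)
        if entry["role"] == ROLE_RESPONSE:
            y = blk
        else:
            xs.append(blk)
    if y is None:
        raise ValueError("manifest declares no response block")
    groups = pd.Series("all", index=y.values.index, name="group")
    return MultiblockDataset(y=y, x_blocks=xs, groups=groups)


def save_release_curve(curve: ReleaseCurve, path: str | Path) -> None:
    """Two-column CSV (time_s, intensity_au) + JSON sidecar with the
    swallow annotation."""
    path = Path(path)
    df = pd.DataFrame({"time_s": curve.time, "intensity_au": curve.intensity})
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps({"swallow_time_s": curve.swallow_time, "baseline": curve.baseline})
        + "\n"
    )
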