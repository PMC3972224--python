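"""Leave-one-subject-out cross-validation and component-count choice.

Each subject is held out in turn; preprocessing statistics (centers,
scales, block balancing factors) and the MB-PLS model are recomputed on
the remaining subjects only, so no information leaks from the held-out
row. Squared prediction errors are accumulated on the preprocessed Y
scale, where the response variables contribute comparably, giving a
PRESS value for every candidate component count.

The number of components can then be chosen by the PRESS minimum, by a
PRESS plateau (stop adding components once the relative improvement
falls below a threshold), or by the explained-Y-variance increment of
the full-data fit (keep dimensions adding at least a threshold percent,
6% by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blocks import MultiblockDataset
from .mbpls import MBPLSModel, fit_mbpls

RULES = ("press_min", "press_plateau", "variance_threshold")


@dataclass
class CVResult:
    """PRESS per candidate component count plus full-fit variance
    increments.

    ``press[h-1]`` is the predictive residual error sum of squares with
    h components (squared preprocessed-Y units, summed over held-out
    subjects and response variables); ``explained_y_increment[h-1]`` is
    the percent of Y variance dimension h adds in the full-data fit.
    """

    press: np.ndarray
    explained_y_increment: np.ndarray
    n_folds: int

    @property
    def h_max(self) -> int:
        return len(self.press)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_components": np.arange(1, self.h_max + 1),
                "PRESS": self.press,
                "explained_Y_increment_pct": self.explained_y_increment,
            }
        )


class FoldError(RuntimeError):
    """A cross-validation fold failed to refit."""

    def __init__(self, fold_label, cause: Exception):
        self.fold_label = fold_label
        super().__init__(f"refit failed for held-out subject {fold_label!r}: {cause}")


def loo_cv(
    dataset: MultiblockDataset,
    h_max: int,
    full_model: MBPLSModel | None = None,
) -> CVResult:
    """Leave-one-subject-out PRESS for 1..h_max components.

    ``full_model`` (a fit on all rows with >= h_max components) may be
    passed to reuse an existing fit for the variance increments;
    otherwise it is computed here.
    """
    n = dataset.n_rows
    if n < 3:
        raise ValueError("need at least 3 subjects for leave-one-out CV")
    if not (1 <= h_max <= n - 2):
        raise ValueError(f"h_max must lie in [1, n - 2] = [1, {n - 2}]")

    if full_model is None or full_model.n_components < h_max:
        full_model = fit_mbpls(dataset, h_max)

    press = np.zeros(h_max)
    subjects = dataset.subject_ids
    for sid in subjects:
        train = dataset.drop_rows([sid])
        held = dataset.select_rows([sid])
        try:
            model = fit_mbpls(train, h_max)
        except Exception as exc:  # noqa: BLE001 - re-raised with fold context
            raise FoldError(sid, exc) from exc
        x_new = {
            b.name: b.values.to_numpy(dtype=float) for b in held.x_blocks
        }
        preds = model.predict_preprocessed(x_new)  # (H, 1, p_y)
        y_true = model.preprocessing.transform_block(
            model.y_name, held.y.values.to_numpy(dtype=float)
        )
        press += np.sum((preds - y_true[None, :, :]) ** 2, axis=(1, 2))

    return CVResult(
        press=press,
        explained_y_increment=full_model.explained_inertia_y[:h_max].copy(),
        n_folds=n,
    )


def select_n_components(
    cv: CVResult,
    rule: str = "variance_threshold",
    threshold: float = 6.0,
) -> int:
    """Choose the number of components from a CV result.

    Rules
    -----
    ``press_min``
        The count minimizing PRESS (earliest on ties).
    ``press_plateau``
        The smallest count whose PRESS improvement over the previous
        count is below ``threshold`` (given as a fraction of the
        previous PRESS, e.g. 0.05); falls back to ``h_max`` when PRESS
        keeps improving.
    ``variance_threshold``
        The largest count whose explained-Y increment in the full fit
        is at least ``threshold`` percent (default 6); 1 when no
        dimension reaches it.
    """
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; choose one of {RULES}")
    if rule == "press_min":
        return int(np.argmin(cv.press)) + 1
    if rule == "press_plateau":
        for h in range(2, cv.h_max + 1):
            prev, cur = cv.press[h - 2], cv.press[h - 1]
            improvement = (prev - cur) / prev if prev > 0 else 0.0
            if improvement < threshold:
                return h
        return cv.h_max
    # variance_threshold
    meets = np.nonzero(cv.explained_y_increment >= threshold)[0]
    return int(meets[-1]) + 1 if len(meets) else 1
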