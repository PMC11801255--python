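"""Global stock prediction: posterior ratios times intact-stock value sets.

Predicted absolute stocks at an age are obtained by multiplying every
posterior draw's curve ratio R(age) against every value in a literature set
of intact stocks for the same compartment (an exhaustive draw x value cross
product).  Net gain over a horizon is the per-draw difference
(R(t_end) - R(0+)) scaled by the same intact values, with R(0+) evaluated by
the curve's age-zero limit rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import PosteriorSamples, _curve_matrix

#: above this many draw x value products, draws are subsampled (seeded)
MAX_CROSS_PRODUCT = 10_000_000


@dataclass(frozen=True)
class IntactStockSet:
    """A set of literature intact-stand stock values for one compartment."""

    compartment: str  # agb | bgb | soil
    values: tuple[float, ...]  # MgC ha^-1
    source: str = "unspecified"

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("intact value set must be non-empty")
        if any(v <= 0 for v in self.values):
            raise ValueError("intact stocks must be positive")

    @classmethod
    def from_csv(cls, path: str | Path, compartment: str) -> "IntactStockSet":
        """Read a single-column CSV of intact stocks (header = column name)."""
        df = pd.read_csv(path)
        col = df.columns[0]
        return cls(
            compartment=compartment,
            values=tuple(float(v) for v in df[col].dropna()),
            source=str(path),
        )


def _ratio_draws(
    samples: PosteriorSamples, ages: np.ndarray, n_values: int, seed: int | None
) -> np.ndarray:
    """Curve ratios per draw x age, subsampling draws if the cross product is huge."""
    n_draws = len(samples)
    matrix = _curve_matrix(samples, ages)
    if n_draws * n_values > MAX_CROSS_PRODUCT:
        keep = MAX_CROSS_PRODUCT // max(n_values, 1)
        rng = np.random.default_rng(0 if seed is None else seed)
        idx = rng.choice(n_draws, size=max(keep, 1), replace=False)
        matrix = matrix[idx]
    return matrix


def predict_stocks(
    samples: PosteriorSamples,
    intact: IntactStockSet,
    ages: Sequence[float],
    seed: int | None = None,
) -> pd.DataFrame:
    """Predicted stock distribution per age: mean and equal-tailed 95% interval.

    The distribution at each age is {R(draw, age) x v} over all posterior
    draws and all intact values; the stratum's compartment must match the
    intact set's.
    """
    if samples.stratum.compartment != intact.compartment:
        raise ValueError(
            f"compartment mismatch: samples are {samples.stratum.compartment}, "
            f"intact values are {intact.compartment}"
        )
    ages_arr = np.asarray(ages, dtype=float)
    values = np.asarray(intact.values, dtype=float)
    ratios = _ratio_draws(samples, ages_arr, len(values), seed)  # (draws, ages)
    rows = []
    for k, age in enumerate(ages_arr):
        products = np.multiply.outer(ratios[:, k], values).ravel()
        rows.append(
            {
                "age_yr": age,
                "mean": float(products.mean()),
                "q2.5": float(np.quantile(products, 0.025)),
                "q97.5": float(np.quantile(products, 0.975)),
            }
        )
    return pd.DataFrame(rows)


def net_gain(
    samples: PosteriorSamples,
    intact: IntactStockSet,
    t_end: float = 40.0,
    seed: int | None = None,
) -> pd.Series:
    """Distribution of the net stock gain (R(t_end) - R(0+)) x intact values.

    R(0+) uses the curve's age-zero limit; gains can be negative for draws
    with a falling curve.  Returns mean and equal-tailed 95% interval in
    MgC ha^-1.
    """
    if not t_end > 0:
        raise ValueError("t_end must be > 0")
    if samples.stratum.compartment != intact.compartment:
        raise ValueError("compartment mismatch")
    values = np.asarray(intact.values, dtype=float)
    ratios = _ratio_draws(samples, np.array([0.0, t_end]), len(values), seed)
    delta = ratios[:, 1] - ratios[:, 0]
    gains = np.multiply.outer(delta, values).ravel()
    return pd.Series(
        {
            "mean": float(gains.mean()),
            "q2.5": float(np.quantile(gains, 0.025)),
            "q97.5": float(np.quantile(gains, 0.975)),
            "t_end": float(t_end),
        }
    )


def ecosystem_net_gain(per_compartment: Sequence[pd.Series]) -> pd.Series:
    """Sum per-compartment mean net gains into an ecosystem-level gain.

    Interval endpoints are summed too, giving a conservative bound that
    ignores cross-compartment posterior correlation (compartments are fit
    independently).
    """
    mean = sum(float(s["mean"]) for s in per_compartment)
    lo = sum(float(s["q2.5"]) for s in per_compartment)
    hi = sum(float(s["q97.5"]) for s in per_compartment)
    return pd.Series({"mean": mean, "q2.5": lo, "q97.5": hi})
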