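"""Per-pair observations: contact counts plus bias covariates.

A single contact-matrix entry carries the observed count ``y`` and four
covariates used by the bias regression: genomic distance ``D`` (bp between
bin midpoints), average GC fraction ``GC``, average transposable-element
count ``TE`` and average DNA-accessibility score ``ACC`` of the two bins.
All four must be strictly positive because the regression acts on their
logs.  ``Observations`` is the vectorized table the sampler consumes;
``PairObservation`` is the scalar record for single entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = ["PairObservation", "Observations", "COVARIATE_NAMES"]

COVARIATE_NAMES = ("D", "GC", "TE", "ACC")


class PairObservation(NamedTuple):
    i: int
    j: int
    y: int
    D: float
    GC: float
    TE: float
    ACC: float


@dataclass(frozen=True)
class Observations:
    """Column-oriented collection of pair observations.

    ``design`` is the (n, 5) matrix [1, log D, log GC, log TE, log ACC]
    entering the log-linear mean model.
    """

    i: np.ndarray
    j: np.ndarray
    y: np.ndarray
    D: np.ndarray
    GC: np.ndarray
    TE: np.ndarray
    ACC: np.ndarray
    design: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.y)
        for name in ("i", "j", "y", "D", "GC", "TE", "ACC"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"field {name!r} has wrong length")
            object.__setattr__(self, name, arr)
        y = np.asarray(self.y)
        if np.any(y < 0) or not np.issubdtype(y.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        for name in COVARIATE_NAMES:
            if np.any(np.asarray(getattr(self, name), dtype=float) <= 0):
                raise ValueError(f"covariate {name} must be strictly positive")
        X = np.column_stack(
            [
                np.ones(n),
                np.log(np.asarray(self.D, dtype=float)),
                np.log(np.asarray(self.GC, dtype=float)),
                np.log(np.asarray(self.TE, dtype=float)),
                np.log(np.asarray(self.ACC, dtype=float)),
            ]
        )
        object.__setattr__(self, "design", X)

    def __len__(self) -> int:
        return len(self.y)

    def row(self, s: int) -> PairObservation:
        return PairObservation(
            int(self.i[s]), int(self.j[s]), int(self.y[s]),
            float(self.D[s]), float(self.GC[s]), float(self.TE[s]), float(self.ACC[s]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"i": self.i, "j": self.j, "y": self.y,
             "D": self.D, "GC": self.GC, "TE": self.TE, "ACC": self.ACC}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Observations":
        return cls(
            i=df["i"].to_numpy(np.int64),
            j=df["j"].to_numpy(np.int64),
            y=df["y"].to_numpy(np.int64),
            D=df["D"].to_numpy(float),
            GC=df["GC"].to_numpy(float),
            TE=df["TE"].to_numpy(float),
            ACC=df["ACC"].to_numpy(float),
        )
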