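"""Indirect standardization: reference rates, expected counts, SIRs.

Expected counts use study-region-internal reference rates by sex and age
group, z_k = sum_i Y_ik / sum_i N_ik, so that sum_i E_i = sum_i Y_i and
the population-weighted mean SIR is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

SEXES = ("F", "M")
AGE_GROUPS = ("65-69", "70-74", "75-79", "80-84", "85+")
#: stratum labels in canonical column order: sex-major, age within sex
STRATA = tuple(f"{s}:{a}" for s in SEXES for a in AGE_GROUPS)
K = len(STRATA)


@dataclass
class StratumTable:
    """Per-area, per-stratum person counts N_ik and case counts Y_ik.

    Strata default to the 10 sex x age-group cells in :data:`STRATA`
    order; smaller custom stratifications are accepted for toy data.
    Case counts are events over a multi-year window and are deliberately
    not capped at N.
    """

    area_ids: list
    N: np.ndarray
    Y: np.ndarray
    strata: tuple = STRATA

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N)
        self.Y = np.asarray(self.Y)
        self.strata = tuple(self.strata)
        n, k = len(self.area_ids), len(self.strata)
        if self.N.shape != (n, k) or self.Y.shape != (n, k):
            raise ValueError(f"N and Y must be ({n}, {k}) arrays")
        for name, arr in (("N", self.N), ("Y", self.Y)):
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative counts")
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.allclose(arr, np.round(arr)):
                    raise ValueError(f"{name} contains non-integer counts")

    @property
    def n(self) -> int:
        return len(self.area_ids)

    @property
    def area_totals(self) -> np.ndarray:
        """Y_i = sum_k Y_ik."""
        return self.Y.sum(axis=1)

    @property
    def population_totals(self) -> np.ndarray:
        return self.N.sum(axis=1)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, aid in enumerate(self.area_ids):
            for k, label in enumerate(self.strata):
                sex, age = label.split(":")
                rows.append((aid, sex, age, int(self.N[i, k]), int(self.Y[i, k])))
        return pd.DataFrame(rows, columns=["area_id", "sex", "age_group", "N", "Y"])

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame) -> "StratumTable":
        frame = frame.copy()
        frame["stratum"] = frame["sex"].astype(str) + ":" + frame["age_group"].astype(str)
        observed = list(dict.fromkeys(frame["stratum"]))
        if set(observed) <= set(STRATA):
            strata = STRATA  # canonical sex x age order
        else:
            strata = tuple(observed)
        area_ids = list(dict.fromkeys(frame["area_id"]))
        idx = {a: i for i, a in enumerate(area_ids)}
        kdx = {s: k for k, s in enumerate(strata)}
        N = np.zeros((len(area_ids), len(strata)), dtype=int)
        Y = np.zeros((len(area_ids), len(strata)), dtype=int)
        for r in frame.itertuples():
            N[idx[r.area_id], kdx[r.stratum]] = r.N
            Y[idx[r.area_id], kdx[r.stratum]] = r.Y
        return cls(area_ids, N, Y, strata)


@dataclass
class ReferenceRates:
    """Study-wide stratum rates z_k (cases per person over the study window)."""

    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 1:
            raise ValueError("z must be a vector of stratum rates")
        if np.any(self.z < 0):
            raise ValueError("rates must be nonnegative")


def reference_rates(table: StratumTable) -> ReferenceRates:
    """Internally standardized rates z_k = sum_i Y_ik / sum_i N_ik."""
    n_k = table.N.sum(axis=0)
    if np.any(n_k == 0):
        empty = [table.strata[k] for k in np.where(n_k == 0)[0]]
        raise ValueError(f"strata with zero total population: {empty}")
    return ReferenceRates(table.Y.sum(axis=0) / n_k)


def expected_counts(table: StratumTable, z: ReferenceRates) -> np.ndarray:
    """E_i = sum_k N_ik z_k."""
    if z.z.shape[0] != len(table.strata):
        raise ValueError("rate vector length does not match table strata")
    return table.N @ z.z


class SirResult(NamedTuple):
    ratio: np.ndarray
    flags: np.ndarray  # "ok" | "zero_zero" | "undefined"


def sir(Y: np.ndarray, E: np.ndarray) -> SirResult:
    """Standardized incidence ratios Y_i / E_i with flags, never exceptions.

    E=0, Y=0 is reported as 0 with flag "zero_zero"; E=0, Y>0 is NaN with
    flag "undefined".
    """
    Y = np.asarray(Y, dtype=float)
    E = np.asarray(E, dtype=float)
    if Y.shape != E.shape:
        raise ValueError("Y and E must have the same length")
    ratio = np.zeros_like(Y)
    flags = np.full(Y.shape, "ok", dtype=object)
    ok = E > 0
    ratio[ok] = Y[ok] / E[ok]
    zz = (~ok) & (Y == 0)
    flags[zz] = "zero_zero"
    und = (~ok) & (Y > 0)
    ratio[und] = np.nan
    flags[und] = "undefined"
    return SirResult(ratio, flags)


def standardization_frame(table: StratumTable) -> pd.DataFrame:
    """Per-area expected counts and SIRs as a DataFrame (CSV-ready)."""
    z = reference_rates(table)
    E = expected_counts(table, z)
    Y = table.area_totals
    s = sir(Y, E)
    return pd.DataFrame(
        {
            "area_id": table.area_ids,
            "Y": Y,
            "E": E,
            "SIR": s.ratio,
            "flag": s.flags,
        }
    )
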