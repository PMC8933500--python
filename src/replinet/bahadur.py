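"""Bahadur expansion of pairwise replicator interactions.

For a focal RNA *i* measured with and without two partner RNAs *j* and *k*,
the log10 fold replication over the four presence/absence combinations is
decomposed on the orthogonal design

    log10(fold_i) = f0 + w_j z_j + w_k z_k + w_jk z_j z_k,
    z = +1 (partner present) / -1 (partner absent),

an exactly determined 4x4 system whose solution is f0 = mean(y) and
w_x = mean(z_x * y). Each first- and second-order coefficient carries a
coefficient of determination

    R^2_x = w_x^2 / (sum((y - f0)^2) / 4),

and because the design is orthogonal the three R^2 terms sum to 1 whenever
the responses vary. A first-order R^2 sum below 1 signals a higher-order
(interactive) effect of the partner pair on the focal RNA's replication.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DESIGN_POINTS",
    "TripletDesign",
    "BahadurCoefficients",
    "fit_bahadur",
    "r_squared",
    "interaction_test",
    "fit_table",
]

#: canonical order of the four (z_j, z_k) design points
DESIGN_POINTS: tuple[tuple[int, int], ...] = ((-1, -1), (1, -1), (-1, 1), (1, 1))

_VAR_EPS = 1e-24  # responses are O(1) log10 folds; below this is no variance


@dataclass(frozen=True)
class TripletDesign:
    """Four log10 fold-replication responses of one focal RNA.

    ``responses`` maps each (z_j, z_k) design point to the log10 fold
    replication of the focal RNA under that partner combination.
    """

    focal: str
    partner_j: str
    partner_k: str
    responses: Mapping[tuple[int, int], float]

    def __post_init__(self) -> None:
        keys = set(self.responses)
        if keys != set(DESIGN_POINTS):
            raise ValueError(
                f"design must contain exactly the four points {DESIGN_POINTS}, got {sorted(keys)}"
            )
        for point, y in self.responses.items():
            if not math.isfinite(y):
                raise ValueError(f"non-finite response {y} at design point {point}")

    @property
    def y(self) -> np.ndarray:
        """Responses in canonical design order."""
        return np.array([self.responses[p] for p in DESIGN_POINTS], dtype=float)

    @classmethod
    def from_folds(
        cls,
        focal: str,
        partner_j: str,
        partner_k: str,
        folds: Mapping[tuple[int, int], float | Sequence[float]],
    ) -> "TripletDesign":
        """Build a design from raw folds; replicates are averaged in log space."""
        responses = {}
        for point, value in folds.items():
            values = np.atleast_1d(np.asarray(value, dtype=float))
            if (values <= 0).any():
                raise ValueError(f"folds must be > 0 at design point {point}")
            responses[point] = float(np.mean(np.log10(values)))
        return cls(focal=focal, partner_j=partner_j, partner_k=partner_k, responses=responses)


@dataclass(frozen=True)
class BahadurCoefficients:
    """Fitted Bahadur coefficients and per-term R^2 for one triplet."""

    f0: float
    w_j: float
    w_k: float
    w_jk: float
    r2_j: float | None
    r2_k: float | None
    r2_jk: float | None
    no_variance: bool

    @property
    def first_order_r2(self) -> float | None:
        if self.no_variance:
            return None
        return self.r2_j + self.r2_k


def fit_bahadur(design: TripletDesign) -> BahadurCoefficients:
    """Exact solution of the orthogonal four-point system.

    f0 = mean(y); w_j = mean(z_j y); w_k = mean(z_k y); w_jk = mean(z_j z_k y).
    Constant responses yield zero coefficients with ``no_variance`` set and
    indeterminate R^2 terms.
    """
    y = design.y
    zj = np.array([p[0] for p in DESIGN_POINTS], dtype=float)
    zk = np.array([p[1] for p in DESIGN_POINTS], dtype=float)
    f0 = float(y.mean())
    w_j = float((zj * y).mean())
    w_k = float((zk * y).mean())
    w_jk = float((zj * zk * y).mean())
    var = float(((y - f0) ** 2).sum() / 4)
    if var < _VAR_EPS:
        return BahadurCoefficients(
            f0=f0, w_j=0.0, w_k=0.0, w_jk=0.0,
            r2_j=None, r2_k=None, r2_jk=None, no_variance=True,
        )
    return BahadurCoefficients(
        f0=f0, w_j=w_j, w_k=w_k, w_jk=w_jk,
        r2_j=w_j**2 / var, r2_k=w_k**2 / var, r2_jk=w_jk**2 / var,
        no_variance=False,
    )


def r_squared(coefficients: BahadurCoefficients, design: TripletDesign) -> dict[str, float | None]:
    """Per-term R^2 recomputed from the design (independent of the fit path)."""
    y = design.y
    var = float(((y - y.mean()) ** 2).sum() / 4)
    if var < _VAR_EPS:
        return {"r2_j": None, "r2_k": None, "r2_jk": None}
    return {
        "r2_j": coefficients.w_j**2 / var,
        "r2_k": coefficients.w_k**2 / var,
        "r2_jk": coefficients.w_jk**2 / var,
    }


def interaction_test(coefficients: BahadurCoefficients, tolerance: float = 0.05) -> bool | None:
    """Is a higher-order (pairwise-interactive) effect present?

    True iff ``R^2_j + R^2_k < 1 - tolerance``; a first-order sum of 1
    means the partners act additively on the focal RNA's log replication.
    Returns ``None`` (indeterminate) for zero-variance designs.
    """
    if tolerance > 1:
        warnings.warn(
            "tolerance > 1 can never detect an interaction (degenerate configuration)",
            stacklevel=2,
        )
    if coefficients.no_variance:
        warnings.warn("zero-variance design: interaction indeterminate", stacklevel=2)
        return None
    return (coefficients.r2_j + coefficients.r2_k) < 1 - tolerance


def fit_table(designs: pd.DataFrame, tolerance: float = 0.05) -> pd.DataFrame:
    """Fit every triplet in a tidy design table.

    Expected columns: focal, partner_j, partner_k, z_j, z_k, fold
    (replicate rows allowed; they are averaged in log space). Returns one
    row per triplet with coefficients, R^2 terms and the interaction flag.
    """
    required = {"focal", "partner_j", "partner_k", "z_j", "z_k", "fold"}
    missing = required - set(designs.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    rows = []
    for (focal, pj, pk), group in designs.groupby(["focal", "partner_j", "partner_k"], sort=True):
        folds = {
            (int(zj), int(zk)): sub["fold"].tolist()
            for (zj, zk), sub in group.groupby(["z_j", "z_k"])
        }
        design = TripletDesign.from_folds(focal, pj, pk, folds)
        coef = fit_bahadur(design)
        flag = None if coef.no_variance else interaction_test(coef, tolerance)
        rows.append(
            {
                "focal": focal, "partner_j": pj, "partner_k": pk,
                "f0": coef.f0, "w_j": coef.w_j, "w_k": coef.w_k, "w_jk": coef.w_jk,
                "r2_j": coef.r2_j, "r2_k": coef.r2_k, "r2_jk": coef.r2_jk,
                "no_variance": coef.no_variance,
                "higher_order_present": flag,
            }
        )
    return pd.DataFrame(rows)
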