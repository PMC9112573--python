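"""Restricted (natural) cubic spline bases.

With k knots t_1 < ... < t_k the basis contributes k-1 regression columns:
the identity (linear term) plus k-2 truncated-cubic combinations

    s_j(x) = [ (x-t_j)_+^3
               - (x-t_{k-1})_+^3 (t_k-t_j)/(t_k-t_{k-1})
               + (x-t_k)_+^3 (t_{k-1}-t_j)/(t_k-t_{k-1}) ] / (t_k-t_1)^2

whose cubic and quadratic tail coefficients cancel, so every column (and
hence any fitted curve) is exactly linear beyond the boundary knots.  The
(t_k-t_1)^2 divisor puts the nonlinear columns on the scale of x, which
matters when they meet a shared ridge penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegeneratePredictor, InvalidArgument

#: Harrell-convention quantile positions for knot placement.
KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


@dataclass(frozen=True)
class SplineSpec:
    """Frozen knot set for one continuous predictor."""

    knots: tuple[float, ...]
    source: tuple[float, ...]  # quantile positions the knots came from

    def __post_init__(self):
        if len(self.knots) < 3:
            raise InvalidArgument("restricted cubic splines need >= 3 knots")
        if not all(a < b for a, b in zip(self.knots, self.knots[1:])):
            raise InvalidArgument(f"knots must be strictly increasing: {self.knots}")

    @property
    def n_columns(self) -> int:
        return len(self.knots) - 1


def place_knots(x, k: int = 4) -> SplineSpec:
    """Place ``k`` knots at the conventional quantiles of the observed values.

    Raises :class:`DegeneratePredictor` when fewer than ``k`` distinct finite
    values exist or the quantiles collide (e.g. a near-constant predictor).
    """
    if k not in KNOT_QUANTILES:
        raise InvalidArgument(f"unsupported knot count {k}; choose from {sorted(KNOT_QUANTILES)}")
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if np.unique(x).size < k:
        raise DegeneratePredictor(f"need >= {k} distinct values to place {k} knots")
    qs = KNOT_QUANTILES[k]
    knots = tuple(float(v) for v in np.quantile(x, qs))
    if not all(a < b for a, b in zip(knots, knots[1:])):
        raise DegeneratePredictor(f"knot quantiles collide for this predictor: {knots}")
    return SplineSpec(knots=knots, source=qs)


def rcs_basis(x, spec: SplineSpec) -> np.ndarray:
    """Evaluate the restricted cubic spline basis: n x (k-1) matrix.

    Column 0 is x itself; values outside the knot range are valid (the
    basis is linear there by construction).
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(spec.knots)
    k = t.size
    tau = (t[-1] - t[0]) ** 2
    d = t[-1] - t[-2]
    cols = [x]
    for j in range(k - 2):
        tj = t[j]
        c1 = (t[-1] - tj) / d
        c2 = (t[-2] - tj) / d
        s = (
            np.clip(x - tj, 0, None) ** 3
            - c1 * np.clip(x - t[-2], 0, None) ** 3
            + c2 * np.clip(x - t[-1], 0, None) ** 3
        ) / tau
        cols.append(s)
    return np.column_stack(cols)
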