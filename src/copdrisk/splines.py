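"""Natural cubic spline basis of age for time-dependent coefficients.

The hazard model lets the log-hazard-ratio per pack-year vary with age by
multiplying cumulative pack-years with a natural (restricted) cubic spline
basis of age.  With ``df`` degrees of freedom the basis has ``df`` columns
and is linear beyond its boundary knots, so extrapolated age effects stay
tame.

The basis here is the textbook truncated-power construction: with knots
``xi_1 < ... < xi_K`` (boundaries included) and

    d_k(x) = [ (x - xi_k)_+^3 - (x - xi_K)_+^3 ] / (xi_K - xi_k)

the natural-spline space is spanned by ``{1, x, d_1 - d_{K-1}, ...,
d_{K-2} - d_{K-1}}``.  Dropping the intercept leaves ``K - 1`` covariate
columns; ``df = 2`` therefore uses three knots (two boundary, one interior).
Columns are rescaled by the boundary span so values stay O(1) over
human age ranges:

    N_1(x) = (x - xi_1) / (xi_K - xi_1)
    N_{j+1}(x) = [ d_j(x) - d_{K-1}(x) ] / (xi_K - xi_1)^2
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SplineBasis", "build_basis", "interaction_columns"]


@dataclass(frozen=True)
class SplineBasis:
    """Natural cubic spline basis determined by its knot sequence.

    Parameters
    ----------
    boundary_knots
        ``(lo, hi)`` ages beyond which every basis function is linear.
    interior_knots
        Strictly inside ``(lo, hi)``; for ``df = 2`` there is exactly one,
        conventionally the median event age.
    """

    boundary_knots: tuple[float, float]
    interior_knots: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        lo, hi = self.boundary_knots
        if not lo < hi:
            raise ValueError(f"boundary knots must satisfy lo < hi, got ({lo}, {hi})")
        for k in self.interior_knots:
            if not lo < k < hi:
                raise ValueError(f"interior knot {k} outside boundaries ({lo}, {hi})")
        if list(self.interior_knots) != sorted(self.interior_knots):
            raise ValueError("interior knots must be sorted")

    @property
    def df(self) -> int:
        return 1 + len(self.interior_knots)

    @property
    def knots(self) -> np.ndarray:
        """All knots, boundaries included, ascending."""
        lo, hi = self.boundary_knots
        return np.asarray([lo, *self.interior_knots, hi], dtype=float)

    def evaluate(self, age) -> np.ndarray:
        """Evaluate the basis; returns shape ``(n, df)`` (or ``(df,)`` for scalars)."""
        x = np.asarray(age, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        xi = self.knots
        span = xi[-1] - xi[0]

        def d(k: int) -> np.ndarray:
            return (
                np.clip(x - xi[k], 0.0, None) ** 3
                - np.clip(x - xi[-1], 0.0, None) ** 3
            ) / (xi[-1] - xi[k])

        cols = [(x - xi[0]) / span]
        d_last = d(len(xi) - 2)
        for j in range(len(xi) - 2):
            cols.append((d(j) - d_last) / span**2)
        out = np.stack(cols, axis=-1)
        return out[0] if scalar else out

    def to_dict(self) -> dict:
        return {
            "boundary_knots": list(self.boundary_knots),
            "interior_knots": list(self.interior_knots),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineBasis":
        return cls(
            boundary_knots=tuple(d["boundary_knots"]),
            interior_knots=tuple(d["interior_knots"]),
        )


def build_basis(event_ages, df: int = 2) -> SplineBasis:
    """Place knots from observed event ages.

    Boundary knots sit at the min/max of ``event_ages``; the ``df - 1``
    interior knots at the evenly spaced quantiles in between (``df = 2``
    puts one knot at the median).  The returned basis is serialized with
    the model fit so predictions reuse the identical knots.
    """
    ages = np.asarray(event_ages, dtype=float)
    distinct = np.unique(ages)
    if distinct.size < df + 2:
        raise ValueError(
            f"need at least {df + 2} distinct ages to build a df={df} basis, "
            f"got {distinct.size}"
        )
    lo, hi = float(ages.min()), float(ages.max())
    qs = np.linspace(0, 1, df + 1)[1:-1]
    interior = tuple(float(q) for q in np.quantile(ages, qs))
    return SplineBasis(boundary_knots=(lo, hi), interior_knots=interior)


def interaction_columns(basis: SplineBasis, age, pack_years) -> np.ndarray:
    """Design columns ``B_j(age) * pack_years`` for the age-varying
    pack-years effect; shape ``(..., df)``."""
    b = basis.evaluate(age)
    py = np.asarray(pack_years, dtype=float)
    return b * py[..., None] if py.ndim else b * py
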