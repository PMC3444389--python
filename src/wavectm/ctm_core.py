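"""Central tendency measure (CTM) of the first-differences scatter plot.

Given a series x(1..N), plot x(i+2)-x(i+1) against x(i+1)-x(i) for the N-2
available points and count the fraction falling strictly inside a disk of
radius rho around the origin:

    CTM = (1/(N-2)) * sum_i [ sqrt((x(i+2)-x(i+1))^2 + (x(i+1)-x(i))^2) < rho ]

A high CTM means the series varies smoothly (points concentrate at the
origin); a low CTM means large step-to-step variability.  The radius is
normalized as a multiple of the standard deviation of the analyzed series,
which makes the measure invariant to uniform scaling and constant shifts —
only the temporal variation pattern matters, not the absolute amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CTMParams", "CTMResult", "first_differences", "ctm_absolute", "ctm_normalized"]


@dataclass(frozen=True)
class CTMParams:
    """Radius as a multiple of the input's standard deviation.

    The operating points are 3.3 (paroxysmal-AF termination mode) and 4.0
    (cardioversion-outcome mode).
    """

    rho_multiplier: float = 3.3

    def __post_init__(self) -> None:
        if not self.rho_multiplier > 0:
            raise ValueError("rho_multiplier must be > 0")


@dataclass
class CTMResult:
    ctm: float            # fraction of scatter points inside the radius, in [0, 1]
    n_points: int         # N - 2
    n_inside: int
    radius_abs: float
    input_std: float
    degenerate: bool = False  # zero-variance input convention: ctm = 1


def first_differences(x: np.ndarray) -> np.ndarray:
    """The N-2 scatter points (x(i+2)-x(i+1), x(i+1)-x(i)) as an (N-2, 2) array."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError(f"need at least 3 samples for first differences, got {len(x)}")
    d = np.diff(x)
    return np.column_stack([d[1:], d[:-1]])


def ctm_absolute(x: np.ndarray, radius_abs: float) -> CTMResult:
    """CTM with an absolute radius; points strictly inside the disk count."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    if not radius_abs > 0:
        raise ValueError("radius must be > 0")
    pts = first_differences(x)
    dist = np.hypot(pts[:, 0], pts[:, 1])
    n_inside = int(np.count_nonzero(dist < radius_abs))
    n_points = len(pts)
    return CTMResult(
        ctm=n_inside / n_points,
        n_points=n_points,
        n_inside=n_inside,
        radius_abs=float(radius_abs),
        input_std=float(np.std(x, ddof=1)),
    )


def ctm_normalized(x: np.ndarray, params: CTMParams = CTMParams()) -> CTMResult:
    """CTM with radius = rho_multiplier * sample std of the analyzed vector.

    The standard deviation uses the (N-1)-denominator sample estimator and is
    computed on the vector itself, per record.  A zero-variance input is the
    degenerate limit where every scatter point sits at the origin: the result
    is CTM = 1 with ``degenerate=True`` rather than an exception, so batch
    runs survive flat segments.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    if len(x) < 3:
        raise ValueError(f"need at least 3 samples, got {len(x)}")
    std = float(np.std(x, ddof=1))
    if std == 0.0 or np.ptp(x) == 0.0:
        n_points = len(x) - 2
        return CTMResult(
            ctm=1.0, n_points=n_points, n_inside=n_points,
            radius_abs=0.0, input_std=0.0, degenerate=True,
        )
    return ctm_absolute(x, params.rho_multiplier * std)
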