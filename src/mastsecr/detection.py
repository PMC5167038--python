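"""Half-normal detection hazard and multi-catch trap allocation.

The per-occasion detection process is governed by a half-normal hazard

    h(d) = lambda0 * exp(-d^2 / (2 sigma^2))

of an animal with activity centre at distance ``d`` from a trap entering
that trap during one occasion.  ``lambda0`` is the cumulative hazard at
distance zero and ``sigma`` (metres) is the spatial scale of detection,
a model-based index of home-range size.  With several traps competing
for the same animal the allocation follows the classical multi-catch
competing-risks form: with total hazard ``H = sum_k h_k`` the animal is
caught in trap ``k`` with probability ``(h_k / H) * (1 - exp(-H))`` and
escapes all traps with probability ``exp(-H)``.

``lambda0`` is treated throughout as a hazard, not a probability: a
per-trap probability formulation cannot coherently allocate one animal
among competing traps, whereas the hazard reading yields an exact
multinomial per occasion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DetectionParams",
    "TrapArray",
    "hazard",
    "occasion_capture_probs",
    "pdot",
]


@dataclass(frozen=True)
class DetectionParams:
    """Per-occasion detection parameters.

    Parameters
    ----------
    lambda0 : float
        Cumulative detection hazard at distance zero (> 0, dimensionless).
    sigma : float
        Spatial scale of detection in metres (> 0).
    b_mult : float, optional
        Multiplicative change in ``lambda0`` from the occasion after an
        animal's first capture within a session (global behavioural
        response; 1 means no response, > 1 trap-happy, < 1 trap-shy).
    """

    lambda0: float
    sigma: float
    b_mult: float = 1.0

    def __post_init__(self) -> None:
        if not self.lambda0 > 0:
            raise ValueError(f"lambda0 must be > 0, got {self.lambda0}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not self.b_mult > 0:
            raise ValueError(f"b_mult must be > 0, got {self.b_mult}")


@dataclass(frozen=True)
class TrapArray:
    """Detector locations for one site, planar metres."""

    trap_ids: tuple[str, ...]
    xy: np.ndarray = field(repr=False)  # (n_traps, 2) float

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy, dtype=float)
        object.__setattr__(self, "xy", xy)
        if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] < 1:
            raise ValueError("xy must be an (n_traps, 2) array with n_traps >= 1")
        if len(self.trap_ids) != xy.shape[0]:
            raise ValueError("trap_ids and xy length mismatch")
        if len(set(self.trap_ids)) != len(self.trap_ids):
            raise ValueError("trap_ids must be unique")
        if len({(x, y) for x, y in xy}) != xy.shape[0]:
            raise ValueError("trap coordinates must be unique")

    @property
    def n_traps(self) -> int:
        return self.xy.shape[0]

    def index_of(self, trap_id: str) -> int:
        try:
            return self.trap_ids.index(trap_id)
        except ValueError:
            raise KeyError(f"unknown trap_id {trap_id!r}") from None

    @classmethod
    def grid(cls, nx: int = 8, ny: int = 8, spacing: float = 10.0,
             origin: tuple[float, float] = (0.0, 0.0)) -> "TrapArray":
        """Regular ``nx`` x ``ny`` grid of traps at ``spacing`` metres."""
        ox, oy = origin
        ids, pts = [], []
        for i in range(nx):
            for j in range(ny):
                ids.append(f"T{i + 1:02d}{j + 1:02d}")
                pts.append((ox + i * spacing, oy + j * spacing))
        return cls(tuple(ids), np.asarray(pts, dtype=float))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TrapArray":
        """Build from a table with columns trap_id, x, y."""
        missing = {"trap_id", "x", "y"} - set(df.columns)
        if missing:
            raise ValueError(f"trap table missing columns: {sorted(missing)}")
        return cls(tuple(df["trap_id"].astype(str)),
                   df[["x", "y"]].to_numpy(dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"trap_id": self.trap_ids, "x": self.xy[:, 0], "y": self.xy[:, 1]})

    def distances_to(self, points: np.ndarray) -> np.ndarray:
        """Euclidean distances, shape (n_points, n_traps)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.sqrt(
            ((pts[:, None, :] - self.xy[None, :, :]) ** 2).sum(axis=2))


def hazard(d, params: DetectionParams) -> np.ndarray | float:
    """Half-normal per-occasion hazard at distance ``d`` (metres).

    Returns ``lambda0 * exp(-d^2 / (2 sigma^2))``; equals ``lambda0`` at
    d = 0 and is strictly decreasing in d.
    """
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("distance d must be >= 0")
    out = params.lambda0 * np.exp(-(d_arr ** 2) / (2.0 * params.sigma ** 2))
    return out if out.ndim else float(out)


def occasion_capture_probs(x, traps: TrapArray, lambda0_eff: float,
                           sigma: float) -> tuple[np.ndarray, float]:
    """Competing-risks allocation of one animal among traps for one occasion.

    Parameters
    ----------
    x : array-like of shape (2,)
        Activity-centre coordinates, metres.
    lambda0_eff : float
        Effective hazard scale for this occasion (the naive ``lambda0``
        before the first capture, ``lambda0 * b_mult`` after it).
    sigma : float
        Spatial scale of detection, metres.

    Returns
    -------
    p_traps : ndarray of shape (n_traps,)
        ``p_k = (h_k / H) * (1 - exp(-H))`` per trap.
    p_none : float
        ``exp(-H)``, the probability of escaping every trap.

    The entries of ``p_traps`` plus ``p_none`` sum to one exactly.
    """
    if not (lambda0_eff > 0 and sigma > 0):
        raise ValueError("lambda0_eff and sigma must be > 0")
    d = traps.distances_to(np.asarray(x, dtype=float))[0]
    h = lambda0_eff * np.exp(-(d ** 2) / (2.0 * sigma ** 2))
    H = h.sum()
    p_none = float(np.exp(-H))
    if H == 0.0:  # total hazard underflows: no trap can catch the animal
        return np.zeros_like(h), 1.0
    p_traps = (h / H) * (1.0 - p_none)
    return p_traps, p_none


def pdot(x, traps: TrapArray, params: DetectionParams, K: int) -> float:
    """Probability of at least one detection over ``K`` occasions.

    Uses the naive ``lambda0`` throughout: the behavioural multiplier can
    only apply after a first capture, and every occasion before the first
    capture is by definition a naive one, so

        pdot(x) = 1 - exp(-K * H(x)).
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    d = traps.distances_to(np.asarray(x, dtype=float))[0]
    H = params.lambda0 * np.exp(-(d ** 2) / (2.0 * params.sigma ** 2)).sum()
    return float(-np.expm1(-K * H))
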