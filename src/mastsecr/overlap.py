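"""Home-range overlap statistics derived from SECR estimates.

With density D in animals/ha and spatial scale sigma in metres, the
dimensionless overlap index is

    k = sigma * sqrt(D) / 100

(sqrt(animals/ha) = sqrt(animals)/100 m, so the factor 100 makes k
unit-free).  Constant k means sigma scales as D^(-1/2): on log-log axes
sigma versus D has slope exactly -1/2, and a shift in k moves the
intercept.  S95 = 6 pi k^2 estimates the number of individuals present
within one animal's 95% home-range area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["k_index", "s95", "phase_average", "OverlapStats", "overlap_table"]

_SIX_PI = 6.0 * np.pi


def k_index(D, sigma):
    """Overlap index k = sigma * sqrt(D) / 100 (D in animals/ha, sigma in m)."""
    D = np.asarray(D, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(D < 0):
        raise ValueError("D must be >= 0")
    if np.any(sigma <= 0):
        raise ValueError("sigma must be > 0")
    out = sigma * np.sqrt(D) / 100.0
    return out if out.ndim else float(out)


def s95(k):
    """Expected individuals within one 95% home range: S95 = 6 pi k^2."""
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("k must be >= 0")
    out = _SIX_PI * k ** 2
    return out if out.ndim else float(out)


def phase_average(values: pd.Series | np.ndarray,
                  phase_labels: pd.Series | np.ndarray) -> pd.DataFrame:
    """Mean and standard error of session-level values within each phase.

    Requires at least two sessions per phase so the SE is defined.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "phase": np.asarray(phase_labels)})
    if df.empty:
        raise ValueError("no sessions supplied")
    out = []
    for phase, grp in df.groupby("phase", sort=True):
        n = len(grp)
        if n < 2:
            raise ValueError(
                f"phase {phase!r} has {n} session(s); need >= 2 for an SE")
        out.append({"phase": phase, "mean": grp["value"].mean(),
                    "se": grp["value"].std(ddof=1) / np.sqrt(n), "n": n})
    return pd.DataFrame(out)


@dataclass(frozen=True)
class OverlapStats:
    """Per-session overlap statistics plus phase-level summaries.

    ``phase_s95`` reports S95 per phase both ways the order of averaging
    allows: ``s95_of_mean_k`` transforms the phase-mean k, while
    ``mean_s95`` averages per-session S95 values.  The two differ by a
    Jensen gap whenever k varies within a phase, so both are exposed.
    """

    per_session: pd.DataFrame   # session, sex, phase, D, sigma, k, S95
    phase_means: pd.DataFrame   # phase(, sex), mean k, se, n
    phase_s95: pd.DataFrame     # phase(, sex), s95_of_mean_k, mean_s95


def overlap_table(records: pd.DataFrame) -> OverlapStats:
    """Compute k and S95 per session and summarise by phase (and sex).

    ``records`` needs columns session, phase, D, sigma, and optionally
    sex; D in animals/ha, sigma in metres.
    """
    need = {"session", "phase", "D", "sigma"}
    missing = need - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    per = records.copy()
    per["k"] = k_index(per["D"].to_numpy(), per["sigma"].to_numpy())
    per["S95"] = s95(per["k"].to_numpy())
    keys = ["phase", "sex"] if "sex" in per.columns else ["phase"]
    means, s95s = [], []
    for key, grp in per.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(keys, key))
        n = len(grp)
        mean_k = grp["k"].mean()
        means.append({**row, "mean_k": mean_k,
                      "se_k": grp["k"].std(ddof=1) / np.sqrt(n) if n > 1
                      else np.nan, "n": n})
        s95s.append({**row, "s95_of_mean_k": s95(mean_k),
                     "mean_s95": grp["S95"].mean()})
    return OverlapStats(per_session=per,
                        phase_means=pd.DataFrame(means),
                        phase_s95=pd.DataFrame(s95s))
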