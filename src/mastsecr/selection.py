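"""AICc model selection over the candidate SECR model grid.

Candidate models let density D, spatial scale sigma and the baseline
hazard lambda0 each be constant or session-specific, with lambda0
optionally carrying a global behavioural response.  Models are ranked by
AICc and summarised with Akaike weights (the normalised evidence for
each model) and evidence ratios.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .likelihood import SecrModel, SecrModelSpec, SecrResults

__all__ = [
    "enumerate_models",
    "fit_candidates",
    "aicc",
    "akaike_weights",
    "evidence_ratio",
    "model_table",
]

logger = logging.getLogger(__name__)


def enumerate_models(
        specs: Sequence[SecrModelSpec] | None = None) -> list[SecrModelSpec]:
    """The default 12-model candidate grid, or a user-supplied list.

    The default crosses D (constant / by-session) x sigma (constant /
    by-session) x lambda0 in three flavours (constant, by-session,
    constant-with-behavioural-response).  Pass ``specs`` to rank any
    other candidate set, e.g. one including session-varying lambda0 with
    a behavioural response on top.
    """
    if specs is not None:
        out = list(specs)
        if len({s for s in out}) != len(out):
            raise ValueError("duplicate model specs")
        return out
    grid = []
    for lam_struct, behav in (("constant", False), ("by_session", False),
                              ("constant", True)):
        for d_struct in ("constant", "by_session"):
            for sig_struct in ("constant", "by_session"):
                grid.append(SecrModelSpec(
                    d_struct=d_struct, sigma_struct=sig_struct,
                    lambda0_struct=lam_struct, behavioral=behav))
    return grid


def fit_candidates(sessions, traps, mask=None,
                   specs: Sequence[SecrModelSpec] | None = None,
                   compute_se: bool = False) -> list[SecrResults]:
    """Fit every candidate structure to the same sessions.

    The all-constant model is fitted first and its estimates seed the
    starting values of the richer structures, which stabilises and
    speeds up the quasi-Newton search.  Standard errors are skipped by
    default since AICc ranking needs only the log-likelihood.
    """
    specs = enumerate_models(specs)
    base = SecrModel(sessions, traps, mask=mask).fit(compute_se=False)
    base_vals = base.per_session().iloc[0]
    fits = []
    for spec in specs:
        model = SecrModel(sessions, traps, mask=mask, spec=spec)
        x0 = model.start_params()
        lay = model.layout
        x0[lay.slices["sigma"]] = np.log(base_vals["sigma"])
        x0[lay.slices["lambda0"]] = np.log(base_vals["lambda0"])
        fits.append(model.fit(start_params=x0, compute_se=compute_se))
    return fits


def aicc(loglik: float, K: int, n: int) -> float:
    """Akaike information criterion with small-sample correction.

    AICc = -2 loglik + 2K + 2K(K+1)/(n - K - 1), with ``n`` the number
    of distinct individuals detected.  Requires n > K + 1.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if n <= K + 1:
        raise ValueError(
            f"AICc undefined for n = {n} <= K + 1 = {K + 1} "
            "(small-sample correction denominator non-positive)")
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """Akaike weights w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2).

    Accepts raw AICc values or Delta-AICc directly (the weights are
    invariant to a common shift).
    """
    vals = np.asarray(aicc_values, dtype=float)
    if vals.size == 0 or not np.any(np.isfinite(vals)):
        raise ValueError("need at least one finite AICc value")
    delta = vals - np.nanmin(vals[np.isfinite(vals)])
    w = np.exp(-delta / 2.0)
    w[~np.isfinite(vals)] = 0.0
    return w / w.sum()


def evidence_ratio(w_i: float, w_j: float) -> float:
    """Evidence ratio w_i / w_j between two models' Akaike weights."""
    if w_j < 0 or w_i < 0:
        raise ValueError("weights must be >= 0")
    if w_j == 0:
        return np.inf
    return w_i / w_j


def model_table(fits: Sequence[SecrResults],
                drop_small_sample: bool = True) -> pd.DataFrame:
    """Rank fitted models by AICc (Table-1 style).

    One row per fit with the structure labels, parameter count, log
    likelihood, AICc, Delta-AICc and Akaike weight; sorted by AICc with
    ties broken by fewer parameters, then input order.  Models whose
    sample size is too small for the AICc correction are excluded from
    the ranking with a logged warning (``drop_small_sample=True``) or
    raise otherwise.
    """
    rows = []
    for order, fit in enumerate(fits):
        spec = fit.model.spec
        try:
            crit = aicc(fit.loglik, fit.k_params, fit.n_individuals)
        except ValueError as err:
            if not drop_small_sample:
                raise
            logger.warning("model %s excluded from AICc ranking: %s",
                           spec.label(), err)
            continue
        rows.append({
            "lambda0": spec.lambda0_struct
            + (" + behavioral" if spec.behavioral else ""),
            "D": spec.d_struct, "sigma": spec.sigma_struct,
            "K_params": fit.k_params, "n": fit.n_individuals,
            "loglik": fit.loglik, "AICc": crit,
            "converged": fit.converged, "_order": order,
        })
    if not rows:
        raise ValueError("no model could be ranked")
    df = pd.DataFrame(rows).sort_values(
        ["AICc", "K_params", "_order"]).reset_index(drop=True)
    df["deltaAICc"] = df["AICc"] - df["AICc"].iloc[0]
    df["weight"] = akaike_weights(df["AICc"].to_numpy())
    return df.drop(columns="_order")
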