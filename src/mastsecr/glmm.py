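"""Second-stage mixed models linking density, space use and mast phase.

Session-specific SECR estimates (D-hat, sigma-hat) become rows of a
space-use table; two Gaussian linear mixed models with a random
intercept per study site are then fitted by maximum likelihood:

* ``density_model``:  log D ~ mast * sex + month
* ``sigma_model``:    log sigma ~ (log D + mast + sex) with all two-way
  interactions + month

``mast`` contrasts the first summer after a beech mast autumn (FSA, the
population peak) against the second (SSA, the crash); SSA and female
are the reference levels, so the mast coefficient reads as the FSA
offset.  Month enters as a centred numeric covariate.  Fixed effects
are screened with Wald Type II chi-square tests: each term is adjusted
for all other terms except the higher-order interactions that contain
it (the term's block is tested in the model omitting those relatives,
using that model's ML covariance).

Estimation uncertainty in the first-stage (D-hat, sigma-hat) is
deliberately ignored: point estimates are taken at face value, which
understates second-stage standard errors.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .likelihood import SecrResults

__all__ = [
    "phase_for_year",
    "assemble_records",
    "SpaceUseLMM",
    "LmmResult",
    "fit_lmm",
    "wald_type2",
    "FORMULAS",
]

logger = logging.getLogger(__name__)

_MONTH_CENTER = 7.5  # mid-point of June(6)..September(9)

# model term lists; `mast` is the FSA indicator, `male` the male indicator
FORMULAS: dict[str, list[str]] = {
    "density_model": ["mast", "male", "mast:male", "month_c"],
    "sigma_model": ["log_D", "mast", "male", "log_D:mast", "log_D:male",
                    "mast:male", "month_c"],
}
_RESPONSE = {"density_model": "log_D", "sigma_model": "log_sigma"}


def phase_for_year(year: int, mast_autumn_years: Iterable[int]) -> str:
    """Phase label of a trapping summer given the mast calendar.

    FSA = first summer after a mast autumn (year - 1 masted), SSA =
    second (year - 2 masted).  Consecutive mast years resolve to FSA.
    """
    masts = set(mast_autumn_years)
    if year - 1 in masts:
        return "FSA"
    if year - 2 in masts:
        return "SSA"
    raise ValueError(
        f"year {year} is neither the first nor the second summer after a "
        f"mast autumn in {sorted(masts)}")


def assemble_records(fits: Iterable[tuple[str, str, SecrResults]],
                     mast_autumn_years: Iterable[int]) -> pd.DataFrame:
    """Space-use table from per-site, per-sex SECR fits.

    ``fits`` yields ``(site, sex, results)`` where each results object
    covers that site's sessions with ``session_id = (site, year, month)``.
    Non-converged fits are dropped with a logged count.  Returns one row
    per (site, year, month, sex): columns site, year, month, sex, phase,
    D_hat, sigma_hat.
    """
    masts = list(mast_autumn_years)
    rows, n_dropped = [], 0
    for site, sex, fit in fits:
        if not fit.converged:
            n_dropped += 1
            continue
        for _, r in fit.per_session().iterrows():
            _, year, month = r["session"]
            rows.append({
                "site": site, "year": int(year), "month": int(month),
                "sex": sex, "phase": phase_for_year(int(year), masts),
                "D_hat": float(r["D"]), "sigma_hat": float(r["sigma"]),
            })
    if n_dropped:
        logger.warning("dropped %d non-converged fits", n_dropped)
    return pd.DataFrame(
        rows, columns=["site", "year", "month", "sex", "phase",
                       "D_hat", "sigma_hat"])


def _design_frame(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    if (df["D_hat"] <= 0).any() or (df["sigma_hat"] <= 0).any():
        raise ValueError("D_hat and sigma_hat must be > 0")
    df["log_D"] = np.log(df["D_hat"])
    df["log_sigma"] = np.log(df["sigma_hat"])
    df["mast"] = (df["phase"] == "FSA").astype(float)
    df["male"] = (df["sex"] == "male").astype(float)
    df["month_c"] = df["month"].astype(float) - _MONTH_CENTER
    return df


def _check_aliasing(df: pd.DataFrame, terms: Sequence[str]) -> None:
    cols = {"Intercept": np.ones(len(df))}
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            cols[t] = df[a].to_numpy() * df[b].to_numpy()
        else:
            cols[t] = df[t].to_numpy()
    X = np.column_stack(list(cols.values()))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by greedy rank growth
        names = list(cols.keys())
        aliased, kept = [], np.ones((len(df), 0))
        for name, col in zip(names, X.T):
            trial = np.column_stack([kept, col])
            if np.linalg.matrix_rank(trial) > kept.shape[1]:
                kept = trial
            else:
                aliased.append(name)
        raise ValueError(f"singular design: aliased terms {aliased}")


class _OlsAsMixed:
    """OLS fit presenting the mixed-model result surface.

    Used when the random-intercept variance is estimated exactly at the
    zero boundary, where the ML mixed model coincides with OLS.  The
    fixed-effect covariance is scaled by the ML residual variance
    (RSS/n) for consistency with the mixed-model Wald tests.
    """

    def __init__(self, formula: str, data: pd.DataFrame):
        res = smf.ols(formula, data=data).fit()
        n = res.nobs
        self.scale = float(res.ssr / n)
        self.cov_re = np.zeros((1, 1))
        self.fe_params = res.params
        self._cov = res.cov_params() * (self.scale / res.scale)
        self.bse_fe = pd.Series(np.sqrt(np.diag(self._cov)),
                                index=res.params.index)

    def cov_params(self) -> pd.DataFrame:
        return self._cov


class LmmResult:
    """Fitted space-use mixed model with Wald Type II term tests."""

    def __init__(self, formula_id: str, records: pd.DataFrame,
                 data: pd.DataFrame, sm_result):
        self.formula_id = formula_id
        self.records = records
        self.data = data
        self.sm_result = sm_result
        self.terms = FORMULAS[formula_id]
        self.group_var = float(np.asarray(sm_result.cov_re).ravel()[0])
        self.resid_var = float(sm_result.scale)
        self.boundary = self.group_var < 1e-8 * max(self.resid_var, 1e-300)
        if self.boundary:
            logger.warning("%s: random-intercept variance at boundary (~0); "
                           "fit retained", formula_id)

    @property
    def fe_params(self) -> pd.Series:
        return self.sm_result.fe_params

    def cov_fixed(self) -> pd.DataFrame:
        cov = self.sm_result.cov_params()
        fe = list(self.sm_result.fe_params.index)
        return cov.loc[fe, fe]

    def anova(self) -> pd.DataFrame:
        """Wald Type II table over all fixed-effect terms."""
        rows = [dict(zip(("term", "chisq", "df", "p"),
                         (t, *wald_type2(self, t)))) for t in self.terms]
        return pd.DataFrame(rows)[["term", "chisq", "df", "p"]] \
            .assign(df=lambda d: d["df"].astype(int))

    def summary(self) -> str:
        lines = [
            f"Space-use mixed model: {self.formula_id}",
            f"  response {_RESPONSE[self.formula_id]}; random intercept per "
            f"site (ML)",
            f"  n = {len(self.data)} session-records, "
            f"{self.data['site'].nunique()} sites",
            f"  site variance {self.group_var:.4g}"
            + (" (boundary)" if self.boundary else "")
            + f"; residual variance {self.resid_var:.4g}",
            "",
            "Fixed effects:",
            pd.DataFrame({"coef": self.sm_result.fe_params,
                          "se": self.sm_result.bse_fe}).to_string(
                float_format=lambda v: f"{v:.4f}"),
            "",
            "Wald Type II tests:",
            self.anova().to_string(
                index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


class SpaceUseLMM:
    """Gaussian linear mixed model for the space-use table.

    Parameters
    ----------
    records : DataFrame
        Columns site, year, month, sex, phase, D_hat, sigma_hat (the
        output of :func:`assemble_records`).
    formula_id : {"density_model", "sigma_model"}
    """

    def __init__(self, records: pd.DataFrame, formula_id: str):
        if formula_id not in FORMULAS:
            raise ValueError(f"unknown formula_id {formula_id!r}; "
                             f"choose from {sorted(FORMULAS)}")
        if records.empty:
            raise ValueError("no records to fit")
        if records["site"].nunique() < 2:
            raise ValueError("need >= 2 sites for a site random intercept")
        self.records = records
        self.formula_id = formula_id
        self.data = _design_frame(records)
        _check_aliasing(self.data, FORMULAS[formula_id])

    def _formula(self, terms: Sequence[str]) -> str:
        return f"{_RESPONSE[self.formula_id]} ~ " + " + ".join(terms)

    def _fit_terms(self, terms: Sequence[str]):
        model = smf.mixedlm(self._formula(terms), data=self.data,
                            groups=self.data["site"])
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            try:
                return model.fit(reml=False, method=["lbfgs", "bfgs"])
            except np.linalg.LinAlgError:
                # random-intercept variance exactly at the 0 boundary:
                # the ML mixed fit degenerates to OLS
                return _OlsAsMixed(self._formula(terms), self.data)

    def fit(self) -> LmmResult:
        return LmmResult(self.formula_id, self.records, self.data,
                         self._fit_terms(FORMULAS[self.formula_id]))


def fit_lmm(records: pd.DataFrame, formula_id: str) -> LmmResult:
    """Fit one of the two space-use mixed models by ML."""
    return SpaceUseLMM(records, formula_id).fit()


def _relatives(term: str, terms: Sequence[str]) -> list[str]:
    """Higher-order terms containing ``term``."""
    parts = set(term.split(":"))
    return [t for t in terms
            if t != term and parts < set(t.split(":"))]


def wald_type2(fit: LmmResult, term: str) -> tuple[float, int, float]:
    """Wald Type II chi-square, df and p-value for one fixed-effect term.

    The term's coefficient block is tested in the model containing every
    other term except the higher-order interactions that include it
    (Type II marginality), using that model's ML covariance.
    """
    terms = fit.terms
    if term not in terms:
        raise ValueError(f"term {term!r} not in model {fit.formula_id}: "
                         f"{terms}")
    kept = [t for t in terms if t not in _relatives(term, terms)]
    model = SpaceUseLMM(fit.records, fit.formula_id)
    res = fit.sm_result if kept == list(terms) else model._fit_terms(kept)
    fe = res.fe_params
    cov = res.cov_params().loc[fe.index, fe.index]
    if term not in fe.index:
        raise ValueError(f"term {term!r} aliased / absent from design")
    b = np.atleast_1d(fe[term])
    V = np.atleast_2d(cov.loc[term, term])
    try:
        chisq = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError:
        raise ValueError(f"term {term!r} has singular covariance (aliased)")
    df = b.size
    return chisq, df, float(stats.chi2.sf(chisq, df))
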