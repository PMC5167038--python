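"""Poisson SECR likelihood over a habitat mask and its maximisation.

The model: animal activity centres follow a homogeneous Poisson process
with intensity ``D`` (animals/ha) over the plane; detection of an animal
with centre ``x`` by a multi-catch trap at distance ``d`` follows the
half-normal hazard of :mod:`mastsecr.detection`.  Integrating over the
unknown centres on a discretised habitat mask with cell area ``c`` (ha),
the full (Poisson-n) log-likelihood of one session is

    log L = -D a(theta) + n log D
            + sum_i log[ c sum_m Pr(omega_i | x_m) ] - log n!

where ``a(theta) = c sum_m pdot(x_m)`` is the effective sampling area,
``n`` the number of distinct animals detected, and ``Pr(omega_i | x)``
the product over occasions of multi-catch multinomial terms, with the
behavioural switch applied from the occasion after an animal's first
capture in that session.  Sessions are treated as independent
populations; parameters may be shared across sessions or vary by
session according to a :class:`SecrModelSpec`.

Estimation is by quasi-Newton maximisation on the log scale of every
parameter; Wald standard errors come from the inverse observed
information (central-difference Hessian of the negative log-likelihood).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.spatial import cKDTree
from scipy.special import gammaln, logsumexp
from scipy.stats import norm

from .detection import DetectionParams, TrapArray

__all__ = [
    "Mask",
    "CaptureSession",
    "SecrModelSpec",
    "SecrModel",
    "SecrResults",
    "build_mask",
    "session_neg_loglik",
    "fit_secr",
    "param_ci",
]


# ---------------------------------------------------------------------------
# mask

@dataclass(frozen=True)
class Mask:
    """Discretised habitat over which activity centres are integrated."""

    points: np.ndarray = field(repr=False)  # (M, 2) metres
    cell_area: float                        # hectares per cell
    buffer: float                           # metres
    spacing: float                          # metres

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def area(self) -> float:
        """Total mask area in hectares."""
        return self.n_points * self.cell_area


def build_mask(traps: TrapArray, buffer: float = 100.0,
               spacing: float = 10.0) -> Mask:
    """Regular grid of mask points clipped to within ``buffer`` m of a trap.

    The candidate grid is aligned with the trap bounding box and extended
    by ``buffer`` on every side; points farther than ``buffer`` from the
    nearest trap (strictly) are dropped, so corners beyond the round
    trap-buffer are excluded.  Cell area is ``spacing**2 / 1e4`` ha.
    """
    if buffer <= 0:
        raise ValueError(f"buffer must be > 0, got {buffer}")
    if spacing <= 0:
        raise ValueError(f"spacing must be > 0, got {spacing}")
    lo = traps.xy.min(axis=0)
    hi = traps.xy.max(axis=0)
    ncells = int(np.ceil(buffer / spacing))
    xs = lo[0] + spacing * np.arange(-ncells, (hi[0] - lo[0]) / spacing + ncells + 0.5)
    ys = lo[1] + spacing * np.arange(-ncells, (hi[1] - lo[1]) / spacing + ncells + 0.5)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    cand = np.column_stack([gx.ravel(), gy.ravel()])
    d, _ = cKDTree(traps.xy).query(cand)
    pts = cand[d <= buffer * (1 + 1e-12)]
    return Mask(points=pts, cell_area=spacing ** 2 / 1e4,
                buffer=buffer, spacing=spacing)


# ---------------------------------------------------------------------------
# capture data

@dataclass(frozen=True)
class CaptureSession:
    """Captures of one site-month trapping bout.

    records are ``(animal_id, occasion, trap_id)`` with 1-based occasion
    indices; an animal occupies at most one trap per occasion.
    """

    session_id: tuple
    n_occasions: int
    records: tuple[tuple[str, int, str], ...]

    def __post_init__(self) -> None:
        if self.n_occasions < 1:
            raise ValueError("n_occasions must be >= 1")
        seen = set()
        for animal, occ, trap in self.records:
            if not 1 <= occ <= self.n_occasions:
                raise ValueError(
                    f"occasion {occ} out of range 1..{self.n_occasions} "
                    f"for animal {animal!r}")
            key = (animal, occ)
            if key in seen:
                raise ValueError(
                    f"duplicate (animal, occasion) = {key} in session "
                    f"{self.session_id}: an animal occupies one trap per occasion")
            seen.add(key)

    @property
    def n_individuals(self) -> int:
        return len({r[0] for r in self.records})

    @property
    def animal_ids(self) -> list[str]:
        return sorted({r[0] for r in self.records})

    def validate_traps(self, traps: TrapArray) -> None:
        known = set(traps.trap_ids)
        bad = sorted({t for _, _, t in self.records} - known)
        if bad:
            raise ValueError(
                f"session {self.session_id} references unknown traps: {bad}")


class _SessionSummary:
    """Sufficient statistics of one session for fast likelihood evaluation.

    For animal i with capture history omega_i, and a mask point x with
    per-trap kernel g_k(x) = exp(-d_k^2 / 2 sigma^2), T = sum_k g_k:

      log Pr(omega_i|x) = sum_{captures k} log g_k  - C_i log T
                          + 1{C_i>0} log(1 - e^{-lam_n T})
                          + (C_i - 1) log(1 - e^{-lam_b T})
                          - u_i lam_n T - v_i lam_b T

    with lam_n the naive and lam_b the post-first-capture hazard scale,
    u_i / v_i counts of no-capture occasions before / after the first
    capture.  The capture-kernel term is C_i-weighted sums of -d_k^2,
    precomputed once as ``A = cap_counts @ d2.T`` so each likelihood
    evaluation only rescales by 1/(2 sigma^2).
    """

    def __init__(self, session: CaptureSession, traps: TrapArray, mask: Mask):
        session.validate_traps(traps)
        self.session = session
        self.K = session.n_occasions
        animals = session.animal_ids
        self.n = len(animals)
        idx = {a: i for i, a in enumerate(animals)}
        d2 = ((mask.points[:, None, :] - traps.xy[None, :, :]) ** 2).sum(axis=2)
        self.d2 = d2                                  # (M, n_traps)
        cap_counts = np.zeros((self.n, traps.n_traps))
        first_occ = np.full(self.n, np.iinfo(np.int32).max)
        n_caps = np.zeros(self.n)
        for animal, occ, trap in session.records:
            i = idx[animal]
            cap_counts[i, traps.index_of(trap)] += 1
            n_caps[i] += 1
            first_occ[i] = min(first_occ[i], occ)
        # A[i, m] = sum over captures of d_k^2 at mask point m
        self.A = cap_counts @ d2.T                    # (n, M)
        self.n_caps = n_caps                          # C_i
        self.n_boost_caps = n_caps - 1.0              # captures after the first
        self.u = first_occ - 1.0                      # naive no-capture occasions
        self.v = (self.K - first_occ) - self.n_boost_caps


def _session_loglik(summ: _SessionSummary, cell_area: float, D: float,
                    lam0: float, sigma: float, b: float) -> float:
    T = np.exp(-summ.d2 / (2.0 * sigma ** 2)).sum(axis=1)     # (M,)
    # floor keeps far mask cells finite on the log scale when sigma is
    # driven very small during optimisation (their contribution is ~0)
    T = np.maximum(T, 1e-290)
    lam_n = lam0
    lam_b = lam0 * b
    pdot = -np.expm1(-summ.K * lam_n * T)
    a_theta = cell_area * pdot.sum()
    if summ.n == 0:
        return -D * a_theta
    logT = np.log(T)
    # same floor as T: a zero capture probability only arises from
    # underflow at irrelevant parameter values during line search
    log1m_n = np.log(np.maximum(-np.expm1(-lam_n * T), 1e-290))
    log1m_b = log1m_n if b == 1.0 else np.log(
        np.maximum(-np.expm1(-lam_b * T), 1e-290))
    LP = (-summ.A / (2.0 * sigma ** 2)
          - np.outer(summ.n_caps, logT)
          + log1m_n[None, :]
          + np.outer(summ.n_boost_caps, log1m_b)
          - np.outer(summ.u, lam_n * T)
          - np.outer(summ.v, lam_b * T))
    integrals = logsumexp(LP, axis=1) + np.log(cell_area)
    return (-D * a_theta + summ.n * np.log(D) + integrals.sum()
            - gammaln(summ.n + 1.0))


def _session_loglik_grad(summ: _SessionSummary, cell_area: float, D: float,
                         lam0: float, sigma: float, b: float,
                         ) -> tuple[float, float, float, float, float]:
    """Log-likelihood and its gradient wrt (D, lambda0, sigma, b).

    Same quantities as :func:`_session_loglik`; the derivative of the
    kernel sum T wrt sigma needs the distance-weighted sum
    W = sum_k g_k d_k^2, and per-animal derivatives are softmax-weighted
    averages over mask points of the derivative of log Pr(omega|x).
    """
    G = np.exp(-summ.d2 / (2.0 * sigma ** 2))
    T = np.maximum(G.sum(axis=1), 1e-290)
    W = (G * summ.d2).sum(axis=1)                    # sum g_k d_k^2
    dT_dsig = W / sigma ** 3
    lam_b = lam0 * b
    K = summ.K
    e_n = np.exp(-lam0 * T)
    pdot = 1.0 - np.exp(-K * lam0 * T)
    a_theta = cell_area * pdot.sum()
    # d a / d lam0 and d a / d sigma
    exp_K = np.exp(-K * lam0 * T)
    da_dlam = cell_area * (K * T * exp_K).sum()
    da_dsig = cell_area * (K * lam0 * dT_dsig * exp_K).sum()
    if summ.n == 0:
        return (-D * a_theta, -a_theta, -D * da_dlam, -D * da_dsig, 0.0)
    one_m_n = np.maximum(-np.expm1(-lam0 * T), 1e-290)
    logT = np.log(T)
    log1m_n = np.log(one_m_n)
    if b == 1.0:
        e_b, one_m_b, log1m_b = e_n, one_m_n, log1m_n
    else:
        e_b = np.exp(-lam_b * T)
        one_m_b = np.maximum(-np.expm1(-lam_b * T), 1e-290)
        log1m_b = np.log(one_m_b)
    LP = (-summ.A / (2.0 * sigma ** 2)
          - np.outer(summ.n_caps, logT)
          + log1m_n[None, :]
          + np.outer(summ.n_boost_caps, log1m_b)
          - np.outer(summ.u, lam0 * T)
          - np.outer(summ.v, lam_b * T))
    lse = logsumexp(LP, axis=1)
    P = np.exp(LP - lse[:, None])                    # softmax weights (n, M)
    # d LP / d lam0 at fixed b (total derivative including lam_b = lam0 b)
    r_n = T * e_n / one_m_n
    r_b = T * e_b / one_m_b
    dLP_dlam = (r_n[None, :]
                + np.outer(summ.n_boost_caps, b * r_b)
                - np.outer(summ.u, T)
                - np.outer(summ.v, b * T))
    # d LP / d sigma
    s_n = lam0 * dT_dsig * e_n / one_m_n
    s_b = lam_b * dT_dsig * e_b / one_m_b
    dLP_dsig = (summ.A / sigma ** 3
                - np.outer(summ.n_caps, dT_dsig / T)
                + s_n[None, :]
                + np.outer(summ.n_boost_caps, s_b)
                - np.outer(summ.u, lam0 * dT_dsig)
                - np.outer(summ.v, lam_b * dT_dsig))
    # d LP / d b at fixed lam0
    dLP_db = (np.outer(summ.n_boost_caps, lam0 * r_b)
              - np.outer(summ.v, lam0 * T))
    ll = (-D * a_theta + summ.n * np.log(D) + lse.sum()
          + summ.n * np.log(cell_area) - gammaln(summ.n + 1.0))
    dD = -a_theta + summ.n / D
    dlam = -D * da_dlam + float((P * dLP_dlam).sum())
    dsig = -D * da_dsig + float((P * dLP_dsig).sum())
    db = float((P * dLP_db).sum())
    return ll, dD, dlam, dsig, db


def session_neg_loglik(session: CaptureSession, traps: TrapArray, mask: Mask,
                       D: float, params: DetectionParams) -> float:
    """Negative log-likelihood of one session at given parameter values."""
    if D <= 0:
        raise ValueError(f"D must be > 0, got {D}")
    if mask.n_points == 0:
        raise ValueError("mask is empty")
    summ = _SessionSummary(session, traps, mask)
    return -_session_loglik(summ, mask.cell_area, D,
                            params.lambda0, params.sigma, params.b_mult)


# ---------------------------------------------------------------------------
# model specification and fitting

_STRUCTS = ("constant", "by_session")


@dataclass(frozen=True)
class SecrModelSpec:
    """Which parameters are shared vs. session-specific.

    ``behavioral`` adds a single global multiplier on lambda0 after an
    animal's first within-session capture.
    """

    d_struct: str = "constant"
    sigma_struct: str = "constant"
    lambda0_struct: str = "constant"
    behavioral: bool = False

    def __post_init__(self) -> None:
        for name in ("d_struct", "sigma_struct", "lambda0_struct"):
            if getattr(self, name) not in _STRUCTS:
                raise ValueError(f"{name} must be one of {_STRUCTS}")

    def n_params(self, n_sessions: int) -> int:
        k = 0
        for s in (self.d_struct, self.sigma_struct, self.lambda0_struct):
            k += n_sessions if s == "by_session" else 1
        return k + (1 if self.behavioral else 0)

    def label(self) -> str:
        lam = {"constant": "(.)", "by_session": "session"}[self.lambda0_struct]
        if self.behavioral:
            lam = lam + " + b" if lam != "(.)" else "b"
        d = {"constant": "(.)", "by_session": "session"}[self.d_struct]
        s = {"constant": "(.)", "by_session": "session"}[self.sigma_struct]
        return f"lambda0~{lam}, D~{d}, sigma~{s}"


class _ParamLayout:
    """Maps the flat log-parameter vector onto per-session (D, lam0, sigma, b)."""

    def __init__(self, spec: SecrModelSpec, n_sessions: int):
        self.spec = spec
        self.S = n_sessions
        pos = 0
        self.slices = {}
        for name, struct in (("D", spec.d_struct),
                             ("sigma", spec.sigma_struct),
                             ("lambda0", spec.lambda0_struct)):
            width = n_sessions if struct == "by_session" else 1
            self.slices[name] = slice(pos, pos + width)
            pos += width
        if spec.behavioral:
            self.slices["b_mult"] = slice(pos, pos + 1)
            pos += 1
        self.n_params = pos

    def expand(self, theta: np.ndarray, name: str) -> np.ndarray:
        """Natural-scale per-session values of one parameter."""
        vals = np.exp(theta[self.slices[name]]) if name in self.slices \
            else np.ones(1)
        return np.broadcast_to(vals, (self.S,)) if vals.size == 1 \
            else vals

    def names(self) -> list[tuple[str, int | None]]:
        out = []
        for name, sl in self.slices.items():
            width = sl.stop - sl.start
            if width == 1:
                out.append((name, None))
            else:
                out.extend((name, s) for s in range(width))
        return out


def _recapture_sigma0(sessions: Sequence[CaptureSession],
                      traps: TrapArray) -> float:
    """Half the mean displacement between successive captures of an animal.

    Falls back to half the minimum inter-trap spacing when no animal was
    recaptured at a different trap.
    """
    disp = []
    for sess in sessions:
        by_animal: dict[str, list[tuple[int, str]]] = {}
        for animal, occ, trap in sess.records:
            by_animal.setdefault(animal, []).append((occ, trap))
        for caps in by_animal.values():
            caps.sort()
            for (_, t1), (_, t2) in zip(caps[:-1], caps[1:]):
                p1 = traps.xy[traps.index_of(t1)]
                p2 = traps.xy[traps.index_of(t2)]
                disp.append(float(np.hypot(*(p1 - p2))))
    if disp and np.mean(disp) > 0:
        return 0.5 * float(np.mean(disp))
    d = traps.distances_to(traps.xy)
    np.fill_diagonal(d, np.inf)
    return 0.5 * float(d.min())


class SecrModel:
    """Spatially explicit capture-recapture model for one detector array.

    Parameters
    ----------
    sessions : sequence of CaptureSession
        Independent trapping bouts sharing the same traps.
    traps : TrapArray
    mask : Mask, optional
        Defaults to ``build_mask(traps, buffer=100, spacing=10)``.
    spec : SecrModelSpec, optional
        Parameter structure; defaults to all-constant without behavioural
        response.
    """

    def __init__(self, sessions: Sequence[CaptureSession], traps: TrapArray,
                 mask: Mask | None = None, spec: SecrModelSpec | None = None):
        if not sessions:
            raise ValueError("at least one session is required")
        self.sessions = list(sessions)
        self.traps = traps
        self.mask = mask if mask is not None else build_mask(traps)
        self.spec = spec if spec is not None else SecrModelSpec()
        self.layout = _ParamLayout(self.spec, len(self.sessions))
        if self.spec.d_struct == "by_session":
            for sess in self.sessions:
                if sess.n_individuals == 0:
                    raise ValueError(
                        f"session {sess.session_id} has no detected animals; "
                        "cannot estimate a session-specific density")
        if sum(s.n_individuals for s in self.sessions) == 0:
            raise ValueError("no detected animals in any session")
        self._summaries = [_SessionSummary(s, traps, self.mask)
                           for s in self.sessions]

    # -- likelihood ---------------------------------------------------------

    def loglike(self, theta: np.ndarray) -> float:
        """Total log-likelihood at the flat log-parameter vector."""
        lay = self.layout
        D = lay.expand(theta, "D")
        lam = lay.expand(theta, "lambda0")
        sig = lay.expand(theta, "sigma")
        b = float(np.exp(theta[lay.slices["b_mult"]])[0]) \
            if self.spec.behavioral else 1.0
        total = 0.0
        for s, summ in enumerate(self._summaries):
            total += _session_loglik(summ, self.mask.cell_area,
                                     D[s], lam[s], sig[s], b)
        return total

    def _neg_loglike(self, theta: np.ndarray) -> float:
        val = self.loglike(theta)
        return -val if np.isfinite(val) else 1e12

    def score(self, theta: np.ndarray) -> np.ndarray:
        """Gradient of the log-likelihood wrt the flat log-parameters."""
        return self._loglike_and_score(theta)[1]

    def _loglike_and_score(self, theta: np.ndarray
                           ) -> tuple[float, np.ndarray]:
        lay = self.layout
        D = lay.expand(theta, "D")
        lam = lay.expand(theta, "lambda0")
        sig = lay.expand(theta, "sigma")
        b = float(np.exp(theta[lay.slices["b_mult"]])[0]) \
            if self.spec.behavioral else 1.0
        total = 0.0
        grad = np.zeros(lay.n_params)

        def _accum(name: str, s: int, dnat: float, value: float) -> None:
            sl = lay.slices[name]
            # chain rule onto the log scale: d/d log(p) = p * d/dp
            idx = sl.start if sl.stop - sl.start == 1 else sl.start + s
            grad[idx] += value * dnat

        for s, summ in enumerate(self._summaries):
            ll, dD, dlam, dsig, db = _session_loglik_grad(
                summ, self.mask.cell_area, D[s], lam[s], sig[s], b)
            total += ll
            _accum("D", s, dD, D[s])
            _accum("lambda0", s, dlam, lam[s])
            _accum("sigma", s, dsig, sig[s])
            if self.spec.behavioral:
                grad[lay.slices["b_mult"].start] += db * b
        return total, grad

    def _neg_loglike_grad(self, theta: np.ndarray
                          ) -> tuple[float, np.ndarray]:
        val, grad = self._loglike_and_score(theta)
        if not np.isfinite(val):
            return 1e12, np.zeros_like(grad)
        return -val, -grad

    def start_params(self) -> np.ndarray:
        lay = self.layout
        theta = np.zeros(lay.n_params)
        area = self.mask.area
        ns = np.array([s.n_individuals for s in self.sessions], dtype=float)
        d_slice = lay.slices["D"]
        if d_slice.stop - d_slice.start == 1:
            theta[d_slice] = np.log(max(ns.mean(), 0.5) / area)
        else:
            theta[d_slice] = np.log(np.maximum(ns, 0.5) / area)
        sigma0 = _recapture_sigma0(self.sessions, self.traps)
        theta[lay.slices["sigma"]] = np.log(sigma0)
        theta[lay.slices["lambda0"]] = np.log(0.3)
        if self.spec.behavioral:
            theta[lay.slices["b_mult"]] = 0.0
        return theta

    # -- fitting ------------------------------------------------------------

    def fit(self, start_params: np.ndarray | None = None,
            maxiter: int = 1000, compute_se: bool = True) -> "SecrResults":
        """Maximise the likelihood; returns a :class:`SecrResults`.

        ``compute_se=False`` skips the observed-information Hessian
        (useful when only the log-likelihood is needed, e.g. for AICc
        ranking); standard errors are then NaN.
        """
        x0 = self.start_params() if start_params is None else np.asarray(
            start_params, dtype=float)
        res = optimize.minimize(
            self._neg_loglike_grad, x0, jac=True, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-6})
        if compute_se:
            se = _wald_se(_num_hessian_from_grad(
                lambda t: self._neg_loglike_grad(t)[1], res.x))
        else:
            se = np.full(res.x.size, np.nan)
        return SecrResults(model=self, params=res.x, bse=se,
                           loglik=-res.fun, converged=bool(res.success),
                           optimizer_message=str(res.message))


def _num_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    n = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        fpp = f(x + ei); fmm = f(x - ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej)
                - f(x - ei + ej) + f(x - ei - ej)) / (4 * h[i] * h[j])
    return H


def _num_hessian_from_grad(grad, x: np.ndarray,
                           rel_step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian from an analytic gradient, symmetrised."""
    n = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        H[i] = (grad(x + ei) - grad(x - ei)) / (2 * h[i])
    return 0.5 * (H + H.T)


def _wald_se(hess: np.ndarray) -> np.ndarray:
    """Standard errors from the observed information; NaN when singular."""
    try:
        cov = np.linalg.inv(hess)
        diag = np.diag(cov).copy()
        diag[diag < 0] = np.nan
        return np.sqrt(diag)
    except np.linalg.LinAlgError:
        return np.full(hess.shape[0], np.nan)


class SecrResults:
    """Maximum-likelihood SECR fit.

    Attributes
    ----------
    params : ndarray
        Estimates on the log scale, in layout order.
    bse : ndarray
        Wald standard errors on the log scale.
    loglik : float
        Maximised log-likelihood (full Poisson-n form, so comparable
        across parameter structures).
    """

    def __init__(self, model: SecrModel, params: np.ndarray, bse: np.ndarray,
                 loglik: float, converged: bool, optimizer_message: str = ""):
        self.model = model
        self.params = params
        self.bse = bse
        self.loglik = loglik
        self.converged = converged
        self.optimizer_message = optimizer_message

    @property
    def k_params(self) -> int:
        return self.model.layout.n_params

    @property
    def n_individuals(self) -> int:
        return sum(s.n_individuals for s in self.model.sessions)

    def estimates(self) -> pd.DataFrame:
        """Natural-scale estimates, one row per parameter group."""
        rows = []
        for (name, sess_idx), est, se in zip(
                self.model.layout.names(), self.params, self.bse):
            sid = (self.model.sessions[sess_idx].session_id
                   if sess_idx is not None else "all")
            rows.append({"session": sid, "parameter": name,
                         "estimate": float(np.exp(est)),
                         "se_log": float(se)})
        return pd.DataFrame(rows)

    def per_session(self) -> pd.DataFrame:
        """Per-session (D, sigma, lambda0) expanded from the structure."""
        lay = self.model.layout
        rows = []
        for s, sess in enumerate(self.model.sessions):
            rows.append({
                "session": sess.session_id,
                "D": float(lay.expand(self.params, "D")[s]),
                "sigma": float(lay.expand(self.params, "sigma")[s]),
                "lambda0": float(lay.expand(self.params, "lambda0")[s]),
                "b_mult": float(np.exp(self.params[lay.slices["b_mult"]])[0])
                if self.model.spec.behavioral else 1.0,
                "n_individuals": sess.n_individuals,
            })
        return pd.DataFrame(rows)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        """Wald intervals on the natural scale (log-scale interval
        exponentiated, so the lower bound is always positive)."""
        if not self.converged:
            raise RuntimeError(
                "confidence intervals refused for a non-converged fit: "
                + self.optimizer_message)
        if not 0 < level < 1:
            raise ValueError("level must be in (0, 1)")
        z = norm.ppf(0.5 + level / 2.0)
        out = self.estimates()
        log_est = self.params
        out["ci_low"] = np.exp(log_est - z * self.bse)
        out["ci_high"] = np.exp(log_est + z * self.bse)
        return out

    def summary(self) -> str:
        df = self.estimates()
        lines = [
            "SECR fit (Poisson likelihood, half-normal multi-catch)",
            f"  structure : {self.model.spec.label()}",
            f"  sessions  : {len(self.model.sessions)}   "
            f"individuals: {self.n_individuals}",
            f"  mask      : {self.model.mask.n_points} points, "
            f"{self.model.mask.area:.2f} ha "
            f"(buffer {self.model.mask.buffer:.0f} m, "
            f"spacing {self.model.mask.spacing:.0f} m)",
            f"  logLik    : {self.loglik:.3f}   parameters: {self.k_params}"
            f"   converged: {self.converged}",
            "",
            df.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


def fit_secr(sessions: Sequence[CaptureSession], traps: TrapArray,
             mask: Mask | None = None,
             spec: SecrModelSpec | None = None) -> SecrResults:
    """Convenience wrapper: build a :class:`SecrModel` and fit it."""
    return SecrModel(sessions, traps, mask=mask, spec=spec).fit()


def param_ci(fit: SecrResults, level: float = 0.95) -> pd.DataFrame:
    """Per-parameter Wald intervals on the natural scale."""
    return fit.conf_int(level)
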