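"""Summary-level nonlinear mixed-effects estimation (model-based meta-analysis).

Each meta-analytic unit (by default every dose arm, treated as its own
"study") carries a bivariate log-normal random effect on clearance and
central volume:

    CL_i = CL * exp(eta_CL,i),   Vc_i = Vc * exp(eta_Vc,i),
    (eta_CL, eta_Vc) ~ N(0, Omega),  Omega from (omega_CL, omega_Vc, rho).

An observed summary concentration with model prediction ``f`` from an arm of
``n`` subjects has standard deviation

    sigma = a + (b / sqrt(n)) * f          (default, "additive" form)

i.e. the proportional component shrinks with the square root of the sample
size, reflecting that arm means of larger trials are less noisy; the
constant floor ``a`` is unweighted.  A quadratic combination
``sqrt(a^2 + (b f / sqrt(n))^2)`` and a fully weighted constant term are
available as options.

The marginal likelihood integrates the random effects out with a Laplace
approximation: the inner mode is found by a damped Gauss-Newton iteration
run simultaneously for all arms (the per-arm problems are independent
2-D optimisations), and the curvature term uses the Gauss-Newton Hessian,
as in first-order-conditional estimation.  The outer problem maximises the
summed Laplace log-likelihood over the transformed parameter vector
(log fixed effects, log variability SDs, atanh correlation, log error
terms) by L-BFGS-B from several seeded starts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import log_ndtr

from . import trial_data as td
from .pk_twocmt import DEFAULT_INFUSION_H, PKParams, concentration_arrays

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class BSVParams:
    """Between-study variability: SDs of the log CL / log Vc deviations and
    their correlation."""

    omega_CL: float
    omega_Vc: float
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.omega_CL < 0 or self.omega_Vc < 0:
            raise ValueError("omegas must be >= 0")
        if not (-1.0 <= self.rho <= 1.0):
            raise ValueError("rho must lie in [-1, 1]")

    def cov(self) -> np.ndarray:
        od = self.rho * self.omega_CL * self.omega_Vc
        return np.array([[self.omega_CL**2, od], [od, self.omega_Vc**2]])


@dataclass(frozen=True)
class ResidualError:
    """Constant (ng/mL) and proportional (fraction) residual SD components."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError("error components must be >= 0")
        if self.a == 0 and self.b == 0:
            raise ValueError("error components cannot both be 0")


@dataclass
class FitOptions:
    btav_mode: str = "arms_as_studies"  # or "separate_btav"
    dose_finding_only: bool = False
    error_form: str = "additive"  # or "quadratic"
    weight_constant: bool = False  # also scale the constant term by 1/sqrt(n)
    #: treat reported concentrations as left-truncated at zero (summary
    #: tables only ever contain positive means); adds log Phi(f/sigma)
    truncated: bool = True
    n_starts: int = 5
    seed: int = 0
    compute_rse: bool = True
    maxiter: int = 250


_PARAM_NAMES = ["CL", "Vc", "Vp", "Q", "omega_CL", "omega_Vc", "rho", "a", "b"]


@dataclass
class FitResult:
    pk: PKParams
    bsv: BSVParams
    error: ResidualError
    rse: dict[str, float]
    loglik: float
    convergence: bool
    n_arms_used: int
    options: FitOptions
    #: SDs of the extra arm-within-study level, separate_btav mode only
    btav: BSVParams | None = None
    #: covariance of the transformed parameter vector (for uncertainty propagation)
    cov_transformed: np.ndarray | None = None
    messages: list[str] = field(default_factory=list)

    def estimates(self) -> dict[str, float]:
        out = {
            "CL": self.pk.CL, "Vc": self.pk.Vc, "Vp": self.pk.Vp, "Q": self.pk.Q,
            "omega_CL": self.bsv.omega_CL, "omega_Vc": self.bsv.omega_Vc,
            "rho": self.bsv.rho, "a": self.error.a, "b": self.error.b,
        }
        if self.btav is not None:
            out["omega_btav_CL"] = self.btav.omega_CL
            out["omega_btav_Vc"] = self.btav.omega_Vc
        return out

    def to_table(self) -> dict[str, dict[str, float]]:
        """Estimates keyed by the conventional report row names."""
        rows = {
            "Clearance (L/day)": ("CL", self.pk.CL),
            "Central volume of distribution (L)": ("Vc", self.pk.Vc),
            "Peripheral volume of distribution (L)": ("Vp", self.pk.Vp),
            "Intercompartment clearance (L/day)": ("Q", self.pk.Q),
            "BSV clearance": ("omega_CL", self.bsv.omega_CL),
            "BSV central volume of distribution": ("omega_Vc", self.bsv.omega_Vc),
            "BSV clearance ~ BSV central volume of distribution": ("rho", self.bsv.rho),
            "Weighted proportional error (%)": ("b", self.error.b),
            "Constant error (ng/mL)": ("a", self.error.a),
        }
        return {label: {"estimate": val, "rse_pct": self.rse.get(key, float("nan"))}
                for label, (key, val) in rows.items()}


# ---------------------------------------------------------------------------
# data preparation


@dataclass
class _ArmTable:
    """Padded per-arm observation arrays for vectorised likelihood work."""

    arm_ids: list[str]
    study_ids: list[str]
    t: np.ndarray  # (n_arms, m) padded
    y: np.ndarray
    mask: np.ndarray  # bool, valid observations
    n: np.ndarray  # (n_arms,)
    dose_mg: np.ndarray
    infusion_h: float = DEFAULT_INFUSION_H

    @property
    def n_arms(self) -> int:
        return len(self.arm_ids)


def prepare_arms(ds: td.Dataset, dose_finding_only: bool = False,
                 min_points: int = 2, min_arms: int = 2) -> _ArmTable:
    """Assemble the PK estimation table from a validated dataset.

    Uses every arm with a concentration series of at least ``min_points``
    points (weekly-schedule arms included: first-cycle exposure does not
    depend on the dosing interval).  Body weight must be present or already
    imputed, since the absolute dose is dose_mgkg x weight.
    """
    ds = td.impute_weight(ds)
    arms = [a for a in ds.arms if a.arm_id in ds.conc
            and len(ds.conc[a.arm_id].times) >= min_points]
    if dose_finding_only:
        by_study: dict[str, set[float]] = {}
        for a in arms:
            if a.phase == td.Phase.I:
                by_study.setdefault(a.study_id, set()).add(a.dose_mgkg)
        keep = {s for s, doses in by_study.items() if len(doses) >= 2}
        arms = [a for a in arms if a.study_id in keep]
    if len(arms) < min_arms:
        raise ValueError(
            f"need at least {min_arms} arms with >= {min_points} concentration points")
    m = max(len(ds.conc[a.arm_id].times) for a in arms)
    t = np.ones((len(arms), m))
    y = np.zeros((len(arms), m))
    mask = np.zeros((len(arms), m), bool)
    for i, a in enumerate(arms):
        cs = ds.conc[a.arm_id]
        k = len(cs.times)
        t[i, :k] = cs.times
        y[i, :k] = cs.conc
        mask[i, :k] = True
    return _ArmTable(
        arm_ids=[a.arm_id for a in arms],
        study_ids=[a.study_id for a in arms],
        t=t, y=y, mask=mask,
        n=np.array([a.n for a in arms], float),
        dose_mg=np.array([a.dose_mgkg * a.median_weight_kg for a in arms]),
    )


# ---------------------------------------------------------------------------
# likelihood machinery (arms_as_studies path, vectorised over arms)


def _sigma(f: np.ndarray, a: float, b: float, sqrt_n: np.ndarray,
           error_form: str, weight_constant: bool) -> tuple[np.ndarray, np.ndarray]:
    """Residual SD and its derivative with respect to the prediction f."""
    aa = a / sqrt_n if weight_constant else a * np.ones_like(sqrt_n)
    aa = aa[:, None]
    c = (b / sqrt_n)[:, None]
    if error_form == "additive":
        sig = aa + c * f
        dsig = np.broadcast_to(c, f.shape)
    elif error_form == "quadratic":
        sig = np.sqrt(aa**2 + (c * f) ** 2)
        dsig = c**2 * f / np.maximum(sig, 1e-300)
    else:
        raise ValueError(f"unknown error_form {error_form!r}")
    return np.maximum(sig, 1e-10), dsig


#: random-effect excursions beyond this are numerically meaningless
_ETA_CLIP = 8.0


def _pred(tab: _ArmTable, CL: np.ndarray, Vc: np.ndarray, Vp: float, Q: float) -> np.ndarray:
    with np.errstate(all="ignore"):
        return concentration_arrays(
            tab.t, tab.dose_mg[:, None], tab.infusion_h, CL[:, None], Vc[:, None], Vp, Q
        )


def _gval(tab, eta, theta_nat, Oinv, logdetO, opts) -> np.ndarray:
    """Per-arm joint negative log density g_i(eta_i); eta shape (n_arms, 2)."""
    CL, Vc, Vp, Q, _, _, _, a, b = theta_nat
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    f = _pred(tab, CL * np.exp(eta[:, 0]), Vc * np.exp(eta[:, 1]), Vp, Q)
    sig, _ = _sigma(f, a, b, np.sqrt(tab.n), opts.error_form, opts.weight_constant)
    r = (tab.y - f) / sig
    point = 0.5 * r**2 + np.log(sig) + 0.5 * _LOG2PI
    if opts.truncated:
        point = point + log_ndtr(f / sig)  # normalise the positive-part density
    data_term = np.where(tab.mask, point, 0.0).sum(axis=1)
    quad = np.einsum("ij,jk,ik->i", eta, Oinv, eta)
    prior = 0.5 * quad + 0.5 * (logdetO + 2 * _LOG2PI)
    return data_term + prior


def _inner_newton(tab, theta_nat, Oinv, logdetO, opts, eta0, tol=1e-9, maxiter=60):
    """Damped Gauss-Newton mode finding, all arms at once.

    Returns (eta_hat, g_at_mode, H_gn (n_arms,2,2)).
    """
    CLp, Vcp, Vp, Q, _, _, _, a, b = theta_nat
    sqrt_n = np.sqrt(tab.n)
    eta = eta0.copy()
    g = _gval(tab, eta, theta_nat, Oinv, logdetO, opts)
    h = 1e-4  # FD step for the prediction Jacobian in eta
    H = np.empty((tab.n_arms, 2, 2))
    for _ in range(maxiter):
        f = _pred(tab, CLp * np.exp(eta[:, 0]), Vcp * np.exp(eta[:, 1]), Vp, Q)
        J = np.empty(f.shape + (2,))
        for k in range(2):
            e = np.zeros(2)
            e[k] = h
            fp = _pred(tab, CLp * np.exp(eta[:, 0] + e[0]), Vcp * np.exp(eta[:, 1] + e[1]), Vp, Q)
            fm = _pred(tab, CLp * np.exp(eta[:, 0] - e[0]), Vcp * np.exp(eta[:, 1] - e[1]), Vp, Q)
            J[..., k] = (fp - fm) / (2 * h)
        sig, dsig = _sigma(f, a, b, sqrt_n, opts.error_form, opts.weight_constant)
        r = (tab.y - f) / sig
        dgdf = (-r + dsig * (1.0 - r**2)) / sig
        if opts.truncated:
            u = f / sig
            # d/df log Phi(u) with u = f/sigma
            hazard = np.exp(-0.5 * u**2 - 0.5 * _LOG2PI - log_ndtr(u))
            dgdf = dgdf + hazard * (1.0 - u * dsig) / sig
        dgdf = np.where(tab.mask, dgdf, 0.0)
        grad = np.einsum("im,imk->ik", dgdf, J) + eta @ Oinv
        Jw = J / sig[..., None] * tab.mask[..., None]
        H = np.einsum("imk,iml->ikl", Jw, Jw) + Oinv
        # solve 2x2 systems
        det = H[:, 0, 0] * H[:, 1, 1] - H[:, 0, 1] * H[:, 1, 0]
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        step = np.empty_like(eta)
        step[:, 0] = (H[:, 1, 1] * grad[:, 0] - H[:, 0, 1] * grad[:, 1]) / det
        step[:, 1] = (-H[:, 1, 0] * grad[:, 0] + H[:, 0, 0] * grad[:, 1]) / det
        if np.max(np.abs(grad)) < tol:
            break
        # backtracking halving per arm
        lam = np.ones(tab.n_arms)
        for _ in range(20):
            eta_try = np.clip(eta - lam[:, None] * step, -_ETA_CLIP, _ETA_CLIP)
            g_try = _gval(tab, eta_try, theta_nat, Oinv, logdetO, opts)
            worse = g_try > g + 1e-12
            if not np.any(worse):
                break
            lam[worse] *= 0.5
        improved = g_try <= g
        eta = np.where(improved[:, None], eta_try, eta)
        g = np.where(improved, g_try, g)
        if not np.any(improved):
            break
    return eta, g, H


def _unpack(theta: np.ndarray) -> tuple:
    """Transformed -> natural: (CL, Vc, Vp, Q, wCL, wVc, rho, a, b)."""
    CL, Vc, Vp, Q = np.exp(theta[:4])
    wCL, wVc = np.exp(theta[4:6])
    rho = np.tanh(theta[6])
    a, b = np.exp(theta[7:9])
    return CL, Vc, Vp, Q, wCL, wVc, rho, a, b


def _omega_inv(wCL: float, wVc: float, rho: float) -> tuple[np.ndarray, float]:
    O = np.array([[wCL**2, rho * wCL * wVc], [rho * wCL * wVc, wVc**2]])
    det = O[0, 0] * O[1, 1] - O[0, 1] ** 2
    det = max(det, 1e-300)
    Oinv = np.array([[O[1, 1], -O[0, 1]], [-O[0, 1], O[0, 0]]]) / det
    return Oinv, float(np.log(det))


class _LaplaceNLL:
    """Negative Laplace marginal log-likelihood with warm-started inner modes."""

    def __init__(self, tab: _ArmTable, opts: FitOptions):
        self.tab = tab
        self.opts = opts
        self.eta_cache = np.zeros((tab.n_arms, 2))

    def __call__(self, theta: np.ndarray) -> float:
        nat = _unpack(theta)
        Oinv, logdetO = _omega_inv(nat[4], nat[5], nat[6])
        eta, g, H = _inner_newton(self.tab, nat, Oinv, logdetO, self.opts, self.eta_cache)
        self.eta_cache = eta
        det = H[:, 0, 0] * H[:, 1, 1] - H[:, 0, 1] * H[:, 1, 0]
        det = np.maximum(det, 1e-300)
        # per-arm Laplace: -g + (d/2) log(2pi) - 0.5 log det H with d = 2
        ll = (-g + _LOG2PI - 0.5 * np.log(det)).sum()
        if not np.isfinite(ll):
            return 1e12
        return -ll


# ---------------------------------------------------------------------------
# separate BTAV path (per-study inner problems of varying dimension)


class _BtavNLL:
    """Laplace NLL where each study has a shared BSV deviation plus
    independent arm-level (BTAV) deviations on CL and Vc."""

    def __init__(self, tab: _ArmTable, opts: FitOptions):
        self.tab = tab
        self.opts = opts
        self.groups: list[np.ndarray] = []
        order: dict[str, list[int]] = {}
        for i, s in enumerate(tab.study_ids):
            order.setdefault(s, []).append(i)
        self.groups = [np.array(ix) for ix in order.values()]
        self.cache = [np.zeros(2 + 2 * len(ix)) for ix in self.groups]

    def _g_group(self, u: np.ndarray, ix: np.ndarray, nat, Oinv, logdetO, tb2) -> float:
        """Joint negative log density in whitened coordinates: the arm-level
        (BTAV) deviations enter as kappa = tau * v so the optimisation is
        well conditioned even for vanishing tau."""
        CLp, Vcp, Vp, Q, _, _, _, a, b = nat
        k = len(ix)
        eta_s = u[:2]
        v = u[2:].reshape(k, 2)
        kap = v * np.asarray(tb2)
        tab = self.tab
        f = concentration_arrays(
            tab.t[ix], tab.dose_mg[ix, None], tab.infusion_h,
            (CLp * np.exp(eta_s[0] + kap[:, 0]))[:, None],
            (Vcp * np.exp(eta_s[1] + kap[:, 1]))[:, None], Vp, Q,
        )
        sig, _ = _sigma(f, a, b, np.sqrt(tab.n[ix]), self.opts.error_form,
                        self.opts.weight_constant)
        r = (tab.y[ix] - f) / sig
        point = 0.5 * r**2 + np.log(sig) + 0.5 * _LOG2PI
        if self.opts.truncated:
            point = point + log_ndtr(f / sig)
        data = np.where(tab.mask[ix], point, 0.0).sum()
        prior = 0.5 * eta_s @ Oinv @ eta_s + 0.5 * (logdetO + 2 * _LOG2PI)
        # whitened arm-level prior: standard normal in v, plus its
        # normalisation; the tau Jacobian is added in the Laplace assembly
        prior += 0.5 * float(np.sum(v**2)) + k * _LOG2PI
        return float(data + prior)

    def __call__(self, theta: np.ndarray) -> float:
        nat = _unpack(theta[:9])
        tb2 = tuple(np.exp(theta[9:11]))
        Oinv, logdetO = _omega_inv(nat[4], nat[5], nat[6])
        total = 0.0
        for gi, ix in enumerate(self.groups):
            k = len(ix)
            d = 2 + 2 * k
            res = optimize.minimize(
                self._g_group, self.cache[gi], args=(ix, nat, Oinv, logdetO, tb2),
                method="BFGS", options={"gtol": 1e-7, "maxiter": 300},
            )
            self.cache[gi] = res.x
            H = _fd_hessian(lambda u: self._g_group(u, ix, nat, Oinv, logdetO, tb2),
                            res.x, 1e-4)
            sign, logdet = np.linalg.slogdet(H)
            if sign <= 0:
                logdet = 50.0  # strongly penalise non-PD curvature
            # kappa = tau*v change of variables contributes k log(tCL*tVc),
            # which cancels the whitened prior's missing normalisation
            total += -res.fun + 0.5 * d * _LOG2PI - 0.5 * logdet
        if not np.isfinite(total):
            return 1e12
        return -total


def _fd_hessian(fun, x: np.ndarray, h: float) -> np.ndarray:
    d = len(x)
    H = np.empty((d, d))
    f0 = fun(x)
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = h
            ej = np.zeros(d); ej[j] = h
            if i == j:
                H[i, i] = (fun(x + ei) - 2 * f0 + fun(x - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
                ) / (4 * h**2)
    return H


# ---------------------------------------------------------------------------
# initial values and the outer fit


def _initial_theta(tab: _ArmTable) -> np.ndarray:
    """Model-free starting values from non-compartmental heuristics."""
    cmax = np.max(np.where(tab.mask, tab.y, 0), axis=1)
    cmax = np.maximum(cmax, 1e-6)
    Vc0 = float(np.median(tab.dose_mg / cmax * 1000.0))  # ng/mL scale
    aucs, lams = [], []
    for i in range(tab.n_arms):
        t = tab.t[i, tab.mask[i]]
        y = np.maximum(tab.y[i, tab.mask[i]], 1e-6)
        if len(t) >= 3:
            tail = slice(max(len(t) - 3, 0), None)
            slope = np.polyfit(t[tail], np.log(y[tail]), 1)[0]
            lam = max(-slope, 1e-5)
            lams.append(lam)
            aucs.append(np.trapezoid(y, t) + y[-1] / lam)
    if aucs:
        CL0 = float(np.median(tab.dose_mg[: len(aucs)] * 1000.0 / np.array(aucs))) * 24.0
    else:
        CL0 = 0.2 * Vc0
    CL0 = min(max(CL0, 1e-3), 100.0)
    Vc0 = min(max(Vc0, 1e-2), 1e3)
    a0 = 0.02 * float(np.median(cmax))
    theta = np.array([
        np.log(CL0), np.log(Vc0), np.log(0.3 * Vc0), np.log(CL0),
        np.log(0.2), np.log(0.2), np.arctanh(0.5), np.log(max(a0, 1e-2)), np.log(0.2),
    ])
    return theta


_BOUNDS9 = [
    (np.log(1e-4), np.log(1e3)),  # CL
    (np.log(1e-3), np.log(1e4)),  # Vc
    (np.log(1e-4), np.log(1e4)),  # Vp
    (np.log(1e-4), np.log(1e3)),  # Q
    (np.log(1e-4), np.log(3.0)),  # omega_CL
    (np.log(1e-4), np.log(3.0)),  # omega_Vc
    (-6.0, 6.0),                  # atanh rho
    (np.log(1e-3), np.log(1e6)),  # a
    (np.log(1e-4), np.log(10.0)), # b
]


def fit(ds: td.Dataset, options: FitOptions | None = None) -> FitResult:
    """Fit the population model to a validated dataset.

    Non-convergence is reported through the ``convergence`` flag and the
    ``messages`` list, never as an exception.
    """
    opts = options or FitOptions()
    tab = prepare_arms(ds, dose_finding_only=opts.dose_finding_only)
    separate = opts.btav_mode == "separate_btav"
    if opts.btav_mode not in ("arms_as_studies", "separate_btav"):
        raise ValueError(f"unknown btav_mode {opts.btav_mode!r}")

    theta0 = _initial_theta(tab)
    bounds = list(_BOUNDS9)
    if separate:
        theta0 = np.concatenate([theta0, [np.log(0.1), np.log(0.1)]])
        bounds += [(np.log(1e-4), np.log(3.0))] * 2

    rng = np.random.default_rng(opts.seed)
    starts = [theta0]
    for _ in range(max(opts.n_starts - 1, 0)):
        jit = rng.normal(0, 0.3, size=len(theta0))
        starts.append(np.clip(theta0 + jit, [lo for lo, _ in bounds], [hi for _, hi in bounds]))

    best = None
    messages: list[str] = []
    for s0 in starts:
        nll = _BtavNLL(tab, opts) if separate else _LaplaceNLL(tab, opts)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                nll, s0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": opts.maxiter, "ftol": 1e-9, "gtol": 1e-5,
                         "eps": 1e-6},
            )
        if best is None or res.fun < best[0].fun:
            best = (res, nll)
    res, nll_obj = best
    theta_hat = res.x
    nat = _unpack(theta_hat[:9])
    converged = bool(res.success and np.isfinite(res.fun))
    if not res.success:
        messages.append(f"optimizer: {res.message}")

    rse = {name: float("nan") for name in _PARAM_NAMES}
    cov_t = None
    if opts.compute_rse:
        try:
            H = _fd_hessian(nll_obj, theta_hat, 1e-4)
            eigvals = np.linalg.eigvalsh(H)
            if np.min(eigvals) <= 0:
                converged = False
                messages.append("observed information not positive definite")
                cov_t = np.linalg.pinv(H)
            else:
                cov_t = np.linalg.inv(H)
            se_t = np.sqrt(np.abs(np.diag(cov_t)))
            vals = list(nat)
            for k, name in enumerate(_PARAM_NAMES):
                if name == "rho":
                    se_nat = se_t[k] * (1 - nat[6] ** 2)
                else:
                    se_nat = se_t[k] * vals[k]
                denom = abs(vals[k]) if abs(vals[k]) > 1e-300 else np.nan
                rse[name] = float(100.0 * se_nat / denom)
            if separate:
                for k, name in zip((9, 10), ("omega_btav_CL", "omega_btav_Vc")):
                    val = float(np.exp(theta_hat[k]))
                    rse[name] = float(100.0 * se_t[k] * val / val)
        except np.linalg.LinAlgError:
            converged = False
            messages.append("failed to invert observed information")

    at_bound = [
        _PARAM_NAMES[k] for k, (lo, hi) in enumerate(bounds[:9])
        if theta_hat[k] <= lo + 1e-8 or theta_hat[k] >= hi - 1e-8
    ]
    if at_bound:
        messages.append(f"estimates at bounds: {at_bound}")

    btav = None
    if separate:
        btav = BSVParams(float(np.exp(theta_hat[9])), float(np.exp(theta_hat[10])), 0.0)

    return FitResult(
        pk=PKParams(CL=nat[0], Vc=nat[1], Vp=nat[2], Q=nat[3]),
        bsv=BSVParams(omega_CL=nat[4], omega_Vc=nat[5], rho=nat[6]),
        error=ResidualError(a=nat[7], b=nat[8]),
        rse=rse, loglik=float(-res.fun), convergence=converged,
        n_arms_used=tab.n_arms, options=opts, btav=btav,
        cov_transformed=cov_t, messages=messages,
    )


# ---------------------------------------------------------------------------
# diagnostics


def empirical_bayes_etas(fit_result: FitResult, ds: td.Dataset) -> dict[str, np.ndarray]:
    """Per-arm posterior modes of (eta_CL, eta_Vc) under the fitted model."""
    opts = fit_result.options
    tab = prepare_arms(ds, dose_finding_only=opts.dose_finding_only)
    nat = (fit_result.pk.CL, fit_result.pk.Vc, fit_result.pk.Vp, fit_result.pk.Q,
           fit_result.bsv.omega_CL, fit_result.bsv.omega_Vc, fit_result.bsv.rho,
           fit_result.error.a, fit_result.error.b)
    Oinv, logdetO = _omega_inv(nat[4], nat[5], nat[6])
    eta, _, _ = _inner_newton(tab, nat, Oinv, logdetO, opts, np.zeros((tab.n_arms, 2)))
    return {arm_id: eta[i] for i, arm_id in enumerate(tab.arm_ids)}


def diagnostics(fit_result: FitResult, ds: td.Dataset, n_sim: int = 200,
                seed: int = 0):
    """Goodness-of-fit and visual-predictive-check tables.

    Returns a dict with a ``gof`` frame (observed, population and individual
    predictions, standardised residuals) and a ``vpc`` frame (per
    observation: the 5/50/95 percentiles of ``n_sim`` model replicates, raw
    and prediction-corrected, and whether the observation falls inside the
    5-95 band).
    """
    import pandas as pd

    if not fit_result.convergence:
        raise ValueError("diagnostics require a converged fit")
    opts = fit_result.options
    tab = prepare_arms(ds, dose_finding_only=opts.dose_finding_only)
    pk, err, bsv = fit_result.pk, fit_result.error, fit_result.bsv
    etas = empirical_bayes_etas(fit_result, ds)
    eta = np.array([etas[a] for a in tab.arm_ids])

    f_pop = _pred(tab, np.full(tab.n_arms, pk.CL), np.full(tab.n_arms, pk.Vc), pk.Vp, pk.Q)
    f_ind = _pred(tab, pk.CL * np.exp(eta[:, 0]), pk.Vc * np.exp(eta[:, 1]), pk.Vp, pk.Q)
    sig_ind, _ = _sigma(f_ind, err.a, err.b, np.sqrt(tab.n), opts.error_form,
                        opts.weight_constant)

    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(bsv.cov() + 1e-12 * np.eye(2))
    sims = np.empty((n_sim,) + tab.y.shape)
    for s in range(n_sim):
        e = rng.standard_normal((tab.n_arms, 2)) @ L.T
        f_s = _pred(tab, pk.CL * np.exp(e[:, 0]), pk.Vc * np.exp(e[:, 1]), pk.Vp, pk.Q)
        sig_s, _ = _sigma(f_s, err.a, err.b, np.sqrt(tab.n), opts.error_form,
                          opts.weight_constant)
        sims[s] = f_s + rng.standard_normal(f_s.shape) * sig_s
    lo, mid, hi = np.percentile(sims, [5, 50, 95], axis=0)
    med_sim = np.median(sims, axis=0)

    gof_rows, vpc_rows = [], []
    for i, arm_id in enumerate(tab.arm_ids):
        for j in range(tab.t.shape[1]):
            if not tab.mask[i, j]:
                continue
            gof_rows.append({
                "arm_id": arm_id, "time_h": tab.t[i, j], "observed": tab.y[i, j],
                "pred_pop": f_pop[i, j], "pred_ind": f_ind[i, j],
                "std_resid": (tab.y[i, j] - f_ind[i, j]) / sig_ind[i, j],
            })
            pc = f_pop[i, j] / max(med_sim[i, j], 1e-12)
            vpc_rows.append({
                "arm_id": arm_id, "time_h": tab.t[i, j], "observed": tab.y[i, j],
                "q05": lo[i, j], "q50": mid[i, j], "q95": hi[i, j],
                "observed_pc": tab.y[i, j] * pc,
                "q05_pc": lo[i, j] * pc, "q50_pc": mid[i, j] * pc, "q95_pc": hi[i, j] * pc,
                "inside_90": bool(lo[i, j] <= tab.y[i, j] <= hi[i, j]),
            })
    return {"gof": pd.DataFrame(gof_rows), "vpc": pd.DataFrame(vpc_rows)}
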