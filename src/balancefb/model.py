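"""Delayed CoM-feedback reconstruction of muscle activity.

Muscle envelopes are reconstructed as the sum of two half-wave-rectified
pathways driven by delayed CoM kinematics (common delay tau, default
100 ms).  For a plantar flexor:

    BC  = pos( e0 + k_d*d(t-tau) + k_v*v(t-tau) + k_a*a(t-tau)
               + k_s*a_init(t-tau) )
    ANT = pos( k_d'*(-d(t-tau)) + k_v'*(-v(t-tau)) + k_a'*(-a(t-tau)) )

where pos(.) keeps the positive part only (excitatory drive).  The
tibialis anterior uses the opposite kinematic signs in both pathways and
has no stiction term.  ``a_init`` is the CoM acceleration gated to zero
once the ankle-angle change reaches the stiction threshold (default
0.5 deg), modelling the short-range-stiffness-related initial burst.

Gains live in a box [0, 10] (per meter / s per meter / s^2 per meter)
and are estimated by minimising the summed squared reconstruction error
over the fit window plus a small quadratic penalty (1e-4) on the
antagonistic ("prime") gains.  The "simple" variant pins the prime gains
at zero; the "extended" variant frees them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .preprocess import ComKinematics

PLANTAR_FLEXORS = ("LG", "MG", "SOL")
ROLE_PF = "plantar_flexor"
ROLE_TA = "tibialis_anterior"

#: names of the free gains for each role, in parameter-vector order
PF_GAIN_NAMES = ("k_d", "k_v", "k_a", "k_s", "k_dp", "k_vp", "k_ap")
TA_GAIN_NAMES = ("k_d", "k_v", "k_a", "k_dp", "k_vp", "k_ap")
PRIME_NAMES = ("k_dp", "k_vp", "k_ap")


class RoleError(ValueError):
    """Gain set inconsistent with the muscle role."""


class FitError(RuntimeError):
    """Optimizer failed to converge; carries the best solution so far."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


def role_of(muscle: str) -> str:
    return ROLE_TA if muscle == "TA" else ROLE_PF


@dataclass
class ModelConfig:
    tau: float = 0.100
    gain_bounds: Tuple[float, float] = (0.0, 10.0)
    penalty_weight: float = 1e-4
    stiction_threshold: float = 0.5
    fit_window: Tuple[float, float] = (-0.5, 1.5)
    gof_window: Tuple[float, float] = (0.0, 1.5)
    variant: str = "extended"  # "simple" | "extended"
    n_starts: int = 8
    seed: int = 0


@dataclass
class FeedbackGains:
    """Fitted feedback weights for one muscle.

    Prime gains (``k_dp``/``k_vp``/``k_ap``) weight the antagonistic
    pathway; ``k_s`` is the stiction gain and is ``None`` for TA.
    """

    k_d: float = 0.0
    k_v: float = 0.0
    k_a: float = 0.0
    k_s: Optional[float] = 0.0
    k_dp: float = 0.0
    k_vp: float = 0.0
    k_ap: float = 0.0
    e0: float = 0.0

    def as_dict(self) -> Dict[str, float]:
        out = {
            "k_d": self.k_d, "k_v": self.k_v, "k_a": self.k_a,
            "k_dp": self.k_dp, "k_vp": self.k_vp, "k_ap": self.k_ap,
            "e0": self.e0,
        }
        if self.k_s is not None:
            out["k_s"] = self.k_s
        return out

    def vector(self, role: str) -> np.ndarray:
        if role == ROLE_PF:
            ks = 0.0 if self.k_s is None else self.k_s
            return np.array(
                [self.k_d, self.k_v, self.k_a, ks, self.k_dp, self.k_vp, self.k_ap]
            )
        return np.array(
            [self.k_d, self.k_v, self.k_a, self.k_dp, self.k_vp, self.k_ap]
        )

    @staticmethod
    def from_vector(x: np.ndarray, role: str, e0: float) -> "FeedbackGains":
        x = np.asarray(x, dtype=float)
        if role == ROLE_PF:
            return FeedbackGains(
                k_d=x[0], k_v=x[1], k_a=x[2], k_s=x[3],
                k_dp=x[4], k_vp=x[5], k_ap=x[6], e0=e0,
            )
        return FeedbackGains(
            k_d=x[0], k_v=x[1], k_a=x[2], k_s=None,
            k_dp=x[3], k_vp=x[4], k_ap=x[5], e0=e0,
        )

    def validate(self, role: str, bounds: Tuple[float, float] = (0.0, 10.0)) -> None:
        if role == ROLE_TA and self.k_s not in (None, 0.0):
            raise RoleError("stiction gain k_s is not defined for tibialis anterior")
        lo, hi = bounds
        for name, val in self.as_dict().items():
            if name == "e0":
                continue
            if not (lo - 1e-12 <= val <= hi + 1e-12):
                raise ValueError(f"gain {name}={val} outside bounds [{lo}, {hi}]")

    def bound_flags(self, bounds: Tuple[float, float] = (0.0, 10.0),
                    tol: float = 1e-6) -> Dict[str, bool]:
        """Which gains sit within ``tol`` of a box bound (upper or lower)."""
        lo, hi = bounds
        return {
            name: bool(abs(val - lo) <= tol or abs(val - hi) <= tol)
            for name, val in self.as_dict().items()
            if name != "e0"
        }


@dataclass
class ReconstructionResult:
    t: np.ndarray
    emg_recon: np.ndarray
    balance_correcting: np.ndarray
    antagonistic: np.ndarray
    cost: float = np.nan
    r2: float = np.nan
    vaf: float = np.nan
    rmse: float = np.nan


def gate_stiction(
    t: np.ndarray,
    a_com: np.ndarray,
    ankle_change: np.ndarray,
    threshold: float = 0.5,
) -> np.ndarray:
    """Stiction-gated initial CoM acceleration.

    Equals ``a_com`` for t in [0, t_gate) where t_gate is the first
    post-onset time at which |ankle change| >= threshold; zero elsewhere
    (including all t < 0).  A zero threshold closes the gate at onset,
    giving an identically zero output.
    """
    if threshold < 0:
        raise ValueError("stiction threshold must be >= 0")
    t = np.asarray(t, dtype=float)
    a_com = np.asarray(a_com, dtype=float)
    ankle_change = np.asarray(ankle_change, dtype=float)
    post = t >= 0
    out = np.zeros_like(a_com)
    crossed = post & (np.abs(ankle_change) >= threshold)
    if np.any(crossed):
        t_gate = t[crossed][0]
        active = post & (t < t_gate)
    else:
        active = post
    out[active] = a_com[active]
    return out


def _delayed(t: np.ndarray, series: np.ndarray, n_shift: int) -> np.ndarray:
    """Shift a series ``n_shift`` samples later in time; samples that
    would need data before the recording start are filled with the
    pre-onset (quiet-stance) mean of the channel."""
    pre = t < 0
    fill = float(np.mean(series[pre])) if np.any(pre) else float(series[0])
    out = np.full_like(series, fill)
    if n_shift == 0:
        return series.copy()
    out[n_shift:] = series[:-n_shift]
    return out


class _Regressors:
    """Delayed kinematic channels + fit/GoF masks, precomputed once per
    (com, config) so repeated cost evaluations during fitting are cheap."""

    def __init__(self, com: ComKinematics, config: ModelConfig):
        fs = com.fs
        n_shift_f = config.tau * fs
        n_shift = int(round(n_shift_f))
        if abs(n_shift_f - n_shift) > 1e-6:
            raise ValueError(
                f"tau={config.tau}s is not an integer number of samples at {fs} Hz"
            )
        t = com.t
        self.t = t
        self.d = _delayed(t, com.d, n_shift)
        self.v = _delayed(t, com.v, n_shift)
        self.a = _delayed(t, com.a, n_shift)
        self.a_init = _delayed(t, com.a_init, n_shift)
        lo, hi = config.fit_window
        self.fit_mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
        if not np.any(self.fit_mask):
            raise ValueError("empty fit window")

    def pathways(self, x: np.ndarray, e0: float, role: str
                 ) -> Tuple[np.ndarray, np.ndarray]:
        if role == ROLE_PF:
            bc_lin = (e0 + x[0] * self.d + x[1] * self.v + x[2] * self.a
                      + x[3] * self.a_init)
            ant_lin = -(x[4] * self.d + x[5] * self.v + x[6] * self.a)
        else:
            bc_lin = e0 - (x[0] * self.d + x[1] * self.v + x[2] * self.a)
            ant_lin = x[3] * self.d + x[4] * self.v + x[5] * self.a
        return np.maximum(bc_lin, 0.0), np.maximum(ant_lin, 0.0)


def reconstruct_emg(
    gains: FeedbackGains,
    com: ComKinematics,
    config: ModelConfig = ModelConfig(),
    role: str = ROLE_PF,
) -> ReconstructionResult:
    """Forward-evaluate the feedback model (series only; no fit metrics)."""
    gains.validate(role, config.gain_bounds)
    reg = _Regressors(com, config)
    bc, ant = reg.pathways(gains.vector(role), gains.e0, role)
    return ReconstructionResult(
        t=com.t, emg_recon=bc + ant, balance_correcting=bc, antagonistic=ant
    )


def model_cost(
    gains: FeedbackGains,
    measured: np.ndarray,
    com: ComKinematics,
    config: ModelConfig = ModelConfig(),
    role: str = ROLE_PF,
) -> float:
    """Summed squared error over the fit window + prime-gain penalty."""
    reg = _Regressors(com, config)
    x = gains.vector(role)
    return _cost_vec(x, gains.e0, np.asarray(measured, float), reg, config, role)


def _cost_vec(x, e0, measured, reg: _Regressors, config: ModelConfig, role: str
              ) -> float:
    bc, ant = reg.pathways(x, e0, role)
    resid = (bc + ant - measured)[reg.fit_mask]
    primes = x[4:7] if role == ROLE_PF else x[3:6]
    return float(np.dot(resid, resid)
                 + config.penalty_weight * float(np.dot(primes, primes)))


def baseline_activity(t: np.ndarray, measured: np.ndarray,
                      window: Tuple[float, float] = (-0.5, 0.0)) -> float:
    """e0: mean measured envelope over the pre-onset window [-0.5, 0)."""
    mask = (t >= window[0] - 1e-9) & (t < window[1] - 1e-9)
    if not np.any(mask):
        raise ValueError("no pre-onset samples for baseline estimation")
    return float(np.mean(measured[mask]))


def _starts(reg: _Regressors, measured: np.ndarray, e0: float, role: str,
            config: ModelConfig, n_free: int, free_primes: bool) -> List[np.ndarray]:
    """Multi-start design: origin, a linearised bounded-least-squares
    solution for the balance-correcting pathway, the box midpoint, and
    seeded random points in the low-gain region."""
    lo, hi = config.gain_bounds
    starts = [np.zeros(n_free)]
    # linearised BC-only initial guess (ignore rectification)
    sign = 1.0 if role == ROLE_PF else -1.0
    cols = [sign * reg.d, sign * reg.v, sign * reg.a]
    if role == ROLE_PF:
        cols.append(reg.a_init)
    A = np.stack(cols, axis=1)[reg.fit_mask]
    b = measured[reg.fit_mask] - e0
    try:
        sol = optimize.lsq_linear(A, b, bounds=(lo, hi))
        x0 = np.zeros(n_free)
        x0[: A.shape[1]] = np.clip(sol.x, lo, hi)
        starts.append(x0)
    except Exception:  # pragma: no cover - lsq_linear is robust
        pass
    starts.append(np.full(n_free, 0.5 * (lo + hi)))
    rng = np.random.default_rng(config.seed)
    while len(starts) < max(config.n_starts, 3):
        starts.append(rng.uniform(lo, min(hi, lo + 2.0), size=n_free))
    return starts[: max(config.n_starts, 3)]


def fit_gains(
    measured: np.ndarray,
    com: ComKinematics,
    config: ModelConfig = ModelConfig(),
    role: str = ROLE_PF,
    extra_starts: Optional[Sequence[FeedbackGains]] = None,
) -> Tuple[FeedbackGains, ReconstructionResult]:
    """Estimate feedback gains by bounded multi-start minimisation.

    ``e0`` is fixed to the pre-onset mean of the measured envelope, not
    optimised.  The cost is piecewise smooth (rectification kinks), so
    each start runs L-BFGS-B and the best candidate is polished with
    Powell; a candidate is never accepted if worse than its own start.
    The simple variant pins prime gains at zero.  ``extra_starts`` lets
    callers seed the extended fit with, e.g., the simple solution.
    """
    measured = np.asarray(measured, dtype=float)
    t = com.t
    e0 = baseline_activity(t, measured, (config.fit_window[0], 0.0))
    reg = _Regressors(com, config)
    names = PF_GAIN_NAMES if role == ROLE_PF else TA_GAIN_NAMES
    n_all = len(names)
    n_bc = 4 if role == ROLE_PF else 3
    free_primes = config.variant == "extended"
    n_free = n_all if free_primes else n_bc
    lo, hi = config.gain_bounds
    bounds = [(lo, hi)] * n_free

    def expand(xf: np.ndarray) -> np.ndarray:
        if free_primes:
            return xf
        x = np.zeros(n_all)
        x[:n_bc] = xf
        return x

    def f(xf: np.ndarray) -> float:
        return _cost_vec(expand(xf), e0, measured, reg, config, role)

    starts = _starts(reg, measured, e0, role, config, n_free, free_primes)
    if extra_starts:
        for g in extra_starts:
            starts.append(np.clip(g.vector(role)[:n_free] if not free_primes
                                  else g.vector(role), lo, hi))

    best_x, best_f = None, np.inf
    n_fail = 0
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, float), lo, hi)
        try:
            res = optimize.minimize(
                f, x0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-12},
            )
            cand_x, cand_f = res.x, float(res.fun)
        except Exception:
            n_fail += 1
            continue
        f0 = f(x0)
        if f0 < cand_f:  # never accept a step backwards from the start
            cand_x, cand_f = x0, f0
        if cand_f < best_f:
            best_x, best_f = cand_x, cand_f
    if best_x is None:
        raise FitError("all optimizer starts failed", best=None)
    # derivative-free polish around the incumbent (handles kinks)
    res = optimize.minimize(
        f, best_x, method="Powell", bounds=bounds,
        options={"maxiter": 4000, "xtol": 1e-10, "ftol": 1e-14},
    )
    if float(res.fun) < best_f:
        best_x, best_f = res.x, float(res.fun)

    gains = FeedbackGains.from_vector(expand(np.clip(best_x, lo, hi)), role, e0)
    recon = reconstruct_emg(gains, com, config, role)
    recon.cost = best_f
    gof = goodness_of_fit(measured, recon.emg_recon, t, config.gof_window)
    recon.r2, recon.vaf, recon.rmse = gof
    return gains, recon


def goodness_of_fit(
    measured: np.ndarray,
    recon: np.ndarray,
    t: np.ndarray,
    window: Tuple[float, float] = (0.0, 1.5),
) -> Tuple[float, float, float]:
    """(r^2, VAF, RMSE) over the window.

    r^2 is the squared Pearson correlation; VAF the uncentered r^2,
    1 - sum((m - r)^2) / sum(m^2); RMSE the root mean squared error.
    A constant measured signal leaves r^2 undefined (NaN + warning).
    """
    mask = (t >= window[0] - 1e-9) & (t <= window[1] + 1e-9)
    if not np.any(mask):
        raise ValueError("goodness-of-fit window not covered")
    m = np.asarray(measured, float)[mask]
    r = np.asarray(recon, float)[mask]
    resid = m - r
    rmse = float(np.sqrt(np.mean(resid**2)))
    denom = float(np.sum(m**2))
    vaf = 1.0 - float(np.sum(resid**2)) / denom if denom > 0 else np.nan
    if np.ptp(m) == 0 or np.ptp(r) == 0:
        warnings.warn("constant signal in GoF window: r^2 undefined")
        r2 = np.nan
    else:
        c = np.corrcoef(m, r)[0, 1]
        r2 = float(c * c)
    return r2, vaf, rmse


def cost_improvement(simple_cost: float, extended_cost: float) -> float:
    """Cost reduction of the extended over the simple model, as percent
    of the simple-model cost."""
    if not simple_cost > 0:
        raise ValueError("simple-model cost must be > 0")
    return 100.0 * (simple_cost - extended_cost) / simple_cost


def fit_both_variants(
    measured: np.ndarray,
    com: ComKinematics,
    config: ModelConfig = ModelConfig(),
    role: str = ROLE_PF,
):
    """Fit simple then extended (extended is additionally started from
    the simple solution, so its optimal cost can never exceed the
    simple one) and return (simple, extended, improvement_percent)."""
    simple_cfg = replace(config, variant="simple")
    ext_cfg = replace(config, variant="extended")
    g_s, r_s = fit_gains(measured, com, simple_cfg, role)
    g_e, r_e = fit_gains(measured, com, ext_cfg, role, extra_starts=[g_s])
    return (g_s, r_s), (g_e, r_e), cost_improvement(r_s.cost, r_e.cost)


def identifiable_gains(
    gains: FeedbackGains,
    com: ComKinematics,
    config: ModelConfig = ModelConfig(),
    role: str = ROLE_PF,
    delta: float = 1e-3,
    tol: float = 1e-6,
) -> Dict[str, bool]:
    """Which gains the data can constrain at this operating point.

    With half-wave rectified pathways a gain multiplying a signal that
    never survives rectification in the fit window leaves the
    reconstruction unchanged; such gains are unidentifiable.  A gain is
    flagged identifiable when perturbing it by ``delta`` changes the
    reconstruction (sup-norm over the fit window) by more than ``tol``.
    """
    reg = _Regressors(com, config)
    base = reconstruct_emg(gains, com, config, role).emg_recon[reg.fit_mask]
    names = PF_GAIN_NAMES if role == ROLE_PF else TA_GAIN_NAMES
    x = gains.vector(role)
    out: Dict[str, bool] = {}
    for i, name in enumerate(names):
        xp = x.copy()
        xp[i] += delta
        pert = FeedbackGains.from_vector(xp, role, gains.e0)
        recon = reconstruct_emg(pert, com, config, role).emg_recon[reg.fit_mask]
        out[name] = bool(np.max(np.abs(recon - base)) > tol)
    return out
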