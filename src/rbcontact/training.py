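"""Pseudo-likelihood training of the grid CRF with an optional lasso penalty.

The objective is the log pseudo-likelihood

    L(θ) = sum_n sum_ij log Pr(r_ij^(n) | r_N^(n), m^(n), a^(n), b^(n), θ)

optionally penalized as L(θ) − C(‖w_f‖₁ + ‖w_g‖₁).  Each per-cell term is the
log of a two-state Gibbs conditional, which is concave in θ because the
potential is linear in θ; the penalized problem therefore has a global
optimum.  Gradients are analytic: for every cell and each state v,

    ∂L/∂w += (Pr(v | neighbors) − 1[v = r_obs]) · ∂U_ij[v]/∂w

with ∂U/∂w_f = f_ij and ∂U/∂w_g = Σ_N g_ijkl.

The L1 term is handled exactly by the split reformulation w = p − q with
p, q ≥ 0, solved with bound-constrained L-BFGS-B: coordinates shrunk to the
bound are exactly zero, so the lasso performs genuine feature selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .coevolution import N_BASES, base_index
from .crf import CRFParams, FeatureConfig, ProteinRNAInstance
from .errors import MissingLabelError, NumericError

# (center slice, neighbor slice) for the four grid directions.
_DIRECTIONS = (
    (np.s_[1:, :], np.s_[:-1, :]),  # neighbor above
    (np.s_[:-1, :], np.s_[1:, :]),  # neighbor below
    (np.s_[:, 1:], np.s_[:, :-1]),  # neighbor left
    (np.s_[:, :-1], np.s_[:, 1:]),  # neighbor right
)


@dataclass
class TrainingConfig:
    """Optimizer settings: lasso strength C, iteration cap, gradient tolerance."""

    lasso_C: float = 0.0
    max_iterations: int = 500
    gradient_tolerance: float = 1e-5
    initial_params: CRFParams | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lasso_C < 0:
            raise ValueError("lasso_C must be nonnegative")
        if self.gradient_tolerance <= 0:
            raise ValueError("gradient_tolerance must be positive")


@dataclass
class FitInfo:
    converged: bool
    n_iter: int
    final_objective: float
    message: str
    objective_trace: list[float] = field(default_factory=list)


class _Encoded:
    """Integer/float views of one instance, shared by value and gradient code."""

    __slots__ = ("m", "r", "d", "shape")

    def __init__(self, instance: ProteinRNAInstance, config: FeatureConfig, need_label: bool):
        self.m = instance.m.values
        self.shape = instance.shape
        if instance.r is None:
            if need_label:
                raise MissingLabelError("training instance has no contact grid")
            self.r = None
        else:
            self.r = instance.r.r.astype(np.int64)
        mapping = config.grouping.mapping
        a_codes = np.array([mapping[ch] for ch in instance.a], dtype=np.int64)
        b_codes = np.array([base_index(ch, allow_gap=False) for ch in instance.b], dtype=np.int64)
        # δ index per cell: (grouped residue) * 4 + base
        self.d = a_codes[:, None] * N_BASES + b_codes[None, :]


def _uf(w_f: np.ndarray, config: FeatureConfig, enc: _Encoded, v: int) -> np.ndarray:
    """w_f · f_ij(v) for every cell, as an (Np, Nr) array."""
    fam, g4 = config.family, config.label_size
    if fam == 1:
        base = 0 if v == 1 else 2
        return w_f[base] + w_f[base + 1] * enc.m
    if fam == 2:
        idx = ((1 - v) * g4 + enc.d) * 2
        return w_f[idx] + w_f[idx + 1] * enc.m
    idx = (1 - v) * g4 + enc.d
    return w_f[idx]


def _f_indices(config: FeatureConfig, enc: _Encoded, v: int):
    """(index array, multiplies-m?) for the active f coordinates at state v."""
    fam, g4 = config.family, config.label_size
    if fam == 1:
        return np.full(enc.shape, 0 if v == 1 else 2, dtype=np.int64), True
    if fam == 2:
        return ((1 - v) * g4 + enc.d) * 2, True
    return (1 - v) * g4 + enc.d, False


def _g_indices(config: FeatureConfig, v: int, s: np.ndarray, d_n: np.ndarray):
    """(index array, multiplies-m?) for the active g coordinates.

    ``v`` is the center state, ``s`` the neighbor's state array, ``d_n`` the
    neighbor's δ index array.
    """
    fam, g4 = config.family, config.label_size
    block = (1 - v) * 2 + (1 - s)
    if fam == 1:
        return block * 2, True
    if fam == 2:
        return (block * g4 + d_n) * 2, True
    return block * g4 + d_n, False


def _state_energies(
    w_f: np.ndarray,
    w_g: np.ndarray,
    config: FeatureConfig,
    enc: _Encoded,
    r: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """U_ij[v] for v = 0, 1 at every cell, conditioning neighbor states on ``r``."""
    us = [_uf(w_f, config, enc, 0), _uf(w_f, config, enc, 1)]
    for center, nbr in _DIRECTIONS:
        s, d_n, m_n = r[nbr], enc.d[nbr], enc.m[nbr]
        for v in (0, 1):
            idx, with_m = _g_indices(config, v, s, d_n)
            contrib = w_g[idx]
            if with_m:
                contrib = contrib + w_g[idx + 1] * m_n
            us[v][center] += contrib
    return us[0], us[1]


def _pll_terms(w_f, w_g, config, enc, r):
    u0, u1 = _state_energies(w_f, w_g, config, enc, r)
    log_z = np.logaddexp(-u0, -u1)
    u_obs = np.where(r == 1, u1, u0)
    value = float((-u_obs - log_z).sum())
    p1 = np.exp(-u1 - log_z)
    return value, p1


def pseudo_log_likelihood(
    params: CRFParams,
    config: FeatureConfig,
    instances: list[ProteinRNAInstance],
) -> float:
    """L(θ): sum of per-cell log conditionals over all labeled instances (≤ 0)."""
    params.check(config)
    total = 0.0
    for inst in instances:
        enc = _Encoded(inst, config, need_label=True)
        value, _ = _pll_terms(params.w_f, params.w_g, config, enc, enc.r)
        total += value
    return total


def _accumulate_gradient(w_f, w_g, config, enc, r, grad_f, grad_g):
    value, p1 = _pll_terms(w_f, w_g, config, enc, r)
    # c[v] = Pr(v) - 1[v = r_obs]; for binary states c[1] = p1 - r, c[0] = -c[1].
    c1 = p1 - r
    for v, cv in ((1, c1), (0, -c1)):
        idx, with_m = _f_indices(config, enc, v)
        np.add.at(grad_f, idx, cv)
        if with_m:
            np.add.at(grad_f, idx + 1, cv * enc.m)
    for center, nbr in _DIRECTIONS:
        s, d_n, m_n = r[nbr], enc.d[nbr], enc.m[nbr]
        for v, cv in ((1, c1), (0, -c1)):
            cvc = cv[center]
            idx, with_m = _g_indices(config, v, s, d_n)
            np.add.at(grad_g, idx, cvc)
            if with_m:
                np.add.at(grad_g, idx + 1, cvc * m_n)
    return value


def pll_gradient(
    params: CRFParams,
    config: FeatureConfig,
    instances: list[ProteinRNAInstance],
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic (∂L/∂w_f, ∂L/∂w_g)."""
    params.check(config)
    grad_f = np.zeros(config.f_dim)
    grad_g = np.zeros(config.g_dim)
    for inst in instances:
        enc = _Encoded(inst, config, need_label=True)
        _accumulate_gradient(params.w_f, params.w_g, config, enc, enc.r, grad_f, grad_g)
    # Per cell, d log Pr / dw = sum_v (Pr(v) - 1[v = r_obs]) dU[v]/dw, which is
    # exactly what _accumulate_gradient sums.
    return grad_f, grad_g


def objective(
    params: CRFParams,
    config: FeatureConfig,
    instances: list[ProteinRNAInstance],
    C: float,
) -> float:
    """Penalized objective L(θ) − C(‖w_f‖₁ + ‖w_g‖₁) (maximized during fit)."""
    if C < 0:
        raise ValueError("C must be nonnegative")
    penalty = C * (np.abs(params.w_f).sum() + np.abs(params.w_g).sum())
    return pseudo_log_likelihood(params, config, instances) - penalty


def _value_and_grad(x, config, encoded):
    """(-L, -dL/dx) for a flat parameter vector x = [w_f; w_g]."""
    d_f = config.f_dim
    w_f, w_g = x[:d_f], x[d_f:]
    grad_f = np.zeros(config.f_dim)
    grad_g = np.zeros(config.g_dim)
    value = 0.0
    for enc in encoded:
        value += _accumulate_gradient(w_f, w_g, config, enc, enc.r, grad_f, grad_g)
    # grad arrays hold +dL/dw; negate both for the minimizer.
    return -value, -np.concatenate([grad_f, grad_g])


def fit(
    instances: list[ProteinRNAInstance],
    feature_config: FeatureConfig,
    training_config: TrainingConfig | None = None,
    return_info: bool = False,
):
    """Maximize the (penalized) pseudo-log-likelihood; returns CRFParams.

    With ``lasso_C > 0`` the problem is solved in split variables w = p − q,
    p, q ≥ 0 under L-BFGS-B, which yields exact zeros and satisfies the
    subgradient optimality condition at the solution.  Deterministic given
    the configuration; initialization defaults to θ = 0.
    """
    if not instances:
        raise ValueError("fit needs at least one labeled instance")
    cfg = training_config or TrainingConfig()
    encoded = [_Encoded(inst, feature_config, need_label=True) for inst in instances]
    dim = feature_config.f_dim + feature_config.g_dim
    C = cfg.lasso_C

    if cfg.initial_params is not None:
        cfg.initial_params.check(feature_config)
        w0 = np.concatenate([cfg.initial_params.w_f, cfg.initial_params.w_g])
    else:
        w0 = np.zeros(dim)

    trace: list[float] = []

    if C == 0.0:
        def fun(x):
            v, g = _value_and_grad(x, feature_config, encoded)
            if not np.isfinite(v):
                raise NumericError("pseudo-log-likelihood became non-finite")
            return v, g

        def callback(xk):
            trace.append(-fun(xk)[0]) if return_info else None

        res = minimize(
            fun, w0, jac=True, method="L-BFGS-B",
            callback=callback if return_info else None,
            options={
                "maxiter": cfg.max_iterations,
                "gtol": cfg.gradient_tolerance,
                "ftol": 1e-13,
            },
        )
        x = res.x
    else:
        def fun_split(z):
            w = z[:dim] - z[dim:]
            v, g = _value_and_grad(w, feature_config, encoded)
            if not np.isfinite(v):
                raise NumericError("penalized objective became non-finite")
            return v + C * z.sum(), np.concatenate([g + C, -g + C])

        def callback_split(zk):
            if return_info:
                trace.append(-fun_split(zk)[0])

        z0 = np.concatenate([np.maximum(w0, 0.0), np.maximum(-w0, 0.0)])
        res = minimize(
            fun_split, z0, jac=True, method="L-BFGS-B",
            bounds=[(0.0, None)] * (2 * dim),
            callback=callback_split if return_info else None,
            options={
                "maxiter": cfg.max_iterations,
                "gtol": cfg.gradient_tolerance,
                "ftol": 1e-13,
            },
        )
        x = res.x[:dim] - res.x[dim:]

    if not res.success and "ITERATIONS" in str(res.message).upper():
        warnings.warn(
            f"optimizer hit the iteration cap ({cfg.max_iterations}); "
            "returning best parameters found",
            RuntimeWarning,
            stacklevel=2,
        )
    params = CRFParams(w_f=x[: feature_config.f_dim], w_g=x[feature_config.f_dim :])
    if return_info:
        info = FitInfo(
            converged=bool(res.success),
            n_iter=int(res.nit),
            final_objective=float(-res.fun),
            message=str(res.message),
            objective_trace=trace,
        )
        return params, info
    return params
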