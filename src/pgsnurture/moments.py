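"""Equilibrium expectations and model-implied covariance matrices.

The three nested models of parental effects are:

* Model 0 — vertical transmission (VT) only, no assortative mating (AM), and
  the PGS is assumed to capture the full trait heritability.
* Model 1 — VT plus primary phenotypic AM (copath ``mu``), PGS still captures
  the full heritability.
* Model 2 — VT, AM, and a latent genetic score (LGS) carrying the
  heritability the PGS misses, orthogonal to the PGS in the base population.

Most derived quantities depend on each other recursively (nonlinear
constraints): genetic nurture ``w`` depends on ``Omega = cov(Y_*, [N]T_*)``,
which depends on ``w``; ``V_F`` depends on ``V_Y`` and vice versa; under AM
the gametic-phase-disequilibrium terms ``g``, ``h``, ``i`` feed back into
``Omega`` and ``Gamma``.  We solve the whole system by successive
substitution from null start values, which also mimics the generation-by-
generation approach of a population to equilibrium: one iteration corresponds
to one generation of AM + VT acting on the previous generation's moments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .params import ModelParams, Scaling, base_constants

MODELS = ("m0", "m1", "m2")
AM_REGIMES = ("equilibrium", "disequilibrium")

#: variable order of the implied covariance matrix
VARIABLES_5 = ("NT_p", "T_p", "NT_m", "T_m", "Y_o")
VARIABLES_7 = VARIABLES_5 + ("Y_p", "Y_m")


class DivergenceError(RuntimeError):
    """The recursion diverged (V_Y -> infinity) for the given parameters."""


@dataclass
class EquilibriumState:
    """Fixed point of the recursive expectations for one parameter set.

    ``g``, ``h``, ``i`` are reported as their *trans* (across-mate) values;
    under the equilibrium AM regime the cis (within-person) values
    ``g_cis`` etc. are identical, under the disequilibrium regime (a single
    generation of AM) they are zero.
    """

    model: str
    am_regime: str
    g: float
    h: float
    i: float
    g_cis: float
    h_cis: float
    i_cis: float
    w: float
    v: float
    Omega: float
    Gamma: float
    V_Y: float
    V_F: float
    mu: float
    r_mate: float
    k: float
    j: float
    theta_T: float
    theta_NT: float
    theta_LT: float
    theta_LNT: float
    n_iter: int
    converged: bool


@dataclass
class VarianceDecomposition:
    """Phenotypic variance components at the fixed point (Table-style)."""

    V_A: float          # full additive genetic variance
    V_A0: float         # additive genetic variance in the base population
    nurture_cov: float  # 2(av + delta w), the G-E covariance term
    V_F: float          # variance due to VT
    V_eps: float
    V_Y: float
    eta: float          # direct genetic nurture, 2 f Omega
    phi_eta: float      # AM-added apparent genetic nurture, 2 f Omega mu V_Y
    phi_delta: float    # AM-induced genetic part of theta_NT, 4 delta g


class ClosedFormModel0(NamedTuple):
    f: float
    delta: float
    w: float
    V_F: float


def _check_model(model: str, am_regime: str) -> None:
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    if am_regime not in AM_REGIMES:
        raise ValueError(f"am_regime must be one of {AM_REGIMES}, got {am_regime!r}")


def equilibrium_state(
    params: ModelParams,
    model: str = "m2",
    am_regime: str = "equilibrium",
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> EquilibriumState:
    """Iterate the recursive expectations to their fixed point.

    Successive substitution from start values ``g = h = i = w = v = 0``,
    ``V_Y = 2 delta^2 k + 2 a^2 j + V_eps``.  One iteration plays the role of
    one generation; convergence is declared when the largest absolute change
    across all tracked quantities falls below ``tol``.  Passing ``tol=0``
    runs exactly ``max_iter`` iterations (useful for approach-to-equilibrium
    trajectories) and returns ``converged=False``.

    Raises
    ------
    DivergenceError
        If V_Y grows without bound (e.g. ``2 f^2 (1 + mu V_Y) >= 1``).
    """
    _check_model(model, am_regime)
    delta, a, f, Ve = params.delta, params.a, params.f, params.V_eps
    if model in ("m0", "m1") and a != 0.0:
        raise ValueError(f"{model} requires a = 0, got a={a}")
    if model == "m0" and params.has_am():
        raise ValueError("Model 0 assumes no AM: mu/r_mate must be 0 or unset")

    fixed_mu = params.mu
    r_target = params.r_mate
    eq = am_regime == "equilibrium"

    g = h = i = w = v = 0.0
    k, j = base_constants(params.scaling, 0.0, 0.0)
    V_Y = 2 * delta * delta * k + 2 * a * a * j + Ve
    V_F = 0.0
    Omega = Gamma = 0.0
    mu = 0.0
    converged = False
    n_iter = 0

    for n_iter in range(1, max_iter + 1):
        if fixed_mu is not None:
            mu = fixed_mu
        elif r_target is not None:
            mu = r_target / V_Y
        else:
            mu = 0.0

        g_cis = g if eq else 0.0
        h_cis = h if eq else 0.0
        i_cis = i if eq else 0.0
        # k, j are constants of the *scaling convention*; conventions defined
        # in the current generation depend on the cis-inflated variances.
        k, j = base_constants(params.scaling, g_cis, h_cis)

        Omega_n = delta * k + 2 * delta * g_cis + 2 * a * i_cis + 0.5 * w
        Gamma_n = a * j + 2 * a * h_cis + 2 * delta * i_cis + 0.5 * v
        g_n = mu * Omega_n * Omega_n
        h_n = mu * Gamma_n * Gamma_n
        i_n = mu * Omega_n * Gamma_n
        infl = 1.0 + mu * V_Y
        w_n = 2 * f * Omega_n * infl
        v_n = 2 * f * Gamma_n * infl
        V_F_n = 2 * f * f * V_Y * infl
        gc = g_n if eq else 0.0
        hc = h_n if eq else 0.0
        ic = i_n if eq else 0.0
        V_A = 2 * a * a * (j + 2 * hc) + 2 * delta * delta * (k + 2 * gc) + 8 * a * ic * delta
        V_Y_n = V_A + V_F_n + 2 * (a * v_n + delta * w_n) + Ve

        change = max(
            abs(g_n - g), abs(h_n - h), abs(i_n - i), abs(w_n - w), abs(v_n - v),
            abs(V_Y_n - V_Y), abs(V_F_n - V_F), abs(Omega_n - Omega), abs(Gamma_n - Gamma),
        )
        g, h, i, w, v = g_n, h_n, i_n, w_n, v_n
        V_Y, V_F, Omega, Gamma = V_Y_n, V_F_n, Omega_n, Gamma_n

        if not math.isfinite(V_Y) or V_Y > 1e10:
            raise DivergenceError(
                f"V_Y diverged for delta={delta}, a={a}, f={f}, "
                f"mu={fixed_mu}, r_mate={r_target}, V_eps={Ve} "
                f"(likely 2 f^2 (1 + mu V_Y) >= 1)"
            )
        if tol > 0 and change < tol:
            converged = True
            break

    if converged:
        # consistency pass: re-express every derived quantity as an exact
        # function of the final V_Y (leaves V_Y itself one sub-tol increment
        # away from its own identity, i.e. exact to working precision)
        if fixed_mu is None and r_target is not None:
            mu = r_target / V_Y
        g_c = g if eq else 0.0
        h_c = h if eq else 0.0
        i_c = i if eq else 0.0
        k, j = base_constants(params.scaling, g_c, h_c)
        Omega = delta * k + 2 * delta * g_c + 2 * a * i_c + 0.5 * w
        Gamma = a * j + 2 * a * h_c + 2 * delta * i_c + 0.5 * v
        g = mu * Omega * Omega
        h = mu * Gamma * Gamma
        i = mu * Omega * Gamma
        infl = 1.0 + mu * V_Y
        w = 2 * f * Omega * infl
        v = 2 * f * Gamma * infl
        V_F = 2 * f * f * V_Y * infl

    g_cis = g if eq else 0.0
    h_cis = h if eq else 0.0
    i_cis = i if eq else 0.0
    infl = 1.0 + mu * V_Y
    theta_NT = 2 * f * Omega * infl + 2 * delta * (g_cis + g) + 2 * a * (i_cis + i)
    theta_T = theta_NT + 2 * delta * k
    theta_LNT = 2 * f * Gamma * infl + 2 * a * (h_cis + h) + 2 * delta * (i_cis + i)
    theta_LT = theta_LNT + 2 * a * j

    return EquilibriumState(
        model=model, am_regime=am_regime,
        g=g, h=h, i=i, g_cis=g_cis, h_cis=h_cis, i_cis=i_cis,
        w=w, v=v, Omega=Omega, Gamma=Gamma,
        V_Y=V_Y, V_F=V_F, mu=mu, r_mate=mu * V_Y, k=k, j=j,
        theta_T=theta_T, theta_NT=theta_NT,
        theta_LT=theta_LT, theta_LNT=theta_LNT,
        n_iter=n_iter, converged=converged,
    )


@dataclass
class ImpliedMoments:
    """Model-implied covariance matrix of the observed family variables."""

    variables: tuple[str, ...]
    cov: np.ndarray
    means: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.means is None:
            self.means = np.zeros(len(self.variables))

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(self.cov, index=list(self.variables), columns=list(self.variables))


def implied_covariance(
    state: EquilibriumState,
    params: ModelParams,
    model: str | None = None,
    with_parents: bool = False,
) -> ImpliedMoments:
    """Expected covariance matrix of (NT_p, T_p, NT_m, T_m, Y_o[, Y_p, Y_m]).

    All means are fixed at zero (observed data must be centred).  Every
    entry follows from path tracing at the fixed point:

    * ``var([N]T_*) = k + g_cis``; cis ``cov(T_*, NT_*) = g_cis``; the four
      across-mate score covariances equal the trans ``g``.
    * ``cov(Y_o, [N]T_*) = theta_[N]T / 2``; ``var(Y) = V_Y``.
    * ``cov(Y_*, [N]T_*) = Omega`` and, across mates, ``Omega mu V_Y``.
    * ``cov(Y_p, Y_m) = mu V_Y^2``.
    * ``cov(Y_o, Y_*)`` sums four chain families — transmitted-PGS
      (``delta Omega``), transmitted-LGS (``a Gamma``), VT (``f V_Y``), and
      each of those again routed through the mate via the copath (factor
      ``mu V_Y``) — giving ``(1 + mu V_Y)(delta Omega + a Gamma + f V_Y)``.
    """
    model = model or state.model
    if not state.converged:
        raise ValueError("equilibrium state did not converge; refusing to build implied moments")
    variables = VARIABLES_7 if with_parents else VARIABLES_5
    n = len(variables)
    S = np.zeros((n, n))

    k = state.k
    g_cis, g_tr = state.g_cis, state.g
    V_Y, mu, Om, Ga = state.V_Y, state.mu, state.Omega, state.Gamma
    delta, a, f = params.delta, params.a, params.f

    # score block: order NT_p, T_p, NT_m, T_m
    paternal = {0, 1}
    for x in range(4):
        S[x, x] = k + g_cis
        for y in range(x + 1, 4):
            same_parent = (x in paternal) == (y in paternal)
            S[x, y] = S[y, x] = g_cis if same_parent else g_tr

    iYo = 4
    half = {0: state.theta_NT / 2, 1: state.theta_T / 2, 2: state.theta_NT / 2, 3: state.theta_T / 2}
    for x in range(4):
        S[iYo, x] = S[x, iYo] = half[x]
    S[iYo, iYo] = V_Y

    if with_parents:
        iYp, iYm = 5, 6
        S[iYp, iYp] = S[iYm, iYm] = V_Y
        S[iYp, iYm] = S[iYm, iYp] = mu * V_Y * V_Y
        cross = Om * mu * V_Y
        for x in range(4):
            own_p = x in paternal
            S[iYp, x] = S[x, iYp] = Om if own_p else cross
            S[iYm, x] = S[x, iYm] = cross if own_p else Om
        po = (1.0 + mu * V_Y) * (delta * Om + a * Ga + f * V_Y)
        S[iYo, iYp] = S[iYp, iYo] = po
        S[iYo, iYm] = S[iYm, iYo] = po

    eig = np.linalg.eigvalsh(S)
    if eig[0] < -1e-8 * max(1.0, eig[-1]):
        raise ValueError(f"implied covariance matrix is not positive semi-definite (min eig {eig[0]:.3g})")
    return ImpliedMoments(variables=variables, cov=S)


def decompose_variance(state: EquilibriumState, params: ModelParams) -> VarianceDecomposition:
    """Variance components of V_Y at the fixed point.

    Satisfies ``V_Y = V_A + V_F + 2(av + delta w) + V_eps`` exactly, along
    and the genetic-nurture split into its direct and AM-induced parts,
    ``eta + phi_eta = w``.
    """
    if not state.converged:
        raise ValueError("equilibrium state did not converge")
    delta, a = params.delta, params.a
    V_A = (
        2 * a * a * (state.j + 2 * state.h_cis)
        + 2 * delta * delta * (state.k + 2 * state.g_cis)
        + 8 * a * state.i_cis * delta
    )
    V_A0 = 2 * a * a * state.j + 2 * delta * delta * state.k
    nurture = 2 * (a * state.v + delta * state.w)
    eta = 2 * params.f * state.Omega
    return VarianceDecomposition(
        V_A=V_A,
        V_A0=V_A0,
        nurture_cov=nurture,
        V_F=state.V_F,
        V_eps=params.V_eps,
        V_Y=state.V_Y,
        eta=eta,
        phi_eta=eta * state.mu * state.V_Y,
        phi_delta=4 * delta * state.g,
    )


def closed_form_model0(theta_NT: float, theta_T: float, V_Y: float) -> ClosedFormModel0:
    """Closed-form Model 0 solution from three observed statistics.

    Under no AM, ``f = theta_NT / theta_T`` (the PGS effect delta cancels
    out), ``delta = theta_T - theta_NT``, ``w = theta_NT`` and
    ``V_F = 2 f^2 V_Y``.  Valid only when the no-AM assumption holds.
    """
    if theta_T == 0:
        raise ValueError("theta_T must be nonzero")
    f = theta_NT / theta_T
    if abs(f) >= 1:
        raise ValueError(
            f"theta_NT/theta_T = {f:.4g} implies |f| >= 1, inconsistent with the model"
        )
    delta = theta_T - theta_NT
    w = theta_NT
    V_F = 2 * f * f * V_Y
    return ClosedFormModel0(f=f, delta=delta, w=w, V_F=V_F)
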