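"""Full-information maximum likelihood fitting of Models 0, 1 and 2.

The models are covariance-structure models with nonlinear equilibrium
constraints.  Rather than handing the constraints to a constrained SEM
optimizer, estimation is architected as a nested procedure: the outer
optimizer moves the free structural parameters (Model 0: delta, f, V_eps;
Model 1 adds the spousal correlation; Model 2 adds the latent path a) and,
inside every likelihood evaluation, the equilibrium fixed point is solved
exactly for all derived quantities (g, h, i, w, v, V_F, V_Y, ...), which
enforces the constraints by construction.

Each family contributes the zero-mean multivariate-normal log-density of
whichever variables it has observed (FIML), so estimates are unbiased under
data missing (completely) at random.  Families are grouped by missingness
pattern and each pattern is reduced to its scatter matrix, making the
likelihood cost independent of sample size.

Usage follows the Model/Results convention::

    model = GeneticNurtureModel(table, model="m2", scaling="base")
    res = model.fit()
    print(res.summary())
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .moments import (
    DivergenceError,
    EquilibriumState,
    VARIABLES_5,
    VARIABLES_7,
    VarianceDecomposition,
    decompose_variance,
    equilibrium_state,
    implied_covariance,
)
from .params import ModelParams, as_scaling

_LOG2PI = math.log(2.0 * math.pi)
_BAD = 1e12  # penalized objective for invalid parameter regions

F_BOUND = 0.95
R_BOUND = 0.95
VEPS_FLOOR = 1e-6

DERIVED_NAMES = (
    "V_F", "w", "v", "V_A", "V_A0", "V_Y", "mu", "r_mate",
    "eta", "phi_eta", "phi_delta", "nurture_cov",
)


@dataclass
class FitSpec:
    """Estimation settings (model choice, SEs, optimizer controls)."""

    model: str = "m1"
    am_regime: str = "equilibrium"
    scaling: str = "base_standardized"
    use_parental_phenotypes: bool | None = None
    assumed_base_h2: float | None = None
    se_method: str = "hessian"      # hessian | bootstrap | none
    n_boot: int = 200
    n_starts: int = 5
    maxfev: int = 6000
    xtol: float = 1e-7
    ftol: float = 1e-10
    fp_tol: float = 1e-12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("m0", "m1", "m2"):
            raise ValueError(f"model must be m0/m1/m2, got {self.model!r}")
        if self.model == "m2" and self.use_parental_phenotypes is False and self.assumed_base_h2 is None:
            raise ValueError("Model 2 without parental phenotypes requires assumed_base_h2")
        if self.assumed_base_h2 is not None and not 0 < self.assumed_base_h2 < 1:
            raise ValueError("assumed_base_h2 must lie in (0, 1) on the standardized-trait scale")


class FitError(RuntimeError):
    pass


def _patterns_from_frame(data: pd.DataFrame, variables: tuple[str, ...]):
    """Group centred records by missingness pattern; keep scatter matrices."""
    X = data[list(variables)].to_numpy(float)
    obs = ~np.isnan(X)
    keep = obs.any(axis=1)
    X, obs = X[keep], obs[keep]
    if len(X) == 0:
        raise ValueError("no families with any observed variable")
    # centre per variable over its observed entries
    for jcol in range(X.shape[1]):
        col = X[:, jcol]
        m = obs[:, jcol]
        if m.sum() >= 2 and np.nanvar(col[m]) == 0.0:
            raise ValueError(f"variable {variables[jcol]!r} has zero variance")
        if m.any():
            col[m] = col[m] - col[m].mean()
    patterns = []
    codes = (obs * (2 ** np.arange(obs.shape[1]))).sum(axis=1)
    for code in np.unique(codes):
        rows = codes == code
        idx = np.flatnonzero(obs[rows][0])
        Xk = X[rows][:, idx]
        patterns.append((tuple(idx), int(rows.sum()), Xk.T @ Xk))
    return patterns, int(len(X))


class GeneticNurtureModel:
    """VT / genetic-nurture model for transmitted and nontransmitted PGSs.

    Parameters
    ----------
    data : DataFrame
        Family table with columns T_p, NT_p, T_m, NT_m, Y_o and, for Model 2
        with parental phenotypes, Y_p and Y_m.  Missing values (NaN) are
        handled by FIML.  Data are centred internally.
    model : {"m0", "m1", "m2"}
    am_regime : {"equilibrium", "disequilibrium"}
    scaling : PGS scaling convention (fixes the constant k inside the fit).
    use_parental_phenotypes : bool, optional
        Default: True for Model 2 when no assumed heritability is given.
    assumed_base_h2 : float, optional
        Base-population heritability of the standardized trait; enables the
        Model 2 assumed-a mode (a^2 = h2 - delta^2) without parental
        phenotypes.
    """

    def __init__(self, data: pd.DataFrame | None, spec: FitSpec | None = None, **kwargs):
        if spec is None:
            spec = FitSpec(**kwargs)
        elif kwargs:
            spec = replace(spec, **kwargs)
        self.spec = spec
        self.data = data
        scaling = as_scaling(spec.scaling)
        self.scaling = scaling

        with_parents = spec.use_parental_phenotypes
        if with_parents is None:
            with_parents = spec.model == "m2" and spec.assumed_base_h2 is None
        if with_parents and spec.model != "m2":
            raise ValueError("parental phenotypes are only part of Model 2")
        self.with_parents = bool(with_parents)
        self.variables = VARIABLES_7 if self.with_parents else VARIABLES_5

        if data is not None:
            missing_cols = [c for c in self.variables if c not in data.columns]
            if missing_cols:
                raise ValueError(f"data lacks columns {missing_cols}")
            self.patterns, self.nobs = _patterns_from_frame(data, self.variables)
        else:
            self.patterns, self.nobs = None, 0

    # -- alternative constructors ------------------------------------------

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "GeneticNurtureModel":
        return cls(data, **kwargs)

    @classmethod
    def from_covariance(cls, cov, nobs: int, **kwargs) -> "GeneticNurtureModel":
        """Build from a sample covariance matrix (complete-data workflows).

        ``cov`` must be the maximum-likelihood (divide-by-n) covariance of
        the centred variables in the model's variable order; the Wishart
        -2lnL then coincides with the record-level FIML value.
        """
        self = cls(None, **kwargs)
        cov = np.asarray(cov, float)
        d = len(self.variables)
        if cov.shape != (d, d):
            raise ValueError(f"covariance must be {d}x{d} for variables {self.variables}")
        self.patterns = [(tuple(range(d)), int(nobs), nobs * cov)]
        self.nobs = int(nobs)
        return self

    # -- parameter transforms ----------------------------------------------

    def _free_names(self) -> list[str]:
        spec = self.spec
        names = ["delta", "f"]
        if spec.model in ("m1", "m2"):
            names.append("r_mate")
        if spec.model == "m2" and spec.assumed_base_h2 is None:
            names.append("a")
        names.append("V_eps")
        return names

    def _to_natural(self, x: np.ndarray) -> dict[str, float]:
        spec = self.spec
        names = self._free_names()
        vals = {}
        for name, xi in zip(names, x):
            if name == "delta" and spec.assumed_base_h2 is not None:
                vals["delta"] = math.sqrt(spec.assumed_base_h2) * math.tanh(xi)
            elif name == "delta":
                vals["delta"] = xi
            elif name == "f":
                vals["f"] = F_BOUND * math.tanh(xi)
            elif name == "r_mate":
                vals["r_mate"] = R_BOUND * math.tanh(xi)
            elif name == "a":
                vals["a"] = xi
            elif name == "V_eps":
                vals["V_eps"] = VEPS_FLOOR + math.exp(xi)
        if spec.assumed_base_h2 is not None and spec.model == "m2":
            vals["a"] = math.sqrt(max(spec.assumed_base_h2 - vals["delta"] ** 2, 0.0))
        return vals

    def _to_working(self, vals: dict[str, float]) -> np.ndarray:
        spec = self.spec
        x = []
        for name in self._free_names():
            val = vals[name]
            if name == "delta" and spec.assumed_base_h2 is not None:
                ratio = np.clip(val / math.sqrt(spec.assumed_base_h2), -0.999, 0.999)
                x.append(math.atanh(ratio))
            elif name == "delta" or name == "a":
                x.append(val)
            elif name == "f":
                x.append(math.atanh(np.clip(val / F_BOUND, -0.999, 0.999)))
            elif name == "r_mate":
                x.append(math.atanh(np.clip(val / R_BOUND, -0.999, 0.999)))
            elif name == "V_eps":
                x.append(math.log(max(val - VEPS_FLOOR, 1e-12)))
        return np.array(x)

    def _make_params(self, vals: dict[str, float]) -> ModelParams:
        return ModelParams(
            delta=vals["delta"], f=vals["f"], a=vals.get("a", 0.0),
            r_mate=vals.get("r_mate") or None, V_eps=vals["V_eps"],
            scaling=self.scaling,
        )

    # -- likelihood ---------------------------------------------------------

    def implied(self, params: ModelParams) -> np.ndarray:
        state = equilibrium_state(
            params, model=self.spec.model, am_regime=self.spec.am_regime,
            tol=self.spec.fp_tol,
        )
        mom = implied_covariance(state, params, model=self.spec.model,
                                 with_parents=self.with_parents)
        return mom.cov

    def loglik(self, params: ModelParams) -> float:
        """FIML log-likelihood of the (centred) data at ``params``.

        Returns ``-inf`` for parameter values whose implied covariance is
        not positive definite or whose recursion diverges, so the optimizer
        retreats.
        """
        try:
            S = self.implied(params)
        except (DivergenceError, ValueError):
            return -np.inf
        ll = 0.0
        for idx, n_k, A_k in self.patterns:
            Sk = S[np.ix_(idx, idx)]
            try:
                c, low = linalg.cho_factor(Sk, lower=True)
            except linalg.LinAlgError:
                return -np.inf
            logdet = 2.0 * np.sum(np.log(np.diag(c)))
            trace = np.trace(linalg.cho_solve((c, low), A_k))
            ll += -0.5 * (n_k * (len(idx) * _LOG2PI + logdet) + trace)
        return float(ll)

    def _objective(self, x: np.ndarray) -> float:
        vals = self._to_natural(x)
        try:
            params = self._make_params(vals)
        except ValueError:
            return _BAD
        ll = self.loglik(params)
        if not np.isfinite(ll):
            return _BAD
        return -ll

    # -- starting values ----------------------------------------------------

    def _sample_cov(self) -> np.ndarray:
        d = len(self.variables)
        S = np.full((d, d), np.nan)
        counts = np.zeros((d, d))
        for idx, n_k, A_k in self.patterns:
            for ii, gi in enumerate(idx):
                for jj, gj in enumerate(idx):
                    if np.isnan(S[gi, gj]):
                        S[gi, gj] = 0.0
                    S[gi, gj] += A_k[ii, jj]
                    counts[gi, gj] += n_k
        with np.errstate(invalid="ignore"):
            return S / np.where(counts > 0, counts, np.nan)

    def _moment_start(self) -> dict[str, float]:
        S = self._sample_cov()
        v = {name: i for i, name in enumerate(self.variables)}
        def sc(a, b):
            val = S[v[a], v[b]]
            return 0.0 if np.isnan(val) else val
        theta_nt = sc("Y_o", "NT_p") + sc("Y_o", "NT_m")
        theta_t = sc("Y_o", "T_p") + sc("Y_o", "T_m")
        V_Y = sc("Y_o", "Y_o") or 1.0
        f0 = float(np.clip(theta_nt / theta_t, -0.6, 0.6)) if theta_t else 0.1
        delta0 = theta_t - theta_nt or 0.2
        vals = {"delta": delta0, "f": f0, "V_eps": 0.5 * V_Y}
        if self.spec.model in ("m1", "m2"):
            if self.with_parents and not np.isnan(S[v["Y_p"], v["Y_m"]]):
                r0 = sc("Y_p", "Y_m") / V_Y
            else:
                g0 = np.mean([sc("T_p", "T_m"), sc("T_p", "NT_m"), sc("NT_p", "T_m"), sc("NT_p", "NT_m")])
                omega0 = theta_t / 2 or 0.3
                r0 = g0 * V_Y / omega0**2
            vals["r_mate"] = float(np.clip(r0, 0.0, 0.8))
        if self.spec.model == "m2" and self.spec.assumed_base_h2 is None:
            vals["a"] = 0.5 * math.sqrt(V_Y)
        if self.spec.assumed_base_h2 is not None:
            h2 = self.spec.assumed_base_h2
            vals["delta"] = float(np.clip(vals["delta"], -0.95 * math.sqrt(h2), 0.95 * math.sqrt(h2)))
        return vals

    # -- fitting -------------------------------------------------------------

    def fit(self, start: dict[str, float] | None = None) -> "GeneticNurtureResults":
        """Maximize the FIML likelihood over the free structural parameters.

        Runs ``n_starts`` Nelder-Mead searches (one moment-based start plus
        jittered copies) on transformed, unbounded scales and keeps the best
        optimum; ties are broken by the smaller parameter-vector norm.
        """
        spec = self.spec
        rng = np.random.default_rng(spec.seed)
        start_vals = start or self._moment_start()
        x0 = self._to_working(start_vals)
        starts = [x0]
        for _ in range(max(spec.n_starts - 1, 0)):
            starts.append(x0 + rng.normal(0.0, 0.3, size=len(x0)))

        log, results = [], []
        for xs in starts:
            res = optimize.minimize(
                self._objective, xs, method="Nelder-Mead",
                options={"maxfev": spec.maxfev, "xatol": spec.xtol,
                         "fatol": spec.ftol, "adaptive": True},
            )
            log.append({"x0": xs.tolist(), "fun": float(res.fun),
                        "nfev": int(res.nfev), "success": bool(res.success)})
            results.append(res)

        finite = [r for r in results if r.fun < _BAD / 2]
        if not finite:
            raise FitError("all optimizer starts ended in invalid parameter regions")
        best_fun = min(r.fun for r in finite)
        candidates = [r for r in finite if r.fun <= best_fun + 1e-8]
        best = min(candidates, key=lambda r: np.linalg.norm(r.x))

        vals = self._to_natural(best.x)
        params = self._make_params(vals)
        state = equilibrium_state(params, model=spec.model, am_regime=spec.am_regime,
                                  tol=spec.fp_tol)
        decomp = decompose_variance(state, params)
        llf = -best.fun

        flags = []
        if abs(vals["f"]) > 0.9 * F_BOUND:
            flags.append("f near bound")
        if "r_mate" in vals and abs(vals["r_mate"]) > 0.9 * R_BOUND:
            flags.append("spousal correlation near bound")
        if vals["V_eps"] < 1e-4:
            flags.append("V_eps near zero")
        if not any(r.success for r in candidates):
            flags.append("optimizer reported non-convergence")

        free = self._free_names()
        if spec.model == "m2" and spec.assumed_base_h2 is not None:
            report = free + ["a"]
        else:
            report = free
        if "a" in vals:
            vals["a"] = abs(vals["a"])  # likelihood is even in a; report magnitude
        estimates = pd.Series({name: vals[name] for name in report})

        result = GeneticNurtureResults(
            model=self, spec=spec, params=estimates, llf=llf,
            state=state, decomposition=decomp, structural=params,
            converged="optimizer reported non-convergence" not in flags,
            boundary_flags=flags, start_log=log, nobs=self.nobs,
        )
        if spec.se_method != "none":
            try:
                result._compute_se(spec.se_method)
            except FitError:
                if spec.se_method == "hessian" and self.data is not None:
                    warnings.warn("singular observed information; falling back to bootstrap SEs",
                                  RuntimeWarning)
                    result._compute_se("bootstrap")
                else:
                    raise
        return result

    # helpers used by SE machinery -----------------------------------------

    def _loglik_natural(self, vec: np.ndarray, names: list[str]) -> float:
        vals = dict(zip(names, vec))
        if self.spec.model == "m2" and self.spec.assumed_base_h2 is not None:
            a2 = self.spec.assumed_base_h2 - vals["delta"] ** 2
            if a2 < 0:
                return -np.inf
            vals["a"] = math.sqrt(a2)
        try:
            return self.loglik(self._make_params(vals))
        except ValueError:
            return -np.inf

    def _derived_natural(self, vec: np.ndarray, names: list[str]) -> np.ndarray:
        vals = dict(zip(names, vec))
        if self.spec.model == "m2" and self.spec.assumed_base_h2 is not None:
            vals["a"] = math.sqrt(max(self.spec.assumed_base_h2 - vals["delta"] ** 2, 0.0))
        params = self._make_params(vals)
        state = equilibrium_state(params, model=self.spec.model,
                                 am_regime=self.spec.am_regime, tol=self.spec.fp_tol)
        dec = decompose_variance(state, params)
        return np.array([
            state.V_F, state.w, state.v, dec.V_A, dec.V_A0, state.V_Y,
            state.mu, state.r_mate, dec.eta, dec.phi_eta, dec.phi_delta,
            dec.nurture_cov,
        ])


@dataclass
class GeneticNurtureResults:
    """Estimates, uncertainties and diagnostics from a fitted model."""

    model: GeneticNurtureModel
    spec: FitSpec
    params: pd.Series
    llf: float
    state: EquilibriumState
    decomposition: VarianceDecomposition
    structural: ModelParams
    converged: bool
    boundary_flags: list[str]
    start_log: list[dict]
    nobs: int
    bse: pd.Series | None = None
    derived: pd.Series = field(default=None)  # type: ignore[assignment]
    derived_bse: pd.Series | None = None
    se_method_used: str | None = None

    def __post_init__(self) -> None:
        if self.derived is None:
            names = self.model._free_names()
            vec = np.array([self.params[n] for n in names])
            self.derived = pd.Series(
                self.model._derived_natural(vec, names), index=list(DERIVED_NAMES)
            )

    @property
    def minus2llf(self) -> float:
        return -2.0 * self.llf

    # -- standard errors ----------------------------------------------------

    def _compute_se(self, method: str) -> None:
        if method == "hessian":
            self._se_hessian()
        elif method == "bootstrap":
            self._se_bootstrap()
        else:
            raise ValueError(f"unknown se_method {method!r}")

    def _se_hessian(self) -> None:
        names = self.model._free_names()
        p = np.array([self.params[n] for n in names])
        steps = 1e-4 * np.maximum(np.abs(p), 0.05)
        npar = len(p)
        H = np.empty((npar, npar))
        f0 = self.model._loglik_natural(p, names)

        def ll(vec):
            out = self.model._loglik_natural(vec, names)
            return out if np.isfinite(out) else f0 - 1e6

        for i in range(npar):
            ei = np.zeros(npar); ei[i] = steps[i]
            H[i, i] = (ll(p + ei) - 2 * f0 + ll(p - ei)) / steps[i] ** 2
            for j in range(i + 1, npar):
                ej = np.zeros(npar); ej[j] = steps[j]
                H[i, j] = H[j, i] = (
                    ll(p + ei + ej) - ll(p + ei - ej) - ll(p - ei + ej) + ll(p - ei - ej)
                ) / (4 * steps[i] * steps[j])
        info = -H
        try:
            cov = linalg.inv(info)
            if not np.all(np.diag(cov) > 0):
                raise linalg.LinAlgError("non-PD information")
        except linalg.LinAlgError as exc:
            raise FitError(f"observed information is singular: {exc}") from exc

        self.bse = pd.Series(np.sqrt(np.diag(cov)), index=names)
        # delta method for derived quantities
        J = np.empty((len(DERIVED_NAMES), npar))
        for i in range(npar):
            ei = np.zeros(npar); ei[i] = steps[i]
            J[:, i] = (
                self.model._derived_natural(p + ei, names)
                - self.model._derived_natural(p - ei, names)
            ) / (2 * steps[i])
        dvar = np.einsum("ki,ij,kj->k", J, cov, J)
        self.derived_bse = pd.Series(np.sqrt(np.maximum(dvar, 0.0)), index=list(DERIVED_NAMES))
        if self.spec.model == "m2" and self.spec.assumed_base_h2 is not None:
            # a is derived from delta: |da/ddelta| = delta / a
            a = self.params["a"]
            self.bse["a"] = (abs(self.params["delta"]) / a * self.bse["delta"]) if a > 0 else np.nan
        self.se_method_used = "hessian"

    def _se_bootstrap(self) -> None:
        if self.model.data is None:
            raise FitError("bootstrap SEs require record-level data")
        spec = self.spec
        rng = np.random.default_rng(spec.seed + 1)
        data = self.model.data.reset_index(drop=True)
        n = len(data)
        names = list(self.params.index)
        draws = np.empty((spec.n_boot, len(names)))
        dnames = list(DERIVED_NAMES)
        ddraws = np.empty((spec.n_boot, len(dnames)))
        start = {k: self.params[k] for k in self.model._free_names()}
        boot_spec = replace(spec, se_method="none", n_starts=1, maxfev=2000)
        for b in range(spec.n_boot):
            sample = data.iloc[rng.integers(0, n, size=n)]
            try:
                sub = GeneticNurtureModel(sample, spec=boot_spec)
                res = sub.fit(start=start)
                draws[b] = [res.params[k] for k in names]
                ddraws[b] = [res.derived[k] for k in dnames]
            except (FitError, ValueError):
                draws[b] = np.nan
                ddraws[b] = np.nan
        self.bse = pd.Series(np.nanstd(draws, axis=0, ddof=1), index=names)
        self.derived_bse = pd.Series(np.nanstd(ddraws, axis=0, ddof=1), index=dnames)
        self.se_method_used = "bootstrap"

    # -- presentation --------------------------------------------------------

    def summary(self) -> str:
        spec = self.spec
        lines = [
            "Genetic nurture / vertical transmission model".center(64),
            "=" * 64,
            f"Model: {spec.model}   AM regime: {spec.am_regime}   scaling: {as_scaling(spec.scaling).value}",
            f"Families: {self.nobs}   -2lnL: {self.minus2llf:.3f}   converged: {self.converged}",
        ]
        if self.boundary_flags:
            lines.append("Flags: " + "; ".join(self.boundary_flags))
        lines.append("-" * 64)
        lines.append(f"{'parameter':<14}{'estimate':>12}{'std err':>12}")
        for name, val in self.params.items():
            se = self.bse.get(name, np.nan) if self.bse is not None else np.nan
            lines.append(f"{name:<14}{val:>12.4f}{se:>12.4f}")
        lines.append("-" * 64)
        lines.append("derived quantities (equilibrium constraints enforced):")
        for name, val in self.derived.items():
            se = self.derived_bse.get(name, np.nan) if self.derived_bse is not None else np.nan
            lines.append(f"{name:<14}{val:>12.4f}{se:>12.4f}")
        lines.append("=" * 64)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "model": self.spec.model,
            "am_regime": self.spec.am_regime,
            "scaling": as_scaling(self.spec.scaling).value,
            "n_families": self.nobs,
            "estimates": self.params.to_dict(),
            "standard_errors": None if self.bse is None else self.bse.to_dict(),
            "derived": self.derived.to_dict(),
            "derived_standard_errors": None if self.derived_bse is None else self.derived_bse.to_dict(),
            "minus2_loglik": self.minus2llf,
            "converged": self.converged,
            "boundary_flags": self.boundary_flags,
            "se_method": self.se_method_used,
        }

    def plot_variance_decomposition(self, ax=None):
        """Stacked bar of V_Y into V_A, V_F, G-E covariance and residual."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(3.2, 4))
        dec = self.decomposition
        parts = {"V_A": dec.V_A, "V_F": dec.V_F, "2(av+δw)": dec.nurture_cov, "V_eps": dec.V_eps}
        bottom = 0.0
        for lab, val in parts.items():
            ax.bar(["V_Y"], [val], bottom=bottom, label=lab)
            bottom += val
        ax.legend()
        ax.set_ylabel("phenotypic variance")
        return ax

    def simulate(self, n_families: int, n_generations: int = 15, seed: int = 0, **kwargs):
        """Forward-simulate a population at the fitted parameter values."""
        from .simulate import SimConfig, simulate_population

        cfg = SimConfig(
            n_families=n_families,
            delta=float(self.params["delta"]),
            a=float(self.params.get("a", 0.0)),
            f=float(self.params["f"]),
            r_mate=float(self.params.get("r_mate", 0.0)),
            V_eps=float(self.params["V_eps"]),
            n_generations=n_generations,
            seed=seed,
            **kwargs,
        )
        return simulate_population(cfg)


# -- functional wrappers ------------------------------------------------------


def loglik(params: ModelParams, data: pd.DataFrame, spec: FitSpec) -> float:
    """FIML log-likelihood of a family table at fixed structural parameters."""
    return GeneticNurtureModel(data, spec=spec).loglik(params)


def loglik_from_cov(params: ModelParams, cov, nobs: int, spec: FitSpec) -> float:
    """Wishart-based log-likelihood from a sample covariance matrix."""
    return GeneticNurtureModel.from_covariance(cov, nobs, spec=spec).loglik(params)


def fit(data: pd.DataFrame, spec: FitSpec | None = None, **kwargs) -> GeneticNurtureResults:
    return GeneticNurtureModel(data, spec=spec, **kwargs).fit()


def fit_assumed_a(data: pd.DataFrame, base_h2: float, spec: FitSpec | None = None,
                  **kwargs) -> GeneticNurtureResults:
    """Model 2 without parental phenotypes, assuming the base heritability.

    ``a`` is tied to delta by ``a^2 = base_h2 - delta^2`` during the fit.
    If the assumed heritability is set too high, w and V_F are biased
    downward (and vice versa).
    """
    if spec is None:
        spec = FitSpec(model="m2", **kwargs)
    spec = replace(spec, model="m2", assumed_base_h2=base_h2,
                   use_parental_phenotypes=False)
    res = GeneticNurtureModel(data, spec=spec).fit()
    # delta is constrained to |delta| < sqrt(h2); an optimum pinned at that
    # bound means the data demand delta^2 >= h2, i.e. no admissible a
    if res.params["delta"] ** 2 >= 0.98 * base_h2:
        raise FitError(
            f"assumed base heritability {base_h2} is at or below the fitted delta^2 "
            f"({res.params['delta'] ** 2:.4f}); no admissible a exists"
        )
    return res


def standard_errors(result: GeneticNurtureResults, method: str = "hessian") -> pd.DataFrame:
    """(Re)compute SEs for a fitted model by the requested method.

    Returns a table of free-parameter and derived-quantity standard errors;
    derived quantities are flagged as such (their SEs come from the delta
    method or from the bootstrap distribution of the constrained solution).
    """
    result._compute_se(method)
    rows = [(k, v, False) for k, v in result.bse.items()] + [
        (k, v, True) for k, v in result.derived_bse.items()
    ]
    return pd.DataFrame(rows, columns=["quantity", "se", "derived"]).set_index("quantity")
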