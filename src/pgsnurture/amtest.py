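"""Moment-based tests of assortative-mating mechanisms.

The four haplotypic PGS variances and six covariances jointly provide ten
estimates of the AM-induced (co)variance ``g``: four variance-based
(``var([N]T_*) - k``), two within-person cis covariances
(``cov(T_*, NT_*)``) and four across-mate trans covariances.  At
equilibrium all ten estimate the same quantity; a single recent generation
of AM produces trans covariance without cis covariance.  Wald chi-square(1)
tests on precision-weighted means of the ten therefore probe (a) whether AM
has produced genetic covariance at all and (b) whether it has reached
equilibrium.  Comparing the spousal phenotypic covariance implied by ``g``
with the observed one diagnoses social- versus genetic-homogamy-like
departures from primary phenotypic assortment.

Sampling covariance of the ten estimates is obtained by a family-level
nonparametric bootstrap (the ten moments share families and are strongly
dependent), implemented with multinomial resampling weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .params import Scaling, as_scaling

SCORE_COLS = ["T_p", "NT_p", "T_m", "NT_m"]

G_LABELS = (
    "var_T_p", "var_NT_p", "var_T_m", "var_NT_m",
    "cis_T_p_NT_p", "cis_T_m_NT_m",
    "trans_T_p_T_m", "trans_T_p_NT_m", "trans_NT_p_T_m", "trans_NT_p_NT_m",
)
CIS_LABELS = G_LABELS[:6]
TRANS_LABELS = G_LABELS[6:]

# (x, y) column pairs behind each of the ten moments
_PAIRS = (
    ("T_p", "T_p"), ("NT_p", "NT_p"), ("T_m", "T_m"), ("NT_m", "NT_m"),
    ("T_p", "NT_p"), ("T_m", "NT_m"),
    ("T_p", "T_m"), ("T_p", "NT_m"), ("NT_p", "T_m"), ("NT_p", "NT_m"),
)


def raw_score_moments(df: pd.DataFrame) -> np.ndarray:
    """The ten raw score moments (4 variances, 2 cis, 4 trans covariances)."""
    X = df[SCORE_COLS].to_numpy(float)
    X = X - X.mean(axis=0)
    n = len(X)
    col = {c: idx for idx, c in enumerate(SCORE_COLS)}
    return np.array([(X[:, col[x]] * X[:, col[y]]).sum() / (n - 1) for x, y in _PAIRS])


def solve_gk(moments: np.ndarray, scaling, base_hap_variance: float | None = 0.5) -> tuple[float, float]:
    """Jointly consistent (g, k) for a scaling convention.

    For conventions defined in the current generation the base constant
    depends on ``g`` (``k = 1/2 - 2g`` or ``1/2 - g``) while the
    variance-based estimates of ``g`` depend on ``k`` — a circularity the
    one-dimensional consistency equation (mean of the six cis estimates
    equals ``g``) resolves in closed form.  For base-population scaling
    ``k`` is simply the known base haplotypic variance.
    """
    s = as_scaling(scaling)
    sum_v = moments[:4].sum()
    c1, c2 = moments[4], moments[5]
    if s is Scaling.base_standardized:
        if base_hap_variance is None:
            raise ValueError(
                "base_standardized scaling requires the base-generation haplotypic "
                "variance; pass base_hap_variance (0.5 for a PGS standardized in the base population)"
            )
        k = base_hap_variance
        g = (sum_v - 4 * k + c1 + c2) / 6.0
    elif s is Scaling.full_pgs_standardized_now:
        g = (2.0 - sum_v - c1 - c2) / 2.0
        k = 0.5 - 2.0 * g
    else:
        g = (sum_v - 2.0 + c1 + c2) / 2.0
        k = 0.5 - g
    return g, k


def _ten_estimates(moments: np.ndarray, k: float) -> np.ndarray:
    out = moments.copy()
    out[:4] -= k
    return out


def _bootstrap_weights(n: int, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    return rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot).astype(float)


def _weighted_cov(X: np.ndarray, W: np.ndarray, pairs: list[tuple[int, int]]) -> np.ndarray:
    """cov(x_i, x_j) per bootstrap replicate from multinomial weights W (B, n)."""
    n = X.shape[0]
    m1 = W @ X / n                                     # (B, d)
    P = np.stack([X[:, i] * X[:, j] for i, j in pairs], axis=1)
    m2 = W @ P / n                                     # (B, npairs)
    out = np.empty_like(m2)
    for idx, (i, j) in enumerate(pairs):
        out[:, idx] = (m2[:, idx] - m1[:, i] * m1[:, j]) * n / (n - 1)
    return out


@dataclass
class GEstimates:
    """Ten moment-based estimates of g with their sampling covariance."""

    values: pd.Series            # indexed by G_LABELS (subset if excluded)
    cov: pd.DataFrame
    k: float
    g_consistent: float
    n_families: int
    n_boot: int
    scaling: str

    @property
    def cis_labels(self) -> list[str]:
        return [l for l in self.values.index if l in CIS_LABELS]

    @property
    def trans_labels(self) -> list[str]:
        return [l for l in self.values.index if l in TRANS_LABELS]


def g_estimates(
    data: pd.DataFrame,
    scaling="base_standardized",
    n_boot: int = 500,
    seed: int = 0,
    base_hap_variance: float | None = 0.5,
) -> GEstimates:
    """The ten g estimates and their bootstrap sampling covariance.

    Under ``base_standardized`` scaling the variance-based estimates need the
    base-generation haplotypic variance; if it is unknown
    (``base_hap_variance=None`` is rejected by :func:`solve_gk`), pass
    ``base_hap_variance="exclude"`` to drop the four variance-based
    estimates with a warning and test on the remaining six.
    """
    complete = data.dropna(subset=SCORE_COLS)
    n = len(complete)
    if n < 30:
        raise ValueError(f"need >= 30 complete PGS quadruples, got {n}")
    exclude_var = base_hap_variance == "exclude"
    if exclude_var:
        warnings.warn(
            "base-generation variance unknown: variance-based g estimates excluded",
            RuntimeWarning,
        )
        base_hap_variance = 0.5  # placeholder; variance rows dropped below

    s = as_scaling(scaling)
    moments = raw_score_moments(complete)
    g_hat, k_hat = solve_gk(moments, s, base_hap_variance)
    values = _ten_estimates(moments, k_hat)

    X = complete[SCORE_COLS].to_numpy(float)
    col = {c: idx for idx, c in enumerate(SCORE_COLS)}
    pairs = [(col[x], col[y]) for x, y in _PAIRS]
    rng = np.random.default_rng(seed)
    W = _bootstrap_weights(n, n_boot, rng)
    boot_moments = _weighted_cov(X, W, pairs)           # (B, 10)
    boot_vals = np.empty_like(boot_moments)
    for b in range(n_boot):
        _, k_b = solve_gk(boot_moments[b], s, base_hap_variance)
        boot_vals[b] = _ten_estimates(boot_moments[b], k_b)

    labels = list(G_LABELS)
    if exclude_var:
        keep = [idx for idx, l in enumerate(labels) if l not in G_LABELS[:4]]
        labels = [labels[idx] for idx in keep]
        values = values[keep]
        boot_vals = boot_vals[:, keep]

    cov = np.cov(boot_vals, rowvar=False)
    return GEstimates(
        values=pd.Series(values, index=labels),
        cov=pd.DataFrame(cov, index=labels, columns=labels),
        k=k_hat, g_consistent=g_hat, n_families=n, n_boot=n_boot, scaling=s.value,
    )


@dataclass
class ChiSquareTest:
    statistic: float
    p_value: float        # two-sided chi-square(1) tail
    p_one_sided: float    # halved tail in the direction of the estimate
    estimate: float
    se: float
    direction: str | None = None


def test_g_nonzero(g: GEstimates) -> ChiSquareTest:
    """Wald chi-square(1) test of the average g being nonzero.

    The statistic is the plain average of the available estimates divided by
    its bootstrap standard error (a fixed linear combination, so the Wald
    statistic is well calibrated even though the ten estimates are strongly
    dependent).  It is two-sided; because the alternative of interest is
    one-sided (g > 0 under primary AM), ``p_one_sided`` halves the tail when
    the mean is positive.
    """
    cov = g.cov.to_numpy()
    vals = g.values.to_numpy()
    wts = np.full(len(vals), 1.0 / len(vals))
    mean = wts @ vals
    var = wts @ cov @ wts
    if np.allclose(vals, 0.0) or var <= 0:
        return ChiSquareTest(0.0, 1.0, 1.0, float(mean), float(np.sqrt(max(var, 0.0))))
    chi2 = mean * mean / var
    p = float(stats.chi2.sf(chi2, df=1))
    p_one = p / 2 if mean > 0 else 1 - p / 2
    return ChiSquareTest(float(chi2), p, float(p_one), float(mean), float(np.sqrt(var)))


def test_cis_trans(g: GEstimates) -> ChiSquareTest:
    """Wald chi-square(1) test of cis mean == trans mean.

    The contrast is the difference of the unweighted group averages with its
    bootstrap variance.  Trans significantly above cis suggests AM at
    disequilibrium (recent onset); equality is what equilibrium AM predicts.
    """
    labels = list(g.values.index)
    cis_idx = [idx for idx, l in enumerate(labels) if l in CIS_LABELS]
    trans_idx = [idx for idx, l in enumerate(labels) if l in TRANS_LABELS]
    if not cis_idx or not trans_idx:
        raise ValueError("both cis and trans estimates are required")
    cov = g.cov.to_numpy()
    vals = g.values.to_numpy()
    lam = np.zeros(len(vals))
    lam[cis_idx] = 1.0 / len(cis_idx)
    lam[trans_idx] = -1.0 / len(trans_idx)
    diff = lam @ vals
    var = lam @ cov @ lam
    if np.allclose(vals[cis_idx].mean(), vals[trans_idx].mean()) and abs(diff) < 1e-14:
        return ChiSquareTest(0.0, 1.0, 1.0, float(diff), float(np.sqrt(max(var, 0.0))), "equal")
    chi2 = diff * diff / var
    p = float(stats.chi2.sf(chi2, df=1))
    direction = "cis>trans" if diff > 0 else "trans>cis"
    p_one = p / 2 if diff < 0 else 1 - p / 2  # one-sided toward disequilibrium
    return ChiSquareTest(float(chi2), p, float(p_one), float(diff), float(np.sqrt(var)), direction)


@dataclass
class HomogamyDiagnostic:
    observed_spousal_cov: float
    implied_spousal_cov: float
    difference: float
    ci_low: float
    ci_high: float
    label: str  # consistent | social-homogamy-like | genetic-homogamy-like


def _homogamy_point(mom: dict) -> tuple[float, float, float]:
    g_bar = np.mean([mom[l] for l in ("c_TpNTp", "c_TmNTm", "t_TpTm", "t_TpNTm", "t_NTpTm", "t_NTpNTm")])
    omega = np.mean([mom["YpTp"], mom["YpNTp"], mom["YmTm"], mom["YmNTm"]])
    v_y = 0.5 * (mom["VYp"] + mom["VYm"])
    if omega == 0:
        raise ValueError("cannot recover mu: cov(Y_*, [N]T_*) is zero")
    mu = g_bar / omega**2
    return mom["YpYm"], mu * v_y * v_y, mom["YpYm"] - mu * v_y * v_y


def homogamy_diagnostic(
    data: pd.DataFrame,
    g: GEstimates | None = None,
    n_boot: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
) -> HomogamyDiagnostic:
    """Compare observed cov(Y_p, Y_m) with the value implied by g.

    ``mu`` is recovered from ``g = Omega^2 mu`` with ``Omega`` estimated from
    ``cov(Y_*, [N]T_*)``; the implied spousal covariance is ``mu V_Y^2``.
    Social homogamy predicts observed > implied, genetic homogamy the
    reverse.  The direction label is issued only when the bootstrap CI on
    the difference excludes zero.

    Here g enters through the within-sample cis/trans covariances (variance-
    based estimates drop out of the comparison, avoiding the k circularity).
    """
    cols = SCORE_COLS + ["Y_p", "Y_m"]
    complete = data.dropna(subset=cols)
    n = len(complete)
    if n < 30:
        raise ValueError(f"homogamy diagnostic needs >= 30 families with parental phenotypes, got {n}")

    X = complete[cols].to_numpy(float)
    col = {c: idx for idx, c in enumerate(cols)}
    keys = {
        "c_TpNTp": ("T_p", "NT_p"), "c_TmNTm": ("T_m", "NT_m"),
        "t_TpTm": ("T_p", "T_m"), "t_TpNTm": ("T_p", "NT_m"),
        "t_NTpTm": ("NT_p", "T_m"), "t_NTpNTm": ("NT_p", "NT_m"),
        "YpTp": ("Y_p", "T_p"), "YpNTp": ("Y_p", "NT_p"),
        "YmTm": ("Y_m", "T_m"), "YmNTm": ("Y_m", "NT_m"),
        "VYp": ("Y_p", "Y_p"), "VYm": ("Y_m", "Y_m"), "YpYm": ("Y_p", "Y_m"),
    }
    names = list(keys)
    pairs = [(col[x], col[y]) for x, y in keys.values()]

    Xc = X - X.mean(axis=0)
    point = {
        name: (Xc[:, i] * Xc[:, j]).sum() / (n - 1) for name, (i, j) in zip(names, pairs)
    }
    observed, implied, diff = _homogamy_point(point)

    rng = np.random.default_rng(seed)
    W = _bootstrap_weights(n, n_boot, rng)
    boot = _weighted_cov(X, W, pairs)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        mom_b = dict(zip(names, boot[b]))
        try:
            diffs[b] = _homogamy_point(mom_b)[2]
        except ValueError:
            diffs[b] = np.nan
    lo, hi = np.nanpercentile(diffs, [100 * alpha / 2, 100 * (1 - alpha / 2)])

    if lo > 0:
        label = "social-homogamy-like"
    elif hi < 0:
        label = "genetic-homogamy-like"
    else:
        label = "consistent"
    return HomogamyDiagnostic(
        observed_spousal_cov=float(observed), implied_spousal_cov=float(implied),
        difference=float(diff), ci_low=float(lo), ci_high=float(hi), label=label,
    )


@dataclass
class AMTestReport:
    g: GEstimates
    mean_g: float
    g_nonzero: ChiSquareTest
    cis_trans: ChiSquareTest
    single_generation_am: bool
    homogamy: HomogamyDiagnostic | None
    alpha: float
    notes: list[str]

    def to_dict(self) -> dict:
        d = {
            "mean_g": self.mean_g,
            "g_estimates": self.g.values.to_dict(),
            "k": self.g.k,
            "g_nonzero": vars(self.g_nonzero),
            "cis_trans": vars(self.cis_trans),
            "single_generation_am": self.single_generation_am,
            "alpha": self.alpha,
            "notes": self.notes,
        }
        if self.homogamy is not None:
            d["homogamy"] = vars(self.homogamy)
        return d


def am_test_report(
    data: pd.DataFrame,
    scaling="base_standardized",
    n_boot: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    base_hap_variance: float | None = 0.5,
) -> AMTestReport:
    """Run the full AM-mechanism battery on a family table.

    The single-generation-AM verdict requires the trans estimates to be
    significantly positive (one-sided) while the cis estimates are not, each
    at level ``alpha``.  No multiplicity correction is applied across the
    battery; the three tests are reported jointly and labelled.
    """
    notes: list[str] = []
    g = g_estimates(data, scaling=scaling, n_boot=n_boot, seed=seed,
                    base_hap_variance=base_hap_variance)
    nonzero = test_g_nonzero(g)
    ct = test_cis_trans(g)

    # group-specific one-sided z tests for the single-generation verdict
    def _group_test(labels: list[str]) -> tuple[float, float]:
        idx = [list(g.values.index).index(l) for l in labels]
        cov = g.cov.to_numpy()[np.ix_(idx, idx)]
        mean = g.values.to_numpy()[idx].mean()
        se = np.sqrt(cov.sum()) / len(idx)
        return float(mean), float(se)

    trans_mean, trans_se = _group_test(g.trans_labels)
    cis_mean, cis_se = _group_test(g.cis_labels)
    trans_sig = trans_mean / trans_se > stats.norm.isf(alpha)
    cis_sig = abs(cis_mean / cis_se) > stats.norm.isf(alpha / 2)
    single_gen = bool(trans_sig and not cis_sig)

    homog = None
    if data.dropna(subset=SCORE_COLS + ["Y_p", "Y_m"]).shape[0] >= 30:
        homog = homogamy_diagnostic(data, g, n_boot=n_boot, seed=seed + 1, alpha=alpha)
    else:
        notes.append("homogamy diagnostic skipped: fewer than 30 families with parental phenotypes")

    return AMTestReport(
        g=g, mean_g=nonzero.estimate, g_nonzero=nonzero, cis_trans=ct,
        single_generation_am=single_gen, homogamy=homog, alpha=alpha, notes=notes,
    )
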