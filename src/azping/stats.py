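"""Inferential layer: survival of spontaneous-only AZs, count models, Hill fit.

Three analyses sit downstream of event detection:

* **Survival analysis.**  An AZ that showed spontaneous activity "survives"
  while it has produced no AP-evoked response; its first evoked event is its
  "death".  Per cell a frame-indexed vector counts surviving AZs (one
  decrement per AZ at its first evoked event, from that frame to the end),
  normalized to start at 1.  The cell-averaged curve is fitted by nonlinear
  least squares with a mono-exponential decay,

      surviving_fraction(t) = exp(-K t)

  or its plateau variant

      surviving_fraction(t) = (1 - plateau) * exp(-K t) + plateau,

  where the plateau is the fraction of AZs predicted never to respond to
  APs ("immortal").  Models are compared by (corrected) Akaike information
  criterion; the survival half-life is t1/2 = ln(2) / K.

* **Negative-binomial mixed model.**  Per-AZ evoked counts are modelled with
  an NB2 response and log link, the spontaneous-count group (0, 1, 2, >=3)
  as a factor, and a random animal intercept.  The marginal likelihood is
  maximized with Gauss-Hermite quadrature over the random effect.  The
  factor effect is tested by likelihood ratio; the monotone increase of the
  four fitted group means by a one-sided Mann-Kendall trend test.

* **Hill saturation fit.**  Cell-wise mean event amplitudes versus external
  Ca2+ follow F([Ca2+]) = F_max * [Ca2+]^h / (K_A^h + [Ca2+]^h) + C with
  cooperativity h and half-saturation K_A.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2, norm
from sklearn.base import BaseEstimator

__all__ = [
    "SurvivalCurve",
    "SurvivalFit",
    "AICSelection",
    "SurvivalDecayModel",
    "NegativeBinomialMixedModel",
    "HillCurve",
    "build_survival_curve",
    "survival_curve_from_conversions",
    "fit_survival",
    "compare_aic",
    "fit_nb_glmm",
    "mann_kendall_trend",
    "fit_hill",
]

GROUP_LEVELS = ("0", "1", "2", ">=3")


# ---------------------------------------------------------------------------
# survival curves


@dataclass
class SurvivalCurve:
    """Per-frame fraction of still exclusively spontaneous AZs."""

    t: np.ndarray  # frame indices
    surviving_fraction: np.ndarray  # cell-average, starts at 1
    per_cell: dict | None = None  # cell_id -> per-cell curve

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t)
        self.surviving_fraction = np.asarray(self.surviving_fraction, dtype=float)
        if len(self.t) != len(self.surviving_fraction):
            raise ValueError("t and surviving_fraction must have equal length")
        if np.any(np.diff(self.surviving_fraction) > 1e-12):
            raise ValueError("surviving fraction must be non-increasing")
        if (self.surviving_fraction.max() > 1 + 1e-12
                or self.surviving_fraction.min() < -1e-12):
            raise ValueError("surviving fraction must lie in [0, 1]")


def _cell_curve(az_ids: Sequence[int], first_evoked: Mapping[int, int],
                n_frames: int) -> np.ndarray:
    az_ids = list(az_ids)
    if not az_ids:
        raise ValueError("cell has no spontaneously active AZs")
    vec = np.full(n_frames, float(len(az_ids)))
    for az in az_ids:
        f = first_evoked.get(int(az))
        if f is not None and 0 <= f < n_frames:
            vec[f:] -= 1.0
    return vec / len(az_ids)


def build_survival_curve(spont_az_ids, evoked_events: pd.DataFrame,
                         n_frames: int) -> SurvivalCurve:
    """Survival curve of exclusively spontaneously active AZs.

    ``spont_az_ids`` is either a sequence of AZ ids (a single cell) or a
    mapping cell_id -> sequence of AZ ids.  ``evoked_events`` needs columns
    ``roi_id`` and ``peak_frame`` plus ``cell_id`` in the multi-cell case;
    only the first evoked event of each AZ decrements the curve.  Per-cell
    curves start at 1 and the unweighted cell mean is returned alongside.
    """
    if not isinstance(spont_az_ids, Mapping):
        spont_az_ids = {0: list(spont_az_ids)}
        evoked_events = evoked_events.assign(cell_id=0)
    if "cell_id" not in evoked_events.columns:
        raise ValueError("multi-cell input needs a cell_id column in events")
    per_cell = {}
    for cell, ids in spont_az_ids.items():
        ev = evoked_events[evoked_events["cell_id"] == cell]
        ev = ev[ev["roi_id"].isin(list(ids))]
        first = ev.groupby("roi_id")["peak_frame"].min().astype(int).to_dict()
        per_cell[cell] = _cell_curve(ids, first, n_frames)
    mean = np.mean(np.stack(list(per_cell.values())), axis=0)
    return SurvivalCurve(np.arange(n_frames), mean, per_cell=per_cell)


def survival_curve_from_conversions(conversions: pd.DataFrame,
                                    n_frames: int) -> SurvivalCurve:
    """Curve from a (cell_id, az_id, convert_frame) table.

    ``convert_frame == -1`` marks AZs that never convert within the
    recording (immortal or censored).
    """
    per_cell = {}
    for cell, grp in conversions.groupby("cell_id"):
        first = {
            int(r.az_id): int(r.convert_frame)
            for r in grp.itertuples(index=False)
            if r.convert_frame >= 0
        }
        per_cell[cell] = _cell_curve(grp["az_id"].tolist(), first, n_frames)
    mean = np.mean(np.stack(list(per_cell.values())), axis=0)
    return SurvivalCurve(np.arange(n_frames), mean, per_cell=per_cell)


# ---------------------------------------------------------------------------
# survival fits and AIC


@dataclass
class SurvivalFit:
    """Fitted plateau-exponential (or plain exponential) survival decay."""

    model: str  # 'exp' or 'exp_plateau'
    K: float  # per-frame decay rate
    plateau: float  # 0 for the plain exponential
    rss: float
    n_params: int
    n_obs: int
    aic: float

    @property
    def half_life(self) -> float:
        return math.log(2.0) / self.K


def _aicc(rss: float, n: int, k: int, corrected: bool = True) -> float:
    rss = max(rss, 1e-300)
    aic = n * math.log(rss / n) + 2 * k
    if corrected and n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


class SurvivalDecayModel(BaseEstimator):
    """Nonlinear least-squares fit of the survival decay.

    Parameters
    ----------
    model : 'exp' or 'exp_plateau'
        Plain mono-exponential or the variant with an "immortal" plateau.
        The plateau model reduces to the plain one exactly at plateau = 0.
    corrected_aic : bool
        Use the small-sample corrected AICc (default) or plain AIC.

    Attributes
    ----------
    K_ : per-frame decay rate (> 0)
    plateau_ : surviving fraction at infinite time (0 for 'exp')
    half_life_ : ln(2) / K_, in frames
    rss_, aic_ : residual sum of squares and information criterion
    """

    def __init__(self, model: str = "exp_plateau", corrected_aic: bool = True):
        self.model = model
        self.corrected_aic = corrected_aic

    @staticmethod
    def _predict(t, K, plateau=0.0):
        return (1.0 - plateau) * np.exp(-K * np.asarray(t, dtype=float)) + plateau

    def fit(self, t: np.ndarray, fraction: np.ndarray | None = None):
        if fraction is None and isinstance(t, SurvivalCurve):
            t, fraction = t.t, t.surviving_fraction
        t = np.asarray(t, dtype=float)
        y = np.asarray(fraction, dtype=float)
        if self.model not in ("exp", "exp_plateau"):
            raise ValueError("model must be 'exp' or 'exp_plateau'")
        # data-driven starting values: K from the early log-slope, plateau
        # from the curve tail
        tail = float(y[-max(len(y) // 20, 1):].mean())
        span = t[-1] if t[-1] > 0 else 1.0
        drop = max(1.0 - tail, 1e-3)
        K0 = max(-math.log(max(tail - 1e-6, 0.05)) / span, 1e-6) \
            if self.model == "exp" else max(3.0 / span * drop, 1e-6)
        if self.model == "exp":
            popt, _ = optimize.curve_fit(
                lambda tt, K: self._predict(tt, K), t, y,
                p0=[K0], bounds=([1e-12], [np.inf]), maxfev=20000,
            )
            K, plateau, k = float(popt[0]), 0.0, 1
        else:
            popt, _ = optimize.curve_fit(
                lambda tt, K, p: self._predict(tt, K, p), t, y,
                p0=[max(K0, 1e-6), min(max(tail, 0.0), 1.0)],
                bounds=([1e-12, 0.0], [np.inf, 1.0]), maxfev=20000,
            )
            K, plateau, k = float(popt[0]), float(popt[1]), 2
        resid = y - self._predict(t, K, plateau)
        rss = float(np.sum(resid**2))
        self.K_ = K
        self.plateau_ = plateau
        self.half_life_ = math.log(2.0) / K
        self.rss_ = rss
        self.n_obs_ = len(y)
        self.n_params_ = k
        self.aic_ = _aicc(rss, len(y), k, corrected=self.corrected_aic)
        # a half-life beyond ~10^6 frames means the curve never decayed
        self.boundary_flag_ = K < 1e-6
        return self

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self._predict(t, self.K_, self.plateau_)

    def result(self) -> SurvivalFit:
        return SurvivalFit(model=self.model, K=self.K_, plateau=self.plateau_,
                           rss=self.rss_, n_params=self.n_params_,
                           n_obs=self.n_obs_, aic=self.aic_)


def fit_survival(curve: SurvivalCurve, model: str = "exp_plateau",
                 corrected_aic: bool = True) -> SurvivalFit:
    """Fit one survival model to the cell-averaged curve."""
    est = SurvivalDecayModel(model=model, corrected_aic=corrected_aic)
    est.fit(curve.t, curve.surviving_fraction)
    return est.result()


@dataclass
class AICSelection:
    """Outcome of an information-criterion comparison of two fits."""

    winner: str
    delta_aic: float  # aic(loser) - aic(winner), >= 0
    aic_a: float
    aic_b: float


def compare_aic(fit_a: SurvivalFit, fit_b: SurvivalFit) -> AICSelection:
    """Select between two fits of the same data; lower criterion wins."""
    if fit_a.n_obs != fit_b.n_obs:
        raise ValueError("fits must be on identical data (lengths differ)")
    if fit_a.aic <= fit_b.aic:
        return AICSelection(fit_a.model, fit_b.aic - fit_a.aic,
                            fit_a.aic, fit_b.aic)
    return AICSelection(fit_b.model, fit_a.aic - fit_b.aic,
                        fit_a.aic, fit_b.aic)


# ---------------------------------------------------------------------------
# negative-binomial mixed model


def _nb_logpmf_terms(y: np.ndarray, log_mu: np.ndarray,
                     theta: float) -> np.ndarray:
    """NB2 log-pmf with size theta: var = mu + mu^2/theta.

    ``log_mu`` may broadcast against ``y[:, None]`` for quadrature nodes.
    """
    mu = np.exp(log_mu)
    log_theta_mu = np.log(theta + mu)
    yy = y[..., None] if log_mu.ndim > y.ndim else y
    const = gammaln(yy + theta) - gammaln(theta) - gammaln(yy + 1)
    return const + theta * (math.log(theta) - log_theta_mu) \
        + yy * (log_mu - log_theta_mu)


class NegativeBinomialMixedModel(BaseEstimator):
    """NB GLMM with a log link and a random animal intercept.

    The marginal likelihood integrates the Gaussian random intercept out by
    Gauss-Hermite quadrature (``n_quad`` nodes) and is maximized with
    L-BFGS-B over the four group log-means, log animal-intercept SD and log
    dispersion.  The factor effect (are the four group means equal?) is a
    likelihood-ratio test against the intercept-only model with the same
    random structure; the positive monotone trend across the four fitted
    means is a one-sided Mann-Kendall test.

    Attributes
    ----------
    group_means_ : ndarray (4,) — fitted evoked-count means per spontaneous
        group at the typical animal (random intercept 0)
    dispersion_ : NB2 size parameter theta (variance mu + mu^2/theta)
    animal_sd_ : SD of the animal intercept on the log scale
    factor_test_p_ : LRT p-value for the group factor (df = 3)
    trend_S_, trend_p_ : Mann-Kendall statistic and one-sided p on the means
    """

    def __init__(self, n_quad: int = 15, tol: float = 1e-8):
        self.n_quad = n_quad
        self.tol = tol

    def _negloglik(self, params, y, g, animal_ptr, nodes, log_w, n_groups):
        beta = params[:n_groups]
        sigma = math.exp(params[n_groups])
        theta = math.exp(params[n_groups + 1])
        eta = beta[g]  # (n,)
        b = math.sqrt(2.0) * sigma * nodes  # (K,)
        log_mu = eta[:, None] + b[None, :]
        ll = _nb_logpmf_terms(y, log_mu, theta)  # (n, K)
        per_animal = np.add.reduceat(ll, animal_ptr, axis=0)  # (n_animals, K)
        return -float(np.sum(logsumexp(per_animal + log_w[None, :], axis=1)))

    def _fit_ll(self, y, g, animal_ptr, n_groups):
        nodes, weights = np.polynomial.hermite.hermgauss(self.n_quad)
        log_w = np.log(weights) - 0.5 * math.log(math.pi)
        counts_mean = np.array([
            max(y[g == k].mean(), 0.05) if np.any(g == k) else 0.5
            for k in range(n_groups)
        ])
        x0 = np.concatenate([np.log(counts_mean), [math.log(0.3), math.log(1.5)]])
        bounds = [(-10.0, 6.0)] * n_groups + [(-6.0, 2.0), (-4.0, 10.0)]
        res = optimize.minimize(
            self._negloglik, x0, method="L-BFGS-B", bounds=bounds,
            args=(y, g, animal_ptr, nodes, log_w, n_groups),
            options={"ftol": self.tol, "gtol": 1e-8, "maxiter": 500},
        )
        return res

    def fit(self, table: pd.DataFrame, y=None):
        df = table.copy()
        for col in ("animal_id", "spont_group", "n_evoked"):
            if col not in df.columns:
                raise ValueError(f"count table needs column '{col}'")
        if df["animal_id"].nunique() < 2:
            raise ValueError(
                "random animal intercept is unidentifiable with one animal"
            )
        g = _encode_groups(df["spont_group"])
        if len(np.unique(g)) < 4:
            raise ValueError("all 4 spontaneous-count groups must be present")
        df = df.assign(_g=g).sort_values("animal_id", kind="stable")
        yv = df["n_evoked"].to_numpy(dtype=float)
        gv = df["_g"].to_numpy()
        animals = df["animal_id"].to_numpy()
        ptr = np.flatnonzero(np.r_[True, animals[1:] != animals[:-1]])

        res_full = self._fit_ll(yv, gv, ptr, 4)
        res_null = self._fit_ll(yv, np.zeros_like(gv), ptr, 1)
        self.converged_ = bool(res_full.success and res_null.success)

        beta = res_full.x[:4]
        self.coef_ = beta
        self.group_means_ = np.exp(beta)
        self.animal_sd_ = math.exp(res_full.x[4])
        self.dispersion_ = math.exp(res_full.x[5])
        self.loglik_ = -res_full.fun
        lr = max(2.0 * (res_null.fun - res_full.fun), 0.0)
        self.factor_test_p_ = float(chi2.sf(lr, df=3))
        self.lr_statistic_ = lr
        S, p = mann_kendall_trend(self.group_means_, alternative="greater")
        self.trend_S_ = S
        self.trend_p_ = p
        return self


def _encode_groups(groups: pd.Series) -> np.ndarray:
    def code(v):
        s = str(v)
        if s in ("0", "1", "2"):
            return int(s)
        if s in (">=3", "≥3", "3+"):
            return 3
        iv = int(v)
        return min(iv, 3)

    return np.asarray([code(v) for v in groups])


def fit_nb_glmm(table: pd.DataFrame, n_quad: int = 15) -> NegativeBinomialMixedModel:
    """Fit the NB mixed model to a (animal_id, spont_group, n_evoked) table."""
    return NegativeBinomialMixedModel(n_quad=n_quad).fit(table)


# ---------------------------------------------------------------------------
# Mann-Kendall trend test


def _mk_statistic(values: np.ndarray) -> int:
    diff = values[None, :] - values[:, None]
    return int(np.sign(np.triu(diff, k=1)).sum())


def _mahonian_counts(n: int) -> np.ndarray:
    """Number of permutations of n items with k inversions, k = 0..n(n-1)/2."""
    counts = np.array([1.0])
    for i in range(2, n + 1):
        kernel = np.ones(i)
        counts = np.convolve(counts, kernel)
    return counts


def mann_kendall_trend(values: Sequence[float],
                       alternative: str = "greater",
                       exact_n: int = 10) -> tuple[int, float]:
    """One-sided Mann-Kendall trend test.

    S = sum_{i<j} sign(v_j - v_i); the null of no trend is rejected for
    large S ('greater') or small S ('less').  The p-value is exact for
    n <= ``exact_n`` (Mahonian-number recursion without ties, full multiset
    enumeration with ties for n <= 8), and uses the tie-corrected normal
    approximation with continuity correction otherwise.  A constant series
    returns S = 0 with the mid-distribution p of 0.5.
    """
    v = np.asarray(list(values), dtype=float)
    n = len(v)
    if n < 3:
        raise ValueError("need at least 3 values")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    S = _mk_statistic(v)
    if alternative == "less":
        S_eff = -S
    else:
        S_eff = S
    _, tie_counts = np.unique(v, return_counts=True)
    has_ties = np.any(tie_counts > 1)
    if np.all(v == v[0]):
        return S, 0.5

    if not has_ties and n <= exact_n:
        T = n * (n - 1) // 2
        counts = _mahonian_counts(n)
        # S = T - 2*inversions, so S >= S_eff  <=>  inv <= (T - S_eff) / 2
        kmax = int(math.floor((T - S_eff) / 2))
        p = float(counts[: kmax + 1].sum() / counts.sum())
        return S, p
    if has_ties and n <= 8:
        total = 0
        ge = 0
        for perm in itertools.permutations(v):
            total += 1
            if _mk_statistic(np.asarray(perm)) >= S_eff:
                ge += 1
        return S, ge / total
    var = n * (n - 1) * (2 * n + 5)
    for t in tie_counts[tie_counts > 1]:
        var -= t * (t - 1) * (2 * t + 5)
    var /= 18.0
    if S_eff > 0:
        z = (S_eff - 1) / math.sqrt(var)
    elif S_eff < 0:
        z = (S_eff + 1) / math.sqrt(var)
    else:
        z = 0.0
    return S, float(norm.sf(z))


# ---------------------------------------------------------------------------
# Hill fit


class HillCurve(BaseEstimator):
    """Hill saturation fit of fluorescence versus external Ca2+.

    F([Ca2+]) = F_max * [Ca2+]^h / (K_A^h + [Ca2+]^h) + C.  At
    [Ca2+] = K_A the fitted curve equals C + F_max / 2 identically.

    Attributes: ``F_max_`` (a.u.), ``K_A_`` (mM), ``h_`` (cooperativity),
    ``C_`` (baseline a.u.).
    """

    @staticmethod
    def _model(x, F_max, K_A, h, C):
        x = np.asarray(x, dtype=float)
        return F_max * x**h / (K_A**h + x**h) + C

    def fit(self, concentrations: Sequence[float], means: Sequence[float]):
        x = np.asarray(list(concentrations), dtype=float)
        y = np.asarray(list(means), dtype=float)
        if np.any(x <= 0):
            raise ValueError("concentrations must be positive")
        if len(x) < 4:
            raise ValueError("need at least 4 concentrations")
        p0 = [max(y.max() - y.min(), 1e-6), float(np.median(x)), 1.5,
              float(y.min())]
        popt, _ = optimize.curve_fit(
            self._model, x, y, p0=p0,
            bounds=([1e-12, 1e-12, 1e-12, -np.inf], [np.inf] * 4),
            maxfev=20000,
        )
        self.F_max_, self.K_A_, self.h_, self.C_ = (float(p) for p in popt)
        self.rss_ = float(np.sum((y - self.predict(x)) ** 2))
        return self

    def predict(self, concentrations: Sequence[float]) -> np.ndarray:
        return self._model(np.asarray(list(concentrations), dtype=float),
                           self.F_max_, self.K_A_, self.h_, self.C_)


def fit_hill(ca_concs: Sequence[float],
             cellwise_means: Sequence[float]) -> HillCurve:
    """Fit the Hill relationship to cell-wise mean amplitudes."""
    return HillCurve().fit(ca_concs, cellwise_means)
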