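"""Enzyme kinetics: initial rates, Michaelis--Menten fits, and pH--rate profiles.

Initial rates come from the slope of the product-absorbance trace
(Beer--Lambert, default extinction coefficient 15,800 1/(M cm) at 380 nm
for the Kemp-elimination product).  Rate-vs-substrate profiles are fitted
with the Michaelis--Menten equation

    v / E0 = kcat * [S] / (KM + [S]),

optionally pooled over preparations.  Because kcat determination relies on
observing curvature, a fit whose KM lands near or beyond the top tested
substrate concentration is flagged (``curvature_detected = False``) and
only kcat/KM is reported as reliable.

The pH dependence of a catalytic parameter P governed by a single
titratable catalytic base follows

    log10 P = log10 P0 + log10( 10**(pH-pKa) / (1 + 10**(pH-pKa)) ),

which plateaus at log10 P0 for pH >> pKa and approaches a line of slope
unity for pH << pKa.  ``fit_single_pka`` fits this model in log space;
``loglinear_slope`` is the diagnostic that rejects it (slope below one with
no plateau), and ``fit_pka_ensemble`` fits a pKa-mixture generalization --
the functional form of that mixture is this package's own construction,
motivated by a Michaelis complex populating conformations whose catalytic
base has different pKa values, and is tagged as such in its output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MichaelisFit",
    "PKaFit",
    "rates_from_absorbance",
    "fit_michaelis",
    "eq1_log10P",
    "fit_single_pka",
    "loglinear_slope",
    "fit_pka_ensemble",
    "read_rate_table",
    "write_rate_table",
]

LN10 = math.log(10.0)

RATE_COLUMNS = ["variant", "pH", "substrate_M", "E0_M", "v_Ms", "replicate"]


@dataclass
class MichaelisFit:
    kcat: float  # 1/s
    KM: float  # M
    kcat_se: float
    KM_se: float
    covariance: np.ndarray
    curvature_detected: bool
    n_points: int

    @property
    def kcat_over_KM(self) -> float:
        return self.kcat / self.KM

    def to_dict(self) -> dict:
        return {
            "kcat": self.kcat,
            "KM": self.KM,
            "kcat_over_KM": self.kcat_over_KM,
            "kcat_se": self.kcat_se,
            "KM_se": self.KM_se,
            "curvature_detected": self.curvature_detected,
            "n_points": self.n_points,
        }


@dataclass
class PKaFit:
    log10_P0: float
    pKa: float
    rss: float
    model: str  # "single-pKa" | "linear" | "ensemble"
    poorly_determined: bool = False
    components: list[dict] = field(default_factory=list)  # ensemble only
    aic: float = math.nan

    def predict(self, pH: np.ndarray) -> np.ndarray:
        pH = np.asarray(pH, float)
        if self.model == "ensemble" and self.components:
            P = np.zeros_like(pH)
            for comp in self.components:
                x = pH - comp["pKa"]
                P = P + comp["weight"] * 10.0 ** comp["log10_P0"] * _frac(x)
            return np.log10(P)
        return eq1_log10P(pH, self.log10_P0, self.pKa)

    def to_dict(self) -> dict:
        return {
            "log10_P0": self.log10_P0,
            "pKa": self.pKa,
            "rss": self.rss,
            "model": self.model,
            "poorly_determined": self.poorly_determined,
            "components": self.components,
            "aic": self.aic,
        }


# ---------------------------------------------------------------------------
# initial rates


def rates_from_absorbance(
    time_s: np.ndarray,
    absorbance: np.ndarray,
    epsilon: float = 15_800.0,
    path_cm: float = 1.0,
    blank_slope: float = 0.0,
    window: int | None = None,
) -> float:
    """Initial rate (M/s) from the early linear part of an absorbance trace.

    ``v = (slope - blank_slope) / (epsilon * path_cm)`` with the slope from
    ordinary least squares over the first ``window`` points (all points by
    default).  A negative blank-corrected rate is clipped to zero with a
    warning.
    """
    t = np.asarray(time_s, float)
    a = np.asarray(absorbance, float)
    if t.ndim != 1 or t.shape != a.shape:
        raise ValueError("time and absorbance must be matching 1-D arrays")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time vector must be strictly increasing")
    if window is not None:
        t, a = t[:window], a[:window]
    if t.size < 3:
        raise ValueError("need at least 3 points in the initial linear window")
    slope = stats.linregress(t, a).slope
    v = (slope - blank_slope) / (epsilon * path_cm)
    if v < 0:
        warnings.warn("negative blank-corrected rate clipped to 0", stacklevel=2)
        v = 0.0
    return float(v)


# ---------------------------------------------------------------------------
# Michaelis--Menten


def _mm(S, kcat, KM):
    return kcat * S / (KM + S)


def fit_michaelis(
    rows: pd.DataFrame,
    curvature_km_factor: float = 0.8,
    weighting: str | None = None,
) -> MichaelisFit:
    """Nonlinear least-squares Michaelis--Menten fit of ``v/E0`` vs ``[S]``.

    Accepts a rate-table slice (possibly pooling several replicates /
    preparations).  Fits are unweighted by default; ``weighting="1/v2"``
    weights points by 1/v**2.  ``curvature_detected`` is True when the
    fitted KM is below ``curvature_km_factor`` times the top tested
    substrate concentration; otherwise the data do not constrain kcat and
    KM separately and only kcat/KM should be trusted.
    """
    S = np.asarray(rows["substrate_M"], float)
    y = np.asarray(rows["v_Ms"], float) / np.asarray(rows["E0_M"], float)
    if np.unique(S).size < 4:
        raise ValueError("need at least 4 distinct substrate concentrations")
    if np.any(S <= 0):
        raise ValueError("substrate concentrations must be positive")

    kcat0 = 1.2 * float(np.max(y))
    half = 0.5 * float(np.max(y))
    KM0 = float(S[np.argmin(np.abs(y - half))])
    KM0 = max(KM0, 1e-12)
    sigma = np.abs(y) if weighting == "1/v2" else None
    guesses = [(kcat0, KM0)]
    # grid restarts guard against convergence to a negative-parameter path
    guesses += [
        (kcat0 * fk, float(np.max(S)) * fm)
        for fk in (0.5, 2.0)
        for fm in (0.1, 1.0, 10.0)
    ]
    last_err: Exception | None = None
    for g in guesses:
        try:
            popt, pcov = optimize.curve_fit(
                _mm, S, y, p0=g, sigma=sigma,
                bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20_000,
            )
        except RuntimeError as err:  # pragma: no cover - rare nonconvergence
            last_err = err
            continue
        if np.all(popt > 0) and np.all(np.isfinite(popt)):
            break
    else:
        raise RuntimeError(
            f"Michaelis-Menten fit failed to converge from all starts: {last_err}"
        )
    se = np.sqrt(np.diag(pcov))
    return MichaelisFit(
        kcat=float(popt[0]),
        KM=float(popt[1]),
        kcat_se=float(se[0]),
        KM_se=float(se[1]),
        covariance=pcov,
        curvature_detected=bool(popt[1] < curvature_km_factor * np.max(S)),
        n_points=int(S.size),
    )


# ---------------------------------------------------------------------------
# pH dependence


def _frac(x: np.ndarray) -> np.ndarray:
    """``10**x / (1 + 10**x)`` computed stably for large |x|."""
    x = np.asarray(x, float)
    with np.errstate(over="ignore"):
        return np.where(x > 0, 1.0 / (1.0 + 10.0 ** (-x)), 10.0**x / (1.0 + 10.0**x))


def eq1_log10P(pH, log10_P0: float, pKa: float):
    """Single-titratable-base pH dependence of a catalytic parameter (log10).

    Strictly increasing in pH; tends to ``log10_P0`` for pH >> pKa and to a
    unit-slope line ``log10_P0 + pH - pKa`` for pH << pKa.
    """
    pH = np.asarray(pH, float)
    x = pH - pKa
    # log10(10**x / (1 + 10**x)) = x - log10(1 + 10**x), via logaddexp for stability
    out = log10_P0 + x - np.logaddexp(0.0, x * LN10) / LN10
    return float(out) if out.ndim == 0 else out


def fit_single_pka(
    pH: np.ndarray, log10_P: np.ndarray, window_margin: float = 3.0
) -> PKaFit:
    """Least-squares fit of the single-pKa model in log10 space.

    A fitted pKa outside ``[min(pH) - margin, max(pH) + margin]`` is flagged
    ``poorly_determined`` (no kink inside the observed window; e.g. a pure
    unit-slope line pushes the pKa above the range).
    """
    pH = np.asarray(pH, float)
    y = np.asarray(log10_P, float)
    if pH.size < 4:
        raise ValueError("need at least 4 pH points")
    # initial pKa from the maximum-curvature point, P0 from the top plateau
    slopes = np.gradient(y, pH)
    pka0 = float(pH[np.argmax(np.abs(np.gradient(slopes, pH)))])
    p0_list = [(float(y.max()), pka0)]
    p0_list += [(float(y.max()), p) for p in np.linspace(pH.min() - 2, pH.max() + 2, 5)]

    def resid(theta):
        return eq1_log10P(pH, theta[0], theta[1]) - y

    best = None
    for p0 in p0_list:
        sol = optimize.least_squares(resid, p0, method="lm", max_nfev=10_000)
        if best is None or sol.cost < best.cost:
            best = sol
    log10_P0, pKa = map(float, best.x)
    rss = float(np.sum(best.fun**2))
    poorly = not (pH.min() - window_margin <= pKa <= pH.max() + window_margin)
    n = pH.size
    aic = n * math.log(max(rss, 1e-300) / n) + 2 * 2
    return PKaFit(
        log10_P0=log10_P0, pKa=pKa, rss=rss, model="single-pKa",
        poorly_determined=poorly, aic=aic,
    )


def loglinear_slope(pH: np.ndarray, log10_P: np.ndarray) -> tuple[float, float]:
    """OLS slope (with standard error) of log10 P on pH.

    The diagnostic for the single-base model: far below the pKa the slope is
    one; a slope clearly below unity with no plateau in the window rejects a
    single-pKa description.
    """
    pH = np.asarray(pH, float)
    y = np.asarray(log10_P, float)
    if pH.size < 3:
        raise ValueError("need at least 3 pH points")
    res = stats.linregress(pH, y)
    return float(res.slope), float(res.stderr)


def fit_pka_ensemble(
    pH: np.ndarray,
    log10_P: np.ndarray,
    n_components: int = 2,
    n_starts: int = 8,
    seed: int = 0,
) -> PKaFit:
    """Fit a pKa-mixture model: P = sum_i w_i * P0 * frac(pH - pKa_i).

    The weights are simplex-constrained (softmax parametrization); the
    single-component case delegates to :func:`fit_single_pka`.  The mixture
    functional form is this package's generalization of the single-base
    model (tagged ``model="ensemble"``), and the returned AIC supports
    comparison against the single-pKa fit.
    """
    pH = np.asarray(pH, float)
    y = np.asarray(log10_P, float)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components == 1:
        return fit_single_pka(pH, y)
    if pH.size < 2 * n_components + 1:
        raise ValueError("need at least 2*n_components + 1 pH points")

    k = n_components

    def unpack(theta):
        log10_P0 = theta[0]
        pkas = theta[1 : 1 + k]
        logits = np.concatenate([theta[1 + k :], [0.0]])
        w = np.exp(logits - logits.max())
        w = w / w.sum()
        return log10_P0, pkas, w

    def model(theta):
        log10_P0, pkas, w = unpack(theta)
        P = np.zeros_like(pH)
        for wi, pka in zip(w, pkas):
            P = P + wi * _frac(pH - pka)
        return log10_P0 + np.log10(np.maximum(P, 1e-300))

    def resid(theta):
        return model(theta) - y

    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        pka0 = np.sort(rng.uniform(pH.min() - 2, pH.max() + 2, size=k))
        theta0 = np.concatenate([[y.max()], pka0, np.zeros(k - 1)])
        sol = optimize.least_squares(resid, theta0, max_nfev=20_000)
        if best is None or sol.cost < best.cost:
            best = sol
    log10_P0, pkas, w = unpack(best.x)
    rss = float(np.sum(best.fun**2))
    order = np.argsort(pkas)
    components = [
        {"weight": float(w[i]), "pKa": float(pkas[i]), "log10_P0": float(log10_P0)}
        for i in order
    ]
    n = pH.size
    n_par = 2 * k  # P0 + k pKas + (k-1) weights
    aic = n * math.log(max(rss, 1e-300) / n) + 2 * n_par
    over = n_par >= n
    return PKaFit(
        log10_P0=float(log10_P0),
        pKa=components[0]["pKa"],
        rss=rss,
        model="ensemble",
        poorly_determined=over,
        components=components,
        aic=aic,
    )


# ---------------------------------------------------------------------------
# IO


def read_rate_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"rate table missing columns: {sorted(missing)}")
    if (df["substrate_M"] <= 0).any() or (df["E0_M"] <= 0).any():
        raise ValueError("substrate_M and E0_M must be positive")
    if (df["v_Ms"] < 0).any():
        raise ValueError("rates must be nonnegative after blank correction")
    return df


def write_rate_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=RATE_COLUMNS)
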