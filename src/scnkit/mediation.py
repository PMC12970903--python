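"""Three-variable mediation with nonparametric bootstrap BC intervals.

Model: X (training duration, years) -> M (a network topology AUC, e.g.
global Cp) -> Y (strokes per 18 holes). All variables are z-standardized,
so the OLS paths are on the standardized-beta scale:

* ``a``: slope of M on X,
* ``b``: slope of Y on M adjusting for X,
* ``c``: total effect of X on Y,
* ``c_prime``: direct effect of X on Y adjusting for M,

with the exact decomposition ``c = c_prime + a*b``. The indirect effect
``a*b`` is tested by resampling subjects with replacement and forming a
bias-corrected (BC) percentile interval: with z0 the normal quantile of the
fraction of bootstrap replicates below the point estimate, the interval
endpoints sit at the Phi(2*z0 +/- z_{0.975}) percentiles of the bootstrap
distribution. A CI excluding zero marks a significant indirect effect.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

_COLLINEAR_TOL = 1e-10


@dataclass
class MediationResult:
    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    significant: bool

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame([asdict(self)]).to_csv(path, index=False)


def _standardize(v: np.ndarray, name: str) -> np.ndarray:
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError(f"variable {name!r} is constant")
    return (v - v.mean()) / sd


def fit_paths(x: np.ndarray, m: np.ndarray, y: np.ndarray
              ) -> tuple[float, float, float, float]:
    """Standardized mediation paths ``(a, b, c, c_prime)``.

    Closed-form OLS on z-scored variables; raises when M is (near-)
    perfectly collinear with X, in which case b and c' are not separately
    identified.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (x.size == m.size == y.size):
        raise ValueError("x, m, y must have equal length")
    if x.size < 10:
        raise ValueError("need at least 10 complete observations")
    zx = _standardize(x, "x")
    zm = _standardize(m, "m")
    zy = _standardize(y, "y")
    r_xm = float(np.mean(zx * zm))
    r_xy = float(np.mean(zx * zy))
    r_my = float(np.mean(zm * zy))
    den = 1.0 - r_xm**2
    if den < _COLLINEAR_TOL:
        raise ValueError("mediator is collinear with the predictor "
                         f"(|corr(x, m)| = {abs(r_xm):.6f}); b and c' are "
                         "not identified")
    a = r_xm
    b = (r_my - r_xy * r_xm) / den
    c_prime = (r_xy - r_my * r_xm) / den
    c = r_xy
    return a, b, c, c_prime


def _bootstrap_ab(x: np.ndarray, m: np.ndarray, y: np.ndarray,
                  n_boot: int, rng: np.random.Generator,
                  max_redraws: int = 10) -> np.ndarray:
    """Vectorized bootstrap of the standardized indirect effect a*b."""
    n = x.size
    idx = rng.integers(0, n, size=(n_boot, n))
    ab = np.full(n_boot, np.nan)
    pending = np.arange(n_boot)
    for _ in range(max_redraws + 1):
        xs, ms, ys = x[idx[pending]], m[idx[pending]], y[idx[pending]]
        sx = xs.std(axis=1)
        sm = ms.std(axis=1)
        sy = ys.std(axis=1)
        zx = (xs - xs.mean(axis=1, keepdims=True))
        zm = (ms - ms.mean(axis=1, keepdims=True))
        zy = (ys - ys.mean(axis=1, keepdims=True))
        with np.errstate(divide="ignore", invalid="ignore"):
            zx /= sx[:, None]
            zm /= sm[:, None]
            zy /= sy[:, None]
            r_xm = np.mean(zx * zm, axis=1)
            r_xy = np.mean(zx * zy, axis=1)
            r_my = np.mean(zm * zy, axis=1)
            den = 1.0 - r_xm**2
            b = (r_my - r_xy * r_xm) / den
        ok = (sx > 0) & (sm > 0) & (sy > 0) & (den > _COLLINEAR_TOL)
        ab[pending[ok]] = (r_xm * b)[ok]
        pending = pending[~ok]
        if pending.size == 0:
            break
        idx[pending] = rng.integers(0, n, size=(pending.size, n))
    else:
        raise ValueError(
            f"{pending.size} bootstrap replicates remained degenerate "
            f"(constant variable) after {max_redraws} redraw attempts")
    return ab


def bootstrap_indirect(x: np.ndarray, m: np.ndarray, y: np.ndarray,
                       n_boot: int = 5000, seed: int = 0) -> MediationResult:
    """Full mediation fit with BC bootstrap CI for the indirect effect."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    a, b, c, c_prime = fit_paths(x, m, y)
    indirect = a * b

    rng = np.random.default_rng(seed)
    boot = _bootstrap_ab(x, m, y, n_boot, rng)

    # bias correction: where the point estimate sits in the bootstrap draw
    prop = np.mean(boot < indirect)
    prop = min(max(prop, 1.0 / (n_boot + 1)), n_boot / (n_boot + 1.0))
    z0 = norm.ppf(prop)
    z_crit = norm.ppf(0.975)
    q_low = norm.cdf(2 * z0 - z_crit)
    q_high = norm.cdf(2 * z0 + z_crit)
    ci_low = float(np.quantile(boot, q_low))
    ci_high = float(np.quantile(boot, q_high))

    return MediationResult(a=a, b=b, c=c, c_prime=c_prime, indirect=indirect,
                           ci_low=ci_low, ci_high=ci_high, n_boot=n_boot,
                           seed=seed,
                           significant=not (ci_low <= 0.0 <= ci_high))


def mediator_key(metric: str, node: str = "") -> str:
    """Canonical name of a candidate mediator ('Cp' or 'nodal_Cp[Region]')."""
    return metric if node in ("", None) else f"{metric}[{node}]"


def select_mediators(comparisons: pd.DataFrame,
                     correlations: pd.DataFrame,
                     x_name: str = "training_duration",
                     y_name: str = "strokes",
                     alpha: float = 0.05) -> list[str]:
    """Candidate mediators: metrics with a significant group difference
    (p_fdr < alpha) that also correlate (p < alpha) with both the predictor
    and the outcome.

    ``correlations`` is long-format with columns variable_x (the mediator
    key), variable_y, p.
    """
    significant = {
        mediator_key(r["metric"], r.get("node", ""))
        for _, r in comparisons.iterrows() if r["p_fdr"] < alpha
    }
    out = []
    for key in sorted(significant):
        sub = correlations[correlations["variable_x"] == key]
        with_x = sub[(sub["variable_y"] == x_name) & (sub["p"] < alpha)]
        with_y = sub[(sub["variable_y"] == y_name) & (sub["p"] < alpha)]
        if len(with_x) > 0 and len(with_y) > 0:
            out.append(key)
    return out
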