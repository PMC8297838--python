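"""Random-intercept linear mixed model of the distance travelled.

The response is ``movementSum`` (metres walked in the 10-minute recording);
fixed effects are temperature category (reference level: intermediate), tag
weight (mg), animal weight (mg) and the temperature interactions with both
weights; the random term is an intercept per cricket, capturing the
repeated-measures correlation across the three recording days::

    movementSum ~ temperature * tag_weight + temperature * animal_weight
                  + (1 | cricket_id)

The model is fitted by REML through statsmodels' ``MixedLM``.  Because the
random structure is a single intercept, the profiled REML log-likelihood has
a closed form in the two variance components; that form is used to compute
Satterthwaite-type approximate denominator degrees of freedom for the t and F
statistics and a boundary-corrected likelihood-ratio test (0.5 chi2_0 +
0.5 chi2_1 mixture) of the random intercept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

REFERENCE_TEMPERATURE = "intermediate"

FORMULA = (
    "movementSum ~ C(temperature_category, Treatment('intermediate')) * tag_weight_mg"
    " + C(temperature_category, Treatment('intermediate')) * animal_weight_mg"
)

#: statsmodels design names -> report labels (Table-style coefficient rows)
_TERM_LABELS = {
    "Intercept": "(Intercept)",
    "C(temperature_category, Treatment('intermediate'))[T.high]": "high temperature",
    "C(temperature_category, Treatment('intermediate'))[T.low]": "low temperature",
    "tag_weight_mg": "tag weight",
    "animal_weight_mg": "animal weight",
    "C(temperature_category, Treatment('intermediate'))[T.high]:tag_weight_mg": "high temperature:tag weight",
    "C(temperature_category, Treatment('intermediate'))[T.low]:tag_weight_mg": "low temperature:tag weight",
    "C(temperature_category, Treatment('intermediate'))[T.high]:animal_weight_mg": "high temperature:animal weight",
    "C(temperature_category, Treatment('intermediate'))[T.low]:animal_weight_mg": "low temperature:animal weight",
}

_ANOVA_TERMS = {
    "temperature": ["high temperature", "low temperature"],
    "tag weight": ["tag weight"],
    "animal weight": ["animal weight"],
    "temperature:tag weight": [
        "high temperature:tag weight",
        "low temperature:tag weight",
    ],
    "temperature:animal weight": [
        "high temperature:animal weight",
        "low temperature:animal weight",
    ],
}


@dataclass
class MixedModelFit:
    """Result bundle of :func:`fit_movement_sum_model`."""

    coefficients: pd.DataFrame  # Estimate, Std. Error, df, t value, Pr(>|t|)
    anova: pd.DataFrame  # term, F, df_num, df_den, p
    random_intercept_variance: float
    residual_variance: float
    random_effect_lrt_stat: float
    random_effect_p: float
    n_obs: int
    n_groups: int


class _RandomInterceptREML:
    """Closed-form profiled REML pieces for a random-intercept model."""

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        order = np.argsort(groups, kind="stable")
        self.y = y[order]
        self.X = X[order]
        _, counts = np.unique(groups[order], return_counts=True)
        self.counts = counts
        self.slices = np.concatenate([[0], np.cumsum(counts)])

    def _per_group(self, sb2: float, se2: float):
        """Yield (y_g, X_g, n_g, lam_g) with lam = sb2/(se2 + n sb2)."""
        for i, n_g in enumerate(self.counts):
            s = slice(self.slices[i], self.slices[i + 1])
            yield self.y[s], self.X[s], n_g, sb2 / (se2 + n_g * sb2)

    def gls_beta(self, sb2: float, se2: float) -> np.ndarray:
        """Generalised-least-squares fixed effects at given variances."""
        p = self.X.shape[1]
        xtvix = np.zeros((p, p))
        xtviy = np.zeros(p)
        for y_g, X_g, n_g, lam in self._per_group(sb2, se2):
            xs, ys = X_g.sum(axis=0), y_g.sum()
            xtvix += (X_g.T @ X_g - lam * np.outer(xs, xs)) / se2
            xtviy += (X_g.T @ y_g - lam * xs * ys) / se2
        return np.linalg.solve(xtvix, xtviy)

    def fit_reml(self) -> tuple[float, float]:
        """Maximise the profiled REML likelihood over the two variances."""
        from scipy.optimize import minimize

        beta, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        resid = self.y - self.X @ beta
        s2 = float(resid @ resid) / max(len(self.y) - self.X.shape[1], 1)

        def neg(log_theta):
            return -self.loglike(np.exp(log_theta[0]), np.exp(log_theta[1]))

        best = None
        for frac in (0.5, 0.05):
            x0 = np.log([max(s2 * frac, 1e-12), max(s2 * (1 - frac), 1e-12)])
            res = minimize(neg, x0, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
            if best is None or res.fun < best.fun:
                best = res
        sb2, se2 = np.exp(best.x)
        # collapse a vanishing random intercept to the boundary
        if sb2 < 1e-10 * se2:
            sb2 = 0.0
        return float(sb2), float(se2)

    def xtvix_inv(self, sb2: float, se2: float) -> np.ndarray:
        """(X' V^-1 X)^-1 — the fixed-effect covariance at these variances."""
        p = self.X.shape[1]
        xtvix = np.zeros((p, p))
        for y_g, X_g, n_g, lam in self._per_group(sb2, se2):
            xs = X_g.sum(axis=0)
            xtvix += (X_g.T @ X_g - lam * np.outer(xs, xs)) / se2
        return np.linalg.inv(xtvix)

    def ml_loglike(self, sb2: float, se2: float) -> float:
        """Profiled (over beta) ML log-likelihood, constants included."""
        n = len(self.y)
        p = self.X.shape[1]
        xtvix = np.zeros((p, p))
        xtviy = np.zeros(p)
        quad = 0.0
        logdet = 0.0
        for y_g, X_g, n_g, lam in self._per_group(sb2, se2):
            xs, ys = X_g.sum(axis=0), y_g.sum()
            xtvix += (X_g.T @ X_g - lam * np.outer(xs, xs)) / se2
            xtviy += (X_g.T @ y_g - lam * xs * ys) / se2
            quad += (y_g @ y_g - lam * ys * ys) / se2
            logdet += (n_g - 1) * np.log(se2) + np.log(se2 + n_g * sb2)
        beta = np.linalg.solve(xtvix, xtviy)
        resid_quad = quad - xtviy @ beta
        return -0.5 * (n * np.log(2.0 * np.pi) + logdet + resid_quad)

    def loglike(self, sb2: float, se2: float) -> float:
        """Profiled REML log-likelihood (additive constant dropped)."""
        p = self.X.shape[1]
        xtvix = np.zeros((p, p))
        xtviy = np.zeros(p)
        quad = 0.0
        logdet = 0.0
        for y_g, X_g, n_g, lam in self._per_group(sb2, se2):
            xs, ys = X_g.sum(axis=0), y_g.sum()
            xtvix += (X_g.T @ X_g - lam * np.outer(xs, xs)) / se2
            xtviy += (X_g.T @ y_g - lam * xs * ys) / se2
            quad += (y_g @ y_g - lam * ys * ys) / se2
            logdet += (n_g - 1) * np.log(se2) + np.log(se2 + n_g * sb2)
        beta = np.linalg.solve(xtvix, xtviy)
        resid_quad = quad - xtviy @ beta
        sign, ld_x = np.linalg.slogdet(xtvix)
        return -0.5 * (logdet + ld_x + resid_quad)


def _satterthwaite_df(
    reml: _RandomInterceptREML, sb2: float, se2: float
) -> np.ndarray:
    """Satterthwaite df per coefficient via the delta method.

    df_i = 2 g_i^2 / (grad g_i' A grad g_i) with g_i the i-th diagonal of
    the fixed-effect covariance as a function of the variance components and
    A the inverse observed REML information, both from finite differences of
    the closed-form profiled likelihood.
    """
    theta = np.array([sb2, se2])
    steps = np.maximum(1e-8, 1e-4 * np.maximum(theta, se2))

    def cov_diag(t):
        return np.diag(reml.xtvix_inv(max(t[0], 0.0), max(t[1], 1e-12)))

    grads = []
    for i in range(2):
        up, dn = theta.copy(), theta.copy()
        up[i] += steps[i]
        dn[i] = max(dn[i] - steps[i], 0.0 if i == 0 else 1e-12)
        grads.append((cov_diag(up) - cov_diag(dn)) / (up[i] - dn[i]))
    grad = np.column_stack(grads)  # (p, 2)

    def ll(t):
        return reml.loglike(max(t[0], 0.0), max(t[1], 1e-12))

    hess = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            ti, tj = steps[i], steps[j]
            pp = theta + np.eye(2)[i] * ti + np.eye(2)[j] * tj
            pm = theta + np.eye(2)[i] * ti - np.eye(2)[j] * tj
            mp = theta - np.eye(2)[i] * ti + np.eye(2)[j] * tj
            mm = theta - np.eye(2)[i] * ti - np.eye(2)[j] * tj
            hess[i, j] = (ll(pp) - ll(pm) - ll(mp) + ll(mm)) / (4 * ti * tj)
    try:
        var_theta = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        var_theta = np.full((2, 2), np.nan)
    g = cov_diag(theta)
    denom = np.einsum("pi,ij,pj->p", grad, var_theta, grad)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = 2.0 * g**2 / denom
    n_resid = len(reml.y) - reml.X.shape[1]
    return np.clip(np.where(np.isfinite(df) & (df > 1), df, n_resid), 1.0, n_resid)


def fit_movement_sum_model(table: pd.DataFrame) -> MixedModelFit:
    """REML fit of the distance-travelled mixed model.

    Requires at least two observations per cricket so the random intercept is
    identified.  Returns the coefficient table (estimate, standard error,
    Satterthwaite-type df, t, p), a Wald F table per model term, the two
    variance components and a boundary likelihood-ratio test of the random
    intercept against the fixed-effects-only model.
    """
    required = {"movementSum", "temperature_category", "tag_weight_mg",
                "animal_weight_mg", "cricket_id"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")
    counts = table.groupby("cricket_id").size()
    if (counts < 2).all():
        raise ValueError("random intercept unidentified: one observation per cricket")

    model = smf.ols(FORMULA, data=table)
    X = np.asarray(model.exog, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "rank-deficient fixed-effect design; check that every temperature "
            "level contains both tagged and untagged crickets"
        )
    reml = _RandomInterceptREML(
        np.asarray(model.endog, dtype=float), X, table["cricket_id"].to_numpy()
    )
    sb2, se2 = reml.fit_reml()
    beta = reml.gls_beta(sb2, se2)
    cov_beta = reml.xtvix_inv(sb2, se2)
    se_beta = np.sqrt(np.diag(cov_beta))
    df = _satterthwaite_df(reml, sb2, se2)
    tvals = beta / se_beta
    pvals = 2.0 * sps.t.sf(np.abs(tvals), df)
    labels = [_TERM_LABELS.get(name, name) for name in model.exog_names]
    coefficients = pd.DataFrame(
        {
            "term": labels,
            "Estimate": beta,
            "Std. Error": se_beta,
            "df": df,
            "t value": tvals,
            "Pr(>|t|)": pvals,
        }
    )

    anova = _wald_anova(coefficients, cov_beta, labels, beta)

    lrt_stat, lrt_p = _random_effect_lrt(reml, sb2, se2)

    return MixedModelFit(
        coefficients=coefficients,
        anova=anova,
        random_intercept_variance=sb2,
        residual_variance=se2,
        random_effect_lrt_stat=lrt_stat,
        random_effect_p=lrt_p,
        n_obs=len(table),
        n_groups=table["cricket_id"].nunique(),
    )


def _wald_anova(coefficients, cov_beta, labels, beta) -> pd.DataFrame:
    rows = []
    for term, members in _ANOVA_TERMS.items():
        idx = [labels.index(m) for m in members if m in labels]
        if not idx:
            continue
        L = np.zeros((len(idx), len(beta)))
        for r, i in enumerate(idx):
            L[r, i] = 1.0
        lb = L @ beta
        lcov = L @ cov_beta @ L.T
        f_stat = float(lb @ np.linalg.solve(lcov, lb)) / len(idx)
        df_den = float(
            np.mean([coefficients["df"].iloc[i] for i in idx])
        )  # approximate: mean Satterthwaite df of the member contrasts
        rows.append(
            {
                "term": term,
                "F": f_stat,
                "df_num": len(idx),
                "df_den": df_den,
                "p": float(sps.f.sf(f_stat, len(idx), df_den)),
            }
        )
    return pd.DataFrame(rows)


def _random_effect_lrt(
    reml: _RandomInterceptREML, sb2: float, se2: float
) -> tuple[float, float]:
    """Boundary LRT of the random intercept: 0.5 chi2_0 + 0.5 chi2_1 mixture.

    Both the alternative (sb2 free) and the null (sb2 = 0, i.e. ordinary
    least squares) are maximised by ML on the closed-form profiled
    likelihood; the REML estimates only seed the optimiser.
    """
    from scipy.optimize import minimize

    def neg_ll(log_theta):
        return -reml.ml_loglike(np.exp(log_theta[0]), np.exp(log_theta[1]))

    x0 = np.log(np.maximum([sb2, se2], 1e-10))
    alt = minimize(neg_ll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10})
    # null: no random intercept -> plain OLS with sigma2 = RSS / n
    beta, *_ = np.linalg.lstsq(reml.X, reml.y, rcond=None)
    rss = float(np.sum((reml.y - reml.X @ beta) ** 2))
    n = len(reml.y)
    ll0 = -0.5 * n * (np.log(2.0 * np.pi) + np.log(rss / n) + 1.0)
    stat = float(max(0.0, 2.0 * (-alt.fun - ll0)))
    p = 0.5 * float(sps.chi2.sf(stat, 1)) if stat > 0 else 1.0
    return stat, p


def distance_reduction_per_100mg(
    coefficients: pd.DataFrame, temperature: str = "low"
) -> float:
    """Distance lost per 100 mg of tag at a given temperature (metres).

    The tag-weight slope at temperature level T is the main effect plus the
    T:tag-weight interaction (zero at the reference level, intermediate);
    the reported reduction is its magnitude over a 100-mg increment.
    """
    terms = coefficients.set_index("term")["Estimate"]
    if "tag weight" not in terms.index:
        raise KeyError("coefficient table lacks the 'tag weight' main effect")
    slope = float(terms["tag weight"])
    if temperature != REFERENCE_TEMPERATURE:
        inter = f"{temperature} temperature:tag weight"
        if inter not in terms.index:
            raise KeyError(f"coefficient table lacks {inter!r}")
        slope += float(terms[inter])
    return abs(slope) * 100.0


def simulate_movement_sum(
    covariates: pd.DataFrame,
    coefficients: dict[str, float],
    random_intercept_sd: float,
    residual_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Draw movementSum from the model's own generative formula.

    ``covariates`` needs cricket_id, temperature_category, tag_weight_mg and
    animal_weight_mg; ``coefficients`` maps report labels (as in the fitted
    coefficient table) to true values.  Used for parameter-recovery checks.
    """
    rng = np.random.default_rng(seed)
    out = covariates.copy()
    high = (out["temperature_category"] == "high").astype(float).to_numpy()
    low = (out["temperature_category"] == "low").astype(float).to_numpy()
    tag = out["tag_weight_mg"].to_numpy(dtype=float)
    animal = out["animal_weight_mg"].to_numpy(dtype=float)
    c = {k: coefficients.get(k, 0.0) for k in _TERM_LABELS.values()}
    mean = (
        c["(Intercept)"]
        + c["high temperature"] * high
        + c["low temperature"] * low
        + c["tag weight"] * tag
        + c["animal weight"] * animal
        + c["high temperature:tag weight"] * high * tag
        + c["low temperature:tag weight"] * low * tag
        + c["high temperature:animal weight"] * high * animal
        + c["low temperature:animal weight"] * low * animal
    )
    ids = out["cricket_id"].to_numpy()
    unique_ids = pd.unique(ids)
    intercepts = dict(
        zip(unique_ids, rng.normal(0.0, random_intercept_sd, size=len(unique_ids)))
    )
    out["movementSum"] = (
        mean
        + np.array([intercepts[i] for i in ids])
        + rng.normal(0.0, residual_sd, size=len(out))
    )
    return out
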