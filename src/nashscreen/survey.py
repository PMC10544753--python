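"""Design-based estimation for stratified multi-PSU survey samples.

Implements the estimators a complex-survey analysis of a stratified
multistage sample needs: weighted prevalence with Taylor-linearized
standard errors, direct age standardization against a fixed standard
population, the first-order Rao–Scott design-corrected chi-square test of
independence, and survey-weighted multinomial logistic regression with a
linearized sandwich covariance.

Variance estimation throughout treats the first-stage sampling units
(PSUs) as independent within strata ("ultimate cluster" assumption):
for per-subject linearized contributions :math:`z_i`, the estimator of
the covariance of their total is

.. math::
    \\hat V = \\sum_h \\frac{n_h}{n_h - 1}
              \\sum_j (t_{hj} - \\bar t_h)(t_{hj} - \\bar t_h)^\\top

with :math:`t_{hj}` the contribution total of PSU *j* in stratum *h*.
Degrees of freedom follow the usual survey convention
``#PSUs − #strata``.  Every point estimate is invariant to rescaling all
weights by a constant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurveyDesign",
    "SurveyEstimate",
    "StandardPopulation",
    "MultinomialResult",
    "STD_US_2000",
    "STD_US_1990",
    "weighted_prevalence",
    "direct_standardize",
    "rao_scott_chi2",
    "build_design_matrix",
    "fit_weighted_multinomial",
    "odds_ratio_table",
]

logger = logging.getLogger(__name__)

OUTCOME_LEVELS = ("normal_mild", "simple_nafld", "nash")


@dataclass
class SurveyDesign:
    """Stratum, PSU, and sampling weight for each subject."""

    stratum: np.ndarray
    psu: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        self.stratum = np.asarray(self.stratum)
        self.psu = np.asarray(self.psu)
        self.weight = np.asarray(self.weight, dtype=float)
        if not (len(self.stratum) == len(self.psu) == len(self.weight)):
            raise ValueError("design arrays must have equal length")
        if (self.weight <= 0).any() or np.isnan(self.weight).any():
            raise ValueError("weights must be positive and non-missing")
        combo = pd.DataFrame({"s": self.stratum, "p": self.psu})
        per = combo.groupby("s", observed=True)["p"].nunique()
        if (per < 2).any():
            bad = per.index[per < 2][0]
            raise ValueError(
                f"stratum {bad!r} has fewer than 2 PSUs; design-based variance undefined"
            )
        self._cell = pd.MultiIndex.from_arrays([self.stratum, self.psu])

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame) -> "SurveyDesign":
        return cls(
            cohort["stratum"].to_numpy(),
            cohort["psu"].to_numpy(),
            cohort["weight"].to_numpy(dtype=float),
        )

    def __len__(self) -> int:
        return len(self.weight)

    @property
    def n_strata(self) -> int:
        return len(np.unique(self.stratum))

    @property
    def n_psus(self) -> int:
        return len(set(zip(self.stratum, self.psu)))

    @property
    def df(self) -> int:
        return self.n_psus - self.n_strata

    def linearized_cov(self, z: np.ndarray) -> np.ndarray:
        """Covariance of the total of per-subject contributions ``z`` (n × p)."""
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.shape[0] != len(self):
            z = z.T
        frame = pd.DataFrame(z)
        frame["_s"] = self.stratum
        frame["_p"] = self.psu
        totals = frame.groupby(["_s", "_p"], observed=True).sum()
        p = z.shape[1]
        V = np.zeros((p, p))
        for _, t in totals.groupby(level=0, observed=True):
            arr = t.to_numpy(dtype=float)
            nh = arr.shape[0]
            dev = arr - arr.mean(axis=0)
            V += (nh / (nh - 1)) * dev.T @ dev
        return V


@dataclass(frozen=True)
class SurveyEstimate:
    """Weighted point estimate with design-based SE and confidence interval."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    df: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("confidence interval must bracket the estimate")


@dataclass(frozen=True)
class StandardPopulation:
    """Age-group proportions of a fixed standard population."""

    proportions: dict[str, float]
    label: str = ""

    def __post_init__(self) -> None:
        vals = np.array(list(self.proportions.values()), dtype=float)
        if (vals < 0).any():
            raise ValueError("standard-population proportions must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-12:
            raise ValueError("standard-population proportions must sum to 1 within 1e-12")


def _std_from_counts(counts: dict[str, float], label: str) -> StandardPopulation:
    total = sum(counts.values())
    return StandardPopulation({k: v / total for k, v in counts.items()}, label)


# US 2000 standard million (ages 20-74, the four analysis age groups).
STD_US_2000 = _std_from_counts(
    {"20_34": 202_052, "35_49": 234_731, "50_64": 149_963, "65_plus": 66_037},
    "US 2000 standard million, ages 20-74",
)
# 1990 US census resident population, same age groups (thousands).
STD_US_1990 = _std_from_counts(
    {"20_34": 62_196, "35_49": 51_451, "50_64": 32_498, "65_plus": 18_107},
    "US 1990 census, ages 20-74",
)


def weighted_prevalence(flags, design: SurveyDesign) -> SurveyEstimate:
    """Design-weighted prevalence of a boolean trait.

    Point estimate is the Hájek ratio ``Σ wᵢ yᵢ / Σ wᵢ``; the SE comes
    from Taylor linearization of the ratio over strata and PSUs, and the
    95% CI is constructed on the logit scale and back-transformed (which
    keeps it inside [0, 1]).
    """
    y = np.asarray(flags, dtype=float)
    if len(y) != len(design):
        raise ValueError("flags and design are not aligned")
    w = design.weight
    W = w.sum()
    p = float(np.sum(w * y) / W)
    z = (w * (y - p) / W)[:, None]
    var = float(design.linearized_cov(z)[0, 0])
    se = float(np.sqrt(max(var, 0.0)))
    dof = design.df
    if se == 0.0 or p <= 0.0 or p >= 1.0:
        lo = hi = p
    else:
        tq = stats.t.ppf(0.975, dof)
        logit = np.log(p / (1 - p))
        se_logit = se / (p * (1 - p))
        lo = float(1 / (1 + np.exp(-(logit - tq * se_logit))))
        hi = float(1 / (1 + np.exp(-(logit + tq * se_logit))))
    return SurveyEstimate(p, se, lo, hi, dof)


def direct_standardize(
    stratum_prevalence: dict[str, float] | pd.Series,
    std: StandardPopulation,
) -> float:
    """Directly standardized prevalence: Σ_g std(g) · prevalence(g)."""
    prev = dict(stratum_prevalence)
    if set(prev) != set(std.proportions):
        raise ValueError(
            f"age groups differ: {sorted(prev)} vs {sorted(std.proportions)}"
        )
    return float(sum(std.proportions[g] * prev[g] for g in prev))


def rao_scott_chi2(
    rows,
    cols,
    design: SurveyDesign,
    design_correction: bool = True,
) -> tuple[float, int, float]:
    """Test of independence on a weighted contingency table.

    Returns ``(statistic, df, p_value)``.  The statistic is the Pearson
    chi-square computed from the design-weighted cell proportions (scaled
    by the number of subjects); with ``design_correction`` the first-order
    Rao–Scott correction divides it by the mean generalized design effect
    estimated from the linearized covariance of the cell and marginal
    proportions.  With equal weights and no correction the statistic is
    exactly the classical Pearson value.
    """
    r = pd.Series(np.asarray(rows), name="r")
    c = pd.Series(np.asarray(cols), name="c")
    keep = r.notna() & c.notna()
    r, c = r[keep], c[keep]
    w = design.weight[keep.to_numpy()]
    n = len(r)

    tab = pd.crosstab(r, c, values=w, aggfunc="sum").fillna(0.0)
    empty_rows = tab.sum(axis=1) == 0
    empty_cols = tab.sum(axis=0) == 0
    if empty_rows.any() or empty_cols.any():
        warnings.warn("empty row/column after weighting; collapsing table")
        tab = tab.loc[~empty_rows, ~empty_cols]
    R, C = tab.shape
    if R < 2 or C < 2:
        raise ValueError("need at least 2 levels in each dimension")

    P = tab.to_numpy() / tab.to_numpy().sum()
    pr, pc = P.sum(axis=1), P.sum(axis=0)
    expected = np.outer(pr, pc)
    x2 = float(n * np.sum((P - expected) ** 2 / expected))
    ddf = (R - 1) * (C - 1)

    if not design_correction:
        return x2, ddf, float(stats.chi2.sf(x2, ddf))

    # Linearized variances of cell and marginal proportion estimators.
    row_levels, col_levels = list(tab.index), list(tab.columns)
    rmat = np.column_stack([(r == lv).to_numpy(dtype=float) for lv in row_levels])
    cmat = np.column_stack([(c == lv).to_numpy(dtype=float) for lv in col_levels])
    sub_design = SurveyDesign(
        design.stratum[keep.to_numpy()], design.psu[keep.to_numpy()], w
    )
    W = w.sum()

    def ratio_vars(ind: np.ndarray, phat: np.ndarray) -> np.ndarray:
        z = w[:, None] * (ind - phat) / W
        return np.diag(sub_design.linearized_cov(z))

    cell_ind = np.einsum("ni,nj->nij", rmat, cmat).reshape(n, R * C)
    v_cell = ratio_vars(cell_ind, P.reshape(-1)).reshape(R, C)
    v_row = ratio_vars(rmat, pr)
    v_col = ratio_vars(cmat, pc)

    trace = (
        n * np.sum(v_cell / expected)
        - n * np.sum(v_row / pr)
        - n * np.sum(v_col / pc)
    )
    delta_bar = max(trace / ddf, 1e-12)
    x2_rs = x2 / delta_bar
    return x2_rs, ddf, float(stats.chi2.sf(x2_rs, ddf))


# --------------------------------------------------------------------------
# survey-weighted multinomial logistic regression
# --------------------------------------------------------------------------

def build_design_matrix(
    data: pd.DataFrame,
    covariates: list[str],
    reference: dict[str, str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Dummy-coded design matrix with intercept.

    Categorical covariates are expanded against the given reference level
    (default: the level's first sorted value).  Raises on zero-variation
    or rank-deficient columns, naming the offender.
    """
    reference = reference or {}
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for cov in covariates:
        ser = data[cov]
        if ser.isna().any():
            raise ValueError(f"covariate {cov!r} has missing values; listwise-delete first")
        if ser.dtype.kind in "biufc" and ser.nunique() > 2:
            if ser.nunique() <= 1:
                raise ValueError(f"covariate {cov!r} has no variation")
            cols.append(ser.to_numpy(dtype=float))
            names.append(cov)
            continue
        levels = sorted(ser.astype(str).unique())
        if len(levels) < 2:
            raise ValueError(f"covariate {cov!r} has no variation")
        ref = reference.get(cov, levels[0])
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not observed for {cov!r}")
        for lv in levels:
            if lv == ref:
                continue
            cols.append((ser.astype(str) == lv).to_numpy(dtype=float))
            names.append(f"{cov}={lv}")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a culprit column by incremental rank
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) < j + 1:
                raise ValueError(f"design matrix rank-deficient at column {names[j]!r}")
    return X, names


@dataclass
class MultinomialResult:
    """Fit of a baseline-category multinomial logit under a survey design."""

    levels: tuple[str, ...]            # levels[0] is the reference
    param_names: list[str]
    coef: np.ndarray                   # (K-1, p)
    cov: np.ndarray                    # ((K-1)p, (K-1)p) sandwich
    df: int
    n_obs: int
    n_iter: int
    gradient_norm: float
    loglik: float = field(default=np.nan)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov)).reshape(self.coef.shape)

    def or_table(self, alpha: float = 0.05) -> pd.DataFrame:
        """Tidy odds-ratio table: one row per non-reference level per term."""
        tq = stats.t.ppf(1 - alpha / 2, self.df) if self.df > 0 else stats.norm.ppf(1 - alpha / 2)
        rows = []
        se = self.se
        for k, level in enumerate(self.levels[1:]):
            for j, name in enumerate(self.param_names):
                b, s = self.coef[k, j], se[k, j]
                tstat = b / s if s > 0 else np.inf
                pval = 2 * stats.t.sf(abs(tstat), self.df) if self.df > 0 else 2 * stats.norm.sf(abs(tstat))
                rows.append(
                    {
                        "outcome": level,
                        "term": name,
                        "coef": b,
                        "se": s,
                        "or": np.exp(b),
                        "ci_low": np.exp(b - tq * s),
                        "ci_high": np.exp(b + tq * s),
                        "p_value": pval,
                    }
                )
        return pd.DataFrame(rows)


def _softmax_probs(X: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Class probabilities (n × K) with baseline level first."""
    eta = X @ B.T                                   # (n, K-1)
    eta = np.column_stack([np.zeros(len(X)), eta])
    eta -= eta.max(axis=1, keepdims=True)
    e = np.exp(eta)
    return e / e.sum(axis=1, keepdims=True)


def fit_weighted_multinomial(
    outcome,
    X: np.ndarray,
    design: SurveyDesign,
    param_names: list[str] | None = None,
    levels: tuple[str, ...] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> MultinomialResult:
    """Weighted multinomial logit by Newton–Raphson with sandwich covariance.

    Maximizes the pseudo-log-likelihood ``Σ wᵢ log pᵢ(yᵢ)`` for a
    baseline-category logit (first level of ``levels`` is the reference),
    iterating Newton steps with step-halving until the gradient's max
    norm falls below ``tol``.  The covariance is the design-based sandwich
    ``H⁻¹ G H⁻¹`` with the score totals linearized over strata/PSUs, and
    confidence intervals downstream use ``df = #PSUs − #strata``.
    """
    y = pd.Series(np.asarray(outcome))
    X = np.asarray(X, dtype=float)
    if levels is None:
        observed = list(pd.unique(y))
        levels = tuple(lv for lv in OUTCOME_LEVELS if lv in observed) or tuple(sorted(observed))
    observed_levels = [lv for lv in levels if (y == lv).any()]
    if len(observed_levels) < 2:
        raise ValueError("outcome must have at least 2 observed levels")
    levels = tuple(observed_levels)
    K = len(levels)
    n, p = X.shape
    if param_names is None:
        param_names = [f"x{j}" for j in range(p)]
    Y = np.column_stack([(y == lv).to_numpy(dtype=float) for lv in levels])
    if not np.all(Y.sum(axis=1) == 1):
        raise ValueError("outcome contains labels outside the declared levels")
    w = design.weight

    B = np.zeros((K - 1, p))

    def loglik(Bm):
        P = _softmax_probs(X, Bm)
        return float(np.sum(w * np.log(np.clip((P * Y).sum(axis=1), 1e-300, None))))

    ll = loglik(B)
    g_norm = np.inf
    for it in range(1, max_iter + 1):
        P = _softmax_probs(X, B)
        resid = Y[:, 1:] - P[:, 1:]                     # (n, K-1)
        grad = (X * w[:, None]).T @ resid               # (p, K-1)
        g = grad.T.reshape(-1)                          # level-major
        g_norm = float(np.max(np.abs(g)))
        if g_norm < tol:
            break
        H = np.zeros(((K - 1) * p, (K - 1) * p))
        for a in range(K - 1):
            for b in range(a, K - 1):
                pa, pb = P[:, a + 1], P[:, b + 1]
                wab = w * (pa * ((a == b) - pb))
                block = X.T @ (X * wab[:, None])
                H[a * p:(a + 1) * p, b * p:(b + 1) * p] = block
                if a != b:
                    H[b * p:(b + 1) * p, a * p:(a + 1) * p] = block
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"singular Hessian at iteration {it}") from exc
        scale = 1.0
        for _ in range(30):
            Bnew = B + scale * step.reshape(K - 1, p)
            llnew = loglik(Bnew)
            if llnew >= ll - 1e-10:
                break
            scale /= 2.0
        B, ll = Bnew, llnew
    else:
        raise RuntimeError(
            f"Newton did not converge in {max_iter} iterations "
            f"(gradient max-norm {g_norm:.3e})"
        )

    if np.any(np.abs(B) > 15):
        logger.warning("possible separation: |coefficient| > 15 detected")

    # sandwich covariance with linearized score totals
    P = _softmax_probs(X, B)
    resid = Y[:, 1:] - P[:, 1:]
    scores = np.einsum("nk,np->nkp", resid * w[:, None], X).reshape(n, (K - 1) * p)
    G = design.linearized_cov(scores)
    H = np.zeros(((K - 1) * p, (K - 1) * p))
    for a in range(K - 1):
        for b in range(a, K - 1):
            pa, pb = P[:, a + 1], P[:, b + 1]
            wab = w * (pa * ((a == b) - pb))
            block = X.T @ (X * wab[:, None])
            H[a * p:(a + 1) * p, b * p:(b + 1) * p] = block
            if a != b:
                H[b * p:(b + 1) * p, a * p:(a + 1) * p] = block
    Hinv = np.linalg.inv(H)
    cov = Hinv @ G @ Hinv

    return MultinomialResult(
        levels=levels,
        param_names=param_names,
        coef=B,
        cov=cov,
        df=design.df,
        n_obs=n,
        n_iter=it,
        gradient_norm=g_norm,
        loglik=ll,
    )


def odds_ratio_table(
    data: pd.DataFrame,
    outcome_col: str,
    covariates: list[str],
    design: SurveyDesign,
    reference: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Unadjusted and adjusted odds ratios, one tidy row per contrast.

    Unadjusted ORs come from refitting with each covariate alone; the
    adjusted fit includes all covariates jointly.  Rows missing any
    covariate or the outcome are listwise-deleted (for both fits alike,
    so the two columns describe the same subjects).
    """
    keep = data[[outcome_col] + covariates].notna().all(axis=1).to_numpy()
    sub = data.loc[keep]
    subd = SurveyDesign(design.stratum[keep], design.psu[keep], design.weight[keep])

    Xa, names_a = build_design_matrix(sub, covariates, reference)
    adj = fit_weighted_multinomial(sub[outcome_col], Xa, subd, names_a)
    adj_tab = adj.or_table().rename(
        columns={"or": "aor", "ci_low": "aor_ci_low", "ci_high": "aor_ci_high",
                 "p_value": "aor_p"}
    )[["outcome", "term", "aor", "aor_ci_low", "aor_ci_high", "aor_p"]]

    unadj_rows = []
    for cov in covariates:
        Xu, names_u = build_design_matrix(sub, [cov], reference)
        una = fit_weighted_multinomial(sub[outcome_col], Xu, subd, names_u)
        t = una.or_table()
        unadj_rows.append(t[t["term"] != "intercept"])
    unadj_tab = pd.concat(unadj_rows, ignore_index=True).rename(
        columns={"or": "or", "ci_low": "or_ci_low", "ci_high": "or_ci_high",
                 "p_value": "or_p"}
    )[["outcome", "term", "or", "or_ci_low", "or_ci_high", "or_p"]]

    merged = adj_tab[adj_tab["term"] != "intercept"].merge(
        unadj_tab, on=["outcome", "term"], how="left"
    )
    return merged[
        ["outcome", "term", "or", "or_ci_low", "or_ci_high", "or_p",
         "aor", "aor_ci_low", "aor_ci_high", "aor_p"]
    ]
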