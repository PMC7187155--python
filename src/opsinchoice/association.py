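"""Mixed-model association stage.

`AssociationModel` reproduces the analysis protocol used throughout the
study: the optimal random-intercept structure is chosen by REML AIC over
all subsets of the candidate grouping factors (with continuous nuisance
covariates such as age competing in the same comparison), fixed effects
are then tested by maximum-likelihood likelihood-ratio tests with
backward elimination (respecting marginality) down to the minimum
adequate model (MAM), and factor effects are summarised by single-step
multiplicity-adjusted pairwise contrasts (the max-|z| analogue of
Tukey's test, computed from the multivariate-normal distribution of the
contrast statistics).

The LRT statistic is Bartlett-scaled by (n - p_full)/n by default: for
Gaussian fixed-effects models this is the monotone transform of the
exact F test, removing the well-known small-sample liberality of the
plain chi-square LRT (pass ``correction="none"`` for the uncorrected
statistic).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

ALPHA = 0.05


# ---------------------------------------------------------------------------
# fixed-effect term algebra

def expand_terms(rhs: str) -> list:
    """Expand a model formula right-hand side into interaction terms.

    '*' expands to all non-empty factor subsets, ':' denotes a single
    interaction, '+' separates components.  Terms are frozensets of
    factor names, ordered by (order, appearance).
    """
    terms, order = [], {}
    for chunk in rhs.split("+"):
        chunk = chunk.strip()
        if not chunk or chunk == "1":
            continue
        if "*" in chunk:
            factors = [f.strip() for f in chunk.split("*")]
            new = [frozenset(c) for r in range(1, len(factors) + 1)
                   for c in itertools.combinations(factors, r)]
        elif ":" in chunk:
            new = [frozenset(f.strip() for f in chunk.split(":"))]
        else:
            new = [frozenset([chunk])]
        for t in new:
            if t not in order:
                order[t] = len(order)
                terms.append(t)
    return sorted(terms, key=lambda t: (len(t), order[t]))


def terms_to_formula(response: str, terms, extra=()) -> str:
    parts = [":".join(sorted(t)) for t in terms] + list(extra)
    rhs = " + ".join(parts) if parts else "1"
    return f"{response} ~ {rhs}"


def droppable_terms(terms) -> list:
    """Terms not nested inside any higher-order term (marginality)."""
    return [t for t in terms
            if not any(t < other for other in terms if other != t)]


# ---------------------------------------------------------------------------
# fitting engine

@dataclass
class _Fit:
    result: object
    llf: float
    k_fixed: int
    n_vc: int
    n_obs: int
    converged: bool
    reml: bool

    @property
    def aic(self) -> float:
        # manual AIC: statsmodels reports NaN for REML mixed fits
        k = self.k_fixed + self.n_vc + 1
        return -2.0 * self.llf + 2.0 * k


def _fit_lmm(data: pd.DataFrame, formula: str, random_terms=(),
             reml: bool = True) -> _Fit:
    """Fit a Gaussian model with crossed random intercepts.

    Random terms are fitted as variance components over a single
    all-encompassing group (the standard device for crossed random
    intercepts); with no random terms the model reduces to OLS.
    """
    random_terms = tuple(random_terms)
    if not random_terms:
        res = smf.ols(formula, data).fit()
        return _Fit(res, float(res.llf), int(res.df_model) + 1, 0,
                    int(res.nobs), True, reml)
    df = data.copy()
    df["_one"] = 1
    vc = {t: f"0 + C({t})" for t in random_terms}
    # individual optimizers occasionally stop at a false optimum while
    # reporting convergence, so fit with several and keep the best llf
    res = None
    err = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula(formula, df, groups="_one",
                                        vc_formula=vc, re_formula="0")
        for method in ("bfgs", "powell", "lbfgs"):
            try:
                cand = model.fit(reml=reml, method=method)
            except (np.linalg.LinAlgError, ValueError, OverflowError) as e:
                err = e
                continue
            if not np.isfinite(cand.llf):
                continue
            if res is None or cand.llf > res.llf + 1e-8:
                res = cand
    if res is None:
        raise np.linalg.LinAlgError(
            f"mixed-model fit failed for {formula!r}: {err}")
    converged = bool(getattr(res, "converged", False))
    return _Fit(res, float(res.llf), len(res.fe_params), len(random_terms),
                int(res.nobs), converged, reml)


def lrt(full: _Fit, reduced: _Fit, correction: str = "bartlett"):
    """Likelihood-ratio test of nested ML fits -> (stat, df, p).

    ``correction="bartlett"`` scales the statistic by (n - p_full)/n,
    the exact-F-equivalent calibration for Gaussian models.
    """
    stat = 2.0 * (full.llf - reduced.llf)
    df = full.k_fixed - reduced.k_fixed
    if df <= 0:
        raise ValueError("models are not strictly nested in the fixed part")
    if correction == "bartlett":
        stat *= max(full.n_obs - full.k_fixed, 1) / full.n_obs
    stat = max(stat, 0.0)
    return stat, df, float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# Model / Results

class AssociationModel:
    """Mixed-model workflow for one response.

    Parameters
    ----------
    data : analysis table (one row per observation).
    response : response column name.
    fixed : fixed-part formula RHS, e.g. ``"rearing_light*species*sex"``.
    random_candidates : grouping-factor columns competing (as random
        intercepts) in the AIC structure selection.
    covariate_candidates : continuous nuisance columns (e.g. age)
        competing in the same AIC comparison as protected fixed terms.
    alpha : significance level of the backward elimination.
    correction : LRT small-sample correction ('bartlett' or 'none').
    """

    def __init__(self, data: pd.DataFrame, response: str, fixed: str,
                 random_candidates=(), covariate_candidates=(),
                 alpha: float = ALPHA, correction: str = "bartlett"):
        self.data = data.reset_index(drop=True)
        self.response = response
        self.fixed_terms = expand_terms(fixed)
        self.random_candidates = tuple(random_candidates)
        self.covariate_candidates = tuple(covariate_candidates)
        self.alpha = alpha
        self.correction = correction
        if response not in data.columns:
            raise ValueError(f"response {response!r} not in data")
        for t in self.fixed_terms:
            for f in t:
                if f not in data.columns:
                    raise ValueError(f"model factor {f!r} not in data")
                if data[f].nunique() < 2:
                    raise ValueError(f"factor {f!r} has < 2 observed levels")

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame, **kw):
        lhs, rhs = formula.split("~")
        return cls(data, lhs.strip(), rhs.strip(), **kw)

    # -- random structure -------------------------------------------------

    def select_random_structure(self):
        """All-subsets REML AIC comparison of the candidate structures.

        The full fixed part is held constant.  Ties break toward fewer
        terms; if every candidate with random terms fails to converge the
        no-random-terms structure is returned with a warning.
        """
        full = terms_to_formula(self.response, self.fixed_terms)
        rows = []
        best = None
        rand_subsets = [tuple(c) for r in range(len(self.random_candidates) + 1)
                        for c in itertools.combinations(self.random_candidates, r)]
        cov_subsets = [tuple(c) for r in range(len(self.covariate_candidates) + 1)
                       for c in itertools.combinations(self.covariate_candidates, r)]
        for rand in rand_subsets:
            for cov in cov_subsets:
                formula = terms_to_formula(self.response, self.fixed_terms, cov)
                try:
                    fit = _fit_lmm(self.data, formula, rand, reml=True)
                    ok = fit.converged and np.isfinite(fit.llf)
                except (np.linalg.LinAlgError, ValueError):
                    fit, ok = None, False
                aic = fit.aic if ok else np.nan
                rows.append({"random": "+".join(rand) or "(none)",
                             "covariates": "+".join(cov) or "(none)",
                             "aic": aic, "converged": ok})
                if ok:
                    key = (round(aic, 6), len(rand) + len(cov))
                    if best is None or key < best[0]:
                        best = (key, rand, cov)
        table = pd.DataFrame(rows)
        if best is None:
            warnings.warn("no candidate random structure converged; "
                          "falling back to no random terms")
            return (), (), table
        return best[1], best[2], table

    # -- fixed effects ----------------------------------------------------

    def drop1(self, terms, random_terms=(), covariates=()):
        """ML LRT of each droppable fixed term against the given model."""
        formula = terms_to_formula(self.response, terms, covariates)
        full = _fit_lmm(self.data, formula, random_terms, reml=False)
        rows = []
        for t in droppable_terms(terms):
            reduced_terms = [u for u in terms if u != t]
            rf = terms_to_formula(self.response, reduced_terms, covariates)
            try:
                reduced = _fit_lmm(self.data, rf, random_terms, reml=False)
                stat, df, p = lrt(full, reduced, self.correction)
                ok = reduced.converged
            except (np.linalg.LinAlgError, ValueError):
                stat = df = p = np.nan
                ok = False
            rows.append({"term": ":".join(sorted(t)), "chi2": stat,
                         "df": df, "p": p, "converged": ok})
        return pd.DataFrame(rows), full

    def fit(self, select_random: bool = True, backward: bool = True):
        """Run the full protocol and return AssociationResults."""
        if select_random and (self.random_candidates or self.covariate_candidates):
            random_terms, covariates, aic_table = self.select_random_structure()
        else:
            random_terms, covariates = self.random_candidates, ()
            aic_table = pd.DataFrame()
        terms = list(self.fixed_terms)
        full_lrt, _ = self.drop1(terms, random_terms, covariates)
        path = []
        if backward:
            while terms:
                table, _ = self.drop1(terms, random_terms, covariates)
                cand = table.dropna(subset=["p"])
                cand = cand[cand["converged"]]
                if cand.empty:
                    break
                worst = cand.loc[cand["p"].idxmax()]
                if worst["p"] <= self.alpha:
                    break
                drop = frozenset(worst["term"].split(":"))
                terms = [t for t in terms if t != drop]
                path.append({"dropped": worst["term"], "p": worst["p"]})
        mam_formula = terms_to_formula(self.response, terms, covariates)
        final = _fit_lmm(self.data, mam_formula, random_terms, reml=True)
        return AssociationResults(self, random_terms, covariates, aic_table,
                                  full_lrt, terms, mam_formula,
                                  pd.DataFrame(path), final)


class AssociationResults:
    """Fitted association workflow: AIC table, LRT table, MAM, contrasts."""

    def __init__(self, model, random_terms, covariates, aic_table, lrt_table,
                 mam_terms, mam_formula, elimination_path, final_fit):
        self.model = model
        self.random_terms = tuple(random_terms)
        self.covariates = tuple(covariates)
        self.aic_table = aic_table
        self.lrt_table = lrt_table
        self.mam_terms = list(mam_terms)
        self.mam_formula = mam_formula
        self.elimination_path = elimination_path
        self.final_fit = final_fit

    @property
    def converged(self) -> bool:
        return self.final_fit.converged

    def term_pvalue(self, term: str) -> float:
        """Full-model LRT p-value of one term (as named in lrt_table)."""
        t = frozenset(term.split(":"))
        for _, row in self.lrt_table.iterrows():
            if frozenset(row["term"].split(":")) == t:
                return float(row["p"])
        raise ValueError(f"term {term!r} is not in the model")

    # -- contrasts --------------------------------------------------------

    def _reference_grid(self, factors) -> pd.DataFrame:
        data = self.model.data
        levels = {}
        for f in factors:
            col = data[f]
            if col.dtype.kind in "if":
                levels[f] = [float(col.mean())]
            else:
                levels[f] = sorted(col.dropna().unique())
        grid = [dict(zip(levels, combo))
                for combo in itertools.product(*levels.values())]
        return pd.DataFrame(grid)

    def contrasts(self, factor: str, by: str | None = None,
                  adjust: str = "single-step") -> pd.DataFrame:
        """All pairwise contrasts of a factor's estimated marginal means.

        Marginal means average model predictions over the reference grid
        of the other model variables.  ``by`` builds a separate contrast
        family inside each level of another factor (e.g. genotype pairs
        within each test light).  p-values are multiplicity-adjusted over
        the family by the single-step max-|z| method; a family of one is
        returned unadjusted.
        """
        fit = self.final_fit
        res = fit.result
        design_info = res.model.data.design_info
        used = sorted({f for t in self.mam_terms for f in t}
                      | set(self.covariates))
        if factor not in used:
            raise ValueError(f"factor {factor!r} is not in the fitted MAM")
        if by is not None and by not in used:
            raise ValueError(f"factor {by!r} is not in the fitted MAM")
        grid = self._reference_grid(used)
        X = np.asarray(patsy.build_design_matrices([design_info], grid)[0])
        beta = np.asarray(res.fe_params if hasattr(res, "fe_params")
                          else res.params)
        cov = np.asarray(res.cov_params())[:len(beta), :len(beta)]

        levels = sorted(self.model.data[factor].dropna().unique())
        by_levels = (sorted(self.model.data[by].dropna().unique())
                     if by else [None])
        rows = []
        for b in by_levels:
            fam = []
            for l1, l2 in itertools.combinations(levels, 2):
                m1 = grid[factor] == l1
                m2 = grid[factor] == l2
                if b is not None:
                    m1 &= grid[by] == b
                    m2 &= grid[by] == b
                c = X[m1.to_numpy()].mean(axis=0) - X[m2.to_numpy()].mean(axis=0)
                est = float(c @ beta)
                var = float(c @ cov @ c)
                fam.append((l1, l2, c, est, var))
            # family-wise adjustment
            zs, covs = [], []
            for l1, l2, c, est, var in fam:
                se = np.sqrt(var) if var > 0 else np.nan
                zs.append(est / se if se and np.isfinite(se) and se > 0
                          else np.nan)
                covs.append(c)
            C = np.vstack(covs)
            V = C @ cov @ C.T
            d = np.sqrt(np.clip(np.diag(V), 1e-300, None))
            R = V / np.outer(d, d)
            for i, (l1, l2, c, est, var) in enumerate(fam):
                se = float(np.sqrt(var)) if var > 0 else np.nan
                z = zs[i]
                if not np.isfinite(z):
                    rows.append({"by": b, "level_1": l1, "level_2": l2,
                                 "estimate": est, "se": se, "z": np.nan,
                                 "p_raw": np.nan, "p_adj": np.nan,
                                 "estimable": False})
                    continue
                p_raw = 2.0 * stats.norm.sf(abs(z))
                if adjust == "single-step" and len(fam) > 1:
                    p_adj = _max_abs_z_pvalue(abs(z), R)
                elif adjust == "sidak" and len(fam) > 1:
                    p_adj = 1.0 - (1.0 - p_raw) ** len(fam)
                else:
                    p_adj = p_raw
                rows.append({"by": b, "level_1": l1, "level_2": l2,
                             "estimate": est, "se": se, "z": float(z),
                             "p_raw": float(p_raw),
                             "p_adj": float(max(p_adj, p_raw)),
                             "estimable": True})
        out = pd.DataFrame(rows)
        if by is None:
            out = out.drop(columns=["by"])
        return out

    def summary(self) -> str:
        lines = [
            "Association model results",
            "=" * 60,
            f"response: {self.model.response}",
            f"random structure: {'+'.join(self.random_terms) or '(none)'}",
            f"nuisance covariates: {'+'.join(self.covariates) or '(none)'}",
            f"MAM: {self.mam_formula}",
            f"converged: {self.converged}",
            "",
            "Full-model likelihood-ratio tests (ML):",
            self.lrt_table.to_string(index=False),
        ]
        if len(self.elimination_path):
            lines += ["", "Backward elimination path:",
                      self.elimination_path.to_string(index=False)]
        return "\n".join(lines)

    def plot_effects(self, factor: str, by: str | None = None, ax=None):
        """Point plot of estimated marginal means (matplotlib)."""
        import matplotlib.pyplot as plt

        used = sorted({f for t in self.mam_terms for f in t}
                      | set(self.covariates))
        grid = self._reference_grid(used)
        design_info = self.final_fit.result.model.data.design_info
        X = np.asarray(patsy.build_design_matrices([design_info], grid)[0])
        beta = np.asarray(self.final_fit.result.fe_params
                          if hasattr(self.final_fit.result, "fe_params")
                          else self.final_fit.result.params)
        grid = grid.assign(_pred=X @ beta)
        if ax is None:
            _, ax = plt.subplots()
        keys = [factor] + ([by] if by else [])
        emm = grid.groupby(keys)["_pred"].mean().reset_index()
        if by:
            for b, sub in emm.groupby(by):
                ax.plot(sub[factor], sub["_pred"], "o-", label=f"{by}={b}")
            ax.legend()
        else:
            ax.plot(emm[factor], emm["_pred"], "o-")
        ax.set_xlabel(factor)
        ax.set_ylabel(f"estimated marginal mean of {self.model.response}")
        return ax


def _max_abs_z_pvalue(z: float, R: np.ndarray) -> float:
    """P(max_j |Z_j| > z) for Z ~ N(0, R) — single-step adjustment."""
    m = R.shape[0]
    R = R + 1e-10 * np.eye(m)
    try:
        lo, hi = np.full(m, -z), np.full(m, z)
        inside = stats.multivariate_normal.cdf(
            hi, mean=np.zeros(m), cov=R, lower_limit=lo, allow_singular=True)
        if np.isnan(inside):
            raise ValueError
        return float(np.clip(1.0 - inside, 0.0, 1.0))
    except Exception:
        # Sidak fallback when the MVN integral is unavailable
        p1 = 2.0 * stats.norm.sf(z)
        return float(1.0 - (1.0 - p1) ** m)


# ---------------------------------------------------------------------------
# correlations and the headline interaction comparison

def preference_expression_correlation(means: pd.DataFrame,
                                      profiles: pd.DataFrame,
                                      pref_col: str = "mean_pref_Q",
                                      genes=None) -> pd.DataFrame:
    """Pearson correlation of per-female mean preference with each
    opsin's expression proportion; df = n - 2, two-sided p."""
    from .qpcr import GENES

    genes = genes or GENES
    merged = means.merge(profiles, left_on="female_id", right_on="sample")
    rows = []
    for gene in genes:
        sub = merged[[pref_col, f"prop_{gene}"]].dropna()
        n = len(sub)
        if n < 4:
            rows.append({"gene": gene, "r": np.nan, "df": n - 2,
                         "p": np.nan, "flag": "too_few_pairs"})
            continue
        x = sub[f"prop_{gene}"].to_numpy()
        y = sub[pref_col].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append({"gene": gene, "r": np.nan, "df": n - 2,
                         "p": np.nan, "flag": "zero_variance"})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"gene": gene, "r": float(r), "df": n - 2,
                     "p": float(p), "flag": ""})
    return pd.DataFrame(rows)


def interaction_comparison(data: pd.DataFrame, response: str = "pref_LD",
                           factor_a: str = "genotype",
                           factor_b: str = "species",
                           condition: str = "test_light",
                           random_terms=("female_id",),
                           correction: str = "bartlett") -> pd.DataFrame:
    """Side-by-side LRTs of ``factor_a x condition`` vs ``factor_b x condition``.

    Fits ``response ~ factor * condition`` for each factor with identical
    random structure and reports the interaction LRT from each, enabling
    the comparison of the two candidate explanations.  Refuses when the
    two factors are completely confounded (identical partitions of the
    observations).
    """
    ct = pd.crosstab(data[factor_a], data[factor_b])
    if ((ct > 0).sum(axis=1) == 1).all() and ((ct > 0).sum(axis=0) == 1).all():
        raise ValueError(
            f"{factor_a} and {factor_b} are completely confounded; "
            "the comparison is not identifiable")
    rows = []
    for fac in (factor_a, factor_b):
        full_f = f"{response} ~ {fac} * {condition}"
        red_f = f"{response} ~ {fac} + {condition}"
        sub = data.dropna(subset=[response, fac, condition]).copy()
        full = _fit_lmm(sub, full_f, random_terms, reml=False)
        red = _fit_lmm(sub, red_f, random_terms, reml=False)
        stat, df, p = lrt(full, red, correction)
        rows.append({"interaction": f"{fac}:{condition}", "chi2": stat,
                     "df": df, "p": p,
                     "converged": full.converged and red.converged})
    return pd.DataFrame(rows)
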