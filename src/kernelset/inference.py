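"""RCBD statistics: ANOVA, estimated marginal means and Tukey HSD.

Trial data are analysed as a fixed-effects linear model for a randomized
complete block design: environment (sowing date), hybrid and treatment
(shading window or stand density) as crossed factors, blocks nested within
environment.  Sums of squares are Type II so that the unbalanced shading
layout (one window tested in a single environment) is handled without
order dependence.  Marginal means are least-squares means: model
predictions averaged with equal weight over the reference grid of the
other factors.  Pairwise comparisons use the studentized range (Tukey),
and the scalar honest significant difference q * sqrt(MSE/n) is reported
alongside, as trial reports customarily print it.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import studentized_range
from statsmodels.stats.anova import anova_lm

__all__ = ["AnovaResult", "fit_rcbd", "marginal_means", "tukey_hsd"]


@dataclass
class AnovaResult:
    """Fitted RCBD model with its effects table.

    ``terms`` has one row per source (df, sum_sq, F, p); ``factors`` are
    the treatment factors (block excluded); the statsmodels results object
    is kept for marginal means and Tukey comparisons.
    """

    terms: pd.DataFrame
    response: str
    factors: list[str]
    block: str
    data: pd.DataFrame
    model: object
    marginal_means: dict = field(default_factory=dict)
    tukey: dict = field(default_factory=dict)

    @property
    def residual_df(self) -> float:
        return float(self.model.df_resid)

    @property
    def mse(self) -> float:
        return float(self.model.mse_resid)


def _term(name: str) -> str:
    return f"C({name})"


def fit_rcbd(plot_table: pd.DataFrame, response: str, factors: list[str],
             interactions: list[tuple[str, ...]] | None = None,
             block: str = "block", nest_block_in: str | None = "env"
             ) -> AnovaResult:
    """Fit the RCBD fixed-effects ANOVA.

    Parameters
    ----------
    plot_table : DataFrame
        One row per plot.
    response : str
        Column to analyse.
    factors : list of str
        Main-effect factor columns (e.g. ``["env", "hybrid", "treatment"]``).
    interactions : list of tuples, optional
        Factor combinations to cross, e.g. ``[("hybrid", "treatment")]``.
    block : str or None
        Block column; blocks are fixed effects.  None drops the block
        term (completely randomized layout).
    nest_block_in : str, optional
        Factor the blocks are nested in (typically the environment); the
        block term becomes its interaction with that factor.  Pass None
        for a single-environment trial.

    Type II sums of squares are used throughout.  Aliased (completely
    confounded) terms raise a ``ValueError`` naming the offending columns.
    """
    df = plot_table.copy()
    for col in [response, *([block] if block else []), *factors]:
        if col not in df.columns:
            raise ValueError(f"column {col!r} not in table")
    for f in factors:
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")
    rhs = [_term(f) for f in factors]
    if block is not None:
        if nest_block_in is not None and nest_block_in in factors:
            rhs.append(f"{_term(nest_block_in)}:{_term(block)}")
        else:
            rhs.append(_term(block))
    for combo in interactions or []:
        unknown = [f for f in combo if f not in factors]
        if unknown:
            raise ValueError(f"interaction references unknown factors {unknown}")
        rhs.append(":".join(_term(f) for f in combo))
    formula = f"Q('{response}') ~ " + " + ".join(rhs)
    fit = smf.ols(formula, data=df).fit()

    rank = np.linalg.matrix_rank(fit.model.exog)
    if rank < fit.model.exog.shape[1]:
        # locate aliased columns via the pivoted QR of the design
        q, r = np.linalg.qr(fit.model.exog)
        diag = np.abs(np.diag(r))
        aliased = [fit.model.exog_names[i] for i in
                   np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"aliased model terms (confounded design): {aliased}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # 0/0 on degenerate fits
        tbl = anova_lm(fit, typ=2)
    tbl = tbl.rename(columns={"PR(>F)": "p"})
    # constant response: every effect SS is ~0 and F is 0/0; report F=0, p=1
    tol = 1e-12 * max(float(fit.centered_tss), 1.0)
    degenerate = (tbl["sum_sq"] < tol) & (tbl.index != "Residual")
    tbl.loc[degenerate, "F"] = 0.0
    tbl.loc[degenerate, "p"] = 1.0
    tbl.index.name = "source"
    result = AnovaResult(terms=tbl.reset_index(), response=response,
                         factors=list(factors), block=block, data=df,
                         model=fit)
    for f in factors:
        result.marginal_means[f] = marginal_means(result, f)
    return result


def _grid_levels(result: AnovaResult) -> dict[str, list]:
    cols = set(result.factors)
    if result.block is not None:
        cols.add(result.block)
    return {c: sorted(result.data[c].unique()) for c in cols}


def marginal_means(result: AnovaResult, factor: str) -> pd.DataFrame:
    """Least-squares means for one factor.

    Model predictions averaged with equal weight over every combination of
    the other factors' observed levels (the reference grid).  Standard
    errors come from the corresponding linear combination of coefficient
    covariances.  Grid cells never observed in the data trigger an
    estimability warning (predictions there lean on the additive
    structure).
    """
    if factor not in result.factors and factor != result.block:
        raise ValueError(f"factor {factor!r} not in the fitted model")
    levels = _grid_levels(result)
    others = {k: v for k, v in levels.items() if k != factor}
    other_names = list(others)
    grid_rows = list(itertools.product(*[others[k] for k in other_names]))

    observed = set(map(tuple, result.data[[factor] + other_names]
                       .itertuples(index=False, name=None)))
    design_info = result.model.model.data.design_info
    from patsy import build_design_matrices

    out = []
    warned = False
    for lev in levels[factor]:
        grid = pd.DataFrame(grid_rows, columns=other_names)
        grid[factor] = lev
        missing = [row for row in
                   grid[[factor] + other_names].itertuples(index=False,
                                                           name=None)
                   if row not in observed]
        if missing and not warned:
            warnings.warn(
                f"{len(missing)} reference-grid cell(s) for {factor}={lev} "
                "unobserved; the marginal mean relies on the model's "
                "additive structure", stacklevel=2)
            warned = True
        X = np.asarray(build_design_matrices([design_info], grid)[0])
        L = X.mean(axis=0)
        est = float(L @ result.model.params)
        se = float(np.sqrt(L @ result.model.cov_params() @ L))
        out.append({factor: lev, "mean": est, "se": se})
    return pd.DataFrame(out)


def tukey_hsd(result: AnovaResult, factor: str, alpha: float = 0.05
              ) -> tuple[pd.DataFrame, float]:
    """Tukey pairwise comparisons of a factor's marginal means.

    Returns the pairwise table (difference, standard error, q statistic
    and studentized-range adjusted p) and the scalar honest significant
    difference ``q(alpha, k, df) * sqrt(MSE / n)`` with n the (harmonic)
    mean replication per level — the "Tukey value" printed next to trial
    tables.  Unbalanced pairs use the Tukey-Kramer standard error.
    """
    mm = marginal_means(result, factor)
    if len(mm) < 2:
        raise ValueError("Tukey comparison needs at least 2 levels")
    counts = result.data.groupby(factor)[result.response].count()
    k = len(mm)
    df_resid = result.residual_df
    mse = result.mse
    n_h = k / float((1.0 / counts).sum())
    q_crit = float(studentized_range.ppf(1.0 - alpha, k, df_resid))
    hsd = q_crit * np.sqrt(mse / n_h)

    rows = []
    for (i, a), (j, b) in itertools.combinations(mm.iterrows(), 2):
        la, lb = a[factor], b[factor]
        diff = float(a["mean"] - b["mean"])
        se_pair = np.sqrt(mse / 2.0 * (1.0 / counts[la] + 1.0 / counts[lb]))
        q_obs = abs(diff) / se_pair if se_pair > 0 else np.inf
        p_adj = float(studentized_range.sf(q_obs, k, df_resid))
        rows.append({"level_a": la, "level_b": lb, "difference": diff,
                     "se": float(se_pair * np.sqrt(2.0)), "q": float(q_obs),
                     "p_adj": min(max(p_adj, 0.0), 1.0),
                     "significant": p_adj < alpha})
    table = pd.DataFrame(rows)
    result.tukey[factor] = {"table": table, "hsd": float(hsd),
                            "alpha": alpha}
    return table, float(hsd)
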