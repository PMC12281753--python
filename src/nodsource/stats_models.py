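"""Inferential layer: log-transforms, mixed-model ANOVA, Tukey letter displays.

Recruitment percentages are analysed on the log scale, ``ln(x + offset)``
with ``offset = 1`` by default (exact zeros occur whenever a treatment draws
nothing from a source category).  The recruitment model is a linear
mixed-effects model with fixed source-category and treatment effects, their
interaction, and a random intercept per field block; per-term significance
uses Wald F statistics with containment denominator degrees of freedom.  If
the random-intercept fit is singular or fails to converge the model is
refit with block as a fixed effect, with a logged warning.

Phenotype and richness comparisons use fixed-effects ANOVA followed by
Tukey HSD on the studentized-range distribution; all-pairs results are
summarized as a compact letter display (insert-and-absorb): groups sharing a
letter are not significantly different at the chosen alpha.
"""

from __future__ import annotations

import itertools
import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from nodsource.core_io import PhenotypeTable, ValidationError
from nodsource.source_tracking import AttributionResult


def log_transform(values, offset: float = 1.0):
    """``ln(x + offset)`` for non-negative values; strictly monotone."""
    if offset <= 0:
        raise ValueError("offset must be positive")
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValidationError("log_transform requires non-negative values")
    out = np.log(arr + offset)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


# ---------------------------------------------------------------------------
# Tukey HSD + compact letter display
# ---------------------------------------------------------------------------


@dataclass
class TukeyCLD:
    """Group means, pairwise Tukey-adjusted p-values, and letter codes."""

    means: pd.Series  # group -> mean
    letters: dict  # group -> string of letters, e.g. "AB"
    pairwise: pd.DataFrame  # group1, group2, diff, se, q, p_adj
    alpha: float

    def consistent(self) -> bool:
        """Exhaustive check: letters agree with the pairwise table."""
        for _, row in self.pairwise.iterrows():
            shared = set(self.letters[row["group1"]]) & set(self.letters[row["group2"]])
            if row["p_adj"] < self.alpha and shared:
                return False
            if row["p_adj"] >= self.alpha and not shared:
                return False
        return True


def _compact_letters(groups: list, significant: set) -> dict:
    """Insert-and-absorb algorithm for a compact letter display.

    ``groups`` are ordered by decreasing mean so the first letter attaches to
    the highest-mean group; ``significant`` holds frozensets of group pairs
    that must not share a letter.
    """
    columns: list[set] = [set(groups)]
    for pair in significant:
        a, b = tuple(pair)
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.extend([col - {a}, col - {b}])
        # absorb: drop columns contained in another
        columns = [
            c for c in columns if c and not any(c < other for other in columns if other is not c)
        ]
    # deduplicate while preserving content
    uniq: list[set] = []
    for c in columns:
        if c not in uniq:
            uniq.append(c)
    # order letters by the best-ranked (highest-mean) group they contain
    rank = {g: i for i, g in enumerate(groups)}
    uniq.sort(key=lambda c: min(rank[g] for g in c))
    alphabet = string.ascii_uppercase
    letters = {g: "" for g in groups}
    for i, col in enumerate(uniq):
        lab = alphabet[i] if i < 26 else f"A{i}"
        for g in col:
            letters[g] += lab
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def tukey_hsd(
    values: pd.Series, groups: pd.Series, alpha: float = 0.05,
    mse: float | None = None, df_resid: float | None = None,
) -> TukeyCLD:
    """All-pairs Tukey(-Kramer) HSD with a compact letter display.

    ``mse``/``df_resid`` default to the one-way ANOVA residual mean square;
    passing the residuals of a larger model pools over its other factors.
    """
    values = pd.Series(np.asarray(values, dtype=float), index=groups.index)
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValidationError("Tukey HSD needs at least 2 groups")
    sizes = groups.value_counts()
    if (sizes < 2).any() and mse is None:
        raise ValidationError(
            f"group(s) with a single observation: {sizes.index[sizes < 2].tolist()}"
        )
    means = values.groupby(groups).mean().loc[levels]
    if mse is None:
        resid = values - means.reindex(groups).to_numpy()
        df_resid = len(values) - len(levels)
        mse = float((resid**2).sum() / df_resid)
    k = len(levels)
    rows = []
    for a, b in itertools.combinations(levels, 2):
        diff = means[a] - means[b]
        se = np.sqrt(mse / 2 * (1 / sizes[a] + 1 / sizes[b]))
        if se == 0:
            q = 0.0 if diff == 0 else np.inf
        else:
            q = abs(diff) / se
        p = float(stats.studentized_range.sf(q, k, df_resid)) if np.isfinite(q) else 0.0
        rows.append({"group1": a, "group2": b, "diff": diff, "se": se, "q": q, "p_adj": min(p, 1.0)})
    pairwise = pd.DataFrame(rows)
    significant = {
        frozenset((r["group1"], r["group2"]))
        for _, r in pairwise.iterrows()
        if r["p_adj"] < alpha
    }
    ordered = list(means.sort_values(ascending=False, kind="stable").index)
    letters = _compact_letters(ordered, significant)
    cld = TukeyCLD(means, letters, pairwise, alpha)
    assert cld.consistent(), "letter display inconsistent with pairwise table"
    return cld


def anova_tukey_cld(
    data: PhenotypeTable | pd.DataFrame,
    response: str,
    factors: list[str],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, TukeyCLD | None]:
    """Fixed-effects ANOVA (one- or two-way with interaction) plus Tukey CLD.

    The Tukey step compares the levels of ``factors[0]`` using the full
    model's residual mean square.  If any level has a single observation the
    Tukey step is skipped with a warning and only the ANOVA is returned.
    """
    df = data.data.copy() if isinstance(data, PhenotypeTable) else data.copy()
    if len(factors) not in (1, 2):
        raise ValueError("factors must name one or two columns")
    for f in factors:
        if df[f].nunique() < 2:
            raise ValidationError(f"factor {f!r} has a single level")
    rhs = " * ".join(f"C({f})" for f in factors)
    model = smf.ols(f"Q('{response}') ~ {rhs}", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    anova.index = [_clean_term(t) for t in anova.index]

    primary = factors[0]
    sizes = df.groupby(primary)[response].count()
    if (sizes < 2).any():
        warnings.warn(
            f"Tukey skipped: group(s) with one observation in {primary!r}", stacklevel=2
        )
        return anova, None
    cld = tukey_hsd(
        df[response],
        df[primary],
        alpha=alpha,
        mse=float(model.mse_resid),
        df_resid=float(model.df_resid),
    )
    return anova, cld


def _clean_term(term: str) -> str:
    return term.replace("C(", "").replace(")", "").replace("Q('", "").replace("'", "")


# ---------------------------------------------------------------------------
# recruitment mixed model
# ---------------------------------------------------------------------------


@dataclass
class RecruitmentModelResult:
    """ANOVA table, pairwise category contrasts and fit metadata."""

    anova: pd.DataFrame  # term, num_df, den_df, F, p
    pairwise: pd.DataFrame  # category1, category2, estimate, p, p_adj
    method: str  # "mixed_lmm" or "fixed_block"
    offset: float
    response: str
    warnings: list = field(default_factory=list)


def _term_contrast_columns(exog_names: list[str]) -> dict:
    """Group design columns by model term (main effects vs interaction)."""
    terms: dict[str, list[int]] = {"category": [], "treatment": [], "category:treatment": []}
    for i, name in enumerate(exog_names):
        if name == "Intercept":
            continue
        if ":" in name:
            terms["category:treatment"].append(i)
        elif name.startswith("C(category"):
            terms["category"].append(i)
        elif name.startswith("C(treatment"):
            terms["treatment"].append(i)
    return {t: idx for t, idx in terms.items() if idx}


def recruitment_model(
    result: AttributionResult | pd.DataFrame,
    response: str = "percent",
    offset: float = 1.0,
    alpha: float = 0.05,
) -> RecruitmentModelResult:
    """Mixed-model ANOVA of log-transformed recruitment values.

    Fits ``ln(response + offset) ~ category * treatment`` with a random
    intercept per block.  Per-term Wald F tests use containment denominator
    degrees of freedom ``n - rank(X) - (n_blocks - 1)``.  Pairwise category
    contrasts average over treatments (balanced marginal means) and are
    Holm-adjusted.  A singular or non-convergent random-intercept fit falls
    back to a fixed-block OLS model, recorded in ``method``.
    """
    df = result.per_block.copy() if isinstance(result, AttributionResult) else result.copy()
    for col in ("category", "treatment", "block", response):
        if col not in df.columns:
            raise ValidationError(f"recruitment data lacks column {col!r}")
    if df["category"].nunique() < 2 or df["treatment"].nunique() < 2:
        raise ValidationError("need >= 2 levels for category and treatment")
    if df["block"].nunique() < 2:
        raise ValidationError("need >= 2 blocks")
    y = log_transform(df[response].to_numpy(), offset)
    if np.ptp(y) == 0:
        raise ValidationError("response has zero variance; nothing to model")
    df = df.assign(_y=y)

    logged: list[str] = []
    # sum-to-zero coding: term Wald tests are marginal (Type-III) tests and
    # interaction effects average out of the category marginal means
    formula = "_y ~ C(category, Sum) * C(treatment, Sum)"
    method = "mixed_lmm"
    fe_params = cov = exog_names = None
    n = len(df)
    n_blocks = df["block"].nunique()
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            mod = smf.mixedlm(formula, df, groups=df["block"])
            fit = mod.fit(reml=True)
        singular = (not fit.converged) or np.isnan(fit.cov_re.to_numpy()).any()
        if not singular:
            fe_names = mod.exog_names
            fe_params = fit.params[: len(fe_names)].to_numpy()
            cov = fit.cov_params().iloc[: len(fe_names), : len(fe_names)].to_numpy()
            exog_names = list(fe_names)
            rank_x = np.linalg.matrix_rank(mod.exog)
            for w in caught:
                logged.append(str(w.message))
    except Exception as exc:  # singular fits raise LinAlgError inside statsmodels
        logged.append(f"mixed model failed ({exc}); using fixed-block model")
        fe_params = None
    if fe_params is None:
        method = "fixed_block"
        ols_fit = smf.ols(formula + " + C(block)", data=df).fit()
        keep = [i for i, nme in enumerate(ols_fit.model.exog_names) if "C(block)" not in nme]
        exog_names = [ols_fit.model.exog_names[i] for i in keep]
        fe_params = ols_fit.params.to_numpy()[keep]
        cov = ols_fit.cov_params().to_numpy()[np.ix_(keep, keep)]
        rank_x = np.linalg.matrix_rank(ols_fit.model.exog) - (n_blocks - 1)
        logged.append("downgraded to fixed-block model")

    den_df = n - rank_x - (n_blocks - 1)
    if den_df <= 0:
        raise ValidationError("no residual degrees of freedom for the Wald F tests")

    term_cols = _term_contrast_columns(exog_names)
    rows = []
    for term, idx in term_cols.items():
        L = np.zeros((len(idx), len(exog_names)))
        for r, i in enumerate(idx):
            L[r, i] = 1.0
        est = L @ fe_params
        vmat = L @ cov @ L.T
        fstat = float(est @ np.linalg.solve(vmat, est) / len(idx))
        p = float(stats.f.sf(fstat, len(idx), den_df))
        rows.append({"term": term, "num_df": len(idx), "den_df": den_df, "F": fstat, "p": p})
    anova = pd.DataFrame(rows).set_index("term")

    # pairwise category contrasts on treatment-averaged (marginal) means;
    # under sum coding these reduce to differences of category main effects
    cats = sorted(pd.unique(df["category"]))
    idx_of = {nme: i for i, nme in enumerate(exog_names)}
    cat_cols = [i for t, idx in term_cols.items() if t == "category" for i in idx]

    def marginal_vector(cat: str) -> np.ndarray:
        v = np.zeros(len(exog_names))
        name = f"C(category, Sum)[S.{cat}]"
        if name in idx_of:
            v[idx_of[name]] = 1.0
        else:  # omitted (last) level: effect is minus the sum of the others
            for i in cat_cols:
                v[i] = -1.0
        return v

    prows = []
    for a, b in itertools.combinations(cats, 2):
        c = marginal_vector(a) - marginal_vector(b)
        est = float(c @ fe_params)
        se = float(np.sqrt(c @ cov @ c))
        tval = est / se if se > 0 else np.inf
        p = 2 * float(stats.t.sf(abs(tval), den_df))
        prows.append({"category1": a, "category2": b, "estimate": est, "p": p})
    pairwise = pd.DataFrame(prows)
    if len(pairwise):
        pairwise["p_adj"] = multipletests(pairwise["p"], alpha=alpha, method="holm")[1]
    return RecruitmentModelResult(anova, pairwise, method, offset, response, logged)
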