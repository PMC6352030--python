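"""Treatment-effect inference for factorial osmotic-dehydration studies.

The study design crosses the osmotic agent (5 solutes) with immersion
time (6 levels) with replicated samples.  Inference on a response
(WC, WL, SG, WL_T, CR or water activity) follows the classical recipe:

* a multifactor ANOVA at alpha = 0.05 — main effects only by default,
  since replicate-level tables report factor main effects;
* Tukey's HSD on each significant factor, with all pairwise contrasts
  sharing the critical half-width q_{alpha,k,df} * sqrt(MS_E / n~)
  (n~ the harmonic mean of the two group sizes, the Tukey-Kramer
  correction for mild imbalance), summarised as a compact letter
  display: levels sharing a letter are not significantly different;
* Pearson's product-moment correlation, e.g. of water activity against
  water content.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "two_way_anova",
    "tukey_hsd",
    "TukeyResult",
    "pearson_r",
    "compact_letter_display",
]


def two_way_anova(
    obs: pd.DataFrame,
    value: str = "value",
    factors: Sequence[str] = ("solute", "time"),
    interaction: bool = False,
) -> pd.DataFrame:
    """Factorial ANOVA table (type II sums of squares).

    Parameters
    ----------
    obs
        Long-format observations: one row per measurement, with the
        response in ``value`` and one column per factor.
    factors
        Factor column names (one or more); each must have >= 2 levels.
    interaction
        Include the two-way interaction term (requires replication;
        main effects only is the default).

    Returns
    -------
    DataFrame indexed by term (factor names, optional interaction,
    ``Residual``) with columns ``sum_sq, df, mean_sq, F, p``.

    F and p are recomputed from the sums of squares so degenerate
    designs are handled explicitly: a zero residual mean square gives
    F = inf (p = 0) for factors with signal, and F = p = NaN when the
    factor itself has no variation (e.g. all observations equal).
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    if len(factors) < 1:
        raise ValueError("need at least one factor")
    for f in factors:
        if f not in obs.columns:
            raise KeyError(f"factor column {f!r} not in observations")
        if obs[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
    if value not in obs.columns:
        raise KeyError(f"value column {value!r} not in observations")
    if interaction and len(factors) != 2:
        raise ValueError("interaction term requires exactly two factors")

    data = pd.DataFrame({"y": obs[value].astype(float).to_numpy()})
    terms = []
    for i, f in enumerate(factors):
        data[f"f{i}"] = obs[f].astype(str).to_numpy()
        terms.append(f"C(f{i})")
    joiner = " * " if interaction else " + "
    model = smf.ols("y ~ " + joiner.join(terms), data=data).fit()
    if model.df_resid < 1:
        raise ValueError("zero error degrees of freedom: add replication "
                         "or drop the interaction term")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-residual designs divide by 0
        tab = anova_lm(model, typ=2)

    rename = {f"C(f{i})": factors[i] for i in range(len(factors))}
    if interaction:
        rename["C(f0):C(f1)"] = ":".join(factors)
    tab = tab.rename(index=rename)

    out = pd.DataFrame({"sum_sq": tab["sum_sq"], "df": tab["df"]})
    if out.loc["Residual", "df"] < 1:
        raise ValueError("zero error degrees of freedom: add replication "
                         "or drop the interaction term")
    out["mean_sq"] = out["sum_sq"] / out["df"]
    ms_e = out.loc["Residual", "mean_sq"]
    df_e = out.loc["Residual", "df"]
    # mean squares below fp round-off relative to the data magnitude are zero
    zero_tol = 1e-12 * (float(np.sum(data["y"].to_numpy() ** 2)) + 1.0)
    F, p = [], []
    for term in out.index:
        if term == "Residual":
            F.append(np.nan)
            p.append(np.nan)
            continue
        ms = out.loc[term, "mean_sq"]
        if ms_e > zero_tol:
            f_val = ms / ms_e
            F.append(f_val)
            p.append(float(sps.f.sf(f_val, out.loc[term, "df"], df_e)))
        elif ms > zero_tol:  # perfect factor fit: infinitely strong evidence
            F.append(np.inf)
            p.append(0.0)
        else:  # no variation anywhere
            F.append(np.nan)
            p.append(np.nan)
    out["F"] = F
    out["p"] = p
    return out


def compact_letter_display(
    levels: Sequence,
    means: Mapping,
    significant_pairs: Sequence[tuple],
) -> dict:
    """Assign letters so that levels sharing one are not significantly different.

    Uses the insert-and-absorb algorithm: start from one group holding
    every level; each significant pair splits any group containing both;
    groups contained in another are absorbed.  Letters are ordered by
    ascending group mean ('a' for the lowest-mean group).
    """
    groups = [set(levels)]
    for a, b in significant_pairs:
        nxt = []
        for g in groups:
            if a in g and b in g:
                nxt.append(g - {a})
                nxt.append(g - {b})
            else:
                nxt.append(g)
        kept: list[set] = []
        for g in sorted(nxt, key=len, reverse=True):
            if g and not any(g <= h for h in kept):
                kept.append(g)
        groups = kept
    groups.sort(key=lambda g: min(means[lv] for lv in g))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {lv: "" for lv in levels}
    for i, g in enumerate(groups):
        for lv in g:
            letters[lv] += alphabet[i % len(alphabet)]
    return {lv: "".join(sorted(s)) for lv, s in letters.items()}


@dataclass
class TukeyResult:
    """Tukey HSD post-hoc summary for one factor."""

    factor: str
    alpha: float
    ms_error: float
    df_error: float
    q_crit: float
    means: pd.Series = field(repr=False)
    contrasts: pd.DataFrame = field(repr=False)
    letters: dict = field(repr=False)


def tukey_hsd(
    obs: pd.DataFrame,
    factor: str,
    *,
    value: str = "value",
    other_factors: Sequence[str] = (),
    alpha: float = 0.05,
) -> TukeyResult:
    """All pairwise Tukey contrasts for one factor, with letter groups.

    The error mean square comes from the main-effects ANOVA over
    ``factor`` and ``other_factors``.  Each contrast row carries the
    mean difference, the +/- limit (the Tukey half-width) and a
    significance flag (|difference| > limit).
    """
    an = two_way_anova(obs, value=value, factors=(factor, *other_factors))
    ms_e = float(an.loc["Residual", "mean_sq"])
    df_e = float(an.loc["Residual", "df"])

    grp = obs.groupby(factor)[value]
    means = grp.mean().astype(float)
    sizes = grp.size()
    k = len(means)
    q_crit = float(sps.studentized_range.ppf(1.0 - alpha, k, df_e))

    rows = []
    sig_pairs = []
    for a, b in itertools.combinations(means.index, 2):
        n_tilde = 2.0 / (1.0 / sizes[a] + 1.0 / sizes[b])
        limit = q_crit * np.sqrt(ms_e / n_tilde)
        diff = means[a] - means[b]
        significant = bool(abs(diff) > limit)
        rows.append({"contrast": f"{a}-{b}", "difference": diff,
                     "limit": limit, "significant": significant})
        if significant:
            sig_pairs.append((a, b))
    contrasts = pd.DataFrame(rows, columns=["contrast", "difference", "limit", "significant"])
    letters = compact_letter_display(list(means.index), means, sig_pairs)
    return TukeyResult(factor=factor, alpha=alpha, ms_error=ms_e, df_error=df_e,
                       q_crit=q_crit, means=means, contrasts=contrasts, letters=letters)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-test p-value.

    Requires n >= 3 and nonzero variance in both arguments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the arguments")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
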