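"""Nonparametric factorial statistics for the cohort analyses.

The WRI metrics are skewed and heteroscedastic, so group comparisons use the
aligned rank transform (ART): for each effect of the 2 (population) x 3 (age
band) design, the response is *aligned* — every other effect, estimated from
the cell means, is stripped out — then ranked, and an ordinary fixed-effects
factorial ANOVA runs on the ranks.  Only the aligned-for effect's row of each
ANOVA is meaningful, so one ANOVA is run per effect.  Post-hoc pairwise
contrasts use the ART-C construction: re-align for the contrasted factor,
re-rank within the two levels being compared, and t-test the ranks, with
Bonferroni correction over the pairwise family within that factor.

Also here: Cohen's d (pooled-SD standardised mean difference, reported with
the ASD - TD sign convention), Spearman correlation matrices between the
motor metrics and clinical scores (deliberately unadjusted for multiplicity),
and the Pearson chi-square test of independence used to check group x age
balance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ArtAnovaResult",
    "PosthocResult",
    "art_anova_two_way",
    "artc_posthoc",
    "cohens_d",
    "spearman_matrix",
    "chi_square_independence",
]


@dataclass(frozen=True)
class ArtAnovaResult:
    """F, p, degrees of freedom and partial eta^2 per effect."""

    effects: dict  # effect name -> dict(F, p, df1, df2, partial_eta2)

    def __getitem__(self, effect: str) -> dict:
        return self.effects[effect]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.effects).T


@dataclass(frozen=True)
class PosthocResult:
    """One pairwise ART-C contrast."""

    contrast: str
    t: float
    p_adjusted: float
    cohens_d: float
    df: float


def _rankdata(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _cell_effects(y: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Estimated effects from (unweighted) cell means of a two-way layout."""
    a_levels = np.unique(a)
    b_levels = np.unique(b)
    cell_mean = np.full((a_levels.size, b_levels.size), np.nan)
    for i, al in enumerate(a_levels):
        for j, bl in enumerate(b_levels):
            mask = (a == al) & (b == bl)
            if not mask.any():
                raise ValueError(f"empty design cell ({al!r}, {bl!r})")
            cell_mean[i, j] = y[mask].mean()
    grand = cell_mean.mean()
    a_eff = cell_mean.mean(axis=1) - grand
    b_eff = cell_mean.mean(axis=0) - grand
    ab_eff = cell_mean - cell_mean.mean(axis=1, keepdims=True) - cell_mean.mean(
        axis=0, keepdims=True
    ) + grand
    ai = np.searchsorted(a_levels, a)
    bi = np.searchsorted(b_levels, b)
    residual = y - cell_mean[ai, bi]
    return residual, a_eff[ai], b_eff[bi], ab_eff[ai, bi], ai, bi, a_levels, b_levels


def _sum_coded_design(ai: np.ndarray, bi: np.ndarray, na: int, nb: int):
    """Intercept + sum-to-zero main-effect and interaction columns."""
    n = ai.size

    def code(idx: np.ndarray, k: int) -> np.ndarray:
        cols = np.zeros((n, k - 1))
        for j in range(k - 1):
            cols[idx == j, j] = 1.0
        cols[idx == k - 1, :] = -1.0
        return cols

    xa = code(ai, na)
    xb = code(bi, nb)
    xab = np.einsum("ni,nj->nij", xa, xb).reshape(n, -1)
    intercept = np.ones((n, 1))
    return intercept, xa, xb, xab


def _rss(x: np.ndarray, y: np.ndarray) -> float:
    resid = y - x @ np.linalg.lstsq(x, y, rcond=None)[0]
    return float(resid @ resid)


def _anova_f_on(y: np.ndarray, ai, bi, na, nb, effect: str):
    """Type-III F test of one effect in the full two-way fixed-effects model."""
    intercept, xa, xb, xab = _sum_coded_design(ai, bi, na, nb)
    full = np.hstack([intercept, xa, xb, xab])
    blocks = {"a": xa, "b": xb, "ab": xab}
    reduced = np.hstack([intercept] + [v for k, v in blocks.items() if k != effect])
    rss_full = _rss(full, y)
    rss_red = _rss(reduced, y)
    df1 = blocks[effect].shape[1]
    df2 = y.size - full.shape[1]
    if df2 <= 0:
        raise ValueError("not enough observations for the full factorial model")
    ss_eff = max(rss_red - rss_full, 0.0)
    ms_err = rss_full / df2
    f = ss_eff / df1 / ms_err if ms_err > 0 else np.inf
    p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    eta2 = ss_eff / (ss_eff + rss_full) if (ss_eff + rss_full) > 0 else 0.0
    return float(f), p, df1, df2, float(eta2)


def art_anova_two_way(
    table: pd.DataFrame,
    response: str,
    factor_a: str = "group",
    factor_b: str = "age_band",
) -> ArtAnovaResult:
    """Aligned-rank-transform two-way ANOVA of ``response``.

    For each effect (factor_a, factor_b, interaction): subtract every other
    estimated effect and the cell residual's complement from the response,
    rank the aligned values (average ranks on ties) and test that effect in
    an ordinary two-way fixed-effects ANOVA on the ranks (Type III sums of
    squares, sum-to-zero coding).  Reports F, p and partial eta^2 per effect.
    """
    df = table.dropna(subset=[response, factor_a, factor_b])
    y = df[response].to_numpy(dtype=float)
    a = df[factor_a].to_numpy()
    b = df[factor_b].to_numpy()
    if np.unique(a).size < 2:
        raise ValueError(f"factor {factor_a!r} needs >= 2 levels")
    # a single level of factor_b collapses the design to a one-way layout;
    # the ART then reduces to the plain rank-transform one-way ANOVA
    residual, a_term, b_term, ab_term, ai, bi, a_levels, b_levels = _cell_effects(y, a, b)
    na, nb = a_levels.size, b_levels.size

    aligned = {
        factor_a: residual + a_term,
        factor_b: residual + b_term,
        "interaction": residual + ab_term,
    }
    keys = {factor_a: "a", factor_b: "b", "interaction": "ab"}
    effects = {}
    for name, values in aligned.items():
        if (keys[name] in ("b", "ab") and nb < 2):
            continue  # untestable in a collapsed one-way layout
        ranks = _rankdata(values)
        f, p, df1, df2, eta2 = _anova_f_on(ranks, ai, bi, na, nb, keys[name])
        effects[name] = {"F": f, "p": p, "df1": df1, "df2": df2, "partial_eta2": eta2}
    return ArtAnovaResult(effects=effects)


def artc_posthoc(
    table: pd.DataFrame,
    response: str,
    factor: str,
    other_factor: str | None = None,
) -> list[PosthocResult]:
    """ART-C pairwise contrasts on ``factor`` with Bonferroni correction.

    The response is aligned for ``factor`` (cell residual plus that factor's
    estimated effect, the other factor of the two-way design inferred from
    the standard cohort columns when not given), then for each level pair the
    aligned values of just those two levels are ranked together and compared
    with a two-sample t-test.  Cohen's d is computed on the *raw* response;
    contrasts are labelled "first - second" in sorted level order, which for
    the population factor yields the ASD - TD sign convention.
    """
    if other_factor is None:
        other_factor = "age_band" if factor == "group" else "group"
    df = table.dropna(subset=[response, factor, other_factor])
    y = df[response].to_numpy(dtype=float)
    a = df[factor].to_numpy()
    b = df[other_factor].to_numpy()
    levels = sorted(np.unique(a).tolist())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 levels")
    residual, a_term, _, _, _, _, _, _ = _cell_effects(y, a, b)
    aligned = residual + a_term

    pairs = list(itertools.combinations(levels, 2))
    results = []
    for u, v in pairs:
        mask = (a == u) | (a == v)
        sub_ranks = _rankdata(aligned[mask])
        ru = sub_ranks[a[mask] == u]
        rv = sub_ranks[a[mask] == v]
        t, p = sps.ttest_ind(ru, rv, equal_var=True)
        d = cohens_d(y[a == u], y[a == v])
        results.append(
            PosthocResult(
                contrast=f"{u} - {v}",
                t=float(t),
                p_adjusted=float(min(1.0, p * len(pairs))),
                cohens_d=d,
                df=float(ru.size + rv.size - 2),
            )
        )
    return results


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-SD standardised mean difference (a - b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    na, nb = a.size, b.size
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        raise ValueError("pooled standard deviation is 0; d undefined")
    return float((a.mean() - b.mean()) / pooled)


def spearman_matrix(
    features: pd.DataFrame,
    scores: pd.DataFrame,
    min_pairs: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho and p for every metric x clinical-score pair.

    Rows are columns of ``features``, columns are columns of ``scores``
    (aligned on index).  Pairs with fewer than ``min_pairs`` complete
    observations are reported as NaN.  No multiplicity adjustment is applied
    — by design, the correlations are exploratory.
    """
    rho = pd.DataFrame(index=features.columns, columns=scores.columns, dtype=float)
    pval = rho.copy()
    common = features.index.intersection(scores.index)
    for f in features.columns:
        x = features.loc[common, f].to_numpy(dtype=float)
        for s in scores.columns:
            y = scores.loc[common, s].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < min_pairs:
                continue
            r, p = sps.spearmanr(x[ok], y[ok])
            rho.loc[f, s] = r
            pval.loc[f, s] = p
    return rho, pval


def chi_square_independence(counts) -> tuple[float, float, int]:
    """Pearson chi-square test of independence on an r x c table.

    No continuity correction; expected counts from the margins.  Raises on a
    zero margin (expected counts undefined).
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2:
        raise ValueError("counts must be a 2-D table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin; expected counts undefined")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p), int(dof)
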