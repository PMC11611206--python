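"""Statistical evaluation of index scores against rating bins.

The central question — does the molecular index separate samples that the
reference soil-health ratings call "very low" ... "very high"? — is
answered nonparametrically: a Kruskal-Wallis test across bins, followed by
all pairwise two-sided Wilcoxon rank-sum (Mann-Whitney U) tests with
Benjamini-Hochberg FDR adjustment, summarized as a compact letter display
(groups sharing a letter do not differ significantly at alpha).

Also here: the ordinary-least-squares regression used to compare index
ratings with indicator ratings (adjusted R², RMSE, Gaussian AIC), and
KEGG-pathway composition summaries of selected enzymes from a user-supplied
EC -> pathway mapping (multi-mapping enzymes contribute one classification
per pathway).
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError


@dataclass
class GroupTestResult:
    kruskal_H: float
    kruskal_p: float
    pairwise: pd.DataFrame        # symmetric matrix of BH-adjusted p-values
    pairwise_raw: pd.DataFrame
    letters: dict[str, str]       # compact letter display per group
    alpha: float
    group_medians: dict[str, float]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    adj_r2: float
    rmse: float
    aic: float
    p_value: float


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p; exact for small groups, else normal
    approximation with continuity correction."""
    method = "exact" if (len(a) <= 8 and len(b) <= 8) else "asymptotic"
    try:
        return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                        method=method).pvalue)
    except ValueError:  # exact method refuses ties
        return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                        method="asymptotic").pvalue)


def compact_letter_display(groups: list[str],
                           significant: pd.DataFrame) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``significant`` is a boolean groups x groups matrix (True where the
    pair differs).  Groups sharing at least one letter are not
    significantly different.
    """
    # start with one column of all groups; split on each significant pair
    columns: list[set[str]] = [set(groups)]
    for i, gi in enumerate(groups):
        for gj in groups[i + 1:]:
            if not significant.loc[gi, gj]:
                continue
            for col in list(columns):
                if gi in col and gj in col:
                    columns.remove(col)
                    columns.append(col - {gi})
                    columns.append(col - {gj})
    # absorb columns contained in another
    columns = [c for c in columns
               if c and not any(c < other for other in columns)]
    # deduplicate, keep stable order by first group appearance
    uniq: list[set[str]] = []
    for c in columns:
        if c not in uniq:
            uniq.append(c)
    uniq.sort(key=lambda c: min(groups.index(g) for g in c))
    alphabet = string.ascii_lowercase
    letters = {g: "" for g in groups}
    for li, col in enumerate(uniq):
        ch = alphabet[li % 26] * (1 + li // 26)
        for g in groups:
            if g in col:
                letters[g] += ch
    return letters


def group_test(scores: pd.Series, bins: pd.Series, alpha: float = 0.05,
               bin_order: list[str] | None = None) -> GroupTestResult:
    """Kruskal-Wallis across bins plus BH-adjusted pairwise rank-sum tests.

    Bins with fewer than 2 samples are excluded with a warning.  Letters
    follow the compact letter display convention: bins sharing a letter are
    not significantly different at ``alpha`` after FDR adjustment.
    """
    df = pd.DataFrame({"score": scores, "bin": bins.loc[scores.index]}).dropna()
    sizes = df.groupby("bin", observed=True).size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"bins with < 2 samples excluded: {small}")
        df = df[~df["bin"].isin(small)]
    present = [b for b in (bin_order or sorted(df["bin"].unique()))
               if b in set(df["bin"])]
    if len(present) < 2:
        raise DataError("need at least 2 non-empty bins")
    samples = {b: df.loc[df["bin"] == b, "score"].to_numpy() for b in present}
    H, p = stats.kruskal(*samples.values())
    pairs = [(a, b) for i, a in enumerate(present) for b in present[i + 1:]]
    raw = [_rank_sum_p(samples[a], samples[b]) for a, b in pairs]
    adj = multipletests(raw, method="fdr_bh")[1] if pairs else []
    raw_m = pd.DataFrame(np.nan, index=present, columns=present)
    adj_m = pd.DataFrame(np.nan, index=present, columns=present)
    for (a, b), pr, pa in zip(pairs, raw, adj):
        raw_m.loc[a, b] = raw_m.loc[b, a] = pr
        adj_m.loc[a, b] = adj_m.loc[b, a] = pa
    sig = adj_m < alpha
    np.fill_diagonal(sig.values, False)
    letters = compact_letter_display(present, sig)
    return GroupTestResult(
        kruskal_H=float(H), kruskal_p=float(p), pairwise=adj_m,
        pairwise_raw=raw_m, letters=letters, alpha=alpha,
        group_medians={b: float(np.median(v)) for b, v in samples.items()})


def fit_rating_regression(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """OLS of y on x with adjusted R², RMSE of fit, Gaussian AIC, slope p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise DataError("regression needs n >= 3")
    if np.std(x) == 0:
        raise DataError("zero-variance predictor")
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    resid = y - fitted
    rss = float(resid @ resid)
    r2 = res.rvalue ** 2
    adj_r2 = 1 - (1 - r2) * (n - 1) / (n - 2)
    rmse = float(np.sqrt(rss / n))
    # Gaussian log-likelihood AIC with k = 3 (slope, intercept, sigma)
    if rss <= 0:
        aic = -np.inf
    else:
        ll = -0.5 * n * (np.log(2 * np.pi) + np.log(rss / n) + 1)
        aic = 2 * 3 - 2 * ll
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            adj_r2=float(adj_r2), rmse=rmse, aic=float(aic),
                            p_value=float(res.pvalue))


def load_pathway_mapping(path: str | Path) -> pd.DataFrame:
    """Two-column TSV (EC, pathway); multiple rows per EC allowed."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise DataError("mapping file needs (EC, pathway) columns")
    df = df.iloc[:, :2]
    df.columns = ["ec", "pathway"]
    return df.astype(str)


def summarize_pathways(ecs_per_indicator: dict[str, list[str]],
                       mapping: pd.DataFrame,
                       include_unmapped: bool = False) -> pd.DataFrame:
    """Pathway composition of selected enzymes per indicator.

    Each enzyme contributes one classification per pathway it maps to
    (multi-mapping counted per classification); proportions are over total
    classifications.  Unmapped ECs go to an "unmapped" bucket, excluded
    from the proportion denominator unless ``include_unmapped``.
    """
    if mapping.empty:
        raise DataError("empty pathway mapping")
    lookup = mapping.groupby("ec")["pathway"].apply(list)
    rows = []
    for ind, ecs in ecs_per_indicator.items():
        counts: dict[str, int] = {}
        unmapped = 0
        for ec in ecs:
            pws = lookup.get(ec)
            if pws is None:
                unmapped += 1
                continue
            for pw in pws:
                counts[pw] = counts.get(pw, 0) + 1
        total = sum(counts.values()) + (unmapped if include_unmapped else 0)
        for pw, c in sorted(counts.items()):
            rows.append({"indicator": ind, "pathway": pw, "count": c,
                         "proportion": c / total if total else np.nan})
        if unmapped:
            rows.append({"indicator": ind, "pathway": "unmapped",
                         "count": unmapped,
                         "proportion": (unmapped / total
                                        if include_unmapped and total else
                                        np.nan)})
    return pd.DataFrame(rows)
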