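"""Spectral-count statistics for extracellular-particle proteomes.

Counts are normalized to the per-sample total (scaled) and log2(x+1)
transformed.  Three analyses mirror the standard semi-quantitative workflow
on such tables: a Spearman correlation between per-protein mean normalized
counts and protein length (longer proteins yield more detectable peptides,
so intact complexes show a positive size-count correlation), a Wilcoxon
matched-pairs signed-rank test between two particle classes over a protein
group, and a two-way fixed-effects ANOVA (protein x class) with per-protein
Tukey HSD comparisons of class means using the pooled error term.

The signed-rank p-value is exact for n <= 25 via the conditional
distribution of the positive-rank sum, computed by dynamic programming over
the (tie-averaged) ranks; this equals full 2^n sign enumeration.  Beyond
n = 25 a normal approximation with continuity and tie corrections is used.
Proteins not detected in a class are treated as raw count 0, matching the
behaviour of short proteins dropping below the detection limit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import islice, permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata, spearmanr, studentized_range

REQUIRED_COLUMNS = ("protein_id", "length_aa", "class", "replicate", "raw_count")

DEFAULT_SCALE = 1e4


class UnbalancedDesignError(ValueError):
    """Raised when the ANOVA design is not fully crossed and balanced."""


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"spectral-count table missing columns: {missing}")
    if (table["raw_count"] < 0).any():
        raise ValueError("raw counts must be non-negative")


def normalize_counts(table: pd.DataFrame, scale: float = DEFAULT_SCALE) -> pd.DataFrame:
    """Add norm (= raw/sample_total * scale) and norm_log2 (= log2(norm+1)).

    A sample is one (class, replicate) column of the underlying experiment;
    per sample the norm column sums to ``scale``.  Zero-total samples are a
    validation error.
    """
    _check_table(table)
    out = table.copy()
    totals = out.groupby(["class", "replicate"])["raw_count"].transform("sum")
    if (totals == 0).any():
        bad = (
            out.loc[totals == 0, ["class", "replicate"]]
            .drop_duplicates()
            .itertuples(index=False)
        )
        raise ValueError(f"zero total spectral counts in samples: {list(bad)}")
    out["norm"] = out["raw_count"] / totals * scale
    out["norm_log2"] = np.log2(out["norm"] + 1.0)
    return out


def protein_class_means(
    table: pd.DataFrame, sample_class: str, protein_subset: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-protein mean norm_log2 (over replicates) in one class.

    Proteins in ``protein_subset`` absent from the class are filled with the
    value a zero raw count would get (log2(0+1) = 0): not-detected is data.
    """
    if "norm_log2" not in table.columns:
        table = normalize_counts(table)
    sub = table[table["class"] == sample_class]
    means = sub.groupby("protein_id").agg(
        norm_log2=("norm_log2", "mean"), length_aa=("length_aa", "first")
    )
    if protein_subset is not None:
        lengths = table.groupby("protein_id")["length_aa"].first()
        means = means.reindex(list(protein_subset))
        means["norm_log2"] = means["norm_log2"].fillna(0.0)
        means["length_aa"] = means["length_aa"].fillna(lengths)
    return means


# ---------------------------------------------------------------------------
# Spearman size-count correlation
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    rho: float
    pvalue: float
    n: int
    method: str


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided permutation p of Spearman's rho by full n! enumeration.

    Ranks use midranks for ties; rho is Pearson on ranks.  Enumeration is
    chunked through numpy so n = 10 (3.6M permutations) stays tractable.
    """
    rx = rankdata(x)
    ry = rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float((rxc**2).sum() * (ryc**2).sum()))
    obs = abs(float(rxc @ ryc) / denom)

    n_ge = 0
    total = 0
    gen = permutations(ryc)
    while True:
        chunk = list(islice(gen, 200_000))
        if not chunk:
            break
        arr = np.asarray(chunk)
        stats = np.abs(arr @ rxc) / denom
        n_ge += int((stats >= obs - 1e-12).sum())
        total += len(chunk)
    return n_ge / total


def size_correlation(
    table: pd.DataFrame,
    protein_subset: Sequence[str] | None = None,
    sample_class: str | None = None,
    exact_max_n: int = 10,
) -> CorrelationResult:
    """Spearman correlation of mean norm_log2 vs protein length.

    For n <= ``exact_max_n`` the p-value is an exact permutation p;
    otherwise the t-distribution approximation is used.  A constant vector
    yields NaN with a warning.
    """
    if sample_class is None:
        classes = table["class"].unique()
        if len(classes) != 1:
            raise ValueError("sample_class required for multi-class tables")
        sample_class = classes[0]
    means = protein_class_means(table, sample_class, protein_subset)
    x = means["norm_log2"].to_numpy(dtype=float)
    y = means["length_aa"].to_numpy(dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("size correlation needs at least 4 proteins")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant vector: size correlation undefined")
        return CorrelationResult(float("nan"), float("nan"), n, "undefined")
    rho = float(spearmanr(x, y).statistic)
    if n <= exact_max_n:
        return CorrelationResult(rho, _exact_spearman_p(x, y), n, "exact-permutation")
    p = float(spearmanr(x, y).pvalue)
    return CorrelationResult(rho, p, n, "t-approximation")


# ---------------------------------------------------------------------------
# Wilcoxon matched-pairs signed-rank test
# ---------------------------------------------------------------------------


@dataclass
class SignedRankResult:
    statistic: float  # W+ = sum of ranks of positive differences
    pvalue: float
    n_used: int
    n_zero_dropped: int
    method: str


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the positive-rank sum given |difference| ranks.

    Doubling midranks makes them integers, so the null distribution of 2*W+
    over all 2^n sign assignments is computed by subset-sum dynamic
    programming; identical to explicit enumeration, feasible for n = 25.
    """
    r2 = np.rint(2.0 * np.asarray(ranks)).astype(np.int64)
    total = int(r2.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total - r + 1]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(2.0 * w_plus))
    p_le = float(dist[: w2 + 1].sum())
    p_ge = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def signed_rank_test(diffs: Sequence[float], exact_max_n: int = 25) -> SignedRankResult:
    """Wilcoxon signed-rank test on a vector of paired differences.

    Zero differences are dropped (and reported); ties in |difference| take
    average ranks.  Exact for n <= ``exact_max_n``, else normal
    approximation with continuity correction and tie-corrected variance.
    """
    d = np.asarray(diffs, dtype=float)
    nonzero = d[d != 0]
    n_zero = len(d) - len(nonzero)
    n = len(nonzero)
    if n == 0:
        return SignedRankResult(float("nan"), float("nan"), 0, n_zero, "degenerate")
    if n < 5:
        raise ValueError("need at least 5 non-zero paired differences")
    ranks = rankdata(np.abs(nonzero))
    w_plus = float(ranks[nonzero > 0].sum())
    if n <= exact_max_n:
        p = _signed_rank_exact_p(ranks, w_plus)
        return SignedRankResult(w_plus, p, n, n_zero, "exact")
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    delta = w_plus - mu
    z = (delta - 0.5 * np.sign(delta)) / math.sqrt(sigma2)
    p = float(2.0 * norm.sf(abs(z)))
    return SignedRankResult(w_plus, min(1.0, p), n, n_zero, "normal-approximation")


def paired_class_test(
    table: pd.DataFrame,
    class_a: str,
    class_b: str,
    protein_subset: Sequence[str] | None = None,
) -> SignedRankResult:
    """Signed-rank test of per-protein mean norm_log2, class_a vs class_b.

    Pairing is by protein; proteins undetected in one class enter at
    norm_log2 = 0 rather than being dropped.
    """
    if protein_subset is None:
        protein_subset = sorted(
            set(table.loc[table["class"].isin([class_a, class_b]), "protein_id"])
        )
    ma = protein_class_means(table, class_a, protein_subset)["norm_log2"]
    mb = protein_class_means(table, class_b, protein_subset)["norm_log2"]
    return signed_rank_test((ma - mb).to_numpy())


# ---------------------------------------------------------------------------
# Two-way ANOVA with per-protein Tukey HSD
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    anova_table: pd.DataFrame  # factors protein, class, interaction, residual
    comparisons: pd.DataFrame  # per-protein pairwise class comparisons
    mse: float
    df_resid: int


def per_protein_class_anova(table: pd.DataFrame) -> AnovaResult:
    """Two-way fixed-effects ANOVA on norm_log2 with Tukey HSD per protein.

    Factors are protein, class and their interaction; the design must be
    fully crossed and balanced with >= 2 replicates.  Within each protein,
    every class pair is compared with the studentized-range statistic
    q = |mean_a - mean_b| / sqrt(MSE / r), where MSE is the pooled residual
    mean square of the full model and r the per-cell replicate count;
    adjusted p-values come from the studentized range distribution with
    k = number of classes and the residual degrees of freedom.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if "norm_log2" not in table.columns:
        table = normalize_counts(table)

    cell_counts = table.groupby(["protein_id", "class"]).size()
    proteins = sorted(table["protein_id"].unique())
    classes = sorted(table["class"].unique())
    if len(proteins) < 2 or len(classes) < 2:
        raise UnbalancedDesignError("need >= 2 proteins and >= 2 classes")
    if len(cell_counts) != len(proteins) * len(classes):
        raise UnbalancedDesignError("design is not fully crossed")
    if cell_counts.nunique() != 1 or int(cell_counts.iloc[0]) < 2:
        raise UnbalancedDesignError(
            "design must be balanced with >= 2 replicates per cell"
        )
    r = int(cell_counts.iloc[0])

    df = table.rename(columns={"class": "sample_class"}).copy()
    model = smf.ols(
        "norm_log2 ~ C(protein_id) + C(sample_class) "
        "+ C(protein_id):C(sample_class)",
        data=df,
    ).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-residual fixtures trip RuntimeWarnings
        aov = sm.stats.anova_lm(model, typ=2)
    aov = aov.rename(
        index={
            "C(protein_id)": "protein",
            "C(sample_class)": "class",
            "C(protein_id):C(sample_class)": "protein:class",
            "Residual": "residual",
        }
    )
    # Convention for degenerate fixtures: a factor with zero sum of squares
    # explains nothing, so F = 0 and p = 1 even when MSE is also zero.
    mse = float(aov.loc["residual", "sum_sq"] / aov.loc["residual", "df"])
    for idx in aov.index:
        if idx == "residual":
            continue
        if np.isclose(aov.loc[idx, "sum_sq"], 0.0):
            aov.loc[idx, "F"] = 0.0
            aov.loc[idx, "PR(>F)"] = 1.0
    df_resid = int(aov.loc["residual", "df"])

    means = (
        df.groupby(["protein_id", "sample_class"])["norm_log2"].mean().unstack()
    )
    k = len(classes)
    rows = []
    for prot in proteins:
        for i in range(k):
            for j in range(i + 1, k):
                ca, cb = classes[i], classes[j]
                diff = float(means.loc[prot, ca] - means.loc[prot, cb])
                if mse > 0:
                    q = abs(diff) / math.sqrt(mse / r)
                    p_adj = float(studentized_range.sf(q, k, df_resid))
                elif diff == 0.0:
                    p_adj = 1.0
                else:
                    p_adj = 0.0
                direction = "equal" if diff == 0 else ("higher" if diff > 0 else "lower")
                rows.append((prot, ca, cb, diff, p_adj, direction))
    comparisons = pd.DataFrame(
        rows,
        columns=["protein_id", "class_a", "class_b", "diff", "p_adj", "direction"],
    )
    return AnovaResult(aov, comparisons, mse, df_resid)
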