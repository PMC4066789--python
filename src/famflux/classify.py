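"""Family classification by abundance fluctuations, and enrichment analyses.

Families with adequate sampling weight are split by the fluctuation index
Q_f (log inverse Fano factor) into three classes:

* overdispersed  Q_f < -0.43   (duplication / intra-species expansion visible)
* poisson_like   -0.43 <= Q_f <= 1   (transfer-loss dominated, Poisson profile)
* peaked         Q_f > 1       (narrower than Poisson; abundance constraint)

plus ``undersampled`` for families below the sampling-noise threshold
w_f ~= 0.38.  Note the threshold direction: higher w_f means *better*
sampling, so families with w_f >= w_min are retained.

Downstream: Fisher exact tests of (functional category x class) contingency,
plasmid log-ratio enrichment scores, and class-restricted genome-genome
distances compared to a reference (e.g. 16S) distance matrix by Spearman
rank correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Thresholds",
    "CLASS_LABELS",
    "classify_families",
    "fisher_exact_2x2",
    "category_enrichment",
    "plasmid_enrichment_score",
    "class_restricted_distance",
    "spearman_distance_correlation",
]

CLASS_LABELS = ("overdispersed", "poisson_like", "peaked", "undersampled")


@dataclass(frozen=True)
class Thresholds:
    """Classification thresholds on Q_f and the sampling-weight floor."""

    q_low: float = -0.43
    q_high: float = 1.0
    w_min: float = 0.38

    def __post_init__(self) -> None:
        if not self.q_low < self.q_high:
            raise ValueError("q_low must be below q_high")


def classify_families(
    stats: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> pd.Series:
    """Assign one class label per family from its Q_f and w_f.

    Boundary equality (Q_f exactly at a threshold) goes to poisson_like;
    missing Q_f yields undersampled with a warning.
    """
    if "Q_f" not in stats or "w_f" not in stats:
        raise ValueError("stats table needs Q_f and w_f columns")
    q = stats["Q_f"].to_numpy(dtype=float)
    w = stats["w_f"].to_numpy(dtype=float)
    missing = ~np.isfinite(q)
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} families lack Q_f; labelled undersampled",
            stacklevel=2,
        )
    labels = np.full(len(stats), "poisson_like", dtype=object)
    labels[q < thresholds.q_low] = "overdispersed"
    labels[q > thresholds.q_high] = "peaked"
    labels[missing | (w < thresholds.w_min)] = "undersampled"
    return pd.Series(labels, index=stats.index, name="class")


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Odds ratio and two-sided Fisher exact p for a 2x2 table [[a,b],[c,d]].

    The two-sided p sums hypergeometric probabilities of all tables with the
    observed margins that are no more probable than the observed one.  The
    odds ratio is ad/bc (inf or 0 at zero cells, NaN when both products
    vanish).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    a, b = t[0]
    c, d = t[1]
    ad, bc = a * d, b * c
    if bc > 0:
        odds = ad / bc
    elif ad > 0:
        odds = np.inf
    else:
        odds = np.nan
    p = float(sps.fisher_exact(t, alternative="two-sided")[1])
    return float(odds), min(p, 1.0)


def category_enrichment(
    labels: pd.Series,
    categories: pd.Series,
    alpha: float = 0.01,
    include_undersampled: bool = False,
) -> pd.DataFrame:
    """Fisher exact test of every (category, class) pair.

    Undersampled families are excluded unless ``include_undersampled``.
    Raw p-values are reported (the classification thresholds were chosen
    with raw P < 0.01 in mind); a Benjamini-Hochberg column is appended for
    transparency.
    """
    labels = labels.dropna()
    categories = categories.reindex(labels.index)
    if categories.isna().any():
        warnings.warn(
            f"{int(categories.isna().sum())} families lack a category; dropped",
            stacklevel=2,
        )
        keep = categories.notna()
        labels, categories = labels[keep], categories[keep]
    if not include_undersampled:
        keep = labels != "undersampled"
        labels, categories = labels[keep], categories[keep]
    classes = [c for c in CLASS_LABELS if c in set(labels)]
    rows = []
    for cat in sorted(categories.unique()):
        in_cat = (categories == cat).to_numpy()
        if not in_cat.any():
            warnings.warn(f"category {cat!r} has no families; skipped", stacklevel=2)
            continue
        for cls in classes:
            in_cls = (labels == cls).to_numpy()
            a = int(np.sum(in_cat & in_cls))
            b = int(np.sum(in_cat & ~in_cls))
            c = int(np.sum(~in_cat & in_cls))
            d = int(np.sum(~in_cat & ~in_cls))
            odds, p = fisher_exact_2x2([[a, b], [c, d]])
            if np.isnan(odds) or odds == 1.0:
                direction = "none"
            elif odds > 1.0:
                direction = "over"
            else:
                direction = "under"
            rows.append(
                {
                    "category": cat,
                    "class": cls,
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "odds_ratio": odds,
                    "p_value": p,
                    "direction": direction,
                    "significant": p < alpha,
                }
            )
    result = pd.DataFrame(rows)
    if len(result):
        result["p_bh"] = multipletests(result["p_value"], method="fdr_bh")[1]
    return result


def plasmid_enrichment_score(
    plasmid_counts: pd.Series,
    background_counts: pd.Series,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Log-ratio enrichment of each family on plasmids.

    score_f = ln of the pseudocounted share of family f among plasmid domains
    over its share among background (whole-genome) domains.  Positive scores
    mark families enriched on mobile elements.
    """
    idx = plasmid_counts.index.union(background_counts.index)
    p = plasmid_counts.reindex(idx, fill_value=0).astype(float) + pseudocount
    g = background_counts.reindex(idx, fill_value=0).astype(float) + pseudocount
    if p.sum() <= 0 or g.sum() <= 0:
        raise ValueError("count vectors must have positive totals")
    score = np.log((p / p.sum()) / (g / g.sum()))
    score.name = "plasmid_score"
    return score


def class_restricted_distance(
    matrix: pd.DataFrame,
    labels: pd.Series,
    cls: str,
    metric: str = "jaccard",
) -> pd.DataFrame:
    """Genome-genome distance computed only from families of one class.

    Default is Jaccard on presence/absence; ``braycurtis`` uses the counts.
    """
    if metric not in ("jaccard", "braycurtis"):
        raise ValueError("metric must be 'jaccard' or 'braycurtis'")
    fams = labels.reindex(matrix.index)
    rows = matrix.loc[fams == cls]
    if len(rows) < 2:
        raise ValueError(f"fewer than two families carry label {cls!r}")
    X = rows.to_numpy().T.astype(float)  # genomes x families
    if metric == "jaccard":
        X = X > 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        D = squareform(pdist(X, metric=metric))
    D = np.nan_to_num(D, nan=0.0)  # genome pairs with empty profiles
    return pd.DataFrame(D, index=matrix.columns, columns=matrix.columns)


def spearman_distance_correlation(D: pd.DataFrame, D_ref: pd.DataFrame) -> float:
    """Spearman rank correlation of two distance matrices over their strict
    upper triangles (average-rank tie handling)."""
    A = np.asarray(D, dtype=float)
    B = np.asarray(D_ref, dtype=float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("distance matrices must be square and equally sized")
    if not (np.allclose(A, A.T) and np.allclose(B, B.T)):
        raise ValueError("distance matrices must be symmetric")
    iu = np.triu_indices(A.shape[0], k=1)
    return float(sps.spearmanr(A[iu], B[iu]).statistic)
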