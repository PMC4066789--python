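"""Cross-species abundance-fluctuation statistics.

Works on a family-by-genome integer count matrix (pandas DataFrame, rows =
families, columns = genomes).  Genomes are grouped into sliding bins of
similar size (total assigned domains) and, per family f and bin b, the
following are computed:

* sampling weight      w_{f,b} = n_b n_b^+ / sum_b n_b^2,   w_f = sum_b w_{f,b}
* L1-to-Poisson        L_{f,b} = 1/2 sum_v |p_{f,b}(v) - Poiss(v; <v>_b)|,
                       aggregated as L_f = sum_b L_{f,b} n_b^+ / sum_b n_b^+
* fluctuation index    Q_{f,b} = ln(<v>_b / Var_b(v)) with a max-over-bins
                       fallback for zero-variance bins, Q_f = sum_b Q_{f,b} w_{f,b}
* occurrence           O_f = fraction of genomes with v > 0
* transfer fraction    H_f = mean over present genomes of H_{f,g}/V_{f,g}

Q_f is the log inverse Fano factor: 0 for Poisson-like profiles, negative
for overdispersed ones, positive for profiles narrower than Poisson.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GenomeBin",
    "genome_sizes",
    "build_bins",
    "sampling_weights",
    "l1_statistic",
    "q_statistic",
    "occurrence",
    "h_index",
    "binned_trend",
    "compute_family_stats",
]

DEFAULT_BIN_WIDTH = 390.0
DEFAULT_BIN_STEP = 100.0
DEFAULT_V_MAX = 450
DEFAULT_MIN_BIN = 10
DEFAULT_Q_CAP = 5.0


@dataclass(frozen=True)
class GenomeBin:
    """One sliding genome-size bin: half-open interval [lower, upper) and the
    column indices of its member genomes."""

    b: int
    lower: float
    upper: float
    members: np.ndarray
    n_b: int


def _counts(matrix: pd.DataFrame) -> np.ndarray:
    counts = matrix.to_numpy()
    if counts.ndim != 2:
        raise ValueError("abundance matrix must be two-dimensional")
    if (counts < 0).any():
        raise ValueError("abundance matrix has negative entries")
    return counts


def genome_sizes(matrix: pd.DataFrame) -> pd.Series:
    """Genome size in assigned domains: column sums of the count matrix."""
    return matrix.sum(axis=0)


def build_bins(
    sizes,
    width: float = DEFAULT_BIN_WIDTH,
    step: float = DEFAULT_BIN_STEP,
    min_bin: int = DEFAULT_MIN_BIN,
) -> list[GenomeBin]:
    """Sliding half-open size bins [x, x+width), advancing by ``step`` from
    min(size) until max(size) is covered.

    Genomes may belong to several overlapping bins.  Bins with fewer than
    ``min_bin`` genomes are dropped.
    """
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be positive")
    s = np.asarray(sizes, dtype=float)
    if s.size == 0:
        raise ValueError("empty size vector")
    bins: list[GenomeBin] = []
    x = float(s.min())
    stop = float(s.max())
    b = 0
    while x <= stop:
        members = np.flatnonzero((s >= x) & (s < x + width))
        if members.size >= min_bin:
            bins.append(
                GenomeBin(b=b, lower=x, upper=x + width, members=members,
                          n_b=int(members.size))
            )
            b += 1
        x += step
    return bins


def _bin_arrays(counts: np.ndarray, bins: list[GenomeBin], include_zeros: bool,
                ddof: int):
    """Per-(family, bin) mean, variance, and nonzero count n_b^+."""
    F = counts.shape[0]
    B = len(bins)
    mean = np.full((F, B), np.nan)
    var = np.full((F, B), np.nan)
    nplus = np.zeros((F, B), dtype=np.int64)
    for b, gb in enumerate(bins):
        sub = counts[:, gb.members].astype(float)
        nz = sub > 0
        nplus[:, b] = nz.sum(axis=1)
        if include_zeros:
            n_eff = np.full(F, gb.n_b, dtype=float)
            m = sub.sum(axis=1) / n_eff
            v = ((sub - m[:, None]) ** 2).sum(axis=1) / n_eff
        else:
            n_eff = nplus[:, b].astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                m = np.where(n_eff > 0, sub.sum(axis=1) / n_eff, np.nan)
                v = np.where(
                    n_eff > 0,
                    (((sub - m[:, None]) ** 2) * nz).sum(axis=1) / n_eff,
                    np.nan,
                )
        if ddof:
            with np.errstate(invalid="ignore", divide="ignore"):
                v = np.where(n_eff > ddof, v * n_eff / (n_eff - ddof), np.nan)
        mean[:, b] = m
        var[:, b] = v
    return mean, var, nplus


def sampling_weights(
    matrix: pd.DataFrame, bins: list[GenomeBin]
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-bin weights w_{f,b} = n_b n_b^+ / sum_b n_b^2 and w_f = sum_b w_{f,b}.

    w_f lies in [0, 1], reaching 1 only for families present in every genome
    of every bin.
    """
    if not bins:
        raise ValueError("no bins supplied")
    counts = _counts(matrix)
    n_b = np.array([gb.n_b for gb in bins], dtype=float)
    denom = float(np.sum(n_b**2))
    nplus = np.stack(
        [(counts[:, gb.members] > 0).sum(axis=1) for gb in bins], axis=1
    ).astype(float)
    w_fb = n_b[None, :] * nplus / denom
    w_fb = pd.DataFrame(w_fb, index=matrix.index,
                        columns=[gb.b for gb in bins])
    w_f = w_fb.sum(axis=1)
    w_f.name = "w_f"
    return w_fb, w_f


def l1_statistic(
    matrix: pd.DataFrame,
    bins: list[GenomeBin],
    v_max: int = DEFAULT_V_MAX,
    include_zeros: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Half-L1 distance between each family's in-bin abundance histogram and
    the Poisson pmf with the same bin mean, truncated at ``v_max``.

    Bins where the family never occurs are skipped; the aggregate weights
    each bin by its nonzero count n_b^+.  Families absent everywhere get NaN.
    """
    if not bins:
        raise ValueError("no bins supplied")
    counts = _counts(matrix)
    F = counts.shape[0]
    B = len(bins)
    v = np.arange(v_max + 1)
    L_fb = np.full((F, B), np.nan)
    nplus = np.zeros((F, B), dtype=np.int64)
    for b, gb in enumerate(bins):
        sub = counts[:, gb.members]
        nz = sub > 0
        npl = nz.sum(axis=1)
        nplus[:, b] = npl
        n_eff = np.full(F, gb.n_b, dtype=float) if include_zeros else npl.astype(float)
        # empirical histogram over 0..v_max (values beyond are truncated away)
        hist = np.zeros((F, v_max + 1))
        if include_zeros:
            keep = sub <= v_max
            rr = np.repeat(np.arange(F), sub.shape[1]).reshape(F, -1)[keep]
            np.add.at(hist, (rr, sub[keep]), 1.0)
            mean = sub.sum(axis=1) / n_eff
        else:
            keep = (sub <= v_max) & nz
            rr = np.repeat(np.arange(F), sub.shape[1]).reshape(F, -1)[keep]
            np.add.at(hist, (rr, sub[keep]), 1.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                mean = np.where(npl > 0, (sub * nz).sum(axis=1) / n_eff, np.nan)
        ok = npl > 0
        if not ok.any():
            continue
        p_emp = hist[ok] / n_eff[ok, None]
        pois = np.exp(sps.poisson.logpmf(v[None, :], mean[ok, None]))
        L_fb[ok, b] = 0.5 * np.abs(p_emp - pois).sum(axis=1)
    L_fb_df = pd.DataFrame(L_fb, index=matrix.index, columns=[gb.b for gb in bins])
    wt = np.where(np.isnan(L_fb), 0.0, nplus.astype(float))
    tot = wt.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        L_f = np.where(tot > 0, np.nansum(L_fb * wt, axis=1) / tot, np.nan)
    L_f = pd.Series(L_f, index=matrix.index, name="L_f")
    return L_fb_df, L_f


def q_statistic(
    matrix: pd.DataFrame,
    bins: list[GenomeBin],
    include_zeros: bool = True,
    ddof: int = 0,
    q_cap: float = DEFAULT_Q_CAP,
    normalize: bool = False,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Log inverse Fano factor per bin and its weighted aggregate.

    Q_{f,b} = ln(<v_f>_b / Var_b(v_f)) for bins with positive variance; a
    zero-variance bin (family present at constant abundance) inherits the
    maximum Q over that family's positive-variance bins, or the cap ``q_cap``
    if no such bin exists (returned flag marks capped families).
    Q_f = sum_b Q_{f,b} w_{f,b}; with ``normalize`` the sum is divided by w_f.
    """
    if not bins:
        raise ValueError("no bins supplied")
    counts = _counts(matrix)
    mean, var, nplus = _bin_arrays(counts, bins, include_zeros, ddof)
    w_fb, w_f = sampling_weights(matrix, bins)
    present = nplus > 0
    pos = present & (var > 0)
    zerovar = present & (var == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(pos, np.log(mean / var), np.nan)
    row_max = np.nanmax(np.where(pos, q, -np.inf), axis=1)
    capped = zerovar.any(axis=1) & ~pos.any(axis=1)
    fallback = np.where(np.isfinite(row_max), row_max, q_cap)
    q = np.where(zerovar, fallback[:, None], q)
    q_df = pd.DataFrame(q, index=matrix.index, columns=[gb.b for gb in bins])
    contrib = np.where(np.isnan(q), 0.0, q) * w_fb.to_numpy()
    Q_f = contrib.sum(axis=1)
    if normalize:
        with np.errstate(invalid="ignore", divide="ignore"):
            Q_f = np.where(w_f.to_numpy() > 0, Q_f / w_f.to_numpy(), np.nan)
    Q_f = np.where(present.any(axis=1), Q_f, np.nan)
    Q_f = pd.Series(Q_f, index=matrix.index, name="Q_f")
    capped = pd.Series(capped, index=matrix.index, name="q_capped")
    return q_df, Q_f, capped


def occurrence(matrix: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Fraction (and count) of genomes carrying at least one family member."""
    counts = _counts(matrix)
    o_count = (counts > 0).sum(axis=1)
    O_f = pd.Series(o_count / counts.shape[1], index=matrix.index, name="O_f")
    o_count = pd.Series(o_count, index=matrix.index, name="O_count")
    return O_f, o_count


def h_index(matrix: pd.DataFrame, transfers: pd.DataFrame) -> pd.Series:
    """Mean transfer fraction H_f = average of H_{f,g}/V_{f,g} over genomes
    where the family is present; NaN for families never present.

    Transfer counts exceeding the abundance (possible with real annotation
    pipelines) are clipped to a ratio of 1 with a warning.
    """
    if not matrix.index.equals(transfers.index) or not matrix.columns.equals(
        transfers.columns
    ):
        raise ValueError("transfer table is not aligned to the abundance matrix")
    V = _counts(matrix).astype(float)
    H = _counts(transfers).astype(float)
    present = V > 0
    excess = (H > V) & present
    if excess.any():
        warnings.warn(
            f"{int(excess.sum())} transfer counts exceed the family abundance; "
            "ratios clipped to 1",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(present, np.minimum(H / np.where(present, V, 1.0), 1.0), 0.0)
    n_present = present.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        H_f = np.where(n_present > 0, ratio.sum(axis=1) / n_present, np.nan)
    return pd.Series(H_f, index=matrix.index, name="H_f")


def binned_trend(x, y, n_bins: int) -> pd.DataFrame:
    """Mean of ``y`` in equal-width bins of ``x`` (empty bins are NaN)."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size == 0:
        raise ValueError("no finite (x, y) pairs")
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    idx = np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        rows.append(
            {
                "bin": b,
                "left": edges[b],
                "right": edges[b + 1],
                "mean_y": y[sel].mean() if sel.any() else np.nan,
                "count": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


def compute_family_stats(
    matrix: pd.DataFrame,
    transfers: pd.DataFrame | None = None,
    width: float = DEFAULT_BIN_WIDTH,
    step: float = DEFAULT_BIN_STEP,
    v_max: int = DEFAULT_V_MAX,
    include_zeros: bool = True,
    min_bin: int = DEFAULT_MIN_BIN,
    q_cap: float = DEFAULT_Q_CAP,
    ddof: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-call per-family statistics table.

    Returns ``(stats, per_bin)`` where ``stats`` has columns w_f, L_f, Q_f,
    O_f, O_count, q_capped (and H_f when a transfer table is given) and
    ``per_bin`` holds the per-(family, bin) diagnostics.
    """
    sizes = genome_sizes(matrix)
    bins = build_bins(sizes, width=width, step=step, min_bin=min_bin)
    if not bins:
        raise ValueError(
            "no genome-size bin reaches the minimum occupancy; "
            "lower min_bin or widen the bins"
        )
    w_fb, w_f = sampling_weights(matrix, bins)
    L_fb, L_f = l1_statistic(matrix, bins, v_max=v_max, include_zeros=include_zeros)
    q_fb, Q_f, capped = q_statistic(
        matrix, bins, include_zeros=include_zeros, ddof=ddof, q_cap=q_cap
    )
    O_f, O_count = occurrence(matrix)
    stats = pd.concat([w_f, L_f, Q_f, O_f, O_count, capped], axis=1)
    if transfers is not None:
        stats["H_f"] = h_index(matrix, transfers)
    per_bin = pd.concat(
        {
            "w_fb": w_fb,
            "L_fb": L_fb,
            "Q_fb": q_fb,
        },
        axis=1,
    )
    per_bin.columns.names = ["statistic", "bin"]
    return stats, per_bin
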