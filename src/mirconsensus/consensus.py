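"""Cross-platform differential-expression consensus via rank products.

Expression measures from different miRNA platforms (two microarray designs
and small RNA-seq, in the motivating three-platform design) are not
directly comparable, but the *rank* of each miRNA's treated/control log2
ratio within a platform replicate is.  The rank product — the geometric
mean of a miRNA's rank ratios across all replicate columns — is therefore
a natural cross-platform consensus statistic: a small RP means the miRNA
sits near the top (or bottom, for the down direction) of every list.

Platforms probe unequal miRNA sets, so miRNAs are partitioned by
*availability pattern* (the subset of platforms that measure them); the
rank product runs within each pattern group, permutation p-values are
computed per group, and Benjamini–Hochberg FDR adjustment is applied to
the pooled union of all groups.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

Direction = Literal["up", "down"]

EXHAUSTIVE_LIMIT = 10**6


@dataclasses.dataclass
class PlatformRatioMatrix:
    """Per-platform replicate log2-ratio matrix (rows = miRNAs).

    ``log2intensity`` optionally carries per-sample log2 intensities used
    by the time-course detection filter.
    """

    platform: str
    log2ratio: pd.DataFrame
    log2intensity: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.log2ratio.shape[1] < 1:
            raise ValueError("at least one replicate column required")
        if self.log2ratio.index.duplicated().any():
            dups = self.log2ratio.index[self.log2ratio.index.duplicated()]
            raise ValueError(f"duplicate miRNA ids in {self.platform}: {list(dups)}")


@dataclasses.dataclass
class MergedRatioMatrix:
    """Union-of-miRNAs matrix with platform-major MultiIndex columns and a
    per-miRNA availability pattern (tuple of platform ids)."""

    values: pd.DataFrame
    patterns: pd.Series


def compute_log2ratios(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    pairing: Sequence[tuple[str, str]] | None = None,
    platform: str = "platform",
) -> PlatformRatioMatrix:
    """log2(treated/control) per miRNA for each paired replicate.

    ``pairing`` lists (treated_column, control_column) pairs; by default
    columns are paired positionally.  Intensities must be positive.
    """
    if pairing is None:
        if treated.shape[1] != control.shape[1]:
            raise ValueError("unpaired column counts; supply explicit pairing")
        pairing = list(zip(treated.columns, control.columns))
    if not treated.index.equals(control.index):
        control = control.reindex(treated.index)
    cols = {}
    for i, (tcol, ccol) in enumerate(pairing):
        t = treated[tcol].astype(float)
        c = control[ccol].astype(float)
        if (t <= 0).any() or (c <= 0).any():
            raise ValueError("non-positive intensity encountered")
        cols[f"rep{i + 1}"] = np.log2(t / c)
    return PlatformRatioMatrix(platform, pd.DataFrame(cols, index=treated.index))


def merge_platforms(matrices: Sequence[PlatformRatioMatrix]) -> MergedRatioMatrix:
    """Union merge across platforms, recording availability patterns."""
    if not matrices:
        raise ValueError("at least one platform required")
    names = [m.platform for m in matrices]
    if len(set(names)) != len(names):
        raise ValueError("duplicate platform ids")
    frames = []
    for m in matrices:
        df = m.log2ratio.copy()
        df.columns = pd.MultiIndex.from_product(
            [[m.platform], df.columns], names=["platform", "replicate"]
        )
        frames.append(df)
    values = pd.concat(frames, axis=1, join="outer").sort_index()
    patterns = pd.Series(
        {
            mirna: tuple(
                m.platform for m in matrices if mirna in m.log2ratio.index
            )
            for mirna in values.index
        },
        name="pattern",
    ).sort_index()
    return MergedRatioMatrix(values=values, patterns=patterns)


# ---------------------------------------------------------------------------
# rank product
# ---------------------------------------------------------------------------


def _pattern_groups(merged: MergedRatioMatrix) -> dict[tuple, list]:
    groups: dict[tuple, list] = {}
    for mirna, pat in merged.patterns.items():
        groups.setdefault(tuple(pat), []).append(mirna)
    return groups


def _group_ranks(
    merged: MergedRatioMatrix, pattern: tuple, members: list, direction: Direction
) -> pd.DataFrame:
    """Per-column average ranks within one availability group.

    direction="up": rank 1 = largest log2 ratio; "down": rank 1 = smallest.
    """
    cols = [c for c in merged.values.columns if c[0] in pattern]
    sub = merged.values.loc[members, cols]
    sign = -1.0 if direction == "up" else 1.0
    ranks = sub.apply(lambda col: rankdata(sign * col.to_numpy()), axis=0)
    return pd.DataFrame(ranks.to_numpy(), index=sub.index, columns=sub.columns)


def _rp_from_ranks(ranks: np.ndarray, G: int) -> np.ndarray:
    """RP = geometric mean of rank ratios r/G across columns."""
    return np.exp(np.log(ranks / G).mean(axis=1))


def rank_product(merged: MergedRatioMatrix, direction: Direction) -> pd.DataFrame:
    """Rank product per miRNA, computed within availability-pattern groups.

    Returns a DataFrame indexed by miRNA with columns ``rp``, ``k``
    (contributing columns), ``group_size`` and ``pattern``.  Groups of
    size 1 are untestable (rank undefined) and reported with NaN rp.
    """
    rows = []
    for pattern, members in sorted(_pattern_groups(merged).items()):
        G = len(members)
        if G < 2:
            warnings.warn(
                f"availability group {pattern} has a single miRNA; untestable"
            )
            for m in members:
                rows.append((m, np.nan, len(pattern), G, pattern))
            continue
        ranks = _group_ranks(merged, pattern, members, direction)
        rp = _rp_from_ranks(ranks.to_numpy(), G)
        k = ranks.shape[1]
        for m, r in zip(ranks.index, rp):
            rows.append((m, float(r), k, G, pattern))
    df = pd.DataFrame(
        rows, columns=["mirna", "rp", "k", "group_size", "pattern"]
    ).set_index("mirna")
    return df.sort_index()


def _exhaustive_null(G: int, k: int) -> np.ndarray:
    """Null RP values for all G^k integer rank tuples (exact pooled null:
    per-column ranks of one gene are marginally uniform and independent
    across independently shuffled columns)."""
    grids = np.meshgrid(*([np.arange(1, G + 1)] * k), indexing="ij")
    acc = np.zeros(grids[0].shape)
    for g in grids:
        acc += np.log(g / G)
    return np.exp(acc / k).ravel()


def permutation_pvalues(
    merged: MergedRatioMatrix,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    direction: Direction = "up",
    method: Literal["auto", "exhaustive", "monte-carlo"] = "auto",
) -> pd.Series:
    """Permutation p-values for the rank product, per availability group.

    Each permutation independently shuffles every column's ranks within
    the group; p(g) = #{null RP <= RP(g)} / (G * n_perm), with a floor of
    one count so a p-value is never below the estimator's resolution.
    Exhaustive enumeration replaces Monte Carlo when (G!)^k <= 10^6
    (``method`` forces one path; "exhaustive" falls back to Monte Carlo
    for groups above the limit).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    out = {}
    for pattern, members in sorted(_pattern_groups(merged).items()):
        G = len(members)
        if G < 2:
            for m in members:
                out[m] = np.nan
            continue
        ranks = _group_ranks(merged, pattern, members, direction)
        R = ranks.to_numpy()
        k = R.shape[1]
        rp = _rp_from_ranks(R, G)
        feasible = math.factorial(G) ** k <= EXHAUSTIVE_LIMIT
        if feasible and method != "monte-carlo":
            null = np.sort(_exhaustive_null(G, k))
            counts = np.searchsorted(null, rp, side="right")
            p = np.maximum(counts, 1) / len(null)
        else:
            acc = np.zeros((n_perm, G))
            for c in range(k):
                idx = np.argsort(rng.random((n_perm, G)), axis=1)
                acc += np.log(R[idx, c] / G)
            null = np.sort(np.exp(acc / k).ravel())
            counts = np.searchsorted(null, rp, side="right")
            p = np.maximum(counts, 1) / (G * n_perm)
        for m, pv in zip(ranks.index, p):
            out[m] = float(pv)
    return pd.Series(out, name=f"p_{direction}").sort_index()


def fdr_adjust(p: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Benjamini–Hochberg step-up over the pooled p-value vector.

    NaN entries (untestable miRNAs) are passed through unadjusted.
    """
    arr = np.asarray(p, dtype=float)
    if np.nanmin(arr, initial=0) < 0 or np.nanmax(arr, initial=0) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(arr, np.nan)
    mask = ~np.isnan(arr)
    if mask.any():
        q[mask] = multipletests(arr[mask], method="fdr_bh")[1]
    if isinstance(p, pd.Series):
        return pd.Series(q, index=p.index, name="q")
    return q


def mean_fold_change(merged: MergedRatioMatrix) -> pd.Series:
    """Geometric mean of per-measurement linear fold changes, i.e.
    2**mean(log2 ratio) over a miRNA's available columns."""
    return pd.Series(
        2.0 ** merged.values.mean(axis=1, skipna=True), name="mean_fc"
    ).sort_index()


def rank_product_analysis(
    merged: MergedRatioMatrix,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Full two-directional rank-product analysis.

    Runs the up and down directions separately, BH-adjusts each direction
    over the union of all miRNAs, and reports per miRNA the smaller
    direction's adjusted p as ``q`` with the direction flag, alongside the
    geometric-mean fold change over all available measurements.
    """
    rng = np.random.default_rng(seed)
    up = rank_product(merged, "up")
    down = rank_product(merged, "down")
    p_up = permutation_pvalues(merged, n_perm, rng, "up")
    p_down = permutation_pvalues(merged, n_perm, rng, "down")
    q_up = fdr_adjust(p_up)
    q_down = fdr_adjust(p_down)
    direction = np.where(q_up.to_numpy() <= q_down.to_numpy(), "up", "down")
    q = np.minimum(q_up.to_numpy(), q_down.to_numpy())
    res = pd.DataFrame(
        {
            "k": up["k"],
            "group_size": up["group_size"],
            "pattern": up["pattern"],
            "rp_up": up["rp"],
            "rp_down": down["rp"],
            "p_up": p_up,
            "p_down": p_down,
            "q": q,
            "direction": direction,
            "mean_fc": mean_fold_change(merged),
        }
    )
    return res


def consensus_list(
    results: pd.DataFrame,
    q_max: float = 0.05,
    fc_min: float = 1.2,
) -> pd.DataFrame:
    """Consensus regulated set: q < q_max and mean |FC| > fc_min (strict).

    Fold-change magnitude is 2**|mean log2 ratio|, so down-regulation by
    the same factor passes the same threshold.
    """
    if results.empty:
        return results
    fc_mag = 2.0 ** np.abs(np.log2(results["mean_fc"].astype(float)))
    keep = (results["q"] < q_max) & (fc_mag > fc_min)
    return results.loc[keep.fillna(False)]


def count_regulated_timecourse(
    matrices: Mapping[str, PlatformRatioMatrix],
    fc_min: float = 1.2,
    detect_log2: float = 7.0,
) -> pd.DataFrame:
    """Count regulated probes per time point, with and without the
    intensity detection filter.

    A probe is up-regulated when its mean fold change 2**mean(log2 ratio)
    exceeds ``fc_min`` (down: below 1/fc_min) and *detected* when at least
    half of its intensity samples exceed ``detect_log2``.
    """
    rows = []
    for tp, mat in matrices.items():
        mean_l2 = mat.log2ratio.mean(axis=1)
        up = mean_l2 > np.log2(fc_min)
        down = mean_l2 < -np.log2(fc_min)
        if mat.log2intensity is None:
            raise ValueError(f"time point {tp}: intensities required")
        inten = mat.log2intensity.reindex(mat.log2ratio.index)
        detected = (inten > detect_log2).sum(axis=1) >= inten.shape[1] / 2.0
        rows.append(
            {
                "timepoint": tp,
                "up": int(up.sum()),
                "down": int(down.sum()),
                "total": int((up | down).sum()),
                "up_detected": int((up & detected).sum()),
                "down_detected": int((down & detected).sum()),
                "total_detected": int(((up | down) & detected).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("timepoint")
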