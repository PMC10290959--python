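"""Stratified, observation-weighted concordance and the meta-analysis screen.

The statistic
-------------
For paired observations (x_i, y_i) within a stratum (a dataset/cohort),
an unordered sample pair (i, j) is *concordant* when
sign(x_i - x_j) = sign(y_i - y_j) != 0 and *discordant* when the signs are
opposite and non-zero; pairs never cross strata. Each pair contributes mass
w_i * w_j, where the default observation weight is 1 / n_stratum so that
every cohort contributes comparably regardless of size.

Two tie conventions for the concordance fraction c are provided:

``half_tie`` (default)
    c = (C + T_x / 2) / (C + D + T_x): pairs tied on the predictor x count
    one half, pairs tied on the response y are incomparable and excluded.
    This matches the convention of the established survival-analysis
    concordance routines.
``full_tie``
    c = (C + T) / (C + D + T) with T all tied mass: every tied pair counts
    fully in the numerator.

c is rescaled to c_scaled = 2c - 1 in [-1, 1] (a Somers'-D-type quantity;
with no ties and a single stratum, c_scaled equals Kendall's tau-a). A
z-score is formed as (c - 1/2) / sqrt(Var0[c]) with a tie-aware analytic
null variance (or an explicit within-stratum permutation estimate), and
two-tailed normal p-values are corrected with Benjamini-Hochberg.

The analytic null variance
--------------------------
Under within-stratum exchangeability of y, c - 1/2 is proportional to the
weighted Kendall score K = sum_{i<j} w_i w_j sign(x_i - x_j) sign(y_i - y_j)
divided by a permutation-invariant denominator, so Var0[c] follows from the
classical tie-corrected null variance of the Kendall S statistic computed
per stratum and scaled by w^4 (weights are equal within a stratum), summed
over strata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import AnalysisConfig, GmcError

__all__ = [
    "StratifiedPairSample",
    "PairCounts",
    "pair_counts_stratified",
    "concordance_from_counts",
    "scale_concordance",
    "null_variance",
    "z_pvalue",
    "bh_adjust",
    "concordance_test",
    "run_meta_screen",
]


@dataclass
class StratifiedPairSample:
    """Paired observations with stratum labels and per-observation weights.

    Weights default to 1 / n_stratum and must be equal within a stratum.
    """

    x: np.ndarray
    y: np.ndarray
    stratum: np.ndarray
    weight: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.stratum = np.asarray(self.stratum)
        n = len(self.x)
        if not (len(self.y) == len(self.stratum) == n):
            raise GmcError("x, y and stratum must have equal length")
        if self.weight is None:
            w = np.empty(n, dtype=float)
            for s in np.unique(self.stratum):
                mask = self.stratum == s
                w[mask] = 1.0 / mask.sum()
            self.weight = w
        else:
            self.weight = np.asarray(self.weight, dtype=float)
            if len(self.weight) != n:
                raise GmcError("weight length mismatch")
            if np.any(self.weight <= 0):
                raise GmcError("weights must be positive")
            for s in np.unique(self.stratum):
                ws = self.weight[self.stratum == s]
                if not np.allclose(ws, ws[0]):
                    raise GmcError(
                        f"weights must be equal within stratum {s!r}"
                    )


@dataclass
class PairCounts:
    """Weighted concordant/discordant/tied pair masses."""

    C: float = 0.0
    D: float = 0.0
    T_x: float = 0.0  # tied on x only
    T_y: float = 0.0  # tied on y only
    T_xy: float = 0.0  # tied on both
    n_comparable: int = 0  # raw count of within-stratum pairs not tied on y
    # permutation-invariant weighted masses used by the variance:
    mass_y_untied: float = 0.0  # pairs not tied on y  (half_tie denominator)
    mass_total: float = 0.0  # all within-stratum pair mass

    def add(self, other: "PairCounts") -> None:
        for f in ("C", "D", "T_x", "T_y", "T_xy",
                  "mass_y_untied", "mass_total"):
            setattr(self, f, getattr(self, f) + getattr(other, f))
        self.n_comparable += other.n_comparable


def _stratum_counts(x, y, w) -> PairCounts:
    n = len(x)
    i, j = np.triu_indices(n, k=1)
    u = np.sign(x[i] - x[j])
    v = np.sign(y[i] - y[j])
    ww = w[i] * w[j]
    prod = u * v
    c = PairCounts(
        C=float(ww[prod == 1].sum()),
        D=float(ww[prod == -1].sum()),
        T_x=float(ww[(u == 0) & (v != 0)].sum()),
        T_y=float(ww[(u != 0) & (v == 0)].sum()),
        T_xy=float(ww[(u == 0) & (v == 0)].sum()),
        n_comparable=int((v != 0).sum()),
    )
    c.mass_y_untied = c.C + c.D + c.T_x
    c.mass_total = float(ww.sum())
    return c


def pair_counts_stratified(sample: StratifiedPairSample) -> PairCounts:
    """Accumulate weighted pair counts over all within-stratum pairs.

    Raises :class:`GmcError` when every stratum has fewer than 2
    observations (no comparable pairs exist).
    """
    total = PairCounts()
    any_pairs = False
    for s in np.unique(sample.stratum):
        mask = sample.stratum == s
        if mask.sum() < 2:
            continue
        any_pairs = True
        total.add(
            _stratum_counts(sample.x[mask], sample.y[mask],
                            sample.weight[mask])
        )
    if not any_pairs:
        raise GmcError("no comparable pairs: all strata have < 2 observations")
    return total


def concordance_from_counts(
    counts: PairCounts, tie_policy: str = "half_tie"
) -> float:
    """Concordance fraction c in [0, 1]; NaN when the denominator is zero."""
    if tie_policy == "half_tie":
        denom = counts.C + counts.D + counts.T_x
        num = counts.C + 0.5 * counts.T_x
    elif tie_policy == "full_tie":
        t = counts.T_x + counts.T_y + counts.T_xy
        denom = counts.C + counts.D + t
        num = counts.C + t
    else:
        raise GmcError(f"unknown tie_policy {tie_policy!r}")
    if denom <= 0:
        return float("nan")
    return num / denom


def scale_concordance(c: float) -> float:
    """Map c in [0, 1] to c_scaled = 2c - 1 in [-1, 1]."""
    return 2.0 * c - 1.0


def _kendall_s_null_variance(x, y) -> float:
    """Tie-corrected null variance of the (unweighted) Kendall S statistic
    under random permutation of y, for one stratum."""
    n = len(x)
    if n < 2:
        return 0.0

    def tie_terms(v):
        _, cnt = np.unique(v, return_counts=True)
        t = cnt[cnt > 1].astype(float)
        return (
            float((t * (t - 1) * (2 * t + 5)).sum()),
            float((t * (t - 1)).sum()),
            float((t * (t - 1) * (t - 2)).sum()),
        )

    vt, t2, t3 = tie_terms(x)
    vu, u2, u3 = tie_terms(y)
    n = float(n)
    var = (n * (n - 1) * (2 * n + 5) - vt - vu) / 18.0
    if n > 2:
        var += t3 * u3 / (9.0 * n * (n - 1) * (n - 2))
    var += t2 * u2 / (2.0 * n * (n - 1))
    return var


def null_variance(
    sample: StratifiedPairSample,
    method: str = "analytic",
    tie_policy: str = "half_tie",
    n_perm: int = 1000,
    seed: int | None = None,
) -> float:
    """Null variance of c under within-stratum exchangeability of y.

    ``analytic`` uses the closed-form tie-aware Kendall-S variance per
    stratum (scaled by the stratum weight to the 4th power, weights being
    equal within a stratum) divided by the squared permutation-invariant
    denominator. ``permutation`` is the empirical variance of c over
    ``n_perm`` within-stratum permutations of y.
    """
    if method == "permutation":
        if n_perm < 100:
            raise GmcError("permutation variance needs n_perm >= 100")
        rng = np.random.default_rng(seed)
        cs = np.empty(n_perm)
        y = sample.y.copy()
        strata = [np.flatnonzero(sample.stratum == s)
                  for s in np.unique(sample.stratum)]
        for k in range(n_perm):
            yp = y.copy()
            for idx in strata:
                yp[idx] = y[rng.permutation(idx)]
            perm = StratifiedPairSample(
                sample.x, yp, sample.stratum, sample.weight
            )
            cs[k] = concordance_from_counts(
                pair_counts_stratified(perm), tie_policy
            )
        return float(np.var(cs[np.isfinite(cs)], ddof=1))
    if method != "analytic":
        raise GmcError(f"unknown variance method {method!r}")

    var_k = 0.0
    counts = PairCounts()
    for s in np.unique(sample.stratum):
        mask = sample.stratum == s
        if mask.sum() < 2:
            continue
        xs, ys = sample.x[mask], sample.y[mask]
        w = float(sample.weight[mask][0])
        var_k += w**4 * _kendall_s_null_variance(xs, ys)
        counts.add(_stratum_counts(xs, ys, sample.weight[mask]))
    denom = (
        counts.mass_y_untied if tie_policy == "half_tie" else counts.mass_total
    )
    if denom <= 0:
        return float("nan")
    return var_k / (4.0 * denom**2)


def z_pvalue(c: float, variance: float) -> tuple[float, float]:
    """z = (c - 1/2) / sqrt(variance) and the two-tailed normal p-value.

    Returns (nan, nan) when the variance is non-positive or c undefined.
    """
    if not np.isfinite(c) or not np.isfinite(variance) or variance <= 0:
        return float("nan"), float("nan")
    z = (c - 0.5) / np.sqrt(variance)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    NaN entries are excluded from the adjustment and returned as NaN.
    """
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.sum():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


@dataclass
class ConcordanceResult:
    counts: PairCounts
    c: float
    c_scaled: float
    variance: float
    z: float
    p: float
    n_datasets_used: int = 1


def concordance_test(
    x,
    y,
    stratum=None,
    weight=None,
    tie_policy: str = "half_tie",
    variance_method: str = "analytic",
    n_perm: int = 1000,
    seed: int | None = None,
) -> ConcordanceResult:
    """Full concordance test for one hypothesis (counts, c, z, p)."""
    x = np.asarray(x, dtype=float)
    if stratum is None:
        stratum = np.zeros(len(x), dtype=int)
    sample = StratifiedPairSample(x, y, stratum, weight)
    counts = pair_counts_stratified(sample)
    c = concordance_from_counts(counts, tie_policy)
    var = null_variance(
        sample, method=variance_method, tie_policy=tie_policy,
        n_perm=n_perm, seed=seed,
    )
    z, p = z_pvalue(c, var)
    n_used = sum(
        1 for s in np.unique(sample.stratum) if (sample.stratum == s).sum() >= 2
    )
    return ConcordanceResult(
        counts=counts,
        c=c,
        c_scaled=scale_concordance(c) if np.isfinite(c) else float("nan"),
        variance=var,
        z=z,
        p=p,
        n_datasets_used=n_used,
    )


SCREEN_COLUMNS = [
    "x_id", "y_id", "n_datasets", "C", "D", "T_x", "T_y", "T_xy",
    "c", "c_scaled", "z", "p", "q", "significant",
]


def run_meta_screen(
    x_matrices: dict[str, pd.DataFrame],
    y_matrices: dict[str, pd.DataFrame],
    x_universe,
    y_universe,
    config: AnalysisConfig | None = None,
    fdr: float | None = None,
    min_datasets: int = 2,
) -> pd.DataFrame:
    """Cross every (x, y) feature pair and test stratified concordance.

    ``x_matrices`` / ``y_matrices`` map dataset_id to a feature x sample
    DataFrame (samples already restricted to the tissue of interest; the
    sample columns of the two matrices are intersected per dataset). For
    each pair, observations are pooled across the datasets where both
    features are measured, with stratum = dataset and weight = 1/n_dataset.

    Pairs covered by fewer than ``min_datasets`` datasets are reported with
    their statistics (when computable) but excluded from the BH adjustment.
    Output rows are ordered by (x_id, y_id).
    """
    config = config or AnalysisConfig()
    alpha = config.fdr_gmi if fdr is None else fdr
    tie_policy = config.tie_policy

    # per-dataset aligned value arrays, features with >=1 finite value
    per_dataset: list[tuple[str, pd.DataFrame, pd.DataFrame]] = []
    for ds in sorted(set(x_matrices) & set(y_matrices)):
        xm, ym = x_matrices[ds], y_matrices[ds]
        common = xm.columns.intersection(ym.columns)
        if len(common) >= 2:
            per_dataset.append((ds, xm[common], ym[common]))

    records = []
    for xf in sorted(x_universe):
        for yf in sorted(y_universe):
            xs_parts, ys_parts, strata_parts = [], [], []
            n_used = 0
            for ds, xm, ym in per_dataset:
                if xf not in xm.index or yf not in ym.index:
                    continue
                xv = xm.loc[xf].to_numpy(dtype=float)
                yv = ym.loc[yf].to_numpy(dtype=float)
                ok = np.isfinite(xv) & np.isfinite(yv)
                if ok.sum() < 2:
                    continue
                xs_parts.append(xv[ok])
                ys_parts.append(yv[ok])
                strata_parts.append(np.full(ok.sum(), ds, dtype=object))
                n_used += 1
            row = {
                "x_id": xf, "y_id": yf, "n_datasets": n_used,
                "C": np.nan, "D": np.nan, "T_x": np.nan, "T_y": np.nan,
                "T_xy": np.nan, "c": np.nan, "c_scaled": np.nan,
                "z": np.nan, "p": np.nan,
            }
            if n_used >= 1:
                res = concordance_test(
                    np.concatenate(xs_parts),
                    np.concatenate(ys_parts),
                    np.concatenate(strata_parts),
                    tie_policy=tie_policy,
                )
                row.update(
                    C=res.counts.C, D=res.counts.D, T_x=res.counts.T_x,
                    T_y=res.counts.T_y, T_xy=res.counts.T_xy,
                    c=res.c, c_scaled=res.c_scaled, z=res.z, p=res.p,
                )
            records.append(row)

    if not records:
        return pd.DataFrame(columns=SCREEN_COLUMNS)
    table = pd.DataFrame.from_records(records)
    tested = (table["n_datasets"] >= min_datasets) & table["p"].notna()
    table["q"] = np.nan
    if tested.any():
        table.loc[tested, "q"] = bh_adjust(table.loc[tested, "p"].to_numpy())
    table["significant"] = table["q"].lt(alpha).fillna(False)
    return table[SCREEN_COLUMNS].reset_index(drop=True)
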