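"""Tumour-versus-normal differential testing and pathway DA/DF scores.

Per dataset and omics layer, features are tested between tumour and normal
samples (two-sided Wilcoxon rank-sum; exact null for small groups) and
called significant at BH-adjusted p < 0.1. Pathway scores aggregate the
calls:

    DA = (#up - #down) / #measured        in [-1, 1]
    DF = (#up + #down) / #measured        in [0, 1]

where the denominator counts pathway constituents measured in that dataset.
DA captures net accumulation vs depletion; DF captures total disruption
regardless of direction. Cross-dataset agreement between the metabolite and
transcript DF scores of a pathway is summarized by Spearman correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .concordance import bh_adjust
from .datamodel import AnalysisConfig, GeneSetCollection, GmcError, OmicsMatrix


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided rank-sum p-value; exact when both groups have <= 8
    observations and the pooled values are tie-free, otherwise the normal
    approximation with tie correction."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue)


def differential_features(
    matrix: OmicsMatrix,
    annotations: pd.DataFrame,
    config: AnalysisConfig | None = None,
    method: str = "wilcoxon",
    external_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-feature tumour-vs-normal differential table.

    Returns a DataFrame indexed by feature with columns p, q and direction
    ("up"/"down"/"none"); direction is non-none exactly when
    q < ``fdr_differential``, with the sign taken from the tumour-minus-
    normal median difference (mean difference as tie-break).

    ``external_table`` mode ingests a precomputed table (e.g. from a
    voom-style linear-model analysis) with columns p (or q) and effect (or
    direction) and applies only the FDR call.
    """
    config = config or AnalysisConfig()
    if method == "external_table":
        if external_table is None:
            raise GmcError("external_table method requires a table")
        t = external_table.copy()
        if "q" not in t.columns:
            if "p" not in t.columns:
                raise GmcError("external table needs a p or q column")
            t["q"] = bh_adjust(t["p"].to_numpy())
        if "p" not in t.columns:
            t["p"] = t["q"]
        if "direction" not in t.columns:
            if "effect" not in t.columns:
                raise GmcError("external table needs effect or direction")
            t["direction"] = np.where(t["effect"] > 0, "up", "down")
        sig = t["q"] < config.fdr_differential
        t.loc[~sig, "direction"] = "none"
        return t[["p", "q", "direction"]]

    ann = annotations.reindex(matrix.sample_ids)
    tumour = [s for s in matrix.sample_ids if ann.loc[s, "tissue"] == "tumour"]
    normal = [s for s in matrix.sample_ids if ann.loc[s, "tissue"] == "normal"]
    if len(tumour) < 2 or len(normal) < 2:
        raise GmcError(
            f"{matrix.dataset_id}: need >= 2 samples per tissue group "
            f"(tumour={len(tumour)}, normal={len(normal)})"
        )
    rows = []
    for feat in matrix.data.index:
        tv = matrix.data.loc[feat, tumour].dropna().to_numpy()
        nv = matrix.data.loc[feat, normal].dropna().to_numpy()
        if len(tv) < 2 or len(nv) < 2:
            rows.append((feat, np.nan, 0.0))
            continue
        p = wilcoxon_rank_sum(tv, nv)
        delta = float(np.median(tv) - np.median(nv))
        if delta == 0:
            delta = float(np.mean(tv) - np.mean(nv))
        rows.append((feat, p, delta))
    out = pd.DataFrame(rows, columns=["feature", "p", "delta"]).set_index("feature")
    out["q"] = bh_adjust(out["p"].to_numpy())
    sig = out["q"] < config.fdr_differential
    out["direction"] = "none"
    out.loc[sig & (out["delta"] > 0), "direction"] = "up"
    out.loc[sig & (out["delta"] < 0), "direction"] = "down"
    return out[["p", "q", "direction"]]


def da_score(members, differential: pd.DataFrame) -> float:
    """(#up - #down) / #measured over the pathway members present in the
    differential table. NaN when no member is measured."""
    measured = [m for m in set(members) if m in differential.index]
    if not measured:
        return float("nan")
    d = differential.loc[measured, "direction"]
    return float(((d == "up").sum() - (d == "down").sum()) / len(measured))


def df_score(members, differential: pd.DataFrame) -> float:
    """(#up + #down) / #measured; NaN when no member is measured."""
    measured = [m for m in set(members) if m in differential.index]
    if not measured:
        return float("nan")
    d = differential.loc[measured, "direction"]
    return float(((d == "up").sum() + (d == "down").sum()) / len(measured))


def pathway_inclusion(
    pathways: GeneSetCollection,
    measured_per_dataset: dict[str, set[str]],
    min_datasets: int = 5,
) -> list[str]:
    """Keep pathways with at least one constituent (gene or metabolite)
    measured in at least ``min_datasets`` of the supplied datasets."""
    kept = []
    for name in sorted(pathways.sets):
        members = pathways.sets[name]
        n = sum(
            1
            for measured in measured_per_dataset.values()
            if members & measured
        )
        if n >= min_datasets:
            kept.append(name)
    return kept


def pathway_scores(
    pathways: GeneSetCollection,
    differentials: dict[tuple[str, str], pd.DataFrame],
    included: list[str] | None = None,
) -> pd.DataFrame:
    """DA/DF score table over (pathway, dataset, omics_kind).

    ``differentials`` maps (dataset_id, omics_kind) to a differential table.
    Rows where no pathway member is measured in that dataset are omitted.
    """
    names = included if included is not None else sorted(pathways.sets)
    rows = []
    for name in names:
        members = pathways.sets[name]
        for (ds, kind), diff in sorted(differentials.items()):
            measured = [m for m in members if m in diff.index]
            if not measured:
                continue
            rows.append({
                "pathway": name,
                "dataset": ds,
                "omics_kind": kind,
                "n_measured": len(measured),
                "DA": da_score(members, diff),
                "DF": df_score(members, diff),
            })
    return pd.DataFrame(
        rows,
        columns=["pathway", "dataset", "omics_kind", "n_measured", "DA", "DF"],
    )


def df_cross_dataset_correlation(
    scores: pd.DataFrame, min_datasets: int = 4
) -> pd.DataFrame:
    """Per pathway, Spearman correlation between the metabolite-DF and
    transcript-DF vectors across datasets, with BH adjustment across
    pathways, plus the synchronous/asynchronous DA sign tally.

    Synchrony counts the sign of DA(transcript) * DA(metabolite) per
    (pathway, dataset); products of zero count as neither.
    """
    rows = []
    for name, grp in scores.groupby("pathway"):
        met = grp[grp["omics_kind"] == "metabolite"].set_index("dataset")
        rna = grp[grp["omics_kind"] == "transcript"].set_index("dataset")
        common = met.index.intersection(rna.index)
        sync = asyn = 0
        for ds in common:
            prod = met.loc[ds, "DA"] * rna.loc[ds, "DA"]
            if prod > 0:
                sync += 1
            elif prod < 0:
                asyn += 1
        rho = p = np.nan
        if len(common) >= min_datasets:
            a = met.loc[common, "DF"].to_numpy()
            b = rna.loc[common, "DF"].to_numpy()
            if np.ptp(a) > 0 and np.ptp(b) > 0:
                res = stats.spearmanr(a, b)
                rho, p = float(res.statistic), float(res.pvalue)
        rows.append({
            "pathway": name,
            "n_datasets": len(common),
            "rho": rho,
            "p": p,
            "n_synchronous": sync,
            "n_asynchronous": asyn,
        })
    out = pd.DataFrame(
        rows,
        columns=["pathway", "n_datasets", "rho", "p",
                 "n_synchronous", "n_asynchronous"],
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
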