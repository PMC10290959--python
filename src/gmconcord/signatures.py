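"""Per-sample gene-set (ssGSEA-style) scoring and signature screens.

A signature score summarizes, within one sample, how concentrated a gene
set's members are at the top of that sample's expression ranking. Genes are
ordered by descending expression; walking down the list, the in-set
empirical distribution (weighted by rank^exponent) is compared against the
out-of-set empirical distribution, and the score is the summed difference
of the two curves. Scores depend only on expression ranks, so any strictly
monotone transform of a sample leaves them unchanged.

The downstream screens delegate to the stratified concordance machinery:
signature scores play the role of x, metabolite abundances the role of y,
with dataset as the stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .concordance import bh_adjust, run_meta_screen
from .datamodel import (
    AnalysisConfig,
    GeneSetCollection,
    GmcError,
    OmicsMatrix,
)


def ssgsea_score(expression: pd.Series, gene_set, exponent: float = 0.25) -> float:
    """Enrichment score of ``gene_set`` within one sample.

    ``expression`` maps gene id -> value. The gene set is intersected with
    the measured genes and must leave both the set and its complement
    non-empty. Ties in expression receive average ranks for the weighting;
    traversal order among tied genes follows descending value with the
    input gene order as a deterministic tie-break.
    """
    genes = expression.index
    in_set = np.fromiter((g in gene_set for g in genes), dtype=bool,
                         count=len(genes))
    n_in = int(in_set.sum())
    if n_in == 0:
        raise GmcError("gene set shares no genes with the sample")
    if n_in == len(genes):
        raise GmcError("gene set covers every measured gene (empty complement)")

    values = expression.to_numpy(dtype=float)
    # average ascending ranks -> higher expression = larger rank statistic
    rho = stats.rankdata(values, method="average")
    order = np.argsort(-values, kind="stable")

    weights = np.where(in_set, np.abs(rho) ** exponent, 0.0)
    total_in = weights[in_set].sum()
    n_out = len(genes) - n_in

    p_in = np.cumsum(weights[order]) / total_in
    p_out = np.cumsum((~in_set)[order].astype(float)) / n_out
    return float(np.sum(p_in - p_out))


@dataclass
class SignatureScoreMatrix:
    """Signature x sample score table with scoring provenance."""

    scores: pd.DataFrame
    exponent: float
    genes_used: dict[str, list[str]] = field(default_factory=dict)
    genes_missing: dict[str, list[str]] = field(default_factory=dict)


def score_signatures(
    matrix: OmicsMatrix,
    signatures: GeneSetCollection,
    config: AnalysisConfig | None = None,
) -> SignatureScoreMatrix:
    """Score every signature in every sample of a transcriptomics matrix.

    Signatures with no measured genes yield an all-NaN row (flagged in the
    provenance); the rest record which member genes were present/absent.
    """
    config = config or AnalysisConfig()
    exponent = config.ssgsea_exponent
    measured = set(matrix.data.index)
    out = pd.DataFrame(
        np.nan, index=signatures.names(), columns=matrix.sample_ids
    )
    used: dict[str, list[str]] = {}
    missing: dict[str, list[str]] = {}
    for name in signatures.names():
        members = signatures.sets[name]
        present = sorted(members & measured)
        used[name] = present
        missing[name] = sorted(members - measured)
        if not present:
            continue
        for s in matrix.sample_ids:
            col = matrix.data[s].dropna()
            out.loc[name, s] = ssgsea_score(col, members, exponent)
    return SignatureScoreMatrix(
        scores=out, exponent=exponent, genes_used=used, genes_missing=missing
    )


def drop_gene_variant(
    signatures: GeneSetCollection, signature: str, gene: str
) -> GeneSetCollection:
    """Leave-one-gene-out variant of one signature (e.g. a mast-cell
    signature without its dominant marker). Errors if the gene is not a
    member."""
    members = signatures.sets[signature]
    if gene not in members:
        raise GmcError(f"{gene!r} is not a member of {signature!r}")
    new_sets = dict(signatures.sets)
    new_sets[f"{signature}_minus_{gene}"] = members - {gene}
    return GeneSetCollection(
        sets=new_sets,
        descriptions=dict(signatures.descriptions),
        classes=dict(signatures.classes),
    )


def signature_metabolite_screen(
    score_matrices: dict[str, pd.DataFrame],
    metabolite_matrices: dict[str, pd.DataFrame],
    config: AnalysisConfig | None = None,
    min_datasets: int = 2,
) -> pd.DataFrame:
    """Concordance meta-screen of signature scores against metabolites.

    ``score_matrices``/``metabolite_matrices`` map dataset_id to
    signature x sample and metabolite x sample tables (samples already
    restricted to the tissue of interest). Significance at
    q < ``fdr_signature``. Set ``min_datasets=1`` for per-dataset screens.
    """
    config = config or AnalysisConfig()
    signatures = sorted(
        set().union(*(set(m.index) for m in score_matrices.values()))
    )
    metabolites = sorted(
        set().union(*(set(m.index) for m in metabolite_matrices.values()))
    )
    return run_meta_screen(
        score_matrices,
        metabolite_matrices,
        signatures,
        metabolites,
        config=config,
        fdr=config.fdr_signature,
        min_datasets=min_datasets,
    )


def pathway_vs_rest_concordance(
    records: pd.DataFrame,
    pathway_membership: dict[str, set[str]],
) -> pd.DataFrame:
    """Per pathway, one-sided rank-sum test of whether member metabolites
    have larger |c_scaled| against a signature than non-members, with BH
    across pathways.

    ``records`` needs columns x_id or metabolite plus c_scaled (one row per
    metabolite, e.g. the ImmuneScore screen restricted to one signature).
    """
    col = "metabolite" if "metabolite" in records.columns else "x_id"
    vals = records.set_index(col)["c_scaled"].abs().dropna()
    rows = []
    for name in sorted(pathway_membership):
        members = [m for m in pathway_membership[name] if m in vals.index]
        others = [m for m in vals.index if m not in pathway_membership[name]]
        if not members or not others:
            rows.append({"pathway": name, "n_members": len(members),
                         "p": np.nan})
            continue
        p = float(
            stats.mannwhitneyu(
                vals.loc[members], vals.loc[others], alternative="greater",
                method="asymptotic",
            ).pvalue
        )
        rows.append({"pathway": name, "n_members": len(members), "p": p})
    out = pd.DataFrame(rows, columns=["pathway", "n_members", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
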