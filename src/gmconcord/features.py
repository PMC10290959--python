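"""Metabolite-name harmonization and the feature-inclusion universes.

The meta-analysis universe is defined by two filters: metabolites must be
quantified in at least ``min_metabolite_datasets`` of the datasets (default
8, i.e. more than half of 15), while genes must be quantified in every
dataset.
"""

from __future__ import annotations

import logging

from .datamodel import AnalysisConfig, HarmonizationMap, OmicsMatrix

logger = logging.getLogger(__name__)


def harmonize_metabolites(
    matrix: OmicsMatrix, hmap: HarmonizationMap
) -> OmicsMatrix:
    """Rename raw metabolite features to harmonized names.

    Features in the discard set are removed; unmapped names pass through
    unchanged (logged). If two raw features map to the same harmonized name
    within one dataset, the one with fewer missing values is kept (ties
    broken by lexicographically smallest raw name); the collision is logged.
    """
    if matrix.omics_kind != "metabolite":
        raise ValueError("harmonization applies to metabolite matrices only")
    df = matrix.data
    keep_rows = [f for f in df.index if f not in hmap.discard]
    n_discarded = len(df.index) - len(keep_rows)
    if n_discarded:
        logger.info(
            "%s: discarded %d unresolvable metabolite(s)",
            matrix.dataset_id,
            n_discarded,
        )

    # group raw names by their harmonized target, resolve collisions
    by_target: dict[str, list[str]] = {}
    for raw in keep_rows:
        target = hmap.mapping.get(raw, raw)
        if raw not in hmap.mapping:
            logger.debug("%s: unmapped metabolite %r kept as-is",
                         matrix.dataset_id, raw)
        by_target.setdefault(target, []).append(raw)

    chosen: dict[str, str] = {}  # raw -> harmonized, winners only
    for target, raws in by_target.items():
        if len(raws) > 1:
            missing = {r: int(df.loc[r].isna().sum()) for r in raws}
            winner = min(raws, key=lambda r: (missing[r], r))
            logger.info(
                "%s: harmonized-name collision on %r among %s; kept %r",
                matrix.dataset_id, target, sorted(raws), winner,
            )
        else:
            winner = raws[0]
        chosen[winner] = target

    out = df.loc[[r for r in keep_rows if r in chosen]].copy()
    out.index = [chosen[r] for r in out.index]
    out.index.name = df.index.name
    return OmicsMatrix(
        matrix.dataset_id, matrix.omics_kind, out, matrix.scale_state
    )


def feature_presence_filter(
    datasets: list[OmicsMatrix], config: AnalysisConfig
) -> tuple[list[str], list[str]]:
    """Return (metabolite universe, gene universe), both sorted.

    A metabolite enters the universe when present in at least
    ``config.min_metabolite_datasets`` metabolomics matrices; the gene
    universe is the intersection of gene ids across all transcriptomics
    matrices. Presence means the feature row exists with at least one
    non-missing value.
    """
    met_counts: dict[str, int] = {}
    gene_universe: set[str] | None = None
    n_met_datasets = 0
    for m in datasets:
        present = set(m.data.index[m.data.notna().any(axis=1)])
        if m.omics_kind == "metabolite":
            n_met_datasets += 1
            for f in present:
                met_counts[f] = met_counts.get(f, 0) + 1
        else:
            gene_universe = (
                present if gene_universe is None else gene_universe & present
            )
    metabolites = sorted(
        f
        for f, n in met_counts.items()
        if n >= config.min_metabolite_datasets
    )
    genes = sorted(gene_universe or set())
    if n_met_datasets and not metabolites:
        logger.warning(
            "metabolite universe is empty at min_metabolite_datasets=%d",
            config.min_metabolite_datasets,
        )
    if gene_universe is not None and not genes:
        logger.warning("gene universe is empty (no gene in all datasets)")
    return metabolites, genes
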