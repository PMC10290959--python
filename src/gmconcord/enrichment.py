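"""Over-representation analysis of pathways among a metabolite's partners.

For each metabolite with at least one significant gene association, the set
of its significantly associated genes is tested against every pathway with
a classical hypergeometric upper-tail test over the screened gene universe,
with BH adjustment within the metabolite (a global mode is available).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .concordance import bh_adjust
from .datamodel import AnalysisConfig, GeneSetCollection, GmcError

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "metabolite", "pathway", "overlap", "set_size", "selected_size",
    "universe_size", "p", "q", "significant",
]


def hypergeometric_test(
    overlap: int, set_size: int, selected_size: int, universe_size: int
) -> float:
    """Upper-tail P(X >= overlap) for X ~ Hypergeom(universe, set, selected)."""
    if not (
        0 <= overlap <= min(set_size, selected_size)
        and set_size <= universe_size
        and selected_size <= universe_size
    ):
        raise GmcError(
            "inconsistent hypergeometric arguments: "
            f"overlap={overlap}, set={set_size}, selected={selected_size}, "
            f"universe={universe_size}"
        )
    return float(
        stats.hypergeom.sf(overlap - 1, universe_size, set_size, selected_size)
    )


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Sample odds ratio (ad/bc) and exact two-sided p-value computed by
    summing hypergeometric outcome probabilities <= the observed one."""
    table = np.asarray(table, dtype=int)
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def enrich_metabolite_neighbourhoods(
    gmi_table: pd.DataFrame,
    pathways: GeneSetCollection,
    gene_universe,
    config: AnalysisConfig | None = None,
    adjust: str = "per_metabolite",
) -> pd.DataFrame:
    """Hypergeometric pathway enrichment of each metabolite's significant
    gene partners.

    ``gmi_table`` needs columns x_id (metabolite), y_id (gene) and
    significant. Only pathways with at least one member in the gene
    universe are tested. Metabolites with no significant genes are skipped.
    Significance is called at q < ``enrichment_alpha``.
    """
    config = config or AnalysisConfig()
    universe = set(gene_universe)
    pathway_members = {
        name: members & universe
        for name, members in pathways.sets.items()
    }
    pathway_members = {n: m for n, m in pathway_members.items() if m}

    sig = gmi_table[gmi_table["significant"].astype(bool)]
    rows = []
    for met, grp in sig.groupby("x_id"):
        selected = set(grp["y_id"]) & universe
        if not selected:
            logger.info("metabolite %r has no significant genes; skipped", met)
            continue
        met_rows = []
        for name in sorted(pathway_members):
            members = pathway_members[name]
            overlap = len(members & selected)
            p = hypergeometric_test(
                overlap, len(members), len(selected), len(universe)
            )
            met_rows.append({
                "metabolite": met,
                "pathway": name,
                "overlap": overlap,
                "set_size": len(members),
                "selected_size": len(selected),
                "universe_size": len(universe),
                "p": p,
            })
        if adjust == "per_metabolite":
            q = bh_adjust([r["p"] for r in met_rows])
            for r, qv in zip(met_rows, q):
                r["q"] = qv
        rows.extend(met_rows)

    if not rows:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    out = pd.DataFrame(rows)
    if adjust == "global":
        out["q"] = bh_adjust(out["p"].to_numpy())
    elif adjust != "per_metabolite":
        raise GmcError(f"unknown adjust mode {adjust!r}")
    out["significant"] = out["q"] < config.enrichment_alpha
    return out[RESULT_COLUMNS].reset_index(drop=True)
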