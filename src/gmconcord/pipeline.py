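"""End-to-end orchestration over a dataset manifest.

``run_all`` executes the analysis sequence: metabolomics preprocessing ->
gene-metabolite concordance screen (tumour samples) -> network distance
annotation and proximal-enrichment test -> tumour/normal pathway DA/DF
scores with cross-dataset DF correlation -> metabolite-neighbourhood
pathway enrichment -> signature scoring and the signature-metabolite
screen. Each stage's outputs are written before the next starts, and a
:class:`RunRecord` captures the config snapshot, seed, stage timings and a
sha256 digest of every output file so that identical reruns can be
verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features, network, pathway, preprocess, signatures
from .concordance import run_meta_screen
from .datamodel import AnalysisConfig, DatasetManifest, GmcError
from .enrichment import enrich_metabolite_neighbourhoods
from .io import (
    read_annotations,
    read_gmt,
    read_harmonization_map,
    read_matrix,
    write_matrix,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


@dataclass
class RunRecord:
    config: dict
    seed: int
    stage_seconds: dict[str, float] = field(default_factory=dict)
    output_digests: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "seed": self.seed,
                "stage_seconds": self.stage_seconds,
                "output_digests": self.output_digests,
                "counts": self.counts,
            },
            indent=2,
            sort_keys=True,
        )


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_table(df: pd.DataFrame, path: Path, record: RunRecord,
                 index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
    record.output_digests[path.name] = _digest(path)


def load_datasets(manifest: DatasetManifest):
    """Read every dataset's matrices and annotations."""
    out = []
    for entry in manifest:
        met = read_matrix(entry.metabolomics_path, "metabolite",
                          entry.dataset_id)
        rna = read_matrix(entry.transcriptomics_path, "transcript",
                          entry.dataset_id)
        ann = read_annotations(entry.annotation_path)
        out.append((entry, met, rna, ann))
    return out


def run_all(
    manifest: DatasetManifest,
    config: AnalysisConfig,
    outdir,
    pathways_gmt=None,
    signatures_gmt=None,
    reaction_network=None,
    harmonization_path=None,
    pathway_min_datasets: int = 5,
) -> RunRecord:
    """Run every stage the inputs support and write TSV outputs to
    ``outdir``. Stages whose optional inputs (pathway GMT, signature GMT,
    reaction network) are absent are skipped with a warning."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    record = RunRecord(config=config.to_dict(), seed=config.seed)
    t0 = time.monotonic()

    loaded = load_datasets(manifest)
    hmap = (
        read_harmonization_map(harmonization_path)
        if harmonization_path
        else None
    )

    # -- preprocess metabolomics ------------------------------------------
    processed = {}
    transcripts_log = {}
    annotations = {}
    reports = []
    for entry, met, rna, ann in loaded:
        if hmap is not None:
            met = features.harmonize_metabolites(met, hmap)
        m, rep = preprocess.preprocess_dataset(met, ann, config)
        processed[entry.dataset_id] = m
        transcripts_log[entry.dataset_id] = preprocess.log2_transform(rna)
        annotations[entry.dataset_id] = ann
        reports.append(rep.to_dict())
        _write_table(
            m.data, outdir / f"{entry.dataset_id}_metabolomics_normalized.tsv",
            record, index=True,
        )
    (outdir / "preprocess_report.jsonl").write_text(
        "\n".join(json.dumps(r, sort_keys=True) for r in reports) + "\n"
    )
    record.output_digests["preprocess_report.jsonl"] = _digest(
        outdir / "preprocess_report.jsonl"
    )
    record.stage_seconds["preprocess"] = time.monotonic() - t0
    t0 = time.monotonic()

    # -- feature universes + GMI screen (tumour samples only) -------------
    all_mats = list(processed.values()) + list(transcripts_log.values())
    met_universe, gene_universe = features.feature_presence_filter(
        all_mats, config
    )
    record.counts["metabolite_universe"] = len(met_universe)
    record.counts["gene_universe"] = len(gene_universe)

    def tissue_view(mat, ann, tissue):
        cols = [s for s in mat.data.columns
                if ann.loc[s, "tissue"] == tissue]
        return mat.data[cols]

    met_tumour = {
        ds: tissue_view(m, annotations[ds], "tumour")
        for ds, m in processed.items()
    }
    rna_tumour = {
        ds: tissue_view(m, annotations[ds], "tumour")
        for ds, m in transcripts_log.items()
    }
    gmi = run_meta_screen(
        met_tumour, rna_tumour, met_universe, gene_universe, config=config
    )
    record.counts["gmi_pairs"] = len(gmi)
    record.counts["gmi_significant"] = int(gmi["significant"].sum())
    logger.info(
        "gmi screen: %d pairs, %d significant at q<%g",
        len(gmi), record.counts["gmi_significant"], config.fdr_gmi,
    )
    _write_table(gmi, outdir / "gmi.tsv", record)
    record.stage_seconds["gmi_screen"] = time.monotonic() - t0
    t0 = time.monotonic()

    # -- network distances + proximal enrichment --------------------------
    if reaction_network is not None:
        graph = network.build_graph(reaction_network)
        dist = network.compute_distances(
            graph, gene_universe, met_universe, config
        )
        _write_table(dist, outdir / "distance.tsv", record)
        enr = network.proximal_enrichment(gmi, dist, config)
        pd.DataFrame(
            [{
                "sig_proximal": enr["table"][0][0],
                "sig_distal": enr["table"][0][1],
                "nonsig_proximal": enr["table"][1][0],
                "nonsig_distal": enr["table"][1][1],
                "odds_ratio": enr["odds_ratio"],
                "p": enr["p"],
            }]
        ).to_csv(outdir / "proximal_enrichment.tsv", sep="\t", index=False,
                 float_format=FLOAT_FORMAT)
        record.output_digests["proximal_enrichment.tsv"] = _digest(
            outdir / "proximal_enrichment.tsv"
        )
    else:
        logger.warning("no reaction network supplied; distance stage skipped")
    record.stage_seconds["network_distance"] = time.monotonic() - t0
    t0 = time.monotonic()

    # -- tumour vs normal pathway DA/DF -----------------------------------
    pathways = read_gmt(pathways_gmt) if pathways_gmt else None
    if pathways is not None:
        differentials = {}
        for ds in processed:
            ann = annotations[ds]
            tissues = set(ann["tissue"])
            if {"tumour", "normal"} <= tissues:
                try:
                    differentials[(ds, "metabolite")] = (
                        pathway.differential_features(
                            processed[ds], ann, config
                        )
                    )
                    differentials[(ds, "transcript")] = (
                        pathway.differential_features(
                            transcripts_log[ds], ann, config
                        )
                    )
                except GmcError as exc:
                    logger.warning("%s: differential stage skipped (%s)",
                                   ds, exc)
        if differentials:
            measured = {}
            for (ds, _), diff in differentials.items():
                measured.setdefault(ds, set()).update(diff.index)
            included = pathway.pathway_inclusion(
                pathways, measured, min_datasets=pathway_min_datasets
            )
            scores = pathway.pathway_scores(pathways, differentials, included)
            _write_table(scores, outdir / "pathway_scores.tsv", record)
            corr = pathway.df_cross_dataset_correlation(scores)
            _write_table(corr, outdir / "df_correlation.tsv", record)
            record.counts["pathways_included"] = len(included)
        else:
            logger.warning(
                "no dataset has both tumour and normal samples; "
                "pathway stage skipped"
            )

        # -- metabolite-neighbourhood enrichment --------------------------
        enrich = enrich_metabolite_neighbourhoods(
            gmi, pathways, gene_universe, config
        )
        _write_table(enrich, outdir / "neighbourhood_enrichment.tsv", record)
        record.counts["enriched_results"] = int(
            enrich["significant"].sum()
        ) if len(enrich) else 0
    else:
        logger.warning("no pathway GMT supplied; pathway stages skipped")
    record.stage_seconds["pathways"] = time.monotonic() - t0
    t0 = time.monotonic()

    # -- signatures --------------------------------------------------------
    if signatures_gmt:
        sig_sets = read_gmt(signatures_gmt)
        score_mats = {}
        for ds, rna in transcripts_log.items():
            sm = signatures.score_signatures(rna, sig_sets, config)
            score_mats[ds] = sm.scores
            _write_table(
                sm.scores, outdir / f"{ds}_signature_scores.tsv", record,
                index=True,
            )
        score_tumour = {
            ds: s[[c for c in s.columns
                   if annotations[ds].loc[c, "tissue"] == "tumour"]]
            for ds, s in score_mats.items()
        }
        sig_screen = signatures.signature_metabolite_screen(
            score_tumour, met_tumour, config
        )
        _write_table(sig_screen, outdir / "signature_metabolite.tsv", record)
        record.counts["signature_pairs"] = len(sig_screen)
        record.counts["signature_significant"] = int(
            sig_screen["significant"].sum()
        )
    else:
        logger.warning("no signature GMT supplied; signature stage skipped")
    record.stage_seconds["signatures"] = time.monotonic() - t0

    (outdir / "run_record.json").write_text(record.to_json() + "\n")
    return record
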