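#!/usr/bin/env python
"""Generate the synthetic multi-cohort study used by the analysis scripts.

Six datasets of unequal size with paired metabolomics/transcriptomics,
six planted proximal gene-metabolite dependencies, a 12-gene immune block
driving two hub metabolites, two-batch structure, per-sample dilution and
MNAR missingness. Also writes the pathway GMT, the signature GMT and a
chain reaction network so every later stage has its inputs.

Outputs: results/synthetic/ (TSV matrices + manifest + truth tables),
results/pathways.gmt, results/signatures.gmt, results/network.tsv.
"""

from pathlib import Path

from gmconcord.datamodel import GeneSetCollection, Reaction, ReactionNetwork
from gmconcord.io import write_gmt, write_reaction_table
from gmconcord.synthetic import (
    ImmuneBlock,
    SyntheticSpec,
    generate_camp_like,
    write_bundles,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 20240901

GENES = [f"G{i + 1:04d}" for i in range(80)]
METS = [f"M{i + 1:03d}" for i in range(25)]
IMMUNE_GENES = tuple(GENES[60:72])
HUBS = ("M021", "M022")


def study_spec() -> SyntheticSpec:
    return SyntheticSpec(
        n_datasets=6,
        samples_per_dataset=(30, 26, 34, 28, 40, 24),
        n_genes=80,
        n_metabolites=25,
        planted_gmi=tuple(
            (f"G{i + 1:04d}", f"M{i + 1:03d}", 3.0, 1.0) for i in range(6)
        ),
        immune_block=ImmuneBlock(
            genes=IMMUNE_GENES, hub_metabolites=HUBS,
            gene_effect=8.0, hub_effect=6.0,
        ),
        metabolite_presence_prob=0.9,
        batch_n=2,
        seed=SEED,
    )


def main() -> None:
    spec = study_spec()
    bundles, truth = generate_camp_like(spec)
    manifest = write_bundles(bundles, truth, RESULTS / "synthetic")
    n_samples = sum(len(b.annotations) for b in bundles)
    print(f"wrote {len(bundles)} datasets, {n_samples} samples total")
    print(f"manifest: {manifest}")

    pathways = GeneSetCollection(sets={
        "GLYCOLYSIS_LIKE": frozenset(set(GENES[:10]) | set(METS[:4])),
        "TCA_LIKE": frozenset(set(GENES[10:20]) | set(METS[4:8])),
        "NUCLEOTIDE_LIKE": frozenset(set(GENES[20:35]) | set(METS[8:12])),
        "IMMUNE_SIGNALLING": frozenset(set(IMMUNE_GENES) | set(HUBS)),
        "LIPID_LIKE": frozenset(set(GENES[40:55]) | set(METS[12:16])),
    })
    write_gmt(pathways, RESULTS / "pathways.gmt")

    signatures = GeneSetCollection(sets={
        "ImmuneScore": frozenset(IMMUNE_GENES),
        "Tcell_like": frozenset(IMMUNE_GENES[:6]),
        "decoy_stromal": frozenset(GENES[40:50]),
    })
    write_gmt(signatures, RESULTS / "signatures.gmt")

    # chain network: reaction i converts M_i to M_{i+1}, catalyzed by G_i,
    # so the planted diagonal pairs sit at reaction distance 1
    reactions = [
        Reaction(f"R{i + 1}", (METS[i], METS[i + 1]), (f"G{i + 1:04d}",))
        for i in range(len(METS) - 1)
    ]
    write_reaction_table(
        ReactionNetwork(reactions=reactions), RESULTS / "network.tsv"
    )
    print("wrote pathways.gmt, signatures.gmt, network.tsv")
    print(f"planted pairs: {len(spec.planted_gmi)}; "
          f"immune block: {len(IMMUNE_GENES)} genes -> hubs {HUBS}")


if __name__ == "__main__":
    main()
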