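"""Synthetic multi-cohort paired omics with known ground truth.

The generator emulates the structure of a heterogeneous pan-cancer
metabolomics/transcriptomics compendium: many datasets of unequal size,
heterogeneous metabolite coverage across datasets, tumour/normal labels,
dataset-specific batch factors and per-sample dilution on the metabolomics
side, missing-not-at-random values concentrated at low abundances, planted
monotone gene-metabolite dependencies, and a latent immune-cell fraction
that jointly drives a block of "immune" genes and a few hub metabolites.

Everything is generated on a log2 latent scale and exponentiated, so
transcript matrices resemble TPM-like positive values and metabolite
matrices resemble raw ion intensities before normalization. All randomness
flows from ``SyntheticSpec.seed``; the same spec reproduces bit-identical
output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .datamodel import OmicsMatrix, Reaction, ReactionNetwork

DEFAULT_SAMPLE_SIZES = (18, 24, 30, 36, 45, 20, 60, 28, 90, 34, 50, 22, 70,
                        40, 110)


@dataclass(frozen=True)
class ImmuneBlock:
    """A latent cell-mixture component: per-sample immune fraction
    f ~ Beta(beta_a, beta_b) adds gene_effect * f to the log2 expression of
    the block genes and hub_effect * f to the log2 abundance of the hub
    metabolites."""

    genes: tuple[str, ...]
    hub_metabolites: tuple[str, ...]
    gene_effect: float = 3.0
    hub_effect: float = 2.0
    beta_a: float = 2.0
    beta_b: float = 5.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Design of one synthetic compendium. Defaults mirror a desk-scale
    analogue of a 15-cohort study with heterogeneous sample sizes."""

    n_datasets: int = 15
    samples_per_dataset: tuple[int, ...] = DEFAULT_SAMPLE_SIZES
    n_genes: int = 300
    n_metabolites: int = 60
    planted_gmi: tuple[tuple[str, str, float, float], ...] = ()
    immune_block: ImmuneBlock | None = None
    metabolite_presence_prob: float = 0.8
    missingness: tuple[float, float] | None = (-2.2, 1.3)  # logit intercept, slope
    batch_n: int = 1
    batch_log2_sd: float = 0.5
    dilution: tuple[float, float] = (0.5, 2.0)
    tumour_fraction: float = 0.7
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_datasets < 1 or self.n_genes < 1 or self.n_metabolites < 1:
            raise ValueError("all counts must be positive")
        if len(self.samples_per_dataset) < self.n_datasets:
            raise ValueError("samples_per_dataset shorter than n_datasets")
        if not 0.0 <= self.metabolite_presence_prob <= 1.0:
            raise ValueError("metabolite_presence_prob must be in [0, 1]")
        if not 0.0 <= self.tumour_fraction <= 1.0:
            raise ValueError("tumour_fraction must be in [0, 1]")
        genes = set(self.gene_ids())
        mets = set(self.metabolite_ids())
        for g, m, _, _ in self.planted_gmi:
            if g not in genes or m not in mets:
                raise ValueError(
                    f"planted pair ({g}, {m}) outside declared feature range"
                )
        if self.immune_block is not None:
            if not set(self.immune_block.genes) <= genes:
                raise ValueError("immune block genes outside declared range")
            if not set(self.immune_block.hub_metabolites) <= mets:
                raise ValueError("hub metabolites outside declared range")

    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]

    def metabolite_ids(self) -> list[str]:
        return [f"M{i + 1:03d}" for i in range(self.n_metabolites)]

    def dataset_ids(self) -> list[str]:
        return [f"DS{i + 1:02d}" for i in range(self.n_datasets)]

    @classmethod
    def recovery(
        cls,
        seed: int = 0,
        n_datasets: int = 5,
        n_samples: int = 30,
        n_genes: int = 50,
        n_metabolites: int = 20,
        n_planted: int = 20,
        slope: float = 3.0,
        noise_sd: float = 1.0,
    ) -> "SyntheticSpec":
        """Planted-pair recovery design: ``n_planted`` monotone pairs
        (gene k, metabolite k) within an n_metabolites x n_genes grid.

        Metabolite coverage is complete in this design so that recovery
        measures the screen's statistical power under dilution, batch and
        MNAR missingness rather than coverage dropout; the general
        generator keeps heterogeneous presence by default.
        """
        planted = tuple(
            (f"G{i + 1:04d}", f"M{i + 1:03d}", slope, noise_sd)
            for i in range(n_planted)
        )
        return cls(
            n_datasets=n_datasets,
            samples_per_dataset=(n_samples,) * n_datasets,
            n_genes=n_genes,
            n_metabolites=n_metabolites,
            planted_gmi=planted,
            metabolite_presence_prob=1.0,
            noise_sd=noise_sd,
            seed=seed,
        )

    @classmethod
    def clean(cls, **kwargs) -> "SyntheticSpec":
        """No missingness, single batch, unit dilution, full presence:
        preprocessing on this output reduces to a pure log2 transform."""
        kwargs.setdefault("missingness", None)
        kwargs.setdefault("dilution", (1.0, 1.0))
        kwargs.setdefault("metabolite_presence_prob", 1.0)
        kwargs.setdefault("batch_n", 1)
        return cls(**kwargs)

    def nulled(self) -> "SyntheticSpec":
        """Same design with every planted effect zeroed."""
        planted = tuple((g, m, 0.0, sd) for g, m, _, sd in self.planted_gmi)
        block = self.immune_block
        if block is not None:
            block = dataclasses.replace(block, gene_effect=0.0, hub_effect=0.0)
        return dataclasses.replace(self, planted_gmi=planted,
                                   immune_block=block)


@dataclass
class SyntheticDataset:
    dataset_id: str
    metabolomics: OmicsMatrix
    transcriptomics: OmicsMatrix
    annotations: pd.DataFrame  # index sample_id, columns tissue, batch


@dataclass
class SyntheticTruth:
    planted: pd.DataFrame  # gene, metabolite, slope, noise_sd
    immune_fraction: dict[str, pd.Series] = field(default_factory=dict)
    dilution: dict[str, pd.Series] = field(default_factory=dict)
    presence: pd.DataFrame | None = None  # metabolites x datasets, bool
    missing_mask: dict[str, pd.DataFrame] = field(default_factory=dict)


def generate_camp_like(
    spec: SyntheticSpec,
) -> tuple[list[SyntheticDataset], SyntheticTruth]:
    """Generate the full compendium described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids()
    mets = spec.metabolite_ids()
    datasets = spec.dataset_ids()

    gene_base = pd.Series(rng.uniform(3.0, 8.0, size=len(genes)), index=genes)
    met_base = pd.Series(rng.uniform(10.0, 16.0, size=len(mets)), index=mets)

    planted_gene_noise = {g: sd for g, _, _, sd in spec.planted_gmi}
    planted_by_met: dict[str, list[tuple[str, float, float]]] = {}
    for g, m, slope, sd in spec.planted_gmi:
        planted_by_met.setdefault(m, []).append((g, slope, sd))

    block = spec.immune_block
    block_genes = set(block.genes) if block else set()
    hub_mets = set(block.hub_metabolites) if block else set()

    presence = pd.DataFrame(
        rng.random((len(mets), len(datasets))) < spec.metabolite_presence_prob,
        index=mets, columns=datasets,
    )

    truth = SyntheticTruth(
        planted=pd.DataFrame(
            list(spec.planted_gmi),
            columns=["gene", "metabolite", "slope", "noise_sd"],
        ),
        presence=presence,
    )

    bundles: list[SyntheticDataset] = []
    for d_idx, ds in enumerate(datasets):
        n = int(spec.samples_per_dataset[d_idx])
        samples = [f"{ds}_S{i + 1:03d}" for i in range(n)]

        n_tumour = int(round(spec.tumour_fraction * n))
        tissue = np.array(["tumour"] * n_tumour + ["normal"] * (n - n_tumour))
        rng.shuffle(tissue)

        batch_ids = np.array(
            [f"B{(i % spec.batch_n) + 1}" for i in range(n)]
        )
        rng.shuffle(batch_ids)
        batch_factor = {
            f"B{b + 1}": float(2.0 ** rng.normal(0.0, spec.batch_log2_sd))
            if spec.batch_n > 1 else 1.0
            for b in range(spec.batch_n)
        }

        f_imm = (
            rng.beta(block.beta_a, block.beta_b, size=n)
            if block is not None
            else np.zeros(n)
        )
        latent = {
            g: rng.normal(0.0, 1.0, size=n) for g, *_ in spec.planted_gmi
        }

        # transcripts: base + planted driver + immune loading + noise
        g_log = np.empty((len(genes), n))
        for i, g in enumerate(genes):
            sd = planted_gene_noise.get(g, spec.noise_sd)
            row = gene_base[g] + rng.normal(0.0, sd, size=n)
            if g in latent:
                row = row + latent[g]
            if g in block_genes:
                row = row + block.gene_effect * f_imm
            g_log[i] = row
        g_lin = pd.DataFrame(2.0 ** g_log, index=genes, columns=samples)

        # metabolites: base + planted response + hub response + noise,
        # then dilution and batch factors on the linear scale
        m_log = np.empty((len(mets), n))
        for i, m in enumerate(mets):
            sd = spec.noise_sd
            contrib = np.zeros(n)
            for g, slope, pair_sd in planted_by_met.get(m, ()):
                contrib = contrib + slope * latent[g]
                sd = pair_sd
            row = met_base[m] + contrib + rng.normal(0.0, sd, size=n)
            if m in hub_mets:
                row = row + block.hub_effect * f_imm
            m_log[i] = row

        lo, hi = spec.dilution
        dil = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
        bfac = np.array([batch_factor[b] for b in batch_ids])
        m_lin = (2.0 ** m_log) * dil * bfac

        # MNAR missingness: logistic in the within-metabolite z of log2
        # abundance, decreasing with abundance
        miss = np.zeros_like(m_lin, dtype=bool)
        if spec.missingness is not None:
            icpt, slope_m = spec.missingness
            z = m_log - m_log.mean(axis=1, keepdims=True)
            sd_rows = m_log.std(axis=1, keepdims=True)
            sd_rows[sd_rows == 0] = 1.0
            z = z / sd_rows
            p_miss = expit(icpt - slope_m * z)
            miss = rng.random(m_lin.shape) < p_miss

        present_mask = presence[ds].to_numpy()
        m_values = np.where(miss, np.nan, m_lin)[present_mask]
        met_df = pd.DataFrame(
            m_values, index=list(np.array(mets)[present_mask]),
            columns=samples,
        )

        ann = pd.DataFrame(
            {"tissue": tissue, "batch": batch_ids}, index=samples
        )
        ann.index.name = "sample_id"

        truth.immune_fraction[ds] = pd.Series(f_imm, index=samples)
        truth.dilution[ds] = pd.Series(dil, index=samples)
        truth.missing_mask[ds] = pd.DataFrame(
            miss, index=mets, columns=samples
        )

        bundles.append(
            SyntheticDataset(
                dataset_id=ds,
                metabolomics=OmicsMatrix(ds, "metabolite", met_df, "linear"),
                transcriptomics=OmicsMatrix(ds, "transcript", g_lin, "linear"),
                annotations=ann,
            )
        )
    return bundles, truth


def generate_null(spec: SyntheticSpec):
    """The same design with all planted and immune effects zeroed; used for
    type-I-error calibration."""
    return generate_camp_like(spec.nulled())


def generate_toy_network(
    n_chain: int, branching: int = 0, currency: str | None = None
) -> ReactionNetwork:
    """Linear reaction chain with optional branches and an optional currency
    metabolite shared by every reaction.

    Reaction ``Ri`` converts ``M{i-1}`` to ``M{i}`` and is catalyzed by
    ``Gi``; consecutive reactions share a metabolite, so gene ``Gi`` is at
    distance ``|i - j| + 1`` from ``M{j}``. Branch reactions ``Bk`` hang off
    ``M1``. The shared currency metabolite is added to every reaction's
    participant list but is NOT placed on the network's currency list; the
    caller decides whether to exclude it.
    """
    reactions = []
    for i in range(1, n_chain + 1):
        mets = [f"M{i - 1}", f"M{i}"]
        if currency:
            mets.append(currency)
        reactions.append(
            Reaction(f"R{i}", tuple(mets), (f"G{i}",), True)
        )
    for b in range(1, branching + 1):
        mets = ["M1", f"MB{b}"]
        if currency:
            mets.append(currency)
        reactions.append(
            Reaction(f"B{b}", tuple(mets), (f"GB{b}",), True)
        )
    return ReactionNetwork(reactions=reactions)


def write_bundles(
    bundles: list[SyntheticDataset],
    truth: SyntheticTruth,
    outdir,
) -> Path:
    """Write the compendium in the TSV/manifest layout the pipeline reads;
    returns the manifest path. Truth tables go to ``truth_*.tsv``."""
    from .io import write_matrix  # local import avoids a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for b in bundles:
        mpath = outdir / f"{b.dataset_id}_metabolomics.tsv"
        tpath = outdir / f"{b.dataset_id}_transcriptomics.tsv"
        apath = outdir / f"{b.dataset_id}_annotations.tsv"
        write_matrix(b.metabolomics, mpath)
        write_matrix(b.transcriptomics, tpath)
        b.annotations.to_csv(apath, sep="\t")
        rows.append({
            "dataset_id": b.dataset_id,
            "cancer_type": "synthetic",
            "platform": "rnaseq",
            "metabolomics_path": mpath.name,
            "transcriptomics_path": tpath.name,
            "annotation_path": apath.name,
        })
    manifest_path = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest_path, sep="\t", index=False)
    truth.planted.to_csv(outdir / "truth_planted.tsv", sep="\t", index=False)
    if truth.presence is not None:
        truth.presence.to_csv(outdir / "truth_presence.tsv", sep="\t")
    dil = pd.concat(
        {ds: s for ds, s in truth.dilution.items()}, names=["dataset", "sample"]
    )
    dil.rename("dilution").to_csv(outdir / "truth_dilution.tsv", sep="\t")
    imm = pd.concat(
        {ds: s for ds, s in truth.immune_fraction.items()},
        names=["dataset", "sample"],
    )
    imm.rename("immune_fraction").to_csv(
        outdir / "truth_immune_fraction.tsv", sep="\t"
    )
    return manifest_path
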