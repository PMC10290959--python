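"""Core domain types shared by every pipeline stage.

A study is a collection of datasets (cohorts). Each dataset contributes one
metabolomics and one transcriptomics feature-by-sample matrix over a shared
set of sample columns, plus tumour/normal (and optionally batch) annotations.
Feature matrices are wrapped in :class:`OmicsMatrix`, which tracks whether
values are on the linear abundance scale or already log2-transformed so that
preprocessing stages can enforce their contracts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GmcError",
    "DataFormatError",
    "OmicsMatrix",
    "SampleAnnotation",
    "DatasetManifest",
    "ManifestEntry",
    "HarmonizationMap",
    "GeneSetCollection",
    "Reaction",
    "ReactionNetwork",
    "AnalysisConfig",
]


class GmcError(Exception):
    """Base class for all errors raised by this package."""


class DataFormatError(GmcError):
    """Malformed or internally inconsistent input data."""


@dataclass
class OmicsMatrix:
    """One dataset's feature x sample abundance table.

    Parameters
    ----------
    dataset_id : str
        Cohort identifier, used as the stratum label downstream.
    omics_kind : {"metabolite", "transcript"}
    data : pandas.DataFrame
        Features on the rows, samples on the columns. NaN marks a missing
        measurement.
    scale_state : {"linear", "log2"}
        Linear abundances must be non-negative; log2 values are unconstrained.
    """

    dataset_id: str
    omics_kind: str
    data: pd.DataFrame
    scale_state: str = "linear"

    def __post_init__(self) -> None:
        if self.omics_kind not in ("metabolite", "transcript"):
            raise DataFormatError(f"unknown omics_kind {self.omics_kind!r}")
        if self.scale_state not in ("linear", "log2"):
            raise DataFormatError(f"unknown scale_state {self.scale_state!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise DataFormatError(
                f"duplicate feature id {dup!r} in dataset {self.dataset_id}"
            )
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise DataFormatError(
                f"duplicate sample id {dup!r} in dataset {self.dataset_id}"
            )
        if self.scale_state == "linear":
            vals = self.data.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise DataFormatError(
                    f"negative value in linear-scale matrix {self.dataset_id}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(
            self.dataset_id, self.omics_kind, self.data.copy(), self.scale_state
        )


@dataclass(frozen=True)
class SampleAnnotation:
    sample_id: str
    tissue: str  # "tumour" | "normal"
    batch: str | None = None

    def __post_init__(self) -> None:
        if self.tissue not in ("tumour", "normal"):
            raise DataFormatError(
                f"tissue must be tumour/normal, got {self.tissue!r}"
            )


@dataclass(frozen=True)
class ManifestEntry:
    dataset_id: str
    cancer_type: str
    platform: str  # "microarray" | "rnaseq"
    metabolomics_path: str
    transcriptomics_path: str
    annotation_path: str

    def __post_init__(self) -> None:
        if self.platform not in ("microarray", "rnaseq"):
            raise DataFormatError(f"unknown platform {self.platform!r}")


@dataclass
class DatasetManifest:
    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        ids = [e.dataset_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise DataFormatError("duplicate dataset_id in manifest")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class HarmonizationMap:
    """Many-to-one raw -> harmonized metabolite-name mapping.

    ``discard`` lists raw names judged to be incorrectly aggregated compounds;
    these are removed from matrices rather than renamed.
    """

    mapping: dict[str, str] = field(default_factory=dict)
    discard: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.discard & set(self.mapping)
        if overlap:
            raise DataFormatError(
                f"names both mapped and discarded: {sorted(overlap)[:5]}"
            )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics) with optional class labels."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise DataFormatError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return sorted(self.sets)


@dataclass(frozen=True)
class Reaction:
    reaction_id: str
    metabolites: tuple[str, ...]
    genes: tuple[str, ...]
    reversible: bool = True

    def __post_init__(self) -> None:
        if not self.metabolites:
            raise DataFormatError(
                f"reaction {self.reaction_id!r} has no metabolite participants"
            )


@dataclass
class ReactionNetwork:
    """Reactions with metabolite participants and catalyzing genes.

    The bipartite gene-reaction-metabolite structure is the substrate for
    reaction-step distances; ``currency_metabolites`` are ubiquitous cofactors
    excluded from reaction-to-reaction connectivity.
    """

    reactions: list[Reaction]
    currency_metabolites: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [r.reaction_id for r in self.reactions]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise DataFormatError(f"duplicate reaction_id {dup!r}")

    @property
    def metabolites(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions:
            out.update(r.metabolites)
        return out

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions:
            out.update(r.genes)
        return out


_TIE_POLICIES = ("half_tie", "full_tie")


@dataclass
class AnalysisConfig:
    """All analysis thresholds, read from a flat key: value config file.

    Defaults mirror the study design: gene-metabolite screens called at
    FDR 0.01, signature-metabolite screens at FDR 0.05, tumour/normal
    differential calls at FDR 0.1, neighbourhood enrichment at adjusted
    p < 0.01, metabolites kept when present in >= 8 datasets, features
    dropped above 80% missingness, PQN reference built from metabolites
    with < 20% missingness, and proximal defined as reaction distance <= 2.
    """

    fdr_gmi: float = 0.01
    fdr_signature: float = 0.05
    fdr_differential: float = 0.1
    enrichment_alpha: float = 0.01
    min_metabolite_datasets: int = 8
    missing_drop_fraction: float = 0.8
    pqn_reference_missing_max: float = 0.2
    proximal_max_distance: int = 2
    distance_cap: int = 10
    tie_policy: str = "half_tie"
    ssgsea_exponent: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fdr_gmi",
            "fdr_signature",
            "fdr_differential",
            "enrichment_alpha",
            "missing_drop_fraction",
            "pqn_reference_missing_max",
        ):
            v = getattr(self, name)
            if not 0.0 <= float(v) <= 1.0:
                raise DataFormatError(f"{name} must be in [0, 1], got {v}")
        if self.proximal_max_distance < 1:
            raise DataFormatError("proximal_max_distance must be >= 1")
        if self.tie_policy not in _TIE_POLICIES:
            raise DataFormatError(
                f"tie_policy must be one of {_TIE_POLICIES}, got {self.tie_policy!r}"
            )

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: Mapping) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise DataFormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))
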