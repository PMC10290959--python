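"""Readers and writers for the plain-text interchange formats.

Matrices are TSV with a header row of sample ids and feature ids in the
first column; empty cells or ``NA`` denote missing values (files written by
this package use the empty string). Gene sets use standard GMT. The reaction
network, manifest, annotation and harmonization tables are simple TSVs, and
the analysis config is a flat key: value YAML mapping.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    AnalysisConfig,
    DataFormatError,
    DatasetManifest,
    GeneSetCollection,
    HarmonizationMap,
    ManifestEntry,
    OmicsMatrix,
    Reaction,
    ReactionNetwork,
)

_MISSING_TOKENS = {"", "NA"}


def read_matrix(path, omics_kind: str, dataset_id: str) -> OmicsMatrix:
    """Read a feature x sample TSV into a linear-scale :class:`OmicsMatrix`.

    Raises :class:`DataFormatError` on duplicate feature/sample ids and on
    non-numeric cells, naming the offending row and column.
    """
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise DataFormatError(f"{path}: repeated feature id {dup!r}")
    if raw.columns.has_duplicates:
        dup = raw.columns[raw.columns.duplicated()][0]
        raise DataFormatError(f"{path}: repeated sample id {dup!r}")
    values = np.full(raw.shape, np.nan)
    arr = raw.to_numpy()
    for j in range(arr.shape[1]):
        col = arr[:, j]
        for i, cell in enumerate(col):
            cell = cell.strip()
            if cell in _MISSING_TOKENS:
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise DataFormatError(
                    f"{path}: non-numeric cell {cell!r} at feature "
                    f"{raw.index[i]!r}, sample {raw.columns[j]!r}"
                ) from None
    data = pd.DataFrame(values, index=raw.index, columns=raw.columns)
    data.index.name = raw.index.name or "feature_id"
    return OmicsMatrix(dataset_id, omics_kind, data, scale_state="linear")


def write_matrix(matrix: OmicsMatrix, path) -> None:
    """Write a matrix as TSV; missing cells become the empty string."""
    df = matrix.data.copy()
    df.index.name = df.index.name or "feature_id"
    df.to_csv(path, sep="\t", na_rep="")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: per line, name, description, then member ids."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataFormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, desc = fields[0], fields[1]
            if name in sets:
                raise DataFormatError(
                    f"{path}:{lineno}: duplicate gene set name {name!r}"
                )
            members = frozenset(m for m in fields[2:] if m)
            sets[name] = members
            descriptions[name] = desc
    if not sets:
        raise DataFormatError(f"{path}: empty GMT file")
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def read_reaction_table(path, currency_metabolites=None) -> ReactionNetwork:
    """Read the reaction-network TSV.

    Columns: reaction_id, metabolites (';'-separated), genes (';'-separated,
    may be empty), reversible (0/1). The currency list is supplied separately
    (it is configuration, not part of the model file).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["reaction_id", "metabolites", "genes", "reversible"]
    if list(df.columns[:4]) != required:
        raise DataFormatError(
            f"{path}: expected columns {required}, got {list(df.columns)}"
        )
    reactions = []
    for _, row in df.iterrows():
        mets = tuple(m for m in row["metabolites"].split(";") if m)
        if not mets:
            raise DataFormatError(
                f"{path}: reaction {row['reaction_id']!r} has no metabolites"
            )
        genes = tuple(g for g in row["genes"].split(";") if g)
        reactions.append(
            Reaction(
                reaction_id=row["reaction_id"],
                metabolites=mets,
                genes=genes,
                reversible=row["reversible"].strip() in ("1", "true", "True"),
            )
        )
    return ReactionNetwork(
        reactions=reactions,
        currency_metabolites=set(currency_metabolites or ()),
    )


def write_reaction_table(network: ReactionNetwork, path) -> None:
    rows = [
        {
            "reaction_id": r.reaction_id,
            "metabolites": ";".join(r.metabolites),
            "genes": ";".join(r.genes),
            "reversible": int(r.reversible),
        }
        for r in network.reactions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    """Sample annotation TSV with columns sample_id, tissue[, batch]."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns or "tissue" not in df.columns:
        raise DataFormatError(f"{path}: needs sample_id and tissue columns")
    bad = set(df["tissue"]) - {"tumour", "normal"}
    if bad:
        raise DataFormatError(f"{path}: unknown tissue labels {sorted(bad)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise DataFormatError(f"{path}: duplicate sample_id {dup!r}")
    if "batch" not in df.columns:
        df["batch"] = ""
    return df.set_index("sample_id")[["tissue", "batch"]]


def read_manifest(path) -> DatasetManifest:
    """Dataset manifest TSV; relative paths resolve against its directory."""
    base = Path(path).parent
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = [
        "dataset_id",
        "cancer_type",
        "platform",
        "metabolomics_path",
        "transcriptomics_path",
        "annotation_path",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing manifest columns {missing}")
    entries = []
    for _, row in df.iterrows():
        paths = {}
        for col in ("metabolomics_path", "transcriptomics_path", "annotation_path"):
            p = Path(row[col])
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise DataFormatError(
                    f"{path}: {row['dataset_id']}: missing file {p}"
                )
            paths[col] = str(p)
        entries.append(
            ManifestEntry(
                dataset_id=row["dataset_id"],
                cancer_type=row["cancer_type"],
                platform=row["platform"],
                metabolomics_path=paths["metabolomics_path"],
                transcriptomics_path=paths["transcriptomics_path"],
                annotation_path=paths["annotation_path"],
            )
        )
    return DatasetManifest(entries=entries)


def read_harmonization_map(path) -> HarmonizationMap:
    """TSV with columns raw_name, harmonized_name; empty harmonized name
    (or '-') flags the raw name for discarding."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "raw_name" not in df.columns or "harmonized_name" not in df.columns:
        raise DataFormatError(
            f"{path}: needs raw_name and harmonized_name columns"
        )
    mapping: dict[str, str] = {}
    discard: set[str] = set()
    for _, row in df.iterrows():
        raw, harm = row["raw_name"], row["harmonized_name"].strip()
        if harm in ("", "-"):
            discard.add(raw)
        else:
            mapping[raw] = harm
    return HarmonizationMap(mapping=mapping, discard=discard)


def read_config(path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a flat key: value YAML mapping."""
    with open(path) as fh:
        loaded = yaml.safe_load(fh)
    if loaded is None:
        loaded = {}
    if not isinstance(loaded, dict):
        raise DataFormatError(f"{path}: config must be a flat key: value map")
    return AnalysisConfig.from_dict(loaded)


def write_config(config: AnalysisConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def read_currency_list(path) -> set[str]:
    """One currency metabolite id per line; blank lines and # comments skipped."""
    out: set[str] = set()
    if path is None or not os.path.exists(path):
        return out
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out
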