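"""Reading, validation and preprocessing of the three input tables.

A study dataset consists of an ASV (or higher-rank) abundance table
(samples x taxa), a taxonomy table (taxon -> Kingdom..Genus) and a sample
metadata table carrying the river coordinates (transect, distance to the
river mouth in km), environmental variables and the response variables
(chlorophyll *a* and an ordered biological status class).

All tables are tab-separated UTF-8 text with a header row.  Samples are
canonically ordered upstream -> downstream (decreasing distance to mouth)
within each transect; every function in the package assumes that order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: taxonomic ranks carried by a taxonomy table, coarse to fine
RANKS = ("Kingdom", "Phylum", "Class", "Order", "Family", "Genus")

#: ranks at which abundance tables may be aggregated
AGGREGATION_RANKS = ("Phylum", "Class", "Family", "Genus")

#: metadata columns that must always be present
REQUIRED_METADATA = ("transect", "distance_to_mouth")


class ValidationError(ValueError):
    """Raised when the three tables are mutually inconsistent."""


@dataclass
class Dataset:
    """A validated triple of abundance, taxonomy and metadata tables.

    Attributes
    ----------
    abundance : pandas.DataFrame
        Samples x taxa, non-negative. Index = sample ids.
    taxonomy : pandas.DataFrame
        Indexed by taxon id, columns = :data:`RANKS`.
    metadata : pandas.DataFrame
        Indexed by sample id. Must contain ``transect`` and
        ``distance_to_mouth``; typically also environmental variables,
        ``chl_a`` and ``status_class``.
    """

    abundance: pd.DataFrame
    taxonomy: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()
        order = _canonical_order(self.metadata)
        self.metadata = self.metadata.loc[order]
        self.abundance = self.abundance.loc[order]

    def validate(self) -> None:
        ab_samples = set(self.abundance.index)
        md_samples = set(self.metadata.index)
        if ab_samples != md_samples:
            missing_md = sorted(ab_samples - md_samples)
            missing_ab = sorted(md_samples - ab_samples)
            raise ValidationError(
                "sample ids differ between abundance and metadata; "
                f"absent from metadata: {missing_md}; "
                f"absent from abundance: {missing_ab}"
            )
        unknown = sorted(set(self.abundance.columns) - set(self.taxonomy.index))
        if unknown:
            raise ValidationError(f"taxa absent from taxonomy table: {unknown}")
        if (self.abundance.to_numpy() < 0).any():
            raise ValidationError("abundance table contains negative entries")
        for col in REQUIRED_METADATA:
            if col not in self.metadata.columns:
                raise ValidationError(f"metadata lacks required column {col!r}")

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.abundance.shape[1]

    def copy(self) -> "Dataset":
        return Dataset(
            self.abundance.copy(), self.taxonomy.copy(), self.metadata.copy()
        )


def _canonical_order(metadata: pd.DataFrame) -> pd.Index:
    """Sample order: by transect, then decreasing distance to mouth."""
    md = metadata[["transect", "distance_to_mouth"]].copy()
    md["transect"] = md["transect"].astype(str)
    ordered = md.sort_values(
        ["transect", "distance_to_mouth"],
        ascending=[True, False],
        kind="mergesort",
    )
    return ordered.index


def load_dataset(asv_path, taxonomy_path, metadata_path) -> Dataset:
    """Read and validate the three TSV tables.

    Parameters are paths to the abundance table (first column = sample id,
    remaining columns = taxa), the taxonomy table (first column = taxon id,
    then the six ranks) and the metadata table (first column = sample id).

    Returns a :class:`Dataset` with samples ordered upstream -> downstream
    within each transect. ``status_class``, when present, is parsed as an
    ordered categorical (lexicographic order of class labels, which matches
    saprobic-class naming conventions such as ``I < II < III``).
    """
    abundance = pd.read_csv(asv_path, sep="\t", index_col=0)
    taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col=0, dtype=str)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)

    for p, df in ((asv_path, abundance), (taxonomy_path, taxonomy), (metadata_path, metadata)):
        if df.shape[0] == 0:
            raise ValidationError(f"{p}: table has no rows")
    missing_ranks = [r for r in RANKS if r not in taxonomy.columns]
    if missing_ranks:
        raise ValidationError(f"taxonomy table lacks rank columns {missing_ranks}")

    if "status_class" in metadata.columns:
        levels = sorted(metadata["status_class"].dropna().astype(str).unique())
        metadata["status_class"] = pd.Categorical(
            metadata["status_class"].astype(str), categories=levels, ordered=True
        )
    return Dataset(abundance=abundance, taxonomy=taxonomy, metadata=metadata)


def write_dataset(dataset: Dataset, directory) -> dict[str, Path]:
    """Write the three tables as TSV into *directory*; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": directory / "asv_table.tsv",
        "taxonomy": directory / "taxonomy.tsv",
        "metadata": directory / "metadata.tsv",
    }
    dataset.abundance.to_csv(paths["abundance"], sep="\t", index_label="sample_id")
    dataset.taxonomy.to_csv(paths["taxonomy"], sep="\t", index_label="taxon_id")
    dataset.metadata.to_csv(paths["metadata"], sep="\t", index_label="sample_id")
    return paths


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Close each row to 1; all-zero rows stay all-zero."""
    totals = counts.sum(axis=1)
    safe = totals.replace(0, 1.0)
    return counts.div(safe, axis=0)


def hellinger_transform(counts: pd.DataFrame) -> pd.DataFrame:
    """Square root of per-row relative abundances.

    Each cell becomes ``sqrt(x / row_sum)``, so every non-zero row has unit
    sum of squares and Euclidean geometry on the result is appropriate for
    species data. All-zero rows map to all-zero rows.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("Hellinger transform requires non-negative entries")
    return np.sqrt(relative_abundance(counts))


def aggregate_taxa(
    matrix: pd.DataFrame, taxonomy: pd.DataFrame, rank: str
) -> pd.DataFrame:
    """Sum abundance columns sharing the same label at *rank*.

    Taxa unlabeled at the rank (NaN or empty string) are pooled into a
    single ``unclassified_<rank>`` column so per-sample totals are conserved
    exactly.
    """
    if rank not in AGGREGATION_RANKS:
        raise ValueError(
            f"unknown rank {rank!r}; expected one of {AGGREGATION_RANKS}"
        )
    labels = taxonomy.loc[matrix.columns, rank].astype("string")
    labels = labels.where(labels.notna() & (labels.str.len() > 0),
                          f"unclassified_{rank}")
    out = matrix.T.groupby(labels.to_numpy()).sum().T
    out.columns.name = rank
    return out


def impute_pmm(
    metadata: pd.DataFrame, k_donors: int = 5, seed: int = 0
) -> pd.DataFrame:
    """Predictive-mean-matching imputation of missing numeric metadata.

    For each numeric variable with missing entries, a linear model is fit on
    the complete cases using the fully observed numeric covariates. Each
    missing entry is replaced by the *observed* value of one of the
    ``k_donors`` donors whose predicted means are closest to the missing
    case's predicted mean (donor drawn uniformly, seeded). Imputed values
    therefore always lie in the variable's observed support.
    """
    rng = np.random.default_rng(seed)
    out = metadata.copy()
    numeric = out.select_dtypes(include=[np.number])
    has_missing = [c for c in numeric.columns if numeric[c].isna().any()]
    if not has_missing:
        return out
    complete_covs = [c for c in numeric.columns if not numeric[c].isna().any()]

    for col in has_missing:
        y = numeric[col]
        obs = y.notna().to_numpy()
        if not obs.any():
            raise ValueError(f"variable {col!r} is entirely missing")
        if complete_covs:
            X = numeric[complete_covs].to_numpy(dtype=float)
            X = np.column_stack([np.ones(len(X)), X])
        else:
            X = np.ones((len(y), 1))
        beta, *_ = np.linalg.lstsq(X[obs], y.to_numpy(dtype=float)[obs], rcond=None)
        pred = X @ beta
        donors_pred = pred[obs]
        donors_val = y.to_numpy(dtype=float)[obs]
        for i in np.flatnonzero(~obs):
            d = np.abs(donors_pred - pred[i])
            k = min(k_donors, len(donors_val))
            nearest = np.argsort(d, kind="stable")[:k]
            out.loc[out.index[i], col] = donors_val[rng.choice(nearest)]
    return out
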