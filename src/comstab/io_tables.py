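"""Tabular I/O and validation: feature tables, sample metadata, environmental matrices.

The canonical in-memory orientation of a feature table is samples as rows and
taxa as columns; readers accept either orientation via a flag because both
conventions are common in amplicon exports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "SampleMetadata",
    "EnvMatrix",
    "ValidationError",
    "read_feature_table",
    "write_feature_table",
    "to_relative_abundance",
    "filter_taxa",
    "read_metadata",
    "write_metadata",
    "read_env_matrix",
    "write_env_matrix",
    "export_network",
    "read_network",
]


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(ids, kind: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {kind}: {dups}")


@dataclass(frozen=True)
class FeatureTable:
    """Samples x taxa abundance matrix.

    ``mode`` is either ``"counts"`` (nonnegative reals, typically integers)
    or ``"relative"`` (every row sums to 1 within 1e-9).
    """

    sample_ids: tuple[str, ...]
    taxon_ids: tuple[str, ...]
    values: np.ndarray  # shape (n_samples, n_taxa)
    mode: str = "counts"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "taxon_ids", tuple(str(t) for t in self.taxon_ids))
        if values.ndim != 2 or values.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError(
                f"values shape {values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.taxon_ids, "taxon ids")
        if np.isnan(values).any():
            raise ValidationError("feature table contains missing values")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative abundance at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        if self.mode not in ("counts", "relative"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.mode == "relative":
            sums = values.sum(axis=1)
            if np.abs(sums - 1.0).max() > 1e-9:
                bad = self.sample_ids[int(np.abs(sums - 1.0).argmax())]
                raise ValidationError(f"relative-mode row for sample {bad!r} does not sum to 1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.sample_ids), columns=list(self.taxon_ids))

    def select_samples(self, sample_ids) -> "FeatureTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return replace(self, sample_ids=tuple(sample_ids), values=self.values[idx, :])

    def select_taxa(self, taxon_ids) -> "FeatureTable":
        idx = [self.taxon_ids.index(t) for t in taxon_ids]
        mode = "counts" if self.mode == "relative" and len(idx) < self.n_taxa else self.mode
        return FeatureTable(self.sample_ids, tuple(taxon_ids), self.values[:, idx], mode=mode)


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample grouping variables and coordinates (decimal degrees)."""

    frame: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "site", "soil_type", "latitude", "longitude")

    def __post_init__(self):
        df = self.frame.copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        _check_unique(df["sample_id"], "sample ids")
        df["latitude"] = df["latitude"].astype(float)
        df["longitude"] = df["longitude"].astype(float)
        if ((df["latitude"].abs() > 90).any()):
            raise ValidationError("latitude outside [-90, 90]")
        if ((df["longitude"].abs() > 180).any()):
            raise ValidationError("longitude outside [-180, 180]")
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.frame["sample_id"].astype(str))

    def aligned_to(self, sample_ids) -> "SampleMetadata":
        df = self.frame.set_index("sample_id")
        missing = [s for s in sample_ids if s not in df.index]
        if missing:
            raise ValidationError(f"metadata missing samples: {missing}")
        return SampleMetadata(df.loc[list(sample_ids)].reset_index())

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy()


@dataclass(frozen=True)
class EnvMatrix:
    """Samples x environmental-variables matrix (one unit per variable)."""

    sample_ids: tuple[str, ...]
    variable_names: tuple[str, ...]
    values: np.ndarray
    missing_policy: str = "fail"  # or "mean_impute"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.variable_names, "variable names")
        if values.shape != (len(self.sample_ids), len(self.variable_names)):
            raise ValidationError("env matrix shape mismatch")
        if np.isnan(values).any():
            if self.missing_policy == "fail":
                j = int(np.isnan(values).any(axis=0).argmax())
                raise ValidationError(
                    f"missing values in environmental variable {self.variable_names[j]!r} "
                    "(missing_policy='fail'; use 'mean_impute' to impute column means)"
                )
            col_means = np.nanmean(values, axis=0)
            values = np.where(np.isnan(values), col_means[None, :], values)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "variable_names", tuple(str(v) for v in self.variable_names))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.sample_ids), columns=list(self.variable_names))

    def aligned_to(self, sample_ids) -> "EnvMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return EnvMatrix(tuple(sample_ids), self.variable_names, self.values[idx], self.missing_policy)

    def with_ratios(self) -> "EnvMatrix":
        """Append C:N = TC/TN and C:P = TC/TP when absent but computable."""
        df = self.to_frame()
        for ratio, num, den in (("C:N", "TC", "TN"), ("C:P", "TC", "TP")):
            if ratio not in df.columns and num in df.columns and den in df.columns:
                df[ratio] = df[num] / df[den]
        return EnvMatrix(self.sample_ids, tuple(df.columns), df.to_numpy(), self.missing_policy)


# ---------------------------------------------------------------------------
# feature table I/O


def read_feature_table(path, format="tsv", orientation="samples_as_rows", mode="counts") -> FeatureTable:
    """Read a feature table from TSV or BIOM-style JSON.

    ``orientation`` applies to TSV: ``"samples_as_rows"`` or ``"taxa_as_rows"``
    (the latter is transposed into the canonical form).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if orientation == "taxa_as_rows":
            df = df.T
        elif orientation != "samples_as_rows":
            raise ValueError(f"unknown orientation {orientation!r}")
        return FeatureTable(tuple(df.index.astype(str)), tuple(df.columns.astype(str)), df.to_numpy(float), mode=mode)
    if format == "biom":
        doc = json.loads(path.read_text())
        taxa = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        dense = np.zeros((len(taxa), len(samples)))
        if doc.get("matrix_type") == "sparse":
            for i, j, v in doc["data"]:
                dense[int(i), int(j)] = v
        else:
            dense[:] = np.asarray(doc["data"], dtype=float)
        return FeatureTable(tuple(samples), tuple(taxa), dense.T, mode=mode)
    raise ValueError(f"unknown format {format!r}")


def write_feature_table(ft: FeatureTable, path, orientation="samples_as_rows") -> None:
    df = ft.to_frame()
    if orientation == "taxa_as_rows":
        df = df.T
    df.index.name = "sample_id" if orientation == "samples_as_rows" else "taxon_id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def to_relative_abundance(ft: FeatureTable) -> FeatureTable:
    """Row-normalize to relative abundances; idempotent on relative input."""
    sums = ft.values.sum(axis=1)
    if (sums <= 0).any():
        bad = ft.sample_ids[int((sums <= 0).argmax())]
        raise ValidationError(f"sample {bad!r} has zero total abundance")
    return FeatureTable(ft.sample_ids, ft.taxon_ids, ft.values / sums[:, None], mode="relative")


def filter_taxa(ft: FeatureTable, min_prevalence: float = 0.2, min_mean_abundance: float = 0.0) -> FeatureTable:
    """Keep taxa present in >= ``min_prevalence`` of samples with mean relative
    abundance >= ``min_mean_abundance``; column order preserved.

    Correlation-based network inference is meaningless for taxa observed in
    only a handful of samples, hence the prevalence default.
    """
    if not (0 <= min_prevalence <= 1 and 0 <= min_mean_abundance <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    rel = to_relative_abundance(ft) if ft.mode == "counts" else ft
    prevalence = (ft.values > 0).mean(axis=0)
    mean_rel = rel.values.mean(axis=0)
    keep = (prevalence >= min_prevalence) & (mean_rel >= min_mean_abundance)
    if not keep.any():
        raise ValidationError("taxon filter removed every taxon")
    kept = [t for t, k in zip(ft.taxon_ids, keep) if k]
    return ft.select_taxa(kept)


# ---------------------------------------------------------------------------
# metadata / environment I/O


def read_metadata(path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, sep="\t", dtype={"sample_id": str, "site": str, "soil_type": str}))


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.frame.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_env_matrix(path, missing_policy="fail") -> EnvMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return EnvMatrix(tuple(df.index.astype(str)), tuple(df.columns.astype(str)), df.to_numpy(float), missing_policy)


def write_env_matrix(env: EnvMatrix, path) -> None:
    df = env.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.12g")


# ---------------------------------------------------------------------------
# network export


def _to_nx(net) -> nx.Graph:
    g = nx.Graph()
    for node, ab in zip(net.node_ids, net.node_abundance):
        g.add_node(node, mean_relative_abundance=float(ab), module=int(net.modules.get(node, -1)) if net.modules else -1)
    for i, j, rho, p, q, sign in net.edges:
        g.add_edge(
            net.node_ids[i], net.node_ids[j],
            rho=float(rho), p=float(p), q=float(q), sign=int(sign), weight=abs(float(rho)),
        )
    return g


def export_network(net, path, format="graphml") -> None:
    """Write a correlation network as GraphML or a weighted edge list (TSV)."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(_to_nx(net), path)
    elif format == "edgelist":
        rows = [
            {"source": net.node_ids[i], "target": net.node_ids[j],
             "rho": rho, "p": p, "q": q, "sign": sign}
            for i, j, rho, p, q, sign in net.edges
        ]
        pd.DataFrame(rows, columns=["source", "target", "rho", "p", "q", "sign"]).to_csv(
            path, sep="\t", index=False, float_format="%.12g")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path) -> nx.Graph:
    return nx.read_graphml(path)
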