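"""Core data containers and delimited-text I/O.

The pipeline operates on three omics layers measured on the same cohort:
blood-cell transcript counts, plasma protein abundances (log-like NPX-style
units) and plasma metabolite abundances (log-like units).  Every container
aligns samples by identifier, never by position.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class LayerKind(str, Enum):
    TRANSCRIPTOMICS = "transcriptomics"
    PROTEOMICS = "proteomics"
    METABOLOMICS = "metabolomics"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicated {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class OmicsLayer:
    """One samples x features numeric matrix with layer kind annotation.

    ``values`` is float64, samples in rows.  After :meth:`impute_min` the
    matrix is guaranteed finite.
    """

    layer_kind: LayerKind
    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    n_imputed: int = 0

    def __post_init__(self) -> None:
        self.layer_kind = LayerKind(self.layer_kind)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def subset_features(self, features: Sequence[str]) -> "OmicsLayer":
        idx = [self.feature_ids.index(f) for f in features]
        return OmicsLayer(self.layer_kind, list(self.sample_ids), [self.feature_ids[i] for i in idx],
                          self.values[:, idx].copy())

    def subset_samples(self, samples: Sequence[str]) -> "OmicsLayer":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in pos]
        if missing:
            raise KeyError(f"samples not in layer: {missing[:5]}")
        idx = [pos[s] for s in samples]
        return OmicsLayer(self.layer_kind, [self.sample_ids[i] for i in idx],
                          list(self.feature_ids), self.values[idx, :].copy())

    def impute_min(self) -> "OmicsLayer":
        """Replace missing values with each feature's observed minimum.

        Mirrors minimum-imputation as used for untargeted metabolomics;
        applied uniformly across layers before analysis.  Features that are
        entirely missing are dropped.
        """
        vals = self.values.copy()
        all_missing = np.all(~np.isfinite(vals), axis=0)
        keep = ~all_missing
        vals = vals[:, keep]
        feats = [f for f, k in zip(self.feature_ids, keep) if k]
        n_imp = 0
        for j in range(vals.shape[1]):
            col = vals[:, j]
            bad = ~np.isfinite(col)
            if bad.any():
                col[bad] = np.nanmin(np.where(np.isfinite(col), col, np.nan))
                n_imp += int(bad.sum())
        out = OmicsLayer(self.layer_kind, list(self.sample_ids), feats, vals)
        out.n_imputed = n_imp
        return out

    def digest(self) -> str:
        h = hashlib.sha256()
        h.update(",".join(self.sample_ids).encode())
        h.update(",".join(self.feature_ids).encode())
        h.update(np.ascontiguousarray(self.values).tobytes())
        return h.hexdigest()[:16]


def read_layer(path: str | Path, layer_kind: LayerKind | str, *, sep: str = "\t",
               samples_in_rows: bool = True) -> OmicsLayer:
    """Read a delimited matrix (first column sample ids, header feature ids).

    Missing values may be encoded as empty cells or ``NA``; they are
    minimum-imputed per feature.  Duplicated identifiers and non-numeric
    cells are hard errors.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    _check_unique(header, "feature" if samples_in_rows else "sample")
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", ""], keep_default_na=False,
                     dtype=str)
    df.columns = header
    if not samples_in_rows:
        df = df.T
    _check_unique(list(df.index.astype(str)), "sample")
    _check_unique(list(df.columns.astype(str)), "feature")
    vals = np.empty(df.shape, dtype=float)
    arr = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = arr[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                vals[i, j] = np.nan
                continue
            try:
                vals[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric cell at sample {df.index[i]!r}, feature "
                    f"{df.columns[j]!r}: {cell!r}") from None
    # drop all-missing rows, then impute per feature
    row_ok = ~np.all(~np.isfinite(vals), axis=1)
    layer = OmicsLayer(layer_kind, list(df.index[row_ok].astype(str)),
                       list(df.columns.astype(str)), vals[row_ok])
    return layer.impute_min()


def write_layer(layer: OmicsLayer, path: str | Path, *, sep: str = "\t") -> None:
    layer.to_frame().to_csv(path, sep=sep, float_format="%.17g")


@dataclass
class SampleTable:
    """Sample metadata: optional group label plus clinical covariates."""

    sample_ids: list[str]
    group_label: list[str] | None = None
    covariates: pd.DataFrame | None = None
    categorical_levels: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample")
        if self.group_label is not None and len(self.group_label) != len(self.sample_ids):
            raise ValueError("group_label length mismatch")
        if self.covariates is not None:
            self.covariates = self.covariates.loc[self.sample_ids]

    def aligned_with(self, layer: OmicsLayer) -> bool:
        return set(self.sample_ids) == set(layer.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(index=self.sample_ids)
        if self.group_label is not None:
            df["group"] = self.group_label
        if self.covariates is not None:
            df = df.join(self.covariates)
        return df


def read_sample_table(path: str | Path, *, sep: str = "\t",
                      group_col: str = "group") -> SampleTable:
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    group = df[group_col].astype(str).tolist() if group_col in df.columns else None
    cov = df.drop(columns=[group_col], errors="ignore")
    levels = {c: sorted(cov[c].dropna().astype(str).unique().tolist())
              for c in cov.columns if cov[c].dtype == object}
    return SampleTable(list(df.index), group, cov if len(cov.columns) else None, levels)


def write_sample_table(table: SampleTable, path: str | Path, *, sep: str = "\t") -> None:
    table.to_frame().to_csv(path, sep=sep)


@dataclass
class GeneSetCollection:
    """Named feature sets (e.g. senescence databases, KEGG-metabolism)."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"empty gene set: {name!r}")
        if len(set(self.sets)) != len(self.sets):  # pragma: no cover - dict keys unique
            raise ValueError("duplicate set names")

    def __len__(self) -> int:
        return len(self.sets)

    def restrict(self, universe: Iterable[str]) -> "GeneSetCollection":
        uni = set(universe)
        kept = {n: [m for m in ms if m in uni] for n, ms in self.sets.items()}
        return GeneSetCollection({n: ms for n, ms in kept.items() if ms}, self.source)

    def union(self) -> set[str]:
        out: set[str] = set()
        for ms in self.sets.values():
            out.update(ms)
        return out


def read_gene_sets(path: str | Path, *, source: str = "") -> GeneSetCollection:
    """Read a standard GMT file (name, description, members; tab-separated)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {lineno}: expected >=3 tab-separated fields")
            name, _desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"GMT line {lineno}: set {name!r} has no members")
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = members
    return GeneSetCollection(sets, source or str(path))


def write_gene_sets(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in coll.sets.items():
            fh.write("\t".join([name, coll.source or "na", *members]) + "\n")


@dataclass
class ResultBundle:
    """One pipeline stage's outputs plus provenance for reproducibility."""

    stage: str
    tables: dict[str, pd.DataFrame]
    provenance: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> Path:
        out = Path(outdir) / self.stage
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", float_format="%.10g")
        with open(out / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True, default=str)
        return out

    @classmethod
    def read(cls, outdir: str | Path, stage: str) -> "ResultBundle":
        out = Path(outdir) / stage
        if not out.is_dir():
            raise FileNotFoundError(f"missing stage artifact: {stage!r} under {outdir}")
        tables = {p.stem: pd.read_csv(p, sep="\t", index_col=0)
                  for p in sorted(out.glob("*.tsv"))}
        prov = {}
        pj = out / "provenance.json"
        if pj.exists():
            prov = json.loads(pj.read_text())
        return cls(stage, tables, prov)


def config_hash(config: Mapping) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]
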