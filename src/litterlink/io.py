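"""Data model and file formats shared by every pipeline stage.

The native table dialect is TSV (UTF-8, tab-separated, no quoting): omics
matrices are features x samples with the feature identifier in the first
column, sample metadata is one row per sample, and gene sets travel as GMT.
Feature and gene identifiers are opaque strings; no identifier translation is
attempted. Readers validate shape and value constraints and point at the
offending cell or line; every writer produces files its reader accepts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("litterlink")

GROUPS = ("GF", "SPF")
SEXES = ("F", "M")
ASSAYS = ("transcriptome", "metabolome")
MATRIX_KINDS = ("counts", "intensities")
METADATA_COLUMNS = ("sample_id", "dam_id", "group", "sex", "tissue", "assay")
DE_COLUMNS = ("gene_id", "log2_fold_change", "p", "p_adj")


class FormatError(ValueError):
    """A file violated the expected table format or a value constraint."""


# ---------------------------------------------------------------------------
# Omics matrices


@dataclass
class OmicsMatrix:
    """A features x samples numeric matrix bound to a kind.

    ``kind='counts'`` requires non-negative integers (stored as int64);
    ``kind='intensities'`` requires non-negative reals, where 0 (or NaN, if
    non-detects were exported that way) marks a non-detect.
    """

    data: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in MATRIX_KINDS:
            raise FormatError(f"unknown matrix kind {self.kind!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate feature id {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        values = self.data.to_numpy()
        if self.kind == "counts":
            if np.isnan(values).any():
                r, c = _first_offender(self.data, np.isnan(values))
                raise FormatError(f"missing count at feature {r!r}, sample {c!r}")
            if (values < 0).any():
                r, c = _first_offender(self.data, values < 0)
                raise FormatError(f"negative count at feature {r!r}, sample {c!r}")
            if np.any(values != np.floor(values)):
                r, c = _first_offender(self.data, values != np.floor(values))
                raise FormatError(f"non-integer count at feature {r!r}, sample {c!r}")
            self.data = self.data.astype(np.int64)
        else:
            finite_neg = np.nan_to_num(values, nan=0.0) < 0
            if finite_neg.any():
                r, c = _first_offender(self.data, finite_neg)
                raise FormatError(f"negative intensity at feature {r!r}, sample {c!r}")
            self.data = self.data.astype(np.float64)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids) -> "OmicsMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return OmicsMatrix(self.data.loc[:, list(sample_ids)].copy(), self.kind)

    def subset_features(self, feature_ids) -> "OmicsMatrix":
        missing = [f for f in feature_ids if f not in self.data.index]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:5]}")
        return OmicsMatrix(self.data.loc[list(feature_ids)].copy(), self.kind)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, OmicsMatrix)
            and self.kind == other.kind
            and self.data.equals(other.data)
        )


def _first_offender(df: pd.DataFrame, mask: np.ndarray) -> tuple[str, str]:
    i, j = np.argwhere(mask)[0]
    return str(df.index[i]), str(df.columns[j])


def read_matrix(path, kind: str) -> OmicsMatrix:
    """Read a features x samples TSV (header row, feature ids in column 1)."""
    raw = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature id {dup!r}")
    def _parse(cell):
        if pd.isna(cell):
            return np.nan
        try:
            return float(cell)  # correctly-rounded parse, exact round trips
        except ValueError:
            return np.nan

    numeric = raw.map(_parse)
    bad = numeric.isna().to_numpy() & raw.notna().to_numpy()
    if bad.any():
        r, c = _first_offender(raw, bad)
        raise FormatError(f"{path}: non-numeric cell at feature {r!r}, sample {c!r}")
    if kind == "counts" and numeric.isna().to_numpy().any():
        r, c = _first_offender(raw, numeric.isna().to_numpy())
        raise FormatError(f"{path}: missing count at feature {r!r}, sample {c!r}")
    try:
        return OmicsMatrix(numeric, kind)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_matrix(matrix: OmicsMatrix, path) -> None:
    df = matrix.data.rename_axis("feature_id")
    if matrix.kind == "counts":
        df.to_csv(path, sep="\t")
    else:
        df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# Sample metadata


def validate_metadata(md: pd.DataFrame) -> pd.DataFrame:
    if tuple(md.columns) != METADATA_COLUMNS:
        raise FormatError(
            f"metadata columns must be exactly {list(METADATA_COLUMNS)}, got {list(md.columns)}"
        )
    md = md.astype(str)
    if md["sample_id"].duplicated().any():
        dup = md.loc[md["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample_id {dup!r}")
    for col, allowed in (("group", GROUPS), ("sex", SEXES), ("assay", ASSAYS)):
        bad = ~md[col].isin(allowed)
        if bad.any():
            raise FormatError(
                f"invalid {col} value {md.loc[bad, col].iloc[0]!r}; allowed: {allowed}"
            )
    n_groups = md.groupby("dam_id")["group"].nunique()
    if (n_groups > 1).any():
        dam = n_groups.index[n_groups > 1][0]
        raise FormatError(f"dam {dam!r} assigned to more than one group")
    return md


def read_metadata(path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", dtype=str)
    return validate_metadata(md)


def write_metadata(md: pd.DataFrame, path) -> None:
    validate_metadata(md).to_csv(path, sep="\t", index=False)


def subset_metadata(
    md: pd.DataFrame, tissue: str | None = None, assay: str | None = None,
    group: str | None = None,
) -> pd.DataFrame:
    out = md
    if tissue is not None:
        out = out[out["tissue"] == tissue]
    if assay is not None:
        out = out[out["assay"] == assay]
    if group is not None:
        out = out[out["group"] == group]
    return out.copy()


# ---------------------------------------------------------------------------
# Gene sets (GMT)


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    description: str
    members: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """term_id -> (description, member gene ids); members are de-duplicated."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, term_id: str, description: str, members) -> None:
        uniq = list(dict.fromkeys(str(m) for m in members if str(m)))
        if not uniq:
            raise FormatError(f"gene set {term_id!r} has no members")
        if term_id in self.sets:
            raise FormatError(f"duplicate gene set id {term_id!r}")
        if len(uniq) < len([m for m in members if str(m)]):
            logger.warning("gene set %s: duplicate members collapsed", term_id)
        self.sets[term_id] = GeneSet(str(term_id), str(description), tuple(uniq))

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __contains__(self, term_id) -> bool:
        return term_id in self.sets

    def __getitem__(self, term_id) -> GeneSet:
        return self.sets[term_id]

    def ids(self) -> list[str]:
        return list(self.sets)


def read_gmt(path) -> GeneSetCollection:
    coll = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >=3 tab-separated fields")
            try:
                coll.add(fields[0], fields[1], fields[2:])
            except FormatError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
    return coll


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in collection:
            fh.write("\t".join([gs.term_id, gs.description, *gs.members]) + "\n")


# ---------------------------------------------------------------------------
# Differential-expression tables


def make_de_table(gene_ids, log2_fold_change, p, p_adj, source: str,
                  zero_variance=None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "gene_id": [str(g) for g in gene_ids],
            "log2_fold_change": np.asarray(log2_fold_change, dtype=float),
            "p": np.asarray(p, dtype=float),
            "p_adj": np.asarray(p_adj, dtype=float),
            "source": source,
        }
    )
    df["zero_variance"] = (
        np.zeros(len(df), dtype=bool) if zero_variance is None else np.asarray(zero_variance)
    )
    return validate_de_table(df)


def validate_de_table(df: pd.DataFrame) -> pd.DataFrame:
    for col in DE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"DE table missing column {col!r}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"DE table: duplicate gene_id {dup!r}")
    if ((df["p"] < 0) | (df["p"] > 1)).any():
        raise FormatError("DE table: p outside [0, 1]")
    if (df["p_adj"] < df["p"] - 1e-12).any():
        raise FormatError("DE table: p_adj < p")
    if "source" not in df.columns:
        df = df.assign(source="external")
    return df


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "source" not in df.columns:
        df["source"] = "external"
    return validate_de_table(df)


def write_de_table(df: pd.DataFrame, path) -> None:
    validate_de_table(df).to_csv(path, sep="\t", index=False)
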