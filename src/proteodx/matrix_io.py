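"""Shared data model and file I/O.

Matrices are plain TSV: first column holds gene ids, header row holds sample
ids, an empty cell (or ``NA``/``NaN``) is a missing value.  The missingness
mask is carried explicitly so that downstream imputation can fill values
while retaining provenance.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

LAYERS = ("protein", "rna")
SCALES = ("linear", "log2", "normalized", "vst")

_MISSING_TOKENS = {"", "NA", "NaN", "nan", "na"}


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric table with an explicit missingness mask.

    Parameters
    ----------
    values
        Numeric DataFrame (genes as rows, samples as columns).  Cells where
        ``mask`` is True are undefined and ignored by all computations; after
        imputation they hold the filled value and the mask records provenance.
    mask
        Boolean DataFrame of the same shape; True marks a missing cell.
    layer
        ``"protein"`` (linear intensities) or ``"rna"`` (integer counts).
    scale
        ``"linear"``, ``"log2"``, ``"normalized"`` or ``"vst"``.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    layer: str
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}")
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate gene ids: {list(dupes)[:5]}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise FormatError(f"duplicate sample ids: {list(dupes)[:5]}")
        if not self.values.index.equals(self.mask.index) or not self.values.columns.equals(
            self.mask.columns
        ):
            raise ValidationError("values and mask must share index/columns")
        observed = self.values.to_numpy(dtype=float)[~self.mask.to_numpy(dtype=bool)]
        if observed.size and np.nanmin(observed) < 0 and self.scale == "linear":
            raise FormatError("negative values in a linear-scale matrix")

    # -- basic accessors -------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def observed(self) -> pd.DataFrame:
        """Values with missing cells replaced by NaN."""
        return self.values.where(~self.mask)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), self.mask.copy(), self.layer, self.scale
        )

    def subset(
        self,
        genes: Iterable[str] | None = None,
        samples: Iterable[str] | None = None,
    ) -> "ExpressionMatrix":
        v, m = self.values, self.mask
        if genes is not None:
            genes = list(genes)
            v, m = v.loc[genes], m.loc[genes]
        if samples is not None:
            samples = list(samples)
            v, m = v[samples], m[samples]
        return ExpressionMatrix(v.copy(), m.copy(), self.layer, self.scale)

    def to_log2(self) -> "ExpressionMatrix":
        """log2-transform a linear matrix; missing cells stay masked (NaN)."""
        if self.scale != "linear":
            raise ValidationError(f"to_log2 requires linear scale, got {self.scale}")
        obs = self.observed().to_numpy(dtype=float)
        with np.errstate(divide="ignore"):
            vals = np.log2(obs)
        out = pd.DataFrame(vals, index=self.genes, columns=self.samples)
        return ExpressionMatrix(out, self.mask.copy(), self.layer, "log2")

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values, self.mask.copy(), self.layer, scale or self.scale
        )


@dataclass
class CohortMeta:
    """Per-sample role (patient/control), batch, and exclusion status."""

    table: pd.DataFrame  # index: sample; columns: role, batch, excluded, exclusion_reason

    REQUIRED = ("role", "batch", "excluded", "exclusion_reason")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValidationError(f"metadata missing column {col!r}")
        bad = set(self.table["role"]) - {"patient", "control"}
        if bad:
            raise ValidationError(f"unknown sample roles: {sorted(bad)}")
        if self.table.index.has_duplicates:
            raise FormatError("duplicate sample ids in metadata")

    @property
    def samples(self) -> pd.Index:
        return self.table.index

    def included(self) -> list[str]:
        return list(self.table.index[~self.table["excluded"].astype(bool)])

    def controls(self, included_only: bool = True) -> list[str]:
        sel = self.table["role"] == "control"
        if included_only:
            sel &= ~self.table["excluded"].astype(bool)
        return list(self.table.index[sel])

    def patients(self, included_only: bool = True) -> list[str]:
        sel = self.table["role"] == "patient"
        if included_only:
            sel &= ~self.table["excluded"].astype(bool)
        return list(self.table.index[sel])

    def exclude(self, sample: str, reason: str) -> None:
        self.table.loc[sample, "excluded"] = True
        self.table.loc[sample, "exclusion_reason"] = reason


NONTARGET_CATEGORIES = ("none", "rbc", "plasma")
CELL_MARKERS = ("none", "b_cell", "t_cell", "nk_cell")


@dataclass
class GeneAnnotation:
    """Per-gene flags: targeted panel, nontarget category, cell marker, coding."""

    table: pd.DataFrame  # index: gene; columns: targeted_panel, nontarget_category, cell_marker, coding

    REQUIRED = ("targeted_panel", "nontarget_category", "cell_marker", "coding")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValidationError(f"annotation missing column {col!r}")
        bad = set(self.table["nontarget_category"]) - set(NONTARGET_CATEGORIES)
        if bad:
            raise ValidationError(f"unknown nontarget categories: {sorted(bad)}")
        bad = set(self.table["cell_marker"]) - set(CELL_MARKERS)
        if bad:
            raise ValidationError(f"unknown cell markers: {sorted(bad)}")

    def for_genes(self, genes: Iterable[str]) -> pd.DataFrame:
        """Annotation rows for `genes`, defaulting absent genes to
        {targeted_panel: False, nontarget_category: none, cell_marker: none, coding: True}."""
        genes = list(genes)
        out = self.table.reindex(genes)
        out["targeted_panel"] = out["targeted_panel"].map(
            lambda v: bool(v) if pd.notna(v) else False
        )
        out["nontarget_category"] = out["nontarget_category"].fillna("none")
        out["cell_marker"] = out["cell_marker"].fillna("none")
        out["coding"] = out["coding"].map(lambda v: bool(v) if pd.notna(v) else True)
        return out

    def markers(self, cell_type: str) -> list[str]:
        return list(self.table.index[self.table["cell_marker"] == cell_type])

    def nontarget(self) -> list[str]:
        return list(self.table.index[self.table["nontarget_category"] != "none"])


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT dialect)."""

    sets: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def restrict(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with `universe`; drop sets that become empty."""
        uni = frozenset(universe)
        kept = {sid: g & uni for sid, g in self.sets.items() if g & uni}
        return GeneSetCollection(kept, {k: self.names.get(k, k) for k in kept})


# ---------------------------------------------------------------------------
# TSV matrix I/O
# ---------------------------------------------------------------------------

def read_matrix(
    path: str | os.PathLike,
    layer: str,
    scale: str = "linear",
    zero_as_missing: bool = False,
) -> ExpressionMatrix:
    """Read a genes-x-samples TSV into an :class:`ExpressionMatrix`.

    Empty cells and ``NA``/``NaN`` tokens are recorded as missing.  A literal
    ``0`` is an observed zero unless ``zero_as_missing`` is set (the
    distinction matters because zero-imputation is a deliberate analysis
    choice, not a file-format convention).
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    samples = header[1:]
    ncol = len(header)
    gene_ids: list[str] = []
    values: list[list[float]] = []
    mask: list[list[bool]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != ncol:
            raise FormatError(
                f"{path}:{lineno}: ragged row ({len(cells)} fields, expected {ncol})"
            )
        gid = cells[0]
        if gid in seen:
            raise FormatError(f"{path}:{lineno}: duplicate gene id {gid!r}")
        seen.add(gid)
        row_v: list[float] = []
        row_m: list[bool] = []
        for col, tok in enumerate(cells[1:], start=2):
            if tok in _MISSING_TOKENS:
                row_v.append(np.nan)
                row_m.append(True)
                continue
            try:
                v = float(tok)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: column {col}: non-numeric value {tok!r}"
                ) from exc
            if v < 0 and scale == "linear":
                raise FormatError(
                    f"{path}:{lineno}: column {col}: negative value {v} in gene {gid!r}"
                )
            if zero_as_missing and v == 0:
                row_v.append(np.nan)
                row_m.append(True)
            else:
                row_v.append(v)
                row_m.append(False)
        gene_ids.append(gid)
        values.append(row_v)
        mask.append(row_m)
    vdf = pd.DataFrame(values, index=gene_ids, columns=samples, dtype=float)
    mdf = pd.DataFrame(mask, index=gene_ids, columns=samples, dtype=bool)
    return ExpressionMatrix(vdf, mdf, layer=layer, scale=scale)


def _format_value(v: float, as_int: bool) -> str:
    if as_int:
        return str(int(round(v)))
    # repr round-trips exactly, keeping write(read(f)) canonical
    return repr(float(v))


def write_matrix(m: ExpressionMatrix, path: str | os.PathLike) -> None:
    """Write a matrix in the canonical TSV dialect (missing = empty cell)."""
    as_int = m.layer == "rna" and m.scale == "linear"
    mask = m.mask.to_numpy(dtype=bool)
    vals = m.values.to_numpy(dtype=float)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(map(str, m.samples)) + "\n")
        for i, gid in enumerate(m.genes):
            cells = [
                "" if mask[i, j] else _format_value(vals[i, j], as_int)
                for j in range(vals.shape[1])
            ]
            fh.write(str(gid) + "\t" + "\t".join(cells) + "\n")


def read_meta(path: str | os.PathLike) -> CohortMeta:
    t = pd.read_csv(path, sep="\t", index_col=0, dtype={"exclusion_reason": str})
    t["excluded"] = t["excluded"].astype(bool)
    t["exclusion_reason"] = t["exclusion_reason"].fillna("")
    return CohortMeta(t)


def write_meta(meta: CohortMeta, path: str | os.PathLike) -> None:
    t = meta.table.copy()
    t.index.name = "sample"
    t.to_csv(path, sep="\t")


def read_annotation(path: str | os.PathLike) -> GeneAnnotation:
    t = pd.read_csv(path, sep="\t", index_col=0)
    t["targeted_panel"] = t["targeted_panel"].astype(bool)
    t["coding"] = t["coding"].astype(bool)
    return GeneAnnotation(t)


def write_annotation(annot: GeneAnnotation, path: str | os.PathLike) -> None:
    t = annot.table.copy()
    t.index.name = "gene"
    t.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Parse a GMT file: ``set_id<TAB>description<TAB>gene1<TAB>gene2...``"""
    sets: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs id, description and >=1 gene"
                )
            sid, desc, genes = cells[0], cells[1], [g for g in cells[2:] if g]
            if sid in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set id {sid!r}")
            if not genes:
                raise FormatError(f"{path}:{lineno}: set {sid!r} has no genes")
            sets[sid] = frozenset(genes)
            names[sid] = desc
    return GeneSetCollection(sets, names)


def write_report(results: Mapping, path: str | os.PathLike) -> None:
    """Serialize a result mapping to pretty JSON (numpy types coerced)."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="index")
        raise TypeError(f"cannot serialize {type(o)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
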