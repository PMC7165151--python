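"""Readers, writers and validated containers for the tabular inputs.

Three kinds of table flow through the analysis:

* a genes x samples expression matrix on a log2 scale (plain TSV with gene
  ids in the first column, or GCT 1.2);
* a per-sample clinical table (TSV) carrying histology, stage, treatment
  and survival fields;
* a somatic-mutation table, either MAF-lite records
  ``(sample_id, gene_id, variant_class)`` or a wide 0/1 indicator matrix.

Every loader validates its invariants up front — duplicate identifiers,
non-finite values, events without times — so that nothing malformed
reaches the statistics downstream.  All files are UTF-8, tab-delimited.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

_NA_TOKENS = {"", "na", "nan", "none", "null", "."}
_BOOL_TRUE = {"1", "true", "t", "yes", "y"}
_BOOL_FALSE = {"0", "false", "f", "no", "n"}

HISTOLOGIES = {"diffuse", "intestinal", "normal"}
SEXES = {"male", "female"}
TUMOR_SITES = {"cardia", "body", "antrum", "whole"}
MOLECULAR_SUBTYPES = {"EBV", "MSI", "GS", "CIN"}

#: canonical vocabulary for MAF-style variant classes
VARIANT_CLASS_ALIASES = {
    "missense": "missense",
    "missense_mutation": "missense",
    "nonsense": "nonsense",
    "nonsense_mutation": "nonsense",
    "stop_gained": "nonsense",
    "frameshift": "frameshift",
    "frame_shift_del": "frameshift",
    "frame_shift_ins": "frameshift",
    "splice_site": "splice_site",
    "inframe_indel": "inframe_indel",
    "in_frame_del": "inframe_indel",
    "in_frame_ins": "inframe_indel",
    "nonstop": "nonstop",
    "nonstop_mutation": "nonstop",
    "start_lost": "start_lost",
    "translation_start_site": "start_lost",
    "silent": "silent",
    "synonymous": "silent",
    "utr": "utr",
    "3'utr": "utr",
    "5'utr": "utr",
    "intron": "intron",
    "igr": "igr",
    "rna": "rna",
    "unspecified": "unspecified",
}

#: classes counted as nonsynonymous for mutation-burden purposes.
#: ``unspecified`` covers indicator-matrix input, which records presence only.
NONSYNONYMOUS_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift", "splice_site", "inframe_indel",
     "nonstop", "start_lost", "unspecified"}
)


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A validated genes x samples matrix of log2-scale expression values.

    Invariants enforced at construction: unique gene and sample identifiers,
    dimensions matching the identifier lists, and all values finite.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise ValidationError(f"duplicate gene identifier {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise ValidationError(f"duplicate sample identifier {dup!r}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = map(int, np.argwhere(~np.isfinite(self.values))[0])
            raise ValidationError(
                f"non-finite expression value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    # -- convenience accessors -------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_ids: Iterable[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([pos[g] for g in gene_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise ValidationError(f"unknown gene id {exc.args[0]!r}") from None

    def sample_index(self, sample_ids: Iterable[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([pos[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise ValidationError(f"unknown sample id {exc.args[0]!r}") from None

    def subset(self, genes: Sequence[str] | None = None,
               samples: Sequence[str] | None = None) -> "ExpressionMatrix":
        gi = self.gene_index(genes) if genes is not None else slice(None)
        si = self.sample_index(samples) if samples is not None else slice(None)
        vals = self.values[gi][:, si]
        return ExpressionMatrix(
            list(genes) if genes is not None else list(self.gene_ids),
            list(samples) if samples is not None else list(self.sample_ids),
            vals,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(float))


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""  # pragma: no cover


def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        return dialect
    return "gct" if path.suffix.lower() == ".gct" else "tsv"


def _numeric_block(cells: pd.DataFrame, gene_ids: Sequence[str],
                   sample_ids: Sequence[str], missing: str) -> np.ndarray:
    """Convert a block of string cells to floats with coordinates on failure."""
    raw = cells.to_numpy(dtype=object)
    lowered = np.char.strip(np.char.lower(raw.astype(str)))
    is_na = np.isin(lowered, sorted(_NA_TOKENS))
    numeric = pd.DataFrame(raw).apply(pd.to_numeric, errors="coerce").to_numpy(float)
    bad = np.isnan(numeric) & ~is_na
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise FormatError(
            f"non-numeric value {raw[i, j]!r} at gene {gene_ids[i]!r} "
            f"(row {i + 1}), sample {sample_ids[j]!r} (column {j + 1})"
        )
    if is_na.any():
        if missing == "reject":
            i, j = map(int, np.argwhere(is_na)[0])
            raise ValidationError(
                f"missing expression value at gene {gene_ids[i]!r}, sample "
                f"{sample_ids[j]!r}; pass missing='median' to impute"
            )
        if missing == "median":
            for i in np.unique(np.argwhere(is_na)[:, 0]):
                row = numeric[i]
                ok = ~np.isnan(row)
                if not ok.any():
                    raise ValidationError(
                        f"gene {gene_ids[i]!r} has no observed values to impute from"
                    )
                row[~ok] = np.median(row[ok])
        else:
            raise ValidationError(f"unknown missing policy {missing!r}")
    return numeric


def _collapse_duplicates(gene_ids: list[str], values: np.ndarray,
                         rule: str) -> tuple[list[str], np.ndarray]:
    ids = pd.Index(gene_ids)
    if not ids.duplicated().any():
        return gene_ids, values
    if rule == "error":
        raise ValidationError(
            f"duplicate gene identifier {ids[ids.duplicated()][0]!r}"
        )
    order: list[str] = list(dict.fromkeys(gene_ids))
    rows = []
    by_gene: dict[str, list[int]] = {}
    for i, g in enumerate(gene_ids):
        by_gene.setdefault(g, []).append(i)
    for g in order:
        idx = by_gene[g]
        if len(idx) == 1:
            rows.append(values[idx[0]])
        elif rule == "max_mean":
            means = values[idx].mean(axis=1)
            rows.append(values[idx[int(np.argmax(means))]])
        elif rule == "mean":
            rows.append(values[idx].mean(axis=0))
        else:
            raise ValidationError(f"unknown duplicate-collapse rule {rule!r}")
    return order, np.vstack(rows)


def read_expression_matrix(path: str | Path, dialect: str | None = None,
                           collapse: str = "max_mean",
                           missing: str = "reject") -> ExpressionMatrix:
    """Read a log2 expression matrix from TSV or GCT 1.2.

    Parameters
    ----------
    dialect:
        ``"tsv"`` or ``"gct"``; inferred from the file suffix when omitted.
    collapse:
        Rule for duplicate gene rows: ``"max_mean"`` keeps the row with the
        highest mean expression (default), ``"mean"`` averages, ``"error"``
        refuses.
    missing:
        ``"reject"`` (default) or ``"median"`` for per-gene median imputation.
    """
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    if dialect == "tsv":
        return _read_tsv_expression(path, collapse, missing)
    if dialect == "gct":
        return _read_gct_expression(path, collapse, missing)
    raise ValidationError(f"unknown expression dialect {dialect!r}")


def _read_tsv_expression(path: Path, collapse: str, missing: str) -> ExpressionMatrix:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: header line has no sample columns: {header!r}")
    sample_ids = [h.strip() for h in header[1:]]
    dup = _first_duplicate(sample_ids)
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError(f"{path}: duplicate sample identifier {dup!r} in header")
    table = pd.read_csv(path, sep="\t", dtype=str, header=None, skiprows=1)
    if table.shape[1] != len(header):
        raise FormatError(
            f"{path}: data rows have {table.shape[1]} columns, header has {len(header)}"
        )
    gene_ids = [str(g) for g in table.iloc[:, 0]]
    values = _numeric_block(table.iloc[:, 1:], gene_ids, sample_ids, missing)
    gene_ids, values = _collapse_duplicates(gene_ids, values, collapse)
    return ExpressionMatrix(gene_ids, sample_ids, values)


def _read_gct_expression(path: Path, collapse: str, missing: str) -> ExpressionMatrix:
    with open(path, encoding="utf-8") as fh:
        version = fh.readline().strip()
        dims = fh.readline().strip().split("\t")
        header = fh.readline().rstrip("\n").split("\t")
    if not version.startswith("#1."):
        raise FormatError(f"{path}: not a GCT file (first line {version!r})")
    try:
        n_genes, n_samples = int(dims[0]), int(dims[1])
    except (ValueError, IndexError):
        raise FormatError(f"{path}: malformed GCT dimension line {dims!r}") from None
    if len(header) < 3 or header[0].lower() != "name":
        raise FormatError(f"{path}: malformed GCT header line {header!r}")
    sample_ids = [h.strip() for h in header[2:]]
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError(
            f"{path}: duplicate sample identifier {_first_duplicate(sample_ids)!r}"
        )
    table = pd.read_csv(path, sep="\t", dtype=str, header=None, skiprows=3)
    if table.shape[0] != n_genes or len(sample_ids) != n_samples:
        raise FormatError(
            f"{path}: declared {n_genes} rows x {n_samples} samples but found "
            f"{table.shape[0]} data rows x {len(sample_ids)} sample columns"
        )
    gene_ids = [str(g) for g in table.iloc[:, 0]]
    values = _numeric_block(table.iloc[:, 2:], gene_ids, sample_ids, missing)
    gene_ids, values = _collapse_duplicates(gene_ids, values, collapse)
    return ExpressionMatrix(gene_ids, sample_ids, values)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path,
                            dialect: str | None = None) -> None:
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    frame = expr.to_frame()
    if dialect == "tsv":
        frame.to_csv(path, sep="\t", index_label="gene_id")
    elif dialect == "gct":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#1.2\n")
            fh.write(f"{expr.n_genes}\t{expr.n_samples}\n")
            fh.write("Name\tDescription\t" + "\t".join(expr.sample_ids) + "\n")
            for g, row in zip(expr.gene_ids, expr.values):
                fh.write(g + "\tna\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    else:
        raise ValidationError(f"unknown expression dialect {dialect!r}")


# ---------------------------------------------------------------------------
# CohortAnnotation
# ---------------------------------------------------------------------------

_STAGE_RE = re.compile(r"^(IV|III|II|I)\s*[ABC]?$", re.IGNORECASE)
_STAGE_ORDINAL = {"I": 1, "II": 2, "III": 3, "IV": 4}


def normalize_stage(raw: object) -> int | None:
    """Collapse an AJCC stage string to its main-stage ordinal (I..IV -> 1..4).

    Substage letters (``IIIb``...) are dropped; numeric input 1..4 is accepted.
    """
    if raw is None:
        return None
    text = str(raw).strip()
    if text.lower() in _NA_TOKENS:
        return None
    try:
        num = float(text)
    except ValueError:
        num = None
    if num is not None:
        if num in (1.0, 2.0, 3.0, 4.0):
            return int(num)
        raise ValidationError(f"unrecognized AJCC stage {raw!r}")
    m = _STAGE_RE.match(text)
    if not m:
        raise ValidationError(f"unrecognized AJCC stage {raw!r}")
    return _STAGE_ORDINAL[m.group(1).upper()]


@dataclass
class CohortAnnotation:
    """Per-sample clinical record: histology, covariates, treatment, survival."""

    sample_id: str
    histology: str | None = None
    pcc: bool | None = None
    age: float | None = None
    sex: str | None = None
    ajcc_stage: int | None = None
    tumor_site: str | None = None
    chemo: bool | None = None
    dfs_time: float | None = None
    dfs_event: bool | None = None
    os_time: float | None = None
    os_event: bool | None = None
    molecular_subtype: str | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_id = str(self.sample_id)
        if self.histology is not None and self.histology not in HISTOLOGIES:
            raise ValidationError(
                f"{self.sample_id}: unknown histology {self.histology!r}"
            )
        if self.sex is not None and self.sex not in SEXES:
            raise ValidationError(f"{self.sample_id}: unknown sex {self.sex!r}")
        if self.tumor_site is not None and self.tumor_site not in TUMOR_SITES:
            raise ValidationError(
                f"{self.sample_id}: unknown tumor site {self.tumor_site!r}"
            )
        if (self.molecular_subtype is not None
                and self.molecular_subtype not in MOLECULAR_SUBTYPES):
            raise ValidationError(
                f"{self.sample_id}: unknown molecular subtype "
                f"{self.molecular_subtype!r}"
            )
        if self.ajcc_stage is not None and self.ajcc_stage not in (1, 2, 3, 4):
            raise ValidationError(
                f"{self.sample_id}: AJCC stage ordinal must be 1..4, "
                f"got {self.ajcc_stage!r}"
            )
        for prefix in ("dfs", "os"):
            time = getattr(self, f"{prefix}_time")
            event = getattr(self, f"{prefix}_event")
            if time is not None and time < 0:
                raise ValidationError(
                    f"{self.sample_id}: negative {prefix} time {time!r}"
                )
            if event is not None and time is None:
                raise ValidationError(
                    f"{self.sample_id}: {prefix}_event present without {prefix}_time"
                )


_CLINICAL_FIELDS = [f.name for f in fields(CohortAnnotation) if f.name != "extras"]


def _opt_str(value: object) -> str | None:
    if value is None:
        return None
    text = str(value).strip()
    return None if text.lower() in _NA_TOKENS else text


def _opt_float(value: object, context: str) -> float | None:
    text = _opt_str(value)
    if text is None:
        return None
    try:
        return float(text)
    except ValueError:
        raise ValidationError(f"{context}: not a number: {value!r}") from None


def _opt_bool(value: object, context: str) -> bool | None:
    text = _opt_str(value)
    if text is None:
        return None
    low = text.lower()
    if low in _BOOL_TRUE:
        return True
    if low in _BOOL_FALSE:
        return False
    try:  # tolerate float-formatted flags ("1.0") from round-tripped tables
        num = float(low)
    except ValueError:
        num = None
    if num in (0.0, 1.0):
        return bool(num)
    raise ValidationError(f"{context}: not a boolean: {value!r}")


def _norm_enum(value: object, mapping: dict[str, str], context: str) -> str | None:
    text = _opt_str(value)
    if text is None:
        return None
    key = text.lower()
    if key not in mapping:
        raise ValidationError(f"{context}: unknown value {value!r}")
    return mapping[key]


_SEX_MAP = {"male": "male", "m": "male", "female": "female", "f": "female"}
_HIST_MAP = {h: h for h in HISTOLOGIES}
_SITE_MAP = {s: s for s in TUMOR_SITES}
_MOL_MAP = {m.lower(): m for m in MOLECULAR_SUBTYPES}


def read_clinical_table(path: str | Path) -> list[CohortAnnotation]:
    """Read a per-sample clinical TSV into validated records, sorted by sample id.

    The only required column is ``sample_id``; every other documented column is
    optional by name, and unrecognized columns are preserved verbatim in
    ``extras``.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in table.columns:
        raise FormatError(f"{path}: clinical table lacks a 'sample_id' column")
    extra_cols = [c for c in table.columns if c not in _CLINICAL_FIELDS]
    records: list[CohortAnnotation] = []
    seen: set[str] = set()
    for _, row in table.iterrows():
        sid = _opt_str(row["sample_id"])
        if sid is None:
            raise ValidationError(f"{path}: empty sample_id")
        if sid in seen:
            raise ValidationError(f"{path}: duplicate sample_id {sid!r}")
        seen.add(sid)
        ctx = f"{path}:{sid}"
        get = lambda col: row[col] if col in table.columns else None  # noqa: E731
        records.append(CohortAnnotation(
            sample_id=sid,
            histology=_norm_enum(get("histology"), _HIST_MAP, ctx),
            pcc=_opt_bool(get("pcc"), ctx),
            age=_opt_float(get("age"), ctx),
            sex=_norm_enum(get("sex"), _SEX_MAP, ctx),
            ajcc_stage=normalize_stage(get("ajcc_stage")),
            tumor_site=_norm_enum(get("tumor_site"), _SITE_MAP, ctx),
            chemo=_opt_bool(get("chemo"), ctx),
            dfs_time=_opt_float(get("dfs_time"), ctx),
            dfs_event=_opt_bool(get("dfs_event"), ctx),
            os_time=_opt_float(get("os_time"), ctx),
            os_event=_opt_bool(get("os_event"), ctx),
            molecular_subtype=_norm_enum(get("molecular_subtype"), _MOL_MAP, ctx),
            extras={c: _opt_str(row[c]) for c in extra_cols},
        ))
    records.sort(key=lambda r: r.sample_id)
    return records


def write_clinical_table(annotations: Sequence[CohortAnnotation],
                         path: str | Path) -> None:
    extra_cols: list[str] = []
    for ann in annotations:
        for c in ann.extras:
            if c not in extra_cols:
                extra_cols.append(c)
    rows = []
    for ann in annotations:
        row: dict[str, object] = {}
        for name in _CLINICAL_FIELDS:
            value = getattr(ann, name)
            if isinstance(value, bool):
                value = int(value)
            row[name] = value
        for c in extra_cols:
            row[c] = ann.extras.get(c)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def clinical_frame(annotations: Sequence[CohortAnnotation]) -> pd.DataFrame:
    """Typed per-sample DataFrame (indexed by sample_id) for modelling code."""
    rows = []
    for ann in annotations:
        rows.append({name: getattr(ann, name) for name in _CLINICAL_FIELDS})
    frame = pd.DataFrame(rows).set_index("sample_id")
    for col in ("age", "dfs_time", "os_time"):
        frame[col] = frame[col].astype(float)
    frame["ajcc_stage"] = frame["ajcc_stage"].astype("Float64")
    return frame


# ---------------------------------------------------------------------------
# MutationTable
# ---------------------------------------------------------------------------

@dataclass
class MutationTable:
    """Somatic mutation records in canonical (sample, gene, class) form.

    ``nonsynonymous_classes`` declares which variant classes count toward
    mutation burden.
    """

    records: pd.DataFrame
    nonsynonymous_classes: frozenset[str] = NONSYNONYMOUS_CLASSES

    def __post_init__(self) -> None:
        required = ["sample_id", "gene_id", "variant_class"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise ValidationError(f"mutation records lack columns {missing}")
        self.records = (
            self.records[required]
            .astype(str)
            .sort_values(required, kind="mergesort")
            .reset_index(drop=True)
        )
        self.nonsynonymous_classes = frozenset(self.nonsynonymous_classes)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.records["sample_id"].unique())

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.records["gene_id"].unique())

    def filtered(self, classes: Iterable[str] | None = None) -> pd.DataFrame:
        if classes is None:
            return self.records
        return self.records[self.records["variant_class"].isin(set(classes))]

    def indicator(self, samples: Sequence[str] | None = None,
                  genes: Sequence[str] | None = None,
                  classes: Iterable[str] | None = None) -> pd.DataFrame:
        """0/1 sample x gene presence matrix (>=1 qualifying record -> 1)."""
        recs = self.filtered(classes)
        samples = list(samples) if samples is not None else self.sample_ids
        genes = list(genes) if genes is not None else sorted(recs["gene_id"].unique())
        mat = pd.DataFrame(0, index=samples, columns=genes, dtype=int)
        hit = recs[recs["sample_id"].isin(samples) & recs["gene_id"].isin(genes)]
        for sid, gid in zip(hit["sample_id"], hit["gene_id"]):
            mat.at[sid, gid] = 1
        return mat


def _normalize_variant_classes(classes: pd.Series, strict: bool) -> pd.Series:
    lowered = classes.str.strip().str.lower()
    unknown = sorted(set(lowered) - set(VARIANT_CLASS_ALIASES))
    if unknown:
        if strict:
            raise ValidationError(
                f"unknown variant class(es) {unknown}; disable strict mode to keep "
                "them verbatim"
            )
        return lowered.map(lambda c: VARIANT_CLASS_ALIASES.get(c, c))
    return lowered.map(VARIANT_CLASS_ALIASES)


def read_mutation_table(path: str | Path, strict: bool = True,
                        nonsynonymous: Iterable[str] = NONSYNONYMOUS_CLASSES,
                        ) -> MutationTable:
    """Read MAF-lite records or a wide 0/1 indicator matrix (auto-detected).

    Record form requires columns ``sample_id``, ``gene_id``, ``variant_class``.
    Any other layout is treated as a wide matrix whose first column holds
    sample ids; wide cells must be 0 or 1, and imported records carry the
    variant class ``unspecified``.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    cols = set(table.columns)
    if {"sample_id", "gene_id", "variant_class"} <= cols:
        recs = table[["sample_id", "gene_id", "variant_class"]].copy()
        if len(recs):
            recs["variant_class"] = _normalize_variant_classes(
                recs["variant_class"].astype(str), strict
            )
        return MutationTable(recs, frozenset(nonsynonymous))
    # wide indicator matrix
    if table.shape[1] < 2:
        raise FormatError(f"{path}: mutation table has no gene columns")
    sample_col = table.columns[0]
    gene_cols = list(table.columns[1:])
    rows = []
    for _, row in table.iterrows():
        sid = _opt_str(row[sample_col])
        if sid is None:
            raise ValidationError(f"{path}: empty sample id in wide matrix")
        for g in gene_cols:
            cell = _opt_str(row[g])
            if cell is None or cell == "0":
                continue
            if cell != "1":
                raise ValidationError(
                    f"{path}: wide mutation matrix must be 0/1; found {cell!r} "
                    f"for sample {sid!r}, gene {g!r}"
                )
            rows.append({"sample_id": sid, "gene_id": g,
                         "variant_class": "unspecified"})
    recs = pd.DataFrame(rows, columns=["sample_id", "gene_id", "variant_class"])
    return MutationTable(recs, frozenset(nonsynonymous))


def write_mutation_table(mut: MutationTable, path: str | Path) -> None:
    mut.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# TestResult
# ---------------------------------------------------------------------------

@dataclass
class TestResult:
    """Container for a hypothesis-test outcome (statistic, p, optional effect)."""

    statistic: float
    p_value: float
    method: str
    df: float | None = None
    effect: float | None = None
    effect_name: str | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.method:
            raise ValidationError("TestResult.method must be nonempty")
        if not (0.0 <= self.p_value <= 1.0) or not np.isfinite(self.p_value):
            raise ValidationError(f"p-value out of [0, 1]: {self.p_value!r}")

    def to_dict(self) -> dict:
        out: dict[str, object] = {
            "method": self.method,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
        }
        if self.df is not None:
            out["df"] = float(self.df)
        if self.effect is not None:
            out["effect"] = float(self.effect)
            out["effect_name"] = self.effect_name
        if self.extras:
            out["extras"] = dict(self.extras)
        return out


def warn(message: str) -> None:
    """Single funnel for data-quality warnings (kept patchable in tests)."""
    warnings.warn(message, UserWarning, stacklevel=3)
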