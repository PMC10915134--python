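"""Shared data types and readers/writers for the standard text formats.

The pipeline consumes four kinds of input: gene signatures (GMT), bulk
expression matrices (TSV or GCT v1.2, genes x samples, log scale), clinical
tables (delimited text with an optional column-mapping config), and somatic
mutation tables (a minimal MAF dialect).  Everything is held in pandas
containers wrapped by light dataclasses that enforce the invariants each
downstream stage assumes.

Gene identifiers are matched as case-sensitive symbols after whitespace
trimming; no alias resolution is attempted.  Duplicate gene rows in an
expression matrix are collapsed by per-sample maximum (a common microarray
convention; the rule is logged and idempotent).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ordered vocabulary of plasma-cell-dyscrasia disease states, from healthy
#: marrow through relapsed/refractory myeloma.
STAGE_ORDER = ("Healthy", "MGUS", "SMM", "NDMM", "RRMM")

#: Recognised molecular subtype labels (consumed as input, never derived).
SUBTYPE_LABELS = ("CD1", "CD2", "HY", "LB", "MF", "MS", "PR")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of log-scale expression values.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are gene identifiers, columns are sample identifiers, values
        are log2-scale intensities or log2(TPM+1).  Identifiers must be
        unique and all values finite; at least 2 genes and 1 sample.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data
        if d.index.has_duplicates:
            dups = d.index[d.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        if d.columns.has_duplicates:
            dups = d.columns[d.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups[:5]}")
        if d.shape[0] < 2 or d.shape[1] < 1:
            raise ValueError(
                f"expression matrix needs >= 2 genes and >= 1 sample, got {d.shape}"
            )
        vals = d.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                f"non-finite expression value at gene {d.index[bad[0]]!r}, "
                f"sample {d.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class GeneSignature:
    """A named marker-gene set for one cell type."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("signature name must be non-empty")
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")
        object.__setattr__(self, "genes", frozenset(self.genes))


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations, indexed by sample identifier.

    Canonical columns (all optional except the index): ``os_time`` /
    ``os_event``, ``efs_time`` / ``efs_event``, ``age``, ``sex``, ``race``,
    ``b2m`` (mg/L), ``albumin`` (g/dL), ``ldh`` and ``ldh_uln`` (U/L),
    boolean cytogenetic flags (``del17p``, ``t_4_14``, ``t_14_16``,
    ``t_11_14``, ``t_8_14``, ``gain1q``), ``stage_label`` (ordered factor
    over :data:`STAGE_ORDER`), ``iss`` / ``r_iss`` / ``r2_iss``,
    ``subtype_label`` and ``progressed``.  Missing numeric values propagate
    as NaN; each downstream operation states its own complete-case policy.
    Unmapped input columns are preserved untouched.
    """

    data: pd.DataFrame

    EVENT_COLS = ("os_event", "efs_event", "progressed")
    TIME_COLS = ("os_time", "efs_time")

    def __post_init__(self) -> None:
        d = self.data
        if d.index.has_duplicates:
            raise ValueError("duplicate sample identifiers in clinical table")
        for col in self.EVENT_COLS:
            if col in d.columns:
                vals = pd.to_numeric(d[col], errors="coerce")
                ok = vals.isna() | vals.isin([0, 1])
                if not ok.all():
                    bad = d.index[~ok][0]
                    raise ValueError(
                        f"{col} outside {{0,1}} for sample {bad!r}"
                    )
        for col in self.TIME_COLS:
            if col in d.columns:
                vals = pd.to_numeric(d[col], errors="coerce")
                if (vals < 0).any():
                    bad = d.index[vals < 0][0]
                    raise ValueError(f"negative {col} for sample {bad!r}")
        if "stage_label" in d.columns:
            labels = d["stage_label"].dropna()
            unknown = set(labels) - set(STAGE_ORDER)
            if unknown:
                raise ValueError(f"unknown stage labels: {sorted(unknown)}")
            self.data["stage_label"] = pd.Categorical(
                d["stage_label"], categories=list(STAGE_ORDER), ordered=True
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def stage_codes(self) -> pd.Series:
        """0-based ordered codes of ``stage_label`` (Healthy = 0 ... RRMM = 4)."""
        return self.data["stage_label"].cat.codes.replace(-1, np.nan)


@dataclass(frozen=True)
class MutationTable:
    """Long-format somatic mutation records.

    One row per (sample, gene, variant_classification) event; repeated
    triples are allowed (multiple hits in one gene).
    """

    data: pd.DataFrame

    REQUIRED = ("sample_id", "gene", "variant_classification")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"mutation table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class SignatureScoreTable:
    """Per-sample permutation-normalised signature scores plus the PBM score.

    ``scores`` holds one z column per signature (samples as rows); ``pbm``
    is the plasma-cell score with the malignancy orientation applied
    (higher = more perturbed plasma-marker expression = more malignant).
    """

    scores: pd.DataFrame
    pbm: pd.Series | None = None
    plasma_signature: str | None = None

    def __post_init__(self) -> None:
        if self.scores.empty:
            raise ValueError("score table is empty")
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise ValueError("score table contains non-finite values")
        if (self.pbm is None) != (self.plasma_signature is None):
            raise ValueError("pbm and plasma_signature must be set together")
        if self.pbm is not None and not self.pbm.index.equals(self.scores.index):
            raise ValueError("pbm index does not match score table samples")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def signature_names(self) -> list[str]:
        return list(self.scores.columns)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_gmt(path) -> list[GeneSignature]:
    """Read gene signatures from a GMT file.

    Each non-empty line is ``name<TAB>description<TAB>gene1<TAB>gene2...``.
    The description field is discarded; duplicate genes within a line are
    collapsed with a warning; duplicate signature names are an error.
    """
    signatures: list[GeneSignature] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name = fields[0].strip()
            genes = [g.strip() for g in fields[2:] if g.strip()]
            if not genes:
                raise FormatError(f"{path}: line {lineno}: no genes listed")
            if name in seen:
                raise FormatError(
                    f"{path}: line {lineno}: duplicate signature name {name!r}"
                )
            if len(set(genes)) < len(genes):
                logger.warning(
                    "signature %r: collapsed %d duplicate gene entries",
                    name,
                    len(genes) - len(set(genes)),
                )
            seen.add(name)
            signatures.append(GeneSignature(name=name, genes=frozenset(genes)))
    return signatures


def write_gmt(signatures: list[GeneSignature], path) -> None:
    """Write signatures as GMT (sorted gene order for determinism)."""
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, "na", *sorted(sig.genes)]) + "\n")


def _collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated().sum())
        logger.warning(
            "collapsing %d duplicate gene rows by per-sample maximum", n_dup
        )
        df = df.groupby(level=0, sort=False).max()
    return df


def read_expression(path, format: str = "tsv") -> ExpressionMatrix:
    """Read a genes x samples expression matrix from TSV or GCT v1.2.

    TSV: header row of sample ids, first column gene ids.  GCT: ``#1.2``
    header, a dimensions line, then NAME / Description columns before the
    samples.  Duplicate gene rows collapse by per-sample maximum.
    """
    if format == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
        samples = header[1:]
        if len(samples) != len(set(samples)):
            raise FormatError(f"{path}: duplicate sample identifiers in header")
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    elif format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise FormatError(f"{path}: expected '#1.2' header, got {version!r}")
            dims = fh.readline().split()
            if len(dims) != 2:
                raise FormatError(f"{path}: malformed GCT dimensions line")
            n_genes, n_samples = int(dims[0]), int(dims[1])
        df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0, dtype={0: str})
        if "Description" in df.columns:
            df = df.drop(columns=["Description"])
        else:
            df = df.drop(columns=df.columns[0])
        if df.shape != (n_genes, n_samples):
            raise FormatError(
                f"{path}: declared dims {(n_genes, n_samples)} do not match "
                f"content {df.shape}"
            )
        if df.columns.has_duplicates:
            raise FormatError(f"{path}: duplicate sample identifiers")
    else:
        raise ValueError(f"unknown expression format {format!r}")

    df.index = df.index.astype(str).str.strip()
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad][0]
            raise FormatError(
                f"{path}: non-numeric value at gene {gene!r}, sample {col!r}"
            )
        df[col] = coerced
    df = _collapse_duplicate_genes(df)
    return ExpressionMatrix(df.astype(float))


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id")


def read_clinical(path, schema: dict[str, str] | None = None) -> ClinicalTable:
    """Read a clinical table from delimited text.

    ``schema`` maps canonical field names (``sample_id``, ``os_time`` ...)
    to the file's column names; unmapped columns are preserved as opaque
    annotations.  With no schema, columns are taken at face value and the
    first column is the sample identifier.
    """
    df = pd.read_csv(path, sep="\t")
    if schema:
        rename = {src: canon for canon, src in schema.items() if src in df.columns}
        missing = [src for src in schema.values() if src not in df.columns]
        if missing:
            raise FormatError(f"{path}: mapped columns not found: {missing}")
        df = df.rename(columns=rename)
    id_col = "sample_id" if "sample_id" in df.columns else df.columns[0]
    df[id_col] = df[id_col].astype(str).str.strip()
    df = df.set_index(id_col)
    df.index.name = "sample_id"
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


def read_maf(path) -> MutationTable:
    """Read a minimal MAF: Hugo_Symbol, Tumor_Sample_Barcode, Variant_Classification."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {
        "Hugo_Symbol": "gene",
        "Tumor_Sample_Barcode": "sample_id",
        "Variant_Classification": "variant_classification",
    }
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required MAF columns: {missing}")
    out = df.rename(columns=required)[list(required.values())]
    for col in out.columns:
        out[col] = out[col].astype(str).str.strip()
    return MutationTable(out.reset_index(drop=True))


def write_maf(table: MutationTable, path) -> None:
    out = table.data.rename(
        columns={
            "gene": "Hugo_Symbol",
            "sample_id": "Tumor_Sample_Barcode",
            "variant_classification": "Variant_Classification",
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_scores(table: SignatureScoreTable, path) -> None:
    """Write a score table as TSV: samples as rows, one column per signature
    plus a ``PBM`` column.  Round-trips through :func:`read_scores` to 1e-9."""
    out = table.scores.copy()
    if table.pbm is not None:
        out["PBM"] = table.pbm
    out.to_csv(path, sep="\t", index_label="sample_id", float_format="%.12g")


def read_scores(path, plasma_signature: str | None = None) -> SignatureScoreTable:
    """Read a score TSV written by :func:`write_scores`."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    df.index = df.index.astype(str)
    pbm = None
    if "PBM" in df.columns:
        pbm = df.pop("PBM")
    if df.shape[1] == 0 and pbm is not None:
        # PBM-only table: the PBM column doubles as the sole signature score
        df = pbm.to_frame(name="PBM")
        plasma_signature = plasma_signature or "PBM"
    if pbm is not None and plasma_signature is None:
        plasma_signature = "plasma"
    return SignatureScoreTable(scores=df, pbm=pbm, plasma_signature=plasma_signature)
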