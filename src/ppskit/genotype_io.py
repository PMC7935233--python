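"""Reading, validation and pre-filtering of genotype / phenotype / annotation tables.

Genotypes are categorical: each cell holds one of the universal codes 1, 2, 3
(e.g. AA = 1, AC = 2, CC = 3) or is missing.  Internally a
:class:`GenotypeMatrix` wraps a float ``pandas.DataFrame`` (subjects x SNPs)
with ``NaN`` marking missing calls, which keeps the downstream linear algebra
vectorised.

The phenotype is the per-subject change in the count of satisfactory sexual
events (ΔSSE) between a placebo run-in period and an active treatment period.
Its dichotomisation ΔSSE_D labels non-responders 1 (ΔSSE <= 0) and responders
2 (ΔSSE >= 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyPanelError, FormatError, ValidationError

VALID_CATEGORIES = (1, 2, 3)

NON_RESPONDER = 1
RESPONDER = 2


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeMatrix:
    """Subjects x SNPs table of genotype categories {1,2,3}; NaN = missing."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].tolist()
            raise ValidationError(f"duplicate subject ids: {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate SNP ids: {dupes}")
        values = df.to_numpy(dtype=float, copy=False)
        bad = ~(np.isnan(values) | np.isin(values, VALID_CATEGORIES))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"genotype category out of alphabet {{1,2,3}} at "
                f"subject {df.index[r]!r}, SNP {df.columns[c]!r}: {values[r, c]!r}"
            )

    @property
    def subject_ids(self) -> list:
        return list(self.data.index)

    @property
    def snp_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_snps(self) -> int:
        return self.data.shape[1]

    def select_snps(self, snp_ids: Sequence) -> "GenotypeMatrix":
        """Pure column selection; retained cells are untouched."""
        return GenotypeMatrix(self.data.loc[:, list(snp_ids)])

    def select_subjects(self, subject_ids: Sequence) -> "GenotypeMatrix":
        return GenotypeMatrix(self.data.loc[list(subject_ids), :])


@dataclass(frozen=True)
class SnpAnnotation:
    """Mapping snp_id -> gene symbol (many SNPs may share a gene)."""

    gene_by_snp: Mapping[str, str]

    def __post_init__(self) -> None:
        for snp, gene in self.gene_by_snp.items():
            if not str(snp).strip():
                raise ValidationError("empty SNP identifier in annotation")
            if not str(gene).strip():
                raise ValidationError(f"empty gene symbol for SNP {snp!r}")


@dataclass(frozen=True)
class OutcomeData:
    """Per-subject ΔSSE and its dichotomisation ΔSSE_D ∈ {1, 2}.

    ``sse_pri`` / ``sse_active`` (the raw event counts in the placebo run-in
    and active period) are retained when the phenotype file provides them;
    group-level evaluation uses them as the paired pre/post measurements.
    """

    delta_sse: pd.Series
    sse_pri: pd.Series | None = None
    sse_active: pd.Series | None = None
    delta_sse_d: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        if self.delta_sse.index.has_duplicates:
            raise ValidationError("duplicate subject ids in outcome data")
        if self.delta_sse.isna().any():
            missing = self.delta_sse.index[self.delta_sse.isna()].tolist()
            raise ValidationError(f"subjects missing outcome: {missing}")
        delta = self.delta_sse.astype(int)
        object.__setattr__(self, "delta_sse", delta)
        labels = pd.Series(
            np.where(delta.to_numpy() <= 0, NON_RESPONDER, RESPONDER),
            index=delta.index,
            dtype=int,
        )
        object.__setattr__(self, "delta_sse_d", labels)

    @property
    def subject_ids(self) -> list:
        return list(self.delta_sse.index)

    def align_to(self, g: GenotypeMatrix) -> "OutcomeData":
        """Check subject sets match and return outcomes in the matrix's order."""
        if set(self.delta_sse.index) != set(g.data.index):
            raise ValidationError("outcome and genotype subject ids differ")
        order = g.data.index
        return OutcomeData(
            delta_sse=self.delta_sse.loc[order],
            sse_pri=None if self.sse_pri is None else self.sse_pri.loc[order],
            sse_active=None if self.sse_active is None else self.sse_active.loc[order],
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_delimited(path, missing_token: str = "NA") -> pd.DataFrame:
    """Comma/tab auto-detected delimited text with a header row."""
    return pd.read_csv(
        path,
        sep=None,
        engine="python",
        index_col=0,
        dtype=str,
        keep_default_na=False,
        na_values=[missing_token],
        comment=None,
    )


def read_genotype_table(path, missing_token: str = "NA") -> GenotypeMatrix:
    """Read a subjects x SNPs table of categories {1,2,3} / missing token.

    Header row carries SNP ids, the first column subject ids; row/column
    order is preserved from the file.
    """
    raw = _read_delimited(path, missing_token)
    values = np.full(raw.shape, np.nan)
    for j, col in enumerate(raw.columns):
        for i, cell in enumerate(raw[col]):
            if isinstance(cell, float) and np.isnan(cell):
                continue
            text = str(cell).strip()
            if text == missing_token or text == "":
                continue
            try:
                v = int(text)
            except ValueError:
                raise FormatError(
                    f"unparseable genotype {cell!r} at row {raw.index[i]!r}, column {col!r}"
                ) from None
            if v not in VALID_CATEGORIES:
                raise FormatError(
                    f"genotype {v} outside alphabet {{1,2,3}} at row "
                    f"{raw.index[i]!r}, column {col!r}"
                )
            values[i, j] = v
    df = pd.DataFrame(values, index=raw.index, columns=raw.columns)
    df.index.name = None
    df.columns.name = None
    return GenotypeMatrix(df)


def write_genotype_table(g: GenotypeMatrix, path, missing_token: str = "NA") -> None:
    formatted = g.data.map(lambda v: missing_token if pd.isna(v) else str(int(v)))
    formatted.rename_axis("subject_id").to_csv(path)


def read_phenotype_table(path) -> OutcomeData:
    """Read subject_id plus either ``delta_sse`` or ``sse_pri``/``sse_active``.

    When the two count columns are given, ΔSSE = active − run-in.
    """
    raw = _read_delimited(path)
    cols = set(raw.columns)

    def _int_col(name: str) -> pd.Series:
        col = raw[name]
        if col.isna().any():
            missing = raw.index[col.isna()].tolist()
            raise ValidationError(f"subjects missing {name}: {missing}")
        try:
            as_float = col.astype(float)
        except ValueError as exc:
            raise FormatError(f"non-numeric value in column {name!r}: {exc}") from None
        if not np.all(as_float == np.round(as_float)):
            bad = raw.index[as_float != np.round(as_float)].tolist()
            raise FormatError(f"non-integer counts in column {name!r} for {bad}")
        return as_float.astype(int)

    if {"sse_pri", "sse_active"} <= cols:
        pri = _int_col("sse_pri")
        active = _int_col("sse_active")
        return OutcomeData(delta_sse=active - pri, sse_pri=pri, sse_active=active)
    if "delta_sse" in cols:
        return OutcomeData(delta_sse=_int_col("delta_sse"))
    raise FormatError(
        "phenotype table needs either a 'delta_sse' column or both "
        "'sse_pri' and 'sse_active'"
    )


def write_phenotype_table(outcome: OutcomeData, path) -> None:
    if outcome.sse_pri is not None and outcome.sse_active is not None:
        df = pd.DataFrame(
            {"sse_pri": outcome.sse_pri, "sse_active": outcome.sse_active}
        )
    else:
        df = pd.DataFrame({"delta_sse": outcome.delta_sse})
    df.rename_axis("subject_id").to_csv(path)


def read_annotation(path) -> SnpAnnotation:
    """Two-column delimited text: snp_id, gene."""
    raw = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if raw.shape[1] < 2:
        raise FormatError("annotation needs two columns: snp_id, gene")
    snp_col, gene_col = raw.columns[:2]
    return SnpAnnotation(dict(zip(raw[snp_col], raw[gene_col])))


def read_vcf_genotypes(path) -> GenotypeMatrix:
    """Ingest diploid genotypes from a (plain-text) VCF.

    0/0 -> 1, 0/1 or 1/0 -> 2, 1/1 -> 3, ./. -> missing.  Multi-allelic
    sites are rejected: the three-category coding has no slot for them.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    reader = VCF(str(path))
    subjects = list(reader.samples)
    snp_ids: list[str] = []
    columns: list[np.ndarray] = []
    for variant in reader:
        if len(variant.ALT) != 1:
            raise FormatError(
                f"multi-allelic site {variant.ID or variant.POS} not representable "
                "in the 1/2/3 genotype coding"
            )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        mapped = np.array(
            [{0: 1.0, 1: 2.0, 3: 3.0}.get(t, np.nan) for t in variant.gt_types]
        )
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        columns.append(mapped)
    data = pd.DataFrame(
        np.column_stack(columns) if columns else np.empty((len(subjects), 0)),
        index=subjects,
        columns=snp_ids,
    )
    return GenotypeMatrix(data)


# ---------------------------------------------------------------------------
# pre-filters
# ---------------------------------------------------------------------------


def filter_candidate_snps(
    g: GenotypeMatrix, ann: SnpAnnotation, genes: Iterable[str]
) -> GenotypeMatrix:
    """A-priori panel restriction: keep SNPs annotated to a candidate gene.

    SNPs without an annotation entry are dropped — the candidate-gene step is
    a whitelist.  SNP order and the subject set are preserved.
    """
    gene_set = set(genes)
    if not gene_set:
        raise ValidationError("candidate gene list is empty")
    keep = [s for s in g.snp_ids if ann.gene_by_snp.get(s) in gene_set]
    if not keep:
        raise EmptyPanelError("no SNP maps to the candidate gene list")
    return g.select_snps(keep)


def exclude_low_count_snps(g: GenotypeMatrix, min_obs: int = 3) -> GenotypeMatrix:
    """Drop SNPs whose rare genotype category is unreliably observed.

    A SNP is kept iff every category observed among its non-missing cells has
    at least ``min_obs`` observations and at least two distinct categories are
    observed (a monomorphic column cannot be oriented by outcome means).
    """
    if g.n_snps == 0:
        raise EmptyPanelError("genotype matrix has no SNPs")
    values = g.data.to_numpy(dtype=float)
    keep: list = []
    for j, snp in enumerate(g.snp_ids):
        col = values[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        cats, counts = np.unique(col, return_counts=True)
        if len(cats) >= 2 and counts.min() >= min_obs:
            keep.append(snp)
    if not keep:
        raise EmptyPanelError("every SNP fails the minimum-observation filter")
    return g.select_snps(keep)


def drop_snps_with_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Default missing-data policy: exclude SNPs with any missing call."""
    complete = [s for s in g.snp_ids if not g.data[s].isna().any()]
    if not complete:
        raise EmptyPanelError("every SNP has missing genotypes")
    return g.select_snps(complete)


def genotype_matrix_from_arrays(
    values, subject_ids: Sequence, snp_ids: Sequence
) -> GenotypeMatrix:
    """Convenience constructor from a plain array."""
    return GenotypeMatrix(
        pd.DataFrame(np.asarray(values, dtype=float), index=list(subject_ids), columns=list(snp_ids))
    )
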