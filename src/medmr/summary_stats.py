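"""Data model and I/O for GWAS summary-statistics tables.

A summary-statistics table holds one row per variant: identifier, genomic
location, allele pair, effect-allele frequency, the per-allele effect
estimate (``beta``) with its standard error, p-value, and sample size.
For binary traits ``beta`` is a log odds ratio; for quantitative traits it
is in SD units of the trait.

Files are tab-separated text with a header.  Column names follow
GWAS-SSF-style defaults (``rsid``, ``chromosome``, ``base_pair_location``,
``effect_allele``, ``other_allele``, ``effect_allele_frequency``, ``beta``,
``standard_error``, ``p_value``, ``n``); heterogeneous source headers are
accommodated through a *dialect*, a mapping from the canonical field names
to the file's column names.  Missing values (allowed only for ``eaf`` and
``n``) are serialized as ``NA``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, InvalidVariantError

BASES = frozenset({"A", "C", "G", "T"})

#: canonical field order, also the column order written by write_summary_stats
CANONICAL_FIELDS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

#: default dialect: canonical field -> GWAS-SSF-style column name
DEFAULT_DIALECT = {
    "variant_id": "rsid",
    "chrom": "chromosome",
    "pos": "base_pair_location",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "effect_allele_frequency",
    "beta": "beta",
    "se": "standard_error",
    "pval": "p_value",
    "n": "n",
}

_MISSING_TOKENS = {"", "NA", "NaN", "nan", ".", "None"}


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association record in one GWAS.

    Raises :class:`InvalidVariantError` / :class:`DomainError` on
    construction if any invariant is violated.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in BASES or self.other_allele not in BASES:
            raise InvalidVariantError(
                f"{self.variant_id}: alleles must be single uppercase bases, got "
                f"{self.effect_allele!r}/{self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise InvalidVariantError(f"{self.variant_id}: identical alleles")
        if not self.pos >= 1:
            raise DomainError(f"{self.variant_id}: pos must be >= 1, got {self.pos}")
        if not self.se > 0:
            raise DomainError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if not (0 < self.pval <= 1):
            raise DomainError(f"{self.variant_id}: pval must be in (0, 1], got {self.pval}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise DomainError(f"{self.variant_id}: eaf must be in [0, 1], got {self.eaf}")
        if self.n is not None and not self.n > 0:
            raise DomainError(f"{self.variant_id}: n must be positive, got {self.n}")
        if not math.isfinite(self.beta):
            raise DomainError(f"{self.variant_id}: beta must be finite")


@dataclass(frozen=True)
class RowRejection:
    """Why one input data row was rejected during parsing."""

    line: int  # 1-based physical line number in the file (header is line 1)
    reason: str


class SummaryStatsTable:
    """An ordered collection of :class:`VariantAssociation` for one trait.

    Internally backed by a :class:`pandas.DataFrame` with the canonical
    columns of :data:`CANONICAL_FIELDS`; ``eaf`` and ``n`` may hold NaN.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        trait_label: str = "",
        trait_type: str = "quantitative",
        rejections: list[RowRejection] | None = None,
    ):
        if trait_type not in ("binary", "quantitative"):
            raise DomainError(f"trait_type must be binary or quantitative, got {trait_type!r}")
        missing = [c for c in CANONICAL_FIELDS if c not in df.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        df = df.loc[:, list(CANONICAL_FIELDS)].reset_index(drop=True)
        df = df.astype(
            {
                "variant_id": str,
                "chrom": str,
                "pos": np.int64,
                "effect_allele": str,
                "other_allele": str,
                "eaf": float,
                "beta": float,
                "se": float,
                "pval": float,
                "n": float,  # float to admit NaN for missing
            }
        )
        self._validate_frame(df)
        self.df = df
        self.trait_label = trait_label
        self.trait_type = trait_type
        self.rejections = list(rejections or [])

    @staticmethod
    def _validate_frame(df: pd.DataFrame) -> None:
        if df["variant_id"].duplicated().any():
            dup = df.loc[df["variant_id"].duplicated(), "variant_id"].iloc[0]
            raise InvalidVariantError(f"duplicate variant_id {dup!r}")
        bad_allele = ~(
            df["effect_allele"].isin(BASES)
            & df["other_allele"].isin(BASES)
            & (df["effect_allele"] != df["other_allele"])
        )
        if bad_allele.any():
            raise InvalidVariantError(
                f"invalid allele pair for {df.loc[bad_allele, 'variant_id'].iloc[0]!r}"
            )
        checks = [
            (df["pos"] < 1, "pos < 1"),
            (~(df["se"] > 0), "se <= 0"),
            (~((df["pval"] > 0) & (df["pval"] <= 1)), "pval outside (0, 1]"),
            (df["eaf"].notna() & ~df["eaf"].between(0, 1), "eaf outside [0, 1]"),
            (df["n"].notna() & ~(df["n"] > 0), "n <= 0"),
            (~np.isfinite(df["beta"]), "non-finite beta"),
        ]
        for mask, what in checks:
            if mask.any():
                vid = df.loc[mask, "variant_id"].iloc[0]
                raise DomainError(f"{vid}: {what}")

    # -- constructors -------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: list[VariantAssociation],
        trait_label: str = "",
        trait_type: str = "quantitative",
    ) -> "SummaryStatsTable":
        df = pd.DataFrame(
            {
                "variant_id": [r.variant_id for r in records],
                "chrom": [r.chrom for r in records],
                "pos": [r.pos for r in records],
                "effect_allele": [r.effect_allele for r in records],
                "other_allele": [r.other_allele for r in records],
                "eaf": [np.nan if r.eaf is None else r.eaf for r in records],
                "beta": [r.beta for r in records],
                "se": [r.se for r in records],
                "pval": [r.pval for r in records],
                "n": [np.nan if r.n is None else r.n for r in records],
            }
        )
        if not records:
            df = _empty_frame()
        return cls(df, trait_label=trait_label, trait_type=trait_type)

    # -- accessors ----------------------------------------------------

    @property
    def records(self) -> list[VariantAssociation]:
        out = []
        for row in self.df.itertuples(index=False):
            out.append(
                VariantAssociation(
                    variant_id=row.variant_id,
                    chrom=row.chrom,
                    pos=int(row.pos),
                    effect_allele=row.effect_allele,
                    other_allele=row.other_allele,
                    eaf=None if pd.isna(row.eaf) else float(row.eaf),
                    beta=float(row.beta),
                    se=float(row.se),
                    pval=float(row.pval),
                    n=None if pd.isna(row.n) else int(row.n),
                )
            )
        return out

    def subset(self, variant_ids) -> "SummaryStatsTable":
        """Rows whose variant_id is in ``variant_ids``, original order kept."""
        mask = self.df["variant_id"].isin(set(variant_ids))
        return SummaryStatsTable(
            self.df.loc[mask], trait_label=self.trait_label, trait_type=self.trait_type
        )

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SummaryStatsTable):
            return NotImplemented
        return (
            self.trait_label == other.trait_label
            and self.trait_type == other.trait_type
            and len(self) == len(other)
            and self.df.equals(other.df)
        )

    def __repr__(self) -> str:
        return (
            f"SummaryStatsTable({self.trait_label!r}, {self.trait_type}, "
            f"{len(self)} variants)"
        )


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": pd.Series(dtype=str),
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "effect_allele": pd.Series(dtype=str),
            "other_allele": pd.Series(dtype=str),
            "eaf": pd.Series(dtype=float),
            "beta": pd.Series(dtype=float),
            "se": pd.Series(dtype=float),
            "pval": pd.Series(dtype=float),
            "n": pd.Series(dtype=float),
        }
    )


def _parse_float(token: str, what: str) -> float | None:
    if token is None or token.strip() in _MISSING_TOKENS:
        return None
    try:
        return float(token)
    except ValueError:
        raise ValueError(f"unparseable {what}: {token!r}") from None


def read_summary_stats(
    path,
    dialect: dict | None = None,
    trait_label: str = "",
    trait_type: str = "quantitative",
    sep: str = "\t",
) -> SummaryStatsTable:
    """Read a delimited summary-statistics file.

    Rows violating the record invariants are rejected, not fatal: the
    returned table carries a per-row report in ``table.rejections`` with
    1-based line numbers.  A *missing column* or an empty file is fatal
    (:class:`FormatError`).

    Parameters
    ----------
    dialect
        Mapping from canonical field names (:data:`CANONICAL_FIELDS`) to
        the file's column names.  Defaults to :data:`DEFAULT_DIALECT`.
    """
    dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for canonical in CANONICAL_FIELDS:
        col = dialect[canonical]
        if col not in raw.columns:
            if canonical in ("eaf", "n"):
                raw[col] = "NA"  # optional columns may be absent entirely
            else:
                raise FormatError(f"missing required column {col!r} (for {canonical})")

    records: list[VariantAssociation] = []
    rejections: list[RowRejection] = []
    for i, row in enumerate(raw.itertuples(index=False)):
        line = i + 2  # header occupies line 1
        # itertuples mangles column names; index positionally instead
        vals = {canon: row[raw.columns.get_loc(dialect[canon])] for canon in CANONICAL_FIELDS}
        try:
            beta = _parse_float(vals["beta"], "beta")
            se = _parse_float(vals["se"], "se")
            pval = _parse_float(vals["pval"], "pval")
            if beta is None or se is None or pval is None:
                raise ValueError("beta, se and pval are required")
            pos_f = _parse_float(vals["pos"], "pos")
            if pos_f is None:
                raise ValueError("pos is required")
            eaf = _parse_float(vals["eaf"], "eaf")
            n_f = _parse_float(vals["n"], "n")
            rec = VariantAssociation(
                variant_id=str(vals["variant_id"]).strip(),
                chrom=str(vals["chrom"]).strip(),
                pos=int(pos_f),
                effect_allele=str(vals["effect_allele"]).strip().upper(),
                other_allele=str(vals["other_allele"]).strip().upper(),
                eaf=eaf,
                beta=beta,
                se=se,
                pval=pval,
                n=None if n_f is None else int(n_f),
            )
        except (ValueError, DomainError, InvalidVariantError) as exc:
            rejections.append(RowRejection(line=line, reason=str(exc)))
            continue
        records.append(rec)

    table = SummaryStatsTable.from_records(records, trait_label=trait_label, trait_type=trait_type)
    table.rejections = rejections
    return table


def write_summary_stats(table: SummaryStatsTable, path, sep: str = "\t") -> None:
    """Write a table as tab-separated text, rereadable by :func:`read_summary_stats`.

    Column order is fixed (the canonical order under default-dialect
    names); missing ``eaf``/``n`` become ``NA``.  Floats use Python's
    shortest round-trip representation so read∘write is the identity.
    """
    out = table.df.copy()
    out["n"] = out["n"].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out["eaf"] = out["eaf"].map(lambda v: "NA" if pd.isna(v) else repr(float(v)))
    for col in ("beta", "se", "pval"):
        out[col] = out[col].map(lambda v: repr(float(v)))
    out.columns = [DEFAULT_DIALECT[c] for c in CANONICAL_FIELDS]
    out.to_csv(path, sep=sep, index=False)
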