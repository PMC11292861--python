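"""Instrument selection: p-value screen, greedy LD clumping, F-statistic filter.

Instrumental variables for two-sample MR are chosen in three steps:

1. keep variants associated with the exposure at ``pval < p_threshold``
   (default 1e-5, the conventional relaxed threshold for traits with few
   genome-wide-significant hits);
2. greedily clump so no two retained variants on one chromosome within
   ``window_kb`` (default 10,000 kb, read as a ±10 Mb radius) have
   ``r² > r2_threshold`` (default 0.001), keeping the most significant
   variant per region;
3. drop weak instruments with ``F = beta²/se² < min_F`` (default 10).

Note that after a screen at p < 1e-5 the F filter cannot remove anything
(p < 1e-5 already implies F > 19.5); it matters for looser p thresholds.

LD comes from a user-supplied or simulated :class:`LDMatrix`; no reference
panel is consulted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .summary_stats import SummaryStatsTable


@dataclass
class LDMatrix:
    """Squared-correlation (r²) matrix over an ordered set of variants."""

    variant_ids: list
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.variant_ids = list(self.variant_ids)
        self.r2 = np.asarray(self.r2, dtype=float)
        m = len(self.variant_ids)
        if self.r2.shape != (m, m):
            raise ConfigurationError(f"r2 must be {m}x{m}, got {self.r2.shape}")
        if not np.allclose(self.r2, self.r2.T):
            raise ConfigurationError("r2 must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ConfigurationError("r2 diagonal must be 1")
        if (self.r2 < 0).any() or (self.r2 > 1).any():
            raise ConfigurationError("r2 entries must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    @classmethod
    def identity(cls, variant_ids) -> "LDMatrix":
        ids = list(variant_ids)
        return cls(ids, np.eye(len(ids)))

    def r2_between(self, a: str, b: str) -> float:
        try:
            return float(self.r2[self._index[a], self._index[b]])
        except KeyError as exc:
            raise ConfigurationError(f"variant {exc.args[0]!r} missing from LD matrix") from None

    def contains(self, variant_id: str) -> bool:
        return variant_id in self._index

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.r2, index=self.variant_ids, columns=self.variant_ids).to_csv(
            path, sep="\t", index_label="variant_id"
        )

    @classmethod
    def read_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float))


@dataclass
class InstrumentSet:
    """Selected instruments plus a provenance log of every exclusion.

    ``exclusions`` is a list of ``(variant_id, reason)`` with reason one of
    ``"threshold"``, ``"clump"``, ``"weak_f"``.
    """

    table: SummaryStatsTable
    p_threshold: float
    min_F: float
    exclusions: list = field(default_factory=list)

    @property
    def variant_ids(self) -> list:
        return list(self.table.df["variant_id"])

    def __len__(self) -> int:
        return len(self.table)


def f_statistic(beta, se):
    """Instrument-strength statistic ``F = beta² / se²`` (scalar or array)."""
    se = np.asarray(se, dtype=float)
    if (se <= 0).any():
        raise DomainError("se must be > 0")
    out = (np.asarray(beta, dtype=float) / se) ** 2
    return float(out) if out.ndim == 0 else out


def select_by_pvalue(table: SummaryStatsTable, p_threshold: float) -> SummaryStatsTable:
    """Rows with ``pval < p_threshold`` (strict), original order preserved."""
    if not (0 < p_threshold <= 1):
        raise DomainError(f"p_threshold must be in (0, 1], got {p_threshold}")
    mask = table.df["pval"] < p_threshold
    return SummaryStatsTable(
        table.df.loc[mask] if mask.any() else table.df.iloc[0:0],
        trait_label=table.trait_label,
        trait_type=table.trait_type,
    )


def _greedy_clump_ids(df: pd.DataFrame, ld: LDMatrix, r2_threshold: float, window_kb: int):
    """Greedy clumping on a canonical frame; returns (kept_ids, removed pairs).

    Index variants are claimed in order of (pval, pos, variant_id); each
    index discards unclaimed same-chromosome variants within ±window_kb
    whose r² with it exceeds the threshold.
    """
    for vid in df["variant_id"]:
        if not ld.contains(vid):
            raise ConfigurationError(f"variant {vid!r} missing from LD matrix")
    order = df.sort_values(
        ["pval", "pos", "variant_id"], kind="mergesort"
    ).reset_index(drop=True)
    window_bp = int(window_kb) * 1000
    unclaimed = dict.fromkeys(order["variant_id"])  # insertion-ordered set
    info = order.set_index("variant_id")[["chrom", "pos"]]
    kept, removed = [], []
    while unclaimed:
        index_id = next(iter(unclaimed))
        del unclaimed[index_id]
        kept.append(index_id)
        chrom, pos = info.loc[index_id, "chrom"], info.loc[index_id, "pos"]
        for other in list(unclaimed):
            if info.loc[other, "chrom"] != chrom:
                continue
            if abs(int(info.loc[other, "pos"]) - int(pos)) > window_bp:
                continue
            if ld.r2_between(index_id, other) > r2_threshold:
                del unclaimed[other]
                removed.append((other, index_id))
    return kept, removed


def clump(
    table: SummaryStatsTable,
    ld: LDMatrix,
    r2_threshold: float = 0.001,
    window_kb: int = 10000,
) -> SummaryStatsTable:
    """LD-clump a table; output contains index variants sorted by position."""
    if len(table) == 0:
        return table
    kept, _ = _greedy_clump_ids(table.df, ld, r2_threshold, window_kb)
    sub = table.df[table.df["variant_id"].isin(set(kept))]
    sub = sub.sort_values(["chrom", "pos", "variant_id"], kind="mergesort")
    return SummaryStatsTable(sub, trait_label=table.trait_label, trait_type=table.trait_type)


def build_instruments(
    table: SummaryStatsTable,
    ld: LDMatrix,
    p_threshold: float = 1e-5,
    r2_threshold: float = 0.001,
    window_kb: int = 10000,
    min_F: float = 10.0,
) -> InstrumentSet:
    """Full selection pipeline: p-value screen → clump → F filter.

    Every excluded variant is logged with the stage that removed it.
    """
    exclusions = []

    screened = select_by_pvalue(table, p_threshold)
    passed = set(screened.df["variant_id"])
    exclusions += [
        (vid, "threshold") for vid in table.df["variant_id"] if vid not in passed
    ]

    if len(screened) > 0:
        kept_ids, removed = _greedy_clump_ids(screened.df, ld, r2_threshold, window_kb)
        exclusions += [(vid, "clump") for vid, _index in removed]
        clumped = screened.df[screened.df["variant_id"].isin(set(kept_ids))]
        clumped = clumped.sort_values(["chrom", "pos", "variant_id"], kind="mergesort")
    else:
        clumped = screened.df

    if len(clumped) > 0:
        f = f_statistic(clumped["beta"].to_numpy(), clumped["se"].to_numpy())
        weak = np.asarray(f) < min_F
        exclusions += [(vid, "weak_f") for vid in clumped.loc[weak, "variant_id"]]
        final = clumped.loc[~weak]
    else:
        final = clumped

    return InstrumentSet(
        table=SummaryStatsTable(
            final if len(final) else table.df.iloc[0:0],
            trait_label=table.trait_label,
            trait_type=table.trait_type,
        ),
        p_threshold=p_threshold,
        min_F=min_F,
        exclusions=exclusions,
    )
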