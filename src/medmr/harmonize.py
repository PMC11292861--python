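"""Align exposure and outcome summary statistics to a shared effect-allele frame.

Two GWAS report the same variant on possibly different allele codings or
strands.  Before computing Wald ratios the outcome effects must be expressed
per copy of the *exposure's* effect allele:

* identical allele pair            -> keep as is
* swapped alleles                  -> negate beta_out, complement eaf_out
* strand-complemented (± swap)     -> complement, then as above
* anything else                    -> drop as unmatched

Palindromic variants (A/T or C/G) are strand-ambiguous: their complement
equals their own swap, so allele letters alone cannot resolve the strand.
They are handled by policy: ``drop_all`` removes every one, while
``drop_ambiguous`` (the default, with an EAF window of ±0.08 around 0.5)
keeps those whose allele frequency is informative enough to orient by EAF
agreement and drops the rest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyIntersectionError, InvalidVariantError
from .summary_stats import BASES, SummaryStatsTable

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: per-variant outcome of harmonization
ACTIONS = ("kept", "sign_flipped", "dropped_palindromic", "dropped_unmatched")


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is {A,T} or {C,G}."""
    if effect_allele not in BASES or other_allele not in BASES:
        raise InvalidVariantError(
            f"invalid alleles {effect_allele!r}/{other_allele!r}"
        )
    if effect_allele == other_allele:
        raise InvalidVariantError("identical alleles")
    return COMPLEMENT[effect_allele] == other_allele


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs on a shared effect-allele frame.

    ``df`` has one row per variant common to both inputs, with columns
    ``variant_id, chrom, pos, effect_allele, other_allele`` (the exposure
    frame), ``beta_exp, se_exp, pval_exp, eaf_exp, beta_out, se_out,
    eaf_out`` and ``action``.  Only ``kept`` / ``sign_flipped`` rows carry
    usable effect pairs; the rest retain their exposure-side values and the
    reason they were dropped.
    """

    exposure_label: str
    outcome_label: str
    df: pd.DataFrame

    @property
    def mr_frame(self) -> pd.DataFrame:
        """Rows usable for MR (action kept or sign_flipped)."""
        return self.df[self.df["action"].isin(("kept", "sign_flipped"))].reset_index(drop=True)

    @property
    def n_snp(self) -> int:
        return int(self.df["action"].isin(("kept", "sign_flipped")).sum())

    @property
    def action_counts(self) -> dict:
        counts = self.df["action"].value_counts().to_dict()
        return {a: int(counts.get(a, 0)) for a in ACTIONS}

    def to_tables(self) -> tuple[SummaryStatsTable, SummaryStatsTable]:
        """Re-emit the usable rows as a pair of already-aligned tables."""
        base = self.mr_frame
        common = base[["variant_id", "chrom", "pos", "effect_allele", "other_allele"]]
        exp = common.assign(
            eaf=base["eaf_exp"], beta=base["beta_exp"], se=base["se_exp"],
            pval=base["pval_exp"], n=np.nan,
        )
        out = common.assign(
            eaf=base["eaf_out"], beta=base["beta_out"], se=base["se_out"],
            pval=base["pval_out"], n=np.nan,
        )
        return (
            SummaryStatsTable(exp, trait_label=self.exposure_label),
            SummaryStatsTable(out, trait_label=self.outcome_label),
        )


def _orient_outcome(ea_e, oa_e, ea_o, oa_o):
    """Classify the outcome allele pair relative to the exposure frame.

    Returns 'same', 'swap' or None (unmatched).  Palindromic pairs are
    resolved elsewhere; here strand complementation is applied for
    non-palindromic pairs only.
    """
    if (ea_o, oa_o) == (ea_e, oa_e):
        return "same"
    if (ea_o, oa_o) == (oa_e, ea_e):
        return "swap"
    comp = (COMPLEMENT[ea_o], COMPLEMENT[oa_o])
    if comp == (ea_e, oa_e):
        return "same"
    if comp == (oa_e, ea_e):
        return "swap"
    return None


def harmonize(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    palindrome_policy: str = "drop_ambiguous",
    eaf_window: float = 0.08,
) -> HarmonizedSet:
    """Harmonize two tables onto the exposure's effect-allele frame.

    Parameters
    ----------
    palindrome_policy
        ``"drop_all"`` drops every palindromic variant; ``"drop_ambiguous"``
        drops palindromic variants whose EAF (either side) is missing or
        within ``eaf_window`` of 0.5 and orients the remainder by EAF
        agreement.

    Raises
    ------
    EmptyIntersectionError
        If the two tables share no variant.
    """
    if palindrome_policy not in ("drop_all", "drop_ambiguous"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")

    merged = exposure.df.merge(
        outcome.df, on="variant_id", suffixes=("_exp", "_out"), how="inner"
    )
    if merged.empty:
        raise EmptyIntersectionError(
            f"no shared variants between {exposure.trait_label!r} and {outcome.trait_label!r}"
        )

    rows = []
    for row in merged.itertuples(index=False):
        ea_e, oa_e = row.effect_allele_exp, row.other_allele_exp
        ea_o, oa_o = row.effect_allele_out, row.other_allele_out
        beta_out, eaf_out = row.beta_out, row.eaf_out
        action = None

        if is_palindromic(ea_e, oa_e):
            # outcome letters must be the same base set (complement == swap)
            rel = None
            if (ea_o, oa_o) == (ea_e, oa_e):
                rel = "same"
            elif (ea_o, oa_o) == (oa_e, ea_e):
                rel = "swap"
            if rel is None:
                action = "dropped_unmatched"
            elif palindrome_policy == "drop_all":
                action = "dropped_palindromic"
            else:
                ambiguous = (
                    pd.isna(row.eaf_exp)
                    or pd.isna(eaf_out)
                    or abs(row.eaf_exp - 0.5) <= eaf_window
                    or abs(eaf_out - 0.5) <= eaf_window
                )
                if ambiguous:
                    action = "dropped_palindromic"
                else:
                    flipped = False
                    if rel == "swap":
                        beta_out, eaf_out, flipped = -beta_out, 1.0 - eaf_out, True
                    # EAF disagreement after letter alignment implies the
                    # outcome GWAS reported the opposite strand: flip again.
                    if (row.eaf_exp < 0.5) != (eaf_out < 0.5):
                        beta_out, eaf_out, flipped = -beta_out, 1.0 - eaf_out, not flipped
                    action = "sign_flipped" if flipped else "kept"
        else:
            rel = _orient_outcome(ea_e, oa_e, ea_o, oa_o)
            if rel is None:
                action = "dropped_unmatched"
            elif rel == "swap":
                beta_out = -beta_out
                if not pd.isna(eaf_out):
                    eaf_out = 1.0 - eaf_out
                action = "sign_flipped"
            else:
                action = "kept"

        rows.append(
            {
                "variant_id": row.variant_id,
                "chrom": row.chrom_exp,
                "pos": row.pos_exp,
                "effect_allele": ea_e,
                "other_allele": oa_e,
                "beta_exp": row.beta_exp,
                "se_exp": row.se_exp,
                "pval_exp": row.pval_exp,
                "eaf_exp": row.eaf_exp,
                "beta_out": beta_out,
                "se_out": row.se_out,
                "pval_out": row.pval_out,
                "eaf_out": eaf_out,
                "action": action,
            }
        )

    return HarmonizedSet(
        exposure_label=exposure.trait_label,
        outcome_label=outcome.trait_label,
        df=pd.DataFrame(rows),
    )
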