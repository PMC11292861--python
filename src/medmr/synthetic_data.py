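"""Synthetic GWAS summary statistics with a known causal chain.

The generator emulates the statistical structure of the three-GWAS design
this package analyzes: a microbial-abundance exposure, a circulating
metabolite mediator and a binary disease outcome, each observed only as
per-variant summary statistics.  Effects follow the structural chain

    exposure  <- γ_j                         (exposure instruments)
    mediator  <- β2 · exposure + δm_k        (mediator's own instruments)
    outcome   <- direct · exposure + β3 · mediator + δo_l + α_j

so an exposure instrument's true outcome effect is
``(direct + β2·β3)·γ_j + α_j`` with ``α_j`` an optional pleiotropic path.
Observed betas add sampling noise with ``se = 1/sqrt(n)`` per trait — a
standardized-genotype convention in which the allele-frequency variance is
absorbed into the effect scale; for the binary outcome ``n`` should be the
*effective* case-control sample size ``4·ncase·nctrl/(ncase+nctrl)``.

True instrument effects are coded on the trait-increasing allele
(``γ_j >= 0``), which keeps "directional" pleiotropy well defined under
MR-Egger's orientation step.  p-values come from the two-sided normal.

Defaults reproduce the headline mediation scenario: β2 = 0.16,
β3 = −0.21, direct = −0.2664, hence total = −0.30 and a true proportion
mediated of 0.112, with the three source-study sample sizes (18,340
exposure; 8,299 mediator; ≈18,800 effective outcome).

Setting ``reverse_effect`` nonzero switches the mediator to a
*reverse-causal* regime — downstream of the outcome instead of the
exposure — used to exercise the reverse-MR gate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

from .instruments import LDMatrix
from .summary_stats import SummaryStatsTable

_BASE_PAIRS = [
    (a, b) for a in "ACGT" for b in "ACGT" if a != b
]  # includes palindromic pairs, as real data does

_TINY_P = 5e-324


class PleiotropyConfig(BaseModel):
    """Pleiotropic outcome effects of the exposure instruments.

    ``kind``: ``none`` | ``balanced`` (mean-zero) | ``directional``.
    ``fraction`` selects how many exposure instruments are invalid.
    """

    model_config = ConfigDict(frozen=True)

    kind: str = "none"
    mean: float = 0.0
    sd: float = 0.0
    fraction: float = Field(default=1.0, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self):
        if self.kind not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy kind {self.kind!r}")
        if self.kind == "balanced" and self.mean != 0.0:
            raise ValueError("balanced pleiotropy must have mean 0")
        return self


class SimulationConfig(BaseModel):
    """Generating parameters for one synthetic three-GWAS dataset."""

    model_config = ConfigDict(frozen=True)

    n_instruments: int = Field(default=15, ge=1)
    n_mediator_instruments: int = Field(default=15, ge=0)
    n_outcome_instruments: int = Field(default=0, ge=0)
    n_null_variants: int = Field(default=30, ge=0)
    instrument_effect_sd: float = Field(default=0.08, gt=0)
    mediator_instrument_effect_sd: float = Field(default=0.15, gt=0)
    outcome_instrument_effect_sd: float = Field(default=0.08, gt=0)
    n_exposure: int = Field(default=18340, ge=2)
    n_mediator: int = Field(default=8299, ge=2)
    n_outcome: int = Field(default=18800, ge=2)  # effective case-control n
    beta2_true: float = 0.16
    beta3_true: float = -0.21
    direct_effect_true: float = -0.2664
    pleiotropy: PleiotropyConfig = PleiotropyConfig()
    weak_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    reverse_effect: float = 0.0
    ld_blocks: tuple = ()  # ((block_size, within_block_r2), ...)
    seed: int  # mandatory

    @model_validator(mode="after")
    def _check_blocks(self):
        for blk in self.ld_blocks:
            size, r2 = blk
            if size < 2 or not (0 <= r2 <= 1):
                raise ValueError(f"invalid LD block {blk!r}")
        if len(self.ld_blocks) > self.n_instruments:
            raise ValueError("more LD blocks than instruments to tag them")
        return self

    @property
    def total_effect_true(self) -> float:
        """Total exposure→outcome effect: direct + β2·β3 (recorded, not free)."""
        return self.direct_effect_true + self.beta2_true * self.beta3_true

    @property
    def true_proportion(self) -> float:
        total = self.total_effect_true
        if total == 0:
            return float("nan")
        return self.beta2_true * self.beta3_true / total


@dataclass
class SimulationTruth:
    """Per-variant generating truth for recovery tests."""

    variant_ids: list
    exposure_effects: np.ndarray
    mediator_effects: np.ndarray
    outcome_effects: np.ndarray
    pleiotropy_offsets: np.ndarray
    weak: np.ndarray  # boolean, exposure instruments scaled to F ≈ 10
    block_id: np.ndarray  # -1 outside LD blocks
    role: list  # per-variant: exposure_iv / ld_companion / mediator_iv / outcome_iv / null
    true_total_effect: float
    true_proportion: float
    config: SimulationConfig


def _draw_effects(rng, n, scale):
    """Positive effect magnitudes, Uniform(0.5, 1.5)·scale."""
    return scale * rng.uniform(0.5, 1.5, size=n)


def _pvals(beta, se):
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, _TINY_P, 1.0)


def _table(rng, ids, chrom, pos, alleles, eaf, true_beta, se, n, label, trait_type,
           noise=None):
    noise = rng.standard_normal(len(ids)) if noise is None else noise
    beta = true_beta + noise * se
    df = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": [a for a, _ in alleles],
            "other_allele": [b for _, b in alleles],
            "eaf": eaf,
            "beta": beta,
            "se": np.full(len(ids), se),
            "pval": _pvals(beta, se),
            "n": float(n),
        }
    )
    return SummaryStatsTable(df, trait_label=label, trait_type=trait_type)


def simulate_mediation_gwas(config: SimulationConfig):
    """Generate (exposure, mediator, outcome) tables, LD matrix and truth.

    All randomness flows from one generator seeded with ``config.seed``;
    identical configs produce identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    se_exp = 1.0 / np.sqrt(config.n_exposure)
    se_med = 1.0 / np.sqrt(config.n_mediator)
    se_out = 1.0 / np.sqrt(config.n_outcome)

    # ---- layout: exposure IVs, LD companions, mediator IVs, outcome IVs, nulls
    n_exp_iv = config.n_instruments
    n_comp = sum(size - 1 for size, _ in config.ld_blocks)
    n_med_iv = config.n_mediator_instruments
    n_out_iv = config.n_outcome_instruments
    n_null = config.n_null_variants
    n_total = n_exp_iv + n_comp + n_med_iv + n_out_iv + n_null

    roles = (
        ["exposure_iv"] * n_exp_iv
        + ["ld_companion"] * n_comp
        + ["mediator_iv"] * n_med_iv
        + ["outcome_iv"] * n_out_iv
        + ["null"] * n_null
    )
    ids = [f"rs{i + 1:06d}" for i in range(n_total)]
    chrom = ["1"] * n_total
    # 1 Mb spacing keeps unlinked variants inside the clumping window so
    # independence is decided by r², not distance; companions sit by their tag
    pos = [1_000_000 * (i + 1) for i in range(n_total)]
    allele_idx = rng.integers(0, len(_BASE_PAIRS), size=n_total)
    alleles = [_BASE_PAIRS[i] for i in allele_idx]
    eaf = rng.uniform(0.05, 0.95, size=n_total)

    # ---- true per-variant effects on the three traits
    gamma = np.zeros(n_total)
    gamma[:n_exp_iv] = _draw_effects(rng, n_exp_iv, config.instrument_effect_sd)
    n_weak = int(round(config.weak_fraction * n_exp_iv))
    weak = np.zeros(n_total, dtype=bool)
    if n_weak:
        weak_idx = rng.choice(n_exp_iv, size=n_weak, replace=False)
        # target F ≈ 10 (slightly under, so observed F straddles the cutoff
        # from below more often than above)
        gamma[weak_idx] = 0.9 * np.sqrt(10.0) * se_exp
        weak[weak_idx] = True

    # LD companions inherit an attenuated tag effect (r = sqrt(r²)) and,
    # below, tag-correlated sampling noise
    block_id = np.full(n_total, -1)
    comp_tag = np.full(n_total, -1)
    offset = n_exp_iv
    for b, (size, r2) in enumerate(config.ld_blocks):
        tag = b  # tag the b-th exposure instrument
        block_id[tag] = b
        r = np.sqrt(r2)
        for k in range(size - 1):
            j = offset + k
            block_id[j] = b
            comp_tag[j] = tag
            gamma[j] = r * gamma[tag]
            pos[j] = pos[tag] + 1000 * (k + 1)
        offset += size - 1

    delta_m = np.zeros(n_total)
    sl = slice(n_exp_iv + n_comp, n_exp_iv + n_comp + n_med_iv)
    delta_m[sl] = _draw_effects(rng, n_med_iv, config.mediator_instrument_effect_sd)
    delta_o = np.zeros(n_total)
    sl = slice(n_exp_iv + n_comp + n_med_iv, n_exp_iv + n_comp + n_med_iv + n_out_iv)
    delta_o[sl] = _draw_effects(rng, n_out_iv, config.outcome_instrument_effect_sd)

    alpha = np.zeros(n_total)
    pl = config.pleiotropy
    if pl.kind != "none":
        n_invalid = int(round(pl.fraction * n_exp_iv))
        invalid = rng.choice(n_exp_iv, size=n_invalid, replace=False)
        alpha[invalid] = rng.normal(pl.mean, pl.sd, size=n_invalid)

    exposure_true = gamma
    if config.reverse_effect != 0.0:
        # reverse-causal regime: the mediator sits downstream of the outcome
        outcome_true = config.direct_effect_true * exposure_true + delta_o + alpha
        mediator_true = config.reverse_effect * outcome_true + delta_m
    else:
        mediator_true = config.beta2_true * exposure_true + delta_m
        outcome_true = (
            config.direct_effect_true * exposure_true
            + config.beta3_true * mediator_true
            + delta_o
            + alpha
        )

    # ---- sampling noise; companions get tag-correlated draws per trait
    def correlated_noise():
        z = rng.standard_normal(n_total)
        for j in np.where(comp_tag >= 0)[0]:
            r = np.sqrt(config.ld_blocks[block_id[j]][1])
            z[j] = r * z[comp_tag[j]] + np.sqrt(1 - r**2) * z[j]
        return z

    exposure = _table(rng, ids, chrom, pos, alleles, eaf, exposure_true, se_exp,
                      config.n_exposure, "exposure", "quantitative",
                      noise=correlated_noise())
    mediator = _table(rng, ids, chrom, pos, alleles, eaf, mediator_true, se_med,
                      config.n_mediator, "mediator", "quantitative",
                      noise=correlated_noise())
    outcome = _table(rng, ids, chrom, pos, alleles, eaf, outcome_true, se_out,
                     config.n_outcome, "outcome", "binary",
                     noise=correlated_noise())

    r2 = np.eye(n_total)
    for b, (_size, blk_r2) in enumerate(config.ld_blocks):
        members = np.where(block_id == b)[0]
        for i in members:
            for j in members:
                if i != j:
                    r2[i, j] = blk_r2
    ld = LDMatrix(ids, r2)

    truth = SimulationTruth(
        variant_ids=ids,
        exposure_effects=exposure_true,
        mediator_effects=mediator_true,
        outcome_effects=outcome_true,
        pleiotropy_offsets=alpha,
        weak=weak,
        block_id=block_id,
        role=roles,
        true_total_effect=config.total_effect_true,
        true_proportion=config.true_proportion,
        config=config,
    )
    return exposure, mediator, outcome, ld, truth


def simulate_null_battery(
    n_tests: int,
    template: SimulationConfig,
    n_true: int = 0,
    true_effect: float = 0.0,
):
    """A battery of exposures against one shared outcome.

    The first ``n_true`` exposures have causal effect ``true_effect`` on
    the outcome; the rest are null.  Each exposure has its own disjoint
    instrument set; the shared outcome table spans all variants.  Returns
    ``(exposure_tables, outcome_table, ld, true_effects)``.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if n_true > n_tests:
        raise ValueError("n_true cannot exceed n_tests")
    rng = np.random.default_rng(template.seed)
    se_exp = 1.0 / np.sqrt(template.n_exposure)
    se_out = 1.0 / np.sqrt(template.n_outcome)
    m = template.n_instruments

    tables = []
    out_frames = []
    all_ids = []
    effects = np.zeros(n_tests)
    effects[:n_true] = true_effect
    for t in range(n_tests):
        ids = [f"rs{t + 1:04d}{i + 1:04d}" for i in range(m)]
        all_ids += ids
        chrom = ["1"] * m
        pos = [1_000_000 * (t * m + i + 1) for i in range(m)]
        alleles = [_BASE_PAIRS[i] for i in rng.integers(0, len(_BASE_PAIRS), size=m)]
        eaf = rng.uniform(0.05, 0.95, size=m)
        gamma = _draw_effects(rng, m, template.instrument_effect_sd)
        tables.append(
            _table(rng, ids, chrom, pos, alleles, eaf, gamma, se_exp,
                   template.n_exposure, f"exposure_{t + 1}", "quantitative")
        )
        out_true = effects[t] * gamma
        out_beta = out_true + rng.standard_normal(m) * se_out
        out_frames.append(
            pd.DataFrame(
                {
                    "variant_id": ids,
                    "chrom": chrom,
                    "pos": pos,
                    "effect_allele": [a for a, _ in alleles],
                    "other_allele": [b for _, b in alleles],
                    "eaf": eaf,
                    "beta": out_beta,
                    "se": np.full(m, se_out),
                    "pval": _pvals(out_beta, se_out),
                    "n": float(template.n_outcome),
                }
            )
        )
    outcome = SummaryStatsTable(
        pd.concat(out_frames, ignore_index=True), trait_label="outcome", trait_type="binary"
    )
    return tables, outcome, LDMatrix.identity(all_ids), effects
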