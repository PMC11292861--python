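"""Benjamini–Hochberg FDR q-values and the joint significance rule.

The metabolite→outcome screen tests ~1400 hypotheses; discoveries are
declared when the raw p-value and the BH step-up q-value both clear their
thresholds (``p < 0.05`` and ``q < 0.2``, strict).  A Bonferroni helper is
included for smaller fixed families (e.g. 0.05/7 ≈ 0.00714).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .errors import ContractError, DomainError


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    ``q_(i) = min_{j >= i} m·p_(j)/j`` on the sorted p-values, mapped back
    to input order.  All p-values must lie in (0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise DomainError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def joint_significance(pvals, qvals, p_max: float = 0.05, q_max: float = 0.2) -> np.ndarray:
    """Flags tests with ``p < p_max`` AND ``q < q_max`` (both strict)."""
    p = np.asarray(pvals, dtype=float)
    q = np.asarray(qvals, dtype=float)
    if p.shape != q.shape:
        raise ContractError(f"length mismatch: {p.shape} vs {q.shape}")
    return (p < p_max) & (q < q_max)


def bonferroni(pvals, alpha: float = 0.05, m: int | None = None):
    """Bonferroni threshold and flags.

    Returns ``(threshold, flags)`` with ``threshold = alpha/m`` and strict
    comparison ``p < threshold``.  ``m`` defaults to the number of tests.
    """
    p = np.asarray(pvals, dtype=float)
    if m is None:
        m = p.size
    if m < 1:
        raise DomainError(f"m must be >= 1, got {m}")
    threshold = alpha / m
    return threshold, p < threshold


@dataclass
class TestBattery:
    """A family of tests with p-values, q-values and joint-rule flags."""

    labels: list
    pvals: np.ndarray
    qvals: np.ndarray
    significant: np.ndarray

    @classmethod
    def from_pvalues(cls, labels, pvals, p_max: float = 0.05, q_max: float = 0.2):
        labels = list(labels)
        p = np.asarray(pvals, dtype=float)
        if len(labels) != p.size:
            raise ContractError("labels and pvals differ in length")
        q = bh_fdr(p)
        return cls(labels=labels, pvals=p, qvals=q,
                   significant=joint_significance(p, q, p_max, q_max))
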