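"""Wald differential-expression calls, BH correction, practical-equivalence
(TOST) testing, and reverted/restored rescue classification.

The region of practical equivalence is a change of no more than 1.5-fold
in either direction, i.e. |l2fc| <= delta with delta = log2(1.5).  Under
the assumption that the observed l2fc is normal with the gene-wise
standard error, the two one-sided tests are

    p_lower = 1 - Phi((l2fc + delta) / SE)     (H0: mu <= -delta)
    p_upper =     Phi((l2fc - delta) / SE)     (H0: mu >= +delta)

and the equivalence p-value is their maximum; small values are evidence
that the true change lies inside the region.

Rescue classification of baseline differentially expressed genes (DEGs,
q < 0.1 by Wald/BH): *reverted* when the treatment contrast is
significant in the opposite direction, *restored* when the treatment
contrast is practically equivalent to no change (BH over the DEG set,
q < 0.05), otherwise *not_rescued*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import ValidationError

#: half-width of the region of practical equivalence on the log2 scale
DELTA_1_5_FOLD = float(np.log2(1.5))


@dataclass
class EquivalenceConfig:
    delta: float = DELTA_1_5_FOLD
    q_de: float = 0.1
    q_equiv: float = 0.05
    reverted_requires_significance: bool = True
    equiv_bh_within_degs: bool = True

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValidationError("delta must be positive")
        if not (0 < self.q_de < 1 and 0 < self.q_equiv < 1):
            raise ValidationError("q thresholds must be in (0, 1)")


def wald_p(l2fc, lfcSE):
    """Two-sided Wald p-value: p = 2 (1 - Phi(|l2fc / SE|))."""
    l2fc = np.asarray(l2fc, dtype=float)
    se = np.asarray(lfcSE, dtype=float)
    if np.any(se <= 0):
        raise ValidationError("lfcSE must be positive")
    return 2.0 * stats.norm.sf(np.abs(l2fc / se))


def bh_adjust(pvals):
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def equivalence_p(l2fc, lfcSE, delta: float = DELTA_1_5_FOLD):
    """TOST p-value against the null of a change larger than ``delta``.

    Returns max of the two one-sided normal tests; at l2fc = +/-delta the
    value is exactly 0.5.
    """
    l2fc = np.asarray(l2fc, dtype=float)
    se = np.asarray(lfcSE, dtype=float)
    if np.any(se <= 0):
        raise ValidationError("lfcSE must be positive")
    if delta <= 0:
        raise ValidationError("delta must be positive")
    p_lower = stats.norm.sf((l2fc + delta) / se)
    p_upper = stats.norm.cdf((l2fc - delta) / se)
    return np.maximum(p_lower, p_upper)


def annotate_de_table(df: pd.DataFrame, delta: float = DELTA_1_5_FOLD) -> pd.DataFrame:
    """Attach Wald p/q, equivalence p/q, and direction columns to a DE table."""
    out = df.copy()
    out["p_wald"] = wald_p(out["log2FoldChange"], out["lfcSE"])
    out["q_wald"] = bh_adjust(out["p_wald"])
    out["p_equiv"] = equivalence_p(out["log2FoldChange"], out["lfcSE"], delta)
    out["q_equiv"] = bh_adjust(out["p_equiv"])
    out["direction"] = np.sign(out["log2FoldChange"]).astype(int)
    return out


@dataclass
class RescueResult:
    """Per-baseline-DEG rescue labels and the rescued fraction.

    ``table`` has one row per baseline DEG with flags and the label in
    {reverted, restored, not_rescued}; a gene carrying both flags is
    labelled reverted (the stronger statement).
    """

    table: pd.DataFrame
    rescued_fraction: float
    n_degs: int


def classify_rescue(
    baseline: pd.DataFrame,
    treatment: pd.DataFrame,
    cfg: EquivalenceConfig | None = None,
) -> RescueResult:
    """Classify baseline DEGs as reverted / restored / not rescued under treatment.

    Baseline DEGs are genes with baseline Wald q < cfg.q_de.  Equivalence
    q-values are BH-adjusted within the baseline-DEG set (the population
    being classified) unless ``cfg.equiv_bh_within_degs`` is False.
    """
    cfg = cfg or EquivalenceConfig()
    base = baseline.set_index("gene_id")
    treat = treatment.set_index("gene_id")

    base_q = pd.Series(bh_adjust(wald_p(base["log2FoldChange"], base["lfcSE"])), index=base.index)
    degs = base.index[base_q < cfg.q_de]
    missing = [g for g in degs if g not in treat.index]
    if missing:
        raise ValidationError(f"baseline DEGs missing from treatment table: {missing[:10]}")

    t = treat.loc[degs]
    t_p_wald = wald_p(t["log2FoldChange"], t["lfcSE"])
    t_q_wald = pd.Series(
        bh_adjust(wald_p(treat["log2FoldChange"], treat["lfcSE"])), index=treat.index
    ).loc[degs]

    sign_base = np.sign(base.loc[degs, "log2FoldChange"].to_numpy())
    sign_treat = np.sign(t["log2FoldChange"].to_numpy())
    flipped = (sign_treat == -sign_base) & (sign_base != 0)
    if cfg.reverted_requires_significance:
        reverted = flipped & (t_q_wald.to_numpy() < cfg.q_de)
    else:
        reverted = flipped

    p_equiv = equivalence_p(t["log2FoldChange"], t["lfcSE"], cfg.delta)
    if cfg.equiv_bh_within_degs:
        q_equiv = bh_adjust(p_equiv)
    else:
        q_all = pd.Series(
            bh_adjust(equivalence_p(treat["log2FoldChange"], treat["lfcSE"], cfg.delta)),
            index=treat.index,
        )
        q_equiv = q_all.loc[degs].to_numpy()
    restored = q_equiv < cfg.q_equiv

    label = np.where(reverted, "reverted", np.where(restored, "restored", "not_rescued"))
    table = pd.DataFrame(
        {
            "gene_id": list(degs),
            "baseline_l2fc": base.loc[degs, "log2FoldChange"].to_numpy(),
            "baseline_q_wald": base_q.loc[degs].to_numpy(),
            "treatment_l2fc": t["log2FoldChange"].to_numpy(),
            "treatment_q_wald": t_q_wald.to_numpy(),
            "p_equiv": p_equiv,
            "q_equiv": q_equiv,
            "reverted_flag": reverted,
            "restored_flag": restored,
            "label": label,
        }
    )
    n_degs = len(degs)
    rescued = int((reverted | restored).sum())
    fraction = rescued / n_degs if n_degs else 0.0
    return RescueResult(table=table, rescued_fraction=fraction, n_degs=n_degs)
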