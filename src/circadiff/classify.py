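"""Categorizing biomarkers into types of rhythmicity (TOR).

Each biomarker is assigned one of four categories from its per-group
rhythmicity p-values: rhythmic only in the reference group (RhyI), only in
the comparison group (RhyII), in both (RhyBoth), or in neither (Arrhy).

The default procedure is a selective sequential model selection: a two-stage
test whose stage-1 statistic asks "is there rhythm in at least one group?"
and whose stage-2 statistic, evaluated only among stage-1 discoveries, asks
"is there rhythm in the second group as well?".  Because the two groups are
independent samples, stage 1 uses the Sidak-combined minimum
``p1 = 1 - (1 - min(pI, pII))^2`` (exactly uniform when both groups are
arrhythmic) and stage 2 uses ``p2 = max(pI, pII)``, which under the stage-2
null (exactly one group rhythmic) behaves like the arrhythmic group's
uniform p-value.  This directly bounds both misclassification events of
interest: calling an arrhythmic biomarker rhythmic, and calling a
one-group-rhythmic biomarker RhyBoth.

Conventional comparator procedures (per-group Venn thresholding, AIC/BIC
model selection over the four joint two-group models) are provided for
benchmarking; they do not control the stage-wise error rates.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cosinor import fit_cosinor, gaussian_loglik

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "bh_adjust",
    "ssms_classify",
    "comparator_classify",
    "joint_model_fits",
]

CATEGORIES = ("RhyI", "RhyII", "RhyBoth", "Arrhy")

TOR_SCHEMA = [
    "gene",
    "p_I",
    "p_II",
    "p_stage1",
    "p_stage2",
    "q_stage1",
    "q_stage2",
    "category",
]


def _check_p(p, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError(f"{name} must contain finite values in [0, 1]")
    return p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} (p_(j) * m / j)`` capped at 1, returned in the
    input order.
    """
    p = _check_p(p, "p")
    return multipletests(p, method="fdr_bh")[1]


def ssms_classify(
    p_I,
    p_II,
    level: float = 0.05,
    adjust: str = "bh",
    gene_ids=None,
) -> pd.DataFrame:
    """Assign TOR categories by sequential two-stage selection.

    Parameters
    ----------
    p_I, p_II : array-like
        Per-gene rhythmicity p-values in the reference / comparison group.
    level : float
        Stage-wise error level (raw alpha, or FDR level when ``adjust="bh"``).
    adjust : {"bh", "none"}
        ``"bh"`` applies Benjamini-Hochberg across all genes at stage 1 and
        within the stage-1 discoveries at stage 2; ``"none"`` thresholds the
        raw stage p-values (used by the simulation studies).
    gene_ids : sequence, optional
        Labels for the output table; defaults to ``g0..g{m-1}``.

    Returns
    -------
    DataFrame
        Columns ``gene, p_I, p_II, p_stage1, p_stage2, q_stage1, q_stage2,
        category``; stage-2 entries are NaN for Arrhy genes (stage 2 is
        never evaluated when stage 1 does not reject).
    """
    p_I = _check_p(p_I, "p_I")
    p_II = _check_p(p_II, "p_II")
    if p_I.size != p_II.size:
        raise ValueError(f"p_I and p_II differ in length ({p_I.size} vs {p_II.size})")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if adjust not in {"bh", "none"}:
        raise ValueError(f"adjust must be 'bh' or 'none', got {adjust!r}")
    m = p_I.size
    genes = [f"g{i}" for i in range(m)] if gene_ids is None else [str(g) for g in gene_ids]
    if len(genes) != m:
        raise ValueError("gene_ids length does not match p-value vectors")

    pmin = np.minimum(p_I, p_II)
    p_stage1 = 1.0 - (1.0 - pmin) ** 2
    q_stage1 = bh_adjust(p_stage1) if adjust == "bh" else p_stage1.copy()
    stage1_reject = q_stage1 <= level if adjust == "bh" else p_stage1 <= level

    p_stage2 = np.full(m, np.nan)
    q_stage2 = np.full(m, np.nan)
    category = np.full(m, "Arrhy", dtype=object)

    sel = np.where(stage1_reject)[0]
    if sel.size:
        p2 = np.maximum(p_I[sel], p_II[sel])
        p_stage2[sel] = p2
        q2 = bh_adjust(p2) if adjust == "bh" else p2
        q_stage2[sel] = q2
        both = q2 <= level
        category[sel[both]] = "RhyBoth"
        single = sel[~both]
        ties = p_I[single] == p_II[single]
        if ties.any():
            logger.info(
                "%d stage-2 tie(s) p_I == p_II assigned RhyI (reference-first)",
                int(ties.sum()),
            )
        category[single] = np.where(p_I[single] <= p_II[single], "RhyI", "RhyII")

    return pd.DataFrame(
        {
            "gene": genes,
            "p_I": p_I,
            "p_II": p_II,
            "p_stage1": p_stage1,
            "p_stage2": p_stage2,
            "q_stage1": q_stage1,
            "q_stage2": q_stage2,
            "category": category,
        },
        columns=TOR_SCHEMA,
    )


def joint_model_fits(y_I, t_I, y_II, t_II, period: float = 24.0) -> dict:
    """Gaussian fits of the four joint two-group models for one biomarker.

    Models: rhythm in neither group, in group I only, in group II only, and
    in both.  Each group keeps its own residual variance; an arrhythmic
    group is fit intercept-only.  Returns ``{model: (loglik, k, n_total)}``
    with ``k`` counting all mean and variance parameters.
    """
    out = {}
    lls = {}
    for lab, (y, t) in {"I": (y_I, t_I), "II": (y_II, t_II)}.items():
        y = np.asarray(y, dtype=float)
        n = y.size
        fit = fit_cosinor(y, t, period)
        tss = float(np.sum((y - y.mean()) ** 2))
        lls[lab] = {
            "rhythmic": (fit.loglik, 4),  # a, b, M, sigma
            "flat": (gaussian_loglik(tss, n), 2),  # M, sigma
            "n": n,
        }
    n_total = lls["I"]["n"] + lls["II"]["n"]
    for model, (m_I, m_II) in {
        "none": ("flat", "flat"),
        "I": ("rhythmic", "flat"),
        "II": ("flat", "rhythmic"),
        "both": ("rhythmic", "rhythmic"),
    }.items():
        ll = lls["I"][m_I][0] + lls["II"][m_II][0]
        k = lls["I"][m_I][1] + lls["II"][m_II][1]
        out[model] = (ll, k, n_total)
    return out


_MODEL_TO_CATEGORY = {"none": "Arrhy", "I": "RhyI", "II": "RhyII", "both": "RhyBoth"}


def comparator_classify(
    p_I=None,
    p_II=None,
    fits_joint=None,
    method: str = "venn",
    level: float = 0.05,
    gene_ids=None,
) -> pd.DataFrame:
    """Comparator TOR procedures: Venn thresholding and AIC/BIC selection.

    Parameters
    ----------
    p_I, p_II : array-like, required for ``method="venn"``
        Per-group rhythmicity p-values, each thresholded at ``level``
        independently and intersected.
    fits_joint : sequence of dicts, required for ``method in {"aic", "bic"}``
        Per-gene output of :func:`joint_model_fits`.
    method : {"venn", "aic", "bic"}

    Returns
    -------
    DataFrame with columns ``gene, category`` (plus ``p_I, p_II`` for venn
    and the per-model criterion values for aic/bic).
    """
    if method == "venn":
        p_I = _check_p(p_I, "p_I")
        p_II = _check_p(p_II, "p_II")
        if p_I.size != p_II.size:
            raise ValueError("p_I and p_II differ in length")
        m = p_I.size
        genes = [f"g{i}" for i in range(m)] if gene_ids is None else list(gene_ids)
        rhy_I = p_I <= level
        rhy_II = p_II <= level
        category = np.select(
            [rhy_I & rhy_II, rhy_I, rhy_II],
            ["RhyBoth", "RhyI", "RhyII"],
            default="Arrhy",
        )
        return pd.DataFrame(
            {"gene": genes, "p_I": p_I, "p_II": p_II, "category": category}
        )
    if method in {"aic", "bic"}:
        if fits_joint is None:
            raise ValueError(f"method {method!r} requires fits_joint")
        rows = []
        genes = (
            [f"g{i}" for i in range(len(fits_joint))]
            if gene_ids is None
            else list(gene_ids)
        )
        for gene, fits in zip(genes, fits_joint):
            crit = {}
            for model, (ll, k, n_total) in fits.items():
                if method == "aic":
                    crit[model] = 2.0 * k - 2.0 * ll
                else:
                    crit[model] = k * math.log(n_total) - 2.0 * ll
            best = min(crit, key=crit.get)
            row = {"gene": gene, "category": _MODEL_TO_CATEGORY[best]}
            row.update({f"{method}_{mdl}": v for mdl, v in crit.items()})
            rows.append(row)
        return pd.DataFrame(rows)
    raise ValueError(f"unknown comparator method {method!r}; use venn, aic or bic")
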