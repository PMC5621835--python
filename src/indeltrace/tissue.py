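"""Tissue presence, 16-fold enrichment calls, Fisher tests and r² heatmap.

Tissue-enriched samples (nerve, vessel, bone/cartilage, skin, muscle,
blood) plus the whole hand are dissected from a regenerated limb.  An
allele is *tissue-enriched* when its normalized abundance in one tissue
exceeds ``fold`` (default 16×) that in every other tissue; abundances carry
a +1 guard, consistent with the log10(RPM+1) convention used elsewhere.
Fisher's exact test (two-tailed, by exact hypergeometric enumeration) asks
whether enriched alleles are disproportionately represented among alleles
that changed frequency across a regeneration.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .amplicon_io import TISSUE_COMPARTMENTS
from .calling import INTACT
from .quantify import log_rpm

ENRICHMENT_FOLD = 16.0
PANEL_LABELS = TISSUE_COMPARTMENTS + ("quaternary_hand",)

TissuePanel = Mapping[str, Mapping[str, float]]   # tissue label -> rpm vector


def panel_alleles(panel: TissuePanel, tissues: Sequence[str] = TISSUE_COMPARTMENTS,
                  ) -> list[str]:
    """Alleles detected (rpm > 0 post-filter) in at least one tissue."""
    present: set[str] = set()
    for t in tissues:
        present.update(a for a, v in panel.get(t, {}).items()
                       if a != INTACT and v > 0)
    return sorted(present)


def tissue_presence(panel: TissuePanel, allele: str,
                    tissues: Sequence[str] = TISSUE_COMPARTMENTS) -> int:
    """Number of the six tissue samples in which the allele is detected."""
    return sum(1 for t in tissues if panel.get(t, {}).get(allele, 0.0) > 0)


def call_enriched(panel: TissuePanel, allele: str, fold: float = ENRICHMENT_FOLD,
                  tissues: Sequence[str] = TISSUE_COMPARTMENTS) -> set[str]:
    """Tissues (0, 1 or 2) in which the allele is ≥fold-enriched.

    Single-tissue enrichment: its guarded abundance exceeds ``fold`` times
    the maximum of the other five.  Double-tissue enrichment: the top two
    tissues each exceed ``fold`` times the maximum of the remaining four,
    without qualifying singly.
    """
    guarded = sorted(((panel.get(t, {}).get(allele, 0.0) + 1.0, t) for t in tissues),
                     reverse=True)
    (v1, t1), (v2, t2), (v3, _t3) = guarded[0], guarded[1], guarded[2]
    if v1 > fold * v2:
        return {t1}
    if v2 > fold * v3:
        return {t1, t2}
    return set()


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-tailed Fisher exact p for a 2×2 table, by exact enumeration.

    Sums hypergeometric point probabilities of all tables with the observed
    margins whose probability does not exceed that of the observed table.
    Computed in exact integer arithmetic, so ties are handled without a
    floating-point fudge factor.
    """
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2 = a + b, c + d
    c1 = a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {x: comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)}
    observed = weights[a]
    numer = sum(w for w in weights.values() if w <= observed)
    denom = sum(weights.values())
    return numer / denom


def tissue_r2_heatmap(panels: Sequence[TissuePanel],
                      labels: Sequence[str] = PANEL_LABELS) -> pd.DataFrame:
    """Pairwise r² of log10(RPM+1) across tissue samples, pooled over animals.

    For each pair of sample types, per-animal allele pairs over the union of
    that animal's detected alleles are pooled; pairs where both logs are
    zero are excluded, consistent with the pooled regressions.
    """
    if not panels:
        raise ValueError("need at least one tissue panel")
    mat = np.full((len(labels), len(labels)), np.nan)
    for i, li in enumerate(labels):
        mat[i, i] = 1.0
        for j in range(i + 1, len(labels)):
            lj = labels[j]
            xs: list[float] = []
            ys: list[float] = []
            for panel in panels:
                if li not in panel or lj not in panel:
                    continue
                union = sorted({a for a in panel[li] if a != INTACT}
                               | {a for a in panel[lj] if a != INTACT})
                for allele in union:
                    xs.append(log_rpm(panel[li].get(allele, 0.0)))
                    ys.append(log_rpm(panel[lj].get(allele, 0.0)))
            x = np.asarray(xs)
            y = np.asarray(ys)
            mask = ~((x == 0) & (y == 0))
            x, y = x[mask], y[mask]
            if x.size >= 3 and np.std(x) > 0 and np.std(y) > 0:
                r = stats.pearsonr(x, y).statistic
                mat[i, j] = mat[j, i] = r ** 2
    return pd.DataFrame(mat, index=list(labels), columns=list(labels))


def enrichment_change_association(enriched: Mapping[str, set[str]],
                                  categories: Mapping[str, str],
                                  category: str,
                                  tissues: Sequence[str] = TISSUE_COMPARTMENTS,
                                  ) -> pd.DataFrame:
    """Per-tissue Fisher test: enriched-in-tissue × in-fold-change-category.

    The universe is the tissue-enriched alleles (those with a non-empty
    enrichment call).  For each tissue, a 2×2 table of (enriched in that
    tissue vs enriched elsewhere) × (in the category vs not) is tested
    two-tailed; no multiple-testing correction, matching a single-tissue
    hypothesis per test.
    """
    universe = [a for a, t in enriched.items() if t]
    rows = []
    for tissue in tissues:
        in_t = [a for a in universe if tissue in enriched[a]]
        out_t = [a for a in universe if tissue not in enriched[a]]
        a_ = sum(1 for x in in_t if categories.get(x) == category)
        b_ = len(in_t) - a_
        c_ = sum(1 for x in out_t if categories.get(x) == category)
        d_ = len(out_t) - c_
        p = 1.0 if not universe else fisher_exact_2x2([[a_, b_], [c_, d_]])
        rows.append({"tissue": tissue, "category": category,
                     "enriched_in_category": a_, "enriched_not_category": b_,
                     "other_in_category": c_, "other_not_category": d_,
                     "pvalue": p})
    return pd.DataFrame(rows)
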