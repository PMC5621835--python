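"""Regeneration-fidelity statistics.

The central statistic is the *percent change in allelic identity* between
two samples: half the summed absolute RPM differences over the union of
allele classes (INTACT included), expressed as percent of total reads.
Since RPM compositions total one million, this is the total-variation
distance between the two clonal compositions, scaled to [0, 100].

Supporting statistics: pooled log10(RPM+1) regressions between limb stages,
frequency bins (low < 1.6%, high > 6.5% of reads), per-allele fold-change
categories, lost/recovered allele accounting across successive limbs, and
cross-animal allele sharing.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calling import INTACT
from .quantify import RPM_SCALE, log_rpm

LOW_RPM = 16_000     # < 1.6% of reads
HIGH_RPM = 65_000    # > 6.5% of reads

CATEGORY_LOST = "lost"
CATEGORY_DECREASED = "decreased"    # more than a one-fold (factor-2) decrease
CATEGORY_RETAINED = "retained"      # less than a one-fold decrease
CATEGORY_INCREASED = "increased"
CATEGORY_NEW = "new"                # absent before, present after

_NORMALIZATION_RTOL = 1e-3


def _check_normalized(vec: Mapping[str, float], label: str) -> None:
    total = sum(vec.values())
    if abs(total - RPM_SCALE) > _NORMALIZATION_RTOL * RPM_SCALE:
        raise ValueError(
            f"{label} vector total {total:.1f} differs from {RPM_SCALE} by >0.1%; "
            "identity change requires RPM-normalized compositions")


def identity_change(rpm_a: Mapping[str, float], rpm_b: Mapping[str, float],
                    include_intact: bool = True) -> float:
    """Percent change in allelic identity between two RPM compositions.

    ``sum_classes |rpm_a - rpm_b| / 2 / 1e6 * 100`` over the union of
    classes (missing classes count as 0).  Both inputs must total one
    million within 0.1%.  With ``include_intact=False`` the INTACT class is
    left out of the sum (no renormalization).
    """
    _check_normalized(rpm_a, "first")
    _check_normalized(rpm_b, "second")
    classes = set(rpm_a) | set(rpm_b)
    if not include_intact:
        classes.discard(INTACT)
    diff = sum(abs(rpm_a.get(c, 0.0) - rpm_b.get(c, 0.0)) for c in classes)
    return diff / 2.0 / RPM_SCALE * 100.0


@dataclass(frozen=True)
class RegressionResult:
    r2: float
    slope: float
    intercept: float
    pvalue: float
    n: int


def pooled_regression(log_before: Sequence[float], log_after: Sequence[float],
                      ) -> RegressionResult:
    """OLS of after on before over log10(RPM+1) pairs.

    Points where both log scores are zero (allele absent from both samples)
    are excluded before fitting; r² is the squared Pearson correlation and
    the p-value is the standard slope test.
    """
    x = np.asarray(log_before, dtype=float)
    y = np.asarray(log_after, dtype=float)
    if x.shape != y.shape:
        raise ValueError("before/after log-score arrays differ in length")
    mask = ~((x == 0) & (y == 0))
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError(f"need at least 3 retained points, got {x.size}")
    fit = stats.linregress(x, y)
    return RegressionResult(r2=fit.rvalue ** 2, slope=fit.slope,
                            intercept=fit.intercept, pvalue=fit.pvalue, n=int(x.size))


def regression_pairs(rpm_before: Mapping[str, float], rpm_after: Mapping[str, float],
                     include_intact: bool = False,
                     ) -> tuple[list[float], list[float], list[str]]:
    """Aligned log10(RPM+1) pairs over the union of allele classes."""
    classes = sorted(set(rpm_before) | set(rpm_after))
    if not include_intact:
        classes = [c for c in classes if c != INTACT]
    xb = [log_rpm(rpm_before.get(c, 0.0)) for c in classes]
    xa = [log_rpm(rpm_after.get(c, 0.0)) for c in classes]
    return xb, xa, classes


def frequency_bin(rpm: float) -> str:
    """'low' (<16,000 RPM), 'high' (>65,000 RPM) or 'mid'."""
    if not 0 <= rpm <= RPM_SCALE:
        raise ValueError("rpm must lie in [0, 1e6]")
    if rpm < LOW_RPM:
        return "low"
    if rpm > HIGH_RPM:
        return "high"
    return "mid"


def fold_change_profile(rpm_before: Mapping[str, float],
                        rpm_after: Mapping[str, float],
                        include_intact: bool = False) -> pd.DataFrame:
    """Per-allele fold changes between two samples.

    ``log10_fold_change = log10((after+1)/(before+1))``.  Categories over
    alleles present before: lost (after = 0), decreased (after ≤ before/2,
    i.e. more than a one-fold decrease), retained (before/2 < after ≤
    before), increased (after > before).  Alleles absent before are 'new'.
    """
    rows = []
    classes = sorted(set(rpm_before) | set(rpm_after))
    for c in classes:
        if c == INTACT and not include_intact:
            continue
        before = rpm_before.get(c, 0.0)
        after = rpm_after.get(c, 0.0)
        if before == 0 and after == 0:
            continue
        if before == 0:
            category = CATEGORY_NEW
        elif after == 0:
            category = CATEGORY_LOST
        elif after <= before / 2.0:
            category = CATEGORY_DECREASED
        elif after <= before:
            category = CATEGORY_RETAINED
        else:
            category = CATEGORY_INCREASED
        rows.append({"allele_name": c, "rpm_before": before, "rpm_after": after,
                     "log10_fold_change": float(np.log10((after + 1.0) / (before + 1.0))),
                     "frequency_bin": frequency_bin(before) if before > 0 else "low",
                     "category": category})
    return pd.DataFrame(rows, columns=["allele_name", "rpm_before", "rpm_after",
                                       "log10_fold_change", "frequency_bin",
                                       "category"])


def lost_recovered_accounting(compartments: Mapping[str, Mapping[str, float]],
                              limb_order: Sequence[str] = ("primary", "secondary",
                                                           "tertiary",
                                                           "quaternary_hand"),
                              ) -> pd.DataFrame:
    """Track alleles that vanish between successive limbs of one animal.

    For each consecutive limb pair, an allele present in the earlier limb
    but absent from the later one is recorded as lost at that transition; it
    counts as *recovered* if it reappears in any compartment after the limb
    where it went missing (later limbs or the dissected tissue panel).
    """
    limbs = [c for c in limb_order if c in compartments]
    if len(limbs) < 2:
        raise ValueError("need at least two limb compartments")
    extra = [c for c in compartments if c not in limb_order]
    rows = []
    for i in range(len(limbs) - 1):
        before, after = limbs[i], limbs[i + 1]
        later = limbs[i + 2:] + extra
        for allele, rpm in compartments[before].items():
            if allele == INTACT or rpm <= 0:
                continue
            if compartments[after].get(allele, 0.0) > 0:
                continue
            recovered_in = [c for c in later
                            if compartments[c].get(allele, 0.0) > 0]
            rows.append({"allele_name": allele, "lost_after": f"{before}->{after}",
                         "rpm_at_loss": rpm, "recovered": bool(recovered_in),
                         "recovered_in": ",".join(recovered_in)})
    return pd.DataFrame(rows, columns=["allele_name", "lost_after", "rpm_at_loss",
                                       "recovered", "recovered_in"])


def unrecovered_fraction(accounting: pd.DataFrame, transition: str) -> float:
    """Summed RPM of unrecovered alleles at a transition, as a fraction of
    the source limb's million reads."""
    df = accounting[(accounting["lost_after"] == transition)
                    & (~accounting["recovered"])]
    return float(df["rpm_at_loss"].sum()) / RPM_SCALE


def allele_sharing(per_animal_presence: Mapping[str, Iterable[str]],
                   ) -> pd.Series:
    """Number of animals carrying each allele (one target's master list)."""
    if len(per_animal_presence) < 2:
        raise ValueError("allele sharing needs at least two animals")
    counts: dict[str, int] = {}
    for _animal, alleles in per_animal_presence.items():
        for a in set(alleles):
            if a == INTACT:
                continue
            counts[a] = counts.get(a, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()
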