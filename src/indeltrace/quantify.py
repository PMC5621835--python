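"""Control-based allele filtering and reads-per-million normalization.

Before normalization, an allele row from a mutant sample is kept only if its
raw read count is (i) at least ``control_fold`` (default 2×) the raw count
of the same allele in the corresponding non-mutant control — amplified and
sequenced alongside the mutants to set allele-specific background — and
(ii) at least ``min_reads`` (default 4).  The INTACT class is never
filtered.  Surviving counts are scaled to reads per million of the sample's
total assigned reads (INTACT + surviving alleles).
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .calling import INTACT

MIN_READS = 4
CONTROL_FOLD = 2.0
RPM_SCALE = 1_000_000


class ControlError(ValueError):
    """Raised when a mutant sample's non-mutant control cannot be resolved."""


def control_map_from_sheet(samples, target_name: str | None = None) -> dict[str, str]:
    """Map every mutant sample to its pool's non-mutant control sample."""
    controls = [s.sample_id for s in samples if s.role == "non_mutant_control"]
    if len(controls) != 1:
        raise ControlError(
            f"expected exactly one non-mutant control in pool"
            + (f" for target {target_name!r}" if target_name else "")
            + f", found {len(controls)}")
    return {s.sample_id: controls[0] for s in samples if s.role == "mutant"}


def filter_alleles(table: pd.DataFrame, control_map: Mapping[str, str],
                   min_reads: int = MIN_READS, control_fold: float = CONTROL_FOLD,
                   strict_fold: bool = False,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the control-background and minimum-read filters.

    An allele row is kept iff ``raw >= control_fold * control`` (ties kept;
    ``strict_fold`` switches to a strict inequality) and ``raw >= min_reads``.
    Returns (kept table, audit table with a kept/excluded_reason column).
    Control samples themselves pass through unfiltered (their counts define
    the background); INTACT rows are never filtered.
    """
    required = {"target", "sample", "allele_name", "raw_count"}
    if not required <= set(table.columns):
        raise ValueError(f"count table missing columns {sorted(required - set(table.columns))}")
    control_lookup: dict[tuple[str, str, str], int] = {}
    control_ids = set(control_map.values())
    for _, row in table[table["sample"].isin(control_ids)].iterrows():
        control_lookup[(row["target"], row["sample"], row["allele_name"])] = int(row["raw_count"])
    missing = {c for c in control_ids if c not in set(table["sample"])}
    for tgt in table["target"].unique():
        samples_here = set(table.loc[table["target"] == tgt, "sample"])
        for s in samples_here:
            c = control_map.get(s)
            if c is not None and c in missing:
                raise ControlError(f"control sample {c!r} missing for target {tgt!r}")

    audit_rows = []
    for _, row in table.iterrows():
        tgt, sample, allele = row["target"], row["sample"], row["allele_name"]
        raw = int(row["raw_count"])
        kept, reason, control_count = True, "", np.nan
        if allele != INTACT and sample in control_map:
            control_count = control_lookup.get((tgt, control_map[sample], allele), 0)
            below_fold = (raw <= control_fold * control_count if strict_fold
                          else raw < control_fold * control_count)
            if below_fold:
                kept, reason = False, "below_control_fold"
            elif raw < min_reads:
                kept, reason = False, "fewer_than_min_reads"
        audit_rows.append({"target": tgt, "sample": sample, "allele_name": allele,
                           "raw_count": raw, "control_count": control_count,
                           "kept": kept, "excluded_reason": reason})
    audit = pd.DataFrame(audit_rows)
    kept = table.loc[audit["kept"].to_numpy()].reset_index(drop=True)
    return kept, audit


def normalize_rpm(table: pd.DataFrame) -> pd.DataFrame:
    """Scale filtered counts to reads per million of assigned reads.

    ``rpm = raw / total * 1e6`` with the total taken per (target, sample)
    over INTACT plus surviving alleles.  Zero-total samples are dropped with
    a warning.
    """
    df = table.copy()
    totals = df.groupby(["target", "sample"])["raw_count"].transform("sum")
    zero = totals == 0
    if zero.any():
        dropped = sorted(df.loc[zero, "sample"].unique())
        warnings.warn(f"dropping zero-total samples: {dropped}", stacklevel=2)
        df, totals = df.loc[~zero], totals.loc[~zero]
    df = df.assign(rpm=df["raw_count"] / totals * RPM_SCALE)
    return df.reset_index(drop=True)


def log_rpm(rpm):
    """log10(RPM + 1); accepts scalars or arrays, rejects negatives."""
    arr = np.asarray(rpm, dtype=float)
    if np.any(arr < 0):
        raise ValueError("rpm must be non-negative")
    out = np.log10(arr + 1.0)
    return float(out) if np.isscalar(rpm) or arr.ndim == 0 else out


def rpm_vector(rpm_table: pd.DataFrame, sample: str,
               target: str | None = None) -> dict[str, float]:
    """One sample's RPM composition as an allele-name-keyed dict."""
    df = rpm_table[rpm_table["sample"] == sample]
    if target is not None:
        df = df[df["target"] == target]
    return dict(zip(df["allele_name"], df["rpm"]))
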