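"""Replicate aggregation, potency cutoffs, and activity-percentile filters.

The filters shrink a bioactivity table monotonically and run in the
pipeline order: replicate aggregation (median) → potency ceiling (≤ cutoff)
→ target-specific percentile filter → global percentile filter.  All
distributional work is done on log10(value_nM); "within the threshold"
is inclusive (≤), matching the inclusive ≤1000 nM potency convention.
"""

from __future__ import annotations

import numpy as np

from .core_io import BioactivityTable, ValidationError, logger


def aggregate_replicates(table: BioactivityTable) -> BioactivityTable:
    """Collapse replicate (compound, target, assay_type) entries to their median."""
    df = (table.df
          .groupby(["compound_id", "target_id", "assay_type"], as_index=False)
          ["value_nM"].median())
    return BioactivityTable(df, validate=False)


def apply_potency_cutoff(table: BioactivityTable,
                         cutoff_nM: float = 1000.0) -> BioactivityTable:
    """Keep records with value_nM <= cutoff_nM (inclusive)."""
    if not cutoff_nM > 0:
        raise ValidationError("cutoff_nM must be positive")
    return BioactivityTable(table.df[table.df["value_nM"] <= cutoff_nM],
                            validate=False)


def target_specific_filter(table: BioactivityTable,
                           percentile: float = 80.0) -> BioactivityTable:
    """Per-target percentile filter on z-scored log10 potencies.

    For each target the log10 values are z-score normalised, the
    ``percentile``-th percentile (linear interpolation) of the normalised
    values is taken as the threshold, and records strictly above it are
    removed — i.e. the least potent tail of each target's own activity
    distribution is dropped.  Single-record and zero-variance targets are
    retained untouched (degenerate normalisation).
    """
    if not (0 < percentile <= 100):
        raise ValidationError("percentile must be in (0, 100]")
    df = table.df
    keep = np.ones(len(df), dtype=bool)
    logv = np.log10(df["value_nM"].to_numpy(dtype=float))
    for _, idx in df.groupby("target_id").indices.items():
        v = logv[idx]
        sd = v.std()  # population sd; the keep decision is scale-invariant
        if sd == 0:
            continue
        z = (v - v.mean()) / sd
        tau = np.percentile(z, percentile)
        keep[idx[z > tau]] = False
    return BioactivityTable(df[keep], validate=False)


def global_activity_filter(table: BioactivityTable,
                           percentile: float = 95.0) -> BioactivityTable:
    """Target-agnostic percentile filter anchored on the noisiest target.

    Log10 values are centred to zero mean per target; the target with the
    highest sample standard deviation of centred values defines the
    threshold τ as its ``percentile``-th percentile, and records with
    centred value strictly above τ are removed across ALL targets.
    """
    if not (0 < percentile <= 100):
        raise ValidationError("percentile must be in (0, 100]")
    df = table.df
    logv = np.log10(df["value_nM"].to_numpy(dtype=float))
    centered = np.empty(len(df))
    best_target, best_sd = None, -np.inf
    groups = df.groupby("target_id").indices
    for tid in sorted(groups):  # sorted → deterministic argmax tie-break
        idx = groups[tid]
        c = logv[idx] - logv[idx].mean()
        centered[idx] = c
        if len(idx) >= 2:
            sd = c.std(ddof=1)
            if sd > best_sd:
                best_target, best_sd = tid, sd
    if best_target is None:
        logger.warning("global_activity_filter: all targets single-record; no-op")
        return BioactivityTable(df, validate=False)
    tau = np.percentile(centered[groups[best_target]], percentile)
    return BioactivityTable(df[centered <= tau], validate=False)


def run_filter_pipeline(table: BioactivityTable,
                        potency_cutoff_nM: float = 1000.0,
                        target_percentile: float = 80.0,
                        global_percentile: float = 95.0,
                        ) -> tuple[BioactivityTable, list[tuple[str, int, int]]]:
    """Run aggregate → potency cutoff → target filter → global filter.

    Returns the filtered table and a per-stage retention log of
    (stage, rows_in, rows_out); shrinkage is asserted at every stage.
    """
    stages = [
        ("aggregate_replicates", lambda t: aggregate_replicates(t)),
        ("potency_cutoff", lambda t: apply_potency_cutoff(t, potency_cutoff_nM)),
        ("target_specific_filter",
         lambda t: target_specific_filter(t, target_percentile)),
        ("global_activity_filter",
         lambda t: global_activity_filter(t, global_percentile)),
    ]
    log = []
    for name, fn in stages:
        n_in = len(table)
        table = fn(table)
        if len(table) > n_in:
            raise AssertionError(f"{name} grew the table: {n_in} -> {len(table)}")
        log.append((name, n_in, len(table)))
        logger.info("%s: %d -> %d rows", name, n_in, len(table))
    return table, log
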