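"""Post-variant-calling filters and per-lineage mutation tallies.

Variant tables are pandas DataFrames with columns
``lineage, position, ref, alt, frequency, read_count, fr_balance, type``
(1-based positions, frequencies as proportions).  The filter chain is

1. base quality filters: forward-reverse balance > 0.05, read count > 10
   (both strict), SNV-only, frequency at or above the 0.5% calling floor;
2. coverage-extreme exclusion: per lineage, positions in the top and bottom
   1% of the coverage ranking are dropped;
3. ancestral subtraction: mutations also called in the ancestor (same
   position, ref and alt) are not de novo and are removed;
4. recurrence (psi) filter: a mutation identity found in more than ``psi``
   lineages is treated as a likely sequencing/read-mapping artifact and
   removed from every lineage.

``tally_counts`` then restricts to a genomic region and a frequency
threshold ``tau`` (strict) and returns per-lineage counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import ObservedCounts

__all__ = [
    "VARIANT_COLUMNS",
    "DetectionConfig",
    "validate_records",
    "apply_base_filters",
    "exclude_extreme_coverage",
    "subtract_ancestral",
    "apply_repeat_filter",
    "apply_filters",
    "tally_counts",
]

VARIANT_COLUMNS = [
    "lineage",
    "position",
    "ref",
    "alt",
    "frequency",
    "read_count",
    "fr_balance",
    "type",
]

CALLING_FLOOR = 0.005  # minimum frequency of the upstream variant caller


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds of the mutation-inclusion rules."""

    tau: float = 0.005
    psi: int = 1
    min_read_count: int = 10
    min_fr_balance: float = 0.05
    coverage_trim_fraction: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 < self.tau < 1.0:
            raise ValueError(f"tau must be in (0, 1), got {self.tau}")
        if self.psi < 1:
            raise ValueError(f"psi must be >= 1, got {self.psi}")
        if not 0.0 <= self.coverage_trim_fraction < 0.5:
            raise ValueError("coverage_trim_fraction must be in [0, 0.5)")


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Validate a variant table; raises naming the offending row."""
    missing = [c for c in VARIANT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    for idx, row in records.iterrows():
        if row["position"] < 1:
            raise ValueError(f"row {idx}: position must be >= 1")
        if not 0.0 < row["frequency"] <= 1.0:
            raise ValueError(f"row {idx}: frequency {row['frequency']} outside (0, 1]")
        if row["type"] == "SNV" and row["ref"] == row["alt"]:
            raise ValueError(f"row {idx}: SNV with ref == alt ({row['ref']})")
    return records


def apply_base_filters(
    records: pd.DataFrame, config: DetectionConfig | None = None
) -> pd.DataFrame:
    """Quality filters: balance, read count (both strict), SNV, calling floor."""
    config = config or DetectionConfig()
    keep = (
        (records["fr_balance"] > config.min_fr_balance)
        & (records["read_count"] > config.min_read_count)
        & (records["type"] == "SNV")
        & (records["frequency"] >= CALLING_FLOOR)
    )
    return records.loc[keep]


def _excluded_positions(depth: np.ndarray, trim_fraction: float) -> np.ndarray:
    """1-based positions whose coverage rank falls in either extreme tail.

    Ranks use average-rank tie handling; a fully tied track excludes
    nothing (every rank sits at the 50th percentile).
    """
    depth = np.asarray(depth, dtype=float)
    n = depth.size
    ranks = pd.Series(depth).rank(method="average").to_numpy()
    pct = (ranks - 0.5) / n
    mask = (pct < trim_fraction) | (pct > 1.0 - trim_fraction)
    return np.flatnonzero(mask) + 1


def exclude_extreme_coverage(
    records: pd.DataFrame,
    coverage: dict[str, np.ndarray] | pd.DataFrame,
    trim_fraction: float = 0.01,
) -> pd.DataFrame:
    """Drop records at coverage-extreme positions of their own lineage.

    ``coverage`` maps lineage -> per-position depth array (or is a long
    DataFrame with columns lineage, position, depth).
    """
    if isinstance(coverage, pd.DataFrame):
        coverage = {
            lin: grp.sort_values("position")["depth"].to_numpy()
            for lin, grp in coverage.groupby("lineage")
        }
    keep = np.ones(len(records), dtype=bool)
    positions = records["position"].to_numpy()
    for lin, depth in coverage.items():
        in_lineage = (records["lineage"] == lin).to_numpy()
        if not in_lineage.any():
            continue
        if positions[in_lineage].max() > len(depth):
            raise ValueError(f"record position outside coverage track for lineage {lin}")
        bad = set(_excluded_positions(depth, trim_fraction).tolist())
        if bad:
            keep &= ~(in_lineage & np.isin(positions, list(bad)))
    uncovered = set(records["lineage"]) - set(coverage)
    if uncovered:
        raise ValueError(f"no coverage track for lineages: {sorted(uncovered)}")
    return records.loc[keep]


def subtract_ancestral(records: pd.DataFrame, ancestral: pd.DataFrame) -> pd.DataFrame:
    """Remove mutations already present in the ancestor.

    Identity is the triple (position, ref, alt); frequency is not compared.
    """
    if len(ancestral) == 0:
        return records
    anc = set(zip(ancestral["position"], ancestral["ref"], ancestral["alt"]))
    keep = [
        (pos, ref, alt) not in anc
        for pos, ref, alt in zip(records["position"], records["ref"], records["alt"])
    ]
    return records.loc[keep]


def apply_repeat_filter(records: pd.DataFrame, psi: int) -> pd.DataFrame:
    """Drop mutation identities recurring in more than ``psi`` lineages.

    An identity in more than ``psi`` distinct lineages is removed from all
    of them; at or below ``psi`` it is kept everywhere it occurs.
    """
    if psi < 1:
        raise ValueError(f"psi must be >= 1, got {psi}")
    if len(records) == 0:
        return records
    n_lineages = records.groupby(["position", "ref", "alt"])["lineage"].transform("nunique")
    return records.loc[n_lineages <= psi]


def apply_filters(
    records: pd.DataFrame,
    config: DetectionConfig | None = None,
    coverage: dict[str, np.ndarray] | pd.DataFrame | None = None,
    ancestral: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full filter chain: base -> coverage -> ancestral -> recurrence."""
    config = config or DetectionConfig()
    out = apply_base_filters(records, config)
    if coverage is not None:
        out = exclude_extreme_coverage(out, coverage, config.coverage_trim_fraction)
    if ancestral is not None:
        out = subtract_ancestral(out, ancestral)
    return apply_repeat_filter(out, config.psi)


def tally_counts(
    records: pd.DataFrame,
    annotation,
    region: str,
    tau: float,
    psi: int = 1,
    lineages=None,
) -> ObservedCounts:
    """Per-lineage counts of mutations above ``tau`` inside a region.

    ``region`` is ``"neutral-insert"`` or ``"whole-genome"``; intervals come
    from a :class:`~baculorate.selection_spectrum.RegionAnnotation` (closed,
    1-based).  ``lineages`` fixes the lineage order (and includes
    zero-count lineages); defaults to the sorted lineages present.
    """
    if region == "neutral-insert":
        intervals = [(s, e) for s, e, cat, *_ in annotation.intervals if cat == "neutral-insert"]
        if not intervals:
            raise ValueError("annotation has no neutral-insert interval")
        length = sum(e - s + 1 for s, e in intervals)
    elif region == "whole-genome":
        intervals = [(1, len(annotation.reference))]
        length = len(annotation.reference)
    else:
        raise ValueError(f"unknown region label: {region!r}")

    pos = records["position"].to_numpy()
    in_region = np.zeros(len(records), dtype=bool)
    for s, e in intervals:
        in_region |= (pos >= s) & (pos <= e)
    kept = records.loc[in_region & (records["frequency"] > tau).to_numpy()]

    if lineages is None:
        lineages = sorted(records["lineage"].unique())
    counts = kept.groupby("lineage").size()
    per_replicate = tuple(int(counts.get(lin, 0)) for lin in lineages)
    if not per_replicate:
        raise ValueError("no lineages to tally")
    return ObservedCounts(per_replicate=per_replicate, region_length=length, tau=tau, psi=psi)
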