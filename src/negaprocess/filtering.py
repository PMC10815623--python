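"""Signal-cleaning cascade for negative controls and low-template profiles.

Negative-control tables are cleaned by (1) dropping signals outside the
kit's recommended read region and (2) dropping signals within 2 bp of any
internal-lane-standard fragment, where spectral pull-up from the strong
ILS peaks contaminates the analysis dyes.  Low-template positive tables
are cleaned by (1) keeping only peaks at marker (locus) positions and
(2) removing cross-dye pull-up peaks, i.e. peaks at the same size
(+/-0.3 bp) as an allelic peak in another dye with height at most 5% of
that peak.  Finally an analytical threshold can be applied per dye
("at and above" is inclusive).

Every filter returns the retained table plus a :class:`FilterReport`
whose counts reconcile exactly (input = removed + retained).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import SizingTable
from .kits import KitConfig

#: closed enumeration of removal reasons
REASONS = ("out_of_read_region", "near_ILS", "pull_up", "off_locus", "below_AT")


@dataclass
class FilterStage:
    """Bookkeeping for one filter pass."""

    name: str
    reason: str
    n_input: int
    n_removed: int
    n_retained: int
    removed_records: pd.DataFrame

    def reconciled(self) -> bool:
        return self.n_input == self.n_removed + self.n_retained


@dataclass
class FilterReport:
    """Audit trail of one or more filter stages."""

    stages: list[FilterStage] = field(default_factory=list)

    def reconciled(self) -> bool:
        return all(s.reconciled() for s in self.stages)

    def total_removed(self) -> int:
        return sum(s.n_removed for s in self.stages)

    def extend(self, other: "FilterReport") -> "FilterReport":
        self.stages.extend(other.stages)
        return self


def _split(
    table: SizingTable, keep: np.ndarray, name: str, reason: str
) -> tuple[SizingTable, FilterReport]:
    assert reason in REASONS
    keep = np.asarray(keep, dtype=bool)
    removed = table.records.loc[~keep].copy()
    removed["reason"] = reason
    stage = FilterStage(
        name=name,
        reason=reason,
        n_input=len(table),
        n_removed=int((~keep).sum()),
        n_retained=int(keep.sum()),
        removed_records=removed.reset_index(drop=True),
    )
    return table.with_records(table.records.loc[keep]), FilterReport([stage])


def filter_read_region(table: SizingTable, kit: KitConfig) -> tuple[SizingTable, FilterReport]:
    """Keep signals inside the kit's recommended read region (closed interval)."""
    lo, hi = kit.read_region
    size = table.records["size_bp"].to_numpy(dtype=float)
    keep = (size >= lo) & (size <= hi)
    return _split(table, keep, "read_region", "out_of_read_region")


def filter_ils_adjacent(
    table: SizingTable, kit: KitConfig, window_bp: float = 2.0
) -> tuple[SizingTable, FilterReport]:
    """Remove signals within ``window_bp`` bases of any ILS fragment.

    Proximity is measured in size (bp) and the window is inclusive
    (distance <= window removes).  Records on the ILS dye itself are always
    removed from analysis.
    """
    if not kit.ils_fragments:
        raise ConfigurationError(
            f"kit {kit.kit_name!r} declares no ILS fragments; cannot filter ILS-adjacent signals"
        )
    size = table.records["size_bp"].to_numpy(dtype=float)
    frags = np.asarray(kit.ils_fragments, dtype=float)
    if len(size):
        dist = np.abs(size[:, None] - frags[None, :]).min(axis=1)
    else:
        dist = np.empty(0)
    on_ils_dye = (table.records["dye"] == kit.ils_dye).to_numpy()
    keep = (dist > window_bp) & ~on_ils_dye
    return _split(table, keep, "ils_adjacent", "near_ILS")


def screen_locus_positions(
    table: SizingTable, kit: KitConfig
) -> tuple[SizingTable, FilterReport]:
    """Keep peaks inside some marker interval on their own dye.

    Retained records are annotated with the marker name.  Off-ladder
    ("OL") allele labels do not by themselves force removal; only position
    decides.
    """
    records = table.records
    marker_names = np.full(len(records), "", dtype=object)
    keep = np.zeros(len(records), dtype=bool)
    size = records["size_bp"].to_numpy(dtype=float)
    dyes = records["dye"].to_numpy()
    for m in kit.markers:
        in_marker = (dyes == m.dye) & (size >= m.size_min) & (size <= m.size_max)
        marker_names[in_marker] = m.name
        keep |= in_marker
    annotated = records.copy()
    annotated["marker"] = marker_names
    out, report = _split(table.with_records(annotated), keep, "locus_screen", "off_locus")
    return out, report


def remove_pullup(
    table: SizingTable,
    allelic_peaks: SizingTable,
    size_tol_bp: float = 0.3,
    height_frac: float = 0.05,
) -> tuple[SizingTable, FilterReport]:
    """Remove cross-dye pull-up peaks.

    A record is removed iff some allelic peak in a *different* dye sits at
    the same position (|delta size| <= ``size_tol_bp``, inclusive) and the
    record's height is at most ``height_frac`` of that peak's height
    (inclusive).  When several allelic peaks qualify positionally, the
    tallest one governs, which is the most conservative removal rule.
    """
    rec = table.records
    peaks = allelic_peaks.records
    if len(rec) == 0 or len(peaks) == 0:
        keep = np.ones(len(rec), dtype=bool)
        return _split(table, keep, "pull_up", "pull_up")

    r_size = rec["size_bp"].to_numpy(dtype=float)
    r_height = rec["height_rfu"].to_numpy(dtype=float)
    r_dye = rec["dye"].to_numpy()
    p_size = peaks["size_bp"].to_numpy(dtype=float)
    p_height = peaks["height_rfu"].to_numpy(dtype=float)
    p_dye = peaks["dye"].to_numpy()

    same_pos = np.abs(r_size[:, None] - p_size[None, :]) <= size_tol_bp
    other_dye = r_dye[:, None] != p_dye[None, :]
    low_enough = r_height[:, None] <= height_frac * p_height[None, :]
    removed = (same_pos & other_dye & low_enough).any(axis=1)
    return _split(table, ~removed, "pull_up", "pull_up")


def apply_threshold(table: SizingTable, thresholds) -> tuple[SizingTable, FilterReport]:
    """Keep peaks at and above the per-dye analytical threshold (inclusive).

    ``thresholds`` is a mapping dye -> RFU or an object with a ``values``
    mapping (a ThresholdSet).  Every dye present in the table must have a
    threshold, otherwise :class:`ConfigurationError` is raised.
    """
    values = getattr(thresholds, "values", thresholds)
    if callable(values):  # dict.values would be a method; ThresholdSet.values is a dict
        values = thresholds
    rec = table.records
    missing = sorted(set(rec["dye"]) - set(values))
    if missing:
        raise ConfigurationError(f"no analytical threshold configured for dye(s): {missing}")
    if len(rec):
        ats = rec["dye"].map(values).to_numpy(dtype=float)
        keep = rec["height_rfu"].to_numpy(dtype=float) >= ats
    else:
        keep = np.zeros(0, dtype=bool)
    return _split(table, keep, "analytical_threshold", "below_AT")


def clean_negative(
    table: SizingTable, kit: KitConfig, ils_window_bp: float = 2.0
) -> tuple[SizingTable, FilterReport]:
    """Standard negative-control cascade: read region, then ILS proximity."""
    out, report = filter_read_region(table, kit)
    if kit.ils_fragments:
        out, r2 = filter_ils_adjacent(out, kit, window_bp=ils_window_bp)
        report.extend(r2)
    return out, report
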