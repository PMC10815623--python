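"""Scoring threshold choices against a reference genotype.

Given a low-template profile of a known control DNA, every retained peak
is either *allelic* (it falls in the bin of an expected allele at its
marker) or *non-allelic* (stutter, residual pull-up, noise); expected
alleles with no matching peak are *dropouts* (Type II errors).  From the
tallies we form a true-positive rate (detected / expected alleles), a
false-positive rate and the total error rate (1 - TPR) + FPR.

The FPR denominator is a package convention: non-allelic peaks divided by
the number of expected alleles, capped at 1.  This makes the Type I term
commensurate with the Type II term and bounds the total error by 2; a
completely dropped-out, artifact-free profile sits exactly at 1.0.

ROC analysis compares threshold methods at one experimental condition:
the method whose (FPR, TPR) point lies closest (Euclidean) to the ideal
corner (0, 1) is optimal; ties break toward the lower FPR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .filtering import remove_pullup, screen_locus_positions
from .io import ReferenceGenotype, SizingTable
from .kits import BIN_HALF_WIDTH_BP, KitConfig

LABEL_ALLELIC = "allelic"
LABEL_NON_ALLELIC = "non_allelic"


@dataclass(frozen=True)
class EvaluationCount:
    """Dropout / non-allelic tallies and error rates for one cell.

    ``condition`` is (template_pg, cycles, dye) with ``dye = None`` for an
    all-dyes aggregate.  Invariants: n_dropouts + n_detected = n_expected;
    tpr = detected/expected; total_error = (1 - tpr) + fpr.
    """

    method: str
    condition: tuple
    n_expected_alleles: int
    n_dropouts: int
    n_true_alleles_detected: int
    n_non_allelic: int
    tpr: float
    fpr: float
    total_error: float


@dataclass
class SweepCurve:
    """Mean dropout / non-allelic counts per dye over an AT sweep.

    ``data`` columns: dye, at_rfu, mean_dropouts, mean_non_allelic.  The
    dropout curve is non-decreasing and the non-allelic curve
    non-increasing in the threshold.
    """

    data: pd.DataFrame

    def for_dye(self, dye: str) -> pd.DataFrame:
        return self.data[self.data["dye"] == dye].reset_index(drop=True)

    def is_monotone(self) -> bool:
        for dye, sub in self.data.groupby("dye"):
            sub = sub.sort_values("at_rfu")
            if np.any(np.diff(sub["mean_dropouts"].to_numpy()) < 0):
                return False
            if np.any(np.diff(sub["mean_non_allelic"].to_numpy()) > 0):
                return False
        return True


def classify_peaks(
    table: SizingTable, genotype: ReferenceGenotype, kit: KitConfig
) -> pd.DataFrame:
    """Label every peak of a locus-screened table as allelic or non-allelic.

    A peak is allelic when its size falls in the +/-0.5 bp bin of an
    expected allele at its annotated marker.  Returns the record frame
    with ``label`` and ``matched_allele`` columns.  Records at markers
    absent from the genotype (or without a marker annotation) raise
    :class:`ValidationError`.
    """
    rec = table.records.copy()
    labels = []
    matched = []
    for row in rec.itertuples(index=False):
        marker_name = row.marker
        if not marker_name:
            raise ValidationError(
                f"record at size {row.size_bp} has no marker annotation; "
                "run screen_locus_positions first"
            )
        if marker_name not in genotype:
            raise ValidationError(f"marker {marker_name!r} absent from reference genotype")
        marker = kit.marker_by_name(marker_name)
        bin_label = marker.bin_for(row.size_bp, BIN_HALF_WIDTH_BP)
        if bin_label is not None and bin_label in genotype[marker_name]:
            labels.append(LABEL_ALLELIC)
            matched.append(bin_label)
        else:
            labels.append(LABEL_NON_ALLELIC)
            matched.append("")
    rec["label"] = labels
    rec["matched_allele"] = matched
    return rec


def expected_alleles(
    genotype: ReferenceGenotype, kit: KitConfig, dye: str | None = None
) -> set[tuple[str, str]]:
    """Expected (marker, allele) pairs, optionally restricted to one dye.

    A homozygous marker contributes a single expected allele.
    """
    out = set()
    for marker_name, alleles in genotype.items():
        marker = kit.marker_by_name(marker_name)
        if dye is not None and marker.dye != dye:
            continue
        for a in alleles:
            out.add((marker_name, a))
    return out


def _rates(n_expected: int, n_detected: int, n_non_allelic: int) -> tuple[float, float, float]:
    if n_expected > 0:
        tpr = n_detected / n_expected
        fpr = min(1.0, n_non_allelic / n_expected)
    else:
        tpr = 1.0
        fpr = 1.0 if n_non_allelic else 0.0
    return tpr, fpr, (1.0 - tpr) + fpr


def count_events(
    labelled: pd.DataFrame,
    genotype: ReferenceGenotype,
    kit: KitConfig,
    dye: str | None = None,
    method: str = "",
    condition: tuple = (),
) -> EvaluationCount:
    """Aggregate a labelled peak table into an :class:`EvaluationCount`."""
    if dye is not None:
        labelled = labelled[labelled["dye"] == dye]
    expected = expected_alleles(genotype, kit, dye)
    detected = {
        (row.marker, row.matched_allele)
        for row in labelled.itertuples(index=False)
        if row.label == LABEL_ALLELIC
    }
    detected &= expected
    n_expected = len(expected)
    n_detected = len(detected)
    n_non_allelic = int((labelled["label"] == LABEL_NON_ALLELIC).sum())
    tpr, fpr, tot = _rates(n_expected, n_detected, n_non_allelic)
    return EvaluationCount(
        method=method,
        condition=condition if condition else (None, None, dye),
        n_expected_alleles=n_expected,
        n_dropouts=n_expected - n_detected,
        n_true_alleles_detected=n_detected,
        n_non_allelic=n_non_allelic,
        tpr=tpr,
        fpr=fpr,
        total_error=tot,
    )


def allelic_reference(
    table: SizingTable, genotype: ReferenceGenotype, kit: KitConfig
) -> SizingTable:
    """Peaks at expected allele positions, used as the pull-up reference."""
    screened, _ = screen_locus_positions(table, kit)
    labelled = classify_peaks(screened, genotype, kit)
    keep = labelled["label"] == LABEL_ALLELIC
    return screened.with_records(screened.records.loc[keep.to_numpy()])


def prepare_positive(
    table: SizingTable, genotype: ReferenceGenotype, kit: KitConfig
) -> pd.DataFrame:
    """Low-template cleaning cascade: locus screen, pull-up removal, labelling."""
    screened, _ = screen_locus_positions(table, kit)
    reference = allelic_reference(table, genotype, kit)
    cleaned, _ = remove_pullup(screened, reference)
    return classify_peaks(cleaned, genotype, kit)


def sweep_thresholds(
    tables: Sequence[SizingTable],
    genotype: ReferenceGenotype,
    kit: KitConfig,
    at_range: Sequence[int] = range(1, 201),
) -> SweepCurve:
    """Mean dropout / non-allelic counts per dye as the AT sweeps ``at_range``.

    Tables are replicates of one condition, already locus-screened or raw
    (screening and pull-up removal are applied here).  Peak labels do not
    depend on the threshold, so each table is classified once and counts
    at every threshold follow from sorted height arrays.
    """
    ats = np.asarray(list(at_range), dtype=float)
    rows = []
    for dye in kit.analysis_dyes:
        n_expected = len(expected_alleles(genotype, kit, dye))
        dropout_acc = np.zeros(len(ats))
        non_allelic_acc = np.zeros(len(ats))
        for table in tables:
            labelled = prepare_positive(table, genotype, kit)
            sub = labelled[labelled["dye"] == dye]
            allelic = sub[sub["label"] == LABEL_ALLELIC]
            # tallest peak per detected allele decides its dropout threshold
            if len(allelic):
                per_allele = (
                    allelic.groupby(["marker", "matched_allele"])["height_rfu"].max()
                )
                det = np.sort(per_allele.to_numpy(dtype=float))
            else:
                det = np.empty(0)
            na = np.sort(
                sub.loc[sub["label"] == LABEL_NON_ALLELIC, "height_rfu"].to_numpy(dtype=float)
            )
            n_det = len(det) - np.searchsorted(det, ats, side="left")
            n_na = len(na) - np.searchsorted(na, ats, side="left")
            dropout_acc += n_expected - n_det
            non_allelic_acc += n_na
        n_rep = max(len(tables), 1)
        for at, d, na_count in zip(ats, dropout_acc / n_rep, non_allelic_acc / n_rep):
            rows.append(
                {"dye": dye, "at_rfu": int(at), "mean_dropouts": d, "mean_non_allelic": na_count}
            )
    return SweepCurve(pd.DataFrame(rows))


def compare_methods(
    threshold_sets: Iterable,
    tables: Sequence[SizingTable],
    genotype: ReferenceGenotype,
    kit: KitConfig,
) -> list[EvaluationCount]:
    """Evaluate each threshold set at each (template, cycles) condition.

    Counts are pooled over all replicate tables of a condition and over
    all analysis dyes; classification logic is identical across methods
    (only the applied thresholds differ).
    """
    prepared = [
        (t.template_pg, t.pcr_cycles, prepare_positive(t, genotype, kit)) for t in tables
    ]
    conditions = sorted({(tpl, cyc) for tpl, cyc, _ in prepared}, key=str)
    n_expected_per_table = len(expected_alleles(genotype, kit))
    out: list[EvaluationCount] = []
    for ts in threshold_sets:
        for tpl, cyc in conditions:
            n_expected = n_detected = n_non_allelic = 0
            for t_tpl, t_cyc, labelled in prepared:
                if (t_tpl, t_cyc) != (tpl, cyc):
                    continue
                ats = labelled["dye"].map(ts.values).to_numpy(dtype=float)
                kept = labelled[labelled["height_rfu"].to_numpy(dtype=float) >= ats]
                detected = {
                    (row.marker, row.matched_allele)
                    for row in kept.itertuples(index=False)
                    if row.label == LABEL_ALLELIC
                }
                n_expected += n_expected_per_table
                n_detected += len(detected)
                n_non_allelic += int((kept["label"] == LABEL_NON_ALLELIC).sum())
            tpr, fpr, tot = _rates(n_expected, n_detected, n_non_allelic)
            out.append(
                EvaluationCount(
                    method=ts.method,
                    condition=(tpl, cyc, None),
                    n_expected_alleles=n_expected,
                    n_dropouts=n_expected - n_detected,
                    n_true_alleles_detected=n_detected,
                    n_non_allelic=n_non_allelic,
                    tpr=tpr,
                    fpr=fpr,
                    total_error=tot,
                )
            )
    return out


@dataclass
class RocResult:
    """ROC points of several methods at one condition plus the optimum."""

    condition: tuple
    points: pd.DataFrame  # columns: method, fpr, tpr, distance
    best_method: str


def roc_points(counts: Sequence[EvaluationCount]) -> RocResult:
    """Order methods in ROC space and pick the point closest to (0, 1).

    All counts must share a condition.  Distance is Euclidean to the ideal
    corner; exact ties resolve toward the lower FPR.
    """
    conditions = {c.condition for c in counts}
    if len(conditions) != 1:
        raise ValidationError(f"ROC points must share one condition, got {conditions}")
    rows = []
    for c in counts:
        dist = float(np.hypot(c.fpr, 1.0 - c.tpr))
        rows.append({"method": c.method, "fpr": c.fpr, "tpr": c.tpr, "distance": dist})
    df = pd.DataFrame(rows).sort_values(["fpr", "tpr"]).reset_index(drop=True)
    # distances equal up to float dust count as tied; ties go to the lower FPR
    ranked = df.assign(_d=df["distance"].round(9)).sort_values(
        ["_d", "fpr"], kind="stable"
    )
    best = ranked.iloc[0]
    return RocResult(condition=next(iter(conditions)), points=df, best_method=str(best["method"]))


def total_error(count: EvaluationCount) -> float:
    """Total error rate: Type II rate (1 - TPR) plus Type I rate (FPR)."""
    return (1.0 - count.tpr) + count.fpr


def counts_frame(counts: Iterable[EvaluationCount]) -> pd.DataFrame:
    """Long results table keyed by (method, template, cycles, dye)."""
    rows = []
    for c in counts:
        tpl, cyc, dye = (c.condition + (None, None, None))[:3]
        rows.append(
            {
                "method": c.method,
                "template_pg": tpl,
                "cycles": cyc,
                "dye": dye,
                "n_expected_alleles": c.n_expected_alleles,
                "n_dropouts": c.n_dropouts,
                "n_detected": c.n_true_alleles_detected,
                "n_non_allelic": c.n_non_allelic,
                "tpr": c.tpr,
                "fpr": c.fpr,
                "total_error": c.total_error,
            }
        )
    return pd.DataFrame(rows)
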