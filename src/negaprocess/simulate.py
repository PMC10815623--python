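"""Synthetic negative-control and low-template positive sizing tables.

No instrument data ships with the package; this module generates tables
with the statistical structure the pipeline assumes, so every stage is
testable end to end.

Negative model (per analysis dye): the number of baseline signals per
injection is Poisson(rate); sizes are uniform over the read region;
heights are lognormal, log-height ~ Normal(log_mean, log_sd^2).  A mild
cycle effect shifts the log-mean upward per extra PCR cycle beyond the
reference, mirroring the observed inflation of baseline signals at high
cycle numbers.

Positive model: every expected allele receives a peak whose median height
scales linearly with template mass and doubles per PCR cycle,
``h = h_ref * (template / template_ref) * 2^(cycles - cycles_ref)``,
multiplied by a lognormal amplification factor drawn once per PCR
replicate and a smaller lognormal injection factor per CE replicate.
Peaks below 1 RFU are not emitted (dropout).  Each emitted allelic peak
spawns a stutter peak one repeat unit shorter with a truncated-normal
ratio, and with a small probability a cross-dye pull-up peak at the same
size (+/-0.3 bp) and 1-5% height.  Baseline noise is superimposed.

The height-template-cycle law is a stand-in: real instruments saturate
and real amplification efficiency is below doubling.  Parameters are
exposed on :class:`SimulationConfig`.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import RECORD_COLUMNS, ReferenceGenotype, SizingTable, empty_records
from .kits import KitConfig, Marker


@dataclass(frozen=True)
class DyeNoiseModel:
    """Baseline noise of one dye: lognormal heights, Poisson signal count."""

    log_mean: float
    log_sd: float
    rate: float

    def __post_init__(self) -> None:
        if self.log_sd <= 0:
            raise ValidationError("log_sd must be positive")
        if self.rate < 0:
            raise ValidationError("rate must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world of the synthetic study.

    Defaults mirror the published study design: three template masses
    (31.25, 15.625, 7.8125 pg), three cycle numbers (27, 29, 31), three
    PCR replicates each injected three times, and nine negative controls
    per cycle number.  ``peak_height_ref`` (median allelic height at the
    reference condition 31.25 pg / 27 cycles) and the noise scales are
    chosen so that low-template profiles show substantial stochastic
    dropout at the thresholds under study, as real sub-32 pg profiles do.
    """

    noise: Mapping[str, DyeNoiseModel]
    peak_height_ref: float = 60.0
    template_ref_pg: float = 31.25
    cycles_ref: int = 27
    peak_log_sd: float = 1.0
    ce_log_sd: float = 0.1
    cycle_log_shift: float = 0.04
    stutter_mean: float = 0.08
    stutter_sd: float = 0.03
    pullup_prob: float = 0.05
    min_height_rfu: float = 1.0
    templates_pg: tuple[float, ...] = (31.25, 15.625, 7.8125)
    cycles: tuple[int, ...] = (27, 29, 31)
    n_pcr_reps: int = 3
    n_ce_reps: int = 3
    n_negatives_per_cycle: int = 9

    def __post_init__(self) -> None:
        if self.peak_height_ref <= 0 or self.template_ref_pg <= 0:
            raise ValidationError("reference height and template must be positive")
        for p in (self.peak_log_sd, self.ce_log_sd, self.stutter_sd):
            if p < 0:
                raise ValidationError("noise scales must be non-negative")
        if not 0 <= self.pullup_prob <= 1:
            raise ValidationError("pullup_prob must be a probability")


def default_noise(kit: KitConfig) -> dict[str, DyeNoiseModel]:
    """Per-dye baseline defaults: blue lowest, purple highest and broadest.

    Log-means around 2.0-2.45 put typical baseline heights at 7-12 RFU
    with maxima of a few tens of RFU, the regime reported for modern
    6-dye chemistries; ~10 signals per injection and dye.
    """
    presets = {
        "B": DyeNoiseModel(2.00, 0.25, 10.0),
        "G": DyeNoiseModel(2.20, 0.28, 10.0),
        "Y": DyeNoiseModel(2.25, 0.28, 10.0),
        "R": DyeNoiseModel(2.15, 0.28, 10.0),
        "P": DyeNoiseModel(2.45, 0.38, 10.0),
    }
    fallback = DyeNoiseModel(2.15, 0.30, 10.0)
    return {d: presets.get(d, fallback) for d in kit.analysis_dyes}


def default_config(kit: KitConfig) -> SimulationConfig:
    return SimulationConfig(noise=default_noise(kit))


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _frame(rows: list[dict]) -> pd.DataFrame:
    if not rows:
        return empty_records()
    df = pd.DataFrame(rows, columns=list(RECORD_COLUMNS))
    df["data_point"] = df["data_point"].astype(np.int64)
    return df


def _noise_rows(
    config: SimulationConfig,
    kit: KitConfig,
    rng: np.random.Generator,
    sample_id: str,
    cycles: int,
) -> list[dict]:
    lo, hi = kit.read_region
    shift = config.cycle_log_shift * (cycles - config.cycles_ref)
    rows: list[dict] = []
    for dye in kit.analysis_dyes:
        model = config.noise[dye]
        n = rng.poisson(model.rate)
        sizes = rng.uniform(lo, hi, size=n)
        heights = np.exp(rng.normal(model.log_mean + shift, model.log_sd, size=n))
        for s, h in zip(sizes, heights):
            if h < config.min_height_rfu:
                continue
            rows.append(
                {
                    "sample_id": sample_id,
                    "dye": dye,
                    "marker": "",
                    "allele": "",
                    "size_bp": float(s),
                    "height_rfu": float(h),
                    "area": float(h * 4.0),
                    "data_point": int(s * 10),
                }
            )
    return rows


def simulate_negative(
    config: SimulationConfig,
    kit: KitConfig,
    seed,
    sample_id: str = "neg",
    cycles: int = 27,
    run_date: _dt.date = _dt.date(2022, 3, 15),
    lab_id: str = "LAB_sim",
) -> SizingTable:
    """One negative-control injection; reproducible given the seed."""
    rng = _rng(seed)
    rows = _noise_rows(config, kit, rng, sample_id, cycles)
    return SizingTable(
        _frame(rows),
        lab_id=lab_id,
        kit_id=kit.kit_name,
        run_date=run_date,
        pcr_cycles=cycles,
        sample_role="negative",
    )


def _allelic_rows(
    config: SimulationConfig,
    kit: KitConfig,
    genotype: ReferenceGenotype,
    template_pg: float,
    cycles: int,
    amp_factors: dict[tuple[str, str], float],
    rng: np.random.Generator,
    sample_id: str,
    disable_artifacts: bool,
) -> list[dict]:
    median = (
        config.peak_height_ref
        * (template_pg / config.template_ref_pg)
        * 2.0 ** (cycles - config.cycles_ref)
    )
    analysis_dyes = list(kit.analysis_dyes)
    rows: list[dict] = []
    for marker_name, alleles in sorted(genotype.items()):
        marker: Marker = kit.marker_by_name(marker_name)
        for allele in sorted(alleles):
            if allele not in marker.bins:
                raise ValidationError(
                    f"genotype allele {allele!r} has no bin at marker {marker_name}"
                )
            center = marker.bins[allele]
            h = (
                median
                * amp_factors[(marker_name, allele)]
                * float(np.exp(rng.normal(0.0, config.ce_log_sd)))
            )
            if h < config.min_height_rfu:
                continue
            size = center + rng.normal(0.0, 0.1)
            rows.append(
                {
                    "sample_id": sample_id,
                    "dye": marker.dye,
                    "marker": marker_name,
                    "allele": allele,
                    "size_bp": float(size),
                    "height_rfu": float(h),
                    "area": float(h * 5.0),
                    "data_point": int(size * 10),
                }
            )
            if disable_artifacts:
                continue
            # stutter one repeat unit below the allele
            ratio = max(0.0, rng.normal(config.stutter_mean, config.stutter_sd))
            h_st = ratio * h
            if h_st >= config.min_height_rfu:
                st_size = size - marker.repeat_unit
                rows.append(
                    {
                        "sample_id": sample_id,
                        "dye": marker.dye,
                        "marker": "",
                        "allele": "",
                        "size_bp": float(st_size),
                        "height_rfu": float(h_st),
                        "area": float(h_st * 5.0),
                        "data_point": int(st_size * 10),
                    }
                )
            # cross-dye pull-up at the same position, 1-5% height
            if len(analysis_dyes) > 1 and rng.random() < config.pullup_prob:
                others = [d for d in analysis_dyes if d != marker.dye]
                pu_dye = others[rng.integers(len(others))]
                pu_size = size + rng.uniform(-0.3, 0.3)
                pu_h = h * rng.uniform(0.01, 0.05)
                if pu_h >= config.min_height_rfu:
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "dye": pu_dye,
                            "marker": "",
                            "allele": "OL",
                            "size_bp": float(pu_size),
                            "height_rfu": float(pu_h),
                            "area": float(pu_h * 4.0),
                            "data_point": int(pu_size * 10),
                        }
                    )
    return rows


def _draw_amp_factors(
    config: SimulationConfig, genotype: ReferenceGenotype, rng: np.random.Generator
) -> dict[tuple[str, str], float]:
    return {
        (m, a): float(np.exp(rng.normal(0.0, config.peak_log_sd)))
        for m, alleles in sorted(genotype.items())
        for a in sorted(alleles)
    }


def simulate_positive(
    config: SimulationConfig,
    kit: KitConfig,
    genotype: ReferenceGenotype,
    template_pg: float,
    cycles: int,
    seed,
    sample_id: str = "pos",
    run_date: _dt.date = _dt.date(2022, 3, 15),
    lab_id: str = "LAB_sim",
    disable_artifacts: bool = False,
    with_noise: bool = True,
) -> SizingTable:
    """One low-template positive injection of the reference control DNA."""
    if template_pg <= 0:
        raise ValidationError("template_pg must be positive")
    unknown = sorted(set(genotype) - set(kit.marker_names))
    if unknown:
        raise ValidationError(f"genotype markers not in kit: {unknown}")
    rng = _rng(seed)
    amp = _draw_amp_factors(config, genotype, rng)
    rows = _allelic_rows(
        config, kit, genotype, template_pg, cycles, amp, rng, sample_id, disable_artifacts
    )
    if with_noise:
        rows += _noise_rows(config, kit, rng, sample_id, cycles)
    return SizingTable(
        _frame(rows),
        lab_id=lab_id,
        kit_id=kit.kit_name,
        run_date=run_date,
        pcr_cycles=cycles,
        sample_role="positive",
        template_pg=template_pg,
    )


def generate_study(
    config: SimulationConfig,
    kit: KitConfig,
    genotype: ReferenceGenotype,
    seed: int,
) -> list[SizingTable]:
    """Full factorial study: positives and negatives with populated metadata.

    3 templates x 3 cycles x 3 PCR reps x 3 CE reps = 81 positive tables
    (CE replicates share the PCR replicate's amplification factors), plus
    9 negatives per cycle number = 27 negative tables.  A single study
    seed drives per-table substreams, so regeneration is byte-identical.
    """
    ss = np.random.SeedSequence(seed)
    tables: list[SizingTable] = []
    run_date = _dt.date(2022, 3, 15)
    for tpl in config.templates_pg:
        for cyc in config.cycles:
            for pcr in range(1, config.n_pcr_reps + 1):
                pcr_rng = np.random.default_rng(ss.spawn(1)[0])
                amp = _draw_amp_factors(config, genotype, pcr_rng)
                for ce in range(1, config.n_ce_reps + 1):
                    rng = np.random.default_rng(ss.spawn(1)[0])
                    sid = f"pos_t{tpl:g}_c{cyc}_p{pcr}_e{ce}"
                    rows = _allelic_rows(
                        config, kit, genotype, tpl, cyc, amp, rng, sid, False
                    )
                    rows += _noise_rows(config, kit, rng, sid, cyc)
                    tables.append(
                        SizingTable(
                            _frame(rows),
                            lab_id="LAB_sim",
                            kit_id=kit.kit_name,
                            run_date=run_date,
                            pcr_cycles=cyc,
                            sample_role="positive",
                            template_pg=tpl,
                        )
                    )
    for cyc in config.cycles:
        for i in range(1, config.n_negatives_per_cycle + 1):
            rng = np.random.default_rng(ss.spawn(1)[0])
            sid = f"neg_c{cyc}_{i}"
            tables.append(
                simulate_negative(
                    config, kit, rng, sample_id=sid, cycles=cyc, run_date=run_date
                )
            )
    return tables


def study_manifest(tables: Sequence[SizingTable]) -> pd.DataFrame:
    """One row per generated table with its condition metadata."""
    rows = []
    for i, t in enumerate(tables):
        sid = t.records["sample_id"].iloc[0] if len(t) else f"table_{i}"
        rows.append(
            {
                "sample_id": sid,
                "sample_role": t.sample_role,
                "template_pg": t.template_pg,
                "pcr_cycles": t.pcr_cycles,
                "lab_id": t.lab_id,
                "kit_id": t.kit_id,
                "run_date": t.run_date.isoformat() if t.run_date else "",
                "n_records": len(t),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# example kit and genotype (synthetic stand-ins)
# ---------------------------------------------------------------------------


def example_kit() -> KitConfig:
    """A synthetic 6-channel kit: five analysis dyes plus an ILS channel.

    Marker geometry is invented (four tetranucleotide markers per dye with
    ten 4-bp-spaced allele bins each); the ILS ladder runs every 20 bp
    across the 80-480 bp read region.  This is a stand-in for a commercial
    kit definition, which is proprietary.  Marker blocks are staggered by
    1.7 bp per dye so that allele bins of different dyes never coincide
    (cross-dye bin distance >= 0.6 bp), as in real multiplex designs;
    otherwise true allelic peaks of different dyes would sit at identical
    sizes and shadow each other in the pull-up filter.
    """
    dyes = ("B", "G", "Y", "R", "P")
    markers = []
    for i, dye in enumerate(dyes):
        for j, base in enumerate((100.0, 160.0, 240.0, 320.0), start=1):
            start = base + 1.7 * i
            bins = {str(5 + k): start + 2.0 + 4.0 * k for k in range(10)}
            markers.append(
                Marker(
                    name=f"M_{dye}{j}",
                    dye=dye,
                    size_min=start,
                    size_max=start + 40.0,
                    repeat_unit=4.0,
                    bins=bins,
                )
            )
    return KitConfig(
        kit_name="SynthFiler6",
        dyes=dyes + ("LIZ",),
        read_region=(80.0, 480.0),
        ils_fragments=tuple(float(x) for x in range(80, 481, 20)),
        markers=tuple(markers),
    )


def example_genotype(kit: KitConfig | None = None) -> ReferenceGenotype:
    """A synthetic reference genotype for the example kit.

    Stand-in for a control-DNA profile (the real certified genotype of a
    commercial control is not reproduced here): every third marker is
    homozygous, the rest heterozygous, allele choices deterministic.
    """
    kit = kit or example_kit()
    genotype: ReferenceGenotype = {}
    for i, m in enumerate(kit.markers):
        labels = sorted(m.bins, key=float)
        if i % 3 == 2:
            genotype[m.name] = frozenset({labels[4]})
        else:
            genotype[m.name] = frozenset({labels[2], labels[6]})
    return genotype
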