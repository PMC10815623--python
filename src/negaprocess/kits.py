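"""STR kit configuration: dye set, internal lane standard, read region, marker bins.

A capillary-electrophoresis STR kit multiplexes markers over several
fluorescent dye channels; one extra channel carries the internal lane
standard (ILS), a fragment ladder co-injected for size calibration.  The
kit configuration records everything the pipeline needs to interpret a
sizing table: which dye labels are legal, which one is the ILS, the
manufacturer-recommended read region, the ILS fragment sizes, and the
marker geometry (size interval per marker plus allele bin centers with
+/-0.5 bp bins).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .errors import FormatError, ValidationError

#: half-width of an allele bin in base pairs; a peak belongs to a bin when
#: its size lies within this distance of the bin center.
BIN_HALF_WIDTH_BP = 0.5


@dataclass(frozen=True)
class Marker:
    """One STR marker: its dye, size interval and allele bins.

    ``bins`` maps allele labels (e.g. ``"12"``, ``"9.3"``) to bin center
    sizes in base pairs.  ``repeat_unit`` is the repeat length in bp, used
    to place stutter one repeat below an allele.
    """

    name: str
    dye: str
    size_min: float
    size_max: float
    repeat_unit: float = 4.0
    bins: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.size_min < self.size_max:
            raise ValidationError(
                f"marker {self.name}: size_min must be < size_max "
                f"({self.size_min} >= {self.size_max})"
            )
        if self.repeat_unit <= 0:
            raise ValidationError(f"marker {self.name}: repeat_unit must be positive")

    def contains(self, size_bp: float) -> bool:
        """Closed-interval membership test in physical bp coordinates."""
        return self.size_min <= size_bp <= self.size_max

    def bin_for(self, size_bp: float, half_width: float = BIN_HALF_WIDTH_BP) -> str | None:
        """Return the label of the nearest allele bin within ``half_width`` bp, or None."""
        best_label: str | None = None
        best_dist = half_width
        for label, center in self.bins.items():
            dist = abs(size_bp - center)
            if dist <= best_dist:
                best_label, best_dist = label, dist
        return best_label


@dataclass(frozen=True)
class KitConfig:
    """Configuration of one STR kit.

    ``dyes`` is ordered and the last entry is the ILS dye; the remaining
    entries are the analysis dyes.  ``read_region`` is a closed interval in
    bp.  ``ils_fragments`` may be empty for ad-hoc kits inferred from a
    sizing table (the ILS-proximity filter then cannot run).
    """

    kit_name: str
    dyes: tuple[str, ...]
    read_region: tuple[float, float]
    ils_fragments: tuple[float, ...] = ()
    markers: tuple[Marker, ...] = ()

    def __post_init__(self) -> None:
        if len(self.dyes) < 2:
            raise ValidationError("a kit needs at least one analysis dye plus the ILS dye")
        if len(set(self.dyes)) != len(self.dyes):
            raise ValidationError("duplicate dye labels in kit configuration")
        lo, hi = self.read_region
        if not lo < hi:
            raise ValidationError(f"read region must satisfy min < max, got [{lo}, {hi}]")
        for m in self.markers:
            if m.dye not in self.analysis_dyes:
                raise ValidationError(
                    f"marker {m.name} assigned to dye {m.dye!r} which is not an analysis dye"
                )
        self._check_marker_overlap()

    def _check_marker_overlap(self) -> None:
        by_dye: dict[str, list[Marker]] = {}
        for m in self.markers:
            by_dye.setdefault(m.dye, []).append(m)
        for dye, markers in by_dye.items():
            markers = sorted(markers, key=lambda m: m.size_min)
            for prev, nxt in zip(markers, markers[1:]):
                if nxt.size_min <= prev.size_max:
                    raise ValidationError(
                        f"overlapping marker intervals on dye {dye}: "
                        f"{prev.name} [{prev.size_min},{prev.size_max}] and "
                        f"{nxt.name} [{nxt.size_min},{nxt.size_max}]"
                    )

    @property
    def n_channels(self) -> int:
        """Number of fluorescence channels including the ILS channel."""
        return len(self.dyes)

    @property
    def ils_dye(self) -> str:
        return self.dyes[-1]

    @property
    def analysis_dyes(self) -> tuple[str, ...]:
        return self.dyes[:-1]

    def markers_on(self, dye: str) -> tuple[Marker, ...]:
        return tuple(m for m in self.markers if m.dye == dye)

    def marker_by_name(self, name: str) -> Marker:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def marker_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.markers)

    def locate(self, dye: str, size_bp: float) -> Marker | None:
        """Return the marker on ``dye`` whose interval contains ``size_bp``, if any."""
        for m in self.markers_on(dye):
            if m.contains(size_bp):
                return m
        return None


def load_kit_config(source: str | Path) -> KitConfig:
    """Load a kit configuration from a YAML file (or YAML text).

    Expected layout::

        kit_name: SynthFiler6
        dyes: [B, G, Y, R, P, LIZ]     # last entry = ILS dye
        read_region: [80, 480]
        ils_fragments: [80, 100, ...]
        markers:
          - name: M_B1
            dye: B
            range: [100, 140]
            repeat_unit: 4
            bins: {"8": 102.0, "9": 106.0}

    Raises :class:`FormatError` for missing keys and :class:`ValidationError`
    when the loaded values violate a kit invariant (e.g. overlapping marker
    intervals on one dye).
    """
    path = Path(source)
    if path.exists():
        text = path.read_text()
    else:
        text = str(source)
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - malformed YAML
        raise FormatError(f"kit configuration is not valid YAML: {exc}") from exc
    if not isinstance(data, dict):
        raise FormatError("kit configuration must be a mapping")

    for key in ("kit_name", "dyes", "read_region", "ils_fragments"):
        if key not in data:
            raise FormatError(f"kit configuration missing required key {key!r}")

    markers = []
    for entry in data.get("markers", []) or []:
        for key in ("name", "dye", "range"):
            if key not in entry:
                raise FormatError(f"marker entry missing required key {key!r}: {entry}")
        lo, hi = entry["range"]
        bins = {str(k): float(v) for k, v in (entry.get("bins") or {}).items()}
        markers.append(
            Marker(
                name=str(entry["name"]),
                dye=str(entry["dye"]),
                size_min=float(lo),
                size_max=float(hi),
                repeat_unit=float(entry.get("repeat_unit", 4.0)),
                bins=bins,
            )
        )

    lo, hi = data["read_region"]
    return KitConfig(
        kit_name=str(data["kit_name"]),
        dyes=tuple(str(d) for d in data["dyes"]),
        read_region=(float(lo), float(hi)),
        ils_fragments=tuple(float(f) for f in data["ils_fragments"]),
        markers=tuple(markers),
    )


def write_kit_config(kit: KitConfig, path: str | Path) -> None:
    """Serialize a kit configuration to the YAML layout read by :func:`load_kit_config`."""
    data = {
        "kit_name": kit.kit_name,
        "dyes": list(kit.dyes),
        "read_region": list(kit.read_region),
        "ils_fragments": list(kit.ils_fragments),
        "markers": [
            {
                "name": m.name,
                "dye": m.dye,
                "range": [m.size_min, m.size_max],
                "repeat_unit": m.repeat_unit,
                "bins": {k: float(v) for k, v in m.bins.items()},
            }
            for m in kit.markers
        ],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
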