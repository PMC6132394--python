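"""Toxic-equivalent (TEQ) aggregation of censored congener panels.

A panel of dioxin, furan and dioxin-like PCB concentrations is collapsed to
a single WHO-TEQ value by weighting each congener with its toxic equivalency
factor (TEF, potency relative to 2,3,7,8-TCDD) and summing.  Congeners at or
below the limit of quantification enter at their LOQ (upper bound), LOQ/2
(middle bound) or zero (lower bound); regulatory practice is upper bound.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

from .errors import LookupError_, ValidationError

BOUNDS = ("upper", "middle", "lower")

#: congener classes making up the regulatory sub-sums
PCDDF_CLASSES = frozenset({"dioxin", "furan"})
ALL_CLASSES = frozenset({"dioxin", "furan", "dl-pcb"})


@dataclass(frozen=True)
class CongenerMeasurement:
    """One congener concentration (pg/g ww); if censored, value is the LOQ."""

    congener_id: str
    value: float
    censored: bool = False

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValidationError(f"negative concentration for {self.congener_id}")


class TEFTable:
    """Mapping congener id -> (TEF weight, congener class) with provenance."""

    def __init__(self, congeners: dict[str, dict], provenance: str = "custom"):
        for cid, entry in congeners.items():
            if entry["tef"] <= 0:
                raise ValidationError(f"TEF for {cid} must be > 0, got {entry['tef']}")
        self._table = {cid: (float(e["tef"]), e.get("class", "dioxin")) for cid, e in congeners.items()}
        self.provenance = provenance

    @classmethod
    def who2005(cls) -> "TEFTable":
        """The bundled WHO-2005 table (29 congeners)."""
        raw = json.loads(
            resources.files("d9assess.data").joinpath("tef_who2005.json").read_text("utf-8")
        )
        return cls(raw["congeners"], provenance=raw["provenance"])

    @classmethod
    def from_json(cls, path) -> "TEFTable":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        return cls(raw["congeners"], provenance=raw.get("provenance", str(path)))

    def __contains__(self, congener_id: str) -> bool:
        return congener_id in self._table

    def __len__(self) -> int:
        return len(self._table)

    def tef(self, congener_id: str) -> float:
        try:
            return self._table[congener_id][0]
        except KeyError:
            raise LookupError_(f"congener {congener_id!r} not in TEF table {self.provenance!r}")

    def congener_class(self, congener_id: str) -> str:
        try:
            return self._table[congener_id][1]
        except KeyError:
            raise LookupError_(f"congener {congener_id!r} not in TEF table {self.provenance!r}")

    def congener_ids(self, classes: Optional[Iterable[str]] = None) -> list[str]:
        if classes is None:
            return list(self._table)
        cs = set(classes)
        return [cid for cid, (_, c) in self._table.items() if c in cs]


def _bounded_value(m: CongenerMeasurement, bound: str) -> float:
    if not m.censored:
        return m.value
    if bound == "upper":
        return m.value
    if bound == "middle":
        return m.value / 2.0
    if bound == "lower":
        return 0.0
    raise ValueError(f"bound must be one of {BOUNDS}, got {bound!r}")


def compute_teq(
    panel: Sequence[CongenerMeasurement],
    tefs: TEFTable,
    bound: str = "upper",
    classes: Optional[Iterable[str]] = None,
) -> float:
    """TEQ = sum_i TEF_i x c_i over the panel (pg/g WHO-TEQ).

    Censored congeners contribute LOQ / LOQ/2 / 0 under the upper / middle /
    lower bound convention.  ``classes`` restricts the sum to a congener
    class subset, e.g. ``PCDDF_CLASSES`` for the dioxin+furan-only TEQ that
    food regulation limits separately from the full PCDD/F + dl-PCB TEQ.
    """
    if bound not in BOUNDS:
        raise ValueError(f"bound must be one of {BOUNDS}, got {bound!r}")
    if not panel:
        raise ValidationError("empty congener panel")
    class_filter = None if classes is None else set(classes)
    total = 0.0
    for m in panel:
        tef = tefs.tef(m.congener_id)  # raises LookupError_ naming the congener
        if class_filter is not None and tefs.congener_class(m.congener_id) not in class_filter:
            continue
        total += tef * _bounded_value(m, bound)
    return total
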