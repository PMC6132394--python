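"""Registry of regulatory reference values and compliance comparison.

Four kinds of reference value coexist: food maximum levels (ML, legally
binding under food regulation), Water Framework Directive biota
environmental quality standards (EQS), OSPAR environmental assessment
criteria (EAC) and national quality standards.  A value complies when its
ratio to the threshold on a common basis is at most 1; exceedance requires a
ratio strictly above 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .conversions import BasisContext, threshold_dw_to_ww, wet_to_dry
from .datamodel import unit_factor
from .errors import AmbiguityError, LookupError_, ValidationError

KINDS = ("ML", "EQS", "EAC", "national_QS")
STATUSES = ("compliant", "exceedance", "not_assessable")


@dataclass(frozen=True)
class ThresholdSpec:
    """One regulatory reference value with its basis and provenance."""

    analyte: str
    matrix_class: str
    value: float
    unit: str
    basis: str
    kind: str
    protection_goal: Optional[str] = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValidationError(f"threshold value must be > 0, got {self.value}")
        if self.basis not in ("wet", "dry"):
            raise ValidationError(f"threshold basis must be wet or dry, got {self.basis!r}")
        if self.kind not in KINDS:
            raise ValidationError(f"threshold kind must be one of {KINDS}, got {self.kind!r}")


@dataclass(frozen=True)
class ComplianceFlag:
    """Outcome of one value-vs-threshold comparison.

    ``ratio`` is value/threshold after reconciliation to a common basis and
    unit; ``basis_note`` records every conversion applied so the comparison
    can be audited or replayed.
    """

    status: str
    ratio: Optional[float]
    basis_note: str = ""


class ThresholdRegistry:
    """Queryable collection of :class:`ThresholdSpec` entries."""

    def __init__(self, specs: list[ThresholdSpec]):
        self.specs = list(specs)

    @classmethod
    def default(cls) -> "ThresholdRegistry":
        raw = json.loads(
            resources.files("d9assess.data").joinpath("thresholds_default.json").read_text("utf-8")
        )
        return cls([ThresholdSpec(**e) for e in raw["thresholds"]])

    @classmethod
    def from_json(cls, path) -> "ThresholdRegistry":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        return cls([ThresholdSpec(**e) for e in raw["thresholds"]])

    def lookup(
        self,
        analyte: str,
        matrix_class: str,
        kind: str,
        protection_goal: Optional[str] = None,
    ) -> ThresholdSpec:
        """Return the unique matching spec.

        ``protection_goal`` disambiguates analytes carrying several values
        of the same kind (e.g. an EQS for secondary poisoning alongside a
        human-health quality standard).
        """
        hits = [
            s
            for s in self.specs
            if s.analyte == analyte and s.matrix_class == matrix_class and s.kind == kind
        ]
        if protection_goal is not None:
            hits = [s for s in hits if s.protection_goal == protection_goal]
        if not hits:
            raise LookupError_(f"no threshold for ({analyte}, {matrix_class}, {kind})")
        if len(hits) > 1:
            raise AmbiguityError(
                f"{len(hits)} thresholds match ({analyte}, {matrix_class}, {kind}); "
                "pass protection_goal to disambiguate"
            )
        return hits[0]

    def applicable(self, analyte: str, matrix_class: str) -> list[ThresholdSpec]:
        """All registered thresholds for an analyte in a matrix class."""
        return [
            s for s in self.specs if s.analyte == analyte and s.matrix_class == matrix_class
        ]


def lookup_threshold(
    registry: ThresholdRegistry,
    analyte: str,
    matrix_class: str,
    kind: str,
    protection_goal: Optional[str] = None,
) -> ThresholdSpec:
    return registry.lookup(analyte, matrix_class, kind, protection_goal)


def check_compliance(
    value: float,
    unit: str,
    basis: str,
    spec: ThresholdSpec,
    context: Optional[BasisContext] = None,
) -> ComplianceFlag:
    """Compare a concentration with a threshold on a common basis.

    Unit differences are bridged by exact power-of-ten factors.  A basis
    mismatch (wet value vs dry threshold or vice versa) is bridged through
    the context's water fraction — the dry-weight threshold is expressed on
    the wet-weight scale of the data, mirroring assessment practice — and
    is recorded in ``basis_note``.  Without a usable water fraction the
    comparison is ``not_assessable``.
    """
    notes: list[str] = []
    try:
        uf = unit_factor(unit, spec.unit)
    except ValidationError as exc:
        return ComplianceFlag("not_assessable", None, f"unit not reconcilable: {exc}")
    v = value * uf
    if uf != 1.0:
        notes.append(f"value converted {unit} -> {spec.unit} (x{uf:g})")

    threshold = spec.value
    if basis != spec.basis:
        if basis == "lipid" or spec.basis == "lipid":
            return ComplianceFlag(
                "not_assessable", None, "lipid-basis comparison not supported"
            )
        w = context.water_fraction if context is not None else None
        if w is None:
            return ComplianceFlag(
                "not_assessable",
                None,
                f"basis mismatch ({basis} value vs {spec.basis} threshold) and no water fraction",
            )
        if basis == "wet" and spec.basis == "dry":
            threshold = threshold_dw_to_ww(spec.value, w)
            notes.append(
                f"threshold converted dry -> wet via water fraction {w:g}: "
                f"{spec.value:g} -> {threshold:g} {spec.unit}"
            )
        elif basis == "dry" and spec.basis == "wet":
            threshold = wet_to_dry(spec.value, w)
            notes.append(
                f"threshold converted wet -> dry via water fraction {w:g}: "
                f"{spec.value:g} -> {threshold:g} {spec.unit}"
            )

    ratio = v / threshold
    status = "exceedance" if ratio > 1.0 else "compliant"
    return ComplianceFlag(status, ratio, "; ".join(notes))
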