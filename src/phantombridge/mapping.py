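"""Port time-integrated activity between the CE and ICRP phantoms.

The CE (Cristy-Eckerman) stylized phantom and the ICRP voxel reference
phantoms partition the body differently; the most consequential difference
for activity bookkeeping is the large intestine, which the CE model splits
into upper/lower segments (ULI/LLI) while the ICRP model uses right colon,
left colon and rectosigmoid (RC/LC/RS). A time-integrated activity (TIA)
vector expressed in CE nomenclature is ported by pooling the CE regions of
each rule and apportioning the pooled activity over the corresponding ICRP
regions, either with the published mapping factors or with exact
mass-fraction weights recomputed from the registry masses.

The apportionment assumes activity is uniformly distributed over the pooled
CE volume; no heterogeneity option is provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .errors import (
    MappingError,
    PhantomMismatchError,
    UnknownRegionError,
    ValidationError,
)
from .regions import PhantomCatalog, load_catalog
from .units import TIA_UNITS

logger = logging.getLogger(__name__)

#: Tolerance on the sum of a rule's allocation factors.
FACTOR_SUM_TOL = 0.005

#: Published apportionment factors for the CE large intestine.
COLON_CONTENTS_FACTORS = (("RC-cont", 0.5), ("LC-cont", 0.25), ("RS-cont", 0.25))
COLON_WALL_FACTORS = (("RC-wall", 0.41), ("LC-wall", 0.41), ("RS-wall", 0.18))

BASES = ("printed_factor", "mass_fraction", "one_to_one", "alias")


@dataclass(frozen=True)
class TIAVector:
    """Time-integrated activity (or TIAC) keyed by region acronym.

    ``entries`` maps region names to nonnegative activities; keys are
    resolved against the phantom's catalog by :meth:`canonicalized` (and by
    every operation that consumes a vector).
    """

    phantom: str
    entries: dict[str, float]
    units: str = TIA_UNITS

    def __post_init__(self) -> None:
        for name, value in self.entries.items():
            if value < 0:
                raise ValidationError(f"negative TIA for {name!r}: {value}")

    def canonicalized(self, catalog: PhantomCatalog) -> "TIAVector":
        """Return a copy with keys replaced by registry acronyms.

        Entries sharing an acronym after resolution are summed. Raises
        :class:`UnknownRegionError` for keys absent from the catalog and
        :class:`PhantomMismatchError` if the catalog is for another phantom.
        """
        if catalog.phantom != self.phantom:
            raise PhantomMismatchError(
                f"vector tagged {self.phantom} but catalog is {catalog.phantom}"
            )
        out: dict[str, float] = {}
        for name, value in self.entries.items():
            acr = catalog.lookup(name).acronym
            out[acr] = out.get(acr, 0.0) + value
        return replace(self, entries=out)

    def total(self) -> float:
        return float(sum(self.entries.values()))

    def scaled(self, alpha: float) -> "TIAVector":
        if alpha < 0:
            raise ValidationError(f"scale factor must be nonnegative, got {alpha}")
        return replace(self, entries={k: alpha * v for k, v in self.entries.items()})

    def get(self, name: str, default: float = 0.0) -> float:
        return self.entries.get(name, default)


@dataclass(frozen=True)
class MappingRule:
    """One CE-region set and its allocation over ICRP regions.

    The CE regions are pooled (summed) before the allocation factors are
    applied, so a rule expresses "the combined activity of these CE regions
    is distributed over these ICRP regions with these weights".
    """

    ce_regions: tuple[str, ...]
    allocations: tuple[tuple[str, float], ...]
    basis: str
    note: str = ""
    review: bool = False  # flags allocations that need user judgement

    def __post_init__(self) -> None:
        if not self.ce_regions:
            raise ValidationError("rule must name at least one CE region")
        if self.basis not in BASES:
            raise ValidationError(f"unknown basis {self.basis!r}")
        if not self.allocations:
            raise ValidationError("rule must allocate to at least one ICRP region")
        for acr, f in self.allocations:
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"factor for {acr!r} out of [0, 1]: {f}")
        s = self.factor_sum()
        if abs(s - 1.0) > FACTOR_SUM_TOL:
            raise ValidationError(
                f"allocation factors for {self.ce_regions} sum to {s}, not 1"
            )

    def factor_sum(self) -> float:
        return float(sum(f for _, f in self.allocations))

    def factor(self, icrp_acronym: str) -> float:
        for acr, f in self.allocations:
            if acr == icrp_acronym:
                return f
        raise KeyError(icrp_acronym)


@dataclass(frozen=True)
class MappingTable:
    """Complete CE-to-ICRP correspondence: source rules plus target map."""

    rules: tuple[MappingRule, ...]
    target_correspondence: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rule in self.rules:
            for ce in rule.ce_regions:
                if ce in seen:
                    raise ValidationError(f"CE region {ce!r} appears in more than one rule")
                seen.add(ce)

    def rule_for(self, ce_acronym: str) -> MappingRule | None:
        for rule in self.rules:
            if ce_acronym in rule.ce_regions:
                return rule
        return None

    def target_for(self, ce_target: str, ce_catalog: PhantomCatalog | None = None) -> str:
        """ICRP target acronym corresponding to a CE target name."""
        key = ce_target
        if ce_catalog is not None:
            key = ce_catalog.lookup(ce_target).acronym
        try:
            return self.target_correspondence[key]
        except KeyError:
            raise UnknownRegionError(ce_target, "CE target correspondence") from None


def mass_fraction_factors(
    icrp_acronyms: list[str], catalog: PhantomCatalog
) -> list[tuple[str, float]]:
    """Apportionment weights proportional to registry masses.

    ``factor_i = m_i / sum_j m_j``; the last factor is set by complement so
    the weights sum to exactly 1. Raises :class:`UnknownMassError` naming
    the offending region when a mass is not recorded.
    """
    if not icrp_acronyms:
        raise ValidationError("need at least one region to apportion over")
    masses = [catalog.lookup(a).mass for a in icrp_acronyms]
    total = sum(masses)
    factors = [m / total for m in masses]
    factors[-1] = 1.0 - sum(factors[:-1])
    return [(catalog.lookup(a).acronym, f) for a, f in zip(icrp_acronyms, factors)]


_ONE_TO_ONE = (
    ("Spleen", "Spleen"),
    ("Thymus", "Thymus"),
    ("Thyroid", "Thyroid"),
    ("Ovaries", "Ovaries"),
    ("Testes", "Testes"),
    ("Uterus", "Uterus"),
    ("Brain", "Brain"),
    ("Breasts", "Breast"),
    ("Ht-wall", "Ht-wall"),
    ("Kidneys", "Kidneys"),
    ("Pancreas", "Pancreas"),
    ("Liver", "Liver"),
    ("GB-cont", "GB-cont"),
    ("Adrenals", "Adrenals"),
    ("ST-cont", "ST-cont"),
    ("ST-wall", "ST-wall"),
    ("UB-wall", "UB-wall"),
    ("A-marrow", "R-marrow"),
    ("UB-cont", "UB-cont"),
)

_TARGET_CORRESPONDENCE = {
    # lung fibrosis and other deterministic endpoints are scored on the
    # parenchyma, so the CE whole-lung target maps to ICRP lung tissue
    "Lungs": "Lung-tis",
    # the bone-cancer target moved from the CE 10-um osteogenic layer to the
    # ICRP 50-um endosteal marrow layer
    "Osteo-cells": "Endosteum",
    # CE whole-wall GI targets vs ICRP mucosal stem-cell layers; the two CE
    # large-intestine walls map to the anatomically closest single layer
    "ST-wall": "ST-stem",
    "SI": "SI-stem",
    "ULI-wall": "RC-stem",
    "LLI-wall": "LC-stem",
    "Brain": "Brain",
    "Ht-wall": "Ht-wall",
    "Kidneys": "Kidneys",
    "Liver": "Liver",
    "Ovaries": "Ovaries",
    "Pancreas": "Pancreas",
    "A-marrow": "R-marrow",
    "Spleen": "Spleen",
    "Testes": "Testes",
    "Thyroid": "Thyroid",
    "UB-wall": "UB-wall",
    "Uterus": "Uterus",
}


def default_mapping(
    ce_catalog: PhantomCatalog | None = None,
    icrp_catalog: PhantomCatalog | None = None,
    recompute_factors: bool = False,
) -> MappingTable:
    """Build the canonical CE-to-ICRP mapping table.

    The colon rules carry the published factors (contents 0.5/0.25/0.25,
    walls 0.41/0.41/0.18). The published wall triple is kept as-is even
    though the exact mass fractions are 0.4054/0.4054/0.1892 (the published
    values round the last entry down so the triple sums to 1.00); passing
    ``recompute_factors=True`` substitutes the exact mass fractions for both
    colon rules.

    The residual-soft-tissue (RST) rule always uses mass fractions over the
    registry muscle and adipose masses. Aliases that need user judgement
    (CE heart contents -> total blood; CE small intestine -> SI contents)
    are flagged ``review=True``.
    """
    ce_catalog = ce_catalog or load_catalog("CE")
    icrp_catalog = icrp_catalog or load_catalog("ICRP")

    if recompute_factors:
        cont = tuple(mass_fraction_factors(["RC-cont", "LC-cont", "RS-cont"], icrp_catalog))
        wall = tuple(mass_fraction_factors(["RC-wall", "LC-wall", "RS-wall"], icrp_catalog))
        colon_basis = "mass_fraction"
    else:
        cont, wall = COLON_CONTENTS_FACTORS, COLON_WALL_FACTORS
        colon_basis = "printed_factor"

    rules = [
        MappingRule(("ULI-cont", "LLI-cont"), cont, colon_basis,
                    note="pooled large-intestine contents apportioned over ICRP colon"),
        MappingRule(("ULI-wall", "LLI-wall"), wall, colon_basis,
                    note="pooled large-intestine walls apportioned over ICRP colon"),
        MappingRule(("Lungs",), (("Lungs", 1.0),), "alias",
                    note="overlap alternatives: Lung-tis, AI (same tissue volume)"),
        MappingRule(("Ht-cont",), (("Blood", 1.0),), "alias", review=True,
                    note="ICRP has no heart-contents source; assigned to total "
                         "blood unscaled - review whether scaling is appropriate"),
        MappingRule(("SI",), (("SI-cont", 1.0),), "alias", review=True,
                    note="CE small intestine has no wall/contents separation"),
        MappingRule(
            ("RST",),
            tuple(mass_fraction_factors(["Muscle", "Adipose"], icrp_catalog)),
            "mass_fraction",
            note="residual soft tissue split over muscle and adipose by mass",
        ),
    ]
    rules += [
        MappingRule((ce,), ((icrp, 1.0),), "one_to_one")
        for ce, icrp in _ONE_TO_ONE
    ]
    # every rule must reference real regions in both registries
    for rule in rules:
        for ce in rule.ce_regions:
            ce_catalog.lookup(ce)
        for acr, _ in rule.allocations:
            icrp_catalog.lookup(acr)
    return MappingTable(tuple(rules), dict(_TARGET_CORRESPONDENCE))


def port_tia(
    tia: TIAVector,
    table: MappingTable | None = None,
    policy: str = "strict",
    ce_catalog: PhantomCatalog | None = None,
    icrp_catalog: PhantomCatalog | None = None,
) -> TIAVector:
    """Re-express a CE-phantom TIA vector in ICRP nomenclature.

    For each rule whose CE regions appear in the input, the pooled activity
    is multiplied by each allocation factor and accumulated on the ICRP
    region. Because every rule's factors sum to 1 (within ±0.005), the
    output total matches the input total to the same tolerance.

    Parameters
    ----------
    policy : {"strict", "passthrough"}
        ``strict`` raises on CE entries no rule covers; ``passthrough``
        copies them unchanged with a warning.
    """
    if tia.phantom != "CE":
        raise PhantomMismatchError(
            f"port_tia expects a CE-tagged vector, got {tia.phantom!r}; "
            "porting is one-way and not idempotent"
        )
    if policy not in ("strict", "passthrough"):
        raise ValueError(f"policy must be 'strict' or 'passthrough', got {policy!r}")
    ce_catalog = ce_catalog or load_catalog("CE")
    icrp_catalog = icrp_catalog or load_catalog("ICRP")
    table = table or default_mapping(ce_catalog, icrp_catalog)

    vec = tia.canonicalized(ce_catalog)
    out: dict[str, float] = {}
    unmapped: list[str] = []
    done: set[str] = set()
    for acr in vec.entries:
        if acr in done:
            continue
        rule = table.rule_for(acr)
        if rule is None:
            unmapped.append(acr)
            continue
        pooled = sum(vec.entries.get(ce, 0.0) for ce in rule.ce_regions)
        done.update(rule.ce_regions)
        if rule.review:
            logger.warning(
                "rule %s -> %s is flagged for review: %s",
                rule.ce_regions, [a for a, _ in rule.allocations], rule.note,
            )
        for icrp_acr, factor in rule.allocations:
            out[icrp_acr] = out.get(icrp_acr, 0.0) + pooled * factor
    if unmapped:
        if policy == "strict":
            raise MappingError(
                "no mapping rule for CE region(s): " + ", ".join(sorted(unmapped))
            )
        for acr in sorted(unmapped):
            logger.warning("no rule for CE region %r; copied unchanged", acr)
            out[acr] = out.get(acr, 0.0) + vec.entries[acr]
    return TIAVector(phantom="ICRP", entries=out, units=tia.units)
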