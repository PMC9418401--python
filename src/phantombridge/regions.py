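"""Region registries for the Cristy-Eckerman and ICRP adult phantoms.

Each phantom ships as a bundled, versioned plain-text registry
(``data/<phantom>_regions.csv``) listing every source and target region with
its acronym, canonical name, role, mass (where recorded), anatomical system
and flags. The registries are the single source of truth for region names:
every other module resolves user input through :func:`load_catalog` /
:meth:`PhantomCatalog.lookup`.

Naming follows the ICRP convention of short hyphenated acronyms
(``RC-cont`` = right colon contents, ``Lung-tis`` = lung tissue, ...);
lookups are case-insensitive and tolerate hyphen/space variants.
"""

from __future__ import annotations

import csv
import difflib
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator

from .errors import AmbiguousNameError, RegistryError, UnknownMassError, UnknownRegionError

PHANTOMS = ("CE", "ICRP")
ROLES = ("source", "target", "both")
SYSTEMS = ("respiratory", "alimentary", "skeletal", "other")
FLAGS = ("other_tissue_source", "overlap_member", "contents", "wall", "stem_cell_layer")

#: Expected region counts per phantom: (n_source, n_target).
EXPECTED_COUNTS = {"ICRP": (79, 43), "CE": (23, 18)}

#: Sets of ICRP source acronyms that denote the same tissue volume. The three
#: lung entries coincide geometrically (lung tissue = lungs minus the
#: pulmonary blood pool; the alveolar-interstitium is the gas-exchange
#: subregion) and differ only for biokinetic bookkeeping.
ICRP_OVERLAP_GROUPS: tuple[frozenset[str], ...] = (
    frozenset({"Lungs", "Lung-tis", "AI"}),
)


def _norm(name: str) -> str:
    """Normalization key: lower case, collapsed whitespace, hyphens unified."""
    s = re.sub(r"\s+", " ", name.strip().lower())
    return s.replace("-", " ")


@dataclass(frozen=True)
class Region:
    """One named compartment of a phantom.

    Parameters
    ----------
    phantom : {"CE", "ICRP"}
    acronym : str
        Short unique identifier within the phantom (e.g. ``"RC-cont"``).
    canonical_name : str
        Full descriptive name (e.g. ``"Right colon (contents)"``).
    role : {"source", "target", "both"}
        Whether decays are scored in it, dose is scored to it, or both.
    mass_g : float or None
        Reference mass in grams; ``None`` when the registry does not record it.
    system : {"respiratory", "alimentary", "skeletal", "other"}
    flags : frozenset of str
        Structural markers; see :data:`FLAGS`.
    """

    phantom: str
    acronym: str
    canonical_name: str
    role: str
    mass_g: float | None
    system: str
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.phantom not in PHANTOMS:
            raise RegistryError(f"invalid phantom {self.phantom!r} for {self.acronym!r}")
        if self.role not in ROLES:
            raise RegistryError(f"invalid role {self.role!r} for {self.acronym!r}")
        if self.system not in SYSTEMS:
            raise RegistryError(f"invalid system {self.system!r} for {self.acronym!r}")
        unknown = self.flags - set(FLAGS)
        if unknown:
            raise RegistryError(f"unknown flags {sorted(unknown)} on {self.acronym!r}")
        if self.mass_g is not None and not self.mass_g > 0:
            raise RegistryError(f"mass must be positive for {self.acronym!r}, got {self.mass_g}")
        if {"contents", "wall"} <= self.flags:
            raise RegistryError(f"{self.acronym!r} cannot be both contents and wall")

    def is_source(self) -> bool:
        return self.role in ("source", "both")

    def is_target(self) -> bool:
        return self.role in ("target", "both")

    @property
    def mass(self) -> float:
        """Mass in grams; raises :class:`UnknownMassError` if not recorded."""
        if self.mass_g is None:
            raise UnknownMassError(
                f"no mass recorded for {self.phantom} region {self.acronym!r}"
            )
        return self.mass_g


class PhantomCatalog:
    """Immutable collection of the regions of one phantom."""

    def __init__(
        self,
        phantom: str,
        regions: Iterable[Region],
        overlap_groups: Iterable[frozenset[str]] = (),
    ):
        self.phantom = phantom
        self.regions: tuple[Region, ...] = tuple(regions)
        self.overlap_groups: tuple[frozenset[str], ...] = tuple(overlap_groups)
        self._by_acronym: dict[str, Region] = {}
        self._by_name: dict[str, list[Region]] = {}
        for r in self.regions:
            if r.phantom != phantom:
                raise RegistryError(f"{r.acronym!r} tagged {r.phantom}, expected {phantom}")
            key = _norm(r.acronym)
            if key in self._by_acronym:
                raise RegistryError(f"duplicate acronym {r.acronym!r} in {phantom} registry")
            self._by_acronym[key] = r
            self._by_name.setdefault(_norm(r.canonical_name), []).append(r)
        for group in self.overlap_groups:
            for acr in group:
                if _norm(acr) not in self._by_acronym:
                    raise RegistryError(
                        f"overlap group member {acr!r} not in {phantom} registry"
                    )

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __contains__(self, name: str) -> bool:
        try:
            self.lookup(name)
            return True
        except (UnknownRegionError, AmbiguousNameError):
            return False

    def lookup(self, name: str) -> Region:
        """Resolve an acronym or canonical name to its :class:`Region`.

        Matching is case-insensitive after whitespace normalization; hyphen
        and space variants are treated as equal. Acronyms take precedence
        over canonical names.
        """
        key = _norm(name)
        if key in self._by_acronym:
            return self._by_acronym[key]
        matches = self._by_name.get(key, [])
        if len(matches) == 1:
            return matches[0]
        if len(matches) > 1:
            acrs = ", ".join(r.acronym for r in matches)
            raise AmbiguousNameError(
                f"name {name!r} matches several {self.phantom} regions: {acrs}"
            )
        universe = list(self._by_acronym) + list(self._by_name)
        near = difflib.get_close_matches(key, universe, n=3, cutoff=0.6)
        suggestions = sorted({self._suggestion_label(k) for k in near})
        raise UnknownRegionError(name, self.phantom, suggestions)

    def _suggestion_label(self, key: str) -> str:
        if key in self._by_acronym:
            return self._by_acronym[key].acronym
        return self._by_name[key][0].acronym

    def count(self, role: str) -> int:
        """Number of regions usable in ``role`` (``both`` counts for either)."""
        if role == "source":
            return sum(r.is_source() for r in self.regions)
        if role == "target":
            return sum(r.is_target() for r in self.regions)
        raise ValueError(f"role must be 'source' or 'target', got {role!r}")

    def sources(self) -> tuple[Region, ...]:
        return tuple(r for r in self.regions if r.is_source())

    def targets(self) -> tuple[Region, ...]:
        return tuple(r for r in self.regions if r.is_target())

    def with_flag(self, flag: str) -> tuple[Region, ...]:
        if flag not in FLAGS:
            raise ValueError(f"unknown flag {flag!r}")
        return tuple(r for r in self.regions if flag in r.flags)

    def mass(self, name: str) -> float:
        return self.lookup(name).mass


def _parse_registry(rows: Iterable[dict], origin: str) -> list[Region]:
    regions = []
    for row in rows:
        try:
            mass_raw = (row.get("mass_g") or "").strip()
            flags_raw = (row.get("flags") or "").strip()
            flags = frozenset(f.strip() for f in flags_raw.split(";") if f.strip())
            regions.append(
                Region(
                    phantom=row["phantom"].strip(),
                    acronym=row["acronym"].strip(),
                    canonical_name=row["canonical_name"].strip(),
                    role=row["role"].strip(),
                    mass_g=float(mass_raw) if mass_raw else None,
                    system=row["system"].strip(),
                    flags=flags,
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise RegistryError(f"corrupted registry {origin}: {exc}") from exc
    return regions


def load_catalog(phantom: str, validate_counts: bool = True) -> PhantomCatalog:
    """Load the bundled registry for ``phantom`` ("CE" or "ICRP").

    The loaded catalog is validated against the expected region counts
    (ICRP: 79 source / 43 target; CE: 23 source / 18 target) so that a
    corrupted data file fails loudly rather than producing silently wrong
    apportionments downstream.
    """
    if phantom not in PHANTOMS:
        raise ValueError(f"phantom must be one of {PHANTOMS}, got {phantom!r}")
    fname = f"{phantom.lower()}_regions.csv"
    ref = resources.files("phantombridge.data").joinpath(fname)
    try:
        text = ref.read_text(encoding="utf-8")
    except OSError as exc:
        raise RegistryError(f"cannot read bundled registry {fname}: {exc}") from exc
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    reader = csv.DictReader(lines)
    regions = _parse_registry(reader, fname)
    groups = ICRP_OVERLAP_GROUPS if phantom == "ICRP" else ()
    catalog = PhantomCatalog(phantom, regions, overlap_groups=groups)
    if validate_counts:
        n_src, n_tgt = catalog.count("source"), catalog.count("target")
        exp = EXPECTED_COUNTS[phantom]
        if (n_src, n_tgt) != exp:
            raise RegistryError(
                f"registry {fname} has {n_src} source / {n_tgt} target regions, "
                f"expected {exp[0]}/{exp[1]}"
            )
    return catalog


def lookup(catalog: PhantomCatalog, name: str) -> Region:
    """Functional alias for :meth:`PhantomCatalog.lookup`."""
    return catalog.lookup(name)


def count_regions(catalog: PhantomCatalog, role: str) -> int:
    """Functional alias for :meth:`PhantomCatalog.count`."""
    return catalog.count(role)
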