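"""Simultaneous-use restrictions on ICRP source regions.

Several ICRP source regions describe the same tissue at different levels of
biokinetic detail (lungs vs lung tissue vs alveolar-interstitium, GI walls
vs their mucosae, marrow compartments). Assigning activity to two
overlapping sources in one calculation double-counts decays, so such pairs
are *prohibited*; other pairs (volume/surface sources of one structure) are
merely *unusual* because both being measured, rather than modeled, is
implausible. The pair list ships as bundled data and is validated against
the ICRP registry at load time.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .errors import PhantomMismatchError, RegistryError
from .mapping import TIAVector
from .regions import PhantomCatalog, load_catalog

SEVERITIES = ("prohibited", "unusual")


@dataclass(frozen=True)
class ConstraintPair:
    """An ordered pair of ICRP source acronyms that should not be co-used."""

    a: str
    b: str
    severity: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise RegistryError(f"constraint pair with identical members: {self.a!r}")
        if self.severity not in SEVERITIES:
            raise RegistryError(f"unknown severity {self.severity!r} for ({self.a}, {self.b})")


@dataclass(frozen=True)
class Violation:
    """A constrained pair found co-positive in a TIA vector."""

    pair: ConstraintPair
    values: tuple[float, float]

    def __post_init__(self) -> None:
        if not (self.values[0] > 0 and self.values[1] > 0):
            raise RegistryError("violation requires both values positive")

    @property
    def severity(self) -> str:
        return self.pair.severity

    def __str__(self) -> str:
        return (
            f"{self.pair.severity}: {self.pair.a}={self.values[0]:g} together with "
            f"{self.pair.b}={self.values[1]:g} ({self.pair.note})"
        )


def constraint_list(catalog: PhantomCatalog | None = None) -> list[ConstraintPair]:
    """Load the bundled pair list, acronyms canonicalized via the registry."""
    catalog = catalog or load_catalog("ICRP")
    ref = resources.files("phantombridge.data").joinpath("icrp_source_constraints.csv")
    lines = [
        ln
        for ln in ref.read_text(encoding="utf-8").splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    pairs = []
    for row in csv.DictReader(lines):
        pairs.append(
            ConstraintPair(
                a=catalog.lookup(row["a"]).acronym,
                b=catalog.lookup(row["b"]).acronym,
                severity=row["severity"].strip(),
                note=(row.get("note") or "").strip(),
            )
        )
    return pairs


def check(
    tia: TIAVector,
    pairs: list[ConstraintPair] | None = None,
    catalog: PhantomCatalog | None = None,
) -> list[Violation]:
    """Return one :class:`Violation` per constrained pair co-positive in ``tia``.

    Zero-valued entries never violate: only pairs in which *both* regions
    carry activity overlap in practice. The result is independent of the
    ordering of the input entries.
    """
    if tia.phantom != "ICRP":
        raise PhantomMismatchError(
            f"usage constraints apply to ICRP vectors, got {tia.phantom!r}"
        )
    catalog = catalog or load_catalog("ICRP")
    pairs = pairs if pairs is not None else constraint_list(catalog)
    vec = tia.canonicalized(catalog)
    violations = []
    for pair in pairs:
        va = vec.get(pair.a)
        vb = vec.get(pair.b)
        if va > 0 and vb > 0:
            violations.append(Violation(pair=pair, values=(va, vb)))
    return violations
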