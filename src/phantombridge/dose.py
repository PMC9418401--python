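"""MIRD-schema S values and absorbed doses.

The absorbed dose to a target region t is

    D(t) = sum_s  A~(s) * S(t <- s),
    S(t <- s) = k * sum_i E_i * Y_i * Phi(t <- s; E_i),

where ``A~`` is the time-integrated activity in source s, the sum over i
runs over the radionuclide's emission lines (energy ``E_i`` in MeV, yield
``Y_i`` per decay), ``Phi`` is the specific absorbed fraction in g^-1 and
``k`` converts MeV/g per decay into the declared output units
(mGy per MBq*s here; see :mod:`phantombridge.units`).

Two SAF providers are supported:

* :class:`SAFMatrix` - tabulated ``Phi(target <- source; E)`` per emission
  type on an energy grid, interpolated log-log between nodes;
* :class:`LegacySAF` - the historical stylized-phantom convention for
  non-penetrating emissions (electrons and alphas): the self-absorbed
  fraction is 1 (``Phi = 1/m_target``), the cross-organ fraction is 0, and a
  wall receives 0.5 times the self-irradiation absorbed fraction of its own
  contents (``Phi = 0.5/m_contents``). Photons have no legacy rule - their
  absorbed fractions were phantom-specific transport results - so photon
  lines always require a supplied matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DoseError, PhantomMismatchError, ValidationError
from .mapping import TIAVector
from .regions import PhantomCatalog, Region
from .units import DOSE_UNITS, S_VALUE_MGY_PER_MBQ_S, S_VALUE_UNITS

ETYPES = ("photon", "electron", "alpha")
NON_PENETRATING = ("electron", "alpha")


@dataclass(frozen=True)
class EmissionLine:
    etype: str
    energy_MeV: float
    yield_per_decay: float

    def __post_init__(self) -> None:
        if self.etype not in ETYPES:
            raise ValidationError(f"unknown emission type {self.etype!r}")
        if not self.energy_MeV > 0:
            raise ValidationError(f"emission energy must be positive, got {self.energy_MeV}")
        if self.yield_per_decay < 0:
            raise ValidationError(f"yield must be nonnegative, got {self.yield_per_decay}")


@dataclass(frozen=True)
class EmissionSpectrum:
    """A radionuclide's emission lines; may be empty (zero dose)."""

    lines: tuple[EmissionLine, ...] = ()
    name: str = ""

    @classmethod
    def from_rows(cls, rows, name: str = "") -> "EmissionSpectrum":
        return cls(tuple(EmissionLine(t, float(e), float(y)) for t, e, y in rows), name)

    def scaled_yields(self, alpha: float) -> "EmissionSpectrum":
        return EmissionSpectrum(
            tuple(
                EmissionLine(l.etype, l.energy_MeV, alpha * l.yield_per_decay)
                for l in self.lines
            ),
            self.name,
        )


def _loglog_interp(energy: float, grid: np.ndarray, values: np.ndarray) -> float:
    """Log-log linear interpolation, exact at nodes, no extrapolation."""
    if energy < grid[0] or energy > grid[-1]:
        raise DoseError(
            f"energy {energy} MeV outside tabulated grid "
            f"[{grid[0]}, {grid[-1]}]; extrapolation is not supported"
        )
    idx = int(np.searchsorted(grid, energy))
    if idx < len(grid) and grid[idx] == energy:
        return float(values[idx])
    lo, hi = idx - 1, idx
    v0, v1 = values[lo], values[hi]
    if v0 <= 0.0 or v1 <= 0.0:
        # log-log undefined at zero; fall back to linear on this segment
        t = (energy - grid[lo]) / (grid[hi] - grid[lo])
        return float(v0 + t * (v1 - v0))
    t = (np.log(energy) - np.log(grid[lo])) / (np.log(grid[hi]) - np.log(grid[lo]))
    return float(np.exp(np.log(v0) + t * (np.log(v1) - np.log(v0))))


class SAFMatrix:
    """Tabulated specific absorbed fractions Phi(target <- source; E), g^-1."""

    def __init__(self, phantom: str | None = None):
        self.phantom = phantom
        self._tables: dict[tuple[str, str, str], tuple[np.ndarray, np.ndarray]] = {}

    def add(self, etype: str, target: str, source: str, energies_MeV, phi_per_g) -> None:
        if etype not in ETYPES:
            raise ValidationError(f"unknown emission type {etype!r}")
        grid = np.asarray(energies_MeV, dtype=float)
        phi = np.asarray(phi_per_g, dtype=float)
        if grid.ndim != 1 or grid.shape != phi.shape or grid.size == 0:
            raise ValidationError(f"grid/value shape mismatch for {target}<-{source}")
        if not np.all(np.diff(grid) > 0):
            raise ValidationError(f"energy grid not strictly increasing for {target}<-{source}")
        if np.any(phi < 0):
            raise ValidationError(f"negative SAF value for {target}<-{source}")
        self._tables[(etype, target, source)] = (grid, phi)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, phantom: str | None = None) -> "SAFMatrix":
        """Build from long-format records (etype, target, source, energy_MeV, phi_per_g)."""
        saf = cls(phantom)
        for (etype, target, source), grp in df.groupby(["etype", "target", "source"]):
            grp = grp.sort_values("energy_MeV")
            saf.add(etype, target, source, grp["energy_MeV"].to_numpy(), grp["phi_per_g"].to_numpy())
        saf.validate_self_terms()
        return saf

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (etype, target, source, e, p)
            for (etype, target, source), (grid, phi) in sorted(self._tables.items())
            for e, p in zip(grid, phi)
        ]
        return pd.DataFrame(rows, columns=["etype", "target", "source", "energy_MeV", "phi_per_g"])

    def validate_self_terms(self) -> None:
        """Every source that also appears as a target must have a self-term."""
        for etype in {k[0] for k in self._tables}:
            targets = {t for (e, t, _) in self._tables if e == etype}
            sources = {s for (e, _, s) in self._tables if e == etype}
            for s in sources & targets:
                if (etype, s, s) not in self._tables:
                    raise ValidationError(
                        f"missing {etype} self-term for region {s!r}"
                    )

    def has(self, etype: str, target: str, source: str) -> bool:
        return (etype, target, source) in self._tables

    def phi(self, etype: str, target: str, source: str, energy_MeV: float) -> float:
        try:
            grid, values = self._tables[(etype, target, source)]
        except KeyError:
            raise DoseError(
                f"no {etype} SAF tabulated for {target} <- {source}"
            ) from None
        return _loglog_interp(energy_MeV, grid, values)

    def targets(self) -> list[str]:
        return sorted({t for (_, t, _) in self._tables})

    def sources(self) -> list[str]:
        return sorted({s for (_, _, s) in self._tables})

    def __len__(self) -> int:
        return len(self._tables)


def _wall_contents_stem(acronym: str, suffix: str) -> str | None:
    low = acronym.lower()
    for sfx in (f"-{suffix}", f" {suffix}"):
        if low.endswith(sfx):
            return acronym[: -len(sfx)]
    return None


def legacy_saf(
    source: Region, target: Region, etype: str, catalog: PhantomCatalog
) -> float:
    """Legacy stylized-phantom SAF for non-penetrating emissions, g^-1.

    Self-irradiation: ``1/m_target``. A wall irradiated by its own contents:
    ``0.5/m_contents`` (half the contents' self-irradiation absorbed
    fraction). Every other source-target pair: 0. Requires the relevant
    masses to be recorded in the registry.
    """
    if etype == "photon":
        raise DoseError(
            "no legacy convention exists for photons; supply an SAF matrix "
            "for photon emissions"
        )
    if etype not in NON_PENETRATING:
        raise ValidationError(f"unknown emission type {etype!r}")
    if source.acronym == target.acronym:
        return 1.0 / target.mass
    t_stem = _wall_contents_stem(target.acronym, "wall")
    s_stem = _wall_contents_stem(source.acronym, "cont")
    if t_stem is not None and s_stem is not None and t_stem.lower() == s_stem.lower():
        return 0.5 / source.mass
    return 0.0


class LegacySAF:
    """SAF provider implementing the legacy non-penetrating conventions.

    Exposes the same ``phi(etype, target, source, energy)`` interface as
    :class:`SAFMatrix`; the energy argument is ignored because the legacy
    rules are energy-independent.
    """

    def __init__(self, catalog: PhantomCatalog):
        self.catalog = catalog
        self.phantom = catalog.phantom

    def has(self, etype: str, target: str, source: str) -> bool:
        return etype in NON_PENETRATING

    def phi(self, etype: str, target: str, source: str, energy_MeV: float = 0.0) -> float:
        return legacy_saf(
            self.catalog.lookup(source), self.catalog.lookup(target), etype, self.catalog
        )

    def targets(self) -> list[str]:
        return [r.acronym for r in self.catalog.targets()]


def s_value(spectrum: EmissionSpectrum, saf, target: str, source: str) -> float:
    """S value in mGy per MBq*s for one target <- source pair.

    ``saf`` is any provider with a ``phi(etype, target, source, energy_MeV)``
    method (:class:`SAFMatrix` or :class:`LegacySAF`).
    """
    total = 0.0
    for line in spectrum.lines:
        phi = saf.phi(line.etype, target, source, line.energy_MeV)
        total += line.energy_MeV * line.yield_per_decay * phi
    return S_VALUE_MGY_PER_MBQ_S * total


@dataclass(frozen=True)
class DoseReport:
    """Absorbed doses per target with per-source contributions."""

    doses: dict[str, float]
    contributions: dict[str, dict[str, float]]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for target, total in self.doses.items():
            parts = sum(self.contributions.get(target, {}).values())
            scale = max(abs(total), abs(parts), 1e-300)
            if abs(total - parts) > 1e-9 * scale:
                raise ValidationError(
                    f"dose for {target!r} ({total}) != sum of contributions ({parts})"
                )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (target, self.doses[target], source, contribution)
            for target in sorted(self.doses)
            for source, contribution in sorted(self.contributions[target].items())
        ]
        return pd.DataFrame(
            rows, columns=["target", "dose_mGy", "source", "contribution_mGy"]
        )


def compute_dose(
    tia: TIAVector,
    spectrum: EmissionSpectrum,
    saf,
    targets: list[str] | None = None,
    strict: bool = True,
    catalog: PhantomCatalog | None = None,
) -> DoseReport:
    """Absorbed dose to each target from a TIA vector (mGy).

    Parameters
    ----------
    tia : TIAVector
        Source activities; its phantom tag must match the SAF provider's.
    saf : SAFMatrix or LegacySAF
        SAF provider; with a matrix, ``strict=False`` skips source-target
        pairs the matrix does not tabulate instead of raising.
    targets : list of str, optional
        Targets to score; defaults to every target the provider knows.
    """
    if catalog is not None:
        tia = tia.canonicalized(catalog)
    saf_phantom = getattr(saf, "phantom", None)
    if saf_phantom is not None and saf_phantom != tia.phantom:
        raise PhantomMismatchError(
            f"TIA vector is {tia.phantom}-tagged but SAF data is for {saf_phantom}"
        )
    if targets is None:
        targets = saf.targets()
    doses: dict[str, float] = {}
    contributions: dict[str, dict[str, float]] = {}
    for target in targets:
        per_source: dict[str, float] = {}
        for source, activity in tia.entries.items():
            needed = {line.etype for line in spectrum.lines if line.yield_per_decay > 0}
            if not strict and not all(saf.has(et, target, source) for et in needed):
                continue
            per_source[source] = activity * s_value(spectrum, saf, target, source)
        contributions[target] = per_source
        doses[target] = float(sum(per_source.values()))
    meta = {
        "convention": type(saf).__name__,
    }
    if isinstance(saf, LegacySAF) and any(l.etype == "alpha" for l in spectrum.lines):
        meta["note"] = "alpha lines scored with the legacy non-penetrating rules"
    meta |= {
        "spectrum": spectrum.name,
        "dose_units": DOSE_UNITS,
        "s_value_units": S_VALUE_UNITS,
        "tia_units": tia.units,
    }
    return DoseReport(doses=doses, contributions=contributions, metadata=meta)


def interpolate_saf(
    saf: SAFMatrix, etype: str, target: str, source: str, energy_MeV: float
) -> float:
    """Functional alias for :meth:`SAFMatrix.phi`."""
    return saf.phi(etype, target, source, energy_MeV)
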