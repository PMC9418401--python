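"""Deterministic synthetic fixtures for end-to-end testing without downloads.

The generators produce internally consistent toy data on real registry
regions: a SAF matrix whose electron self-terms reproduce the legacy
``1/m`` convention exactly, whose photon self-terms decay with energy, and
whose cross-terms fall off exponentially with the rank distance between
regions; and TIA vectors over phantom source regions that exercise the
pooling/apportionment paths (the CE fixture always carries ULI/LLI
contents). One pseudo-random stream per call, seeded from the spec; no
global state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dose import SAFMatrix
from .errors import ValidationError
from .mapping import TIAVector
from .regions import PhantomCatalog, load_catalog

#: Energy grid (MeV) used for generated SAF tables.
ENERGY_GRID_MEV = (0.01, 0.03, 0.1, 0.3, 1.0, 3.0)


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs for the synthetic generators.

    ``cross_decay`` controls how fast cross-irradiation falls off with rank
    distance between regions; ``tia_scale`` sets the magnitude (MBq*s) of
    generated activities.
    """

    seed: int = 0
    n_regions: int = 8
    saf_self_scale: float = 1.0
    cross_decay: float = 1.0
    tia_scale: float = 100.0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValidationError("need at least 2 regions for a fixture")
        for name in ("saf_self_scale", "cross_decay", "tia_scale"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")


def _fixture_regions(spec: FixtureSpec, catalog: PhantomCatalog) -> list[str]:
    """First ``n_regions`` source-and-target regions, registry order."""
    both = [r for r in catalog.regions if r.role == "both"]
    if len(both) < spec.n_regions:
        raise ValidationError(
            f"catalog has only {len(both)} source+target regions, "
            f"need {spec.n_regions}"
        )
    return [r.acronym for r in both[: spec.n_regions]]


def _fixture_masses(
    spec: FixtureSpec, catalog: PhantomCatalog, acronyms: list[str]
) -> dict[str, float]:
    """Registry masses where recorded, synthetic lognormal masses elsewhere."""
    rng = np.random.default_rng(spec.seed)
    masses = {}
    for acr in acronyms:
        region = catalog.lookup(acr)
        if region.mass_g is not None:
            masses[acr] = region.mass_g
            rng.lognormal(np.log(100.0), 0.8)  # keep the stream aligned
        else:
            masses[acr] = float(rng.lognormal(np.log(100.0), 0.8))
    return masses


def _photon_attenuation(energy_MeV: float) -> float:
    """Self-absorbed photon fraction a(E): in (0, 1), decreasing in E."""
    return 0.9 / (1.0 + energy_MeV)


def gen_synthetic_saf(spec: FixtureSpec, catalog: PhantomCatalog | None = None) -> SAFMatrix:
    """Square electron+photon SAF matrix over the first fixture regions.

    Electron self-terms equal ``saf_self_scale / m`` at every energy (the
    legacy convention when the scale is 1); photon self-terms are
    ``a(E)/m`` with ``a`` monotonically decreasing; cross-terms are the
    target's self-term damped by ``exp(-cross_decay * rank_distance)``, so
    the self-term always dominates its row.
    """
    catalog = catalog or load_catalog("ICRP")
    acronyms = _fixture_regions(spec, catalog)
    masses = _fixture_masses(spec, catalog, acronyms)
    grid = np.asarray(ENERGY_GRID_MEV)
    saf = SAFMatrix(phantom=catalog.phantom)
    for i, target in enumerate(acronyms):
        e_self = spec.saf_self_scale / masses[target]
        p_self = np.array([_photon_attenuation(e) / masses[target] for e in grid])
        for j, source in enumerate(acronyms):
            damp = np.exp(-spec.cross_decay * abs(i - j))
            saf.add("electron", target, source, grid, np.full(grid.shape, e_self * damp))
            saf.add("photon", target, source, grid, p_self * damp)
    saf.validate_self_terms()
    return saf


#: CE source regions the TIA fixture draws on (pooling paths included).
_CE_FIXTURE_REGIONS = (
    "ULI-cont", "LLI-cont", "Liver", "Kidneys", "Spleen",
    "ST-cont", "Lungs", "A-marrow", "RST", "Ht-cont",
)

#: Non-overlapping ICRP source regions for direct ICRP fixtures.
_ICRP_FIXTURE_REGIONS = (
    "RC-cont", "LC-cont", "RS-cont", "Liver", "Kidneys",
    "Spleen", "ST-cont", "Lung-tis", "R-marrow", "UB-cont",
)


def gen_synthetic_tia(spec: FixtureSpec, phantom: str = "CE") -> TIAVector:
    """Reproducible nonnegative TIA vector over phantom source regions.

    The CE fixture always contains ``ULI-cont`` and ``LLI-cont`` so the
    colon apportionment path is exercised; the ICRP fixture uses only
    non-overlapping sources, so it passes the co-use validator.
    """
    if phantom not in ("CE", "ICRP"):
        raise ValueError(f"phantom must be 'CE' or 'ICRP', got {phantom!r}")
    names = _CE_FIXTURE_REGIONS if phantom == "CE" else _ICRP_FIXTURE_REGIONS
    rng = np.random.default_rng(spec.seed)
    values = spec.tia_scale * rng.random(len(names))
    return TIAVector(phantom=phantom, entries=dict(zip(names, values.tolist())))
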