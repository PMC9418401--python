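"""Blood-pool double-counting correction.

The ICRP phantoms carry total-body blood as a distinct source region, while
organ activities quantified from nuclear-medicine images include whatever
blood happens to be inside the organ. Using an imaged organ value together
with a measured blood value therefore counts the organ's blood pool twice.
The correction subtracts, from each imaged organ, the fraction of
total-body blood activity residing in that organ's blood pool according to
a reference blood-distribution model, and carries the full blood activity
on the dedicated ``Blood`` source region.

The 58% lung blood *mass* share is a separate bookkeeping constant: it
relates the masses of the ICRP "lungs" (tissue plus blood) and "lung
tissue" regions. It is not an activity fraction and is never used as a
default in the activity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .errors import PhantomMismatchError, ValidationError
from .mapping import TIAVector
from .regions import PhantomCatalog, load_catalog

logger = logging.getLogger(__name__)

#: Mass fraction of the lungs occupied by blood in the adult reference model.
LUNG_BLOOD_MASS_FRACTION = 0.58

#: ICRP acronym of the total-body blood source region.
BLOOD_ACRONYM = "Blood"


@dataclass(frozen=True)
class BloodDistribution:
    """Fraction of total-body blood residing in each organ's blood pool."""

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        for region, frac in self.fractions.items():
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(
                    f"blood fraction for {region!r} out of [0, 1]: {frac}"
                )
        total = sum(self.fractions.values())
        if total > 1.0 + 1e-9:
            raise ValidationError(f"blood fractions sum to {total} > 1")

    def canonicalized(self, catalog: PhantomCatalog) -> "BloodDistribution":
        out: dict[str, float] = {}
        for region, frac in self.fractions.items():
            acr = catalog.lookup(region).acronym
            out[acr] = out.get(acr, 0.0) + frac
        return replace(self, fractions=out)


@dataclass(frozen=True)
class LungComposition:
    """Mass split of the ICRP "lungs" region into tissue and blood."""

    blood_mass_fraction: float = LUNG_BLOOD_MASS_FRACTION

    def __post_init__(self) -> None:
        if not 0.0 < self.blood_mass_fraction < 1.0:
            raise ValidationError(
                f"blood mass fraction must be in (0, 1), got {self.blood_mass_fraction}"
            )


def split_lung_mass(
    lungs_mass_g: float, composition: LungComposition = LungComposition()
) -> tuple[float, float]:
    """Split a "lungs" mass into ``(tissue_g, blood_g)``.

    The blood share is ``blood_mass_fraction`` (58% by default); the tissue
    share is the complement, so the parts always sum to the input exactly.
    """
    if not lungs_mass_g > 0:
        raise ValidationError(f"lungs mass must be positive, got {lungs_mass_g}")
    blood_g = composition.blood_mass_fraction * lungs_mass_g
    tissue_g = lungs_mass_g - blood_g
    return tissue_g, blood_g


def parenchymal_tia(
    imaged: TIAVector,
    total_blood_tia: float,
    dist: BloodDistribution,
    policy: str = "error",
    catalog: PhantomCatalog | None = None,
) -> TIAVector:
    """Subtract organ blood-pool activity from image-derived organ TIAs.

    For every organ with a distribution entry, the corrected value is
    ``imaged - fraction * total_blood_tia``; organs without an entry pass
    through unchanged (logged). The output carries the full
    ``total_blood_tia`` on the ``Blood`` source region.

    Parameters
    ----------
    policy : {"error", "clamp"}
        What to do when a correction would drive an organ negative (blood
        pool larger than the imaged activity): raise, or clamp to zero with
        a warning. Clamping breaks exact activity conservation.
    """
    if imaged.phantom != "ICRP":
        raise PhantomMismatchError(
            f"blood correction applies to ICRP vectors, got {imaged.phantom!r}"
        )
    if total_blood_tia < 0:
        raise ValidationError(f"total blood TIA must be nonnegative, got {total_blood_tia}")
    if policy not in ("error", "clamp"):
        raise ValueError(f"policy must be 'error' or 'clamp', got {policy!r}")
    catalog = catalog or load_catalog("ICRP")
    vec = imaged.canonicalized(catalog)
    fractions = dist.canonicalized(catalog).fractions
    if vec.get(BLOOD_ACRONYM) > 0:
        raise ValidationError(
            "imaged vector already carries a Blood entry; correcting it again "
            "would double-count the blood pool"
        )
    out: dict[str, float] = {}
    for acr, value in vec.entries.items():
        if acr == BLOOD_ACRONYM:
            continue
        frac = fractions.get(acr)
        if frac is None:
            logger.info("no blood-distribution entry for %r; passed through", acr)
            out[acr] = value
            continue
        corrected = value - frac * total_blood_tia
        if corrected < 0:
            if policy == "error":
                raise ValidationError(
                    f"blood correction drives {acr!r} negative "
                    f"({value} - {frac} * {total_blood_tia} = {corrected}); "
                    "use policy='clamp' to truncate at zero"
                )
            logger.warning(
                "blood correction clamped %r to 0 (was %g)", acr, corrected
            )
            corrected = 0.0
        out[acr] = corrected
    out[BLOOD_ACRONYM] = float(total_blood_tia)
    return TIAVector(phantom="ICRP", entries=out, units=imaged.units)
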