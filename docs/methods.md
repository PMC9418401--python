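# Methods

## The problem and the model

Internal dosimetry in the MIRD schema factors the absorbed dose to a target
region r_T into physics and physiology:

    D(r_T) = Σ_S Ã(r_S) · S(r_T ← r_S)
    S(r_T ← r_S) = k · Σ_i E_i · Y_i · Φ(r_T ← r_S; E_i)

Ã is the time-integrated activity (TIA, MBq·s; the cumulative number of
decays in the source region), E_i and Y_i the energy (MeV) and per-decay
yield of each emission line, and Φ the specific absorbed fraction (SAF,
g⁻¹): the fraction of emitted energy absorbed in the target per unit target
mass. The constant k = 1.602176634 × 10⁻¹⁰ Gy per (MeV·g⁻¹·decay) is folded
into the package's unit chain (MeV, g, MBq·s in; S values in mGy/(MBq·s);
doses in mGy), centralized in `phantombridge.units`.

The package's job is not radiation transport — Φ values come either from a
user-supplied table or from the legacy stylized-phantom conventions — but
the *transition* between two phantom nomenclatures: the stylized
Cristy–Eckerman (CE) adult (23 source / 18 target regions) and the ICRP
voxel reference adult (79 source / 43 target regions). The operations are
exact bookkeeping: registry resolution, mass-based apportionment, overlap
validation, blood-pool subtraction, and the S-value sum above.

## Region registries and data provenance

Both registries ship as versioned CSV files
(`phantom,acronym,canonical_name,role,mass_g,system,flags`). Entries record
a mass only where the package's own operations need one or where the value
anchors a documented correspondence:

* ICRP colon contents 150/75/75 g and walls 186.24/186.24/86.91 g (the
  apportionment masses);
* alimentary stem-cell target layers 1.35/1.26/0.759/0.616/3.71 g and
  endosteum 580 g, against CE whole-wall targets 220/167/158/677 g and
  osteogenic cells 108 g (the target-mass correspondence);
* muscle 29 000 g and adipose 18 200 g (ICRP 89 adult-male reference
  values), required by the residual-soft-tissue rule.

All other masses are deliberately *unknown*: operations that need them fail
with an error naming the region rather than silently importing values from
other sources. The 41 ICRP sources flagged `other_tissue_source` are the
remainder-candidate tissues (contents, surface-deposit and bound
compartments, whole-organ overlap pools, blood and the explicitly mapped
major organs are excluded); the flag is registry data and editable.

The three lung entries (`Lungs`, `Lung-tis`, `AI`) are recorded as an
overlap group: they denote nested volumes of the same tissue and differ
only for biokinetic bookkeeping. Lookups are case-insensitive and treat
hyphen/space variants as equal, matching acronyms before canonical names.

## Activity mapping

A mapping rule pools its CE regions before splitting: the colon rules act
on Ã(ULI)+Ã(LLI) as one pot, which is exactly how the apportionment is
defined. Mass-fraction weights are f_i = m_i/Σm_j with the last weight set
by complement, so the sequential sum is exactly 1 and porting conserves
total activity to better than the ±0.005 factor-sum tolerance.

Two factor sets exist for the colon walls. The published factors
0.41/0.41/0.18 sum to exactly 1.00; the exact mass fractions are
0.405407/0.405407/0.189186, whose rectosigmoid entry rounds to 0.19. The
default table carries the published triple (basis `printed_factor`) so that
results match the published transition exactly; `recompute_factors=True`
(CLI `--recompute-factors`) substitutes the exact fractions. This is a
deliberate design choice: reproducibility of the published mapping by
default, self-consistency on request.

Other genuinely open correspondences were resolved as follows and flagged
`review=True` where user judgement is warranted:

* **CE heart contents → ICRP total blood**, unscaled. The ICRP phantom has
  no heart-contents source; whether the value should be rescaled (total
  blood mass far exceeds heart-contents mass) depends on how the input was
  quantified, so the alias is flagged rather than silently scaled.
* **CE small intestine → ICRP SI contents.** The CE geometry does not
  separate SI wall from contents; assigning the pooled value to the
  contents matches the ingestion-dominated use case but is flagged.
* **CE residual soft tissue → muscle + adipose** by mass fraction
  (0.614/0.386 with the registry masses). The rule errors informatively if
  those masses are removed from the registry.
* **Target correspondence** maps each CE target to a single ICRP target
  (lungs → lung tissue, osteogenic cells → endosteum, GI walls → mucosal
  stem-cell layers). The two CE large-intestine walls correspond
  collectively to three ICRP stem-cell layers; the one-to-one map uses the
  anatomically closest choices ULI-wall → right colon and LLI-wall → left
  colon. This map names targets only and never moves activity.

Porting is one-way: `port_tia` refuses ICRP-tagged input, since applying
the rules twice is meaningless. Unmapped CE entries are an error under
`strict` and copied with a warning under `passthrough`.

## Co-use validation

The constraint table (bundled CSV) lists source pairs that are *prohibited*
(anatomical overlap — using both double-counts decays) or *unusual*
(volume/surface pairs of one structure that could only both be known from
modeling). Multi-entry rows are expanded to explicit pairs (29 in total).
Zero-valued entries never violate: only co-positive pairs overlap in
practice, and a vector that merely mentions a region with Ã = 0 is not
using it. The default mapping can never produce a prohibited pair because
its ICRP image contains no two overlapping sources.

## Blood correction

When total-body blood is a distinct source, an image-derived organ value
contains the organ's blood pool and would be double-counted. The correction
is Ã_parenchyma = Ã_imaged − f_organ · Ã_blood, with f_organ from a
reference blood-distribution table supplied by the user (a documented
example ships in `data/example_blood_distribution.csv`; its values are
representative, not authoritative). Organs absent from the distribution
pass through, logged. A negative corrected value means the assumed blood
fraction exceeds the imaged activity; the default policy raises,
`clamp` truncates to zero with a warning (and breaks exact conservation,
which is why it is not the default).

The 58% lung blood mass share is kept separate from this machinery: it is
a *mass* constant relating the "lungs" and "lung tissue" regions
(`split_lung_mass`, tissue = 42%, blood = 58%, parts summing exactly to the
whole) and is never used as a default activity fraction. Whether choosing
"lungs" vs "lung tissue" as a source should trigger any mass re-assignment
is left to the user; nothing is automatic.

## Dose engine numerics

* **Legacy conventions** (electrons and alphas, the historical
  non-penetrating treatment): self Φ = 1/m_target, wall ← its own contents
  Φ = 0.5/m_contents, all other pairs 0. Wall/contents pairing is by
  acronym stem (`X-wall` ↔ `X-cont`). Photons have no legacy rule — their
  absorbed fractions were phantom-specific transport results — so photon
  lines always require a supplied matrix. Alpha lines reuse the electron
  rules and the report is annotated when they do.
* **Tabulated SAFs** are interpolated log–log between grid nodes (SAF
  energy dependence is close to power-law over decade-wide grids), exact at
  nodes, with no extrapolation outside the grid. If a bracketing value is
  zero the segment falls back to linear interpolation, since log–log is
  undefined there. The interpolation rule is this package's choice,
  documented rather than inherited.
* Doses are assembled per target as an explicit per-source breakdown whose
  sum is the reported total (checked to 1 × 10⁻⁹ relative at construction);
  the engine is linear in both Ã and yields by construction, and tests pin
  it against a hand-assembled matrix–vector product at 1 × 10⁻¹² relative.

## Synthetic data

The fixture generators produce internally consistent toy data on real
registry regions, sized for desk-scale verification (8 regions, a 6-point
energy grid from 0.01 to 3 MeV, activities of order 100 MBq·s): electron
self-SAFs reproduce the legacy 1/m convention exactly, photon self-SAFs
decay monotonically with energy as 0.9/(1+E) per gram, cross-terms fall off
as exp(−distance) in registry rank, and regions without registry masses
receive reproducible lognormal masses (median 100 g). Each generator draws
from a single stream seeded by `FixtureSpec.seed`; no global state.

What the fixtures do *not* emulate: real SAF anisotropy and the geometric
adjacency structure of organs (rank distance is an ordering artifact, not
anatomy), realistic radionuclide spectra, measurement noise, or biokinetic
time structure (TIAs spring into existence already integrated). Passing
tests therefore demonstrate the bookkeeping — conservation, registry
resolution, convention arithmetic — not the accuracy of any transport data.

## Known limitations

* No radiation transport, voxel geometry, decay-chain handling or
  patient-specific mass scaling; the scope is nomenclature transition and
  the MIRD sum.
* Registry masses outside the documented set are unknown by design; legacy
  dose calculations require masses and will fail for regions that lack
  them until the user supplies a registry override.
* The respiratory-tract and alimentary-tract biokinetic models are
  represented only by their region names; no deposition or transit
  modeling.
* The example blood distribution is illustrative; clinical use requires a
  reference-model table chosen by the user.
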