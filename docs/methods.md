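# Methods

## Mass arithmetic

All masses are monoisotopic, computed from hard-coded IUPAC atomic masses
(C 12.0, H 1.0078250319, N 14.0030740052, O 15.9949146221, S 31.97207069 Da)
so results do not depend on any external table version. The proton mass
(1.007276 Da) is kept distinct from the hydrogen atom mass: the [M+H]⁺
adduct gains a bare proton. Charge is fixed at +1 throughout — the assay
this package models observes only singly protonated species on a unit-
resolution triple quadrupole — and isotope-averaged masses, isotope
patterns, and other adducts (Na⁺, K⁺) are deliberately out of scope.
Nominal (integer) m/z is round-half-away-from-zero of the exact m/z; this
reproduces the unit-resolution values an instrument method file lists
(628/831/1034/1237 for CO3–CO6 precursors, 204 for the GlcNAc B1 ion).

Elemental formulas are integer count vectors over C/H/N/O/S. Signed counts
are allowed for *group deltas* (e.g. "replace N-acetyl with palmitoyl" =
−C2H2O +C16H30O); a formula declared a molecule must have all counts ≥ 0
and is validated at that point, which catches impossible structures early.

## Structure model

A CO of length n has formula n×C8H13NO5 + H2O (anhydro residues plus one
closing water). An LCO replaces the acetyl on the non-reducing terminal
nitrogen (position R1) with a fatty acyl chain Cc:d, whose group formula is
CcH(2c−2−2d)O(1+h) (h = hydroxyl count, default 0). Substituent positions
follow the standard Nod-factor generic structure: R2–R4 sit on the
non-reducing terminal residue, R5–R6 on the reducing terminal residue. Each
substituent replaces one hydrogen; the deltas are Me +CH2, Ac +C2H2O,
Cb +CHNO, S +SO3, Fuc +C6H10O4, MeFuc +C7H12O4, FucS +C6H10O7S. Site
plausibility is enforced (e.g. sulfate and the fucosyl family only at R6,
N-methyl only at R2); a substituent at a disallowed site raises an error.

Canonical names use the field's nomenclature — `CO4`,
`LCO-IV(C16:0,Me,S)` — with the non-hydrogen substituent codes sorted, so
the name is independent of assignment order. Names are the deduplication
key during enumeration: in grammars where one code is admitted at two
positions the colliding assignments merge under one name, which is the
intended structural-identity semantics (printed LCO names do not carry
positions either).

### Grammar defaults

* backbone lengths {3, 4, 5} — the range observed for LCOs;
* acyl library C12–C22, even carbon counts only, 0–3 double bonds.
  Even chains are the biologically realistic choice (fatty-acid synthesis
  elongates in C2 units); they also avoid an artifactual exact degeneracy
  in which Cc:d plus N-methyl is isobaric with C(c+1):d in both precursor
  and every B ion, which would make annotation ill-posed for reasons that
  have nothing to do with real samples. The library is a configuration
  field, not a constant — odd chains or hydroxylated chains can be added;
* substituent options R2 {H, Me}, R3 {H, Cb}, R4 {H, Ac}, R5 {H},
  R6 {H, S, Fuc, MeFuc, FucS}.

This default grammar yields 2880 structures, 1984 unique precursor m/z and
8640 transitions. The much larger totals a lab-scale database can reach
depend entirely on the grammar supplied; `db_stats` reports structure,
precursor (both readings: entries-per-structure and unique m/z at 4-decimal
rounding) and unique transition counts for any grammar so external
databases can be compared. When supplying an explicit `position_options`
mapping, unlisted positions default to {H} (the full default sets apply
only when the mapping is omitted entirely).

## Fragmentation model

Only B ions are generated: the glycosidic-cleavage series retaining the
non-reducing end as an oxocarbenium, Bᵢ = i residues + attached acyl and
R2–R4 deltas + proton, for i = 1…n−1. Reducing-end substituents (R5–R6)
never appear in any B ion — this is why, for example, a sulfated and a
non-sulfated LCO-IV share an identical product-ion list while their
precursors differ by 79.9568 Da. Y/C/Z ions are not modelled. Transition
records keep (precursor, product, ion label, optional expected retention
time); dedup compares m/z at 4 decimals, below instrument resolution but
above float noise.

## Peak extraction and matching

Chromatographic peaks are local maxima (scipy `find_peaks`) rising at least
max(`min_height`, `snr_threshold` × noise) above the baseline level, where
baseline = trace median and noise = median absolute deviation — both robust
when peaks occupy part of the trace. Accepted apexes must be separated by
one full width at half maximum; of two closer apexes the taller wins.
Defaults: `snr_threshold` 10 (an MAD-scaled threshold near 7 Gaussian σ, so
pure-noise traces essentially never fire), `min_height` 10 (absolute floor
for noise-free traces whose MAD is 0).

Traces are assigned to panel transitions when both precursor and product
m/z fall within `mz_tolerance` (default 0.5 Da, unit-resolution quadrupole);
a trace within tolerance of several transitions is assigned to the nearest
with a logged warning, keeping output deterministic. Per structure, the
matched-transition count is the largest set of its transitions with apexes
within `rt_coelution_window` (default 0.1 min) of a common retention time,
anchored on observed apexes and tie-broken to the earliest anchor.
Confidence tiers: ≥2 co-eluting transitions → **high**; exactly one
transition at the structure's expected retention time (within
`rt_expected_window`, defaulting to the co-elution window) → **low**; one
transition without retention-time corroboration is logged as uncorroborated
and reported as **none**, as is zero. Expected retention times are optional
metadata, populated in practice from synthetic standards; no retention-time
prediction is attempted.

Untargeted annotation filters database candidates to backbones of 3–6
GlcNAc residues, requires the precursor match within tolerance (default
0.3 Da) and at least `min_products` (default 2) theoretical B ions among
the spectrum's product ions, and ranks by matched-product count, then
precursor error, then name (a total, deterministic order).

## Synthetic data

The simulator emulates one MRM injection: every panel transition yields a
trace on a uniform time grid (default 1–11 min, matching a 10-minute LC
gradient plus hold, step 0.01 min); each non-dropped transition of a
planted structure receives a Gaussian elution peak A·exp(−(t−t₀)²/2σ²) at
the structure's true retention time (σ default 0.05 min ≈ 7 s FWHM,
amplitude uniform in 200–1000 counts); all traces carry a constant detector
baseline (default 20 counts) plus additive Gaussian noise (default σ 5
counts), clipped at zero. Decoy peaks are placed at wrong retention times
on non-planted panel transitions (stressing co-elution logic) and on
random off-panel m/z pairs (stressing tolerance logic). Per-transition
dropout is Bernoulli. A truth table records, per planted structure, the
true retention time and exactly which transitions were emitted or dropped.
All randomness flows from one `numpy` generator seeded from the config, so
identical seeds give byte-identical trace files.

Untargeted simulation draws k database structures without replacement and
emits, per structure, a spectrum holding its precursor m/z, all its B ions,
and a configurable number of uniform-random noise products.

What the simulator does **not** emulate: ion suppression and matrix
effects, retention-time drift between runs, peak tailing/fronting,
intensity calibration to any instrument, and chemical noise with structured
m/z. Tests passing on these synthetics therefore demonstrate the internal
consistency of the pipeline (correct m/z math, correct grouping and tier
logic, seeded reproducibility) — not detection performance on real
exudates.

## Numerical and design notes

* Problem sizes in the test suite are desk-scale by design: the default
  2880-structure grammar, panels of tens of transitions, 200 untargeted
  spectra — enough to exercise every code path and the statistical
  invariants while keeping the whole suite in seconds.
* Tie-breaks are explicit everywhere randomness or float comparison could
  make output order ambiguous: enumeration sorts by canonical name,
  matching iterates structures in name order, co-elution anchors resolve to
  the earliest retention time, annotation ties resolve by name.
* The CLI uses `;` to separate structure names (names such as
  `LCO-IV(C16:0,S)` contain commas).
* Bioassay columns in the evidence matrix (root-hair branching,
  reporter-gene induction) are pass-through booleans from input tables; the
  package never computes them. Targeted and untargeted high-confidence
  evidence are collapsed into the single `ms_high` flag.
* Quantification is out of scope: matched intensities are used only for
  peak acceptance, never converted to concentrations.
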