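# Methods

## Model representation and rule semantics

Molecules are typed site graphs: each site may carry an internal state
(e.g. `~0`/`~P` for a phosphotyrosine, `~i`/`~a` for an inaccessible or
accessible hapten) and at most one bond. A chemical species is a fully
specified, connected complex; identity is decided by a canonical label
computed with iterative color refinement on (molecule type, site states,
bond partners) and trial individualization on ties, taking the
lexicographically smallest serialization. For the complex sizes this model
produces (≤ ~14 molecules) the search is exact and fast; labels are
deterministic across runs and independent of molecule order and bond-index
numbering.

A rule is a pair of pattern lists plus a rate law. Patterns may omit sites
(no constraint), leave states unspecified, and require a bond without naming
the partner (`!+`). The transformation of a rule — bond additions/deletions,
state changes, molecule creations/deletions — is derived once by matching
reactant and product molecules positionally by type, left to right, which is
how rules are conventionally written. `DeleteMolecules` removes only the
matched molecules, leaving orphaned fragments as independent species (used
for lipid consumption); without it, deletion removes the whole complex.

**Rates.** Applying a rule to a species tuple enumerates all embeddings of
the reactant patterns and assigns each resulting reaction the rate constant
`k × (embedding count) / |Aut|`, where `|Aut|` counts automorphisms of the
reactant pattern multiset (pattern swaps times internal symmetries). This is
the convention under which each *unordered* set of reactant molecules is
counted exactly once: homodimerization `A(a)+A(a)` gets `k/2·x²`, symmetric
dissociation gets `k` (2 embeddings / 2 automorphisms). Reversible rules are
expanded into two irreversible parts before generation.

**Network generation** iterates to a fixed point from the seed species,
visiting every ordered species tuple exactly once, so the result is
independent of rule order (tested). Bivalent ligand chemistry admits
unbounded chains, so generation enforces a configurable cap on molecules per
species (default 6 for ligand-containing models; the example Lat-branch
models use 14, which is above their largest reachable complex, so nothing is
truncated there). Truncation is flagged on the network and logged, never
silent. Ring closure cannot occur because binding rules are strictly
bimolecular, which automatically encodes the no-cyclic-aggregates assumption
of the ligand model.

## The interaction library

Molecule types use UniProt names with rat residue numbering. Amounts are
copy numbers per cell under a well-mixed assumption for three implicit
compartments (extracellular fluid, plasma membrane, cytosol); bimolecular
rate constants are per copy number per second.

- **Ligand–receptor**: the antigen is a carrier with two hapten sites that
  flip between inaccessible and accessible states; the receptor unit
  (IgE-bound FcεRI) is bivalent (`f1`,`f2`). Because site names within a
  molecule must be unique, the two equivalent sites are written as named
  pairs with one rule variant per site at equal rates; solution binding and
  crosslinking carry separate constants.
- **Proximal**: Lyn and Fyn associate constitutively with the receptor via
  their unique domains and, after β-chain phosphorylation, via their SH2
  domains with enhanced catalytic rates. Receptor phosphorylation is strictly
  *trans*: the kinase anchored on one receptor reaches the β- and γ-chain
  tyrosines of a second receptor across the ligand bridge (the rule patterns
  span kinase–receptor–ligand–receptor). Syk binds the doubly phosphorylated
  γ-ITAM (one site, `g`) through its tandem SH2 domains and *trans*
  autophosphorylates the activation loop (`Y519_Y520`, one site) of a second
  receptor-bound Syk, faster when its own loop is phosphorylated. Two
  simplifications: Syk's linker-region tyrosines are not modeled (Syk carries
  only `tSH2`, `PTK`, `Y519_Y520`), and Lyn/Fyn activation loops have no
  explicit site — their receptor-recruitment positive loops remain, their
  autophosphorylation loops are represented only in the influence-graph
  annotations of Syk.
- **Pag1/Csk**: Lyn/Fyn bind Pag1 (SH3), phosphorylate it in cis, the
  phosphosite recruits Csk, and Csk phosphorylates the SFK C-terminal
  tyrosine in cis (same Pag1). The phosphorylated tail closes onto the SFK's
  own SH2 domain (an intramolecular bond), which blocks SH2-mediated
  receptor recruitment — autoinhibition emerges from site occupancy rather
  than from a dedicated "inactive" flag.
- **Lat branch (numbered rules 1–48)** and **lipid background (49–51)** are
  transcribed verbatim (whitespace-normalized) into executable form. One
  transcription note: the membrane-enhanced receptor-binding rule for Inpp5d
  (rule 39) engages the catalytic `IPP` site, and the dissociation rule
  releases only `SH2`-bonds, so that binding mode is effectively
  irreversible; the text is kept as published in the curated set rather than
  "corrected", and the Inpp5d module is not part of the simulated example
  models.
- **Implicit phosphatases**: one first-order dephosphorylation rule per
  0/P phosphosite with a single shared rate constant `kDephos`. By default a
  bound phosphosite is shielded (the pattern requires a free site); a
  configuration flag relaxes this to act on bound sites too.

### Input signal for the reduced models

The example models do not include the ligand/proximal machinery; active Syk
is by definition the receptor-engaged, loop-phosphorylated form (so the
numbered rules' `tSH2!+` requirements apply), and active Fyn the
receptor-engaged (`U!+`) form. The input signal `s` activates each kinase at
rate `s × (inactive amount)`, implemented as a unary rule that tethers the
kinase to a membrane `Anchor` molecule (created bound) and, for Syk, sets
the activation loop; deactivation is first order per kinase
(`kdeactSyk`, `kdeactFyn`) and deletes the anchor. At `s = 0` active kinase
decays to zero. In "clamped" mode no activation/deactivation rules are
included and fixed fractions of the kinase pools are seeded in the anchored
form, holding activity constant over time.

### The Gab2 positive-feedback selection

Under well-mixed mass action, the PH–PIP₃ binding rule alone creates no
positive loop: the printed Fyn→Gab2 and PI3K→PIP₂ rules require the Lat
complex as context, and membrane tethering confers no rate advantage in a
well-mixed model. The feedback selection therefore comprises three rules:
PH–PIP₃ binding (rule 15) plus two membrane companions that make the
recruitment productive — Fyn (receptor-engaged) phosphorylates
PIP₃-tethered Gab2, and PI3K held by PIP₃-tethered phospho-Gab2 captures
PIP₂ — both at the same rate constants as their Lat-complex counterparts,
since enzyme and substrate are membrane-localized in both contexts (the same
logic behind the library's 100-fold membrane enhancements for Inpp5d). This
is the package's interpretation of "the interactions responsible for the
positive feedback"; the no-feedback model simply omits all three.

### Lipid turnover

The numbered lipid rules interconvert PI4P/PIP₂/PIP₃ and cleave PIP₂ but
provide no IP₃ sink and no backbone source, so IP₃ would have no nontrivial
steady state (rise times and bifurcation diagrams are defined against steady
states). Two auxiliary first-order background reactions close the cycle:
IP₃ degradation (`kdegIp3`) and DAG recycling to PI4P (`kRecycleDag`), which
conserves the lipid backbone pool. They live in the lipid-background
sub-library, clearly separated from the numbered rules.

## Parameterization

Numeric rate constants and seed copy numbers are **documented placeholders**:
the published model's parameter files are supplementary material that is not
part of this package's sources. Values were chosen once, in physiological
ranges (association 1e-6–2e-5 per copy per second, i.e. ~1e6–1e7 /M/s for a
~1 pL cell; dissociation 0.01–1 /s; catalysis 0.5–20 /s; protein pools
2e4–1e5 copies; lipid pools 1e5–3e5), and calibrated so that the default
parameterization lies in the qualitative regime the example models are known
to exhibit: saturating Lat phosphorylation at high input, fast adaptor
exchange on Lat relative to phosphosite turnover (which makes the
phospho-Gab2 pool, and hence PIP₃ production, roughly quadratic in Lat
phosphorylation), bistability with the feedback selection and monostability
without it. Two structural constraints always hold: the 100-fold Inpp5d
membrane enhancements (rule-level multipliers), and faster Syk catalysis
with a phosphorylated activation loop (`kpSykLat136_1 ≥ kpSykLat136_2`,
`kpSykLat175_2 ≥ kpSykLat175_1`).

The clamped-input conditions are `SYK_HIGH = 1.0` and
`SYK_INTERMEDIATE = 0.05` (relative active-Syk levels, constant Fyn), chosen
so the two conditions differ about fourfold in total Lat phosphorylation —
the high condition saturates Lat. Under these defaults the peak-IP₃
fold-difference is ~2.7 with feedback and ~25 without. The published
analysis reports a >100-fold contrast without feedback; reproducing that
number requires the original supplementary parameterization. With
first-order phosphatases and explicit IP₃ turnover, the no-feedback contrast
is bounded by a product of at most three Lat-phosphorylation-linear stages
(Plcg1 recruitment × PIP₃ production × Btk-driven Y783 phosphorylation),
which at a fourfold Lat-P contrast caps it near the observed value; pushing
it higher by unsaturating the Plcg1 arm raises the with-feedback ratio above
its own reported bound by the same factor.

## Numerical choices

- Integrator: BDF with an analytic sparse Jacobian (default tolerances
  rtol 1e-8, atol 1e-10 in copy-number units); Radau available for
  high-accuracy verification of small systems; trajectories are clipped at
  zero on report and negative excursions beyond tolerance are logged.
- Steady state: integrate over geometrically growing horizons until
  `max |dx/dt| / (|x| + floor) < tol` holds across the trailing 10% of the
  horizon; non-convergence raises an error flagged as possible oscillation.
  Stability is the sign of the dominant eigenvalue of the Jacobian projected
  onto the stoichiometric subspace (conserved moieties contribute structural
  zeros and are removed first); eigenvalues within a relative `1e-8` band of
  zero are reported indeterminate.
- Bifurcation sweeps: 50 log-spaced points per direction by default; each
  point is continued from the previous steady state, the first from the seed
  amounts (up) or from the up sweep's final state (down). Bistability is a
  branch disagreement above 1% relative (absolute floor 1 copy), comfortably
  above the steady-state tolerance; only stable states are recorded, and
  failed points are flagged, not fatal. Window endpoints are resolved to one
  grid step.
- Rise time: first upward crossing of `fraction × final value`, linearly
  interpolated; the trajectory must be settled (≤1% change over the trailing
  10% of the span); non-monotone approaches return the last crossing with a
  warning.
- The acceptance script uses 12-point sweeps, six rise-time levels, and
  ~110-point time grids to 3e5 s — sizes chosen to characterize the window
  and kinetics while keeping a full reproduction run under a minute.

## What the toy fixtures do and do not show

The fixture generator emulates the elementary motifs the engine must get
right: reversible dimerization (analytic equilibrium), a catalytic cycle
(enzyme-substrate binding with irreversible turnover), bivalent
ligand/receptor aggregation (combinatorial species growth and cap
truncation), and a cubic autocatalytic switch whose steady states solve a
closed-form cubic (bistability against a root-finding oracle). Passing these
shows the rewrite semantics, symmetry factors, ODE derivation, and sweep
logic are correct; it does not validate the biological parameterization of
the FcεRI library, which remains placeholder-calibrated as described above.

## Known limitations

- Deterministic (ODE) simulation only; no stochastic or spatial simulation.
- No compartment volumes: copy-number units with implicit compartments.
- Rate parameters and copy numbers are placeholders (see above); analyses
  of the example models are qualitative, not quantitative predictions.
- The aggregate cap truncates ligand-induced chains; ring closure is
  excluded by construction.
- Influence-graph edges are curated annotations shipped with the library
  (plus optional condensed path-summary edges at the granularity of the
  published motif map), not inferred from rule structure.
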