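# Methods

## The mapping model

A PA-labeled *O*-glycan is characterized by four orthogonal observables:

1. **GU (amide)** — retention on a size-fractionation column, expressed in
   glucose units against a PA-isomalto-oligosaccharide ladder (DP 1–20);
2. **GU (C30)** — retention on an extended reversed-phase column, same
   ladder convention;
3. **nominal mass** — integer [M+H]⁺;
4. **charge class** — count of anionic groups (Neu5Ac + sulfate), the
   categorical outcome of Mono-Q anion-exchange pre-fractionation. The
   Mono-Q dimension has no GU axis; it is modeled purely as a gate, and one
   sulfate is weighted like one sialic acid.

The reference map bundles 27 structures (16 neutral, 7 sialylated,
4 sulfated) with their coordinates on both GU axes and printed masses.
Identification is a tolerance box around the query: an entry is a candidate
if it passes the charge gate and lies within the per-axis GU tolerance and
the mass tolerance. Candidates are ranked by
`sqrt(Σ (ΔGU/tol)²)` over the supplied axes, so each axis contributes on the
same normalized scale; ties break by smaller mass deviation, then by
canonical structure string.

## Tolerances and ambiguity

Defaults: ±0.2 GU per axis, ±1 Da nominal mass, all configurable (YAML
config or API). The map's minimum pairwise two-axis (Chebyshev) gap is
0.1 GU — the di-sialylated core-1 isomer pair at (amide 2.7, C30 2.2) vs
(2.7, 2.3), which also shares mass 1044 and charge 2. A 0.2 GU tolerance
therefore cannot separate that pair; every other pair is resolvable. The
toolkit never silently picks a winner: whenever more than one entry
survives the tolerances, the result carries an `ambiguous` flag and the
full candidate list, reflecting the bench reality that such isomers are
distinguished by enzymatic derivatization (e.g. which sialyltransferase
produced them), not by retention alone. Downstream accuracy accounting uses
the same policy: an ambiguous assignment is correct if the true structure
is among the reported candidates.

## Mass conventions

Residue (dehydrated) masses used:

| class  | monoisotopic | average | nominal |
|--------|--------------|---------|---------|
| Hex    | 162.0528     | 162.141 | 162     |
| HexNAc | 203.0794     | 203.195 | 203     |
| dHex   | 146.0579     | 146.143 | 146     |
| Neu5Ac | 291.0954     | 291.255 | 291     |
| SO₃    | 79.9568      | 80.063  | 80      |

plus water (18.0106 / 18.015 / 18) and the PA increment (78.0582 / 78.118 /
78; reductive amination with 2-aminopyridine adds C₅H₆N₂ + 2H − O). The
integer **nominal [M+H]⁺** (nominal sum + 1) reproduces all 27 printed map
masses exactly and is the validation convention; `round(monoisotopic + 1.00728)`
agrees within ±1 Da everywhere but drifts one dalton high for the largest
(7-residue) structures, which is why map validation tolerates ±1 while
exact comparisons use the nominal convention. Rounding, where needed, is
half-away-from-zero. MS/MS worked examples occasionally quote precursor
windows 1 Da above [M+H]⁺ (isolation-window convention); the ±1 Da mass
tolerance absorbs this.

## Structure grammar

Input accepts the field's condensed notation with Unicode or ASCII anomer
symbols, branches in parentheses or square brackets immediately before
their parent, linkage inline (`β1-3`) or parenthesized (`(b1-3)`), sulfate
as a `HSO3-6`/`S6-` prefix or `[6S]` modifier, and an optional `-PA`
suffix. A non-root residue written without any linkage parses with unknown
anomer/positions (`?`). Canonical output uses Unicode anomers, `[6S]`
modifiers, and parenthesized branches with children ordered by parent
attachment position ascending, the lowest-position child continuing the
written chain; equality and map lookup compare canonical strings. Note the
canonical form may legitimately reorder branches relative to a source
string (e.g. `GalNAcα1-3(Fucα1-2)Gal…` canonicalizes with the 2-linked
fucose written first); both parse to the same tree. Invariants enforced at
parse time: Neu5Ac links from C2 and everything else from C1; no two
substituents on one hydroxyl; sulfates only on free ring positions 1–6.

## Enzymatic operations

Exoglycosidase rules (editable TSV) specify released residue name(s),
anomeric configuration and an optional exact linkage. One digestion round
removes every currently-terminal matching residue; exhaustive digestion
iterates to a fixpoint. Two deliberate conventions: the PA-tagged root is
never removable, and **sulfated residues resist exoglycosidases** (standard
behavior for 6-O-sulfated GlcNAc against hexosaminidase); both are
rule-independent guards. Sialylation adds Neu5Ac (α2-3 or α2-6) to a named
acceptor whose target hydroxyl is free; if several residues qualify, the
caller must disambiguate by the acceptor's own linkage — guessing is an
error, not a default. GlcNAc6ST-1 sulfation enumerates terminal GlcNAc
residues with a free C6 and returns all mono-sulfated products ordered by
the enzyme's branch preference: the β1-6-linked GlcNAc first, remaining
sites by attachment position. The ordering is a deterministic preference,
not kinetics; rates live in the simulator. Whether the enzyme can act on
internal GlcNAc is unaddressed in the source data; terminal-only is
assumed.

## Fragment-based branching evidence

Only B/Y glycosidic cleavages are modeled (no cross-ring A/X ions, no
intensities, no sodiated series). Each non-root residue defines one bond;
its subtree is the B piece (nominal m/z = residue sum + proton) and the
remainder the PA-retaining Y piece (nominal [M+H]⁺). The topology verdict
uses the multiset of per-cleavage Y compositions: *branched* if two
different cleavages give the same composition (symmetric arms) or two
distinct compositions share a residue count; *linear* if the distinct
compositions form the complete inclusion ladder of suffix sizes n−1…1;
otherwise *indeterminate*. This agrees with the true topology for every
map structure of ≥3 residues. Caveat: the symmetric-arm case relies on
recognizing duplicate fragment masses as two cleavages, which a real
spectrum shows only as one peak — on instrument data the verdict for such
structures should be treated as supporting, not conclusive, evidence.

## Profiling and quantitation

Peaks carry a `group_id` linking the C30 and amide observations of one
analyte, the Mono-Q fraction label and its user-declared charge class
(N = 0, MS = 1, DS = 2). Times convert to GU per column; the group is
matched with a joint query over all observed axes plus the charge gate, so
agreement between columns is required by construction. A group whose joint
query is empty while a single axis alone would match is marked *conflicted*
and reported as unassigned with its area still in the denominator — never
silently dropped. Molar percent = group area / total non-excluded area ×
100, under the equimolar-fluorescence assumption for PA derivatives
(one fluorophore per reducing end). The C30 area is the quantitation
value when present (it is the dimension on which fractions are collected);
amide-only groups fall back to their amide area. Percents are computed over
the total glycan pool, not per charge fraction. Exclusion labels (default
`melibiose`, the lectin-elution sugar that contaminates IgA preparations)
remove carryover peaks before the denominator is formed; excluding every
peak is a hard error.

## Simulator

The simulator emulates the separation, not the chromatography: per column
an affine GU→time model (amide 5 + 1.2·GU min, C30 3 + 2.0·GU min —
arbitrary, fixed, invertible), exact ladders from the same model, Gaussian
GU noise (default σ = 0.05 GU, a realistic inter-run reproducibility for
GU indexing), and multiplicative area noise. True coordinates come from the
map, so simulated mixtures exercise calibration, gating, matching and
quantitation end to end; a zero-noise run reproduces the generating mixture
exactly. What it does *not* emulate: peak shapes and overlap, baseline
drift, detector saturation, co-elution of unmapped species, and
inter-column area disagreement — so passing pipeline tests demonstrate the
logic of the workflow, not robustness to raw-trace artifacts.

The sulfotransferase branch-preference experiment is modeled as two-site
first-order parallel kinetics on a substrate carrying one β1-6 and one
β1-3 terminal GlcNAc: with preference ratio r and total rate k, site rates
are k·r/(1+r) and k/(1+r); only mono-sulfated products form, matching the
observed product pair. Time-course amounts were published only as figures,
so the model is validated by parameter recovery (refitting r and k from
noisy synthetic curves at the experiment's 1/5/24/48 h sampling design)
rather than against printed values.

## Numerical choices and problem sizes

GU calibration is piecewise linear (the standard GU convention; monotone by
construction) with linear extrapolation of the terminal segments, flagged
and warned — sub-GU-1 map entries (down to 0.4) make extrapolation below
DP 1 routine. Calibration inverse round-trips hold to 1e-9 within the
calibrated range. Composition enumeration is exhaustive over the bound box
(defaults Hex ≤ 6, HexNAc ≤ 6, dHex ≤ 2, Neu5Ac ≤ 4, SO₃ ≤ 2; ~2 200
cells), so no search heuristics are involved. Test-suite statistics use
fixed seeds throughout: 1 000 random queries for the matcher-vs-brute-force
equivalence, and ≥500 simulated peak groups (full-map mixtures, σ = 0.05 GU)
for the Monte-Carlo assignment-accuracy check — sizes chosen to make the
checks decisive while the whole suite runs in seconds.

## Known limitations

* The map covers 27 structures; retention prediction for unmapped
  structures is explicitly out of scope — queries off the map return empty
  results, not guesses.
* Charge gating treats sulfate and sialic acid as equivalent single
  charges; true Mono-Q elution distinguishes them more finely.
* The nominal-mass convention is exact for the bundled map but, like all
  nominal conventions, will drift from monoisotopic reality for much larger
  glycans (≥ ~3 000 Da).
* The branched/linear verdict weakens on symmetric-arm structures on real
  spectra (see above).
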