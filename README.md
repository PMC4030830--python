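# oglycomap

A toolkit for identifying and quantifying mucin-type *O*-glycans by
multidimensional HPLC mapping of their pyridylaminated (PA) derivatives.

## The problem

*O*-glycans released from glycoproteins are often small — mono- to
heptasaccharides — and rich in isomers that mass spectrometry alone cannot
distinguish (e.g. three different structures share the composition
(Hex)₁(HexNAc)₂ and a nominal [M+H]⁺ of 665 Da). HPLC mapping solves this by
giving each PA-labeled glycan a reproducible coordinate pair: its **glucose
units (GU)** on an amide (size-fractionation) column and on a C30 (extended
reversed-phase) column, measured against a ladder of PA-isomalto-
oligosaccharides (glucose polymers, DP 1–20). An anion-exchange (Mono-Q)
pre-fractionation separates neutral, mono- and di-anionic pools first.
Identification is coincidence of (GU amide, GU C30) with a reference entry,
backed by mass, charge class, and — for map-ambiguous isomers — in-silico
exoglycosidase digestion whose product must land on another map entry.

`oglycomap` packages this workflow:

* a **27-structure reference map** of neutral, sialylated and sulfated
  PA-*O*-glycans with GU coordinates on both columns and printed masses;
* a parser/serializer for **condensed glycan notation**
  (`Galβ1-3(GlcNAcβ1-6)GalNAc-PA`, ASCII `Gal(b1-3)[GlcNAc(b1-6)]GalNAc-PA`,
  sulfate as `HSO3-6GlcNAc…` or `GlcNAc[6S]…`);
* a **mass engine** (monoisotopic, average, and the integer nominal [M+H]⁺
  convention that reproduces every printed map mass exactly) and a
  composition search over a bounded (Hex, HexNAc, dHex, Neu5Ac, SO₃) box;
* **GU calibration** (piecewise-linear, invertible, extrapolation-flagged);
* tolerance-based **identification** with charge gating, per-axis
  normalized scoring and explicit ambiguity flags;
* **in-silico enzymology**: six exoglycosidase rules, α2,3/α2,6-
  sialyltransferases, and GlcNAc6ST-1 sulfation with its β1-6-branch
  preference;
* **B/Y fragment prediction** and a branched-vs-linear verdict from
  PA-retaining fragments;
* end-to-end **molar-percent profiling** of peak lists (areas of PA
  derivatives are treated as equimolar fluorescence responses);
* a **simulator** for calibration ladders, noisy peak lists, and sulfation
  time courses, so the whole pipeline is testable without an instrument.

## Worked example

The classic identification walk-through — an unknown mucin *O*-glycan
eluting at GU 3.2 (amide) / 4.6 (C30) with a MALDI mass of 665 Da:

```sh
$ oglycomap identify --gu-amide 3.2 --gu-c30 4.6 --mass 665
rank	structure	score	d_amide	d_c30	d_mass	ambiguous
1	Galβ1-3(GlcNAcβ1-6)GalNAc-PA	0.0000	+0.000	+0.000	+0.000	False
```

A single candidate within tolerance: the branched core-2 trisaccharide.
Its fragments confirm the branch —

```sh
$ oglycomap fragments -s "Galβ1-3(GlcNAcβ1-6)GalNAc-PA"
# precursor [M+H]+ 665
type	composition	pa_retaining	mz_nominal
B	(Hex)1	False	163
Y	(HexNAc)2-PA	True	503
B	(HexNAc)1	False	204
Y	(Hex)1(HexNAc)1-PA	True	462
# topology verdict: branched
```

Two distinct PA-retaining fragments of the same size (one missing the Hex,
one missing a HexNAc) mean two branches off the core. Enzymatic
confirmation in silico:

```sh
$ oglycomap digest --enzyme "b1,3-galactosidase" -s "Galβ1-3(GlcNAcβ1-6)GalNAc-PA"
product	GlcNAcβ1-6GalNAc-PA
removed	1
cleaved	True
```

The digestion product is itself a map entry at C30 GU 6.3, so the observed
post-digestion shift to that coordinate closes the identification. Masses
for any structure:

```sh
$ oglycomap mass -s "Gal(b1-3)[GlcNAc(b1-6)]GalNAc-PA"
canonical	Galβ1-3(GlcNAcβ1-6)GalNAc-PA
composition	(Hex)1(HexNAc)2-PA
monoisotopic_M	664.2804
average_M	664.664
nominal_M	664
nominal_MH	665
```

Other subcommands: `search` (compositions from a mass), `calibrate`
(ladder CSV → GU conversions), `sialylation` / `sulfation` (derived
standards), `profile` (peaks CSV → molar-percent TSV), and
`simulate peaks` / `simulate sulfation` for synthetic fixtures.
`oglycomap --version` prints the bundled map checksum.

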