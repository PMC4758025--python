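# Methods

This note documents the models, defaults, numerical choices and known
limitations of `isoxl`. Empirical statements here are limited to what the
test suite and `scripts/acceptance.py` themselves compute.

## Mass model

All masses are neutral monoisotopic Da from a single frozen constants
table (`isoxl.constants`); average masses are never used, matching
Orbitrap-class precursor accuracy. Precursor masses are stored internally
as neutral masses and converted to/from m/z only at file boundaries
(MGF `PEPMASS` is m/z). The worked precursor pair printed in the
literature for this workflow (2388.329/2400.404 Da, z = 4) is treated as
a pair of neutral masses; this is a documented convention, and the
m/z converters allow the opposite reading.

The BS3 bridge remaining after both NHS esters react with primary amines
is the suberic diacyl group C8H10O2, 138.0681 Da. The hydrolyzed
(dead-end) form adds water (156.0786 Da); a loop link adds the bare
bridge. The heavy (D12) form adds 12 × (m(²H) − m(¹H)) = 12.07532 Da in
every attachment form; candidate arithmetic carries this through exactly
(machine precision), so the heavy/light precursor difference is
12.0753 Da by construction.

## Digestion

Fully tryptic digestion with per-residue-type missed-cleavage budgets
(K ≤ 3, R ≤ 1 by default), mirroring how these limits are quoted for
cross-link searches rather than a single combined total. Cleavage before
proline is suppressed by default (classic trypsin specificity;
configurable off). The protein N-terminal methionine is not auto-removed.
Variable modifications are restricted to methionine oxidation
(+15.9949 Da, ≤ 2 sites); all combinations are enumerated as separate
peptide forms, and the 200–5000 Da mass window is applied to the modified
peptide mass. A linker-modified K at a peptide C-terminus still counts
toward the missed-cleavage budget (the alternative — exempting the
cross-linked K — would enlarge the search space by one missed cleavage in
rare edge cases; at the scales this package targets the effect was judged
negligible and the simpler budget kept).

Decoys are reversed sequences with a `REV_` prefix; reversal is an
involution, palindromic collisions are warned about but kept. I/L are
kept as distinct letters.

## Candidate enumeration and fragments

Site classes follow amine/hydroxyl-directed chemistry: the anchoring
site is K or a protein N-terminus; the second site is K, S, T, Y or an
N-terminus (the first class is a subset of the second). A K at position 1
of an N-terminal peptide yields two distinct sites (alpha-amine and side
chain). Exactly one linker per candidate is modelled. Pair candidates are
canonicalized with the longer peptide as α (ties broken lexicographically),
so reported pairs are unique. Enumeration is windowed at 3 ppm of the
observed precursor against a mass-sorted peptide index; dead-end and loop
forms are generated alongside two-peptide candidates, in both linker
forms.

b/y fragments are generated at charges 1–2 within a 100–2000 m/z window.
A fragment spanning the link site carries the linker contribution: bridge
plus the entire partner peptide for two-peptide links, the hydrolyzed
linker for dead-ends. For loop links the bridge is added once to any
fragment covering at least one of the two sites; fragments inside an
opened loop are not modelled separately. Neutral losses are off by
default.

## Spectrum matching and score

Peaks below a noise floor are removed before matching. The noise level is
estimated as the median intensity of the lower-intensity half of the
peaks, multiplied by the S/N setting (2.0); the floor is additionally
capped at the base-peak intensity so the strongest peaks always survive.
The lower-half median was chosen over the whole-spectrum median because a
whole-spectrum median sits inside the *signal* population whenever
fragment peaks outnumber noise peaks and then removes most genuine
fragments; the lower-half median tracks the noise level in both
signal-rich and noise-dominated spectra.

Each theoretical fragment matches its nearest surviving peak within
±0.8 Da; a peak may satisfy several fragments (flagged ambiguous). The
PSM score is

    score = −10·log10 P(X ≥ k),  X ~ Binomial(n, p)

with k matched fragments of n theoretical ones in range and p the
per-fragment random-match probability (2 × tol × surviving-peak count /
spanned m/z range, clamped to (0, 1)), plus an explained-intensity bonus
of 20 × (matched / total surviving intensity). The score is deterministic,
non-negative and monotone in k. No fixed score threshold is ever used:
score scales are engine-specific, so the acceptance threshold is always
derived from the decoy FDR (target 5% by default) of the dataset at hand.

## Isotope-pair validation

Criterion 1 requires identical peptide/site/modification assignment in
the light and heavy searches and a precursor difference within 5 ppm (of
the light precursor) of the 12.0753 Da shift — ppm rather than absolute
because instrument error scales with mass. Criterion 2 requires
|ΔRT| ≤ 0.5 min; d0/d12 isotopologue co-elution on reversed phase is
near-exact and the tolerance only absorbs scan-scheduling jitter.
Criterion 3 compares matched fragment *labels* (series, index, peptide,
charge), which are linker-form independent, by Jaccard similarity with a
0.6 threshold; labels whose observed light→heavy m/z shift is neither ~0
nor ~12.0753/z are dropped from the intersection. Pairing is 1:1 greedy
by score sum (ties by smaller |ΔRT|, then deterministic key order);
unpaired PSMs are reported with the missing-partner reason. Validation is
symmetric under swapping which run is called light (with the expected
shift negated).

Redundant peptide-level identifications (missed-cleavage and oxidation
variants, repeated spectra) are collapsed to unique residue-pair links by
grouping on the sorted ((protein, residue position)) pair, with an
N-terminal attachment mapped to residue 1.

## Structural filtering

Reactive atoms: K→NZ, S→OG, T→OG1, Y→OH, N-terminus→backbone N. If the
side-chain atom is absent from a resolved residue the filter falls back
to CB, then CA, adding a recorded 3 Å slack to the cutoff. Residues
present in the entity (SEQRES) sequence but without atoms are flagged
unresolved; a link with an unresolved site is reported **unconstrained**,
never pass/fail — flexible, unresolved termini are precisely where
cross-linkers react most, and silently passing or failing such links
would both be wrong.

The SAS distance is the shortest path through solvent between the two
reactive atoms: a 3-D grid (1.0 Å spacing) over the endpoints' bounding
box plus margin marks cells within (vdW + 1.4 Å probe) of any heavy atom
as blocked (vdW radii C 1.7, N 1.55, O 1.52, S 1.8 Å; hydrogens ignored;
the two query residues are unblocked), endpoints snap to the nearest free
cell within 2× spacing (snap offsets added), and a 26-connected
uniform-cost search with step costs {1, √2, √3} × spacing returns the
path length, or ∞ if no free path exists (buried endpoints included). An
optional `max_path` cap aborts the search early; the 35 Å filter uses it
so pass/fail never requires exploring the whole box. Because every step
cost equals its Euclidean length, SAS ≥ Euclidean always holds; the
26-connectivity overestimates open-space distances by ≤ ~8%.

The 35 Å default cutoff reflects the 11.4 Å BS3 spacer plus two lysine
side chains (~13 Å) plus ~10 Å of conformational dynamics. SAS is the
primary criterion, with the Euclidean distance reported alongside.

## Docking assessment

CAPRI conventions in one constants block: residue–residue contacts at
5 Å (any heavy-atom pair), interface residues at 10 Å, backbone =
N/CA/C/O. f_nat is the fraction of reference contacts reproduced; an
interface-residue recall is reported alongside because "fraction of the
native interaction site" is ambiguous between the two. Ligand RMSD is
computed over the ligand backbone after superposing on the receptor
backbone (no further fitting); interface RMSD after superposing on the
reference interface backbone. Superposition is closed-form Kabsch
(covariance SVD, det +1 enforced; collinear input rejected). Classes:
high if f_nat ≥ 0.5 and (L-RMSD ≤ 1 or i-RMSD ≤ 1); medium if ≥ 0.3 and
(≤ 5 or ≤ 2); acceptable if ≥ 0.1 and (≤ 10 or ≤ 4); else incorrect.

## SPR fitting

Steady-state responses only; kinetics are out of scope. The one-site
isotherm R(C) = R_max·C/(K_D + C) is fitted by unweighted nonlinear least
squares (bounded Levenberg–Marquardt via trust-region reflective),
started from K_D = concentration nearest half the maximal response and
R_max = 1.1 × maximal response; standard errors come from the covariance
at the optimum. Non-convergence returns a flagged result, never an
exception. A fit with K_D above half the top concentration or a relative
K_D SE above 0.5 is flagged poorly determined ("approximate" affinity,
the situation of weak binders in a 50 μM-top series). The default
titration grid is two-fold dilutions from 50 μM down to ~98 nM
(10 points), three replicates, 2% multiplicative Gaussian noise floored
at zero — the screening conditions the recovery studies emulate. The fit
is scale-equivariant in concentration and recovers noiseless synthetic
data exactly.

## Synthetic data generator

The generator emulates the isotope-coded cross-linking study conditions,
not physics: chains are random K-rich sequences (≥ 8% K, modest R so
tryptic peptides stay informative) laid out as ideal α-helical Cα traces
(1.5 Å rise, 100°/residue, 2.3 Å radius) on a 17 Å grid, so inter-chain
reactive distances straddle the 35 Å cutoff. A configurable fraction of
chains have their first 2–5 residues unresolved, emulating flexible
termini missing from crystal structures; B-factors rise toward chain
ends. Planted links (20 by default, 90% involving an N-terminus) must
satisfy SAS ≤ 35 Å when both sites are resolved; a pair with an
unresolved site is accepted as geometrically unconstrained, matching how
termini-involving links evade structure-based prediction. Site pairs
falling on a single tryptic peptide are not planted (they would be loop
links, not the peptide-pair links being modelled).

Per link, one light and one heavy MS2 spectrum are emitted at charge 3–4
(1+/2+ precursors are rejected instrument-side): b/y fragments at charges
1–2, each retained with probability 0.7, intensities log-normal
(median 1000, σ_log 0.5), 30 uniform noise peaks (median 80), retention
times shared up to 0.05 min Gaussian jitter, precursors differing by
exactly the d12 shift plus independent 0.5 ppm mass error. Because
isotopologues ionize and fragment near-identically, the fragment
retention mask and per-fragment intensities are drawn once per link and
shared between the two forms, with a 5% independent per-spectrum dropout
and 10% intensity jitter — this is what makes criteria 2 and 3
scientifically meaningful on simulated data. Ten noise-only spectra per
true spectrum supply the false-positive load. All draws flow through one
seeded generator in a fixed order, so FASTA/PDB/MGF outputs are
byte-identical for a fixed seed.

What the generator does **not** model — isotope envelopes, chimeric
spectra, charge-state distributions beyond the z ≥ 3 rule, retention
prediction, real side-chain geometry — bounds what passing tests show
about real data: they validate the decision logic (search, FDR, pairing,
distances), not robustness to instrument artefacts.

## Problem sizes and reproducibility

The end-to-end study conditions used by the test suite are 4 chains of
50 residues, 20 planted links, 440 spectra; the SPR recovery studies use
100 seeded triplicate titrations per affinity. The pipeline's data
products (TSV/FASTA/PDB/MGF) are reproducible byte-for-byte under a fixed
seed; the run log is excluded from that guarantee because it carries
wall-clock timestamps.

## Known limitations

- Site localization between neighbouring reactive residues is genuinely
  ambiguous when no distinguishing fragment survives; ties are broken
  deterministically (N-terminal/lower site preferred), and both runs of a
  pair break them identically.
- One linker per candidate; multiply cross-linked peptides are not
  searched.
- MS1 features (elution profiles, isotope patterns) are not used; RT is
  taken from the MS2 scan header.
- The SAS grid treats the structure as rigid and ignores hydrogens and
  side-chain flexibility beyond the fallback slack.
- Quantification from light/heavy intensity ratios is out of scope; the
  1:1 mixing is used for validation only.
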