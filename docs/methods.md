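# Methods

## Model and assumptions

A glycopeptide is modelled as a peptide backbone (neutral monoisotopic
mass *B*) carrying one N-glycan, a rooted tree of monosaccharide
residues (Hex, HexNAc, NeuAc, NeuGc, dHex) whose reducing-end HexNAc is
bonded to the sequon asparagine.  Glycosidic cleavages that retain the
peptide produce Y ions at *B + g*, where *g* ranges over the masses of
connected subtrees containing the root (plus *g* = 0 for the naked
peptide).  Spectra cannot distinguish isobaric subtrees, so matching
operates on the distinct-mass set; subtree multiplicity is kept only for
reporting.  All internal masses are neutral; reports print MH⁺ because
published backbone masses are conventionally singly protonated.  The
0,2X0 cross-ring ion is fixed at +83.037114 Da (HexNAc − C₄H₈O₄).

Assumptions inherited from the acquisition design: each CID scan shares
its precursor with the triggering HCD scan (pairing tolerance 10 ppm,
RT gap ≤ 10 s); the MS3 precursor is the Y1 ion selected from the HCD
scan, with charge 1+ or 2+ (both are tried); MS2 fragments may appear at
any charge up to the precursor charge.

## Scoring

Matched-peak assignment is greedy by smallest |ppm|: one peak satisfies
at most one theoretical ion and each (ion, spectrum, charge) slot takes
one peak, which prevents double counting.  The score is

    [ Σᵢ intenᵢ · (1 − (|merrᵢ|/tolᵢ)⁴) ] · ratio_ion^α · ratio_core^β

summing matched peaks over both spectra of the pair; a theoretical ion
counts once toward `ratio_ion` if matched in either spectrum.  The
quartic weight is the concrete form chosen for the published
"quartic polynomial" penalty: 1 at zero error, 0 at the tolerance edge,
continuous at the boundary.  α = 0.22, β = 0.45 (the published
cross-validated values); fragment tolerance 20 ppm, precursor 10 ppm.
Intensity is raw (absolute); per-spectrum base-peak normalisation is
available by configuration, default off.  The theoretical core set is
restricted to composition-consistent ions (Y3/Y4/Y5 need ≥1/2/3 Hex, the
fucosylated forms ≥1 dHex, Y2 and up ≥2 HexNAc) so non-fucosylated or
small glycans are not penalised for unreachable ions.  Candidates whose
deduced backbone falls below 500 Da are discarded as chemically
implausible.  Ties are broken by more core ions matched, then database
order, and flagged.

## Glycan FDR

The decoy is spectrum-based: the candidate's theoretical ion offsets are
perturbed and rescored with the identical function.  Three
constructions: i.i.d. +U[1, 30] Da per ion (default; integer shifts by
config), fixed +11 Da, and mass reversal (total glycan mass minus each
Y mass).  Y0 is shifted like every other deduced Y ion (config flag to
exempt it).  One decoy per candidate; random shifts are drawn from a
per-(pair, candidate) seeded stream so results are independent of search
order.

The mixture model works on log1p-transformed scores.  The incorrect
component is anchored on the decoys: a point mass at zero (decoys that
matched nothing — no positive threshold retains them) plus a Gamma fit
to the positive decoy scores, both held fixed.  EM over the target
scores updates π₀ and a Gaussian correct component with exact M-steps,
so the log-likelihood is non-decreasing by construction (asserted in
tests).  Because incorrect *target* matches can score far above any
mass-perturbed decoy — a wrong glycan whose subtree masses partially
coincide with the true ladder harvests real, intense peaks — π₀ is
additionally estimated by an unconstrained two-Gaussian EM on the
targets, guarded by a BIC comparison against a single Gaussian so a
clean unimodal score population is not split; the final π₀ is the larger
of the two estimates.  This deliberately errs conservative: the adaptive
estimate may absorb genuinely correct low-scoring matches into the
incorrect component, raising reported FDR above the truth, which is the
direction the original validation also showed (real error well below the
reported 1%).

FDR(t) = π₀ · S_incorrect(t) / S_mixture(t) with model survival
functions; q(s) = min over t ≤ s of FDR(t), hence monotone.  Runs with
fewer than 50 target or decoy scores fall back to classical competitive
target-decoy counting.

The decoy construction drives the estimate through S_incorrect: the
mass-reversal decoy leaves Y0 ↔ full-glycan and other near-symmetric
masses identical to target masses, so its decoys score near target
level and the reported FDR is inflated severely; a constant +11 Da
keeps decoy ions on the peptide mass-defect comb of the chemical
background (0.0053 Da off at z = 1, inside a 20 ppm window), so it
matches structured background more often than a continuous shift, which
leaves the comb almost surely.  The continuous +U[1, 30] default is the
most nearly exchangeable with coincidental matches and gives the
closest-to-conservative estimate — the benchmark reproduces exactly this
ordering.

## MS3 peptide search

Semi-tryptic digestion (cleave after K/R, not before P; ≤2 missed
cleavages; length 5–40), N→J substitution inside N-X-S/T/C sequons with
X ≠ P (overlapping sequons each substituted), fixed carbamidomethyl-C
(+57.021464), variable oxidation-M (+15.994915) and HexNAc-J
(+203.079373), at most 3 variable modifications.  Candidates lie within
±3 Da of the neutral MS3 precursor; theoretical ions are singly charged
b/y plus the −203.079 HexNAc loss for fragments containing the modified
J (the glycosidic bond stays labile in MS3); fragment tolerance ±0.5 Da
(ion trap).  The PSM score is hyperscore-flavoured —
(ln Nb! + ln Ny! + 1) · ln(1 + matched intensity fraction) — any score
monotone in evidence suffices because acceptance is FDR-calibrated, and
it is documented as replaceable.  Decoys are reversed proteins with the
sequon substitution re-applied after reversal, keeping modifiable-site
statistics comparable; classical target-decoy q-values; only
HexNAc-on-J PSMs at q ≤ 0.01 are accepted.

## Alignment and reporting

A GSM aligns to the PSM whose naked backbone mass (peptide mass minus
the HexNAc on J) is within 20 ppm of the deduced backbone and whose RT
is within 6 minutes (the typical span of a microheterogeneity cluster),
best by |ppm| then |ΔRT|; one GSM yields at most one GPSM while one PSM
may support many GSMs.  An optional constant RT-offset calibration
(median ΔRT of aligned anchors) is provided for systematic between-run
shift, default off.  Non-redundancy collapses on (peptide, protein site,
glycan COMPOSITION): composition, not structure, because isomers sharing
all Y masses are not distinguishable and microheterogeneity tables list
compositions.  The ion-complementarity report counts core species
matched in HCD only / CID only / both and non-core ions per kind.

## Synthetic data

The generator emulates the two-run product-dependent design with
planted ground truth.  Defaults (the study conditions): 5 ppm Gaussian
MS2 mass error; 0.1 Da MS3 error; precursor charges 2–4; a 60-minute
gradient with ≤3-minute RT jitter between runs; HCD pick probabilities
Y0 0.8, Y1 0.95 (dominant, the premise of the data-dependent MS3
trigger), 0,2X0 0.7, outer Y 0.2, oxonium series 1.0 with 138.055 most
intense; CID inner 0.5, outer 0.8, 0,2X0 0.02; MS3 b/y 0.85 and neutral
loss 0.5.  Background: 150 peaks per spectrum, 70% "chemical"
(fragment-like, on the 1.00048 Da/nominal mass-defect comb, log-normal
intensity spanning the dynamic range) and 30% uniformly distributed
faint electronic noise.  The chemical fraction matters: real deisotoped
HCD spectra carry hundreds of unassigned fragment-like peaks on the
comb, and without them the +11 and reversal decoys lose the structured
background they exploit, making the decoy-method comparison physically
unreproducible.  The default glycan database (50 random N-glycans on the
trimannosyl core) excludes NeuGc, matching human-serum-like samples and
avoiding built-in exact-isobar twins.

Degraded ("weak") plants scale the pick probabilities by 0.35 and double
the noise — they supply genuine incorrect matches for the FDR
benchmarks.  Planted-false spectra use an exact isobaric composition
swap found by searching the composition lattice (NeuGc + dHex =
NeuAc + Hex to ~1 µDa): a spectrum is generated from a structure absent
from the database whose swapped twin is present, yielding
wrong-composition matches that pass every filter.  Such confounders are
score-indistinguishable in principle — no decoy method can flag them —
so they are excluded from the recovery/error benchmark and exist to
demonstrate exactly this limitation.

What passing the synthetic benchmark does not show about real data:
peaks are monoisotopic only (no isotope envelopes, since the pipeline
deisotopes), there is no co-isolation or chimeric fragmentation, the RT
model is uniform rather than chromatographic, intensity models are
log-normal per ion class rather than physical, and the protein
background is six small synthetic proteins rather than a proteome.

## Benchmarks and problem sizes

The end-to-end benchmark plants 200 well-fragmented and 150 degraded
glycopeptides against a 50-glycan database (700 target+decoy trials),
sized to run in about a minute per decoy method; recovery is measured on
the well-fragmented class at 1% glycan + 1% PSM FDR, and realized error
at the GPSM level (glycan AND peptide checked against the plant) —
wrong-glycan GSMs carry wrong deduced backbones and mostly fail
alignment, so GPSM-level error is the right analogue of a
manually-verified glycopeptide list.  The mixture-recovery check draws
2000 scores from Gamma(2, 1) / Normal(10, 1.5) with π₀ = 0.4 and
requires recovery within ±0.05.

## Numerical choices and degenerate inputs

Distinct Y masses merge below 10 µDa; rooted-tree isomorphism uses a
canonical sorted encoding; deisotoping is greedy intensity-descending
without isotope-pattern fitting; empty spectra, empty databases, zero
plants and candidates at exactly the tolerance edge are all defined (the
quartic weight vanishes at the edge; a precursor equal to the glycan
mass discards the candidate).  The Gamma location sits 0.05 below the
smallest positive decoy score to avoid the shape<1 density singularity;
EM convergence is Δloglik < 1e-6 or 500 iterations, non-convergence is
flagged and the last iterate returned.

## Known limitations

Glycan identification is database-ranked; topology beyond the database
is not inferred, and linkage/anomericity are out of scope.  Exact
isobaric composition swaps (NeuGc+dHex vs NeuAc+Hex) are
undetectable by mass alone.  The MS3 engine is a minimal, replaceable
search engine, not a reimplementation of a production peptide search
tool; protein inference stops at accession lists.  The +11-decoy
inflation observed on real instruments is reproduced only in direction
here: its magnitude depends on the density and intensity structure of
real chemical background, which the generator only approximates.
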