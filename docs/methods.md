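# Methods

## Mass model

All masses are monoisotopic, from a hard-coded CODATA/NIST element table
(`oligoms.chem.ELEMENT_MASSES`) so results are bit-stable. An *internal
residue* is defined as the nucleoside-3′-monophosphate minus one water; the
neutral mass of a chain is then

    M = Σ residues + H₂O + Δ₅′ + Δ₃′

with terminus adjustments relative to the 5′-OH/3′-linear-phosphate baseline:
Δ(5′-P) = +HPO₃ (79.96633 Da), Δ(3′-OH) = −HPO₃, Δ(3′-cP) = −H₂O
(a 2′,3′-cyclic phosphate is one water lighter than the linear phosphate).
This convention makes 5′-OH/3′-P — the natural product of endonucleolytic
cleavage and the termini used for score training — the adjustment-free case.
Negative-mode m/z uses the deprotonation convention
m/z = (M − z·1.007276)/z; positive mode and adducts are out of scope.

Modified residues are rows of a single-character alphabet (case-sensitive
letters and digits; lowercase a/c/g/u denote 2′-O-methyl forms) carrying the
residue formula and the neutral base formula, user-extensible via TSV. Well
over 50 modification codes can coexist in one digest.

## Isotope labeling

A labeling scheme is a set of substitution rules applied to elemental
formulas, never per-residue constants, so heavy−light differences are exactly
the summed per-atom isotope deltas. Uniform metabolic labels (¹⁵N, ¹³C)
substitute every atom of an element; residue-specific rules substitute a fixed
count (e.g. 5,6-²H-uracil feeding: two deuteriums retained on C and U-derived
pyrimidines, one on pseudouridine, whose C5 hydrogen is lost when the C–C
glycosidic bond forms). Purines are left unlabeled under the deuterated-uracil
scheme because they are not biosynthesized from the fed uracil. These rules
reproduce the characteristic ambiguities of labeled RNA: U−C = 0.984 Da
natural, |U−C| = 0.013 Da under uniform ¹⁵N, and a 0.022 Da Ψ/C shift under
deuterated-uracil feeding (≈22 ppm at trinucleotide scale).

## Digestion

Cleavage is modeled 3′ of any residue in the enzyme's specificity set, leaving
3′-P/5′-OH products; the parent's own termini are inherited by the chain-end
fragments. Missed cleavages up to a configured maximum are enumerated
exhaustively; coordinates are 1-based inclusive to match standard residue
numbering in modification reports. Built-in specificities: T1 after G (and
m⁷G), A after pyrimidines including Ψ, dihydrouridine, m¹Ψ, m³U and m⁵C.
Cusativin (after C), MC1 (after U/Ψ) and MAZ (after A) ship as editable
literature-default approximations — their exact base preferences vary between
preparations, so they are configuration, not asserted constants. 2′-O-methyl
residues never appear in specificity sets since both RNase mechanisms require
a free 2′-OH. Nonspecific digestion enumerates substrings bounded by min/max
length to keep the library finite. Partial-cleavage efficiency models are a
non-goal.

## Fragment ions

For an n-mer, each series contributes ions at indices 1…n−1 counted from its
own terminus. Neutral masses are anchored at the d series (prefix chain with
its 3′-phosphate):

    dᵢ = Σ₁..ᵢ res + H₂O + Δ₅′      cᵢ = dᵢ − H₂O
    bᵢ = dᵢ − HPO₃                  aᵢ = bᵢ − H₂O
    a-Bᵢ = aᵢ − (neutral base of residue i)
    yⱼ = Σ last j res + H₂O + Δ₃′   wⱼ = yⱼ + HPO₃
    xⱼ = wⱼ − H₂O                   zⱼ = yⱼ − H₂O
    y-Pⱼ = yⱼ − HPO₃,  z-Pⱼ = zⱼ − HPO₃   (3′-P oligos only)

The complementary pairs a+w, b+x, c+y, d+z each reconstruct the neutral
precursor mass exactly (atom conservation across a single backbone cleavage
with hydrogen transfer); the test suite asserts this identity to <1e-4 Da on
random modified oligos and is the primary oracle for the offset table. a-B is
emitted for i = 1…n−1 like every other series. Precursor losses (M, M−H₂O,
M−HPO₃, M−base for each distinct base) are generated at the precursor charge
states only; they are exclusion/annotation ions and never count toward n or L.
Charge states come from editable length-keyed tables (defaults: precursor
z = 1 for ≤3-mers rising to 1–3 for ≥8-mers; fragment z = 1, adding 2 from
length 4), reflecting that observable charge distributions are empirical,
per-platform inputs. Internal fragments and isotope-envelope prediction are
non-goals.

## Decoys and SeqX

A decoy is a random permutation of a target's residues with the 3′-terminal
residue fixed (preserving the enzyme's cleavage signature); homopolymeric
prefixes yield no decoy. Decoys duplicating another decoy or any target
sequence are discarded, so the decoy:target ratio is at most one.

SeqX consolidation merges same-length entries whose precursor m/z agree within
the MS1 threshold at every shared charge *and* whose series-aligned fragments
all agree within the MS2 threshold. Grouping uses transitive closure
(union-find), making the result order-independent and idempotent; members keep
their own masses but are renamed with an X placeholder at differing positions
("AXG: ACG|AYG" / "AXG: AYG|ACG"). Decoys indistinguishable from any target
are removed. For the deuterated ACG/AΨG pair the binding constraint is the a₂
ion at ≈40 ppm (a-B cancels exactly because the label difference lives on the
base), so consolidation engages once tolerances reach ≈23/41 ppm. Which MS2 ions ought
to participate in the comparison is genuinely open; the all-ions rule was
chosen as the strictest defensible criterion, and the predicate is a single
function that can be relaxed if a workflow warrants it.

## Scoring

S_p = (ΣI_match/ΣI_all)·(n/L)·(1 + Σ_s B_s). Peaks matching the precursor or a
precursor-loss ion are identified first and excluded — together with a ±1.5 m/z
window around each (wide enough to cover isotope envelopes; configurable) —
from ΣI_all and from the normalization maximum. Unmatched noise peaks remain
in ΣI_all; that denominator is what penalizes wrong candidates. Assignment is
greedy by ascending |ppm error| with each peak and each theoretical ion used
once (ties: higher intensity, then lower m/z), which is deterministic and, on
spectra whose candidate ions are separated by more than twice the tolerance,
provably optimal in (matches, total error) — the property the brute-force
enumeration oracle checks.

The consecutive-match reward uses B_s = β·α·k_s with k_s the number of
adjacent matched index pairs (i, i+1) inside series s, charge states pooled
per series; defaults β = 0.025, α = 2. This linear-in-consecutive-pairs form
is the natural extension of the SEQUEST-style consecutive-ion reward with a
separate amplification factor; since other reward shapes (e.g. run-length
nonlinearities) are plausible, the term is isolated in one pure function
(`consecutive_bonus`) and can be swapped without touching the matcher. L
counts all generated candidate ions of the entry across its tabulated fragment
charges. S_p is zero when nothing matches, scale-invariant under uniform
intensity rescaling, and non-decreasing as correct peaks are added.

Ranking ties break by larger n, then target before decoy, then lexicographic
sequence. When the top score is zero, all ΔS_p values are reported as zero and
flagged degenerate.

## FDR and diagnostics

Simple FDR = D/T over rank-1 OSMs at a uniform cutoff (the D/T rather than
(D+1)/T convention, matching common usage in concatenated target-decoy
searches). The cutoff for a requested level is the minimal observed score
whose FDR is at or below the level; unreachable levels return +inf with a
warning. The default statistical view can be restricted to targets with at
least one competing decoy (short RNA oligos sometimes admit none). Offset
diagnostics report mean/σ (sample σ; MAD-based option) and histograms of
signed ppm errors; the mean is the global offset correction, and 2σ is the
heuristic used to choose SeqX thresholds. Mixture-model FDR and posterior
error probabilities are non-goals.

## Synthetic data

The generator draws spectra from target entries only: the precursor peak, each
fragment detected with probability p (default 0.9), log-normal intensities,
Gaussian ppm jitter (3 ppm MS1 / 8 ppm MS2 — typical Q-TOF-class accuracy),
and uniform-m/z noise peaks with weaker intensities (default 10/spectrum).
Optionally the recorded precursor sits on the M±1 isotopologue. It emulates
peak-picked negative-mode CID spectra sufficiently to exercise matching,
scoring, FDR calibration and coverage end to end; it does **not** model
fragmentation propensities, chromatography, co-isolation or isotope envelopes,
so synthetic recovery rates validate the bookkeeping and statistics, not
instrument-level performance on real data. Everything is driven by one seeded
generator; fixed seeds give byte-identical mgf files, decoy sets and OSM
tables.

## Problem sizes in the test suite

Unit fixtures are trinucleotides to 13-mers; the workflow tests use two
random 150-nt references (T1, one missed cleavage, ≈140 entries with decoys)
and 200 simulated spectra — large enough for stable recovery and FDR
estimates while keeping the default suite fast on a single CPU.

## Known limitations

- The exact published form of the consecutive-match reward and of the SeqX
  MS2 sub-criterion are approximated as described above.
- Average (non-monoisotopic) masses, positive-ion mode, adducts, internal
  fragments, intensity prediction, retention-time modeling and isotope-ratio
  quantitation are out of scope.
- Cusativin/MC1/MAZ specificity sets are pragmatic defaults, not measured
  constants; users with characterized enzyme lots should override them.
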