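# Methods

## Degenerate-codon model

A degenerate codon is a triple of IUPAC ambiguity letters; its meaning is
the equimolar mixture of all concrete codons in the Cartesian product of
the three base sets. Equimolar mixing within each letter is an assumption
about the synthesis chemistry (standard mixed-base coupling); biased
mixes and trimer phosphoramidite synthesis are out of scope. Residue
distributions follow by translating each concrete codon under NCBI
translation table 1 and summing uniform weights 1/expansion_count.

Two translation modes are exposed. `standard` is the default. Because
common display hosts (e.g. *E. coli* TG1) are amber suppressors that read
TAG as Gln, `amber_suppressed` reassigns the TAG mass to Gln while
leaving TAA/TGA as stops. Every report records the mode in force.

Diversity products (DNA variants per cassette, stop-free peptides, pool
totals) use arbitrary-precision integers throughout: a 28-codon NNK
stretch has 32²⁸ ≈ 1.4×10⁴² DNA variants, far beyond 64-bit range. The
number of distinct stop-free peptides factorizes over positions (they
are independent), as the product of per-position distinct non-stop
residue counts; this is validated against brute-force peptide
enumeration for all test cassettes with ≤10⁵ DNA variants.

## Cassette design

VL CDR3 spans Kabat 91–96. Variant A fixes Tyr91 (the residue observed
in roughly half of natural kappa chains); variant B randomizes 91 with
NNK. Mixed 50:50, the pool shows ≈50% Tyr91 plus the small Tyr mass of
NNK, approximating the natural bias. Positions 92 and 93 carry the
restricted DRC (N/S/D/G/Y/C) and RRY (N/S/D/G) codons, 94 and 96 carry
NNK, and 95 is fixed Pro. VH CDR3 cassettes place k NNK codons between
fixed Arg94 and Asp101 anchors (the conserved salt bridge); k runs 5–22
in the S sublibrary and 9–28 in the L sublibrary, one cassette per
length, pooled equimolar by default with an optional length-weight
vector. Loop length always counts randomized residues only — the
anchors are excluded.

Kabat insertion labelling assigns 95…100 and then 100a…100z, supporting
loops up to 32 randomized residues; longer requests raise an error
rather than inventing labels.

Fixed-position codons default to common human codons (Tyr→TAT, Pro→CCT,
Arg→CGT, Asp→GAT) and are configurable, as the construct's exact primer
sequences are not public. For the same reason the shipped template is
synthetic: a fixed surrogate scFv with plausible framework codons, a
parent VL CDR3 (YSELPT) containing the SacI site and a parent VH CDR3
(RASWGD) containing the NheI site, each unique template-wide. It is
explicitly labelled synthetic wherever it appears.

## Template depletion

Residual unmutated template is removed enzymatically via the two unique
sites. `check_template_sites` verifies placement (site inside its CDR3
interval) and genome-wide uniqueness; both sites are palindromic, so
forward-strand scanning covers both strands.

`cassette_site_regeneration_risk` computes the exact probability that a
random cassette realization contains a recognition site, including
windows overlapping up to 5 nt of each fixed arm. Occurrence windows
overlap, so per-window probabilities do not simply add; instead a
distribution over KMP-automaton states (lengths of the currently
matched site prefix) is propagated across the independent per-position
base distributions, giving the exact containment probability in
O(length × |site|). The computation is validated against brute-force
enumeration on small cassettes. For the shipped design the risk is
exactly zero for both assigned sites — no frame of an NNK stretch (or
arm-overlapping window) can complete GAGCTC in the VL cassettes or
GCTAGC in the VH cassettes, because each alignment requires a base the
design cannot produce at some position.

## Primer QC

Rules: |ΔGC| between arms ≤ 5 percentage points (inclusive), each arm
GC strictly below 50%, and each arm Tm within ±3 °C of 45 °C
(inclusive). The Tm tolerance is a package default — the underlying
protocol states only "closely to 45 °C" — and is configurable. Tm uses
the Wallace rule 2(A+T)+4(G+C) for arms ≤14 nt and nearest-neighbor
thermodynamics (Allawi & SantaLucia 1997 unified parameters, SantaLucia
1998 salt correction, 50 mM Na⁺, 25 nM per strand) for longer arms; the
method used is recorded in each report. GC rules are evaluated on the
arms only, since the degenerate core has no defined GC content.

Equimolar pooling solves v_i = n/c_i for a per-primer molar target
(default 100 pmol), so equal-concentration primers contribute equal
volumes; molecule counts are reported via N = c·N_A·v.

## Repertoire QC

CDR3s are located by approximate matching of 12-nt framework anchors
flanking each designed interval, allowing one mismatch per anchor by
default. The best-scoring placement wins; a tie between equally good
placements, or a missing anchor, marks the clone unanchored. Extracted
regions with length not a multiple of 3 are flagged frameshift; in-frame
regions containing a stop are flagged internal_stop.

A clone is flagged as residual template if either extracted CDR3 equals
the template CDR3 exactly or contains the depletion site assigned to
that region — mirroring the enzymatic logic, under which any plasmid
retaining a site is cut. A mutant that regenerates a site by chance is
therefore reported as template, which is the operationally correct call
(it is depleted like one); for the shipped design this event has
probability exactly zero (see above).

Summary statistics (length histograms, position × residue count
matrices, per-position Shannon entropy in bits, logo frequency
matrices) are computed over *usable* clones: extracted, in-frame,
non-template and — by default — stop-free, since stop-containing clones
cannot display in a non-suppressor context; the exclusion is
toggleable. Template clones are tallied separately and kept out of the
diversity statistics. VH positions are pooled across loop lengths by
Kabat label (how the natural-repertoire comparison bins them is a
reporting choice; a length-stratified alternative is available because
label-pooling is not the only defensible convention). Reference
comparison uses the Jensen–Shannon divergence, base 2, per shared
position (0 for identical distributions, 1 bit for disjoint support).

Library size from serial dilutions is count × dilution / plated
fraction per replicate, reported as mean ± sample SD.

## Synthetic-data generator

The generator emulates sequencing randomly picked colonies of the
constructed library: it draws a sublibrary (default S:L = 0.306:0.694,
the ratio of the reported sublibrary colony counts, with a VL-only
option defaulting to weight 0), a uniform VH loop length within the
sublibrary range, a VL variant (50:50), realizes every degenerate
position uniformly, splices the realizations into the template
framework, and with probability `template_fraction` emits the unmutated
template instead. Sequencing errors are applied post-realization —
substitutions first, then indels (insertion/deletion 50:50, uniform
inserted base) — each per-base Bernoulli. One PRNG stream per run makes
outputs byte-identical for a fixed config and seed.

What it does not emulate: chromatogram noise structure, the synthesis
length bias visible in real length distributions (uniform lengths are
the default; a weight vector is exposed), PCR recombination, and any
Kunkel biochemistry beyond its composition-level consequence (the
template fraction). Passing tests therefore demonstrate correctness of
the analysis logic under the stated generative model, not robustness to
every artefact of real Sanger data.

ELISA fixtures draw binder wells from a high lognormal component
(median 1.2 A450 units, σ_log 0.2) and non-binders/negative controls
from a low one (median 0.08, σ_log 0.15) — a conventional positive/
background separation for a strong screen; the parameters are
configurable, and recovery degrades monotonically as the components
overlap. Panning fixtures grow the output/input ratio geometrically per
round with optional lognormal noise.

## Screening triage

Enrichment is output/input titer per round plus consecutive-round fold
changes. ELISA hits satisfy A450 ≥ threshold × negative-control level
with threshold 4 by default; equality counts as a hit. The control
level is the arithmetic mean of the negative wells (median optional;
which summary the original screen used is not documented, so the mean
is the default and the choice is explicit). Hit calling is monotone in
absorbance and invariant to common scaling of all wells. Candidates are
ranked by descending fold-over-control with lexicographic id
tie-breaking for determinism.

## Problem sizes and numerical choices

The test suite exercises the full 15³ degenerate-codon space against
enumeration oracles, brute-force-validates diversity counts for
cassettes up to 10⁵ DNA variants, and uses repertoires of 190 clones
for round-trip checks and 10,000 clones for distributional checks
(spiked-template recovery judged against the exact Clopper–Pearson 95%
interval; empirical NNK position frequencies within total-variation
0.05 of theory). Probability sums are validated to 1e-12; logo rows to
1e-9. `scripts/acceptance.py` reports the spiked-template recovery at
n = 10,000 and template_fraction 0.111.
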