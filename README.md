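# scfvlib

Design, diversity accounting and QC toolkit for **semisynthetic scFv
phage-display antibody libraries** whose diversity is concentrated in the
CDR3 loops.

Synthetic antibody libraries are built by oligonucleotide-directed
(Kunkel) mutagenesis: degenerate primer cassettes are annealed onto a
uracil-containing single-stranded template, and the mutant strand is
enriched in an *ung+* host. `scfvlib` covers the computational side of
designing and characterizing such a library:

* **Degenerate-codon algebra** — exact expansion of IUPAC ambiguity codons
  (NNK, DRC, RRY, …), translation under the standard genetic code
  (optionally with amber suppression, TAG→Gln), and exact-integer
  accounting of DNA- and protein-level cassette diversity.
* **CDR3 cassette design** — VL CDR3 cassettes spanning Kabat 91–96
  (two variants for the ~50% natural Tyr91 bias, conserved Pro95;
  restricted DRC/RRY codons at 92/93, NNK at 94/96) and VH CDR3 cassettes
  of 5–22 (S sublibrary) or 9–28 (L sublibrary) NNK residues between the
  conserved Arg94/Asp101 salt-bridge anchors, with Kabat insertion
  labelling (100a…100z).
* **Template-depletion checks** — verification that the unmutated template
  carries unique SacI (VL CDR3) and NheI (VH CDR3) sites, and an exact
  automaton-based computation of the probability that a randomized
  cassette regenerates a recognition site by chance.
* **Primer QC** — arm GC balance (|ΔGC| ≤ 5 points), GC < 50%, Tm ≈ 45 °C
  (Wallace rule for short arms, nearest-neighbor thermodynamics beyond),
  and equimolar pooling volumes via n = c·v, N = c·N_A·v.
* **Repertoire QC** — anchor-based CDR3 extraction from sequenced clones,
  loop-length histograms, per-position residue counts and Shannon
  entropies, residual-template detection, sequence-logo matrices, and
  Jensen–Shannon comparison against a natural-repertoire reference;
  library sizing from serial-dilution colony counts.
* **Screening triage** — panning output/input enrichment trajectories and
  ELISA hit calling by the ≥4-fold-over-negative-control rule.
* **Synthetic data** — a seeded generator producing clone reads, ELISA
  plates and panning titers with full ground truth, so the whole pipeline
  is testable offline.

## Worked example

```python
from scfvlib import aa_distribution
from scfvlib.cassette_design import default_library_design, theoretical_library_stats
from scfvlib.repertoire_qc import analyze_reads, estimate_library_size, summarize_repertoire
from scfvlib.synthetic_data import GeneratorConfig, generate_repertoire

# NNK encodes all 20 residues with a single stop (TAG) at mass 1/32
dist = aa_distribution("NNK")
print(len(dist.residue_support), dist.stop_probability)   # 20 0.03125

# Theoretical reservoir of the S+L design (exact integers, rendered here
# in scientific notation)
design = default_library_design()
_, totals = theoretical_library_stats(design)
print(totals["S"]["n_cassettes"], totals["S"]["dna_diversity_sci"])  # 18 1.34e+33
print(totals["L"]["n_cassettes"], totals["L"]["dna_diversity_sci"])  # 20 1.44e+42

# Library size from colony counts (count × dilution / plated fraction)
mean, sd, _ = estimate_library_size([168, 175, 176], [1e8])
print(f"{mean:.3g} ± {sd:.2g}")                           # 1.73e+10 ± 4.4e+08

# Simulate sequencing 190 colonies of the library and summarize
reads, truth = generate_repertoire(design, GeneratorConfig(seed=42, n_clones=190))
clones = analyze_reads(reads, design)
summary = summarize_repertoire(clones, design)
print(summary.n_total, summary.n_usable, summary.template_count)  # 190 89 0
print(summary.entropy["VL"]["95"])                        # 0.0 (fixed Pro)
```

The usable count (89 of 190) reflects clones whose realized cassettes are
stop-free under the standard code: a k-NNK loop survives with probability
(31/32)^k, so long VH loops frequently carry a TAG codon (which an
amber-suppressor display host would read through; pass
`mode="amber_suppressed"` to analyze under that convention).
`template_count` is 0 because no residual template was spiked in.

A command-line interface mirrors the library (`scfvlib design`,
`scfvlib primer-qc`, `scfvlib repertoire-qc`, `scfvlib triage`,
`scfvlib synth repertoire|elisa|panning`).

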