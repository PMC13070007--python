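# Methods

This note records the models the package implements, the defaults it
chooses where the procedure admits more than one reasonable reading, and
what the synthetic data do and do not establish about real experiments.

## Library design

A saturation round is defined by a parent scFv, a set of *backbone*
substitutions fixed in earlier rounds, and the remaining mutable CDR
sites. Each site contributes one variant per allowed amino acid (by
default the 19 non-parental canonical residues), so the library size is
`1 + Σ_site |allowed|`; the reference configuration of 74 sites gives
1,406 variants plus the backbone-only parent entry, shrinking to
73 × 19 = 1,387 and 72 × 19 = 1,368 as one and two positions are frozen.

Which residues to *exclude* from saturation (rare neighbouring residues,
low-diversity positions) is expert curation driven by external antibody
sequence statistics; it is not reproducible from first principles, so the
package models it as a user-supplied per-site exclusion map and treats
74 × 19 as the reference point.

Coordinates are 0-based half-open internally; display labels attached to
positions are opaque strings, which avoids committing to any particular
antibody numbering scheme (Kabat, IMGT, Chothia). Mutation strings use the
`<parentAA><label><newAA>` convention, comma-joined with light-chain sites
before heavy-chain sites and ascending position within a chain.

Reverse translation uses one fixed high-usage codon per amino acid. Any
valid encoding suffices because synthesis is outsourced and selection acts
on the translated protein; the table is configurable.

## Read pipeline

The amplicon is sequenced as an ordered set of segments (eight in the
reference design) that tile the concatenated CDR windows, carrying a
sample index and a 14-mer UMI. Choices made where the protocol is
under-determined:

- **UMI collapse key** is (UMI, full read sequence) with zero UMI mismatch
  tolerance: the same UMI with a different sequence stays a distinct
  molecule. This is the conservative reading — PCR errors inside a UMI
  family inflate the molecule count slightly rather than silently voting
  on a consensus.
- **Counting unit** defaults to UMI-collapsed molecules; counting raw
  reads is available behind a flag (`count_molecules=False`), since count
  ratios can legitimately be computed either way.
- **Error handling** is purely structural: a molecule whose translated
  window differs from the round backbone by two or more amino acids, or by
  one amino acid not enumerated in the design, is *unassigned*. A single
  matching alteration is that clone; zero alterations is the parent. There
  is no quality-score filtering. An internal stop codon, a non-ACGT base
  or a mis-sized segment marks the molecule *untranslatable*. All sinks
  are reported in a QC table and satisfy conservation
  (assigned + unassigned + untranslatable = molecules).
- **Singleton novel variants** (one alteration outside the design) are not
  promoted to new clones, because scoring is defined over designed clones.
- **Barcode mismatch tolerance** defaults to 0; with a tolerance, a read
  within distance of two barcodes is discarded as ambiguous.
- Per-segment trimming and frame are supplied as a layout (JSON); the
  default layout tiles the CDR window evenly with no trimming, matching
  what the bundled read simulator emits.

Classification is exact-match against the enumerated design rather than a
nearest-neighbour search; tests verify it agrees with an exhaustive
minimum-Hamming-distance scan over the backbone and all clones.

## Scoring

Counts get 95% normal-approximation bounds n ± 2√n (lower bound floored
at 0). Stringency biases the statistics against false positives:

- binding ratio = lower(n_TRBC2) / max(upper(n_TRBC1), ε)
- enrichment ratio = (lower(n_TRBC2)/N_TRBC2) / (max(n_input, ε)/N_input)

with ε = 1 read as the denominator floor (keeps zero-count denominators
finite and scales with depth). Two points are deliberate interpretations:
the confidence bound inside the enrichment ratio is applied to the
TRBC2-bound clone count only — the stringency rule names the cell-bound
pools, and input totals are large enough that their bounds are negligible
— and sample totals are raw column sums over assigned clones, not
CI-adjusted. Both are configurable (`use_ci`).

Normalization to 0–100 is a linear min–max map per statistic per library
(an all-equal vector maps to 0). Ranking defaults to descending
min(binding_norm, enrichment_norm) — a next-round backbone should be high
on *both* statistics — with ties broken by raw binding ratio then clone
id; a pure binding-ratio ordering is available (`top_k_by_binding`).

## SPR kinetics

Pure 1:1 Langmuir, no mass-transport or bulk-refractive-index terms:
association R(t) = Req·(1 − e^(−(ka·C + kd)·t)) with
Req = Rmax·C/(C + KD), dissociation R(t) = R(t_c)·e^(−kd·(t − t_c)).
The default schedule mirrors a multi-cycle protocol: threefold dilutions
from 1,000 nM down to 4.1 nM (six cycles), 60 s contact, 300 s
dissociation, 1 Hz sampling. Fitting is global least squares sharing
(ka, kd, Rmax) across all cycles, run in log-parameter space from a 5 × 5
log-spaced multistart grid over ka ∈ [10³, 10⁷] M⁻¹s⁻¹ and
kd ∈ [10⁻⁵, 10⁻¹] s⁻¹ (commercial instrument software internals are not
public; a multistart grid is the robust generic choice). Noiseless
simulated data are recovered to better than 10⁻³ relative; with 1% Rmax
noise the fitted KD at a true 10 nM is typically within a few percent.

The off-rate survival fraction is e^(−kd·t) with kd in s⁻¹ — a
first-order dissociation model. At kd = 0.0013 s⁻¹ and t = 600 s the
package reports 0.4584; an antibody with that off-rate keeps roughly 46%
of its complexes through a 10-minute window, the kinetic argument for
preferring slow off-rates in internalization-dependent applications.
(An equilibrium constant in molar units cannot appear in this exponent
dimensionally; the rate constant is the only consistent reading.)

## Assay metrics

Quadrant percentages, malignant fraction and DAR are plain ratios,
reported at full precision. Drug loads must be integer-labelled by the
user — identifying half-loaded species in a hydrophobic-interaction
chromatogram is a judgment call outside the package. Dose-response fitting
is a 4-parameter logistic on untransformed doses with the orientation
canonicalized to top ≥ bottom via the sign of the hill slope; flat data
raise rather than return an arbitrary IC50. Responses are assumed
normalized upstream (fraction of untreated control).

## Synthetic data

`simulate_panning` draws each sample as an independent multinomial: input
counts from the clone fractions f, bound pools from proportions ∝ f·p
where p is the per-clone capture probability on that cell line. Capture
probabilities are specified directly (interpretable ground truth); an
optional equilibrium-occupancy link p = C·KA/(1 + C·KA) is provided for
affinity-driven scenarios. One bind–wash–sequence pass per library is
modelled — no phage re-amplification between rounds.

`emit_reads` realizes a count table as segmented reads: fresh random
14-mer UMI per molecule, geometric PCR duplication (default mean 2 reads
per molecule), independent per-base substitution errors (default 0.001,
an Illumina-like order of magnitude), and exact sample barcodes. Defaults
were chosen once as plausible bench values and are configurable.

What the simulations do **not** model: phage growth/amplification bias,
chimeric PCR artifacts, wash-stringency and nonspecific background
binding, quality-score structure, and indels. Passing tests therefore
demonstrate that the pipeline arithmetic is correct and that the scoring
recovers a planted selective clone under sampling noise; they do not
certify performance on real panning data, where amplification bias and
background binding dominate the error budget.

Problem sizes used in the self-checks: the end-to-end recovery runs on a
toy 8-site design (153 clones) at 100,000 molecules per sample over 100
seeds — large enough for the multinomial noise regime the scoring assumes,
small enough to iterate on a laptop; KD-recovery uses 100 seeded
replicates of the six-cycle schedule, and the acceptance script reports
the median over 25 replicates.

## Known limitations

- Classification requires an exact length match of the translated window;
  indels are out of scope by construction.
- The enrichment ratio's confidence-bound placement and the 0–100
  normalization are the package's own documented interpretations of an
  under-specified procedure; both have flags to switch behaviour.
- The 1:1 fit assumes a shared Rmax across cycles (perfect regeneration).
- Sites fully excluded by the user silently drop out of the design rather
  than erroring; the manifest records the realized site count.
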