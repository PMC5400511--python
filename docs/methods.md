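# Methods

## The curation model

The pipeline assumes a four-arm wild-type design plus a genetic-null
control: for each of two copper conditions (BCS chelation, CuCl₂ loading)
the bait is immunoprecipitated with and without an excess of its antigenic
peptide, and the same isolation is performed once in bait-null cells.
Spectral counts (PSMs) are the semi-quantitative abundance measure; they
are additive evidence, so replicate samples within an arm are summed before
any ratio is formed (a per-replicate majority-vote mode would be a natural
alternative, but summing is the default because single-replicate designs
are common and a sum loses nothing there).

Calling is per condition. For protein *i*, with summed counts `a` in the
−peptide arm and `b` in the +peptide arm:

- `b == 0` and `a >= min_count` (default 2) → ratio `+inf`, automatic pass.
  A protein seen repeatedly only without competitor is the strongest
  qualitative evidence this design offers.
- otherwise ratio `(a + c)/(b + c)` with symmetric pseudocount `c = 0.5`,
  pass iff strictly greater than the threshold `τ = 2`. The pseudocount
  keeps single-spectrum observations from passing on division noise; the
  strict inequality is the primary convention, with a `--ge`/`inclusive`
  switch for the ≥ reading.
- proteins never observed in the −peptide arm receive no record and cannot
  be hits; the bait itself is evaluated like any prey but reported
  separately, never as an interactor.

Null subtraction removes a hit iff its summed PSM across null-cell −peptide
samples reaches `null_min_count` (default 2, not 1, so a single stray
spectrum in the null control does not discard a hit). Curation without a
null control is refused unless explicitly requested.

Conditions are reconciled as union (= the interactome) and intersection
(= the core of stable interactors seen regardless of copper state). The
union convention for "the interactome" is a deliberate choice where an
aggregation rule had to be fixed; the per-condition sets are always
reported alongside so nothing is lost.

Contaminant-list overlap is reported as a percentage of the interactome
(one decimal, half-up rounding) and members are annotated, **not**
removed — a bead-proteome compendium is a quality check, not ground truth
for any particular antibody/matrix combination. `drop_contaminants`
converts the annotation into a filter for users who want it.

## Over-representation scoring

For a hit list of size `n` in a universe of `N` symbols and a set with `K`
universe members of which `k` are hits: exact upper-tail hypergeometric
`p = P(X ≥ k)` (never a normal approximation), BH step-up `q` across all
sets tested in a collection, Haldane-corrected odds ratio (correction 0.5
applied only when a 2×2 cell is zero), the hypergeometric standardization
`z = (k − nK/N)/sd` with `sd² = nK(N−K)(N−n)/(N²(N−1))`, and the combined
ranking score `z · (−log₁₀ p)`. Degenerate margins (empty/full set or hit
list, `N = 1`) give `z = 0` and hence a combined score of 0; depleted sets
score negative.

Two deliberate choices here. First, `z` is the hypergeometric
standardization rather than the rank-based deviation computed by web
enrichment services; the latter depends on service-side background
permutation tables that cannot be reproduced offline, so published
combined-score magnitudes from such services are not comparable targets.
Second, the default universe is the detected proteome (all proteins
quantified in any IP arm) intersected with the collection's members — the
standard guard against abundance bias in AP-MS ORA — with a user-supplied
universe as an override. Gene symbols are matched case-insensitively
(symbol casing is inconsistent across published collections); opaque
protein identifiers are never case-folded.

## The synthetic-data generator

`SimulationConfig` defaults describe a realistic neuronal-cell bait IP and
are the conditions under which the pipeline is validated:

| parameter | default | meaning |
|---|---|---|
| `n_true` | 150 | true preys |
| `n_background` | 800 | bead-background proteins |
| `frac_shared` | 0.5 | preys bound under both copper conditions |
| `mu_true` | 25 | mean PSM of a prey in its −peptide arm |
| `mu_background` | 8 | mean PSM of a background protein, every arm |
| `suppression` | 0.1 | prey mean multiplier in +peptide arms |
| `dispersion` | 5 | negative-binomial size (Poisson as → ∞) |
| `frac_contaminant` | 0.3 | background proteins on the contaminant list |
| `bait_psm` | 200 | fixed bait count in −peptide WT arms |
| `null_leak` | 0.05 | prey null-arm mean as a fraction of `mu_background` |

Counts are negative binomial in (mean, size) parameterization because
overdispersion is the norm for spectral counts. Condition-private preys are
split evenly after removing the shared fraction, the rounding remainder
going to the BCS-only group. Zero draws are omitted from the PSM table —
an undetected protein is simply absent from a sample, as in real search
output. Bait counts are fixed rather than sampled so bait-detection
behaviour is deterministic. One top-level seed drives everything, with
per-arm substreams `seed + offset` (offsets 1–5 in arm order), so adding an
arm cannot reshuffle draws in existing arms.

**Null-arm leak.** True preys draw null-arm counts at mean
`null_leak × mu_background` (default `mu_background/20`) rather than
structurally zero, so null subtraction is exercised nontrivially;
`null_leak = 0` gives exact zeros. The default was fixed by a Monte-Carlo
calibration of the negative-binomial tail before the validation thresholds
were frozen: at size 5, a mean of 0.4 trips the `null_min_count = 2` filter
for ≈7% of true preys — enough to make null subtraction consequential —
whereas a mean of 0.8 removes ≈19%, which no longer describes a null line
that merely *leaks* trace bait expression.

**No-competition control.** With `suppression = 1` the +peptide arm carries
no signal and the filter must not discriminate between classes. Pass rates
are only exchangeable when the two classes share a count distribution
(the pass probability of an iid ratio depends on the mean through
CV² = 1/μ + 1/size), so this control runs with `mu_true = mu_background`;
with unequal abundances a pass-rate difference reflects dispersion
geometry, not specificity leakage.

**What the generator does not emulate:** peptide-level evidence and protein
inference, correlated abundances between interacting proteins, shared
peptides, batch effects between arms, intensity information, or a rescue
arm. Passing tests therefore demonstrate correctness of the curation
arithmetic and its statistical behaviour under the stated count model — not
robustness to protein-inference artefacts or batch structure in real data.

## Validation sizes and numerics

The test suite validates the hypergeometric tail against full enumeration
on every parameter tuple with N ≤ 12, BH against the direct step-up
definition on 1000 random vectors, and the whole curation path against a
straight-line recomputation (plain loops over the written TSV/YAML) on
simulated experiments of ≤ 50 proteins; recovery is measured on three
default-sized simulations (950 proteins each) and the no-competition
control on 50 replicates of 80 proteins, sizes chosen to keep Monte-Carlo
error well below the margins being asserted while the suite runs in
seconds. Ratio comparisons at the threshold use exact arithmetic on
integers plus a single pseudocount addition; the overlap percentage is
computed in decimal arithmetic to make half-up rounding exact. Floating
oracle comparisons use 1e-12 absolute tolerance.

## Known limitations

- Scoring is a ratio threshold, not a probabilistic interaction model
  (no SAINT/CompPASS-style posteriors); there is no peptide-to-protein
  inference, no intensity-based quantitation, and no FDR at the
  identification level — the input is assumed to be a filtered PSM table.
- GO term redundancy is not collapsed; each set is tested independently.
- The identifier namespace is opaque: bridging protein accessions to gene
  symbols is the caller's responsibility when collections and PSM tables
  disagree.
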