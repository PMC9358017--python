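# Methods

## Site models

Every sense codon has nine single-base neighbors (three per position).
Classifying each neighbor by translation gives the counts Sti, Stv
(synonymous transitions/transversions), Nti, Ntv (non-synonymous,
nonsense included), and Nti′, Ntv′ (the subset landing on stop codons).

The **equal-rate model** assigns each change weight 1/3 per position:
S = (Sti+Stv)/3, NS = (Nti+Ntv)/3, so S + NS = 3 for every codon.

The **modified model** weights each transition neighbor by κ (the
transition:transversion rate ratio) and removes nonsense substitutions:

    S  = (κ·Sti + Stv) / (κ + 2)
    NS = (κ·(Nti − Nti′) + (Ntv − Ntv′)) / (κ + 2)

The denominator κ+2 normalizes each position's three neighbors (one
transition of weight κ, two transversions of weight 1) to 3 sites per
codon, so S + NS + (κ·Nti′ + Ntv′)/(κ+2) = 3 exactly. Removing the
nonsense weight reflects the assumption that nonsense mutations are
effectively lethal (they truncate the downstream frame) and therefore
never appear as observable non-synonymous variation.

Assumptions worth stating: a single genome-wide κ (no site- or
context-specific rates), no codon-usage weighting of sites, and complete
lethality of nonsense changes. At κ = 1 with no stop-adjacent codons the
modified model collapses to the equal-rate one.

### Numerical choices

- Arithmetic is exact (`fractions.Fraction`) whenever κ is an integer, so
  the 61-codon tables are bit-stable; non-integer κ falls back to floats.
- Display rounding is half-away-from-zero to 3 decimals (7/6 → 1.167).
- Totals are sums of unrounded per-codon values, rounded once at the end:
  total S at κ = 4 is exactly (4·62 + 72)/6 = 53.333; sums of pre-rounded
  cells differ in the third decimal and are deliberately not used.
- Neighbor enumeration order is fixed (position 1→3, alternative base
  A<C<G<T) so all emitted tables are byte-identical across runs.

## Pairwise dN/dS

For two equal-length, in-frame, codon-aligned sequences, codon pairs are
compared positionally. Pairs differing at exactly one position are
classified synonymous/non-synonymous by translation; pairs differing at
two or three positions are excluded from the counts (no substitution-
pathway averaging) and reported (`n_multi`) so the information loss is
visible; pairs containing a stop codon or ambiguity are likewise excluded
and reported. pS = Sd/S_sites, pN = Nd/N_sites with site totals averaged
over the two sequences (a `sites="first"` option uses the first sequence
only); dN/dS = pN/pS. A ratio with Sd = 0 is flagged undefined, never
reported as zero.

No multiple-hit correction is applied by default, matching the
single-substitution counting rule; an optional Jukes–Cantor transform
(−3/4·ln(1−4p/3)) is available for both proportions. Terminal stop
codons are stripped; an internal stop is an error by default (the method
expects intact CDS) with an explicit skip option. The initiation codon is
included in site sums by default (`skip_start` excludes it).

`compare_methods` scores each gene pair under both site models and
reports percent increase, the gene's TFD:FFD codon ratio (TFD = codons of
the nine two-fold degenerate amino acids; FFD = Val/Pro/Thr/Ala/Gly
codons; six-fold family boxes count as neither), its pretermination-codon
fraction, and Pearson correlations of percent increase against both
covariates (undefined with fewer than three usable genes).

## fS statistic

SNPs are extracted from a multi-strain codon alignment against a
designated reference: one record per distinct non-reference allele per
column, with carrier counts. Default counting is per distinct allele
(invariant to strain sampling depth); `count="strains"` weights by
carriers. Columns whose reference codon contains a gap/ambiguity (or is a
stop) are skipped entirely; a non-reference codon with ambiguity, or
differing from the reference at ≥2 positions (not a single-base change),
drops only that strain's observation.

Counts aggregate by reference codon identity. With s₉ synonymous
neighbors out of nine, Se = s₉/9·(So+NSo), NSe = (9−s₉)/9·(So+NSo), and
fS = So/Se (0 when nothing synonymous was observed; undefined for ATG
and TGG, whose s₉ = 0 — hence the 59-codon statistic). Se+NSe = So+NSo
holds exactly, and ΣSo+ΣNSo equals the number of classified records.

Under a neutral κ:1 substitution process the within-codon synonymous
fraction is (κSti+Stv)/W with W the codon's total accepted weight, giving
analytic limits fS → 3κ/(κ+2) for TFD codons (= 2 at κ = 4) and fS → 1
for FFD codons (exact under allele dedup too, because FFD codons'
synonymous and total neighbor sets have identical Ti:Tv composition).
Split-box codons of Leu/Arg/Ser behave like TFD, family boxes like FFD.

The TFD-vs-FFD comparison uses a two-sided Mann–Whitney U with the
normal approximation and tie correction, without continuity correction so
identical samples give p = 1 exactly; codons with zero observed
polymorphisms are excluded from class summaries.

## Simulator

A star phylogeny: n descendants evolve independently from one reference,
each accumulating a fixed number of *accepted* single-base substitutions
(event-count parameterization keeps tests exact-n and fast; no
continuous-time machinery is needed for calibration purposes). Per event
a codon is drawn uniformly and one of its nine neighbors with probability
κ/(3κ+6) (transition) or 1/(3κ+6) (transversion); the change is accepted
with probability 1 (synonymous), ω (missense), or 0 (nonsense, when
rejection is on). A rejected event redraws *both* codon and change
(capped at 10⁴ attempts), so accepted events land on codons in proportion
to their total accepted weight — the condition under which the neutral
(ω = 1) process yields E[Sd]/S = E[Nd]/NS′ under the κ-matched modified
site model, hence dN/dS → 1. Keeping the codon fixed on redraw would
break this identity; that asymmetry is why full redraw was chosen.

One `numpy.random.Generator` drives each run, seeded explicitly; the seed
is echoed into the FASTA header for provenance. With nonsense rejection
on, no simulated record ever contains a stop codon.

What the generator emulates: a polymorphism panel of conspecific strains
(or a diverged ortholog pair) under uniform mutation pressure with
tunable purifying selection. What it does not emulate: phylogenetic
structure beyond the star, indels, recombination, codon-usage bias of
real genomes (the default reference is uniform over the 61 sense codons),
site-rate heterogeneity, and context-dependent mutation. Passing
calibration tests therefore validates the counting machinery and the
neutral-limit algebra, not the method's behavior on real genomic data.

κ estimation: at third positions of fourfold and family-box codons all
three changes are synonymous (one Ti, two Tv), so the synonymous Ti:Tv
count ratio there is κ:2 and κ̂ = 2·Ti/Tv. Counts are weighted by carrier
strains, which keeps the per-event ratio unbiased where distinct-allele
counting would saturate the (more frequent) transition allele first.

## Test and calibration problem sizes

Chosen as the package's own study conditions: the fS calibration uses a
10,000-codon reference, 100 strains and 200 accepted substitutions per
strain (20,000 events; ~0.7 SNPs per codon column) — dense enough that
every codon type accumulates hundreds of observations, sparse enough
that multi-hit codons stay rare. The dN/dS calibration pools 50
independent 500-codon pairs at 100 substitutions per lineage; κ recovery
uses 20 strains × 200 substitutions on 6,000 codons (≥500 informative
SNPs at all tested κ). All stochastic tests run on fixed seeds.

## Known limitations

- Sites are unweighted by codon frequency; the method is a counting
  refinement, not a likelihood model (no ω estimation, no rate matrices).
- Multi-hit codon exclusion discards information at high divergence; the
  Jukes–Cantor option corrects proportions, not the exclusion itself.
- fS aggregates over codon positions genome-wide; gene-level fS would
  need deeper sampling than the statistic was designed for.
- Only the standard genetic code ships; the table loader is data-driven
  but degeneracy classes and pretermination sets are defined for the
  standard code.
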