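# Methods

## The genetic setting

*T. monococcum* (A^m) and *T. urartu* (A^u) are diploid wheats with seven
homeologous chromosome pairs and largely colinear genomes. Their hybrids
are almost sterile, but rare fertile derivatives exist, so two kinds of
material can be produced and analysed with molecular markers: selfed
progenies of hybrid-derived founder plants whose chromosomes are A^m/A^u
mosaics, and backcross-derived introgression lines carrying single A^u
segments in an A^m background. The package implements the marker analyses
these materials call for, plus a simulator that generates both kinds of
population with known truth.

All coordinates are genetic (centimorgans) on a backbone linkage map;
intervals are closed, linkage groups numbered 1–7. Two marker systems are
modelled: *dominant* fragments (AFLP-like) where the heterozygote is
indistinguishable from the presence homozygote, each fragment labelled by
the species whose genome carries the amplifiable allele
(Am_specific / Au_specific / shared); and *codominant* loci (SSR-like)
with calls RR / RD / DD (R = recurrent A^m allele, D = donor A^u allele).

## The cross simulator

Meiosis draws a Poisson number of crossovers per linkage group with mean
length/100 and uniform breakpoint positions — no crossover interference.
The Kosambi function, which embodies partial interference, is used only to
convert estimated recombination fractions to map distances; the simulator
deliberately keeps the interference-free model, and this asymmetry is the
reason simulated rf→cM conversions are not expected to reproduce simulated
physical spacing exactly beyond short ranges.

Pedigrees start from a cross of the two pure founder genomes and compose
`self` and `backcross` steps with explicit population sizes; all
randomness flows from a single integer seed, so runs are bit-reproducible.
Expected summaries have closed forms used as test oracles: donor genome
fraction 2^−(t+1) after t backcrosses, per-locus heterozygosity 0.5^g
after g selfing generations.

Segregation distortion — the gametic selection that eliminates donor
regions in real wide crosses — is modelled by rejection sampling: a gamete
carrying the donor origin at a distortion region's midpoint is accepted
with odds p/(1−p) relative to a non-carrier, giving donor transmission
probability p from a heterozygous parent, down to complete elimination at
p = 0.

Marker scoring applies dominance masking (an Am_specific fragment is
present iff ≥1 homolog is A^m at its position), with an optional
independent per-call error rate. The fertility generator is a labelled
stand-in — expected fertility clamp(baseline − penalty × donor fraction,
0, 1), seeds binomial over 2 florets/spikelet — because no quantitative
genotype–fertility law exists for this system; it produces realistic
record tables, nothing more.

What the simulator does *not* emulate: crossover interference, cytoplasmic
or imprinting effects behind the strong cross-direction asymmetry of
hybrid fertility, genotyping artefacts beyond symmetric call errors
(e.g. size homoplasy of comigrating fragments), and linkage-map errors in
the backbone. Passing tests therefore demonstrate correctness of the
inference algorithms under Mendelian, well-anchored conditions, not
robustness to every pathology of real AFLP data.

## Two-point linkage

Codominant F2 pairs: maximum likelihood by EM. Every two-locus genotype
class determines its recombinant-gamete count except the double
heterozygote, which is split between parental and recombinant phase
configurations at posterior ratio 2r²/((1−r)²+r²); iteration
r ← E[recombinants]/2n to |Δr| < 1e-8 (max 500 iterations, grid fallback
on non-convergence, plus a coarse-grid probe guarding boundary starts).

Dominant F2 pairs use the class probabilities
(coupling, k = (1−r)²; repulsion, k = r²):
P(both absent) = k/4, P(one absent) = (1−k)/4 each,
P(both present) = (2+k)/4, maximised directly in one dimension (bounded
search, xatol 1e-10, endpoints probed). With phase unknown both models are
fitted and the higher likelihood wins; an exact tie yields phase
`unknown`, and such pairs are excluded from downstream phase calls —
repulsion-phase dominant pairs in F2 are weakly informative and must not
force a call. LOD = log10 L(r̂) − log10 L(0.5). Estimates at the 0/0.5
boundary and near-empty tables are flagged.

Grouping scans rf thresholds 0.250 down to 0.050 in steps of 0.050
(the step size is this package's choice; only the range is standard) and
takes single-linkage connected components over edges with r̂ ≤ threshold
and LOD ≥ 3, producing a nested trajectory — stricter thresholds refine
looser groups.

Kosambi: d = 25·ln((1+2r)/(1−2r)) cM, computed as 50·atanh(2r) for
precision near zero; inverse r = 0.5·tanh(d/50). Round-trip exact to
1e-12 across the domain.

## Mosaic founder reconstruction

The founder of a selfed segregating population carries, per linkage
group, two homologs that are mosaics of A^m and A^u. Fragments sitting on
both homologs are monomorphic-present in the offspring; fragments on
exactly one homolog segregate (presence fraction 3/4 under Mendelian
selfing); fragments on neither are absent. The pipeline:

1. **Species assignment** from reference parent profiles: Am_specific if
   present in ≥1 A^m reference and no A^u reference (symmetrically);
   present in both → shared; present in none → unassigned. Shared and
   unassigned fragments carry no origin information and are excluded.
2. **Dose classification**: presence fraction ≥ 1−tol → monomorphic
   (founder homozygous for that origin at that position); ≤ tol →
   fragment origin absent; otherwise segregating. tol defaults to 0.02,
   comfortably separating 3/4 segregation from monomorphism at n ≳ 100.
3. **Subgroup formation** along the anchored order of each group:
   maximal runs of monomorphic fragments of one species, and runs of
   segregating fragments joined by adjacent two-point estimates passing
   r̂ ≤ 0.25 and LOD ≥ 3 (the minimum-evidence gate).
4. **Classification**: single-species subgroups are homozygous regions.
   Mixed subgroups are phased by walking adjacent pairs — coupling keeps a
   fragment on the current homolog, repulsion switches — partitioning
   members onto two homolog chains. If each chain is species-uniform the
   region is heterozygous (all Am–Au pairs in repulsion); any species
   change along a chain is an internal breakpoint, one crossover on that
   homolog, and the subgroup is a mosaic (Am and Au fragments in
   coupling). Pairs of unknown phase break the chain; a mixed subgroup
   with no usable phase is reported unresolved, never guessed.
5. **Assembly**: anchored intervals (the hull of each subgroup's backbone
   positions) are painted in map order. Anchoring conflicts — members
   mapping to two linkage groups, the signature of duplicated chromosome
   blocks — are flagged and left unanchored, never silently dropped.
   Overlapping intervals with contradictory labels are a hard error.

**Crossover counting** is homolog-level: a boundary between a homozygous
and a heterozygous interval is one exchange event; between the two
opposite homozygous states, two (both homologs must switch); each internal
breakpoint of a mosaic subgroup is one exchange on the affected homolog
(a phase "swap" inside a heterozygous stretch yields two, one per chain).
Event positions are midpoints between the bounding fragments of differing
state, so with fragments every Δ cM the position error is below Δ.
Counting with explicit multiplicity is what makes the inferred events
comparable one-to-one with the gamete-level crossovers a simulator plants;
a diplotype-only count would systematically miss one event at every
hom–hom boundary and both events of every swap.

Undetectable by construction: pairs of crossovers falling in the same
inter-fragment interval on the *same* homolog (the state returns before
the next fragment), and events beyond the outermost anchored fragment.
Both are rare at 2 cM fragment spacing — with ~20 planted events per
founder genome the expected collision count is ≈0.4 — which is why
recovery lands at ≈96%, not 100%, on the simulated founders.

## Introgression panels

Donor segments are maximal runs of DD/RD calls along a group; missing
calls bridge a run up to 20 cM (sparse fingerprint panels make single
missing loci common), beyond which the run splits. Segment borders sit at
the midpoint between the outermost donor locus and the nearest flanking
RR locus; terminal runs extend to the group end; when a gap split leaves
no RR call between two runs, the boundary is the midpoint between the
facing donor loci. A segment containing any RD call is heterozygous.

Panel selection is greedy maximum-new-coverage with lexicographic
tie-breaks, stopping when no line adds more than 1 cM (min_gain, which
keeps sub-resolution slivers out of the panel); optionally restricted to
single-segment lines, the nonredundant-panel convention. Coverage reports
give the union length per group (exact interval arithmetic, validated
against 0.01-cM rasterisation) and percentages to one decimal.

## Diversity

Distances over binary fragment profiles use only jointly scored fragments
(pairwise deletion — no imputation); Jaccard is the default, Dice and
simple matching are options, since the classical AFLP literature varies
and the choice is left explicit. PCoA is classical scaling: eigen-
decomposition of the double-centred −½D², coordinates from the top-k
nonnegative eigenvalues, explained fractions relative to the positive
eigenvalue sum. Negative eigenvalues (non-Euclidean inputs) are truncated
and reported — no Lingoes/Cailliez correction — a simple convention the
result object makes visible. Species-specific counting: a fragment is
specific to one species when present in ≥1 of its lines and absent in
every non-excluded line of the other; intermediate accessions carrying
both species' fragments are excluded by an explicit list before counting.

## Macrocolinearity

Loci shared by name between two maps are classified homeologous when the
second map places them on the declared homeolog of their first-map group
(identity 1→1…7→7 by default, as the two A genomes share numbering);
otherwise non-homeologous, the translocation signal. Kendall τ over
shared homeologous loci summarises within-chromosome order concordance;
τ needs ≥2 loci with distinct positions on both maps, else it is NaN.

## Fertility and transgressive traits

Fertility of a cross is 100 × seeds/(2 × spikelets) (florets per spikelet
configurable), one decimal; seed counts exceeding available florets warn
but do not error. Histograms use decile bins with a closed top bin; all
maximal bins are reported as mode classes and two or more set a bimodal
flag.

The transgressive test runs a one-way ANOVA over all entries of a trait;
the residual mean square gives the pooled standard error; each line is
compared to the better parent with
t = (x̄_line − x̄_bp)/(s·√(1/n_line + 1/n_bp)) on the residual degrees of
freedom, one-sided at α = 0.05 (the question is exceedance), while the
two parents are compared two-sided. No multiple-testing correction by
default, with Bonferroni as an option. Note the power ceiling this
design implies: at two replicates per entry a line planted 3 pooled SDs
above the best parent has noncentrality exactly 3, so one-sided 5% power
is bounded by Φ(3 − 1.645) ≈ 0.91 regardless of residual df — about 0.88
at df = 12. The package reports the measured power honestly rather than
overstating the design's sensitivity.

## Problem sizes and numerics

Validation runs use 7 linkage groups totalling 984 cM, fragments every
2 cM, 200 selfed offspring and 20 founders for mosaic recovery; 1000
random tables for the rf grid-oracle comparison and 200 replicates per r
for bias; 1000 lines for the BC6 expectation; 1000 simulations each for
transgressive power and type-I error. These sizes give standard errors
comfortably below the margins being asserted. Tolerances: EM 1e-8 on r;
bounded search xatol 1e-10; eigenvalues |λ| < 1e-10 treated as zero;
interval arithmetic compared to rasterisation within 0.05 cM. Degenerate
inputs (empty tables, all-zero distance matrices, zero residual df,
zero-variance traits, unanchorable subgroups) are reported or skipped
with warnings, never silently imputed.
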