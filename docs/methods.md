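# Methods

famscan discovers and classifies members of a multi-subfamily protein
gene family in fragmented draft genome assemblies, reconstructs the
family's presence/absence history on a species tree, and tests
constrained tree topologies. This note records the models, the default
parameters and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that affect results.

## Profile hidden Markov models

A profile is estimated from a gapped training alignment restricted to one
subfamily and one fragment region.

**Architecture.** Match columns are assigned by occupancy: column *k* is
a match column iff its non-gap fraction is at least `symfrac` (default
0.5, the conventional choice). Match emissions use background-
proportional pseudocounts, e_k(a) = (c_k(a) + τ q(a)) / (C_k + τ) with
τ = 5.0 by default; c_k are residue counts weighted by position-based
(Henikoff) sequence weights computed on match columns (uniform weighting
is available). Insert states emit the background distribution.
Transition probabilities are Laplace-smoothed (+1) counts of the
match/insert/delete path each row implies; delete-adjacent-to-insert
configurations, which the three-state architecture cannot represent, keep
the direct delete transition while the insert run's boundary transitions
attach to match ends. The background distribution q is the fixed
empirical amino-acid frequency vector of the JTT model, shipped as
package constants, so that profiles built from different inputs share a
common null model; alignment-derived backgrounds can be supplied.

**Local alignment scoring.** The model is unihit and local at both ends:
an alignment fragment enters at any match state *i* and exits at any
match state *j ≥ i*, with a uniform prior 2/(M(M+1)) over the M(M+1)/2
possible (i, j) fragments. Target residues outside the aligned core are
emitted by the background and contribute zero log-odds; the forward sum
runs over every placement of the core in the target. There is no
parametric target-length model: appending background-distributed flanks
changes the score only through the extra (weak) placements in the forward
sum, which the test suite bounds at half a bit for ten flanking residues.
All dynamic programming is carried out in natural-log space with
max-factored sums (the delete chain uses row-max-scaled cumulative sums);
scores are reported in bits. Correctness is defined by exhaustive path
enumeration, which the tests perform for all profiles with M ≤ 3 against
targets up to length 6 at 10⁻⁹ tolerance. The architecture deliberately
omits HMMER3's Dirichlet mixture priors, entropy weighting, multihit
model, and length model; published E-values from HMMER searches are
therefore reproducible in rank behavior, not magnitude.

**E-value calibration.** Each profile is calibrated by scoring `n_cal`
(default 200) i.i.d. background sequences of length `len_cal` (default
2M) and fitting a Gumbel distribution to the bit scores by the method of
moments (λ = π/(σ√6), μ = mean − γ/λ). The per-target tail probability
P(S′ ≥ S) = 1 − exp(−exp(−λ(S − μ))) times the number of scanned
segments gives the E-value. Calibration seeds are recorded in the
serialized profile; the suite checks that null searches yield on average
≈ e hits at threshold e for e ∈ {1, 5, 10}.

**Logos.** Position information content is the relative entropy
R_k = Σ_a e_k(a) log₂(e_k(a)/q(a)); letter heights are e_k(a)·R_k. A
position is flagged as an indel site when its match→insert or
match→delete probability exceeds 0.10.

## Fragment regions and the library

Draft assemblies contain genes as short exons on small contigs, so
profiles are built from four fragment regions of the reference alignment
(named TM1-4, TM4-5, TM6 and TM6-7 after the transmembrane landmarks
they straddle in the GPCR-like target family). Regions are plain
column intervals supplied in configuration; the synthetic family ships
defaults (fractions of the protein body, excluding the C-terminal tail so
the tail-less subfamily trains on equal footing). Rows with fewer than
half the region's columns occupied are dropped from a region's training
set, echoing a full-length-only training policy. A (subfamily, region)
pair whose training set vanishes is recorded as missing rather than
failing the build, since single-region evidence still occurs in practice.

## Classification and ortholog calling

Contigs are translated in all six frames, split at stop codons, and
segments of ≥ 20 residues (shorter matches are uninformative) are scored
against every calibrated profile; hits with E ≤ 10⁻⁵ are retained (the
threshold is configurable and logged — published worked examples show
accepted e-values far below this). Every profile legitimately matches
every family member, so a target's subfamily is the **column winner**:
the profile with the smallest E-value among those scanned against it,
ties broken by higher bit score then name and flagged ambiguous.
Winners are validated **reciprocally**: the segment is searched back
against the whole library including decoy profiles built from unrelated
families, and the assignment stands only if the best-scoring profile
belongs to the assigned subfamily.

Winning hits are grouped by (species, subfamily); distinct fragment
regions are counted across contigs, because exons of one gene are
routinely assembled onto different contigs. A call is *accepted* with at
least two regions of evidence (configurable) and all reciprocal checks
passed; one region gives *ambiguous*; a reciprocal failure gives
*rejected*.

## Presence/absence history

Accepted calls define a species × subfamily presence matrix. Gain and
loss events are placed on a user species tree by binary Fitch parsimony
(equal gain/loss costs) with the state above the root fixed to absent, so
a family present at the root is annotated as an initial gain there.
Ambiguous reconstructions are flagged. Because gene loss dominates the
histories this pipeline targets, a Dollo option (single gain at the MRCA
of present tips, losses below) is available as a configuration switch.
Unscanned species enter the reconstruction as missing data.

## Protein likelihood and topology tests

Per-site log-likelihoods on fixed topologies use Felsenstein pruning
under JTT exchangeabilities with discrete-gamma rate variation (four
equal-probability categories represented by their means — the
conventional default) plus a proportion of invariant sites. Under +I the
variable-site rate matrix is rescaled by 1/(1 − p_inv) so branch lengths
remain expected substitutions per site at any p_inv. Gaps and unknown
residues are missing data. Equilibrium frequencies default to the JTT
values; "empirical" frequencies counted from the alignment with add-one
smoothing are a switch. Transition matrices come from a symmetric
eigendecomposition, cached per model. Branch lengths, α, and p_inv are
fitted by coordinate ascent with bounded scalar optimization (tolerance
10⁻⁶, at most 20 sweeps); the total log-likelihood is non-decreasing
across sweeps by construction (a candidate update is kept only if it does
not lower the likelihood). Tree search is out of scope: topologies are
inputs, and monophyly constraints are applied by checking bipartitions of
the unrooted tree (a set and its complement are the same bipartition, so
the complement of a monophyletic set is monophyletic — documented
semantics).

SH and AU tests operate on the site-likelihood table by RELL resampling:
replicates redraw site indices and sum stored per-site values, without
re-optimization (branch lengths are re-optimized once per topology on the
original alignment, the standard approximation). The SH procedure
centers each topology's replicate totals on its replicate mean and
compares observed deficits against the resampled worst-case deficit,
which makes it conservative; the suite verifies a type-I error ≤ 7% at
α = 5% under the null. The AU test runs bootstraps at ten scales
0.5–1.4, records per-scale winning proportions BP(r) with ties split
equally, clamps them to [1/(2B), 1 − 1/(2B)], and fits
Φ⁻¹(1 − BP(r)) = d√r + c/√r by closed-form weighted least squares
(binomial delta-method weights; maximum likelihood would differ
negligibly at the default B = 1000); p = 1 − Φ(d − c). Curves pinned at
0 or 1 at every scale are flagged degenerate and reported at the clamp
limit.

## Synthetic data: what it emulates and what it does not

The generator is the package's study condition, not a tuning dial. It
emulates: a K = 5 subfamily family diverged from one ancestral protein of
350 residues over a subfamily branch of 0.7 substitutions/site; fifteen
diagnostic motif columns per subfamily (disjoint across subfamilies,
re-drawn at each subfamily ancestor and evolving at a 0.05 rate
multiplier within that subfamily — the motif structure visible in family
logos); one subfamily lacking a 50-residue C-terminal tail; evolution
along a 12-species tree (root-to-tip depth ≈ 0.4) under JTT with
four-category gamma rates (α = 1); gene duplication and loss as Poisson
processes on branches (defaults 0.05 and 0.30 per unit branch length —
loss-dominated, a handful of lineage-specific losses per run);
reverse-translation with uniform synonymous codons (codon bias is
irrelevant because the scan operates on translations); genes split into
three exons at codon boundaries with GT..AG introns (60–200 nt); and
embedding on background contigs at random positions and strands, with
half the genes fragmented one-exon-per-contig. Duplicates enter at the
start of the branch they arise on — a simplification of
continuous-time placement.

It does not emulate: insertions/deletions within the protein family
(training alignments are therefore exact; real alignments would add
alignment error), GPCR structural constraints, pseudogene decay,
sequencing error, or assembly artifacts beyond fragmentation. Passing
recovery tests therefore demonstrates the pipeline's statistical
machinery — discrimination by profile scores, evidence aggregation,
parsimony reconstruction — under honest fragmentation and loss, but not
robustness to alignment error or decayed pseudogenes.

Exon splits are restricted to codon boundaries so that concatenated exon
translations reproduce the source protein exactly (the truth-table
reconstruction oracle); real splice sites can interrupt codons.

## Problem sizes used in validation

The validation suite runs the full pipeline at the default study
conditions (5 subfamilies × 12 species, ~60 genes, ~45 contigs per
genome) once; likelihood recovery uses 4-taxon trees with 500-site
alignments over 20 replicates; SH type-I calibration uses 300 sites, 200
replicates and B = 500 with two optimization sweeps per topology fit;
the AU Gaussian check uses B = 2000. These sizes were chosen to give
stable Monte-Carlo estimates at interactive runtimes.

## Known limitations

* E-values are calibrated at a single target length (2M); scores against
  much longer segments drift upward with log-length through the placement
  sum, which the Gumbel fit does not model. At the fragment lengths the
  pipeline scans this effect is well inside the calibration noise.
* The classification matrix records only the best hit per
  (subfamily, region, target); multi-domain targets with repeated hits of
  one profile are collapsed.
* Fitch parsimony with equal costs can be ambiguous; ambiguous event
  placements are flagged rather than resolved, and the Dollo switch
  changes the reconstruction, not the matrix.
* The likelihood engine compresses nothing: site patterns are evaluated
  per column. This is simple and exact but leaves easy speedups on the
  table for large alignments.
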