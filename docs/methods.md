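# Methods

This note documents the models and procedures silicomap implements, the
parameters that matter, what the simulator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## 1. SSR detection and motif classes

`ssrscan.find_tracts` reports **maximal perfect tandem runs** of primitive
units of length 2–4. A tract cannot be extended by one unit copy on either
side; phase-shifted reports of one periodic region are merged to the
leftmost whole-copy tract; where tracts of different periods overlap
(e.g. a dinucleotide run abutting a tetranucleotide run), the longer tract
wins, ties broken by smaller start. Defaults require ≥6 copies for
dinucleotides and ≥5 for tri-/tetranucleotides; mononucleotide runs and
units of 5–6 bases are excluded. These thresholds are configurable — SSR
mining pipelines differ widely in their minimum-count settings — and
perfect repeats only (no imperfection tolerance) is the simplest defensible
contract: compound or interrupted SSRs simply split at each mismatch.

**Motif canonicalization.** All cyclic rotations of a motif and of its
reverse complement name the same repeat, so tallies use a canonical class
representative. We follow the SSR-marker literature's naming ("(CT)n",
"(AC)n"): the representative is the lexicographically smallest rotation of
the *pyrimidine-richer* strand, with ties (equal pyrimidine content, e.g.
AC/GT) broken by the smallest rotation overall. This maps TC, CT, GA, AG →
CT and AC, CA, GT, TG → AC. A pure lexicographic minimum over all eight
strings would rename the CT class "AG", which no SSR catalogue uses. The
rule is idempotent and invariant under rotation and reverse complement,
which the property tests verify.

## 2. Read clustering (the assembly stand-in)

Marker-discovery pipelines of this kind traditionally assemble whole reads
(CAP3-style, ~95% identity) and compare alleles within contigs. Whole-read
assembly is strained by the very polymorphism being sought — a 10-repeat
and a 14-repeat allele differ by 8 gapped columns — so clustering here
**excises the feature interval** (SSR tract or TE segment) before
comparing reads, and groups on the flanks alone. This is the key
deliberate divergence from assembly-based grouping.

Mechanics: candidate pairs must share ≥3 canonical 15-mers drawn from the
flanks; candidates are verified by global (Needleman–Wunsch) alignment of
the concatenated flanks in both orientations, identity = matching columns /
aligned columns with gaps counted, accepted at ≥95% identity over ≥40
columns. Accepted pairs are merged single-linkage (mirroring transitive
contig membership) with a parity-tracking union-find so every member is
reported on the representative strand. Cluster ids derive from the smallest
member read id, making output independent of input order.

At the simulator's error rate (0.5%/base) occasional reads whose tract is
interrupted by an error carry residual repeat sequence in a "flank" and can
split off as singleton clusters; recovery scoring therefore judges each
true locus by the cluster holding the majority of its reads.

## 3. Polymorphism classification

For an SSR cluster the per-line consensus repeat count is a majority vote
over that line's reads; the cluster is *polymorphic* when consensuses
differ, *monomorphic* when equal, *single_line* when only one line is
observed, and *conflicted* when motif classes disagree or a two-line
cluster has a tied within-line vote (a within-line tie cannot change a
single-line call, so such clusters stay single_line). `min_reads_per_line`
defaults to 1, so a singlet can be compared against a multi-read contig. A
transposon cluster of junction reads is *polymorphic* — a cultivar-specific
insertion — exactly when its members come from one line.

TE segments are located by local alignment of the read to the element
consensus (both strands), scored as matches over aligned columns; a hit
needs ≥30 aligned columns at ≥80% identity. The permissive identity floor
tolerates divergence in MITE terminal inverted repeats; both thresholds are
configurable.

Report percentages are rounded half-up to one decimal, the convention of
the printed marker tables (e.g. 126/2952 → 4.3%, 302/535 → 56.4%).

## 4. Primer design

A self-contained Primer3-style picker. Candidate windows of 18–27 bases
are enumerated in the flanks outside the target feature (the right primer
reported as the reverse complement of its template window) and filtered:
Tm ∈ [57, 63] °C, GC ∈ [0.30, 0.70], no homopolymer ≥5, 3′-end exact-
complement self/cross runs ≤4 bases, product length ∈ [80, 400]. These
mirror common Primer3 defaults; all are configurable. The dimer check is exact-complement suffix matching, not
thermodynamic — simpler and directly testable. Pairs are ranked by a
penalty summing weighted deviations from optima (length 20, Tm 60 °C,
GC 0.5, plus a |ΔTm| term); ties break leftmost, then shortest product.
When a TE candidate lacks one usable flank, that primer is drawn from the
element's interior so the pair still spans one junction — the standard
fallback for one-sided junction templates.

Melting temperatures use the unified nearest-neighbor parameters
(Allawi & SantaLucia 1997: ten stack ΔH/ΔS values plus terminal AT/GC
initiation) with entropy salt correction 0.368·(N−1)·ln[Na⁺] at fixed
50 mM monovalent cation and 250 nM primer (primer assumed in excess, so
the concentration term is R·ln C_p). The fixed conditions are part of the
public contract so reported Tm values are bit-reproducible; the test suite
cross-checks against an independent implementation of the same table to
0.1 °C.

## 5. F2 linkage mapping

**Segregation.** Codominant loci are tested against 1:2:1 (df 2), dominant
against 3:1 (df 1), plain χ² without continuity correction. Distortion is
flagged at p < 0.05 with no multiple-testing correction, since per-group
distortion ratios are reported raw.

**Two-point recombination.** The estimate maximizes the standard F2
two-locus multinomial likelihood in coupling phase. Rather than
special-casing the 9 codominant classes and each dominant collapse, the
implementation enumerates the ten unordered gamete-pair configurations
(each gamete parental with probability (1−r)/2 or recombinant with r/2)
and conditions on the genotype set compatible with the observed code pair;
this uniformly handles codominant × dominant mixes and the double-
heterozygote coupling/repulsion mixture ((1−r)² + r²)/2. EM imputes the
expected number of recombinant gametes per individual (E-step) and sets
r to expected recombinants over 2n (M-step), iterating to |Δr| < 1e-6,
clamped to [0, 0.5]. LOD = log₁₀ L(r̂) − log₁₀ L(0.5). Dominant × dominant
pairs with the dominant alleles in repulsion are estimated but flagged
non-identifiable. Missing genotypes are dropped pairwise; pairs with fewer
than 10 joint observations are skipped. Every estimate in the test suite is
cross-checked against a 2,001-point grid search over [0, 0.5]; because the
grid itself quantizes at 2.5e-4, the oracle refines its argmax by quadratic
interpolation through the three surrounding points before demanding
agreement to 1e-4.

**Grouping and ordering.** Linkage groups are single-linkage connected
components of the graph with an edge when LOD ≥ threshold (default 4.0,
the low end of the customary 4–10 sweep; `group_sweep` reports the whole
sweep) and r̂ ≤ 0.30. Within a group the order starts from the tightest
pair, grows by greedy chain extension (append at the cheaper end), and is
refined by 2-opt segment reversals minimizing SARF — the sum of adjacent
recombination fractions — to a local optimum; orientation is normalized so
the lexicographically smaller terminal locus comes first. Positions are
cumulative Haldane distances of adjacent r̂ (adjacent fractions capped at
0.499 to keep positions finite). This two-point + SARF/2-opt stack replaces
the proprietary regression-mapping algorithm of commercial mapping
software; positions are chained two-point distances, not multipoint
regression — a documented divergence. Map density is reported as group
length / (loci − 1), i.e. cM per marker *interval*: this is the convention
that reproduces the printed per-group density cells (79.9/7 = 11.4,
199.8/37 = 5.4), whereas length/loci does not.

## 6. QTL analysis

**Haley–Knott scan.** At each test position (default 1 cM steps) the QTL
genotype distribution is computed per individual conditional on the nearest
non-missing flanking markers, by enumerating gamete configurations with
Haldane transition probabilities — dominant marker codes condition on their
compatible genotype sets, and a position landing on an informative
codominant marker collapses to its indicators. The phenotype is regressed
on x_a = P(QQ)−P(qq) and x_d = P(Qq); LOD = (n/2)·log₁₀(RSS₀/RSS₁), PVE =
1 − RSS₁/RSS₀. Using only the nearest flanking markers (no full multipoint
smoothing) is accurate at the simulated marker densities (≈10 cM spacing)
and keeps each position a closed-form computation. A fixed-cofactor
residualization hook exists but is not a composite-interval-mapping
substitute and is not validated as one.

**Permutation threshold.** Phenotype labels are permuted (default 1,000
times; recovery experiments use 200 for speed), the genome-wide maximum
LOD recorded per permutation, and the empirical (1−α) quantile (linear
"type 7" interpolation) returned. Rank-deficient design matrices are
projected via an SVD basis of their true column space so degenerate
positions cannot inflate permuted maxima. Calibration was verified
directly: over 100 independent null phenotypes, 4 scans exceeded their own
thresholds (nominal rate 5%). Because the threshold is *built* to be
exceeded by 5% of null scans, calibration checks compare the observed
exceedance rate to 5% within binomial error rather than demanding a
literal ≥95% at small replicate counts.

**Genotype-combination (GMM-style) search.** All single loci and unordered
pairs are enumerated (combination length ≤ 2, minimum group size 1, both
configurable); individuals missing at any member locus are dropped; a
one-way ANOVA across joint-genotype groups gives F, p and R² = SSB/SST,
ranked by p then F. R² for a single codominant locus equals the PVE of
marker regression at that locus (tested to 1e-10). Undersized groups are
dropped; combinations left with fewer than two groups or no residual
degrees of freedom are skipped.

## 7. The simulator: what it emulates, what it does not

`simulate_two_line_reads` emulates two enrichment libraries from two inbred
lines: per SSR locus, i.i.d.-uniform flanks (default 150 bases) screened so
no two loci share a 20-mer — this prevents accidental cluster merging and
makes clustering precision attributable to the algorithm, not to flank
collisions; a motif from a weighted pool (default 45% CT / 30% AC dinucleotide,
15% tri, 10% tetra, echoing the dominance of CT and AC classes in
enrichment libraries built with (AC)n/(CT)n probes); repeat counts uniform
on 8–20 with polymorphic loci offset by 1–3 repeats; substitution errors
i.i.d. at 0.5%/base, a stand-in for Sanger-era error since no quantitative
error model is published for the original reads (indels are off by default
so repeat counts in reads stay exact). TE sites carry a synthetic
180-base MITE-like consensus with 24-base terminal inverted repeats;
line-specific sites (default 43%, a cultivar-specific fraction typical of
MITE insertion surveys in closely related cultivars) emit junction reads
from the carrier line only.

`simulate_f2` draws each gamete as a Markov walk along each chromosome,
switching allele between adjacent loci with probability r =
inverse-Haldane of the cM gap — i.e. no crossover interference, matching
the Haldane function used in mapping. Segregation distortion is viability
selection (rejection sampling on per-genotype weights), the simplest
mechanism that reproduces a distorted χ². `simulate_phenotypes` builds
quantitative traits as Σ(a·x_a + d·x_d) + Gaussian noise, with x_a ∈
{−1, 0, +1}, x_d ∈ {0, 1}, and an epistatic trait that is high only for
individuals homozygous for the designated allele at *both* loci of a pair
(≈1/16 of an F2 for unlinked loci), with noise proportional to the class
mean as seed-oil ratios show.

Not emulated — so passing tests say nothing about: homoeologous
cross-amplification between subgenomes of a polyploid (a major real-world
false-positive source), chimeric or low-quality reads, vector/linker
contamination, quality scores (no FASTQ), locus dropout correlated with GC,
crossover interference, and epistasis beyond the two-locus double-recessive
pattern.

## 8. Problem sizes and defaults

Recovery experiments run at the sizes the simulator defaults encode: 200
SSR loci (30% polymorphic) × 4 reads/line/locus, 100 TE sites (43%
line-specific); F2 populations of n = 200 (mapping, QTL) and n = 186
(epistasis); two 140 cM chromosomes of 15 loci; 200 permutations and
20 null replicates in QTL calibration checks. These sizes put binomial
error well inside the asserted 3-s.e. bands while keeping any single test
in seconds.

## 9. Known limitations

* Chained two-point Haldane positions accumulate estimation noise with map
  length; multipoint likelihood would shrink it.
* 2-opt ordering is a local optimum of SARF; exhaustive checks hold to 12
  loci, but very tight or distorted maps can in principle trap it.
* The EM for dominant×dominant repulsion pairs is honest about its flat
  likelihood (flagged, not hidden), but downstream grouping treats the
  point estimate like any other.
* detect_te counts inter-block gap columns as the longer of the two gap
  sides, a mild approximation of gapped-alignment identity.
* The primer picker's dimer screen is combinatorial, not thermodynamic;
  hairpins are not modeled.
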