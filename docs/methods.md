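# Methods

## Model of meiosis

The package assumes salmonid-style near-complete crossover interference:
per chromosome arm and meiosis, at most one crossover occurs, with
probability `p_arm` specific to the parent's sex; given a crossover, its
position along the arm is uniform in cumulative-θ coordinates, so an
inter-marker interval receives it in proportion to its θ share. Both arms
of a metacentric chromosome segregate through a shared centromere, and
crossovers on the two arms are independent. Consequences used throughout:

- θ between two markers on one arm equals the difference of their
  cumulative positions (θ is additive; the Morgan distance 100·θ is
  exact), and the recombinant sets of nested intervals are themselves
  nested, so with complete data the SARF-minimising order of an arm is
  exactly the true order whenever every adjacent interval contains at
  least one observed recombinant.
- θ between markers on opposite arms is `p_a(1−p_b) + p_b(1−p_a)` for the
  centromere-to-marker pieces: additivity breaks across the centromere
  (two-arm double crossovers exist). This is why the ratio-of-means
  heterochiasmy estimate is biased a few percent below the per-arm ratio
  when cross-centromere pairs enter the pair set, and why order recovery
  is assessed with per-arm logic in mind.

## Two-point estimation

Transmissions are inferred per parent (pseudo-testcross): each offspring
is coded by the parental haplotype received; genotypes compatible with
both parental alleles (possible only with shared parental alleles) are
coded ambiguous and excluded pairwise rather than resolved by EM, so N is
always a count of unambiguous meioses and the recombinant count R is a
plain binomial observation. Phase is chosen per pair by recombinant
minimisation (`R → min(R, N−R)`); grandparental genotypes only orient
haplotype labels. `θ̂ = R/N` and the LOD is the log10 likelihood ratio
against θ = 1/2, with the 0·log 0 := 0 limits; θ̂ = 1/2 gives LOD 0 and
such pairs never link. The estimator is verified against exhaustive
likelihood-grid search in the test suite.

## Grouping and the false-edge budget

Groups are single-linkage components over pairs with LOD ≥ 3.0 (the
conventional threshold for maps of this scale). That threshold is not
genome-wide safe at this family size: for an unlinked pair at N = 48
meioses, P(LOD ≥ 3) ≈ 2.2×10⁻⁴ after phase minimisation, and ~300
markers yield ~4×10⁴ tested pairs per parent — roughly eight expected
false joins, each of which would fuse two chromosomes. `cluster_markers`
therefore adds a guard: an edge must also satisfy

    2 · BinomCDF(R; N, 1/2) · (number of tested pairs) ≤ fp_budget

with `fp_budget = 0.05` expected false edges genome-wide by default. The
budget was calibrated by simulation at the package's default study design;
its side effect is honest: markers whose best evidence cannot beat the
genome-wide chance level (mostly shared-allele intercross loci, whose
pairwise N is a quarter of the family size) remain unassigned, mirroring
the fraction of real markers such studies fail to place. A simple θ
ceiling guard (`max_theta`) is also available and off by default.

## Ordering, ripple and the consensus map

Within a group, markers pairwise linked at LOD ≥ 4.0 form the orderable
core; the rest are anchored as accessory loci at their strongest partner's
position. Core order minimises SARF — exhaustively for cores of ≤ 8
markers (enumeration is reversal-symmetric), and by greedy chaining with
2-opt, segment-relocation (or-opt) and ripple refinement beyond that. The
ripple pass permutes every sliding window (default width 3) and restarts
on any strict improvement.

The consensus map merges sex-map groups sharing markers. Framework
markers (heterozygous in both parents) are ordered on pooled counts
(R_f + R_m over N_f + N_m); the remaining markers are inserted one at a
time at the SARF-minimising slot, and a marker whose two best slots tie
within 1e-9 is dropped and reported — the analogue of loci that cannot be
placed accurately when the sexes disagree. The final ripple verifies the
inserted markers while keeping the framework subsequence fixed: female-
only and male-only edges live on recombination scales that differ by the
heterochiasmy ratio, so letting them rearrange the pooled-count framework
order demonstrably degrades it. Groups with no between-sex overlap carry
over flagged single-sex. Tie-breaks everywhere are lexicographic, and
group ids are assigned by decreasing size, making reruns byte-identical.

Sex-map distances default to Haldane cM (Morgan and Kosambi available);
the consensus uses Kosambi on pooled θ̂. Consensus totals are therefore
*not* the sum of the sex-map totals: pooled θ̂ averages the two sexes'
meioses, giving a sex-averaged scale roughly midway between them.

## Heterochiasmy (recomdif)

The pair set contains marker pairs co-resident in a consensus group and
informative in both parents, excluding duplicated (`/i`, `/ii`) loci and
the sex locus. The ratio is mean(R_female)/mean(R_male) over pairs, with
the per-pair range reported; significance comes from a G-test (2·Σ O ln
O/E, df = 1) on the pooled recombinant/non-recombinant × sex table —
pooling is the only table construction with one degree of freedom. The
pair-set filter is configurable because "shared within linked segments"
admits readings from whole-group co-membership (used here) to within-arm
segments; the whole-group reading includes cross-centromere pairs and
therefore underestimates the per-arm ratio by ~5–15% at the default
genome (observed 4.4–5.5 for a true per-arm ratio of 5.4).

## Comparative inference

Arm homology requires ≥ 2 supporting markers (donor-centromere-flagged
and donor-homeolog-flagged markers excluded); single-marker hits are kept
as an explicit putative tier, the judgement applied to terminal
translocated fragments. Structure: ≥ 2 supported arms ⇒ metacentric, 1 ⇒
acrocentric, 0 ⇒ unresolved. Homeologous group pairs accumulate one
support unit per duplicated base locus whose two copies map to different
groups; same-group copies are reported as anomalies. Order comparison
computes orientation-maximised |Kendall τ| over shared annotated markers
with donor positions, counts unsigned-adjacency breakpoints, and reports
the longest run of ≥ 3 consecutive shared markers whose donor order is
exactly reversed, with its local cM span. Three-marker reversed runs also
arise from ordering noise at 48 meioses, so inversion calls are reported
per map (consensus and female) and deserve corroboration; the planted
4-marker block is detected through its overlap with a reported run.
Genome summary: a group is a conserved chromosome when its supported arm
set equals a donor chromosome's arm set; groups combining arms of several
donor chromosomes are fusions; donor metacentrics split over several
groups are fissions; the haploid arm number is the count of distinct
supported donor arms.

## The simulator and what it does (not) show

`simulate_family` draws a hidden genome and pushes it through founders,
meioses and genotyping. Defaults define the reference study: 48
offspring; 361 marker rows over 34 chromosomes (16 metacentric + 18
acrocentric, 50 arms, ~7 markers per arm, roughly evenly spaced with
jitter — the coverage a curated microsatellite panel aims for); female
per-arm crossover probabilities uniform on 0.26–0.38 (≈ 26–38 cM female
arms), male = female/5.4; marker classes 55% fully informative (ab×cd or
ab×ac), 15% dam-only, 15% sire-only, 8% shared-allele intercross, 7%
uninformative, matching the fraction of loci such panels typically map;
allele pools of 4–8 fragment sizes (three allozyme loci with 2–3
alleles); 5% missing calls in F0 and F2; 16 duplicated pairs on 9
homeologous arm pairings (support counts 3,3,2,2,2,1,1,1,1), duplicated
loci drawn fully informative since only polymorphic duplicates are
mappable; a sire-heterozygous sex locus mid-arm on the first acrocentric
chromosome, carried as the offspring sex column and converted to a marker
at fit time; 80% of markers carry donor-arm annotations, with occasional
donor-centromere flags on the most centromeric marker of an arm.

The donor karyotype is built deterministically from the simulated
genome: 10 metacentrics and 2 acrocentrics conserved, the remaining
simulated acrocentric arms fused pairwise into donor metacentrics
(fissions in the simulated lineage), the remaining simulated metacentric
arms kept as donor acrocentrics (fusions). One interior run of four
consecutive annotated, well-informative markers has its donor positions
mirrored — a planted inverted block with collinear flanking context (a
whole-arm reversal would be invisible on strand-free maps).

Not emulated: tetrasomic/multivalent male meiosis and pseudolinkage,
genotyping error beyond an optional allele-swap rate (default 0),
mutation, population-level allele frequencies, and physical (cytogenetic)
chromosome assignment. Passing recovery tests therefore shows the
pipeline's statistics are sound under disomic inheritance with complete
interference; they say nothing about robustness to paralog
mis-amplification beyond the configurable duplicated-pool overlap.

## Numerical and design choices

- All randomness flows from one integer seed through independent child
  streams (genome, founders, meioses, noise); reruns are byte-identical,
  including file outputs (2-decimal cM, sorted JSON).
- θ = 1/2 maps to the 50 cM Morgan bound by default (`cap_cm`); Haldane
  and Kosambi diverge there and are capped at the same sentinel.
- SARF comparisons use a strict 1e-12 improvement margin; insertion
  instability uses the 1e-9 tolerance; pairs without data count θ = 0.5.
- Degenerate inputs: markers monomorphic or missing in a parent simply
  contribute no meioses; a parent with no informative markers yields an
  empty map; an empty recomdif pair set is an error (ratio undefined);
  Mendelian-inconsistent offspring calls are masked with a warning by
  default (strict mode available) since non-parental alleles in real data
  usually reflect paralog amplification, not pedigree error.
- Problem sizes in the test suite (one default family of 48 × 361, a
  handful of small families, 10,000-gamete interference and calibration
  checks, 200 small ordering instances) keep the whole suite around half
  a minute while leaving each estimate's sampling error well inside the
  asserted tolerances.

## Known limitations

- The recomdif ratio estimator inherits the cross-centromere bias
  discussed above; a within-arm pair filter would remove it but requires
  arm assignments, which real first-pass maps may lack.
- Order recovery at 48 meioses is identifiability-limited: adjacent
  markers separated by zero observed recombinants cannot be ordered, and
  single-recombinant separations are fragile; the recovery tests excuse
  only the former.
- The false-edge budget trades a few unassigned low-information markers
  for protection against chromosome-fusing false joins; at much larger
  family sizes the guard is inert (true links pass it easily).
- Consensus map length depends on the pooled-count convention; with
  strong heterochiasmy it is shorter than the female map, so totals are
  comparable only within one convention.
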