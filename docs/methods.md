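# Methods

## Clonal-barcode mapping

The core assumption is clonal phenotype stability: cells of one T-cell
clone, identified by an identical TCRβ CDR3 nucleotide rearrangement,
belong to the same helper subset whether they were captured in a sorted
bulk repertoire or in a single-cell experiment. Matching is therefore an
exact, donor-scoped hash join between the resolved per-cell clonotype and
the selected clonotypes of each sorted-subset repertoire of the same donor.
No fuzzy (Hamming-neighborhood) matching is offered: nucleotide-level CDR3
identity within a donor is already essentially collision-free, and
similarity matching would conflate convergent recombination with clonality.

Contig QC keeps productive, V/J-spanning TRA/TRB contigs with an in-frame
CDR3 and no stop codon in the amino-acid sequence. When a cell carries
several contigs of one chain, the highest-UMI contig wins; UMI ties break
to the lexicographically smallest CDR3nt so reruns are bit-identical.
Cells matching several subsets are kept in each subset's row (the subsets
are displayed independently); a best-subset-by-bulk-frequency column is
available for users needing unique labels.

Key parameters:

| parameter | default | meaning |
|---|---|---|
| `top_n` | 500 | clonotypes per sorted repertoire, ranked by read count; uniformizes repertoires and trims sorting/sequencing cross-contamination |
| `rank_window` | off | 1-based rank slice (e.g. 101–500) for clone-size stratified mapping |
| `MatchKey.granularity` | `cdr3nt` | exact CDR3 nucleotide identity; `cdr3nt_vj` additionally requires equal V/J calls (off by default because bulk and single-cell pipelines name segments differently) |
| `MatchKey.chain` | `TRB` | β chain is the default barcode; the α chain works symmetrically |
| `subsample_n` | 20,000 | annotated cells drawn uniformly without replacement before computing matrices, making dot plots comparable across arms |
| `min_cells` | 8 | subsets with fewer matched/gated cells have an undefined accuracy index |

Top-N slices keep their whole-repertoire frequencies (never renormalized):
those frequencies are per-cell alpha weights in downstream plots.

## Accuracy index

For subset *j* with distribution *p* over clusters, S = −Σ p ln p / ln N,
where N counts occupied clusters only. The ratio is base-invariant; natural
logs are used. N = 1 yields S := 0 (maximally focused; the raw ratio is
0/0). S lives in [0, 1]; lower is more focused. The index deliberately
ignores *which* cluster a subset lands in — it scores unevenness, not
agreement with any reference labeling, which is what makes it usable for
gate optimization where no reference exists.

Method comparison uses a two-sided Wilcoxon rank-sum test on the pooled
defined S values. For small samples the p-value is computed by exhaustive
permutation enumeration with midranks (exact under ties); above 20,000
group assignments it falls back to the tie-corrected normal approximation.
With all pooled values identical the statistic is degenerate and p is
defined as 1.

## Repertoire statistics

Cluster clonality is |unique CDR3β| / cell count over TCR-resolved cells,
per donor per cluster; empty clusters are undefined rather than zero.
Cluster overlap uses the D metric D = |A∩B|/(|A|·|B|) within a donor,
reported as log₂(1 + 10⁶·D). Donor matrices are aggregated cellwise by the
mean over donors where the pair is defined (median and sum are options;
the choice is recorded in output metadata). The diagonal (self-overlap,
log₂(1 + 10⁶/n)) is computed but reported separately — it is a clonality
proxy, not a cross-cluster statistic.

The shared-clonotype partition slices two same-donor repertoires to their
top-2,000 CDR3nt clonotypes and computes, per overlapping clonotype, the
standard deviation of its two frequencies. With two observations the
sample (n−1) convention gives sd = |f_A − f_B|/√2; this is the default,
with the population convention |Δ|/2 behind a flag so the sensitivity of
the 0.001 cutoff is checkable. Clonotypes with sd < 0.001 are kept as
genuinely shared; the rest — abundant in one sort, marginal in the other —
are treated as sorting contamination and rejected. Every top-slice A
clonotype lands in exactly one of A_only / shared_kept / shared_rejected.

## CITE-seq comparator

ADT counts are CLR-normalized: clr_i = ln(1 + x_i/g) with g the geometric
mean over the positive entries of the vector, divided by the full vector
length (zeros included). All-zero vectors map to zero. The margin is
configurable — per cell across the panel (default) or per marker across a
batch's cells — and per-batch application is the default for the marker
margin; both choices are recorded in the normalization metadata because
reported CLR conventions vary across toolchains.

Gating is sequential: Treg (CD25 above, CD127 below) is consumed first,
then Tfh (CXCR5⁺CCR10⁻), Th22 (CCR10⁺CXCR5⁻), then the chemokine-receptor
splits Th1 (CCR6⁻CXCR3⁺CCR4⁻), Th1-17 (CCR6⁺CXCR3⁺CCR4⁻), Th17
(CCR6⁺CXCR3⁻CCR4⁺), Th2a (CCR6⁻CXCR3⁻CCR4⁺CRTh2⁺), Th2 (same, CRTh2⁻).
Consumption of earlier gates encodes the leading "NOT CD25^high CD127^low"
of every effector sort gate. The hierarchy is a data structure
(YAML-serializable), fully overridable; markers absent from the panel can
be served from per-cell RNA expression (the CCR10 case). An optional
leading memory gate (NOT CCR7⁺CD45RA⁺) can be prepended by supplying a
custom hierarchy when those markers exist.

Thresholds are chosen to minimize the mean defined S over gated subsets.
The default optimizer is exhaustive over small per-marker grids (one
threshold per marker, shared across nodes — as in FACS, where a marker has
one gate); ties break to the first combination in grid order, making the
result deterministic. Coordinate descent is available for large grids and
may stop in a local minimum (logged). Data-driven grids default to CLR
quantiles per marker.

The comparator contract: gated subsets are scored with exactly the same
subsampling, matrices, and Shannon code path as the clonotype arm.

## Synthetic data

The generator emulates the study design the method targets: by default 3
donors, 16 clusters, 8 subsets × 600 clones per donor, clone sizes from a
discrete power law with exponent 2.5 (truncated at 10,000) — the
heavy-tailed clonality that makes top-N selection meaningful — bulk depth
30,000 reads, 2,000 cells per donor, TCR capture probability 0.9, and a
0.1 decoy-contig fraction exercising chain resolution. Each subset's
program concentrates 0.85 of its mass on a distinct home cluster, with the
remainder uniform; program vectors are fully overridable. Sorting impurity
routes a clone of subset s into tube t with configurable probability, at
full clone size — a mis-sorted clone is present in both tubes, which is
what lets the SD filter recognize it as genuinely shared. ADT counts are
negative-binomial with subset-signature means (positive markers 60,
negative 5, size 10 by default); the high-noise regime used in the
comparator experiment overlaps the intensities (25 vs 12, size 1.5).
Cross-donor CDR3 collisions are absent by default and injectable to test
donor scoping.

What the generator does not emulate — and hence what passing tests do not
establish about real data: transcriptome-derived clustering (clusters are
sampled labels, so cluster assignment noise is binomial, not
expression-driven), doublets and ambient ADT background, TCR sequencing
errors, repertoire overlap between unrelated subsets beyond configured
impurity, and clonal plasticity over time (resampling cells from the same
truth emulates a second, program-stable time point).

## Numerical and design choices

- The accuracy index is computed with the explicit minus sign so S ∈ [0,1]
  and lower values mean sharper mapping.
- Zero proportions contribute zero entropy terms; distribution rows must
  sum to 1 within 1e-6.
- Duplicate clonotype rows in bulk tables are merged by summing counts;
  all count ties anywhere break lexicographically on CDR3nt.
- Repertoire readers default to VDJtools column names with AIRR and MiXCR
  aliases and a user column map; frequencies are recomputed from counts
  whenever counts exist.
- Barcodes are donor-scoped; the global cell key is (donor_id, barcode).
- Floating-point TSV output uses 6 significant digits; reruns with equal
  config and seed are byte-identical.
- Problem sizes in the test bench (3 donors × 2,000 cells for recovery; 20
  replicates of 1 donor × 1,500 cells for the comparator) were chosen as
  the smallest designs at which the binomial sampling error of a 0.85
  program leaves dominant-cluster recovery and the arm comparison
  unambiguous.

## Known limitations

- Exact-identity matching cannot represent clones whose bulk and
  single-cell CDR3 calls disagree by sequencing error; such cells are
  silently unmatched.
- The accuracy index rewards any concentration, including concentration on
  a wrong cluster; it is an evenness score, not a correctness score, and
  ground-truth agreement is only measurable on synthetic data.
- Gate optimization with per-marker (not per-node) thresholds cannot
  express marker thresholds that differ between hierarchy levels; supply
  an explicit GateSpec for that.
- The D metric depends on repertoire sizes; comparisons across clusters of
  very different cell counts should use the reported per-pair donor counts.
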