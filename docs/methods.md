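# Methods

## The analysis model

RRBS enriches CpG-dense genome fractions: MspI cuts C^CGG, fragments are
size-selected, end-repaired (the CG overhang filled in with unmethylated
nucleotides), bisulfite-converted and sequenced. Unmethylated cytosines
read T; methylated cytosines read C. Three statistical stages follow.

**Conversion-error estimation.** The fill-in cytosine is unmethylated by
construction, so any C basecall there reflects incomplete conversion or
T>C sequencing error. Only reads whose 3' end overlaps the adapter by at
least `min_overlap` (default 11) bases locate the fill-in position
reliably; the estimator counts C (*n*<sub>Cf</sub>) and T
(*n*<sub>Tf</sub>) at the base immediately preceding the adapter and
returns E = n<sub>Cf</sub>/(n<sub>Cf</sub>+n<sub>Tf</sub>). Real RRBS
end repair fills two bases, but only the cytosine is informative; the
single-position convention is used throughout, and the simulator
implements the same convention so the estimator is validated by parameter
recovery. Adapter location uses exact suffix/prefix matching (no
mismatches), leftmost match winning when ambiguous.

**Methylation calling.** Each covered cytosine (plus strand; contexts
CpG/CHG/CHH with H ∈ {A,C,T}) with depth N ≥ `min_depth` (default 5) gets
the one-sided binomial tail p = P(X ≥ K | N, E), K = methylated basecalls.
K = 0 gives p = 1 by construction. All contexts enter one
Benjamini–Hochberg family; a site is methylated when q ≤ 1%. The depth
floor exists because low-N sites cannot reach significance yet inflate the
family size; it is a package choice, not a claim about any particular
dataset. BH is delegated to statsmodels; the binomial tail to
scipy.stats.binom.sf — both are verified in tests against exact-rational
summation oracles.

**Differential methylation.** Sites covered ≥ `min_depth` (default 10) in
both conditions are tested with the two-sided Fisher's exact test; the
two-sided rule sums hypergeometric probabilities of all tables with the
observed margins whose probability is at most that of the observed table,
with a 1e-7 relative tolerance guarding floating-point ties. The
implementation evaluates the full hypergeometric pmf over the table
support (vectorized) rather than calling a per-table library routine; it
is checked exhaustively against an exact-integer enumeration oracle for
all tables with margins ≤ 30 and spot-checked against
scipy.stats.fisher_exact. BH at 5% FDR defines DMCs; direction is
hypo-LD when the LD level is lower. The q-value method is BH throughout —
a deliberate, parameter-free choice where alternative FDR estimators
(e.g. SLIM) exist. No minimum level-difference filter is applied beyond
the test itself.

**Gene mapping and annotation.** A DMC maps to a gene when it lies in the
gene span or the 2-kb strand-aware upstream promoter; a DMC in overlapping
genes counts once for each. Feature annotation partitions sites with
precedence exon > intron > promoter > intergenic so fractions sum to 1;
introns are gene span minus exons; promoters are clipped at contig
boundaries. The category percentages reported by the pipeline are
fractions of methylated CpGs per category.

## The synthetic study generator

The generator emulates the structure of the real data, not its content:

- **Genome**: i.i.d. bases at 42% GC with CCGG motifs seeded at
  `ccgg_per_kb` (default 4/kb in the pipeline) so MspI fragments exist at
  useful densities; non-overlapping genes at 1/kb, 500–1500 bp, 1–4 exons
  whose first/last exons abut the gene ends.
- **Methylome**: each plus-strand CpG draws a true level from a
  two-component beta mixture, Beta(1,20) (low) vs Beta(20,1) (high) —
  bimodal, matching the empirical either-high-or-low pattern. Exonic CpGs
  take the high component with probability 0.20, others 0.01,
  concentrating methylation in exons (gene-body methylation). Both
  conditions share levels except at `n_dmc` planted sites (default 50,
  echoing the scale of the real DMC list) separated by ≥ `dmc_effect`
  (default 0.6), half hyper- and half hypo-methylated in LD.
- **Reads**: 50 bp single-end from the 5' ends of internal MspI fragments
  (so every read begins YGG), uniform fragment sampling, per-molecule
  Bernoulli methylation per site (no epiallele correlation), conversion
  failure 0.006 (the magnitude estimated in real libraries), one
  always-unmethylated fill-in base at the fragment 3' end, adapter
  read-through on short inserts, uniform substitution error 0.001, flat
  Phred 40 qualities. Reads are simulated from the plus strand only, and
  the pileup consumes origin coordinates directly — no aligner is built
  or modeled.

**Fragment size selection.** The nominal gel window is 40–200 bp, but a
50 bp read shows ≥ 11 adapter bases only for inserts ≤ 38 bp. The pipeline
therefore keeps fragments from 20 bp up (gel selection in practice leaks
short fragments); without this the conversion-error estimator would have
no usable reads at these read lengths.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: PCR duplicates, quality decay along the read,
M-bias, minus-strand reads, paired ends, epiallele correlation between
neighbouring CpGs, overdispersion between biological replicates (the
emulated design has one pooled library per condition), mapping error
(reads carry their true origin), and indels. Parameter-recovery results
demonstrate correctness of the statistics under the stated model, not
robustness to these artefacts.

## Off-target scanner

The dsRNA is diced into all overlapping 19-mers (Dicer-product length) and
each is matched exactly against every transcript window and the window's
reverse complement ("complement" is implemented as biological antisense;
plain complement would pair nonsensically 5'→3'). No mismatch tolerance
and no seed-region weighting — the tool answers the conservative question
"does any perfect 19-mer match exist?". A dsRNA always self-hits its
source transcript, which is used as a sanity rule. Behaviour is verified
against a brute-force all-substrings oracle.

## MethylQuant statistics

Efficiency: sliding window (default 5 cycles) over log10 fluorescence of
points above baseline (3× the median of the first five cycles); the
window with the best coefficient of determination gives slope s and
efficiency 10^s, exact on noiseless exponentials; estimates with best
R² < 0.99 are flagged as lacking a clean exponential phase. Replicate
efficiencies are averaged arithmetically. The ratio uses group means of
Ct (not medians) and is invariant to adding a constant to all Ct values.

Permutation test: condition labels are reallocated uniformly within each
primer class; the statistic is |log ratio| (two-sided) and the add-one
estimator p = (1+b)/(n+1) avoids p = 0. With three biological replicates
per group the null is supported on C(6,3)² = 400 equiprobable
reallocations and the identity/mirror assignments always tie the observed
separation, so the attainable minimum p is ≈ 0.095 regardless of n_perm.
This granularity is intrinsic to replicate-level reallocation; datasets
analysed with finer permutation units (individual wells or fluorescence
readings) can report much smaller p-values and are not directly
comparable.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open internally; GFF3 is written 1-based
  inclusive; cytosine reports carry a 1-based `pos1` column.
- E = 1 is rejected as a degenerate null; K = 0 sites always get p = 1.
- All-zero Fisher tables are errors; equal-level paired sites get
  direction "none" and are excluded from direction tallies.
- Context truncated by the contig end is classified CHH and flaggable.
- Empty inputs return explicit empty results (empty pileup, all-zero
  bimodality summary with `is_empty`, empty gene table) rather than
  raising, except where the operation is meaningless (no paired sites, no
  adapter reads).
- Determinism: every stochastic routine takes an integer seed and uses an
  isolated numpy Generator; the pipeline derives child seeds from the
  master seed, and reruns are byte-identical including FASTQ output.

## Problem sizes

The shipped configurations are sized for quick, repeated runs on a laptop
CPU: a 100 kb genome (~4,800 CpGs, ~370 retained fragments, ~11,000 reads
per condition) for the end-to-end study, 10,000-site families for caller
calibration, 5,050-site families across 20 seeds for DMC recovery, and
exhaustive Fisher verification up to margins of 30. All scale linearly if
larger studies are wanted.
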