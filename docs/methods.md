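# Methods

## The sequencing problem and the read model

Illumina cluster identification and early-cycle quality filtering (roughly
the first 25 cycles) rely on neighbouring clusters producing distinct
fluorescent signals. An amplicon pool whose molecules are identical outside
a handful of variable positions defeats this: at most cycles a single base
dominates. `phaseq` models two remedies — spiking in PhiX and prepending
phased inserts — and the activity screen that motivates them.

Every read is modelled as the deterministic composition

```
insert (0/9/12/15/18 nt) · anchor GGG · transcript-or-product · linker · adapter stub
```

truncated at the machine read length (default 150 cycles) or padded by
continuing into the linker and a repeated fixed adapter stub. The anchor is
the read-side image of the three riboguanosines of the template-switching
oligo used in 5′-RACE; uncleaved molecules contribute the full transcript,
cleaved molecules the transcript from the cleavage offset. All coordinates
are 0-based, half-open; cycle 0 is the first sequenced base. Templates are
stored in transcript orientation; the template-strand/T7-promoter
representation used for oligo synthesis is an I/O convention, not internal
state.

## Positional entropy

At each cycle the base composition p = (p_A, p_C, p_G, p_T) gives the
Shannon entropy H = −Σ pᵢ log₂ pᵢ in bits, with 0·log 0 := 0, so
0 ≤ H ≤ 2 with H = 2 iff the composition is uniform. Profiles are
summarised by the mean and the **population** SD across cycles (dividing by
the number of cycles, not cycles − 1): the cycles are the entire population
of interest, not a sample.

Two routes produce a profile:

* `analytic_freq_matrix` — the exact mixture: each read class (insert
  length × cleavage state, weighted by its mixing proportion) contributes
  its base indicator per cycle, with fully randomized (N) positions
  contributing ¼ to each base. No sampling is involved.
* `simulate_run` — Monte-Carlo: reads are drawn class by class with uniform
  bases at randomized positions. By the law of large numbers the simulated
  profile converges to the analytic one; at 10⁶ reads the per-cycle
  deviation is below ~0.005 bits, and the test suite asserts the agreement.

PhiX is modelled, by default, as a fraction f of reads with iid uniform
bases, so each composition row becomes (1−f)·row + f·(¼,¼,¼,¼). A
genome-sampling mode (uniform read-length windows over a supplied genome)
exists but is off by default; the iid approximation is what the entropy
predictions use. For observed reads, ambiguous base calls (N) are excluded
from the affected cycle's count and the row is renormalized.

The default simulated condition uses only full-length (uncleaved) library
reads; the cleaved fraction is exposed for synthetic-data realism but the
headline entropy conditions set it to 0.

## Phased insert design

Constraints: k insert lengths (default 9/12/15/18; k must be a multiple of
4 for exact balance), a balance window (default the shortest length), a
maximal within-insert homopolymer run (default 2) and forbidden boundary
sequences (default: no 3′ G, which would extend the downstream GGG anchor).
The search assigns, per windowed cycle, a random permutation of a multiset
with k/4 copies of each base across the k inserts; tail cycles beyond the
window assign mutually distinct random bases to the inserts still running
(diversity rather than balance — tails only affect cycles ~9–24, where
reads are already out of register). Violating assignments are redrawn per
cycle (up to 64 times) inside a bounded number of whole-candidate restarts
(default 10,000); infeasible constraint sets fail with a diagnostic. The
procedure is deterministic given its seed.

A balanced equal-proportion set yields exactly 2.0 bits at every windowed
cycle; with four distinct lengths the first-cycle bases are all distinct, so
the set is automatically prefix-free, which `PhasedInsertSet` validates —
the property demultiplexing relies on.

## Demultiplexing, classification and w

Demultiplexing matches each insert against the read prefix (Hamming
distance, default 0 mismatches) and requires the anchor to follow exactly;
ties at equal mismatch count resolve to the longest insert (longer matches
are less likely by chance). Classification compares the trimmed read with
the transcript start (uncleaved: leader present) and with the cleavage-site
sequence (cleaved), over a probe of leader length + 4 bases with randomized
positions as wildcards; templates whose leader is a prefix of the product
are rejected as undecidable. Genotypes are the bases at the randomized
positions (offset by the cleavage site for cleaved reads); reads with
ambiguity codes there are dropped and tallied. Per genotype,
w = N_cleaved/(N_cleaved + N_uncleaved); never-observed genotypes are
*missing*, not zero. Count conservation (assigned + unassigned + dropped =
total) holds for every run. No quality filter is applied by default — an
optional mean-Q threshold exists — and reads are taken in sequencing
orientation (single-end, fixed architecture; no reverse-complement search).

## Mutant grids, correlation, detection

Around a 6-nt reference genotype (positions 0–2 and 3–5 = the two
pseudoknot halves, paired antiparallel so position i pairs with 5−i) the
single mutants number 6×3 = 18 and the one-per-half double mutants form a
9×9 grid. Grid columns are ordered as the Watson–Crick compensatory
partners of the rows (paired position, complementary alternative base), so
the diagonal holds the compensatory double mutants. The grid is a pure
reindexing of the genotype table. Correlation against a reference activity
table is Pearson's r over pairwise-complete genotypes (missing entries are
excluded and counted; handling of missing values in prior datasets is not
standardized, and pairwise-complete is the conventional choice), requiring
≥ 3 shared genotypes and nonzero variance.

Rare-genotype detection is Binomial(n, P): the zero-detection probability
is (1−P)ⁿ, evaluated in log space, with a seeded Monte-Carlo twin that
draws once from Binomial(n, P) per iteration (distributionally identical to
n Bernoulli draws, and much faster) and reports the fraction of zero-draw
iterations. Defaults n = 689,334, P = 4.45 × 10⁻⁶, 200,000 iterations give
≈ 0.0465; n is treated as a free parameter of the model.

## The synthetic library fixture

The packaged construct (`phaseq.synthetic_library`) is labelled synthetic:
it reproduces every documented architectural property of a twister
ribozyme screening library — 5-nt leader starting GG (so anchor + leader
begin with a GGGGG homopolymer in uncleaved reads), 54-nt body, six N
positions in two distal 3-nt halves with wild type CCCGGG, cleavage offset
5, 25-nt linker, 60-nt adapter context, and four balanced 9/12/15/18-nt
inserts generated by the design module — while its concrete fixed bases
were drawn once, uniformly with homopolymer runs capped at 3, from a frozen
seed (20193). Consequences: quantities that depend only on the architecture
(control mean 0.08 = 6·2/150 bits exactly, SD 0.39; PhiX-only mean 1.03;
2.0 bits over the first nine phased cycles; all counting properties) are
exact, while the phased-condition means depend mildly on the realized fixed
bases through chance base coincidences among the four 3-nt-shifted read
classes; the realization gives 1.41 (phased) and 1.72 (phased + 25% PhiX)
analytically, with 10⁶-read simulations matching to < 0.005 bits.

## The synthetic run generator

`generate_run` emulates the screen: genotypes sampled uniformly, cleavage
Bernoulli with the genotype's true w (default truth: iid Beta(2, 2)
activities — a broad unimodal spread over [0, 1]; alternatively a
pseudoknot pattern with Watson–Crick-paired genotypes high and all others
low), inserts by their mixing proportions, iid substitution errors (no
indels — sufficient to exercise mismatch tolerance without complicating
demultiplexing semantics), constant Q37 qualities, and an optional PhiX
fraction of uniform reads. Truth tables are exact and output is
byte-identical across identical seeds. It does **not** model indels,
position- or quality-dependent error rates, cluster optics or the
passing-filter mechanism, so passing recovery tests demonstrates correct
bookkeeping and estimator behaviour under sampling noise, not robustness to
instrument artefacts; instrument outcomes such as percent clusters passing
filter are not computable from this model and are not predicted.

## Problem sizes and numerical choices

Entropy comparisons between simulation and the analytic oracle use 10⁶
reads (matching the headline predictions); end-to-end w-recovery tests use
a reduced 2-position variant of the library (16 genotypes) at 2 × 10⁴ reads
so that every genotype exceeds 100 reads and the 3-standard-error binomial
band is meaningful at high depth. Proportion vectors must sum to 1 within
1e-9 (1e-6 for user-supplied entropy inputs); frequency-matrix rows are
validated likewise. Seeds are mandatory for every stochastic operation.
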