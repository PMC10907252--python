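# Methods

## Model

A DGR locus comprises a reverse transcriptase (RT), an accessory protein,
a template repeat (TR), and one or more target genes each carrying one or
more variable repeats (VRs) homologous to the TR. Mutagenic retrohoming
is modelled as: each adenine position of the TR independently, with
probability *p*, is replaced by a nucleotide drawn uniformly from
{A,C,G,T}; all other positions are copied verbatim. Because the draw may
return A, the per-adenine *change* probability is 3p/4. A locus missing
RT, accessory or TR is *degenerate*; its VRs can still be analysed with a
donor TR supplied externally (trans diversification).

All coordinates are 0-based half-open internally and 1-based inclusive in
every on-disk table.

### TR–VR alignment and variable positions

TR and VR are near-equal-length homologs. Equal-length pairs are compared
column by column (which is also the optimal global alignment under the
scoring used); unequal lengths go through Biopython's global
`PairwiseAligner` with match +1, mismatch 0, gap open/extend −2. Aligned
columns whose TR base is adenine form the *variable* class; other aligned
columns are *conserved*; gap columns and columns containing N belong to
neither. A pair whose conserved-column identity falls below 80% is
flagged `weak_pair` (genuine repeat pairs match at essentially all non-A
sites) but still analysed. Variable columns are mapped strand-aware into
genome coordinates and codon context (codon index and position 1–3,
counted 5'→3' in gene orientation, honouring the CDS `frame_offset`).

### Sequence space

A codon with targeted offset set *S* reaches exactly 4^|S| nucleotide
variants (the reference allele is itself an outcome). Distinct
polypeptides per VR = product over codons of the number of distinct
non-stop amino acids among those variants; codons vary independently, so
the product equals the deduplicated count of full-length peptides — a
property asserted against a brute-force enumeration oracle for every
random VR with ≤6 targeted positions. Per-target and genome totals are
products of the level below. Codon offsets falling outside any VR are
held fixed. All counts are exact Python integers; the scientific
rendering (2 significant digits) is computed without float conversion.
Stop-reachable codons are excluded from the amino-acid counts and listed
separately (`nonsense_report`), since targeted codons in real DGRs are
composed to avoid nonsense outcomes.

### Read selection and pileups

Duplicated DGR loci cause cross-mapping, which fabricates apparent
diversity. A read is kept for a VR iff it overlaps the VR by ≥1 bp and
its mate maps on the same contig with a gap ≤1000 bp between the nearest
ends of the two alignments (the mate's end is approximated as its start +
query length, exact for ungapped alignments). Secondary, supplementary
and duplicate records are excluded; no base-quality floor is applied by
default. Alignments are streamed in coordinate order (plain SAM works
without an index; sortedness is verified on the fly). Pileups report
every position of the region including zero-depth ones; only A/C/G/T
calls count toward depth — N and deletion columns contribute nothing.

### Diversity statistics and the decision rule

Per position with depth d > 0: π = 1 − Σ_b (count_b/d)², the probability
two reads drawn with replacement differ; and the non-reference proportion
1 − count(ref)/d. Positions with depth < 6 (i.e. not >5×) are masked from
everything. A VR is called diversified for a metric when

    mean_A > mean_nonA + 2·sd(nonA)

with strict inequality, where sd is the *sample* standard deviation
(n−1). A call needs ≥1 unmasked A-targeted and ≥3 unmasked non-targeted
positions; otherwise it is *absent* (with a reason), which is distinct
from false. When sd(nonA) = 0 the rule degenerates to a strict comparison
of means and is accepted as such. Per-VR means are unweighted by depth.
Aggregation to target or locus level is a logical OR over present calls;
an aggregate with no present calls reports "no data". The genome-wide
summary reports median π over unmasked positions and an SNV density per
10 kb, where an SNV is defined here as an unmasked position with
non-reference proportion ≥0.1 — a package decision; no standard SNV
threshold exists for this statistic.

### Donor matching

A candidate donor TR is *compatible* with a VR iff their alignment has
zero mismatches at non-adenine columns and covers the entire VR. Matching
is performed in locus orientation; the reverse complement is also
searched and flagged, as are gapped alignments. Per VR the mode is *cis*
(own TR compatible), *trans* (only a foreign TR compatible) or *orphan*
(none). Mode describes capability, not current activity — an undamaged
donor relationship can outlive actual diversification.

## Simulator

The generator emulates a near-clonal aggregate: one circular-genome
contig (default 20 kb) with complete DGR loci laid out as RT — accessory
— TR — target CDS, the VR planted as an exact TR copy inside the CDS; a
population of `n_cells` (default 100) of which a fraction *d* (default
0.5) carries VRs independently rewritten by retrohoming at *p* = 0.5;
expected non-reference fraction d·p·3/4 at A-targeted positions and 0
elsewhere. Reads are 250 bp pairs at 50× with 500 ± 50 bp inserts and
uniform error 1% (defaults chosen to mirror aggregate-scale short-read
metagenome sequencing of near-clonal consortia); qualities are constant,
and the known-by-construction alignments are emitted as coordinate-sorted
SAM so tests need no mapper. A fast path draws per-position counts
directly: depth ~ Poisson(coverage), counts multinomial around the
population allele frequencies mixed with error. Identical seeds give
byte-identical FASTQ/SAM/truth outputs.

What the simulator does **not** model: mutation bias at A sites, shared
haplotypes from clonal expansion of a diversified cell (each diversified
cell is an independent event — a conservative null for within-aggregate
π), indels, quality-score structure, strand bias, transposon-mediated
locus degradation, and real mapping ambiguity (alignments are ideal, so
the mate filter's effectiveness against cross-mapping is exercised only
structurally, not adversarially). Passing tests therefore demonstrate
statistical correctness of the detection machinery under these
conditions, not robustness to every artefact of real metagenomes.

## Operating characteristics (computed, not assumed)

The validation harnesses simulate 100 aggregates × 20 VRs (100 bp VRs,
25% TR adenines, grouped 4 VRs per synthetic locus). Under the null
(d = 0, error 1%, 50×) the 2-sd rule's false-positive rate is bounded at
0.10 in tests and lands far below it: the threshold is built from the
per-position sd, while the A-class mean averages ~25 positions, so the
rule is strongly conservative. At d = 0.5, p = 0.5, 50× (per-position
effect 0.1875, π ≈ 0.33 vs error background ≈ 0.02) power is ≥95% per VR
and locus recovery complete. `scripts/acceptance.py` recomputes all of
this from a single seed; problem sizes (20 kb genomes, 100-cell
populations, 500-VR oracle sweeps) are chosen so the whole run completes
in well under a minute-scale budget on one CPU while keeping binomial
standard errors small.

## Numerical and design choices

- ">5× coverage" is enforced as depth ≥ 6 (strict inequality).
- Sample sd (ddof = 1) over non-targeted positions; configurable via
  `ProfileConfig.sd_multiplier` and the minimum-position counts.
- Mate distance anchored at nearest alignment ends (conservative,
  symmetric); measured mate end approximated from query length.
- TR–VR gap columns are excluded from both column classes rather than
  guessed; a gapped donor match is reported but flagged.
- π is computed over {A,C,G,T} only; zero-depth positions are undefined
  (masked), never coerced to 0.
- Exact integers everywhere in sequence-space counting; mantissa rounding
  half-up at 2 significant digits.
- The locus table's VR intervals are authoritative for which TR adenine
  columns count as variable positions; aligned flanks outside the
  annotated VR are ignored.

## Limitations

Variant phasing across a VR, haplotype reconstruction, FDR control across
many aggregates, de novo DGR discovery, RT phylogenetics and domain
annotation are out of scope. The SNV density definition above is not
comparable across tools without harmonising the frequency threshold.
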