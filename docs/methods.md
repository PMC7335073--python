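# Methods

## The measurement being modelled

Deep enzymology quantifies the intrinsic flanking-sequence preference of a
DNA methyltransferase. A pool of double-stranded substrates is built in
which a central target dinucleotide (CpG, or CpA/CpT/CpC for non-CpG
activity) is flanked by random nucleotides — 10 per side by default —
between fixed primer arms. After in-vitro methylation, a hairpin is
ligated so that one sequencing read carries the bisulfite images of both
strands of one molecule; comparing the two strands position by position
recovers the original sequence (conversion ambiguity is resolved by the
complementary strand) and the methylation state of both target cytosines.
Averaging states per flanking context yields the enzyme's preference
profile.

## Simulator

The simulator (`simpool`) emulates exactly the steps the analysis needs to
invert, no more:

* **Pool synthesis** — flanks i.i.d. uniform over A/C/G/T between fixed
  arms. Default layout: 20-nt arms free of CpG dinucleotides (their
  cytosines are guaranteed non-substrates and serve as conversion
  controls), 10-nt flanks, an 8-nt cytosine-free hairpin linker (invariant
  under conversion, hence a reliable segmentation anchor).
* **Methylation** — one Bernoulli event per strand-site with probability
  given by a preference model (explicit per-context lookup, or a
  base rate times per-position per-base weights clamped to [0, 1]). Top
  and bottom strands of a CpG are drawn independently, each conditioned on
  its own 5'→3' strand context. A single-hit Bernoulli matches the
  measured quantity (fraction methylated at one time point); no
  processivity or kinetic model is attempted.
* **Bisulfite conversion and sequencing** — unmethylated C→T with
  probability `conversion_rate` (default 0.998), methylated C→T with
  probability `inappropriate_conversion` (default 0.002), uniform
  substitution errors at `seq_error` (default 0.001), constant Q37
  qualities with an optional fraction of Q10 3' tails to exercise
  trimming. One read per molecule; byte-identical output per seed.

What the simulator does **not** emulate: PCR amplification bias, indels,
chimeras, coverage heterogeneity between molecules, or any coupling
between the two strands' methylation events. Tests passing on simulated
data therefore certify the correctness of the reconstruction and the
statistics under the stated noise model, not robustness to artefacts the
model excludes.

## Read processing

* **Trimming** — the maximal 3' suffix in which every base is below
  Q20 is removed (idempotent suffix rule; the simplest rule consistent
  with trimming low-quality read tails).
* **Selection** — fixed amplicon layout, no indel alignment: the linker
  must match at its designed offset and all four arm anchors must match,
  each within Hamming distance 1 by default, where an expected C also
  matches T (conversion-tolerant). Rejections are typed (`no-linker`,
  `short-antisense`, `arm-mismatch`) and counted, never silently dropped.
* **Reconstruction** — the 6-row decision table over (sense, oriented
  antisense) pairs: (A,T)→A, (T,A)→T, (G,C)→G with the bottom C
  methylated, (G,T)→G bottom converted, (C,G)→C methylated, (T,G)→C
  converted. The remaining 10 ordered pairs are pair-mismatches: the
  position is masked to N and counted; molecules exceeding 1 masked
  position (configurable) or with an undetermined target state fail QC.
* **Conversion QC** — fraction of fixed-arm control cytosines read as T
  over QC-passing molecules. Flank cytosines are deliberately excluded:
  they can be genuine enzymatic targets.

## Statistics

* Context tables carry both the raw level m/n (reporting) and the
  smoothed (m+0.5)/(n+1) (any downstream ratio or ranking; never
  divides by zero). Each strand event counts once with its own strand
  context; events store the full flank width and narrower tables (k = 2,
  3) slice the central window, so all widths are consistent by
  construction.
* The positional enrichment statistic uses the **population** standard
  deviation of the four observed/expected ratios (a fixed 4-point
  spread, not a sample), and takes the expected composition from the
  processed events themselves rather than the theoretical ¼ — this
  cancels pool-synthesis bias. Events are labelled hard
  methylated/unmethylated; no level weighting.
* The B/A preference divides each enzyme's smoothed profile by its own
  mean over the shared covered contexts before taking the ratio, making
  R(s) invariant to overall activity and exposure differences between
  experiments. Rankings are descending with lexicographic tie-break
  (deterministic); minimum coverage for ranking/correlation defaults to
  10 events per context.
* Similarity bins count matches over the 6 flank positions only (the
  central CG always matches). Repeat analysis enumerates forward-strand
  CpGs, reads the context on both strands, and keeps per enzyme the
  better rank; sequences are linear by default with a `circular` flag
  for satellite consensus monomers. Each enzyme is ranked in its own
  preference ordering (the alternative — ranking both in the B/A
  ordering — is available by passing that ranking explicitly).
* Cellular summaries: depth filter ≥10× inclusive; per-site level
  meth/depth accumulated as site-weighted means (each site weight 1);
  strands kept separate by default with an option to collapse symmetric
  CpG pairs by summing counts. The binomial test is the exact upper
  tail; its null rate defaults to the measured spike-in non-conversion
  rate; Benjamini–Hochberg q-values are attached and non-significant
  sites are retained with their p-values. In the aggregated tables
  n_total is the number of sites and n_meth the sum of levels, so
  level_raw is the site-weighted mean and the TSV schema matches the
  in-vitro tables for direct correlation.

## Numerical and design choices

* Tie-breaks everywhere are lexicographic on the context string;
  reported orderings are fully deterministic.
* Degenerate inputs raise typed errors rather than returning NaN: empty
  profiles, zero control observations, zero variance in a correlation,
  fewer than 3 shared contexts.
* Enrichment positions where a base is absent among all events are
  flagged NaN and excluded from the normalising maximum.
* Coordinates are 1-based in cytosine reports (the consumed dialect) and
  0-based half-open internally.
* Problem sizes used by the test suite and the acceptance script: the
  round-trip check uses 10,000 molecules at the full 10-base flank
  width; parameter recovery uses ±2 flanks (256 contexts) with 18,000
  molecules per enzyme, which puts every context above 100 strand
  events; the permutation null uses 100 label permutations over 3,000
  events. These sizes give binomial/permutation resolution comfortably
  inside the asserted bounds while keeping a full run in seconds.

## Known limitations

* The preference model is per-position/per-context marginal; epistatic
  (dinucleotide-interaction) preferences are out of scope.
* Reconstruction assumes the fixed amplicon layout; reads with indels
  fail selection rather than being re-aligned.
* The cellular module consumes post-alignment call tables; alignment,
  deduplication and methylation extraction are external.
* Reproduction of published rankings from deposited experimental tables
  is an optional validation path requiring those downloads; it is not
  part of the default suite.
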