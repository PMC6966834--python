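# Methods

This note documents the models and procedures `segtangle` implements,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic validation does and does not show
about real data.

## 1. The generative model behind the association step

The association analysis assumes a simple generative world, and the
synthetic generator (`segtangle.synthetic`) makes that world explicit so
it can be tested against.

**Presence.** Each virus is present in each sample with probability
`virus_prevalence` (default 0.5), drawn once per (virus, sample): *all*
segments of a virus share the draw. This is the defining property the
association step exploits.

**Abundance.** In a sample where a virus is present, its abundance is
10^Normal(`log10_abundance_mean`, `log10_abundance_sd`) RPKM (defaults
1.25 and 1.0, putting the median virus near 18 RPKM — mid-range for real
infections, which span roughly 0.2 to tens of thousands of RPKM). Each
segment multiplies this by 10^Normal(0, `segment_rel_abundance_sd`);
the default jitter of 0.3 reflects the visibly unequal but strongly
coupled per-segment coverage of real segmented viruses, for which no
published variance estimate exists — it is a free parameter. Fragment
counts are round(RPKM × length_kb × library_size/10⁶); fragments (read
pairs), not reads, are the count unit everywhere, which keeps the RPKM
arithmetic self-consistent (6 fragments on a 2 kb contig in an
18.75 M-fragment library = 0.16 RPKM exactly).

**Background.** Host-transcript-like contigs get independent
Bernoulli(0.5) presence and i.i.d. per-sample abundance from the same
log-normal. This makes any co-occurrence among them pure chance, which
is the correct null for false-association rates but is *pessimistic
about nothing else*: real host transcripts are often present in all
samples with correlated expression (co-regulation), which can produce
correlated pairs the generator never creates. See §7.

**Libraries.** Sizes default to 10⁷ fragments with ×/÷3 log-uniform
jitter (a realistic scale; real studies do not report a canonical
value). If a sample's contig fragments would exceed its library, counts
are rescaled proportionally — competition for the sequencer.

**Strand counts** are Binomial(total, f) per contig and sample with f
set by genome sense: 0.998 for +ssRNA (the observed value for a real
+ssRNA virus in a strand-specific library), 0.65 for dsRNA and 0.35 for
−ssRNA. The latter two are only qualitatively constrained ("weakly
biased") and are configurable.

**Sequences.** Segments are 1.5–2 kbp with a single ORF covering ≥ 70%
of the segment (target 72%), a 3′ poly-A tract (15 nt), and — on all
but the second segment, mirroring the observed 4-of-5 pattern — a shared
150 nt 3′-terminal motif per genome. The ORF is laid out as
5′UTR | M…stop | spacer | motif | poly-A, with an in-frame stop at the
UTR end so the planted ORF cannot extend upstream, and the random parts
are resampled until exactly one ORF ≥ 300 nt exists in all six frames.
Generated motifs end in two non-A bases so the motif/poly-A boundary is
exact under the tail detector's mismatch allowance. Sister-virus pairs
(virus 2k, 2k+1) carry homologous proteins: a controlled fraction of
residues (never the initiator methionine) is point-mutated to reach
`target_aa_identity` (default 0.64), then back-translated with uniform
random synonymous codons — the paper-silent choice that avoids imposing
a codon bias that would confound the composition module. Sister
segments reuse their partner's length so the coding-fraction constraint
holds. No indels are planted, so measured identity ≈ 1 − mutated
fraction; the alignment step is still exercised in full.

**Small RNA.** `viral_replicating` profiles put ~80% of reads at 21 nt,
split strands near 50/50, and draw start positions uniformly along the
contig; `host_transcript` profiles spread lengths uniformly over
18–30 nt, put ≥ 97% of reads on one strand, and cluster starts at a few
hotspot loci (miRNA/degradation-like). These are caricatures at the
favourable end of realistic: real viral profiles can be weaker and real
host loci can occasionally look two-stranded (hairpins), so the
measured sensitivity/specificity of 1.0 is a ceiling, not a field
estimate.

Everything is deterministic given `seed` (one `numpy` Generator drives
the whole scenario).

## 2. viRNA signature and the dark-candidate filter

`score_small_rna` reduces a length × strand histogram to three numbers:
fraction of reads at the peak length (21 nt by default — Drosophila-like
Dicer-2; configurable for other host clades), minority-strand fraction,
and the minimum per-strand coverage breadth (fraction of 100 nt windows
hit). The signature calls viral when all three clear their thresholds
(defaults 0.5, 0.2, 0.5). No quantitative cutoffs exist in the
literature for "substantial" viRNA production; these values separate the
two simulated classes by a wide margin and are exposed in configuration.
An empty histogram is an *error*, not a negative: missing small-RNA data
cannot support either conclusion.

`classify_dark_candidate` is the conjunction used to nominate dark-virus
candidates: length ≥ 1000 nt, absent from DNA, no detectable homology
(both flags are inputs — homology searching is out of scope), an ORF
≥ 300 nt (100 codons, a conventional floor far below real segment ORFs),
and the viRNA signature. Every failed conjunct is reported, so the
filter is auditable; an exhaustive 2⁵ truth-table test pins this down.

## 3. Co-occurrence association

Correlation is Pearson (Spearman available) on log₁₀(RPKM + ε),
ε = 0.01, computed over **all** samples, not only jointly-present ones:
shared absence is evidence of co-travel under the presence model, and
dropping absent samples would discard it. Presence is ≥ 5 fragments —
just below the weakest accepted real-world evidence of six read pairs.
Pairs with a constant log-abundance vector have undefined r and are
flagged rather than zeroed.

Groups are connected components of the graph with edges where r ≥ 0.87
and concordance ≥ 0.9. The 0.87 default is adopted from the smallest
correlation observed among confirmed co-occurring segments in real data;
it is an *observed minimum* reinterpreted as a threshold, and should be
tuned per dataset. Connected components mirror the transitive logic of
associating fragments through shared datasets; complete-linkage
(maximal cliques) is available for stricter grouping. Raising `r_min`
can only refine a clustering (edges are dropped, never added), which is
tested as a property.

`find_candidate_segments` scores every non-member contig by its
*weakest* link (minimum r over seed members), so a candidate must
co-occur with every established segment; ties break by mean r, then
mean concordance, then contig id. This is the in-silico version of the
search that recovered a real missing fifth segment.

## 4. Genome sense

The qualitative strand-bias rules are quantified as bands on the exact
(Clopper–Pearson) 95% CI of the positive-strand fraction:
`positive_ss` iff the lower bound ≥ 0.95; `double_stranded_like` iff the
whole CI lies in (0.5, 0.95); `negative_ss` iff the upper bound
≤ 0.5 − 0.02; otherwise `ambiguous`. The 0.95/0.02 boundaries are this
package's quantification of "very strongly" vs "weakly" biased — no
numeric boundary exists in the literature — and are configurable. Using
the interval rather than the point estimate means small-n data returns
`ambiguous` instead of a confident wrong call; there is a genuine
ambiguous band (e.g. fractions near 0.95) between the ds-like and
positive calls. Sense is called at group level by pooling member
counts, since segments of one genome share a sense. Poly-A-enriched
libraries artificially enrich mRNA-like products; they are flagged
untrusted (`library_type: polyA`), never corrected.

## 5. Abundance summary

Per-sample group RPKM is total member fragments per total member
kilobase per million library fragments (a length-weighted pooling, so a
genome's RPKM is not dominated by its shortest segment), summarised
(min/median/max, largest library fraction) over samples where every
member is present. A group never present is flagged, not an error.

## 6. Composition

ρ(XY) = f(XY)/(f(X)·f(Y)) with dinucleotide frequencies from
overlapping windows, counted linearly on the given strand with no
reverse-complement symmetrisation — the inputs are +ssRNA coding
sequences, where strand identity is meaningful. Mononucleotide
frequencies use all valid positions; windows spanning a non-ACGT
character are dropped and the skip count reported. Ratios with an
absent constituent base are flagged missing rather than fabricated.

PCA is centred but unscaled by default (the 16 ratios are already
normalised and share a scale); scaling is a flag. A fully degenerate
input (identical profiles) reports zero scores and zero variance
fractions instead of NaN. LDA reports leave-one-out accuracy and the
per-class confusion matrix; with ≥ 16 features and few samples the
within-class covariance is singular, so shrinkage (`lsqr`, auto) is
applied with a warning — accuracy estimates in that regime deserve
scepticism, and the permutation-label analysis quantifies exactly how
little power exists at n = 32 sequences of < 2 kbp (LOO accuracy
statistically indistinguishable from chance).

## 7. Annotation

* ORFs: complete ATG→stop over six frames, longest first, ties by frame
  index then 5′-most start; stop-free runs are not called (a truncated
  CDS is reported as absent, not guessed). Coordinates are 0-based
  half-open internally, 1-based inclusive in written reports.
* Poly-A: longest 3′ suffix with ≤ 1 non-A base, trimmed to start with
  A; present at ≥ 8 nt.
* Shared 3′ motif: poly-A tails stripped, terminal 200 nt windows
  compared by ungapped identity (right-aligned); the motif group is the
  largest clique at pairwise identity ≥ 0.7, and the motif length is
  the longest suffix keeping mean pairwise identity ≥ 0.7. Ungapped
  comparison is appropriate because the motif sits at a fixed distance
  from the 3′ end; unrelated sequences sit near 25% identity and never
  group.
* Identity: global Needleman–Wunsch, affine gaps (BLOSUM62, open 11,
  extend 1, a gap of length k costing 11 + (k−1)). Percent identity
  counts identical columns over aligned columns *excluding terminal
  gaps*, with internal gap columns kept in the denominator as
  mismatches. No identity convention is standard across the literature;
  this one is stated prominently because it directly affects reported
  percentages. Inputs are canonicalised (lexicographic order) before
  aligning so co-optimal alignments cannot make the result asymmetric.
  Whether published pairwise identities derive from direct pairwise
  alignment or from an MSA is usually unstated; this package reports
  direct pairwise values.

## 8. Problem sizes and numerical choices

The validation suite and the acceptance script use: 50 replicate worlds
of 30 samples × 205 contigs for association recovery; 100 seeds per
class for signature and sense recovery; 20 worlds (100 segment pairs)
for sister identity; 20 × 100 kb i.i.d. sequences for the composition
null; and 40 label permutations at n = 32 for the power analysis. These
sizes give Monte-Carlo standard errors comfortably below the tolerances
asserted while keeping the whole validation in the tens of seconds.
Tolerances follow from the statistics: binomial 3-SE bands for presence
fractions, ±3 percentage points for realized identity, a 2-SE allowance
on Monte-Carlo estimates of CI coverage, and |mean − 0.5| < 0.08 for
the LOO permutation null (leave-one-out is slightly anti-conservative
under the null, so a pure binomial band would be too tight).

## 9. Known limitations

* The generator's background model contains no co-regulated host
  transcripts, no cross-sample batch effects, and no shared
  contamination — all of which can create co-occurring non-viral pairs
  in real data. Passing the association tests therefore demonstrates
  correctness of the method under its own model, not a field
  false-positive rate.
* Small-RNA profiles are simulated at favourable depth (10⁴ reads per
  contig); shallow real libraries will push the filter toward the
  missing-data error path rather than confident calls.
* No read-level simulation, sequencing error, or assembly artefacts;
  contigs are taken as given.
* Homology flags and DNA-presence flags are inputs; the package neither
  runs similarity searches nor screens contamination.
* The composition module implements one ρ convention (linear,
  coding-strand); published host-prediction statistics vary and exact
  numeric agreement with any particular one is not expected.
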