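# Methods

## Data model

The reference is a rooted phylogeny (newick; multifurcations allowed,
branch lengths optional) over samples whose haploid genotypes at
biallelic SNVs are given as a VCF. Branches are identified with their
child node, so every non-root node carries exactly one branch and "the
clade below a branch" is unambiguous; clade membership is indexed as a
bitset over leaf positions, which makes per-branch genotype mismatch
counting a few machine-word operations. Leaf names are matched to VCF
sample columns exactly and case-sensitively; a pre-flight check reports
leaves without genotypes and samples absent from the tree, and zero
overlap is fatal.

## SNP-to-branch assignment

For a site with genotype vector g over the leaves and a hypothesis
(branch b, derived allele d ∈ {ref, alt}), the log-likelihood is

    L(b, d) = Σ_leaves log P(g_i | expected_i),
    expected_i = derived inside clade(b), ancestral outside,
    P(match) = 1 − ε,  P(mismatch) = ε,  missing: contributes 0.

With one shared ε (default 0.001) this reduces to minimum-mismatch
search, so an exhaustive enumeration oracle can check the argmax
exactly; the implementation evaluates all (branch, polarity) pairs with
vectorized clade-bitset counts. Polarity is inferred per site by
scoring both orientations; an ancestral-allele `AA` INFO annotation,
when present and matching ref or alt, pins it instead. Branch lengths
play no role in assignment.

Exclusions: records that are not single-base biallelic SNVs
(`excluded_multiallelic`), sites whose non-missing genotypes are all
equal (`excluded_monomorphic`; all-missing sites are counted here too),
and sites whose best fit still implies more than `max_mismatch`
(default 3) flipped genotypes (`excluded_low_likelihood`). The
low-likelihood rule is expressed as a margin in nats below the
perfect-fit log-likelihood, margin = max_mismatch · (log(1−ε) − log ε),
so the tolerated mismatch count is independent of ε. Heterozygous
diploid-coded calls are treated as missing (haploid loci) and counted.

**Root-edge ambiguity.** With a bifurcating root, a site on a
root-child branch is indistinguishable from the complementary
hypothesis — the sibling root branch with flipped polarity — because
both describe the same unrooted split. The deterministic tie-break
(fewest mismatches, then smallest branch id, alt-polarity first) sends
such sites to the first root child. This is information-preserving:
support/conflict tallies built from the flipped assignment are
equivalent for placement, and branch labelling maps a marker whose
derived allele matches the coded-ancestral allele of a root-child
assignment onto the sibling root clade. Consequences: assignment
recovery is only meaningful at the split level, and rooted placement
*onto* one of the two root-child edges cannot be resolved from genotype
data alone.

## Pileup filtering

Base calls at assigned sites are collected from indexed BAMs requiring
base quality ≥ 20 and mapping quality ≥ 25 (defaults), or supplied as
per-site count tables or a pre-called query VCF. Filtering is a total
function per site:

1. drop bases matching neither REF nor ALT;
2. mode `default`: if the site alleles are {C,T} and exactly one T
   remains, drop it; likewise a lone A at a {G,A} site (the singleton
   rule is applied after step 1 and regardless of total depth; a C at a
   C/T site is never singleton-filtered); mode `transversions`: return
   missing for every {C,T} and {G,A} site; mode `no-filter`: keep all;
3. call the most frequent remaining base iff its fraction of retained
   calls is ≥ the consensus fraction (default 0.7; ties at the
   threshold pass), mapping it to ancestral/derived via the site's
   inferred derived allele; otherwise missing.

## Placement

Non-missing calls at assigned SNPs are binned per branch into support
(derived) and conflict (ancestral) counts.

**Best path.** Every root-to-tip path is walked from the root; a path
is stopped at the first branch whose *own* conflict count exceeds
`max_conflict` (default 3) — that branch and everything below it become
ineligible, while the prefix above remains a candidate. Every
admissible prefix is scored by cumulative support; the argmax is
reported with ties broken by fewer cumulative conflicts, then shallower
branch, then smaller branch id. The tie flag is set only when tied
candidates are not nested on a single root-to-tip chain (prefix
extensions that add no data are not genuine ties). The insertion point
along the winning branch is support_on / (support_on + conflict_on)
measured from the parent end (0.5 when both are zero): derived
on-branch markers lie above the divergence point, ancestral ones below.
The annotation string `[support_above-conflict_above;
support_on-conflict_on]` is appended to the query's leaf name in the
output newick.

**Likelihood.** For candidate edge e,

    log L(e) = Σ_{b ≠ e} [ S_b · log w(b,e) + C_b · log(1 − w(b,e)) ],
    w(b,e) = 1 − ε  if b is a strict ancestor of e,  else ε,

i.e. a query attached on e is expected derived exactly at SNPs on
strict ancestors of e and ancestral elsewhere, while markers on e
itself are ignored — a conservative simplification, since markers on
the attachment branch may fall on either side of the divergence point.
ε defaults to 0.01 for queries (higher than the reference ε: residual
post-filter aDNA error). Posteriors are exp(L)/Σexp(L) under a uniform
prior over edges (log-sum-exp normalized); a length-weighted prior was
considered and left out to keep the posterior a pure likelihood ratio.
Edges with posterior > 0.01 are reported (the argmax always is). The
99% placement clade is the deepest branch on the root-to-argmax chain
whose inclusive clade carries > 0.99 of the posterior mass; defining it
along that chain (rather than globally) guarantees it contains the
point estimate even when the posterior is diffuse, and an empty chain
(no branch qualifies) is reported as root-level ambiguity.

Identifiability: the true edge is the unique zero-mismatch hypothesis
exactly when the query has ≥ 1 derived and ≥ 1 ancestral call among the
edge's own markers; with no own-branch data, an attachment is not
distinguishable from its siblings, and the conservative clade is the
informative output. Because the best-path rule stops at branches with
> `max_conflict` conflicts, a query diverging mid-branch on a
marker-dense branch is deliberately placed at the parent prefix — the
documented conservative behaviour of the traversal, not an error.

## Haplogroup refinement

Curated markers (name, label, position, ancestral/derived alleles) are
matched to assigned SNPs by position and derived allele to label
branches; the label hierarchy is long-form name nesting (X below Y iff
X startswith Y), with a synonym hook for short names. Refinement
anchors at the nearest labelled ancestor-or-self of the placement
branch and returns the longest label, at or below the anchor label,
supported by ≥ 1 derived-observed marker; support for diverging
sublineages falls back to their deepest common ancestor label and
reports the contenders as alternates, so added *conflicting* data can
shorten the label — the monotonicity of refinement holds only for
consistent data. Markers with provisional/uncertain status (tilde or
parenthesis suffixes) are retained but flagged and can support a
terminal label only when no unflagged marker contradicts them.

## Simulator

The generator emulates the study conditions end to end: a Yule-style
random rooted tree (uniform leaf splits, lengths ~ U(0.5, 1.5)); sites
placed on branches proportionally to length at unique positions
(infinite sites), so every variant's carriers are exactly one clade;
VCF polarity swapped per site with probability 0.5 (recorded) to
exercise polarity inference; per-leaf missingness. The default panel
density is 30 sites per branch, matching the order of sites-per-branch
in large published Y-chromosome panels. The query attaches mid-branch:
derived at strict-ancestor SNPs and at the proximal ⌈f·k⌉ of the
attachment branch's own k SNPs (f = 0.5 default; an option fixes the
number of distal ancestral markers instead), ancestral elsewhere. Reads
per site are Poisson(coverage); each read suffers uniform base error,
then deamination: C read as T, G read as A, independently per read with
probability δ. Identical configs give byte-identical files.

What the simulator does *not* model: fragment-length and within-read
damage gradients (damage is position-independent), reference bias,
duplicate reads, contamination, tree-estimation error, and recurrent
mutation in the panel (only independent genotype flips). Passing
recovery tests therefore demonstrates correctness of the assignment /
filtering / placement machinery under the stated error model, not
performance on real ancient libraries.

## Default parameters

| parameter | default | meaning |
| --- | --- | --- |
| ε (reference) | 0.001 | genotype-error rate in panel assignment |
| max_mismatch | 3 | implied mismatches tolerated before site exclusion |
| min BQ / MQ | 20 / 25 | pileup base/mapping quality gates |
| consensus | 0.70 | fraction of retained calls the top base must reach |
| filter mode | default | singleton-transition removal |
| max_conflict | 3 | per-branch conflicts that stop a best path |
| ε (query) | 0.01 | per-call error in likelihood placement |
| posterior threshold | 0.01 | reporting cutoff for edges |
| clade P | 0.01 | 1 − P mass defines the placement clade |

## Numerical and procedural choices

Log-space throughout with scipy's log-sum-exp for normalization; exact
integer mismatch counts (no floating-point comparisons) in both argmax
searches; deterministic tie-breaks everywhere (documented above), so
identical inputs give byte-identical outputs across the whole CLI.
Evaluation problem sizes (hundreds of simulations at 16–64 tips with
~30 sites per branch, coverage 1–5) were chosen so each measured rate
is a stable small-sample estimate while the whole evaluation stays in
the minutes range on a single core.

## Known limitations

Rooted placement onto a root-child edge is unidentifiable (see
root-edge ambiguity above). The likelihood ignores branch lengths and
per-site base counts (hard calls only). Joint placement of multiple
queries, branch-length re-estimation, damage-pattern rescaling and
graphical outputs are out of scope; outputs are newick and TSV.
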