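# Methods

This note documents the models and conventions behind `btchar`, the
parameters that matter, what the synthetic generators do and do not
emulate, and the design choices made where more than one convention was
defensible.

## In-silico PCR

A primer is an IUPAC string; a template base matches a primer base iff it
lies in that code's expansion set (R = A/G, Y = C/T, K = G/T, S = G/C, W, M,
B, D, H, V, N as usual). Sites are found on the plus strand by direct
left-to-right comparison and on the minus strand by matching the reverse
complement of the primer, reported at the site's leftmost plus-strand base.
All coordinates are 1-based inclusive; product length is end − start + 1.
This convention is forced by the published primer coordinates (a product at
78–1472 is 1395 bp).

Defaults: `max_mismatch = 0` — the wet-lab annealing stringency of a PCR is
not knowable in silico, so the default demands exact (degenerate-aware)
matches, and mismatch tolerance is an explicit knob. Increasing
`max_mismatch` can only add hits (tested property). Amplicon size limits
default to 50–5000 bp to suppress spurious pairings of distant sites.

Typing assigns the label of the *unique* reverse primer that yields a
product with the shared forward primer; two or more productive reverse
primers raise an error rather than applying a priority order, since real
typing reports unambiguous assignments only.

Contig merging returns the shortest superstring in which a suffix of the
first contig exactly equals a prefix of the second with at least
`min_overlap` bases. The maximal valid overlap length is unique for
suffix/prefix merging, so the result is well defined even for periodic
sequences (merging a sequence with itself at full overlap returns the
sequence).

Percent identity is a deliberately minimal BLAST-like surrogate: global
alignment with free end gaps (match +1, mismatch −1, gap −2), identity =
matches / aligned columns excluding terminal gaps, query cover = fraction
of query residues inside the aligned region, both rounded to integers. It
is meant for reporting how closely an assembled amplicon matches a
user-supplied reference, not for database search; identities against
external reference genes are therefore not expected to reproduce
BLAST-reported values digit for digit.

Percentages of positive isolates are rounded half away from zero (18/80 =
22.5% reports as 23%).

## Unique-peptide protein inference

Digestion uses the simple Keil trypsin rule — cleave after K or R except
before P — with configurable missed cleavages (default 0 for the index).
The uniqueness index maps every tryptic peptide of every family member to
the set of members containing it **as a substring of the full sequence**,
not by digest-to-digest set equality. This choice means a peptide carrying
a missed cleavage still classifies correctly; it approximates the
alignment-based uniqueness check a practitioner would run against reference
sequences. `equate_il` (default off) identifies I and L before matching,
since their residue masses are indistinguishable by MS; the default keeps
them distinct so that index-level uniqueness matches sequence-level
uniqueness exactly.

The evidence filter retains peptides of length 6–20 with contribution score
strictly greater than 2 and no modification, then collapses duplicate
peptide strings, keeping the highest-contribution representative (the
source procedure says only that one member of each duplicate group is
kept; the choice of representative does not affect counts). A protein
whose unused score is ≤ 2 is excluded before peptide-level evidence is
considered; otherwise it is positively identified iff at least two retained
peptides are unique to it. Coverage is the percentage of residue positions
covered by at least one occurrence of any retained peptide, computed
post-filter and reported to 2 decimals.

## Probit dose-response

Model: dead ~ Binomial(n, Φ(a + b·log₁₀ dose)) per dose group, replicates
at the same dose pooled. Log base 10 and no historical +5 probit offset, so
the reported slope is probits per tenfold dose increment. The fit is the
maximum-likelihood solution obtained by Fisher scoring (IRLS, relative
tolerance 1e−10, up to 100 iterations); 0% and 100% groups enter the
likelihood untransformed. Degenerate inputs raise: fewer than two distinct
doses, all-dead/all-alive data, diverging slope (complete separation), or a
non-positive fitted slope.

Goodness of fit is the Pearson χ² over dose groups with df = groups − 2.
When χ²/df > 1 the covariance matrix is multiplied by the heterogeneity
factor and interval critical values use t(df) instead of z — the behavior
of the classic Polo software; when χ²/df ≤ 1 no deflation is applied. This
only-inflate convention makes intervals mildly conservative (measured
coverage sits in the upper half of the nominal band in the simulation
tests).

LC50 = 10^(−a/b). Fiducial limits solve Fieller's quadratic
(a + ρb)² = c²·var(a + ρb) for ρ = log₁₀ LC50 with the scaled covariance;
when g = c²·var(b)/b² ≥ 1 the interval is unbounded and is reported as
undefined rather than a number. With a well-determined slope (g → 0) the
limits agree with the delta method (tested to 1%). Significance between two
LC50s is declared iff the two 95% intervals are disjoint, touching
endpoints counting as overlap.

Natural-response is not estimated as a third parameter; Abbott's
pre-correction (observed − control)/(1 − control), floored at zero, is
available and optional because the assays this models showed ≤ 3%
control mortality. Mortality summaries report pooled-replicate percent
kill to 2 significant figures, ties away from zero (29/32 → 90.625 → 91).

## Protein characterization

Translation uses the standard genetic code; the ORF must be a multiple of 3
and start with a start codon (check can be disabled), internal stops raise
with the codon position, and a single terminal stop is consumed — so a
stop-terminated ORF of 3(n+1) bp encodes n residues. Molecular mass is the
sum of residue masses plus one water, with **average** masses by default
(average, not monoisotopic, is what matches the ~88.5 kDa scale quoted for
a 789-residue toxin); monoisotopic is a mode switch. Residue differences
require equal-length inputs and do no alignment.

Gel filtration uses Kav = (Ve − V0)/(Vc − V0), least-squares linear in
log₁₀(mass kDa) over the calibration standards (slope negative on a working
column: larger proteins elute earlier). The query peak's apparent mass
inverts the line, and the oligomer order is the nearest integer ratio of
apparent to monomer mass, floored at 1 ("approximately 4 times the monomer"
reads as a tetramer). The published difference table between the Vip3Aa16
and Vip3Aa65 variants ships as a position→(residue, residue) constant with
a fixture builder that places those residues on a synthetic neutral
backbone; only the differing positions are meaningful, the backbone is not
the real protein.

## Synthetic-data generators

One master seed; each generator draws from a deterministic child stream, so
a whole run is reproducible byte for byte.

- **Reference family**: one random base protein (K/R sites guaranteed every
  ~10 residues so tryptic peptides have usable lengths); each member gets
  exactly `divergence` point substitutions at recorded positions.
  Substitutions avoid K, R and P as either original or replacement, so all
  members share one cleavage pattern and a member's unique peptides are
  exactly its substitution-bearing peptides. Defaults: 600 residues, 3
  members, 25 substitutions — family-level divergence small enough that
  most peptides are shared, as in real Cry1 homologs.
- **Isolate genomes**: uniform random nucleotides (3000 bp default);
  carriers get one concrete expansion of each screening primer planted at
  the published binding coordinates (reverse primer as reverse complement)
  plus one typing-primer site pair for a carrier type drawn with
  probabilities 0.69/0.19/0.12 (the observed vip3Aa/vip3Af/vip3Ag
  prevalence); non-carriers are verified to contain no productive site pair
  and regenerated on (astronomically rare) accidental matches. Defaults: 80
  isolates, 18 carriers.
- **Peptide tables**: rows drawn from the tryptic digest of the designated
  true proteins; contribution scores from a shifted exponential (2 + Exp(3))
  for true rows — only the > 2 cutoff matters downstream — with injected
  defect rows guaranteeing at least one violation of each filter (short,
  long, at-cutoff score, modified, duplicate). If the family has a
  non-true member, it appears as a decoy entry with unused score 1.5 so the
  protein-level threshold is exercised.
- **Bioassays**: doses form a geometric series centered on the true LC50
  (5 threefold dilutions by default, 16 larvae per dose as in the emulated
  surface-contamination design); dead ~ Binomial(n, c + (1−c)·Φ(b·(log₁₀ d
  − log₁₀ LC50))) — the complement rule, which Abbott's correction inverts
  exactly. Default control mortality is 0 (the emulated controls showed
  essentially none).
- **Calibration**: elution volumes from a fixed Kav line (slope −0.36,
  intercept 1.14, V0 = 9 ml, Vc = 24 ml — chosen so the high-molecular-
  weight kit standards and a ~346 kDa query fall in range on a typical
  analytical column) plus Gaussian noise, resampled into [V0, Vc].

What the generators do **not** emulate: real spectra or chromatograms (only
score columns), sequence homology structure beyond point substitutions (no
indels, domain shuffling or shared subfamily blocks), PCR artifacts
(mispriming, chimeras), overdispersed or correlated larval mortality
(replicates are exchangeable binomials), or column non-ideality. Passing
tests therefore demonstrate the correctness of the arithmetic, rules and
estimators under the stated statistical model — not robustness to every
failure mode of real instruments.

## Problem sizes in the checks

The recovery and coverage checks use 200 and 500 simulated assays at 48
larvae per dose (three replicates of 16 pooled), which gives medians within
a few percent of truth and interval coverage near the nominal 95%. The
brute-force oracle comparisons (primer scanning, digestion, uniqueness,
coverage, alignment scoring) run on hundreds of small random instances per
test; these sizes were chosen to make the suites sharp yet quick.

## Known limitations

- Uniqueness is exact-substring based; a single substitution makes a
  peptide unique even though a search engine might still assign its spectra
  ambiguously.
- Fiducial limits for very small assays (16 larvae/dose) are occasionally
  unbounded (g ≥ 1); callers receive NaN limits and comparisons refuse to
  run rather than fabricate an interval.
- Percent-identity is a scoring surrogate, not BLAST; use it for relative
  comparisons against supplied references.
- The real cloned-gene sequence (GenBank MH290720) is not bundled; the
  translation/mass route is exercised on generated ORFs and, when the user
  supplies the accession FASTA, on the real gene.
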