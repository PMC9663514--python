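# Methods

## The eJM motif model

The model scores a candidate 6-residue window `w` against a reference
window `r` as a position-weighted substitution score
`S(w; r, λ) = Σᵢ λᵢ · M(wᵢ, rᵢ)` with `M` = PAM250.  Two references are
carried: the ErbB4 JM-a isoform's residues 627–632 (`GPTSHD`) and the
JM-b isoform's (`GSSIED`).  These windows are fixed by the isoforms'
residue-level differences: the isoforms share G627 and D632 and differ at
628 (P/S), 629 (T/S), 630 (S/I) and 631 (H/E).  The final weightings are
the two binary schemes over positions {1,4,5} and {1,5,6}; chemically,
position 1 is the glycine anchor and the weighted pair is the hydrogen-bond
donor/acceptor couple sitting three or four residues downstream.  A
sequence's motif score is the maximum of `S` over all contiguous 6-mers
and over both weightings (the "three to four residues apart" spacings are
alternative realizations of one motif, hence max, not sum).  Class
assignment compares the JM-a-reference score with the JM-b-reference
score; ties go to JM-b-like because the JM-b state is interpreted as the
*absence* of a JM-a motif rather than a motif of its own.  Window ties
resolve to the smallest offset, and a length-6 sequence has exactly one
window.

Categorization accuracy on a labelled panel is tested against chance with
the upper binomial tail `P(X ≥ k)`, `X ~ Binomial(n, ½)` — each receptor
is a coin flip under the null of uninformative scoring.

The curated panel in `ejmotif.panels` contains the ten ErbB4 sequences
whose STAT5 class is a clean categorical experimental call: the two
wild-type isoform regions, the two motif-breaking JM-a mutants (H631E and
S630I/H631E, both of which switch the receptor to STAT5b activation), and
the six JM-b point mutants, none of which restores STAT5a signaling.
Mutants with graded readouts (fold-change reductions without a clean class
switch, e.g. H631K or JM-a D632L) are deliberately excluded from the
panel: the model places H631K exactly on the class boundary (where the
tie rule calls motif absence) and keeps JM-a D632L JM-a-like through the
{1,4,5} weighting, both consistent with their intermediate phenotypes but
not clean enough to serve as labels.

### Enrichment and conservation nulls

`ejm_enrichment` asks whether the 30-residue eJM window scores higher for
the JM-a motif than the rest of the receptor's ectodomain.  Per receptor,
`n_perm` equal-length windows are sampled uniformly (without replacement
while possible) from the ectodomain upstream of the eJM; the test
statistic is the mean, across receptors, of the eJM window's mid-rank
exceedance over its sampled windows, and the permutation p-value uses the
`(1 + hits)/(n_perm + 1)` convention, so its floor is `1/(n_perm+1)`.
`conservation_similarity` reports mean ± sd percent identity of per-taxon
motif regions against the human reference and, when ortholog ectodomains
are supplied, a permutation p from random same-length windows (10,000
draws by default, seeded).

## Interactome statistics

**Normalization.**  Each (experiment, sample, fraction) column is divided
by its column total (fractions with zero total are dropped with a
warning); normalized fractions are summed within a sample to give a total
protein intensity; and each experiment is rescaled so its median detected
protein total equals 1.  All per-experiment medians are thereby equal, and
"one median unit" becomes the natural scale for the pseudocount:
`pseudolog2(x) = log2(x + 1)` on this scale compares a protein to the
typical detected protein.  (A pseudocount of 1 on the raw fraction-share
scale would swamp values of order 1/n_proteins and no fold change could
ever clear the 0.5 threshold.)

**Empirical null and calls.**  The null for interactor calling is an
Epanechnikov-kernel density (K(u) = ¾(1 − u²) on |u| ≤ 1) fitted to the
vector-control totals, with an exact piecewise-polynomial CDF
(`W(u) = ½ + ¾u − ¼u³` per kernel) — no numerical integration.  The KDE is
fitted on the pseudolog2 scale because intensities span orders of
magnitude and a single bandwidth on the raw scale over-smooths the bulk;
the transform is monotone so the tail probability is unchanged in
definition.  Bandwidth defaults to Silverman's rule.  Two combining
strategies are exposed:

- `combine="fisher"` (default): per experiment, the protein's mean bait
  total is scored against that experiment's null of per-protein mean
  control totals (upper tail, floored at `1/(n_control+1)`), and the
  per-experiment p-values are combined with Fisher's method.  This is
  calibrated when experiments are independent and is the more sensitive
  path, because floors multiply across experiments; it turns
  anti-conservative if protein abundances are strongly correlated across
  experiments.
- `combine="pooled"`: experiments are pooled before the p-value — one
  null of per-protein mean control totals, one statistic per protein.
  Always calibrated, but the single floor of `1/(n_proteins+1)` bounds how
  small adjusted p-values can get, which limits sensitivity after BH
  correction over the same proteins.

A protein is a significant interactor iff its mean pseudolog2 fold change
against control exceeds 0.5 **and** its BH-adjusted p is ≤ 0.05.  Zeros are
true "not detected" values and are never imputed.

**Binary class test.**  For class-specific preys the abundance matrix is
reduced to detected/not-detected per bait (robust to the zero-inflated
value distribution).  For a prey seen in `k_A` of `m_A` class-A baits and
`k_B` of `m_B` class-B baits, the representation ratio is
`(k_A/m_A)/(k_B/m_B)` and the p-value is `P(X ≥ k_A)` with
`X ~ Binomial(k_A+k_B, m_A/(m_A+m_B))` — under the null, each detection
falls on a bait class with probability proportional to class size.  A prey
is class-specific iff ratio ≥ 5 and p < 0.05.  The construction is exactly
label-symmetric.

**Overlap arithmetic.**  Annotation-set overlaps are scored against a
normal distribution fitted to overlaps of 30 random same-size draws
(lower tail for a lack-of-overlap hypothesis), or with a 1-df chi-square
on a 2×2 table without continuity correction.

## Cluster separation of interactomes

Features (prey abundances or presences) are zero-filled and standardized
to unit variance, then embedded with neighborhood component analysis
(PCA initialization, seeded).  Separation is the ratio of mean
within-class to mean between-class pairwise Euclidean distance —
scale- and rotation-invariant, 1 for unstructured data, defined as 1 when
all points coincide.  The permutation test shuffles labels preserving
class sizes and re-runs the *full* pipeline per permutation (refitting
NCA, so the observed and null statistics are exchangeable under the null;
a `refit=False` switch re-scores a fixed embedding instead).  The observed
ratio's lower-tail probability is read from an Epanechnikov-KDE CDF over
the null ratios, floored at `1/(n_perm+1)`.

## Glycan arrays

Sample columns are divided by their total RFU and rescaled by the grand
mean of sample totals, preserving RFU-like magnitude while equalizing
total signal.  The background rule drops a value iff CV% > 50 **or**
RFU < 50 (strict inequalities per the "over"/"under" thresholds); an
AND-variant is exposed by flag.  Differential binding is ranked by
`log2((rfu_a+1)/(rfu_b+1))` descending, ties broken lexicographically by
glycan id.

Structures are parsed from IUPAC-condensed strings by recursive descent:
the rightmost residue is the reducing-end root, parenthesized segments are
branches on the residue that follows, and edges carry anomeric
configuration plus child/parent linkage positions.  Spacer suffixes
(`-SpN`) are stripped; `-Asn` is kept as a root annotation.  Parsing and
serialization round-trip exactly.  A structure is an N-glycan when it
carries the trimannosyl-chitobiose core (Manα1-3/6 arms on
Manβ1-4GlcNAcβ1-4GlcNAc) and a *complex* N-glycan when at least one core
arm bears a GlcNAc-initiated antenna (β1-2/4/6); mannose-only antennae
(high-mannose) are excluded by that rule.

Determinant enrichment compares, among filtered N-glycans, the normalized
JM-a RFUs of determinant-bearing high-affinity glycans (rfu_a ≥ 1.5·rfu_b)
with those of the similar-or-less-preferring reference group
(rfu_a < 1.5·rfu_b), using a two-sided Mann–Whitney U (exact for combined
n ≤ 20, otherwise the tie-corrected normal approximation) and BH
adjustment across the 17-determinant family.  Note that GlcNAcβ1-4 matches
the chitobiose core of every N-glycan, not only antennae — relevant when
interpreting that determinant's row.

## Colocalization

Pearson correlation is computed over all masked pixels without
thresholding; overlap = Σab/√(Σa²Σb²); k1 = Σab/Σa², k2 = Σab/Σb² (so
k1·k2 = overlap² identically); m1/m2 are the intensity fractions of each
channel where the *other* channel exceeds its threshold (Otsu by default —
the thresholds used in the original imaging analyses are not on record,
so they are an explicit parameter here).  Constant channels raise an
error for Pearson.  PLA quantification divides total above-threshold
signal by the nucleus count obtained by global thresholding plus
connected components with a minimum-area filter.

## Synthetic data: what it does and does not emulate

Each generator is a pure function of its arguments (same seed ⇒ identical
bytes) and returns ground truth sufficient to score recall, FDR and bias
downstream.

- *eJM panels*: uniform random 30-mers with a class reference window
  planted at a random offset, then per-position mutation (always to a
  different residue).  Real eJM regions have biased composition and
  phylogenetic correlation; passing tests show the classifier recovers
  planted motifs, not that it resolves borderline natural sequences.
- *LFQ tables*: log-normal background (2^N(20, 1.5) per measurement,
  the LFQ magnitude regime), independent across measurements, zeroed with
  probability π (default 0.3); spiked preys are multiplied by the spike
  fold in bait samples only.  Defaults: 3 experiments (the replicate
  convention of the underlying assays), 2 samples per condition, 3
  fractions.  The generator does not model persistent per-protein
  abundance across samples, peptide-level effects, or
  intensity-dependent missingness — so the Fisher path's independence
  assumption holds by construction here, and its behaviour on strongly
  correlated real replicates must be judged separately (see the pooled
  alternative above).
- *glycan screens*: structures from a small grammar (≈50% complex
  N-glycans with 2 antennae, 20% high-mannose, 30% short O-glycan-like
  chains); JM-a RFU = baseline × the product of multiplicative effects of
  the determinants present; replicates at a target CV (default 15%, 4
  replicates).  Real CFG arrays have ~600 structures, correlated
  determinants and saturation effects.
- *punctae images*: Gaussian spots (amplitude 1000, PSF σ = 2 px) with a
  controllable shared fraction between channels and clipped additive
  Gaussian noise; no optics beyond the Gaussian PSF, no background
  gradients.
- *ortholog panels*: per-position mutation at rate 1 − target identity —
  a star phylogeny, not a realistic tree.

## Numerical choices and problem sizes

Window ties → smallest offset; class ties → JM-b-like.  KDE bandwidth:
Silverman's rule with a tiny positive floor for near-constant data.
Permutation p-values use the `(1+hits)/(n+1)` convention throughout.
BH adjustment delegates to the standard step-up implementation and is
checked against a brute-force oracle.  NCA runs with `max_iter=50` on
standardized features; rank-deficient fits fall back to an identity
projection with a warning.

Test and acceptance problem sizes are chosen to make the statistical
checks sharp at interactive runtimes: 500 proteins for null calibration,
200/10 for spiked recovery, 200 repeats × 100 permutations for the
cluster-test calibration, 120-glycan screens, 1000 parser round-trips,
16-taxon conservation panels.

## Known limitations

- The receptor panel shipped with the package covers the ErbB4 isoforms
  and their mutants; classifying other RTKs requires supplying their eJM
  sequences (FASTA input is supported).
- The interactor caller tests abundance against the *marginal* control
  distribution, as the original procedure does; preys whose enrichment is
  large relative to their own baseline but small relative to the overall
  abundance spread are intrinsically hard for this statistic.
- The Mann–Whitney determinant test treats glycans as exchangeable;
  structural correlation between determinants is not modelled (only
  corrected for multiplicity).
- `is_complex_nglycan` implements the core + GlcNAc-antenna rule; hybrid
  N-glycans (one GlcNAc antenna, one mannose arm) count as complex under
  this rule.
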