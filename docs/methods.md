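# Methods

## Mass arithmetic and digestion

Monoisotopic residue masses are fixed at five-decimal standard values;
water is 18.010565 Da and the proton 1.00727646 Da. Peptide mass is the
residue sum plus one water, plus any variable modification deltas
(oxidized methionine, +15.994915 Da, is the only variable modification;
up to two per peptide are enumerated when building the search index).
Isoleucine and leucine are distinct letters with equal mass; output keeps
the database letter. Input sequences are treated as already mature — no
transit-peptide or initiator-methionine logic.

Tryptic digestion cuts after K or R except before P. The cross-link
searches default to three missed cleavages because a linker-modified
lysine suppresses cleavage at its own site. Carbon counting sums
per-residue formula carbons (G=2 … W=11); the condensation water carries
no carbon, so the count is additive over concatenation.

## Cross-linker model

DSS (disuccinimidyl suberate) reacts with lysine side chains and the
protein N-terminal α-amine. The intact bridge adds the suberate spacer
C8H10O2 = 138.06808 Da (light, d0); the heavy form (d12) adds
12.07532 Da more. Only the difference is physically printed on the
precursor pairs, so the absolute bridge mass is taken from standard DSS
chemistry. Reactive-site rules on tryptic peptides: internal lysines
qualify; a peptide's C-terminal lysine does not (a linked lysine would
have blocked the tryptic cut that produced it) unless it is the protein
C-terminus, which we allow and flag; position 1 of the protein N-terminal
peptide qualifies via the α-amine. Mono-links/dead-ends and intra-peptide
loop-links are not searched; both are extension points.

## Candidate enumeration

Linkable peptides (with their Met-oxidation variants) are indexed by
mass. For an observed precursor neutral mass M and isotope form, all
unordered peptide pairs with mass(α)+mass(β)+bridge within 10 ppm of M
are enumerated, one candidate per reactive-site combination, ordered by
theoretical mass then lexicographically. The acceptance inequality
|theo − M| ≤ theo·tol is inverted into exact bounds on the pair mass,
so the indexed search is equivalent to brute-force pairing at any
tolerance (property-tested against an exhaustive oracle).

## Deconvolution and precursor pairing

Fragment neutral mass is M = z·(m/z) − z·m_proton. Each MS2 peak is
interpreted at every charge 1..(precursor charge − 1); hypotheses above
the precursor neutral mass are discarded and hypotheses agreeing within
0.01 Da are merged keeping the most intense representative — the simplest
deterministic rule. Acquisition-side exclusions (charge limits) are
treated as properties of the data, not re-imposed by the reader.
Light/heavy precursor pairs are detected as precursor masses differing by
12.07532 Da within 10 ppm, optionally gated on a 120 s retention-time
window. Because how pairing evidence was fused into the original
identification lists is not derivable, pairing is an annotation
("paired" isotope evidence on validated hits), not a hard filter.

## Scoring

For each peptide of a candidate pair, ions b1..b(n−1) and y1..y(n−1) are
generated; ions spanning the linked residue carry bridge + intact partner
peptide. Matching is one-to-one: candidate (ion, peak) pairs within the
dual tolerance (0.05 Da or 10 ppm, whichever is wider at that mass) are
assigned greedily by increasing mass error; the count is cross-checked in
tests against a maximum-bipartite-matching oracle. The null model takes
peaks as uniform over the scored mass range (100 Da up to the precursor
mass), giving p = n_peaks · 2·tol_eff / range with tol_eff evaluated at
mid-range; the p-value is the Poisson survival P[X ≥ n_matched] at
μ = N·p and the E-value multiplies by the number of candidates scored
for that spectrum. The constant-density p estimator is a design choice;
it is conservative on real spectra whose peaks cluster at low mass.

## Two-step search

Step 1 keeps, per spectrum, the best cross-link candidate from the small
targeted database if its E-value is ≤ e_max (default 0.01; configurable —
the threshold the original workflow used is not stated anywhere
recoverable). Step 2 re-scores the spectrum against the whole proteome,
adding linear peptides at the same precursor mass, and validates the
step-1 pair only if it remains top-ranked ("top_ranked" mode). An
alternative mode ("evalue_factor") accepts the pair when its re-scored
E-value is within a configurable factor of the whole-proteome best, for
workflows that prefer near-ties not to kill a hit. No decoy-FDR layer is
applied by default; the validation step is the error control, as in the
two-step design itself.

## Stoichiometry

Per replicate: (1) single-subunit bands of the primary gel system are
carbon-normalized to molar values; (2) the secondary system is calibrated
through its comigrated band — the band's molar value is computed by
splitting its signal in proportion to each member's reference-derived
copies × carbons and carbon-normalizing, and the scale factor is
(sum of the members' resolved values) / (band molar value); this
definition, rather than signal/(Σ carbons), is the one that recovers
arbitrary copy vectors exactly, since a composite band's raw signal is
carbon-weighted; (3) composite bands are partitioned by splitting their
summed *signal* by the 2D system's raw spot fractions and then
carbon-normalizing per subunit — signal-space first, because
signal ∝ copies × carbons (the order is switchable but this is the
consistent one); (4) everything is normalized to the reference subunit
(PSAF), so the reference is identically 1 by construction. Means and
standard errors (sample sd/√n, n = 3 replicates by default) are taken
across replicates; copies are rounded to the nearest integer, ties away
from zero, with a warning when the fractional part falls in [0.4, 0.6].
Band membership is declared in the input table, never inferred from
migration. Per-system gains cancel: the primary system through reference
normalization, the secondary through calibration, the 2D system because
only its fractions are used.

## Topology and restraints

Cross-link records (2 or 3 member subunits each) form a hypergraph;
triples expand to flagged pairwise edges in the projection, so pairwise
edge count ≥ hyperedge count with equality iff no triples. The packaged
22-record product table contains exactly one triple. Peptides are placed
on structure chains by exact substring match, falling back to the best
gapless sliding alignment at ≥ 60% identity (ties raise an ambiguity
error); this stands in for a short-query protein BLAST in cross-species
mapping. Cα–Cα distances use a 30.0 Å default threshold; 26–30 Å is
reported as a soft band, not a second cutoff. Structure parsing (PDB and
mmCIF polymer Cα records) goes through gemmi; chain↔subunit mapping is
user-supplied. Homology-model placement of unmappable subunits is out of
scope — externally produced model coordinates are accepted as input.

## Synthetic data

`gen_proteome` draws uniform-composition sequences (10 proteins of
80–120 residues by default) and guarantees ≥ 2 internal lysines per
protein. `gen_spectra` plants cross-links between randomly chosen
linkable peptides: the default study conditions are 50 planted links,
80% fragment sampling, 5 ppm Gaussian mass error, 10 uniform noise peaks
(intensities exponential), precursor charges 3–6, fragments emitted
singly charged, and optional heavy twins at +12.07532 Da. `gen_gel_signals`
builds band tables for three gel systems with the study's band
membership map (two composite bands sharing one subunit, one comigrated
calibration band), per-system log-uniform gains and lognormal
multiplicative noise of specified CV (mean-1 parameterization). These
defaults size the full test suite and the acceptance script to seconds
on one CPU. Not emulated: isotope envelopes, retention-time structure,
correlated/chemical noise, profile peaks, and real amino-acid
composition bias — so passing tests demonstrate correctness of the
algorithms under their stated statistical model, not instrument-grade
performance.

## Numerical and degenerate-input choices

Mass comparisons use relative (ppm) bounds evaluated on the theoretical
mass; candidate tie-breaks are lexicographic on (protein id, start);
score ties break by higher matched-ion count then lexicographic key, so
all result tables are byte-stable across reruns. Empty spectra score
p = 1; empty candidate lists yield empty rankings; zero-carbon or
zero-signal denominators raise errors naming the offender.

## mzML support

mzML is read by a compact built-in stream parser (spectrum-level
cvParams, 32/64-bit base64 arrays, zlib or uncompressed) and written by a
matching minimal writer; MGF goes through pyteomics and is the format of
choice for fixtures since it is plain text. Vendor raw files, profile
centroiding and isotope-envelope fitting are out of scope.
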