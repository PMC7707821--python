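# Methods

## The assay being modeled

`dmscreen` analyses pooled deep-mutational-scanning screens in which each
receptor variant is linked to several random 15-nt barcodes located in the
3′ UTR of a cAMP-response-element (CRE) reporter transcript. Under agonist,
barcode abundance in RNA-seq reflects cellular abundance × reporter
induction; under forskolin, which activates adenylyl cyclase downstream of
the receptor, the reporter is maximally induced regardless of variant, so
forskolin counts estimate cellular abundance alone. Frameshifted library
members (a by-product of single-base deletions in microarray-derived oligos)
provide an internal loss-of-function null.

## Barcode mapping

Merged reads are split into a fixed-length 15-nt barcode and the insert.
Barcodes with fewer than three reads are dropped (no majority call is
possible). Three filters remove barcodes tagging more than one variant:

* **Offset filter.** Each observed insert is placed on the full reference
  CDS by infix ("fit") alignment and the barcode is flagged when any start
  differs by more than 5 nt from the modal sequence's start. Fit alignment
  is used deliberately instead of a soft-clipping local aligner: when an
  insert's first bases contain a designed codon change plus one sequencing
  error, Smith–Waterman trims the mismatch-dense head and reports a shifted
  start, flagging a clean barcode. Fit alignment consumes the whole query,
  mirroring a read mapper's reported position. A sequence whose best
  placement needs more than 0.3 edits per base is treated as unalignable,
  i.e. contamination. (A Smith–Waterman aligner with match 1 / mismatch −1 /
  gap open −2 / extend −1 remains available in the module.)
* **Length filter.** Any two distinct insert lengths flag the barcode:
  synthesis deletions arrive at full penetrance on their oligo, so mixed
  lengths mean mixed templates, while Illumina substitution errors preserve
  length.
* **Collision filter.** A non-modal insert with more than one read at
  Levenshtein distance ≥ 4 from the modal insert flags the barcode. Designed
  variants within a segment differ by ~4 edits (two bases of each of two
  codons), so distance ≥ 4 with read support indicates two designed variants
  sharing a barcode, while singleton outliers and 1–2-edit sequencing errors
  are spared. The threshold is configurable, including an exactly-4 mode.

Consensus is the read-count-weighted majority base per position over inserts
of the modal length, with `N` at exact ties. Classification proceeds:
exact match against the designed-variant dictionary → missense; otherwise
the net frame shift of a global alignment to the segment reference — which
for a global alignment equals the length difference — decides frameshift
(shift ∤ 3) vs unassigned in-frame indel; equal-length sequences are trimmed
to whole codons in the CDS frame, translated, and a perfect full-length
protein match is synonymous (wild type when nucleotide-identical). The
CIGAR of the edlib alignment supplies the indel specification. Edit-distance
CIGARs are not used to *decide* frame disruption because a unit-cost aligner
can represent a cluster of substitutions as cheaper compensating indels.
In-frame indels are binned as unassigned, not frameshift. Consensus
sequences containing `N` can never match exactly and fall through to
unassigned unless translation is unaffected.

Coordinates are 1-based for residues and 0-based half-open for nucleotide
intervals throughout.

## Activity scores

Retained barcodes must appear in both forskolin replicates with mean
forskolin RPM in [0.2, 10), computed on raw counts; barcodes missing from a
drug column get count 0 there. The RPM window is depth-relative: 0.2 RPM
corresponds to ~10 reads at the depths the thresholds were designed for, so
synthetic runs at other depth-to-barcode ratios should pass a widened or
disabled window (the study-scale recovery below uses no upper bound, since
every simulated barcode sits near 100 RPM and no saturation artifact is
simulated).

Each column receives a pseudocount scaled to the shallowest column,
p<sub>c,r</sub> = N<sub>c,r</sub>/min N, and is normalized to its depth
including pseudocounts: q = (n+p)/(N+Bp) with B the retained barcode count.
Drug replicate r is divided by forskolin replicate r (per-replicate pairing
preserves replicate independence for error propagation; a mean-forskolin
mode is exposed). Variant activity per replicate is the unweighted mean over
its barcodes divided by the mean over frameshift variants — each frameshift
consensus (barcode) is its own variant — making the frameshift mean exactly
1 in every condition and replicate, an invariant the code asserts.
Replicates are averaged unweighted; their barcode-level standard deviations
combine as sd = √(sd₁²+sd₂²)/2. SEM and CV are computed across barcodes
after replicate averaging.

## Annotation

**Mutational tolerance** is the unweighted mean activity of the measured
substitutions at a residue and condition; residues with fewer than five
measured substitutions are flagged low-coverage. Ranking sorts ascending
tolerance (most intolerant first) with ties broken by residue index; extreme
sets are the n most activating variants at vehicle and n least active at
EC100 (stable sorts, variant label as tiebreak).

**Loss of function.** A variant is potentially LoF when
a + SEM < mean_fs − 2·sd_fs, with the frameshift statistics taken from the
same replicate-averaged activity scale and condition; equality is not LoF.
Population tables join on (position, wt, mut) strictly — a wild-type
mismatch is an error, never a silent drop.

**Conservation.** Per alignment column, the amino-acid distribution
(gaps excluded) is compared with a background by Jensen–Shannon divergence
in bits, JSD = H(M) − ½(H(P)+H(Q)). Only columns where the reference row
carries a residue are scored; scores are min–max rescaled to [0,1] over the
scored columns. Columns with >50 % gaps are flagged, all-gap columns are
reported missing. The default background is the BLOSUM62 amino-acid
frequency vector standard in divergence-based conservation scoring; a
uniform background is available. A fully conserved column against the
uniform background scores 0.8549 bits.

## Clustering

Amino acids are grouped into eight physicochemical classes ((+): R,H,K;
(−): D,E; aromatic: F,W,Y; amide: N,Q; nucleophilic: C,S,T; hydrophobic:
I,L,V,M; small: G,A; proline: P). Per residue, condition and class the mean
activity is log2-transformed (activities floored at ε = 10⁻³; pseudocounts
make true zeros rare, the floor only guards −∞) and standardized per column
after combining all conditions into one matrix; missing entries are
mean-imputed (0 on the standardized scale) with the mask recorded.

The matrix is embedded with UMAP at every grid point of
n_neighbors ∈ {4,8,16,32} × n_components ∈ {2,…,10} (36 runs), min_dist = 0
and n_epochs = 2000 held fixed, each run seeded deterministically from the
master seed, and each embedding is clustered with HDBSCAN at minPts = 10
(min cluster size and core-distance k both set to minPts, matching the
common R implementation's contract). A fixed 2D embedding (n_neighbors = 4)
is produced for display. Because manual consolidation of per-run labels is
not reproducible, the package mechanizes it: the co-clustering frequency of
each residue pair over all runs (noise points never co-cluster) defines a
dissimilarity 1 − C, average-linkage hierarchical clustering is cut at the
requested k (default 6), and stability is the mean within-cluster
co-clustering frequency.

## Side-chain orientation

For membrane-span residues (membrane assignment and solvent-accessible
surface area are inputs, not computed), charge sensitivity is the
standardized negative mean activity of H,K,R,D,E substitutions per
condition; hydrophobic sensitivity the same over I,L,V,M. Standardization is
within condition over scored residues; a zero-spread condition yields all-
zero z-scores. Residues with z_chg > 0 split into charge_only (z_hyd ≤ 0,
lipid-facing) and globally_intolerant (z_hyd > 0, core-facing); all others
are "other". Group comparisons use the two-sided Mann–Whitney U test — exact
when both groups have ≤ 8 observations and no ties, otherwise the normal
approximation with tie and continuity correction.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, with
defaults chosen as the study conditions:

| parameter | default | meaning |
|---|---|---|
| barcodes_per_variant | 10 | Poisson mean (median 10) |
| deletion_rate | 0.10 | oligos carrying a 1-nt deletion that reach the library |
| chimera_rate | 0.02 | cross-segment barcode contamination |
| collision_rate | 0.02 | within-segment two-variant barcodes |
| synonymous_rate | 0.02 | wild-type-protein control barcodes |
| seq_error_rate | 0.001 /base | read substitution errors |
| depth | 2×10⁶ | reads per count-table column |
| nb_dispersion | 0.1 | negative binomial: var = m + αm² |
| abundance_sigma | 0.5 | lognormal SD of cell abundance |
| hill_ec50 / slope | 150 nM / 1 | dose–response midpoint and shape |
| basal / span | 0.05 / 1.0 | reporter induction floor and range |
| frameshift_floor | 0.15 | frameshift activity, × WT span |
| doses | 0 / 150 / 625 / 5000 nM | vehicle, EC50, EC100, Emax |

Synthesis deletions are far more common on microarray-derived oligos than
0.10 (roughly half of oligos carry one), but the fraction surviving cloning
and selection into the assayed library is not knowable a priori; 0.10 is
used as the default study condition and is configurable. True variant
activities are drawn from a mixture (60 % wild-type-like N(1, 0.15²), 30 %
loss-of-function U(0.05, 0.7), 10 % gain U(1.2, 2.0)). Reporter induction is
f(a, d) = basal + span·a·dʰ/(EC50ʰ+dʰ), so vehicle carries no variant signal
and saturating agonist reads activity out nearly linearly; counts are
gamma-Poisson (negative binomial) around depth-scaled abundance × induction,
independent across the two replicates.

The generator does **not** simulate: PCR chimeras below the barcode level,
quality-score structure, UMI-style error networks, barcode-level reporter
position effects, saturated high-abundance barcodes (the motivation for the
upper RPM cut), or dose-dependent cell loss. Passing recovery tests
therefore demonstrate correctness of the estimator under the stated noise
model, not robustness to every artifact of a real screen.

## Problem sizes and numerical choices

The study-scale recovery runs 53 residues × 19 = 1,007 variants × ~10
barcodes at 2×10⁶ reads per column — the per-barcode depth regime of the
full-size screen at a size convenient for routine re-runs. Mapping-stage
checks use 24-residue designs (456 variants). The clustering acceptance runs
the full 36-run sweep on a 412-row planted matrix. Degenerate cases are
defined explicitly: zero-spread standardization yields zeros; consensus ties
yield `N`; k = 1 consensus clustering yields one cluster with stability 1;
empty clusters are omitted with a warning; zero-depth count columns and
missing forskolin replicates are hard errors.

## Known limitations

* Consensus calling ignores base qualities.
* The collision filter compares against the modal sequence only, as the
  rule defines; three-way collisions with no modal majority can evade it.
* Activity variance is estimated per variant without shrinkage; variants
  with one barcode report no SD.
* Consensus clustering replaces a manual assignment step; the number of
  clusters is user-chosen, not inferred.
* Conservation rescaling is min–max over scored columns, so scores are
  comparable within one alignment, not across alignments.
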