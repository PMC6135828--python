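# Methods

This note documents the quantitative model behind `apmsnet`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate about real data.

## Distributed spectral counting

Spectral counts (SpC) — the number of MS/MS spectra matched to a protein's
peptides in one run — are a label-free proxy for protein amount. Peptides
shared between paralogs cannot be attributed directly; `apmsnet` apportions
a shared peptide *j*'s count sSpC_j across its sharing set in proportion to
each protein's unique evidence:

    d_{k,j} = uSpC_k / Σ_{i ∈ share(j)} uSpC_i
    dSpC_k  = uSpC_k + Σ_j d_{k,j} · sSpC_j

The apportionment conserves counts exactly: Σ_k dSpC_k equals the run's
total spectral counts. A shared peptide whose entire sharing set has zero
unique evidence is split equally among the set; any other rule would either
discard counts or require information the run does not contain.

Length normalization yields the distributed spectral abundance factor and
its run- and bait-normalized forms:

    dSAF_k   = dSpC_k / L_k
    dNSAF_k  = dSAF_k / Σ_j dSAF_j          (sums to 1 per run)
    dBNSAF_k = dSAF_k / dSAF_bait           (bait ratio, per replicate)

L_k is the residue count of the full database entry; if the tagged construct
is the entry, the tag is included — lengths must match the database used to
assign peptides. dBNSAF is computed per replicate so that run-to-run
variation in bait expression cancels; it is identical whether computed from
dSAF or dNSAF because the run-level normalizer divides out. Replicates are
aggregated as the mean and sample standard deviation (n−1; zero when a group
has a single run) with non-detections entered as 0, which keeps means
comparable across baits, and a detection fraction (runs with dSpC > 0).

Known limitation: unique-evidence weighting is exact only when each sharing
protein's unique-peptide fraction reflects its contribution to the shared
peptides. For families whose members have different peptide inventories
(e.g. a 3-member family with 24/23/20 nominal peptides), the member with the
smallest inventory receives a systematically low share — about −3.5% in the
simulator's MTA-like family. This is inherent to the distribution rule, not
an implementation artifact; it is why the recovery check below tolerates 5%
rather than pure counting noise.

## Enrichment versus tag-only controls

A prey is called significant for a bait when all three filters hold, with
strict inequalities:

* log2FC > 2, where log2FC = log2((m_bait + ε)/(m_ctrl + ε)); per-run dSpC
  are rescaled to the mean run total of the compared runs before averaging,
  so means stay on the count scale, and ε = 0.5 counts is a half-count
  continuity correction. The rescaling reference is symmetric in the two
  arms, so swapping bait and control negates every log2FC exactly.
* FDR < 0.05, Benjamini–Hochberg step-up over the proteins tested for that
  bait. The p-value is a one-sided exact conditional binomial test on
  replicate-aggregated counts: given x_b + x_c total spectra for a protein,
  x_b ~ Binomial(x_b + x_c, N_b/(N_b + N_c)) under the null, with N the
  aggregate run totals; p = P(X ≥ x_b). The test is deterministic,
  assumption-light, and exactly checkable against an independent
  implementation. It does not model biological overdispersion across
  replicates, so its nominal calibration is demonstrated under the
  simulator's multinomial replicate model, not claimed for real data.
* detection in more than 50% of bait replicates (dSpC > 0).

## Differential network

Per condition (N- or C-terminal tag), preys significant for at least one of
the condition's baits form a consensus network; a prey's weight is the
arithmetic mean of the per-bait mean dBNSAF over the condition's baits
(non-significant baits contribute their measured value; min/max consensus
modes are provided). Preys absent from a condition carry weight 0 rather
than being dropped, so one-sided interactions still produce edges. The
differential network keeps preys with |w_C − w_N| ≥ 0.2 (inclusive — the
plain reading of a "minimum change"), labels the direction by the sign of
the change, and sets edge width to |Δ|. Node attributes give each prey's
dBNSAF shares across the four bait constructs (zero-sum rows are flagged
rather than normalized). How per-bait values are pooled into one
condition-level weight before differencing is a declared convention of this
package; the mean is symmetric and easy to test.

## Complex profiles and clustering

Mean dBNSAF values are scaled ×1000 for presentation (typical prey:bait
ratios are ≪ 1). Bait/protein profiles are clustered on the scaled values
with Euclidean dissimilarity and complete linkage — the distance is part of
the method; the linkage is a deterministic choice documented here. The
log2(value + 1) transform is applied only to the exported display matrix,
never to the clustering input; ε = 1 keeps undetected subunits (value 0) at
display value 0. The shipped complex table (CCT, prefoldin, Sin3, NuRD,
CoREST, MiDAC, with RBBP4/7 shared between Sin3 and NuRD) is hand-curated
annotation meant to be edited, not a computed artifact.

## Synthetic experiments

The simulator emulates a tag-position comparison: two bait paralogs
(HDAC1/HDAC2), each with an N- or C-terminal tag, 3 replicates per
construct, plus tag-only controls. Defaults, chosen once as a realistic
desk-scale configuration:

| parameter | default | meaning |
|---|---|---|
| total spectra per run (T) | 20,000 | fixed multinomial budget per run |
| replicates | 3 | per bait construct and for controls |
| bait abundance | 1.0 | reference unit; prey dBNSAF = capture efficiency |
| capture, favored condition | 0.2–0.6 | CCT/prefoldin under N; Sin3/NuRD/CoREST/MiDAC under C |
| capture, disfavored condition | 0.004 | trace carry-over |
| contaminants | 100, log-normal | median 3% of bait, ln-sd 1.0, identical in all runs |
| shared peptide fraction | 0.3 | within paralog families |

Counts are drawn multinomially over present proteins with weights a_k·L_k,
then over each protein's ⌈L/30⌉ nominal peptides. Peptides are identifiers,
not sequences: tryptic fragmentation, detectability bias and PSM-level FDR
are not simulated. Within a paralog family each member shares
round(0.3 × its peptide count) peptides as a nested prefix of a family pool,
so every member's unique fraction is ≈ 0.7 and the distribution weights are
proportional to true shared contributions up to rounding. Complex subunits
use the real proteins' residue counts (paralogs are homologs; their lengths
are similar, and that similarity matters for the distribution stage).
Ground-truth dBNSAF is a_prey/a_bait, since expected dSAF ∝ a.

Because replicates are independent multinomial draws, the simulator has no
between-replicate biological overdispersion; passing calibration tests show
the enrichment test's nominal behavior under its own assumptions, not
robustness to overdispersed real data. The generator also supports
calibration layouts: a contaminant-only null (bait abundance 0, so any
enrichment call on the background is a false positive) and planted preys
with a fixed bait:control fold change.

## Verification summary

The test suite and `scripts/acceptance.py` recompute, from scratch:

* the worked linker example, 27 residues × 3.8 Å/residue = 102.6 Å;
* exact count conservation and ΣdNSAF = 1 on 1000 random evidence tables
  (≤ 6 proteins, ≤ 10 peptides, counts ≤ 20);
* agreement of the vectorized distribution with a naive per-peptide loop to
  1e−12 on 1000 random instances;
* dSAF/dNSAF ratio invariance of dBNSAF to 1e−12 on a full simulated
  experiment;
* recovery of planted dBNSAF at T = 10⁶ (3 replicates): per-prey relative
  error < 5% for complex-subunit preys with truth ≥ 0.01, regression slope
  ≈ 1, R² > 0.95. Contaminants are excluded from the per-prey bound — their
  log-normal abundances straddle the 0.01 cut, where the bound would measure
  the random draw rather than the estimator;
* enrichment calibration over 20 seeds: false-positive rate on a 2000-protein
  null within binomial error of the nominal 5%, and ≥ 90% recall of 8-fold
  planted preys with expected bait counts ≥ 10;
* differential-edge recovery on noiseless weights (all |Δ| ≥ 0.3, none
  ≤ 0.1, boundary 0.2 included, directions consistent);
* the top-level split of bait profiles into the N-tag and C-tag pairs under
  default simulation conditions.

Problem sizes (1000 random instances, 20 calibration seeds, T = 10⁶ for
recovery, T = 5×10⁴ for calibration) are the package's chosen desk-scale
study conditions; the whole verification runs in about a minute.
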