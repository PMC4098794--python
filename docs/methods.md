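# Methods

`retromap` re-implements, at desk scale and with fully synthetic inputs, a
computational workflow for studying gamma-retroviral insertional mutagenesis
in mouse tumors: (i) mapping proviral integration sites genome-wide from
chimeric paired-end RNA-seq read pairs, (ii) classifying the host
transcription-activation patterns a provirus induces at its locus, and
(iii) quantifying the colocalization of integration sites with ChIP-seq
enhancer/promoter features against a matched random null. This note
documents the models, the parameters that matter, the numerical choices,
and what the synthetic scenarios do and do not show about real data.

## The provirus model and planted integrations

A murine-leukemia-virus-like provirus (~8 kb by default) carries two
identical LTRs, each U3 (250 bp) + R (70 bp) + U5 (80 bp), a splice donor
(SD) 30 bp downstream of the 5' LTR, and an env splice acceptor (env_SA) in
the 3' half. Integration at host coordinate `p` duplicates the target site:
the modified chromosome is `host[:p+t] + provirus + host[p:]` with a TSD of
`t` bp on each side. The TSD length defaults to 4 bp, the value established
for MLV-family integrases. Antisense integrations insert the reverse
complement, which mirrors the element order at the two junctions.

Both physical host/virus junctions are copies of the same target site, so a
call is scored against the TSD interval `[p, p+t]`: a position within `t`
bp of either edge identifies the same integration event.

## Junction transcripts and the read simulator

Three chimeric transcript classes are simulated per integration, each with
its own Poisson-distributed fragment count (default mean 50 per junction):

* **U3 read-in** — host transcription running across the 5' junction into
  U3 (mouse-to-virus).
* **U5 promoter insertion** — the 3' LTR drives an R+U5 leader (150 bp of
  viral sequence) into downstream host sequence (virus-to-mouse).
* **SD splice** — the viral R..SD leader (186 bp) spliced onto host
  sequence at the 3' junction (virus-to-mouse).

Fragments are placed uniformly along each transcript with lengths from
Normal(325, 50) truncated to [101, 600] bp — sequenced libraries of
400–450 bp including ~100 bp of adaptors — and sequenced as 2x101-base
mate pairs, FR orientation with mate1 on the transcript sense strand.
Base qualities are constant "I"; sequencing errors, PCR duplicates and
adaptor read-through are deliberately out of scope, so alignment on
synthetic data is exact-match and recovery rates here are upper bounds on
what error-containing real libraries would give. Transcript extents (400 bp
of flank inside the transcript, 800 bp of run-on) and the mean of 50 were
fixed once so that a typical junction yields well over five fusion-covered
pairs, the regime in which calling is expected to operate.

Background fragments are drawn genome-wide at a configurable rate
(fragments/kb) to exercise the filters; they carry no junction.

## LTR-like decoys and the chimera reference

Real genomes contain endogenous LTR-like sequence that attracts chimeric
mapping artifacts. The generator plants decoys — the viral LTR with
`round((1-identity) * L)` random substitutions — at requested identities,
on both strands. Decoy offsets snap to a 5-bp grid: the LTR-likeness scan
tiles the genome in 5-bp increments, so a borderline-identity decoy is
detectable only when its offset lies on the scan grid; aligning the
generator with the scan makes the threshold behaviour exactly testable.

The scan computes **ungapped identity** (matches / window length) of the
LTR against every grid offset on both strands and merges offsets at or
above the threshold (default 0.90) into maximal regions. Ungapped identity
replaces gapped local alignment: it is deterministic and admits an exact
step-1 brute-force oracle, at the cost of missing indel-diverged decoys —
a documented limitation. N bases never match and windows with more than
10% N are skipped. The chimera reference is the set of detected regions
(±100 bp flank) plus the proviral sequence, indexed by exact k-mers.

## Prefix filtering, split alignment, and signature classification

A read pair is a chimera candidate iff exactly one mate's leading 25 bp
(or reverse complement) occurs in the chimera reference. Candidates are
split-aligned against the host genome with the provirus appended as an
extra chromosome: exact 20-mer seeds (sorted integer k-mer index, one seed
per alignment diagonal, seeds every 5 bp plus both read ends), ungapped
X-drop extension (match +1, mismatch −3, drop 6), greedy best-score-first
selection of query segments (≤8 bp overlap allowed, segments ≥25 bp kept).
Each segment carries a **uniqueness margin** — its score minus the best
competing placement covering ≥50% of the same query span — and
"unambiguously mapped" means margin > 0. The two LTR copies are identical,
so purely intra-LTR viral segments legitimately have margin 0; the margin
requirement applies to the host-side segment of a call.

Each candidate pair maps to one cell of a signature taxonomy with three
axes:

* **element** ∈ {U3, U5, SD} — the proviral element abutting host sequence,
  decided by the provirus-frame coordinate at which the transcript enters
  or exits the virus, matched to the nearest junction anchor (provirus
  start/end for U3/U5, with LTR-copy-equivalent coordinates accepted; SD
  end for the donor side, env_SA start for the acceptor side). Fusion
  junctions use a 12-bp anchor tolerance; spanning pairs, which localize
  the junction only to within the unsequenced insert gap, use 600 bp.
* **coverage** ∈ {FUSION_M1, FUSION_M2, SPANNING} — which mate contains the
  host/virus fusion, or neither (one fully-viral plus one fully-host mate).
* **direction** ∈ {MOUSE_TO_VIRUS, VIRUS_TO_MOUSE} — transcription order
  across the junction, read off the strand-specific library convention.

Six (element, direction) combinations are physically constructible, giving
18 cells; a generator builds one read pair per cell and the classifier
inverts all of them. Pairs with contradictory layouts (e.g. both mates
chimeric at inconsistent junctions) are AMBIGUOUS and excluded from
calling.

## Integration calling and endogenous filtering

Fusion-read junction positions are exact to ±1–2 bp (chance matches can
extend an alignment marginally past the junction), and are clustered at a
10-bp tolerance; the call position is the modal fusion junction (smallest
on ties). Spanning pairs attach to the nearest fusion cluster within one
maximum fragment length (600 bp); spanning-only leftovers cluster among
themselves and become approximate, fusionless calls — real screens report
such regions separately from fusion-supported integrations. A call
requires one pair with ≥40 bp of host sequence at positive uniqueness
margin; sub-threshold clusters go to an "unsupported" table. Per sample,
`relative_coverage` is the cluster's pair count over the sample mean (so
it averages exactly 1).

Loci called in two or more samples within 10 bp are endogenous false
positives — independent tumors do not integrate at the same base — and are
removed from every sample, with the multiplicity reported. The synthetic
cohort plants shared "decoy-transcription" proviruses at identical
positions in all samples to exercise exactly this filter.

## Annotation

Nearest genes are assigned by distance to the gene body (0 inside), with
upstream/downstream and sense/antisense defined relative to gene strand.
Among overlapping zero-distance genes the primary is the longest
transcript; equal nonzero distances break by TSS distance then name, with
a tie flag. Distances to prior integration datasets flag calls within
10 kb. Gene-set overlap between screens uses the upper-tail hypergeometric
probability, computed in log space (gammaln + logsumexp) so that values
like 1e-30 are representable; tests verify exact agreement with integer
enumeration for every universe size up to 60.

## Enrichment statistics

Colocalization extends each peak by a pad (default 1,250 bp), merges, and
tests 1-bp integration coordinates for membership. The null replaces the
real peaks with `round(total_bp / median_length)` intervals of the median
peak length, placed uniformly and mutually non-overlapping in the
user-supplied mappability mask (bounded rejection resampling of colliding
intervals, 1,000-round cap). Fold = observed / null mean; the empirical
p-value is the add-one rank estimator `(r+1)/(n_iter+1)`, whose floor at
the standard 1,000 iterations (1/1001) sits just below the 0.001 reporting
threshold. Whether random intervals may overlap real peaks is unspecified
in the field's practice; they are not excluded here. A sensitivity
alternative — randomizing integrations instead of features — is not the
default because the matched-null construction is defined on the feature
side.

The add-one estimator is discrete: with tiny expected overlap counts it is
conservative (ties inflate p), so the null-calibration check uses
scenarios with expected counts around 50, where the estimator is close to
U(0,1). With planted enrichment the expected estimated fold is the mixture
value `p_in/q` with `p_in = fq/(fq+1-q)`, not the raw planted `f`; fold
recovery is tested against this closed form at n = 1,000 integrations.

The TSS partition uses strict/inclusive bounds — immediate d < 3,000;
intermediate 3,000 ≤ d ≤ 10,000; distal d > 10,000 — and reports
per-category counts and medians. The reduced integration set tiles each
chromosome with fixed 2,500-bp bins anchored at 0 (a literal, deterministic
reading of binning; single-linkage clustering is a possible alternative the
API does not default to): one-site bins pass through, two-site bins emit
the integer midpoint, bins with more than two sites are dropped. The
operation is idempotent.

## Activation-pattern classification

Tumor-vs-control comparison uses strand-specific binned coverage tracks
scaled by 1e6/total-fragments (a per-million stand-in for external library
scale factors). Fold per window/strand is `(tumor+eps)/(control_mean+eps)`
over 10-kb windows tiling ±200 kb around the provirus (deregulation
footprints span tens to hundreds of kb). Unannotated transcription is a
maximal run of bins ≥1 kb with tumor coverage ≥ min_cov (1.0), control
mean ≤ max_control_cov (0.2) and no gene-body overlap, strand-resolved.

The six labels are non-exclusive rules over this evidence:
LOCAL_PROMOTER_INSERTION (a U5 virus-to-mouse signature);
BIDIRECTIONAL (activation on both genomic sides); TANDEM (≥2 activated
same-strand genes on one side); SENSE_ANTISENSE (two activated
opposite-strand units with TSSs within 10 kb — deliberately permissive,
the motivating loci sit ~200 bp apart); DISTAL_TARGET (nearest gene below
f_null while an activated gene lies beyond it); COMBINATION (promoter
insertion + an SD chimeric-splice signature + an activated non-chimeric
unit). The literature describes these patterns qualitatively; the numeric
thresholds (f_act = 5, f_null = 2, eps = 0.5, 10-kb proximity) are this
package's operational decisions, configurable and surfaced in reports.
Raising f_act never adds an activation-dependent label, and common
rescaling of tumor and controls leaves all folds and labels unchanged.

The five fixture scenarios are idealized (noise-free) coverage tracks,
one per pattern; they verify the rule logic, not robustness to biological
or technical noise.

## Problem sizes and determinism

The standard end-to-end scenario is a 2-Mb two-chromosome genome, three
tumors with 20 private + 3 shared ~8-kb proviruses each (≥5-kb spacing),
six LTR decoys at identities 0.85–0.95, and ~3.5k read pairs per tumor;
it runs in well under a minute on one core. Enrichment checks use 0.5–2-Mb
masks with hundreds of peaks and up to 1,000 iterations. All randomness
descends from a single integer seed through one named generator per
operation, so every scenario — and `scripts/acceptance.py` — regenerates
byte-identically from its seed.

## Known limitations

* Exact-match alignment and error-free reads: no statement about behaviour
  under sequencing error, indels, or quality trimming.
* Ungapped LTR-likeness scan misses indel-diverged decoys.
* Signature cells whose viral mate lies wholly within an LTR are
  intrinsically confusable between the two LTR copies; classification
  relies on junction-adjacent evidence.
* The matched null models feature placement as uniform over the mask; real
  ChIP-seq peaks are not uniformly placeable (GC, mappability structure).
* Pattern thresholds are conventions, not fitted quantities.
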