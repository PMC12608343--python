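# Methods

## Scope and model

minisplice implements the dry-lab half of a minigene splicing-assay workflow.
The wet-lab half — cloning, transfection, RNA extraction, RT-PCR, capillary
electrophoresis — is out of scope; the package starts from an already-sized
peak table and a description of the construct, and ends at five-tier ACMG/AMP
classifications and cohort summaries. Likewise the in-silico predictors
(SpliceAI, SPiP, MMSplice, AlphaMissense) are never executed: their scores
are inputs, and the selection filter and census operate on whatever score
table the user supplies.

## Coordinates

All interfaces use HGVS conventions: 1-based, inclusive, with coding (c.)
positions numbered from the A of the start codon and intronic positions
expressed as signed offsets from the nearest exonic base. Internally the
transcript model keeps a spliced transcript coordinate alongside genomic
spans; minus-strand genes are normalized to transcript orientation at load
time so every downstream computation is strand-agnostic. Only
single-nucleotide substitutions are parsed; deletions, duplications and
delins raise an unsupported-variant error, since the assay workflow this
package serves operates on SNVs.

Intronic positions map back from genomic coordinates using the proximal-half
rule: the half of the intron nearer the upstream exon (including the centre
base) takes a positive offset from that exon's last base, the distal half a
negative offset from the downstream exon's first base.

Region labels partition every position into exonic, exonic-splice-region,
splice-site-intronic and deep-intronic. The splice-region windows default to
the VEP convention — 3 exonic and 8 intronic bases from each junction — and
are configurable, because no single published boundary exists for "deep
intronic"; any census over region labels is therefore explicitly
window-dependent.

## Splice-site coordinate convention

A pseudoexon is specified by its cryptic acceptor and donor coordinates. The
convention is fixed so that the coordinates name the splice *sites*, not the
included bases: the acceptor coordinate is the last intronic base of the 3′
AG, the donor coordinate the first intronic base of the 5′ GT, and the
included segment is everything strictly between them. Under this convention
an acceptor at c.X−263 with a donor at c.X−168 yields |−263| − |−168| − 1 =
94 nt. This is the only convention under which those printed site
coordinates and the printed 94-nt product length are simultaneously
consistent, which is why it is hard-coded rather than configurable.

A 94-nt insertion after c.1006 changes the coding length by 94 ≡ 1 (mod 3),
hence a frameshift with affected codon ceil(1007/3) = 336; the first in-frame
stop downstream of the affected codon is reported as the PTC. Protein
notation is emitted in the reduced form `p.(Xxx336YyyfsTerN)` and only when
sequence is available; the full HGVS protein grammar is not implemented.

## Fragment lengths and peak assignment

Expected amplicon lengths are additive: vector flank lengths plus included
exonic length, shifted by each event's delta. Observed peaks are matched to
candidate events within a tolerance of ±2 nt, reflecting typical capillary
sizing jitter against an internal standard; a length matching zero or more
than one candidate is kept but labelled `unassigned` (ties carry a diagnostic
naming the colliding candidates). Fragments longer than 500 nt — the ceiling
of the common 500-size standard — are flagged unquantifiable: such isoforms
(e.g. full intron retention) are real but invisible to capillary sizing, and
the simulator reproduces exactly this censoring.

## PSI estimation

The point estimate is the pooled formula: an isoform's summed peak height
across replicates over the summed height of all detected isoforms across
replicates, × 100. Peak *height* (not area) is the abundance measure.
Multiple peaks assigned to one isoform within a replicate are summed first.
Replicate dispersion is the population standard deviation (divisor *n*) of
the per-replicate PSIs — with two replicates this equals half the absolute
difference. Unassigned peaks are excluded from the denominator by default
(the denominator is defined over *detected isoforms*), with a switch to
include them; every exclusion is logged. Reported PSIs and deltas are
rounded to one decimal at the interface; internal values are unrounded.

When replicate total heights are equal, the pooled estimate coincides with
the mean of per-replicate PSIs; with unequal totals it is the
height-weighted version. δPSI is undefined at wild-type PSI 0 and is flagged
rather than returned as infinity.

## Functional criteria and evidence combination

PS3 is assigned at ΔPSI ≤ −54 percentage points of full-length inclusion.
The −54 cutoff is the calibration point of the assay: an intronic variant
from a molecularly confirmed patient — which can have no mechanism other
than splicing — showed a ~54% reduction, so reductions at least that large
are treated as disease-causing. BS3 is assigned to intronic and synonymous
variants at ΔPSI ≥ −10 points; missense and nonsense variants never receive
BS3, because an intact splicing pattern cannot exonerate a protein-level
effect. A wild-type baseline gate applies first: if the wild-type construct
includes the full-length isoform below 70% and the variant decreases it
further, no functional criterion is assigned (weakly recognized exons are
intrinsically noisy in the reporter), while increases remain interpretable.
An unknown baseline passes the gate; the packaged fixture stores baselines
only where published.

Evidence combination follows the standard five-tier combining rules.  Two
engine-level decisions were genuinely open and are resolved as follows:

* **PM2 conflict exemption.** A strict "any pathogenic code + any benign
  code → VUS" rule would misclassify rare-but-benign variants, where PM2
  (absent from population databases) routinely co-occurs with benign
  supporting codes. PM2 is therefore excluded from the conflict test; any
  *other* pathogenic code co-occurring with benign codes yields VUS.
* **PP3 retention on reclassification.** When a missense/nonsense variant is
  reclassified on splicing evidence, the protein-impact codes PS1, PM1, PM5,
  PP2 and BP1 are stripped. PP3 is retained: for these variants it scores
  the splicing prediction, not amino-acid impact.

PP5/BP6 (reputable-source assertions) are honored as supporting evidence
despite their deprecation in some frameworks, because the evidence tables
this engine consumes use them. Strength modulation (e.g. PS3 at moderate) is
not modeled.

Cohort summaries report the before→after transition matrix as the primary
result; "upgraded"/"downgraded" counts under any naming convention derive
from it. "Not reclassified" (no functional criterion) is kept distinct from
"retained" (criterion added, class unchanged).

## Selection filter and census

The candidate filter passes a variant when gnomAD AF < 0.01 **and** at least
one predictor fires: SpliceAI DS MAX ≥ 0.2, or a SPiP interpretation
beginning with a whitelist entry ("Alter by SPiCE", "Alter BP", "Alter by
MES (Poly TC)" — prefix matching, since interpretations print as compound
labels), or |MMSplice Δ logit ψ| > 1. OR semantics are deliberate: a
branchpoint-only hit with a flat SpliceAI profile is still a candidate. All
firing criteria are returned for audit. Note the filter describes
*selectability*, not cohort membership — curated cohorts legitimately include
variants that fail every in-silico criterion.

Census shares over the DS MAX bands ([0.2, 0.5), [0.5, 0.8), [0.8, 1.0]) are
truncated — not rounded — to one decimal place; truncation is the convention
the reference bin counts reproduce (655/238/205 over 1098 → 59.6/21.6/18.6).

## Synthetic data

The simulator emulates the assay's design parameters: two biological
replicates, multiplicative log-normal peak-height noise, a 500-nt sizing
ceiling. Heights are `total_height × fraction × LogNormal(mean 1, CV)`;
multiplicative noise reflects positive, scale-dependent fluorescence
intensities, and the default CV of 0.1 brackets the replicate standard
deviations seen in practice (roughly ±0.5 to ±8 PSI points at two
replicates). Generated minigenes carry valid GT/AG dinucleotides at every
designed junction and optionally a planted cryptic acceptor/donor pair at
requested offsets. Score-table generation draws rows from controlled firing
categories with truth labels.

What the simulator does *not* reproduce — and hence what passing tests do
not show about real data: splice-site strength is not mechanistically linked
to isoform fractions (fractions are specified, not derived); there are no
heteroduplex or PCR-artifact peaks, no size-calling bias, and no
between-construct transfection-efficiency variation. Synthetic recovery
results therefore validate the estimator and decision arithmetic, not the
biology.

Problem sizes used by the test suite and calibration checks: 500 seeded
tables for the PSI normalization and calibration properties (mean absolute
error < 3 points at truth 80/20, CV 0.1, n = 2), 3 × 500 seeded end-to-end
runs for decision recovery (designed deltas placed ≥ 10 points from both
thresholds; recovery ≥ 99%), 100 random edits for the ORF oracle
comparison, and the full ≤ 6-code subset lattice of a 12-code alphabet
(2,510 sets) for the combining-rules oracle.

## Degenerate inputs and tie-breaks

Zero total peak height is an error (nothing was detected); an all-subthreshold
table yields an empty labelled table with a warning, not an error. Ambiguous
length matches are never silently resolved — they are flagged as ties.
Pseudoexon coordinates in different introns, or implying non-positive
length, are rejected. Intronic offsets must anchor on the correct exon
boundary and may not run past the flanking intron. The ACMG combiner rejects
unknown codes rather than ignoring them.

## Known limitations

* Only SNVs are parsed; protein-notation handling is limited to the
  synonymous/nonsense/missense triage and the reduced frameshift notation.
* The census region breakdown depends on the configured splice-region
  windows; published deep-intronic totals from other groups are not
  reproducible without knowing their windows.
* The baseline gate needs a wild-type PSI; where none is supplied the gate
  is assumed passed, which is permissive by construction.
* Evidence codes are inputs: the engine combines them but does not evaluate
  their underlying claims (phase for PM3, phenotype specificity for PP4, …).
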