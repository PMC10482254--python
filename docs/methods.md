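# Methods

## Scope and design

`cosegscan` implements the desk-scale analysis appropriate to a single
family segregating a rare, fully penetrant autosomal dominant trait:
qualitative cosegregation logic over marker genotypes, a multi-stage rare
variant filter over exome calls, and simple computable prioritization
signals. No LOD-score linkage, phasing, CNV calling or annotation
computation is attempted; variants arrive already called and annotated
(consequence class, per-database AC/AN, damage predictions) in a VCF
dialect with two extra FORMAT fields (`SS` read-seed support, `CL` clonal
reads) that standard callers do not emit and the simulator therefore
generates.

Complete penetrance (carrier ⇔ affected) is assumed throughout.
Individuals of unknown affection are excluded from both the affected and
unaffected filter sets: an unphenotyped member constrains nothing, and
treating them as unaffected would discard true candidates. Inheritance is
autosomal only.

## Coordinates and the length convention

All internal coordinates are 1-based inclusive. Interval length is defined
as `end − start`, **not** `end − start + 1`, because that is the arithmetic
that reproduces every printed Length in the packaged linked-region table;
the more common convention would be off by one on all 19 rows. BED export
converts to 0-based half-open.

The packaged region table is transcribed verbatim. For variant filtering,
`load_linked_regions()` extends one terminal-band region (8q24) to the
chromosome 8 terminus: the printed boundaries are inner boundaries (the
outermost compatible markers), and the packaged candidate table itself
contains a retained variant distal to the printed 8q24 end, so membership
testing against the raw transcription would contradict the candidate set it
accompanies. This is the only edit, it is applied in code (the fixture file
is untouched), and both region loaders are public.

## Region scan

A marker is compatible when some allele is carried by every affected and
no unaffected sequenced member (unphased genotypes; no transmission
modeling). Missing genotypes follow `missing_policy`: `compatible`
(default — a missing genotype cannot disprove sharing) or `incompatible`.

Runs are grown greedily left to right; a run closes at its last compatible
marker once the enclosed incompatible-marker count would exceed
`max_errors_per_region` (default 0). Runs shorter than `min_markers`
(default 3) compatible markers are dropped. Boundaries are `inner`
(outermost compatible markers, default) or `outer` (flanking incompatible
markers, clipped to the chromosome's outermost markers). Greedy growth is
deterministic on sorted input and makes reported regions monotone
non-shrinking in the error tolerance (property-tested).

Defaults here are package choices, not published facts: the original
mapping tool's internals and tolerances are undocumented, so the scan
implements the stated set-logic principle only, and the packaged region
table is treated as a fixture rather than a reproduction target.

## Filter cascade

Stage order: carrier-call QC → consequence class + in-house rarity →
absent-in-unaffected → present-in-affected (heterozygous) → population
frequency → linked region → optional confirmation gate. Numeric defaults
(`CascadeConfig`): seed support ≥ 2, depth ≥ 10, alt fraction within
[0.15, 0.80] inclusive at both ends, ≤ 5 clonal reads, indels ≤ 7 nt,
allele frequency strictly < 0.002 per database with data, in-house count
≤ 2.

Interpretation choices:

- **QC applies to carrier calls only.** A homozygous-reference call is
  absence evidence, not a variant call, and is not held to the 15% alt
  fraction floor (which it could never meet).
- **Clonal reads** cap the counted depth: duplicates beyond the cap are
  excluded from the allele-fraction denominator, and a call with more than
  the cap fails QC outright.
- **Rarity is retain-if-rare**: a variant is kept only when its AF is
  strictly below threshold in *every* database that reports it. A database
  with no entry is "no evidence", distinct from AC = 0, and passes under
  the default `missing_freq_policy="pass"`.
- **Absent means no copy** of the alt allele (hom-ref), and **present
  means heterozygous**: a homozygous-alt affected member fails, consistent
  with the dominant single-copy model that the 80% alt-fraction ceiling
  encodes.
- **Missing calls** follow `missing_call_policy`: `fail_variant` (default)
  fails the variant at the cosegregation stage that needed the call;
  `ignore_sample` drops that member from the check.
- Multi-allelic sites are decomposed before filtering; each alt allele is
  filtered independently. The trace stops at a variant's first failing
  stage, which makes per-stage survivor counts non-increasing by
  construction.

The helper `max_allele_count_below(an, threshold)` gives the largest
admissible allele count under the strict threshold (25 at AN = 13,000 and
0.002 — the boundary count 26 equals the threshold exactly and is
excluded).

## Simulator

The generator emulates the study design the analysis assumes: a
three-generation, six-member template (3 affected / 3 unaffected sequenced),
three chromosomes at 1 cM/Mb with 50 markers each, 120 background exome
variants, Poisson(40) depth, Binomial(depth, 0.5) heterozygous alt reads
with a 0.001 error rate, Binomial(alt, 0.5) seed support, Binomial(depth,
0.02) clonal reads, and no genotype dropout unless configured. One integer
seed drives five independent substreams (markers, founders, meiosis,
variants, read noise), so identical (config, seed) gives byte-identical
outputs.

Meiosis follows Haldane (Poisson crossover count, uniform placement, no
interference). Transmission of the implanted causal allele is conditioned
on the template affection pattern by flipping the gamete's haplotype
labels when needed — valid because the two parental haplotypes are
exchangeable under Haldane — so carrier status equals affection status in
every run. Templates with an affected member who has no affected parent
(de novo) or two carrier parents are rejected.

Markers default to the fully informative idealization (each founder
haplotype carries its own allele), standing in for the haplotype
information a dense phased SNP array provides; `biallelic` mode with a
configurable MAF range is available. The causal position itself is always
genotyped as a marker whose variant allele is private to the family. These
two choices make causal-locus recovery a construction property: the causal
marker is compatible in every error-free run, so a scan with
`min_markers=1` always covers the locus, and the recovery tests use
exactly that setting because the single-marker guarantee is what the
construction provides. Background exome variants transmit Mendelianly but
independently per site (no linkage to the marker map), and their
configured allele frequencies are reused as the database AC/AN annotations
(AN fixed at 280,000) so rarity filtering is testable against simulation
truth.

What the simulator does **not** model: read-level data, haplotype-structured
sequencing error, interference, CNVs, population structure, incomplete
penetrance or phenocopies. Passing recovery tests therefore demonstrates
the pipeline's logic, not its performance on real exomes.

The decoy builder emits variants that violate exactly one cascade stage
each (low depth, out-of-band fraction, thin seed support, clonal excess,
disallowed class, long indel, in-house excess, carrier unaffected, missing
or non-heterozygous affected, common allele, exact-threshold allele,
off-region position) and pass all others, giving the cascade a
full-coverage negative control.

## Prioritization

`damage_tier` reduces two prediction tools to a four-way concordance:
`concordant_damaging` (PolyPhen not benign ∧ SIFT deleterious),
`concordant_benign` (benign ∧ tolerated), `undefined` (either class
missing, e.g. splice-site variants), else `discordant`. Conservation
labels are carried through verbatim, never recomputed, and no
literature-based grouping is attempted — only computable signals enter the
report.

`developmental_window_flag` formalizes "elevated expression during a
developmental window" as a z-contrast: log2(x + 1) per gene, z-scored
across samples, flag iff mean z inside the age window minus outside
exceeds a threshold. Defaults — window 0.1–2.4 years, threshold 1.0 z —
are package choices; the permutation test in the suite shows the default
threshold holds the false-flag rate of an age-shuffled null well under 5%
at the 39-sample design the default is sized for. Zero-variance genes are
never flagged. The criterion being one formalization of a qualitative
idea, the report carries it as a boolean with its contrast value, not as a
significance claim.

## Pipeline and reproducibility

`run_pipeline` executes acquire (simulate or load) → scan (or load
regions) → filter → report, writing `regions.bed`, `survivors.vcf`,
`trace.tsv`, `report.tsv` and `manifest.json`. The manifest snapshots the
config, seed and input SHA-256 digests; reruns from the same manifest are
byte-identical on `trace.tsv` and `report.tsv` (timings are recorded but
excluded from that contract). Missing inputs fail before any stage runs.

## Problem sizes

The packaged fixture analysis (31 variants, 19 regions, 6 members) runs in
milliseconds. The validation suite uses 2-chromosome, 15-marker,
20-variant simulations for its 100-seed recovery sweeps, 200–1000 random
instances for the brute-force oracle comparisons, 10⁴ gametes for
crossover calibration, and ~5000 founders for allele-frequency recovery —
sizes chosen so the full suite completes in about a minute while keeping
every statistical check at meaningful power.

## Known limitations

- Marker-level set logic is weaker than haplotype-based mapping on sparse
  biallelic data; real arrays need the informativeness that phasing
  provides (which is why the simulator's default is fully informative).
- The scan's error tolerance merges runs greedily; a different tie-break
  could report different (equally valid) maximal runs.
- `dominant_consistency` enumerates carrier assignments exhaustively over
  unknown-affection members, which is exponential in their number — fine
  for family-scale pedigrees, unsuitable for population pedigrees.
- The confirmation stage is a supplied boolean gate, not an assay model.
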