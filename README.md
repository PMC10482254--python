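# cosegscan

Candidate-gene discovery for a single family segregating a fully penetrant
autosomal dominant trait: a cosegregation **region scan** over marker
genotypes, followed by a multi-stage **exome variant filter cascade** with a
complete audit trail, plus candidate **prioritization** (damage-prediction
concordance, developmental expression windows) and a seeded **synthetic
family simulator** for validation.

The package is aimed at the classic single-family design — a handful of
affected and unaffected relatives, no replication cohort — where the
analysis is qualitative set logic rather than likelihood-based linkage.

## The model

Let `A` be the affected and `U` the unaffected sequenced members of a
pedigree, under complete penetrance (carrier ⇔ affected).

**Region scan.** A marker with genotypes `g(s)` is *compatible* with
dominant cosegregation iff

```
∃ allele a :  (∀ s ∈ A: a ∈ g(s))  ∧  (∀ s ∈ U: a ∉ g(s))
```

Maximal runs of consecutive compatible markers on a chromosome are reported
as linked regions (configurable error tolerance, minimum run length, and
inner/outer boundary convention). Region length is defined as `end − start`
on 1-based inclusive coordinates, matching the published region tables this
package round-trips.

**Filter cascade.** Each variant (decomposed to one ALT allele per record)
passes, in order: (1) carrier-call QC — ≥ 2 read seeds, ≥ 10 reads, alt
fraction in [15%, 80%] on a clonal-capped depth, ≤ 5 clonal reads;
(2) consequence class (nonsense, frameshifting indel ≤ 7 nt, missense,
splice site) and ≤ 2 in-house observations; (3) alt allele absent from every
unaffected member; (4) heterozygous in every affected member; (5) allele
frequency strictly < 0.002 in every population database reporting the
variant (AC/AN semantics); (6) position inside a linked region. A
`FilterTrace` records the pass/fail reason per variant per stage, so the
survivor funnel is fully auditable.

**Simulator.** Founder haplotypes recombine under the Haldane model
(crossovers ~ Poisson(map length in Morgans), uniform placement); a causal
allele implanted heterozygously in an affected founder is transmitted so
that carrier status equals affection status. Read depths, alt fractions,
seed support and clonal counts are drawn from configurable noise models, so
causal-variant recovery through the full scan + cascade is a testable
construction property.

## Worked example

```python
from cosegscan import (load_candidate_vcf, load_family_pedigree,
                       load_linked_regions, make_decoy_set, run_cascade)

pedigree  = load_family_pedigree()      # 3 affected + 3 unaffected members
candidates = load_candidate_vcf()       # 11 packaged candidate variants
regions    = load_linked_regions()      # 19 linked regions
decoys     = make_decoy_set(candidates, pedigree, regions, n_decoys=20)

survivors, trace = run_cascade(candidates + decoys, pedigree, regions)
for stage, count in trace.survivors_per_stage().items():
    print(f"after {stage:<22}: {count}")
print(len(survivors), "survivors")
```

prints

```
after qc                    : 21
after variant_class         : 18
after absent_in_unaffected  : 17
after present_in_affected   : 14
after population_frequency  : 12
after linked_region         : 11
11 survivors
```

Each of the 20 decoys violates exactly one stage and is removed there; the
11 genuine candidates — heterozygous in all affected members, absent in all
unaffected, rare in the population and inside linked regions — survive every
stage. The `examples/` directory has one short script per capability
(simulation, scanning, filtering, prioritization, full pipeline), and the
`cosegscan` command exposes the same steps as `simulate`, `scan`, `filter`,
`report`, `run` and `config init` subcommands.

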