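"""Simulate a three-generation family segregating a dominant trait.

Generates marker genotypes with Haldane recombination and an exome-like
variant table with an implanted heterozygous causal variant, then prints
where the causal allele was placed and who carries it.
"""

from cosegscan import SimulationConfig, simulate_family

result = simulate_family(SimulationConfig(), seed=17)

print(f"markers simulated : {len(result.matrix.markers)}")
print(f"exome variants    : {len(result.variants)}")
print(f"causal variant    : {result.truth.causal_chrom}:{result.truth.causal_pos}")
print(f"carriers          : {', '.join(result.truth.carriers)}")

causal = next(r for r in result.variants if r.key == result.truth.causal_key)
for sample, call in sorted(causal.calls.items()):
    gt = "./." if call.alleles is None else f"{call.alleles[0]}/{call.alleles[1]}"
    print(f"  {sample}: GT={gt} depth={call.depth} alt={call.alt_reads}")

# The carriers are exactly the affected members (complete penetrance); their
# 0/1 genotypes with ~50% alt reads are what the filter cascade expects of a
# dominant heterozygous variant.
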