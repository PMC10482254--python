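"""Independent brute-force oracles shared by the property tests.

These re-derive results from first principles (allele loops, direct run
enumeration), independently of the scanning code paths they check.
"""

import numpy as np

from cosegscan.linkage import Marker, MarkerGenotypeMatrix, marker_compatible
from cosegscan.model import GenomicInterval
from cosegscan.pedigree import Individual, Pedigree


def flat_family(n_affected=3, n_unaffected=3):
    return Pedigree(
        [
            Individual(f"A{i}", None, None, "unknown", "affected")
            for i in range(n_affected)
        ]
        + [
            Individual(f"U{i}", None, None, "unknown", "unaffected")
            for i in range(n_unaffected)
        ]
    )


def brute_compatible(genotypes, affected, unaffected):
    """Loop over every allele present at the marker (no missing calls)."""
    alleles = {a for gt in genotypes.values() for a in gt}
    return any(
        all(allele in genotypes[s] for s in affected)
        and all(allele not in genotypes[s] for s in unaffected)
        for allele in alleles
    )


def random_marker_matrix(rng, ped, n_chrom=3, n_markers=50):
    samples = ped.affected_sequenced + ped.unaffected_sequenced
    alleles = ["A", "B", "C", "D"]
    markers, genotypes = [], []
    for c in range(n_chrom):
        positions = np.sort(
            rng.choice(np.arange(1, 10**7), size=n_markers, replace=False)
        )
        for pos in positions:
            markers.append(Marker(str(c + 1), int(pos)))
            k = int(rng.integers(2, 5))
            genotypes.append(
                {
                    s: (alleles[rng.integers(k)], alleles[rng.integers(k)])
                    for s in samples
                }
            )
    return MarkerGenotypeMatrix(markers, genotypes)


def brute_runs(matrix, ped):
    """Maximal all-compatible marker runs, enumerated directly."""
    by_chrom = {}
    for marker, genotypes in zip(matrix.markers, matrix.genotypes):
        by_chrom.setdefault(marker.chrom, []).append(
            (marker.pos, marker_compatible(genotypes, ped))
        )
    regions = []
    for chrom, rows in by_chrom.items():
        i = 0
        while i < len(rows):
            if rows[i][1]:
                j = i
                while j + 1 < len(rows) and rows[j + 1][1]:
                    j += 1
                regions.append(GenomicInterval(chrom, rows[i][0], rows[j][0]))
                i = j + 1
            else:
                i += 1
    return sorted(regions, key=lambda iv: (iv.chrom, iv.start))
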