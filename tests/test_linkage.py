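"""Region scan: marker compatibility and run enumeration vs brute force."""

import numpy as np
import pytest

import cosegscan as cs
from cosegscan.linkage import (
    Marker,
    MarkerGenotypeMatrix,
    ScanParams,
    evaluate_scan,
    marker_compatible,
    scan_regions,
)
from cosegscan.model import DataError, GenomicInterval
from cosegscan.pedigree import Individual, Pedigree


def flat_pedigree(n_affected=3, n_unaffected=3):
    inds = [
        Individual(f"A{i}", None, None, "unknown", "affected")
        for i in range(n_affected)
    ] + [
        Individual(f"U{i}", None, None, "unknown", "unaffected")
        for i in range(n_unaffected)
    ]
    return Pedigree(inds)


def brute_force_compatible(genotypes, affected, unaffected):
    """Loop over every allele present at the marker."""
    alleles = {
        a
        for s in list(affected) + list(unaffected)
        if genotypes.get(s) is not None
        for a in genotypes[s]
    }
    for allele in alleles:
        in_all_affected = all(
            genotypes.get(s) is None or allele in genotypes[s] for s in affected
        )
        in_no_unaffected = all(
            genotypes.get(s) is None or allele not in genotypes[s]
            for s in unaffected
        )
        if in_all_affected and in_no_unaffected:
            # compatible-policy nuance: affected with missing genotype may
            # carry anything, so only non-missing affected constrain
            if all(
                genotypes.get(s) is None or allele in genotypes[s]
                for s in affected
            ):
                return True
    # vacuous case: all affected missing
    if all(genotypes.get(s) is None for s in affected):
        return True
    return False


def brute_force_runs(flags, positions, chrom):
    """Maximal all-compatible runs (zero tolerated errors, min 1 marker)."""
    runs, i = [], 0
    while i < len(flags):
        if flags[i]:
            j = i
            while j + 1 < len(flags) and flags[j + 1]:
                j += 1
            runs.append(GenomicInterval(chrom, positions[i], positions[j]))
            i = j + 1
        else:
            i += 1
    return runs


class TestMarkerCompatible:
    def test_shared_allele_absent_from_unaffected(self):
        ped = flat_pedigree()
        genotypes = {
            "A0": ("A", "B"), "A1": ("A", "B"), "A2": ("A", "B"),
            "U0": ("B", "B"), "U1": ("B", "B"), "U2": ("B", "B"),
        }
        assert marker_compatible(genotypes, ped)

    def test_shared_allele_present_in_unaffected(self):
        ped = flat_pedigree()
        genotypes = {
            "A0": ("A", "B"), "A1": ("B", "B"), "A2": ("A", "B"),
            "U0": ("B", "B"), "U1": ("B", "B"), "U2": ("B", "B"),
        }
        assert not marker_compatible(genotypes, ped)

    def test_no_affected_is_an_error(self):
        ped = Pedigree([Individual("U", None, None, "unknown", "unaffected")])
        with pytest.raises(DataError):
            marker_compatible({"U": ("A", "A")}, ped)

    def test_missing_policies_differ(self):
        ped = flat_pedigree(1, 1)
        genotypes = {"A0": None, "U0": ("A", "A")}
        assert marker_compatible(genotypes, ped, "compatible")
        assert not marker_compatible(genotypes, ped, "incompatible")

    def test_matches_brute_force_on_random_markers(self):
        """1000 random markers with up to 4 alleles, 3 affected + 3
        unaffected, some genotypes missing."""
        rng = np.random.default_rng(11)
        ped = flat_pedigree()
        affected, unaffected = ped.affected_sequenced, ped.unaffected_sequenced
        alleles = ["A", "B", "C", "D"]
        for _ in range(1000):
            k = int(rng.integers(1, 5))
            genotypes = {}
            for s in affected + unaffected:
                if rng.random() < 0.1:
                    genotypes[s] = None
                else:
                    genotypes[s] = (
                        alleles[rng.integers(k)], alleles[rng.integers(k)]
                    )
            assert marker_compatible(genotypes, ped, "compatible") == \
                brute_force_compatible(genotypes, affected, unaffected)


def random_matrix(rng, ped, n_chrom=3, n_markers=50):
    markers, genotypes = [], []
    samples = ped.affected_sequenced + ped.unaffected_sequenced
    alleles = ["A", "B", "C", "D"]
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


class TestScanRegions:
    def test_fully_compatible_chromosome_is_one_region(self):
        ped = flat_pedigree(1, 1)
        markers = [Marker("1", p) for p in (10, 20, 30)]
        genotypes = [{"A0": ("A", "B"), "U0": ("B", "B")}] * 3
        matrix = MarkerGenotypeMatrix(markers, genotypes)
        (region,) = scan_regions(matrix, ped, ScanParams(min_markers=1))
        assert (region.start, region.end) == (10, 30)

    def test_no_compatible_markers_yields_nothing(self):
        ped = flat_pedigree(1, 1)
        markers = [Marker("1", p) for p in (10, 20)]
        genotypes = [{"A0": ("B", "B"), "U0": ("B", "B")}] * 2
        matrix = MarkerGenotypeMatrix(markers, genotypes)
        assert scan_regions(matrix, ped, ScanParams(min_markers=1)) == []

    def test_unsorted_matrix_rejected(self):
        ped = flat_pedigree(1, 1)
        markers = [Marker("1", 20), Marker("1", 10)]
        genotypes = [{"A0": ("A", "B"), "U0": ("B", "B")}] * 2
        with pytest.raises(DataError):
            scan_regions(MarkerGenotypeMatrix(markers, genotypes), ped)

    def test_outer_boundaries_reach_flanking_markers(self):
        ped = flat_pedigree(1, 1)
        compat = {"A0": ("A", "B"), "U0": ("B", "B")}
        incompat = {"A0": ("B", "B"), "U0": ("B", "B")}
        markers = [Marker("1", p) for p in (10, 20, 30, 40, 50)]
        matrix = MarkerGenotypeMatrix(
            markers, [incompat, compat, compat, compat, incompat]
        )
        (inner,) = scan_regions(matrix, ped, ScanParams(min_markers=1))
        (outer,) = scan_regions(
            matrix, ped, ScanParams(min_markers=1, boundary_mode="outer")
        )
        assert (inner.start, inner.end) == (20, 40)
        assert (outer.start, outer.end) == (10, 50)

    def test_matches_brute_force_runs_on_random_matrices(self):
        """200 random 3x50 matrices, zero error tolerance, min 1 marker."""
        rng = np.random.default_rng(5)
        ped = flat_pedigree()
        params = ScanParams(max_errors_per_region=0, min_markers=1)
        for _ in range(200):
            matrix = random_matrix(rng, ped)
            got = scan_regions(matrix, ped, params)
            expected = []
            by_chrom = {}
            for m, g in zip(matrix.markers, matrix.genotypes):
                by_chrom.setdefault(m.chrom, []).append(
                    (m.pos, marker_compatible(g, ped))
                )
            for chrom, rows in sorted(by_chrom.items()):
                positions = [p for p, _ in rows]
                flags = [f for _, f in rows]
                expected.extend(brute_force_runs(flags, positions, chrom))
            assert got == sorted(expected, key=lambda iv: (iv.chrom, iv.start))

    def test_every_marker_inside_zero_error_regions_is_compatible(self):
        rng = np.random.default_rng(23)
        ped = flat_pedigree()
        params = ScanParams(max_errors_per_region=0, min_markers=1,
                            missing_policy="incompatible")
        matrix = random_matrix(rng, ped)
        regions = scan_regions(matrix, ped, params)
        for m, g in zip(matrix.markers, matrix.genotypes):
            if any(iv.contains(m.chrom, m.pos) for iv in regions):
                assert marker_compatible(g, ped, "incompatible")

    def test_regions_never_shrink_with_error_tolerance(self):
        rng = np.random.default_rng(42)
        ped = flat_pedigree()
        for _ in range(30):
            matrix = random_matrix(rng, ped, n_chrom=2, n_markers=40)
            for k in range(3):
                lo = scan_regions(matrix, ped, ScanParams(k, min_markers=1))
                hi = scan_regions(matrix, ped, ScanParams(k + 1, min_markers=1))
                for region in lo:
                    assert any(
                        h.chrom == region.chrom
                        and h.start <= region.start
                        and h.end >= region.end
                        for h in hi
                    ), (k, region)


class TestEvaluateScan:
    def test_locus_inside_region_is_covered(self):
        regions = [GenomicInterval("2", 100, 200)]
        result = evaluate_scan(regions, ("2", 150), genome_bp=1000)
        assert result.covered and result.genome_fraction_linked == 0.1

    def test_empty_region_list(self):
        result = evaluate_scan([], ("1", 5), genome_bp=100)
        assert not result.covered and result.genome_fraction_linked == 0.0

    def test_causal_locus_always_recovered_without_noise(self, small_sim_config):
        """Error-free simulated families: the implanted locus is inside a
        reported region in every run, and the causal marker itself is
        compatible."""
        params = ScanParams(min_markers=1)
        for seed in range(100):
            result = cs.simulate_family(small_sim_config, seed=seed)
            truth = result.truth
            idx = next(
                i for i, m in enumerate(result.matrix.markers)
                if m.chrom == truth.causal_chrom and m.pos == truth.causal_pos
            )
            assert marker_compatible(result.matrix.genotypes[idx], result.pedigree)
            regions = scan_regions(result.matrix, result.pedigree, params)
            ev = evaluate_scan(
                regions, (truth.causal_chrom, truth.causal_pos), truth.genome_bp
            )
            assert ev.covered

    def test_more_unaffected_members_shrink_linked_fraction(self):
        """Monte-Carlo trend: 3 unaffected members exclude more of the
        genome than 1 (extra carriers of alternative haplotypes)."""
        def template(n_unaffected):
            inds = [
                Individual("I_1", None, None, "male", "affected"),
                Individual("I_2", None, None, "female", "unaffected"),
                Individual("II_1", "I_1", "I_2", "male", "affected"),
            ]
            for k in range(n_unaffected - 1):
                inds.append(
                    Individual(f"II_{k + 2}", "I_1", "I_2", "female", "unaffected")
                )
            return Pedigree(inds)

        config = cs.SimulationConfig(
            chromosomes=(cs.ChromosomeSpec("1", 50_000_000, 50.0),),
            markers_per_chrom=25,
            n_background_variants=0,
        )
        params = ScanParams(min_markers=1)

        def mean_fraction(n_unaffected):
            fractions = []
            for seed in range(40):
                result = cs.simulate_family(
                    config, seed=seed, pedigree=template(n_unaffected)
                )
                regions = scan_regions(result.matrix, result.pedigree, params)
                fractions.append(
                    evaluate_scan(
                        regions,
                        (result.truth.causal_chrom, result.truth.causal_pos),
                        result.truth.genome_bp,
                    ).genome_fraction_linked
                )
            return np.mean(fractions)

        assert mean_fraction(3) < mean_fraction(1)
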