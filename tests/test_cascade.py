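"""Filter cascade: per-stage predicates, full runs, and monotonicity."""

import dataclasses

import numpy as np
import pytest

import cosegscan as cs
from cosegscan.cascade import (
    CascadeConfig,
    consequence_pass,
    cosegregation_pass,
    max_allele_count_below,
    qc_pass,
    rarity_pass,
    region_pass,
    run_cascade,
)
from cosegscan.model import DataError, GenotypeCall, VariantRecord


def call(sample="A0", alleles=(0, 1), depth=20, alt=10, seeds=3, clonal=0):
    return GenotypeCall(sample, alleles, depth=depth, alt_reads=alt,
                        seed_support=seeds, clonal_reads=clonal)


def record(**kwargs):
    fields = dict(chrom="11", pos=50_000_000, ref="G", alt="A",
                  consequence="missense", popfreqs={"GNOMAD": (1, 280_000)},
                  inhouse_count=0)
    fields.update(kwargs)
    return VariantRecord(**fields)


class TestQc:
    @pytest.mark.parametrize(
        "kwargs, expected, reason",
        [
            (dict(depth=9, alt=5, seeds=3, clonal=0), False, "depth"),
            (dict(depth=20, alt=10, seeds=3, clonal=2), True, ""),
            (dict(depth=20, alt=2, seeds=2, clonal=0), False, "fraction"),
            (dict(depth=10, alt=9, seeds=3, clonal=0), False, "fraction"),
            (dict(depth=20, alt=3, seeds=3, clonal=0), True, ""),  # exactly 15%
            (dict(depth=20, alt=16, seeds=3, clonal=0), True, ""),  # exactly 80%
            (dict(depth=20, alt=10, seeds=1, clonal=0), False, "seed"),
            (dict(depth=20, alt=10, seeds=3, clonal=6), False, "clonal"),
        ],
    )
    def test_thresholds(self, kwargs, expected, reason):
        result = qc_pass(call(**kwargs))
        assert result.passed is expected
        assert reason in result.reason

    def test_zero_depth_with_alt_reads_is_a_data_error(self):
        bad = GenotypeCall("s", (0, 1))
        bad.depth, bad.alt_reads = 0, 3  # bypass constructor check
        with pytest.raises(DataError):
            qc_pass(bad)


class TestConsequence:
    @pytest.mark.parametrize(
        "consequence, indel_len, expected",
        [
            ("missense", 0, True),
            ("splice_site", 0, True),
            ("nonsense", 0, True),
            ("frameshift_indel", 7, True),
            ("frameshift_indel", 8, False),
            ("other", 0, False),
            (None, 0, False),
        ],
    )
    def test_class_selection(self, consequence, indel_len, expected):
        rec = record(consequence=consequence, indel_length=indel_len,
                     alt="G" + "A" * indel_len if indel_len else "A")
        assert consequence_pass(rec).passed is expected


class TestRarity:
    @pytest.mark.parametrize(
        "ac, an, expected",
        [
            (2, 282710, True),
            (513, 280690, True),      # ~0.00183, just under
            (600, 280000, False),     # ~0.00214
            (560, 280000, False),     # exactly 0.002: strict <
        ],
    )
    def test_frequency_threshold(self, ac, an, expected):
        rec = record(popfreqs={"GNOMAD": (ac, an)})
        assert rarity_pass(rec).passed is expected

    def test_inhouse_threshold(self):
        assert rarity_pass(record(inhouse_count=2)).passed
        assert not rarity_pass(record(inhouse_count=3)).passed

    def test_all_databases_must_be_rare(self):
        rec = record(popfreqs={"GNOMAD": (1, 280_000), "EVS": (100, 13_000)})
        assert not rarity_pass(rec).passed

    def test_missing_frequency_policy(self):
        rec = record(popfreqs={})
        assert rarity_pass(rec, CascadeConfig(missing_freq_policy="pass")).passed
        assert not rarity_pass(rec, CascadeConfig(missing_freq_policy="fail")).passed

    def test_an_zero_is_a_data_error(self):
        with pytest.raises(DataError):
            rarity_pass(record(popfreqs={"GNOMAD": (0, 0)}))


class TestCosegregation:
    def test_het_in_affected_absent_in_unaffected(self, family):
        rec = record(calls={
            s: call(s) for s in family.affected_sequenced
        } | {
            s: call(s, alleles=(0, 0), alt=0, seeds=0)
            for s in family.unaffected_sequenced
        })
        assert cosegregation_pass(rec, family).passed

    def test_incomplete_segregation_fails(self, family):
        calls = {s: call(s) for s in family.affected_sequenced}
        calls["III_1"] = call("III_1", alleles=(0, 0), alt=0, seeds=0)
        calls |= {
            s: call(s, alleles=(0, 0), alt=0, seeds=0)
            for s in family.unaffected_sequenced
        }
        assert not cosegregation_pass(record(calls=calls), family).passed

    def test_carrier_unaffected_fails(self, family):
        calls = {s: call(s) for s in family.affected_sequenced}
        calls |= {
            s: call(s, alleles=(0, 0), alt=0, seeds=0)
            for s in family.unaffected_sequenced
        }
        calls["II_2"] = call("II_2")  # het in an unaffected member
        assert not cosegregation_pass(record(calls=calls), family).passed


class TestRegionPass:
    def test_table1_chr2_membership(self, table1_regions):
        assert region_pass(record(chrom="2", pos=150_000_000), table1_regions)
        assert not region_pass(record(chrom="2", pos=146_360_625), table1_regions)

    def test_matches_brute_force_membership(self, table1_regions):
        rng = np.random.default_rng(3)
        chroms = sorted({iv.chrom for iv in table1_regions}) + ["X"]
        for _ in range(10_000):
            chrom = chroms[rng.integers(len(chroms))]
            pos = int(rng.integers(1, 250_000_000))
            rec = record(chrom=chrom, pos=pos)
            expected = False
            for iv in table1_regions:
                if iv.chrom == chrom and iv.start <= pos <= iv.end:
                    expected = True
            assert region_pass(rec, table1_regions) is expected


class TestRunCascade:
    def test_fixture_with_decoys_yields_eleven_survivors(
        self, candidates, family, linked_regions
    ):
        decoys = cs.make_decoy_set(candidates, family, linked_regions)
        assert len(decoys) >= 20
        survivors, trace = run_cascade(
            candidates + decoys, family, linked_regions
        )
        assert len(survivors) == 11
        assert {r.gene for r in survivors} == {r.gene for r in candidates}
        assert all(trace.failure_stage(d.key) is not None for d in decoys)

    def test_each_decoy_fails_exactly_its_stage(
        self, candidates, family, linked_regions
    ):
        stage_by_tag = {
            "QC": "qc",
            "CLASS": "variant_class",
            "COSEG": ("absent_in_unaffected", "present_in_affected"),
            "POPFREQ": "population_frequency",
            "REGION": "linked_region",
        }
        decoys = cs.make_decoy_set(candidates, family, linked_regions)
        _, trace = run_cascade(decoys, family, linked_regions)
        for decoy in decoys:
            tag = decoy.gene.split("_")[1]
            expected = stage_by_tag[tag]
            failed = trace.failure_stage(decoy.key)
            if isinstance(expected, tuple):
                assert failed in expected, decoy.gene
            else:
                assert failed == expected, decoy.gene

    def test_empty_input(self, family, linked_regions):
        survivors, trace = run_cascade([], family, linked_regions)
        assert survivors == []
        assert all(v == 0 for v in trace.survivors_per_stage().values())

    def test_order_independence(self, candidates, family, linked_regions):
        decoys = cs.make_decoy_set(candidates, family, linked_regions)
        records = candidates + decoys
        forward, _ = run_cascade(records, family, linked_regions)
        backward, _ = run_cascade(records[::-1], family, linked_regions)
        assert [r.key for r in forward] == [r.key for r in backward]

    def test_trace_counts_are_non_increasing(
        self, candidates, family, linked_regions
    ):
        decoys = cs.make_decoy_set(candidates, family, linked_regions)
        _, trace = run_cascade(candidates + decoys, family, linked_regions)
        counts = list(trace.survivors_per_stage().values())
        assert counts == sorted(counts, reverse=True)

    def test_tightening_any_threshold_never_adds_survivors(
        self, candidates, family, linked_regions
    ):
        decoys = cs.make_decoy_set(candidates, family, linked_regions)
        records = candidates + decoys
        base_config = CascadeConfig()
        base, _ = run_cascade(records, family, linked_regions, base_config)
        base_keys = {r.key for r in base}
        tighter = [
            dict(min_seed_support=base_config.min_seed_support + 2),
            dict(min_depth=base_config.min_depth + 15),
            dict(min_alt_fraction=0.30),
            dict(max_alt_fraction=0.60),
            dict(max_clonal_reads=0),
            dict(max_indel_nt=2),
            dict(allowed_consequences=frozenset({"missense"})),
            dict(max_pop_af=0.0001),
            dict(max_inhouse=0),
        ]
        for change in tighter:
            config = dataclasses.replace(base_config, **change)
            survivors, _ = run_cascade(records, family, linked_regions, config)
            assert {r.key for r in survivors} <= base_keys, change

    def test_causal_variant_recovered_in_every_noise_free_run(
        self, small_sim_config
    ):
        """100 seeded simulations without clonal/error noise: the implanted
        variant survives the cascade inside scan-derived regions."""
        config = dataclasses.replace(
            small_sim_config, base_error_rate=0.0, clonal_rate=0.0
        )
        params = cs.ScanParams(min_markers=1)
        for seed in range(100):
            result = cs.simulate_family(config, seed=seed)
            regions = cs.scan_regions(result.matrix, result.pedigree, params)
            survivors, _ = run_cascade(
                result.variants, result.pedigree, regions
            )
            assert result.truth.causal_key in {r.key for r in survivors}, seed


class TestAlleleCountBound:
    def test_strictness_at_the_threshold(self):
        assert max_allele_count_below(13_000, 0.002) == 25
        assert 25 / 13_000 < 0.002 <= 26 / 13_000

    @pytest.mark.parametrize("an", [996, 12_365, 13_005, 280_000])
    def test_bound_is_tight_for_various_denominators(self, an):
        ac = max_allele_count_below(an, 0.002)
        assert ac / an < 0.002
        assert (ac + 1) / an >= 0.002
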