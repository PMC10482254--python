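"""The multi-stage exome variant filter cascade.

Stage order, applied per variant (all records are decomposed to one alt
allele each before filtering):

1. ``qc`` — read-level quality of every call that carries the alt allele:
   read-seed support, coverage, allele fraction band, clonal-read cap.
2. ``variant_class`` — consequence class (nonsense, frameshifting indel
   of <= 7 nt, missense, splice site) and in-house database rarity
   (at most 2 prior observations).
3. ``absent_in_unaffected`` — no unaffected sequenced member carries any
   copy of the alt allele.
4. ``present_in_affected`` — every affected sequenced member is
   heterozygous for the alt allele (hom-alt fails: the dominant model
   expects one mutant copy).
5. ``population_frequency`` — allele frequency strictly below the rarity
   threshold in every population database that reports the variant.
6. ``linked_region`` — the position falls inside a cosegregating region.
7. ``confirmation`` (optional) — an orthogonal confirmation flag, gated
   only when ``require_confirmed`` is set.

Each variant's trace stops at its first failing stage, so per-stage
survivor counts form a non-increasing funnel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

from .model import (
    DataError,
    FilterTrace,
    GenomicInterval,
    GenotypeCall,
    VariantRecord,
)
from .pedigree import Pedigree

STAGE_ORDER = [
    "qc",
    "variant_class",
    "absent_in_unaffected",
    "present_in_affected",
    "population_frequency",
    "linked_region",
    "confirmation",
]


@dataclass
class CascadeConfig:
    """Thresholds of the filter cascade.

    Defaults encode the variant-detection criteria of a dominant-model
    family exome screen: >= 2 read seeds, >= 10 reads of coverage, a
    non-reference allele fraction between 15% and 80% (inclusive at both
    ends), at most 5 clonal reads counted, indels up to 7 nt, the four
    protein-affecting consequence classes, a population allele frequency
    strictly below 0.002 in every database with data, and at most 2
    in-house observations.
    """

    min_seed_support: int = 2
    min_depth: int = 10
    min_alt_fraction: float = 0.15
    max_alt_fraction: float = 0.80
    max_clonal_reads: int = 5
    max_indel_nt: int = 7
    allowed_consequences: frozenset = frozenset(
        {"nonsense", "frameshift_indel", "missense", "splice_site"}
    )
    max_pop_af: float = 0.002
    max_inhouse: int = 2
    missing_freq_policy: str = "pass"
    missing_call_policy: str = "fail_variant"
    require_confirmed: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.min_alt_fraction < self.max_alt_fraction <= 1):
            raise DataError("need 0 <= min_alt_fraction < max_alt_fraction <= 1")
        for name in ("min_seed_support", "min_depth", "max_clonal_reads",
                     "max_indel_nt", "max_inhouse"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be >= 0")
        if self.missing_freq_policy not in ("pass", "fail"):
            raise DataError(f"unknown missing_freq_policy {self.missing_freq_policy!r}")
        if self.missing_call_policy not in ("fail_variant", "ignore_sample"):
            raise DataError(f"unknown missing_call_policy {self.missing_call_policy!r}")


class PassResult(NamedTuple):
    passed: bool
    reason: str

    def __bool__(self) -> bool:  # allows `if qc_pass(...)`
        return self.passed


def qc_pass(call: GenotypeCall, config: CascadeConfig = CascadeConfig()) -> PassResult:
    """Read-level QC for a call carrying the alt allele.

    The allele fraction is computed on a clonal-capped depth: duplicate
    reads beyond ``max_clonal_reads`` at one start site are not counted in
    the denominator.
    """
    if call.depth == 0 and call.alt_reads > 0:
        raise DataError(f"{call.sample_id}: alt reads with zero depth")
    if call.seed_support < config.min_seed_support:
        return PassResult(False, f"seed_support {call.seed_support} < {config.min_seed_support}")
    if call.clonal_reads > config.max_clonal_reads:
        return PassResult(False, f"clonal_reads {call.clonal_reads} > {config.max_clonal_reads}")
    counted_depth = call.depth - max(0, call.clonal_reads - config.max_clonal_reads)
    if counted_depth < config.min_depth:
        return PassResult(False, f"depth {counted_depth} < {config.min_depth}")
    fraction = call.alt_reads / counted_depth
    if fraction < config.min_alt_fraction:
        return PassResult(False, f"alt fraction {fraction:.3f} < {config.min_alt_fraction}")
    if fraction > config.max_alt_fraction:
        return PassResult(False, f"alt fraction {fraction:.3f} > {config.max_alt_fraction}")
    return PassResult(True, "")


def consequence_pass(
    record: VariantRecord, config: CascadeConfig = CascadeConfig()
) -> PassResult:
    """Consequence-class selection (with the indel length cap)."""
    if record.consequence is None:
        return PassResult(False, "unannotated")
    if record.consequence not in config.allowed_consequences:
        return PassResult(False, f"consequence {record.consequence}")
    if record.is_indel and record.indel_length > config.max_indel_nt:
        return PassResult(False, f"indel {record.indel_length} nt > {config.max_indel_nt}")
    return PassResult(True, "")


def _popfreq_pass(record: VariantRecord, config: CascadeConfig) -> PassResult:
    reported = False
    for db, (ac, an) in record.popfreqs.items():
        if an == 0:
            raise DataError(f"{db}: AN = 0 at {record.chrom}:{record.pos}")
        reported = True
        af = ac / an
        if af >= config.max_pop_af:
            return PassResult(False, f"{db} AF {af:.5f} >= {config.max_pop_af}")
    if not reported and config.missing_freq_policy == "fail":
        return PassResult(False, "no population frequency data")
    return PassResult(True, "")


def _inhouse_pass(record: VariantRecord, config: CascadeConfig) -> PassResult:
    if record.inhouse_count is not None and record.inhouse_count > config.max_inhouse:
        return PassResult(False, f"inhouse_count {record.inhouse_count} > {config.max_inhouse}")
    return PassResult(True, "")


def rarity_pass(
    record: VariantRecord, config: CascadeConfig = CascadeConfig()
) -> PassResult:
    """Population rarity: AF strictly < threshold in every database with
    data, and at most ``max_inhouse`` in-house observations.

    A database with no entry for the variant is no evidence of commonness
    and passes under the default ``missing_freq_policy="pass"``.
    """
    result = _popfreq_pass(record, config)
    if not result.passed:
        return result
    return _inhouse_pass(record, config)


def _absent_in_unaffected(
    record: VariantRecord, pedigree: Pedigree, config: CascadeConfig
) -> PassResult:
    for sample in pedigree.unaffected_sequenced:
        call = record.calls.get(sample)
        if call is None or call.is_missing:
            if config.missing_call_policy == "fail_variant":
                return PassResult(False, f"missing call for unaffected {sample}")
            continue
        if call.carries_alt():
            return PassResult(False, f"alt allele present in unaffected {sample}")
    return PassResult(True, "")


def _present_in_affected(
    record: VariantRecord, pedigree: Pedigree, config: CascadeConfig
) -> PassResult:
    affected = pedigree.affected_sequenced
    if not affected:
        raise DataError("cosegregation check needs >= 1 affected sequenced member")
    for sample in affected:
        call = record.calls.get(sample)
        if call is None or call.is_missing:
            if config.missing_call_policy == "fail_variant":
                return PassResult(False, f"missing call for affected {sample}")
            continue
        if not call.is_het_alt():
            return PassResult(False, f"affected {sample} not heterozygous for alt")
    return PassResult(True, "")


def cosegregation_pass(
    record: VariantRecord,
    pedigree: Pedigree,
    config: CascadeConfig = CascadeConfig(),
) -> PassResult:
    """Full cosegregation test: heterozygous QC-passing call in every
    affected member, no copy of the alt allele in any unaffected member."""
    result = _absent_in_unaffected(record, pedigree, config)
    if not result.passed:
        return result
    result = _present_in_affected(record, pedigree, config)
    if not result.passed:
        return result
    for sample in pedigree.affected_sequenced:
        call = record.calls.get(sample)
        if call is None or call.is_missing:
            continue
        qc = qc_pass(call, config)
        if not qc.passed:
            return PassResult(False, f"affected {sample}: {qc.reason}")
    return PassResult(True, "")


def region_pass(
    record: VariantRecord, regions: Sequence[GenomicInterval]
) -> bool:
    """True iff the position lies inside some region on its chromosome
    (1-based inclusive endpoints)."""
    return any(iv.contains(record.chrom, record.pos) for iv in regions)


def _qc_stage(record: VariantRecord, config: CascadeConfig) -> PassResult:
    """QC every call that claims the alt allele (carrier calls).

    Non-carrier calls are absence evidence, not variant calls, and are not
    held to the carrier QC thresholds.
    """
    for sample, call in sorted(record.calls.items()):
        if call.is_missing or not call.carries_alt():
            continue
        result = qc_pass(call, config)
        if not result.passed:
            return PassResult(False, f"{sample}: {result.reason}")
    return PassResult(True, "")


def run_cascade(
    records: Sequence[VariantRecord],
    pedigree: Pedigree,
    regions: Sequence[GenomicInterval],
    config: CascadeConfig = CascadeConfig(),
) -> tuple[list[VariantRecord], FilterTrace]:
    """Run the full cascade; returns (survivors, trace).

    The survivor set has set semantics: it is independent of the input
    record order (records are processed and returned in genomic order).
    """
    if not pedigree.affected_sequenced:
        raise DataError("cascade needs >= 1 affected sequenced member")
    stages = [s for s in STAGE_ORDER if s != "confirmation" or config.require_confirmed]
    trace = FilterTrace(stages)
    survivors: list[VariantRecord] = []
    ordered = sorted(records, key=lambda r: r.key)
    for record in ordered:
        alive = True
        for stage in stages:
            if stage == "qc":
                result = _qc_stage(record, config)
            elif stage == "variant_class":
                result = consequence_pass(record, config)
                if result.passed:
                    result = _inhouse_pass(record, config)
            elif stage == "absent_in_unaffected":
                result = _absent_in_unaffected(record, pedigree, config)
            elif stage == "present_in_affected":
                result = _present_in_affected(record, pedigree, config)
            elif stage == "population_frequency":
                result = _popfreq_pass(record, config)
            elif stage == "linked_region":
                ok = region_pass(record, regions)
                result = PassResult(ok, "" if ok else "outside all linked regions")
            elif stage == "confirmation":
                ok = record.confirmed is True
                result = PassResult(ok, "" if ok else "not confirmed")
            trace.record(record.key, stage, result.passed, result.reason)
            if not result.passed:
                alive = False
                break
        if alive:
            survivors.append(record)
    return survivors, trace


def max_allele_count_below(an: int, threshold: float = 0.002) -> int:
    """Largest allele count AC with AC/AN strictly below ``threshold``.

    E.g. with AN = 13000 haplotypes and threshold 0.002 the admissible
    counts are 0..25 (26/13000 equals the threshold exactly and is
    excluded).
    """
    if an <= 0:
        raise DataError("AN must be positive")
    ac = math.ceil(threshold * an) - 1
    while (ac + 1) / an < threshold:  # guard against float rounding
        ac += 1
    return max(ac, 0)


def trace_to_frame(trace: FilterTrace):
    """FilterTrace as a tidy DataFrame (one row per variant per stage)."""
    import pandas as pd

    rows = [
        {
            "chrom": key[0],
            "pos": key[1],
            "ref": key[2],
            "alt": key[3],
            "stage": stage,
            "passed": passed,
            "reason": reason,
        }
        for key, stage, passed, reason in trace.iter_rows()
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "stage", "passed", "reason"]
    )
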