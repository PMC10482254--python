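"""Core domain types shared across the package.

Coordinates are 1-based and inclusive throughout, matching the convention of
the printed region and variant tables this package works with.  BED export
(see :mod:`cosegscan.io`) converts to 0-based half-open on the way out.

The one deliberately unusual convention is :meth:`GenomicInterval.length`,
which returns ``end - start`` rather than the more common
``end - start + 1``: that is the arithmetic that reproduces the Length
column of the published linked-region table, and it is kept so that
round-tripping those tables is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Tuple

#: Closed vocabulary of variant consequence classes.
CONSEQUENCES = frozenset(
    {"nonsense", "frameshift_indel", "missense", "splice_site", "other"}
)

#: Variant identity: (chrom, pos, ref, alt).
VariantKey = Tuple[str, int, str, str]


class DataError(ValueError):
    """Raised when input data violate a structural precondition."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive genomic interval.

    ``length()`` is defined as ``end - start`` (NOT ``end - start + 1``);
    this matches the published Length column for every linked region and is
    the convention used everywhere in this package.
    """

    chrom: str
    start: int
    end: int
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataError(
                f"interval start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.start < 1:
            raise DataError(f"interval start must be >= 1, got {self.start}")

    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class GenotypeCall:
    """One sample's genotype and read support at one variant site.

    ``alleles`` is an unordered pair of allele indices (0 = reference,
    1 = the record's alt after decomposition), or ``None`` for a missing
    call.  ``seed_support`` counts reads whose high-quality 25 bp seed
    supports the variant; ``clonal_reads`` counts extra reads sharing an
    identical start site (PCR duplicates beyond the first).
    """

    sample_id: str
    alleles: Optional[Tuple[int, int]]
    depth: int = 0
    alt_reads: int = 0
    seed_support: int = 0
    clonal_reads: int = 0

    def __post_init__(self) -> None:
        if self.alleles is not None:
            a, b = self.alleles
            self.alleles = (min(a, b), max(a, b))
        if not (0 <= self.alt_reads <= self.depth):
            raise DataError(
                f"{self.sample_id}: alt_reads {self.alt_reads} outside "
                f"[0, depth={self.depth}]"
            )
        if self.seed_support > self.alt_reads:
            raise DataError(
                f"{self.sample_id}: seed_support {self.seed_support} exceeds "
                f"alt_reads {self.alt_reads}"
            )
        if self.clonal_reads < 0:
            raise DataError(f"{self.sample_id}: negative clonal_reads")

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    def carries_alt(self) -> bool:
        """True if the call includes at least one copy of the alt allele."""
        return self.alleles is not None and 1 in self.alleles

    def is_het_alt(self) -> bool:
        """True for exactly one reference and one alt allele."""
        return self.alleles == (0, 1)


@dataclass
class PredictionAnnotation:
    """In-silico damage predictions and conservation labels for a variant.

    Any field may be None (e.g. splice-site variants have no protein-level
    prediction).
    """

    polyphen_score: Optional[float] = None
    polyphen_class: Optional[str] = None  # benign | possibly damaging | probably damaging
    sift_score: Optional[float] = None
    sift_class: Optional[str] = None  # tolerated | deleterious
    conservation_nt: Optional[str] = None  # weakly | moderately | highly
    conservation_aa: Optional[str] = None

    POLYPHEN_CLASSES = ("benign", "possibly damaging", "probably damaging")
    SIFT_CLASSES = ("tolerated", "deleterious")
    CONSERVATION_CLASSES = ("weakly", "moderately", "highly")

    def __post_init__(self) -> None:
        if self.polyphen_class is not None and self.polyphen_class not in self.POLYPHEN_CLASSES:
            raise DataError(f"unknown polyphen class {self.polyphen_class!r}")
        if self.sift_class is not None and self.sift_class not in self.SIFT_CLASSES:
            raise DataError(f"unknown SIFT class {self.sift_class!r}")
        for v in (self.conservation_nt, self.conservation_aa):
            if v is not None and v not in self.CONSERVATION_CLASSES:
                raise DataError(f"unknown conservation label {v!r}")


@dataclass
class VariantRecord:
    """One (site, alt allele) pair flowing through the filter cascade.

    Multi-allelic VCF sites are decomposed into one record per alt before
    anything else happens; allele index 1 always means "this record's alt".

    ``popfreqs`` maps database name -> (allele count AC, allele number AN).
    A database absent from the map means "no evidence", which the cascade
    treats distinctly from AC = 0.  ``inhouse_count`` is the number of
    observations in a local in-house variant database (None if unknown).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: Optional[str] = None
    indel_length: int = 0
    gene: Optional[str] = None
    popfreqs: dict[str, Tuple[int, int]] = field(default_factory=dict)
    inhouse_count: Optional[int] = None
    predictions: Optional[PredictionAnnotation] = None
    calls: dict[str, GenotypeCall] = field(default_factory=dict)
    confirmed: Optional[bool] = None  # orthogonal confirmation assay, if any

    def __post_init__(self) -> None:
        if self.consequence is not None and self.consequence not in CONSEQUENCES:
            raise DataError(
                f"consequence {self.consequence!r} not in {sorted(CONSEQUENCES)}"
            )
        if self.indel_length < 0:
            raise DataError("indel_length must be >= 0")
        for db, (ac, an) in self.popfreqs.items():
            if ac > an:
                raise DataError(f"{db}: AC {ac} > AN {an} at {self.chrom}:{self.pos}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return self.indel_length > 0


@dataclass
class StageOutcome:
    stage: str
    passed: bool
    reason: str = ""


class FilterTrace:
    """Audit trail of a cascade run.

    Per variant, an ordered list of stage outcomes ending at the first
    failure; per stage, the count of variants surviving it.  Survivor counts
    are non-increasing in stage order by construction.
    """

    def __init__(self, stage_order: list[str]):
        self.stage_order = list(stage_order)
        self.outcomes: dict[VariantKey, list[StageOutcome]] = {}

    def record(self, key: VariantKey, stage: str, passed: bool, reason: str = "") -> None:
        history = self.outcomes.setdefault(key, [])
        if history and not history[-1].passed:
            raise DataError(f"variant {key} already failed at {history[-1].stage}")
        history.append(StageOutcome(stage, passed, reason))

    def entered(self, stage: str) -> int:
        return sum(
            1
            for history in self.outcomes.values()
            for o in history
            if o.stage == stage
        )

    def survivors_per_stage(self) -> dict[str, int]:
        counts = {}
        for stage in self.stage_order:
            counts[stage] = sum(
                1
                for history in self.outcomes.values()
                for o in history
                if o.stage == stage and o.passed
            )
        return counts

    def failure_stage(self, key: VariantKey) -> Optional[str]:
        history = self.outcomes.get(key, [])
        if history and not history[-1].passed:
            return history[-1].stage
        return None

    def iter_rows(self) -> Iterator[Tuple[VariantKey, str, bool, str]]:
        for key, history in self.outcomes.items():
            for o in history:
                yield key, o.stage, o.passed, o.reason
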