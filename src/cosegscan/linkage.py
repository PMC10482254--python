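"""Dominant-model cosegregation region scan over a marker genotype matrix.

The scan implements the set-logic principle of dominant linkage mapping on
unphased genotypes: a marker is *compatible* with the trait if some allele
is carried by every affected sequenced member and by no unaffected
sequenced member.  Maximal runs of consecutive compatible markers along a
chromosome are reported as candidate linked regions.

No phasing and no likelihood model (LOD score) is attempted: with a single
family and a fully penetrant dominant model, the qualitative shared-allele
criterion is the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd

from .model import DataError, GenomicInterval
from .pedigree import Pedigree

AllelePair = Optional[Tuple[Hashable, Hashable]]


@dataclass(frozen=True)
class Marker:
    chrom: str
    pos: int
    cm: Optional[float] = None


@dataclass
class MarkerGenotypeMatrix:
    """Ordered markers x individuals, unphased allele pairs (missing = None)."""

    markers: list[Marker]
    genotypes: list[dict[str, AllelePair]]  # parallel to markers

    def __post_init__(self) -> None:
        if len(self.markers) != len(self.genotypes):
            raise DataError("markers and genotype rows differ in length")

    def check_sorted(self) -> None:
        by_chrom: dict[str, list[int]] = {}
        for m in self.markers:
            by_chrom.setdefault(m.chrom, []).append(m.pos)
        for chrom, positions in by_chrom.items():
            if positions != sorted(positions):
                raise DataError(f"markers on {chrom} are not position-sorted")

    def to_tsv(self, path) -> None:
        samples = sorted({s for row in self.genotypes for s in row})
        rows = []
        for marker, row in zip(self.markers, self.genotypes):
            out = {
                "chrom": marker.chrom,
                "pos": marker.pos,
                "cM": "" if marker.cm is None else marker.cm,
            }
            for s in samples:
                gt = row.get(s)
                out[s] = "./." if gt is None else f"{gt[0]}/{gt[1]}"
            rows.append(out)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MarkerGenotypeMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        samples = [c for c in df.columns if c not in ("chrom", "pos", "cM")]
        markers, genotypes = [], []
        for _, row in df.iterrows():
            cm = row.get("cM")
            markers.append(
                Marker(str(row["chrom"]), int(row["pos"]),
                       None if pd.isna(cm) else float(cm))
            )
            geno: dict[str, AllelePair] = {}
            for s in samples:
                value = str(row[s])
                if value in ("./.", "nan", ""):
                    geno[s] = None
                else:
                    a, b = value.split("/")
                    geno[s] = (a, b)
            genotypes.append(geno)
        return cls(markers, genotypes)


@dataclass
class ScanParams:
    """Tuning knobs of the region scan.

    All defaults are package choices: zero tolerated incompatible markers
    inside a run, at least 3 compatible markers per reported region, inner
    boundaries (positions of the outermost compatible markers), and missing
    genotypes treated as compatible (a missing genotype cannot disprove
    sharing).
    """

    max_errors_per_region: int = 0
    min_markers: int = 3
    boundary_mode: str = "inner"
    missing_policy: str = "compatible"

    def __post_init__(self) -> None:
        if self.max_errors_per_region < 0:
            raise DataError("max_errors_per_region must be >= 0")
        if self.min_markers < 1:
            raise DataError("min_markers must be >= 1")
        if self.boundary_mode not in ("inner", "outer"):
            raise DataError(f"unknown boundary_mode {self.boundary_mode!r}")
        if self.missing_policy not in ("compatible", "incompatible"):
            raise DataError(f"unknown missing_policy {self.missing_policy!r}")


def marker_compatible(
    genotypes: Mapping[str, AllelePair],
    pedigree: Pedigree,
    missing_policy: str = "compatible",
) -> bool:
    """True iff some allele is carried by every affected and no unaffected.

    Under ``missing_policy="compatible"`` a missing genotype imposes no
    constraint (an affected with no call could carry any allele, an
    unaffected with no call is not evidence of carriage); under
    ``"incompatible"`` any missing genotype among sequenced members makes
    the marker incompatible.
    """
    affected = pedigree.affected_sequenced
    unaffected = pedigree.unaffected_sequenced
    if not affected:
        raise DataError("marker_compatible needs >= 1 affected sequenced member")

    members = affected + unaffected
    if missing_policy == "incompatible":
        if any(genotypes.get(s) is None for s in members):
            return False

    candidate: Optional[set] = None
    for s in affected:
        gt = genotypes.get(s)
        if gt is None:
            continue  # compatible policy: no constraint
        alleles = set(gt)
        candidate = alleles if candidate is None else candidate & alleles
        if not candidate:
            return False
    if candidate is None:
        return True  # no affected genotyped: vacuously compatible

    forbidden = set()
    for s in unaffected:
        gt = genotypes.get(s)
        if gt is not None:
            forbidden.update(gt)
    return bool(candidate - forbidden)


def scan_regions(
    matrix: MarkerGenotypeMatrix,
    pedigree: Pedigree,
    params: ScanParams = ScanParams(),
) -> list[GenomicInterval]:
    """Report maximal runs of compatible markers per chromosome.

    Runs are grown greedily left to right: a run starts at a compatible
    marker and extends rightward while the number of enclosed incompatible
    markers stays within ``max_errors_per_region``; it is closed at its last
    compatible marker.  Runs with fewer than ``min_markers`` compatible
    markers are dropped.  With ``boundary_mode="outer"`` endpoints are the
    flanking incompatible markers (or the chromosome's outermost markers).
    """
    matrix.check_sorted()
    flags = [
        marker_compatible(row, pedigree, params.missing_policy)
        for row in matrix.genotypes
    ]

    by_chrom: dict[str, list[int]] = {}
    for idx, marker in enumerate(matrix.markers):
        by_chrom.setdefault(marker.chrom, []).append(idx)

    regions: list[GenomicInterval] = []
    for chrom in by_chrom:
        indices = by_chrom[chrom]
        n = len(indices)
        i = 0
        while i < n:
            if not flags[indices[i]]:
                i += 1
                continue
            errors = 0
            last_compatible = i
            n_compatible = 0
            j = i
            while j < n:
                if flags[indices[j]]:
                    last_compatible = j
                    n_compatible += 1
                else:
                    errors += 1
                    if errors > params.max_errors_per_region:
                        break
                j += 1
            if n_compatible >= params.min_markers:
                first_idx, last_idx = indices[i], indices[last_compatible]
                if params.boundary_mode == "inner":
                    start = matrix.markers[first_idx].pos
                    end = matrix.markers[last_idx].pos
                else:
                    left = i - 1
                    right = last_compatible + 1
                    start = matrix.markers[
                        indices[left] if left >= 0 else indices[0]
                    ].pos
                    end = matrix.markers[
                        indices[right] if right < n else indices[-1]
                    ].pos
                regions.append(GenomicInterval(chrom, start, end))
            i = last_compatible + 1
    regions.sort(key=lambda iv: (iv.chrom, iv.start))
    return regions


@dataclass
class ScanEvaluation:
    covered: bool
    genome_fraction_linked: float


def evaluate_scan(
    regions: Sequence[GenomicInterval],
    true_locus: Union[GenomicInterval, Tuple[str, int]],
    genome_bp: int,
) -> ScanEvaluation:
    """Recovery metrics of a scan against a known causal locus.

    ``covered`` is True if the locus (point or interval midpoint is not
    used: an interval counts as covered if any reported region contains its
    start) lies inside some reported region; ``genome_fraction_linked`` is
    the summed region length over the simulated genome length.
    """
    if isinstance(true_locus, GenomicInterval):
        chrom, pos = true_locus.chrom, true_locus.start
    else:
        chrom, pos = true_locus
    covered = any(iv.contains(chrom, pos) for iv in regions)
    if genome_bp <= 0:
        raise DataError("genome_bp must be positive")
    fraction = sum(iv.length() for iv in regions) / genome_bp
    return ScanEvaluation(covered=covered, genome_fraction_linked=fraction)
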