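"""Seeded generator of synthetic families: pedigree, recombining marker
genotypes, and exome-like variant tables with an implanted cosegregating
causal variant.

The generator emulates the statistical structure the analysis assumes — a
three-generation family segregating a fully penetrant autosomal dominant
allele — and stands in for undeposited study data.  Meiosis follows the
Haldane model: crossover counts are Poisson with mean equal to the map
length in Morgans, crossover positions uniform on the genetic map, no
interference.  Transmission of the causal allele is conditioned on the
template affection pattern (valid because the two parental haplotypes are
exchangeable under Haldane), so affection status equals carrier status in
every run.

Background exome variants are transmitted Mendelianly but independently
per site (no linkage between exome sites and the marker map); their
configured population allele frequencies are reused as the database AC/AN
annotations so that rarity filtering is testable against simulation truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .cascade import CascadeConfig
from .linkage import Marker, MarkerGenotypeMatrix
from .model import DataError, GenomicInterval, GenotypeCall, VariantRecord
from .pedigree import Individual, Pedigree


@dataclass(frozen=True)
class ChromosomeSpec:
    label: str
    length_bp: int
    map_length_cm: float


def default_family() -> Pedigree:
    """Six sequenced members over three generations: an affected founder,
    an affected child, an affected grandchild, and three unaffected
    members (the founder's spouse, a married-in parent, an unaffected
    sibling)."""
    return Pedigree(
        [
            Individual("I_1", None, None, "male", "affected"),
            Individual("I_2", None, None, "female", "unaffected"),
            Individual("II_1", "I_1", "I_2", "male", "affected"),
            Individual("II_2", None, None, "female", "unaffected"),
            Individual("III_1", "II_1", "II_2", "male", "affected"),
            Individual("III_2", "II_1", "II_2", "female", "unaffected"),
        ]
    )


@dataclass
class SimulationConfig:
    """Study conditions of a simulated family.

    Defaults: three chromosomes at 1 cM/Mb, 50 markers each, a random
    causal locus, 120 background exome variants whose allele frequencies
    are an even mixture of rare (AF ~ U(0, 0.002)) and common
    (AF ~ U(0.01, 0.5)) components, Poisson(40) depth, Binomial(depth, 0.5)
    heterozygous alt reads with a 0.001 base error rate, and no genotype
    dropout.
    """

    chromosomes: Tuple[ChromosomeSpec, ...] = (
        ChromosomeSpec("1", 120_000_000, 120.0),
        ChromosomeSpec("2", 100_000_000, 100.0),
        ChromosomeSpec("3", 80_000_000, 80.0),
    )
    markers_per_chrom: int = 50
    marker_informativeness: str = "founder"  # "founder" (fully informative) | "biallelic"
    causal_locus: Union[str, Tuple[str, int]] = "random"
    n_background_variants: int = 120
    rare_weight: float = 0.5
    rare_af_range: Tuple[float, float] = (0.0, 0.002)
    common_af_range: Tuple[float, float] = (0.01, 0.5)
    marker_maf_range: Tuple[float, float] = (0.1, 0.5)
    depth_mean: float = 40.0
    het_alt_rate: float = 0.5
    base_error_rate: float = 0.001
    seed_rate: float = 0.5
    clonal_rate: float = 0.02
    genotype_dropout_rate: float = 0.0
    database_name: str = "GNOMAD"
    database_an: int = 280_000
    inhouse_panel_size: int = 200

    def __post_init__(self) -> None:
        for name in ("rare_weight", "het_alt_rate", "base_error_rate",
                     "seed_rate", "clonal_rate", "genotype_dropout_rate"):
            if not (0 <= getattr(self, name) <= 1):
                raise DataError(f"{name} must be in [0, 1]")
        if self.markers_per_chrom < 1 or self.n_background_variants < 0:
            raise DataError("counts must be positive")
        if self.marker_informativeness not in ("founder", "biallelic"):
            raise DataError(
                f"unknown marker_informativeness {self.marker_informativeness!r}"
            )
        for spec in self.chromosomes:
            if spec.length_bp <= 0 or spec.map_length_cm < 0:
                raise DataError(f"bad chromosome spec {spec}")

    def genome_bp(self) -> int:
        return sum(c.length_bp for c in self.chromosomes)

    def chromosome(self, label: str) -> ChromosomeSpec:
        for spec in self.chromosomes:
            if spec.label == label:
                return spec
        raise DataError(f"chromosome {label!r} not declared")


@dataclass
class SimulationTruth:
    causal_chrom: str
    causal_pos: int
    causal_ref: str
    causal_alt: str
    carriers: list[str]
    genome_bp: int

    @property
    def causal_key(self):
        return (self.causal_chrom, self.causal_pos, self.causal_ref, self.causal_alt)


@dataclass
class SimulationResult:
    pedigree: Pedigree
    matrix: MarkerGenotypeMatrix
    variants: list[VariantRecord]
    truth: SimulationTruth


def _meiosis(
    haplotypes: Tuple[np.ndarray, np.ndarray],
    cm_positions: np.ndarray,
    map_length_cm: float,
    rng: np.random.Generator,
    query_cm: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray, int, Optional[int]]:
    """One gamete under the Haldane model.

    Crossover count ~ Poisson(map length in Morgans), crossover positions
    uniform on the map, no interference.  Returns (gamete alleles, origin
    per marker in {0, 1}, crossover count, origin at ``query_cm`` if
    given).
    """
    n_cross = int(rng.poisson(map_length_cm / 100.0))
    breaks = np.sort(rng.uniform(0.0, map_length_cm, size=n_cross))
    start = int(rng.integers(2))
    origin = (start + np.searchsorted(breaks, cm_positions, side="right")) % 2
    gamete = np.where(origin == 0, haplotypes[0], haplotypes[1])
    origin_at = None
    if query_cm is not None:
        origin_at = int((start + np.searchsorted(breaks, query_cm, side="right")) % 2)
    return gamete, origin, n_cross, origin_at


def sample_crossover_counts(
    map_length_cm: float, n: int, seed: int = 0
) -> np.ndarray:
    """Crossover counts of ``n`` independent gametes (for calibration)."""
    rng = np.random.default_rng(seed)
    cm = np.array([0.0])
    haps = (np.zeros(1, dtype=np.int8), np.ones(1, dtype=np.int8))
    return np.array(
        [_meiosis(haps, cm, map_length_cm, rng)[2] for _ in range(n)]
    )


def _sample_positions(rng: np.random.Generator, n: int, length_bp: int) -> np.ndarray:
    """``n`` distinct sorted positions in [1, length_bp)."""
    draw = np.empty(0, dtype=np.int64)
    while True:
        draw = np.concatenate(
            [draw, rng.integers(1, length_bp, size=4 * n, dtype=np.int64)]
        )
        uniq = np.unique(draw)
        if len(uniq) >= n:
            chosen = rng.choice(uniq, size=n, replace=False)
            return np.sort(chosen)


def _topological_order(pedigree: Pedigree) -> list[str]:
    order, seen = [], set()

    def visit(ind_id: str) -> None:
        if ind_id in seen:
            return
        for parent in pedigree.parents(ind_id):
            if parent in pedigree.individuals:
                visit(parent)
        seen.add(ind_id)
        order.append(ind_id)

    for ind_id in sorted(pedigree.individuals):
        visit(ind_id)
    return order


def simulate_family(
    config: SimulationConfig = SimulationConfig(),
    seed: int = 0,
    pedigree: Optional[Pedigree] = None,
) -> SimulationResult:
    """Simulate one family; identical (config, seed) gives identical output.

    The causal allele is implanted heterozygously in one affected founder
    and transmitted so that carrier status equals the template's affection
    status (complete penetrance).  Every affected member must be a founder
    or have an affected parent in the template.
    """
    if pedigree is None:
        pedigree = default_family()
    carriers = {i.id for i in pedigree if i.affection == "affected"}
    if not carriers:
        raise DataError("template has no affected members")

    ss = np.random.SeedSequence(seed)
    marker_rng, founder_rng, meiosis_rng, variant_rng, noise_rng = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )

    # --- causal locus ------------------------------------------------------
    if config.causal_locus == "random":
        lengths = np.array([c.length_bp for c in config.chromosomes], dtype=float)
        idx = int(marker_rng.choice(len(lengths), p=lengths / lengths.sum()))
        causal_chrom = config.chromosomes[idx].label
        causal_pos = int(marker_rng.integers(1, config.chromosomes[idx].length_bp))
    else:
        causal_chrom, causal_pos = config.causal_locus
        spec = config.chromosome(causal_chrom)  # raises if undeclared
        if not (1 <= causal_pos <= spec.length_bp):
            raise DataError(
                f"causal locus {causal_pos} outside chromosome {causal_chrom}"
            )

    # --- marker map --------------------------------------------------------
    # The causal position itself is always genotyped as a marker (its
    # variant allele is private to the family), which is what makes the
    # region scan's recovery of the causal locus a construction property
    # rather than a matter of marker spacing.
    markers: list[Marker] = []
    mafs: list[float] = []
    chrom_slices: dict[str, slice] = {}
    cm_by_chrom: dict[str, np.ndarray] = {}
    for spec in config.chromosomes:
        positions = _sample_positions(
            marker_rng, config.markers_per_chrom, spec.length_bp
        )
        if spec.label == causal_chrom:
            positions = np.unique(np.append(positions, causal_pos))
        cm = positions / spec.length_bp * spec.map_length_cm
        start = len(markers)
        for pos, cpos in zip(positions, cm):
            markers.append(Marker(spec.label, int(pos), float(cpos)))
            mafs.append(
                float(marker_rng.uniform(*config.marker_maf_range))
            )
        chrom_slices[spec.label] = slice(start, len(markers))
        cm_by_chrom[spec.label] = cm
    causal_marker_idx = next(
        i for i, m in enumerate(markers)
        if m.chrom == causal_chrom and m.pos == causal_pos
    )

    # --- founder haplotypes ------------------------------------------------
    founder_ids = pedigree.founders()
    affected_founders = [f for f in founder_ids if f in carriers]
    if not affected_founders:
        raise DataError("template needs an affected founder to seed the allele")
    seed_founder = sorted(affected_founders)[0]

    maf_arr = np.array(mafs)
    haps: dict[str, dict[str, Tuple[np.ndarray, np.ndarray]]] = {}
    causal_hap: dict[str, Optional[int]] = {}

    # "founder" informativeness gives every founder haplotype its own
    # allele at every marker (the fully informative idealization, standing
    # in for the haplotype information a dense phased array provides);
    # "biallelic" draws A/B alleles at the configured MAF.  Either way the
    # causal marker carries the variant allele only on the carrier
    # founder's implanted haplotype.
    hap_counter = [0]
    carrier_code = [1]

    def founder_haplotype(is_causal_hap: bool) -> dict[str, np.ndarray]:
        hap_id = hap_counter[0]
        hap_counter[0] += 1
        if config.marker_informativeness == "founder":
            full = np.full(len(markers), hap_id, dtype=np.int32)
            if is_causal_hap:
                carrier_code[0] = hap_id
        else:
            full = (founder_rng.random(len(markers)) < maf_arr).astype(np.int32)
            full[causal_marker_idx] = 1 if is_causal_hap else 0
        return {c: full[s] for c, s in chrom_slices.items()}

    order = _topological_order(pedigree)

    for ind_id in order:
        ind = pedigree[ind_id]
        if ind.is_founder or not all(
            p in pedigree.individuals for p in pedigree.parents(ind_id)
        ):
            h0 = founder_haplotype(ind_id == seed_founder)
            h1 = founder_haplotype(False)
            haps[ind_id] = {c: (h0[c], h1[c]) for c in chrom_slices}
            causal_hap[ind_id] = 0 if ind_id == seed_founder else None
            continue

        parents = (ind.father_id, ind.mother_id)
        carrier_parents = [p for p in parents if causal_hap[p] is not None]
        if len(carrier_parents) > 1:
            raise DataError("templates with two carrier parents are not supported")
        if ind_id in carriers and not carrier_parents:
            raise DataError(
                f"affected {ind_id} has no carrier parent in the template "
                "(de novo events are not simulated)"
            )

        parent_gametes = []
        transmitted_causal = []
        for parent in parents:
            parent_carrier_hap = causal_hap[parent]
            gamete: dict[str, np.ndarray] = {}
            carries = False
            for spec in config.chromosomes:
                hap_pair = haps[parent][spec.label]
                query = None
                if spec.label == causal_chrom and parent_carrier_hap is not None:
                    query = causal_pos / spec.length_bp * spec.map_length_cm
                g, origin, _, origin_at = _meiosis(
                    hap_pair, cm_by_chrom[spec.label], spec.map_length_cm,
                    meiosis_rng, query_cm=query,
                )
                if query is not None:
                    carries = origin_at == parent_carrier_hap
                    # Condition on the template affection pattern: the two
                    # parental haplotypes are exchangeable under Haldane, so
                    # flipping the whole gamete is a valid conditional draw.
                    want = ind_id in carriers
                    if carries != want:
                        origin = 1 - origin
                        g = np.where(origin == 0, hap_pair[0], hap_pair[1])
                        carries = want
                gamete[spec.label] = g
            parent_gametes.append(gamete)
            transmitted_causal.append(carries)

        haps[ind_id] = {
            c: (parent_gametes[0][c], parent_gametes[1][c]) for c in chrom_slices
        }
        if transmitted_causal[0]:
            causal_hap[ind_id] = 0
        elif transmitted_causal[1]:
            causal_hap[ind_id] = 1
        else:
            causal_hap[ind_id] = None

    # sanity: conditioning must reproduce the template pattern exactly
    for ind in pedigree:
        if (causal_hap[ind.id] is not None or ind.id == seed_founder) != (
            ind.id in carriers
        ):
            raise DataError(
                f"causal transmission failed to match affection for {ind.id}"
            )

    # --- marker genotype matrix -------------------------------------------
    def allele_name(global_idx: int, value: int) -> str:
        if global_idx == causal_marker_idx:
            return "B" if value == carrier_code[0] else "A"
        if config.marker_informativeness == "founder":
            return f"a{value}"
        return "B" if value else "A"

    genotypes: list[dict] = []
    ids = [i.id for i in pedigree]
    for spec in config.chromosomes:
        sl = chrom_slices[spec.label]
        for local_idx in range(sl.stop - sl.start):
            global_idx = sl.start + local_idx
            row = {}
            for ind_id in ids:
                if (
                    config.genotype_dropout_rate > 0
                    and noise_rng.random() < config.genotype_dropout_rate
                ):
                    row[ind_id] = None
                    continue
                h0, h1 = haps[ind_id][spec.label]
                pair = sorted(
                    [
                        allele_name(global_idx, int(h0[local_idx])),
                        allele_name(global_idx, int(h1[local_idx])),
                    ]
                )
                row[ind_id] = (pair[0], pair[1])
            genotypes.append(row)
    matrix = MarkerGenotypeMatrix(markers, genotypes)

    # --- exome-like variant records ---------------------------------------
    consequences = np.array(
        ["missense", "other", "nonsense", "splice_site", "frameshift_indel"]
    )
    conseq_p = np.array([0.45, 0.35, 0.05, 0.05, 0.10])

    def synth_calls(copies_by_sample: dict[str, int]) -> dict[str, GenotypeCall]:
        calls = {}
        for sample, copies in copies_by_sample.items():
            if (
                config.genotype_dropout_rate > 0
                and noise_rng.random() < config.genotype_dropout_rate
            ):
                calls[sample] = GenotypeCall(sample, None)
                continue
            depth = max(1, int(noise_rng.poisson(config.depth_mean)))
            p_alt = {
                0: config.base_error_rate,
                1: config.het_alt_rate,
                2: 1.0 - config.base_error_rate,
            }[copies]
            alt = int(noise_rng.binomial(depth, p_alt))
            ss_reads = int(noise_rng.binomial(alt, config.seed_rate)) if alt else 0
            clonal = int(noise_rng.binomial(depth, config.clonal_rate))
            alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[copies]
            calls[sample] = GenotypeCall(
                sample, alleles, depth=depth, alt_reads=alt,
                seed_support=ss_reads, clonal_reads=clonal,
            )
        return calls

    variants: list[VariantRecord] = []
    causal_copies = {i.id: (1 if i.id in carriers else 0) for i in pedigree}
    variants.append(
        VariantRecord(
            chrom=causal_chrom,
            pos=causal_pos,
            ref="G",
            alt="A",
            consequence="missense",
            gene="GENE_CAUSAL",
            popfreqs={config.database_name: (0, config.database_an)},
            inhouse_count=0,
            calls=synth_calls(causal_copies),
        )
    )

    lengths = np.array([c.length_bp for c in config.chromosomes], dtype=float)
    used_positions = {(causal_chrom, causal_pos)}
    for k in range(config.n_background_variants):
        while True:
            idx = int(variant_rng.choice(len(lengths), p=lengths / lengths.sum()))
            chrom = config.chromosomes[idx].label
            pos = int(variant_rng.integers(1, config.chromosomes[idx].length_bp))
            if (chrom, pos) not in used_positions:
                used_positions.add((chrom, pos))
                break
        if variant_rng.random() < config.rare_weight:
            af = float(variant_rng.uniform(*config.rare_af_range))
        else:
            af = float(variant_rng.uniform(*config.common_af_range))
        conseq = str(variant_rng.choice(consequences, p=conseq_p))
        indel_len = int(variant_rng.integers(1, 11)) if conseq == "frameshift_indel" else 0
        ref, alt = ("G", "A") if indel_len == 0 else ("G", "G" + "A" * indel_len)

        copies: dict[str, int] = {}
        for ind_id in order:
            ind = pedigree[ind_id]
            if ind.is_founder:
                copies[ind_id] = int(
                    (variant_rng.random() < af) + (variant_rng.random() < af)
                )
            else:
                inherited = 0
                for parent in pedigree.parents(ind_id):
                    parent_copies = copies[parent]
                    p_transmit = parent_copies / 2.0
                    inherited += int(variant_rng.random() < p_transmit)
                copies[ind_id] = inherited
        ac = int(round(af * config.database_an))
        variants.append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                consequence=conseq,
                indel_length=indel_len,
                gene=f"GENE{k:04d}",
                popfreqs={config.database_name: (ac, config.database_an)},
                inhouse_count=int(variant_rng.binomial(config.inhouse_panel_size, af)),
                calls=synth_calls(copies),
            )
        )

    truth = SimulationTruth(
        causal_chrom=causal_chrom,
        causal_pos=causal_pos,
        causal_ref="G",
        causal_alt="A",
        carriers=sorted(carriers),
        genome_bp=config.genome_bp(),
    )
    return SimulationResult(pedigree, matrix, variants, truth)


# ---------------------------------------------------------------------------
# Decoy construction
# ---------------------------------------------------------------------------

def _clean_calls(
    pedigree: Pedigree,
    het_samples: Sequence[str],
    depth: int = 40,
) -> dict[str, GenotypeCall]:
    calls = {}
    for ind in pedigree:
        if ind.id in het_samples:
            alt = depth // 2
            calls[ind.id] = GenotypeCall(
                ind.id, (0, 1), depth=depth, alt_reads=alt,
                seed_support=max(2, alt // 2), clonal_reads=1,
            )
        else:
            calls[ind.id] = GenotypeCall(
                ind.id, (0, 0), depth=depth, alt_reads=0,
                seed_support=0, clonal_reads=0,
            )
    return calls


def make_decoy_set(
    base_records: Sequence[VariantRecord],
    pedigree: Pedigree,
    regions: Sequence[GenomicInterval],
    config: CascadeConfig = CascadeConfig(),
    n_decoys: int = 20,
) -> list[VariantRecord]:
    """Build >= ``n_decoys`` variants that each violate exactly one cascade
    stage and pass all others.

    Decoys are placed inside the longest supplied region (except the
    region-violation decoys, placed beyond every region on their
    chromosome) at positions distinct from the base records.
    """
    affected = pedigree.affected_sequenced
    unaffected = pedigree.unaffected_sequenced
    if not affected or not unaffected:
        raise DataError("decoy construction needs affected and unaffected members")
    if not regions:
        raise DataError("decoy construction needs at least one region")

    host = max(regions, key=lambda iv: iv.length())
    taken = {(r.chrom, r.pos) for r in base_records}
    cursor = [host.start]

    def next_pos() -> int:
        pos = cursor[0]
        while (host.chrom, pos) in taken:
            pos += 1
        if pos > host.end:
            raise DataError("host region too small to place all decoys")
        taken.add((host.chrom, pos))
        cursor[0] = pos + max(1, host.length() // (4 * n_decoys))
        return pos

    outside_chrom = regions[0].chrom
    outside_pos = max(iv.end for iv in regions if iv.chrom == outside_chrom) + 1
    while any(iv.contains(outside_chrom, outside_pos) for iv in regions):
        outside_pos += 1

    rare = (1, 280_000)
    a0, a1, a2 = (affected + affected)[:3]  # cycle if fewer than 3 affected
    u0 = unaffected[0]

    def base(gene: str, **kwargs) -> VariantRecord:
        fields = dict(
            chrom=host.chrom,
            pos=next_pos(),
            ref="G",
            alt="A",
            consequence="missense",
            gene=gene,
            popfreqs={"GNOMAD": rare},
            inhouse_count=0,
            calls=_clean_calls(pedigree, affected),
        )
        fields.update(kwargs)
        return VariantRecord(**fields)

    def tweak_call(record: VariantRecord, sample: str, **kwargs) -> VariantRecord:
        record.calls[sample] = replace(record.calls[sample], **kwargs)
        return record

    builders = [
        # --- qc ---
        lambda i: tweak_call(
            base(f"DECOY{i:02d}_QC_DEPTH"), a0,
            depth=8, alt_reads=4, seed_support=2, clonal_reads=0,
        ),
        lambda i: tweak_call(
            base(f"DECOY{i:02d}_QC_LOWFRAC"), a0,
            depth=40, alt_reads=4, seed_support=2, clonal_reads=0,
        ),
        lambda i: tweak_call(
            base(f"DECOY{i:02d}_QC_HIGHFRAC"), a0,
            depth=40, alt_reads=36, seed_support=10, clonal_reads=0,
        ),
        lambda i: tweak_call(
            base(f"DECOY{i:02d}_QC_SEEDS"), a1,
            depth=40, alt_reads=20, seed_support=1, clonal_reads=0,
        ),
        lambda i: tweak_call(
            base(f"DECOY{i:02d}_QC_CLONAL"), a1,
            depth=40, alt_reads=20, seed_support=8,
            clonal_reads=config.max_clonal_reads + 4,
        ),
        # --- variant_class ---
        lambda i: base(f"DECOY{i:02d}_CLASS_CONSEQ", consequence="other"),
        lambda i: base(
            f"DECOY{i:02d}_CLASS_INDEL",
            consequence="frameshift_indel",
            indel_length=config.max_indel_nt + 5,
            alt="G" + "A" * (config.max_indel_nt + 5),
        ),
        lambda i: base(
            f"DECOY{i:02d}_CLASS_INHOUSE", inhouse_count=config.max_inhouse + 1
        ),
        # --- absent_in_unaffected ---
        lambda i: tweak_call(
            base(f"DECOY{i:02d}_COSEG_UNAFF"), u0,
            alleles=(0, 1), depth=40, alt_reads=20, seed_support=10, clonal_reads=1,
        ),
        # --- present_in_affected ---
        lambda i: tweak_call(
            base(f"DECOY{i:02d}_COSEG_MISSING"), a2,
            alleles=None, depth=0, alt_reads=0, seed_support=0, clonal_reads=0,
        ),
        lambda i: tweak_call(
            base(f"DECOY{i:02d}_COSEG_HOMALT"), a2,
            alleles=(1, 1), depth=40, alt_reads=31, seed_support=10, clonal_reads=1,
        ),
        lambda i: tweak_call(
            base(f"DECOY{i:02d}_COSEG_HOMREF"), a0,
            alleles=(0, 0), depth=40, alt_reads=0, seed_support=0, clonal_reads=0,
        ),
        # --- population_frequency ---
        lambda i: base(
            f"DECOY{i:02d}_POPFREQ", popfreqs={"GNOMAD": (2800, 280_000)}
        ),
        lambda i: base(
            f"DECOY{i:02d}_POPFREQ_EDGE",
            popfreqs={"GNOMAD": (560, 280_000)},  # exactly the threshold
        ),
        # --- linked_region ---
        lambda i: base(
            f"DECOY{i:02d}_REGION", chrom=outside_chrom, pos=outside_pos + i
        ),
    ]

    decoys = []
    i = 0
    while len(decoys) < n_decoys:
        decoys.append(builders[i % len(builders)](i))
        i += 1
    return decoys
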