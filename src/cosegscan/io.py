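"""Readers and writers for the formats the pipeline touches.

Formats
-------
* PED/FAM six-column pedigree files (optional seventh column: sequenced 0/1).
* VCF 4.2 via pysam, with a small dialect extension: per-sample FORMAT
  fields ``SS`` (read-seed support) and ``CL`` (clonal reads), and INFO keys
  ``CONSEQ``, ``GENE``, ``AC_<DB>``/``AN_<DB>``, ``INHOUSE`` and the
  prediction keys ``PPH_S/PPH_C/SIFT_S/SIFT_C/COND_NT/COND_AA``.  Standard
  callers do not emit SS/CL, so the synthetic generator produces them.
* Region lists in two dialects: ``bed`` (0-based half-open) and
  ``table1_tsv`` (1-based inclusive with a Length = end - start column,
  reproducing the published linked-region table's formatting).

Packaged fixtures (transcribed from the published tables, GRCh37/hg19):
``table1_regions.tsv`` (19 linked regions), ``table2_variants.vcf``
(11 candidate variants with per-member genotypes), ``fig1_family.ped``
(the six-member, three-generation family), ``table3_annotations.tsv``
(damage predictions and per-database frequencies).
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Optional, Sequence, Union

import pysam

from .model import (
    DataError,
    GenomicInterval,
    GenotypeCall,
    PredictionAnnotation,
    VariantRecord,
)
from .pedigree import Individual, Pedigree, PedigreeError

PathLike = Union[str, Path]

_PHENOTYPE_CODES = {"1": "unaffected", "2": "affected", "0": "unknown", "-9": "unknown"}
_SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}

#: hg19 q-terminus of chromosome 8; used by :func:`load_linked_regions`.
_CHR8_HG19_END = 146_364_022

_PREDICTION_KEYS = ("PPH_S", "PPH_C", "SIFT_S", "SIFT_C", "COND_NT", "COND_AA")


class VcfParseError(DataError):
    pass


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

def read_ped(path: PathLike) -> Pedigree:
    """Read a whitespace-delimited PED/FAM file into a Pedigree.

    Columns: family, individual, father, mother, sex (1=male, 2=female,
    0=unknown), phenotype (1=unaffected, 2=affected, 0/-9=unknown); an
    optional seventh column flags sequenced status (1/0, default 1).
    A ``0`` parent code marks a founder.
    """
    individuals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise PedigreeError(f"{path}:{lineno}: expected >= 6 columns")
            _, ind_id, father, mother, sex, pheno = fields[:6]
            if pheno not in _PHENOTYPE_CODES:
                raise PedigreeError(
                    f"{path}:{lineno}: phenotype code {pheno!r} not in "
                    f"{sorted(_PHENOTYPE_CODES)}"
                )
            if sex not in _SEX_CODES:
                raise PedigreeError(f"{path}:{lineno}: sex code {sex!r}")
            sequenced = True
            if len(fields) >= 7:
                sequenced = fields[6] not in ("0",)
            if father == ind_id or mother == ind_id:
                raise PedigreeError(f"{path}:{lineno}: {ind_id} is its own parent")
            individuals.append(
                Individual(
                    id=ind_id,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex=_SEX_CODES[sex],
                    affection=_PHENOTYPE_CODES[pheno],
                    sequenced=sequenced,
                )
            )
    if not individuals:
        raise PedigreeError(f"{path}: empty pedigree file")
    return Pedigree(individuals)


def write_ped(pedigree: Pedigree, path: PathLike, family_id: str = "FAM1") -> None:
    sex_out = {"male": "1", "female": "2", "unknown": "0"}
    pheno_out = {"unaffected": "1", "affected": "2", "unknown": "0"}
    with open(path, "w") as fh:
        for ind in pedigree:
            fh.write(
                "\t".join(
                    [
                        family_id,
                        ind.id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        sex_out[ind.sex],
                        pheno_out[ind.affection],
                        "1" if ind.sequenced else "0",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

def write_regions(
    intervals: Sequence[GenomicInterval], path: PathLike, dialect: str = "bed"
) -> None:
    """Write intervals as ``bed`` (0-based half-open) or ``table1_tsv``
    (1-based inclusive, with a Length = end - start column)."""
    if dialect == "bed":
        with open(path, "w") as fh:
            for iv in intervals:
                name = iv.label or "."
                fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\n")
    elif dialect == "table1_tsv":
        with open(path, "w") as fh:
            fh.write("Chr\tLocus\tStart\tEnd\tLength\n")
            for iv in intervals:
                fh.write(
                    f"{iv.chrom}\t{iv.label or '.'}\t{iv.start}\t{iv.end}"
                    f"\t{iv.length()}\n"
                )
    else:
        raise DataError(f"unknown region dialect {dialect!r}")


def read_regions(path: PathLike, dialect: str = "bed") -> list[GenomicInterval]:
    intervals = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if dialect == "bed":
        for ln in lines:
            fields = ln.split("\t")
            chrom, start0, end = fields[0], int(fields[1]), int(fields[2])
            label = fields[3] if len(fields) > 3 and fields[3] != "." else None
            intervals.append(GenomicInterval(chrom, start0 + 1, end, label))
    elif dialect == "table1_tsv":
        header = lines[0].split("\t")
        if header[:2] != ["Chr", "Locus"]:
            raise DataError(f"{path}: not a table1_tsv file (header {header})")
        for ln in lines[1:]:
            chrom, locus, start, end, length = ln.split("\t")
            iv = GenomicInterval(chrom, int(start), int(end), locus)
            if iv.length() != int(length):
                raise DataError(
                    f"{path}: Length column {length} != end - start "
                    f"{iv.length()} for {chrom}:{start}-{end}"
                )
            intervals.append(iv)
    else:
        raise DataError(f"unknown region dialect {dialect!r}")
    return intervals


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _info_scalar(info, key, idx=None):
    if key not in info:
        return None
    value = info[key]
    if isinstance(value, tuple):
        value = value[idx if idx is not None else 0]
    return value


def read_vcf(path: PathLike, pedigree: Optional[Pedigree] = None) -> list[VariantRecord]:
    """Read a VCF into VariantRecords, one per ALT allele.

    Multi-allelic sites are decomposed; in a decomposed record, allele
    index 1 means "this alt" and any other alt of the original site maps to
    0.  Missing annotations stay missing (``None`` / absent database), never
    defaults.  If a pedigree is given, every VCF sample must appear in it.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"{path}: {exc}") from exc
    samples = list(vf.header.samples)
    if pedigree is not None:
        unmatched = [s for s in samples if s not in pedigree.individuals]
        if unmatched:
            raise VcfParseError(
                f"{path}: samples absent from pedigree: {', '.join(unmatched)}"
            )

    records: list[VariantRecord] = []
    for rec in vf:
        alts = rec.alts or ()
        for alt_idx, alt in enumerate(alts):
            info = rec.info
            popfreqs = {}
            for key in info.keys():
                if key.startswith("AC_"):
                    db = key[3:]
                    an = _info_scalar(info, f"AN_{db}")
                    ac = _info_scalar(info, key, alt_idx)
                    if ac is not None and an is not None:
                        popfreqs[db] = (int(ac), int(an))
            conseq = _info_scalar(info, "CONSEQ", alt_idx)
            inhouse = _info_scalar(info, "INHOUSE", alt_idx)
            indel_len = abs(len(alt) - len(rec.ref)) if rec.ref and alt else 0
            pred_values = [_info_scalar(info, k) for k in _PREDICTION_KEYS]
            predictions = None
            if any(v is not None for v in pred_values):
                pph_s, pph_c, sift_s, sift_c, cond_nt, cond_aa = pred_values
                predictions = PredictionAnnotation(
                    polyphen_score=None if pph_s is None else float(pph_s),
                    polyphen_class=None if pph_c is None else pph_c.replace("_", " "),
                    sift_score=None if sift_s is None else float(sift_s),
                    sift_class=sift_c,
                    conservation_nt=cond_nt,
                    conservation_aa=cond_aa,
                )
            calls = {}
            for sample in samples:
                sc = rec.samples[sample]
                gt = sc.get("GT")
                if gt is None or all(a is None for a in gt):
                    alleles = None
                else:
                    # original index alt_idx+1 -> 1; all other alleles -> 0
                    alleles = tuple(
                        1 if a == alt_idx + 1 else 0 for a in gt if a is not None
                    )
                    if len(alleles) == 1:
                        alleles = (alleles[0], alleles[0])
                depth = sc.get("DP")
                ad = sc.get("AD")
                alt_reads = None
                if ad is not None and len(ad) > alt_idx + 1:
                    alt_reads = ad[alt_idx + 1]
                calls[sample] = GenotypeCall(
                    sample_id=sample,
                    alleles=alleles,
                    depth=int(depth) if depth is not None else 0,
                    alt_reads=int(alt_reads) if alt_reads is not None else 0,
                    seed_support=int(sc.get("SS") or 0),
                    clonal_reads=int(sc.get("CL") or 0),
                )
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    consequence=conseq,
                    indel_length=indel_len,
                    gene=_info_scalar(info, "GENE"),
                    popfreqs=popfreqs,
                    inhouse_count=None if inhouse is None else int(inhouse),
                    predictions=predictions,
                    calls=calls,
                    confirmed=(
                        None
                        if "CONFIRMED" not in info
                        else bool(int(_info_scalar(info, "CONFIRMED")))
                    ),
                )
            )
    return records


def _vcf_header(records: Sequence[VariantRecord], samples: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    header.add_line("##reference=GRCh37/hg19")
    contigs = []
    for rec in records:
        if rec.chrom not in contigs:
            contigs.append(rec.chrom)
    for chrom in contigs:
        header.add_line(f"##contig=<ID={chrom}>")
    header.add_line(
        '##INFO=<ID=CONSEQ,Number=A,Type=String,Description="Consequence class">'
    )
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
    header.add_line(
        '##INFO=<ID=INHOUSE,Number=A,Type=Integer,Description="In-house database count">'
    )
    header.add_line(
        '##INFO=<ID=CONFIRMED,Number=1,Type=Integer,Description="Orthogonal confirmation (1/0)">'
    )
    dbs = sorted({db for rec in records for db in rec.popfreqs})
    for db in dbs:
        header.add_line(
            f'##INFO=<ID=AC_{db},Number=A,Type=Integer,Description="Allele count in {db}">'
        )
        header.add_line(
            f'##INFO=<ID=AN_{db},Number=1,Type=Integer,Description="Allele number in {db}">'
        )
    header.add_line('##INFO=<ID=PPH_S,Number=1,Type=Float,Description="PolyPhen score">')
    header.add_line('##INFO=<ID=PPH_C,Number=1,Type=String,Description="PolyPhen class">')
    header.add_line('##INFO=<ID=SIFT_S,Number=1,Type=Float,Description="SIFT score">')
    header.add_line('##INFO=<ID=SIFT_C,Number=1,Type=String,Description="SIFT class">')
    header.add_line(
        '##INFO=<ID=COND_NT,Number=1,Type=String,Description="Nucleotide conservation">'
    )
    header.add_line(
        '##INFO=<ID=COND_AA,Number=1,Type=String,Description="Amino-acid conservation">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
    )
    header.add_line(
        '##FORMAT=<ID=SS,Number=1,Type=Integer,Description="Read-seed support">'
    )
    header.add_line(
        '##FORMAT=<ID=CL,Number=1,Type=Integer,Description="Clonal (duplicate) reads">'
    )
    for s in samples:
        header.add_sample(s)
    return header


def write_vcf(
    records: Sequence[VariantRecord],
    path: PathLike,
    samples: Optional[Sequence[str]] = None,
) -> None:
    """Write decomposed VariantRecords to an uncompressed VCF."""
    if samples is None:
        seen: list[str] = []
        for rec in records:
            for s in rec.calls:
                if s not in seen:
                    seen.append(s)
        samples = seen
    header = _vcf_header(records, samples)
    ordered = sorted(records, key=lambda r: (r.chrom, r.pos, r.alt))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in ordered:
            vr = out.new_record(
                contig=rec.chrom, start=rec.pos - 1, alleles=(rec.ref, rec.alt)
            )
            if rec.consequence is not None:
                vr.info["CONSEQ"] = (rec.consequence,)
            if rec.gene is not None:
                vr.info["GENE"] = rec.gene
            if rec.inhouse_count is not None:
                vr.info["INHOUSE"] = (rec.inhouse_count,)
            if rec.confirmed is not None:
                vr.info["CONFIRMED"] = int(rec.confirmed)
            for db, (ac, an) in rec.popfreqs.items():
                vr.info[f"AC_{db}"] = (ac,)
                vr.info[f"AN_{db}"] = an
            pred = rec.predictions
            if pred is not None:
                if pred.polyphen_score is not None:
                    vr.info["PPH_S"] = pred.polyphen_score
                if pred.polyphen_class is not None:
                    vr.info["PPH_C"] = pred.polyphen_class.replace(" ", "_")
                if pred.sift_score is not None:
                    vr.info["SIFT_S"] = pred.sift_score
                if pred.sift_class is not None:
                    vr.info["SIFT_C"] = pred.sift_class
                if pred.conservation_nt is not None:
                    vr.info["COND_NT"] = pred.conservation_nt
                if pred.conservation_aa is not None:
                    vr.info["COND_AA"] = pred.conservation_aa
            for sample in samples:
                call = rec.calls.get(sample)
                sc = vr.samples[sample]
                if call is None or call.alleles is None:
                    sc["GT"] = (None, None)
                else:
                    sc["GT"] = call.alleles
                if call is not None:
                    sc["DP"] = call.depth
                    sc["AD"] = (call.depth - call.alt_reads, call.alt_reads)
                    sc["SS"] = call.seed_support
                    sc["CL"] = call.clonal_reads
            out.write(vr)


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("cosegscan.data") / name)


def load_table1_regions() -> list[GenomicInterval]:
    """The 19 published linked regions, transcribed verbatim (hg19)."""
    return read_regions(_data_path("table1_regions.tsv"), dialect="table1_tsv")


def load_linked_regions() -> list[GenomicInterval]:
    """The linked regions as used for variant filtering.

    Identical to :func:`load_table1_regions` except that the terminal-band
    8q24 region's distal end is extended to the hg19 chromosome 8 terminus.
    The printed boundaries are inner boundaries (positions of the outermost
    compatible markers), and the published candidate set itself contains a
    retained variant distal to the printed 8q24 end, so for membership
    testing the terminal region runs to the chromosome end.
    """
    out = []
    for iv in load_table1_regions():
        if iv.chrom == "8" and iv.end == 143270729:
            iv = GenomicInterval(iv.chrom, iv.start, _CHR8_HG19_END, iv.label)
        out.append(iv)
    return out


def load_family_pedigree() -> Pedigree:
    """The six-member, three-generation family: 3 affected, 3 unaffected."""
    return read_ped(_data_path("fig1_family.ped"))


def load_candidate_vcf() -> list[VariantRecord]:
    """The 11 published candidate variants with per-member genotypes."""
    return read_vcf(_data_path("table2_variants.vcf"), load_family_pedigree())


def load_candidate_annotations() -> dict[str, PredictionAnnotation]:
    """Damage predictions for the candidate genes, keyed by gene symbol."""
    from .report import read_annotations

    return read_annotations(_data_path("table3_annotations.tsv"))
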