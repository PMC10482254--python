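"""Pedigree structure and dominant-inheritance consistency checking.

The package analyses a single nuclear-or-extended family segregating an
autosomal dominant trait.  The pedigree defines the affected and unaffected
sequenced member sets that every downstream filter conditions on.

Complete penetrance is assumed (carrier <=> affected); individuals of
unknown affection are excluded from both filter sets rather than treated as
unaffected, because an unphenotyped member constrains nothing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional

from .model import DataError

AFFECTIONS = ("affected", "unaffected", "unknown")
SEXES = ("male", "female", "unknown")


class PedigreeError(DataError):
    """Raised for structurally invalid pedigrees."""


@dataclass
class Individual:
    id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: str = "unknown"
    affection: str = "unknown"
    sequenced: bool = True

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise PedigreeError(f"{self.id}: unknown sex code {self.sex!r}")
        if self.affection not in AFFECTIONS:
            raise PedigreeError(f"{self.id}: unknown affection {self.affection!r}")

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


class Pedigree:
    """A set of individuals with parentage and affection status."""

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self.individuals:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self.individuals[ind.id] = ind
        if not self.individuals:
            raise PedigreeError("empty pedigree")

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals.values())

    def __getitem__(self, ind_id: str) -> Individual:
        return self.individuals[ind_id]

    @property
    def affected_sequenced(self) -> list[str]:
        return [
            i.id for i in self.individuals.values()
            if i.sequenced and i.affection == "affected"
        ]

    @property
    def unaffected_sequenced(self) -> list[str]:
        return [
            i.id for i in self.individuals.values()
            if i.sequenced and i.affection == "unaffected"
        ]

    def parents(self, ind_id: str) -> list[str]:
        ind = self.individuals[ind_id]
        return [p for p in (ind.father_id, ind.mother_id) if p is not None]

    def founders(self) -> list[str]:
        return [i.id for i in self.individuals.values() if i.is_founder]


def validate_pedigree(pedigree: Pedigree) -> list[str]:
    """Return a list of violations; an empty list means the pedigree is valid.

    Checks: parent references resolve, the parentage graph is acyclic,
    parental sexes are consistent with their role, parents come in pairs,
    and the cosegregation filters' precondition (>= 1 affected and >= 1
    unaffected sequenced member) holds.
    """
    report: list[str] = []
    for ind in pedigree:
        if (ind.father_id is None) != (ind.mother_id is None):
            report.append(f"{ind.id}: only one parent specified")
        for role, pid, wrong_sex in (
            ("father", ind.father_id, "female"),
            ("mother", ind.mother_id, "male"),
        ):
            if pid is None:
                continue
            if pid not in pedigree.individuals:
                report.append(f"{ind.id}: {role} {pid!r} not in pedigree")
            elif pedigree[pid].sex == wrong_sex:
                report.append(f"{ind.id}: {role} {pid} has sex {wrong_sex}")

    # cycle detection over the "child -> parent" graph
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {i: WHITE for i in pedigree.individuals}

    def visit(node: str) -> bool:
        colour[node] = GREY
        for parent in pedigree.parents(node):
            if parent not in colour:
                continue
            if colour[parent] == GREY:
                return True
            if colour[parent] == WHITE and visit(parent):
                return True
        colour[node] = BLACK
        return False

    for node in list(colour):
        if colour[node] == WHITE and visit(node):
            report.append(f"parentage cycle involving {node}")

    if not pedigree.affected_sequenced:
        report.append("no affected sequenced members")
    if not pedigree.unaffected_sequenced:
        report.append("no unaffected sequenced members")
    return report


def dominant_consistency(pedigree: Pedigree) -> str:
    """Classify the affection pattern under a fully penetrant dominant model.

    Assumes carrier <=> affected for every individual of known affection;
    an unknown-affection individual's carrier state is unconstrained, so the
    search below tries both states for each.

    Returns ``"consistent"`` if some carrier assignment transmits the allele
    from parent to child with no de novo event, ``"de_novo_required"`` if
    every assignment needs at least one carrier without a carrier parent
    (founders excepted), and ``"inconsistent"`` if no assignment exists at
    all.
    """
    if not any(i.affection == "affected" for i in pedigree):
        raise PedigreeError("dominant_consistency needs at least one affected member")

    ids = sorted(pedigree.individuals)
    unknown = [i for i in ids if pedigree[i].affection == "unknown"]
    fixed = {
        i: pedigree[i].affection == "affected"
        for i in ids
        if pedigree[i].affection != "unknown"
    }

    best: Optional[int] = None
    for bits in itertools.product((False, True), repeat=len(unknown)):
        carrier = dict(fixed)
        carrier.update(zip(unknown, bits))
        de_novo = 0
        for i in ids:
            if not carrier[i]:
                continue
            parents = [p for p in pedigree.parents(i) if p in carrier]
            if not parents:
                continue  # founder (or parents outside pedigree): may carry freely
            if not any(carrier[p] for p in parents):
                de_novo += 1
        if best is None or de_novo < best:
            best = de_novo
        if best == 0:
            break

    if best is None:
        return "inconsistent"
    return "consistent" if best == 0 else "de_novo_required"
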