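"""Candidate prioritization: damage-prediction concordance, developmental
expression-window flagging, and the final report table.

The damage tier summarises agreement between two prediction tools
(PolyPhen-style three-class and SIFT-style two-class):
``concordant_damaging`` when both point at damage, ``concordant_benign``
when both point away, ``discordant`` otherwise, ``undefined`` when either
class is missing (e.g. splice-site variants have no protein-level
prediction).

The expression flag formalises "elevated expression during a developmental
age window" as a z-score contrast: expression values are log2-transformed
(with a pseudocount), z-scored per gene across samples, and the gene is
flagged when the mean z inside the window exceeds the mean z outside by
more than a threshold.  This is one formalization of a qualitative
criterion and the report labels it as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .model import (
    DataError,
    FilterTrace,
    PredictionAnnotation,
    VariantRecord,
)

PathLike = Union[str, Path]

TIERS = ("concordant_damaging", "discordant", "concordant_benign", "undefined")


def damage_tier(annotation: PredictionAnnotation) -> str:
    """Concordance tier of the two damage predictions.

    ``concordant_damaging`` iff PolyPhen class is not benign AND SIFT class
    is deleterious; ``concordant_benign`` iff benign AND tolerated;
    ``undefined`` iff either class is undefined; else ``discordant``.
    """
    pph, sift = annotation.polyphen_class, annotation.sift_class
    if pph is None or sift is None:
        return "undefined"
    if pph != "benign" and sift == "deleterious":
        return "concordant_damaging"
    if pph == "benign" and sift == "tolerated":
        return "concordant_benign"
    return "discordant"


def read_annotations(path: PathLike) -> dict[str, PredictionAnnotation]:
    """Read a gene-keyed annotation TSV (scores, classes, conservation).

    The literal ``undef`` (or an empty cell) means the field is undefined.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("undef")

    def parse(value: str, as_float: bool = False):
        if value in ("undef", "", "na"):
            return None
        return float(value) if as_float else value

    annotations = {}
    for _, row in df.iterrows():
        annotations[row["gene"]] = PredictionAnnotation(
            polyphen_score=parse(row.get("polyphen_score", "undef"), as_float=True),
            polyphen_class=parse(row.get("polyphen_class", "undef")),
            sift_score=parse(row.get("sift_score", "undef"), as_float=True),
            sift_class=parse(row.get("sift_class", "undef")),
            conservation_nt=parse(row.get("conservation_nt", "undef")),
            conservation_aa=parse(row.get("conservation_aa", "undef")),
        )
    return annotations


class ExpressionMatrix:
    """Gene-by-sample expression values with a per-sample age (years)."""

    def __init__(self, values: pd.DataFrame, ages: pd.Series):
        if not values.columns.equals(ages.index):
            raise DataError("expression columns and age index differ")
        if (ages < 0).any():
            raise DataError("ages must be >= 0")
        if (values.values < 0).any():
            raise DataError("expression values must be non-negative")
        self.values = values
        self.ages = ages.astype(float)

    @classmethod
    def from_tsv(cls, path: PathLike) -> "ExpressionMatrix":
        """Read a TSV whose first column is ``gene``; the row with gene
        ``age`` carries per-sample ages in years."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        if "age" not in df.index:
            raise DataError(f"{path}: no 'age' row")
        ages = df.loc["age"]
        values = df.drop(index="age")
        return cls(values, ages)

    def to_tsv(self, path: PathLike) -> None:
        out = pd.concat([self.ages.to_frame("age").T, self.values])
        out.index.name = "gene"
        out.to_csv(path, sep="\t")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


@dataclass
class WindowFlag:
    flag: bool
    contrast: float
    summary: str


def developmental_window_flag(
    matrix: ExpressionMatrix,
    gene: str,
    window_years: Tuple[float, float] = (0.1, 2.4),
    z_threshold: float = 1.0,
    pseudocount: float = 1.0,
) -> WindowFlag:
    """Flag a gene whose expression is elevated inside an age window.

    Values are log2(x + pseudocount)-transformed and z-scored per gene
    across samples; the flag is raised iff mean z inside the window minus
    mean z outside exceeds ``z_threshold``.  A zero-variance gene is never
    flagged (summary ``"constant"``).
    """
    if gene not in matrix.values.index:
        raise DataError(f"gene {gene!r} not in expression matrix")
    lo, hi = window_years
    inside = (matrix.ages >= lo) & (matrix.ages <= hi)
    if inside.sum() < 2 or (~inside).sum() < 2:
        raise DataError("window needs >= 2 samples inside and outside")

    x = np.log2(matrix.values.loc[gene].to_numpy(dtype=float) + pseudocount)
    sd = x.std()
    if sd <= 1e-12 * max(1.0, abs(float(x.mean()))):  # zero-variance gene
        return WindowFlag(False, 0.0, "constant")
    z = (x - x.mean()) / sd
    contrast = float(z[inside.to_numpy()].mean() - z[~inside.to_numpy()].mean())
    summary = (
        f"mean z inside {lo}-{hi}y minus outside = {contrast:.2f} "
        f"(threshold {z_threshold})"
    )
    return WindowFlag(contrast > z_threshold, contrast, summary)


REPORT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "popfreqs",
    "inhouse_count",
    "damage_tier",
    "expression_flag",
    "trace",
]


def write_report(
    survivors: Sequence[VariantRecord],
    annotations: Mapping[str, PredictionAnnotation],
    expression_flags: Mapping[str, WindowFlag],
    path: PathLike,
    trace: Optional[FilterTrace] = None,
) -> pd.DataFrame:
    """Write the final candidate table (one row per surviving variant).

    ``annotations`` and ``expression_flags`` are keyed by gene symbol;
    keys that match no survivor raise an error listing the orphans.
    Returns the frame that was written.
    """
    genes = {rec.gene for rec in survivors if rec.gene is not None}
    orphans = sorted(set(annotations) - genes) + sorted(
        set(expression_flags) - genes
    )
    if orphans:
        raise DataError(f"annotation keys match no survivor: {', '.join(orphans)}")

    rows = []
    for rec in sorted(survivors, key=lambda r: r.key):
        annotation = annotations.get(rec.gene) if rec.gene else None
        if annotation is None:
            annotation = rec.predictions
        flag = expression_flags.get(rec.gene) if rec.gene else None
        freq_text = ";".join(
            f"{db}:{ac}/{an}" for db, (ac, an) in sorted(rec.popfreqs.items())
        )
        stage_text = ""
        if trace is not None:
            outcomes = trace.outcomes.get(rec.key, [])
            stage_text = ",".join(o.stage for o in outcomes if o.passed)
        rows.append(
            {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alt,
                "gene": rec.gene or ".",
                "consequence": rec.consequence or ".",
                "popfreqs": freq_text or ".",
                "inhouse_count": "." if rec.inhouse_count is None else rec.inhouse_count,
                "damage_tier": damage_tier(annotation) if annotation else "undefined",
                "expression_flag": "." if flag is None else str(flag.flag),
                "trace": stage_text or ".",
            }
        )
    frame = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)
    return frame
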