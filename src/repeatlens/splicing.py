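"""Classification of exon4-exon5 reads into four splicing events.

The intron-4 region of *TERT* produces four read-level events: canonical
splicing (a junction skipping the whole intron), INS1 (splicing from 38 bp
inside the intron, i.e. a 38-bp extension of exon 4), INS1b (splicing from
480 bp inside the intron), and unspliced intron retention (a contiguous
alignment crossing the exon/intron boundary by at least 20 bp).  Reads
extending 1-19 bp past the boundary, or with any other junction geometry,
are excluded from all denominators.

Per-sample event fractions use canonical + INS1 + INS1b + unspliced reads
as the denominator; the retention fraction is the non-canonical share of
that denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import MATCH, SKIP, AlignmentRecord


class SpliceEvent(str, Enum):
    CANONICAL = "CANONICAL"
    INS1 = "INS1"
    INS1B = "INS1B"
    UNSPLICED = "UNSPLICED"
    EXCLUDED = "EXCLUDED"


#: events entering the fraction denominator, in reporting order
DENOMINATOR_EVENTS = (
    SpliceEvent.CANONICAL,
    SpliceEvent.INS1,
    SpliceEvent.INS1B,
    SpliceEvent.UNSPLICED,
)


@dataclass(frozen=True)
class GeneModel:
    """Exon4-intron4-exon5 intervals (half-open, contiguous) and constants."""

    contig: str
    exon4: tuple[int, int]
    intron4: tuple[int, int]
    exon5: tuple[int, int]
    ins1_offset: int = 38
    ins1b_offset: int = 480
    min_extension: int = 20

    def __post_init__(self) -> None:
        if not (self.exon4[1] == self.intron4[0] and self.intron4[1] == self.exon5[0]):
            raise ValueError("intervals must abut in order exon4-intron4-exon5")
        if self.intron4[1] - self.intron4[0] < self.ins1b_offset:
            raise ValueError("intron4 shorter than the INS1b offset")

    def to_dict(self) -> dict:
        return {
            "contig": self.contig,
            "exon4": list(self.exon4),
            "intron4": list(self.intron4),
            "exon5": list(self.exon5),
            "ins1_offset": self.ins1_offset,
            "ins1b_offset": self.ins1b_offset,
            "min_extension": self.min_extension,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneModel":
        return cls(
            d["contig"],
            tuple(d["exon4"]),
            tuple(d["intron4"]),
            tuple(d["exon5"]),
            d.get("ins1_offset", 38),
            d.get("ins1b_offset", 480),
            d.get("min_extension", 20),
        )


def default_gene_model() -> GeneModel:
    """Synthetic gene model with the true offset constants (38/480/20 bp)."""
    return GeneModel("TERTsim", exon4=(200, 400), intron4=(400, 1700), exon5=(1700, 1900))


@dataclass
class SpliceEventCounts:
    """Per-sample event counts with fractions over the defined denominator."""

    canonical: int = 0
    ins1: int = 0
    ins1b: int = 0
    unspliced: int = 0
    excluded: int = 0

    @property
    def denominator(self) -> int:
        return self.canonical + self.ins1 + self.ins1b + self.unspliced

    def fractions(self) -> dict:
        """Fractions of the four in-denominator events; NaN if denominator 0."""
        d = self.denominator
        if d == 0:
            return {e.value: float("nan") for e in DENOMINATOR_EVENTS}
        return {
            SpliceEvent.CANONICAL.value: self.canonical / d,
            SpliceEvent.INS1.value: self.ins1 / d,
            SpliceEvent.INS1B.value: self.ins1b / d,
            SpliceEvent.UNSPLICED.value: self.unspliced / d,
        }


def classify_read(rec: AlignmentRecord, gm: GeneModel) -> SpliceEvent:
    """Assign one aligned read to a splice-event class.

    CANONICAL: a SKIP block spanning exactly the intron.
    INS1 / INS1B: a SKIP block from intron_start + 38 (resp. + 480) to the
    intron end.
    UNSPLICED: a MATCH block crossing the exon4/intron4 boundary and
    extending at least ``min_extension`` bases into the intron, with no
    SKIP block inside the intron.
    Everything else (including 1-19 bp extensions) is EXCLUDED.
    """
    i_start, i_end = gm.intron4
    if rec.contig != gm.contig or rec.ref_end <= gm.exon4[0] or rec.pos >= gm.exon5[1]:
        return SpliceEvent.EXCLUDED
    has_intron_skip = False
    for op, s, e in rec.segments():
        if op == SKIP:
            if (s, e) == (i_start, i_end):
                return SpliceEvent.CANONICAL
            if e == i_end and s == i_start + gm.ins1_offset:
                return SpliceEvent.INS1
            if e == i_end and s == i_start + gm.ins1b_offset:
                return SpliceEvent.INS1B
            if s < i_end and e > i_start:
                has_intron_skip = True
    if not has_intron_skip:
        for op, s, e in rec.segments():
            if op == MATCH and s < i_start and e > i_start:
                if e - i_start >= gm.min_extension:
                    return SpliceEvent.UNSPLICED
                return SpliceEvent.EXCLUDED
    return SpliceEvent.EXCLUDED


def count_events(records, gm: GeneModel) -> SpliceEventCounts:
    """Classify one sample's reads and tally event counts."""
    counts = SpliceEventCounts()
    for rec in records:
        event = classify_read(rec, gm)
        if event is SpliceEvent.CANONICAL:
            counts.canonical += 1
        elif event is SpliceEvent.INS1:
            counts.ins1 += 1
        elif event is SpliceEvent.INS1B:
            counts.ins1b += 1
        elif event is SpliceEvent.UNSPLICED:
            counts.unspliced += 1
        else:
            counts.excluded += 1
    return counts


def retention_fraction(counts: SpliceEventCounts) -> float:
    """Share of intron-retaining reads: (INS1 + INS1b + unspliced) / denom."""
    d = counts.denominator
    if d == 0:
        raise ValueError("denominator is 0; retention fraction undefined")
    return (counts.ins1 + counts.ins1b + counts.unspliced) / d


def genotype_trend(fractions, dosages, covariates: pd.DataFrame | None = None):
    """OLS of per-sample event fractions on genotype dosage (0/1/2).

    Covariate columns that are constant are dropped with a warning; the
    returned tuple is (beta, se, two-sided Wald p) for the dosage term.
    """
    y = np.asarray(fractions, dtype=float)
    d = np.asarray(dosages, dtype=float)
    if y.shape[0] != d.shape[0] or y.shape[0] < 3:
        raise ValueError("need >= 3 samples with matching dosages")
    X = pd.DataFrame({"dosage": d})
    if covariates is not None:
        for col in covariates.columns:
            v = np.asarray(covariates[col], dtype=float)
            if np.ptp(v) == 0:
                import logging

                logging.getLogger("repeatlens").warning(
                    "dropping constant covariate %r", col
                )
                continue
            X[col] = v
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("collinear covariates in trend model")
    fit = sm.OLS(y, X).fit()
    return float(fit.params["dosage"]), float(fit.bse["dosage"]), float(fit.pvalues["dosage"])
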