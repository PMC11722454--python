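"""Readers and writers for the light-weight text formats the pipeline touches.

All internal coordinates are 0-based, half-open.  Conversions to the 1-based
conventions of SAM/VCF happen only at the format boundary, in this module.

The formats handled here are deliberately restricted subsets:

* FASTA — full support via Biopython.
* bedGraph — 4-column ``contig start end depth`` with sorted, non-overlapping
  intervals; expanded to a per-base :class:`DepthTrack` on read.
* minimal SAM — header optional; only the ``M``/``N``/``S`` CIGAR operations
  are understood (soft clips are dropped from the reference-span blocks).
* VCF-lite — plain-text VCF with a GT FORMAT field; only biallelic rows are
  kept, multi-allelic rows are skipped with a warning.

Every reader/writer pair is a lossless round trip on its supported subset.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("repeatlens")

MATCH = "M"
SKIP = "N"

#: sentinel for a missing allele call in a genotype table
MISSING = -1

_VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates the supported format subset."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over the alphabet ``{A, C, G, T, N}``."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"empty sequence for record {self.id!r}")
        bad = set(self.seq) - _VALID_BASES
        if bad:
            raise FormatError(
                f"record {self.id!r} contains non-DNA characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class DepthTrack:
    """Per-base read depth over ``[start, start + len(depths))`` on ``contig``."""

    contig: str
    start: int
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if self.depths.ndim != 1 or self.depths.size < 1:
            raise ValueError("depths must be a non-empty 1-D vector")
        if np.any(self.depths < 0):
            raise ValueError("depths must be non-negative")

    @property
    def end(self) -> int:
        return self.start + self.depths.size

    def slice(self, start: int, end: int) -> np.ndarray:
        """Per-base depths over the half-open sub-interval ``[start, end)``."""
        if start < self.start or end > self.end or end <= start:
            raise ValueError(
                f"query [{start}, {end}) outside track [{self.start}, {self.end})"
            )
        return self.depths[start - self.start : end - self.start]


@dataclass(frozen=True)
class AlignmentRecord:
    """A spliced alignment as an ordered run of MATCH/SKIP reference blocks.

    ``pos`` is the 0-based leftmost aligned reference position.  The first and
    last block must be MATCH and no two adjacent blocks share an operation, so
    the block structure is canonical.
    """

    read_id: str
    contig: str
    pos: int
    blocks: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("alignment must have at least one block")
        ops = [op for op, _ in self.blocks]
        if ops[0] != MATCH or ops[-1] != MATCH:
            raise ValueError("first and last block must be MATCH")
        if any(a == b for a, b in zip(ops, ops[1:])):
            raise ValueError("adjacent blocks must alternate MATCH/SKIP")
        if any(op not in (MATCH, SKIP) for op in ops):
            raise ValueError("block ops must be MATCH or SKIP")
        if any(length < 1 for _, length in self.blocks):
            raise ValueError("block lengths must be >= 1")

    @property
    def ref_end(self) -> int:
        return self.pos + sum(length for _, length in self.blocks)

    def segments(self) -> list[tuple[str, int, int]]:
        """Blocks as ``(op, ref_start, ref_end)`` half-open intervals."""
        out, cursor = [], self.pos
        for op, length in self.blocks:
            out.append((op, cursor, cursor + length))
            cursor += length
        return out


@dataclass
class PhasedGenotypeTable:
    """Biallelic genotypes for ``samples x variants`` with per-sample phasing.

    ``alleles[i, j]`` is the ordered ``(hapA, hapB)`` pair of 0/1 allele codes
    for sample *i* at variant *j*; :data:`MISSING` marks no-calls.
    """

    samples: list[str]
    variants: pd.DataFrame  # columns: id, contig, pos, ref, alt
    alleles: np.ndarray  # (n_samples, n_variants, 2) int8
    phased: np.ndarray  # (n_samples,) bool

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.phased = np.asarray(self.phased, dtype=bool)
        n, m = len(self.samples), len(self.variants)
        if self.alleles.shape != (n, m, 2):
            raise ValueError(
                f"alleles shape {self.alleles.shape} != ({n}, {m}, 2)"
            )
        codes = set(np.unique(self.alleles))
        if not codes <= {0, 1, MISSING}:
            raise ValueError("allele codes must be 0, 1 or the missing sentinel")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def dosage(self) -> np.ndarray:
        """Alt-allele dosage (0/1/2) per sample x variant; NaN where missing."""
        a = self.alleles.astype(float)
        a[a == MISSING] = np.nan
        return a.sum(axis=2)

    def chromosome_alleles(self, variant_id: str) -> np.ndarray:
        """Flattened per-chromosome alleles (2n,) for one variant."""
        j = self.variants.index[self.variants["id"] == variant_id]
        if len(j) != 1:
            raise KeyError(f"variant {variant_id!r} not found exactly once")
        return self.alleles[:, j[0], :].reshape(-1)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into upper-cased :class:`SequenceRecord` objects."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# bedGraph


def read_depth_bedgraph(
    path: str | Path, contig: str, start: int, end: int
) -> DepthTrack:
    """Expand a 4-column bedGraph into per-base depths over ``[start, end)``.

    Positions not covered by any interval get depth 0.  Intervals must be
    sorted and non-overlapping within the queried contig.
    """
    if end <= start:
        raise ValueError(f"empty query interval [{start}, {end})")
    depths = np.zeros(end - start, dtype=float)
    prev_end = None
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{line_no}: expected 4 columns")
            c, s, e, d = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if c != contig:
                continue
            if prev_end is not None and s < prev_end:
                raise FormatError(
                    f"{path}:{line_no}: intervals overlap or are unsorted"
                )
            prev_end = e
            lo, hi = max(s, start), min(e, end)
            if lo < hi:
                depths[lo - start : hi - start] = d
    return DepthTrack(contig, start, depths)


def write_bedgraph(track: DepthTrack, path: str | Path) -> None:
    """Write a track as run-length-compressed bedGraph lines."""
    with open(path, "w") as fh:
        d = track.depths
        run_start = 0
        for i in range(1, d.size + 1):
            if i == d.size or d[i] != d[run_start]:
                fh.write(
                    f"{track.contig}\t{track.start + run_start}"
                    f"\t{track.start + i}\t{d[run_start]:g}\n"
                )
                run_start = i


# ---------------------------------------------------------------------------
# minimal SAM

_CIGAR_RE = re.compile(r"(\d+)([A-Z=])")


def _parse_cigar(cigar: str) -> tuple[tuple[str, int], ...]:
    blocks: list[tuple[str, int]] = []
    consumed = 0
    for m in _CIGAR_RE.finditer(cigar):
        length, op = int(m.group(1)), m.group(2)
        consumed += m.end() - m.start()
        if op == "S":  # soft clip: no reference span
            continue
        if op not in (MATCH, SKIP):
            raise FormatError(f"unsupported CIGAR op {op!r} in {cigar!r}")
        if blocks and blocks[-1][0] == op:
            blocks[-1] = (op, blocks[-1][1] + length)
        else:
            blocks.append((op, length))
    if consumed != len(cigar):
        raise FormatError(f"malformed CIGAR {cigar!r}")
    return tuple(blocks)


def _format_cigar(blocks: Sequence[tuple[str, int]]) -> str:
    return "".join(f"{length}{op}" for op, length in blocks)


def read_sam_min(path: str | Path) -> list[AlignmentRecord]:
    """Read a minimal SAM file (QNAME FLAG RNAME POS MAPQ CIGAR ...)."""
    records = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("@"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{line_no}: fewer than 6 SAM columns")
            qname, _, rname, pos, _, cigar = parts[:6]
            records.append(
                AlignmentRecord(
                    read_id=qname,
                    contig=rname,
                    pos=int(pos) - 1,  # SAM is 1-based
                    blocks=_parse_cigar(cigar),
                )
            )
    return records


def write_sam_min(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                f"{rec.read_id}\t0\t{rec.contig}\t{rec.pos + 1}\t60\t"
                f"{_format_cigar(rec.blocks)}\t*\t0\t0\t*\t*\n"
            )


# ---------------------------------------------------------------------------
# VCF-lite


def read_phased_vcf_lite(path: str | Path) -> PhasedGenotypeTable:
    """Read a plain-text VCF keeping only biallelic rows with a GT field."""
    samples: list[str] = []
    var_rows = []
    allele_rows = []
    phased_all: np.ndarray | None = None
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 10:
                    raise FormatError(f"{path}: no sample columns in header")
                samples = cols[9:]
                phased_all = np.ones(len(samples), dtype=bool)
                continue
            if not samples:
                raise FormatError(f"{path}: data line before #CHROM header")
            parts = line.split("\t")
            chrom, pos, vid, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
            if "," in alt:
                logger.warning("skipping multi-allelic row %s:%d (%s)", chrom, pos, vid)
                continue
            fmt = parts[8].split(":")
            try:
                gt_idx = fmt.index("GT")
            except ValueError:
                raise FormatError(f"{path}:{line_no}: no GT in FORMAT") from None
            row = np.full((len(samples), 2), MISSING, dtype=np.int8)
            for i, cell in enumerate(parts[9 : 9 + len(samples)]):
                gt = cell.split(":")[gt_idx]
                sep = "|" if "|" in gt else "/"
                if sep == "/":
                    phased_all[i] = False
                a, b = (gt.split(sep) + ["."])[:2]
                row[i, 0] = MISSING if a == "." else int(a)
                row[i, 1] = MISSING if b == "." else int(b)
            var_rows.append((vid, chrom, pos - 1, ref, alt))  # to 0-based
            allele_rows.append(row)
    if phased_all is None:
        raise FormatError(f"{path}: missing #CHROM header")
    variants = pd.DataFrame(var_rows, columns=["id", "contig", "pos", "ref", "alt"])
    alleles = (
        np.stack(allele_rows, axis=1)
        if allele_rows
        else np.zeros((len(samples), 0, 2), dtype=np.int8)
    )
    return PhasedGenotypeTable(samples, variants, alleles, phased_all)


def write_phased_vcf_lite(table: PhasedGenotypeTable, path: str | Path) -> None:
    sep = {True: "|", False: "/"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for j, var in table.variants.iterrows():
            cells = []
            for i in range(table.n_samples):
                a, b = table.alleles[i, j]
                sa = "." if a == MISSING else str(int(a))
                sb = "." if b == MISSING else str(int(b))
                cells.append(f"{sa}{sep[bool(table.phased[i])]}{sb}")
            fh.write(
                f"{var['contig']}\t{var['pos'] + 1}\t{var['id']}\t{var['ref']}\t"
                f"{var['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# flat key-value config


def read_config(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` config file; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{line_no}: expected 'key = value'")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out
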