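"""Synthetic-data generators emulating the statistical structure of the study.

Every downstream stage of the pipeline (depth classification, tag-SNP
discovery, splice-read classification, association models) can be exercised
against these generators with known ground truth:

* diploid VNTR genotypes under Hardy-Weinberg equilibrium, with Short
  allele classes {24, 25.5, 27} and Long classes {40.5, 66.5} copies;
* a phased SNP panel in which one designated two-SNP haplotype tags the
  Long allele at configurable fidelity, plus noise SNPs in weak LD;
* per-base depth tracks whose repeat-interval coverage scales linearly
  with total diploid copy number, with negative-binomial noise;
* spliced reads drawn from four event classes (canonical, INS1, INS1b,
  unspliced) with genotype-dependent mixing proportions;
* quantitative phenotypes with additive haplotype effects and an optional
  age-group interaction.

All generators are deterministic given ``SimConfig.seed``; independent
random streams are derived per generator so results do not depend on call
order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import AlignmentRecord, DepthTrack, PhasedGenotypeTable, SequenceRecord
from .repeats import CONSENSUS_38, DiploClass, RepeatAllele, diplotype

#: genomic interval profiled for depth (0-based half-open), 2,290 bp
REPEAT_INTERVAL = ("chr5", 1_275_210, 1_277_500)

#: total diploid copies of the reference-like Short/Short genotype (2 x 27)
REFERENCE_DIPLOID_COPIES = 54.0

#: splice-event classes, in the order used by mixing-probability vectors
EVENT_CLASSES = ("canonical", "ins1", "ins1b", "unspliced")


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions: a Long-allele frequency of
    0.20, Short copy classes centred near 25.9 copies, a rare 66.5-copy
    Long allele, 30x baseline coverage, a 97%-fidelity tagging haplotype,
    and splice-event mixtures per intron-4 SNP genotype (CC/CT/TT) matching
    the reported read fractions (e.g. canonical 68.3% in CC, INS1b 7.0% in
    TT).
    """

    seed: int = 0
    n_samples: int = 605
    long_freq: float = 0.20
    short_copy_probs: dict = field(
        default_factory=lambda: {24.0: 0.25, 25.5: 0.25, 27.0: 0.50}
    )
    long_copy_probs: dict = field(
        default_factory=lambda: {40.5: 0.875, 66.5: 0.125}
    )
    # depth model
    baseline_depth: float = 30.0
    depth_dispersion: float = 10.0
    depth_alpha: float = 1.0
    # tag-SNP panel
    tag_fidelity: float = 0.97
    tag_background: float = 0.03
    n_noise_snps: int = 58
    # intron-4 SNP (T allele tracks the Long allele imperfectly)
    snp_t_given_long: float = 0.90
    snp_t_given_short: float = 0.10
    # splice reads
    read_len: int = 150
    reads_per_sample: int = 5000
    event_probs: dict = field(
        default_factory=lambda: {
            "CC": {"canonical": 0.683, "ins1": 0.020, "ins1b": 0.000, "unspliced": 0.297},
            "CT": {"canonical": 0.638, "ins1": 0.020, "ins1b": 0.038, "unspliced": 0.304},
            "TT": {"canonical": 0.573, "ins1": 0.020, "ins1b": 0.070, "unspliced": 0.337},
        }
    )
    # allele sequences
    mutation_rate: float = 0.01
    flank_len: int = 300
    # phenotypes (haplotype = VNTR class x intron-4 SNP allele; Short-C ref)
    pheno_intercept: float = 59.7
    pheno_effects: dict = field(
        default_factory=lambda: {
            "SHORT_T": -12.2,
            "LONG_C": -15.92,
            "LONG_T": -24.18,
        }
    )
    pheno_sd: float = 30.0
    beta_sex: float = 0.0
    beta_age: float = 0.0
    interaction_hap: str = "LONG_T"
    interaction_slope: float = 0.0
    age_range: tuple = (40.0, 80.0)

    def validate(self) -> None:
        if not 0.0 <= self.long_freq <= 1.0:
            raise ValueError(f"long_freq {self.long_freq} outside [0, 1]")
        for name, probs in (
            ("short_copy_probs", self.short_copy_probs),
            ("long_copy_probs", self.long_copy_probs),
        ):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        for gt, probs in self.event_probs.items():
            if set(probs) != set(EVENT_CLASSES):
                raise ValueError(f"event_probs[{gt}] missing classes")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"event_probs[{gt}] must sum to 1")
        if not 0.0 <= self.tag_fidelity <= 1.0:
            raise ValueError("tag_fidelity outside [0, 1]")
        if self.baseline_depth <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named stream of this config."""
        return np.random.default_rng([int(self.seed), int(stream)])


_STREAM_POPULATION = 1
_STREAM_PANEL = 2
_STREAM_COVERAGE = 3
_STREAM_ALLELE = 4
_STREAM_READS = 5
_STREAM_PHENO = 6


@dataclass
class SimTruth:
    """Ground truth for a simulated cohort.

    Chromosome-level arrays have shape ``(n, 2)``; haplotype A is column 0.
    """

    config: SimConfig
    copies: np.ndarray  # (n, 2) repeat copy numbers
    is_long: np.ndarray  # (n, 2) bool
    snp_t: np.ndarray  # (n, 2) 0/1, intron-4 SNP T allele
    sex: np.ndarray  # (n,) 0/1
    age: np.ndarray  # (n,) years
    phenotype: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.copies.shape[0]

    @property
    def total_copies(self) -> np.ndarray:
        return self.copies.sum(axis=1)

    @property
    def diplo_class(self) -> np.ndarray:
        """Per-sample label: LONG_ANY iff either chromosome is Long."""
        return np.where(
            self.is_long.any(axis=1),
            DiploClass.LONG_ANY.value,
            DiploClass.SHORT_SHORT.value,
        )

    @property
    def snp_genotype(self) -> np.ndarray:
        """Intron-4 SNP genotype per sample as 'CC', 'CT' or 'TT'."""
        dosage = self.snp_t.sum(axis=1)
        return np.array(["CC", "CT", "TT"])[dosage]

    def diplotypes(self) -> list:
        return [
            diplotype(
                RepeatAllele.from_copies(self.copies[i, 0]),
                RepeatAllele.from_copies(self.copies[i, 1]),
            )
            for i in range(self.n)
        ]

    def haplotype_labels(self) -> np.ndarray:
        """(n, 2) haplotype names in {SHORT_C, SHORT_T, LONG_C, LONG_T}."""
        vntr = np.where(self.is_long, "LONG", "SHORT")
        snp = np.where(self.snp_t == 1, "T", "C")
        return np.char.add(np.char.add(vntr, "_"), snp)


def gen_population(cfg: SimConfig) -> SimTruth:
    """Draw a cohort of diploid VNTR genotypes under Hardy-Weinberg.

    Each chromosome is independently Long with probability
    ``cfg.long_freq``; copy numbers are then drawn from the class-specific
    allele distributions.  The intron-4 SNP T allele is placed on each
    chromosome conditional on its VNTR class, inducing realistic partial LD.
    """
    cfg.validate()
    rng = cfg.rng(_STREAM_POPULATION)
    n = cfg.n_samples
    is_long = rng.random((n, 2)) < cfg.long_freq

    short_vals = np.array(sorted(cfg.short_copy_probs))
    short_p = np.array([cfg.short_copy_probs[v] for v in short_vals])
    long_vals = np.array(sorted(cfg.long_copy_probs))
    long_p = np.array([cfg.long_copy_probs[v] for v in long_vals])

    copies = np.where(
        is_long,
        rng.choice(long_vals, size=(n, 2), p=long_p),
        rng.choice(short_vals, size=(n, 2), p=short_p),
    )
    p_t = np.where(is_long, cfg.snp_t_given_long, cfg.snp_t_given_short)
    snp_t = (rng.random((n, 2)) < p_t).astype(np.int8)
    sex = rng.integers(0, 2, size=n).astype(np.int8)
    lo, hi = cfg.age_range
    age = rng.uniform(lo, hi, size=n)
    return SimTruth(cfg, copies, is_long, snp_t, sex, age)


def gen_tag_panel(truth: SimTruth, cfg: SimConfig | None = None) -> PhasedGenotypeTable:
    """Build a phased SNP panel whose two designated SNPs tag the Long allele.

    The joint "1-1" haplotype of the two tag SNPs appears on each Long
    chromosome with probability ``tag_fidelity`` and on Short chromosomes
    with probability ``tag_background``; the remaining three haplotypes are
    drawn uniformly.  Noise SNPs get MAF ~ U(0.01, 0.5) and weak LD with
    the VNTR class via a per-SNP copy probability derived from a fidelity
    drawn U(0.5, 0.85) (fidelity 0.5 means independence).
    """
    cfg = cfg or truth.config
    rng = cfg.rng(_STREAM_PANEL)
    n = truth.n
    long_flat = truth.is_long.reshape(-1)

    p_tag = np.where(long_flat, cfg.tag_fidelity, cfg.tag_background)
    tagged = rng.random(2 * n) < p_tag
    # untagged chromosomes carry one of the three Short-associated haplotypes,
    # the double-reference haplotype being the most common
    other = np.array([(0, 0), (1, 0), (0, 1)], dtype=np.int8)
    fallback = other[rng.choice(3, size=2 * n, p=[0.8, 0.1, 0.1])]
    tag1 = np.where(tagged, 1, fallback[:, 0]).astype(np.int8)
    tag2 = np.where(tagged, 1, fallback[:, 1]).astype(np.int8)

    import pandas as pd

    columns = [tag1, tag2, truth.snp_t.reshape(-1)]
    ids = ["tag1", "tag2", "ivs4"]
    positions = [1_255_000, 1_258_000, 1_242_000]
    noise_pos = np.sort(
        rng.choice(np.arange(1_100_000, 1_500_000), size=cfg.n_noise_snps, replace=False)
    )
    for k in range(cfg.n_noise_snps):
        maf = rng.uniform(0.01, 0.5)
        fidelity = rng.uniform(0.5, 0.85)
        copy_prob = 2.0 * fidelity - 1.0
        copied = rng.random(2 * n) < copy_prob
        noise = (rng.random(2 * n) < maf).astype(np.int8)
        columns.append(np.where(copied, long_flat.astype(np.int8), noise))
        ids.append(f"noise{k:03d}")
        positions.append(int(noise_pos[k]))

    order = np.argsort(positions, kind="stable")
    variants = pd.DataFrame(
        {
            "id": [ids[j] for j in order],
            "contig": "chr5",
            "pos": [positions[j] for j in order],
            "ref": "A",
            "alt": "G",
        }
    )
    alleles = np.stack([columns[j] for j in order], axis=1)  # (2n, m)
    alleles = alleles.reshape(n, 2, -1).transpose(0, 2, 1)  # (n, m, 2)
    samples = [f"S{i:04d}" for i in range(n)]
    return PhasedGenotypeTable(samples, variants, alleles.astype(np.int8), np.ones(n, bool))


def expected_repeat_depth(total_copies: float, cfg: SimConfig) -> float:
    """Mean repeat-interval depth for a sample with C total diploid copies."""
    c = float(total_copies)
    if c <= 0:
        raise ValueError("total copies must be positive")
    scale = 1.0 + cfg.depth_alpha * (c - REFERENCE_DIPLOID_COPIES) / REFERENCE_DIPLOID_COPIES
    return cfg.baseline_depth * max(scale, 0.0)


def _negbin(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p).astype(float)


def gen_coverage(
    truth: SimTruth,
    cfg: SimConfig | None = None,
    interval: tuple[str, int, int] = REPEAT_INTERVAL,
    flank_len: int = 500,
) -> list[DepthTrack]:
    """Simulate per-base depth tracks over the repeat interval plus flanks.

    Within the repeat interval the negative-binomial mean scales linearly
    with the total diploid copy number C (reference-like samples with
    C = 54 are flat in expectation); flanking bases stay at baseline depth.
    """
    cfg = cfg or truth.config
    contig, start, end = interval
    if end - start < 1:
        raise ValueError("interval must span at least one base")
    rng = cfg.rng(_STREAM_COVERAGE)
    lo, hi = start - flank_len, end + flank_len
    width = hi - lo
    in_repeat = np.zeros(width, dtype=bool)
    in_repeat[start - lo : end - lo] = True

    tracks = []
    for i in range(truth.n):
        mean = np.full(width, cfg.baseline_depth)
        mean[in_repeat] = expected_repeat_depth(truth.total_copies[i], cfg)
        tracks.append(DepthTrack(contig, lo, _negbin(rng, mean, cfg.depth_dispersion)))
    return tracks


def _random_flank(rng: np.random.Generator, length: int, consensus: str) -> str:
    """Random DNA free of any near-copy of the consensus unit."""
    import edlib

    bases = np.array(list("ACGT"))
    while True:
        seq = "".join(rng.choice(bases, size=length))
        hit = edlib.align(consensus, seq, mode="HW", task="distance", k=10)
        if hit["editDistance"] < 0:
            return seq


def gen_allele_fasta(
    copies: float, cfg: SimConfig, mutation_rate: float | None = None
) -> SequenceRecord:
    """Construct one VNTR allele sequence between fixed unique flanks.

    The array is ``floor(copies)`` consensus units (each carrying
    independent per-base substitutions at ``mutation_rate``) plus, for a
    half copy, the first 19 bases of the consensus.  Flanks are generated
    once from the seed and contain no near-copy of the consensus.
    """
    if copies <= 0 or round(copies * 2) != copies * 2:
        raise ValueError(f"copies must be a positive multiple of 0.5, got {copies}")
    rate = cfg.mutation_rate if mutation_rate is None else mutation_rate
    flank_rng = cfg.rng(_STREAM_ALLELE)  # flanks fixed across alleles
    flank5 = _random_flank(flank_rng, cfg.flank_len, CONSENSUS_38)
    flank3 = _random_flank(flank_rng, cfg.flank_len, CONSENSUS_38)

    rng = cfg.rng(_STREAM_ALLELE + 100 + int(round(copies * 2)))
    unit = np.array(list(CONSENSUS_38))
    bases = np.array(list("ACGT"))
    parts = []
    for _ in range(int(math.floor(copies))):
        copy = unit.copy()
        if rate > 0:
            hit = rng.random(unit.size) < rate
            if hit.any():
                copy[hit] = bases[rng.integers(0, 4, size=int(hit.sum()))]
        parts.append("".join(copy))
    if round(copies * 2) % 2 == 1:
        parts.append(CONSENSUS_38[:19])
    array = "".join(parts)
    label = f"{copies:g}".replace(".", "_")
    return SequenceRecord(f"allele_{label}", flank5 + array + flank3)


def allele_flanks(cfg: SimConfig) -> tuple[str, str]:
    """The fixed 5'/3' flanks used by :func:`gen_allele_fasta` for this seed."""
    rng = cfg.rng(_STREAM_ALLELE)
    return (
        _random_flank(rng, cfg.flank_len, CONSENSUS_38),
        _random_flank(rng, cfg.flank_len, CONSENSUS_38),
    )


def gen_splice_reads(
    truth: SimTruth, cfg: SimConfig | None = None, gene_model=None
) -> tuple[list[AlignmentRecord], list[str]]:
    """Simulate exon4-exon5 reads from the four splice-event classes.

    Each read's class is drawn from the event mixture of the sample's
    intron-4 SNP genotype.  Read start positions are uniform subject to the
    class-defining feature (junction or boundary crossing) lying strictly
    inside the read.  Returns the alignment records and the per-read
    generating class (ground truth).
    """
    from .splicing import default_gene_model

    cfg = cfg or truth.config
    gm = gene_model or default_gene_model()
    rng = cfg.rng(_STREAM_READS)
    read_len = cfg.read_len
    intron_len = gm.intron4[1] - gm.intron4[0]
    genotypes = truth.snp_genotype

    records: list[AlignmentRecord] = []
    labels: list[str] = []
    for i in range(truth.n):
        gt = genotypes[i]
        if gt not in cfg.event_probs:
            raise ValueError(f"no event probabilities for genotype {gt!r}")
        probs = np.array([cfg.event_probs[gt][e] for e in EVENT_CLASSES])
        classes = rng.choice(len(EVENT_CLASSES), size=cfg.reads_per_sample, p=probs)
        for k, ci in enumerate(classes):
            event = EVENT_CLASSES[ci]
            if event == "canonical":
                a = int(rng.integers(1, read_len))
                blocks = ((("M"), a), (("N"), intron_len), (("M"), read_len - a))
                pos = gm.intron4[0] - a
            elif event in ("ins1", "ins1b"):
                offset = gm.ins1_offset if event == "ins1" else gm.ins1b_offset
                a = int(rng.integers(1, read_len))
                skip_len = intron_len - offset
                blocks = ((("M"), a), (("N"), skip_len), (("M"), read_len - a))
                pos = gm.intron4[0] + offset - a
            else:  # unspliced: contiguous read crossing the boundary
                ext = int(rng.integers(gm.min_extension, read_len))
                blocks = ((("M"), read_len),)
                pos = gm.intron4[0] + ext - read_len
            records.append(
                AlignmentRecord(f"S{i:04d}_r{k:05d}", gm.contig, pos, blocks)
            )
            labels.append(event)
    return records, labels


def gen_phenotypes(truth: SimTruth, cfg: SimConfig | None = None) -> np.ndarray:
    """Draw quantitative phenotypes with additive haplotype effects.

    y = intercept + sum_h dosage_h * effect_h + b_sex*sex + b_age*age
        [+ slope * dosage_interaction_hap * age_group] + N(0, pheno_sd).

    Age groups are 5-year bins anchored at the cohort minimum age.  The
    result is also stored on ``truth.phenotype``.
    """
    cfg = cfg or truth.config
    rng = cfg.rng(_STREAM_PHENO)
    haps = truth.haplotype_labels()
    y = np.full(truth.n, cfg.pheno_intercept, dtype=float)
    for hap, effect in cfg.pheno_effects.items():
        y += (haps == hap).sum(axis=1) * effect
    y += cfg.beta_sex * truth.sex + cfg.beta_age * truth.age
    if cfg.interaction_slope != 0.0:
        age_group = np.floor((truth.age - truth.age.min()) / 5.0)
        dose = (haps == cfg.interaction_hap).sum(axis=1)
        y += cfg.interaction_slope * dose * age_group
    if cfg.pheno_sd > 0:
        y += rng.normal(0.0, cfg.pheno_sd, size=truth.n)
    truth.phenotype = y
    return y
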