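"""Synthetic data generators with planted ground truth.

The generators emulate the statistical structure of a drug-inducible
transcription-factor (Gata4-GR) experiment in two cell contexts:

* **ES cells** sampled at 0, 3, 6, 12, 24, 48 and 72 h after induction, and
* **Flk1(+) mesoderm** progenitors sampled at 0, 12, 24, 36, 48 and 72 h,

each in wild-type (WT) and Dnmt3a/Dnmt3b double-knockout (DKO) genotypes,
with (Dex+) or without (Dex-) induction of the factor.  Mesoderm baseline
(0 h) and Dex+ samples are simulated in triplicate, everything else in
duplicate, mirroring the study's array-labeling scheme.

Every simulated gene carries exactly one archetype label so that each
downstream stage (differential expression, Venn cascade, clustering,
immediate-response extraction) can be validated against known truth.
Additional generators produce ChIP fragment-midpoint tracks with planted
enriched regions and bisulfite PCR-clone reads with per-CpG methylation
probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = [
    "ARCHETYPES",
    "SimConfig",
    "SyntheticTruth",
    "ChipSimSpec",
    "BisulfiteSimSpec",
    "simulate_timecourse_expression",
    "simulate_immediate_expression",
    "simulate_chip_tags",
    "simulate_peak_windows",
    "simulate_bisulfite_clones",
    "random_cpg_region",
]

#: Gene response archetypes.
#:
#: group1_endoderm       responds to induction in ES cells (both genotypes)
#:                       and in DKO mesoderm, but not in WT mesoderm.
#: group2_cardiac        responds to induction in DKO mesoderm only.
#: methylation_sensitive constitutively elevated in DKO (both contexts),
#:                       independent of induction.
#: wt_and_dko_responder  responds to induction in both genotypes (and both
#:                       contexts) equally.
#: non_responder         flat.
ARCHETYPES = (
    "group1_endoderm",
    "group2_cardiac",
    "methylation_sensitive",
    "wt_and_dko_responder",
    "non_responder",
)

# Differential genes are a small minority of the measured transcriptome
# (a few hundred of ~20k genes in genome-wide arrays); keeping that
# property at desk scale preserves the exchangeability assumption of
# quantile normalization.
_DEFAULT_FRACTIONS = {
    "group1_endoderm": 0.025,
    "group2_cardiac": 0.020,
    "methylation_sensitive": 0.040,
    "wt_and_dko_responder": 0.050,
    "non_responder": 0.865,
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the expression time-course simulation.

    All effect sizes and noise scales are in log2 units.  ``meth_log2fc``
    is the constitutive DKO shift of methylation-sensitive genes; its
    default (2.5) lies strictly above the 4-fold bar so the "more than
    4-fold" strict inequality selects these genes.
    """

    n_genes: int = 1000
    probes_per_gene: int = 3
    archetype_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FRACTIONS)
    )
    effect_log2fc: float = 2.0
    meth_log2fc: float = 2.5
    noise_sd: float = 0.25
    sample_offset_sd: float = 0.1
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    # responder and methylation-silenced genes sit low before induction /
    # demethylation (developmental genes are off in the starting cells)
    silenced_baseline_mean: float = 6.5
    silenced_baseline_sd: float = 0.75
    timepoints_mesoderm: Sequence[int] = (0, 12, 24, 36, 48, 72)
    timepoints_es: Sequence[int] = (0, 3, 6, 12, 24, 48, 72)
    timepoints_immediate: Sequence[int] = (0, 1, 2, 3)
    n_immediate_hyper: int = 15
    n_immediate_other: int = 49
    ramp_hours: float = 24.0
    immediate_ramp_hours: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.probes_per_gene < 1:
            raise ValueError("n_genes and probes_per_gene must be >= 1")
        if self.noise_sd < 0 or self.sample_offset_sd < 0:
            raise ValueError("noise scales must be >= 0")
        total = sum(self.archetype_fractions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(
                f"archetype fractions must sum to 1, got {total:.6g}"
            )
        unknown = set(self.archetype_fractions) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted per-gene labels.

    ``labels`` maps gene symbol -> archetype; ``immediate`` is the set of
    genes whose induction effect reaches full size within 1 h (the 3-h
    immediate-response analysis recovers exactly these).
    """

    labels: pd.Series
    immediate: frozenset

    def genes_of(self, archetype: str) -> frozenset:
        return frozenset(self.labels.index[self.labels == archetype])

    @property
    def group1(self) -> frozenset:
        return self.genes_of("group1_endoderm")

    @property
    def group2(self) -> frozenset:
        return self.genes_of("group2_cardiac")

    @property
    def hyper_responsive(self) -> frozenset:
        """Genes responding to induction preferentially in DKO mesoderm."""
        return self.group1 | self.group2

    @property
    def methylation_sensitive(self) -> frozenset:
        return self.genes_of("methylation_sensitive")

    @property
    def shared_responders(self) -> frozenset:
        return self.genes_of("wt_and_dko_responder")


def _allocate_counts(n: int, fractions: Mapping[str, float]) -> dict:
    """Largest-remainder apportionment of n genes over archetypes."""
    keys = [a for a in ARCHETYPES if a in fractions]
    raw = np.array([fractions[a] * n for a in keys])
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in order[:short]:
        counts[i] += 1
    return dict(zip(keys, counts.tolist()))


def make_truth(config: SimConfig) -> SyntheticTruth:
    """Deterministic archetype assignment for a config (seed-derived)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    counts = _allocate_counts(config.n_genes, config.archetype_fractions)
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    labels = np.concatenate(
        [np.repeat(a, c) for a, c in counts.items()]
    )
    rng.shuffle(labels)
    series = pd.Series(labels, index=genes, name="archetype")

    hyper = [g for g in genes if series[g] in ("group1_endoderm", "group2_cardiac")]
    shared = [g for g in genes if series[g] == "wt_and_dko_responder"]
    n_ih = min(config.n_immediate_hyper, len(hyper))
    n_io = min(config.n_immediate_other, len(shared))
    immediate = frozenset(hyper[:n_ih]) | frozenset(shared[:n_io])
    return SyntheticTruth(labels=series, immediate=immediate)


def _build_design(config: SimConfig) -> pd.DataFrame:
    rows = []
    for context, timepoints in (
        ("mesoderm", config.timepoints_mesoderm),
        ("ES", config.timepoints_es),
    ):
        for genotype in ("WT", "DKO"):
            for t in timepoints:
                if t == 0:
                    n_rep = 3 if context == "mesoderm" else 2
                    for r in range(1, n_rep + 1):
                        rows.append((context, genotype, "Dex-", t, r))
                    continue
                for treatment in ("Dex-", "Dex+"):
                    if context == "mesoderm" and treatment == "Dex+":
                        n_rep = 3
                    else:
                        n_rep = 2
                    for r in range(1, n_rep + 1):
                        rows.append((context, genotype, treatment, t, r))
    design = pd.DataFrame(
        rows, columns=["context", "genotype", "treatment", "time_h", "replicate"]
    )
    design.index = [
        f"{c[:2]}_{g}_{'p' if tr == 'Dex+' else 'm'}{t:02d}h_r{r}"
        for c, g, tr, t, r in design.itertuples(index=False)
    ]
    design.index.name = "sample_id"
    return design


def _ramp(t: float, t_full: float) -> float:
    return min(max(t, 0.0) / t_full, 1.0) if t_full > 0 else 1.0


def _effect(
    archetype: str,
    immediate: bool,
    context: str,
    genotype: str,
    treatment: str,
    time_h: float,
    config: SimConfig,
) -> float:
    """Additive log2 shift of one gene in one design cell."""
    shift = 0.0
    if archetype == "methylation_sensitive" and genotype == "DKO":
        shift += config.meth_log2fc
    if treatment != "Dex+":
        return shift
    t_full = config.immediate_ramp_hours if immediate else config.ramp_hours
    ramp = _ramp(time_h, t_full) * config.effect_log2fc
    if archetype == "group1_endoderm":
        if context == "ES" or genotype == "DKO":
            shift += ramp
    elif archetype == "group2_cardiac":
        if context == "mesoderm" and genotype == "DKO":
            shift += ramp
    elif archetype == "wt_and_dko_responder":
        shift += ramp
    return shift


def _simulate_matrix(
    config: SimConfig, truth: SyntheticTruth, design: pd.DataFrame, stream: int
) -> tuple[ExpressionMatrix, pd.Series]:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, stream]))
    genes = list(truth.labels.index)
    n_g, n_p = len(genes), config.probes_per_gene
    silenced = (truth.labels != "non_responder").to_numpy()
    baselines = np.where(
        silenced,
        rng.normal(config.silenced_baseline_mean, config.silenced_baseline_sd, n_g),
        rng.normal(config.baseline_mean, config.baseline_sd, n_g),
    )

    effects = np.empty((n_g, len(design)))
    for j, row in enumerate(design.itertuples(index=False)):
        context, genotype, treatment, time_h, _ = row
        for i, g in enumerate(genes):
            effects[i, j] = _effect(
                truth.labels.iloc[i],
                g in truth.immediate,
                context,
                genotype,
                treatment,
                time_h,
                config,
            )

    gene_signal = baselines[:, None] + effects
    probe_ids = [f"{g}_p{k + 1}" for g in genes for k in range(n_p)]
    probe_signal = np.repeat(gene_signal, n_p, axis=0)
    offsets = rng.normal(0.0, config.sample_offset_sd, size=len(design))
    noise = rng.normal(0.0, config.noise_sd, size=probe_signal.shape)
    values = pd.DataFrame(
        probe_signal + offsets[None, :] + noise,
        index=probe_ids,
        columns=design.index,
    )
    probe_map = pd.Series(
        np.repeat(genes, n_p), index=probe_ids, name="gene"
    )
    return ExpressionMatrix(values=values, design=design, level="probe"), probe_map


def simulate_timecourse_expression(
    config: SimConfig,
) -> tuple[ExpressionMatrix, pd.Series, SyntheticTruth]:
    """Simulate the probe-level 72-h time-course expression experiment.

    Returns the probe-level matrix, the probe->gene map, and the planted
    truth.  Archetype effects ramp linearly from zero at t=0 to the full
    ``effect_log2fc`` by 24 h (1 h for immediate genes) and persist.
    Deterministic for a fixed seed.
    """
    truth = make_truth(config)
    design = _build_design(config)
    matrix, probe_map = _simulate_matrix(config, truth, design, stream=23)
    return matrix, probe_map, truth


def simulate_immediate_expression(
    config: SimConfig, truth: SyntheticTruth | None = None
) -> tuple[ExpressionMatrix, pd.Series, SyntheticTruth]:
    """Simulate the short-term (0-3 h) induction experiment in mesoderm.

    Shares the gene truth with :func:`simulate_timecourse_expression` for
    the same config, so overlaps between immediate and persistent
    responder sets are meaningful.  Duplicate samples per design cell.
    """
    if truth is None:
        truth = make_truth(config)
    rows = []
    for genotype in ("WT", "DKO"):
        for t in config.timepoints_immediate:
            treatment = "Dex-" if t == 0 else "Dex+"
            for r in (1, 2):
                rows.append(("mesoderm", genotype, treatment, t, r))
    design = pd.DataFrame(
        rows, columns=["context", "genotype", "treatment", "time_h", "replicate"]
    )
    design.index = [
        f"im_{g}_{'p' if tr == 'Dex+' else 'm'}{t:02d}h_r{r}"
        for _, g, tr, t, r in design.itertuples(index=False)
    ]
    design.index.name = "sample_id"
    matrix, probe_map = _simulate_matrix(config, truth, design, stream=29)
    return matrix, probe_map, truth


# ---------------------------------------------------------------------------
# ChIP tag-track simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChipSimSpec:
    """Parameters of the ChIP fragment-midpoint track simulation.

    ``planted_peaks`` is a list of ``(center, width, enrichment)`` tuples.
    Enrichment is defined as the expected experiment/background density
    ratio at the peak center; excess tags are drawn from a Gaussian
    (sd = width/6) truncated to the peak interval, giving a well-defined
    summit.  ``gene_offsets`` cycle over planted peaks to place annotated
    gene intervals at known distances from the peak centers.
    """

    chrom: str = "chrS"
    chrom_length: int = 100_000
    n_background_tags: int = 20_000
    planted_peaks: Sequence[tuple[int, int, float]] = ()
    motif_placement: float = 0.8
    gene_offsets: Sequence[int] = (0, 2_000, 6_000)
    gene_length: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chrom_length <= 0:
            raise ValueError("chromosome length must be positive")
        if self.n_background_tags < 1:
            raise ValueError("need at least one background tag")
        for center, width, enrichment in self.planted_peaks:
            if enrichment <= 0:
                raise ValueError("peak enrichment must be > 0")
            if not (0 <= center - width // 2 and center + width // 2 <= self.chrom_length):
                raise ValueError(
                    f"peak at {center} (width {width}) outside chromosome"
                )


def simulate_chip_tags(
    spec: ChipSimSpec,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Simulate experiment and background tag positions plus annotation.

    Background tags are uniform on [0, chrom_length).  The experiment
    track has the same uniform rate plus, per planted peak, a Poisson
    number of excess tags ``(enrichment - 1) * rate * sqrt(2*pi) * sd``
    centered on the peak.  Gene intervals are placed at the configured
    offsets downstream of successive peak centers (cycled).

    Returns sorted integer arrays (experiment, background) and a BED-like
    annotation frame with columns chrom/start/end/name.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.chrom_length
    rate = spec.n_background_tags / L
    background = np.sort(
        rng.integers(0, L, size=spec.n_background_tags)
    ).astype(np.int64)

    exp_parts = [rng.integers(0, L, size=spec.n_background_tags)]
    for center, width, enrichment in spec.planted_peaks:
        sd = max(width / 6.0, 1.0)
        lam = max(enrichment - 1.0, 0.0) * rate * math.sqrt(2 * math.pi) * sd
        n_extra = rng.poisson(lam)
        extra = rng.normal(center, sd, size=n_extra)
        lo, hi = center - width / 2, center + width / 2
        extra = np.clip(extra, max(lo, 0), min(hi, L - 1))
        exp_parts.append(np.round(extra).astype(np.int64))
    experiment = np.sort(np.concatenate(exp_parts)).astype(np.int64)

    ann_rows = []
    for i, (center, _, _) in enumerate(spec.planted_peaks):
        offset = spec.gene_offsets[i % len(spec.gene_offsets)]
        start = min(center + offset, L - 1)
        end = min(start + spec.gene_length, L)
        ann_rows.append((spec.chrom, int(start), int(end), f"Gene{i:02d}"))
    annotation = pd.DataFrame(
        ann_rows, columns=["chrom", "start", "end", "name"]
    )
    return experiment, background, annotation


_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def simulate_peak_windows(
    n_windows: int,
    width: int = 500,
    motif: str = "TGATAA",
    motif_fraction: float = 0.8,
    seed: int = 0,
) -> list[str]:
    """Random equal-length peak windows with a motif planted at the center
    of a fraction of them (uniform background sequence elsewhere)."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    windows = []
    for _ in range(n_windows):
        seq = bases[rng.integers(0, 4, size=width)]
        if rng.random() < motif_fraction:
            inst = [rng.choice(list(_IUPAC[c])) for c in motif.upper()]
            start = (width - len(inst)) // 2
            seq[start : start + len(inst)] = inst
        windows.append("".join(seq))
    return windows


# ---------------------------------------------------------------------------
# Bisulfite clone simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BisulfiteSimSpec:
    """Parameters of the bisulfite PCR-clone read simulation.

    ``per_cpg_meth_prob`` gives, per CpG in the region (5'->3'), the
    probability that the CpG cytosine is methylated (retained as C after
    conversion).  Non-CpG cytosines convert to T except with probability
    ``conversion_failure_rate``.
    """

    region_sequence: str
    per_cpg_meth_prob: Sequence[float]
    n_clones: int = 24
    conversion_failure_rate: float = 0.005
    sequencing_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        seq = self.region_sequence.upper()
        n_cpg = seq.count("CG")
        if n_cpg == 0:
            raise ValueError("region contains no CpG")
        if len(self.per_cpg_meth_prob) != n_cpg:
            raise ValueError(
                f"need {n_cpg} CpG probabilities, got {len(self.per_cpg_meth_prob)}"
            )
        for p in self.per_cpg_meth_prob:
            if not 0.0 <= p <= 1.0:
                raise ValueError("methylation probabilities must be in [0,1]")
        if not 0.0 <= self.conversion_failure_rate <= 1.0:
            raise ValueError("conversion_failure_rate must be in [0,1]")
        if self.n_clones < 1:
            raise ValueError("need at least one clone")


def simulate_bisulfite_clones(spec: BisulfiteSimSpec) -> list[str]:
    """Simulate bisulfite-converted top-strand clone reads.

    Each clone retains each CpG cytosine as C with its per-CpG probability
    (else T); every other C converts to T except with the conversion
    failure rate.  Optional uniform substitution errors are applied last.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    seq = spec.region_sequence.upper()
    cpg_pos = [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]
    clones = []
    for _ in range(spec.n_clones):
        read = list(seq)
        for k, i in enumerate(cpg_pos):
            read[i] = "C" if rng.random() < spec.per_cpg_meth_prob[k] else "T"
        for i, b in enumerate(seq):
            if b == "C" and i not in cpg_pos:
                read[i] = "C" if rng.random() < spec.conversion_failure_rate else "T"
        if spec.sequencing_error_rate > 0:
            for i in range(len(read)):
                if rng.random() < spec.sequencing_error_rate:
                    read[i] = rng.choice([b for b in "ACGT" if b != read[i]])
        clones.append("".join(read))
    return clones


def random_cpg_region(
    length: int = 300, n_cpg: int = 12, seed: int = 0, name: str = "region"
) -> str:
    """Random DNA region with at least ``n_cpg`` CpG dinucleotides planted
    at evenly spaced positions (convenience for fixtures)."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seq = bases[rng.integers(0, 4, size=length)]
    step = length // (n_cpg + 1)
    for k in range(1, n_cpg + 1):
        i = k * step
        seq[i], seq[i + 1] = "C", "G"
    # avoid accidental CpG truncation at the end
    return "".join(seq)
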