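"""End-to-end orchestration: simulate -> normalize -> DE -> extract ->
cluster -> peaks -> annotate -> methylation -> report.

``run_pipeline`` executes every stage on synthetic data generated from a
single seeded configuration and emits a machine-readable JSON summary
holding every gene-set count (the per-comparison up/down counts at 2- and
4-fold, the Venn partitions at 24 h and 72 h, persistent and immediate
responder counts and their overlap, group sizes), peak and link counts,
the central-motif statistic, and methylation percentages.  The run is
fully deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from . import cluster as _cluster
from . import io as _io
from .bisulfite import ReferenceRegion, call_methylation, compare_profiles
from .chip import (
    TagTrack,
    call_peaks,
    central_motif_enrichment,
    differential_peaks,
    associate_peaks_to_genes,
)
from .expression import (
    ContrastSpec,
    fit_moderated_t,
    merge_probes_to_genes,
    quantile_normalize,
    select_de_genes,
)
from .responders import (
    extract_hyper_responsive,
    immediate_responders,
    persistent_responders,
)
from .synthetic import (
    BisulfiteSimSpec,
    ChipSimSpec,
    SimConfig,
    random_cpg_region,
    simulate_bisulfite_clones,
    simulate_chip_tags,
    simulate_immediate_expression,
    simulate_peak_windows,
    simulate_timecourse_expression,
)

logger = logging.getLogger("methgate")

__all__ = ["RunConfig", "run_pipeline", "summarize_counts"]


@dataclass
class RunConfig:
    """All thresholds and simulation parameters of one pipeline run.

    Every published-analysis threshold is a named default here: 2- and
    4-fold change cuts at p < 0.01 for the expression cascade, KDE
    bandwidth 30 bp with candidate threshold 5.0 and background
    enrichment 3.0 for peak calling, 5 kb for peak-gene association, and
    95% conversion / 90% identity QC for bisulfite clones.
    """

    seed: int = 0
    outdir: str | None = None
    # expression simulation
    n_genes: int = 1000
    effect_log2fc: float = 2.0
    noise_sd: float = 0.25
    sample_offset_sd: float = 0.1
    # selection thresholds
    fc_fold: float = 2.0
    fc_fold_strong: float = 4.0
    p_max: float = 0.01
    # ChIP
    bandwidth: float = 30.0
    candidate_threshold: float = 5.0
    enrichment_threshold: float = 3.0
    max_distance: int = 5000
    n_peaks_dko: int = 12
    n_peaks_shared: int = 6
    peak_enrichment: float = 8.0
    peak_width: int = 400
    motif: str = "WGATAR"
    central_bin: int = 100
    n_motif_windows: int = 200
    motif_window: int = 500
    motif_placement: float = 0.8
    # bisulfite
    n_clones: int = 24
    min_conversion: float = 0.95
    min_identity: float = 0.90
    conversion_failure_rate: float = 0.005
    meth_prob_high: float = 0.9
    meth_prob_low: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "fc_fold", "fc_fold_strong", "p_max", "bandwidth",
            "candidate_threshold", "enrichment_threshold", "max_distance",
            "min_conversion", "min_identity",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def sim_config(self, noiseless: bool = False) -> SimConfig:
        cfg = SimConfig(
            n_genes=self.n_genes,
            effect_log2fc=self.effect_log2fc,
            noise_sd=self.noise_sd,
            sample_offset_sd=self.sample_offset_sd,
            seed=self.seed,
        )
        if noiseless:
            cfg = replace(cfg, noise_sd=0.0, sample_offset_sd=0.0)
        return cfg


def _count_up_down(result, fc_fold, p_max):
    up = select_de_genes(result, fc_fold, p_max, "up")
    down = select_de_genes(result, fc_fold, p_max, "down")
    return up, down


def summarize_counts(stage_outputs: dict) -> dict:
    """Assemble the JSON-ready summary from stage outputs.

    ``stage_outputs`` carries the objects produced by the stages (gene
    sets, Venn partitions, peaks, links, profiles); the summary holds
    only counts, fractions and percentages.
    """
    s = stage_outputs
    venn72, venn24 = s["venn_72h"], s["venn_24h"]
    summary = {
        "seed": s["seed"],
        "n_genes": s["n_genes"],
        "comparisons": s["comparison_counts"],
        "venn_72h": {
            "region_counts": venn72.region_counts,
            "set_totals": venn72.set_totals,
        },
        "venn_24h": {
            "region_counts": venn24.region_counts,
            "set_totals": venn24.set_totals,
        },
        "hyper_responsive_72h": len(s["hyper_72h"]),
        "hyper_responsive_24h": len(s["hyper_24h"]),
        "persistent_responders": len(s["persistent"]),
        "immediate_responders": len(s["immediate"]),
        "immediate_persistent_overlap": len(
            s["immediate"].members & s["persistent"].members
        ),
        "group1_size": len(s["group1"]),
        "group2_size": len(s["group2"]),
        "chip": {
            "peaks_dko": len(s["peaks_dko"]),
            "peaks_wt": len(s["peaks_wt"]),
            "dko_specific_peaks": len(s["dko_specific"]),
            "peak_gene_links": len(s["links"]),
        },
        "motif": {
            "bin_sites": s["bin_sites"],
            "total_sites": s["total_sites"],
            "central_fraction": (
                s["bin_sites"] / s["total_sites"] if s["total_sites"] else 0.0
            ),
            "p": s["motif_p"],
        },
        "methylation": s["methylation"],
    }
    return summary


def run_pipeline(config: RunConfig, noiseless: bool = False) -> dict:
    """Execute every stage on synthetic data; return the summary dict.

    When ``outdir`` is set, all intermediate artifacts (matrices, gene
    lists, peaks, links, clone FASTA, summary JSON) are written there.
    """
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    # --- expression arm -------------------------------------------------
    sim = config.sim_config(noiseless=noiseless)
    probe_matrix, probe_map, truth = simulate_timecourse_expression(sim)
    normalized = quantile_normalize(probe_matrix)
    gene_matrix = merge_probes_to_genes(normalized, probe_map)

    comparison_counts = {}
    for label, group_a, group_b in (
        (
            "WT_DexM_vs_DKO_DexM_72h",
            dict(context="mesoderm", genotype="WT", treatment="Dex-", time_h=72),
            dict(context="mesoderm", genotype="DKO", treatment="Dex-", time_h=72),
        ),
        (
            "WT_DexP_vs_DKO_DexP_72h",
            dict(context="mesoderm", genotype="WT", treatment="Dex+", time_h=72),
            dict(context="mesoderm", genotype="DKO", treatment="Dex+", time_h=72),
        ),
        (
            "DKO_DexM_vs_DKO_DexP_72h",
            dict(context="mesoderm", genotype="DKO", treatment="Dex-", time_h=72),
            dict(context="mesoderm", genotype="DKO", treatment="Dex+", time_h=72),
        ),
        (
            "WT_DexM_vs_WT_DexP_72h",
            dict(context="mesoderm", genotype="WT", treatment="Dex-", time_h=72),
            dict(context="mesoderm", genotype="WT", treatment="Dex+", time_h=72),
        ),
    ):
        result = fit_moderated_t(
            gene_matrix, ContrastSpec(group_a=group_a, group_b=group_b, label=label)
        )
        entry = {}
        for fold in (config.fc_fold, config.fc_fold_strong):
            up, down = _count_up_down(result, fold, config.p_max)
            entry[f"up_{fold:g}x"] = len(up)
            entry[f"down_{fold:g}x"] = len(down)
        comparison_counts[label] = entry

    hyper_72h, venn_72h = extract_hyper_responsive(
        gene_matrix, 72, config.fc_fold, config.p_max
    )
    hyper_24h, venn_24h = extract_hyper_responsive(
        gene_matrix, 24, config.fc_fold, config.p_max
    )
    persistent = persistent_responders(hyper_24h, hyper_72h)

    immediate_matrix, _, _ = simulate_immediate_expression(sim, truth)
    immediate_gene = merge_probes_to_genes(
        quantile_normalize(immediate_matrix), probe_map
    )
    immediate = immediate_responders(immediate_gene, config.fc_fold, config.p_max)

    # --- clustering of the persistent responders ------------------------
    if len(persistent) >= 2:
        profiles = _cluster.condition_mean_profiles(
            gene_matrix, sorted(persistent.members)
        )
        dist = _cluster.pearson_distance(profiles)
        tree = _cluster.average_linkage_cluster(dist, list(profiles.index))
        es_fc = _cluster.es_response_log2fc(gene_matrix, profiles.index)
        group1, group2 = _cluster.split_groups(tree, es_fc)
    else:
        from .expression import GeneSet

        tree = None
        group1 = GeneSet("group1", frozenset())
        group2 = GeneSet("group2", frozenset())

    # --- ChIP arm --------------------------------------------------------
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    chrom_len = 100_000
    spacing = chrom_len // (config.n_peaks_dko + 1)
    centers = [(i + 1) * spacing for i in range(config.n_peaks_dko)]
    dko_peak_spec = tuple(
        (c, config.peak_width, config.peak_enrichment) for c in centers
    )
    shared_centers = centers[: config.n_peaks_shared]
    wt_peak_spec = tuple(
        (c, config.peak_width, config.peak_enrichment) for c in shared_centers
    )
    dko_spec = ChipSimSpec(
        chrom_length=chrom_len,
        planted_peaks=dko_peak_spec,
        motif_placement=config.motif_placement,
        seed=int(rng.integers(2**31)),
    )
    wt_spec = ChipSimSpec(
        chrom_length=chrom_len,
        planted_peaks=wt_peak_spec,
        motif_placement=config.motif_placement,
        seed=int(rng.integers(2**31)),
    )
    dko_exp, dko_bg, annotation = simulate_chip_tags(dko_spec)
    wt_exp, wt_bg, _ = simulate_chip_tags(wt_spec)
    dko_track = TagTrack("chrS", dko_exp, chrom_len)
    wt_track = TagTrack("chrS", wt_exp, chrom_len)
    peaks_dko = call_peaks(
        dko_track,
        TagTrack("chrS", dko_bg, chrom_len),
        config.candidate_threshold,
        config.enrichment_threshold,
        config.bandwidth,
    )
    peaks_wt = call_peaks(
        wt_track,
        TagTrack("chrS", wt_bg, chrom_len),
        config.candidate_threshold,
        config.enrichment_threshold,
        config.bandwidth,
    )
    dko_specific = differential_peaks(
        peaks_dko, dko_track, wt_track, config.enrichment_threshold,
        config.bandwidth,
    )
    links = associate_peaks_to_genes(peaks_dko, annotation, config.max_distance)

    windows = simulate_peak_windows(
        config.n_motif_windows,
        width=config.motif_window,
        motif_fraction=config.motif_placement,
        seed=int(rng.integers(2**31)),
    )
    bin_sites, total_sites, motif_p = central_motif_enrichment(
        windows, motif=config.motif, central_bin=config.central_bin
    )

    # --- bisulfite arm ---------------------------------------------------
    region_seq = random_cpg_region(length=300, n_cpg=12, seed=config.seed)
    region = ReferenceRegion(name="peak_region", sequence=region_seq)
    n_cpg = len(region.cpg_positions)
    fail_rate = 0.0 if noiseless else config.conversion_failure_rate
    profiles = {}
    for sample, prob in (
        ("WT_mesoderm", config.meth_prob_high),
        ("DKO_mesoderm", config.meth_prob_low),
    ):
        spec = BisulfiteSimSpec(
            region_sequence=region_seq,
            per_cpg_meth_prob=[prob] * n_cpg,
            n_clones=config.n_clones,
            conversion_failure_rate=fail_rate,
            seed=int(rng.integers(2**31)),
        )
        clones = simulate_bisulfite_clones(spec)
        profiles[sample] = call_methylation(
            region,
            clones,
            min_conversion=config.min_conversion,
            min_identity=config.min_identity,
        )
        if outdir:
            _io.write_fasta(
                [(f"{sample}_clone{k + 1:02d}", c) for k, c in enumerate(clones)],
                outdir / f"clones_{sample}.fa",
            )
    delta, meth_p = compare_profiles(
        profiles["WT_mesoderm"], profiles["DKO_mesoderm"]
    )
    methylation = {
        "WT_mesoderm_percent": profiles["WT_mesoderm"].percent_methylated,
        "DKO_mesoderm_percent": profiles["DKO_mesoderm"].percent_methylated,
        "delta_percent": delta,
        "fisher_p": meth_p,
    }

    stage_outputs = {
        "seed": config.seed,
        "n_genes": config.n_genes,
        "comparison_counts": comparison_counts,
        "venn_72h": venn_72h,
        "venn_24h": venn_24h,
        "hyper_72h": hyper_72h,
        "hyper_24h": hyper_24h,
        "persistent": persistent,
        "immediate": immediate,
        "group1": group1,
        "group2": group2,
        "peaks_dko": peaks_dko,
        "peaks_wt": peaks_wt,
        "dko_specific": dko_specific,
        "links": links,
        "bin_sites": bin_sites,
        "total_sites": total_sites,
        "motif_p": motif_p,
        "methylation": methylation,
        "truth": truth,
        "gene_matrix": gene_matrix,
        "tree": tree,
    }
    summary = summarize_counts(stage_outputs)

    if outdir:
        _io.write_expression(
            gene_matrix, outdir / "gene_matrix.tsv", outdir / "design.tsv"
        )
        for name, gs in (
            ("hyper_72h", hyper_72h),
            ("hyper_24h", hyper_24h),
            ("persistent", persistent),
            ("immediate", immediate),
            ("group1", group1),
            ("group2", group2),
        ):
            _io.write_gene_set(gs, outdir / f"genes_{name}.txt")
        for region_name, members in venn_72h.regions.items():
            _io.write_gene_set(
                type(hyper_72h)(label=region_name, members=members),
                outdir / f"venn72_{region_name}.txt",
            )
        _io.write_peaks_bed6(peaks_dko, outdir / "peaks_dko.bed")
        _io.write_bed(annotation, outdir / "annotation.bed")
        if tree is not None:
            (outdir / "tree.nwk").write_text(tree.to_newick() + "\n")
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
    return summary
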