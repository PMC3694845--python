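"""KDE-based ChIP enrichment peak calling and peak annotation.

Tag tracks are strandless fragment midpoints on a single chromosome.
The tag density is a Gaussian kernel density (default bandwidth 30 bp)
scaled by the total tag count, i.e. expected tags per bp; it is sampled
at every integer position.  Candidate regions are maximal runs where the
experiment density reaches ``candidate_threshold`` times the genome-wide
mean density; a candidate is kept as a peak when the experiment /
background density ratio at its summit — both tracks scaled to equal
totals and the background floored at its genome-wide mean — reaches
``enrichment_threshold``.  Defaults: bandwidth 30, candidate 5.0,
enrichment 3.0, and gene association within 5 kb.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

logger = logging.getLogger("methgate")

__all__ = [
    "TagTrack",
    "Peak",
    "PeakGeneLink",
    "kde_density",
    "call_peaks",
    "differential_peaks",
    "associate_peaks_to_genes",
    "central_motif_enrichment",
]

_TRUNCATE = 8.0  # kernel support in bandwidths; tail mass ~ 1e-15


@dataclass(frozen=True)
class TagTrack:
    """Sorted fragment-midpoint positions on one chromosome."""

    chrom: str
    positions: np.ndarray
    chrom_length: int

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "positions", np.sort(pos))
        if pos.size and (pos.min() < 0 or pos.max() >= self.chrom_length):
            raise ValueError("tag positions outside chromosome bounds")

    @property
    def total_tags(self) -> int:
        return int(self.positions.size)


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    summit: int
    score: float  # experiment KDE density at summit (tags per bp)
    enrichment: float  # experiment/background density ratio at summit

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("peak start must be < end")
        if not self.start <= self.summit < self.end:
            raise ValueError("summit must lie inside the peak")


@dataclass(frozen=True)
class PeakGeneLink:
    peak: Peak
    gene: str
    gene_start: int
    gene_end: int
    distance: int  # bp gap; 0 if peak and gene overlap


def kde_density(track: TagTrack, bandwidth: float = 30.0) -> np.ndarray:
    """Gaussian tag density sampled at every bp (expected tags per bp).

    The kernel mass is conserved by edge reflection, so the density sums
    to the total tag count (to within kernel-truncation tolerance).
    """
    if track.total_tags == 0:
        raise ValueError("empty tag track")
    counts = np.bincount(track.positions, minlength=track.chrom_length).astype(
        float
    )
    return gaussian_filter1d(
        counts, sigma=bandwidth, mode="reflect", truncate=_TRUNCATE
    )


def _candidate_runs(mask: np.ndarray) -> list:
    """(start, end) half-open runs of True in a boolean array."""
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def call_peaks(
    experiment: TagTrack,
    background: TagTrack,
    candidate_threshold: float = 5.0,
    enrichment_threshold: float = 3.0,
    bandwidth: float = 30.0,
) -> list:
    """Call enriched peaks from experiment vs background tag tracks."""
    if experiment.chrom != background.chrom:
        raise ValueError("experiment and background tracks on different chromosomes")
    if background.total_tags == 0:
        raise ValueError("background track has zero tags")
    dens_exp = kde_density(experiment, bandwidth)
    dens_bg = kde_density(background, bandwidth)
    scale = experiment.total_tags / background.total_tags
    dens_bg_scaled = dens_bg * scale
    mean_exp = experiment.total_tags / experiment.chrom_length
    floor = mean_exp  # genome-wide mean background density after scaling

    peaks = []
    for start, end in _candidate_runs(dens_exp >= candidate_threshold * mean_exp):
        summit = int(start + np.argmax(dens_exp[start:end]))
        ratio = dens_exp[summit] / max(dens_bg_scaled[summit], floor)
        if ratio >= enrichment_threshold:
            peaks.append(
                Peak(
                    chrom=experiment.chrom,
                    start=int(start),
                    end=int(end),
                    summit=summit,
                    score=float(dens_exp[summit]),
                    enrichment=float(ratio),
                )
            )
    logger.info("call_peaks: %d peaks", len(peaks))
    return peaks


def differential_peaks(
    peaks_target: list,
    target_track: TagTrack,
    reference_track: TagTrack,
    enrichment_threshold: float = 3.0,
    bandwidth: float = 30.0,
) -> list:
    """Target peaks whose summit density exceeds the reference track's by
    ``enrichment_threshold`` after depth scaling (reference floored at its
    genome-wide mean) — 'target-specific' peaks."""
    if not peaks_target:
        return []
    dens_t = kde_density(target_track, bandwidth)
    dens_r = kde_density(reference_track, bandwidth)
    scale = target_track.total_tags / reference_track.total_tags
    floor = target_track.total_tags / target_track.chrom_length
    kept = []
    for peak in peaks_target:
        ratio = dens_t[peak.summit] / max(dens_r[peak.summit] * scale, floor)
        if ratio >= enrichment_threshold:
            kept.append(peak)
    logger.info(
        "differential_peaks: %d of %d retained", len(kept), len(peaks_target)
    )
    return kept


def associate_peaks_to_genes(
    peaks: list, annotation: pd.DataFrame, max_distance: int = 5000
) -> list:
    """Link each peak to its nearest gene interval within ``max_distance``.

    ``annotation`` has columns chrom/start/end/name (BED semantics,
    0-based half-open).  The gene with the minimal gap wins; ties go to
    the smaller gene start.  Peaks farther than ``max_distance`` from
    every gene yield no link.
    """
    if annotation.empty:
        raise ValueError("gene annotation is empty")
    ann = annotation.sort_values(["start", "end", "name"]).reset_index(drop=True)
    links = []
    for peak in peaks:
        genes = ann[ann["chrom"] == peak.chrom]
        if genes.empty:
            continue
        g_start = genes["start"].to_numpy(dtype=np.int64)
        g_end = genes["end"].to_numpy(dtype=np.int64)
        gaps = np.maximum(
            0, np.maximum(g_start - peak.end, peak.start - g_end)
        )
        best = int(np.lexsort((g_start, gaps))[0])
        if gaps[best] <= max_distance:
            row = genes.iloc[best]
            links.append(
                PeakGeneLink(
                    peak=peak,
                    gene=str(row["name"]),
                    gene_start=int(row["start"]),
                    gene_end=int(row["end"]),
                    distance=int(gaps[best]),
                )
            )
    logger.info(
        "associate_peaks_to_genes: %d links for %d peaks", len(links), len(peaks)
    )
    return links


_IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYWSKMBDHVN", "TGCAYRWSMKVHDBN")


def _revcomp(motif: str) -> str:
    return motif.translate(_COMPLEMENT)[::-1]


def _match_starts(seq: str, motif: str) -> list:
    # lookahead regex finds overlapping matches
    pattern = "(?=" + "".join(
        c if len(_IUPAC_CODES[c]) == 1 else f"[{_IUPAC_CODES[c]}]"
        for c in motif
    ) + ")"
    return [m.start() for m in re.finditer(pattern, seq)]


def central_motif_enrichment(
    peak_sequences: list,
    motif: str = "WGATAR",
    central_bin: int = 100,
) -> tuple[int, int, float]:
    """Central enrichment of a consensus motif in summit-centered windows.

    Per sequence the best (closest-to-center, either strand) match of the
    IUPAC consensus is located; ``bin_sites`` counts sequences whose best
    match center falls within the ``central_bin``-bp central bin, and
    ``total_sites`` counts sequences with any match.  The p-value is the
    one-sided binomial tail P(X >= bin_sites | n = total_sites, q), where
    q is the exact fraction of searchable start positions whose match
    center lies in the bin.  Returns (bin_sites, total_sites, p);
    p = 1 when no sequence matches.
    """
    if not peak_sequences:
        raise ValueError("no peak sequences")
    width = len(peak_sequences[0])
    if any(len(s) != width for s in peak_sequences):
        raise ValueError("peak windows must have equal length")
    if central_bin > width:
        raise ValueError("central bin wider than window")
    motif = motif.upper()
    m = len(motif)
    rc = _revcomp(motif)
    window_center = (width - 1) / 2.0
    half_bin = central_bin / 2.0

    searchable = width - m + 1
    if searchable <= 0:
        raise ValueError("motif longer than window")
    starts = np.arange(searchable)
    centers = starts + (m - 1) / 2.0
    n_bin_positions = int(np.sum(np.abs(centers - window_center) <= half_bin))
    q = n_bin_positions / searchable

    bin_sites = 0
    total_sites = 0
    for seq in peak_sequences:
        seq = seq.upper()
        hits = _match_starts(seq, motif)
        if rc != motif:
            hits = sorted(set(hits) | set(_match_starts(seq, rc)))
        if not hits:
            continue
        total_sites += 1
        offsets = [abs(h + (m - 1) / 2.0 - window_center) for h in hits]
        if min(offsets) <= half_bin:
            bin_sites += 1

    if total_sites == 0:
        return 0, 0, 1.0
    p = float(stats.binom.sf(bin_sites - 1, total_sites, q))
    return bin_sites, total_sites, min(p, 1.0)
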