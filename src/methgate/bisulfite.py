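"""Bisulfite clone alignment and per-CpG methylation calling.

Clone reads are PCR products of bisulfite-converted top-strand DNA:
unmethylated cytosines read as T, methylated CpG cytosines stay C.  Reads
are globally aligned against the reference with an asymmetric scoring
scheme (match +1, mismatch -1, gap -2) in which a reference C opposite a
read T also counts as a match, since that is the expected conversion
outcome.  Per clone, each reference CpG is called methylated (read C),
unmethylated (read T) or missing (gap/other base); clones failing either
the conversion-QC (fraction of non-CpG cytosines converted) or the
alignment-identity threshold are excluded.  The summary statistic is the
percentage of methylated CpG calls pooled over all included clones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

logger = logging.getLogger("methgate")

__all__ = [
    "ReferenceRegion",
    "CloneAlignment",
    "MethylationProfile",
    "align_clone",
    "call_methylation",
    "compare_profiles",
]

METHYLATED, UNMETHYLATED, MISSING = 1, 0, -1


@dataclass(frozen=True)
class ReferenceRegion:
    """A reference amplicon; CpG cytosine offsets are derived, not given."""

    name: str
    sequence: str
    cpg_positions: tuple = field(init=False)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        positions = tuple(
            i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"
        )
        object.__setattr__(self, "cpg_positions", positions)
        if not positions:
            raise ValueError(f"region {self.name!r} contains no CpG")


@dataclass
class CloneAlignment:
    """Alignment of one clone read against the reference top strand."""

    clone_id: str
    ref_to_read: dict  # reference offset -> read base or None (gap)
    identity: float  # matched columns / alignment length, C~T = match
    score: float


def _aligner() -> Align.PairwiseAligner:
    alphabet = "ACGTN"
    matrix = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for x in alphabet:
        for y in alphabet:
            matrix[x, y] = 1.0 if x == y else -1.0
    matrix["C", "T"] = 1.0  # bisulfite conversion: ref C ~ read T
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    return aligner


def align_clone(
    reference: ReferenceRegion, read: str, clone_id: str = "clone"
) -> CloneAlignment:
    """Globally align a clone read to the reference (C->T tolerant).

    The read length must be within 50-150% of the reference length.
    Identity is the fraction of alignment columns that are matches under
    the bisulfite scoring (reference C vs read T counts as a match).
    """
    read = read.upper()
    ref = reference.sequence
    if not 0.5 * len(ref) <= len(read) <= 1.5 * len(ref):
        raise ValueError(
            f"read length {len(read)} outside 50-150% of reference "
            f"({len(ref)})"
        )
    alignment = _aligner().align(ref, read)[0]

    ref_to_read: dict = {}
    matches = 0
    columns = 0
    ref_aln, read_aln = alignment[0], alignment[1]
    ref_pos = -1
    for rbase, qbase in zip(ref_aln, read_aln):
        columns += 1
        if rbase != "-":
            ref_pos += 1
            ref_to_read[ref_pos] = None if qbase == "-" else qbase
        if rbase == "-" or qbase == "-":
            continue
        if rbase == qbase or (rbase == "C" and qbase == "T"):
            matches += 1
    identity = matches / columns if columns else 0.0
    return CloneAlignment(
        clone_id=clone_id,
        ref_to_read=ref_to_read,
        identity=identity,
        score=float(alignment.score),
    )


@dataclass
class MethylationProfile:
    """Per-clone x per-CpG methylation calls for one region."""

    region: ReferenceRegion
    calls: np.ndarray  # clones x CpGs, values in {1, 0, -1}
    clone_ids: list
    conversion_rates: list
    identities: list
    excluded_clones: list  # (clone_id, reason)

    @property
    def n_methylated(self) -> int:
        return int(np.sum(self.calls == METHYLATED))

    @property
    def n_unmethylated(self) -> int:
        return int(np.sum(self.calls == UNMETHYLATED))

    @property
    def percent_methylated(self) -> float:
        """Percentage of methylated CpGs pooled over included clones."""
        called = self.n_methylated + self.n_unmethylated
        if called == 0:
            return float("nan")
        return 100.0 * self.n_methylated / called

    def lollipop(self) -> str:
        """Text rendering: filled circles = methylated, open = unmethylated."""
        rows = []
        for cid, row in zip(self.clone_ids, self.calls):
            glyphs = "".join(
                "●" if c == METHYLATED else "○" if c == UNMETHYLATED else "·"
                for c in row
            )
            rows.append(f"{cid}\t{glyphs}")
        return "\n".join(rows)


def call_methylation(
    reference: ReferenceRegion,
    reads,
    min_conversion: float = 0.95,
    min_identity: float = 0.90,
) -> MethylationProfile:
    """Align clones, call per-CpG methylation and apply conversion QC.

    ``reads`` is a sequence of (clone_id, sequence) pairs or bare
    sequences.  Clones whose non-CpG-cytosine conversion rate falls below
    ``min_conversion``, or whose alignment identity falls below
    ``min_identity``, are excluded from the profile with a reason.
    """
    ref = reference.sequence
    cpg = set(reference.cpg_positions)
    non_cpg_c = [i for i, b in enumerate(ref) if b == "C" and i not in cpg]

    items = [
        r if isinstance(r, tuple) else (f"clone{k + 1:02d}", r)
        for k, r in enumerate(reads)
    ]
    if not items:
        raise ValueError("no clone reads supplied")

    kept_rows, clone_ids, conv_rates, identities = [], [], [], []
    excluded = []
    for clone_id, seq in items:
        try:
            aln = align_clone(reference, seq, clone_id)
        except ValueError as exc:
            excluded.append((clone_id, f"unalignable: {exc}"))
            continue
        if aln.identity < min_identity:
            excluded.append(
                (clone_id, f"identity {aln.identity:.3f} < {min_identity}")
            )
            continue
        converted = total = 0
        for i in non_cpg_c:
            base = aln.ref_to_read.get(i)
            if base in ("C", "T"):
                total += 1
                if base == "T":
                    converted += 1
        conv_rate = converted / total if total else 1.0
        if conv_rate < min_conversion:
            excluded.append(
                (clone_id, f"conversion {conv_rate:.3f} < {min_conversion}")
            )
            continue
        row = []
        for i in reference.cpg_positions:
            base = aln.ref_to_read.get(i)
            if base == "C":
                row.append(METHYLATED)
            elif base == "T":
                row.append(UNMETHYLATED)
            else:
                row.append(MISSING)
        kept_rows.append(row)
        clone_ids.append(clone_id)
        conv_rates.append(conv_rate)
        identities.append(aln.identity)

    if excluded:
        logger.info(
            "call_methylation(%s): excluded %d clones", reference.name,
            len(excluded),
        )
    calls = (
        np.array(kept_rows, dtype=int)
        if kept_rows
        else np.empty((0, len(reference.cpg_positions)), dtype=int)
    )
    return MethylationProfile(
        region=reference,
        calls=calls,
        clone_ids=clone_ids,
        conversion_rates=conv_rates,
        identities=identities,
        excluded_clones=excluded,
    )


def compare_profiles(
    a: MethylationProfile, b: MethylationProfile
) -> tuple[float, float]:
    """Difference in percent methylation (a - b) with a two-sided
    Fisher's exact p-value on the pooled methylated/unmethylated table.

    The study reports no statistical test for methylation differences;
    Fisher's exact test is this package's addition.
    """
    if a.region.name != b.region.name:
        raise ValueError("profiles are from different regions")
    table = np.array(
        [
            [a.n_methylated, a.n_unmethylated],
            [b.n_methylated, b.n_unmethylated],
        ]
    )
    if table[0].sum() == 0 or table[1].sum() == 0:
        raise ValueError("cannot compare an empty methylation profile")
    delta = a.percent_methylated - b.percent_methylated
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(delta), float(p)
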