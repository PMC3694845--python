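"""Plain-text readers and writers for all pipeline artifacts.

Formats: expression matrices as TSV with a sidecar design TSV, tag tracks
as one integer position per line, annotations as BED (0-based half-open),
gene sets as one symbol per line, clone reads and reference regions as
FASTA, peaks as BED6 (score column = enrichment x 100, integer).  Every
writer is paired with a reader that round-trips without loss.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chip import Peak, TagTrack
from .expression import ExpressionMatrix, GeneSet

__all__ = [
    "write_expression", "read_expression",
    "write_gene_set", "read_gene_set",
    "write_tag_track", "read_tag_track",
    "write_bed", "read_bed",
    "write_peaks_bed6", "read_peaks_bed6",
    "write_fasta", "read_fasta",
    "write_probe_map", "read_probe_map",
]


def write_expression(matrix: ExpressionMatrix, values_path, design_path) -> None:
    matrix.values.to_csv(values_path, sep="\t", index_label="feature")
    matrix.design.to_csv(design_path, sep="\t", index_label="sample_id")


def read_expression(values_path, design_path, level: str = "probe") -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="feature")
    values.index.name = None
    design = pd.read_csv(design_path, sep="\t", index_col="sample_id")
    values.columns.name = design.index.name
    return ExpressionMatrix(values=values, design=design, level=level)


def write_probe_map(probe_map: pd.Series, path) -> None:
    probe_map.rename("gene").to_csv(path, sep="\t", index_label="probe")


def read_probe_map(path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", index_col="probe")
    frame.index.name = None
    return frame["gene"]


def write_gene_set(gene_set: GeneSet, path) -> None:
    Path(path).write_text(
        "".join(f"{g}\n" for g in sorted(gene_set.members))
    )


def read_gene_set(path, label: str | None = None) -> GeneSet:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return GeneSet(
        label=label or Path(path).stem,
        members=frozenset(ln for ln in lines if ln),
    )


def write_tag_track(track: TagTrack, path) -> None:
    header = f"# chrom={track.chrom} length={track.chrom_length}\n"
    body = "".join(f"{p}\n" for p in track.positions)
    Path(path).write_text(header + body)


def read_tag_track(path) -> TagTrack:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ValueError(f"{path}: missing tag-track header line")
    fields = dict(kv.split("=") for kv in lines[0][1:].split())
    positions = np.array([int(ln) for ln in lines[1:] if ln.strip()], dtype=np.int64)
    return TagTrack(
        chrom=fields["chrom"],
        positions=positions,
        chrom_length=int(fields["length"]),
    )


def write_bed(annotation: pd.DataFrame, path) -> None:
    annotation[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path) -> pd.DataFrame:
    """Read a BED4+ file (chrom, start, end, name); malformed lines are
    rejected with their line number."""
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"{path}:{lineno}: expected >= 4 BED columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
        if start < 0 or end <= start:
            raise ValueError(f"{path}:{lineno}: invalid interval [{start},{end})")
        rows.append((parts[0], start, end, parts[3]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_peaks_bed6(peaks: list, path) -> None:
    lines = []
    for i, pk in enumerate(peaks):
        score = int(round(pk.enrichment * 100))
        lines.append(
            f"{pk.chrom}\t{pk.start}\t{pk.end}\tpeak{i:04d}\t{score}\t.\t{pk.summit}\t{pk.score:.6g}\n"
        )
    Path(path).write_text("".join(lines))


def read_peaks_bed6(path) -> list:
    peaks = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 8:
            raise ValueError(f"{path}:{lineno}: expected 8 columns")
        peaks.append(
            Peak(
                chrom=parts[0],
                start=int(parts[1]),
                end=int(parts[2]),
                summit=int(parts[6]),
                score=float(parts[7]),
                enrichment=int(parts[4]) / 100.0,
            )
        )
    return peaks


def write_fasta(records, path) -> None:
    """Write (id, sequence) pairs as FASTA."""
    seq_records = [
        SeqRecord(Seq(seq), id=str(name), description="")
        for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path) -> list:
    return [
        (record.id, str(record.seq)) for record in SeqIO.parse(str(path), "fasta")
    ]
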