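"""Output formats: RLFS detail table, FASTA, BED6 and UCSC custom track.

All four views describe the same record set.  Coordinates are written 0-based
half-open (the BED convention) in every format.  Feature names follow
``{feature}_{model}_{ordinal}`` with ordinals assigned in coordinate order per
sequence and strand, so outputs are stable and diff-able.
"""

from __future__ import annotations

from typing import IO, Sequence

from .scan import RlfsRecord
from .sequence_io import reverse_complement, write_fasta

TABLE_COLUMNS = (
    "seq_name", "model", "strand",
    "rlfs_start", "rlfs_end",
    "riz_start", "riz_end", "riz_length", "riz_g_pct", "n_g_clusters",
    "linker_length",
    "rez_start", "rez_end", "rez_length", "rez_g_pct",
    "riz_sequence", "linker_sequence", "rez_sequence",
)

FEATURES = ("RLFS", "RIZ", "REZ")


def _require_source(rec: RlfsRecord) -> str:
    if rec.source is None:
        raise ValueError(
            f"record on {rec.seq_name} carries no source sequence; feature "
            "substrings are unavailable"
        )
    return rec.source.residues


def _strand_sequence(rec: RlfsRecord, start: int, end: int) -> str:
    """Feature residues as read on the record's own (scanned) strand."""
    sub = _require_source(rec)[start:end]
    return sub if rec.strand == "+" else reverse_complement(sub)


def feature_sequences(rec: RlfsRecord) -> tuple[str, str, str]:
    """(RIZ, linker, REZ) residues in scanned-strand orientation."""
    riz = _strand_sequence(rec, rec.riz_start, rec.riz_end)
    rez = _strand_sequence(rec, rec.rez_start, rec.rez_end)
    if rec.strand == "+":
        linker = _strand_sequence(rec, rec.riz_end, rec.rez_start)
    else:
        linker = _strand_sequence(rec, rec.rez_end, rec.riz_start)
    return riz, linker, rez


def _ordinals(records: Sequence[RlfsRecord]) -> list[int]:
    """Per (sequence, strand) 1-based ordinals in coordinate order."""
    order = sorted(
        range(len(records)),
        key=lambda i: (records[i].ref_name, records[i].strand, records[i].start,
                       records[i].end),
    )
    ordinals = [0] * len(records)
    counters: dict[tuple[str, str], int] = {}
    for i in order:
        key = (records[i].ref_name, records[i].strand)
        counters[key] = counters.get(key, 0) + 1
        ordinals[i] = counters[key]
    return ordinals


def write_table(records: Sequence[RlfsRecord], sink: IO[str]) -> int:
    """Write the tab-separated RLFS detail table; returns the row count.

    Columns are ``TABLE_COLUMNS``; coordinates 0-based half-open; the three
    sequence columns are oriented on the record's strand so that
    RIZ + linker + REZ concatenate to the R-loop-forming strand's sequence.
    """
    sink.write("\t".join(TABLE_COLUMNS) + "\n")
    n = 0
    for rec in records:
        riz_seq, linker_seq, rez_seq = feature_sequences(rec)
        row = (
            rec.ref_name, rec.model, rec.strand,
            str(rec.start), str(rec.end),
            str(rec.riz_start), str(rec.riz_end), str(rec.riz_length),
            f"{100 * rec.riz_g_fraction:.2f}", str(rec.n_clusters),
            str(rec.linker_length),
            str(rec.rez_start), str(rec.rez_end), str(rec.rez_length),
            f"{100 * rec.rez_g_fraction:.2f}",
            riz_seq, linker_seq, rez_seq,
        )
        sink.write("\t".join(row) + "\n")
        n += 1
    return n


def write_rlfs_fasta(records: Sequence[RlfsRecord], sink: IO[str]) -> int:
    """Write one FASTA record per RLFS (RIZ-through-REZ span).

    The written sequence is the R-loop-forming strand's sequence, i.e. the
    forward-strand span reverse-complemented for '-' records.  Headers encode
    source name, interval, strand and model.
    """
    out = []
    ordinals = _ordinals(records)
    for rec, ordinal in zip(records, ordinals):
        span = _strand_sequence(rec, rec.start, rec.end)
        name = (
            f"{rec.ref_name}:{rec.start}-{rec.end}({rec.strand})"
            f" RLFS_{rec.model}_{ordinal}"
        )
        out.append((name, span))
    return write_fasta(out, sink)


def bed_lines(
    records: Sequence[RlfsRecord], feature_scope: str = "RLFS"
) -> list[str]:
    """Render records as BED6 lines for one feature scope or 'all'."""
    if feature_scope != "all" and feature_scope not in FEATURES:
        raise ValueError(f"feature_scope must be one of {FEATURES + ('all',)}")
    scopes = FEATURES if feature_scope == "all" else (feature_scope,)
    ordinals = _ordinals(records)
    lines = []
    for rec, ordinal in zip(records, ordinals):
        for feature in scopes:
            start, end = rec.feature_interval(feature)
            name = f"{feature}_{rec.model}_{ordinal}"
            lines.append(
                f"{rec.ref_name}\t{start}\t{end}\t{name}\t0\t{rec.strand}"
            )
    return lines


def write_bed(
    records: Sequence[RlfsRecord], sink: IO[str], feature_scope: str = "RLFS"
) -> int:
    """Write BED6 (chrom, start, end, name, score, strand); returns line count."""
    lines = bed_lines(records, feature_scope)
    for line in lines:
        sink.write(line + "\n")
    return len(lines)


def write_custom_track(
    records: Sequence[RlfsRecord], sink: IO[str], track_name: str = "RLFS"
) -> int:
    """Write a UCSC custom track: one track block per feature type.

    Records must be in chromosome coordinates (remapped onto an anchor);
    otherwise the browser would misplace them, so an error advises remapping.
    Returns the number of payload (BED) lines.
    """
    for rec in records:
        if rec.chrom is None:
            raise ValueError(
                f"record on {rec.seq_name} is not anchored to a chromosome; "
                "remap with an anchor (chrom, start, strand) before writing a "
                "custom track"
            )
    n = 0
    for feature in FEATURES:
        name = f"{track_name}_{feature}"
        if " " in name:
            name = f'"{name}"'
        description = f'"{feature} predictions ({track_name})"'
        sink.write(f"track name={name} description={description} visibility=2\n")
        n += write_bed(records, sink, feature_scope=feature)
    return n
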