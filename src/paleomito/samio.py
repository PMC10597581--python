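"""Minimal SAM interchange built on pysam.

Dialect: QNAME, FLAG (0/16/4), RNAME, 1-based POS, MAPQ, CIGAR over M/I/D,
SEQ, QUAL, and an ``NM:i`` tag.  Reads that wrap the circular origin are
written with their full span starting at POS; importers normalize reference
positions modulo the reference length.

On import, ``unique_best`` is proxied by MAPQ >= 30 (the stringency filter
applied to externally produced alignments).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pysam

from .mapping import MappedRead

_OP_CODE = {"M": 0, "I": 1, "D": 2}
_CODE_OP = {0: "M", 1: "I", 2: "D", 7: "M", 8: "M"}

IMPORT_MIN_MAPQ = 30


def write_sam(
    mapped: list[MappedRead], ref_id: str, ref_length: int, path: str | Path
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": ref_id, "LN": ref_length}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for m in mapped:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = m.read_id
            seg.flag = 16 if m.strand == "-" else 0
            seg.reference_id = 0
            seg.reference_start = m.ref_start
            seg.mapping_quality = 60 if m.unique_best else 0
            seg.cigartuples = [(_OP_CODE[op], n) for op, n in m.cigar]
            seg.query_sequence = m.seq
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(int(q) + 33) for q in m.quals)
            )
            seg.set_tag("NM", int(m.edit_distance))
            out.write(seg)


def read_sam(path: str | Path) -> tuple[list[MappedRead], dict[str, int]]:
    """Import mapped reads; returns (reads, {ref_id: ref_length}).

    Unmapped records and records on unknown references are skipped.  Soft and
    hard clips are stripped (clipped bases are not part of the alignment).
    """
    mapped: list[MappedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as handle:
        lengths = dict(zip(handle.references, handle.lengths))
        for seg in handle.fetch(until_eof=True):
            if seg.is_unmapped or seg.reference_name is None:
                continue
            ref_len = lengths[seg.reference_name]
            cigar: list[tuple[str, int]] = []
            seq = seg.query_sequence or ""
            quals = seg.query_qualities
            # strip soft clips from seq/quals; drop other non-MID ops
            lead_clip = 0
            kept_len = 0
            for code, n in seg.cigartuples or ():
                if code == 4:  # S
                    if not cigar:
                        lead_clip = n
                    continue
                if code in (5, 6):  # H, P
                    continue
                op = _CODE_OP.get(code)
                if op is None:
                    raise ValueError(f"unsupported CIGAR op code {code}")
                cigar.append((op, n))
                if op in ("M", "I"):
                    kept_len += n
            seq = seq[lead_clip : lead_clip + kept_len]
            q = (
                np.asarray(quals[lead_clip : lead_clip + kept_len])
                if quals is not None
                else np.zeros(kept_len, dtype=np.int64)
            )
            nm = seg.get_tag("NM") if seg.has_tag("NM") else 0
            mapped.append(
                MappedRead(
                    read_id=seg.query_name,
                    ref_id=seg.reference_name,
                    ref_start=seg.reference_start % ref_len,
                    strand="-" if seg.is_reverse else "+",
                    cigar=tuple(cigar),
                    seq=seq,
                    quals=q,
                    ref_length=ref_len,
                    edit_distance=int(nm),
                    score=0,
                    unique_best=seg.mapping_quality >= IMPORT_MIN_MAPQ,
                )
            )
    return mapped, lengths
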