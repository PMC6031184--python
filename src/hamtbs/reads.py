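"""Aligned read-pair containers and SAM/FASTQ input-output.

Reads are stored in reference orientation against the assayed-strand
amplicon sequence: ``Mate.bases[j]`` is the base aligned to 1-based
reference position ``Mate.start + j``.  Amplicon alignments are gapless
(amplicon sequencing essentially never produces indels against its own
reference), so a mate is fully described by its start and its base/quality
arrays.  SAM records with indel-containing CIGARs are skipped with a
warning on input.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .errors import PairingError
from .panel_model import Panel

_REVCOMP_TABLE = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _REVCOMP_TABLE[_a] = _b


@dataclass
class Mate:
    """One aligned mate: 1-based inclusive start plus base/quality arrays."""

    start: int
    bases: np.ndarray  # uint8 ASCII codes
    quals: np.ndarray  # uint8 Phred scores

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError("base and quality strings differ in length")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def end(self) -> int:
        """1-based inclusive end; ``start - 1`` for an empty (fully trimmed) mate."""
        return self.start + len(self.bases) - 1

    @property
    def seq(self) -> str:
        return self.bases.tobytes().decode("ascii")

    @classmethod
    def from_strings(cls, start: int, seq: str, qual: int | Sequence[int]) -> "Mate":
        bases = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        if isinstance(qual, int):
            quals = np.full(len(bases), qual, dtype=np.uint8)
        else:
            quals = np.asarray(qual, dtype=np.uint8)
        return cls(start=start, bases=bases, quals=quals)


@dataclass
class AlignedPair:
    """A read pair aligned to one amplicon (mate2 may be absent)."""

    amplicon: str
    name: str
    mate1: Mate | None
    mate2: Mate | None = None

    def mates(self) -> list[Mate]:
        return [m for m in (self.mate1, self.mate2) if m is not None and len(m) > 0]


def write_sam(pairs: Iterable[AlignedPair], panel: Panel, path: str | Path) -> None:
    """Write pairs as an aligned SAM file with one @SQ line per amplicon.

    Mate 1 is recorded on the forward strand, mate 2 on the reverse strand
    (the standard FR amplicon orientation).  Fully trimmed (empty) mates
    are omitted.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": amp.name, "LN": amp.length} for amp in panel],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for pair in pairs:
            present = [
                (m, is_first)
                for m, is_first in ((pair.mate1, True), (pair.mate2, False))
                if m is not None and len(m) > 0
            ]
            paired = len(present) == 2
            tid = out.get_tid(pair.amplicon)
            for m, is_first in present:
                a = pysam.AlignedSegment(out.header)
                a.query_name = pair.name
                a.reference_id = tid
                a.reference_start = m.start - 1
                a.cigartuples = [(0, len(m))]
                a.query_sequence = m.seq
                a.query_qualities = m.quals.tolist()
                a.mapping_quality = 60
                flag = 0
                if paired:
                    other = present[1][0] if is_first else present[0][0]
                    flag |= 0x1 | 0x2  # paired, proper pair
                    flag |= 0x40 if is_first else 0x80
                    if is_first:
                        flag |= 0x20  # mate reverse
                    else:
                        flag |= 0x10  # reverse
                    a.next_reference_id = tid
                    a.next_reference_start = other.start - 1
                    span = max(m.end, other.end) - min(m.start, other.start) + 1
                    a.template_length = span if is_first else -span
                a.flag = flag
                out.write(a)


def read_sam(path: str | Path) -> list[AlignedPair]:
    """Read gapless amplicon alignments from SAM, pairing mates by name.

    Secondary, supplementary and unmapped records are ignored; records with
    indel-containing CIGARs are skipped with a warning.  Mates of one
    template mapped to different amplicons raise :class:`PairingError`.
    """
    pairs: dict[str, AlignedPair] = {}
    order: list[str] = []
    n_indel = 0
    with pysam.AlignmentFile(str(path), "r") as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if any(op not in (0, 7, 8) for op, _ in (rec.cigartuples or [])):
                n_indel += 1
                continue
            mate = Mate(
                start=rec.reference_start + 1,
                bases=np.frombuffer(
                    rec.query_sequence.encode("ascii"), dtype=np.uint8
                ).copy(),
                quals=np.asarray(rec.query_qualities, dtype=np.uint8),
            )
            name = rec.query_name
            if name not in pairs:
                pairs[name] = AlignedPair(
                    amplicon=rec.reference_name, name=name, mate1=None, mate2=None
                )
                order.append(name)
            pair = pairs[name]
            if pair.amplicon != rec.reference_name:
                raise PairingError(
                    f"mates of {name} map to different amplicons: "
                    f"{pair.amplicon} vs {rec.reference_name}"
                )
            if rec.is_paired and rec.is_read2:
                pair.mate2 = mate
            elif pair.mate1 is None:
                pair.mate1 = mate
            else:
                pair.mate2 = mate
    if n_indel:
        warnings.warn(f"skipped {n_indel} indel-containing alignment(s)")
    return [pairs[name] for name in order]


def _open_text(path: str | Path, mode: str = "wt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def write_fastq(
    pairs: Iterable[AlignedPair], r1_path: str | Path, r2_path: str | Path | None = None
) -> None:
    """Write pairs as FASTQ; mate 2 is reverse-complemented to sequencer
    orientation.  ``.gz`` suffixes enable gzip compression."""
    r1 = _open_text(r1_path)
    r2 = _open_text(r2_path) if r2_path is not None else None
    try:
        for pair in pairs:
            if pair.mate1 is not None and len(pair.mate1) > 0:
                m = pair.mate1
                qual = (m.quals + 33).tobytes().decode("ascii")
                r1.write(f"@{pair.name}/1\n{m.seq}\n+\n{qual}\n")
            if pair.mate2 is not None and len(pair.mate2) > 0 and r2 is not None:
                m = pair.mate2
                rc = _REVCOMP_TABLE[m.bases[::-1]]
                qual = (m.quals[::-1] + 33).tobytes().decode("ascii")
                r2.write(f"@{pair.name}/2\n{rc.tobytes().decode('ascii')}\n+\n{qual}\n")
    finally:
        r1.close()
        if r2 is not None:
            r2.close()
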