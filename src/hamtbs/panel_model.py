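"""Amplicon panel representation for targeted bisulfite sequencing.

An amplicon panel is a collection of PCR targets tiled over a locus of
interest.  Each amplicon assays exactly one bisulfite strand; bottom-strand
amplicons are reverse-complemented on load so that all downstream logic
(context enumeration, in-silico conversion, methylation calling) operates
on the assayed strand in a single orientation.

Coordinate conventions
----------------------
* BED input is 0-based, half-open (standard BED).
* Every reported site position is 1-based *within the amplicon*, counted
  along the assayed strand.  This matches common per-cytosine report
  conventions and round-trips unambiguously.
* Primer footprints (optional BED columns 7 and 8) are given in bases from
  each end of the assayed-strand sequence.  Positions inside a primer
  footprint are synthetic oligo rather than template and are masked from
  methylation calling and conversion-rate denominators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import CoordinateError, PanelFormatError

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")

#: Hard validity bounds on amplicon length (bp); outside -> error.
DEFAULT_LENGTH_BOUNDS = (100, 600)
#: Typical design range (bp); outside -> warning only.
TYPICAL_LENGTH_RANGE = (200, 450)
#: Empirical ceiling on samples x amplicons multiplexed per sequencing run.
DEFAULT_MAX_LOADING = 2500

CONTEXTS = ("CpG", "CHG", "CHH")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_bases(seq: str, where: str) -> None:
    bad = set(seq) - _VALID_BASES
    if bad:
        raise PanelFormatError(f"{where}: invalid characters {sorted(bad)!r}")


@dataclass(frozen=True)
class AmpliconDef:
    """One PCR target.

    Parameters
    ----------
    name:
        Unique amplicon identifier.
    chrom, start, end:
        Genomic interval, 0-based half-open.
    strand:
        Assayed bisulfite strand, ``"top"`` or ``"bottom"``.
    fwd_primer_len, rev_primer_len:
        Primer footprint lengths in bases at the 5' and 3' end of the
        assayed-strand sequence.
    ref_seq:
        Upper-case genomic (top-strand) sequence of the interval,
        length ``end - start``.
    """

    name: str
    chrom: str
    start: int
    end: int
    ref_seq: str
    strand: str = "top"
    fwd_primer_len: int = 0
    rev_primer_len: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("top", "bottom"):
            raise PanelFormatError(
                f"{self.name}: strand must be 'top' or 'bottom', got {self.strand!r}"
            )
        if self.start < 0 or self.end <= self.start:
            raise CoordinateError(
                f"{self.name}: invalid interval [{self.start}, {self.end})"
            )
        if self.end - self.start != len(self.ref_seq):
            raise CoordinateError(
                f"{self.name}: interval length {self.end - self.start} != "
                f"sequence length {len(self.ref_seq)}"
            )
        _check_bases(self.ref_seq, self.name)
        if self.fwd_primer_len < 0 or self.rev_primer_len < 0:
            raise PanelFormatError(f"{self.name}: negative primer length")
        if self.fwd_primer_len + self.rev_primer_len >= self.length:
            raise PanelFormatError(
                f"{self.name}: primer footprints cover the whole amplicon"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def assayed_seq(self) -> str:
        """Sequence in assayed-strand orientation (internal working frame)."""
        if self.strand == "top":
            return self.ref_seq
        return reverse_complement(self.ref_seq)

    def in_primer(self, pos: int) -> bool:
        """Whether 1-based assayed-strand position ``pos`` lies in a primer."""
        return pos <= self.fwd_primer_len or pos > self.length - self.rev_primer_len

    def genomic_pos(self, pos: int) -> int:
        """Map a 1-based assayed-strand position to a 1-based genomic position."""
        if self.strand == "top":
            return self.start + pos
        return self.end - pos + 1


@dataclass(frozen=True)
class ContextSite:
    """A classified cytosine on the assayed strand of one amplicon."""

    amplicon: str
    pos: int  # 1-based on the assayed strand
    context: str  # CpG / CHG / CHH
    in_primer: bool
    is_reference_cpg: bool


@dataclass(frozen=True)
class CapacityReport:
    """Panel loading / capacity arithmetic for one multiplexing scenario."""

    n_samples: int
    n_amplicons: int
    mean_len: float
    max_loading: int
    loading_factor: int
    region_bp: float
    feasible: bool


class Panel:
    """An ordered collection of amplicons with unique names."""

    def __init__(self, amplicons: Sequence[AmpliconDef]):
        self.amplicons: tuple[AmpliconDef, ...] = tuple(amplicons)
        names = [a.name for a in self.amplicons]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise PanelFormatError(f"duplicate amplicon names: {sorted(dupes)}")
        self._by_name = {a.name: a for a in self.amplicons}
        self._warn_overlaps()

    def _warn_overlaps(self) -> None:
        by_key: dict[tuple[str, str], list[AmpliconDef]] = {}
        for a in self.amplicons:
            by_key.setdefault((a.chrom, a.strand), []).append(a)
        for (chrom, strand), group in by_key.items():
            group = sorted(group, key=lambda a: a.start)
            for prev, cur in zip(group, group[1:]):
                if cur.start < prev.end:
                    warnings.warn(
                        f"amplicons {prev.name} and {cur.name} overlap on "
                        f"{chrom} ({strand} strand)",
                        stacklevel=3,
                    )

    def __iter__(self) -> Iterator[AmpliconDef]:
        return iter(self.amplicons)

    def __len__(self) -> int:
        return len(self.amplicons)

    def __getitem__(self, name: str) -> AmpliconDef:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.amplicons)

    def validate(
        self,
        length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS,
        typical_range: tuple[int, int] = TYPICAL_LENGTH_RANGE,
    ) -> None:
        """Check amplicon lengths against hard bounds and the typical range.

        Lengths outside ``length_bounds`` raise :class:`PanelFormatError`;
        lengths merely outside ``typical_range`` emit a warning, since
        unusually short or long PCRs amplify but tend to behave poorly.
        """
        lo, hi = length_bounds
        tlo, thi = typical_range
        for a in self.amplicons:
            if not lo <= a.length <= hi:
                raise PanelFormatError(
                    f"{a.name}: length {a.length} bp outside valid range "
                    f"[{lo}, {hi}]"
                )
            if not tlo <= a.length <= thi:
                warnings.warn(
                    f"{a.name}: length {a.length} bp outside typical design "
                    f"range [{tlo}, {thi}]",
                    stacklevel=2,
                )


def amplicon_contexts(amp: AmpliconDef) -> list[ContextSite]:
    """Classify every cytosine of one amplicon's assayed strand.

    A cytosine is classified by its following reference bases: ``CG`` is
    CpG, ``C[ACT]G`` is CHG, ``C[ACT][ACT]`` is CHH.  Cytosines whose
    downstream context is truncated by the amplicon end, or interrupted by
    an N, are skipped as unclassifiable.
    """
    s = amp.assayed_seq
    n = len(s)
    sites: list[ContextSite] = []
    for i, base in enumerate(s):
        if base != "C":
            continue
        nxt = s[i + 1] if i + 1 < n else None
        if nxt == "G":
            ctx = "CpG"
        elif nxt in ("A", "C", "T"):
            if i + 2 >= n:
                continue
            nxt2 = s[i + 2]
            if nxt2 == "G":
                ctx = "CHG"
            elif nxt2 in ("A", "C", "T"):
                ctx = "CHH"
            else:  # N
                continue
        else:  # end of amplicon or N
            continue
        sites.append(
            ContextSite(
                amplicon=amp.name,
                pos=i + 1,
                context=ctx,
                in_primer=amp.in_primer(i + 1),
                is_reference_cpg=(ctx == "CpG"),
            )
        )
    return sites


def enumerate_contexts(panel: Panel) -> list[ContextSite]:
    """All classified cytosines of the panel, in panel order."""
    sites: list[ContextSite] = []
    for amp in panel:
        sites.extend(amplicon_contexts(amp))
    return sites


def contexts_to_frame(panel: Panel) -> pd.DataFrame:
    """Context sites as a DataFrame with genomic coordinates (for TSV export)."""
    rows = []
    for amp in panel:
        for site in amplicon_contexts(amp):
            rows.append(
                {
                    "amplicon": site.amplicon,
                    "chrom": amp.chrom,
                    "pos": site.pos,
                    "genomic_pos": amp.genomic_pos(site.pos),
                    "strand": amp.strand,
                    "context": site.context,
                    "in_primer": site.in_primer,
                    "is_reference_cpg": site.is_reference_cpg,
                }
            )
    cols = [
        "amplicon", "chrom", "pos", "genomic_pos", "strand",
        "context", "in_primer", "is_reference_cpg",
    ]
    return pd.DataFrame(rows, columns=cols)


def convert_reference(seq: str, mode: str) -> str:
    """In-silico bisulfite conversion of a reference sequence.

    ``mode="unmethylated"`` converts every C to T (complete conversion of a
    fully unmethylated template); ``mode="cpg_methylated"`` converts every C
    except those immediately followed by G (fully CpG-methylated template).
    """
    if mode not in ("unmethylated", "cpg_methylated"):
        raise ValueError(f"unknown conversion mode {mode!r}")
    _check_bases(seq, "convert_reference")
    if mode == "unmethylated":
        return seq.replace("C", "T")
    out = []
    n = len(seq)
    for i, b in enumerate(seq):
        if b == "C" and not (i + 1 < n and seq[i + 1] == "G"):
            out.append("T")
        else:
            out.append(b)
    return "".join(out)


def capacity(
    n_samples: int,
    n_amplicons: int,
    mean_len: float,
    max_loading: int = DEFAULT_MAX_LOADING,
) -> CapacityReport:
    """Multiplexing capacity arithmetic.

    The *loading factor* (samples x amplicons pooled on one run) determines
    whether a design is feasible on a benchtop sequencer without excessive
    dropout; ``region_bp`` is the total target territory the design covers.
    """
    if min(n_samples, n_amplicons) < 0 or mean_len < 0 or max_loading < 0:
        raise ValueError("capacity arguments must be non-negative")
    loading = n_samples * n_amplicons
    region = n_amplicons * mean_len
    return CapacityReport(
        n_samples=n_samples,
        n_amplicons=n_amplicons,
        mean_len=mean_len,
        max_loading=max_loading,
        loading_factor=loading,
        region_bp=region,
        feasible=loading <= max_loading,
    )


_STRAND_CODES = {"+": "top", "-": "bottom", "top": "top", "bottom": "bottom"}


def load_panel(
    bed_path: str | Path,
    fasta_path: str | Path,
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS,
    typical_range: tuple[int, int] = TYPICAL_LENGTH_RANGE,
) -> Panel:
    """Load a panel from a BED file plus the reference FASTA.

    BED columns: chrom, start, end[, name, score, strand, fwd_primer_len,
    rev_primer_len].  Missing names default to ``chrom:start-end``; missing
    strand defaults to top; missing primer columns default to 0.
    """
    contigs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    amplicons: list[AmpliconDef] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise PanelFormatError(f"{bed_path}:{lineno}: fewer than 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 and fields[3] != "." else f"{chrom}:{start}-{end}"
            strand = "top"
            if len(fields) > 5 and fields[5] != ".":
                try:
                    strand = _STRAND_CODES[fields[5]]
                except KeyError:
                    raise PanelFormatError(
                        f"{bed_path}:{lineno}: bad strand {fields[5]!r}"
                    ) from None
            fwd = int(fields[6]) if len(fields) > 6 else 0
            rev = int(fields[7]) if len(fields) > 7 else 0
            if chrom not in contigs:
                raise CoordinateError(
                    f"{bed_path}:{lineno}: contig {chrom!r} absent from FASTA"
                )
            contig_seq = contigs[chrom]
            if start < 0 or end > len(contig_seq) or start >= end:
                raise CoordinateError(
                    f"{bed_path}:{lineno}: interval [{start}, {end}) outside "
                    f"contig {chrom} (length {len(contig_seq)})"
                )
            amplicons.append(
                AmpliconDef(
                    name=name,
                    chrom=chrom,
                    start=start,
                    end=end,
                    ref_seq=contig_seq[start:end],
                    strand=strand,
                    fwd_primer_len=fwd,
                    rev_primer_len=rev,
                )
            )
    panel = Panel(amplicons)
    if panel.amplicons:
        panel.validate(length_bounds=length_bounds, typical_range=typical_range)
    return panel


def write_panel(panel: Panel, bed_path: str | Path, fasta_path: str | Path) -> None:
    """Write a panel as one FASTA contig per amplicon plus a matching BED.

    Intended for round-tripping simulated panels through the file-based
    interface; each amplicon becomes its own contig named after itself.
    """
    with open(fasta_path, "w") as fa:
        for amp in panel:
            fa.write(f">{amp.name}\n{amp.ref_seq}\n")
    with open(bed_path, "w") as bed:
        for amp in panel:
            strand = "+" if amp.strand == "top" else "-"
            bed.write(
                f"{amp.name}\t0\t{amp.length}\t{amp.name}\t0\t{strand}"
                f"\t{amp.fwd_primer_len}\t{amp.rev_primer_len}\n"
            )
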