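"""Per-site methylation quantification from aligned amplicon reads.

At every assayed-strand cytosine position (primer-masked positions
excluded) a read base C counts as methylated and T as unmethylated;
other bases (sequencing error or variant) and bases below the minimum
Phred quality are ignored — the standard bisulfite calling convention.

Analysis is not limited to reference CpGs: any non-reference position
where at least one quality-passing read shows a C immediately followed by
a G is emitted as a read-evidenced CpG (``is_reference_cpg=False``).  Its
counts come from reads carrying the CpG pattern only (C·G methylated,
T·G unmethylated), so a PCR artifact appears at the coverage of the
artifact reads alone with ~100% methylation, while a SNP-created CpG —
where every template carries the G allele — appears at full coverage.
Separating the two is the job of the QC filters downstream.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedConversionRateError, UnknownAmpliconError
from .panel_model import Panel, amplicon_contexts
from .reads import AlignedPair, read_sam

_C, _G, _T = (ord(b) for b in "CGT")

CALL_COLUMNS = [
    "sample", "amplicon", "pos", "context", "is_reference_cpg",
    "n_meth", "n_unmeth", "coverage", "meth_fraction",
]

#: Default minimum Phred base quality for a base to be informative.
DEFAULT_MIN_BASEQ = 20


class CallTable:
    """Site-level methylation calls keyed by (sample, amplicon, pos, context)."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in CALL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"call table missing columns {missing}")
        df = df[CALL_COLUMNS].reset_index(drop=True)
        key = ["sample", "amplicon", "pos", "context"]
        if df.duplicated(subset=key).any():
            raise ValueError("duplicate (sample, amplicon, pos, context) keys")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def empty(cls) -> "CallTable":
        return cls(pd.DataFrame(columns=CALL_COLUMNS))

    @classmethod
    def concat(cls, tables: Iterable["CallTable"]) -> "CallTable":
        frames = [t.df for t in tables]
        if not frames:
            return cls.empty()
        return cls(pd.concat(frames, ignore_index=True))

    def cpg_sites(self, reference_only: bool = False) -> pd.DataFrame:
        df = self.df[self.df["context"] == "CpG"]
        if reference_only:
            df = df[df["is_reference_cpg"]]
        return df

    def to_tsv(self, path: str | Path, panel: Panel | None = None) -> None:
        """Write calls as TSV; with a panel, genomic coordinates are added."""
        df = self.df.copy()
        if panel is not None:
            df["chrom"] = [panel[a].chrom for a in df["amplicon"]]
            df["strand"] = [panel[a].strand for a in df["amplicon"]]
            df["genomic_pos"] = [
                panel[a].genomic_pos(int(p))
                for a, p in zip(df["amplicon"], df["pos"])
            ]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CallTable":
        return cls(pd.read_csv(path, sep="\t"))


def _group_mates(pairs: Iterable[AlignedPair]) -> dict[str, dict[tuple[int, int], list]]:
    """Mates grouped by amplicon, then by (start, length) for vectorisation."""
    grouped: dict[str, dict[tuple[int, int], list]] = defaultdict(
        lambda: defaultdict(list)
    )
    for pair in pairs:
        for mate in pair.mates():
            grouped[pair.amplicon][(mate.start, len(mate))].append(mate)
    return grouped


def call_sites(
    alignments: str | Path | Iterable[AlignedPair],
    panel: Panel,
    sample: str = "sample",
    min_baseq: int = DEFAULT_MIN_BASEQ,
) -> CallTable:
    """Quantify methylation per site from aligned (overlap-trimmed) reads.

    ``alignments`` may be a SAM path or an iterable of
    :class:`~hamtbs.reads.AlignedPair`.  Reference context sites of every
    amplicon with at least one aligned pair are always reported (with zero
    counts where uncovered); read-evidenced non-reference CpGs are reported
    where at least one read shows the C·G pattern.
    """
    if isinstance(alignments, (str, Path)):
        pairs: Iterable[AlignedPair] = read_sam(alignments)
    else:
        pairs = alignments
    grouped = _group_mates(pairs)
    unknown = set(grouped) - set(panel.names)
    if unknown:
        raise UnknownAmpliconError(
            f"alignments reference amplicons absent from the panel: {sorted(unknown)}"
        )

    rows: list[dict] = []
    for amp in panel:
        if amp.name not in grouped:
            continue
        sites = amplicon_contexts(amp)
        length = amp.length
        is_cyt = np.zeros(length, dtype=bool)
        is_refcpg = np.zeros(length, dtype=bool)
        in_primer = np.zeros(length, dtype=bool)
        for i in range(1, length + 1):
            in_primer[i - 1] = amp.in_primer(i)
        for site in sites:
            is_cyt[site.pos - 1] = True
            if site.is_reference_cpg:
                is_refcpg[site.pos - 1] = True

        n_meth = np.zeros(length, dtype=np.int64)
        n_unmeth = np.zeros(length, dtype=np.int64)
        cg_meth = np.zeros(length, dtype=np.int64)
        cg_unmeth = np.zeros(length, dtype=np.int64)

        for (start, ln), mates in grouped[amp.name].items():
            bases = np.stack([m.bases for m in mates])
            quals = np.stack([m.quals for m in mates])
            ok = quals >= min_baseq
            refpos = np.arange(start - 1, start - 1 + ln)
            informative = is_cyt[refpos] & ~in_primer[refpos]
            c_counts = ((bases == _C) & ok).sum(axis=0)
            t_counts = ((bases == _T) & ok).sum(axis=0)
            n_meth[refpos[informative]] += c_counts[informative]
            n_unmeth[refpos[informative]] += t_counts[informative]
            if ln >= 2:
                ok2 = ok[:, :-1] & ok[:, 1:]
                cg_m = ((bases[:, :-1] == _C) & (bases[:, 1:] == _G) & ok2).sum(axis=0)
                cg_u = ((bases[:, :-1] == _T) & (bases[:, 1:] == _G) & ok2).sum(axis=0)
                p0 = refpos[:-1]
                eligible = ~is_refcpg[p0] & ~in_primer[p0]
                cg_meth[p0[eligible]] += cg_m[eligible]
                cg_unmeth[p0[eligible]] += cg_u[eligible]

        for site in sites:
            if site.in_primer:
                continue
            p = site.pos - 1
            cov = int(n_meth[p] + n_unmeth[p])
            rows.append(
                {
                    "sample": sample,
                    "amplicon": amp.name,
                    "pos": site.pos,
                    "context": site.context,
                    "is_reference_cpg": site.is_reference_cpg,
                    "n_meth": int(n_meth[p]),
                    "n_unmeth": int(n_unmeth[p]),
                    "coverage": cov,
                    "meth_fraction": n_meth[p] / cov if cov else np.nan,
                }
            )
        for p in np.flatnonzero(cg_meth > 0):
            cov = int(cg_meth[p] + cg_unmeth[p])
            rows.append(
                {
                    "sample": sample,
                    "amplicon": amp.name,
                    "pos": int(p) + 1,
                    "context": "CpG",
                    "is_reference_cpg": False,
                    "n_meth": int(cg_meth[p]),
                    "n_unmeth": int(cg_unmeth[p]),
                    "coverage": cov,
                    "meth_fraction": cg_meth[p] / cov,
                }
            )
    return CallTable(pd.DataFrame(rows, columns=CALL_COLUMNS))


def conversion_table(calls: CallTable) -> pd.DataFrame:
    """Bisulfite conversion rate per sample x amplicon.

    The rate is the fraction of CHH-context cytosine observations read as T
    (CHH cytosines are essentially unmethylated in genomic DNA, so retained
    Cs measure conversion failure).  CHG observations are reported by the
    caller but deliberately excluded from the denominator.  Units with no
    CHH coverage get a NaN rate.
    """
    df = calls.df
    units = df[["sample", "amplicon"]].drop_duplicates().reset_index(drop=True)
    chh = df[df["context"] == "CHH"]
    agg = (
        chh.groupby(["sample", "amplicon"], as_index=False)[["n_unmeth", "coverage"]]
        .sum()
    )
    out = units.merge(agg, on=["sample", "amplicon"], how="left")
    out["conversion_rate"] = np.where(
        out["coverage"].fillna(0) > 0,
        out["n_unmeth"] / out["coverage"],
        np.nan,
    )
    return out[["sample", "amplicon", "conversion_rate"]]


def conversion_rate(calls: CallTable, sample: str, amplicon: str) -> float:
    """Conversion rate of one sample x amplicon unit.

    Raises :class:`UndefinedConversionRateError` when the unit has no CHH
    observations, so an undefined rate is reported rather than silently
    passed downstream.
    """
    df = calls.df
    chh = df[
        (df["sample"] == sample)
        & (df["amplicon"] == amplicon)
        & (df["context"] == "CHH")
    ]
    total = int(chh["coverage"].sum())
    if total == 0:
        raise UndefinedConversionRateError(
            f"no CHH coverage for sample {sample!r}, amplicon {amplicon!r}"
        )
    return float(chh["n_unmeth"].sum() / total)
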