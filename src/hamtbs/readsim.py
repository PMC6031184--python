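"""Synthetic bisulfite amplicon sequencing data with known ground truth.

The simulator emulates the data produced by bisulfite PCR of control DNA:
for each template fragment, every CpG cytosine on the assayed strand is
methylated with its profile probability; methylated cytosines are protected
and read as C, while unmethylated cytosines (CpG or otherwise) are
deaminated with probability ``conversion_efficiency`` and read as T
(unconverted ones remain C, modelling incomplete conversion).  Uniform
per-base call errors are applied on top.  Fragments cover the full
amplicon, sequenced as paired-end reads from both ends, which overlap
whenever ``2 x read_length`` exceeds the amplicon length.

Methylation states are drawn independently per fragment and per site
(no haplotype correlation) and conversion failures are i.i.d. per
cytosine; both are sufficient for site-level statistics.  PCR duplicates,
indels and adapter read-through are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .panel_model import AmpliconDef, Panel, amplicon_contexts, convert_reference
from .reads import AlignedPair, Mate

_A, _C, _G, _T = (ord(b) for b in "ACGT")

# substitution alternatives for uniform base-call errors, indexed by base
_ALT_BASES = np.array(
    [[_C, _G, _T], [_A, _G, _T], [_A, _C, _T], [_A, _C, _G]], dtype=np.uint8
)
_BASE_ROW = np.zeros(256, dtype=np.int64)
for _i, _b in enumerate((_A, _C, _G, _T)):
    _BASE_ROW[_b] = _i

TRUTH_COLUMNS = [
    "amplicon", "pos", "context", "is_reference_cpg",
    "true_methylation", "conversion_efficiency", "artifact",
]


@dataclass
class SimConfig:
    """Simulation parameters for one sample.

    depth:
        Template fragments per amplicon.
    conversion_efficiency:
        Probability that an unmethylated cytosine is deaminated (read T).
    base_error_rate:
        Per-base probability of a uniform miscall.
    read_length:
        Mate length in bp (capped at the amplicon length).
    base_quality:
        Constant Phred score assigned to every base.
    overlap_low_quality:
        If set, mate 2 bases inside the mate overlap get this (lower)
        quality instead, to exercise quality-aware overlap trimming.
    """

    depth: int = 2000
    conversion_efficiency: float = 0.99
    base_error_rate: float = 0.001
    read_length: int = 300
    paired: bool = True
    seed: int | None = None
    base_quality: int = 37
    overlap_low_quality: int | None = None

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ConfigurationError("depth must be non-negative")
        for name in ("conversion_efficiency", "base_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.read_length < 1:
            raise ConfigurationError("read_length must be positive")


class MethylationProfile:
    """True methylation fraction per (amplicon, CpG position)."""

    def __init__(self, levels: Mapping[tuple[str, int], float]):
        for key, v in levels.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(
                    f"methylation level for {key} outside [0, 1]: {v}"
                )
        self._levels = dict(levels)

    def __len__(self) -> int:
        return len(self._levels)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._levels

    def level(self, amplicon: str, pos: int) -> float:
        try:
            return self._levels[(amplicon, pos)]
        except KeyError:
            raise ConfigurationError(
                f"profile has no entry for CpG {amplicon}:{pos}"
            ) from None

    def items(self):
        return self._levels.items()

    @classmethod
    def uniform(cls, panel: Panel, level: float) -> "MethylationProfile":
        """Every reference CpG of the panel set to ``level``."""
        if not 0.0 <= level <= 1.0:
            raise ConfigurationError(f"level outside [0, 1]: {level}")
        levels = {
            (site.amplicon, site.pos): level
            for amp in panel
            for site in amplicon_contexts(amp)
            if site.is_reference_cpg
        }
        return cls(levels)

    def validate_against(self, panel: Panel) -> None:
        missing = [
            (site.amplicon, site.pos)
            for amp in panel
            for site in amplicon_contexts(amp)
            if site.is_reference_cpg and (site.amplicon, site.pos) not in self._levels
        ]
        if missing:
            raise ConfigurationError(
                f"profile missing {len(missing)} panel CpG(s), e.g. {missing[0]}"
            )


def mix_titration(panel: Panel, levels: Sequence[float]) -> list[MethylationProfile]:
    """Uniform profiles emulating a titration series of mixed control DNA.

    Each level produces one profile with every panel CpG at that fraction,
    the in-silico analogue of mixing fully methylated and unmethylated
    control DNA at the given ratio.
    """
    return [MethylationProfile.uniform(panel, level) for level in levels]


@dataclass
class SimResult:
    """Simulated reads plus the per-site truth table."""

    pairs: list[AlignedPair]
    truth: pd.DataFrame


def _mate_qualities(
    amp_len: int, read_len: int, config: SimConfig
) -> tuple[np.ndarray, np.ndarray]:
    q1 = np.full(read_len, config.base_quality, dtype=np.uint8)
    q2 = np.full(read_len, config.base_quality, dtype=np.uint8)
    if config.overlap_low_quality is not None:
        m2_start = amp_len - read_len + 1
        # mate2 offsets whose reference position also falls inside mate1
        n_overlap = max(0, read_len - m2_start + 1)
        q2[:n_overlap] = config.overlap_low_quality
    return q1, q2


def _simulate_amplicon(
    amp: AmpliconDef,
    profile: MethylationProfile,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[AlignedPair]:
    seq = amp.assayed_seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    length = len(arr)
    depth = config.depth
    if depth == 0:
        return []

    c_pos = np.flatnonzero(arr == _C)
    is_cpg = np.zeros(length, dtype=bool)
    is_cpg[:-1] = (arr[:-1] == _C) & (arr[1:] == _G)
    p_site = np.array(
        [
            profile.level(amp.name, int(p) + 1) if is_cpg[p] else 0.0
            for p in c_pos
        ]
    )

    mat = np.repeat(arr[None, :], depth, axis=0)
    if c_pos.size:
        methylated = rng.random((depth, c_pos.size)) < p_site
        converted = ~methylated & (
            rng.random((depth, c_pos.size)) < config.conversion_efficiency
        )
        sub = mat[:, c_pos]
        sub[converted] = _T
        mat[:, c_pos] = sub
    if config.base_error_rate > 0:
        err = rng.random(mat.shape) < config.base_error_rate
        idx = np.nonzero(err)
        if idx[0].size:
            pick = rng.integers(0, 3, idx[0].size)
            mat[idx] = _ALT_BASES[_BASE_ROW[mat[idx]], pick]

    read_len = min(config.read_length, length)
    pairs: list[AlignedPair] = []
    if config.paired:
        q1, q2 = _mate_qualities(length, read_len, config)
        m2_start = length - read_len + 1
        for i in range(depth):
            pairs.append(
                AlignedPair(
                    amplicon=amp.name,
                    name=f"{amp.name}:frag{i}",
                    mate1=Mate(1, mat[i, :read_len], q1),
                    mate2=Mate(m2_start, mat[i, length - read_len :], q2),
                )
            )
    else:
        q1 = np.full(read_len, config.base_quality, dtype=np.uint8)
        for i in range(depth):
            pairs.append(
                AlignedPair(
                    amplicon=amp.name,
                    name=f"{amp.name}:frag{i}",
                    mate1=Mate(1, mat[i, :read_len], q1),
                )
            )
    return pairs


def _truth_table(panel: Panel, profile: MethylationProfile, config: SimConfig) -> pd.DataFrame:
    rows = []
    for amp in panel:
        for site in amplicon_contexts(amp):
            rows.append(
                {
                    "amplicon": site.amplicon,
                    "pos": site.pos,
                    "context": site.context,
                    "is_reference_cpg": site.is_reference_cpg,
                    "true_methylation": (
                        profile.level(site.amplicon, site.pos)
                        if site.is_reference_cpg
                        else 0.0
                    ),
                    "conversion_efficiency": config.conversion_efficiency,
                    "artifact": False,
                }
            )
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def simulate_sample(
    panel: Panel, profile: MethylationProfile, config: SimConfig
) -> SimResult:
    """Simulate one sample's reads over the whole panel.

    Returns aligned pairs (reference orientation, correct coordinates) and
    a truth table holding the generating methylation level and conversion
    efficiency for every classified cytosine.  A fixed seed yields
    byte-identical output.
    """
    profile.validate_against(panel)
    rng = np.random.default_rng(config.seed)
    pairs: list[AlignedPair] = []
    for amp in panel:
        pairs.extend(_simulate_amplicon(amp, profile, config, rng))
    return SimResult(pairs=pairs, truth=_truth_table(panel, profile, config))


def inject_artifacts(
    pairs: Iterable[AlignedPair],
    panel: Panel,
    positions: Sequence[tuple[str, int]],
    n_reads: int,
    read_length: int = 300,
    base_quality: int = 37,
    seed: int | None = None,
) -> tuple[list[AlignedPair], pd.DataFrame]:
    """Append PCR-artifact read pairs presenting a spurious CpG.

    Each position must be a non-CpG cytosine of the reference (1-based,
    assayed strand).  For every position, ``n_reads`` fully converted
    full-length pairs are added that differ from a clean template only at
    the artifact: an unconverted C at the position immediately followed by
    a G, mimicking an amplification error that fabricates a CpG.  Such
    sites later present at very low coverage with ~100% apparent
    methylation.  Construction is deterministic; ``seed`` is accepted for
    interface symmetry only.

    Returns the extended pair list plus truth rows flagging each artifact.
    """
    del seed  # construction is deterministic
    out = list(pairs)
    truth_rows = []
    for amp_name, pos in positions:
        amp = panel[amp_name]
        seq = amp.assayed_seq
        if pos < 1 or pos + 1 > amp.length:
            raise ConfigurationError(
                f"artifact position {amp_name}:{pos} outside amplicon"
            )
        if seq[pos - 1] != "C":
            raise ConfigurationError(
                f"artifact position {amp_name}:{pos} is not a cytosine"
            )
        if seq[pos] == "G":
            raise ConfigurationError(
                f"artifact position {amp_name}:{pos} is a reference CpG"
            )
        backbone = convert_reference(seq, "unmethylated")
        art = np.frombuffer(backbone.encode("ascii"), dtype=np.uint8).copy()
        art[pos - 1] = _C
        art[pos] = _G
        length = amp.length
        read_len = min(read_length, length)
        m2_start = length - read_len + 1
        qual = np.full(read_len, base_quality, dtype=np.uint8)
        for i in range(n_reads):
            out.append(
                AlignedPair(
                    amplicon=amp.name,
                    name=f"{amp.name}:artifact{pos}:{i}",
                    mate1=Mate(1, art[:read_len], qual),
                    mate2=Mate(m2_start, art[length - read_len :], qual),
                )
            )
        if n_reads > 0:
            truth_rows.append(
                {
                    "amplicon": amp.name,
                    "pos": pos,
                    "context": "CpG",
                    "is_reference_cpg": False,
                    "true_methylation": float("nan"),
                    "conversion_efficiency": float("nan"),
                    "artifact": True,
                }
            )
    return out, pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)


def inject_snp_cpg(
    pairs: Iterable[AlignedPair],
    panel: Panel,
    amplicon: str,
    pos: int,
    meth_level: float = 0.5,
    seed: int | None = None,
) -> list[AlignedPair]:
    """Rewrite all reads of one amplicon to carry a SNP creating a CpG.

    Every template of ``amplicon`` gets a G at ``pos + 1`` (the variant
    allele) and a methylation state at ``pos`` drawn per fragment with
    probability ``meth_level`` (C if methylated, T otherwise).  Unlike a
    PCR artifact, the resulting non-reference CpG appears at full coverage
    with an intermediate methylation level, which is exactly the signature
    QC must preserve.
    """
    amp = panel[amplicon]
    if pos < 1 or pos + 1 > amp.length:
        raise ConfigurationError(f"SNP position {amplicon}:{pos} outside amplicon")
    if amp.assayed_seq[pos] == "G" and amp.assayed_seq[pos - 1] == "C":
        raise ConfigurationError(f"{amplicon}:{pos} is already a reference CpG")
    rng = np.random.default_rng(seed)
    out: list[AlignedPair] = []
    for pair in pairs:
        if pair.amplicon != amplicon:
            out.append(pair)
            continue
        meth = rng.random() < meth_level
        new_mates: dict[str, Mate | None] = {}
        for key, mate in (("mate1", pair.mate1), ("mate2", pair.mate2)):
            if mate is None or len(mate) == 0:
                new_mates[key] = mate
                continue
            bases = mate.bases.copy()
            if mate.start <= pos <= mate.end:
                bases[pos - mate.start] = _C if meth else _T
            if mate.start <= pos + 1 <= mate.end:
                bases[pos + 1 - mate.start] = _G
            new_mates[key] = Mate(mate.start, bases, mate.quals)
        out.append(
            AlignedPair(pair.amplicon, pair.name, new_mates["mate1"], new_mates["mate2"])
        )
    return out


def synthetic_panel(
    n_amplicons: int = 7,
    n_cpgs: int = 5,
    n_chh: int = 20,
    length: int = 330,
    fwd_primer_len: int = 0,
    rev_primer_len: int = 0,
    seed: int = 0,
    name_prefix: str = "amp",
    chrom: str = "simchr",
) -> Panel:
    """Construct a panel of synthetic amplicons with controlled contexts.

    Each amplicon is an A/T background carrying exactly ``n_cpgs`` CpG
    dinucleotides and ``n_chh`` CHH cytosines, evenly spread outside the
    primer footprints with at least 4 bp spacing so no incidental CpG/CHG
    contexts arise.  CHH cytosines give the conversion-rate denominator the
    same role unmethylated genomic cytosines play in real amplicons.
    """
    rng = np.random.default_rng(seed)
    n_sites = n_cpgs + n_chh
    amps = []
    for k in range(n_amplicons):
        bg = rng.choice(np.frombuffer(b"AT", dtype=np.uint8), size=length)
        lo = fwd_primer_len + 2
        hi = length - rev_primer_len - 4
        site_pos = np.linspace(lo, hi, n_sites).astype(int)
        if n_sites > 1 and np.diff(site_pos).min() < 4:
            raise ConfigurationError(
                "amplicon too short for the requested number of sites"
            )
        # interleave CpGs evenly among the sites
        cpg_slots = set(np.linspace(0, n_sites - 1, n_cpgs).astype(int).tolist())
        if len(cpg_slots) != n_cpgs:
            raise ConfigurationError("cannot place distinct CpG slots")
        seq = bg.copy()
        for slot, p in enumerate(site_pos):
            seq[p] = _C
            if slot in cpg_slots:
                seq[p + 1] = _G
        amps.append(
            AmpliconDef(
                name=f"{name_prefix}{k + 1}",
                chrom=chrom,
                start=k * (length + 50),
                end=k * (length + 50) + length,
                ref_seq=seq.tobytes().decode("ascii"),
                strand="top",
                fwd_primer_len=fwd_primer_len,
                rev_primer_len=rev_primer_len,
            )
        )
    return Panel(amps)
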