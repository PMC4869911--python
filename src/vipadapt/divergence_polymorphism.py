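"""Lineage substitution calling, site frequency spectra and pN/pS statistics.

Substitutions on a focal lineage (e.g. human) are called from three-species
codon alignments (focal, outgroup1, outgroup2): a position is a candidate
only where the two outgroups agree with each other and differ from the focal
sequence, and the position is not segregating in the focal population.
Polymorphism-side statistics are built from polarized variants carrying a
derived allele frequency (DAF) and a synonymous/non-synonymous class.

Coordinates are 0-based half-open internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq

from .errors import AlignmentError, ParameterError, UndefinedRatioError

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")

SYN = "syn"
NONSYN = "nonsyn"


@dataclass(frozen=True)
class VariantSite:
    """A polarized polymorphic site.

    daf is the derived allele frequency, strictly inside (0, 1);
    allele_count is the number of derived copies in the sample (used for
    singleton exclusion).
    """

    gene_id: str
    daf: float
    klass: str
    allele_count: int = 2

    def __post_init__(self):
        if not 0.0 < self.daf < 1.0:
            raise ParameterError(f"daf must be in (0,1), got {self.daf}")
        if self.klass not in (SYN, NONSYN):
            raise ParameterError(f"klass must be '{SYN}' or '{NONSYN}', got {self.klass!r}")


@dataclass
class MkCounts:
    """McDonald-Kreitman 2x2 contingency counts."""

    DN: int = 0
    DS: int = 0
    pN: int = 0
    pS: int = 0

    def __post_init__(self):
        for name in ("DN", "DS", "pN", "pS"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ParameterError(f"{name} must be a non-negative integer, got {v}")

    def __add__(self, other: "MkCounts") -> "MkCounts":
        return MkCounts(self.DN + other.DN, self.DS + other.DS,
                        self.pN + other.pN, self.pS + other.pS)


@dataclass
class SfsTable:
    """Binned site frequency spectrum, one count vector per variant class.

    Bins are half-open [lo, hi) except the last, which is closed. Counts are
    float-valued so that rescaled spectra stay exact.
    """

    bin_edges: np.ndarray
    counts_nonsyn: np.ndarray
    counts_syn: np.ndarray
    sample_label: str = ""
    overflow_nonsyn: float = 0.0
    overflow_syn: float = 0.0

    @property
    def midpoints(self) -> np.ndarray:
        e = self.bin_edges
        return (e[:-1] + e[1:]) / 2.0

    def total(self, klass: str) -> float:
        if klass == NONSYN:
            return float(self.counts_nonsyn.sum() + self.overflow_nonsyn)
        return float(self.counts_syn.sum() + self.overflow_syn)


def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def call_substitutions(
    alignment: Sequence[str],
    polymorphic_positions: Iterable[int] = (),
) -> MkCounts:
    """Call fixed focal-lineage substitutions from a 3-way codon alignment.

    ``alignment`` is (focal, outgroup1, outgroup2), equal-length nucleotide
    strings with length divisible by 3, in frame. A nucleotide position is
    callable when outgroup1 == outgroup2 != focal and the position index is
    not in ``polymorphic_positions`` (fixed-in-focal requirement). Codons
    carrying more than one callable difference, ambiguous bases, or a stop in
    either state are skipped and logged (conservative).

    Returns an :class:`MkCounts` with only DN and DS populated.
    """
    if len(alignment) != 3:
        raise AlignmentError("alignment must contain exactly 3 sequences (focal, out1, out2)")
    focal, out1, out2 = (s.upper() for s in alignment)
    if not (len(focal) == len(out1) == len(out2)):
        raise AlignmentError("sequences must have equal length")
    if len(focal) % 3 != 0:
        raise AlignmentError(f"alignment length {len(focal)} is not a multiple of 3")
    poly = frozenset(polymorphic_positions)

    dn = ds = 0
    n_skipped = 0
    for start in range(0, len(focal), 3):
        cf = focal[start:start + 3]
        c1 = out1[start:start + 3]
        c2 = out2[start:start + 3]
        if any(b not in _VALID_BASES for b in cf + c1 + c2):
            n_skipped += 1
            logger.debug("codon at %d skipped: ambiguous base", start)
            continue
        # outgroup consensus with focal base where outgroups disagree
        consensus = []
        n_diff = 0
        for k in range(3):
            pos = start + k
            if c1[k] == c2[k] and c1[k] != cf[k] and pos not in poly:
                consensus.append(c1[k])
                n_diff += 1
            else:
                consensus.append(cf[k])
        if n_diff == 0:
            continue
        if n_diff > 1:
            n_skipped += 1
            logger.debug("codon at %d skipped: %d differences", start, n_diff)
            continue
        aa_f = translate_codon(cf)
        aa_a = translate_codon("".join(consensus))
        if aa_f == "*" or aa_a == "*":
            n_skipped += 1
            logger.debug("codon at %d skipped: stop codon", start)
            continue
        if aa_f == aa_a:
            ds += 1
        else:
            dn += 1
    if n_skipped:
        logger.info("call_substitutions skipped %d codons", n_skipped)
    return MkCounts(DN=dn, DS=ds, pN=0, pS=0)


def filter_daf(variants: Sequence[VariantSite], lo: float, hi: float) -> list[VariantSite]:
    """Retain variants with lo <= daf <= hi (closed interval)."""
    if not 0.0 <= lo < hi <= 1.0:
        raise ParameterError(f"require 0 <= lo < hi <= 1, got lo={lo}, hi={hi}")
    return [v for v in variants if lo <= v.daf <= hi]


def exclude_singletons(variants: Sequence[VariantSite]) -> list[VariantSite]:
    """Drop variants seen in exactly one chromosome of the sample."""
    return [v for v in variants if v.allele_count != 1]


def mispolarize(
    variants: Sequence[VariantSite],
    epsilon: float,
    seed: int,
    sample_size: int | None = None,
) -> list[VariantSite]:
    """Flip daf -> 1 - daf with probability ``epsilon`` per variant.

    Emulates ancestral-state misassignment, which piles spurious variants
    into the high-frequency tail of the unfolded SFS; this is the motivation
    for fitting the asymptotic curve only below DAF 0.5.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ParameterError("epsilon must be in [0,1]")
    rng = np.random.default_rng(seed)
    out = []
    for v in variants:
        if rng.random() < epsilon:
            n = sample_size
            ac = (n - v.allele_count) if n is not None else v.allele_count
            out.append(replace(v, daf=1.0 - v.daf, allele_count=ac))
        else:
            out.append(v)
    return out


def default_bin_edges(width: float = 0.1) -> np.ndarray:
    n = int(round(1.0 / width))
    return np.linspace(0.0, 1.0, n + 1)


def build_sfs(
    variants: Sequence[VariantSite],
    bin_edges: Sequence[float] | None = None,
    exclude_singletons_flag: bool = False,
    sample_label: str = "",
) -> SfsTable:
    """Bin variants into a per-class site frequency spectrum.

    Singletons (allele_count == 1) are removed first when the flag is set,
    mirroring the sequencing-error guard used for pN/pS. Variants with DAF
    outside [min_edge, max_edge] land in per-class overflow buckets.
    """
    edges = np.asarray(default_bin_edges() if bin_edges is None else bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ParameterError("bin_edges must be strictly increasing with >= 2 entries")
    if edges[0] < 0 or edges[-1] > 1:
        raise ParameterError("bin_edges must lie within [0, 1]")
    vs = list(variants)
    if exclude_singletons_flag:
        vs = exclude_singletons(vs)
    counts = {SYN: np.zeros(len(edges) - 1), NONSYN: np.zeros(len(edges) - 1)}
    overflow = {SYN: 0.0, NONSYN: 0.0}
    for v in vs:
        if v.daf < edges[0] or v.daf > edges[-1]:
            overflow[v.klass] += 1
            logger.debug("variant daf=%g outside bin range -> overflow", v.daf)
            continue
        # half-open bins, last bin closed
        i = int(np.searchsorted(edges, v.daf, side="right")) - 1
        i = min(i, len(edges) - 2)
        counts[v.klass][i] += 1
    if overflow[SYN] or overflow[NONSYN]:
        logger.info("build_sfs overflow: %s syn, %s nonsyn", overflow[SYN], overflow[NONSYN])
    return SfsTable(
        bin_edges=edges,
        counts_nonsyn=counts[NONSYN],
        counts_syn=counts[SYN],
        sample_label=sample_label,
        overflow_nonsyn=overflow[NONSYN],
        overflow_syn=overflow[SYN],
    )


def rescale_sfs(sfs_control: SfsTable, n_focal: int, n_control: int) -> SfsTable:
    """Rescale a control SFS by the focal/control set-size ratio.

    Makes a large control cohort's spectrum directly comparable with a
    smaller focal cohort: every count is multiplied by n_focal / n_control.
    """
    if n_control <= 0:
        raise ParameterError("n_control must be > 0")
    f = n_focal / n_control
    return SfsTable(
        bin_edges=sfs_control.bin_edges.copy(),
        counts_nonsyn=sfs_control.counts_nonsyn * f,
        counts_syn=sfs_control.counts_syn * f,
        sample_label=sfs_control.sample_label,
        overflow_nonsyn=sfs_control.overflow_nonsyn * f,
        overflow_syn=sfs_control.overflow_syn * f,
    )


RAW = "raw"
PS_PLUS_ONE = "ps_plus_one"


def pnps_gene(pN: float, pS: float, mode: str = PS_PLUS_ONE) -> float:
    """Per-gene pN/pS constraint statistic.

    ``ps_plus_one`` returns pN/(pS+1), defined even when pS = 0 (the standard
    guard for short coding sequences with no synonymous variant); ``raw``
    returns pN/pS and raises when pS = 0.
    """
    if pN < 0 or pS < 0:
        raise ParameterError("counts must be >= 0")
    if mode == RAW:
        if pS == 0:
            raise UndefinedRatioError("pN/pS undefined with pS=0 in raw mode")
        return pN / pS
    if mode == PS_PLUS_ONE:
        return pN / (pS + 1.0)
    raise ParameterError(f"unknown mode {mode!r}")


MEAN_OF_RATIOS = "mean_of_ratios"
RATIO_OF_SUMS = "ratio_of_sums"


def pnps_group(pairs: Sequence[tuple[float, float]], mode: str = RATIO_OF_SUMS) -> float:
    """Group-level pN/pS over (pN, pS) pairs.

    ``ratio_of_sums`` pools counts (sum pN / sum pS), the form used as the
    matching/permutation statistic; ``mean_of_ratios`` averages per-gene
    pN/(pS+1).
    """
    pairs = list(pairs)
    if not pairs:
        raise ParameterError("pnps_group requires a non-empty input")
    if mode == RATIO_OF_SUMS:
        tot_n = sum(p for p, _ in pairs)
        tot_s = sum(s for _, s in pairs)
        if tot_s == 0:
            raise UndefinedRatioError("pooled pS is 0")
        return tot_n / tot_s
    if mode == MEAN_OF_RATIOS:
        return float(np.mean([pnps_gene(p, s, PS_PLUS_ONE) for p, s in pairs]))
    raise ParameterError(f"unknown mode {mode!r}")
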