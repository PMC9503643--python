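"""Termini detection from strand-specific read starting-position coverage.

The starting-position coverage (SPC) of a base is the number of reads whose
5' mapped end falls exactly there, counted per strand.  Physical ends of the
packaged DNA molecules are over-represented as read starts because shearing
can never split a terminus into the interior of a fragment, so:

* a single sharp SPC peak on one strand marks a preferred headful packaging
  initiation (pac) site;
* opposing peaks on both strands mark fixed termini (cos or DTR; DTR shows
  doubled plain coverage over the repeat between the peaks);
* no peak at all is what headful packaging without a preferred start — or a
  circularly permuted population — looks like.

Peak strength is summarised by the ratio R of the highest to the
second-highest SPC on the same strand, reported to two decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy import stats

from .simulate import ReadSet, revcomp

__all__ = [
    "StrandProfiles",
    "PeakStat",
    "TerminiCall",
    "DetectionParams",
    "UndefinedRatioError",
    "compute_spc",
    "peak_ratio",
    "detect_termini",
    "reorganize",
    "circular_permutation_offset",
    "junction_spanning_reads",
]

LOW_COVERAGE_DEPTH = 200.0  # warn below this mean fold-coverage


class UndefinedRatioError(ValueError):
    """Raised when the peak ratio is requested on an all-zero SPC array."""


@dataclass
class StrandProfiles:
    """Per-strand SPC arrays and plain per-base coverage.

    Arrays are indexed 0-based internally; index i corresponds to 1-based
    genome position i + 1.
    """

    genome_length: int
    spc_fwd: np.ndarray
    spc_rev: np.ndarray
    coverage: np.ndarray

    @property
    def n_alignments(self) -> int:
        return int(self.spc_fwd.sum() + self.spc_rev.sum())

    @property
    def mean_depth(self) -> float:
        return float(self.coverage.mean())


@dataclass
class PeakStat:
    """The top SPC position on one strand and the peak-height ratio R."""

    position: int  # 1-based, lowest coordinate attaining the maximum
    strand: str
    top_count: int
    second_count: int
    ratio: float  # top/second, rounded to 2 decimals; inf when second == 0
    infinite: bool = False

    def as_dict(self) -> dict:
        return {
            "position": self.position,
            "strand": self.strand,
            "top_count": self.top_count,
            "second_count": self.second_count,
            "ratio": None if self.infinite else self.ratio,
            "infinite": self.infinite,
        }


@dataclass
class DetectionParams:
    """Significance thresholds for calling an SPC peak.

    A peak is significant when its count is at least ``min_top_count``, the
    ratio R is at least ``min_ratio``, and the count is implausible under a
    Poisson background with the strand-wise mean SPC as its mean
    (tail probability below ``max_poisson_p``).  ``dtr_coverage_factor`` is
    the repeat-interval coverage enrichment (relative to the genome-wide
    mean) above which opposing fixed termini are subclassed as DTR rather
    than cos: a fully repeated interval doubles coverage, 1.5 allows noise.
    """

    min_ratio: float = 5.0
    min_top_count: int = 20
    max_poisson_p: float = 1e-6
    dtr_coverage_factor: float = 1.5
    low_coverage_depth: float = LOW_COVERAGE_DEPTH


@dataclass
class TerminiCall:
    """Inferred packaging class with the supporting peak statistics."""

    strategy_call: str  # HEADFUL_PAC | HEADFUL_RANDOM_OR_PERMUTED | FIXED_TERMINI_COS | FIXED_TERMINI_DTR | UNDETERMINED
    pac: Optional[PeakStat] = None
    left_terminus: Optional[PeakStat] = None
    right_terminus: Optional[PeakStat] = None
    mean_depth: float = 0.0
    low_coverage_warning: bool = False
    repeat_interval: Optional[tuple[int, int]] = None  # 1-based inclusive, forward circular
    repeat_coverage_ratio: Optional[float] = None
    notes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "strategy_call": self.strategy_call,
            "pac": self.pac.as_dict() if self.pac else None,
            "left_terminus": self.left_terminus.as_dict() if self.left_terminus else None,
            "right_terminus": self.right_terminus.as_dict() if self.right_terminus else None,
            "mean_depth": round(self.mean_depth, 2),
            "low_coverage_warning": self.low_coverage_warning,
            "repeat_interval": list(self.repeat_interval) if self.repeat_interval else None,
            "repeat_coverage_ratio": (
                round(self.repeat_coverage_ratio, 3)
                if self.repeat_coverage_ratio is not None
                else None
            ),
            "notes": self.notes,
        }


def _as_arrays(alignments) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalise alignment input to (ref_start, forward, length) arrays."""
    if isinstance(alignments, ReadSet):
        return alignments.ref_start, alignments.forward, alignments.read_length
    rows = list(alignments)
    if not rows:
        e = np.empty(0, int)
        return e, np.empty(0, bool), e.copy()
    starts = np.array([r[0] for r in rows], dtype=int)
    fwd = np.array([r[1] == "+" for r in rows], dtype=bool)
    lens = np.array([r[2] for r in rows], dtype=int)
    return starts, fwd, lens


def compute_spc(alignments, genome_length: int) -> StrandProfiles:
    """Tally per-strand 5'-end counts and per-base coverage.

    ``alignments`` is either a :class:`~pacscope.simulate.ReadSet` or an
    iterable of ``(ref_start, strand, read_length)`` with ``ref_start`` the
    1-based 5' mapped end.  A forward read covers ``ref_start`` and the
    read_length - 1 bases to its right; a reverse read covers ``ref_start``
    and the bases to its left; both wrap circularly.
    """
    G = genome_length
    starts, fwd, lens = _as_arrays(alignments)
    if len(starts) and (starts.min() < 1 or starts.max() > G):
        bad = starts[(starts < 1) | (starts > G)][0]
        raise ValueError(f"ref_start {bad} outside 1..{G}")
    s0 = starts - 1  # 0-based
    spc_fwd = np.bincount(s0[fwd], minlength=G).astype(np.int64)
    spc_rev = np.bincount(s0[~fwd], minlength=G).astype(np.int64)

    # coverage via circular difference array: forward reads cover [s, s+L-1],
    # reverse reads cover [s-L+1, s]
    diff = np.zeros(G + 1, dtype=np.int64)
    left = np.where(fwd, s0, s0 - lens + 1) % G
    full_wraps = lens // G
    rem = lens % G
    if len(starts):
        np.add.at(diff, left, 1)
        end = left + rem  # exclusive
        over = end >= G
        np.add.at(diff, np.where(over, G, end), -1)
        if over.any():
            diff[0] += over.sum()
            np.add.at(diff, end[over] - G, -1)
    coverage = np.cumsum(diff[:G]) + (full_wraps.sum() if len(starts) else 0)
    return StrandProfiles(G, spc_fwd, spc_rev, coverage.astype(np.int64))


def peak_ratio(spc: np.ndarray, strand: str = "+") -> PeakStat:
    """Highest vs. second-highest SPC on one strand.

    The peak position is the lowest coordinate attaining the maximum.  If the
    maximum value occurs at two or more positions the second-highest equals
    the top and R = 1.00.  A positive top over a zero second-highest gives an
    infinite ratio, flagged rather than silently large.  An all-zero array
    has no defined ratio and raises :class:`UndefinedRatioError`.
    """
    spc = np.asarray(spc)
    if spc.size < 2:
        raise ValueError("SPC array must have length >= 2")
    top = int(spc.max())
    if top == 0:
        raise UndefinedRatioError("all SPC counts are zero; peak ratio undefined")
    pos0 = int(np.argmax(spc))  # lowest index attaining the max
    rest = spc.copy()
    rest[pos0] = -1
    second = int(rest.max())
    if second == 0:
        return PeakStat(pos0 + 1, strand, top, 0, math.inf, infinite=True)
    return PeakStat(pos0 + 1, strand, top, second, round(top / second, 2))


def _significant(peak: Optional[PeakStat], strand_mean: float, p: DetectionParams) -> bool:
    if peak is None:
        return False
    if peak.top_count < p.min_top_count:
        return False
    if not peak.infinite and peak.ratio < p.min_ratio:
        return False
    tail = stats.poisson.sf(peak.top_count - 1, max(strand_mean, 1e-12))
    return bool(tail < p.max_poisson_p)


def _circular_interval_mean(arr: np.ndarray, start0: int, stop0: int) -> float:
    """Mean of arr over the circular interval start0..stop0 inclusive (0-based)."""
    if start0 <= stop0:
        return float(arr[start0 : stop0 + 1].mean())
    return float(np.concatenate([arr[start0:], arr[: stop0 + 1]]).mean())


def detect_termini(
    profiles: StrandProfiles, params: DetectionParams | None = None
) -> TerminiCall:
    """Classify the packaging strategy from strand profiles.

    Decision table: exactly one strand with a significant peak -> headful
    packaging with a pac site at that peak; both strands -> fixed termini,
    subclassed DTR when the interval between the opposing peaks (walked
    forward from the forward-strand peak) shows coverage enrichment, else
    cos; neither -> headful-random or a circularly permuted population,
    which are indistinguishable from start positions alone.  Zero alignments
    give UNDETERMINED.
    """
    p = params or DetectionParams()
    G = profiles.genome_length
    mean_depth = profiles.mean_depth
    call = TerminiCall(
        strategy_call="UNDETERMINED",
        mean_depth=mean_depth,
        low_coverage_warning=mean_depth < p.low_coverage_depth,
    )
    if profiles.n_alignments == 0:
        call.notes.append("no alignments")
        return call

    peaks: dict[str, Optional[PeakStat]] = {}
    for strand, arr in (("+", profiles.spc_fwd), ("-", profiles.spc_rev)):
        try:
            peaks[strand] = peak_ratio(arr, strand)
        except UndefinedRatioError:
            peaks[strand] = None
    sig = {
        s: _significant(peaks[s], float(arr.mean()), p)
        for s, arr in (("+", profiles.spc_fwd), ("-", profiles.spc_rev))
    }

    if sig["+"] and sig["-"]:
        left, right = peaks["+"], peaks["-"]
        call.left_terminus, call.right_terminus = left, right
        start0, stop0 = left.position - 1, right.position - 1
        ratio = _circular_interval_mean(profiles.coverage, start0, stop0) / max(
            mean_depth, 1e-12
        )
        call.repeat_interval = (left.position, right.position)
        call.repeat_coverage_ratio = ratio
        call.strategy_call = (
            "FIXED_TERMINI_DTR" if ratio >= p.dtr_coverage_factor else "FIXED_TERMINI_COS"
        )
    elif sig["+"] or sig["-"]:
        pk = peaks["+"] if sig["+"] else peaks["-"]
        call.pac = pk
        call.strategy_call = "HEADFUL_PAC"
    else:
        call.strategy_call = "HEADFUL_RANDOM_OR_PERMUTED"
    return call


def reorganize(circular_sequence: str, pac: int, strand: str = "+") -> str:
    """Cut a circular sequence open so the packaging-initiation base is position 1.

    For strand '-', the sequence is reverse-complemented first and then
    rotated so the complement of the pac base leads.
    """
    L = len(circular_sequence)
    if not 1 <= pac <= L:
        raise ValueError(f"pac {pac} outside 1..{L}")
    if strand not in ("+", "-"):
        raise ValueError("strand must be '+' or '-'")
    if strand == "-":
        circular_sequence = revcomp(circular_sequence)
        pac = L - pac + 1
    return circular_sequence[pac - 1 :] + circular_sequence[: pac - 1]


def circular_permutation_offset(seq_a: str, seq_b: str) -> Optional[int]:
    """Smallest rotation k with rotate(seq_a, k) == seq_b, or None.

    rotate(s, k) = s[k:] + s[:k].  Two independent assemblies of the same
    circularly permuted phage genome should differ by exactly such a
    rotation.
    """
    if len(seq_a) != len(seq_b) or not seq_a:
        return None
    k = (seq_a + seq_a).find(seq_b)
    return None if k == -1 else k % len(seq_a)


def junction_spanning_reads(alignments, genome_length: int, pac: int) -> int:
    """Reads whose covered interval spans the junction of the pac-organised genome.

    The junction sits between the last and first base of the reorganised
    genome, i.e. between circular positions pac-1 and pac of the original
    assembly.  Reads crossing it can only come from molecules longer than
    one genome length — direct evidence of terminal redundancy.
    """
    G = genome_length
    if not 1 <= pac <= G:
        raise ValueError(f"pac {pac} outside 1..{G}")
    starts, fwd, lens = _as_arrays(alignments)
    if len(starts) == 0:
        return 0
    left0 = np.where(fwd, starts - 1, starts - lens) % G  # 0-based leftmost covered base
    j = (pac - 1) % G  # junction precedes 0-based position j
    prev = (j - 1) % G
    # read covers both prev and j  <=>  offset of prev within the read <= L - 2
    covers = ((prev - left0) % G) <= (lens - 2)
    covers &= lens >= 2
    full_wrap = lens >= G + 1
    return int(np.count_nonzero(covers | full_wrap))
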