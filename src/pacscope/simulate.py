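"""Synthetic packaging substrates and shotgun reads for phage termini analysis.

Tailed dsDNA phages replicate through head-to-tail concatemers and cut
individual virion genomes out of them in strategy-specific ways: precise
cohesive (cos) ends, fixed direct terminal repeats (DTR), or headful
packaging in which each procapsid takes slightly more than one genome
length, starting either at a preferred *pac* site or at effectively random
positions.  This module generates ground-truth virion molecules and a
paired-end shotgun library over them, so the detection stages can be tested
without any sequencing data.

Coordinates are 1-based inclusive on the circular reference in every public
field; arithmetic is modulo the genome length G.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Strategy",
    "CircularGenome",
    "PackagingSpec",
    "VirionMolecule",
    "SimulatedRead",
    "ReadSet",
    "SimulationResult",
    "make_reference",
    "build_concatemer",
    "package_series",
    "package_fixed_termini",
    "package_random",
    "shear_and_read",
    "simulate",
    "circular_substring",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class Strategy(str, Enum):
    """The packaging strategies the simulator can emulate."""

    COS_5P = "cos_5p"
    COS_3P = "cos_3p"
    DTR_SHORT = "dtr_short"
    DTR_LONG = "dtr_long"
    HEADFUL_PAC = "headful_pac"
    HEADFUL_RANDOM = "headful_random"

    @property
    def is_headful(self) -> bool:
        return self in (Strategy.HEADFUL_PAC, Strategy.HEADFUL_RANDOM)

    @property
    def is_fixed(self) -> bool:
        return not self.is_headful


@dataclass(frozen=True)
class CircularGenome:
    """A circular reference sequence — the replication and packaging substrate."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("genome sequence must be non-empty")
        if set(self.sequence) - set("ACGT"):
            raise ValueError("genome sequence must contain only A/C/G/T")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def circular_slice(self, start: int, length: int) -> str:
        """Substring of ``length`` bases starting at 1-based circular ``start``."""
        return circular_substring(self.sequence, start, length)


def circular_substring(sequence: str, start: int, length: int) -> str:
    """Circular substring: 1-based start, wrapping as often as needed."""
    G = len(sequence)
    if not 1 <= start <= G:
        raise ValueError(f"start {start} outside 1..{G}")
    i = start - 1
    reps = (i + length) // G + 1
    return (sequence * reps)[i : i + length]


@dataclass
class PackagingSpec:
    """Parameters of one packaging strategy.

    ``headful_length`` H must exceed G for headful strategies; the excess
    r = H/G - 1 is the terminal redundancy.  ``headful_sd`` models the
    imprecision of the "procapsid physically full" cut: each molecule's
    packaged length is drawn Normal(H, headful_sd), so only the
    series-initiating cut is position-fixed.  Set it to 0 for exactly
    deterministic i*H continuation starts.
    """

    strategy: Strategy
    pac_position: int = 1  # headful strategies only
    headful_length: int = 0  # H; must be > G for headful
    headful_sd: float = 0.0
    series_length: int = 4  # S: molecules per packaging series
    concatemer_copies: int = 0  # C; 0 = derive the minimum needed
    dtr_length: int = 0  # DTR strategies only
    overhang_length: int = 0  # cos strategies only
    start: int = 1  # fixed-termini molecule start (1-based)

    def validate(self, genome_length: int) -> None:
        G = genome_length
        s = self.strategy
        if s.is_headful:
            if self.headful_length <= G:
                raise ValueError(
                    f"headful_length ({self.headful_length}) must exceed the "
                    f"genome length ({G}) — the headful excess is the terminal redundancy"
                )
            if not 1 <= self.pac_position <= G:
                raise ValueError(f"pac_position {self.pac_position} outside 1..{G}")
            if self.series_length < 1:
                raise ValueError("series_length must be >= 1")
        elif s in (Strategy.DTR_SHORT, Strategy.DTR_LONG):
            if not 1 <= self.dtr_length < G:
                raise ValueError(f"dtr_length must be in 1..{G - 1}")
        else:  # cos
            if self.overhang_length < 1:
                raise ValueError("overhang_length must be >= 1 for cos strategies")
        if not 1 <= self.start <= G:
            raise ValueError(f"start {self.start} outside 1..{G}")


@dataclass
class VirionMolecule:
    """One linear packaged DNA molecule with its ground-truth circular origin."""

    molecule_id: int
    start: int  # 1-based circular coordinate of the first base
    length: int
    sequence: str
    series_index: int = 0  # 0 = series-initiating molecule
    overhang: int = 0  # annotated cohesive-end length (cos only)
    overhang_end: str = ""  # "5p" or "3p"


@dataclass(frozen=True)
class SimulatedRead:
    """One read; ``ref_start`` is the 5' mapped end in circular reference coordinates.

    For a forward read the 5' end is its leftmost reference base; for a
    reverse read it is the rightmost.  The read covers ``read_length`` bases
    extending 3'-ward (rightward for +, leftward for -), wrapping circularly.
    """

    molecule_id: int
    mate: int
    ref_start: int
    strand: str  # "+" or "-"
    read_length: int


@dataclass
class ReadSet:
    """Column-oriented container for a simulated read library.

    Sequences are not materialised here; they are extracted from the genome
    on demand when writing FASTQ/SAM (``bases_for``), which keeps large
    simulations cheap.
    """

    molecule_id: np.ndarray  # int
    mate: np.ndarray  # int (1|2)
    ref_start: np.ndarray  # int, 1-based 5' mapped end
    forward: np.ndarray  # bool
    read_length: np.ndarray  # int

    def __len__(self) -> int:
        return len(self.ref_start)

    def __iter__(self) -> Iterator[SimulatedRead]:
        for i in range(len(self)):
            yield SimulatedRead(
                molecule_id=int(self.molecule_id[i]),
                mate=int(self.mate[i]),
                ref_start=int(self.ref_start[i]),
                strand="+" if self.forward[i] else "-",
                read_length=int(self.read_length[i]),
            )

    def total_bases(self) -> int:
        return int(self.read_length.sum())

    def bases_for(self, i: int, genome: CircularGenome) -> str:
        """Read sequence of record ``i`` against ``genome`` (5'->3')."""
        start = int(self.ref_start[i])
        length = int(self.read_length[i])
        if self.forward[i]:
            return genome.circular_slice(start, length)
        G = genome.length
        left = (start - length) % G + 1  # leftmost covered base
        return revcomp(genome.circular_slice(left, length))

    @staticmethod
    def concatenate(parts: Sequence["ReadSet"]) -> "ReadSet":
        return ReadSet(
            molecule_id=np.concatenate([p.molecule_id for p in parts]),
            mate=np.concatenate([p.mate for p in parts]),
            ref_start=np.concatenate([p.ref_start for p in parts]),
            forward=np.concatenate([p.forward for p in parts]),
            read_length=np.concatenate([p.read_length for p in parts]),
        )


def make_reference(length: int, gc: float, seed: int) -> CircularGenome:
    """Uniformly random circular genome with the requested GC fraction.

    Bases are drawn i.i.d. with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2, so
    the realised GC content fluctuates around ``gc`` with binomial sampling
    noise.  Identical (length, gc, seed) triples give identical sequences.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be within [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    letters = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=probs)
    return CircularGenome(id=f"synthetic_{length}_{seed}", sequence=letters.tobytes().decode())


def build_concatemer(genome: CircularGenome, copies: int, origin: int = 1) -> str:
    """Head-to-tail concatemer: the rotation starting at ``origin``, repeated.

    Emulates the rolling-circle replication intermediate from which packaging
    series are cut.
    """
    if copies < 1:
        raise ValueError("copies must be >= 1")
    G = genome.length
    if not 1 <= origin <= G:
        raise ValueError(f"origin {origin} outside 1..{G}")
    rotation = genome.sequence[origin - 1 :] + genome.sequence[: origin - 1]
    return rotation * copies


def package_series(
    concatemer: str,
    spec: PackagingSpec,
    genome_length: int,
    rng: np.random.Generator | None = None,
    id_offset: int = 0,
) -> list[VirionMolecule]:
    """Cut one processive headful series out of a concatemer.

    The concatemer must begin at the pac site.  Molecule 0 starts exactly at
    ``spec.pac_position``; each subsequent molecule starts where the previous
    headful cut left off.  With ``spec.headful_sd == 0`` every molecule is
    exactly ``spec.headful_length`` long and molecule i starts at
    ``(pac - 1 + i*H) mod G + 1``; a positive sd jitters each headful,
    modelling the non-specific "procapsid full" cut.
    """
    if spec.strategy is not Strategy.HEADFUL_PAC:
        raise ValueError("package_series requires the HEADFUL_PAC strategy")
    spec.validate(genome_length)
    G = genome_length
    H = spec.headful_length
    S = spec.series_length
    if spec.headful_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        lengths = np.rint(rng.normal(H, spec.headful_sd, size=S)).astype(int)
        lengths = np.maximum(lengths, G + 1)  # headful always exceeds one genome
    else:
        lengths = np.full(S, H, dtype=int)
    if int(lengths.sum()) > len(concatemer):
        raise ValueError(
            f"concatemer of {len(concatemer)} bases too short for "
            f"{S} headfuls totalling {int(lengths.sum())}"
        )
    molecules = []
    offset = 0  # 0-based position within the concatemer
    for i in range(S):
        L = int(lengths[i])
        seq = concatemer[offset : offset + L]
        start = (spec.pac_position - 1 + offset) % G + 1
        molecules.append(
            VirionMolecule(
                molecule_id=id_offset + i,
                start=start,
                length=L,
                sequence=seq,
                series_index=i,
            )
        )
        offset += L
    return molecules


def package_fixed_termini(
    genome: CircularGenome, spec: PackagingSpec, n: int = 1
) -> list[VirionMolecule]:
    """Package ``n`` identical fixed-termini molecules (cos or DTR).

    DTR molecules are G + dtr_length bases long, with the first dtr_length
    bases repeated verbatim at the end.  cos molecules are exactly G bases
    with an annotated cohesive overhang at the 5' or 3' end (the overhang is
    an annotation, not extra sequence: the nicked strands reanneal to one
    genome length).
    """
    if not spec.strategy.is_fixed:
        raise ValueError("package_fixed_termini requires a cos or DTR strategy")
    spec.validate(genome.length)
    G = genome.length
    if spec.strategy in (Strategy.DTR_SHORT, Strategy.DTR_LONG):
        length = G + spec.dtr_length
        overhang, end = 0, ""
    else:
        length = G
        overhang = spec.overhang_length
        end = "5p" if spec.strategy is Strategy.COS_5P else "3p"
    seq = genome.circular_slice(spec.start, length)
    return [
        VirionMolecule(
            molecule_id=i,
            start=spec.start,
            length=length,
            sequence=seq,
            series_index=0,
            overhang=overhang,
            overhang_end=end,
        )
        for i in range(n)
    ]


def package_random(
    genome: CircularGenome, spec: PackagingSpec, n: int, seed: int | np.random.Generator
) -> list[VirionMolecule]:
    """Headful molecules with uniformly random starts (no preferred pac site)."""
    if spec.strategy is not Strategy.HEADFUL_RANDOM:
        raise ValueError("package_random requires the HEADFUL_RANDOM strategy")
    spec.validate(genome.length)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    G = genome.length
    starts = rng.integers(1, G + 1, size=n)
    if spec.headful_sd > 0:
        lengths = np.maximum(
            np.rint(rng.normal(spec.headful_length, spec.headful_sd, size=n)).astype(int),
            G + 1,
        )
    else:
        lengths = np.full(n, spec.headful_length, dtype=int)
    return [
        VirionMolecule(
            molecule_id=i,
            start=int(starts[i]),
            length=int(lengths[i]),
            sequence=genome.circular_slice(int(starts[i]), int(lengths[i])),
            series_index=0,
        )
        for i in range(n)
    ]


def shear_fragments(
    molecule_length: int, frag_mean: float, frag_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Fragment lengths partitioning one molecule.

    Lengths are Normal(frag_mean, frag_sd) truncated at >= 50 bases; the last
    fragment absorbs the remainder so the lengths sum exactly to the molecule
    length (conservation under shearing; both molecule termini are fragment
    ends).
    """
    n_guess = max(8, int(molecule_length / max(frag_mean, 1.0) * 1.5) + 8)
    lengths: list[int] = []
    total = 0
    while total < molecule_length:
        draw = np.maximum(np.rint(rng.normal(frag_mean, frag_sd, size=n_guess)), 50).astype(int)
        for L in draw:
            if total + L >= molecule_length:
                lengths.append(molecule_length - total)
                total = molecule_length
                break
            lengths.append(int(L))
            total += int(L)
    out = np.array([L for L in lengths if L > 0], dtype=int)
    return out


def shear_and_read(
    molecules: Sequence[VirionMolecule],
    genome_length: int,
    frag_mean: float = 550.0,
    frag_sd: float = 55.0,
    read_length: int = 251,
    seed: int | np.random.Generator = 0,
    depth: float | None = None,
) -> ReadSet:
    """Shear molecules and sequence both ends of every fragment.

    Each fragment yields a forward read from its left end (mate 1) and a
    reverse read from its right end (mate 2); reads are truncated to the
    fragment length when the fragment is shorter than ``read_length``.
    ``ref_start`` records the 5' mapped end of each read in circular
    reference coordinates, which is what makes molecule termini visible as
    start-position pile-ups downstream.

    ``depth`` is accepted only for the error contract (it must be positive
    when given); the molecule list itself determines the realised coverage.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    if depth is not None and depth <= 0:
        raise ValueError("depth must be positive")
    if frag_mean < read_length:
        warnings.warn(
            f"mean fragment length {frag_mean} below read length {read_length}: "
            "reads will be truncated to their fragments",
            stacklevel=2,
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    G = genome_length
    parts = []
    for mol in molecules:
        frags = shear_fragments(mol.length, frag_mean, frag_sd, rng)
        offsets = np.concatenate([[0], np.cumsum(frags[:-1])])  # 0-based within molecule
        rlen = np.minimum(frags, read_length)
        # mate 1: forward from the fragment's left end
        fwd_start = (mol.start - 1 + offsets) % G + 1
        # mate 2: reverse, 5' end at the fragment's right end
        rev_start = (mol.start - 1 + offsets + frags - 1) % G + 1
        k = len(frags)
        parts.append(
            ReadSet(
                molecule_id=np.repeat(mol.molecule_id, 2 * k),
                mate=np.concatenate([np.ones(k, int), np.full(k, 2, int)]),
                ref_start=np.concatenate([fwd_start, rev_start]).astype(int),
                forward=np.concatenate([np.ones(k, bool), np.zeros(k, bool)]),
                read_length=np.concatenate([rlen, rlen]).astype(int),
            )
        )
    if not parts:
        e = np.empty(0, int)
        return ReadSet(e, e.copy(), e.copy(), np.empty(0, bool), e.copy())
    return ReadSet.concatenate(parts)


@dataclass
class SimulationResult:
    """Genome, ground-truth molecules and the simulated read library."""

    genome: CircularGenome
    spec: PackagingSpec
    molecules: list[VirionMolecule]
    reads: ReadSet

    @property
    def mean_depth(self) -> float:
        return self.reads.total_bases() / self.genome.length


DEFAULT_GENOME_LENGTH = 86_193
DEFAULT_GC = 0.4907


def default_spec(strategy: Strategy, genome_length: int = DEFAULT_GENOME_LENGTH, **kw) -> PackagingSpec:
    """A PackagingSpec with study-condition defaults for ``strategy``.

    Headful: H = 1.04 G, sd = 0.5% of H, series length 4.  DTR: 500 b (short)
    or 5,000 b (long).  cos: 12-base overhang.
    """
    H = int(round(1.04 * genome_length))
    base = dict(
        strategy=strategy,
        headful_length=H,
        headful_sd=0.005 * H,
        series_length=4,
        pac_position=1,
        start=1,
    )
    if strategy is Strategy.DTR_SHORT:
        base["dtr_length"] = 500
    elif strategy is Strategy.DTR_LONG:
        base["dtr_length"] = 5_000
    elif strategy in (Strategy.COS_5P, Strategy.COS_3P):
        base["overhang_length"] = 12
    base.update(kw)
    return PackagingSpec(**base)


def simulate(
    strategy: Strategy | str,
    genome: CircularGenome | None = None,
    genome_length: int = DEFAULT_GENOME_LENGTH,
    gc: float = DEFAULT_GC,
    seed: int = 1,
    depth: float = 200.0,
    frag_mean: float = 550.0,
    frag_sd: float = 55.0,
    read_length: int = 251,
    **spec_kw,
) -> SimulationResult:
    """End-to-end simulation: reference -> molecules -> paired shotgun reads.

    ``depth`` is the target fold-coverage of the genome by read bases; the
    number of molecules (or headful series) is derived from it.  Additional
    keyword arguments override :func:`default_spec` fields (``pac_position``,
    ``dtr_length``, ``headful_sd``, ...).
    """
    strategy = Strategy(strategy)
    if depth <= 0:
        raise ValueError("depth must be positive")
    if genome is None:
        genome = make_reference(genome_length, gc, seed)
    G = genome.length
    spec = default_spec(strategy, G, **spec_kw)
    spec.validate(G)
    rng = np.random.default_rng(seed)

    mol_len = spec.headful_length if strategy.is_headful else (
        G + spec.dtr_length if strategy in (Strategy.DTR_SHORT, Strategy.DTR_LONG) else G
    )
    # expected sequenced bases per molecule: two reads per ~frag_mean of molecule
    bases_per_mol = 2.0 * min(read_length, frag_mean) * (mol_len / frag_mean)
    n_mol = max(1, int(np.ceil(depth * G / bases_per_mol)))

    if strategy is Strategy.HEADFUL_PAC:
        n_series = max(1, int(np.ceil(n_mol / spec.series_length)))
        copies = spec.concatemer_copies or int(
            np.ceil(spec.series_length * spec.headful_length * 1.05 / G)
        ) + 1
        concatemer = build_concatemer(genome, copies, origin=spec.pac_position)
        molecules = []
        for s in range(n_series):
            molecules.extend(
                package_series(concatemer, spec, G, rng=rng, id_offset=s * spec.series_length)
            )
    elif strategy is Strategy.HEADFUL_RANDOM:
        molecules = package_random(genome, spec, n_mol, rng)
    else:
        molecules = package_fixed_termini(genome, spec, n=n_mol)

    reads = shear_and_read(
        molecules, G, frag_mean=frag_mean, frag_sd=frag_sd, read_length=read_length, seed=rng
    )
    return SimulationResult(genome=genome, spec=spec, molecules=molecules, reads=reads)
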