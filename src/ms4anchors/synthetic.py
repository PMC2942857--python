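"""Seeded fixtures: planted shared motifs with controlled inconsistencies.

The generator emulates the one regime the pipeline is designed for: a set
of sequences sharing exact, repeat-free local similarities (the planted
motifs) embedded in unrelated background.  Each motif is planted once in
every carrier sequence, in catalogue order; a *swap directive* transposes
the order of two motifs in chosen sequences, which manufactures exactly
the succession-order conflicts the consistency engine must detect (the
minority carriers contribute the low-weight back edges).

Background residues are sampled i.i.d. from the alphabet.  A sequence is
re-sampled (bounded retries) whenever chance background re-creates an
occurrence of any catalogue motif, so that — best effort — the planted
occurrences are the only multi-sequence exact repeats.  The ground truth
is computed from the final sequences' actual planted coordinates, never
from intent, so tests cannot chase phantom columns.

What the generator does *not* emulate: substitutions or indels inside
motifs, compositional bias, homology spread over diverged copies — i.e.
everything that makes real protein families hard.  A green recovery test
establishes correctness of the machinery on exact repeats, not benchmark
performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InfeasibleSpecError
from .ms4 import ColumnSet, columns_from_site_maps
from .sitespace import SequenceSet

__all__ = ["PlantSpec", "GeneratedFixture", "generate"]

PROTEIN20 = "ACDEFGHIKLMNPQRSTVWY"

_MAX_RETRIES = 50


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for one fixture.

    Parameters
    ----------
    n_seqs :
        Number of sequences.
    length_range :
        Inclusive (lo, hi) total residue count per sequence; raised to
        the motif footprint when a draw falls short.
    alphabet :
        Residue alphabet for background sampling (default: the 20
        standard amino acids).
    motifs :
        Exact motif strings, planted in catalogue order.
    carriers :
        Per motif, the sequence indices carrying it; ``None`` means all
        sequences carry every motif.
    swaps :
        ``(motif_i, motif_j, sequences)`` directives: in each listed
        sequence the two motifs trade places in the planting order.
    seed :
        RNG seed; a single documented stream drives all sampling.
    """

    n_seqs: int = 4
    length_range: tuple[int, int] = (40, 60)
    alphabet: str = PROTEIN20
    motifs: tuple[str, ...] = ("WYDKHMCF",)
    carriers: tuple[tuple[int, ...], ...] | None = None
    swaps: tuple[tuple[int, int, tuple[int, ...]], ...] = ()
    seed: int = 0

    def carrier_sets(self) -> list[tuple[int, ...]]:
        if self.carriers is None:
            return [tuple(range(self.n_seqs))] * len(self.motifs)
        return [tuple(c) for c in self.carriers]

    def validate(self) -> None:
        lo, hi = self.length_range
        if self.n_seqs < 1:
            raise InfeasibleSpecError("need at least one sequence")
        if lo < 1 or hi < lo:
            raise InfeasibleSpecError(f"bad length range {self.length_range}")
        if not self.motifs or any(not m for m in self.motifs):
            raise InfeasibleSpecError("motifs must be non-empty strings")
        if any(set(m) - set(self.alphabet) for m in self.motifs):
            raise InfeasibleSpecError("motif uses characters outside the alphabet")
        carriers = self.carrier_sets()
        if len(carriers) != len(self.motifs):
            raise InfeasibleSpecError("one carrier subset per motif required")
        for c in carriers:
            if any(not 0 <= s < self.n_seqs for s in c):
                raise InfeasibleSpecError(f"carrier index out of range in {c}")
            if len(set(c)) != len(c):
                raise InfeasibleSpecError(f"duplicate carrier in {c}")
        for i, j, seqs_ in self.swaps:
            if not (0 <= i < len(self.motifs) and 0 <= j < len(self.motifs)) or i == j:
                raise InfeasibleSpecError(f"bad swap motif pair ({i}, {j})")
            for s in seqs_:
                if s not in carriers[i] or s not in carriers[j]:
                    raise InfeasibleSpecError(
                        f"swap sequence {s} does not carry both motifs {i} and {j}"
                    )
        for s in range(self.n_seqs):
            footprint = sum(
                len(m) for m, c in zip(self.motifs, carriers) if s in c
            )
            if footprint > hi:
                raise InfeasibleSpecError(
                    f"motifs need {footprint} residues in sequence {s}, "
                    f"but the maximum length is {hi}"
                )


@dataclass(frozen=True)
class GeneratedFixture:
    """A generated sequence set with its planted ground truth.

    ``truth`` holds one column per motif offset across that motif's
    carriers (motifs with a single carrier contribute none);
    ``placements`` maps ``(motif_index, sequence)`` to the motif's start
    offset in the final sequence.
    """

    sequences: SequenceSet
    truth: ColumnSet
    placements: dict[tuple[int, int], int] = field(repr=False)
    seed: int = 0

    def __iter__(self):
        # allow `seqs, truth = generate(spec)` style unpacking
        return iter((self.sequences, self.truth))


def _motif_order(spec: PlantSpec, s: int) -> list[int]:
    carriers = spec.carrier_sets()
    order = [i for i in range(len(spec.motifs)) if s in carriers[i]]
    for i, j, seqs_ in spec.swaps:
        if s in seqs_:
            a, b = order.index(i), order.index(j)
            order[a], order[b] = order[b], order[a]
    return order


def _build_sequence(
    spec: PlantSpec, s: int, rng: np.random.Generator
) -> tuple[str, dict[int, int]]:
    lo, hi = spec.length_range
    order = _motif_order(spec, s)
    footprint = sum(len(spec.motifs[i]) for i in order)
    alphabet = list(spec.alphabet)
    for _ in range(_MAX_RETRIES):
        total = int(rng.integers(max(lo, footprint), hi + 1))
        background = total - footprint
        # split background into len(order)+1 gaps
        gaps = rng.multinomial(background, [1.0 / (len(order) + 1)] * (len(order) + 1))
        parts: list[str] = []
        starts: dict[int, int] = {}
        pos = 0
        for k, motif_idx in enumerate(order):
            fill = "".join(rng.choice(alphabet, size=int(gaps[k])))
            parts.append(fill)
            pos += len(fill)
            starts[motif_idx] = pos
            motif = spec.motifs[motif_idx]
            parts.append(motif)
            pos += len(motif)
        parts.append("".join(rng.choice(alphabet, size=int(gaps[-1]))))
        residues = "".join(parts)
        expected = {i: 1 for i in order}
        clean = True
        for i, motif in enumerate(spec.motifs):
            count = sum(
                1
                for q in range(len(residues) - len(motif) + 1)
                if residues[q : q + len(motif)] == motif
            )
            if count != expected.get(i, 0):
                clean = False
                break
        if clean:
            return residues, starts
    # retry cap exhausted: accept the last draw (best effort); truth still
    # reflects the actual planted coordinates
    return residues, starts


def generate(spec: PlantSpec) -> GeneratedFixture:
    """Generate sequences plus ground-truth columns, deterministically.

    The same spec (including seed) always yields byte-identical
    sequences and an identical truth set.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records: list[tuple[str, str]] = []
    placements: dict[tuple[int, int], int] = {}
    for s in range(spec.n_seqs):
        residues, starts = _build_sequence(spec, s, rng)
        records.append((f"s{s + 1}", residues))
        for motif_idx, start in starts.items():
            placements[(motif_idx, s)] = start
    seqs = SequenceSet(tuple(records))

    carriers = spec.carrier_sets()
    maps: list[dict[int, int]] = []
    for i, motif in enumerate(spec.motifs):
        if len(carriers[i]) < 2:
            continue
        for t in range(len(motif)):
            maps.append({s: placements[(i, s)] + t for s in carriers[i]})
    truth = columns_from_site_maps(maps)
    return GeneratedFixture(
        sequences=seqs, truth=truth, placements=placements, seed=spec.seed
    )
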