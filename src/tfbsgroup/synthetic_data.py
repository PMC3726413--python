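"""Synthetic planted (l,d) benchmark samples.

A sample is built in four steps: draw a parent motif of length l uniformly
over {A,C,G,T}^l; draw N i.i.d. uniform background sequences of length L;
pick q of the N sequences; in each picked sequence overwrite a uniformly
placed length-l window with a mutated copy of the parent (d positions
chosen without replacement, each re-drawn uniformly from all four bases,
so the realized Hamming distance is *at most* d and averages 3d/4).

A single seeded RNG drives every draw in a fixed order
(parent -> background -> selection -> per-sequence mutation/offset), so a
sample is bitwise reproducible from (l, d, N, L, q, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ALPHABET, SequenceRecord, SequenceSet

__all__ = [
    "PlantedSample",
    "generate_parent_motif",
    "generate_background",
    "make_instance",
    "plant_sample",
]


@dataclass(frozen=True)
class PlantedSample:
    """A benchmark SequenceSet plus its ground truth."""

    seqs: SequenceSet
    parent: str
    sites: tuple[tuple[int, int], ...]  # (seq_index, offset), 0-based
    l: int
    d: int
    n_seqs: int
    length: int
    q: int
    seed: int | None = None

    def site_strings(self) -> list[str]:
        """The planted instance at each recorded site."""
        return [
            self.seqs[i].seq[off : off + self.l] for i, off in self.sites
        ]


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _random_string(n: int, rng: np.random.Generator) -> str:
    return "".join(ALPHABET[b] for b in rng.integers(0, 4, size=n))


def generate_parent_motif(l: int, rng: np.random.Generator | int | None = None) -> str:
    """Draw a parent motif: l i.i.d. uniform bases."""
    if l < 1:
        raise ValueError(f"motif length must be >= 1, got {l}")
    return _random_string(l, _as_rng(rng))


def generate_background(
    n_seqs: int, length: int, rng: np.random.Generator | int | None = None
) -> SequenceSet:
    """Draw N i.i.d. uniform background sequences of length L."""
    if n_seqs < 1 or length < 1:
        raise ValueError("n_seqs and length must be positive")
    rng = _as_rng(rng)
    return SequenceSet(
        [
            SequenceRecord(f"seq{i}", _random_string(length, rng))
            for i in range(n_seqs)
        ]
    )


def make_instance(
    parent: str, d: int, rng: np.random.Generator | int | None = None
) -> str:
    """Mutate a copy of *parent* at d distinct positions.

    Each chosen position is re-drawn uniformly from all four bases (the
    draw may equal the original), so Hamming(instance, parent) <= d.
    """
    l = len(parent)
    if not 0 <= d < l:
        raise ValueError(f"need 0 <= d < l, got d={d}, l={l}")
    rng = _as_rng(rng)
    positions = rng.choice(l, size=d, replace=False)
    bases = rng.integers(0, 4, size=d)
    out = list(parent)
    for pos, b in zip(positions, bases):
        out[pos] = ALPHABET[b]
    return "".join(out)


def plant_sample(
    l: int,
    d: int,
    n_seqs: int = 20,
    length: int = 600,
    q: int | None = None,
    rng: np.random.Generator | int | None = None,
    seed: int | None = None,
    multi_occurrence: bool = False,
) -> PlantedSample:
    """Generate a planted (l,d) sample with recorded ground truth.

    q defaults to n_seqs (every sequence carries one instance, the
    benchmark convention). With ``multi_occurrence`` each selected
    sequence receives 1 or 2 non-overlapping instances, exercising the
    zero-or-one-or-multiple-occurrences (ZOMOPS) regime; q=0 gives the
    pure-background zero-occurrence case.
    """
    if q is None:
        q = n_seqs
    if q > n_seqs:
        raise ValueError(f"q={q} exceeds the number of sequences {n_seqs}")
    if l > length:
        raise ValueError(f"motif length l={l} exceeds sequence length {length}")
    if rng is None and seed is not None:
        rng = seed
    rng = _as_rng(rng)

    parent = generate_parent_motif(l, rng)
    seqs = [list(_random_string(length, rng)) for _ in range(n_seqs)]
    selected = sorted(rng.choice(n_seqs, size=q, replace=False)) if q else []

    sites: list[tuple[int, int]] = []
    for i in selected:
        n_here = int(rng.integers(1, 3)) if multi_occurrence else 1
        placed: list[int] = []
        for _ in range(n_here):
            inst = make_instance(parent, d, rng)
            for _attempt in range(200):
                off = int(rng.integers(0, length - l + 1))
                if all(abs(off - p) >= l for p in placed):
                    break
            else:  # no non-overlapping slot found; keep the single site
                continue
            seqs[i][off : off + l] = inst
            placed.append(off)
            sites.append((i, off))

    records = [SequenceRecord(f"seq{i}", "".join(s)) for i, s in enumerate(seqs)]
    return PlantedSample(
        seqs=SequenceSet(records),
        parent=parent,
        sites=tuple(sorted(sites)),
        l=l,
        d=d,
        n_seqs=n_seqs,
        length=length,
        q=q,
        seed=seed,
    )


def write_truth_tsv(sample: PlantedSample, path) -> None:
    """Write ground truth as TSV (seq_id, offset0, instance, parent)."""
    with open(path, "w") as fh:
        fh.write("seq_id\toffset0\tinstance\tparent\n")
        for (i, off), inst in zip(sample.sites, sample.site_strings()):
            fh.write(f"{sample.seqs[i].id}\t{off}\t{inst}\t{sample.parent}\n")


def write_truth_bed(sample: PlantedSample, path) -> None:
    """Write ground-truth sites as BED6 (score 0, forward strand)."""
    with open(path, "w") as fh:
        for i, off in sample.sites:
            fh.write(
                f"{sample.seqs[i].id}\t{off}\t{off + sample.l}\t"
                f"{sample.parent}\t0\t+\n"
            )
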