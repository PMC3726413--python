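"""Motif significance scoring, ranking and de-duplication.

The significance score is a coverage-weighted relative entropy (in bits)
of the motif's aligned instance columns against a mononucleotide
background estimated from the input sequences:

    score = (support / N) * sum_j sum_k f_jk * log2(f_jk / b_k)

with f_jk the frequency of base k at column j over instance l-mers and
b_k the background frequency (floored at 0.01 and renormalized, so the
log never blows up). Higher is more significant; a fully supported,
perfectly conserved column contributes log2(1/b_k) ~ 2 bits against a
uniform background. The scorer is deliberately parameter-free and
pluggable (the search accepts any callable of the same shape) since
over-representation scores of this family vary between tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log2
from typing import Sequence

from .io_formats import ALPHABET, SequenceSet
from .refinement import CandidateMotif

__all__ = [
    "BackgroundModel",
    "background_frequencies",
    "significance_score",
    "rank_and_dedupe",
]

_FLOOR = 0.01


@dataclass(frozen=True)
class BackgroundModel:
    """Mononucleotide background frequencies over {A,C,G,T}."""

    b: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.b.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"background frequencies sum to {total}, not 1")
        # after flooring at _FLOOR and renormalizing, the smallest
        # attainable frequency is _FLOOR / (1 + 3 * _FLOOR)
        lo = _FLOOR / (1 + 3 * _FLOOR)
        if any(self.b.get(k, 0.0) < lo - 1e-12 for k in ALPHABET):
            raise ValueError(f"every frequency must be >= {lo:.4g}")


def background_frequencies(seqs: SequenceSet) -> BackgroundModel:
    """Empirical base frequencies, floored at 0.01 and renormalized.

    Ambiguous (N) bases are ignored in the counts.
    """
    counts = {k: 0 for k in ALPHABET}
    for rec in seqs:
        for k in ALPHABET:
            counts[k] += rec.seq.count(k)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no unambiguous bases in the input")
    freqs = {k: max(counts[k] / total, _FLOOR) for k in ALPHABET}
    z = sum(freqs.values())
    return BackgroundModel({k: v / z for k, v in freqs.items()})


def significance_score(
    motif: CandidateMotif,
    bg: BackgroundModel,
    n_seqs: int,
    seqs: SequenceSet | None = None,
    lmers: Sequence[str] | None = None,
) -> float:
    """Coverage-weighted relative entropy of the motif columns (bits).

    Instance l-mers are read from *seqs* at the motif's recorded sites
    unless given directly via *lmers*. Raw column counts are used (no
    pseudocounts) with the 0*log(0) = 0 convention.
    """
    if len(motif.instances) < 2:
        raise ValueError("a motif needs at least 2 instances to be scored")
    l = len(motif.consensus)
    if lmers is None:
        if seqs is None:
            raise ValueError("provide either seqs or lmers")
        lmers = [seqs[i].seq[off : off + l] for i, off in motif.instances]
    n_inst = len(lmers)
    rel_entropy = 0.0
    for j in range(l):
        col = [s[j] for s in lmers]
        for k in ALPHABET:
            f = col.count(k) / n_inst
            if f > 0.0:
                rel_entropy += f * log2(f / bg.b[k])
    return (motif.support / n_seqs) * rel_entropy


def rank_and_dedupe(
    motifs: Sequence[CandidateMotif], k: int
) -> list[CandidateMotif]:
    """Sort by score (desc), drop repeated consensuses, keep the top k.

    Ties are broken by larger support, then lexicographically smaller
    consensus, so the ranking is a total deterministic order.
    """
    ranked = sorted(motifs, key=lambda m: (-m.score, -m.support, m.consensus))
    seen: set[str] = set()
    out: list[CandidateMotif] = []
    for m in ranked:
        if m.consensus in seen:
            continue
        seen.add(m.consensus)
        out.append(m)
        if len(out) == k:
            break
    return out
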