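"""Greedy refinement of a community of l-mers into a candidate motif.

A community from the graph partition is only a coarse group of candidate
sites. Refinement (three steps) pulls it toward the true motif:

1. build the consensus of the current member l-mers;
2. re-collect instances: within a window of +/- l around each current
   member's own position (its own sequence only), keep every l-mer
   within Hamming distance d of the consensus, then iterate
   collect/consensus until the consensus stops changing;
3. try global frame shifts of up to floor(l/3) in either direction,
   keep the best-scoring frame, and re-collect once in that frame.

Overlapping qualifying offsets within one sequence are collapsed to the
single best one (minimum distance to consensus, leftmost on ties) so a
site cannot be double-counted at shifts of itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io_formats import SequenceSet
from .lmer_graph import hamming

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateMotif",
    "consensus_of",
    "collect_within_windows",
    "refine_to_fixpoint",
    "shift_optimize",
]

_BASE_ORDER = "ACGT"  # also the tie-break order for consensus columns

Site = tuple[int, int]  # (seq_index, offset), 0-based


@dataclass
class CandidateMotif:
    """A consensus string with its supporting sites.

    ``support`` is the number of distinct sequences covered (a sequence
    may contribute several non-overlapping instances under the
    zero-one-or-multiple-occurrences constraint). ``score`` is set by
    the scoring stage.
    """

    consensus: str
    instances: tuple[Site, ...]
    support: int = 0
    score: float = 0.0
    provenance: int | None = None

    def __post_init__(self) -> None:
        self.support = len({i for i, _ in self.instances})


def consensus_of(lmers) -> str:
    """Per-column majority base; ties broken in A < C < G < T order."""
    lmers = list(lmers)
    if not lmers:
        raise ValueError("cannot take the consensus of an empty collection")
    l = len(lmers[0])
    if any(len(s) != l for s in lmers):
        raise ValueError("all l-mers must have equal length")
    out = []
    for j in range(l):
        col = [s[j] for s in lmers]
        out.append(max(_BASE_ORDER, key=lambda b: (col.count(b), -_BASE_ORDER.index(b))))
    return "".join(out)


def _is_acgt(s: str) -> bool:
    return all(c in _BASE_ORDER for c in s)


def collect_within_windows(
    current: tuple[Site, ...] | list[Site],
    consensus: str,
    d: int,
    seqs: SequenceSet,
) -> tuple[Site, ...]:
    """Re-collect instances near the current members (step 1).

    For each current site (i, pos), candidate offsets in sequence i are
    [max(0, pos-l), min(pos+l, L_i-l)]. Offsets whose l-mer is within
    distance d of the consensus qualify; overlapping qualifiers within a
    sequence collapse to the minimum-distance one (leftmost on ties).
    """
    l = len(consensus)
    windows: dict[int, set[int]] = {}
    for i, pos in current:
        l_seq = len(seqs[i])
        lo, hi = max(0, pos - l), min(pos + l, l_seq - l)
        windows.setdefault(i, set()).update(range(lo, hi + 1))
    collected: list[Site] = []
    for i in sorted(windows):
        seq = seqs[i].seq
        qual: list[tuple[int, int]] = []  # (distance, offset)
        for off in sorted(windows[i]):
            lmer = seq[off : off + l]
            if not _is_acgt(lmer):
                continue
            dist = hamming(consensus, lmer)
            if dist <= d:
                qual.append((dist, off))
        # collapse overlapping qualifiers: repeatedly take the best
        # (min distance, then leftmost) and drop everything overlapping it
        while qual:
            best = min(qual)
            collected.append((i, best[1]))
            qual = [qd for qd in qual if abs(qd[1] - best[1]) >= l]
    return tuple(sorted(collected))


def refine_to_fixpoint(
    community,
    l: int,
    d: int,
    seqs: SequenceSet,
    max_iters: int = 30,
    provenance: int | None = None,
) -> CandidateMotif | None:
    """Iterate collect/consensus to a fixed point (steps 1-2).

    ``community`` is an iterable of (seq_index, offset) sites of l-mers.
    Returns None when the instance set empties out or fewer than two
    distinct sequences remain supported (a motif needs at least two
    sites to be over-represented). Termination is guaranteed by cycle
    detection on the sequence of consensuses plus the iteration cap.
    """
    sites = tuple(sorted(set(community)))
    if not sites:
        return None
    consensus = consensus_of([seqs[i].seq[off : off + l] for i, off in sites])
    seen = {(consensus, sites)}
    for _ in range(max_iters):
        new_sites = collect_within_windows(sites, consensus, d, seqs)
        if not new_sites:
            return None
        new_cons = consensus_of([seqs[i].seq[off : off + l] for i, off in new_sites])
        if new_sites == sites and new_cons == consensus:
            break  # joint fixed point: re-refining changes nothing
        if (new_cons, new_sites) in seen:
            # cycle: adopt the repeated state and align instances once
            sites = collect_within_windows(new_sites, new_cons, d, seqs)
            consensus = new_cons
            if not sites:
                return None
            break
        sites, consensus = new_sites, new_cons
        seen.add((new_cons, new_sites))
    motif = CandidateMotif(consensus=consensus, instances=sites, provenance=provenance)
    if motif.support < 2:
        return None
    return motif


def shift_optimize(
    motif: CandidateMotif,
    seqs: SequenceSet,
    d: int,
    score_fn,
) -> CandidateMotif:
    """Try global frame shifts of up to floor(l/3) bases (step 3).

    Every shift delta in [-floor(l/3), +floor(l/3)] moves all instances
    together (clamped per-instance to sequence bounds); the consensus and
    significance score of each shifted frame are recomputed and the best
    frame wins (ties prefer smaller |delta|, then the leftward shift).
    One final collect/consensus pass in the winning frame tidies up the
    instance set. ``score_fn(motif) -> float`` supplies the significance
    score.
    """
    l = len(motif.consensus)
    span = l // 3
    best: CandidateMotif | None = None
    best_key: tuple[float, int, int] | None = None
    for delta in sorted(range(-span, span + 1), key=lambda t: (abs(t), t > 0)):
        shifted = sorted(
            {
                (i, min(max(off + delta, 0), len(seqs[i]) - l))
                for i, off in motif.instances
            }
        )
        lmers = [seqs[i].seq[off : off + l] for i, off in shifted]
        if not lmers:
            continue
        cand = CandidateMotif(
            consensus=consensus_of(lmers),
            instances=tuple(shifted),
            provenance=motif.provenance,
        )
        if cand.support < 2:
            continue
        cand.score = score_fn(cand)
        key = (-cand.score, abs(delta), int(delta > 0))
        if best_key is None or key < best_key:
            best, best_key = cand, key
    if best is None:
        return motif
    final_sites = collect_within_windows(best.instances, best.consensus, d, seqs)
    if final_sites:
        final = CandidateMotif(
            consensus=consensus_of(
                [seqs[i].seq[off : off + l] for i, off in final_sites]
            ),
            instances=final_sites,
            provenance=motif.provenance,
        )
        if final.support >= 2:
            final.score = score_fn(final)
            return final
    return best
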