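"""N-partite l-mer graph construction.

Every length-l window of every input sequence is a vertex; two vertices
from *different* sequences are joined when the Hamming distance between
their l-mers is at most a threshold x. Planted motif instances (each
within distance d of a common parent) are pairwise within 2d, so at
x = 2d they form a clique across sequences; at the relaxed d <= x <= 2d
they form a dense subgraph while the random background stays sparse.

l-mers are packed 2 bits per base into 64-bit words, so a pairwise
distance block is XOR + popcount on integer arrays. The blocked
computation is exactly equivalent to the naive all-pairs definition and
is checked against it in the test suite.
"""

from __future__ import annotations

import logging
import warnings
from fractions import Fraction
from math import comb
from typing import Iterable, NamedTuple

import numpy as np

from .io_formats import ALPHABET, SequenceSet

logger = logging.getLogger(__name__)

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _BASE_CODE[ord(_b)] = _i

#: every second bit set; used to fold a 2-bit XOR into one indicator bit
_ODD_MASK = np.uint64(0x5555555555555555)
_BASES_PER_WORD = 32


class LmerVertex(NamedTuple):
    seq_index: int
    offset: int
    lmer: str


class LmerVertices:
    """Ordered l-mer vertices of a SequenceSet, in (seq_index, offset) order.

    Windows overlapping an ambiguous base (N) are skipped; the count of
    skipped windows is kept on ``n_skipped`` and logged.
    """

    def __init__(self, seqs: SequenceSet, l: int) -> None:
        if l < 1:
            raise ValueError("l must be >= 1")
        if l > seqs.l_min:
            raise ValueError(
                f"l={l} exceeds the shortest sequence length {seqs.l_min}"
            )
        self.seqs = seqs
        self.l = l
        seq_idx: list[np.ndarray] = []
        offs: list[np.ndarray] = []
        code_blocks: list[np.ndarray] = []
        n_skipped = 0
        for i, rec in enumerate(seqs):
            base = _BASE_CODE[np.frombuffer(rec.seq.encode(), dtype=np.uint8)]
            win = np.lib.stride_tricks.sliding_window_view(base, l)
            valid = (win < 4).all(axis=1)
            n_skipped += int((~valid).sum())
            win = win[valid]
            offsets = np.nonzero(valid)[0]
            seq_idx.append(np.full(len(offsets), i, dtype=np.int32))
            offs.append(offsets.astype(np.int32))
            code_blocks.append(_pack(win, l))
        self.seq_index = np.concatenate(seq_idx)
        self.offset = np.concatenate(offs)
        self.codes = np.concatenate(code_blocks, axis=0)
        self.n_skipped = n_skipped
        if n_skipped:
            logger.info("skipped %d l-mers overlapping ambiguous bases", n_skipped)

    def __len__(self) -> int:
        return len(self.offset)

    def __getitem__(self, v: int) -> LmerVertex:
        i, off = int(self.seq_index[v]), int(self.offset[v])
        return LmerVertex(i, off, self.seqs[i].seq[off : off + self.l])

    def lmer(self, v: int) -> str:
        return self[v].lmer


def _pack(windows: np.ndarray, l: int) -> np.ndarray:
    """Pack (n, l) base-code windows into (n, ceil(l/32)) uint64 words."""
    n_words = (l + _BASES_PER_WORD - 1) // _BASES_PER_WORD
    out = np.zeros((windows.shape[0], n_words), dtype=np.uint64)
    for j in range(l):
        w, r = divmod(j, _BASES_PER_WORD)
        out[:, w] |= windows[:, j].astype(np.uint64) << np.uint64(2 * r)
    return out


def _pair_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All-pairs Hamming distances between packed code blocks a and b."""
    n_words = a.shape[1]
    dist = np.zeros((a.shape[0], b.shape[0]), dtype=np.uint16)
    for w in range(n_words):
        z = a[:, w, None] ^ b[None, :, w]
        dist += np.bitwise_count((z | (z >> np.uint64(1))) & _ODD_MASK).astype(
            np.uint16
        )
    return dist


def enumerate_lmers(seqs: SequenceSet, l: int) -> LmerVertices:
    """Enumerate l-mer vertices in (seq_index, offset) order."""
    return LmerVertices(seqs, l)


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(c1 != c2 for c1, c2 in zip(a, b))


class AdjacencyGraph:
    """Undirected unweighted graph in CSR form with sorted neighbor lists."""

    def __init__(self, n_vertices: int, indptr: np.ndarray, indices: np.ndarray):
        self.n_vertices = n_vertices
        self.indptr = indptr
        self.indices = indices
        self.degrees = np.diff(indptr).astype(np.int64)
        self.m = int(self.degrees.sum() // 2)

    @classmethod
    def from_edges(
        cls, n_vertices: int, edges: Iterable[tuple[int, int]]
    ) -> "AdjacencyGraph":
        e = np.asarray(list(edges), dtype=np.int64).reshape(-1, 2)
        u = np.concatenate([e[:, 0], e[:, 1]])
        v = np.concatenate([e[:, 1], e[:, 0]])
        order = np.lexsort((v, u))
        u, v = u[order], v[order]
        indptr = np.zeros(n_vertices + 1, dtype=np.int64)
        np.add.at(indptr, u + 1, 1)
        np.cumsum(indptr, out=indptr)
        return cls(n_vertices, indptr, v)

    def neighbors(self, v: int) -> np.ndarray:
        return self.indices[self.indptr[v] : self.indptr[v + 1]]

    def edges(self) -> Iterable[tuple[int, int]]:
        for u in range(self.n_vertices):
            for v in self.neighbors(u):
                if u < v:
                    yield u, int(v)


class MotifGraph(AdjacencyGraph):
    """The N-partite l-mer graph at Hamming threshold x."""

    def __init__(self, vertices: LmerVertices, x: int, indptr, indices):
        super().__init__(len(vertices), indptr, indices)
        self.vertices = vertices
        self.l = vertices.l
        self.x = x

    @property
    def seq_index(self) -> np.ndarray:
        return self.vertices.seq_index

    @property
    def offset(self) -> np.ndarray:
        return self.vertices.offset


def build_graph(
    vertices: LmerVertices,
    x: int,
    d: int | None = None,
    memory_cap_bytes: int = 1 << 30,
) -> MotifGraph:
    """Build the N-partite graph with edges at Hamming distance <= x.

    When *d* is supplied, x outside the recommended band [d, 2d] triggers
    a warning (too small a threshold drops true instance pairs; too large
    a threshold floods the graph with background edges) but is allowed.
    The pairwise computation is blocked so peak working memory stays
    under ``memory_cap_bytes``; the result is independent of block size.
    """
    if len(vertices) == 0:
        raise ValueError("empty vertex set")
    if x < 0:
        raise ValueError("x must be >= 0")
    if d is not None and not d <= x <= 2 * d:
        warnings.warn(
            f"x={x} lies outside the recommended band [d, 2d] = [{d}, {2 * d}]",
            stacklevel=2,
        )
    n = len(vertices)
    # ~4 transient (block x block) uint64/uint16 arrays live at once
    block = max(64, int((memory_cap_bytes / 40) ** 0.5))
    codes = vertices.codes
    seq_idx = vertices.seq_index
    us: list[np.ndarray] = []
    vs: list[np.ndarray] = []
    for i0 in range(0, n, block):
        i1 = min(i0 + block, n)
        for j0 in range(i0, n, block):
            j1 = min(j0 + block, n)
            dist = _pair_distances(codes[i0:i1], codes[j0:j1])
            ok = dist <= x
            ok &= seq_idx[i0:i1, None] != seq_idx[None, j0:j1]
            if i0 == j0:
                ok &= np.tri(i1 - i0, j1 - j0, k=-1, dtype=bool).T
            ui, vi = np.nonzero(ok)
            us.append(ui.astype(np.int64) + i0)
            vs.append(vi.astype(np.int64) + j0)
    u = np.concatenate(us)
    v = np.concatenate(vs)
    ug = np.concatenate([u, v])
    vg = np.concatenate([v, u])
    order = np.lexsort((vg, ug))
    ug, vg = ug[order], vg[order]
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(indptr, ug + 1, 1)
    np.cumsum(indptr, out=indptr)
    graph = MotifGraph(vertices, x, indptr, vg)
    logger.info(
        "l-mer graph: %d vertices, %d edges at x=%d", n, graph.m, x
    )
    return graph


def p_random_match(l: int, x: int) -> float:
    """Probability that two random l-mers are within Hamming distance x.

    p(l, x) = sum_{i=0..x} C(l, i) (3/4)^i (1/4)^(l-i), evaluated with
    exact rational arithmetic (stable for l well beyond 60) and returned
    as a float.
    """
    if x < 0 or x > l:
        raise ValueError(f"need 0 <= x <= l, got x={x}, l={l}")
    total = sum(Fraction(comb(l, i) * 3**i, 4**l) for i in range(x + 1))
    return float(total)


def expected_edge_count(n_seqs: int, length: int, l: int, x: int) -> float:
    """Expected number of random cross-sequence edges at threshold x.

    0.5 * N * (N-1) * (L-l+1)^2 * p(l, x) for N i.i.d. uniform sequences
    of length L.
    """
    if length < l:
        raise ValueError("sequence length must be >= l")
    w = length - l + 1
    return 0.5 * n_seqs * (n_seqs - 1) * w * w * p_random_match(l, x)


def write_edge_tsv(graph: MotifGraph, path) -> None:
    """Debug dump: one line per edge (u_seq, u_off, v_seq, v_off, distance)."""
    vt = graph.vertices
    with open(path, "w") as fh:
        fh.write("u_seq\tu_off\tv_seq\tv_off\tdistance\n")
        for u, v in graph.edges():
            d = hamming(vt.lmer(u), vt.lmer(v))
            fh.write(
                f"{vt.seq_index[u]}\t{vt.offset[u]}\t"
                f"{vt.seq_index[v]}\t{vt.offset[v]}\t{d}\n"
            )
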