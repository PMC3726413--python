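"""FASTA input and motif-report/BED output.

All coordinates are 0-based half-open, both internally and in every file
this module writes. The tool scans the forward strand only, so the BED
strand column is always ``+``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Characters accepted on input. Lowercase is normalized to uppercase;
#: N marks an ambiguous base and excludes any l-mer overlapping it.
VALID_CHARS = frozenset("ACGTacgtNn")
ALPHABET = "ACGT"


class FastaParseError(ValueError):
    """Raised when an input FASTA file violates the expected format."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named DNA sequence over {A,C,G,T,N} (uppercase)."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class SequenceSet:
    """Ordered collection of uniquely named DNA sequences.

    The search substrate: sequence i of the set is one part of the
    N-partite l-mer graph, so at least two records are required before
    any motif search can run.
    """

    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate sequence id {dup!r}")
        for r in self.records:
            if not r.seq:
                raise ValueError(f"record {r.id!r} has an empty sequence")
            bad = set(r.seq) - set("ACGTN")
            if bad:
                raise ValueError(
                    f"record {r.id!r} contains illegal characters {sorted(bad)}"
                )

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def l_max(self) -> int:
        return max(len(r) for r in self.records)

    @property
    def l_min(self) -> int:
        return min(len(r) for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    def __iter__(self):
        return iter(self.records)


def _find_line(path: Path, needle: str) -> int | None:
    """Best-effort line number of the first line containing *needle*."""
    try:
        with open(path) as fh:
            for k, line in enumerate(fh, 1):
                if needle in line:
                    return k
    except OSError:
        pass
    return None


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Lowercase bases are uppercased. ``N`` bases are retained; downstream
    l-mer enumeration skips windows that overlap them (a count is logged
    here so silent data loss is visible).

    Raises :class:`FastaParseError` for empty files, duplicate ids and
    characters outside ``ACGTNacgtn`` (naming the offending line).
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    n_ambiguous = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        bad = set(raw) - VALID_CHARS
        if bad:
            ch = sorted(bad)[0]
            lineno = _find_line(path, ch)
            where = f" at line {lineno}" if lineno else ""
            raise FastaParseError(
                f"{path}: illegal character {ch!r} in record {rec.id!r}{where}"
            )
        if rec.id in seen:
            lineno = _find_line(path, f">{rec.id}")
            raise FastaParseError(
                f"{path}: duplicate sequence id {rec.id!r}"
                + (f" (line {lineno})" if lineno else "")
            )
        if not raw:
            raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence")
        seen.add(rec.id)
        seq = raw.upper()
        if "N" in seq:
            n_ambiguous += 1
        records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    if n_ambiguous:
        logger.info("%s: %d record(s) contain ambiguous 'N' bases", path, n_ambiguous)
    return SequenceSet(records)


def write_fasta(seqs: SequenceSet, path: str | Path) -> None:
    """Write standard FASTA with 60-column line wrapping."""
    if seqs.n == 0:
        raise ValueError("refusing to write an empty SequenceSet")
    bio = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in seqs]
    SeqIO.write(bio, str(path), "fasta")


def write_motif_report(
    motifs: Sequence, path: str | Path, seqs: SequenceSet | None = None
) -> None:
    """Write the ranked motif table as TSV, plus a companion instance list.

    Main file columns: rank, consensus, score, support, n_instances.
    When *seqs* is given, a companion file ``<path>.instances.tsv`` lists
    every predicted site as (rank, seq_id, offset0, lmer). Offsets are
    0-based (a header comment says so, keeping the convention explicit
    for downstream scripts). ``motifs`` must already be ranked.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# offsets are 0-based\n")
        fh.write("rank\tconsensus\tscore\tsupport\tn_instances\n")
        for rank, m in enumerate(motifs, 1):
            fh.write(
                f"{rank}\t{m.consensus}\t{m.score:.6g}\t{m.support}\t"
                f"{len(m.instances)}\n"
            )
    if seqs is None:
        return
    inst_path = path.with_name(path.name + ".instances.tsv")
    with open(inst_path, "w") as fh:
        fh.write("rank\tseq_id\toffset0\tlmer\n")
        for rank, m in enumerate(motifs, 1):
            l = len(m.consensus)
            for seq_index, off in m.instances:
                rec = seqs[seq_index]
                fh.write(f"{rank}\t{rec.id}\t{off}\t{rec.seq[off:off + l]}\n")


def bed_score(score: float, l: int) -> int:
    """Map a significance score onto the BED [0, 1000] score column.

    The score is at most 2·l for a perfectly conserved, fully supported
    motif against a uniform background, so we scale by 1000/(2l) and clip.
    """
    return int(min(1000, max(0, round(score * 1000.0 / (2 * l)))))


def write_sites_bed(motif, seqs: SequenceSet, path: str | Path) -> None:
    """Write one motif's predicted sites as BED6 (0-based half-open, '+')."""
    l = len(motif.consensus)
    lines = []
    for seq_index, off in motif.instances:
        rec = seqs[seq_index]
        if off < 0 or off + l > len(rec):
            raise ValueError(
                f"site ({rec.id}, {off}) out of range for sequence of length {len(rec)}"
            )
        lines.append(
            f"{rec.id}\t{off}\t{off + l}\t{motif.consensus}\t"
            f"{bed_score(motif.score, l)}\t+\n"
        )
    with open(path, "w") as fh:
        fh.writelines(lines)


def read_truth_tsv(path: str | Path) -> tuple[str, list[tuple[str, int]]]:
    """Read a planted-truth TSV (seq_id, offset0, instance, parent).

    Returns (parent, [(seq_id, offset0), ...]).
    """
    parent = ""
    sites: list[tuple[str, int]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: k for k, name in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            row = line.rstrip("\n").split("\t")
            parent = row[idx["parent"]]
            sites.append((row[idx["seq_id"]], int(row[idx["offset0"]])))
    return parent, sites


def read_motif_report(path: str | Path) -> list[dict]:
    """Read back a motif report TSV written by :func:`write_motif_report`."""
    rows: list[dict] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "rank":
                continue
            rows.append(
                {
                    "rank": int(parts[0]),
                    "consensus": parts[1],
                    "score": float(parts[2]),
                    "support": int(parts[3]),
                    "n_instances": int(parts[4]),
                }
            )
    return rows
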