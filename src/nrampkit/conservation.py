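"""Filter a large family alignment and profile per-position conservation.

Workflow mirrors how conservation percentages are typically quoted for a
reference structure: take an existing family-wide multiple sequence alignment,
drop fragments and sequences missing the family's diagnostic motifs (for
Nramps, the TM1 'DPGN' and TM6 'MPH' motifs), locate the reference sequence,
map its ungapped residue numbering onto alignment columns, and report residue
frequencies at the mapped column ("Q378: 86% Q, 11% N"). Gapped sequences at a
column count in the denominator by default — a gap is a category — so the
quoted percentages for all residues plus gap sum to 100.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from Bio import AlignIO, SeqIO

logger = logging.getLogger(__name__)

GAP_CHARS = ("-", ".")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_REFERENCE_PATTERNS = ("Q9RTP8", "DraNramp", "DRARA")


@dataclass
class MSA:
    """Ordered alignment records; all aligned sequences share one length."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.records:
            self.n_columns = 0
            return
        lengths = {len(seq) for _id, seq in self.records}
        if len(lengths) != 1:
            bad = next(
                rid for rid, seq in self.records if len(seq) != len(self.records[0][1])
            )
            raise ValueError(f"ragged alignment: record {bad!r} has a different length")
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in alignment")
        self.n_columns = lengths.pop()

    def __len__(self) -> int:
        return len(self.records)

    def column(self, col: int) -> str:
        """1-based alignment column as a string of uppercased symbols."""
        return "".join(seq[col - 1].upper() for _id, seq in self.records)


@dataclass
class ColumnMap:
    """Bijection: reference ungapped position (1-based) → alignment column (1-based)."""

    reference_id: str
    mapping: dict[int, int]

    def column_of(self, position: int) -> int:
        if position not in self.mapping:
            raise KeyError(
                f"position {position} not modeled in reference {self.reference_id!r} "
                f"(covers 1-{max(self.mapping) if self.mapping else 0})"
            )
        return self.mapping[position]


@dataclass
class ConservationEntry:
    position: int
    reference_residue: str
    counts: dict[str, int]
    n_sequences: int
    queried_residue: str
    queried_fraction: float

    @property
    def queried_percent(self) -> int:
        """Rounded-half-up integer percent for the queried residue."""
        return int(self.queried_fraction * 100 + 0.5)

    @property
    def gap_fraction(self) -> float:
        return self.counts.get("-", 0) / self.n_sequences


def ungap(seq: str) -> str:
    out = seq
    for g in GAP_CHARS:
        out = out.replace(g, "")
    return out.upper()


def read_alignment(path: str | Path, format: str = "fasta") -> MSA:
    """Read an aligned FASTA or Stockholm file, preserving record order."""
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unknown alignment format {format!r}")
    if format == "fasta":
        # SeqIO tolerates ragged records; MSA.__post_init__ reports the offender
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    else:
        aln = AlignIO.read(str(path), "stockholm")
        records = [(r.id, str(r.seq)) for r in aln]
    if not records:
        raise ValueError(f"{path}: no alignment records")
    return MSA(records)


def filter_sequences(
    msa: MSA,
    min_len: int = 400,
    max_len: int = 600,
    motifs: tuple[str, ...] = ("DPGN", "MPH"),
) -> MSA:
    """Keep records whose ungapped length is in [min_len, max_len] and whose
    ungapped sequence contains every motif as an exact substring.

    Idempotent; an empty result is allowed (warned, not raised).
    """
    kept = []
    for rid, seq in msa.records:
        plain = ungap(seq)
        if not min_len <= len(plain) <= max_len:
            continue
        if any(motif.upper() not in plain for motif in motifs):
            continue
        kept.append((rid, seq))
    if not kept:
        logger.warning("filter_sequences: no records passed the filter")
    return MSA(kept)


def find_reference(msa: MSA, patterns: tuple[str, ...] = DEFAULT_REFERENCE_PATTERNS) -> str:
    """First record id containing any of the patterns (case-insensitive)."""
    for rid, _seq in msa.records:
        if any(p.lower() in rid.lower() for p in patterns):
            return rid
    raise KeyError(f"no record id matches any of {patterns}")


def map_reference(msa: MSA, ref_id: str) -> ColumnMap:
    """Map the reference's ungapped positions onto alignment columns."""
    seq = None
    for rid, s in msa.records:
        if rid == ref_id:
            seq = s
            break
    if seq is None:
        near = [rid for rid, _ in msa.records if ref_id.lower() in rid.lower()][:5]
        hint = f"; near-matches: {near}" if near else ""
        raise KeyError(f"reference id {ref_id!r} not in alignment{hint}")
    mapping: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(seq, start=1):
        if ch not in GAP_CHARS:
            pos += 1
            mapping[pos] = col
    return ColumnMap(ref_id, mapping)


def conservation_at(
    msa: MSA, cmap: ColumnMap, position: int, residue: str
) -> ConservationEntry:
    """Residue frequencies at the alignment column behind a reference position.

    The denominator is all sequences in the alignment (gap counted as its own
    category); percents for the 20 amino acids + gap therefore sum to 100.
    """
    col = cmap.column_of(position)
    column = msa.column(col)
    counts = Counter("-" if c in GAP_CHARS else c for c in column)
    ref_row = dict(msa.records)[cmap.reference_id]
    ref_res = ref_row[col - 1].upper()
    residue = residue.upper()
    return ConservationEntry(
        position=position,
        reference_residue=ref_res,
        counts=dict(counts),
        n_sequences=len(msa),
        queried_residue=residue,
        queried_fraction=counts.get(residue, 0) / len(msa),
    )


def profile_to_tsv(
    msa: MSA, cmap: ColumnMap, path: str | Path, positions: list[int] | None = None
) -> None:
    """Export (ref position, ref aa, top aa, top %, gap %) rows for positions."""
    positions = positions or sorted(cmap.mapping)
    with open(path, "w") as fh:
        fh.write("position\tref_aa\ttop_aa\ttop_pct\tgap_pct\n")
        for pos in positions:
            col = msa.column(cmap.column_of(pos))
            counts = Counter("-" if c in GAP_CHARS else c for c in col)
            top_aa, top_n = max(
                ((aa, counts.get(aa, 0)) for aa in AMINO_ACIDS), key=lambda kv: kv[1]
            )
            ref_res = dict(msa.records)[cmap.reference_id][cmap.column_of(pos) - 1]
            fh.write(
                f"{pos}\t{ref_res.upper()}\t{top_aa}\t{100 * top_n / len(msa):.2f}\t"
                f"{100 * counts.get('-', 0) / len(msa):.2f}\n"
            )


def write_fasta(msa: MSA, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in msa.records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
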