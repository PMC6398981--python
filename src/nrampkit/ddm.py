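"""Distance-difference-matrix (DDM) analysis of conformational change.

A DDM compares two conformations of the same protein without any
superposition: intramolecular Cα–Cα distances are rigid-transform invariants,
so every nonzero entry reflects genuine internal rearrangement. To summarise
which helices move relative to which, the residue-level difference matrix is
pooled over pairs of predefined helix segments with an RMS — the coarse
matrix. For a 10+1-TM LeuT-fold transporter the natural segmentation breaks
TMs 1, 6 and 10 at their helix-breaking elements, giving 14 segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import squareform, pdist

from nrampkit.structure_io import CaTrace, ResidueLabel

#: packaged approximate DraNramp segmentation (synthetic stand-in, see file docstring)
DEFAULT_SEGMENTS_PATH = Path(__file__).parent / "data" / "dra_nramp_segments_synthetic.tsv"


@dataclass
class DistanceMatrix:
    labels: list[ResidueLabel]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("values must be n×n matching labels")


@dataclass
class DifferenceMatrix:
    """Signed per-pair distance change between two conformations (a − b)."""

    labels: list[ResidueLabel]
    values: np.ndarray


@dataclass
class SegmentSet:
    """Named residue intervals (1-based inclusive, author numbering).

    ``segments`` maps name → list of (start, end) intervals; several intervals
    per name are allowed (e.g. a helix interrupted by a disordered stretch).
    Segments must be pairwise disjoint.
    """

    segments: dict[str, list[tuple[int, int]]]

    def __post_init__(self) -> None:
        claimed: dict[int, str] = {}
        for name, intervals in self.segments.items():
            for lo, hi in intervals:
                if hi < lo:
                    raise ValueError(f"segment {name}: empty interval {lo}-{hi}")
                for num in range(lo, hi + 1):
                    if num in claimed:
                        raise ValueError(
                            f"residue {num} claimed by both {claimed[num]} and {name}"
                        )
                    claimed[num] = name

    @property
    def names(self) -> list[str]:
        return list(self.segments)

    def member_indices(self, labels: list[ResidueLabel]) -> dict[str, np.ndarray]:
        """Indices into ``labels`` for each segment; errors on empty segments."""
        out = {}
        for name, intervals in self.segments.items():
            rows = [
                i
                for i, (_c, num, _ic) in enumerate(labels)
                if any(lo <= num <= hi for lo, hi in intervals)
            ]
            if not rows:
                raise ValueError(f"segment {name!r} has no residues among the labels")
            out[name] = np.asarray(rows)
        return out

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SegmentSet":
        """Read a segment config: columns name, chain, start, end (chain unused here)."""
        segments: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith("#") or line.lower().startswith("name\t"):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValueError(f"bad segment row (need 4 columns): {line!r}")
                name, _chain, start, end = parts[:4]
                segments.setdefault(name, []).append((int(start), int(end)))
        return cls(segments)


@dataclass
class CoarseMatrix:
    """Segment-pair RMS of distance-difference entries, in Å."""

    segment_names: list[str]
    values: np.ndarray

    def largest_offdiagonal(self, k: int = 4) -> list[tuple[str, str, float]]:
        """The k largest off-diagonal entries as (segment, segment, Å), descending."""
        n = len(self.segment_names)
        entries = [
            (self.segment_names[i], self.segment_names[j], float(self.values[i, j]))
            for i in range(n)
            for j in range(i + 1, n)
        ]
        entries.sort(key=lambda e: -e[2])
        return entries[:k]


def distance_matrix(trace: CaTrace) -> DistanceMatrix:
    """All pairwise Cα–Cα Euclidean distances of a trace."""
    if len(trace) == 0:
        raise ValueError("empty trace")
    if len(trace) == 1:
        vals = np.zeros((1, 1))
    else:
        vals = squareform(pdist(trace.positions))
    return DistanceMatrix(list(trace.labels), vals)


def difference_matrix(a: DistanceMatrix, b: DistanceMatrix) -> DifferenceMatrix:
    """a − b restricted to common labels, ordered as in ``a``.

    Matching is on (residue number, insertion code) so depositions with
    different chain ids still compare.
    """

    def key(lab: ResidueLabel):
        return lab[1:]

    b_idx = {key(lab): i for i, lab in enumerate(b.labels)}
    rows_a, rows_b, labels = [], [], []
    for i, lab in enumerate(a.labels):
        j = b_idx.get(key(lab))
        if j is not None:
            rows_a.append(i)
            rows_b.append(j)
            labels.append(lab)
    if len(labels) < 2:
        raise ValueError("fewer than 2 common labels between distance matrices")
    sub_a = a.values[np.ix_(rows_a, rows_a)]
    sub_b = b.values[np.ix_(rows_b, rows_b)]
    return DifferenceMatrix(labels, sub_a - sub_b)


def coarse_grain(dm: DifferenceMatrix, segments: SegmentSet) -> CoarseMatrix:
    """RMS-pool a difference matrix over segment pairs.

    C[s, t] = sqrt(mean over residue pairs (a in s, b in t, a ≠ b) of Δ(a,b)²).
    Diagonal blocks use unordered within-segment pairs; self-pairs (the
    structural-zero diagonal) are excluded everywhere so they cannot dilute
    the average.
    """
    members = segments.member_indices(dm.labels)
    names = segments.names
    k = len(names)
    out = np.zeros((k, k))
    sq = dm.values**2
    for i, s in enumerate(names):
        rs = members[s]
        for j in range(i, k):
            rt = members[names[j]]
            block = sq[np.ix_(rs, rt)]
            if i == j:
                n = len(rs)
                if n < 2:
                    out[i, j] = 0.0
                else:
                    iu = np.triu_indices(n, k=1)
                    out[i, j] = np.sqrt(block[iu].mean())
            else:
                out[i, j] = out[j, i] = np.sqrt(block.mean())
    return CoarseMatrix(names, out)


def coarse_matrix_to_tsv(cm: CoarseMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("segment\t" + "\t".join(cm.segment_names) + "\n")
        for name, row in zip(cm.segment_names, cm.values):
            fh.write(name + "\t" + "\t".join(f"{v:.3f}" for v in row) + "\n")


def matrix_to_tsv(dm: DistanceMatrix | DifferenceMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        header = "\t".join(f"{c}:{n}{ic}" for c, n, ic in dm.labels)
        fh.write("label\t" + header + "\n")
        for (c, n, ic), row in zip(dm.labels, dm.values):
            fh.write(f"{c}:{n}{ic}\t" + "\t".join(f"{v:.3f}" for v in row) + "\n")


def plot_coarse_matrix(cm: CoarseMatrix, path: str | Path, title: str = "") -> None:
    """Heatmap with 0 Å mapped to the darkest colour (stationary = dark)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(cm.values, cmap="viridis", vmin=0.0)
    ax.set_xticks(range(len(cm.segment_names)), cm.segment_names, rotation=90)
    ax.set_yticks(range(len(cm.segment_names)), cm.segment_names)
    fig.colorbar(im, ax=ax, label="RMS Δdistance (Å)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def default_segments() -> SegmentSet:
    """The packaged 14-segment DraNramp definition (approximate; see the TSV)."""
    return SegmentSet.from_tsv(DEFAULT_SEGMENTS_PATH)
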