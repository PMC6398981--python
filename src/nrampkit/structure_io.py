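"""Read macromolecular coordinates and expose label-addressable residues and Cα traces.

Parsing is delegated to :mod:`gemmi`; the in-memory model here is a deliberately
small, ordered view tailored to the downstream geometry: author residue
numbering is the universal coordinate convention (D56, Q378, ... are author
numbers in all four DraNramp depositions), altloc duplicates are collapsed to
the highest-occupancy conformer, and waters/metals are retained as hetero
residues so the coordination module can address them by name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

#: label triple addressing a residue: (chain_id, author number, insertion code)
ResidueLabel = tuple[str, int, str]


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed or contains no atoms."""


@dataclass
class Atom:
    """A single atom with author metadata.

    position is in Å; occupancy in [0, 1]; altloc is '' once conformers are
    collapsed; b_factor in Å².
    """

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    chain_id: str
    number: int
    insertion_code: str
    name: str
    is_hetero: bool
    atoms: list[Atom] = field(default_factory=list)

    @property
    def label(self) -> ResidueLabel:
        return (self.chain_id, self.number, self.insertion_code)

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class StructureModel:
    """Ordered chains of residues from model 1 of a coordinate file."""

    id: str
    chains: dict[str, list[Residue]]
    title: str = ""

    def __post_init__(self) -> None:
        if not self.chains:
            raise StructureParseError(f"{self.id}: model has no chains")

    def residues(self, chain: str | None = None) -> Iterator[Residue]:
        if chain is not None:
            yield from self.chains.get(chain, [])
        else:
            for residues in self.chains.values():
                yield from residues

    def protein_residues(self, chain: str | None = None) -> list[Residue]:
        return [r for r in self.residues(chain) if not r.is_hetero]

    def hetero_residues(self, chain: str | None = None) -> list[Residue]:
        return [r for r in self.residues(chain) if r.is_hetero]


@dataclass
class CaTrace:
    """Ordered Cα coordinates keyed by residue label."""

    labels: list[ResidueLabel]
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.labels) != len(self.positions):
            raise ValueError("labels and positions must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate residue labels in trace")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self) -> dict[ResidueLabel, int]:
        return {lab: i for i, lab in enumerate(self.labels)}

    def subset(self, labels: Sequence[ResidueLabel]) -> "CaTrace":
        idx = self.index()
        rows = [idx[lab] for lab in labels]
        return CaTrace(list(labels), self.positions[rows])


def _collapse_altlocs(raw: list[Atom]) -> list[Atom]:
    """Keep the highest-occupancy conformer per atom name; ties break on altloc."""
    best: dict[str, Atom] = {}
    for atom in raw:
        prev = best.get(atom.name)
        if (
            prev is None
            or atom.occupancy > prev.occupancy
            or (atom.occupancy == prev.occupancy and atom.altloc < prev.altloc)
        ):
            best[atom.name] = atom
    out = []
    seen: set[str] = set()
    for atom in raw:  # preserve file order
        if atom.name not in seen:
            seen.add(atom.name)
            a = best[atom.name]
            a.altloc = ""
            out.append(a)
    return out


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    ``format`` is one of ``pdb``, ``mmcif`` or ``auto`` (extension sniffing).
    Only model 1 of multi-model files is read. Raises
    :class:`StructureParseError` on unreadable input or an atom-free file.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        elif format == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and "unknown format" in str(exc):
            raise
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc

    st.setup_entities()
    if len(st) == 0:
        raise StructureParseError(f"{path}: no atoms (file contains no model)")
    model = st[0]

    chains: dict[str, list[Residue]] = {}
    n_atoms = 0
    for chain in model:
        residues = chains.setdefault(chain.name, [])
        for res in chain:
            het = res.het_flag == "H" or res.entity_type in (
                gemmi.EntityType.NonPolymer,
                gemmi.EntityType.Water,
            )
            atoms = []
            for atom in res:
                atoms.append(
                    Atom(
                        name=atom.name,
                        element=atom.element.name.upper(),
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                        altloc=atom.altloc if atom.altloc != "\x00" else "",
                        b_factor=atom.b_iso,
                    )
                )
            atoms = _collapse_altlocs(atoms)
            n_atoms += len(atoms)
            residues.append(
                Residue(
                    chain_id=chain.name,
                    number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    name=res.name,
                    is_hetero=het,
                    atoms=atoms,
                )
            )
    chains = {c: r for c, r in chains.items() if r}
    if n_atoms == 0 or not chains:
        raise StructureParseError(f"{path}: no atoms")
    return StructureModel(id=st.name or path.stem, chains=chains, title=st.name or "")


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a model back out as PDB (one model, author numbering preserved)."""
    st = gemmi.Structure()
    st.name = model.id
    gm = gemmi.Model("1")
    for chain_id, residues in model.chains.items():
        gc = gemmi.Chain(chain_id)
        for res in residues:
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
            gr.het_flag = "H" if res.is_hetero else "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.position)
                ga.occ = atom.occupancy
                ga.b_iso = atom.b_factor
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def ca_trace(model: StructureModel, chain: str | None = None) -> CaTrace:
    """Extract the ordered Cα trace of ``chain`` (or all chains).

    Residues lacking a Cα (hetero groups, incompletely modeled residues) are
    skipped and logged. Raises ``ValueError`` if no Cα is found at all.
    """
    labels: list[ResidueLabel] = []
    positions: list[np.ndarray] = []
    for res in model.residues(chain):
        ca = res.atom("CA")
        if ca is not None and ca.element in ("C", ""):
            labels.append(res.label)
            positions.append(ca.position)
        elif not res.is_hetero:
            logger.debug("residue %s %s has no CA; skipped", res.name, res.label)
    if not labels:
        where = f"chain {chain}" if chain else "model"
        raise ValueError(f"{model.id}: no Cα atoms found in {where}")
    return CaTrace(labels, np.array(positions))


def common_labels(
    *traces: CaTrace, ignore_chain: bool = True
) -> list[ResidueLabel]:
    """Residue labels present in every trace, ordered as in the first.

    Matching is on (residue number, insertion code) by default — the convention
    when comparing depositions of the same protein that share author numbering
    but may use different chain ids. An empty intersection is returned (with a
    warning), not raised.
    """
    if len(traces) < 2:
        raise ValueError("need at least two traces")

    def key(lab: ResidueLabel):
        return lab[1:] if ignore_chain else lab

    common = set(map(key, traces[0].labels))
    for t in traces[1:]:
        common &= set(map(key, t.labels))
    result = [lab for lab in traces[0].labels if key(lab) in common]
    if not result:
        logger.warning("common_labels: empty intersection across %d traces", len(traces))
    return result


def match_traces(
    a: CaTrace, b: CaTrace, ignore_chain: bool = True
) -> tuple[CaTrace, CaTrace]:
    """Restrict two traces to their common labels, in ``a``'s order."""
    labs = common_labels(a, b, ignore_chain=ignore_chain)

    def key(lab: ResidueLabel):
        return lab[1:] if ignore_chain else lab

    keys = {key(lab) for lab in labs}
    a_labs = [lab for lab in a.labels if key(lab) in keys]
    b_index = {key(lab): i for i, lab in enumerate(b.labels)}
    b_labs = [b.labels[b_index[key(lab)]] for lab in a_labs]
    return a.subset(a_labs), b.subset(b_labs)


def trace_to_tsv(trace: CaTrace, path: str | Path) -> None:
    """Export a trace as TSV: chain, resnum, icode, x, y, z (3 decimals)."""
    with open(path, "w") as fh:
        fh.write("chain\tresnum\ticode\tx\ty\tz\n")
        for (chain, num, icode), pos in zip(trace.labels, trace.positions):
            fh.write(f"{chain}\t{num}\t{icode}\t{pos[0]:.3f}\t{pos[1]:.3f}\t{pos[2]:.3f}\n")
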