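"""Metal coordination-sphere geometry and atom-pair distances.

The coordination sphere of a bound transition metal (Mn²⁺, Cd²⁺, ...) is the
set of electron-donating atoms — carboxylate/carbonyl oxygens, amide nitrogens
and oxygens, thioether sulfurs, water oxygens — within a distance cutoff of
the ion. Contacts out to ~3.4 Å are routinely counted as coordinating in
moderate-resolution structures, hence the 3.5 Å default cutoff. A bidentate
carboxylate contributes one entry per oxygen, so the atom-level coordination
number can exceed the number of ligating residues (e.g. seven ligands from
four residues plus two waters when both aspartate oxygens engage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nrampkit.structure_io import Atom, Residue, StructureModel, WATER_NAMES

DEFAULT_CUTOFF = 3.5

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

LIGAND_CLASSES = (
    "sidechain-O",
    "sidechain-N",
    "sidechain-S",
    "backbone-carbonyl-O",
    "water-O",
    "other",
)


class SelectorError(ValueError):
    """An atom selector resolved to nothing or was ambiguous."""


@dataclass
class SphereEntry:
    residue: Residue
    atom: Atom
    distance: float
    ligand_class: str


@dataclass
class CoordinationSphere:
    center_residue: Residue
    center_atom: Atom
    cutoff: float
    entries: list[SphereEntry]

    @property
    def coordination_number(self) -> int:
        return len(self.entries)

    @property
    def ligating_residues(self) -> list[Residue]:
        """Unique residues contributing at least one entry, nearest first."""
        seen, out = set(), []
        for e in self.entries:
            if e.residue.label not in seen:
                seen.add(e.residue.label)
                out.append(e.residue)
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chain\tresnum\ticode\tresname\tatom\tdistance_A\tclass\n")
            for e in self.entries:
                c, n, ic = e.residue.label
                fh.write(
                    f"{c}\t{n}\t{ic}\t{e.residue.name}\t{e.atom.name}\t"
                    f"{e.distance:.3f}\t{e.ligand_class}\n"
                )


def classify_ligand(residue: Residue, atom: Atom) -> str:
    if residue.is_water:
        return "water-O" if atom.element == "O" else "other"
    if atom.name in BACKBONE_ATOMS:
        return "backbone-carbonyl-O" if atom.name in ("O", "OXT") else "other"
    if atom.element == "O":
        return "sidechain-O"
    if atom.element == "N":
        return "sidechain-N"
    if atom.element == "S":
        return "sidechain-S"
    return "other"


def select_atoms(model: StructureModel, selector: str) -> list[tuple[Residue, Atom]]:
    """Resolve a mini-syntax atom selector.

    Syntax: ``chain/resnum/resname/atomname`` where trailing fields may be
    omitted and any field may be ``*`` (wildcard) or a ``|``-separated list
    (e.g. ``A/56/ASP/OD1|OD2``). A single bare field (``MN``) matches by
    residue name or element symbol. Raises :class:`SelectorError` when
    nothing matches.
    """
    parts = selector.strip().split("/")

    def field_match(value: str, pattern: str) -> bool:
        return pattern in ("", "*") or value.upper() in pattern.upper().split("|")

    matches: list[tuple[Residue, Atom]] = []
    if len(parts) == 1:
        pat = parts[0]
        for res in model.residues():
            for atom in res.atoms:
                if field_match(res.name, pat) or field_match(atom.element, pat):
                    matches.append((res, atom))
    else:
        parts += ["*"] * (4 - len(parts))
        chain_p, num_p, name_p, atom_p = parts[:4]
        for res in model.residues():
            if not field_match(res.chain_id, chain_p):
                continue
            if not field_match(str(res.number), num_p):
                continue
            if not field_match(res.name, name_p):
                continue
            for atom in res.atoms:
                if field_match(atom.name, atom_p):
                    matches.append((res, atom))
    if not matches:
        raise SelectorError(f"selector {selector!r} matched no atoms")
    return matches


def pair_distance(
    model: StructureModel, sel_a: str, sel_b: str, mode: str = "min"
) -> float:
    """Distance in Å between two atom selections.

    ``mode='min'`` takes the minimum over all pairs (the natural reading of
    "the metal–aspartate distance" for a bidentate carboxylate);
    ``mode='specific'`` requires each selector to resolve to a unique atom.
    """
    atoms_a = select_atoms(model, sel_a)
    atoms_b = select_atoms(model, sel_b)
    if mode == "specific":
        for sel, atoms in ((sel_a, atoms_a), (sel_b, atoms_b)):
            if len(atoms) != 1:
                listing = ", ".join(f"{r.name}{r.number}/{a.name}" for r, a in atoms[:8])
                raise SelectorError(
                    f"selector {sel!r} must be unique in mode='specific'; matched: {listing}"
                )
    elif mode != "min":
        raise ValueError(f"unknown mode {mode!r}")
    pa = np.array([a.position for _, a in atoms_a])
    pb = np.array([a.position for _, a in atoms_b])
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    return float(d.min())


def coordination_sphere(
    model: StructureModel,
    center: str,
    cutoff: float = DEFAULT_CUTOFF,
    include_waters: bool = True,
) -> CoordinationSphere:
    """All O/N/S atoms within ``cutoff`` of a unique center atom, classified.

    Carbon and hydrogen never coordinate and are excluded; water oxygens are
    included unless ``include_waters=False``. Entries are sorted by distance.
    Raises :class:`SelectorError` if the center selector is ambiguous, listing
    the matches.
    """
    centers = select_atoms(model, center)
    if len(centers) != 1:
        listing = ", ".join(
            f"{r.chain_id}/{r.number}/{r.name}/{a.name}" for r, a in centers[:10]
        )
        raise SelectorError(
            f"center selector {center!r} matched {len(centers)} atoms: {listing}"
        )
    center_res, center_atom = centers[0]
    entries: list[SphereEntry] = []
    for res in model.residues():
        if res.label == center_res.label and res.name == center_res.name:
            continue
        if res.is_water and not include_waters:
            continue
        for atom in res.atoms:
            if atom.element not in ("O", "N", "S"):
                continue
            d = float(np.linalg.norm(atom.position - center_atom.position))
            if d <= cutoff:
                entries.append(SphereEntry(res, atom, d, classify_ligand(res, atom)))
    entries.sort(key=lambda e: e.distance)
    return CoordinationSphere(center_res, center_atom, cutoff, entries)
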