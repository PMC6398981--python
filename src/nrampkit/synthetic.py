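"""Synthetic structures, alignments, and fluorescence traces with known truth.

These generators stand in for the real study inputs (deposited transporter
coordinates, a family-wide alignment, plate-reader time courses) so that every
analysis stage can be exercised end-to-end with analytic ground truth:

* :func:`make_helical_bundle` — an idealised α-helical TM bundle (rise 1.5 Å
  and 100°/residue twist on a 2.3 Å Cα helix radius) arranged on a ring, with
  matching per-helix segment definitions.
* :func:`apply_rigid_motion` — a proper rigid motion applied to one residue
  interval, emulating a swinging or translating helix.
* :func:`make_msa` — an alignment with exact per-column residue counts and
  motifs anchored at reference positions.
* :func:`simulate_trace` — forward-modelled Fura-2/BCECF traces from known
  uptake kinetics and dye calibrations, with seeded Gaussian channel noise.

The geometry is adequate for testing distance/superposition machinery, not
for physical realism (no sidechains, no membrane, no photobleaching).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from nrampkit.ddm import SegmentSet
from nrampkit.structure_io import Atom, Residue, StructureModel
from nrampkit.transport import (
    BcecfCalibration,
    FluorescenceTrace,
    FuraCalibration,
    bcecf_ratio,
    fura2_ratio,
)

HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # Å, Cα helix radius


@dataclass
class BundleSpec:
    n_helices: int = 4
    residues_per_helix: int = 20
    ring_radius: float = 8.0  # Å
    rise: float = HELIX_RISE
    twist: float = HELIX_TWIST
    helix_radius: float = HELIX_RADIUS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_helices < 1 or self.residues_per_helix < 1:
            raise ValueError("counts must be ≥ 1")
        if self.ring_radius <= 0:
            raise ValueError("ring_radius must be positive")


@dataclass
class MotionSpec:
    """Proper rigid motion of one residue interval (1-based inclusive)."""

    segment: tuple[int, int]
    angle_deg: float = 0.0
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    pivot: tuple[float, float, float] | None = None  # default: segment centroid

    def __post_init__(self) -> None:
        if np.linalg.norm(self.axis) == 0:
            raise ValueError("rotation axis must be non-zero")


@dataclass
class TraceSpec:
    """Ground truth for a simulated assay trace.

    mode 'metal' forward-models Fura-2-reported free-metal accumulation at
    constant external substrate S_uM with rate v = Vmax·S/(KM+S);
    mode 'metal_quench' models normalised quenching of both Fura-2 channels;
    mode 'proton' models a prescribed internal pH relaxation read out through
    BCECF channels. Noise is per-channel multiplicative Gaussian with
    fractional σ.
    """

    mode: str = "metal"
    KM: float = 30.0  # µM
    Vmax: float = 0.05  # µM/s internal accumulation
    S_uM: float = 30.0
    fura: FuraCalibration | None = None
    bcecf: BcecfCalibration | None = None
    pH_start: float = 7.0
    pH_end: float = 6.8
    pH_tau: float = 60.0  # s, exponential relaxation constant
    quench_depth: float = 0.6  # max fraction of fluorescence lost
    noise_sigma: float = 0.0
    dt: float = 1.0  # s
    duration: float = 300.0  # s
    t_add: float = 30.0  # substrate addition
    t_ionomycin: float = 240.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be ≥ 0")
        if self.dt <= 0:
            raise ValueError("sampling interval must be positive")
        if self.mode not in ("metal", "metal_quench", "proton"):
            raise ValueError(f"unknown trace mode {self.mode!r}")


def rotation_matrix(axis, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about ``axis`` by ``angle_deg``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    theta = np.radians(angle_deg)
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)


def random_rigid_transform(rng: np.random.Generator, max_translation: float = 20.0):
    """A uniformly random proper rotation and a random translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.uniform(-max_translation, max_translation, size=3)
    return R, t


def make_helical_bundle(spec: BundleSpec) -> tuple[StructureModel, SegmentSet]:
    """Build an ideal Cα-only helical bundle and its per-helix segments.

    Helices stand parallel to z on a ring of ``ring_radius``, alternating
    up/down (antiparallel packing); residues are numbered consecutively across
    helices in chain A. Deterministic for a given spec.
    """
    residues: list[Residue] = []
    segments: dict[str, list[tuple[int, int]]] = {}
    resnum = 0
    for h in range(spec.n_helices):
        phi = 2.0 * np.pi * h / spec.n_helices
        center = np.array([spec.ring_radius * np.cos(phi), spec.ring_radius * np.sin(phi), 0.0])
        direction = 1.0 if h % 2 == 0 else -1.0
        start = resnum + 1
        for i in range(spec.residues_per_helix):
            resnum += 1
            ang = np.radians(spec.twist * i)
            local = np.array(
                [
                    spec.helix_radius * np.cos(ang),
                    spec.helix_radius * np.sin(ang) * direction,
                    spec.rise * i * direction,
                ]
            )
            residues.append(
                Residue(
                    chain_id="A",
                    number=resnum,
                    insertion_code="",
                    name="ALA",
                    is_hetero=False,
                    atoms=[Atom(name="CA", element="C", position=center + local)],
                )
            )
        segments[f"H{h + 1}"] = [(start, resnum)]
    model = StructureModel(id=f"bundle{spec.n_helices}x{spec.residues_per_helix}", chains={"A": residues})
    return model, SegmentSet(segments)


def apply_rigid_motion(model: StructureModel, motion: MotionSpec) -> StructureModel:
    """Return a copy with ``motion`` applied to the atoms of its segment only."""
    lo, hi = motion.segment
    targets = [
        atom.position
        for res in model.residues()
        if lo <= res.number <= hi
        for atom in res.atoms
    ]
    if not targets:
        raise ValueError(f"segment {lo}-{hi} selects no atoms")
    R = rotation_matrix(motion.axis, motion.angle_deg)
    pivot = (
        np.asarray(motion.pivot, dtype=float)
        if motion.pivot is not None
        else np.mean(targets, axis=0)
    )
    t = np.asarray(motion.translation, dtype=float)

    new_chains: dict[str, list[Residue]] = {}
    for chain_id, residues in model.chains.items():
        out = []
        for res in residues:
            atoms = []
            for atom in res.atoms:
                pos = atom.position
                if lo <= res.number <= hi:
                    pos = R @ (pos - pivot) + pivot + t
                atoms.append(
                    Atom(
                        name=atom.name,
                        element=atom.element,
                        position=pos.copy(),
                        occupancy=atom.occupancy,
                        altloc=atom.altloc,
                        b_factor=atom.b_factor,
                    )
                )
            out.append(
                Residue(
                    chain_id=res.chain_id,
                    number=res.number,
                    insertion_code=res.insertion_code,
                    name=res.name,
                    is_hetero=res.is_hetero,
                    atoms=atoms,
                )
            )
        new_chains[chain_id] = out
    return StructureModel(id=model.id + "_moved", chains=new_chains, title=model.title)


def make_msa(
    n_seqs: int,
    length: int,
    column_truth: dict[int, dict[str, int | float]] | None = None,
    motifs: list[tuple[str, int]] | None = None,
    seed: int = 0,
) -> "MSA":
    """Generate an ungapped alignment with exact per-column composition.

    ``column_truth`` maps 1-based columns to residue → count (integers summing
    to ``n_seqs``; exact empirical counts) or residue → frequency (floats
    summing to 1; counts are the rounded expectation, remainder to the most
    frequent residue). ``motifs`` anchors exact substrings at 1-based
    positions in every sequence. The first record is the reference
    'REF_synthetic'. Deterministic for a given seed.
    """
    from nrampkit.conservation import MSA

    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    consensus = rng.choice(alphabet, size=length)
    rows = np.tile(consensus, (n_seqs, 1))

    for motif, pos in motifs or []:
        if pos < 1 or pos + len(motif) - 1 > length:
            raise ValueError(f"motif {motif!r} at {pos} exceeds length {length}")
        rows[:, pos - 1 : pos - 1 + len(motif)] = list(motif.upper())

    for col, spec_counts in (column_truth or {}).items():
        if not 1 <= col <= length:
            raise ValueError(f"column {col} outside 1..{length}")
        values = list(spec_counts.values())
        if all(float(v).is_integer() for v in values):
            counts = {aa: int(v) for aa, v in spec_counts.items()}
            if sum(counts.values()) != n_seqs:
                raise ValueError(
                    f"column {col}: counts sum to {sum(counts.values())}, need {n_seqs}"
                )
        else:
            if abs(sum(values) - 1.0) > 1e-9:
                raise ValueError(f"column {col}: frequencies must sum to 1")
            counts = {aa: int(round(f * n_seqs)) for aa, f in spec_counts.items()}
            top = max(counts, key=counts.get)  # absorb rounding remainder
            counts[top] += n_seqs - sum(counts.values())
        column = np.array([aa for aa, c in counts.items() for _ in range(c)])
        rng.shuffle(column)
        rows[:, col - 1] = column

    records = [("REF_synthetic", "".join(rows[0]))]
    records += [(f"seq{i:05d}", "".join(rows[i])) for i in range(1, n_seqs)]
    return MSA(records)


def simulate_trace(spec: TraceSpec) -> tuple[FluorescenceTrace, dict[str, np.ndarray]]:
    """Forward-model a two-channel assay trace; returns (trace, ground truth).

    Ground truth carries the noiseless underlying series: 'concentration_uM'
    (metal mode), 'fraction_imported' (quench mode) or 'pH' (proton mode),
    plus 'time'.
    """
    rng = np.random.default_rng(spec.seed)
    time = np.arange(0.0, spec.duration + spec.dt / 2, spec.dt)
    after = np.clip(time - spec.t_add, 0.0, None)
    events = {"substrate": spec.t_add, "ionomycin": spec.t_ionomycin}

    if spec.mode == "metal":
        calib = spec.fura or FuraCalibration(Kd=0.2, Rmin=0.5, Rmax=5.0, beta=2.0)
        v = spec.Vmax * spec.S_uM / (spec.KM + spec.S_uM)
        conc = v * after
        # cap well below dye saturation so the ratio stays invertible
        cap = 0.95 * calib.Kd * calib.beta * (calib.Rmax - calib.Rmin)
        conc = np.minimum(conc, cap)
        ratio = np.asarray(fura2_ratio(conc, calib))
        ch_den = np.full_like(time, 1000.0)
        ch_num = 1000.0 * ratio
        channels = {"ex340": ch_num, "ex380": ch_den}
        truth = {"time": time, "concentration_uM": conc, "rate_uM_per_s": np.array([v])}
    elif spec.mode == "metal_quench":
        ramp = max(spec.t_ionomycin - spec.t_add, spec.dt)
        frac = np.clip(after / ramp, 0.0, 1.0)
        frac = np.where(time >= spec.t_ionomycin, 1.0, frac)
        f = 1000.0 * (1.0 - spec.quench_depth * frac)
        channels = {"ex340": f.copy(), "ex380": f.copy()}
        truth = {"time": time, "fraction_imported": frac}
    else:  # proton
        calib = spec.bcecf or BcecfCalibration(pKa_dye=6.98, Rmin=0.2, Rmax=2.0)
        ph = spec.pH_start + (spec.pH_end - spec.pH_start) * (
            1.0 - np.exp(-after / spec.pH_tau)
        )
        ratio = np.asarray(bcecf_ratio(ph, calib))
        channels = {"ex450": 1000.0 * ratio, "ex490": np.full_like(time, 1000.0)}
        truth = {"time": time, "pH": ph}

    if spec.noise_sigma > 0:
        for name in channels:
            channels[name] = channels[name] * (
                1.0 + rng.normal(0.0, spec.noise_sigma, size=time.shape)
            )
            channels[name] = np.maximum(channels[name], 1e-6)

    return FluorescenceTrace(time=time, channels=channels, events=events), truth
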