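"""Rigid least-squares superposition, per-residue deviations, segment rotation angles.

The superposition is the classic Kabsch solution: the proper rotation
minimising the sum of squared distances between matched coordinate sets, with
no outlier-rejection cycles — every matched pair contributes, which is the
convention used when whole-structure RMSDs between transporter conformations
are reported (large local motions such as a swinging TM1a are part of the
number, not rejected).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from nrampkit.structure_io import CaTrace, ResidueLabel, match_traces


@dataclass
class SuperpositionResult:
    """Rigid transform mapping mobile onto reference, with deviation bookkeeping.

    ``rotation`` is proper (det +1); ``rmsd**2`` equals the mean of the squared
    per-label deviations by construction.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int
    per_label_deviation: dict[ResidueLabel, float] = field(default_factory=dict)

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted rigid transform to an (n, 3) coordinate array."""
        return np.asarray(coords) @ self.rotation.T + self.translation


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t with R @ mobile + t ≈ reference.

    Raises ``ValueError`` for fewer than 3 pairs or a degenerate (collinear)
    configuration where the rotation is not uniquely determined.
    """
    mobile = np.asarray(mobile, dtype=float).reshape(-1, 3)
    reference = np.asarray(reference, dtype=float).reshape(-1, 3)
    if mobile.shape != reference.shape:
        raise ValueError("coordinate sets must have identical shapes")
    n = len(mobile)
    if n < 3:
        raise ValueError(f"need at least 3 matched pairs, got {n}")
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    P = mobile - mob_c
    Q = reference - ref_c
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    # rank-deficient cross-covariance: points collinear in at least one set
    if S[1] <= 1e-10 * max(S[0], 1.0):
        raise ValueError("degenerate configuration: matched points are collinear")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref_c - R @ mob_c
    return R, t


def kabsch_superpose(
    mobile: CaTrace | np.ndarray,
    reference: CaTrace | np.ndarray,
    match: list[tuple[ResidueLabel, ResidueLabel]] | None = None,
) -> SuperpositionResult:
    """Superpose ``mobile`` onto ``reference`` over all matched pairs.

    If both inputs are traces and ``match`` is None, pairs are formed on
    (residue number, insertion code). ``match`` may supply an explicit list of
    (mobile label, reference label) pairs. Bare (n, 3) arrays are matched by
    row index and labelled 1..n.
    """
    if isinstance(mobile, CaTrace) and isinstance(reference, CaTrace):
        if match is not None:
            mob = mobile.subset([m for m, _ in match])
            ref = reference.subset([r for _, r in match])
        else:
            mob, ref = match_traces(mobile, reference)
        labels = mob.labels
        mob_xyz, ref_xyz = mob.positions, ref.positions
    else:
        mob_xyz = np.asarray(mobile, dtype=float).reshape(-1, 3)
        ref_xyz = np.asarray(reference, dtype=float).reshape(-1, 3)
        labels = [("", i + 1, "") for i in range(len(mob_xyz))]

    R, t = kabsch(mob_xyz, ref_xyz)
    moved = mob_xyz @ R.T + t
    dev = np.linalg.norm(moved - ref_xyz, axis=1)
    rmsd = float(np.sqrt(np.mean(dev**2)))
    return SuperpositionResult(
        rotation=R,
        translation=t,
        rmsd=rmsd,
        n_pairs=len(dev),
        per_label_deviation=dict(zip(labels, dev.tolist())),
    )


def per_residue_deviation(result: SuperpositionResult) -> list[tuple[ResidueLabel, float]]:
    """Per-label deviations in Å, in match order (the ColorByRMSD-style profile)."""
    return list(result.per_label_deviation.items())


def deviations_to_tsv(result: SuperpositionResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("chain\tresnum\ticode\tdeviation_A\n")
        for (chain, num, icode), d in result.per_label_deviation.items():
            fh.write(f"{chain}\t{num}\t{icode}\t{d:.3f}\n")


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    """Unit first principal component, oriented along the endpoint direction."""
    centered = coords - coords.mean(axis=0)
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)
    axis = Vt[0]
    endpoint = coords[-1] - coords[0]
    if np.dot(axis, endpoint) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def segment_rotation_angle(
    a: CaTrace,
    b: CaTrace,
    segment: tuple[int, int],
    chain: str | None = None,
) -> float:
    """Angle (degrees) between a segment's principal axes in two structures.

    ``segment`` is a 1-based inclusive author-numbering interval (e.g. TM1a).
    The traces are assumed already expressed in a common frame — typically
    after superposing on all common Cα — so the angle reads as the swing of
    that helix between conformations. The principal axis of each segment's
    centered Cα cloud is oriented N→C by the endpoint direction, and the
    angle is folded into [0°, 90°].
    """
    lo, hi = segment

    def pick(trace: CaTrace) -> np.ndarray:
        rows = [
            i
            for i, (ch, num, _ic) in enumerate(trace.labels)
            if lo <= num <= hi and (chain is None or ch == chain)
        ]
        return trace.positions[rows]

    pa, pb = pick(a), pick(b)
    if len(pa) < 4 or len(pb) < 4:
        raise ValueError(
            f"segment {lo}-{hi}: need ≥4 Cα in both traces (got {len(pa)}, {len(pb)})"
        )
    cosang = float(np.clip(np.dot(_principal_axis(pa), _principal_axis(pb)), -1.0, 1.0))
    angle = float(np.degrees(np.arccos(cosang)))
    return min(angle, 180.0 - angle)
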