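"""Restraint potentials, effective distances, tensor fits and violations.

These are the same functional forms the MD engine applies, evaluated
statically on structures so that converted restraints can be validated
without running a simulation:

* the flat-bottom distance potential with its harmonic wall and linear
  tail beyond the second upper bound,
* the flat-bottom dihedral potential on the circle,
* r^-6 effective distances over the atom pairs of one restraint,
* a least-squares alignment tensor that back-calculates residual dipolar
  couplings from internuclear unit vectors.

Degrees at the interface, radians inside the energy formulas (force
constants are per rad^2); distances in nm throughout.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .restraint_build import (
    ConverterConfig,
    DihedralRestraint,
    DistanceRestraint,
    OrientationRestraint,
    wrap_angle,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

def distance_energy(r: float, restraint: DistanceRestraint, k_dr: float) -> float:
    """Flat-bottom distance restraint energy [kJ mol-1] at distance r [nm].

    Zero between r0 and r1, harmonic below r0 and between r1 and r2,
    linear (constant force) beyond r2; continuous everywhere.
    """
    if r <= 0:
        raise ValueError("distance must be positive")
    r0, r1, r2 = restraint.r0, restraint.r1, restraint.r2
    if r < r0:
        return 0.5 * k_dr * (r - r0) ** 2
    if r < r1:
        return 0.0
    if r < r2:
        return 0.5 * k_dr * (r - r1) ** 2
    return 0.5 * k_dr * (r2 - r1) * (2.0 * r - r2 - r1)


def dihedral_energy(phi: float, restraint: DihedralRestraint, k_dihr: float) -> float:
    """Flat-bottom dihedral energy [kJ mol-1] at angle phi [degrees].

    The deviation phi - phi0 is wrapped into (-180, 180]; the energy is
    zero within +/- dphi of the centre and harmonic in the (radian) excess
    outside, making it invariant under phi -> phi + 360.
    """
    d = abs(wrap_angle(phi - restraint.phi0))
    if d <= restraint.dphi:
        return 0.0
    excess = math.radians(d - restraint.dphi)
    return 0.5 * k_dihr * excess ** 2


def effective_distance(pair_distances: Sequence[float], mode: str = "mean") -> float:
    """r^-6 effective distance [nm] over the pairs of one restraint.

    ``mean``: (<r^-6>)^(-1/6) — the NOE-averaging convention;
    ``sum``:  (sum r^-6)^(-1/6) — the ambiguous-restraint convention,
    always <= the smallest individual distance.
    """
    arr = np.asarray(pair_distances, dtype=float)
    if arr.size == 0:
        raise ValueError("effective_distance needs at least one distance")
    if np.any(arr <= 0):
        raise ValueError("distances must be positive")
    inv6 = arr ** -6.0
    total = inv6.mean() if mode == "mean" else inv6.sum()
    if mode not in ("mean", "sum"):
        raise ValueError(f"unknown averaging mode {mode!r}")
    return float(total ** (-1.0 / 6.0))


# ---------------------------------------------------------------------------
# alignment tensor
# ---------------------------------------------------------------------------

@dataclass
class AlignmentTensor:
    """Symmetric traceless 3x3 alignment tensor, stored as 5 components."""

    s_xx: float
    s_yy: float
    s_xy: float
    s_xz: float
    s_yz: float
    underdetermined: bool = False

    @property
    def matrix(self) -> np.ndarray:
        return np.array([
            [self.s_xx, self.s_xy, self.s_xz],
            [self.s_xy, self.s_yy, self.s_yz],
            [self.s_xz, self.s_yz, -self.s_xx - self.s_yy],
        ])

    def back_calculate(self, unit_vector: np.ndarray, const: float) -> float:
        """Coupling [Hz] predicted for one internuclear unit vector."""
        v = np.asarray(unit_vector, dtype=float)
        return float(const * v @ self.matrix @ v)


def _design_row(v: np.ndarray, const: float) -> np.ndarray:
    x, y, z = v
    # const * v^T A v with A = [[a,c,d],[c,b,e],[d,e,-a-b]]
    return const * np.array([x * x - z * z, y * y - z * z,
                             2 * x * y, 2 * x * z, 2 * y * z])


def _unit_vectors(structure, restraints: Sequence[OrientationRestraint]) -> np.ndarray:
    vecs = []
    for r in restraints:
        i, j = r.atoms
        d = np.asarray(structure[j]) - np.asarray(structure[i])
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValueError(f"coincident atoms in orientation restraint {r.label}")
        vecs.append(d / norm)
    return np.array(vecs)


def fit_alignment_tensor(structure, restraints: Sequence[OrientationRestraint]
                         ) -> AlignmentTensor:
    """Least-squares alignment tensor from observed couplings.

    ``structure`` maps 1-based atom indices to coordinates (nm).  With
    fewer than five independent observations the system is flagged
    underdetermined and the minimum-norm solution is returned.
    """
    restraints = list(restraints)
    if not restraints:
        raise ValueError("no orientation restraints to fit")
    vecs = _unit_vectors(structure, restraints)
    design = np.array([_design_row(v, r.const) for v, r in zip(vecs, restraints)])
    obs = np.array([r.observed if hasattr(r, "observed") else r.obs
                    for r in restraints])
    sol, _, rank, _ = np.linalg.lstsq(design, obs, rcond=None)
    underdetermined = rank < 5
    if underdetermined:
        logger.warning("alignment tensor fit underdetermined (rank %d < 5); "
                       "minimum-norm solution returned", rank)
    return AlignmentTensor(*sol, underdetermined=underdetermined)


def back_calculate_all(structure, restraints: Sequence[OrientationRestraint],
                       tensor: AlignmentTensor) -> np.ndarray:
    vecs = _unit_vectors(structure, restraints)
    return np.array([tensor.back_calculate(v, r.const)
                     for v, r in zip(vecs, restraints)])


# ---------------------------------------------------------------------------
# violations
# ---------------------------------------------------------------------------

@dataclass
class ViolationReport:
    """Per-restraint violations and energies, plus per-class means.

    Distance violations are in nm, dihedral in degrees, orientation in Hz;
    energies in kJ mol-1.  A class with no evaluated restraints has mean
    ``nan``.
    """

    distance: dict[int, float] = field(default_factory=dict)
    dihedral: dict[int, float] = field(default_factory=dict)
    orientation: dict[tuple[int, int], float] = field(default_factory=dict)
    distance_energy: dict[int, float] = field(default_factory=dict)
    dihedral_energy: dict[int, float] = field(default_factory=dict)
    orientation_energy: dict[tuple[int, int], float] = field(default_factory=dict)
    excluded: dict[str, int] = field(default_factory=lambda: {
        "distance": 0, "dihedral": 0, "orientation": 0})

    def _mean(self, d: dict) -> float:
        return float(np.mean(list(d.values()))) if d else float("nan")

    @property
    def mean_distance(self) -> float:
        return self._mean(self.distance)

    @property
    def mean_dihedral(self) -> float:
        return self._mean(self.dihedral)

    @property
    def mean_orientation(self) -> float:
        return self._mean(self.orientation)


def _pair_distance(structure, i: int, j: int) -> float:
    return float(np.linalg.norm(np.asarray(structure[j]) - np.asarray(structure[i])))


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Torsion angle in degrees for four points (IUPAC sign convention)."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1 /= np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    return math.degrees(math.atan2(y, x))


def violations(structure,
               distances: Iterable[DistanceRestraint] = (),
               dihedrals: Iterable[DihedralRestraint] = (),
               orientations: Iterable[OrientationRestraint] = (),
               config: Optional[ConverterConfig] = None) -> ViolationReport:
    """Evaluate all restraints on one structure.

    ``structure`` maps 1-based global atom indices to coordinates in nm.
    Distance violations are computed on the r^-6 effective distance of each
    restraint's pairs; orientation violations are deviations from the
    couplings back-calculated after a per-experiment tensor fit.
    Restraints whose atoms are absent from the structure are excluded and
    counted.
    """
    config = config or ConverterConfig()
    report = ViolationReport()

    for r in distances:
        try:
            ds = [_pair_distance(structure, i, j) for i, j in r.pairs]
        except (KeyError, IndexError):
            report.excluded["distance"] += 1
            continue
        r_eff = effective_distance(ds, mode=config.averaging)
        viol = max(0.0, r_eff - r.r1, r.r0 - r_eff)
        key = r.source_id if r.source_id is not None else r.label
        report.distance[key] = viol
        report.distance_energy[key] = distance_energy(r_eff, r, config.k_dr)

    for n, r in enumerate(dihedrals):
        try:
            pts = [structure[i] for i in r.atoms]
        except (KeyError, IndexError):
            report.excluded["dihedral"] += 1
            continue
        phi = dihedral_angle(*pts)
        viol = max(0.0, abs(wrap_angle(phi - r.phi0)) - r.dphi)
        key = r.source_id if r.source_id is not None else n
        report.dihedral[key] = viol
        report.dihedral_energy[key] = dihedral_energy(phi, r, config.k_dihr)

    by_experiment: dict[int, list[OrientationRestraint]] = {}
    for r in orientations:
        try:
            for i in r.atoms:
                structure[i]
        except (KeyError, IndexError):
            report.excluded["orientation"] += 1
            continue
        by_experiment.setdefault(r.experiment, []).append(r)
    for exp, group in sorted(by_experiment.items()):
        tensor = fit_alignment_tensor(structure, group)
        calc = back_calculate_all(structure, group, tensor)
        for r, c in zip(group, calc):
            dev = abs(c - r.obs)
            report.orientation[(exp, r.label)] = dev
            report.orientation_energy[(exp, r.label)] = (
                0.5 * config.k_or * r.weight * (c - r.obs) ** 2)
    return report
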