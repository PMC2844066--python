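"""Geometric assembly of microtubule protofilaments and the 13-pf lattice.

A protofilament is a head-to-tail stack of αβ-tubulin dimers repeated
along the microtubule (+z) axis with an 79.4 Å rise per dimer. Thirteen
protofilaments form the closed wall: protofilament k sits at radius
R = s / (2·sin(π/n)) (chord formula, s = 53 Å lateral spacing), azimuth
k·360/n, with the 3-start helical stagger k·3·rise/(2·n) ≈ 9.16 Å that
creates the B-lattice seam.

The literal transform series reported for the source model
(per-protofilament axial rotation 14°, angular shift 10° at 53 Å) does
not close a 13-fold ring (13·10° ≠ 360°); it is available as the
``paper_literal`` mode, which builds the corresponding open arc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

CHAIN_LABELS = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


class StructureFormatError(ValueError):
    pass


class LatticeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Rigid transforms


@dataclass(frozen=True)
class RigidTransform:
    """x ↦ R·x + t with R a proper rotation."""

    rotation: np.ndarray
    translation: np.ndarray

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def translate(x: float, y: float, z: float) -> "RigidTransform":
        return RigidTransform(np.eye(3), np.array([x, y, z], dtype=float))

    @staticmethod
    def rotate_z(degrees: float) -> "RigidTransform":
        a = math.radians(degrees)
        c, s = math.cos(a), math.sin(a)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        return RigidTransform(rot, np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        return RigidTransform(rot_inv, -rot_inv @ self.translation)


# ---------------------------------------------------------------------------
# Dimer model and PDB I/O


@dataclass
class DimerModel:
    """An αβ-tubulin dimer: one :class:`biotite` atom array plus chain roles."""

    atoms: struc.AtomArray
    alpha_chain: str
    beta_chain: str

    def __post_init__(self) -> None:
        for role, chain in (("alpha", self.alpha_chain), ("beta", self.beta_chain)):
            if not np.any(self.atoms.chain_id == chain):
                raise StructureFormatError(f"{role} chain {chain!r} is empty/missing")
        if self.alpha_chain == self.beta_chain:
            raise StructureFormatError("alpha and beta chains must differ")

    @property
    def n_atoms(self) -> int:
        return self.atoms.array_length()

    def chain_coords(self, role: str) -> np.ndarray:
        chain = self.alpha_chain if role == "alpha" else self.beta_chain
        return self.atoms.coord[self.atoms.chain_id == chain]

    def centroid(self) -> np.ndarray:
        return self.atoms.coord.mean(axis=0)

    def monomer_centroids(self) -> tuple[np.ndarray, np.ndarray]:
        return (self.chain_coords("alpha").mean(axis=0),
                self.chain_coords("beta").mean(axis=0))

    def residue_range(self, role: str) -> tuple[int, int]:
        chain = self.alpha_chain if role == "alpha" else self.beta_chain
        res = self.atoms.res_id[self.atoms.chain_id == chain]
        return int(res.min()), int(res.max())


def read_structure(
    path, chain_map: "dict[str, str] | None" = None
) -> DimerModel:
    """Read a PDB dimer; assign chains to α/β roles.

    ``chain_map`` maps roles to chain ids, e.g. ``{"alpha": "A", "beta":
    "B"}``; when omitted the first two chains in file order are taken as α
    and β. A single-chain file without a mapping is an error.
    """
    try:
        pdb = PDBFile.read(path)
        atoms = pdb.get_structure(model=1)
    except Exception as exc:
        line_no = _find_bad_line(path)
        where = f" (line {line_no})" if line_no else ""
        raise StructureFormatError(f"cannot parse PDB {path}{where}: {exc}") from exc
    chains = list(dict.fromkeys(atoms.chain_id))
    if chain_map is None:
        if len(chains) < 2:
            raise StructureFormatError(
                f"{path}: found {len(chains)} chain(s); a two-chain dimer or an "
                "explicit chain mapping is required"
            )
        chain_map = {"alpha": chains[0], "beta": chains[1]}
    for role in ("alpha", "beta"):
        if chain_map.get(role) not in chains:
            raise StructureFormatError(
                f"{path}: mapped {role} chain {chain_map.get(role)!r} not present "
                f"(chains: {chains})"
            )
    return DimerModel(atoms, chain_map["alpha"], chain_map["beta"])


def _find_bad_line(path) -> int | None:
    try:
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                if line.startswith(("ATOM", "HETATM")):
                    try:
                        float(line[30:38]); float(line[38:46]); float(line[46:54])
                    except ValueError:
                        return i
    except OSError:
        return None
    return None


def write_dimer(dimer: DimerModel, path) -> None:
    pdb = PDBFile()
    pdb.set_structure(dimer.atoms)
    pdb.write(path)


# ---------------------------------------------------------------------------
# Orientation


def orient_dimer(dimer: DimerModel) -> tuple[DimerModel, RigidTransform]:
    """Center the dimer and align the α→β monomer axis with +z.

    β toward the plus end, matching the standard microtubule polarity
    convention. The rotation is the minimal one (axis = v × z), hence
    deterministic and reflection-free; an already-oriented dimer gets the
    identity transform.
    """
    ca, cb = dimer.monomer_centroids()
    v = cb - ca
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise LatticeError("monomer centroids coincide; cannot orient dimer")
    v = v / norm
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(v, z)
    s = np.linalg.norm(axis)
    c = float(np.dot(v, z))
    if s < 1e-12:
        rot = np.eye(3) if c > 0 else _rotation_about(np.array([1.0, 0, 0]), math.pi)
    else:
        rot = _rotation_about(axis / s, math.atan2(s, c))
    centroid = dimer.atoms.coord.mean(axis=0)
    transform = RigidTransform(rot, -rot @ centroid)
    atoms = dimer.atoms.copy()
    atoms.coord = transform.apply(dimer.atoms.coord)
    return DimerModel(atoms, dimer.alpha_chain, dimer.beta_chain), transform


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    x, y, z = axis
    c, s = math.cos(angle), math.sin(angle)
    t = 1 - c
    return np.array([
        [t * x * x + c, t * x * y - s * z, t * x * z + s * y],
        [t * x * y + s * z, t * y * y + c, t * y * z - s * x],
        [t * x * z - s * y, t * y * z + s * x, t * z * z + c],
    ])


# ---------------------------------------------------------------------------
# Lattice parameters and model


@dataclass(frozen=True)
class LatticeParameters:
    """Helical-lattice geometry.

    dimer_rise and lateral_spacing are in Å; per_pf_twist (degrees about
    the microtubule axis) defaults to 360/n for a closed ring and
    per_pf_stagger (Å) to the 3-start rule 3·rise/(2·n). pf_axial_rotation
    (14°) and pf_shift_angle (10°) are only used in ``paper_literal``
    mode, which reproduces the literal open-arc transform series.
    """

    n_protofilaments: int = 13
    dimer_rise: float = 79.4
    lateral_spacing: float = 53.0
    dimers_per_protofilament: int = 3
    per_pf_twist: float | None = None
    per_pf_stagger: float | None = None
    pf_axial_rotation: float = 14.0
    pf_shift_angle: float = 10.0
    paper_literal: bool = False

    def __post_init__(self) -> None:
        if self.n_protofilaments < 1:
            raise LatticeError("n_protofilaments must be >= 1")
        if self.dimer_rise <= 0 or self.lateral_spacing <= 0:
            raise LatticeError("dimer_rise and lateral_spacing must be > 0")
        if self.dimers_per_protofilament < 1:
            raise LatticeError("dimers_per_protofilament must be >= 1")

    @property
    def twist(self) -> float:
        if self.paper_literal:
            return self.pf_shift_angle
        if self.per_pf_twist is not None:
            return self.per_pf_twist
        return 360.0 / self.n_protofilaments

    @property
    def stagger(self) -> float:
        if self.per_pf_stagger is not None:
            return self.per_pf_stagger
        return 3.0 * self.dimer_rise / (2.0 * self.n_protofilaments)

    @property
    def radius(self) -> float:
        """Protofilament-axis radius from the chord formula.

        A single protofilament has no chord to speak of; it is placed at
        half the lateral spacing by convention.
        """
        if self.n_protofilaments == 1 and not self.paper_literal:
            return self.lateral_spacing / 2.0
        half = math.radians(self.twist) / 2.0
        if abs(math.sin(half)) < 1e-12:
            raise LatticeError("twist angle too small to derive a radius")
        return self.lateral_spacing / (2.0 * math.sin(half))


@dataclass(frozen=True)
class PlacedCopy:
    protofilament: int
    dimer: int
    transform: RigidTransform


@dataclass
class LatticeModel:
    """Placed copies of one oriented dimer; the microtubule axis is +z."""

    dimer: DimerModel
    copies: list[PlacedCopy]
    params: LatticeParameters | None = None

    @property
    def n_copies(self) -> int:
        return len(self.copies)

    def copy_coords(self, copy: PlacedCopy) -> np.ndarray:
        return copy.transform.apply(self.dimer.atoms.coord)

    def realize(self) -> struc.AtomArray:
        """Concatenate all copies into one atom array.

        Adds ``copy_pf`` and ``copy_dimer`` annotations so downstream
        exposure analysis can address individual copies.
        """
        n = self.dimer.n_atoms
        arrays = []
        pf_ann, dimer_ann = [], []
        for copy in self.copies:
            atoms = self.dimer.atoms.copy()
            atoms.coord = self.copy_coords(copy)
            arrays.append(atoms)
            pf_ann.append(np.full(n, copy.protofilament, dtype=int))
            dimer_ann.append(np.full(n, copy.dimer, dtype=int))
        merged = struc.concatenate(arrays)
        merged.set_annotation("copy_pf", np.concatenate(pf_ann))
        merged.set_annotation("copy_dimer", np.concatenate(dimer_ann))
        return merged


def build_protofilament(
    dimer: DimerModel, n_dimers: int = 3, dimer_rise: float = 79.4
) -> LatticeModel:
    """Stack ``n_dimers`` copies along +z at multiples of the dimer rise."""
    if n_dimers < 1:
        raise LatticeError("n_dimers must be >= 1")
    copies = [
        PlacedCopy(0, i, RigidTransform.translate(0.0, 0.0, i * dimer_rise))
        for i in range(n_dimers)
    ]
    return LatticeModel(dimer, copies)


def build_lattice(
    protofilament: LatticeModel, params: LatticeParameters
) -> LatticeModel:
    """Replicate a protofilament into the n-fold wall (or paper-literal arc).

    Protofilament k is spun about its own axis by k·pf_axial_rotation
    (paper-literal mode only), shifted to radius R, raised by k·stagger
    and rotated to azimuth k·twist. All transforms are recorded so every
    copy can be superposed back onto the input dimer exactly.
    """
    pfs = {c.protofilament for c in protofilament.copies}
    if pfs != {0}:
        raise LatticeError("input must be a single protofilament (index 0)")
    radius = params.radius
    copies: list[PlacedCopy] = []
    for k in range(params.n_protofilaments):
        spin = (
            RigidTransform.rotate_z(k * params.pf_axial_rotation)
            if params.paper_literal
            else RigidTransform.identity()
        )
        placement = (
            RigidTransform.rotate_z(k * params.twist)
            .compose(RigidTransform.translate(radius, 0.0, k * params.stagger))
            .compose(spin)
        )
        for copy in protofilament.copies:
            copies.append(
                PlacedCopy(k, copy.dimer, placement.compose(copy.transform))
            )
    return LatticeModel(protofilament.dimer, copies, params)


# ---------------------------------------------------------------------------
# PDB output


def write_structure(
    lattice: LatticeModel, path, max_chains_per_model: int = len(CHAIN_LABELS)
) -> "list[tuple[int, int, str, str]]":
    """Write the assembly as PDB, cycling chain labels per copy-chain.

    Each placed copy contributes its two chains; chain labels cycle
    through A-Z, a-z, 0-9. When more chain instances than labels are
    needed the assembly is split across MODEL records. Returns the
    (protofilament, dimer, original chain, assigned label) mapping.
    """
    if not lattice.copies:
        raise LatticeError("empty lattice")
    chain_order = [lattice.dimer.alpha_chain, lattice.dimer.beta_chain]
    mapping: list[tuple[int, int, str, str]] = []
    model_chunks: list[list[struc.AtomArray]] = [[]]
    label_i = 0
    for copy in lattice.copies:
        atoms = lattice.dimer.atoms.copy()
        atoms.coord = lattice.copy_coords(copy)
        if label_i + len(chain_order) > max_chains_per_model:
            model_chunks.append([])
            label_i = 0
        new_chain = np.empty(atoms.array_length(), dtype="U4")
        for orig in chain_order:
            label = CHAIN_LABELS[label_i % len(CHAIN_LABELS)]
            label_i += 1
            new_chain[atoms.chain_id == orig] = label
            mapping.append((copy.protofilament, copy.dimer, orig, label))
        atoms.chain_id = new_chain
        model_chunks[-1].append(atoms)

    if len(model_chunks) == 1:
        pdb = PDBFile()
        pdb.set_structure(struc.concatenate(model_chunks[0]))
        pdb.write(path)
    else:
        with open(path, "w") as fh:
            for m, chunk in enumerate(model_chunks, 1):
                pdb = PDBFile()
                pdb.set_structure(struc.concatenate(chunk))
                fh.write(f"MODEL     {m:>4}\n")
                fh.write("\n".join(
                    ln for ln in pdb.lines if ln.strip() and ln != "END"
                ))
                fh.write("\nENDMDL\n")
            fh.write("END\n")
    return mapping


def copy_centroid_radius(lattice: LatticeModel, copy: PlacedCopy) -> float:
    xy = lattice.copy_coords(copy).mean(axis=0)[:2]
    return float(np.linalg.norm(xy))


def outer_diameter(lattice: LatticeModel) -> float:
    """Maximal radial atom extent × 2, in Å."""
    best = 0.0
    for copy in lattice.copies:
        coords = lattice.copy_coords(copy)
        best = max(best, float(np.linalg.norm(coords[:, :2], axis=1).max()))
    return 2.0 * best
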