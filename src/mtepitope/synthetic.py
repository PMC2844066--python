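"""Synthetic fixtures with planted ground truth.

Every generator is a pure function of its seed, producing the inputs the
analysis modules consume in controlled form: isotype-like sequence
families with known consensus, sequences with Asp-Pro sites planted at
chosen bonds, SPOT reactivity patterns with planted epitopes and
configurable spot noise, and coarse-grained dimers (one 3 Å pseudo-atom
per residue on two stacked spheroids) whose residues can be planted on
the inward- or outward-facing side so their radial class after lattice
assembly is known by construction.

The coarse dimer emulates only the geometry the lattice and exposure
code paths need — realistic tubulin folds, side chains and atomic
packing are deliberately absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import biotite.structure as struc

from .lattice import DimerModel
from .scan import ScanDesign, SpotReactivity
from .sequences import AMINO_ACIDS, MultipleAlignment, ProteinSequence, SequenceRegion

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}

#: Tubulin-like monomer half-dimensions (Å): a monomer is roughly a
#: 46 × 40 × 65 Å globule.
TUBULIN_MONOMER_SEMIAXES = (23.0, 20.0, 32.5)


class GenerationError(ValueError):
    pass


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


# ---------------------------------------------------------------------------
# Sequence families


def make_isotype_family(
    base: ProteinSequence,
    n: int = 9,
    substitution_rate: float = 0.1,
    seed: int = 0,
    indel_rate: float = 0.0,
) -> MultipleAlignment:
    """n variants of ``base`` with i.i.d. substitutions, trivially aligned.

    With ``indel_rate`` > 0 each row additionally loses individual
    residues (rendered as gap characters) at that per-site rate; default
    is the gapless family whose consensus is the base by construction at
    rate 0.
    """
    if n < 2:
        raise GenerationError("need n >= 2 family members")
    if not 0 <= substitution_rate < 0.5:
        raise GenerationError("substitution rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    aa = list(AMINO_ACIDS)
    rows = []
    for k in range(1, n + 1):
        chars = []
        for c in base.residues:
            if rng.random() < substitution_rate:
                choices = [x for x in aa if x != c]
                c = choices[rng.integers(len(choices))]
            if indel_rate > 0 and rng.random() < indel_rate:
                c = "-"
            chars.append(c)
        rows.append((f"{base.id}_iso{k}", "".join(chars)))
    return MultipleAlignment(rows=rows)


# ---------------------------------------------------------------------------
# Cleavage-site sequences


def make_cleavage_sequence(
    length: int, sites: "list[int]", seed: int = 0, seq_id: str = "synthetic"
) -> ProteinSequence:
    """Random sequence with DP planted exactly at each ``site`` bond.

    A site p forces residue p = D and p+1 = P; everywhere else the DP
    dipeptide is excluded, so motif scanning recovers exactly ``sites``.
    """
    sites = sorted(sites)
    if sites and (sites[0] < 1 or sites[-1] >= length):
        raise GenerationError("site outside sequence")
    for a, b in zip(sites, sites[1:]):
        if b - a < 2:
            raise GenerationError(f"sites {a} and {b} too close to pack")
    rng = np.random.default_rng(seed)
    forced = {}
    for p in sites:
        forced[p - 1] = "D"
        forced[p] = "P"
    chars: list[str] = []
    aa = list(AMINO_ACIDS)
    for i in range(length):
        if i in forced:
            chars.append(forced[i])
            continue
        while True:
            c = aa[rng.integers(len(aa))]
            if chars and chars[-1] == "D" and c == "P" and (i - 1) not in forced:
                continue  # would create an unplanned DP
            if forced.get(i + 1) == "P" and c == "D":
                continue
            if forced.get(i - 1) == "D" and c == "P":
                continue
            chars.append(c)
            break
    return ProteinSequence(seq_id, "".join(chars))


# ---------------------------------------------------------------------------
# Scan reactivity


def simulate_scan_reactivity(
    scan: ScanDesign,
    epitope: SequenceRegion,
    false_positive: float = 0.0,
    false_negative: float = 0.0,
    seed: int = 0,
    threshold: float = 1.0,
) -> SpotReactivity:
    """Spot intensities for a planted linear epitope.

    A spot is truly positive iff its peptide span contains the whole
    epitope; truth is then flipped with the configured false-positive /
    false-negative probabilities. Positive spots draw intensities in
    (1.5, 3.0), negative in (0, 0.5), around the threshold 1.0.
    """
    if len(epitope) > scan.peptide_length:
        raise GenerationError("epitope longer than the scan peptides")
    rng = np.random.default_rng(seed)
    intensities: dict[int, float] = {}
    for i, span in enumerate(scan.peptides, 1):
        positive = span.contains(epitope)
        if positive and rng.random() < false_negative:
            positive = False
        elif not positive and rng.random() < false_positive:
            positive = True
        if positive:
            intensities[i] = 1.5 + 1.5 * rng.random()
        else:
            intensities[i] = 0.5 * rng.random()
    return SpotReactivity(intensities, threshold)


# ---------------------------------------------------------------------------
# Coarse-grained dimers


@dataclass
class CoarseDimerTruth:
    """Ground-truth planted classes, keyed (chain role, residue number)."""

    classes: "dict[tuple[str, int], str]"


def _ellipsoid_point(direction: np.ndarray, semiaxes: tuple) -> np.ndarray:
    sx, sy, sz = semiaxes
    d = direction / np.linalg.norm(direction)
    scale = 1.0 / math.sqrt((d[0] / sx) ** 2 + (d[1] / sy) ** 2 + (d[2] / sz) ** 2)
    return d * scale


def _cap_directions(pole: float, count: int) -> np.ndarray:
    """Deterministic spread of ``count`` directions within ~25° of ±x."""
    out = []
    for j in range(count):
        theta = 0.0 if count == 1 else -0.45 + 0.9 * j / (count - 1)
        phi = 0.3 * math.sin(3.1 * j)  # slight out-of-plane fan
        d = np.array([
            pole * math.cos(theta) * math.cos(phi),
            math.sin(phi),
            math.sin(theta),
        ])
        out.append(d / np.linalg.norm(d))
    return np.array(out)


def make_coarse_dimer(
    residues_per_monomer: int = 100,
    monomer_semiaxes: tuple = TUBULIN_MONOMER_SEMIAXES,
    planted: "dict[tuple[str, int], str] | None" = None,
    seed: int = 0,
    dimer_rise: float = 79.4,
    alpha_seq: ProteinSequence | None = None,
    beta_seq: ProteinSequence | None = None,
) -> tuple[DimerModel, CoarseDimerTruth]:
    """Coarse dimer: one pseudo-atom (element X, 3 Å) per residue.

    α and β monomers are spheroids stacked along z (α below, β above,
    centers half a dimer rise apart, matching the head-to-tail repeat).
    ``planted`` maps (role, residue number) to "outer"/"lumen": those
    residues sit on the ∓x-facing cap so that after default lattice
    assembly (the local +x axis points radially outward) their radial
    class is forced; remaining residues spread over the rest of the
    spheroid surface. Residue names follow the paired sequences when
    given, else a seeded random sequence. Same seed, same coordinates.
    """
    n = residues_per_monomer
    if n < 10:
        raise GenerationError("need at least 10 residues per monomer")
    planted = dict(planted or {})
    for (role, rid), klass in planted.items():
        if role not in ("alpha", "beta") or not 1 <= rid <= n:
            raise GenerationError(f"planted residue ({role}, {rid}) out of range")
        if klass not in ("outer", "lumen"):
            raise GenerationError(f"planted class {klass!r} not outer/lumen")
    rng = np.random.default_rng(seed)
    seqs = {
        "alpha": alpha_seq.residues if alpha_seq else random_sequence(n, rng),
        "beta": beta_seq.residues if beta_seq else random_sequence(n, rng),
    }
    for role, s in seqs.items():
        if len(s) < n:
            raise GenerationError(f"{role} sequence shorter than {n} residues")

    # generic surface directions, keeping the ±x caps free for plants
    from .exposure import sphere_points

    generic = [d for d in sphere_points(4 * n) if abs(d[0]) < 0.82]
    centers = {"alpha": np.array([0.0, 0.0, -dimer_rise / 4.0]),
               "beta": np.array([0.0, 0.0, +dimer_rise / 4.0])}
    chain_ids = {"alpha": "A", "beta": "B"}

    coords, chains, res_ids, res_names = [], [], [], []
    for role in ("alpha", "beta"):
        plants = {rid: k for (r, rid), k in planted.items() if r == role}
        outer_ids = sorted(rid for rid, k in plants.items() if k == "outer")
        lumen_ids = sorted(rid for rid, k in plants.items() if k == "lumen")
        caps = {}
        for rid, d in zip(outer_ids, _cap_directions(+1.0, len(outer_ids))):
            caps[rid] = d
        for rid, d in zip(lumen_ids, _cap_directions(-1.0, len(lumen_ids))):
            caps[rid] = d
        free = [d for d in generic]
        rng_local = np.random.default_rng(seed + (1 if role == "beta" else 0))
        order = rng_local.permutation(len(free))
        free_iter = iter(order)
        for rid in range(1, n + 1):
            d = caps.get(rid)
            if d is None:
                d = free[next(free_iter)]
            p = centers[role] + _ellipsoid_point(np.asarray(d, float),
                                                monomer_semiaxes)
            coords.append(p)
            chains.append(chain_ids[role])
            res_ids.append(rid)
            res_names.append(ONE_TO_THREE[seqs[role][rid - 1]])

    atoms = struc.AtomArray(2 * n)
    atoms.coord = np.array(coords)
    atoms.chain_id = np.array(chains)
    atoms.res_id = np.array(res_ids)
    atoms.res_name = np.array(res_names)
    atoms.atom_name = np.full(2 * n, "CA")
    atoms.element = np.full(2 * n, "X")
    atoms.hetero = np.zeros(2 * n, dtype=bool)
    dimer = DimerModel(atoms, alpha_chain="A", beta_chain="B")
    return dimer, CoarseDimerTruth(planted)
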