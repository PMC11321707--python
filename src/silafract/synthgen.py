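"""Synthetic data generator for peptide/counterion self-assembly analysis.

Every data stream the analysis consumes can be generated here with known
ground truth: coarse-grained trimer building blocks (one bead per residue,
counterion beads bridging the chains), larger assemblies of controlled
morphology (linear / planar / compact / diffusion-limited), HSQC-like peak
tables with shift perturbations and assembly-dependent intensity
attenuation, Stejskal-Tanner DOSY decays, two-rate silicification kinetic
traces with a residual dissolved plateau, and density-matched crowded-box
parameters.

All outputs are bit-reproducible for a fixed seed; per-stream seeds are
derived from one master seed and recorded in a :class:`GroundTruthManifest`.

Units: lengths in Å internally (nm where stated), masses in Da, times in s,
gradients in T/m, diffusion in m²/s.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.SeqUtils import molecular_weight
from scipy.spatial.transform import Rotation

from .structio import AssemblyFrame, COUNTERION_BEAD, PEPTIDE_BEAD
from .nmrcalc import DosySeries, KineticTraces, PeakTable, GAMMA_1H

__all__ = [
    "PeptideSpec",
    "BuildingBlock",
    "MorphologySpec",
    "GroundTruthManifest",
    "R5",
    "peptide_mass",
    "generate_building_block",
    "aggregate_assembly",
    "reference_peak_table",
    "synth_peak_tables",
    "synth_dosy_series",
    "synth_kinetic_traces",
    "build_crowded_box",
    "chain_label",
    "PlacementError",
]

WATER_MASS = 18.0153  # Da, added once per peptide
ATOMIC_MASS_UNIT_G = 1.66054e-24  # g per Da

_AA_CODES = set("ACDEFGHIKLMNPQRSTVWY")

# counterion bead masses (Da): inorganic phosphate, and a long-chain
# polyamine modelled as a single bead of a typical ~C15N5 polyamine
COUNTERION_MASS = {"phosphate": 94.97, "LCPA": 285.0}
COUNTERION_RESNAME = {"phosphate": "PO4", "LCPA": "LCP"}


class PlacementError(RuntimeError):
    """Geometry placement failed after bounded retries."""


@dataclass(frozen=True)
class PeptideSpec:
    """A peptide chain at one-bead-per-residue resolution.

    ``surface_residues`` flags the residues sitting at the assembly surface
    (for R5: the C-terminal RRIL motif, positions 16-19), which attenuate
    faster in silicification assays.
    """

    name: str
    sequence: str
    bead_radius: float = 3.0  # Å
    surface_residues: frozenset[int] = frozenset({16, 17, 18, 19})

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = set(self.sequence) - _AA_CODES
        if bad:
            raise ValueError(f"unknown residue code(s) {sorted(bad)} in sequence")
        if self.bead_radius <= 0:
            raise ValueError("bead_radius must be positive")
        n = len(self.sequence)
        if not set(self.surface_residues) <= set(range(1, n + 1)):
            raise ValueError("surface_residues outside 1..len(sequence)")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def per_residue_mass(self) -> np.ndarray:
        """Average residue masses (Da); one water is NOT included here."""
        return np.asarray(
            [molecular_weight(a, seq_type="protein") - WATER_MASS for a in self.sequence]
        )


# the study's unmodified silaffin-derived 19-mer
R5 = PeptideSpec(name="R5", sequence="SSKKSGSYSGSKGSKRRIL")


@dataclass(frozen=True)
class BuildingBlock:
    """A rigid cluster of ``n_copies`` peptide chains bridged by counterions.

    ``linker_sites`` are (residue_i, residue_j) pairs; one counterion bead
    bridges residue_i of each chain to residue_j of the cyclically next
    chain (Arg-Pi-Arg-type bridges for R5).
    """

    peptide: PeptideSpec = R5
    n_copies: int = 3
    linker_sites: tuple[tuple[int, int], ...] = ((16, 17),)
    counterion: str = "phosphate"
    counterion_radius: float = 2.0  # Å

    def __post_init__(self) -> None:
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")
        n = self.peptide.n_residues
        for a, b in self.linker_sites:
            if not (1 <= a <= n and 1 <= b <= n):
                raise ValueError(f"linker site ({a},{b}) outside residue range 1..{n}")
        if self.counterion not in COUNTERION_MASS:
            raise ValueError(f"unknown counterion {self.counterion!r}")


@dataclass(frozen=True)
class MorphologySpec:
    """Controlled assembly morphology; the generator's dimensionality knob.

    ``mode``: linear (1D), planar (2D), compact (3D) or dla
    (diffusion-limited random attachment).  ``target_valency`` is the aimed
    mean number of peptide-peptide contact partners per monomer.
    """

    mode: str = "compact"
    n_blocks: int = 25
    target_valency: float = 3.0
    contact_gap: float = 3.0  # Å, surface-surface gap of attached blocks
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("linear", "planar", "compact", "dla"):
            raise ValueError(f"unknown morphology mode {self.mode!r}")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.target_valency < 0:
            raise ValueError("target_valency must be >= 0")

    @property
    def true_dimensionality(self) -> float:
        return {"linear": 1.0, "planar": 2.0, "compact": 3.0, "dla": 2.5}[self.mode]


# ---------------------------------------------------------------------------
# masses
# ---------------------------------------------------------------------------

def peptide_mass(spec: PeptideSpec | str) -> float:
    """Average molecular weight of a peptide in Da (residues + one water)."""
    seq = spec.sequence if isinstance(spec, PeptideSpec) else spec
    if not seq:
        raise ValueError("sequence must be non-empty")
    bad = set(seq) - _AA_CODES
    if bad:
        raise ValueError(f"unknown residue code(s) {sorted(bad)}")
    return float(molecular_weight(seq, seq_type="protein"))


# ---------------------------------------------------------------------------
# chain labels
# ---------------------------------------------------------------------------

_ALPHA = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def chain_label(index: int) -> str:
    """A, B, ..., Z, then two-character AA, AB, ... (702 labels)."""
    if index < 26:
        return _ALPHA[index]
    index -= 26
    if index < 26 * 26:
        return _ALPHA[index // 26] + _ALPHA[index % 26]
    raise ValueError("more than 702 chains not supported by the PDB dialect")


# ---------------------------------------------------------------------------
# building-block geometry
# ---------------------------------------------------------------------------

_BOND_LENGTH = 3.8  # Å, consecutive-bead spacing (Cα-Cα scale)
_OVERLAP_FACTOR = 0.8  # no two non-bonded beads closer than 0.8 x (r_i + r_j)
_CHAIN_CONFINE_R = 6.0  # Å, confinement radius of one collapsed chain


def _grow_chain(
    rng: np.random.Generator,
    center: np.ndarray,
    n_res: int,
    bead_radius: float,
    other_beads: np.ndarray | None,
    other_radius_sum: float,
    max_restarts: int = 150,
) -> np.ndarray:
    """Grow one collapsed chain as a confined self-avoiding random walk.

    Restarts relax the confinement radius by 5% each time, so crowded seeds
    trade a slightly looser coil for guaranteed termination.
    """
    min_self = _OVERLAP_FACTOR * 2 * bead_radius
    for restart in range(max_restarts):
        confine_r = _CHAIN_CONFINE_R * (1.0 + 0.05 * restart)
        pos = np.empty((n_res, 3))
        first_ok = False
        for _try in range(60):
            # sample the first bead anywhere in the confinement ball; widen
            # with the attempt number so crowded starts still find a pocket
            radius = confine_r * min(0.3 + 0.02 * _try, 1.2)
            pos[0] = center + radius * rng.uniform(0.0, 1.0) ** (1 / 3) * _rand_unit(rng)
            if other_beads is None or not len(other_beads) or (
                np.min(np.linalg.norm(other_beads - pos[0], axis=1)) >= other_radius_sum
            ):
                first_ok = True
                break
        if not first_ok:
            continue
        d_prev = _rand_unit(rng)
        ok = True
        for k in range(1, n_res):
            placed = False
            for _try in range(40):
                step = 0.35 * d_prev + 1.0 * _rand_unit(rng)
                drift = center - pos[k - 1]
                r = np.linalg.norm(drift)
                if r > confine_r:
                    # confinement strengthens with the excursion distance
                    step = step + (0.6 + 0.5 * (r - confine_r) / confine_r) * drift / r
                step /= np.linalg.norm(step)
                cand = pos[k - 1] + _BOND_LENGTH * step
                # self-avoidance against non-adjacent beads of this chain
                if k >= 2:
                    if np.min(np.linalg.norm(pos[: k - 1] - cand, axis=1)) < min_self:
                        continue
                # avoidance against previously placed chains of the block
                if other_beads is not None and len(other_beads):
                    if np.min(np.linalg.norm(other_beads - cand, axis=1)) < other_radius_sum:
                        continue
                pos[k] = cand
                d_prev = step
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return pos
    raise PlacementError("could not grow a self-avoiding chain; spec too crowded")


def _rand_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def generate_building_block(block: BuildingBlock, seed: int = 0) -> AssemblyFrame:
    """Generate one rigid trimer-like building block.

    ``n_copies`` collapsed bead chains (one bead per residue) are packed
    around a common centre; one counterion bead bridges each ``linker_sites``
    pair between cyclically adjacent chains.  No two non-bonded beads sit
    closer than 0.8x the sum of their radii.

    The whole geometry is regrown (deterministic substreams) when a
    counterion cannot be bridged in a particular conformation; the placement
    error only propagates once every retry is exhausted.
    """
    last_error: PlacementError | None = None
    for attempt, child_seed in enumerate(np.random.SeedSequence(seed).spawn(8)):
        try:
            return _build_block_once(block, np.random.default_rng(child_seed))
        except PlacementError as exc:
            last_error = exc
    raise last_error


def _build_block_once(block: BuildingBlock, rng: np.random.Generator) -> AssemblyFrame:
    pep = block.peptide
    n_res = pep.n_residues
    r_bead = pep.bead_radius
    masses_chain = pep.per_residue_mass()
    masses_chain[-1] += WATER_MASS  # book the peptide water on the C-terminus

    n = block.n_copies
    # chain centres on a regular polygon; adjacent coil centres ~1.25x the
    # confinement radius apart so neighbouring coils just interleave
    adjacent = 1.25 * _CHAIN_CONFINE_R
    ring_r = 0.0 if n == 1 else adjacent / (2 * np.sin(np.pi / n))

    positions: list[np.ndarray] = []
    chains: list[str] = []
    resid: list[int] = []
    resname: list[str] = []
    mass: list[float] = []
    bead_class: list[str] = []

    placed_beads = np.empty((0, 3))
    for i in range(n):
        ang = 2 * np.pi * i / max(n, 1)
        center = ring_r * np.asarray([np.cos(ang), np.sin(ang), 0.0])
        coords = _grow_chain(
            rng,
            center,
            n_res,
            r_bead,
            placed_beads if len(placed_beads) else None,
            _OVERLAP_FACTOR * 2 * r_bead,
        )
        placed_beads = np.vstack([placed_beads, coords])
        positions.append(coords)
        lbl = chain_label(i)
        chains += [lbl] * n_res
        resid += list(range(1, n_res + 1))
        resname += list(pep.sequence)
        mass += list(masses_chain)
        bead_class += [PEPTIDE_BEAD] * n_res

    pep_pos = np.vstack(positions)

    # counterion linker beads between cyclically adjacent chains
    ion_mass = COUNTERION_MASS[block.counterion]
    ion_name = COUNTERION_RESNAME[block.counterion]
    r_ion = block.counterion_radius
    min_ion_gap = _OVERLAP_FACTOR * (r_bead + r_ion)
    ion_id = 1
    if n >= 2:
        pairs = [(i, (i + 1) % n) for i in range(n)] if n > 2 else [(0, 1)]
        for (ci, cj) in pairs:
            for (ra, rb) in block.linker_sites:
                a = positions[ci][ra - 1]
                b = positions[cj][rb - 1]
                # search along the bridge segment, offset outward from the
                # block centre and laterally, for the roomiest spot clearing
                # min_ion_gap from every peptide bead
                mid = 0.5 * (a + b)
                out_dir = mid - pep_pos.mean(axis=0)
                nrm = np.linalg.norm(out_dir)
                out_dir = _rand_unit(rng) if nrm < 1e-9 else out_dir / nrm
                directions = [out_dir] + [
                    (out_dir + 0.8 * _rand_unit(rng))
                    / np.linalg.norm(out_dir + 0.8 * _rand_unit(rng))
                    for _ in range(5)
                ]
                best_cand, best_clear = None, -np.inf
                for direction in directions:
                    for lam in np.linspace(0.15, 0.85, 9):
                        for h in np.linspace(0.0, 6.0, 13):
                            cand = (
                                a + lam * (b - a) + h * direction
                                + rng.normal(scale=0.15, size=3)
                            )
                            clear = float(np.min(np.linalg.norm(pep_pos - cand, axis=1)))
                            if clear > best_clear:
                                best_cand, best_clear = cand, clear
                            if clear >= min_ion_gap:
                                break
                        if best_clear >= min_ion_gap:
                            break
                    if best_clear >= min_ion_gap:
                        break
                placed = best_clear >= min_ion_gap
                cand = best_cand
                if not placed:
                    raise PlacementError(
                        f"could not place counterion bridging chains {ci},{cj} "
                        f"at sites ({ra},{rb})"
                    )
                positions.append(cand.reshape(1, 3))
                chains.append(chain_label(ci))  # bookkeeping: attached to chain ci
                resid.append(n_res + ion_id)
                resname.append(ion_name)
                mass.append(ion_mass)
                bead_class.append(COUNTERION_BEAD)
                ion_id += 1
                pep_pos = np.vstack([pep_pos, cand])

    all_pos = np.vstack(positions)
    all_pos -= all_pos.mean(axis=0)
    return AssemblyFrame(
        positions=all_pos,
        chain=np.asarray(chains, dtype=object),
        resid=np.asarray(resid),
        resname=np.asarray(resname, dtype=object),
        mass=np.asarray(mass),
        bead_class=np.asarray(bead_class, dtype=object),
    )


# ---------------------------------------------------------------------------
# assembly aggregation
# ---------------------------------------------------------------------------

def _bead_radii(frame: AssemblyFrame, r_pep: float, r_ion: float) -> np.ndarray:
    return np.where(np.asarray(frame.bead_class) == PEPTIDE_BEAD, r_pep, r_ion)


def _min_surface_gap(
    pos_a: np.ndarray, rad_a: np.ndarray, pos_b: np.ndarray, rad_b: np.ndarray
) -> float:
    d = np.linalg.norm(pos_a[:, None, :] - pos_b[None, :, :], axis=-1)
    return float(np.min(d - rad_a[:, None] - rad_b[None, :]))


def _contact_distance(
    base: np.ndarray,
    radii: np.ndarray,
    rot: Rotation,
    u: np.ndarray,
    parent_pos: np.ndarray,
    parent_rad: np.ndarray,
    gap: float,
    t_hi: float,
) -> float:
    """Bisect the centre-centre distance t along u at which the rotated block
    first clears a minimum surface gap ``gap`` from the parent block."""
    child = rot.apply(base)

    def g(t: float) -> float:
        return _min_surface_gap(child + t * u, radii, parent_pos, parent_rad) - gap

    lo, hi = 0.0, t_hi
    while g(hi) < 0:
        hi *= 1.5
        if hi > 50 * t_hi:
            raise PlacementError("contact bisection failed to bracket")
    for _ in range(48):
        mid = 0.5 * (lo + hi)
        if g(mid) < 0:
            lo = mid
        else:
            hi = mid
    return hi


def _ballistic_landing(
    pep_base: np.ndarray,
    pep_radii: np.ndarray,
    rot: Rotation,
    u: np.ndarray,
    aim: np.ndarray,
    centers: np.ndarray,
    placed_pos: list[np.ndarray],
    pep_mask: np.ndarray,
    gap: float,
    d0: float,
) -> tuple[np.ndarray, int] | None:
    """First-contact landing of a block travelling along aim + s·u (s from +∞).

    Returns the landing centre and the index of the block touched first, or
    None when the line misses every placed block.
    """
    rel = rot.apply(pep_base)

    def min_gap_vs(j: int, s: float) -> float:
        child = rel + aim + s * u
        other = placed_pos[j][pep_mask]
        d = np.linalg.norm(child[:, None, :] - other[None, :, :], axis=-1)
        return float(np.min(d - pep_radii[:, None] - pep_radii[None, :]))

    rel_c = centers - aim
    proj = rel_c @ u
    perp = np.linalg.norm(rel_c - proj[:, None] * u, axis=1)
    candidates = np.where(perp < 1.6 * d0)[0]
    if len(candidates) == 0:
        return None

    best_s, best_j = None, None
    for j in candidates:
        s_near = float(proj[j])
        if min_gap_vs(j, s_near) - gap > 0:
            continue  # closest approach already clears: the line misses j
        lo, hi = s_near, s_near + 2.5 * d0
        while min_gap_vs(j, hi) - gap < 0:
            hi += d0
            if hi > s_near + 30 * d0:  # pragma: no cover - degenerate geometry
                return None
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if min_gap_vs(j, mid) - gap < 0:
                lo = mid
            else:
                hi = mid
        if best_s is None or hi > best_s:
            best_s, best_j = hi, int(j)
    if best_s is None:
        return None
    return aim + best_s * u, best_j


def _settle_toward(
    rel_beads: np.ndarray,
    radii: np.ndarray,
    start: np.ndarray,
    target: np.ndarray,
    placed: list[np.ndarray],
    placed_radii: np.ndarray,
    min_gap: float,
) -> np.ndarray:
    """Slide a rigid block from ``start`` toward ``target`` until its minimum
    surface gap against the placed beads reaches ``min_gap``."""
    w = target - start
    dist = float(np.linalg.norm(w))
    if dist < 1e-9:
        return start
    w = w / dist

    def gap_at(t: float) -> float:
        child = rel_beads + start + t * w
        best = np.inf
        for other in placed:
            d = np.linalg.norm(child[:, None, :] - other[None, :, :], axis=-1)
            g = float(np.min(d - radii[:, None] - placed_radii[None, :]))
            best = min(best, g)
            if best < min_gap - 5.0:
                break
        return best

    if gap_at(0.0) <= min_gap:
        return start
    lo, hi = 0.0, dist
    if gap_at(hi) > min_gap:
        return target
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        if gap_at(mid) > min_gap:
            lo = mid
        else:
            hi = mid
    return start + lo * w


def _ulam_spiral(n: int) -> np.ndarray:
    """First n points of a square spiral on the integer plane."""
    pts = [(0, 0)]
    x = y = 0
    step, leg = 1, 0
    dirs = [(1, 0), (0, 1), (-1, 0), (0, -1)]
    while len(pts) < n:
        dx, dy = dirs[leg % 4]
        for _ in range(step):
            x, y = x + dx, y + dy
            pts.append((x, y))
            if len(pts) == n:
                break
        leg += 1
        if leg % 2 == 0:
            step += 1
    return np.asarray([(px, py, 0) for px, py in pts[:n]], dtype=float)


def _lattice_sites(mode: str, n: int) -> np.ndarray:
    if mode == "linear":
        return np.asarray([(k, 0, 0) for k in range(n)], dtype=float)
    if mode == "planar":
        return _ulam_spiral(n)
    # compact: integer lattice points sorted by distance from origin
    m = int(np.ceil(n ** (1 / 3))) + 2
    grid = np.mgrid[-m : m + 1, -m : m + 1, -m : m + 1].reshape(3, -1).T.astype(float)
    order = np.lexsort((grid[:, 2], grid[:, 1], grid[:, 0], np.linalg.norm(grid, axis=1)))
    return grid[order][:n]


def aggregate_assembly(block_frame: AssemblyFrame, morph: MorphologySpec) -> AssemblyFrame:
    """Aggregate rigid copies of a building block into a connected assembly.

    Each new block is randomly rotated, positioned on the morphology's site
    pattern and then pulled along the line to its nearest placed neighbour
    until the surface-surface gap equals ``morph.contact_gap``.  Attaching
    every block to exactly one parent keeps the mean per-monomer contact
    valency roughly morphology-independent; the achieved valency is checked
    against ``morph.target_valency`` and a warning (with the achieved value)
    is emitted when it falls outside +-25%.
    """
    rng = np.random.default_rng(morph.seed)
    base = block_frame.positions - block_frame.positions.mean(axis=0)
    n_beads = len(base)
    pep_radius = 3.0
    ion_radius = 2.0
    radii = _bead_radii(block_frame, pep_radius, ion_radius)
    # contact calibration runs on peptide beads only: an attachment must
    # create a peptide-peptide contact, not merely touch a counterion
    pep_mask = block_frame.peptide_mask()
    pep_base = base[pep_mask]
    pep_radii = radii[pep_mask]

    # reference contact distance of two unrotated copies along x
    ux = np.asarray([1.0, 0.0, 0.0])
    d0 = _contact_distance(
        pep_base, pep_radii, Rotation.identity(), ux, pep_base, pep_radii,
        morph.contact_gap, t_hi=60.0,
    )
    # lattice spacing slightly above the contact distance so that only the
    # parent attachment is guaranteed to touch (linear/planar site patterns);
    # compact mode instead aggregates ballistically toward the cluster centre
    spacing = 1.35 * d0

    n = morph.n_blocks
    if morph.mode in ("dla", "compact"):
        sites = None
    else:
        sites = _lattice_sites(morph.mode, n) * spacing

    centers = np.zeros((n, 3))
    rots: list[Rotation] = [Rotation.identity()]
    placed_pos = [base.copy()]
    placed_rad = [radii]

    for k in range(1, n):
        best = None
        for attempt in range(12):
            rot = Rotation.random(random_state=rng)
            if morph.mode == "compact":
                # centre-seeking ballistic aggregation: of a few random
                # straight-line approaches, keep the first-contact landing
                # closest to the cluster centre of mass (space-filling growth)
                com = centers[:k].mean(axis=0)
                landing = None
                best_d = np.inf
                for _cand in range(6):
                    aim = com + 0.1 * d0 * rng.uniform(-1, 1, size=3)
                    u = _rand_unit(rng)
                    hit = _ballistic_landing(
                        pep_base, pep_radii, rot, u, aim,
                        centers[:k], placed_pos, pep_mask, morph.contact_gap, d0,
                    )
                    if hit is None:
                        continue
                    d_com = float(np.linalg.norm(hit[0] - com))
                    if d_com < best_d:
                        landing, best_d = hit, d_com
                if landing is None:
                    continue
                c, parent = landing
                # settle: slide the landed block toward the cluster centre
                # until its surface gap against any placed block closes to
                # 2 Å (dense aggregates relax into local pockets without
                # interdigitating)
                c = _settle_toward(
                    rot.apply(pep_base), pep_radii, c, com,
                    [placed_pos[j][pep_mask] for j in range(k)], pep_radii,
                    min_gap=2.0,
                )
            else:
                if sites is None:  # dla: random attachment off a random block
                    parent = int(rng.integers(0, k))
                    u = _rand_unit(rng)
                else:
                    p = sites[k]
                    d_to_placed = np.linalg.norm(centers[:k] - p, axis=1)
                    parent = int(np.argmin(d_to_placed))
                    u = p - centers[parent]
                    nu = np.linalg.norm(u)
                    u = ux if nu < 1e-9 else u / nu
                t = _contact_distance(
                    pep_base, pep_radii, rot, u,
                    (placed_pos[parent] - centers[parent])[pep_mask],  # parent-centred
                    pep_radii,
                    morph.contact_gap, t_hi=2.0 * d0,
                )
                c = centers[parent] + t * u
            child = rot.apply(base) + c
            # clearance against all non-parent blocks
            clear = np.inf
            for j in range(k):
                if j == parent:
                    continue
                if np.linalg.norm(centers[j] - c) > 3.5 * d0:
                    continue
                gap = _min_surface_gap(child, radii, placed_pos[j], placed_rad[j])
                clear = min(clear, gap)
            score = clear
            if best is None or score > best[0]:
                best = (score, c, rot, child)
            if clear > -_OVERLAP_FACTOR * 0.25 * 2 * pep_radius:
                break
        assert best is not None
        _, c, rot, child = best
        centers[k] = c
        rots.append(rot)
        placed_pos.append(child)
        placed_rad.append(radii)

    # assemble the frame with fresh chain labels per block
    chain_map: dict[tuple[int, str], str] = {}
    next_label = 0
    chains_out = []
    for k in range(n):
        for c in block_frame.chain:
            key = (k, str(c))
            if key not in chain_map:
                chain_map[key] = chain_label(next_label)
                next_label += 1
            chains_out.append(chain_map[key])

    frame = AssemblyFrame(
        positions=np.vstack(placed_pos),
        chain=np.asarray(chains_out, dtype=object),
        resid=np.tile(block_frame.resid, n),
        resname=np.tile(np.asarray(block_frame.resname, dtype=object), n),
        mass=np.tile(block_frame.mass, n),
        bead_class=np.tile(np.asarray(block_frame.bead_class, dtype=object), n),
    )
    frame.positions -= frame.positions.mean(axis=0)

    if morph.target_valency > 0:
        from .fractal import detect_contacts, mean_valency

        v = mean_valency(detect_contacts(frame))
        if abs(v - morph.target_valency) > 0.25 * morph.target_valency:
            warnings.warn(
                f"achieved mean valency {v:.2f} outside +-25% of target "
                f"{morph.target_valency:.2f} for mode {morph.mode!r} (best effort)",
                stacklevel=2,
            )
    return frame


# ---------------------------------------------------------------------------
# peak tables
# ---------------------------------------------------------------------------

def reference_peak_table(spec: PeptideSpec = R5, seed: int = 0) -> PeakTable:
    """A plausible amide HSQC reference table for a peptide (unit intensity).

    1H shifts near 8.2 ppm, 15N shifts near 118 ppm, deterministically
    scattered per residue for a given seed.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_residues
    import pandas as pd

    df = pd.DataFrame(
        {
            "resid": np.arange(1, n + 1),
            "resname": list(spec.sequence),
            "shift_a": np.round(8.25 + rng.uniform(-0.45, 0.45, size=n), 3),
            "shift_b": np.round(118.0 + rng.uniform(-6.0, 6.0, size=n), 3),
            "intensity": np.ones(n),
        }
    )
    return PeakTable(df, nucleus_pair="H-N")


def synth_peak_tables(
    reference: PeakTable,
    bound_fraction: float,
    csp_profile: np.ndarray | Sequence[float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    surface_residues: Sequence[int] = (),
    surface_intensity_factor: float = 1.0,
) -> PeakTable:
    """Perturbed peak table emulating counterion-driven self-assembly.

    Shifts move by ``csp_profile`` (per residue, applied to both dimensions
    in the spectrometer's natural 1:1 ppm sense on shift_a and shift_b/5)
    plus Gaussian noise; intensities attenuate to ``1 - bound_fraction`` of
    the reference (residues in ``surface_residues`` further multiplied by
    ``surface_intensity_factor``), emulating that only the dissolved
    fraction remains NMR-visible.
    """
    if not 0.0 <= bound_fraction <= 1.0:
        raise ValueError("bound_fraction must be in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    df = reference.df.copy()
    n = len(df)
    prof = np.zeros(n) if csp_profile is None else np.asarray(csp_profile, dtype=float)
    if len(prof) != n:
        raise ValueError("csp_profile length must match the reference table")
    df["shift_a"] = df["shift_a"] + prof + rng.normal(scale=noise_sd, size=n)
    df["shift_b"] = df["shift_b"] + 5.0 * prof + rng.normal(scale=noise_sd, size=n)
    boost = np.ones(n)
    mask = df["resid"].isin(list(surface_residues)).to_numpy()
    boost[mask] = surface_intensity_factor
    df["intensity"] = (
        df["intensity"] * (1.0 - bound_fraction) * boost
        + rng.normal(scale=noise_sd, size=n)
    ).clip(lower=0.0)
    return PeakTable(df, nucleus_pair=reference.nucleus_pair)


# ---------------------------------------------------------------------------
# DOSY
# ---------------------------------------------------------------------------

#: default acquisition mirrors the study: 128 points, 0 -> 0.1 T/m, Delta 60 ms
DEFAULT_DOSY_ACQUISITION = {
    "gradients": np.linspace(0.0, 0.1, 128),
    "delta": 10.0e-3,  # s, gradient pulse length: not printed; chosen so the
    # endpoint attenuation is ~0.3 at the weak 0.1 T/m maximum gradient,
    # the level a spectroscopist dials in for a reliable diffusion fit
    "big_delta": 60.0e-3,  # s, diffusion delay
    "gamma": GAMMA_1H,
}


def synth_dosy_series(
    D: float,
    acquisition: dict | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    I0: float = 1.0,
    temperature: float = 298.15,
    viscosity: float = 8.937e-4,
) -> DosySeries:
    """Stejskal-Tanner decay I(g) = I0 exp(-D g² γ² δ² (Δ - δ/3)) + noise."""
    if D <= 0:
        raise ValueError("diffusion coefficient must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    acq = dict(DEFAULT_DOSY_ACQUISITION)
    if acquisition:
        acq.update(acquisition)
    g = np.asarray(acq["gradients"], dtype=float)
    if np.any(np.diff(g) <= 0):
        raise ValueError("gradient grid must be strictly increasing")
    if np.any(g < 0):
        raise ValueError("gradients must be non-negative")
    delta, big_delta, gamma = acq["delta"], acq["big_delta"], acq["gamma"]
    if not delta < big_delta:
        raise ValueError("gradient pulse length delta must be below Delta")
    b = gamma**2 * g**2 * delta**2 * (big_delta - delta / 3.0)
    rng = np.random.default_rng(seed)
    integ = I0 * np.exp(-D * b) + rng.normal(scale=noise_sd, size=len(g))
    return DosySeries(
        gradient=g,
        integral=integ,
        delta=delta,
        big_delta=big_delta,
        gamma=gamma,
        temperature=temperature,
        viscosity=viscosity,
    )


# ---------------------------------------------------------------------------
# silicification kinetics
# ---------------------------------------------------------------------------

#: residual dissolved fractions reported for the studied conditions,
#: usable as generator presets for the plateau
RESIDUAL_PLATEAU_PRESETS = {
    "R5_25mM_silicic": 0.17,
    "synSil_low_LCPA": 0.20,
    "synSil_high_LCPA": 0.09,
}

#: 7 h of spectra every ~140 s (the real-time acquisition cadence)
DEFAULT_KINETIC_TIME_GRID = np.arange(0.0, 7 * 3600.0 + 1, 140.0)


def synth_kinetic_traces(
    spec: PeptideSpec = R5,
    surface_rate: float = 2.0e-3,
    core_rate: float = 1.0e-3,
    plateau_fraction: float = 0.17,
    time_grid: np.ndarray | Sequence[float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> KineticTraces:
    """Two-rate silicification decay traces, one per residue.

    Surface-flagged residues (silica nucleates at the template surface, so
    their signals vanish first) decay with ``surface_rate``, all others with
    ``core_rate``; every trace follows
    I(t) = (1 - plateau) exp(-k t) + plateau, starting at 1 and decaying
    toward the residual dissolved plateau.
    """
    if not (surface_rate >= core_rate > 0):
        raise ValueError("need surface_rate >= core_rate > 0")
    if not 0.0 <= plateau_fraction <= 1.0:
        raise ValueError("plateau_fraction must be in [0, 1]")
    t = (
        DEFAULT_KINETIC_TIME_GRID.copy()
        if time_grid is None
        else np.asarray(time_grid, dtype=float)
    )
    if t.size == 0:
        raise ValueError("time grid must be non-empty")
    rng = np.random.default_rng(seed)
    resids = np.arange(1, spec.n_residues + 1)
    surface = np.isin(resids, list(spec.surface_residues))
    rates = np.where(surface, surface_rate, core_rate)
    traces = (1.0 - plateau_fraction) * np.exp(
        -rates[:, None] * t[None, :]
    ) + plateau_fraction
    traces = traces + rng.normal(scale=noise_sd, size=traces.shape)
    traces = traces / traces[:, :1]  # normalize to the first point per residue
    return KineticTraces(
        time=t,
        intensities=traces,
        resids=resids,
        resnames=np.asarray(list(spec.sequence), dtype=object),
        surface_flags=surface,
    )


# ---------------------------------------------------------------------------
# crowded box
# ---------------------------------------------------------------------------

def build_crowded_box(peptide_mass_da: float, n_peptides: int, rh_nm: float) -> dict:
    """Density-matched crowded-box parameters.

    density = 9 m u / (4 π Rh³) with u the atomic mass unit in grams, and a
    cubic edge chosen so that edge³ x density equals the total peptide mass.
    Returns ``{"density_g_per_ml": ..., "edge_nm": ...}``.
    """
    if peptide_mass_da <= 0 or n_peptides <= 0 or rh_nm <= 0:
        raise ValueError("all crowded-box inputs must be positive")
    rh_cm = rh_nm * 1e-7
    density = 9.0 * peptide_mass_da * ATOMIC_MASS_UNIT_G / (4.0 * np.pi * rh_cm**3)
    volume_cm3 = n_peptides * peptide_mass_da * ATOMIC_MASS_UNIT_G / density
    edge_nm = volume_cm3 ** (1.0 / 3.0) * 1e7
    return {"density_g_per_ml": float(density), "edge_nm": float(edge_nm)}


# ---------------------------------------------------------------------------
# ground-truth manifest
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthManifest:
    """Everything needed to regenerate a synthetic dataset bit-identically."""

    seed: int
    parameters: dict = field(default_factory=dict)
    true_dimensionality: float | None = None
    true_bound_fraction: float | None = None
    true_decay_rates: dict | None = None
    true_diffusion_coefficient: float | None = None
    stream_seeds: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            if isinstance(o, frozenset):
                return sorted(o)
            return str(o)

        text = json.dumps(asdict(self), indent=2, default=default, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "GroundTruthManifest":
        p = Path(text_or_path) if not str(text_or_path).lstrip().startswith("{") else None
        data = json.loads(p.read_text() if p else text_or_path)
        return cls(**data)


def derive_stream_seeds(master_seed: int, streams: Sequence[str]) -> dict[str, int]:
    """Deterministic per-stream seeds (< 2^31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(streams))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(streams, children)
    }
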