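"""Fractal-cluster metrics of coarse-grained peptide assemblies.

Per frame (or averaged over a trajectory window) this module computes the
radius of gyration, molecular volume V_mol = κ·Mw (κ = 1.21 Å³/Da, the
standard protein specific-volume prefactor), compactness
φ = V_mol / ((4/3)π Rg³), mean contact valency per monomer, and the fractal
dimension d_f = 3(1 − log φ / log valency); plus an independent mass-radius
scaling estimate of the dimension used as an oracle for generated
morphologies.

Contacts are chain-pair contacts: two peptide chains are in contact when any
bead pair comes within ``cutoff`` of surface-surface distance
(distance − sum of bead radii).  Counterion beads never enter peptide-peptide
contacts; chain pairs sharing a nearby counterion are reported separately as
bridging contacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structio import AssemblyFrame, Trajectory, COUNTERION_BEAD, PEPTIDE_BEAD

__all__ = [
    "KAPPA_DEFAULT",
    "RG_OVER_RH",
    "DEFAULT_CONTACT_CUTOFF",
    "DEFAULT_BEAD_RADII",
    "FractalMetrics",
    "MassRadiusFit",
    "compute_rg",
    "detect_contacts",
    "mean_valency",
    "connected_clusters",
    "molecular_volume",
    "compactness",
    "fractal_dimension",
    "mass_radius_dimension",
    "rg_to_rh",
    "unwrap_frame",
    "analyze_frame",
    "analyze_trajectory",
]

KAPPA_DEFAULT = 1.21  # Å³/Da
RG_OVER_RH = 1.1
DEFAULT_CONTACT_CUTOFF = 4.5  # Å between bead surfaces
DEFAULT_BEAD_RADII = {PEPTIDE_BEAD: 3.0, COUNTERION_BEAD: 2.0}


@dataclass
class FractalMetrics:
    """Cluster metrics for one frame or a trajectory-window average."""

    rg: float  # Å
    mw_total: float  # Da, peptide mass of the analysed cluster
    v_mol: float  # Å³ (= kappa * mw_total exactly)
    phi: float
    valency: float
    d_f: float
    kappa: float = KAPPA_DEFAULT
    n_chains: int = 0
    n_clusters: int = 1
    d_f_flag: str = "ok"  # ok | undefined | out-of-range
    rg_sd: float = 0.0
    phi_sd: float = 0.0
    valency_sd: float = 0.0
    d_f_sd: float = 0.0
    n_frames: int = 1
    per_frame: pd.DataFrame | None = field(default=None, repr=False)


@dataclass
class MassRadiusFit:
    """Mass-radius scaling fit: slope of log N(<r) vs log r."""

    dimension: float
    r_min: float
    r_max: float
    n_radii: int


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def compute_rg(
    frame: AssemblyFrame,
    selection: np.ndarray | Iterable[str] | None = None,
    mass_weighted: bool = True,
) -> float:
    """Radius of gyration (Å): RMS distance from the (mass-weighted) centre.

    ``selection`` is a boolean bead mask or an iterable of chain labels;
    ``None`` uses every bead.  Frames with a box must be unwrapped first
    (see :func:`unwrap_frame`).
    """
    if selection is None:
        sub = frame
    elif isinstance(selection, np.ndarray) and selection.dtype == bool:
        sub = frame.subset(selection)
    else:
        sub = frame.select_chains(selection)
    if sub.n_beads == 0:
        raise ValueError("empty selection")
    w = sub.mass if mass_weighted else np.ones(sub.n_beads)
    com = np.average(sub.positions, axis=0, weights=w)
    sq = np.sum((sub.positions - com) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=w)))


def _radii_for(frame: AssemblyFrame, bead_radii: dict[str, float]) -> np.ndarray:
    return np.asarray([bead_radii[str(c)] for c in frame.bead_class], dtype=float)


def _pairs_within(
    pos: np.ndarray, box: np.ndarray | None, center_cutoff: float
) -> np.ndarray:
    """Index pairs with centre distance <= cutoff, minimum-image when boxed."""
    if box is not None:
        wrapped = np.mod(pos, box)
        # cKDTree with boxsize implements the minimum-image convention
        tree = cKDTree(wrapped, boxsize=box)
    else:
        tree = cKDTree(pos)
    pairs = tree.query_pairs(center_cutoff, output_type="ndarray")
    return pairs


def _pair_distances(
    pos: np.ndarray, box: np.ndarray | None, pairs: np.ndarray
) -> np.ndarray:
    d = pos[pairs[:, 0]] - pos[pairs[:, 1]]
    if box is not None:
        d -= box * np.round(d / box)
    return np.linalg.norm(d, axis=1)


def detect_contacts(
    frame: AssemblyFrame,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    bead_radii: dict[str, float] | None = None,
) -> nx.Graph:
    """Chain-level contact graph of an assembly frame.

    Nodes are peptide chain labels; an edge joins chains i, j when any bead
    pair sits within ``cutoff`` of surface-surface distance, with the number
    of such bead pairs stored as edge attribute ``n_pairs``.  Counterion
    beads are excluded from peptide-peptide contacts; chain pairs bridged by
    a shared counterion (both within cutoff of the same counterion bead) are
    listed in ``graph.graph["bridges"]``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    radii_map = dict(DEFAULT_BEAD_RADII)
    if bead_radii:
        radii_map.update(bead_radii)
    radii = _radii_for(frame, radii_map)
    g = nx.Graph()
    for c in frame.chains:
        g.add_node(c)

    center_cutoff = cutoff + 2 * max(radii_map.values())
    pairs = _pairs_within(frame.positions, frame.box, center_cutoff)
    bridges: dict[tuple[str, str], int] = {}
    if len(pairs):
        dist = _pair_distances(frame.positions, frame.box, pairs)
        surf = dist - radii[pairs[:, 0]] - radii[pairs[:, 1]]
        touching = pairs[surf <= cutoff]
        cls = np.asarray(frame.bead_class)
        ch = np.asarray(frame.chain)
        ion_partners: dict[int, set[str]] = {}
        for i, j in touching:
            ci, cj = str(ch[i]), str(ch[j])
            pep_i = cls[i] == PEPTIDE_BEAD
            pep_j = cls[j] == PEPTIDE_BEAD
            if pep_i and pep_j:
                if ci != cj:
                    if g.has_edge(ci, cj):
                        g[ci][cj]["n_pairs"] += 1
                    else:
                        g.add_edge(ci, cj, n_pairs=1)
            elif pep_i != pep_j:  # peptide-counterion proximity
                ion = int(j if pep_i else i)
                ion_partners.setdefault(ion, set()).add(ci if pep_i else cj)
        for partners in ion_partners.values():
            ps = sorted(partners)
            for a_i in range(len(ps)):
                for b_i in range(a_i + 1, len(ps)):
                    key = (ps[a_i], ps[b_i])
                    bridges[key] = bridges.get(key, 0) + 1
    g.graph["bridges"] = [(a, b, n) for (a, b), n in sorted(bridges.items())]
    return g


def mean_valency(graph: nx.Graph, mode: str = "partners") -> float:
    """Mean contacts per monomer.

    ``partners`` (default) counts distinct contacting chains (graph degree);
    ``pairs`` counts bead-pair contacts per chain.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph has no nodes")
    if mode == "partners":
        return float(np.mean([d for _, d in graph.degree()]))
    if mode == "pairs":
        return float(
            np.mean(
                [
                    sum(graph[n][m].get("n_pairs", 1) for m in graph[n])
                    for n in graph.nodes
                ]
            )
        )
    raise ValueError("mode must be 'partners' or 'pairs'")


def connected_clusters(graph: nx.Graph) -> list[set[str]]:
    """Connected components, largest ("the assembly") first."""
    comps = sorted(nx.connected_components(graph), key=len, reverse=True)
    return [set(c) for c in comps]


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------

def molecular_volume(mw_total: float, kappa: float = KAPPA_DEFAULT) -> float:
    """V_mol = κ · Mw in Å³ (κ in Å³/Da)."""
    if mw_total < 0:
        raise ValueError("mass must be non-negative")
    return kappa * mw_total


def compactness(
    frame: AssemblyFrame,
    cluster: Iterable[str] | None = None,
    kappa: float = KAPPA_DEFAULT,
) -> float:
    """Compactness φ = V_mol / ((4/3) π Rg³) of one cluster.

    V_mol uses the cluster's total peptide mass; Rg is the mass-weighted
    gyration radius over the cluster's peptide beads.
    """
    sub = frame if cluster is None else frame.select_chains(cluster)
    pep = sub.subset(sub.peptide_mask())
    if pep.n_beads == 0:
        raise ValueError("cluster holds no peptide beads")
    rg = compute_rg(pep)
    if rg <= 0:
        raise ValueError("undefined compactness: cluster Rg is zero")
    v_mol = molecular_volume(float(np.sum(pep.mass)), kappa)
    return float(v_mol / ((4.0 / 3.0) * np.pi * rg**3))


def fractal_dimension(phi: float, valency: float) -> float:
    """d_f = 3 (1 − log φ / log valency); log-base invariant.

    Defined for φ > 0 and valency > 1 (batch callers should trap the
    ValueError and flag the frame instead).
    """
    if phi <= 0:
        raise ValueError("phi must be positive")
    if valency <= 1:
        raise ValueError("valency must exceed 1 for a defined d_f")
    return 3.0 * (1.0 - math.log(phi) / math.log(valency))


def rg_to_rh(rg: float) -> float:
    """Hydrodynamic radius from gyration radius: Rh = Rg / 1.1 (same units)."""
    if rg < 0:
        raise ValueError("Rg must be non-negative")
    return rg / RG_OVER_RH


def mass_radius_dimension(
    frame: AssemblyFrame,
    cluster: Iterable[str] | None = None,
    bead_radius: float = 3.0,
    n_radii: int = 24,
) -> MassRadiusFit:
    """Independent mass-radius estimate of the fractal dimension.

    Counts beads within radius r of the cluster's centre of mass and fits
    the slope of log N(<r) vs log r over r in [2·bead_radius, Rg].  This
    estimator never sees φ or the valency, so it can serve as an oracle for
    the analytic d_f.
    """
    sub = frame if cluster is None else frame.select_chains(cluster)
    if sub.n_beads < 20:
        raise ValueError("need at least 20 beads for a mass-radius fit")
    com = np.average(sub.positions, axis=0, weights=sub.mass)
    r_beads = np.linalg.norm(sub.positions - com, axis=1)
    rg = compute_rg(sub)
    r_min = 2.0 * bead_radius
    r_max = rg
    if r_max <= r_min * 1.2:
        raise ValueError("cluster too small: Rg does not exceed the inner window")
    radii = np.geomspace(r_min, r_max, n_radii)
    counts = np.searchsorted(np.sort(r_beads), radii, side="right")
    # radii enclosing almost no beads carry no scaling information (the
    # centre of mass can sit in a packing void); drop them from the fit
    keep = counts >= 5
    if keep.sum() < 3:
        raise ValueError("too few occupied radii for a fit")
    # Poisson counts: var(log N) ~ 1/N, so weight residuals by sqrt(N)
    slope = float(
        np.polyfit(
            np.log(radii[keep]), np.log(counts[keep]), 1,
            w=np.sqrt(counts[keep].astype(float)),
        )[0]
    )
    return MassRadiusFit(dimension=slope, r_min=r_min, r_max=r_max, n_radii=int(keep.sum()))


# ---------------------------------------------------------------------------
# periodic-boundary unwrapping
# ---------------------------------------------------------------------------

def unwrap_frame(frame: AssemblyFrame) -> AssemblyFrame:
    """Unwrap chains straddling periodic boundaries (no-op without a box).

    Within each chain, beads follow their predecessor by minimum image in
    residue order; whole chains are then shifted by box multiples toward the
    chain they sit closest to, by greedy traversal from the first chain.
    """
    if frame.box is None:
        return frame
    box = frame.box
    pos = frame.positions.copy()
    ch = np.asarray(frame.chain)
    labels = list(dict.fromkeys(str(c) for c in ch))
    idx_by_chain = {lbl: np.where(ch == lbl)[0] for lbl in labels}

    for lbl in labels:
        idx = idx_by_chain[lbl]
        order = idx[np.argsort(frame.resid[idx])]
        for prev, cur in zip(order, order[1:]):
            d = pos[cur] - pos[prev]
            pos[cur] -= box * np.round(d / box)

    placed = [labels[0]]
    remaining = labels[1:]
    centroids = {lbl: pos[idx_by_chain[lbl]].mean(axis=0) for lbl in labels}
    while remaining:
        best = None
        for lbl in remaining:
            for ref in placed:
                d = centroids[lbl] - centroids[ref]
                shift = -box * np.round(d / box)
                dist = np.linalg.norm(d + shift)
                if best is None or dist < best[0]:
                    best = (dist, lbl, shift)
        _, lbl, shift = best
        pos[idx_by_chain[lbl]] += shift
        centroids[lbl] = centroids[lbl] + shift
        placed.append(lbl)
        remaining.remove(lbl)

    out = AssemblyFrame(
        positions=pos,
        chain=frame.chain.copy(),
        resid=frame.resid.copy(),
        resname=frame.resname.copy(),
        mass=frame.mass.copy(),
        bead_class=frame.bead_class.copy(),
        box=None,  # unwrapped coordinates are no longer box-consistent
        time=frame.time,
    )
    return out


# ---------------------------------------------------------------------------
# frame / trajectory analysis
# ---------------------------------------------------------------------------

def analyze_frame(
    frame: AssemblyFrame,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    kappa: float = KAPPA_DEFAULT,
    valency_mode: str = "partners",
) -> FractalMetrics:
    """All fractal metrics of one frame, computed on the largest cluster."""
    work = unwrap_frame(frame)
    graph = detect_contacts(work, cutoff=cutoff)
    clusters = connected_clusters(graph)
    biggest = clusters[0]
    sub_graph = graph.subgraph(biggest)
    valency = mean_valency(sub_graph, mode=valency_mode)
    pep = work.select_chains(biggest).subset(
        work.select_chains(biggest).peptide_mask()
    )
    rg = compute_rg(pep)
    mw = float(np.sum(pep.mass))
    v_mol = molecular_volume(mw, kappa)
    phi = compactness(work, biggest, kappa)
    flag = "ok"
    try:
        d_f = fractal_dimension(phi, valency)
        if not 0.0 <= d_f <= 3.0:
            flag = "out-of-range"
    except ValueError:
        d_f = float("nan")
        flag = "undefined"
    return FractalMetrics(
        rg=rg, mw_total=mw, v_mol=v_mol, phi=phi, valency=valency, d_f=d_f,
        kappa=kappa, n_chains=sub_graph.number_of_nodes(), n_clusters=len(clusters),
        d_f_flag=flag,
    )


def _window_frames(traj: Trajectory, window) -> list[AssemblyFrame]:
    frames = list(traj)
    if window is None:
        return frames
    if isinstance(window, str):
        w = window.strip().lower()
        if w.startswith("last:") and w.endswith("%"):
            frac = float(w[5:-1]) / 100.0
        elif w.startswith("last:"):
            frac = float(w[5:])
        else:
            raise ValueError(f"cannot parse window {window!r}; use e.g. 'last:20%'")
        n = max(1, int(round(frac * len(frames))))
        return frames[-n:]
    if isinstance(window, float):
        n = max(1, int(round(window * len(frames))))
        return frames[-n:]
    if isinstance(window, tuple) and len(window) == 2:
        t0, t1 = window
        sel = [f for f in frames if t0 <= f.time <= t1]
        if not sel:
            raise ValueError("window selects no frames")
        return sel
    raise ValueError(f"unsupported window spec {window!r}")


def analyze_trajectory(
    traj: Trajectory,
    window=None,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    kappa: float = KAPPA_DEFAULT,
    valency_mode: str = "partners",
) -> FractalMetrics:
    """Windowed fractal metrics: per-frame analysis on the largest cluster,
    averaged (mean ± sd) over the window; the per-frame series is kept on
    ``result.per_frame`` for plotting or export.

    ``window`` may be None (all frames), a fraction (0.2 = last 20%),
    a string like ``"last:20%"``, or a (t0, t1) time span.
    """
    frames = _window_frames(traj, window)
    rows = []
    for f in frames:
        m = analyze_frame(f, cutoff=cutoff, kappa=kappa, valency_mode=valency_mode)
        rows.append(
            {
                "time": f.time, "rg": m.rg, "mw_total": m.mw_total, "v_mol": m.v_mol,
                "phi": m.phi, "valency": m.valency, "d_f": m.d_f,
                "d_f_flag": m.d_f_flag, "n_chains": m.n_chains,
                "n_clusters": m.n_clusters,
            }
        )
    df = pd.DataFrame(rows)
    d_f_vals = df["d_f"].to_numpy(dtype=float)
    defined = np.isfinite(d_f_vals)
    flag = "ok"
    if not defined.any():
        flag = "undefined"
    elif (df["d_f_flag"] != "ok").any():
        flag = "out-of-range"
    mw = float(df["mw_total"].mean())
    return FractalMetrics(
        rg=float(df["rg"].mean()),
        mw_total=mw,
        v_mol=molecular_volume(mw, kappa),
        phi=float(df["phi"].mean()),
        valency=float(df["valency"].mean()),
        d_f=float(np.nanmean(d_f_vals)) if defined.any() else float("nan"),
        kappa=kappa,
        n_chains=int(round(df["n_chains"].mean())),
        n_clusters=int(round(df["n_clusters"].mean())),
        d_f_flag=flag,
        rg_sd=float(df["rg"].std(ddof=0)),
        phi_sd=float(df["phi"].std(ddof=0)),
        valency_sd=float(df["valency"].std(ddof=0)),
        d_f_sd=float(np.nanstd(d_f_vals)) if defined.any() else float("nan"),
        n_frames=len(df),
        per_frame=df,
    )
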