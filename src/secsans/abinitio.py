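"""Ab initio dummy-atom shape reconstruction from a scattering curve.

A low-resolution particle shape is represented by equal spheres ("beads") on a
close-packed lattice filling a search sphere of diameter Dmax.  Starting from
a random bead configuration, simulated annealing toggles beads on and off to
minimize the misfit to the target curve plus a compactness penalty, optionally
under two-fold (P2) rotational symmetry about z.  Independent runs are then
aligned by principal axes, averaged on the lattice, and compared through the
normalized spatial discrepancy (NSD).

The model intensity can be evaluated by the exact Debye double sum or by a
spherical-harmonic multipole expansion

    I(Q) = sum_lm |A_lm(Q)|^2,    A_lm(Q) = sqrt(4 pi) sum_j g_j j_l(Q r_j) Y*_lm(Omega_j),

truncated at an order set by the sampling theorem (lmax ~ Qmax * Rmax); both
are modulated by the single-bead sphere form factor.  The two backends agree
to better than 1% on the measured Q range, which pins down the intended
quantity irrespective of notational conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.special import spherical_jn, sph_harm_y

from ._debye import debye_sum
from .curves import ScatteringCurve, rebin_curve
from .formfactor import intensity_sphere


@dataclass(frozen=True)
class BeadModel:
    """Dummy-atom model: bead centers (A), common bead radius, symmetry tag
    (P1 or P2 about z) and per-bead occupancy in (0, 1]."""

    coordinates: np.ndarray
    bead_radius: float
    symmetry: str = "P1"
    occupancy: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.coordinates, dtype=float))
        object.__setattr__(self, "coordinates", c)
        if c.shape[1] != 3:
            raise ValueError("coordinates must be (n, 3)")
        if len(c) == 0:
            raise ValueError("empty model")
        if self.bead_radius <= 0:
            raise ValueError("bead_radius must be positive")
        if self.symmetry not in ("P1", "P2"):
            raise ValueError("symmetry must be 'P1' or 'P2'")
        occ = self.occupancy
        occ = np.ones(len(c)) if occ is None else np.asarray(occ, dtype=float)
        object.__setattr__(self, "occupancy", occ)
        if occ.shape != (len(c),) or np.any(occ <= 0) or np.any(occ > 1):
            raise ValueError("occupancy must be per-bead in (0, 1]")

    def __len__(self) -> int:
        return len(self.coordinates)

    def centered(self) -> "BeadModel":
        return replace(self, coordinates=self.coordinates - self.coordinates.mean(0))


@dataclass(frozen=True)
class AnnealConfig:
    """Simulated-annealing protocol.

    ``t_start`` defaults to the standard deviation of the score change over
    100 random toggles; ``moves_per_stage`` to 20x the initial bead count;
    ``lmax`` (multipole order used for reporting) to the sampling-theorem rule.
    """

    n_beads_initial: int | None = None
    t_start: float | None = None
    cooling: float = 0.9
    moves_per_stage: int | None = None
    compactness_weight: float = 1.0
    seed: int = 0
    lmax: int | None = None
    max_stages: int = 100
    stall_stages: int = 3
    stall_tol: float = 0.01
    quench_passes: int = 10
    n_fit_points: int = 40

    def __post_init__(self) -> None:
        if not (0.0 < self.cooling < 1.0):
            raise ValueError("cooling must lie in (0, 1)")
        for name in ("moves_per_stage", "n_beads_initial"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# lattice and intensity backends


def lattice_sites(dmax: float, bead_radius: float) -> np.ndarray:
    """Close-packed (face-centered cubic) lattice sites inside the Dmax/2 sphere.

    Nearest-neighbour spacing is the bead diameter; fcc gives the 12-neighbour
    close packing of equal spheres.
    """
    s = 2.0 * bead_radius
    a = s / np.sqrt(2.0)
    R = dmax / 2.0
    m = int(np.ceil(R / a))
    rng = np.arange(-m, m + 1)
    i, j, k = np.meshgrid(rng, rng, rng, indexing="ij")
    keep = (i + j + k) % 2 == 0
    pts = np.column_stack([i[keep], j[keep], k[keep]]) * a
    inside = (pts**2).sum(1) <= R**2
    return pts[inside]


def auto_lmax(qmax: float, rmax: float) -> int:
    """Multipole truncation order from the sampling-theorem rule."""
    return max(5, int(np.ceil(qmax * rmax)) + 3)


def bead_intensity(
    model: BeadModel,
    q: np.ndarray,
    backend: str = "multipole",
    lmax: int | None = None,
) -> np.ndarray:
    """Scattering of a bead model, modulated by the single-bead form factor."""
    q = np.asarray(q, dtype=float)
    coords = model.coordinates
    w = model.occupancy
    ff = intensity_sphere(q, model.bead_radius)
    if backend == "debye":
        return ff * debye_sum(coords, q, weights=w)
    if backend != "multipole":
        raise ValueError(f"unknown backend {backend!r}")
    center = coords.mean(0)
    rel = coords - center
    r = np.linalg.norm(rel, axis=1)
    rmax = float(r.max()) if len(r) else 0.0
    if lmax is None:
        lmax = auto_lmax(float(q.max()), max(rmax, 1e-9))
    else:
        need = auto_lmax(float(q.max()), max(rmax, 1e-9))
        if lmax < need:
            warnings.warn(
                f"lmax={lmax} below sampling-theorem order {need}; raising automatically"
            )
            lmax = need
    theta = np.arccos(np.divide(rel[:, 2], r, out=np.zeros_like(r), where=r > 0))
    phi = np.arctan2(rel[:, 1], rel[:, 0])
    qr = np.outer(q, r)
    out = np.zeros(q.size)
    for l in range(lmax + 1):
        jl = spherical_jn(l, qr)  # (nq, n)
        for m in range(0, l + 1):
            y = sph_harm_y(l, m, theta, phi)  # (n,)
            a_lm = jl @ (w * np.conj(y))
            term = np.abs(a_lm) ** 2
            out += term if m == 0 else 2.0 * term
    return ff * 4.0 * np.pi * out


# ---------------------------------------------------------------------------
# annealing reconstruction


def _p2_mate_indices(sites: np.ndarray, spacing: float) -> np.ndarray:
    """Index of the 180-deg-about-z image of each lattice site (exact on fcc)."""
    from scipy.spatial import cKDTree

    imaged = sites * np.array([-1.0, -1.0, 1.0])
    tree = cKDTree(sites)
    dist, idx = tree.query(imaged)
    if np.any(dist > 1e-6 * spacing):
        raise RuntimeError("lattice is not closed under the P2 rotation")
    return idx


def _components(on_idx: np.ndarray, neighbors: list[np.ndarray]) -> list[np.ndarray]:
    on = set(int(i) for i in on_idx)
    seen: set[int] = set()
    comps = []
    for start in on_idx:
        start = int(start)
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in neighbors[u]:
                v = int(v)
                if v in on and v not in seen:
                    seen.add(v)
                    stack.append(v)
        comps.append(np.array(sorted(comp)))
    return sorted(comps, key=len, reverse=True)


def reconstruct_shape(
    curve: ScatteringCurve,
    dmax: float,
    symmetry: str = "P1",
    config: AnnealConfig | None = None,
    bead_radius: float | None = None,
) -> BeadModel:
    """Anneal a bead model against a target curve.

    Beads live on an fcc lattice inside the sphere of diameter ``dmax``
    (default bead radius dmax/40).  The score is the scale-optimized curve
    chi^2 plus ``compactness_weight`` times the fraction of beads with fewer
    than 3 neighbours; moves toggle one random bead (and its symmetry mate
    under P2) with Metropolis acceptance.  Deterministic given the seed; the
    returned model is the connected best-scoring configuration.
    """
    if len(curve) < 20:
        raise ValueError("target curve must have at least 20 points")
    if dmax <= 0:
        raise ValueError("dmax must be positive")
    cfg = config or AnnealConfig()
    rng = np.random.default_rng(cfg.seed)
    r_bead = bead_radius if bead_radius is not None else dmax / 40.0
    sites = lattice_sites(dmax, r_bead)
    n_sites = len(sites)
    spacing = 2.0 * r_bead

    # fit grid: rebin the target for speed
    target = rebin_curve(curve, min(cfg.n_fit_points, len(curve)))
    qf = target.q
    i_dat = target.intensity
    sig = target.sigma if target.sigma is not None else 0.01 * np.abs(i_dat) + 1e-12 * np.max(np.abs(i_dat))
    wgt = 1.0 / sig**2
    ff = intensity_sphere(qf, r_bead)
    nq = qf.size

    dists = np.sqrt(((sites[:, None, :] - sites[None, :, :]) ** 2).sum(-1))
    neighbors = [np.nonzero((dists[k] < 1.001 * spacing) & (dists[k] > 0))[0] for k in range(n_sites)]
    mate = _p2_mate_indices(sites, spacing) if symmetry == "P2" else None

    # initial configuration: a random connected cluster grown from a random
    # seed site (random walk style), symmetrized under P2
    n_init = min(cfg.n_beads_initial or n_sites // 2, n_sites)
    on = np.zeros(n_sites, dtype=bool)
    start = int(rng.integers(n_sites))
    on[start] = True
    frontier = set(int(x) for x in neighbors[start])
    while int(on.sum()) < n_init and frontier:
        pick = int(rng.choice(sorted(frontier)))
        frontier.discard(pick)
        if on[pick]:
            continue
        on[pick] = True
        frontier |= {int(x) for x in neighbors[pick] if not on[x]}
    if mate is not None:
        on[mate[np.nonzero(on)[0]]] = True  # symmetrize the start

    sinc_rows = np.sinc(dists * (qf[:, None, None] / np.pi)).transpose(1, 2, 0) if n_sites**2 * nq * 8 < 2e9 and n_sites <= 700 else None
    # c[k, :] = sum over ON j != k of sinc(Q d_kj)
    def sinc_row(k: int) -> np.ndarray:
        if sinc_rows is not None:
            return sinc_rows[k]
        return np.sinc(np.outer(dists[k], qf) / np.pi)

    c = np.zeros((n_sites, nq))
    for j in np.nonzero(on)[0]:
        c += sinc_row(j)
    c[np.nonzero(on)[0]] -= 1.0  # remove self sinc(0)=1 for on sites

    i_mod = np.zeros(nq)
    onidx = np.nonzero(on)[0]
    i_mod = (c[onidx].sum(0)) + float(on.sum())  # sum_k on (c_k + 1)

    ncount = np.array([int(on[nb].sum()) for nb in neighbors])
    loose_cnt = int(((ncount < 3) & on).sum())

    def chi2_of(i_model: np.ndarray, n_on: int) -> float:
        if n_on == 0:
            return np.inf
        im = ff * i_model
        s_num = float(np.sum(wgt * im * i_dat))
        s_den = float(np.sum(wgt * im * im))
        s = max(s_num / s_den, 0.0) if s_den > 0 else 0.0
        return float(np.sum(wgt * (i_dat - s * im) ** 2)) / nq

    def score_parts(i_model, n_on, loose):
        loose_frac = loose / n_on if n_on else 1.0
        return chi2_of(i_model, n_on) + cfg.compactness_weight * loose_frac

    n_on = int(on.sum())
    cur = score_parts(i_mod, n_on, loose_cnt)

    neighbor_sets = [set(int(x) for x in nb) for nb in neighbors]

    def proposal_delta(k: int) -> tuple[np.ndarray, int, int]:
        """(delta_I, delta_n_on, delta_loose) for toggling site k (and mate)."""
        pair = [k] if mate is None or mate[k] == k else [k, int(mate[k])]
        state = bool(on[k])  # P2 pairs stay synchronized
        sign = -1.0 if state else 1.0
        d_i = np.zeros(nq)
        for idx, site in enumerate(pair):
            ck = c[site]
            for prev in pair[:idx]:
                ck = ck + sign * np.sinc(dists[site, prev] * qf / np.pi)
            d_i += sign * (2.0 * ck + 1.0)
        d_n = (1 if not state else -1) * len(pair)
        # looseness: re-evaluate only the affected sites
        dnc = 1 if not state else -1
        affected = set(pair)
        for s in pair:
            affected |= neighbor_sets[s]
        d_loose = 0
        for a in affected:
            on_before = bool(on[a])
            on_after = (not state) if a in pair else on_before
            nc_after = ncount[a] + dnc * sum(1 for s in pair if a in neighbor_sets[s])
            d_loose += int(on_after and nc_after < 3) - int(on_before and ncount[a] < 3)
        return d_i, d_n, d_loose

    def apply_toggle(k: int) -> None:
        nonlocal n_on, loose_cnt, i_mod, c
        pair = [k] if mate is None or mate[k] == k else [k, int(mate[k])]
        for site in pair:
            row = sinc_row(site)
            if on[site]:
                on[site] = False
                n_on -= 1
                c -= row
                c[site] += 1.0
                i_mod -= 2.0 * c[site] + 1.0
                for nb in neighbors[site]:
                    ncount[nb] -= 1
            else:
                i_mod += 2.0 * c[site] + 1.0
                on[site] = True
                n_on += 1
                c += row
                c[site] -= 1.0
                for nb in neighbors[site]:
                    ncount[nb] += 1
        loose_cnt = int(((ncount < 3) & on).sum())

    # initial temperature: std of score changes over 100 random toggles
    if cfg.t_start is None:
        deltas = []
        for k in rng.integers(0, n_sites, 100):
            d_i, d_n, d_loose = proposal_delta(int(k))
            new = score_parts(i_mod + d_i, n_on + d_n, loose_cnt + d_loose)
            deltas.append(new - cur)
        t = float(np.std(deltas)) or 1.0
    else:
        t = cfg.t_start

    moves = cfg.moves_per_stage or 20 * max(n_on, 1)
    best_score = cur
    best_on = on.copy()
    stall = 0
    min_beads = 10

    for stage in range(cfg.max_stages):
        # refresh the incremental sums to avoid float drift over long runs
        c = np.zeros((n_sites, nq))
        for j in np.nonzero(on)[0]:
            c += sinc_row(j)
        c[np.nonzero(on)[0]] -= 1.0
        i_mod = c[np.nonzero(on)[0]].sum(0) + float(on.sum())
        cur = score_parts(i_mod, n_on, loose_cnt)
        accepted = 0
        stage_best = best_score
        ks = rng.integers(0, n_sites, moves)
        us = rng.random(moves)
        for k, u in zip(ks, us):
            k = int(k)
            if not on[k] and ncount[k] == 0:
                continue  # grow only adjacent to the existing model
            d_i, d_n, d_loose = proposal_delta(k)
            if n_on + d_n < min_beads:
                continue
            new = score_parts(i_mod + d_i, n_on + d_n, loose_cnt + d_loose)
            if new <= cur or u < np.exp(-(new - cur) / t):
                apply_toggle(k)
                cur = score_parts(i_mod, n_on, loose_cnt)
                accepted += 1
                if cur < best_score:
                    best_score = cur
                    best_on = on.copy()
        if accepted == 0:
            if stage == 0:
                raise RuntimeError("annealing failed to accept any move in the first stage")
            break
        # stall counting only once the chain has cooled (low acceptance),
        # otherwise the hot exploration phase triggers premature stops
        cold = accepted < 0.15 * moves
        improved = stage_best - best_score >= cfg.stall_tol * abs(stage_best)
        stall = stall + 1 if (cold and not improved) else 0
        if stall >= cfg.stall_stages:
            break
        t *= cfg.cooling

    def reset_state(config: np.ndarray) -> None:
        nonlocal on, n_on, ncount, loose_cnt, c, i_mod, cur
        on[:] = config
        n_on = int(on.sum())
        ncount = np.array([int(on[nb].sum()) for nb in neighbors])
        loose_cnt = int(((ncount < 3) & on).sum())
        c = np.zeros((n_sites, nq))
        for j in np.nonzero(on)[0]:
            c += sinc_row(j)
        c[np.nonzero(on)[0]] -= 1.0
        i_mod = c[np.nonzero(on)[0]].sum(0) + float(on.sum())
        cur = score_parts(i_mod, n_on, loose_cnt)

    def quench() -> None:
        nonlocal cur
        for _ in range(cfg.quench_passes):
            improved_any = False
            for k in rng.permutation(n_sites):
                k = int(k)
                if not on[k] and ncount[k] == 0:
                    continue
                d_i, d_n, d_loose = proposal_delta(k)
                if n_on + d_n < min_beads:
                    continue
                new = score_parts(i_mod + d_i, n_on + d_n, loose_cnt + d_loose)
                if new < cur - 1e-12:
                    apply_toggle(k)
                    cur = score_parts(i_mod, n_on, loose_cnt)
                    improved_any = True
            if not improved_any:
                break

    def largest_symmetric_component(idx: np.ndarray) -> np.ndarray:
        comps = _components(idx, neighbors)
        if symmetry != "P2":
            return comps[0]
        for comp in comps:
            if set(mate[comp]) == set(comp):
                return comp
        comp = comps[0]
        return np.array(sorted(set(comp) | set(mate[comp])))

    # polish: quench the best configuration, then alternate pruning to the
    # largest connected component with re-quenching (additions grow only next
    # to existing beads, so the model heals back into one compact body)
    reset_state(best_on)
    quench()
    if cur < best_score:
        best_score, best_on = cur, on.copy()
    for _ in range(3):
        idx = np.nonzero(best_on)[0]
        comp = largest_symmetric_component(idx)
        if len(comp) == len(idx):
            break
        pruned = np.zeros(n_sites, dtype=bool)
        pruned[comp] = True
        reset_state(pruned)
        quench()
        best_score, best_on = cur, on.copy()

    final_idx = largest_symmetric_component(np.nonzero(best_on)[0])
    return BeadModel(sites[final_idx], r_bead, symmetry=symmetry)


# ---------------------------------------------------------------------------
# alignment, averaging, NSD


def _principal_frame(coords: np.ndarray) -> np.ndarray:
    """Rotation whose rows are the principal axes (descending variance),
    right-handed, with a deterministic sign convention (third moment, falling
    back to the largest loading) so that alignment is idempotent."""
    c = coords - coords.mean(0)
    cov = c.T @ c / len(c)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    axes = vecs[:, order].T

    def fixed_sign(v: np.ndarray) -> np.ndarray:
        proj = c @ v
        skew = float(np.sum(proj**3))
        if abs(skew) > 1e-9 * (np.abs(proj) ** 3).sum():
            return v if skew > 0 else -v
        lead = v[np.argmax(np.abs(v))]
        return v if lead > 0 else -v

    e1 = fixed_sign(axes[0])
    e2 = fixed_sign(axes[1])
    e3 = np.cross(e1, e2)
    return np.vstack([e1, e2, e3])


_FLIPS = [
    np.diag([1.0, 1.0, 1.0]),
    np.diag([1.0, -1.0, -1.0]),
    np.diag([-1.0, 1.0, -1.0]),
    np.diag([-1.0, -1.0, 1.0]),
]


def align_models(models: list[BeadModel]) -> list[BeadModel]:
    """Center each model, rotate to principal axes, and flip (proper axis-sign
    combinations) to minimize NSD against the first model."""
    if not models:
        raise ValueError("need at least one model")
    out = []
    ref = None
    for m in models:
        c = m.coordinates - m.coordinates.mean(0)
        R = _principal_frame(c)
        c = c @ R.T
        if ref is None:
            aligned = replace(m, coordinates=c)
            ref = aligned
        else:
            best, best_nsd = None, np.inf
            for F in _FLIPS:
                cand = c @ F.T
                v = nsd(replace(m, coordinates=cand), ref)
                if v < best_nsd:
                    best, best_nsd = cand, v
            aligned = replace(m, coordinates=best)
        out.append(aligned)
    return out


def average_models(models: list[BeadModel], occupancy_cut: float = 0.5) -> BeadModel:
    """Lattice-occupancy average of aligned models.

    Bead positions are snapped to cubic cells of the close-packed lattice
    pitch (bead diameter / sqrt 2, which separates all fcc sites exactly);
    cells occupied in at least ``occupancy_cut`` of the models are kept, with
    the occupancy fraction recorded per kept bead.
    """
    if not models:
        raise ValueError("need at least one model")
    if len(models) == 1:
        return models[0].centered()
    r_bead = models[0].bead_radius
    if any(abs(m.bead_radius - r_bead) > 1e-9 for m in models):
        raise ValueError("models must share one bead radius")
    s = 2.0 * r_bead / np.sqrt(2.0)
    origin = models[0].coordinates.min(0)
    cells: dict[tuple[int, int, int], list] = {}
    for im, m in enumerate(models):
        seen = set()
        for xyz in m.coordinates:
            key = tuple(np.round((xyz - origin) / s).astype(int))
            rec = cells.setdefault(key, [set(), []])
            rec[0].add(im)
            rec[1].append(xyz)
            seen.add(key)
    n = len(models)
    coords, occ = [], []
    for key, (who, pos) in cells.items():
        frac = len(who) / n
        if frac >= occupancy_cut:
            coords.append(np.mean(pos, axis=0))
            occ.append(frac)
    if not coords:
        raise ValueError("no cell reaches the occupancy cut; lower occupancy_cut")
    return BeadModel(np.array(coords), r_bead, symmetry=models[0].symmetry, occupancy=np.array(occ))


def _mean_nn(coords: np.ndarray) -> float | None:
    from scipy.spatial import cKDTree

    if len(coords) < 2:
        return None
    d, _ = cKDTree(coords).query(coords, k=2)
    return float(np.mean(d[:, 1]))


def nsd(a: BeadModel, b: BeadModel, spacing: float | None = None) -> float:
    """Normalized spatial discrepancy between two bead models.

    Root-mean-square of cross nearest-neighbour distances, each direction
    normalized by the reference spacing (per-set mean nearest-neighbour
    spacing by default; bead diameter for single-bead sets; or an explicit
    ``spacing``).  Zero for identical sets, symmetric in its arguments.
    """
    from scipy.spatial import cKDTree

    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty model")
    if spacing is not None:
        sa = sb = spacing
    else:
        sa = _mean_nn(a.coordinates) or 2.0 * a.bead_radius
        sb = _mean_nn(b.coordinates) or 2.0 * b.bead_radius
    d_ab, _ = cKDTree(b.coordinates).query(a.coordinates)
    d_ba, _ = cKDTree(a.coordinates).query(b.coordinates)
    return float(np.sqrt(0.5 * (np.mean(d_ab**2) / sa**2 + np.mean(d_ba**2) / sb**2)))


# ---------------------------------------------------------------------------
# PDB-format I/O (one dummy CA atom per bead; occupancy column carries occupancy)


def write_beads_pdb(model: BeadModel, path: str | Path) -> None:
    import gemmi

    st = gemmi.Structure()
    st.name = "bead model"
    mdl = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, (xyz, occ) in enumerate(zip(model.coordinates, model.occupancy), start=1):
        res = gemmi.Residue()
        res.name = "DUM"
        res.seqid = gemmi.SeqId(i, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*xyz)
        atom.occ = float(occ)
        atom.b_iso = float(model.bead_radius)
        res.add_atom(atom)
        chain.add_residue(res)
    mdl.add_chain(chain)
    st.add_model(mdl)
    st.raw_remarks = [f"REMARK bead_radius {model.bead_radius:.3f} symmetry {model.symmetry}"]
    st.write_pdb(str(path))


def read_beads_pdb(path: str | Path, bead_radius: float | None = None, symmetry: str = "P1") -> BeadModel:
    import gemmi

    st = gemmi.read_pdb(str(path))
    coords, occ, radii = [], [], []
    for mdl in st:
        for chain in mdl:
            for res in chain:
                for atom in res:
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    occ.append(atom.occ)
                    radii.append(atom.b_iso)
    if not coords:
        raise ValueError(f"{path}: no atoms")
    r = bead_radius if bead_radius is not None else (float(np.median(radii)) or 1.0)
    return BeadModel(np.array(coords), r, symmetry=symmetry, occupancy=np.array(occ))
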