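"""Occupancy-derived cost surfaces, least-cost corridors and circuit theory.

Habitat cells cost 1 - psi (occupancy probability), non-habitat costs a
configurable multiple, settlements are impermeable. Least-cost paths use
Dijkstra on an 8-connected lattice with sqrt(2)-weighted diagonals; circuit
(isolation-by-resistance) solves use a 4-connected graph Laplacian with
per-edge resistance equal to the mean of the two cell costs, yielding
pairwise effective resistances, current maps and corridor bottlenecks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra
from scipy.sparse.linalg import spsolve

COST_FLOOR = 1e-6


@dataclass
class CostRaster:
    cost: np.ndarray                  # per-cell movement cost, NaN = NODATA
    cell_size_km: float
    impermeable: np.ndarray           # bool; excluded from every graph
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.cost.shape

    def permeable(self) -> np.ndarray:
        return np.isfinite(self.cost) & ~self.impermeable


def build_cost_surface(psi_raster: np.ndarray, landcover: np.ndarray,
                       nonhabitat_multiplier: float = 3.0,
                       habitat_class: int = 1, settlement_class: int = 2,
                       cell_size_km: float = 10.0) -> CostRaster:
    """Cost surface from occupancy probability and a landcover raster.

    Habitat cells cost 1 - psi; other (permeable) landcover costs
    ``nonhabitat_multiplier`` x 1.0, always above any habitat cost;
    settlement cells are impermeable. Rasters must be co-registered.
    """
    psi = np.asarray(psi_raster, dtype=float)
    lc = np.asarray(landcover)
    if psi.shape != lc.shape:
        raise ValueError(f"raster shapes differ: {psi.shape} vs {lc.shape}")
    cost = np.full(psi.shape, float(nonhabitat_multiplier))
    habitat = lc == habitat_class
    cost[habitat] = np.clip(1.0 - psi[habitat], COST_FLOOR, None)
    impermeable = lc == settlement_class
    cost[np.isnan(psi) & habitat] = np.nan
    return CostRaster(cost=cost, cell_size_km=cell_size_km,
                      impermeable=impermeable,
                      provenance={"nonhabitat_multiplier": nonhabitat_multiplier})


# ---------------------------------------------------------------------------
# Lattice graphs
# ---------------------------------------------------------------------------

_NEIGH8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_NEIGH4 = [(-1, 0), (0, -1), (0, 1), (1, 0)]


def _lattice_edges(raster: CostRaster, neighborhood: int):
    """Edge list (i, j, mean cost, step length) over permeable cells."""
    ok = raster.permeable()
    rows, cols = raster.shape
    idx = -np.ones((rows, cols), dtype=int)
    idx[ok] = np.arange(ok.sum())
    cost = np.where(ok, np.clip(raster.cost, COST_FLOOR, None), np.nan)
    offsets = _NEIGH8 if neighborhood == 8 else _NEIGH4
    src, dst, w_cost, w_len = [], [], [], []
    for dr, dc in offsets:
        if (dr, dc) < (0, 0) or (dr == 0 and dc < 0):
            continue  # each undirected edge once
        r0a, r1a = max(0, -dr), min(rows, rows - dr)
        c0a, c1a = max(0, -dc), min(cols, cols - dc)
        a = idx[r0a:r1a, c0a:c1a]
        b = idx[r0a + dr:r1a + dr, c0a + dc:c1a + dc]
        ca = cost[r0a:r1a, c0a:c1a]
        cb = cost[r0a + dr:r1a + dr, c0a + dc:c1a + dc]
        valid = (a >= 0) & (b >= 0)
        step = math.sqrt(2.0) if dr != 0 and dc != 0 else 1.0
        src.append(a[valid])
        dst.append(b[valid])
        w_cost.append(0.5 * (ca[valid] + cb[valid]))
        w_len.append(np.full(valid.sum(), step))
    return (idx, np.concatenate(src), np.concatenate(dst),
            np.concatenate(w_cost), np.concatenate(w_len))


@dataclass
class PathResult:
    cells: list[tuple[int, int]]
    accumulated_cost: float           # least-cost distance (LCPD)
    geographic_length_km: float
    corridor_mask: np.ndarray | None = None
    corridor_cost: float | None = None       # LCCD
    highway_crossings: int | None = None
    flagged: str | None = None

    @property
    def reachable(self) -> bool:
        return math.isfinite(self.accumulated_cost)


def _region_mask(shape, region) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    if isinstance(region, np.ndarray) and region.dtype == bool:
        return region
    for r, c in region:
        mask[r, c] = True
    return mask


def least_cost_path(raster: CostRaster, source, target,
                    road_mask: np.ndarray | None = None,
                    restrict: np.ndarray | None = None) -> PathResult:
    """Least-cost path between two cell regions (Dijkstra, 8-connected).

    Edge weight = mean of the two cell costs x step length (1 or sqrt 2)
    x cell size; region-to-region distance is the minimum over member
    cells. Ties are broken by scipy's deterministic row-major node order.
    """
    work = raster
    if restrict is not None:
        cost = np.where(restrict, raster.cost, np.nan)
        work = CostRaster(cost=cost, cell_size_km=raster.cell_size_km,
                          impermeable=raster.impermeable)
    idx, src, dst, wc, wl = _lattice_edges(work, 8)
    n = int(idx.max()) + 1
    weights = wc * wl * raster.cell_size_km
    g = sparse.csr_matrix(
        (np.concatenate([weights, weights]),
         (np.concatenate([src, dst]), np.concatenate([dst, src]))),
        shape=(n, n))
    smask = _region_mask(raster.shape, source) & work.permeable()
    tmask = _region_mask(raster.shape, target) & work.permeable()
    s_nodes = idx[smask]
    t_nodes = idx[tmask]
    if len(s_nodes) == 0 or len(t_nodes) == 0:
        return PathResult([], math.inf, math.inf, flagged="region impermeable")
    dist, pred, _src_of = dijkstra(g, indices=s_nodes, min_only=True,
                                   return_predecessors=True)
    best_t = t_nodes[np.argmin(dist[t_nodes])]
    if not math.isfinite(dist[best_t]):
        return PathResult([], math.inf, math.inf, flagged="no permeable route")
    # backtrack
    coords = np.argwhere(idx >= 0)
    order = idx[idx >= 0]
    node_rc = np.zeros((n, 2), dtype=int)
    node_rc[order] = coords
    path_nodes = [best_t]
    while pred[path_nodes[-1]] >= 0:
        path_nodes.append(pred[path_nodes[-1]])
    path_nodes.reverse()
    cells = [tuple(node_rc[v]) for v in path_nodes]
    length = 0.0
    crossings = None
    for a, b in zip(cells[:-1], cells[1:]):
        step = math.sqrt(2.0) if a[0] != b[0] and a[1] != b[1] else 1.0
        length += step * raster.cell_size_km
    if road_mask is not None:
        crossings = int(sum(road_mask[r, c] for r, c in cells))
    return PathResult(cells=cells, accumulated_cost=float(dist[best_t]),
                      geographic_length_km=length,
                      highway_crossings=crossings)


def corridor_cost(path: PathResult, raster: CostRaster,
                  buffer_km: float = 1.5) -> PathResult:
    """Buffer a least-cost path into a corridor and recompute its cost.

    The corridor mask holds every cell whose center lies within
    ``buffer_km`` of the path; the corridor cost (LCCD) is the least-cost
    distance recomputed on the graph restricted to the mask, so a cheaper
    parallel route inside the corridor can undercut the raw path cost.
    """
    if not path.cells:
        raise ValueError("empty path cannot be buffered")
    on_path = np.zeros(raster.shape, dtype=bool)
    for r, c in path.cells:
        on_path[r, c] = True
    dist_cells = ndimage.distance_transform_edt(~on_path)
    mask = dist_cells * raster.cell_size_km <= buffer_km
    mask |= on_path
    s, t = path.cells[0], path.cells[-1]
    if not (mask[s] and mask[t]):
        raise ValueError("buffer excludes path endpoints")
    sub = least_cost_path(raster, [s], [t], restrict=mask)
    return PathResult(cells=path.cells,
                      accumulated_cost=path.accumulated_cost,
                      geographic_length_km=path.geographic_length_km,
                      corridor_mask=mask,
                      corridor_cost=sub.accumulated_cost,
                      highway_crossings=path.highway_crossings)


# ---------------------------------------------------------------------------
# Circuit theory
# ---------------------------------------------------------------------------

@dataclass
class ResistanceResult:
    labels: list[str]
    resistance: np.ndarray            # pairwise effective resistance (RD)
    current_maps: dict[tuple[str, str], np.ndarray]
    cumulative_current: np.ndarray | None
    bottlenecks: dict[tuple[str, str], np.ndarray]
    flags: list[str] = field(default_factory=list)


def _circuit_system(raster: CostRaster, regions: dict[str, np.ndarray],
                    neighborhood: int = 4):
    """Laplacian with each source region collapsed to one supernode."""
    idx, src, dst, wc, _wl = _lattice_edges(raster, neighborhood)
    n = int(idx.max()) + 1
    # per-edge resistance: mean cell cost x cell size; conductance inverse
    cond = 1.0 / (wc * raster.cell_size_km)
    node_map = np.arange(n)
    labels = list(regions)
    super_ids = {}
    next_id = n
    for lab in labels:
        mask = _region_mask(raster.shape, regions[lab]) & raster.permeable()
        members = idx[mask]
        if len(members) == 0:
            raise ValueError(f"region {lab} has no permeable cells")
        node_map[members] = next_id
        super_ids[lab] = next_id
        next_id += 1
    # compress ids
    used = np.unique(np.concatenate([node_map[src], node_map[dst]]))
    remap = {old: new for new, old in enumerate(used)}
    m = len(used)
    s2 = np.array([remap[v] for v in node_map[src]])
    d2 = np.array([remap[v] for v in node_map[dst]])
    keep = s2 != d2  # drop intra-supernode edges
    s2, d2, cond = s2[keep], d2[keep], cond[keep]
    g = sparse.coo_matrix((np.concatenate([cond, cond]),
                           (np.concatenate([s2, d2]),
                            np.concatenate([d2, s2]))), shape=(m, m)).tocsr()
    deg = np.asarray(g.sum(axis=1)).ravel()
    lap = sparse.diags(deg) - g
    sup = {lab: remap[sid] for lab, sid in super_ids.items() if sid in remap}
    missing = [lab for lab in labels if lab not in sup]
    return lap.tocsc(), sup, remap, node_map, idx, (s2, d2, cond), missing


def effective_resistance(raster: CostRaster, regions: dict[str, np.ndarray],
                         neighborhood: int = 4,
                         compute_currents: bool = False,
                         bottleneck_percentile: float = 95.0,
                         corridor_masks: dict[tuple[str, str], np.ndarray] | None = None
                         ) -> ResistanceResult:
    """Pairwise effective resistance between regions via Laplacian solves.

    Per-cell conductance is the inverse cost; each region collapses to a
    supernode; for every pair a unit current is injected/extracted and the
    potential difference is the resistance distance. With
    ``compute_currents`` the per-cell current magnitudes and the cells above
    ``bottleneck_percentile`` (within the corridor mask if given) are kept.
    """
    if len(regions) < 2:
        raise ValueError("need at least two regions")
    lap, sup, remap, node_map, idx, edges, missing = _circuit_system(
        raster, regions, neighborhood)
    labels = list(regions)
    k = len(labels)
    rd = np.full((k, k), np.inf)
    np.fill_diagonal(rd, 0.0)
    flags = [f"region {lab} disconnected from graph" for lab in missing]
    current_maps: dict[tuple[str, str], np.ndarray] = {}
    bottlenecks: dict[tuple[str, str], np.ndarray] = {}
    cumulative = None
    m = lap.shape[0]
    s2, d2, cond = edges
    adj = sparse.coo_matrix((np.ones(len(s2)), (s2, d2)), shape=(m, m))
    from scipy.sparse.csgraph import connected_components
    _, comp = connected_components(adj, directed=False)
    for i in range(k):
        for j in range(i + 1, k):
            la, lb = labels[i], labels[j]
            if la not in sup or lb not in sup:
                continue
            a, b = sup[la], sup[lb]
            if comp[a] != comp[b]:
                flags.append(f"disconnected pair {la}-{lb}")
                continue
            ground = a
            keep = np.ones(m, dtype=bool)
            keep[ground] = False
            rhs = np.zeros(m)
            rhs[b] = 1.0
            sub = lap[keep][:, keep]
            try:
                v_red = spsolve(sub.tocsc(), rhs[keep])
            except Exception:
                flags.append(f"singular system for {la}-{lb}")
                continue
            v = np.zeros(m)
            v[keep] = v_red
            if not np.all(np.isfinite(v)):
                flags.append(f"disconnected pair {la}-{lb}")
                continue
            rd[i, j] = rd[j, i] = float(v[b] - v[a])
            if compute_currents:
                i_edge = cond * np.abs(v[s2] - v[d2])
                node_cur = np.zeros(m)
                np.add.at(node_cur, s2, i_edge)
                np.add.at(node_cur, d2, i_edge)
                node_cur *= 0.5
                grid = np.full(raster.shape, np.nan)
                ok = idx >= 0
                cell_nodes = np.array([remap.get(v_, -1)
                                       for v_ in node_map[idx[ok]]])
                vals = np.where(cell_nodes >= 0,
                                node_cur[np.clip(cell_nodes, 0, None)], np.nan)
                grid[ok] = vals
                current_maps[(la, lb)] = grid
                cumulative = grid.copy() if cumulative is None else cumulative + np.nan_to_num(grid)
                sel = grid.copy()
                if corridor_masks and (la, lb) in corridor_masks:
                    sel = np.where(corridor_masks[(la, lb)], sel, np.nan)
                finite = sel[np.isfinite(sel)]
                if len(finite):
                    thr = np.percentile(finite, bottleneck_percentile)
                    bottlenecks[(la, lb)] = np.isfinite(sel) & (sel >= thr)
    return ResistanceResult(labels=labels, resistance=rd,
                            current_maps=current_maps,
                            cumulative_current=cumulative,
                            bottlenecks=bottlenecks, flags=flags)


def current_map_bottlenecks(raster: CostRaster, regions: dict[str, np.ndarray],
                            pair: tuple[str, str], percentile: float = 95.0,
                            corridor_mask: np.ndarray | None = None
                            ) -> tuple[np.ndarray, np.ndarray, float]:
    """Current map for one region pair plus its bottleneck cell set.

    Returns (current map, bottleneck bool mask, effective resistance).
    """
    masks = {pair: corridor_mask} if corridor_mask is not None else None
    res = effective_resistance(raster, {k: regions[k] for k in pair},
                               compute_currents=True,
                               bottleneck_percentile=percentile,
                               corridor_masks=masks)
    key = pair if pair in res.current_maps else (pair[1], pair[0])
    if key not in res.current_maps:
        raise ValueError(f"pair {pair} is disconnected")
    return res.current_maps[key], res.bottlenecks[key], float(res.resistance[0, 1])
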