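"""MAP contact inference on the grid CRF.

The total potential  E(r) = Σ_ij U_ij(r)  decomposes exactly into unary
terms (w_f · f_ij) and one term per grid edge, because each edge {s, t}
appears in exactly two local potentials:

    edge cost(v_s, v_t) = w_g · g_st(v_s, v_t, obs_t) + w_g · g_ts(v_t, v_s, obs_s).

MAP inference minimizes E(r) with sequential tree-reweighted message passing
(TRW-S), which maintains a monotonically non-decreasing lower bound on the
minimum energy and is exact for binary submodular energies; an exhaustive
enumeration oracle is provided for small grids.  Per-cell contact
probabilities for ROC scoring are the local conditionals evaluated against a
conditioning grid (by default, the TRW-S MAP labeling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .crf import ContactGrid, CRFParams, FeatureConfig, ProteinRNAInstance
from .errors import GridSizeError, NumericError
from .training import _Encoded, _g_indices, _state_energies, _uf


@dataclass
class GridEnergy:
    """Unary and per-edge state costs of the decomposed grid energy.

    ``horizontal[i, j, vs, vt]`` is the cost of edge (i,j)-(i,j+1) with the
    left cell in state vs; ``vertical[i, j, vs, vt]`` covers (i,j)-(i+1,j)
    with the upper cell in state vs.
    """

    unary: np.ndarray      # (Np, Nr, 2)
    horizontal: np.ndarray  # (Np, Nr-1, 2, 2)
    vertical: np.ndarray    # (Np-1, Nr, 2, 2)

    def __post_init__(self) -> None:
        if not (
            np.isfinite(self.unary).all()
            and np.isfinite(self.horizontal).all()
            and np.isfinite(self.vertical).all()
        ):
            raise NumericError("grid energy contains non-finite entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.unary.shape[:2]


@dataclass
class TRWSInfo:
    lower_bounds: list[float] = field(default_factory=list)
    energies: list[float] = field(default_factory=list)
    n_iterations: int = 0
    certified_optimal: bool = False


def _edge_cost(w_g, config, enc, v_s, v_t, d_s, m_s, d_t, m_t):
    """w_g·g(v_s, v_t, obs_t) + w_g·g(v_t, v_s, obs_s) for cell arrays."""
    idx1, with_m = _g_indices(config, v_s, np.asarray(v_t), d_t)
    cost = w_g[idx1] + (w_g[idx1 + 1] * m_t if with_m else 0.0)
    idx2, _ = _g_indices(config, v_t, np.asarray(v_s), d_s)
    cost = cost + w_g[idx2] + (w_g[idx2 + 1] * m_s if with_m else 0.0)
    return cost


def build_energy(
    params: CRFParams, config: FeatureConfig, instance: ProteinRNAInstance
) -> GridEnergy:
    """Split Σ_ij U_ij into unary and edge tables (exact for every configuration)."""
    params.check(config)
    enc = _Encoded(instance, config, need_label=False)
    n_p, n_r = instance.shape
    unary = np.stack(
        [_uf(params.w_f, config, enc, 0), _uf(params.w_f, config, enc, 1)], axis=-1
    )
    horizontal = np.zeros((n_p, max(n_r - 1, 0), 2, 2))
    vertical = np.zeros((max(n_p - 1, 0), n_r, 2, 2))
    d, m = enc.d, enc.m
    for vs, vt in product((0, 1), repeat=2):
        if n_r > 1:
            horizontal[:, :, vs, vt] = _edge_cost(
                params.w_g, config, enc, vs, vt,
                d[:, :-1], m[:, :-1], d[:, 1:], m[:, 1:],
            )
        if n_p > 1:
            vertical[:, :, vs, vt] = _edge_cost(
                params.w_g, config, enc, vs, vt,
                d[:-1, :], m[:-1, :], d[1:, :], m[1:, :],
            )
    return GridEnergy(unary=unary, horizontal=horizontal, vertical=vertical)


def energy_of(energy: GridEnergy, grid: ContactGrid | np.ndarray) -> float:
    """Total decomposed energy of a configuration."""
    r = grid.r if isinstance(grid, ContactGrid) else np.asarray(grid)
    n_p, n_r = energy.shape
    total = float(energy.unary[np.arange(n_p)[:, None], np.arange(n_r)[None, :], r].sum())
    if n_r > 1:
        total += float(
            energy.horizontal[
                np.arange(n_p)[:, None], np.arange(n_r - 1)[None, :], r[:, :-1], r[:, 1:]
            ].sum()
        )
    if n_p > 1:
        total += float(
            energy.vertical[
                np.arange(n_p - 1)[:, None], np.arange(n_r)[None, :], r[:-1, :], r[1:, :]
            ].sum()
        )
    return total


def brute_force_map(energy: GridEnergy) -> ContactGrid:
    """Exhaustive MAP for grids of at most 20 cells.

    Configurations are enumerated in lexicographic order of the flattened
    grid; ties resolve to the lexicographically smallest configuration.
    """
    n_p, n_r = energy.shape
    n = n_p * n_r
    if n > 20:
        raise GridSizeError(f"{n_p}x{n_r} grid too large for enumeration")
    codes = np.arange(2 ** n, dtype=np.int64)
    # bit (n-1-pos) of the code = state of flat cell `pos`, so row order of
    # `states` is the lexicographic order of configurations.
    states = (codes[:, None] >> (n - 1 - np.arange(n))[None, :]) & 1
    states = states.astype(np.int8)
    flat_unary = energy.unary.reshape(n, 2)
    totals = flat_unary[np.arange(n)[None, :], states].sum(axis=1, dtype=float)
    grid_states = states.reshape(-1, n_p, n_r)
    for i in range(n_p):
        for j in range(n_r - 1):
            totals += energy.horizontal[i, j][grid_states[:, i, j], grid_states[:, i, j + 1]]
    for i in range(n_p - 1):
        for j in range(n_r):
            totals += energy.vertical[i, j][grid_states[:, i, j], grid_states[:, i + 1, j]]
    best = int(np.argmin(totals))  # first minimum = lexicographically smallest
    return ContactGrid(r=grid_states[best])


def _chain_min(node_costs: list[list[float]], edge_costs: list) -> float:
    """Exact min-energy of a chain by forward dynamic programming."""
    c0, c1 = node_costs[0]
    for k, ec in enumerate(edge_costs):
        n0, n1 = node_costs[k + 1]
        c0, c1 = (
            n0 + min(c0 + ec[0][0], c1 + ec[1][0]),
            n1 + min(c0 + ec[0][1], c1 + ec[1][1]),
        )
    return min(c0, c1)


def trws_map(
    energy: GridEnergy,
    max_iterations: int = 100,
    tol: float = 1e-9,
    return_info: bool = False,
):
    """Sequential tree-reweighted message passing MAP inference.

    Messages are updated in raster order (then in reverse) with edge
    weighting γ from the row/column monotonic-chain decomposition; the lower
    bound is the sum of exact chain minima of the message-reparameterized
    energy and never decreases.  Each sweep decodes a labeling and the best
    one seen (by true energy) is returned; when the bound meets the best
    energy the labeling is certified optimal and iteration stops early.
    """
    n_p, n_r = energy.shape
    unary = energy.unary.tolist()
    hc = energy.horizontal.tolist()
    vc = energy.vertical.tolist()

    info = TRWSInfo()

    if n_p * n_r == 1:
        grid = np.array([[int(np.argmin(energy.unary[0, 0]))]], dtype=np.int8)
        info.certified_optimal = True
        info.lower_bounds.append(float(energy.unary[0, 0].min()))
        info.energies.append(info.lower_bounds[-1])
        result = ContactGrid(r=grid)
        return (result, info) if return_info else result

    # γ_s = 1 / max(#forward neighbors, #backward neighbors) in raster order.
    gamma = [
        [
            1.0
            / max(
                (j < n_r - 1) + (i < n_p - 1),
                (j > 0) + (i > 0),
                1,
            )
            for j in range(n_r)
        ]
        for i in range(n_p)
    ]

    zero = [0.0, 0.0]
    mh_f = [[list(zero) for _ in range(max(n_r - 1, 0))] for _ in range(n_p)]
    mh_b = [[list(zero) for _ in range(max(n_r - 1, 0))] for _ in range(n_p)]
    mv_f = [[list(zero) for _ in range(n_r)] for _ in range(max(n_p - 1, 0))]
    mv_b = [[list(zero) for _ in range(n_r)] for _ in range(max(n_p - 1, 0))]

    def theta_hat(i, j):
        t0, t1 = unary[i][j]
        if j > 0:
            t0 += mh_f[i][j - 1][0]; t1 += mh_f[i][j - 1][1]
        if j < n_r - 1:
            t0 += mh_b[i][j][0]; t1 += mh_b[i][j][1]
        if i > 0:
            t0 += mv_f[i - 1][j][0]; t1 += mv_f[i - 1][j][1]
        if i < n_p - 1:
            t0 += mv_b[i][j][0]; t1 += mv_b[i][j][1]
        return t0, t1

    def pass_sweep(forward: bool):
        rows = range(n_p) if forward else range(n_p - 1, -1, -1)
        for i in rows:
            cols = range(n_r) if forward else range(n_r - 1, -1, -1)
            for j in cols:
                g = gamma[i][j]
                t0, t1 = theta_hat(i, j)
                if forward:
                    if j < n_r - 1:  # message to the right neighbor
                        a0 = g * t0 - mh_b[i][j][0]
                        a1 = g * t1 - mh_b[i][j][1]
                        cost = hc[i][j]
                        m0 = min(a0 + cost[0][0], a1 + cost[1][0])
                        m1 = min(a0 + cost[0][1], a1 + cost[1][1])
                        lo = min(m0, m1)
                        mh_f[i][j][0] = m0 - lo; mh_f[i][j][1] = m1 - lo
                    if i < n_p - 1:  # message to the neighbor below
                        a0 = g * t0 - mv_b[i][j][0]
                        a1 = g * t1 - mv_b[i][j][1]
                        cost = vc[i][j]
                        m0 = min(a0 + cost[0][0], a1 + cost[1][0])
                        m1 = min(a0 + cost[0][1], a1 + cost[1][1])
                        lo = min(m0, m1)
                        mv_f[i][j][0] = m0 - lo; mv_f[i][j][1] = m1 - lo
                else:
                    if j > 0:  # message to the left neighbor
                        a0 = g * t0 - mh_f[i][j - 1][0]
                        a1 = g * t1 - mh_f[i][j - 1][1]
                        cost = hc[i][j - 1]
                        m0 = min(a0 + cost[0][0], a1 + cost[0][1])
                        m1 = min(a0 + cost[1][0], a1 + cost[1][1])
                        lo = min(m0, m1)
                        mh_b[i][j - 1][0] = m0 - lo; mh_b[i][j - 1][1] = m1 - lo
                    if i > 0:  # message to the neighbor above
                        a0 = g * t0 - mv_f[i - 1][j][0]
                        a1 = g * t1 - mv_f[i - 1][j][1]
                        cost = vc[i - 1][j]
                        m0 = min(a0 + cost[0][0], a1 + cost[0][1])
                        m1 = min(a0 + cost[1][0], a1 + cost[1][1])
                        lo = min(m0, m1)
                        mv_b[i - 1][j][0] = m0 - lo; mv_b[i - 1][j][1] = m1 - lo

    def decode(forward: bool) -> np.ndarray:
        grid = np.zeros((n_p, n_r), dtype=np.int8)
        rows = range(n_p) if forward else range(n_p - 1, -1, -1)
        for i in rows:
            cols = range(n_r) if forward else range(n_r - 1, -1, -1)
            for j in cols:
                v0, v1 = unary[i][j]
                if forward:
                    if j > 0:  # decoded left neighbor
                        s = grid[i, j - 1]
                        v0 += hc[i][j - 1][s][0]; v1 += hc[i][j - 1][s][1]
                    if i > 0:  # decoded upper neighbor
                        s = grid[i - 1, j]
                        v0 += vc[i - 1][j][s][0]; v1 += vc[i - 1][j][s][1]
                    if j < n_r - 1:
                        v0 += mh_b[i][j][0]; v1 += mh_b[i][j][1]
                    if i < n_p - 1:
                        v0 += mv_b[i][j][0]; v1 += mv_b[i][j][1]
                else:
                    if j < n_r - 1:
                        s = grid[i, j + 1]
                        v0 += hc[i][j][0][s]; v1 += hc[i][j][1][s]
                    if i < n_p - 1:
                        s = grid[i + 1, j]
                        v0 += vc[i][j][0][s]; v1 += vc[i][j][1][s]
                    if j > 0:
                        v0 += mh_f[i][j - 1][0]; v1 += mh_f[i][j - 1][1]
                    if i > 0:
                        v0 += mv_f[i - 1][j][0]; v1 += mv_f[i - 1][j][1]
                grid[i, j] = 0 if v0 <= v1 else 1
        return grid

    def lower_bound() -> float:
        # Reparameterized node and edge costs; rows and columns are the
        # monotonic chains, each node split between its row and its column.
        row_w = 0.5 if (n_p > 1 and n_r > 1) else 1.0
        col_w = 0.5 if (n_p > 1 and n_r > 1) else 1.0
        t = [[theta_hat(i, j) for j in range(n_r)] for i in range(n_p)]
        bound = 0.0
        if n_r > 1:
            for i in range(n_p):
                nodes = [(row_w * t[i][j][0], row_w * t[i][j][1]) for j in range(n_r)]
                edges = []
                for j in range(n_r - 1):
                    c = hc[i][j]
                    edges.append(
                        [
                            [c[0][0] - mh_f[i][j][0] - mh_b[i][j][0],
                             c[0][1] - mh_f[i][j][1] - mh_b[i][j][0]],
                            [c[1][0] - mh_f[i][j][0] - mh_b[i][j][1],
                             c[1][1] - mh_f[i][j][1] - mh_b[i][j][1]],
                        ]
                    )
                bound += _chain_min(nodes, edges)
        if n_p > 1:
            for j in range(n_r):
                nodes = [(col_w * t[i][j][0], col_w * t[i][j][1]) for i in range(n_p)]
                edges = []
                for i in range(n_p - 1):
                    c = vc[i][j]
                    edges.append(
                        [
                            [c[0][0] - mv_f[i][j][0] - mv_b[i][j][0],
                             c[0][1] - mv_f[i][j][1] - mv_b[i][j][0]],
                            [c[1][0] - mv_f[i][j][0] - mv_b[i][j][1],
                             c[1][1] - mv_f[i][j][1] - mv_b[i][j][1]],
                        ]
                    )
                bound += _chain_min(nodes, edges)
        return bound

    best_grid = None
    best_energy = np.inf
    prev_bound = -np.inf
    stall = 0
    def _viterbi(nodes, edges):
        """Exact two-state chain argmin; ties prefer state 0."""
        n = len(nodes)
        c = [nodes[0][0], nodes[0][1]]
        back = []
        for k in range(1, n):
            ec = edges[k - 1]
            cand0 = (c[0] + ec[0][0], c[1] + ec[1][0])
            cand1 = (c[0] + ec[0][1], c[1] + ec[1][1])
            b0 = 0 if cand0[0] <= cand0[1] else 1
            b1 = 0 if cand1[0] <= cand1[1] else 1
            back.append((b0, b1))
            c = [nodes[k][0] + cand0[b0], nodes[k][1] + cand1[b1]]
        state = 0 if c[0] <= c[1] else 1
        out = [state]
        for k in range(n - 2, -1, -1):
            state = back[k][state]
            out.append(state)
        out.reverse()
        return out

    def decode_rows(top_down: bool) -> np.ndarray:
        """Assign whole rows by exact chain DP given already-decoded rows;
        vertical edges toward undecoded rows enter through their messages."""
        grid = np.zeros((n_p, n_r), dtype=np.int8)
        rows = range(n_p) if top_down else range(n_p - 1, -1, -1)
        for i in rows:
            nodes = []
            for j in range(n_r):
                v0, v1 = unary[i][j]
                if top_down:
                    if i > 0:
                        s = grid[i - 1, j]
                        v0 += vc[i - 1][j][s][0]; v1 += vc[i - 1][j][s][1]
                    if i < n_p - 1:
                        v0 += mv_b[i][j][0]; v1 += mv_b[i][j][1]
                else:
                    if i < n_p - 1:
                        s = grid[i + 1, j]
                        v0 += vc[i][j][0][s]; v1 += vc[i][j][1][s]
                    if i > 0:
                        v0 += mv_f[i - 1][j][0]; v1 += mv_f[i - 1][j][1]
                nodes.append((v0, v1))
            grid[i, :] = _viterbi(nodes, hc[i])
        return grid

    def decode_cols(left_right: bool) -> np.ndarray:
        grid = np.zeros((n_p, n_r), dtype=np.int8)
        cols = range(n_r) if left_right else range(n_r - 1, -1, -1)
        for j in cols:
            nodes = []
            for i in range(n_p):
                v0, v1 = unary[i][j]
                if left_right:
                    if j > 0:
                        s = grid[i, j - 1]
                        v0 += hc[i][j - 1][s][0]; v1 += hc[i][j - 1][s][1]
                    if j < n_r - 1:
                        v0 += mh_b[i][j][0]; v1 += mh_b[i][j][1]
                else:
                    if j < n_r - 1:
                        s = grid[i, j + 1]
                        v0 += hc[i][j][0][s]; v1 += hc[i][j][1][s]
                    if j > 0:
                        v0 += mh_f[i][j - 1][0]; v1 += mh_f[i][j - 1][1]
                nodes.append((v0, v1))
            edges = [vc[i][j] for i in range(n_p - 1)]
            grid[:, j] = _viterbi(nodes, edges)
        return grid

    def consider(grid):
        nonlocal best_energy, best_grid
        e = energy_of(energy, grid)
        if e < best_energy - 1e-15 or best_grid is None:
            best_energy, best_grid = e, grid

    proposals: list[np.ndarray] = []

    def harvest():
        proposals.clear()
        for grid in (
            decode(forward=True),
            decode(forward=False),
            decode_rows(top_down=True),
            decode_rows(top_down=False),
            decode_cols(left_right=True),
            decode_cols(left_right=False),
        ):
            proposals.append(grid)
            consider(grid)

    def fuse_proposals(limit: int = 12):
        """Exhaustive search over the ambiguous cells, conditioned on the best
        labeling elsewhere.

        Ambiguous cells are those where the decode proposals disagree or
        where the reweighted min-marginals γ·θ̂ are (near-)tied — at a TRW-S
        fixed point the tied cells are exactly where the underlying LP
        relaxation can go fractional, so the message passing cannot decide
        them and an explicit search is warranted.
        """
        if not proposals:
            return
        stack = np.stack(proposals + [best_grid])
        ambiguous = stack.min(axis=0) != stack.max(axis=0)
        scale = float(np.abs(energy.unary).mean() + 1.0)
        tau = 1e-6 * scale
        for i in range(n_p):
            for j in range(n_r):
                t0, t1 = theta_hat(i, j)
                if gamma[i][j] * abs(t0 - t1) <= tau:
                    ambiguous[i, j] = True
        cells = np.argwhere(ambiguous)
        k = len(cells)
        if k == 0 or k > limit:
            return
        base = best_grid.copy()
        for code in range(2 ** k):
            for t, (i, j) in enumerate(cells):
                base[i, j] = (code >> t) & 1
            consider(base.copy())

    for it in range(1, max_iterations + 1):
        pass_sweep(forward=True)
        harvest()
        pass_sweep(forward=False)
        harvest()
        bound = lower_bound()
        info.lower_bounds.append(bound)
        info.energies.append(best_energy)
        info.n_iterations = it
        if best_energy - bound <= tol:
            info.certified_optimal = True
            break
        if bound - prev_bound <= tol:
            stall += 1
            if stall >= 2:
                break
        else:
            stall = 0
        prev_bound = bound

    if not info.certified_optimal:
        fuse_proposals()
        if best_energy - info.lower_bounds[-1] <= tol:
            info.certified_optimal = True

    result = ContactGrid(r=best_grid)
    return (result, info) if return_info else result


def score_grid(
    params: CRFParams,
    config: FeatureConfig,
    instance: ProteinRNAInstance,
    conditioning: ContactGrid | None = None,
    max_iterations: int = 50,
) -> np.ndarray:
    """Per-cell contact probabilities Pr(r_ij = 1 | conditioning neighbors).

    The conditioning grid defaults to the TRW-S MAP labeling under the same
    parameters.  With w_g = 0 the scores are independent of the conditioning.
    """
    params.check(config)
    if conditioning is None:
        conditioning = trws_map(build_energy(params, config, instance), max_iterations)
    enc = _Encoded(instance, config, need_label=False)
    r = conditioning.r.astype(np.int64)
    u0, u1 = _state_energies(params.w_f, params.w_g, config, enc, r)
    # Pr(1) = exp(-u1) / (exp(-u0) + exp(-u1)) = logistic(u0 - u1)
    from scipy.special import expit

    return expit(u0 - u1)
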