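"""Two-point linkage analysis and genetic map construction.

Recombination fractions between CP markers are estimated by maximum
likelihood over the joint two-locus class table.  The hidden variables are
the parental haplotype origins transmitted at the two loci; a parent is
*informative* for a pair when it is heterozygous at both loci, and each
informative parent contributes one meiosis whose recombination indicator
has prior (1-r, r).  Phase (coupling/repulsion per informative parent) is
enumerated and the most likely configuration kept.  Fully informative
same-parent pairs (e.g. lmxll x lmxll) reduce to r = min(f, 1-f) with f
the mismatch fraction; mixed and hkxhk x hkxhk pairs are solved by EM over
the class probabilities, treating the ambiguous hk class properly.

Grouping follows the JoinMap-style independence-LOD criterion
(G-squared of the two-locus independence test scaled by 2*ln 10, components
of the graph thresholded at a minimum independence LOD, conventionally
9), after excluding markers with too many missing calls.  Ordering is
a greedy insertion seeded from the most informative linked pair followed by
2-opt segment-reversal polishing of a LOD-weighted least-squares conflict
between map distances and pairwise two-point Kosambi distances.  Maternal
and paternal maps are merged into a consensus through shared hkxhk bridge
markers by monotone (isotonic) piecewise-linear alignment, with a re-group
fallback for group pairs lacking bridges.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import numpy as np
import pandas as pd

from .maputil import kosambi, kosambi_inverse, haldane, haldane_inverse
from .segtype import LMXLL, NNXNP, HKXHK

LN10 = np.log(10.0)

__all__ = [
    "kosambi", "kosambi_inverse", "haldane", "haldane_inverse",
    "RfEstimate", "estimate_rf", "estimate_rf_bulk", "independence_lod_matrix",
    "group_markers", "order_group", "ordering_objective", "build_parental_maps",
    "merge_consensus", "map_summary", "LinkageGroup", "GeneticMap", "rf_matrix",
]


def _mat_het(seg):
    return seg in (LMXLL, HKXHK)


def _pat_het(seg):
    return seg in (NNXNP, HKXHK)


def _ncls(seg):
    return 3 if seg == HKXHK else 2


@lru_cache(maxsize=None)
def _pair_model(st1, st2, phase_m, phase_p):
    """Emission table and recombination flags for one phase configuration.

    Returns ``(E, rec_m, rec_p, n_inf)`` where ``E[s, c]`` is the
    probability of observed class pair c (flattened c1 * K2 + c2) given
    hidden state s, and rec_* flag whether state s involves a recombination
    in that parent's meiosis (0 for a non-informative parent).
    """
    mat_inf = _mat_het(st1) and _mat_het(st2)
    pat_inf = _pat_het(st1) and _pat_het(st2)
    k1, k2 = _ncls(st1), _ncls(st2)

    mat_states = list(itertools.product((0, 1), repeat=2)) if mat_inf else [None]
    pat_states = list(itertools.product((0, 1), repeat=2)) if pat_inf else [None]

    def code(st, a_m, a_p):
        if st == LMXLL:
            return a_m
        if st == NNXNP:
            return a_p
        return a_m + a_p

    E, rec_m, rec_p = [], [], []
    for hm in mat_states:
        for hp in pat_states:
            dist = np.zeros(k1 * k2)
            # allele branches: (value, weight) per parent per locus
            branches = []
            for j, st in enumerate((st1, st2)):
                if _mat_het(st):
                    if mat_inf:
                        phase = 0 if j == 0 else phase_m
                        branches.append([((("m", j), phase ^ hm[j]), 1.0)])
                    else:
                        branches.append([((("m", j), 0), 0.5), ((("m", j), 1), 0.5)])
                if _pat_het(st):
                    if pat_inf:
                        phase = 0 if j == 0 else phase_p
                        branches.append([((("p", j), phase ^ hp[j]), 1.0)])
                    else:
                        branches.append([((("p", j), 0), 0.5), ((("p", j), 1), 0.5)])
            for combo in itertools.product(*branches):
                alleles = {key: val for (key, val), _ in combo}
                weight = np.prod([w for _, w in combo])
                c1 = code(st1, alleles.get(("m", 0), 0), alleles.get(("p", 0), 0))
                c2 = code(st2, alleles.get(("m", 1), 0), alleles.get(("p", 1), 0))
                dist[c1 * k2 + c2] += weight
            E.append(dist)
            rec_m.append(0 if hm is None else int(hm[0] != hm[1]))
            rec_p.append(0 if hp is None else int(hp[0] != hp[1]))
    return np.array(E), np.array(rec_m, dtype=float), np.array(rec_p, dtype=float), int(mat_inf) + int(pat_inf)


@dataclass
class RfEstimate:
    """Two-point estimate between a marker pair."""

    r: float
    lod: float
    ind_lod: float
    phase: tuple  # (maternal, paternal) in {"coupling", "repulsion", None}
    usable: bool
    n_joint: int

    def __post_init__(self):
        if self.usable and not (-1e-9 <= self.r <= 0.5 + 1e-9):
            raise ValueError("recombination fraction outside [0, 0.5]")


def _count_tables(codes, pairs_i, pairs_j, k1, k2):
    c1 = codes[pairs_i]
    c2 = codes[pairs_j]
    joint = (c1 >= 0) & (c2 >= 0)
    T = np.empty((len(pairs_i), k1 * k2), dtype=float)
    for a in range(k1):
        for b in range(k2):
            T[:, a * k2 + b] = ((c1 == a) & (c2 == b) & joint).sum(axis=1)
    return T, joint.sum(axis=1)


def _prior(r, rec_m, rec_p, mat_inf, pat_inf):
    """State priors (P, S) as a function of r (P,)."""
    r = r[:, None]
    pm = rec_m[None, :] * r + (1 - rec_m[None, :]) * (1 - r) if mat_inf else 1.0
    pp = rec_p[None, :] * r + (1 - rec_p[None, :]) * (1 - r) if pat_inf else 1.0
    norm = 0.25 if (mat_inf and pat_inf) else 0.5
    return norm * pm * pp


def _loglik(T, prior, E):
    probs = prior @ E
    return np.where(T > 0, T * np.log(np.maximum(probs, 1e-300)), 0.0).sum(axis=1)


def estimate_rf_bulk(codes, seg_types, pairs_i, pairs_j, min_joint: int = 20,
                     max_iter: int = 60):
    """Batched two-point estimation for many marker pairs.

    ``codes`` is the (m, n) CP-code matrix, ``seg_types`` the per-marker
    segregation type, ``pairs_i``/``pairs_j`` index arrays of equal length.
    Returns a dict of arrays: r, lod, phase_m, phase_p, usable, n_joint.
    Pairs sharing no informative meiosis (e.g. lmxll x nnxnp) or with fewer
    than ``min_joint`` joint observations are flagged unusable.
    """
    pairs_i = np.asarray(pairs_i)
    pairs_j = np.asarray(pairs_j)
    P = len(pairs_i)
    seg_types = np.asarray(seg_types, dtype=object)
    r_out = np.full(P, np.nan)
    lod_out = np.zeros(P)
    ph_m = np.full(P, -1, dtype=np.int8)
    ph_p = np.full(P, -1, dtype=np.int8)
    usable = np.zeros(P, dtype=bool)
    n_joint_out = np.zeros(P, dtype=np.int64)

    st_i = seg_types[pairs_i]
    st_j = seg_types[pairs_j]
    for st1, st2 in itertools.product((LMXLL, NNXNP, HKXHK), repeat=2):
        sel = np.flatnonzero((st_i == st1) & (st_j == st2))
        if len(sel) == 0:
            continue
        mat_inf = _mat_het(st1) and _mat_het(st2)
        pat_inf = _pat_het(st1) and _pat_het(st2)
        k1, k2 = _ncls(st1), _ncls(st2)
        T, n_joint = _count_tables(codes, pairs_i[sel], pairs_j[sel], k1, k2)
        n_joint_out[sel] = n_joint
        if not (mat_inf or pat_inf):
            continue
        ok = n_joint >= min_joint
        usable[sel] = ok

        phase_opts = list(itertools.product((0, 1) if mat_inf else (-1,),
                                            (0, 1) if pat_inf else (-1,)))
        best_ll = np.full(len(sel), -np.inf)
        best_r = np.full(len(sel), np.nan)
        best_pm = np.full(len(sel), -1, dtype=np.int8)
        best_pp = np.full(len(sel), -1, dtype=np.int8)
        ll_half = None
        for pm_cfg, pp_cfg in phase_opts:
            E, rec_m, rec_p, n_inf = _pair_model(st1, st2, max(pm_cfg, 0), max(pp_cfg, 0))
            r = np.full(len(sel), 0.25)
            denom = np.maximum(n_joint, 1) * n_inf
            for _ in range(max_iter):
                prior = _prior(r, rec_m, rec_p, mat_inf, pat_inf)
                probs = prior @ E
                W = np.where(T > 0, T / np.maximum(probs, 1e-300), 0.0)
                Npost = prior * (W @ E.T)
                num = Npost @ rec_m + Npost @ rec_p
                r = np.clip(num / denom, 0.0, 0.4999)
            prior = _prior(r, rec_m, rec_p, mat_inf, pat_inf)
            ll = _loglik(T, prior, E)
            if ll_half is None:
                half = np.full(len(sel), 0.5)
                ll_half = _loglik(T, _prior(half, rec_m, rec_p, mat_inf, pat_inf), E)
            better = ll > best_ll + 1e-12
            best_ll = np.where(better, ll, best_ll)
            best_r = np.where(better, r, best_r)
            best_pm = np.where(better, pm_cfg, best_pm)
            best_pp = np.where(better, pp_cfg, best_pp)
        r_out[sel] = np.minimum(best_r, 0.5)
        lod_out[sel] = np.maximum((best_ll - ll_half) / LN10, 0.0)
        ph_m[sel] = best_pm
        ph_p[sel] = best_pp
    return {
        "r": r_out,
        "lod": lod_out,
        "phase_m": ph_m,
        "phase_p": ph_p,
        "usable": usable,
        "n_joint": n_joint_out,
    }


def _phase_name(code):
    return {0: "coupling", 1: "repulsion"}.get(int(code), None)


def estimate_rf(codes1, codes2, seg1: str, seg2: str, min_joint: int = 20) -> RfEstimate:
    """Two-point estimate for one marker pair (wrapper over the bulk path).

    ``codes1``/``codes2`` are CP-code vectors over the same progeny.
    """
    codes = np.vstack([codes1, codes2]).astype(np.int8)
    res = estimate_rf_bulk(codes, [seg1, seg2], [0], [1], min_joint=min_joint)
    ind = independence_lod_matrix(codes, [seg1, seg2], min_joint=0)[0, 1]
    return RfEstimate(
        r=float(res["r"][0]),
        lod=float(res["lod"][0]),
        ind_lod=float(ind),
        phase=(_phase_name(res["phase_m"][0]), _phase_name(res["phase_p"][0])),
        usable=bool(res["usable"][0]),
        n_joint=int(res["n_joint"][0]),
    )


def independence_lod_matrix(codes, seg_types=None, min_joint: int = 20):
    """Independence LOD (G-squared / (2 ln 10)) for every marker pair.

    Vectorised over the full pair matrix via one-hot count products; pairs
    with fewer than ``min_joint`` joint observations score 0.
    """
    codes = np.asarray(codes)
    m = codes.shape[0]
    I = [(codes == c).astype(np.float32) for c in range(3)]
    C = {(a, b): I[a] @ I[b].T for a in range(3) for b in range(3)}
    n_joint = sum(C.values())
    R = [sum(C[(a, b)] for b in range(3)) for a in range(3)]
    S = [sum(C[(a, b)] for a in range(3)) for b in range(3)]
    G2 = np.zeros((m, m), dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        for a in range(3):
            for b in range(3):
                O = C[(a, b)]
                term = O * np.log(O * n_joint / np.maximum(R[a] * S[b], 1e-300))
                G2 += np.where(O > 0, term, 0.0)
    G2 = np.maximum(2.0 * G2, 0.0)
    out = G2 / (2.0 * LN10)
    out[n_joint < min_joint] = 0.0
    np.fill_diagonal(out, 0.0)
    return out


def group_markers(codes, seg_types, ind_lod_min: float = 9.0, max_missing: int = 9,
                  min_joint: int = 20, ladder=range(2, 31)):
    """Partition markers into linkage groups.

    Markers with more than ``max_missing`` missing calls are excluded
    first; the remaining markers are grouped as connected components of
    the graph with edges where the independence LOD is >= ``ind_lod_min``
    (study threshold 9).  Returns ``(groups, excluded, ladder_report)``
    where groups are index arrays sorted by size and the ladder report
    lists the component count across the whole threshold range (2..30)
    for diagnostics.
    """
    codes = np.asarray(codes)
    missing = (codes < 0).sum(axis=1)
    included = np.flatnonzero(missing <= max_missing)
    excluded = np.flatnonzero(missing > max_missing)
    if len(included) == 0:
        return [], excluded, pd.DataFrame(columns=["ind_lod_min", "n_groups"])
    sub = codes[included]
    ind = independence_lod_matrix(sub, None, min_joint=min_joint)

    def components(threshold):
        g = nx.Graph()
        g.add_nodes_from(range(len(included)))
        ii, jj = np.nonzero(np.triu(ind >= threshold, k=1))
        g.add_edges_from(zip(ii.tolist(), jj.tolist()))
        return [np.sort(included[list(comp)]) for comp in nx.connected_components(g)]

    ladder_report = pd.DataFrame(
        {"ind_lod_min": list(ladder), "n_groups": [len(components(t)) for t in ladder]}
    )
    groups = components(ind_lod_min)
    groups.sort(key=len, reverse=True)
    return groups, excluded, ladder_report


def ordering_objective(order, d, w):
    """LOD-weighted least-squares conflict between the map implied by an
    order (positions = cumulative adjacent two-point distances) and all
    pairwise two-point distances."""
    order = np.asarray(order)
    adj = d[order[:-1], order[1:]]
    cum = np.concatenate(([0.0], np.cumsum(adj)))
    if len(order) == d.shape[0]:
        pos = np.empty(len(order))
        pos[order] = cum
        D = np.abs(pos[:, None] - pos[None, :])
        # d, w are symmetric with zero diagonal: sum the full matrix and halve
        return float(0.5 * (w * (D - d) ** 2).sum())
    D = np.abs(cum[:, None] - cum[None, :])
    dd = d[order][:, order]
    ww = w[order][:, order]
    return float(0.5 * (ww * (D - dd) ** 2).sum())


def order_group(r, lod, usable=None, min_lod: float = 3.0, r_cap: float = 0.49,
                max_passes: int = 10):
    """Order one linkage group from its pairwise estimates.

    Greedy insertion seeded from the most informative linked pair, each
    next marker (strongest remaining linkage to the placed set) inserted at
    the objective-minimising position, then 2-opt segment-reversal
    polishing.  Pairs below ``min_lod`` ("weak linkages") get weight zero.
    Returns ``(order, positions, warnings)``.
    """
    r = np.asarray(r, dtype=float)
    m = r.shape[0]
    lod = np.asarray(lod, dtype=float)
    if usable is None:
        usable = np.isfinite(r)
    w = np.where(usable & (lod >= min_lod), lod, 0.0)
    np.fill_diagonal(w, 0.0)
    d = kosambi(np.clip(np.nan_to_num(r, nan=0.5), 0.0, r_cap))
    warnings = []
    if m == 1:
        return np.array([0]), np.array([0.0]), warnings
    if not (w > 0).any():
        warnings.append("no linked pairs; arbitrary order")
        order = np.arange(m)
        return order, np.concatenate([[0.0], np.cumsum(d[order[:-1], order[1:]])]), warnings

    i0, j0 = np.unravel_index(np.argmax(w), w.shape)
    order = [int(i0), int(j0)]
    placed = set(order)
    remaining = [k for k in range(m) if k not in placed]
    while remaining:
        link = [w[k, order].max() for k in remaining]
        pick = int(np.argmax(link))
        k = remaining.pop(pick)
        if link[pick] <= 0:
            warnings.append(f"marker index {k} not linked to its group; appended")
            order.append(k)
            placed.add(k)
            continue
        best, best_obj = None, np.inf
        for p in range(len(order) + 1):
            cand = order[:p] + [k] + order[p:]
            obj = ordering_objective(cand, d, w)
            if obj < best_obj - 1e-12:
                best, best_obj = cand, obj
        order = best
        placed.add(k)

    order = np.asarray(order)
    best_obj = ordering_objective(order, d, w)
    for _ in range(max_passes):
        improved = False
        # 2-opt: segment reversals
        for i in range(m - 1):
            for j in range(i + 1, m):
                cand = order.copy()
                cand[i:j + 1] = cand[i:j + 1][::-1]
                obj = ordering_objective(cand, d, w)
                if obj < best_obj - 1e-9:
                    order, best_obj = cand, obj
                    improved = True
        # or-opt: relocate short segments (reversals alone cannot move a
        # misplaced block past its neighbours)
        for seg in (1, 2, 3):
            if m <= seg + 1:
                continue
            for i in range(m - seg + 1):
                rest = np.concatenate([order[:i], order[i + seg:]])
                block = order[i:i + seg]
                for p in range(len(rest) + 1):
                    if p == i:
                        continue
                    cand = np.concatenate([rest[:p], block, rest[p:]])
                    obj = ordering_objective(cand, d, w)
                    if obj < best_obj - 1e-9:
                        order, best_obj = cand, obj
                        improved = True
                        break
        if not improved:
            break
    adj = d[order[:-1], order[1:]]
    positions = np.concatenate([[0.0], np.cumsum(adj)])
    return order, positions, warnings


@dataclass
class LinkageGroup:
    """Ordered markers with cM positions (0 at the first marker)."""

    id: str
    markers: list  # marker ids
    positions: np.ndarray
    kind: str = ""
    weights: np.ndarray = None  # per-marker summed pairwise LOD (ordering evidence)
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.positions) and abs(self.positions[0]) > 1e-9:
            raise ValueError("first position must be 0")
        if np.any(np.diff(self.positions) < -1e-9):
            raise ValueError("positions must be non-decreasing")

    def __len__(self):
        return len(self.markers)

    @property
    def length(self):
        return float(self.positions[-1]) if len(self.positions) else 0.0


@dataclass
class GeneticMap:
    kind: str  # maternal | paternal | consensus
    groups: list
    provenance: dict = field(default_factory=dict)

    def frame(self):
        rows = []
        for g in self.groups:
            for mk, pos in zip(g.markers, g.positions):
                rows.append((mk, g.id, float(pos)))
        return pd.DataFrame(rows, columns=["marker", "lg", "cM"])

    def group(self, lg_id):
        for g in self.groups:
            if g.id == lg_id:
                return g
        raise KeyError(lg_id)

    def marker_positions(self):
        return {mk: (g.id, float(p)) for g in self.groups for mk, p in zip(g.markers, g.positions)}


def _chrom_majority_name(chroms):
    vals, counts = np.unique(np.asarray(chroms, dtype=object), return_counts=True)
    top = str(vals[np.argmax(counts)])
    digits = "".join(ch for ch in top if ch.isdigit())
    return f"LG{digits}" if digits else f"LG_{top}"


def _build_map(bins, indices, kind, ind_lod_min, max_missing, min_joint, min_lod):
    codes = bins.codes[indices]
    seg = bins.df["seg_set"].to_numpy()[indices]
    ids = bins.df["id"].to_numpy()[indices]
    chroms = bins.df["chrom"].to_numpy()[indices]
    groups_idx, excluded, ladder = group_markers(codes, seg, ind_lod_min, max_missing, min_joint)
    lgs = []
    for gi in groups_idx:
        ii, jj = np.triu_indices(len(gi), k=1)
        res = estimate_rf_bulk(codes[gi], seg[gi], ii, jj, min_joint=min_joint)
        rmat = np.full((len(gi), len(gi)), np.nan)
        lmat = np.zeros((len(gi), len(gi)))
        umat = np.zeros((len(gi), len(gi)), dtype=bool)
        rmat[ii, jj] = rmat.T[ii, jj] = res["r"]
        lmat[ii, jj] = lmat.T[ii, jj] = res["lod"]
        umat[ii, jj] = umat.T[ii, jj] = res["usable"]
        order, positions, warn = order_group(rmat, lmat, umat, min_lod=min_lod)
        weights = np.where(umat, lmat, 0.0).sum(axis=1)[order]
        lgs.append(
            LinkageGroup(
                id=_chrom_majority_name(chroms[gi][order]),
                markers=ids[gi][order].tolist(),
                positions=positions,
                kind=kind,
                weights=weights,
                warnings=warn,
            )
        )
    # disambiguate duplicate LG names (two components with the same majority chromosome)
    seen = {}
    for lg in sorted(lgs, key=lambda g: -len(g.markers)):
        if lg.id in seen:
            seen[lg.id] += 1
            lg.id = f"{lg.id}.{seen[lg.id]}"
        else:
            seen[lg.id] = 1
    lgs.sort(key=lambda g: g.id)
    return GeneticMap(kind=kind, groups=lgs, provenance={
        "ind_lod_min": ind_lod_min, "max_missing": max_missing,
        "min_joint": min_joint, "min_lod": min_lod,
        "excluded_markers": int(len(excluded)), "ladder": ladder.to_dict("list"),
    })


def build_parental_maps(bins, ind_lod_min: float = 9.0, max_missing: int = 9,
                        min_joint: int = 20, min_lod: float = 3.0):
    """Build the maternal map from {lmxll, hkxhk} bins and the paternal map
    from {nnxnp, hkxhk} bins (hkxhk contributes through its partially
    informative classes)."""
    seg = bins.df["seg_set"].to_numpy()
    maternal_idx = np.flatnonzero((seg == LMXLL) | (seg == HKXHK))
    paternal_idx = np.flatnonzero((seg == NNXNP) | (seg == HKXHK))
    maternal = (
        _build_map(bins, maternal_idx, "maternal", ind_lod_min, max_missing, min_joint, min_lod)
        if len(maternal_idx)
        else GeneticMap("maternal", [])
    )
    paternal = (
        _build_map(bins, paternal_idx, "paternal", ind_lod_min, max_missing, min_joint, min_lod)
        if len(paternal_idx)
        else GeneticMap("paternal", [])
    )
    return maternal, paternal


def _isotonic(y, w=None):
    """Pool-adjacent-violators: non-decreasing fit to y."""
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if w is None else np.asarray(w, dtype=float)
    level, weight, count = [], [], []
    for yi, wi in zip(y, w):
        level.append(yi)
        weight.append(wi)
        count.append(1)
        while len(level) > 1 and level[-2] > level[-1]:
            tot = weight[-1] + weight[-2]
            level[-2] = (level[-2] * weight[-2] + level[-1] * weight[-1]) / tot
            weight[-2] = tot
            count[-2] += count[-1]
            level.pop()
            weight.pop()
            count.pop()
    return np.repeat(level, count)


def _project(x_from, x_anchor, y_anchor):
    """Piecewise-linear map through anchor points with end-slope extrapolation."""
    x_anchor = np.asarray(x_anchor, dtype=float)
    y_anchor = np.asarray(y_anchor, dtype=float)
    # collapse duplicate abscissae
    ux, inv = np.unique(x_anchor, return_inverse=True)
    uy = np.bincount(inv, weights=y_anchor) / np.bincount(inv)
    if len(ux) == 1:
        return np.asarray(x_from, dtype=float) - ux[0] + uy[0]
    out = np.interp(x_from, ux, uy)
    lo_slope = (uy[1] - uy[0]) / (ux[1] - ux[0]) if ux[1] > ux[0] else 1.0
    hi_slope = (uy[-1] - uy[-2]) / (ux[-1] - ux[-2]) if ux[-1] > ux[-2] else 1.0
    x_from = np.asarray(x_from, dtype=float)
    below = x_from < ux[0]
    above = x_from > ux[-1]
    out = np.where(below, uy[0] + (x_from - ux[0]) * lo_slope, out)
    out = np.where(above, uy[-1] + (x_from - ux[-1]) * hi_slope, out)
    return out


def merge_consensus(maternal: GeneticMap, paternal: GeneticMap, bins=None,
                    min_bridges: int = 2, ind_lod_min: float = 9.0,
                    max_missing: int = 9, min_joint: int = 20, min_lod: float = 3.0):
    """Merge parental maps into a consensus map via hkxhk bridge markers.

    Counterpart groups (same LG id, assigned by majority chromosome) with
    at least ``min_bridges`` shared markers are aligned by a monotone
    piecewise-linear (isotonic) fit through the shared-marker position
    pairs; non-bridge paternal markers are projected onto the maternal
    scale and bridge markers get the mean of their two aligned positions.
    Group pairs without enough bridges fall back to jointly re-grouping
    and re-ordering the union of their markers (requires ``bins``).
    Groups with no counterpart are carried through with a warning.
    """
    mat_ids = {g.id: g for g in maternal.groups}
    pat_ids = {g.id: g for g in paternal.groups}
    consensus = []
    for lg_id in sorted(set(mat_ids) | set(pat_ids)):
        mg = mat_ids.get(lg_id)
        pg = pat_ids.get(lg_id)
        if mg is None or pg is None:
            src = mg if pg is None else pg
            lg = LinkageGroup(lg_id, list(src.markers), src.positions - src.positions[0],
                              kind="consensus", weights=src.weights,
                              warnings=[f"no counterpart group for {lg_id}; carried through"])
            consensus.append(lg)
            continue
        shared = [mk for mk in mg.markers if mk in set(pg.markers)]
        if len(shared) >= min_bridges:
            mpos = dict(zip(mg.markers, mg.positions))
            ppos = dict(zip(pg.markers, pg.positions))
            bm = np.array([mpos[mk] for mk in shared])
            bp = np.array([ppos[mk] for mk in shared])
            # each group's cM axis has an arbitrary direction; align the
            # paternal group to the maternal one before the isotonic fit
            if len(shared) >= 2 and np.corrcoef(np.argsort(np.argsort(bm)),
                                                np.argsort(np.argsort(bp)))[0, 1] < 0:
                top = float(pg.positions[-1])
                ppos = {mk: top - p for mk, p in ppos.items()}
                bp = np.array([ppos[mk] for mk in shared])
            order = np.argsort(bm, kind="stable")
            bm = bm[order]
            bp_iso = _isotonic(bp[order])
            # consensus bridge axis: neither parent's recombination events are
            # compressed, so each bridge interval takes the longer parental span
            cons_anchor = np.maximum.accumulate(np.maximum(bm - bm[0], bp_iso - bp_iso[0]))
            mat_proj = dict(zip(mg.markers, _project([mpos[mk] for mk in mg.markers], bm, cons_anchor)))
            pat_proj = dict(zip(pg.markers, _project([ppos[mk] for mk in pg.markers], bp_iso, cons_anchor)))
            entries = {}
            for mk in mg.markers:
                entries[mk] = [mat_proj[mk]]
            for mk in pg.markers:
                entries.setdefault(mk, []).append(pat_proj[mk])
            mrank = {mk: i for i, mk in enumerate(mg.markers)}
            prank = {mk: i for i, mk in enumerate(pg.markers)}
            mw = dict(zip(mg.markers, mg.weights if mg.weights is not None else np.ones(len(mg))))
            pw = dict(zip(pg.markers, pg.weights if pg.weights is not None else np.ones(len(pg))))

            def mean_rank(mk):
                ranks, ws = [], []
                if mk in mrank:
                    ranks.append(mrank[mk])
                    ws.append(mw.get(mk, 1.0))
                if mk in prank:
                    ranks.append(prank[mk])
                    ws.append(pw.get(mk, 1.0))
                return float(np.average(ranks, weights=ws))

            markers = sorted(entries, key=lambda mk: (float(np.mean(entries[mk])), mean_rank(mk)))
            positions = np.array([float(np.mean(entries[mk])) for mk in markers])
            positions = np.maximum.accumulate(positions)
            positions -= positions[0]
            consensus.append(LinkageGroup(lg_id, markers, positions, kind="consensus"))
        else:
            if bins is None:
                raise ValueError(f"group {lg_id} has <{min_bridges} bridges and no bins "
                                 "were supplied for the re-group fallback")
            union = list(dict.fromkeys(list(mg.markers) + list(pg.markers)))
            id_to_idx = {mk: i for i, mk in enumerate(bins.df["id"])}
            idx = np.array([id_to_idx[mk] for mk in union])
            codes = bins.codes[idx]
            seg = bins.df["seg_set"].to_numpy()[idx]
            ii, jj = np.triu_indices(len(idx), k=1)
            res = estimate_rf_bulk(codes, seg, ii, jj, min_joint=min_joint)
            rmat = np.full((len(idx), len(idx)), np.nan)
            lmat = np.zeros_like(rmat)
            umat = np.zeros(rmat.shape, dtype=bool)
            rmat[ii, jj] = rmat.T[ii, jj] = res["r"]
            lmat[ii, jj] = lmat.T[ii, jj] = res["lod"]
            umat[ii, jj] = umat.T[ii, jj] = res["usable"]
            order, positions, warn = order_group(rmat, lmat, umat, min_lod=min_lod)
            consensus.append(
                LinkageGroup(lg_id, [union[k] for k in order], positions, kind="consensus",
                             warnings=warn + ["re-grouped union (bridge fallback)"])
            )
    consensus.sort(key=lambda g: g.id)
    return GeneticMap(kind="consensus", groups=consensus,
                      provenance={"maternal": maternal.provenance, "paternal": paternal.provenance})


def map_summary(gmap: GeneticMap, snp_counts=None) -> pd.DataFrame:
    """Per-group summary mirroring the published map table.

    Average adjacent interval per group = length / (n - 1); the "Average"
    row uses total length / (total markers - number of groups).  If
    ``snp_counts`` (mapping marker id -> member-SNP count) is given, SNP
    totals are included.
    """
    rows = []
    for g in gmap.groups:
        n = len(g)
        rows.append(
            {
                "lg": g.id,
                "n_markers": n,
                "length_cM": round(g.length, 1),
                "avg_interval_cM": g.length / (n - 1) if n > 1 else np.nan,
                "n_snps": int(sum(snp_counts.get(mk, 0) for mk in g.markers)) if snp_counts else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    total_n = int(df["n_markers"].sum())
    total_len = float(df["length_cM"].sum())
    k = len(gmap.groups)
    avg_row = {
        "lg": "Average",
        "n_markers": total_n / k if k else np.nan,
        "length_cM": total_len / k if k else np.nan,
        "avg_interval_cM": total_len / (total_n - k) if total_n > k else np.nan,
        "n_snps": df["n_snps"].sum() / k if snp_counts else np.nan,
    }
    tot_row = {
        "lg": "Total",
        "n_markers": total_n,
        "length_cM": total_len,
        "avg_interval_cM": np.nan,
        "n_snps": df["n_snps"].sum() if snp_counts else np.nan,
    }
    return pd.concat([df, pd.DataFrame([avg_row, tot_row])], ignore_index=True)


def rf_matrix(gmap: GeneticMap, bins, min_joint: int = 20):
    """Pairwise recombination fractions of mapped markers in map order
    (the heat-map diagnostic; low-r blocks should sit on the diagonal)."""
    frame = gmap.frame()
    id_to_idx = {mk: i for i, mk in enumerate(bins.df["id"])}
    idx = np.array([id_to_idx[mk] for mk in frame["marker"]])
    codes = bins.codes[idx]
    seg = bins.df["seg_set"].to_numpy()[idx]
    ii, jj = np.triu_indices(len(idx), k=1)
    res = estimate_rf_bulk(codes, seg, ii, jj, min_joint=min_joint)
    out = np.full((len(idx), len(idx)), np.nan)
    out[ii, jj] = out.T[ii, jj] = res["r"]
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=frame["marker"], columns=frame["marker"])
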