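"""Trait statistics, QTL scanning and heritability for a CP population.

Traits are summarised with small-sample adjusted moments (the SPSS-style
skewness/kurtosis estimators), Shapiro-Wilk normality, between-season
Pearson correlation and one-way ANOVA.  Non-normal traits can be
transformed (ln / sqrt / cubic root / Tukey ladder-of-powers chosen by
Shapiro W).

The scan itself is Haley-Knott style interval mapping for the four-class
pseudo-testcross model: per-progeny transmission probabilities of the four
gamete classes {AC, AD, BC, BD} (maternal x paternal haplotype) are
computed on a cM grid by two independent 2-state hidden Markov chains (one
per parental meiosis, transition = inverse map function of the distance,
emissions from phase-resolved marker codes with a small miscall rate), and
the trait is regressed on the expected class indicators at each grid
point.  LOD = (n/2) log10(RSS0/RSS1); peaks at LOD >= 2.5; support
intervals by the 1- and 2-LOD drop rule; PVE = 100 (1 - RSS1/RSS0).
Non-normalisable traits are scanned marker-wise with the tie-corrected
Kruskal-Wallis test (significance P < .005).

Narrow-sense heritability h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2) is
estimated by REML on a genomic relationship matrix built from the
numerically coded parental-allele indicators of all markers (spectral
decomposition plus a 1-D profile-likelihood search over h2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .maputil import inverse_map
from .segtype import LMXLL, NNXNP, HKXHK

TUKEY_LADDER = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0)
GAMETE_CLASSES = ("AC", "AD", "BC", "BD")


@dataclass
class Trait:
    """A phenotype vector with its distribution summary."""

    name: str
    environment: str
    values: np.ndarray
    n: int = 0
    mean: float = np.nan
    sd: float = np.nan
    skewness: float = np.nan
    kurtosis: float = np.nan
    shapiro_w: float = np.nan
    shapiro_p: float = np.nan
    pearson_r: Optional[float] = None
    pearson_p: Optional[float] = None
    anova_f: Optional[float] = None
    anova_p: Optional[float] = None
    flags: list = field(default_factory=list)

    @property
    def normal(self):
        """Normality call at the conventional Shapiro-Wilk P > .05."""
        return bool(self.shapiro_p > 0.05) if np.isfinite(self.shapiro_p) else False


def trait_stats(values, paired=None, name: str = "", environment: str = "") -> Trait:
    """Distribution summary of one trait, optionally paired with the same
    trait from another environment (year) for Pearson r and one-way ANOVA.

    Moments use the small-sample adjusted (bias-corrected) estimators;
    missing values are ignored (pairwise-complete for the paired stats).
    """
    values = np.asarray(values, dtype=float)
    obs = values[np.isfinite(values)]
    if len(obs) < 3:
        raise ValueError("need at least 3 non-missing values")
    t = Trait(name=name, environment=environment, values=values, n=len(obs))
    t.mean = float(obs.mean())
    t.sd = float(obs.std(ddof=1))
    if t.sd == 0:
        t.flags.append("constant trait; Shapiro-Wilk undefined")
        t.skewness = np.nan
        t.kurtosis = np.nan
    else:
        t.skewness = float(stats.skew(obs, bias=False))
        t.kurtosis = float(stats.kurtosis(obs, bias=False))
        w, p = stats.shapiro(obs)
        t.shapiro_w, t.shapiro_p = float(w), float(p)
    if paired is not None:
        paired = np.asarray(paired, dtype=float)
        both = np.isfinite(values) & np.isfinite(paired)
        if both.sum() >= 3 and values[both].std() > 0 and paired[both].std() > 0:
            r, p = stats.pearsonr(values[both], paired[both])
            t.pearson_r, t.pearson_p = float(r), float(p)
        f, p = stats.f_oneway(obs, paired[np.isfinite(paired)])
        t.anova_f, t.anova_p = float(f), float(p)
    return t


def _power(x, lam):
    if lam == 0.0:
        return np.log(x)
    if lam > 0:
        return x ** lam
    return -(x ** lam)  # sign preserved so order is kept


def transform_trait(values, method: str = "tukey", eps: float = 1e-6):
    """Transform a trait towards normality.

    ``method`` is one of ln / sqrt / curt / tukey / none.  The Tukey option
    picks the ladder-of-powers exponent (lambda in {-2,-1,-1/2,0,1/2,1,2})
    maximising Shapiro-Wilk W.  Values are shifted by |min|+eps when the
    transform needs positive support.  Returns ``(transformed, info)`` with
    the method, chosen lambda and applied shift recorded in ``info``.
    """
    values = np.asarray(values, dtype=float)
    obs_mask = np.isfinite(values)
    if not obs_mask.any():
        raise ValueError("all values missing")
    info = {"method": method, "shift": 0.0, "lambda": None}

    def shifted(need_positive):
        lo = np.nanmin(values)
        bound = 0.0 if need_positive else -0.0
        if (need_positive and lo <= 0) or (not need_positive and lo < 0):
            shift = abs(lo) + eps
            info["shift"] = float(shift)
            return values + shift
        return values

    if method == "none":
        return values.copy(), info
    if method == "ln":
        return np.log(shifted(True)), info
    if method == "sqrt":
        return np.sqrt(shifted(False)), info
    if method == "curt":
        return np.cbrt(values), info
    if method == "tukey":
        x = shifted(True)
        best_w, best_lam, best = -np.inf, None, None
        for lam in TUKEY_LADDER:
            y = _power(x, lam)
            obs = y[obs_mask]
            if not np.all(np.isfinite(obs)) or obs.std() == 0:
                continue
            w, _ = stats.shapiro(obs)
            if w > best_w:
                best_w, best_lam, best = w, lam, y
        info["lambda"] = best_lam
        return best, info
    raise ValueError(f"unknown transform method {method!r}")


# ---------------------------------------------------------------------------
# transmission probabilities

_INFORMATIVE = {"maternal": (LMXLL, HKXHK), "paternal": (NNXNP, HKXHK)}


def infer_phases(seg_types, codes, min_joint: int = 20):
    """Resolve per-marker linkage phases for each parent.

    For each parental meiosis, the relative phase (coupling/repulsion) of
    every informative marker pair comes from the two-point estimate; phases
    are then propagated by XOR over a maximum-spanning tree of the
    pairwise-LOD graph, so each marker is phased through its most reliable
    links rather than a fragile nearest-neighbour chain.  Returns
    ``(phase_m, phase_p)`` int8 arrays (-1 where the parent is uninformative).
    """
    import networkx as nx

    from .linkage import estimate_rf_bulk

    seg_types = np.asarray(seg_types, dtype=object)
    m = len(seg_types)
    out = {}
    for parent, key in (("maternal", "phase_m"), ("paternal", "phase_p")):
        inf_idx = np.flatnonzero(np.isin(seg_types, _INFORMATIVE[parent]))
        phases = np.full(m, -1, dtype=np.int8)
        if len(inf_idx) == 1:
            phases[inf_idx[0]] = 0
        elif len(inf_idx) > 1:
            ii, jj = np.triu_indices(len(inf_idx), k=1)
            res = estimate_rf_bulk(codes, seg_types, inf_idx[ii], inf_idx[jj],
                                   min_joint=min_joint)
            g = nx.Graph()
            g.add_nodes_from(range(len(inf_idx)))
            ok = res["usable"] & (res[key] >= 0) & (res["lod"] > 0)
            for a, b, lod, rel in zip(ii[ok], jj[ok], res["lod"][ok], res[key][ok]):
                g.add_edge(int(a), int(b), weight=float(lod), rel=int(rel))
            tree = nx.maximum_spanning_tree(g)
            local = np.zeros(len(inf_idx), dtype=np.int8)
            for comp in nx.connected_components(tree):
                root = min(comp)
                for parent_node, child in nx.bfs_edges(tree, root):
                    rel = tree.edges[parent_node, child]["rel"]
                    local[child] = local[parent_node] ^ rel
            phases[inf_idx] = local
        out[parent] = phases
    return out["maternal"], out["paternal"]


def _emission_table(seg, phase, eps):
    """P(observed code | chain state s) for one marker, shape (3 codes + missing handled outside, 2 states).

    The chain state s is the haplotype origin in the frame of the group's
    first informative marker; the transmitted allele is s XOR phase.
    """
    out = np.ones((2, 3))
    for s in (0, 1):
        a = s ^ int(phase)
        if seg in (LMXLL, NNXNP):
            out[s, 0] = (1 - eps) if a == 0 else eps
            out[s, 1] = (1 - eps) if a == 1 else eps
            out[s, 2] = 0.0  # code 2 never emitted by a 1:1 marker
        else:  # hkxhk: marginalise the other parent's Bernoulli allele
            for c in range(3):
                p = 0.0
                for other in (0, 1):
                    t = a + other
                    p += 0.5 * ((1 - eps) if c == t else eps / 2)
                out[s, c] = p
    return out


@dataclass
class TransmissionGrid:
    """Per-progeny gamete-class probabilities along one linkage group."""

    lg: str
    grid: np.ndarray  # cM positions
    probs: np.ndarray  # (n_progeny, n_grid, 4) classes AC, AD, BC, BD

    def __post_init__(self):
        total = self.probs.sum(axis=2)
        if not np.allclose(total, 1.0, atol=1e-6):
            raise ValueError("class probabilities must sum to 1")


def _chain_posteriors(marker_pos, emissions, grid, r_fn):
    """Posterior chain-state probabilities at grid positions.

    The hidden chain lives on the markers (transition between consecutive
    markers = r_fn of their distance, matching the no-interference
    crossover process); a grid point between two markers is interpolated
    with single transitions to its flanking markers, so the two-point
    conditional probabilities hold exactly.  ``emissions`` is
    (n_progeny, n_markers, 2); returns (n_progeny, n_grid, 2).
    """
    n = emissions.shape[0]
    M = emissions.shape[1]
    G = len(grid)
    if M == 0:
        return np.full((n, G, 2), 0.5)

    def step(v, r):
        return v * (1 - r) + v[..., ::-1] * r

    rs = r_fn(np.diff(marker_pos)) if M > 1 else np.empty(0)
    # alpha_j: P(state at marker j | obs <= j), includes emission j
    alpha = np.empty((n, M, 2))
    a = np.full((n, 2), 0.5) * emissions[:, 0, :]
    alpha[:, 0, :] = a / np.maximum(a.sum(axis=1, keepdims=True), 1e-300)
    for j in range(1, M):
        a = step(alpha[:, j - 1, :], rs[j - 1]) * emissions[:, j, :]
        alpha[:, j, :] = a / np.maximum(a.sum(axis=1, keepdims=True), 1e-300)
    # b_j ~ P(obs >= j | state at marker j), includes emission j
    b = np.empty((n, M, 2))
    v = emissions[:, M - 1, :].copy()
    b[:, M - 1, :] = v / np.maximum(v.sum(axis=1, keepdims=True), 1e-300)
    for j in range(M - 2, -1, -1):
        v = emissions[:, j, :] * step(b[:, j + 1, :], rs[j])
        b[:, j, :] = v / np.maximum(v.sum(axis=1, keepdims=True), 1e-300)

    post = np.empty((n, G, 2))
    right = np.searchsorted(marker_pos, grid, side="left")
    for k, (g, jr) in enumerate(zip(grid, right)):
        if jr < M and abs(marker_pos[jr] - g) < 1e-9:  # at a marker
            if jr + 1 < M:
                p = alpha[:, jr, :] * step(b[:, jr + 1, :], rs[jr])
            else:
                p = alpha[:, jr, :]
        elif jr == 0:  # before the first marker
            p = step(b[:, 0, :], r_fn(marker_pos[0] - g))
        elif jr == M:  # after the last marker
            p = step(alpha[:, M - 1, :], r_fn(g - marker_pos[M - 1]))
        else:
            left = step(alpha[:, jr - 1, :], r_fn(g - marker_pos[jr - 1]))
            rightward = step(b[:, jr, :], r_fn(marker_pos[jr] - g))
            p = left * rightward
        post[:, k, :] = p / np.maximum(p.sum(axis=1, keepdims=True), 1e-300)
    return post


def transmission_probs(gmap, bins, step_cM: float = 1.0, eps: float = 0.01,
                       map_function: str = "kosambi", min_joint: int = 20):
    """Four-class transmission probability grids for every linkage group.

    ``gmap`` is a :class:`~f1binmap.linkage.GeneticMap` whose markers are
    present in ``bins``; emissions use an ``eps`` per-call miscall rate.
    """
    id_to_idx = {mk: i for i, mk in enumerate(bins.df["id"])}
    grids = []
    for g in gmap.groups:
        missing = [mk for mk in g.markers if mk not in id_to_idx]
        if missing:
            raise ValueError(f"markers absent from bins: {missing[:3]}...")
        idx = np.array([id_to_idx[mk] for mk in g.markers])
        codes = bins.codes[idx]
        seg = bins.df["seg_set"].to_numpy()[idx]
        phase_m, phase_p = infer_phases(seg, codes, min_joint=min_joint)
        n = codes.shape[1]
        grid = np.arange(0.0, g.length + step_cM * 0.5, step_cM)
        if len(grid) == 0 or grid[-1] < g.length - 1e-9:
            grid = np.append(grid, g.length)
        post = {}
        for parent, phases in (("maternal", phase_m), ("paternal", phase_p)):
            inf = np.flatnonzero(phases >= 0)
            # co-located markers share a chain position; their emissions multiply
            mk_pos, slot = np.unique(g.positions[inf], return_inverse=True)
            emissions = np.ones((n, len(mk_pos), 2))
            for j, k in zip(inf, slot):
                table = _emission_table(seg[j], phases[j], eps)
                c = codes[j]
                e = np.ones((n, 2))
                obs = c >= 0
                e[obs, :] = table[:, c[obs]].T
                emissions[:, k, :] *= e
            post[parent] = _chain_posteriors(mk_pos, emissions, grid,
                                             lambda d: inverse_map(d, map_function))
        probs = np.einsum("ngs,ngt->ngst", post["maternal"], post["paternal"]).reshape(
            n, len(grid), 4
        )
        grids.append(TransmissionGrid(lg=g.id, grid=grid, probs=probs))
    return grids


# ---------------------------------------------------------------------------
# scans

@dataclass
class QtlPeak:
    lg: str
    cM: float
    lod: float
    pve: float
    interval_1lod: tuple
    interval_2lod: tuple

    def __post_init__(self):
        if not (self.interval_1lod[0] - 1e-9 <= self.cM <= self.interval_1lod[1] + 1e-9):
            raise ValueError("support interval must contain its peak")


@dataclass
class QtlScanResult:
    frame: pd.DataFrame  # lg, cM, lod, pve
    peaks: list
    trait: str = ""
    environment: str = ""
    kw: Optional[pd.DataFrame] = None


def _drop_interval(grid, lod, peak_idx, drop):
    floor = lod[peak_idx] - drop
    lo = peak_idx
    while lo > 0 and lod[lo - 1] >= floor:
        lo -= 1
    hi = peak_idx
    while hi < len(lod) - 1 and lod[hi + 1] >= floor:
        hi += 1
    return float(grid[lo]), float(grid[hi])


def interval_mapping(trait_values, grids, lod_threshold: float = 2.5,
                     peak_sep_cM: float = 10.0, trait: str = "",
                     environment: str = "") -> QtlScanResult:
    """Haley-Knott regression scan over transmission-probability grids.

    At each grid point the trait is regressed on the expected gamete-class
    probabilities (intercept + 3 contrasts).  Peaks are local maxima with
    LOD >= ``lod_threshold`` separated by at least ``peak_sep_cM``; support
    intervals follow the 1- and 2-LOD drop rule and PVE is the RSS-based
    variance fraction at the peak.
    """
    y = np.asarray(trait_values, dtype=float)
    mask = np.isfinite(y)
    yo = y[mask]
    n = len(yo)
    if n < 8:
        raise ValueError("too few phenotyped progeny")
    rss0 = float(((yo - yo.mean()) ** 2).sum())
    if rss0 == 0:
        raise ValueError("constant trait")
    rows = []
    any_info = False
    for tg in grids:
        X = tg.probs[mask]  # (n, G, 4)
        if np.ptp(X, axis=(0, 1)).max() > 1e-9:
            any_info = True
        for k, pos in enumerate(tg.grid):
            design = np.column_stack([np.ones(n), X[:, k, 1:]])
            coef, _, _, _ = np.linalg.lstsq(design, yo, rcond=None)
            rss1 = float(((yo - design @ coef) ** 2).sum())
            rss1 = min(rss1, rss0)
            lod = (n / 2.0) * np.log10(rss0 / max(rss1, 1e-300))
            pve = 100.0 * (1.0 - rss1 / rss0)
            rows.append((tg.lg, float(pos), float(lod), float(pve)))
    if not any_info:
        raise ValueError("transmission probabilities are degenerate everywhere")
    frame = pd.DataFrame(rows, columns=["lg", "cM", "lod", "pve"])

    peaks = []
    for lg, sub in frame.groupby("lg", sort=False):
        grid = sub["cM"].to_numpy()
        lod = sub["lod"].to_numpy()
        pve = sub["pve"].to_numpy()
        is_max = np.ones(len(grid), dtype=bool)
        if len(grid) > 1:
            is_max[1:] &= lod[1:] >= lod[:-1]
            is_max[:-1] &= lod[:-1] >= lod[1:]
        available = is_max.copy()
        while True:
            cand = np.flatnonzero(available & (lod >= lod_threshold))
            if len(cand) == 0:
                break
            best = cand[np.argmax(lod[cand])]
            i1 = _drop_interval(grid, lod, best, 1.0)
            i2 = _drop_interval(grid, lod, best, 2.0)
            peaks.append(QtlPeak(lg=lg, cM=float(grid[best]), lod=float(lod[best]),
                                 pve=float(pve[best]), interval_1lod=i1, interval_2lod=i2))
            available &= np.abs(grid - grid[best]) >= peak_sep_cM
    peaks.sort(key=lambda p: (-p.lod))
    return QtlScanResult(frame=frame, peaks=peaks, trait=trait, environment=environment)


def kw_scan(trait_values, bins, alpha: float = 0.005) -> pd.DataFrame:
    """Marker-wise tie-corrected Kruskal-Wallis scan.

    Markers with fewer than two genotype classes holding at least two
    observations each are skipped.  ``significant`` applies the strict
    P < ``alpha`` rule (.005 by convention here).
    """
    y = np.asarray(trait_values, dtype=float)
    rows = []
    for i in range(len(bins)):
        codes = bins.codes[i]
        ok = (codes >= 0) & np.isfinite(y)
        groups = [y[ok & (codes == c)] for c in range(3)]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) < 2:
            continue
        pooled = np.concatenate(groups)
        if np.all(pooled == pooled[0]):
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*groups)
        rows.append((bins.df["id"].iloc[i], float(h), len(groups) - 1, float(p), p < alpha))
    return pd.DataFrame(rows, columns=["marker", "H", "df", "pvalue", "significant"])


def permutation_lod_threshold(trait_values, grids, n_perm: int = 200, alpha: float = 0.05,
                              rng=None) -> float:
    """Genome-wide LOD threshold from trait permutations.

    Permuting the trait against the transmission grids preserves the
    marker-correlation structure; the (1-alpha) quantile of the permuted
    genome-wide maximum LOD is the empirical significance threshold.  Off
    by default in the scan (which uses the conventional fixed LOD), but the
    honest choice when family-wise calibration matters.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    y = np.asarray(trait_values, dtype=float).copy()
    maxima = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(y)
        maxima[b] = interval_mapping(perm, grids, lod_threshold=np.inf).frame["lod"].max()
    return float(np.quantile(maxima, 1.0 - alpha))


# ---------------------------------------------------------------------------
# heritability

@dataclass
class Heritability:
    h2: float
    sigma_g2: float
    sigma_e2: float

    def __post_init__(self):
        if not -1e-9 <= self.h2 <= 1.0 + 1e-9:
            raise ValueError("h2 must lie in [0, 1]")


def _allele_design(bins) -> np.ndarray:
    """Centered parental-allele indicator columns for all markers.

    1:1 markers contribute one indicator (the informative parent's
    transmitted allele); hkxhk markers contribute the expected maternal and
    paternal indicators (hh=0, hk=1/2, kk=1 each).  Missing calls are mean
    imputed (i.e. zero after centering).
    """
    cols = []
    seg = bins.df["seg_set"].to_numpy()
    for i in range(len(bins)):
        c = bins.codes[i].astype(float)
        miss = c < 0
        if seg[i] == HKXHK:
            dose = c / 2.0
            for col in (dose.copy(), dose.copy()):
                col[miss] = np.nan
                cols.append(col)
        else:
            c[miss] = np.nan
            cols.append(c)
    Z = np.column_stack(cols)
    mu = np.nanmean(Z, axis=0)
    Z = np.where(np.isnan(Z), mu, Z) - mu
    return Z


def heritability(bins, trait_values, min_progeny: int = 50, min_markers: int = 50) -> Heritability:
    """REML estimate of narrow-sense heritability from a marker-based
    genomic relationship matrix (spectral decomposition + 1-D search)."""
    y = np.asarray(trait_values, dtype=float)
    mask = np.isfinite(y)
    if mask.sum() < min_progeny:
        raise ValueError(f"need >= {min_progeny} phenotyped progeny")
    if len(bins) < min_markers:
        raise ValueError(f"need >= {min_markers} markers")
    Z = _allele_design(bins)[mask]
    y = y[mask]
    n = len(y)
    K = Z @ Z.T
    scale = np.trace(K) / n
    if scale <= 0:
        raise ValueError("degenerate relationship matrix")
    K /= scale
    evals, U = np.linalg.eigh(K)
    evals = np.maximum(evals, 0.0)
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    def crit(h2):
        v = h2 * evals + (1.0 - h2)
        xvx = (xt ** 2 / v).sum()
        beta = (xt * yt / v).sum() / xvx
        resid = yt - xt * beta
        rss = (resid ** 2 / v).sum()
        return (n - 1) * np.log(max(rss, 1e-300)) + np.log(v).sum() + np.log(xvx)

    res = optimize.minimize_scalar(crit, bounds=(0.0, 0.999), method="bounded",
                                   options={"xatol": 1e-6})
    h2 = float(res.x)
    v = h2 * evals + (1.0 - h2)
    xvx = (xt ** 2 / v).sum()
    beta = (xt * yt / v).sum() / xvx
    rss = ((yt - xt * beta) ** 2 / v).sum()
    sigma_tot = rss / (n - 1)
    return Heritability(h2=h2, sigma_g2=float(h2 * sigma_tot), sigma_e2=float((1 - h2) * sigma_tot))


# ---------------------------------------------------------------------------
# cross-environment matching and physical intervals

def qtl_stability(result_a: QtlScanResult, result_b: QtlScanResult, tol_cM: float = 10.0):
    """Greedy nearest pairing of peaks across environments.

    Peaks match when on the same linkage group and strictly closer than
    ``tol_cM``.  Returns a list of ``(peak_a, peak_b, delta_cM)``.
    """
    pairs = []
    for i, pa in enumerate(result_a.peaks):
        for j, pb in enumerate(result_b.peaks):
            if pa.lg == pb.lg:
                delta = abs(pa.cM - pb.cM)
                if delta < tol_cM:
                    pairs.append((delta, i, j))
    pairs.sort(key=lambda t: t[0])
    used_a, used_b, matched = set(), set(), []
    for delta, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((result_a.peaks[i], result_b.peaks[j], float(delta)))
    return matched


def _merge_intervals(iv):
    iv = sorted(iv)
    out = []
    for start, end in iv:
        if out and start <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def qtl_to_physical(result: QtlScanResult, gmap, bins, drop: int = 1,
                    annotation: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Physical genomic intervals (and genes) under each QTL peak.

    Bins whose map position falls inside the ``drop``-LOD support interval
    are mapped to their physical spans; overlapping spans merge.  If an
    ``annotation`` frame (chrom, start, end, gene_id) is supplied, genes
    intersecting each merged interval are listed.
    """
    if drop not in (1, 2):
        raise ValueError("drop must be 1 or 2")
    marker_pos = gmap.marker_positions()
    meta = bins.df.set_index("id")
    rows = []
    for peak in result.peaks:
        lo, hi = peak.interval_1lod if drop == 1 else peak.interval_2lod
        spans = []
        for mk, (lg, pos) in marker_pos.items():
            if lg != peak.lg or not (lo <= pos <= hi):
                continue
            if mk not in meta.index:
                continue
            rec = meta.loc[mk]
            spans.append((str(rec["chrom"]), int(rec["start"]), int(rec["end"])))
        by_chrom = {}
        for chrom, s, e in spans:
            by_chrom.setdefault(chrom, []).append((s, e))
        for chrom, iv in by_chrom.items():
            for s, e in _merge_intervals(iv):
                genes = []
                if annotation is not None:
                    hit = annotation[(annotation["chrom"] == chrom)
                                     & (annotation["end"] >= s) & (annotation["start"] <= e)]
                    genes = hit["gene_id"].tolist()
                rows.append({
                    "trait": result.trait, "environment": result.environment,
                    "lg": peak.lg, "peak_cM": peak.cM, "lod": peak.lod, "pve": peak.pve,
                    "interval_lo_cM": lo, "interval_hi_cM": hi,
                    "chrom": chrom, "start": s, "end": e,
                    "genes": ";".join(genes),
                })
    return pd.DataFrame(rows, columns=["trait", "environment", "lg", "peak_cM", "lod", "pve",
                                       "interval_lo_cM", "interval_hi_cM", "chrom", "start",
                                       "end", "genes"])
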