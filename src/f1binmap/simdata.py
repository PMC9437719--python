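"""Synthetic F1 outcross populations with full ground truth.

Emulates the data a bin-mapping study starts from: a two-parent cross of
heterozygous outbreeders, ~176 progeny genotyped at bi-allelic SNPs falling
in the three pseudo-testcross segregation types (lmxll / nnxnp / hkxhk at
1:1, 1:1, 1:2:1), crossovers along a true genetic map, per-call genotyping
error, missing data and read-depth-like support, plus a fragmented and
partly misassigned reference layout for the anchoring stage.

Meioses are simulated as a two-state Markov chain over parental haplotype
origin; the transition probability between adjacent markers is the inverse
map function (Kosambi by default) of the inter-marker distance, i.e. no
crossover interference.  Parental phase is drawn at random per marker and
recorded in the truth object but withheld from downstream modules, which
must infer it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import maputil

SEG_NAMES = ("lmxll", "nnxnp", "hkxhk")

#: Segregation-type mixture observed in deep-resequencing F1 SNP sets
#: (heterozygous-in-one-parent types dominate; double-het sites are rarer).
DEFAULT_SEG_MIX = {"lmxll": 0.435, "nnxnp": 0.417, "hkxhk": 0.148}


def _as_list(value, n, name):
    if np.isscalar(value):
        return [value] * n
    value = list(value)
    if len(value) != n:
        raise ValueError(f"{name} must be scalar or length {n}")
    return value


@dataclass
class SimConfig:
    """Parameters of a simulated F1 population.

    Defaults follow a typical fruit-tree outcross design: 176 progeny, 17
    chromosomes of ~30 Mb / 80 cM, 1% genotyping error, 5% missing calls
    and negative-binomial per-call support with mean ~14 (matching ~14x
    resequencing coverage).  Unit tests typically use 2-3 chromosomes.
    """

    n_progeny: int = 176
    n_chrom: int = 17
    chrom_len_bp: int | Sequence[int] = 30_000_000
    chrom_len_cM: float | Sequence[float] = 80.0
    snps_per_chrom: int | Sequence[int] = 400
    seg_type_mix: dict = field(default_factory=lambda: dict(DEFAULT_SEG_MIX))
    error_rate: float = 0.01
    missing_rate: float = 0.05
    support_mean: float = 14.0
    support_shape: float = 5.0
    map_function: str = "kosambi"
    seed: int = 0

    def __post_init__(self):
        if self.n_progeny < 1:
            raise ValueError("n_progeny must be >= 1")
        if self.n_chrom < 1:
            raise ValueError("n_chrom must be >= 1")
        self.chrom_len_bp = [int(v) for v in _as_list(self.chrom_len_bp, self.n_chrom, "chrom_len_bp")]
        self.chrom_len_cM = [float(v) for v in _as_list(self.chrom_len_cM, self.n_chrom, "chrom_len_cM")]
        self.snps_per_chrom = [int(v) for v in _as_list(self.snps_per_chrom, self.n_chrom, "snps_per_chrom")]
        if any(v <= 0 for v in self.chrom_len_bp) or any(v <= 0 for v in self.chrom_len_cM):
            raise ValueError("chromosome lengths must be > 0")
        if any(v < 1 for v in self.snps_per_chrom):
            raise ValueError("snps_per_chrom must be >= 1")
        mix = {k: float(self.seg_type_mix.get(k, 0.0)) for k in SEG_NAMES}
        total = sum(mix.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError("seg_type_mix proportions must sum to 1")
        if any(v < 0 for v in mix.values()):
            raise ValueError("seg_type_mix proportions must be >= 0")
        self.seg_type_mix = mix
        for rate in (self.error_rate, self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.map_function not in ("kosambi", "haldane"):
            raise ValueError("map_function must be 'kosambi' or 'haldane'")

    def inverse_map(self, d_cM):
        return maputil.inverse_map(d_cM, self.map_function)

    def to_dict(self):
        return {
            "n_progeny": self.n_progeny,
            "n_chrom": self.n_chrom,
            "chrom_len_bp": list(self.chrom_len_bp),
            "chrom_len_cM": list(self.chrom_len_cM),
            "snps_per_chrom": list(self.snps_per_chrom),
            "seg_type_mix": dict(self.seg_type_mix),
            "error_rate": self.error_rate,
            "missing_rate": self.missing_rate,
            "support_mean": self.support_mean,
            "support_shape": self.support_shape,
            "map_function": self.map_function,
            "seed": self.seed,
        }


@dataclass
class QtlTruth:
    chrom_index: int
    cM: float
    marker_index: int
    effects: list
    pve: float
    classes: np.ndarray  # per-progeny class 0..3 (2*maternal + paternal hap)


@dataclass
class TraitTruth:
    """Per-progeny decomposition of a simulated trait."""

    genetic_values: np.ndarray
    qtls: list
    h2_polygenic: float
    polygenic_values: np.ndarray
    noise: np.ndarray


@dataclass
class SimTruth:
    """Ground truth of a simulated population.

    Per chromosome: marker coordinates (bp and cM), segregation types,
    parental phases, the homozygous-parent allele, the error-free genotype
    matrix, and the transmitted haplotype-origin matrices for both meioses
    (progeny x markers; 0/1 = parental haplotype).
    """

    config: SimConfig
    chrom_names: list
    positions: list  # per chrom: int64 array (bp)
    cM: list  # per chrom: float array
    seg_types: list  # per chrom: int8 array, index into SEG_NAMES
    mat_phase: list  # per chrom: int8, allele carried by maternal hap 1
    pat_phase: list
    hom_allele: list  # per chrom: int8 allele of the homozygous parent (-1 if none)
    mat_hap: list  # per chrom: (n_progeny, m) int8 haplotype origin
    pat_hap: list
    genotypes_true: list  # per chrom: (m, n_progeny) int8 error-free states

    def n_markers(self):
        return int(sum(len(p) for p in self.positions))

    def marker_frame(self):
        """All markers as a tidy frame with ids ``{chrom}:{pos}``."""
        rows = []
        for c, name in enumerate(self.chrom_names):
            for j, pos in enumerate(self.positions[c]):
                rows.append(
                    (f"{name}:{pos}", name, int(pos), float(self.cM[c][j]), SEG_NAMES[self.seg_types[c][j]])
                )
        return pd.DataFrame(rows, columns=["marker", "chrom", "pos", "cM", "seg_type"])

    def crossovers(self, parent="maternal"):
        """Per chromosome, per progeny: marker-interval indices where the
        transmitted haplotype switches."""
        haps = self.mat_hap if parent == "maternal" else self.pat_hap
        out = []
        for h in haps:
            switches = h[:, 1:] != h[:, :-1]
            out.append([np.flatnonzero(row) for row in switches])
        return out

    def to_json(self, path):
        payload = {
            "config": self.config.to_dict(),
            "chrom_names": self.chrom_names,
            "positions": [p.tolist() for p in self.positions],
            "cM": [c.tolist() for c in self.cM],
            "seg_types": [s.tolist() for s in self.seg_types],
            "mat_phase": [p.tolist() for p in self.mat_phase],
            "pat_phase": [p.tolist() for p in self.pat_phase],
            "hom_allele": [h.tolist() for h in self.hom_allele],
            "mat_hap": [h.tolist() for h in self.mat_hap],
            "pat_hap": [h.tolist() for h in self.pat_hap],
            "genotypes_true": [g.tolist() for g in self.genotypes_true],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            payload = json.load(fh)
        cfg = SimConfig(**payload["config"])
        return cls(
            config=cfg,
            chrom_names=payload["chrom_names"],
            positions=[np.asarray(p, dtype=np.int64) for p in payload["positions"]],
            cM=[np.asarray(c, dtype=float) for c in payload["cM"]],
            seg_types=[np.asarray(s, dtype=np.int8) for s in payload["seg_types"]],
            mat_phase=[np.asarray(p, dtype=np.int8) for p in payload["mat_phase"]],
            pat_phase=[np.asarray(p, dtype=np.int8) for p in payload["pat_phase"]],
            hom_allele=[np.asarray(h, dtype=np.int8) for h in payload["hom_allele"]],
            mat_hap=[np.asarray(h, dtype=np.int8) for h in payload["mat_hap"]],
            pat_hap=[np.asarray(h, dtype=np.int8) for h in payload["pat_hap"]],
            genotypes_true=[np.asarray(g, dtype=np.int8) for g in payload["genotypes_true"]],
        )


@dataclass
class PopulationCalls:
    """Observed multi-sample genotype table (VCF-shaped, in memory)."""

    chrom: np.ndarray  # per marker str
    pos: np.ndarray  # per marker int
    ref: np.ndarray
    alt: np.ndarray
    parent_calls: np.ndarray  # (m, 2) int8 genotype states
    calls: np.ndarray  # (m, n_progeny) int8: 0 hom_ref, 1 het, 2 hom_alt, -1 missing
    support: np.ndarray  # (m, n_progeny) int32
    progeny_names: list
    parent_names: tuple = ("P1_maternal", "P2_paternal")
    header_meta: dict = field(default_factory=dict)


def _simulate_meiosis(rng, n_progeny, r_adj):
    """Two-state Markov chain of haplotype origin along one chromosome."""
    m = len(r_adj) + 1
    hap = np.empty((n_progeny, m), dtype=np.int8)
    hap[:, 0] = rng.integers(0, 2, size=n_progeny)
    if m > 1:
        switch = rng.random((n_progeny, m - 1)) < r_adj[None, :]
        hap[:, 1:] = hap[:, [0]] ^ (np.cumsum(switch, axis=1, dtype=np.int64) & 1).astype(np.int8)
    return hap


def simulate_population(cfg: SimConfig, rng=None):
    """Simulate genotype calls for an F1 cross.

    Returns ``(pop, truth)`` where ``pop`` is a :class:`PopulationCalls`
    (write it out with :func:`f1binmap.fileio.write_vcf`) and ``truth`` the
    :class:`SimTruth` needed by the recovery tests.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_progeny
    chrom_names = [f"Chr{c + 1}" for c in range(cfg.n_chrom)]
    mix = np.array([cfg.seg_type_mix[k] for k in SEG_NAMES])

    positions, cms, segs, mphase, pphase, homal = [], [], [], [], [], []
    mat_haps, pat_haps, g_trues = [], [], []
    obs_chrom, obs_pos, par_calls, obs_calls, obs_support = [], [], [], [], []

    for c in range(cfg.n_chrom):
        m = cfg.snps_per_chrom[c]
        L = cfg.chrom_len_bp[c]
        pos = np.sort(rng.choice(np.arange(1, L + 1, dtype=np.int64), size=m, replace=False)) if L >= m else None
        if pos is None:
            raise ValueError("chromosome shorter than requested SNP count")
        cm = pos / L * cfg.chrom_len_cM[c]
        seg = rng.choice(len(SEG_NAMES), size=m, p=mix).astype(np.int8)
        ph_m = rng.integers(0, 2, size=m, dtype=np.int8)
        ph_p = rng.integers(0, 2, size=m, dtype=np.int8)
        hom = np.where(seg == 2, -1, rng.integers(0, 2, size=m)).astype(np.int8)

        r_adj = cfg.inverse_map(np.diff(cm))
        hap_m = _simulate_meiosis(rng, n, r_adj)
        hap_p = _simulate_meiosis(rng, n, r_adj)

        mat_het = seg != 1  # lmxll or hkxhk
        pat_het = seg != 0  # nnxnp or hkxhk
        # transmitted allele per parent: phase XOR haplotype when het, the
        # fixed homozygous allele otherwise
        a_m = np.where(mat_het[None, :], ph_m[None, :] ^ hap_m, hom[None, :])
        a_p = np.where(pat_het[None, :], ph_p[None, :] ^ hap_p, hom[None, :])
        g0 = (a_m + a_p).astype(np.int8).T  # (m, n)

        calls = g0.copy()
        if cfg.error_rate > 0:
            err = rng.random(calls.shape) < cfg.error_rate
            # miscall: replace with one of the two other states
            shift = rng.integers(1, 3, size=calls.shape)
            calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
        if cfg.missing_rate > 0:
            calls = np.where(rng.random(calls.shape) < cfg.missing_rate, -1, calls).astype(np.int8)
        p_nb = cfg.support_shape / (cfg.support_shape + cfg.support_mean)
        support = rng.negative_binomial(cfg.support_shape, p_nb, size=calls.shape).astype(np.int32)

        pc = np.empty((m, 2), dtype=np.int8)
        pc[:, 0] = np.where(mat_het, 1, 2 * hom)
        pc[:, 1] = np.where(pat_het, 1, 2 * hom)

        positions.append(pos)
        cms.append(cm)
        segs.append(seg)
        mphase.append(ph_m)
        pphase.append(ph_p)
        homal.append(hom)
        mat_haps.append(hap_m)
        pat_haps.append(hap_p)
        g_trues.append(g0)
        obs_chrom.append(np.full(m, chrom_names[c], dtype=object))
        obs_pos.append(pos)
        par_calls.append(pc)
        obs_calls.append(calls)
        obs_support.append(support)

    truth = SimTruth(
        config=cfg,
        chrom_names=chrom_names,
        positions=positions,
        cM=cms,
        seg_types=segs,
        mat_phase=mphase,
        pat_phase=pphase,
        hom_allele=homal,
        mat_hap=mat_haps,
        pat_hap=pat_haps,
        genotypes_true=g_trues,
    )
    m_total = sum(cfg.snps_per_chrom)
    pop = PopulationCalls(
        chrom=np.concatenate(obs_chrom),
        pos=np.concatenate(obs_pos),
        ref=np.full(m_total, "A", dtype=object),
        alt=np.full(m_total, "G", dtype=object),
        parent_calls=np.vstack(par_calls),
        calls=np.vstack(obs_calls),
        support=np.vstack(obs_support),
        progeny_names=[f"F{i + 1:03d}" for i in range(n)],
        header_meta={"simulator": "f1binmap", "seed": cfg.seed, "config": json.dumps(cfg.to_dict())},
    )
    return pop, truth


def _qtl_classes(truth: SimTruth, chrom_index: int, cM: float):
    """Transmitted-gamete class (2*maternal + paternal haplotype) at the
    marker nearest to the requested map position."""
    cm = truth.cM[chrom_index]
    j = int(np.argmin(np.abs(cm - cM)))
    classes = 2 * truth.mat_hap[chrom_index][:, j] + truth.pat_hap[chrom_index][:, j]
    return j, classes.astype(np.int8)


def simulate_traits(truth: SimTruth, qtl_spec, h2_polygenic=0.0, rng=None):
    """Simulate one quantitative trait with planted QTLs.

    ``qtl_spec`` is a list of ``(chrom_index, cM, effects, pve)`` where
    ``effects`` is the 4-vector of gamete-class means (classes AC, AD, BC,
    BD = maternal x paternal haplotype) and ``pve`` the variance fraction
    the QTL should explain.  A polygenic term built from all markers'
    transmitted alleles explains ``h2_polygenic``; the residual variance is
    Gaussian noise.  Components are rescaled by their realized standard
    deviation so variance fractions hold in expectation.

    Returns ``(values, trait_truth)``.
    """
    if rng is None:
        rng = np.random.default_rng(truth.config.seed + 1)
    n = truth.config.n_progeny
    qtls = []
    pve_sum = 0.0
    genetic = np.zeros(n)
    for chrom_index, cm, effects, pve in qtl_spec:
        effects = np.asarray(effects, dtype=float)
        if effects.shape != (4,):
            raise ValueError("effects must be a length-4 class-mean vector")
        if not 0.0 <= pve <= 1.0:
            raise ValueError("PVE must lie in [0, 1]")
        if not 0 <= chrom_index < truth.config.n_chrom:
            raise ValueError("QTL chromosome index out of range")
        if not 0.0 <= cm <= truth.config.chrom_len_cM[chrom_index]:
            raise ValueError("QTL position outside the true map")
        j, classes = _qtl_classes(truth, chrom_index, cm)
        g = effects[classes]
        sd = g.std()
        if sd > 0:
            g = (g - g.mean()) / sd * np.sqrt(pve)
        else:
            g = np.zeros(n)
        genetic += g
        pve_sum += pve
        qtls.append(QtlTruth(chrom_index, float(cm), j, effects.tolist(), float(pve), classes))
    if not 0.0 <= h2_polygenic <= 1.0:
        raise ValueError("h2_polygenic must lie in [0, 1]")
    if pve_sum + h2_polygenic > 1.0 + 1e-9:
        raise ValueError("total explained variance (QTL PVE + polygenic h2) exceeds 1")

    poly = np.zeros(n)
    if h2_polygenic > 0:
        cols = []
        for c in range(truth.config.n_chrom):
            seg = truth.seg_types[c]
            mat_het = seg != 1
            pat_het = seg != 0
            a_m = (truth.mat_phase[c][None, :] ^ truth.mat_hap[c])[:, mat_het]
            a_p = (truth.pat_phase[c][None, :] ^ truth.pat_hap[c])[:, pat_het]
            cols.extend([a_m, a_p])
        Z = np.hstack(cols).astype(float)
        Z -= Z.mean(axis=0)
        beta = rng.normal(size=Z.shape[1])
        poly = Z @ beta
        sd = poly.std()
        if sd > 0:
            poly = (poly - poly.mean()) / sd * np.sqrt(h2_polygenic)
    noise_var = max(0.0, 1.0 - pve_sum - h2_polygenic)
    noise = rng.normal(scale=np.sqrt(noise_var), size=n)
    values = genetic + poly + noise
    return values, TraitTruth(genetic_values=genetic + poly, qtls=qtls, h2_polygenic=float(h2_polygenic),
                              polygenic_values=poly, noise=noise)


def fragment_genome(truth: SimTruth, n_scaffolds: int, misassign_rate: float,
                    unanchored_rate: float = 0.0, min_markers_per_scaffold: int = 0, rng=None):
    """Cut the simulated chromosomes into scaffolds and build a partly
    wrong "current reference" anchoring.

    A fraction ``misassign_rate`` of scaffolds is given a wrong chromosome
    and/or a flipped orientation in the reference anchoring; a further
    ``unanchored_rate`` is dropped from the reference entirely (emulating
    unassembled scaffolds).  Scaffold-local coordinates run with a random
    true orientation.  Returns ``(layout, reference, true_agp)`` where
    ``layout`` has the true placements, ``reference`` the injected-error
    anchoring and ``true_agp`` the AGP frame of the true assembly.
    """
    from .synteny import build_agp_frame

    if not 0.0 <= misassign_rate <= 1.0:
        raise ValueError("misassign_rate must lie in [0, 1]")
    if not 0.0 <= unanchored_rate <= 1.0:
        raise ValueError("unanchored_rate must lie in [0, 1]")
    cfg = truth.config
    if n_scaffolds < cfg.n_chrom:
        raise ValueError("need at least one scaffold per chromosome")
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)

    # scaffolds per chromosome: proportional to length, each >= 1
    lengths = np.asarray(cfg.chrom_len_bp, dtype=float)
    quota = lengths / lengths.sum() * n_scaffolds
    counts = np.maximum(1, np.floor(quota).astype(int))
    while counts.sum() < n_scaffolds:
        counts[np.argmax(quota - counts)] += 1
    while counts.sum() > n_scaffolds:
        c = int(np.argmax(counts - quota))
        if counts[c] > 1:
            counts[c] -= 1
        else:  # pragma: no cover - degenerate tiny configs
            break

    rows = []
    sid = 0
    for c in range(cfg.n_chrom):
        L = cfg.chrom_len_bp[c]
        k = counts[c]
        pos = truth.positions[c]
        if k == 1:
            cuts = []
        elif min_markers_per_scaffold > 0:
            m = len(pos)
            if m < k * min_markers_per_scaffold:
                raise ValueError("not enough markers for min_markers_per_scaffold")
            extra = rng.multinomial(m - k * min_markers_per_scaffold, np.full(k, 1.0 / k))
            sizes = min_markers_per_scaffold + extra
            idx = np.cumsum(sizes)[:-1]
            cuts = [(int(pos[i - 1]) + int(pos[i])) // 2 for i in idx]
        else:
            cuts = sorted(rng.choice(np.arange(2, L, dtype=np.int64), size=k - 1, replace=False).tolist())
        bounds = [1] + [c_ + 1 for c_ in cuts] + [L + 1]
        for s in range(k):
            start, end = bounds[s], bounds[s + 1] - 1
            sid += 1
            rows.append(
                {
                    "scaffold": f"scf{sid:04d}",
                    "length": end - start + 1,
                    "true_chrom": truth.chrom_names[c],
                    "true_start": start,
                    "true_end": end,
                    "true_orient": "+" if rng.random() < 0.5 else "-",
                }
            )
    layout = pd.DataFrame(rows)

    ref = layout[["scaffold", "length"]].copy()
    ref_chrom = layout["true_chrom"].to_numpy().copy().astype(object)
    ref_orient = layout["true_orient"].to_numpy().copy().astype(object)
    unanchored = rng.random(len(layout)) < unanchored_rate
    mis = (~unanchored) & (rng.random(len(layout)) < misassign_rate)
    chrom_set = list(truth.chrom_names)
    for i in np.flatnonzero(mis):
        mode = rng.integers(0, 3)  # 0: wrong chrom, 1: flip, 2: both
        if mode in (0, 2) and len(chrom_set) > 1:
            others = [c for c in chrom_set if c != ref_chrom[i]]
            ref_chrom[i] = others[rng.integers(0, len(others))]
        if mode in (1, 2) or (mode == 0 and len(chrom_set) == 1):
            ref_orient[i] = "-" if ref_orient[i] == "+" else "+"
    ref_chrom[unanchored] = None
    ref_orient[unanchored] = None
    ref["chrom"] = ref_chrom
    ref["orient"] = ref_orient
    ref["misassigned"] = mis
    ref["unanchored"] = unanchored

    order = layout.sort_values(["true_chrom", "true_start"])
    true_agp = build_agp_frame(
        [
            (r.true_chrom, r.scaffold, int(r.length), r.true_orient)
            for r in order.itertuples()
        ]
    )
    return layout, ref, true_agp


def marker_scaffold_positions(truth: SimTruth, layout: pd.DataFrame):
    """Scaffold-local coordinates of every true marker.

    Returns a frame (marker, chrom, pos, cM, seg_type, scaffold, scaf_pos)
    where ``scaf_pos`` honours the scaffold's true orientation.
    """
    frames = []
    for chrom, sub in layout.groupby("true_chrom", sort=False):
        c = truth.chrom_names.index(chrom)
        pos = truth.positions[c]
        starts = sub["true_start"].to_numpy()
        ends = sub["true_end"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos <= ends[np.clip(idx, 0, len(ends) - 1)])
        sc = sub["scaffold"].to_numpy()[idx]
        orient = sub["true_orient"].to_numpy()[idx]
        local = np.where(
            orient == "+",
            pos - starts[idx] + 1,
            ends[idx] - pos + 1,
        )
        frames.append(
            pd.DataFrame(
                {
                    "marker": [f"{chrom}:{p}" for p in pos],
                    "chrom": chrom,
                    "pos": pos,
                    "cM": truth.cM[c],
                    "seg_type": [SEG_NAMES[s] for s in truth.seg_types[c]],
                    "scaffold": sc,
                    "scaf_pos": local,
                }
            )[ok]
        )
    return pd.concat(frames, ignore_index=True)
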