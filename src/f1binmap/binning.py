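"""Five-step bin-marker construction.

SNPs of one segregation type on one chromosome are collapsed into bin
markers delimited by recombination breakpoints:

i.   tile the chromosome into fixed physical windows (500 kb here; the
     window call per progeny is the majority CP code of member SNPs, ties
     and all-missing windows are missing),
ii.  fill missing window calls with the majority of the nearest non-missing
     flanking calls (two per side by default) when a strict majority exists,
iii. fill missing runs whose two flanking calls agree,
iv.  correct singleton miscodes (a call that differs from both immediate
     neighbours, which are non-missing and identical, is replaced),
v.   merge maximal runs of adjacent windows with element-wise identical
     genotype vectors into one bin marker.

Bins inherit the physical span of their member SNPs (clipped to the
extreme member positions) and the summed SNP count; within one
segregation set and chromosome they are non-overlapping and sorted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segtype import LMXLL, NNXNP, HKXHK

BIN_PREFIX = {LMXLL: "lm", NNXNP: "np", HKXHK: "hk"}


def phase_normalize(codes, seg_type: str, min_overlap: int = 5):
    """Align the code polarity of physically ordered SNPs of one set.

    The lm/ll (or nn/np) polarity of a raw SNP code depends on which
    parental haplotype carries the variant allele, which varies SNP to SNP.
    Majority voting inside a window is only meaningful after polarity is
    made locally consistent: each SNP is compared against its predecessor
    and flipped when they disagree in more than half of the jointly typed
    progeny.  Adjacent SNPs are tightly linked at window scale, so the
    chained comparison is reliable.

    Double-het (hkxhk) sites carry one phase bit per parent.  Flipping both
    bits is the observable hh<->kk relabelling, but a single-parent flip
    mixes hh/kk with hk and cannot be undone from codes alone, so hkxhk
    SNPs on a chromosome fall into exactly two reconcilable phase families.
    Each SNP is assigned to the family whose last member it is class-
    compatible with (joint hh/kk occupancy dominating hh/kk-vs-hk crossing)
    and oriented within it; families are binned separately.

    Returns ``(normalized codes, family index per SNP)``; the family index
    is all zeros for the 1:1 sets.
    """
    codes = np.asarray(codes, dtype=np.int8).copy()
    m = len(codes)
    family = np.zeros(m, dtype=np.int8)
    if seg_type != HKXHK:
        for i in range(1, m):
            prev, cur = codes[i - 1], codes[i]
            joint = (prev >= 0) & (cur >= 0)
            n = int(joint.sum())
            if n < min_overlap:
                continue
            agree = int((prev[joint] == cur[joint]).sum())
            if 2 * agree < n:
                codes[i] = np.where(cur >= 0, 1 - cur, cur)
        return codes, family

    members = {}  # family -> indices, in order

    def scores(prev, cur):
        p_info = (prev == 0) | (prev == 2)
        c_info = (cur == 0) | (cur == 2)
        both = p_info & c_info
        cross = int((p_info & (cur == 1)).sum() + ((prev == 1) & c_info).sum())
        agree = int((prev[both] == cur[both]).sum())
        return int(both.sum()), cross, agree

    for i in range(m):
        # pooled comparison against the most recent members of each family;
        # an undecidable SNP opens a new family rather than polluting one
        # (spurious families only fragment bins, pollution corrupts them)
        best = None
        for fam, idxs in members.items():
            both = cross = agree = 0
            for j in idxs[-3:]:
                b, c, a = scores(codes[j], codes[i])
                both += b
                cross += c
                agree += a
            if both + cross < min_overlap:
                continue
            info = both / (both + cross)
            if info > 0.5 and (best is None or info > best[0]):
                best = (info, fam, both, agree)
        if best is None:
            fam = len(members)
            members[fam] = [i]
            family[i] = fam
        else:
            _, fam, both, agree = best
            if 2 * agree < both:
                codes[i] = np.where(codes[i] >= 0, 2 - codes[i], codes[i])
            family[i] = fam
            members[fam].append(i)
    return codes, family


@dataclass
class BinMarker:
    id: str
    seg_set: str
    chrom: str
    start: int  # 1-based inclusive bp span over member SNPs
    end: int
    snp_count: int
    genotypes: np.ndarray  # CP codes over progeny
    member_windows: list = field(default_factory=list)

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("bin start must be <= end")
        if self.snp_count < 1:
            raise ValueError("bin must contain at least one SNP")


@dataclass
class WindowBins:
    """Step-i output: occupied fixed tiles with majority calls."""

    seg_set: str
    chrom: str
    window_bp: int
    window_index: np.ndarray  # tile number k, tile = [k*W+1, (k+1)*W]
    snp_count: np.ndarray
    snp_min_pos: np.ndarray
    snp_max_pos: np.ndarray
    matrix: np.ndarray  # (n_windows, n_progeny) CP codes


def window_bin(positions, codes, seg_set: str, chrom: str = "", window_bp: int = 500_000,
               seg_types=None) -> WindowBins:
    """Step i: majority-call SNPs into fixed physical windows.

    ``positions`` must be sorted; ``codes`` is the (m, n) CP-code matrix of
    a single segregation set (pass ``seg_types`` to have that verified).
    Per window and progeny the call is the majority code over non-missing
    member SNPs; ties and all-missing cells are missing; empty windows are
    omitted.
    """
    positions = np.asarray(positions)
    codes = np.asarray(codes)
    if seg_types is not None and len(set(map(str, seg_types))) > 1:
        raise ValueError("window_bin requires sites of a single segregation set")
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    win = (positions - 1) // window_bp
    uniq, inverse = np.unique(win, return_inverse=True)
    w, n = len(uniq), codes.shape[1]
    counts = np.zeros((w, n, 3), dtype=np.int32)
    for c in range(3):
        np.add.at(counts[:, :, c], inverse, (codes == c).astype(np.int32))
    top = counts.max(axis=2)
    n_top = (counts == top[:, :, None]).sum(axis=2)
    call = np.argmax(counts, axis=2).astype(np.int8)
    call[(top == 0) | (n_top > 1)] = -1  # all-missing or tie

    snp_count = np.bincount(inverse, minlength=w)
    first = np.searchsorted(win, uniq, side="left")
    last = np.searchsorted(win, uniq, side="right") - 1
    return WindowBins(
        seg_set=seg_set,
        chrom=chrom,
        window_bp=window_bp,
        window_index=uniq,
        snp_count=snp_count.astype(np.int64),
        snp_min_pos=positions[first],
        snp_max_pos=positions[last],
        matrix=call,
    )


def _fill_nearest_majority(matrix, per_side):
    """Step ii: fill missing with the strict majority of the nearest
    non-missing calls (``per_side`` above and below), simultaneously."""
    out = matrix.copy()
    w, n = matrix.shape
    for j in range(n):
        col = matrix[:, j]
        nonmiss = np.flatnonzero(col >= 0)
        if len(nonmiss) == 0:
            continue
        for i in np.flatnonzero(col < 0):
            right = np.searchsorted(nonmiss, i)
            picks = np.concatenate([nonmiss[max(0, right - per_side):right],
                                    nonmiss[right:right + per_side]])
            if len(picks) == 0:
                continue
            vals = col[picks]
            cnt = np.bincount(vals, minlength=3)
            best = int(np.argmax(cnt))
            if cnt[best] * 2 > len(vals):  # strict majority
                out[i, j] = best
    return out


def _fill_flanked_runs(matrix):
    """Step iii: fill maximal missing runs whose flanks agree."""
    out = matrix.copy()
    w, n = matrix.shape
    for j in range(n):
        col = out[:, j]
        i = 0
        while i < w:
            if col[i] >= 0:
                i += 1
                continue
            k = i
            while k < w and col[k] < 0:
                k += 1
            if i > 0 and k < w and col[i - 1] == col[k]:
                col[i:k] = col[i - 1]
            i = k
    return out


def _correct_singletons(matrix, radius=1):
    """Step iv: replace a call that differs from its surrounding calls when
    the surroundings (``radius`` windows each side) are non-missing and all
    identical."""
    out = matrix.copy()
    w, n = matrix.shape
    if w < 2 * radius + 1:
        return out
    center = matrix[radius:w - radius]
    neighbors = np.stack(
        [matrix[radius + off:w - radius + off] for off in range(-radius, radius + 1) if off != 0]
    )
    all_same = np.all(neighbors == neighbors[0], axis=0) & np.all(neighbors >= 0, axis=0)
    fix = all_same & (center >= 0) & (center != neighbors[0])
    out[radius:w - radius][fix] = np.broadcast_to(neighbors[0], center.shape)[fix]
    return out


def impute_and_correct(wb: WindowBins, per_side: int = 2, enable_nearest_fill: bool = True,
                       radius: int = 1) -> WindowBins:
    """Steps ii-iv on a window-bin matrix, applied in order, one pass each.

    ``per_side`` controls the step-ii neighbourhood (two nearest non-missing
    calls per side by default, i.e. k=4); set ``enable_nearest_fill=False``
    to skip step ii.  ``radius`` is the step-iv surrounding width.
    """
    m = wb.matrix
    if enable_nearest_fill:
        m = _fill_nearest_majority(m, per_side)
    m = _fill_flanked_runs(m)
    m = _correct_singletons(m, radius)
    return WindowBins(wb.seg_set, wb.chrom, wb.window_bp, wb.window_index,
                      wb.snp_count, wb.snp_min_pos, wb.snp_max_pos, m)


def merge_identical(wb: WindowBins, require_nonmissing: bool = False, id_start: int = 1):
    """Step v: merge adjacent windows with identical genotype vectors.

    Missing matches only missing by default (vectors must be element-wise
    equal, -1 included); with ``require_nonmissing=True`` two windows merge
    only where every progeny is non-missing and equal.  The merged bin span
    is clipped to the member SNPs' extreme positions and the SNP counts are
    summed.
    """
    m = wb.matrix
    w = m.shape[0]
    bins = []
    if w == 0:
        return bins
    if require_nonmissing:
        same = np.all((m[1:] == m[:-1]) & (m[1:] >= 0), axis=1)
    else:
        same = np.all(m[1:] == m[:-1], axis=1)
    breaks = np.concatenate([[0], np.flatnonzero(~same) + 1, [w]])
    prefix = BIN_PREFIX[wb.seg_set]
    for b, (i, k) in enumerate(zip(breaks[:-1], breaks[1:])):
        bins.append(
            BinMarker(
                id=f"{prefix}{id_start + b:04d}",
                seg_set=wb.seg_set,
                chrom=wb.chrom,
                start=int(wb.snp_min_pos[i]),
                end=int(wb.snp_max_pos[k - 1]),
                snp_count=int(wb.snp_count[i:k].sum()),
                genotypes=m[i].copy(),
                member_windows=wb.window_index[i:k].tolist(),
            )
        )
    return bins


@dataclass
class BinSet:
    """All bin markers of a population as aligned frame + code matrix."""

    df: pd.DataFrame  # id, seg_set, chrom, start, end, snp_count
    codes: np.ndarray  # (n_bins, n_progeny)
    progeny_names: list

    def __len__(self):
        return len(self.df)

    def subset(self, mask):
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return BinSet(self.df.iloc[idx].reset_index(drop=True), self.codes[idx], self.progeny_names)

    def missing_counts(self):
        return (self.codes < 0).sum(axis=1)


def make_bins(site_table, window_bp: int = 500_000, per_side: int = 2,
              enable_nearest_fill: bool = True, radius: int = 1,
              require_nonmissing: bool = False, normalize_phase: bool = True) -> BinSet:
    """Run the five-step pipeline per segregation set and chromosome.

    ``site_table`` is a classified, filtered :class:`~f1binmap.segtype.SiteTable`.
    Sets are binned independently; ids are numbered per set genome-wide.
    SNP code polarity is phase-normalised along each chromosome first (see
    :func:`phase_normalize`); disable only for pre-phased input.
    """
    counters = {LMXLL: 1, NNXNP: 1, HKXHK: 1}
    all_bins = []
    chrom_order = list(dict.fromkeys(site_table.chrom.tolist()))
    for seg in (LMXLL, NNXNP, HKXHK):
        for chrom in chrom_order:
            sel = (site_table.seg_type == seg) & (site_table.chrom == chrom)
            if not sel.any():
                continue
            idx = np.flatnonzero(sel)
            order = idx[np.argsort(site_table.pos[idx], kind="stable")]
            snp_codes = site_table.codes[order]
            if normalize_phase:
                snp_codes, families = phase_normalize(snp_codes, seg)
            else:
                families = np.zeros(len(order), dtype=np.int8)
            chrom_bins = []
            for fam in np.unique(families):
                sub = families == fam
                wb = window_bin(site_table.pos[order][sub], snp_codes[sub], seg, chrom, window_bp)
                wb = impute_and_correct(wb, per_side, enable_nearest_fill, radius)
                bins = merge_identical(wb, require_nonmissing, id_start=counters[seg])
                counters[seg] += len(bins)
                chrom_bins.extend((b, int(fam)) for b in bins)
            chrom_bins.sort(key=lambda bf: (bf[0].start, bf[0].end))
            all_bins.extend(chrom_bins)
    if not all_bins:
        raise ValueError("no bins produced; is the site table classified and non-empty?")
    df = pd.DataFrame(
        {
            "id": [b.id for b, _ in all_bins],
            "seg_set": [b.seg_set for b, _ in all_bins],
            "chrom": [b.chrom for b, _ in all_bins],
            "start": [b.start for b, _ in all_bins],
            "end": [b.end for b, _ in all_bins],
            "snp_count": [b.snp_count for b, _ in all_bins],
            "family": [f for _, f in all_bins],
        }
    )
    codes = np.vstack([b.genotypes for b, _ in all_bins])
    return BinSet(df=df, codes=codes, progeny_names=list(site_table.progeny_names))
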