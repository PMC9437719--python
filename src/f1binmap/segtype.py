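"""Segregation typing, quality masking and Mendelian filtering of SNP sites.

Bi-allelic sites in a full-sib (CP / pseudo-testcross) family fall into
three informative segregation types, named by the standard CP genotype
codes:

* ``lmxll`` - first (maternal) parent heterozygous, the other homozygous;
  progeny segregate lm:ll = 1:1,
* ``nnxnp`` - paternal parent heterozygous; progeny nn:np = 1:1,
* ``hkxhk`` - both parents heterozygous; progeny hh:hk:kk = 1:2:1.

Homozygous-by-homozygous sites are uninformative.  Calls whose read
support falls outside [4, 200] are masked to missing before typing, and
sites whose progeny counts deviate from the Mendelian ratio (Pearson
chi-square, P < 0.05) are discarded as segregation-distorted.

Genotype states are coded 0 (hom ref), 1 (het), 2 (hom alt), -1 (missing).
CP genotypes are coded per type: lmxll ll=0/lm=1; nnxnp nn=0/np=1; hkxhk
hh=0/hk=1/kk=2; -1 missing.  The numeric code of a 1:1 site is the
indicator of the informative parent's transmitted "variant" allele (up to
a per-site flip that downstream phase inference absorbs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

LMXLL = "lmxll"
NNXNP = "nnxnp"
HKXHK = "hkxhk"
UNINFORMATIVE = "uninformative"
UNCLASSIFIABLE = "unclassifiable"

#: CP genotype symbols per segregation type, indexed by numeric code.
CP_SYMBOLS = {
    LMXLL: ("ll", "lm"),
    NNXNP: ("nn", "np"),
    HKXHK: ("hh", "hk", "kk"),
}
MISSING_SYMBOL = "--"

EXPECTED_RATIOS = {
    LMXLL: np.array([0.5, 0.5]),
    NNXNP: np.array([0.5, 0.5]),
    HKXHK: np.array([0.25, 0.5, 0.25]),
}


def n_classes(seg_type: str) -> int:
    return 3 if seg_type == HKXHK else 2


def cp_symbols(seg_type: str, codes) -> list:
    """Numeric CP codes -> symbol strings for one site."""
    table = CP_SYMBOLS[seg_type]
    return [MISSING_SYMBOL if c < 0 else table[c] for c in np.asarray(codes)]


@dataclass
class SnpSite:
    """One bi-allelic variant with parental and progeny calls."""

    chrom: str
    pos: int
    alleles: tuple = ("A", "G")
    parent_calls: tuple = (-1, -1)
    progeny_calls: np.ndarray = None
    support: Optional[np.ndarray] = None
    biallelic: bool = True
    seg_type: Optional[str] = None
    recoded: Optional[np.ndarray] = None
    impossible_count: int = 0
    chi2: Optional[float] = None
    df: Optional[int] = None
    pvalue: Optional[float] = None
    flags: list = field(default_factory=list)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (1-based coordinate)")
        if self.progeny_calls is not None:
            self.progeny_calls = np.asarray(self.progeny_calls, dtype=np.int8)
        if self.support is not None:
            self.support = np.asarray(self.support)


def mask_support(calls, support, min_support: int = 4, max_support: int = 200):
    """Mask calls whose per-call read support is < min_support or
    > max_support (bounds themselves are retained)."""
    calls = np.asarray(calls)
    support = np.asarray(support)
    if np.any(support < 0):
        raise ValueError("negative read support")
    if support.shape != calls.shape:
        raise ValueError("support must be aligned with calls")
    bad = (support < min_support) | (support > max_support)
    return np.where(bad, -1, calls).astype(np.int8)


def mask_low_confidence(site: SnpSite, min_support: int = 4, max_support: int = 200) -> SnpSite:
    """Support-based quality mask for a single site (see :func:`mask_support`)."""
    if site.support is None:
        raise ValueError("site carries no support counts")
    masked = mask_support(site.progeny_calls, site.support, min_support, max_support)
    return replace(site, progeny_calls=masked)


def classify_matrix(parent_calls, calls, swap_parents: bool = False):
    """Vectorised segregation typing and CP recoding.

    Parameters
    ----------
    parent_calls : (m, 2) int array, maternal parent first.
    calls : (m, n) int array of progeny genotype states.
    swap_parents : exchange parental roles (flips lmxll <-> nnxnp).

    Returns ``(seg_types, codes, impossible_counts)``; impossible progeny
    genotypes (e.g. the opposite homozygote under het x hom) are set to
    missing and counted per site.
    """
    parent_calls = np.asarray(parent_calls)
    calls = np.asarray(calls, dtype=np.int8)
    p1 = parent_calls[:, 1 if swap_parents else 0]
    p2 = parent_calls[:, 0 if swap_parents else 1]
    m = len(p1)
    seg = np.full(m, UNINFORMATIVE, dtype=object)
    seg[(p1 == -1) | (p2 == -1)] = UNCLASSIFIABLE
    hom1 = (p1 == 0) | (p1 == 2)
    hom2 = (p2 == 0) | (p2 == 2)
    is_lm = (p1 == 1) & hom2
    is_np = (p2 == 1) & hom1
    is_hk = (p1 == 1) & (p2 == 1)
    seg[is_lm] = LMXLL
    seg[is_np] = NNXNP
    seg[is_hk] = HKXHK

    codes = np.full_like(calls, -1)
    impossible = np.zeros(m, dtype=np.int64)

    # het x hom and hom x het: het progeny -> code 1, the hom parent's
    # genotype -> code 0, the opposite homozygote is impossible
    for mask, hom_parent in ((is_lm, p2), (is_np, p1)):
        if not mask.any():
            continue
        sub = calls[mask]
        hom = hom_parent[mask, None]
        out = np.full_like(sub, -1)
        out[sub == 1] = 1
        out[sub == hom] = 0
        imp = (sub >= 0) & (sub != 1) & (sub != hom)
        impossible[mask] = imp.sum(axis=1)
        codes[mask] = out

    if is_hk.any():
        sub = calls[is_hk]
        codes[is_hk] = np.where(sub >= 0, sub, -1)
    return seg, codes, impossible


def classify_segregation(site: SnpSite, swap_parents: bool = False) -> SnpSite:
    """Classify one site into a CP segregation type and recode progeny."""
    if not site.biallelic:
        raise ValueError("site is not bi-allelic")
    seg, codes, imp = classify_matrix(
        np.asarray(site.parent_calls).reshape(1, 2), site.progeny_calls.reshape(1, -1), swap_parents
    )
    flags = list(site.flags)
    if seg[0] == UNCLASSIFIABLE:
        flags.append("missing parental call")
    return replace(site, seg_type=seg[0], recoded=codes[0], impossible_count=int(imp[0]), flags=flags)


def class_counts(seg_type: str, codes) -> np.ndarray:
    codes = np.asarray(codes)
    k = n_classes(seg_type)
    return np.bincount(codes[codes >= 0], minlength=k)[:k]


def segregation_chi2(site: SnpSite):
    """Pearson chi-square of the observed CP class counts against the
    Mendelian ratio (1:1, df=1, or 1:2:1, df=2).  Returns (chi2, df, P)."""
    if site.seg_type not in EXPECTED_RATIOS:
        raise ValueError("site is not informative; classify it first")
    counts = class_counts(site.seg_type, site.recoded)
    total = counts.sum()
    if total == 0:
        site.flags.append("no informative calls")
        return np.nan, len(counts) - 1, np.nan
    expected = EXPECTED_RATIOS[site.seg_type] * total
    chi2, p = stats.chisquare(counts, expected)
    site.chi2, site.df, site.pvalue = float(chi2), len(counts) - 1, float(p)
    return site.chi2, site.df, site.pvalue


def chi2_bulk(seg_types, codes):
    """Vectorised segregation chi-square over many sites."""
    codes = np.asarray(codes)
    m = len(seg_types)
    chi2 = np.full(m, np.nan)
    df = np.zeros(m, dtype=int)
    pval = np.full(m, np.nan)
    seg_types = np.asarray(seg_types, dtype=object)
    for seg in (LMXLL, NNXNP, HKXHK):
        mask = seg_types == seg
        if not mask.any():
            continue
        k = n_classes(seg)
        sub = codes[mask]
        counts = np.stack([(sub == c).sum(axis=1) for c in range(k)], axis=1).astype(float)
        total = counts.sum(axis=1)
        ok = total > 0
        exp = EXPECTED_RATIOS[seg][None, :] * total[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.where(ok, ((counts - exp) ** 2 / np.where(exp > 0, exp, 1)).sum(axis=1), np.nan)
        idx = np.flatnonzero(mask)
        chi2[idx] = stat
        df[idx] = k - 1
        pval[idx] = np.where(ok, stats.chi2.sf(stat, k - 1), np.nan)
    return chi2, df, pval


@dataclass
class SiteTable:
    """A set of sites held as aligned arrays (the bulk workhorse)."""

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    parent_calls: np.ndarray
    calls: np.ndarray
    support: Optional[np.ndarray]
    progeny_names: list
    biallelic: np.ndarray = None
    seg_type: np.ndarray = None
    codes: np.ndarray = None
    impossible: np.ndarray = None
    chi2: np.ndarray = None
    df: np.ndarray = None
    pvalue: np.ndarray = None

    def __post_init__(self):
        if self.biallelic is None:
            self.biallelic = np.ones(len(self.pos), dtype=bool)

    def __len__(self):
        return len(self.pos)

    @classmethod
    def from_population(cls, pop):
        return cls(
            chrom=pop.chrom,
            pos=pop.pos,
            ref=pop.ref,
            alt=pop.alt,
            parent_calls=pop.parent_calls,
            calls=pop.calls.copy(),
            support=pop.support,
            progeny_names=list(pop.progeny_names),
        )

    def mask_low_confidence(self, min_support: int = 4, max_support: int = 200):
        if self.support is None:
            raise ValueError("table carries no support counts")
        self.calls = mask_support(self.calls, self.support, min_support, max_support)
        return self

    def classify(self, swap_parents: bool = False):
        self.seg_type, self.codes, self.impossible = classify_matrix(
            self.parent_calls, self.calls, swap_parents
        )
        return self

    def segregation_test(self):
        if self.codes is None:
            raise ValueError("classify before testing segregation")
        self.chi2, self.df, self.pvalue = chi2_bulk(self.seg_type, self.codes)
        return self

    def site(self, i: int) -> SnpSite:
        return SnpSite(
            chrom=str(self.chrom[i]),
            pos=int(self.pos[i]),
            alleles=(str(self.ref[i]), str(self.alt[i])),
            parent_calls=tuple(int(v) for v in self.parent_calls[i]),
            progeny_calls=self.calls[i],
            support=None if self.support is None else self.support[i],
            biallelic=bool(self.biallelic[i]),
            seg_type=None if self.seg_type is None else self.seg_type[i],
            recoded=None if self.codes is None else self.codes[i],
        )

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": [f"{c}:{p}" for c, p in zip(self.chrom, self.pos)],
                "chrom": self.chrom,
                "pos": self.pos,
                "seg_type": self.seg_type,
                "chi2": self.chi2,
                "df": self.df,
                "pvalue": self.pvalue,
                "impossible": self.impossible,
            }
        )


def filter_sites(table: SiteTable, p_min: float = 0.05, require_biallelic: bool = True,
                 max_impossible_rate: float = 0.05):
    """Retain bi-allelic, informative, Mendelian-consistent sites.

    A site is kept iff it is bi-allelic, classified lmxll/nnxnp/hkxhk, its
    impossible-genotype rate is <= ``max_impossible_rate``, and its
    segregation P-value is >= ``p_min`` (the strict ``P < p_min`` rule
    rejects).  Returns ``(retained SiteTable, rejection-log frame)``.
    """
    if table.pvalue is None:
        table.segregation_test()
    n = table.calls.shape[1]
    reasons = np.full(len(table), "", dtype=object)
    informative = np.isin(table.seg_type, (LMXLL, NNXNP, HKXHK))
    if require_biallelic:
        reasons[~table.biallelic] = "not biallelic"
    sel = reasons == ""
    reasons[sel & ~informative] = "uninformative parental genotypes"
    sel = reasons == ""
    too_many_imp = table.impossible > max_impossible_rate * n
    reasons[sel & too_many_imp] = "impossible-genotype rate above threshold"
    sel = reasons == ""
    no_calls = informative & np.isnan(table.pvalue)
    reasons[sel & no_calls] = "no informative calls"
    sel = reasons == ""
    distorted = informative & (table.pvalue < p_min)
    reasons[sel & distorted] = "distorted segregation"
    keep = reasons == ""

    log = pd.DataFrame(
        {
            "chrom": table.chrom[~keep],
            "pos": table.pos[~keep],
            "reason": reasons[~keep],
        }
    )
    kept = SiteTable(
        chrom=table.chrom[keep],
        pos=table.pos[keep],
        ref=table.ref[keep],
        alt=table.alt[keep],
        parent_calls=table.parent_calls[keep],
        calls=table.calls[keep],
        support=None if table.support is None else table.support[keep],
        progeny_names=table.progeny_names,
        biallelic=table.biallelic[keep],
        seg_type=table.seg_type[keep],
        codes=table.codes[keep],
        impossible=table.impossible[keep],
        chi2=table.chi2[keep],
        df=table.df[keep],
        pvalue=table.pvalue[keep],
    )
    return kept, log
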