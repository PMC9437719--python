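"""SNP-bin-pair collinearity, marker-class accounting and genetic-map-guided
scaffold anchoring.

Two genetic maps built on the same fragmented reference can be compared
through SNP-bin pairs (SBPs): a SNP marker of one map paired with a bin
marker of the other when the SNP's physical position falls inside the bin
span (``within_bin``) or at least on the same scaffold (``same_scaffold``).
The fraction of SBPs whose members map to corresponding linkage groups
measures inter-map collinearity.

Against a reference anchoring, mapped markers split into three classes:
co-anchored (scaffold anchored to the corresponding chromosome), misaligned
(anchored to a different chromosome) and new-anchored / unassembled
(scaffold not anchored at all).  Collinearity per group is
100 * co / (co + mis).

Scaffolds are re-anchored from the maps alone: assigned group by
marker-count-weighted majority, order by weighted mean cM, orientation by
the sign of the rank correlation between cM and scaffold bp; scaffolds
whose marker runs support two groups are split at the bin edge between the
runs.  The result is written as AGP v2.1 with fixed 100-bp map-evidence
gaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

AGP_COLUMNS = [
    "object", "object_beg", "object_end", "part_number", "component_type",
    "id_or_length", "beg_or_type", "end_or_linkage", "orient_or_evidence",
]


@dataclass
class Sbp:
    """A SNP marker (map A) paired with a bin marker (map B)."""

    snp_marker: str
    bin_id: str
    scaffold: str
    relation: str  # within_bin | same_scaffold
    lg_snp: str
    lg_bin: str
    concordant: bool


def find_sbps(snp_map: pd.DataFrame, bin_map: pd.DataFrame, lg_pairing=None):
    """Pair every SNP marker with one bin marker sharing its scaffold.

    ``snp_map`` needs columns (marker, lg, scaffold, scaf_pos); ``bin_map``
    needs (id, lg, scaffold, start, end) with scaffold-local spans.  A SNP
    inside a bin span pairs as ``within_bin`` (nearest bin midpoint on
    ties), otherwise the nearest bin on the same scaffold pairs as
    ``same_scaffold``; SNPs on scaffolds without bins stay unpaired.
    Returns ``(sbp_frame, n_unpaired)``.
    """
    pairing = lg_pairing or {}
    bins_by_scaffold = {k: v for k, v in bin_map.groupby("scaffold")}
    rows = []
    unpaired = 0
    for rec in snp_map.itertuples():
        sub = bins_by_scaffold.get(rec.scaffold)
        if sub is None or len(sub) == 0:
            unpaired += 1
            continue
        pos = rec.scaf_pos
        inside = sub[(sub["start"] <= pos) & (pos <= sub["end"])]
        if len(inside):
            mid = (inside["start"] + inside["end"]) / 2.0
            best = inside.iloc[int(np.argmin(np.abs(mid - pos)))]
            relation = "within_bin"
        else:
            dist = np.minimum(np.abs(sub["start"] - pos), np.abs(sub["end"] - pos))
            best = sub.iloc[int(np.argmin(dist.to_numpy()))]
            relation = "same_scaffold"
        lg_bin = best["lg"]
        expected = pairing.get(rec.lg, rec.lg)
        rows.append(
            Sbp(
                snp_marker=rec.marker,
                bin_id=best["id"],
                scaffold=rec.scaffold,
                relation=relation,
                lg_snp=rec.lg,
                lg_bin=lg_bin,
                concordant=bool(lg_bin == expected),
            )
        )
    frame = pd.DataFrame([vars(s) for s in rows])
    return frame, unpaired


def sbp_concordance(sbps: pd.DataFrame) -> float:
    """Percentage of SBPs whose SNP and bin map to corresponding groups."""
    if len(sbps) == 0:
        return np.nan
    return 100.0 * float(sbps["concordant"].sum()) / len(sbps)


def collinearity_percent(co_anchored: int, misaligned: int) -> float:
    """Collinearity = 100 * co / (co + mis)."""
    total = co_anchored + misaligned
    return 100.0 * co_anchored / total if total else np.nan


def classify_vs_reference(map_frame: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Classify mapped markers against a reference anchoring.

    ``map_frame`` needs columns (marker, lg, scaffold); ``reference`` maps
    scaffold -> chrom (NaN/None = unanchored).  The LG <-> chromosome
    correspondence is the majority reference chromosome of each group's
    anchored markers, computed before classification.  Returns the
    per-group collinearity table with an appended Total row.
    """
    ref = reference.set_index("scaffold")["chrom"]
    df = map_frame.copy()
    df["ref_chrom"] = df["scaffold"].map(ref)
    corresponding = {}
    for lg, sub in df.groupby("lg"):
        anchored = sub["ref_chrom"].dropna()
        corresponding[lg] = anchored.mode().iloc[0] if len(anchored) else None
    rows = []
    for lg, sub in df.groupby("lg"):
        anchored = sub["ref_chrom"].notna()
        co = int((sub["ref_chrom"] == corresponding[lg]).sum()) if corresponding[lg] else 0
        mis = int(anchored.sum()) - co
        new = int((~anchored).sum())
        total = co + mis + new
        rows.append(
            {
                "lg": lg,
                "chrom": corresponding[lg],
                "n_markers": total,
                "co_anchored": co,
                "misaligned": mis,
                "new_anchored": new,
                "pct_new_anchored": 100.0 * new / total if total else np.nan,
                "pct_collinearity": collinearity_percent(co, mis),
            }
        )
    table = pd.DataFrame(rows).sort_values("lg").reset_index(drop=True)
    tot_co = int(table["co_anchored"].sum())
    tot_mis = int(table["misaligned"].sum())
    tot_new = int(table["new_anchored"].sum())
    tot_n = int(table["n_markers"].sum())
    total_row = {
        "lg": "Total",
        "chrom": None,
        "n_markers": tot_n,
        "co_anchored": tot_co,
        "misaligned": tot_mis,
        "new_anchored": tot_new,
        "pct_new_anchored": 100.0 * tot_new / tot_n if tot_n else np.nan,
        "pct_collinearity": collinearity_percent(tot_co, tot_mis),
    }
    return pd.concat([table, pd.DataFrame([total_row])], ignore_index=True)


# ---------------------------------------------------------------------------
# anchoring

def _runs(labels):
    runs = []
    for i, lab in enumerate(labels):
        if runs and runs[-1][0] == lab:
            runs[-1][2] = i
        else:
            runs.append([lab, i, i])
    return [(lab, s, e) for lab, s, e in runs]


def _orient(cm, bp):
    vals = np.unique(bp)
    if len(vals) < 2 or len(np.unique(cm)) < 2:
        return "?", np.nan
    rho, _ = stats.spearmanr(cm, bp)
    if not np.isfinite(rho) or rho == 0:
        return "?", 0.0
    return ("+" if rho > 0 else "-"), float(rho)


def anchor_scaffolds(map_markers, layout: pd.DataFrame, map_weights=None,
                     min_run: int = 2, gap_length: int = 100):
    """Re-anchor scaffolds from one or more genetic maps.

    ``map_markers`` is a list of frames, one per map, with columns
    (marker, lg, cM, scaffold, scaf_pos); ``layout`` has (scaffold,
    length).  Per scaffold the assigned group is the weight-summed majority
    LG; when two marker runs of >= ``min_run`` markers each support
    different groups, the scaffold is split midway between the runs.
    Order within a group is the weighted mean cM and orientation the sign
    of the cM-vs-bp rank correlation ('?' with fewer than two distinct
    positions, placed as '+' and flagged).  Returns ``(anchors, agp)``.
    """
    if map_weights is None:
        map_weights = [1.0] * len(map_markers)
    frames = []
    for w, mm in zip(map_weights, map_markers):
        sub = mm[["marker", "lg", "cM", "scaffold", "scaf_pos"]].copy()
        sub["weight"] = float(w)
        frames.append(sub)
    markers = pd.concat(frames, ignore_index=True)

    pieces = []  # (piece-id, parent, beg, end, marker sub-frame)
    lengths = layout.set_index("scaffold")["length"]
    for scaffold, length in lengths.items():
        sub = markers[markers["scaffold"] == scaffold].sort_values("scaf_pos")
        if len(sub) == 0:
            pieces.append((scaffold, scaffold, 1, int(length), sub))
            continue
        runs = [r for r in _runs(sub["lg"].tolist())]
        strong = [(lab, s, e) for lab, s, e in runs if e - s + 1 >= min_run]
        distinct = list(dict.fromkeys(lab for lab, _, _ in strong))
        if len(distinct) < 2:
            pieces.append((scaffold, scaffold, 1, int(length), sub))
            continue
        # split midway between consecutive strong runs of different groups
        cuts = []
        for (la, sa, ea), (lb, sb, eb) in zip(strong[:-1], strong[1:]):
            if la == lb:
                continue
            left = sub.iloc[ea]["scaf_pos"]
            right = sub.iloc[sb]["scaf_pos"]
            cuts.append(int((left + right) // 2))
        bounds = [1] + [c + 1 for c in sorted(set(cuts))] + [int(length) + 1]
        for k, (b, e) in enumerate(zip(bounds[:-1], bounds[1:])):
            part = sub[(sub["scaf_pos"] >= b) & (sub["scaf_pos"] <= e - 1)]
            name = f"{scaffold}{chr(ord('a') + k)}" if len(bounds) > 2 else scaffold
            pieces.append((name, scaffold, b, e - 1, part))

    rows = []
    for name, parent, beg, end, sub in pieces:
        if len(sub) == 0:
            rows.append({"scaffold": name, "parent": parent, "beg": beg, "end": end,
                         "length": end - beg + 1, "lg": None, "order_cM": np.nan,
                         "orientation": None, "n_markers": 0, "order_corr": np.nan,
                         "flag": "no markers"})
            continue
        votes = sub.groupby("lg")["weight"].sum().sort_values(ascending=False)
        lg = votes.index[0]
        in_lg = sub[sub["lg"] == lg]
        order_cm = float(np.average(in_lg["cM"], weights=in_lg["weight"]))
        orient, rho = _orient(in_lg["cM"].to_numpy(), in_lg["scaf_pos"].to_numpy())
        rows.append({"scaffold": name, "parent": parent, "beg": beg, "end": end,
                     "length": end - beg + 1, "lg": lg, "order_cM": order_cm,
                     "orientation": orient, "n_markers": int(len(in_lg)),
                     "order_corr": rho,
                     "flag": "ambiguous orientation" if orient == "?" else ""})
    anchors = pd.DataFrame(rows)

    placed = anchors[anchors["lg"].notna()].sort_values(["lg", "order_cM"])
    components = [
        (str(r.lg), str(r.scaffold), int(r.length), r.orientation if r.orientation in "+-" else "+")
        for r in placed.itertuples()
    ]
    agp = build_agp_frame(components, gap_length=gap_length)
    return anchors, agp


def assembly_stats(anchors: pd.DataFrame, genome_size: int):
    """Total placed scaffold length and its percentage of the genome."""
    placed = anchors[anchors["lg"].notna()] if "lg" in anchors else anchors
    anchored = int(placed["length"].sum())
    return anchored, 100.0 * anchored / genome_size if genome_size else np.nan


def anchoring_accuracy(anchors: pd.DataFrame, layout: pd.DataFrame,
                       allow_group_reversal: bool = True) -> float:
    """Fraction of scaffold bases placed on the true chromosome with the
    true orientation (optionally up to a whole-group reversal, since a
    linkage group's cM axis has an arbitrary direction)."""
    truth = layout.set_index("scaffold")[["true_chrom", "true_orient", "length"]]
    total = float(layout["length"].sum())
    per_chrom_direct, per_chrom_flip = {}, {}
    for r in anchors.itertuples():
        parent = getattr(r, "parent", r.scaffold)
        if parent not in truth.index:
            continue
        t = truth.loc[parent]
        digits_lg = "".join(ch for ch in str(r.lg) if ch.isdigit()) if r.lg else None
        digits_chr = "".join(ch for ch in str(t.true_chrom) if ch.isdigit())
        if not digits_lg or digits_lg != digits_chr:
            continue
        length = float(r.length)
        same = r.orientation == t.true_orient
        key = str(t.true_chrom)
        per_chrom_direct[key] = per_chrom_direct.get(key, 0.0) + (length if same else 0.0)
        per_chrom_flip[key] = per_chrom_flip.get(key, 0.0) + (0.0 if same else length)
    if allow_group_reversal:
        correct = sum(max(per_chrom_direct.get(k, 0), per_chrom_flip.get(k, 0))
                      for k in set(per_chrom_direct) | set(per_chrom_flip))
    else:
        correct = sum(per_chrom_direct.values())
    return correct / total if total else np.nan


# ---------------------------------------------------------------------------
# AGP v2.1 reading/writing

def build_agp_frame(components, gap_length: int = 100) -> pd.DataFrame:
    """AGP v2.1 frame from ``(object, component_id, length, orientation)``
    tuples in placement order, with fixed map-evidence gaps between
    consecutive components of an object."""
    rows = []
    pos = {}
    part = {}
    prev_obj = None
    for obj, comp, length, orient in components:
        if obj not in pos:
            pos[obj] = 1
            part[obj] = 1
        elif obj == prev_obj:
            rows.append([obj, pos[obj], pos[obj] + gap_length - 1, part[obj],
                         "N", gap_length, "scaffold", "yes", "map"])
            pos[obj] += gap_length
            part[obj] += 1
        rows.append([obj, pos[obj], pos[obj] + length - 1, part[obj],
                     "W", comp, 1, length, orient])
        pos[obj] += length
        part[obj] += 1
        prev_obj = obj
    return pd.DataFrame(rows, columns=AGP_COLUMNS)


def write_agp(frame: pd.DataFrame, path, comment: str = ""):
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        if comment:
            fh.write(f"# {comment}\n")
        frame.to_csv(fh, sep="\t", header=False, index=False)


def read_agp(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="#", header=None, names=AGP_COLUMNS)
    for col in ("object_beg", "object_end", "part_number"):
        frame[col] = frame[col].astype(int)
    return frame


def validate_agp(frame: pd.DataFrame):
    """Check AGP structural invariants: 1-based contiguous object spans,
    alternating component/gap rows, positive component spans."""
    for obj, sub in frame.groupby("object", sort=False):
        sub = sub.sort_values("part_number")
        expect = 1
        prev_type = None
        for r in sub.itertuples():
            if r.object_beg != expect:
                raise ValueError(f"{obj}: part {r.part_number} does not start at {expect}")
            if r.object_end < r.object_beg:
                raise ValueError(f"{obj}: inverted span at part {r.part_number}")
            if r.component_type == "W":
                beg, end = int(r.beg_or_type), int(r.end_or_linkage)
                if end - beg != r.object_end - r.object_beg:
                    raise ValueError(f"{obj}: component span mismatch at part {r.part_number}")
            elif r.component_type == "N":
                if prev_type != "W":
                    raise ValueError(f"{obj}: gap not preceded by a component")
            else:
                raise ValueError(f"unsupported component type {r.component_type}")
            if prev_type == "N" and r.component_type == "N":
                raise ValueError(f"{obj}: adjacent gap rows")
            expect = r.object_end + 1
            prev_type = r.component_type
        if prev_type == "N":
            raise ValueError(f"{obj}: trailing gap row")
    return True


def agp_components(frame: pd.DataFrame):
    """Per object: ordered list of (component_id, orientation)."""
    out = {}
    for obj, sub in frame.groupby("object", sort=False):
        sub = sub[sub["component_type"] == "W"].sort_values("part_number")
        out[obj] = [(r.id_or_length, r.orient_or_evidence) for r in sub.itertuples()]
    return out


def agp_matches(agp_a: pd.DataFrame, agp_b: pd.DataFrame, allow_reversal: bool = True,
                match_object_digits: bool = True) -> bool:
    """Do two AGPs describe the same assembly, object by object, optionally
    up to whole-object reversal (order reversed, orientations flipped)?"""
    comp_a = agp_components(agp_a)
    comp_b = agp_components(agp_b)

    def norm(name):
        digits = "".join(ch for ch in str(name) if ch.isdigit())
        return digits if (match_object_digits and digits) else str(name)

    a = {norm(k): v for k, v in comp_a.items()}
    b = {norm(k): v for k, v in comp_b.items()}
    if set(a) != set(b):
        return False
    flip = {"+": "-", "-": "+", "?": "?"}
    for key in a:
        fwd = a[key] == b[key]
        rev = a[key] == [(c, flip[o]) for c, o in reversed(b[key])]
        if not (fwd or (allow_reversal and rev)):
            return False
    return True
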