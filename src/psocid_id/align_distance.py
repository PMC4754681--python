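"""Pairwise alignment, genetic distances and barcode-gap summaries.

Distances are computed on pairwise global alignments (affine gaps) under
pairwise deletion: columns with a gap or ambiguity code on either side are
excluded.  Two models are offered: the uncorrected proportion of differing
sites (p-distance) and the Kimura 2-parameter correction,

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q)),

where P and Q are the transition and transversion proportions.  The
barcode-gap summary contrasts, per species, the extremes of the
within-species and between-species distance distributions; a species shows a
barcoding gap when its smallest interspecific distance exceeds its largest
intraspecific distance.  The headline significance test is a Welch
two-sample t-test on the per-species intra-max versus inter-min values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._align_core import encode, nw_affine, pair_counts
from .seq_io import BarcodeLibrary

#: Default alignment scores (match, mismatch, gap open, gap extend).
DEFAULT_SCORES = {"match": 1.0, "mismatch": -1.0, "gap_open": -2.0, "gap_extend": -0.5}


class K2PSaturationWarning(UserWarning):
    """Distance too large for the K2P log correction; reported as NaN."""


@dataclass
class PairwiseAlignment:
    """Global alignment of two sequences as equal-length gapped strings."""

    seq_a_aligned: str
    seq_b_aligned: str
    score: float

    def __post_init__(self) -> None:
        if len(self.seq_a_aligned) != len(self.seq_b_aligned):
            raise ValueError("aligned strings differ in length")

    def __len__(self) -> int:
        return len(self.seq_a_aligned)


def global_align(a: str, b: str, match: float = 1.0, mismatch: float = -1.0,
                 gap_open: float = -2.0, gap_extend: float = -0.5) -> PairwiseAlignment:
    """Needleman-Wunsch with affine gaps; ties broken diagonal > up > left."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    ea, eb = encode(a), encode(b)
    score, pa, pb, k = nw_affine(ea, eb, match, mismatch, gap_open, gap_extend)
    row_a = "".join(a[i] if i >= 0 else "-" for i in pa[:k])
    row_b = "".join(b[j] if j >= 0 else "-" for j in pb[:k])
    return PairwiseAlignment(row_a, row_b, float(score))


def _alignment_counts(aln: PairwiseAlignment) -> tuple[int, int, int]:
    ea = encode(aln.seq_a_aligned.replace("-", ""))
    eb = encode(aln.seq_b_aligned.replace("-", ""))
    pa = np.empty(len(aln), np.int32)
    pb = np.empty(len(aln), np.int32)
    ia = ib = 0
    for c, (x, y) in enumerate(zip(aln.seq_a_aligned, aln.seq_b_aligned)):
        if x == "-":
            pa[c] = -1
        else:
            pa[c] = ia
            ia += 1
        if y == "-":
            pb[c] = -1
        else:
            pb[c] = ib
            ib += 1
    comp, diff, ts = pair_counts(ea, eb, pa, pb, len(aln))
    return comp, diff, ts


def p_distance(aln: PairwiseAlignment) -> float:
    """Proportion of differing sites under pairwise deletion; NaN if no
    comparable columns remain."""
    comp, diff, _ = _alignment_counts(aln)
    if comp == 0:
        return math.nan
    return diff / comp


def k2p_from_counts(comp: int, diff: int, ts: int) -> float:
    if comp == 0:
        return math.nan
    P = ts / comp
    Q = (diff - ts) / comp
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        warnings.warn(
            f"K2P distance saturated (P={P:.4f}, Q={Q:.4f}); returning NaN",
            K2PSaturationWarning, stacklevel=2,
        )
        return math.nan
    return max(0.0, -0.5 * math.log(w1 * math.sqrt(w2)))


def k2p_distance(aln: PairwiseAlignment) -> float:
    """Kimura 2-parameter distance; NaN (with a warning) when saturated."""
    comp, diff, ts = _alignment_counts(aln)
    return k2p_from_counts(comp, diff, ts)


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray
    model: str

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match id count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")


def distance_matrix(lib: BarcodeLibrary, model: str = "k2p",
                    **scores: float) -> DistanceMatrix:
    """All-pairs genetic distances from pairwise global alignments."""
    if model not in ("p", "k2p"):
        raise ValueError(f"unknown distance model {model!r}")
    if len(lib) < 2:
        raise ValueError("need at least 2 records for a distance matrix")
    kw = {**DEFAULT_SCORES, **scores}
    args = (kw["match"], kw["mismatch"], kw["gap_open"], kw["gap_extend"])
    encoded = [encode(r.seq) for r in lib]
    n = len(encoded)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        _, pa, pb, k = nw_affine(encoded[i], encoded[j], *args)
        comp, diff, ts = pair_counts(encoded[i], encoded[j], pa, pb, k)
        if model == "p":
            dij = diff / comp if comp else math.nan
        else:
            dij = k2p_from_counts(comp, diff, ts)
        d[i, j] = d[j, i] = dij
    return DistanceMatrix([r.id for r in lib], d, model)


def gap_summary(dm: DistanceMatrix, lib: BarcodeLibrary) -> pd.DataFrame:
    """Per-species intra/inter distance extremes and the barcode-gap flag.

    Species with a single record get NaN intraspecific fields (undefined,
    not an error); the gap flag is then NaN as well.
    """
    idx = {rid: i for i, rid in enumerate(dm.ids)}
    species_ids = lib.species_index
    if len(species_ids) < 1:
        raise ValueError("library has no species")
    rows = []
    for sp, ids in species_ids.items():
        members = [idx[r] for r in ids]
        others = [i for rid, i in idx.items() if rid not in set(ids)]
        intra = [dm.d[i, j] for i, j in combinations(members, 2)]
        inter = [dm.d[i, j] for i in members for j in others]
        intra = [x for x in intra if not math.isnan(x)]
        inter = [x for x in inter if not math.isnan(x)]
        row = {"species": sp, "n_records": len(members)}
        if intra:
            row.update(intra_min=min(intra), intra_mean=float(np.mean(intra)),
                       intra_max=max(intra))
        else:
            row.update(intra_min=math.nan, intra_mean=math.nan, intra_max=math.nan)
        if inter:
            row.update(inter_min=min(inter), inter_mean=float(np.mean(inter)),
                       inter_max=max(inter))
        else:
            row.update(inter_min=math.nan, inter_mean=math.nan, inter_max=math.nan)
        if intra and inter:
            row["gap"] = row["inter_min"] > row["intra_max"]
        else:
            row["gap"] = math.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("species")


def write_gap_summary(summary: pd.DataFrame, path: str | Path) -> None:
    summary.to_csv(path, sep="\t")


@dataclass
class WelchTestResult:
    t: float
    df: float
    p: float


def welch_t_test(sample_a, sample_b) -> WelchTestResult:
    """Welch two-sample t-test (unequal variances), two-sided."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        raise ValueError("degenerate samples: both variances are zero")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchTestResult(t=float(res.statistic), df=float(res.df),
                           p=float(res.pvalue))
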